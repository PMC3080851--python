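"""Constitutive law, energies, equilibration and the annealing cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parenchyma.lattice import apply_prestrain, build_cubic_network
from parenchyma.mechanics import (
    BoundaryCondition,
    ConstitutiveParams,
    EquilibriumCriteria,
    anneal,
    equilibrate,
    resultant_forces,
    spring_energy,
    spring_force,
    spring_tensions,
    total_energy,
)


class TestSpringForce:
    def test_zero_and_compressive_strain(self, params):
        assert spring_force(0.0, params) == 0.0
        assert spring_force(-0.3, params) == 0.0

    def test_linear_proportionality(self, params):
        assert spring_force(0.2, params) == pytest.approx(0.2)
        assert spring_force(0.4, params) == pytest.approx(0.4)

    @given(e1=st.floats(1e-6, 2.0), de=st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_power_law_strictly_increasing(self, e1, de):
        p = ConstitutiveParams(law="power")
        assert spring_force(e1 + de, p) > spring_force(e1, p)

    def test_power_law_tangent_doubles_at_reference_strain(self):
        p = ConstitutiveParams(law="power")
        h = 1e-7
        slope = (spring_force(0.3 + h, p) - spring_force(0.3 - h, p)) / (2 * h)
        assert slope == pytest.approx(2 * p.A, rel=1e-5)


class TestSpringEnergy:
    def test_zero_at_rest_length(self, params):
        assert spring_energy(0.7, 0.7, params) == 0.0
        assert spring_energy(0.5, 0.7, params) == 0.0   # slack

    @pytest.mark.parametrize("law", ["linear", "power"])
    @pytest.mark.parametrize("form", ["extension", "strain"])
    def test_energy_derivative_equals_tension(self, law, form):
        """dE/dL must equal the spring tension (scale * material law)."""
        p = ConstitutiveParams(law=law, energy_form=form)
        L0, L = 0.7, 0.85
        h = 1e-6
        dEdL = (spring_energy(L + h, L0, p) - spring_energy(L - h, L0, p)) \
            / (2 * h)
        scale = L0 if form == "extension" else 1.0
        tension = scale * spring_force((L - L0) / L0, p)
        assert dEdL == pytest.approx(tension, rel=1e-6)

    def test_extension_form_closed_form(self):
        p = ConstitutiveParams()
        assert spring_energy(1.3, 1.0, p) == pytest.approx(0.5 * 0.3 ** 2)

    def test_invalid_lengths(self, params):
        with pytest.raises(ValueError):
            spring_energy(-1.0, 1.0, params)
        with pytest.raises(ValueError):
            spring_energy(1.0, 0.0, params)


class TestTotalEnergy:
    def test_unstrained_network_has_zero_energy(self, cubic2, params):
        assert total_energy(cubic2, BoundaryCondition.fixed(), params) == 0.0

    def test_uniform_prestrain_closed_form(self, params):
        """Affine expansion strains every spring equally, so the energy is the
        sum of per-spring closed forms."""
        net = build_cubic_network(3)
        apply_prestrain(net, 1.2)
        expected = float(np.sum(0.5 * net.spring_k *
                                (0.2 * net.spring_L0) ** 2))
        E = total_energy(net, BoundaryCondition.fixed(), params)
        assert E == pytest.approx(expected, rel=1e-12)

    def test_breaking_springs_never_raises_energy(self, cubic2_eq, params):
        E0 = total_energy(cubic2_eq, BoundaryCondition.fixed(), params)
        cubic2_eq.break_springs([0, 5, 10])
        E1 = total_energy(cubic2_eq, BoundaryCondition.fixed(), params)
        assert E1 <= E0

    def test_translation_invariance(self, cubic2_eq, params):
        E0 = total_energy(cubic2_eq, BoundaryCondition.fixed(), params)
        cubic2_eq.positions += np.array([17.0, -3.0, 5.0])
        E1 = total_energy(cubic2_eq, BoundaryCondition.fixed(), params)
        assert E1 == pytest.approx(E0, rel=1e-12)


class TestEquilibrate:
    def test_intact_lattice_interior_nodes_do_not_move(self, params):
        """Affine scaling of the intact lattice is already the equilibrium."""
        net = build_cubic_network(3)
        apply_prestrain(net, 1.2)
        pos0 = net.positions.copy()
        rep = equilibrate(net)
        assert rep.converged
        assert np.abs(net.positions - pos0).max() < 1e-9

    def test_force_criteria_hold_at_equilibrium(self, damaged2, params):
        crit = EquilibriumCriteria()
        mx, mn = crit.resolved(damaged2, params)
        forces = resultant_forces(damaged2, BoundaryCondition.fixed(), params)
        free = ~damaged2.node_is_boundary
        mag = np.linalg.norm(forces[free], axis=1)
        assert mag.max() < mx

    def test_no_spring_reports_negative_tension(self, damaged2, params):
        assert (spring_tensions(damaged2, params) >= 0).all()

    def test_gd_energy_sequence_non_increasing(self, params):
        """Each Armijo gradient-descent step must not raise the energy."""
        from parenchyma.destruction import remove_faces
        net = build_cubic_network(2)
        apply_prestrain(net, 1.2)
        internal = [f.id for f in net.faces if not f.is_boundary]
        remove_faces(net, internal[:2])
        crit = EquilibriumCriteria(max_iterations=1)
        energies = [total_energy(net, BoundaryCondition.fixed(), params)]
        for _ in range(40):
            equilibrate(net, criteria=crit, method="gd")
            energies.append(total_energy(net, BoundaryCondition.fixed(),
                                         params))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_gd_and_lbfgs_reach_same_minimum(self, params):
        from parenchyma.destruction import remove_faces

        def damaged():
            net = build_cubic_network(2)
            apply_prestrain(net, 1.2)
            internal = [f.id for f in net.faces if not f.is_boundary]
            remove_faces(net, internal[:3])
            return net

        a, b = damaged(), damaged()
        equilibrate(a, method="lbfgs")
        equilibrate(b, method="gd")
        Ea = total_energy(a, BoundaryCondition.fixed(), params)
        Eb = total_energy(b, BoundaryCondition.fixed(), params)
        assert Eb == pytest.approx(Ea, rel=1e-6)

    def test_convexity_return_to_same_energy(self, damaged2, params):
        """Random perturbations relax back to the same (global) minimum."""
        E0 = total_energy(damaged2, BoundaryCondition.fixed(), params)
        rng = np.random.default_rng(3)
        free = ~damaged2.node_is_boundary
        for _ in range(20):
            saved = damaged2.positions.copy()
            damaged2.positions[free] += rng.normal(0, 0.05, (free.sum(), 3))
            equilibrate(damaged2)
            E = total_energy(damaged2, BoundaryCondition.fixed(), params)
            assert E == pytest.approx(E0, rel=1e-6)
            damaged2.positions = saved

    def test_isolated_face_centers_frozen(self, params):
        from parenchyma.destruction import remove_faces
        net = build_cubic_network(2)
        apply_prestrain(net, 1.2)
        fid = next(f.id for f in net.faces if not f.is_boundary)
        remove_faces(net, [fid])
        center = net.faces[fid].center_node
        pos0 = net.positions[center].copy()
        equilibrate(net)
        assert np.array_equal(net.positions[center], pos0)


class TestAnneal:
    def test_same_seed_same_trajectory(self, damaged2):
        a = damaged2.positions.copy()
        temps = [1e-5, 1e-6]
        anneal(damaged2, temperatures=temps, sweeps_per_temp=5, seed=11)
        after1 = damaged2.positions.copy()
        damaged2.positions = a.copy()
        anneal(damaged2, temperatures=temps, sweeps_per_temp=5, seed=11)
        assert np.array_equal(after1, damaged2.positions)

    def test_increasing_schedule_rejected(self, damaged2):
        with pytest.raises(ValueError):
            anneal(damaged2, temperatures=[1e-6, 1e-5])

    def test_zero_temperature_only_accepts_downhill(self, damaged2, params):
        E0 = total_energy(damaged2, BoundaryCondition.fixed(), params)
        anneal(damaged2, temperatures=[0.0], sweeps_per_temp=10, seed=2)
        E1 = total_energy(damaged2, BoundaryCondition.fixed(), params)
        assert E1 <= E0 + 1e-12

    def test_anneal_agrees_with_gradient_descent(self, params):
        """Convex energy surface: annealing and gradient descent find the
        same global minimum on a damaged 2x2x2 fixture."""
        from parenchyma.destruction import remove_faces

        def damaged():
            net = build_cubic_network(2)
            apply_prestrain(net, 1.2)
            internal = [f.id for f in net.faces if not f.is_boundary]
            remove_faces(net, internal[:2])
            return net

        g = damaged()
        equilibrate(g, method="gd")
        Eg = total_energy(g, BoundaryCondition.fixed(), params)
        s = damaged()
        anneal(s, seed=5)
        Es = total_energy(s, BoundaryCondition.fixed(), params)
        assert Es >= Eg - 1e-4 * abs(Eg)
        assert Es == pytest.approx(Eg, rel=1e-4)
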