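"""Wall-removal policies, topological pruning and the destruction loop."""

import numpy as np
import pandas as pd
import pytest

from parenchyma.lattice import apply_prestrain, build_cubic_network
from parenchyma.mechanics import BoundaryCondition, equilibrate
from parenchyma.destruction import (
    DestructionPolicy,
    NetworkExhausted,
    Trajectory,
    face_load,
    face_loads,
    remove_faces,
    run_destruction,
    select_faces,
)
from parenchyma.measure import airspace_clusters


class TestPolicyValidation:
    def test_bad_pattern(self):
        with pytest.raises(ValueError):
            DestructionPolicy(pattern="melt")

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_force_fraction_range(self, r):
        with pytest.raises(ValueError):
            DestructionPolicy(pattern="mixed", force_fraction=r)

    def test_bad_faces_per_step(self):
        with pytest.raises(ValueError):
            DestructionPolicy(faces_per_step=0)


class TestFaceLoad:
    def test_uniform_lattice_equal_loads(self, cubic2_eq, params):
        loads = face_loads(cubic2_eq, params)
        internal = [f.id for f in cubic2_eq.faces if not f.is_boundary]
        vals = loads[internal]
        assert np.allclose(vals, vals[0])
        # 4 springs, each with tension k*(L - L0) at 20% strain
        t = 1.0 * 0.2 * np.sqrt(2.0) / 2.0
        assert vals[0] == pytest.approx(4 * t, rel=1e-9)

    def test_unstrained_faces_carry_no_load(self, cubic2, params):
        assert np.all(face_loads(cubic2, params) == 0.0)

    def test_stress_concentration_on_neighbors(self, cubic4_eq, params):
        """Removing one wall raises the load on the four parallel walls that
        share its edges above the load of distant walls."""
        box_center = 0.5 * (cubic4_eq.bounding_box[0]
                            + cubic4_eq.bounding_box[1])
        center_face = min(
            (f for f in cubic4_eq.faces if not f.is_boundary),
            key=lambda f: np.linalg.norm(
                cubic4_eq.positions[f.center_node] - box_center))
        cpos = cubic4_eq.positions[center_face.center_node].copy()
        # parallel neighbours: internal faces sharing an edge with the removed
        # face and with the same orientation (same set of face-normal springs)
        neighbours = set()
        for (u, v), (sid, adjoining) in cubic4_eq.edge_map.items():
            if center_face.id in adjoining:
                neighbours.update(adjoining)
        neighbours.discard(center_face.id)
        remove_faces(cubic4_eq, [center_face.id])
        equilibrate(cubic4_eq)
        loads = face_loads(cubic4_eq, params)
        near = [f for f in neighbours if not cubic4_eq.faces[f].is_boundary]
        baseline = 4 * 1.0 * 0.2 * np.sqrt(2.0) / 2.0
        far = [f.id for f in cubic4_eq.faces
               if not f.is_boundary and not f.removed and f.id not in near
               and np.linalg.norm(cubic4_eq.positions[f.center_node]
                                  - cpos) > 2.0]
        assert loads[near].max() > np.max(loads[far])
        assert loads[near].max() > baseline

    def test_removed_face_rejected(self, cubic2_eq):
        fid = next(f.id for f in cubic2_eq.faces if not f.is_boundary)
        remove_faces(cubic2_eq, [fid])
        with pytest.raises(ValueError):
            face_load(cubic2_eq, fid)


class TestSelectFaces:
    def test_policy_degeneracies(self, cubic4_eq, params):
        """r=0 mixed equals random, r=1 mixed equals force (same RNG path)."""
        for r, pattern in [(0.0, "random"), (1.0, "force")]:
            mixed = DestructionPolicy(pattern="mixed", force_fraction=r,
                                      faces_per_step=4, seed=9)
            pure = DestructionPolicy(pattern=pattern, faces_per_step=4, seed=9)
            a = select_faces(cubic4_eq, mixed, 3, np.random.default_rng(9),
                             params)
            b = select_faces(cubic4_eq, pure, 3, np.random.default_rng(9),
                             params)
            assert a == b

    def test_first_step_is_random_for_force_pattern(self, cubic4_eq, params):
        """At step 0 the force policy seeds destruction at random: two
        different RNG streams pick different faces despite identical loads."""
        pol = DestructionPolicy(pattern="force", faces_per_step=4)
        a = select_faces(cubic4_eq, pol, 0, np.random.default_rng(1), params)
        b = select_faces(cubic4_eq, pol, 0, np.random.default_rng(2), params)
        assert set(a) != set(b)

    def test_force_selects_elevated_neighbors(self, cubic4_eq, params):
        box_center = 0.5 * (cubic4_eq.bounding_box[0]
                            + cubic4_eq.bounding_box[1])
        fid = min((f for f in cubic4_eq.faces if not f.is_boundary),
                  key=lambda f: np.linalg.norm(
                      cubic4_eq.positions[f.center_node] - box_center)).id
        remove_faces(cubic4_eq, [fid])
        equilibrate(cubic4_eq)
        loads = face_loads(cubic4_eq, params)
        pol = DestructionPolicy(pattern="force", faces_per_step=4)
        picked = select_faces(cubic4_eq, pol, 1, np.random.default_rng(0),
                              params)
        eligible = [f.id for f in cubic4_eq.faces
                    if not f.is_boundary and not f.removed]
        top = np.sort(loads[eligible])[-4:]
        assert np.allclose(np.sort(loads[picked]), top)

    def test_exhaustion_signalled(self, cubic2_eq):
        internal = [f.id for f in cubic2_eq.faces if not f.is_boundary]
        remove_faces(cubic2_eq, internal[:-2])
        pol = DestructionPolicy(pattern="random", faces_per_step=4)
        with pytest.raises(NetworkExhausted):
            select_faces(cubic2_eq, pol, 5, np.random.default_rng(0))

    def test_no_duplicates_in_mixed_selection(self, cubic4_eq, params):
        pol = DestructionPolicy(pattern="mixed", force_fraction=0.5,
                                faces_per_step=8)
        picked = select_faces(cubic4_eq, pol, 2, np.random.default_rng(4),
                              params)
        assert len(picked) == len(set(picked)) == 8


class TestRemoveFaces:
    def test_single_internal_face_of_2cube(self, cubic2_eq):
        """4 face springs break and no edge spring (each edge still borders
        other faces)."""
        fid = next(f.id for f in cubic2_eq.faces if not f.is_boundary)
        n_broken0 = int(cubic2_eq.spring_broken.sum())
        remove_faces(cubic2_eq, [fid])
        assert int(cubic2_eq.spring_broken.sum()) - n_broken0 == 4
        assert all(cubic2_eq.spring_broken[s]
                   for s in cubic2_eq.faces[fid].face_springs)

    def test_edge_spring_breaks_when_all_adjoining_walls_gone(self, cubic2_eq):
        # the central interior edge of the 2^3 block borders 4 internal faces
        edge, (sid, adjoining) = max(
            ((e, v) for e, v in cubic2_eq.edge_map.items()
             if not any(cubic2_eq.faces[f].is_boundary for f in v[1])),
            key=lambda t: len(t[1][1]))
        assert len(adjoining) == 4
        remove_faces(cubic2_eq, sorted(adjoining))
        assert cubic2_eq.spring_broken[sid]

    def test_boundary_face_rejected(self, cubic2_eq):
        fid = next(f.id for f in cubic2_eq.faces if f.is_boundary)
        with pytest.raises(ValueError):
            remove_faces(cubic2_eq, [fid])

    def test_double_removal_rejected(self, cubic2_eq):
        fid = next(f.id for f in cubic2_eq.faces if not f.is_boundary)
        remove_faces(cubic2_eq, [fid])
        with pytest.raises(ValueError):
            remove_faces(cubic2_eq, [fid])

    def test_removing_nothing_is_identity(self, cubic2_eq):
        broken = cubic2_eq.spring_broken.copy()
        remove_faces(cubic2_eq, [])
        assert np.array_equal(cubic2_eq.spring_broken, broken)


class TestRunDestruction:
    def _net(self, n=3):
        net = build_cubic_network(n)
        apply_prestrain(net, 1.2)
        equilibrate(net)
        return net

    def test_deterministic_given_seed(self):
        pol = DestructionPolicy(pattern="force", faces_per_step=2, seed=12)
        a = run_destruction(self._net(), pol, max_steps=4)
        b = run_destruction(self._net(), pol, max_steps=4)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.manifest == b.manifest

    def test_k_ratio_weakly_decreasing(self):
        pol = DestructionPolicy(pattern="random", faces_per_step=4, seed=3)
        traj = run_destruction(self._net(), pol, max_steps=8)
        k = traj.data.K_over_K0.to_numpy()
        assert np.all(np.diff(k) < 0.02)

    def test_volume_conserved_along_run(self):
        net = self._net()
        box = net.box_volume
        pol = DestructionPolicy(pattern="force", faces_per_step=3, seed=8)
        run_destruction(net, pol, max_steps=6)
        total = sum(c.volume for c in airspace_clusters(net))
        assert total == pytest.approx(box, rel=1e-6)

    def test_no_face_removed_twice(self):
        net = self._net()
        pol = DestructionPolicy(pattern="random", faces_per_step=4, seed=5)
        run_destruction(net, pol, max_steps=10, measure_modulus=False)
        removed = [f.id for f in net.faces if f.removed]
        assert len(removed) == len(set(removed))
        assert not any(net.faces[f].is_boundary for f in removed)

    def test_trajectory_roundtrip(self, tmp_path):
        pol = DestructionPolicy(pattern="force", faces_per_step=2, seed=1)
        traj = run_destruction(self._net(), pol, max_steps=3)
        traj.save(tmp_path / "t.csv")
        back = Trajectory.load(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back.data, traj.data,
                                      check_dtype=False)
        assert back.manifest["policy"] == traj.manifest["policy"]


def test_pattern_contrast_smoke():
    """Force-based cutting concentrates damage: at a matched wall count in
    the growth phase its volume variance exceeds random cutting's, while
    random merges airspaces faster (larger mean)."""
    def run(pattern, seed):
        net = build_cubic_network(4)
        apply_prestrain(net, 1.2)
        equilibrate(net)
        pol = DestructionPolicy(pattern=pattern, faces_per_step=4, seed=seed)
        return run_destruction(net, pol, measure_modulus=False,
                               max_faces=30, max_steps=10)

    m_force = run("force", 21).data.iloc[-1]
    m_rand = run("random", 22).data.iloc[-1]
    assert m_force["m2"] > m_rand["m2"]
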