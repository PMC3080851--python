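"""Constitutive law, network energies and numerical equilibration.

Springs are tension-only: they develop force only at positive strain
ε = (L - L0)/L0.  The material law is either linear, f(ε) = k·ε, or a
monotone power law f(ε) = A·ε + B·ε^p (p > 1).  A per-spring scale converts
the material law into spring tension; with the default ``extension`` energy
form the scale is L0, so a linear spring has tension k·(L - L0) and energy
(k/2)(L - L0)², while the ``strain`` form uses scale 1 (tension k·ε, energy
(k/2)L0·ε²).  Normalized results (K/K0 and the cutting order) are insensitive
to this global prefactor choice.

Three boundary conditions are supported: ``fixed`` (boundary nodes pinned),
``force`` (constant external forces on boundary nodes, all nodes free) and
``pressure`` (facet forces from a uniform pressure on the exterior surface,
updated in an outer loop as the geometry changes; negative pressure distends).

Equilibration minimizes the (convex) energy with analytic gradients until the
dual force criteria hold: both the maximum and the mean resultant-force
magnitude over free nodes fall below their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .lattice import Network

__all__ = [
    "ConstitutiveParams",
    "BoundaryCondition",
    "EquilibriumCriteria",
    "EquilibriumReport",
    "spring_force",
    "spring_energy",
    "spring_tensions",
    "total_energy",
    "resultant_forces",
    "exterior_volume",
    "pressure_facet_forces",
    "equilibrate",
    "anneal",
]


@dataclass(frozen=True)
class ConstitutiveParams:
    """Material law of the alveolar-wall springs.

    Parameters
    ----------
    law : {"linear", "power"}
    k : linear stiffness (model force units; the analogue of a Young modulus).
    A, B, p : power-law coefficients, f(ε) = A·ε + B·ε**p for ε > 0.  Defaults:
        A = k, p = 3 and B chosen so the tangent stiffness doubles at ε = 0.3.
    energy_form : {"extension", "strain"}; see module docstring.
    """

    law: str = "linear"
    k: float = 1.0
    A: float | None = None
    B: float | None = None
    p: float = 3.0
    energy_form: str = "extension"

    def __post_init__(self):
        if self.law not in ("linear", "power"):
            raise ValueError(f"unknown law {self.law!r}")
        if self.energy_form not in ("extension", "strain"):
            raise ValueError(f"unknown energy_form {self.energy_form!r}")
        if self.law == "power":
            if self.p <= 1:
                raise ValueError("power-law exponent p must exceed 1")
            if self.A is None:
                object.__setattr__(self, "A", self.k)
            if self.B is None:
                # tangent stiffness A + p·B·ε^(p-1) doubles at ε = 0.3
                object.__setattr__(
                    self, "B", self.A / (self.p * 0.3 ** (self.p - 1.0)))


def spring_force(strain, params: ConstitutiveParams):
    """Material force law f(ε): zero for ε <= 0 (no support of compression)."""
    eps = np.maximum(np.asarray(strain, dtype=float), 0.0)
    if params.law == "linear":
        f = params.k * eps
    else:
        f = params.A * eps + params.B * eps ** params.p
    return f if f.ndim else float(f)


def _energy_density(eps, params: ConstitutiveParams):
    """∫₀^ε f(ε') dε' for ε > 0 (per unit rest length, unscaled)."""
    eps = np.maximum(eps, 0.0)
    if params.law == "linear":
        return 0.5 * params.k * eps ** 2
    return 0.5 * params.A * eps ** 2 + \
        params.B * eps ** (params.p + 1.0) / (params.p + 1.0)


def _scale(L0, params: ConstitutiveParams):
    return L0 if params.energy_form == "extension" else np.ones_like(L0)


def spring_energy(length, L0, params: ConstitutiveParams | None = None):
    """Elastic energy of one spring stretched from L0 to ``length``.

    Equals scale·L0·∫ f dε, the integral of the spring tension over the
    extension; zero at or below the rest length.
    """
    params = params or ConstitutiveParams()
    length = np.asarray(length, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if np.any(length <= 0) or np.any(L0 <= 0):
        raise ValueError("lengths must be positive")
    eps = (length - L0) / L0
    e = _scale(L0, params) * L0 * _energy_density(eps, params)
    return e if e.ndim else float(e)


@dataclass
class BoundaryCondition:
    """Boundary condition for equilibration.

    mode : {"fixed", "force", "pressure"}
    external_forces : (N, 3) array of constant nodal forces (force and
        pressure modes; zero rows for unloaded nodes), or None.
    pressure : applied pressure (pressure mode); negative values distend.
    """

    mode: str = "fixed"
    external_forces: np.ndarray | None = None
    pressure: float = 0.0

    def __post_init__(self):
        if self.mode not in ("fixed", "force", "pressure"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")

    @classmethod
    def fixed(cls) -> "BoundaryCondition":
        return cls("fixed")

    @classmethod
    def force(cls, external_forces) -> "BoundaryCondition":
        return cls("force", np.asarray(external_forces, dtype=float))

    @classmethod
    def pressure_bc(cls, pressure: float,
                    external_forces=None) -> "BoundaryCondition":
        ext = None if external_forces is None else \
            np.asarray(external_forces, dtype=float)
        return cls("pressure", ext, float(pressure))


@dataclass
class EquilibriumCriteria:
    """Dual force thresholds plus iteration/outer-loop limits.

    ``None`` tolerances resolve at call time to 1e-6·k·cell_size (max) and
    1e-7·k·cell_size (mean).  ``energy_change_tol`` bounds the relative change
    in free energy between successive pressure-mode outer iterations.
    """

    max_force_tol: float | None = None
    mean_force_tol: float | None = None
    max_iterations: int = 50000
    energy_change_tol: float = 1e-10
    max_outer_iterations: int = 60

    def resolved(self, net: Network, params: ConstitutiveParams):
        scale = params.k * net.cell_size
        mx = self.max_force_tol if self.max_force_tol is not None \
            else 1e-6 * scale
        mn = self.mean_force_tol if self.mean_force_tol is not None \
            else 1e-7 * scale
        if mx <= 0 or mn <= 0:
            raise ValueError("force tolerances must be positive")
        return mx, mn


@dataclass
class EquilibriumReport:
    converged: bool
    iterations: int
    max_force: float
    mean_force: float
    energy: float
    outer_iterations: int = 1


# ----------------------------------------------------------- vector helpers

def spring_tensions(net: Network, params: ConstitutiveParams | None = None,
                    positions: np.ndarray | None = None) -> np.ndarray:
    """Tension of every spring (zero for broken or slack springs)."""
    params = params or ConstitutiveParams()
    pos = net.positions if positions is None else positions
    i, j = net.spring_endpoints[:, 0], net.spring_endpoints[:, 1]
    d = pos[j] - pos[i]
    L = np.linalg.norm(d, axis=1)
    eps = (L - net.spring_L0) / net.spring_L0
    t = net.spring_k * _scale(net.spring_L0, params) * spring_force(eps, params)
    t[net.spring_broken] = 0.0
    return t


def _spring_energy_and_forces(net, pos, params):
    """Total spring energy and per-node spring forces (= -∂U/∂x)."""
    i, j = net.spring_endpoints[:, 0], net.spring_endpoints[:, 1]
    d = pos[j] - pos[i]
    L = np.linalg.norm(d, axis=1)
    L = np.maximum(L, 1e-300)
    eps = (L - net.spring_L0) / net.spring_L0
    sc = net.spring_k * _scale(net.spring_L0, params)
    active = (~net.spring_broken) & (eps > 0)
    e = np.where(active, sc * net.spring_L0 * _energy_density(eps, params), 0.0)
    t = np.where(active, sc * spring_force(eps, params), 0.0)
    fvec = (t / L)[:, None] * d            # force on node i, toward j
    forces = np.zeros_like(pos)
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return float(e.sum()), forces


def _ext_surface(net: Network):
    """Cached triangulation of the exterior surface with outward signs."""
    cache = getattr(net, "_ext_surface", None)
    if cache is not None:
        return cache
    inc = net.incidence()
    bset = set(inc["boundary_faces"].tolist())
    sign_of = {}
    for fid, cid, s in zip(inc["cf_face"], inc["cf_cell"], inc["cf_sign"]):
        if int(fid) in bset:
            sign_of[int(fid)] = float(s)
    mask = np.isin(inc["tri_face"], inc["boundary_faces"])
    tri_sign = np.array([sign_of[int(f)] for f in inc["tri_face"][mask]])
    cache = (inc["tri_c"][mask], inc["tri_a"][mask], inc["tri_b"][mask],
             tri_sign)
    net._ext_surface = cache
    return cache


def exterior_volume(net: Network, positions: np.ndarray | None = None) -> float:
    """Volume enclosed by the exterior (boundary-face) surface."""
    pos = net.positions if positions is None else positions
    c, a, b, s = _ext_surface(net)
    vols = np.einsum("ij,ij->i", pos[c], np.cross(pos[a], pos[b])) / 6.0
    return float(np.sum(s * vols))


def pressure_facet_forces(net: Network, pressure: float,
                          positions: np.ndarray | None = None) -> np.ndarray:
    """Nodal forces from pressure acting on the exterior surface triangles.

    Each triangle with outward area vector S contributes a force -P·S split
    equally over its three nodes (gradient of the P·V energy term at frozen
    geometry); negative P pushes outward.
    """
    pos = net.positions if positions is None else positions
    c, a, b, s = _ext_surface(net)
    area = 0.5 * s[:, None] * np.cross(pos[b] - pos[c], pos[a] - pos[c])
    # outward area vector of triangle (c, a, b) with sign s
    area = -area  # cross(b-c, a-c) is inward for ccw outward loops
    f = (-pressure / 3.0) * area
    forces = np.zeros_like(pos)
    np.add.at(forces, c, f)
    np.add.at(forces, a, f)
    np.add.at(forces, b, f)
    return forces


def total_energy(net: Network, bc: BoundaryCondition,
                 params: ConstitutiveParams | None = None) -> float:
    """Total (free) energy: spring energy plus boundary work terms.

    fixed: U;  force: U - Σ F·x;  pressure: U - Σ F·x + P·V with V the
    exterior enclosed volume.  Broken springs contribute exactly zero.
    """
    params = params or ConstitutiveParams()
    U, _ = _spring_energy_and_forces(net, net.positions, params)
    E = U
    if bc.external_forces is not None:
        E -= float(np.sum(bc.external_forces * net.positions))
    if bc.mode == "pressure":
        E += bc.pressure * exterior_volume(net)
    return E


def resultant_forces(net: Network, bc: BoundaryCondition,
                     params: ConstitutiveParams | None = None) -> np.ndarray:
    """Net force on every node: springs + external (+ current facet forces)."""
    params = params or ConstitutiveParams()
    _, forces = _spring_energy_and_forces(net, net.positions, params)
    if bc.external_forces is not None:
        forces = forces + bc.external_forces
    if bc.mode == "pressure":
        forces = forces + pressure_facet_forces(net, bc.pressure)
    return forces


def _free_mask(net: Network, bc: BoundaryCondition) -> np.ndarray:
    """Free (movable) nodes: honours the boundary mode and freezes isolated
    nodes whose incident springs are all broken (face centres of removed
    walls), which are excluded from the force criteria."""
    if bc.mode == "fixed":
        free = ~net.node_is_boundary
    else:
        free = np.ones(net.n_nodes, dtype=bool)
    alive = ~net.spring_broken
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    ends = net.spring_endpoints[alive]
    np.add.at(deg, ends[:, 0], 1)
    np.add.at(deg, ends[:, 1], 1)
    return free & (deg > 0)


# --------------------------------------------------------------- minimizers

def _solve_inner(net, params, free, ext_forces, criteria, method, mx, mn):
    """Minimize U - Σ F_ext·x over the free nodes.  Returns (iters, converged)."""
    pos = net.positions
    idx = np.flatnonzero(free)
    if len(idx) == 0:
        return 0, True
    # external work measured from the starting positions: a constant shift
    # that keeps |objective| small so the line search is not limited by
    # float64 resolution of the energy
    x_ref = pos[idx].copy()

    def fun(x):
        p = pos.copy()
        p[idx] = x.reshape(-1, 3)
        U, forces = _spring_energy_and_forces(net, p, params)
        if ext_forces is not None:
            U -= float(np.sum(ext_forces[idx] * (p[idx] - x_ref)))
            forces = forces + ext_forces
        g = -forces[idx].ravel()
        return U, g

    def force_norms(x):
        _, g = fun(x)
        mag = np.linalg.norm(g.reshape(-1, 3), axis=1)
        return float(mag.max()), float(mag.mean())

    x = pos[idx].ravel().copy()
    iters = 0
    if method == "lbfgs":
        for _ in range(4):
            res = minimize(fun, x, jac=True, method="L-BFGS-B",
                           options={"maxiter": criteria.max_iterations,
                                    "maxcor": 20, "ftol": 1e-18,
                                    "gtol": 0.2 * mx})
            x = res.x
            iters += res.nit
            fmax, fmean = force_norms(x)
            if (fmax < mx and fmean < mn) or iters >= criteria.max_iterations:
                break
        if not (fmax < mx and fmean < mn):
            # damped fixed-step polish: needs no energy comparisons, so it can
            # squeeze the residual below the float64 energy-resolution floor
            # where the line search stalls
            stiff = np.zeros(len(pos))
            sc = net.spring_k * _scale(net.spring_L0, params) / net.spring_L0
            np.add.at(stiff, net.spring_endpoints[:, 0], sc)
            np.add.at(stiff, net.spring_endpoints[:, 1], sc)
            alpha = 0.5 / max(float(stiff[idx].max()), 1e-12)
            for _ in range(400):
                _, g = fun(x)
                x = x - alpha * g
                iters += 1
                fmax, fmean = force_norms(x)
                if fmax < mx and fmean < mn:
                    break
    elif method == "gd":
        E, g = fun(x)
        step = 0.1 * net.cell_size
        while iters < criteria.max_iterations:
            mag = np.linalg.norm(g.reshape(-1, 3), axis=1)
            if mag.max() < mx and mag.mean() < mn:
                break
            # Armijo backtracking along -g
            gg = float(np.dot(g, g))
            t = step
            for _ in range(60):
                E_new, g_new = fun(x - t * g)
                if E_new <= E - 1e-4 * t * gg:
                    break
                t *= 0.5
            x = x - t * g
            E, g = E_new, g_new
            step = min(t * 1.5, 1.0 * net.cell_size)
            iters += 1
    else:
        raise ValueError(f"unknown method {method!r}")

    pos[idx] = x.reshape(-1, 3)
    fmax, fmean = force_norms(x)
    return iters, (fmax < mx and fmean < mn)


def equilibrate(net: Network, bc: BoundaryCondition | None = None,
                criteria: EquilibriumCriteria | None = None,
                params: ConstitutiveParams | None = None,
                method: str = "lbfgs") -> EquilibriumReport:
    """Drive the network to mechanical equilibrium (positions updated in place).

    The energy surface of the tension-only network is convex, so gradient
    methods find the global minimum; ``method="lbfgs"`` (default) and
    ``method="gd"`` (plain gradient descent with Armijo backtracking) reach the
    same state.  Convergence requires both the maximum and the mean
    resultant-force magnitude over free nodes to fall below their thresholds.
    In pressure mode an outer loop refreshes the facet forces after each inner
    minimization until the free energy stops changing and the force criteria
    hold with the updated facet forces.

    Non-convergence is reported, not raised: the returned
    :class:`EquilibriumReport` carries the residual force norms.
    """
    bc = bc or BoundaryCondition.fixed()
    criteria = criteria or EquilibriumCriteria()
    params = params or ConstitutiveParams()
    mx, mn = criteria.resolved(net, params)
    free = _free_mask(net, bc)

    total_iters = 0
    outer_done = 1
    if bc.mode == "pressure":
        prev_F = None
        converged = False
        for outer in range(criteria.max_outer_iterations):
            outer_done = outer + 1
            facet = pressure_facet_forces(net, bc.pressure)
            ext = facet if bc.external_forces is None \
                else facet + bc.external_forces
            it, _ = _solve_inner(net, params, free, ext, criteria, method,
                                 mx, mn)
            total_iters += it
            F = total_energy(net, bc, params)
            forces = resultant_forces(net, bc, params)
            mag = np.linalg.norm(forces[free], axis=1)
            crit_ok = bool(mag.max() < mx and mag.mean() < mn)
            if prev_F is not None and \
                    abs(F - prev_F) <= criteria.energy_change_tol * \
                    (1.0 + abs(F)) and crit_ok:
                converged = True
                break
            prev_F = F
    else:
        ext = bc.external_forces
        it, converged = _solve_inner(net, params, free, ext, criteria,
                                     method, mx, mn)
        total_iters += it

    forces = resultant_forces(net, bc, params)
    mag = np.linalg.norm(forces[free], axis=1) if free.any() else np.zeros(1)
    net.needs_equilibration = False
    return EquilibriumReport(bool(converged), total_iters,
                             float(mag.max()), float(mag.mean()),
                             total_energy(net, bc, params), outer_done)


def anneal(net: Network, bc: BoundaryCondition | None = None,
           temperatures=None, sweeps_per_temp: int = 80,
           step_size: float | None = None, seed: int = 0,
           params: ConstitutiveParams | None = None) -> EquilibriumReport:
    """Simulated-annealing minimization (Metropolis), for small cross-checks.

    Per-node random displacements are accepted with probability
    exp(-ΔE/T); the temperature schedule must be decreasing and is followed by
    a zero-temperature (downhill-only) polish with shrinking steps.  Seeded
    and fully reproducible.  Supports fixed and force boundary modes.
    """
    bc = bc or BoundaryCondition.fixed()
    if bc.mode == "pressure":
        raise ValueError("anneal supports fixed and force modes only")
    params = params or ConstitutiveParams()
    rng = np.random.default_rng(seed)
    free_idx = np.flatnonzero(_free_mask(net, bc))
    pos = net.positions

    E0, _ = _spring_energy_and_forces(net, pos, params)
    if temperatures is None:
        Tmax = max(E0, 1e-6) * 1e-4
        temperatures = Tmax * 0.65 ** np.arange(24)
    temperatures = np.asarray(list(temperatures), dtype=float)
    if np.any(np.diff(temperatures) > 0):
        raise ValueError("temperature schedule must be decreasing")
    if step_size is None:
        step_size = 0.05 * net.cell_size

    # per-node incident springs for incremental energy evaluation
    incident: dict[int, np.ndarray] = {}
    for n in free_idx:
        mask = (net.spring_endpoints[:, 0] == n) | \
               (net.spring_endpoints[:, 1] == n)
        incident[int(n)] = np.flatnonzero(mask & ~net.spring_broken)

    def local_energy(n, p_n):
        sids = incident[int(n)]
        if len(sids) == 0:
            return 0.0
        i, j = net.spring_endpoints[sids, 0], net.spring_endpoints[sids, 1]
        pi = np.where((i == n)[:, None], p_n, pos[i])
        pj = np.where((j == n)[:, None], p_n, pos[j])
        L = np.linalg.norm(pj - pi, axis=1)
        L0 = net.spring_L0[sids]
        eps = (L - L0) / L0
        sc = net.spring_k[sids] * _scale(L0, params)
        e = sc * L0 * _energy_density(eps, params)
        E = float(e.sum())
        if bc.external_forces is not None:
            E -= float(np.dot(bc.external_forces[n], p_n))
        return E

    def sweep(T, step):
        for n in free_idx:
            old = pos[n].copy()
            new = old + rng.normal(0.0, step, 3)
            dE = local_energy(n, new) - local_energy(n, old)
            if dE <= 0 or (T > 0 and rng.random() < np.exp(-dE / T)):
                pos[n] = new

    for T in temperatures:
        for _ in range(sweeps_per_temp):
            sweep(T, step_size)
    step = step_size
    for _ in range(12):                       # zero-temperature polish
        for _ in range(sweeps_per_temp):
            sweep(0.0, step)
        step *= 0.4

    E = total_energy(net, bc, params)
    forces = resultant_forces(net, bc, params)
    mag = np.linalg.norm(forces[free_idx], axis=1) if len(free_idx) else \
        np.zeros(1)
    return EquilibriumReport(True, int(len(temperatures) * sweeps_per_temp),
                             float(mag.max()), float(mag.mean()), E)
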