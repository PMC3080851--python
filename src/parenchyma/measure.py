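"""Airspace volumes, volume-distribution moments and the bulk modulus.

Airspaces are the connected clusters of cells merged by removed internal
walls; their volumes are computed by the Gauss divergence theorem as sums of
signed tetrahedra (fan triangulation of every remaining face about its centre
node, apex at the origin).  Because a shared intact face contributes with
opposite signs to its two cells, a cluster volume is simply the sum over its
member cells of their per-cell signed face contributions — removed faces are
excluded and internal shared faces cancel, leaving exactly the cluster's
boundary surface.

The bulk modulus is probed as in an excised-tissue experiment: the fixed
boundary is replaced by the equivalent holding forces, a small distending
pressure increment is superposed on the exterior surface, the network is
re-equilibrated, and K = ΔP/(ΔV/V0).  The probe restores the network state
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import Network
from .mechanics import (
    BoundaryCondition,
    ConstitutiveParams,
    EquilibriumCriteria,
    _spring_energy_and_forces,
    equilibrate,
    exterior_volume,
)

__all__ = [
    "AirspaceCluster",
    "ModulusMeasurement",
    "polyhedron_volume",
    "cell_volumes",
    "airspace_clusters",
    "volume_moments",
    "default_probe_pressure",
    "bulk_modulus",
]


@dataclass
class AirspaceCluster:
    """A maximal set of cells merged by removed internal walls."""

    id: int
    member_cells: frozenset[int]
    volume: float


@dataclass
class ModulusMeasurement:
    """Result of one bulk-modulus probe, K = delta_P / (ΔV / V0)."""

    K: float
    delta_P: float
    V0: float
    V1: float
    converged: bool


def polyhedron_volume(triangles) -> float:
    """Volume of a closed, consistently outward-oriented triangulated surface.

    ``triangles`` is an (T, 3, 3) array (or nested list) of vertex
    coordinates.  The volume is the sum of signed tetrahedra with apex at the
    origin, valid for non-convex shapes and invariant under translation.
    Raises ``ValueError`` if the surface is not closed (the oriented area
    vectors do not sum to zero).
    """
    tri = np.asarray(triangles, dtype=float)
    if tri.ndim != 3 or tri.shape[1:] != (3, 3):
        raise ValueError("triangles must have shape (T, 3, 3)")
    areas = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    scale = np.abs(areas).sum()
    if scale == 0 or np.linalg.norm(areas.sum(axis=0)) > 1e-9 * scale:
        raise ValueError("surface is not closed/consistently oriented")
    vols = np.einsum("ij,ij->i", tri[:, 0],
                     np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(vols.sum())


def _face_fan_volumes(net: Network) -> np.ndarray:
    """Signed fan-tetrahedron volume of every face at current positions."""
    inc = net.incidence()
    pos = net.positions
    c, a, b = inc["tri_c"], inc["tri_a"], inc["tri_b"]
    tet = np.einsum("ij,ij->i", pos[c], np.cross(pos[a], pos[b])) / 6.0
    fv = np.zeros(net.n_faces)
    np.add.at(fv, inc["tri_face"], tet)
    return fv


def cell_volumes(net: Network) -> np.ndarray:
    """Signed-surface volume of every cell, removed faces excluded.

    For intact cells this is the polyhedron volume; for cells with removed
    walls it is the cell's (open-surface) contribution to its cluster volume.
    """
    inc = net.incidence()
    fv = _face_fan_volumes(net)
    removed = np.array([f.removed for f in net.faces])
    contrib = np.where(removed[inc["cf_face"]], 0.0,
                       inc["cf_sign"] * fv[inc["cf_face"]])
    out = np.zeros(net.n_cells)
    np.add.at(out, inc["cf_cell"], contrib)
    return out


def airspace_clusters(net: Network) -> list[AirspaceCluster]:
    """Partition cells into airspace clusters and compute their volumes.

    Cells are connected when the internal face between them has been removed;
    each cluster's volume is the divergence-theorem volume of its remaining
    boundary surface (sum of member-cell contributions; shared intact faces
    cancel pairwise).
    """
    rows, cols = [], []
    for f in net.faces:
        if f.removed:
            if len(f.adjacent_cells) != 2:
                raise RuntimeError("removed face is not internal")
            a, b = f.adjacent_cells
            rows.append(a)
            cols.append(b)
    n = net.n_cells
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    vols = cell_volumes(net)
    cluster_vol = np.zeros(n_comp)
    np.add.at(cluster_vol, labels, vols)
    members: list[set[int]] = [set() for _ in range(n_comp)]
    for cid, lab in enumerate(labels):
        members[lab].add(cid)
    return [AirspaceCluster(i, frozenset(members[i]), float(cluster_vol[i]))
            for i in range(n_comp)]


def volume_moments(clusters, v_ref: float = 1.0, standardized: bool = False):
    """Mean and moments 2-4 of normalized airspace volumes.

    Volumes are divided by ``v_ref`` (the initial single-cell volume) so the
    moments are dimensionless.  Returns (μ, m2, m3, m4) with
    m_k = mean((v - μ)**k); with ``standardized=True`` the third and fourth
    moments are returned as skewness m3/m2^1.5 and kurtosis m4/m2² (zero for
    a degenerate distribution).
    """
    if len(clusters) == 0:
        raise ValueError("need at least one cluster")
    v = np.array([c.volume if isinstance(c, AirspaceCluster) else float(c)
                  for c in clusters]) / v_ref
    mu = float(v.mean())
    d = v - mu
    m2 = float((d ** 2).mean())
    m3 = float((d ** 3).mean())
    m4 = float((d ** 4).mean())
    if standardized:
        if m2 > 1e-24:
            m3, m4 = m3 / m2 ** 1.5, m4 / m2 ** 2
        else:
            m3 = m4 = 0.0
    return mu, m2, m3, m4


def default_probe_pressure(net: Network,
                           params: ConstitutiveParams | None = None) -> float:
    """Default probe amplitude: 1% of the recoil pressure scale k·ε0/cell."""
    params = params or ConstitutiveParams()
    eps0 = max(net.prestrain - 1.0, 0.1)
    return 0.01 * params.k * eps0 / net.cell_size


def bulk_modulus(net: Network, delta_P: float | None = None,
                 criteria: EquilibriumCriteria | None = None,
                 params: ConstitutiveParams | None = None,
                 method: str = "lbfgs") -> ModulusMeasurement:
    """Measure the bulk modulus by a small pressure perturbation.

    Starting from a fixed-boundary equilibrium: (i) the resultant spring force
    on each boundary node is balanced by an equal-and-opposite constant
    external force and the boundary is released (the configuration remains an
    equilibrium); (ii) a small distending pressure ``delta_P`` is superposed
    on the exterior surface; (iii) the network re-equilibrates under the
    pressure boundary (outer facet-force loop); (iv) K = ΔP/(ΔV/V0) from the
    exterior enclosed volume before/after.  The probe is side-effect-free.
    """
    params = params or ConstitutiveParams()
    criteria = criteria or EquilibriumCriteria()
    if delta_P is None:
        delta_P = default_probe_pressure(net, params)
    if delta_P <= 0:
        raise ValueError("delta_P must be positive")

    saved = net.positions.copy()
    saved_flag = net.needs_equilibration
    try:
        _, spring_forces = _spring_energy_and_forces(net, net.positions, params)
        hold = np.zeros_like(net.positions)
        bmask = net.node_is_boundary
        hold[bmask] = -spring_forces[bmask]
        V0 = exterior_volume(net)
        bc = BoundaryCondition.pressure_bc(-delta_P, hold)
        rep = equilibrate(net, bc, criteria, params, method=method)
        V1 = exterior_volume(net)
    finally:
        result_pos = net.positions
        net.positions = saved
        net.needs_equilibration = saved_flag
    dV = V1 - V0
    K = delta_P / (dV / V0) if dV > 0 else float("inf")
    return ModulusMeasurement(float(K), float(delta_P), V0, V1, rep.converged)
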