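"""Construction of space-filling polyhedral spring networks.

A cuboidal block of lung parenchyma is modelled as a tiling of space-filling
polyhedral cells (cubes or tetrakaidecahedra), each cell standing in for one
alveolus.  Every polygonal face (an alveolar septum) carries springs from its
centroid to each of its vertices; every geometric edge of the tiling (a septal
junction line) carries a single shared edge spring.  The outermost vertices and
face centres are flagged as boundary nodes so that the block can be
pre-strained with its surface held fixed.

Node positions, spring topology and face/cell incidence are stored in flat
numpy arrays on :class:`Network`; faces and cells keep explicit vertex cycles
so that signed fan triangulations (used for airspace volumes and pressure
loads) are available without runtime orientation tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "Spring",
    "Face",
    "Cell",
    "Network",
    "build_cubic_network",
    "build_tkd_network",
    "apply_prestrain",
]

ROLE_VERTEX = 0
ROLE_FACE_CENTER = 1
KIND_FACE = 0
KIND_EDGE = 1

_ROLE_NAMES = {ROLE_VERTEX: "vertex", ROLE_FACE_CENTER: "face_center"}
_KIND_NAMES = {KIND_FACE: "face", KIND_EDGE: "edge"}


@dataclass
class Node:
    """Read-only view of one node (vertex or face centre)."""

    id: int
    position: np.ndarray
    role: str
    is_boundary: bool


@dataclass
class Spring:
    """Read-only view of one tension-only spring."""

    id: int
    endpoints: tuple[int, int]
    rest_length: float
    kind: str
    stiffness: float
    broken: bool


@dataclass
class Face:
    """One polygonal wall: an ordered vertex cycle plus its centre node."""

    id: int
    vertex_nodes: list[int]
    center_node: int
    face_springs: list[int]
    adjacent_cells: list[int]
    removed: bool = False
    is_boundary: bool = False


@dataclass
class Cell:
    """One polyhedral unit cell (idealized alveolus)."""

    id: int
    faces: list[int]
    lattice_index: tuple[int, int, int] = (0, 0, 0)


class Network:
    """Mutable state of a spring-network simulation.

    Attributes
    ----------
    positions : (N, 3) float array of node coordinates.
    node_role : (N,) uint8, ``ROLE_VERTEX`` or ``ROLE_FACE_CENTER``.
    node_is_boundary : (N,) bool, True for nodes on the bounding box surface.
    spring_endpoints : (S, 2) int array of node ids.
    spring_L0 : (S,) unstretched lengths.
    spring_kind : (S,) uint8, ``KIND_FACE`` or ``KIND_EDGE``.
    spring_k : (S,) stiffnesses (model units, default 1).
    spring_broken : (S,) bool mask; broken springs carry no force or energy.
    faces, cells : lists of :class:`Face` / :class:`Cell`.
    edge_map : dict mapping each unordered vertex pair to
        ``(edge_spring_id, set of face ids sharing the edge)``.
    bounding_box : (lo, hi) corner coordinates of the cuboid.
    prestrain : cumulative uniform expansion factor applied so far.
    """

    def __init__(self):
        self.positions = np.zeros((0, 3))
        self.node_role = np.zeros(0, dtype=np.uint8)
        self.node_is_boundary = np.zeros(0, dtype=bool)
        self.spring_endpoints = np.zeros((0, 2), dtype=np.int64)
        self.spring_L0 = np.zeros(0)
        self.spring_kind = np.zeros(0, dtype=np.uint8)
        self.spring_k = np.zeros(0)
        self.spring_broken = np.zeros(0, dtype=bool)
        self.faces: list[Face] = []
        self.cells: list[Cell] = []
        self.edge_map: dict[tuple[int, int], tuple[int, set[int]]] = {}
        self.bounding_box = (np.zeros(3), np.zeros(3))
        self.prestrain = 1.0
        self.cell_size = 1.0
        self.lattice_type = "cubic"
        self.needs_equilibration = False
        self._incidence = None

    # ------------------------------------------------------------------ views
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_springs(self) -> int:
        return len(self.spring_L0)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def node(self, i: int) -> Node:
        return Node(i, self.positions[i].copy(), _ROLE_NAMES[self.node_role[i]],
                    bool(self.node_is_boundary[i]))

    def spring(self, s: int) -> Spring:
        i, j = self.spring_endpoints[s]
        return Spring(s, (int(i), int(j)), float(self.spring_L0[s]),
                      _KIND_NAMES[self.spring_kind[s]], float(self.spring_k[s]),
                      bool(self.spring_broken[s]))

    @property
    def box_volume(self) -> float:
        lo, hi = self.bounding_box
        return float(np.prod(hi - lo))

    def break_springs(self, spring_ids) -> None:
        self.spring_broken[np.asarray(spring_ids, dtype=np.int64)] = True
        self.needs_equilibration = True

    # --------------------------------------------------------- incidence cache
    def incidence(self) -> dict:
        """Static topology arrays shared by the measurement and mechanics code.

        ``tri_*`` triangulate every face as a fan about its centre node;
        ``cf_*`` list (cell, face) incidences with the sign that makes the fan
        contribution point outward from the cell.  Topology never changes after
        construction (damage only flips ``removed``/``broken`` masks), so these
        are built once.
        """
        if self._incidence is not None:
            return self._incidence
        tri_c, tri_a, tri_b, tri_face = [], [], [], []
        face_tri_start = np.zeros(self.n_faces + 1, dtype=np.int64)
        for f in self.faces:
            vs = f.vertex_nodes
            m = len(vs)
            for t in range(m):
                tri_c.append(f.center_node)
                tri_a.append(vs[t])
                tri_b.append(vs[(t + 1) % m])
                tri_face.append(f.id)
            face_tri_start[f.id + 1] = face_tri_start[f.id] + m
        tri_c = np.array(tri_c, dtype=np.int64)
        tri_a = np.array(tri_a, dtype=np.int64)
        tri_b = np.array(tri_b, dtype=np.int64)
        tri_face = np.array(tri_face, dtype=np.int64)

        # per-(cell, face) outward signs from the as-built geometry
        pos = self.positions
        d = np.cross(pos[tri_a] - pos[tri_c], pos[tri_b] - pos[tri_c])
        face_normal = np.zeros((self.n_faces, 3))
        np.add.at(face_normal, tri_face, d)
        face_centroid = pos[[f.center_node for f in self.faces]]
        cell_centroid = np.zeros((self.n_cells, 3))
        for c in self.cells:
            vs = set()
            for fid in c.faces:
                vs.update(self.faces[fid].vertex_nodes)
            cell_centroid[c.id] = pos[sorted(vs)].mean(axis=0)
        cf_cell, cf_face, cf_sign = [], [], []
        for c in self.cells:
            for fid in c.faces:
                out = face_centroid[fid] - cell_centroid[c.id]
                s = 1.0 if float(np.dot(face_normal[fid], out)) >= 0 else -1.0
                cf_cell.append(c.id)
                cf_face.append(fid)
                cf_sign.append(s)
        # face spring -> face index (for face loads)
        fs_spring, fs_face = [], []
        for f in self.faces:
            for s in f.face_springs:
                fs_spring.append(s)
                fs_face.append(f.id)
        self._incidence = {
            "tri_c": tri_c, "tri_a": tri_a, "tri_b": tri_b, "tri_face": tri_face,
            "face_tri_start": face_tri_start,
            "cf_cell": np.array(cf_cell, dtype=np.int64),
            "cf_face": np.array(cf_face, dtype=np.int64),
            "cf_sign": np.array(cf_sign),
            "fs_spring": np.array(fs_spring, dtype=np.int64),
            "fs_face": np.array(fs_face, dtype=np.int64),
            "boundary_faces": np.array([f.id for f in self.faces if f.is_boundary],
                                       dtype=np.int64),
            "internal_faces": np.array([f.id for f in self.faces if not f.is_boundary],
                                       dtype=np.int64),
        }
        return self._incidence

    # ------------------------------------------------------------- serialization
    def to_json(self) -> str:
        """Serialize to the interchange JSON schema (0-based ids)."""
        obj = {
            "meta": {
                "lattice_type": self.lattice_type,
                "cell_size": self.cell_size,
                "prestrain": self.prestrain,
                "bounding_box": [self.bounding_box[0].tolist(),
                                 self.bounding_box[1].tolist()],
                "needs_equilibration": self.needs_equilibration,
            },
            "nodes": {
                "position": self.positions.tolist(),
                "role": [_ROLE_NAMES[r] for r in self.node_role],
                "is_boundary": self.node_is_boundary.tolist(),
            },
            "springs": {
                "endpoints": self.spring_endpoints.tolist(),
                "rest_length": self.spring_L0.tolist(),
                "kind": [_KIND_NAMES[k] for k in self.spring_kind],
                "stiffness": self.spring_k.tolist(),
                "broken": self.spring_broken.tolist(),
            },
            "faces": [
                {"vertex_nodes": f.vertex_nodes, "center_node": f.center_node,
                 "face_springs": f.face_springs, "adjacent_cells": f.adjacent_cells,
                 "removed": f.removed, "is_boundary": f.is_boundary}
                for f in self.faces
            ],
            "cells": [
                {"faces": c.faces, "lattice_index": list(c.lattice_index)}
                for c in self.cells
            ],
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        obj = json.loads(text)
        net = cls()
        meta = obj["meta"]
        net.lattice_type = meta["lattice_type"]
        net.cell_size = meta["cell_size"]
        net.prestrain = meta["prestrain"]
        net.bounding_box = (np.array(meta["bounding_box"][0]),
                            np.array(meta["bounding_box"][1]))
        net.needs_equilibration = meta.get("needs_equilibration", False)
        role_codes = {v: k for k, v in _ROLE_NAMES.items()}
        kind_codes = {v: k for k, v in _KIND_NAMES.items()}
        net.positions = np.array(obj["nodes"]["position"], dtype=float)
        net.node_role = np.array([role_codes[r] for r in obj["nodes"]["role"]],
                                 dtype=np.uint8)
        net.node_is_boundary = np.array(obj["nodes"]["is_boundary"], dtype=bool)
        net.spring_endpoints = np.array(obj["springs"]["endpoints"], dtype=np.int64)
        net.spring_L0 = np.array(obj["springs"]["rest_length"], dtype=float)
        net.spring_kind = np.array([kind_codes[k] for k in obj["springs"]["kind"]],
                                   dtype=np.uint8)
        net.spring_k = np.array(obj["springs"]["stiffness"], dtype=float)
        net.spring_broken = np.array(obj["springs"]["broken"], dtype=bool)
        net.faces = [Face(i, f["vertex_nodes"], f["center_node"], f["face_springs"],
                          f["adjacent_cells"], f["removed"], f["is_boundary"])
                     for i, f in enumerate(obj["faces"])]
        net.cells = [Cell(i, c["faces"], tuple(c["lattice_index"]))
                     for i, c in enumerate(obj["cells"])]
        net._rebuild_edge_map()
        return net

    def _rebuild_edge_map(self) -> None:
        edge_spring = {}
        for s in range(self.n_springs):
            if self.spring_kind[s] == KIND_EDGE:
                i, j = self.spring_endpoints[s]
                edge_spring[(min(i, j), max(i, j))] = s
        self.edge_map = {e: (s, set()) for e, s in edge_spring.items()}
        for f in self.faces:
            vs = f.vertex_nodes
            for t in range(len(vs)):
                u, v = vs[t], vs[(t + 1) % len(vs)]
                key = (min(u, v), max(u, v))
                self.edge_map[key][1].add(f.id)


# ============================================================= cubic builder

def _as_dims(n_cells_per_side) -> tuple[int, int, int]:
    if np.isscalar(n_cells_per_side):
        n = int(n_cells_per_side)
        dims = (n, n, n)
    else:
        dims = tuple(int(v) for v in n_cells_per_side)
        if len(dims) != 3:
            raise ValueError("n_cells_per_side must be an int or a 3-tuple")
    if any(d < 1 for d in dims):
        raise ValueError("cell counts must be positive")
    return dims


def build_cubic_network(n_cells_per_side, cell_size: float = 1.0) -> Network:
    """Build an intact block of cubic cells.

    Parameters
    ----------
    n_cells_per_side : int or (nx, ny, nz)
        Number of cells along each axis (a scalar builds an n³ block).
    cell_size : float
        Edge length of one cell in model length units.

    For an n³ block the construction yields n³ cells, 3n²(n+1) faces,
    3n(n+1)² edge springs and 4 face springs per face; n = 8 reproduces the
    512-cell, 1728-face, 8856-spring reference system.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx, ny, nz = _as_dims(n_cells_per_side)

    net = Network()
    net.cell_size = float(cell_size)
    net.lattice_type = "cubic"

    # vertex grid
    shape = (nx + 1, ny + 1, nz + 1)
    vid = np.arange(np.prod(shape)).reshape(shape)
    grid = np.stack(np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                                np.arange(nz + 1), indexing="ij"), axis=-1)
    vpos = grid.reshape(-1, 3).astype(float) * cell_size

    vertex_boundary = ((grid[..., 0] == 0) | (grid[..., 0] == nx) |
                       (grid[..., 1] == 0) | (grid[..., 1] == ny) |
                       (grid[..., 2] == 0) | (grid[..., 2] == nz)).reshape(-1)

    dims = (nx, ny, nz)
    faces: list[Face] = []
    centers: list[np.ndarray] = []
    center_boundary: list[bool] = []
    face_lookup = {}  # (axis, i, j, k) -> face id

    def vert(i, j, k):
        return int(vid[i, j, k])

    for axis in range(3):
        a, b = [d for d in range(3) if d != axis]
        for ia in range(dims[axis] + 1):
            for ib in range(dims[a]):
                for ic in range(dims[b]):
                    idx = [0, 0, 0]
                    idx[axis] = ia
                    loop = []
                    for da, db in ((0, 0), (1, 0), (1, 1), (0, 1)):
                        idx[a] = ib + da
                        idx[b] = ic + db
                        loop.append(vert(*idx))
                    fid = len(faces)
                    is_bnd = ia == 0 or ia == dims[axis]
                    faces.append(Face(fid, loop, -1, [], [], False, is_bnd))
                    centers.append(vpos[loop].mean(axis=0))
                    center_boundary.append(is_bnd)
                    face_lookup[(axis, ia, ib, ic)] = fid

    # cells
    cells: list[Cell] = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cid = len(cells)
                fids = [
                    face_lookup[(0, i, j, k)], face_lookup[(0, i + 1, j, k)],
                    face_lookup[(1, j, i, k)], face_lookup[(1, j + 1, i, k)],
                    face_lookup[(2, k, i, j)], face_lookup[(2, k + 1, i, j)],
                ]
                cells.append(Cell(cid, fids, (i, j, k)))
                for fid in fids:
                    faces[fid].adjacent_cells.append(cid)

    _assemble(net, vpos, vertex_boundary, centers, center_boundary, faces, cells,
              lo=np.zeros(3), hi=np.array(dims, dtype=float) * cell_size)
    return net


# ======================================================== 14-hedron builder

def _canonical_tkd_faces():
    """Face loops of the truncated octahedron with vertices perm(0, ±1, ±2).

    Returns a list of vertex-coordinate loops (tuples of int 3-tuples), each
    ordered around the face.  6 squares + 8 hexagons.
    """
    verts = set()
    from itertools import permutations
    for p in permutations((0, 1, 2)):
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    v = (p[0] * sx, p[1] * sy, p[2] * sz)
                    verts.add(v)
    verts = sorted(verts)

    def order_loop(pts, normal):
        c = np.mean(pts, axis=0)
        normal = np.asarray(normal, dtype=float)
        normal /= np.linalg.norm(normal)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        ang = [np.arctan2(np.dot(p - c, w), np.dot(p - c, u)) for p in pts]
        return [tuple(int(round(x)) for x in p)
                for _, p in sorted(zip(ang, pts), key=lambda t: t[0])]

    loops = []
    for axis in range(3):
        for s in (1, -1):
            pts = [np.array(v, dtype=float) for v in verts if v[axis] * s == 2]
            loops.append(order_loop(pts, np.eye(3)[axis] * s))
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                nrm = (sx, sy, sz)
                pts = [np.array(v, dtype=float) for v in verts
                       if v[0] * sx + v[1] * sy + v[2] * sz == 3]
                loops.append(order_loop(pts, nrm))
    return loops


def _clip_loop(loop, normal, d, tol=1e-9):
    """Sutherland–Hodgman clip of one polygon against half-space n·x <= d."""
    out = []
    m = len(loop)
    for t in range(m):
        p = np.asarray(loop[t], dtype=float)
        q = np.asarray(loop[(t + 1) % m], dtype=float)
        dp = float(np.dot(normal, p)) - d
        dq = float(np.dot(normal, q)) - d
        if dp <= tol:
            out.append(p)
        if (dp < -tol and dq > tol) or (dp > tol and dq < -tol):
            t_ = dp / (dp - dq)
            out.append(p + t_ * (q - p))
    return out


def _dedupe_loop(loop, tol=1e-7):
    res = []
    for p in loop:
        if not res or np.linalg.norm(p - res[-1]) > tol:
            res.append(p)
    if len(res) > 1 and np.linalg.norm(res[0] - res[-1]) <= tol:
        res.pop()
    return res


def _poly_area(loop):
    if len(loop) < 3:
        return 0.0
    c = np.mean(loop, axis=0)
    area = np.zeros(3)
    for t in range(len(loop)):
        area += np.cross(loop[t] - c, loop[(t + 1) % len(loop)] - c)
    return 0.5 * float(np.linalg.norm(area))


def _clip_convex_cell(face_loops, planes, tol=1e-9):
    """Clip a convex polyhedron (list of oriented face loops) by half-spaces.

    ``planes`` is a list of (normal, d) with the kept region n·x <= d.  After
    each clip the cut is capped with a new polygon so the cell stays closed.
    """
    loops = [[np.asarray(p, dtype=float) for p in lp] for lp in face_loops]
    for normal, d in planes:
        normal = np.asarray(normal, dtype=float)
        new_loops = []
        cap_pts = []
        for lp in loops:
            cl = _dedupe_loop(_clip_loop(lp, normal, d, tol))
            if len(cl) >= 3 and _poly_area(cl) > 1e-9:
                new_loops.append(cl)
                for p in cl:
                    if abs(float(np.dot(normal, p)) - d) <= 1e-7:
                        cap_pts.append(p)
        if cap_pts:
            # deduplicate and order the cap polygon by angle about its centroid
            uniq = []
            for p in cap_pts:
                if all(np.linalg.norm(p - q) > 1e-7 for q in uniq):
                    uniq.append(p)
            if len(uniq) >= 3:
                c = np.mean(uniq, axis=0)
                nrm = normal / np.linalg.norm(normal)
                ref = np.array([1.0, 0.0, 0.0])
                if abs(np.dot(ref, nrm)) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                u = np.cross(nrm, ref)
                u /= np.linalg.norm(u)
                w = np.cross(nrm, u)
                ang = [np.arctan2(float(np.dot(p - c, w)), float(np.dot(p - c, u)))
                       for p in uniq]
                cap = [p for _, p in sorted(zip(ang, uniq), key=lambda t: t[0])]
                if _poly_area(cap) > 1e-9:
                    new_loops.append(cap)
        loops = new_loops
    return loops


def build_tkd_network(n_cells_per_side, cell_size: float = 1.0) -> Network:
    """Build a block of tetrakaidecahedral (truncated-octahedron) cells.

    The 14-hedra sit on a body-centred lattice; cells whose centres fall
    outside the cuboid are discarded and cells straddling the surface are
    clipped to it, gaining cap faces on the box planes.  Interior cells have
    the full 14 faces (6 squares, 8 regular hexagons).  ``cell_size`` is the
    cube-equivalent edge length: one full cell has volume ``cell_size**3``.

    An n-per-side block contains n³ full body-centred cells plus (n+1)³
    (possibly clipped) corner-lattice cells.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx, ny, nz = _as_dims(n_cells_per_side)

    canon = _canonical_tkd_faces()
    L = 4.0  # lattice constant of the natural tiling; cell volume 32
    box_hi = np.array([nx, ny, nz], dtype=float) * L
    planes = []
    for axis in range(3):
        e = np.eye(3)[axis]
        planes.append((-e, 0.0))
        planes.append((e, box_hi[axis]))

    centers3 = []
    for i in range(nx + 1):
        for j in range(ny + 1):
            for k in range(nz + 1):
                centers3.append((np.array([i, j, k], dtype=float) * L, (i, j, k)))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                centers3.append((np.array([i + 0.5, j + 0.5, k + 0.5]) * L,
                                 (i, j, k)))

    scale = cell_size / 32.0 ** (1.0 / 3.0)

    key_of = {}
    vpos_list = []

    def node_key(p):
        key = tuple(np.round(p, 6))
        if key not in key_of:
            key_of[key] = len(vpos_list)
            vpos_list.append(np.asarray(key, dtype=float))
        return key_of[key]

    faces: list[Face] = []
    cells: list[Cell] = []
    face_by_vset = {}

    for center, lidx in centers3:
        cell_loops = [[np.asarray(p, dtype=float) + center for p in lp]
                      for lp in canon]
        needs_clip = any(
            min(p[axis] for lp in cell_loops for p in lp) < -1e-9 or
            max(p[axis] for lp in cell_loops for p in lp) > box_hi[axis] + 1e-9
            for axis in range(3))
        if needs_clip:
            cell_loops = _clip_convex_cell(cell_loops, planes)
        if not cell_loops:
            continue
        cid = len(cells)
        fids = []
        for lp in cell_loops:
            vids = [node_key(p) for p in lp]
            vset = frozenset(vids)
            if vset in face_by_vset:
                fid = face_by_vset[vset]
                faces[fid].adjacent_cells.append(cid)
            else:
                fid = len(faces)
                face_by_vset[vset] = fid
                faces.append(Face(fid, vids, -1, [], [cid], False, False))
            fids.append(fid)
        cells.append(Cell(cid, fids, lidx))

    vpos = np.array(vpos_list)
    on_surface = np.zeros(len(vpos), dtype=bool)
    for axis in range(3):
        on_surface |= np.abs(vpos[:, axis]) <= 1e-7
        on_surface |= np.abs(vpos[:, axis] - box_hi[axis]) <= 1e-7

    centers = []
    center_boundary = []
    for f in faces:
        f.is_boundary = len(f.adjacent_cells) == 1
        centers.append(vpos[f.vertex_nodes].mean(axis=0))
        center_boundary.append(f.is_boundary)

    net = Network()
    net.cell_size = float(cell_size)
    net.lattice_type = "tkd"
    _assemble(net, vpos * scale, on_surface, [c * scale for c in centers],
              center_boundary, faces, cells, lo=np.zeros(3), hi=box_hi * scale)
    return net


# =============================================================== assembly

def _assemble(net, vpos, vertex_boundary, centers, center_boundary,
              faces, cells, lo, hi):
    """Wire vertices + face centres + springs into ``net`` (shared by builders)."""
    n_vertex = len(vpos)
    centers = np.array(centers).reshape(-1, 3)
    net.positions = np.vstack([vpos, centers])
    net.node_role = np.concatenate([
        np.full(n_vertex, ROLE_VERTEX, dtype=np.uint8),
        np.full(len(centers), ROLE_FACE_CENTER, dtype=np.uint8)])
    net.node_is_boundary = np.concatenate([
        np.asarray(vertex_boundary, dtype=bool),
        np.asarray(center_boundary, dtype=bool)])

    endpoints = []
    kinds = []
    # face springs: centre -> each vertex, in face order
    for f in faces:
        f.center_node = n_vertex + f.id
        f.face_springs = []
        for v in f.vertex_nodes:
            f.face_springs.append(len(endpoints))
            endpoints.append((f.center_node, v))
            kinds.append(KIND_FACE)
    # edge springs: one per distinct geometric edge
    edge_faces: dict[tuple[int, int], set[int]] = {}
    for f in faces:
        vs = f.vertex_nodes
        for t in range(len(vs)):
            u, v = vs[t], vs[(t + 1) % len(vs)]
            key = (min(u, v), max(u, v))
            edge_faces.setdefault(key, set()).add(f.id)
    edge_map = {}
    for key in sorted(edge_faces):
        sid = len(endpoints)
        endpoints.append(key)
        kinds.append(KIND_EDGE)
        edge_map[key] = (sid, edge_faces[key])

    net.spring_endpoints = np.array(endpoints, dtype=np.int64)
    net.spring_kind = np.array(kinds, dtype=np.uint8)
    d = net.positions[net.spring_endpoints[:, 0]] - \
        net.positions[net.spring_endpoints[:, 1]]
    net.spring_L0 = np.linalg.norm(d, axis=1)
    if np.any(net.spring_L0 <= 0):
        raise RuntimeError("degenerate spring of zero length")
    net.spring_k = np.ones(len(endpoints))
    net.spring_broken = np.zeros(len(endpoints), dtype=bool)
    net.faces = faces
    net.cells = cells
    net.edge_map = edge_map
    net.bounding_box = (np.asarray(lo, dtype=float), np.asarray(hi, dtype=float))
    net.prestrain = 1.0
    net.needs_equilibration = False
    net._incidence = None


# ============================================================== prestrain

def apply_prestrain(network: Network, expansion_factor: float) -> Network:
    """Uniformly expand the network about the box centre.

    Rest lengths are unchanged, so every spring acquires strain
    ``expansion_factor - 1`` (for a previously unstrained block).  Boundary
    nodes are already flagged and stay fixed under the fixed-boundary
    condition; the network is marked as needing re-equilibration.  Tension-only
    springs require net extension, hence ``expansion_factor > 1``.
    """
    if expansion_factor <= 1.0:
        raise ValueError("expansion_factor must exceed 1 "
                         "(springs do not support compression)")
    lo, hi = network.bounding_box
    center = 0.5 * (lo + hi)
    network.positions = center + expansion_factor * (network.positions - center)
    network.bounding_box = (center + expansion_factor * (lo - center),
                            center + expansion_factor * (hi - center))
    network.prestrain *= expansion_factor
    network.needs_equilibration = True
    return network
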