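"""Alveolar-wall destruction policies and the step-wise destruction loop.

Walls (internal faces) are removed a fixed number per step, chosen either
uniformly at random, by highest carried force (mimicking mechanical rupture of
enzymatically weakened septa), or by a mixture of the two.  The first step of
a force-based process is spatially random — the initial seed of destruction —
after which the force rule takes over and the damage history shapes where the
load concentrates.  Removing a face breaks its face springs; an edge spring is
broken once every wall adjoining that edge is gone.

:func:`run_destruction` drives select → remove → re-equilibrate → measure
until the stiffness has dropped to the target fraction, returning one
:class:`Trajectory` row per step (airspace-volume moments and normalized bulk
modulus), fully reproducible from the policy seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import Network
from .mechanics import (
    BoundaryCondition,
    ConstitutiveParams,
    EquilibriumCriteria,
    equilibrate,
    spring_tensions,
)
from .measure import (
    airspace_clusters,
    bulk_modulus,
    default_probe_pressure,
    volume_moments,
)

__all__ = [
    "DestructionPolicy",
    "Trajectory",
    "face_load",
    "face_loads",
    "select_faces",
    "remove_faces",
    "run_destruction",
]

MOMENT_COLUMNS = ["mu", "m2", "m3", "m4"]


@dataclass
class DestructionPolicy:
    """Which walls to remove per step.

    pattern : {"random", "force", "mixed"}
    faces_per_step : Nf, walls removed per step.
    force_fraction : r in [0, 1]; fraction of Nf removed by force in the
        mixed pattern (r=1 reduces to force, r=0 to random).
    seed : RNG seed for the policy's random choices.
    load_aggregate : {"sum", "mean", "max"} — how face-spring tensions are
        aggregated into the force carried by a wall.
    """

    pattern: str = "force"
    faces_per_step: int = 4
    force_fraction: float = 1.0
    seed: int = 0
    load_aggregate: str = "sum"

    def __post_init__(self):
        if self.pattern not in ("random", "force", "mixed"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.faces_per_step < 1:
            raise ValueError("faces_per_step must be positive")
        if not 0.0 <= self.force_fraction <= 1.0:
            raise ValueError("force_fraction must lie in [0, 1]")
        if self.load_aggregate not in ("sum", "mean", "max"):
            raise ValueError(f"unknown aggregate {self.load_aggregate!r}")


def face_loads(net: Network, params: ConstitutiveParams | None = None,
               aggregate: str = "sum") -> np.ndarray:
    """Force carried by every face: aggregated unbroken face-spring tensions.

    Removed faces report 0 (they carry nothing); slack faces report 0.
    """
    inc = net.incidence()
    t = spring_tensions(net, params)[inc["fs_spring"]]
    loads = np.zeros(net.n_faces)
    if aggregate == "sum":
        np.add.at(loads, inc["fs_face"], t)
    elif aggregate == "mean":
        np.add.at(loads, inc["fs_face"], t)
        cnt = np.zeros(net.n_faces)
        np.add.at(cnt, inc["fs_face"], 1.0)
        loads = loads / np.maximum(cnt, 1.0)
    else:
        np.maximum.at(loads, inc["fs_face"], t)
    return loads


def face_load(net: Network, face_id: int,
              params: ConstitutiveParams | None = None,
              aggregate: str = "sum") -> float:
    """Force carried by one (not removed) wall."""
    face = net.faces[face_id]
    if face.removed:
        raise ValueError(f"face {face_id} has been removed")
    return float(face_loads(net, params, aggregate)[face_id])


def _eligible_faces(net: Network) -> np.ndarray:
    return np.array([f.id for f in net.faces
                     if not f.is_boundary and not f.removed], dtype=np.int64)


class NetworkExhausted(RuntimeError):
    """Fewer eligible internal faces remain than the policy needs."""


def select_faces(net: Network, policy: DestructionPolicy, step_index: int,
                 rng: np.random.Generator,
                 params: ConstitutiveParams | None = None) -> list[int]:
    """Choose the walls to remove at this step.

    random — Nf eligible faces uniformly without replacement.
    force — spatially random at step 0 (the initial seed of destruction),
        thereafter the Nf highest-load eligible faces, ties broken by the
        seeded RNG.
    mixed — round(r·Nf) by force and the remainder randomly (also fully
        random at step 0), without duplicates.
    """
    nf = policy.faces_per_step
    eligible = _eligible_faces(net)
    if len(eligible) < nf:
        raise NetworkExhausted(
            f"{len(eligible)} eligible faces < faces_per_step={nf}")

    if policy.pattern == "random":
        n_force = 0
    elif policy.pattern == "force":
        n_force = nf
    else:
        n_force = int(round(policy.force_fraction * nf))
    if step_index == 0:
        n_force = 0

    chosen: list[int] = []
    if n_force > 0:
        loads = face_loads(net, params, policy.load_aggregate)[eligible]
        order = np.lexsort((rng.random(len(eligible)), loads))
        chosen.extend(int(f) for f in eligible[order[-n_force:]])
    n_rand = nf - len(chosen)
    if n_rand > 0:
        rest = eligible[~np.isin(eligible, chosen)]
        chosen.extend(int(f) for f in rng.choice(rest, n_rand, replace=False))
    return chosen


def remove_faces(net: Network, face_ids) -> Network:
    """Remove walls: break their face springs and prune orphaned edge springs.

    A boundary face cannot be removed (the exterior must stay watertight);
    an edge spring is broken when all faces adjoining its edge are removed.
    """
    for fid in face_ids:
        face = net.faces[fid]
        if face.is_boundary:
            raise ValueError(f"face {fid} is a boundary face")
        if face.removed:
            raise ValueError(f"face {fid} already removed")
    to_break: list[int] = []
    for fid in face_ids:
        face = net.faces[fid]
        face.removed = True
        to_break.extend(face.face_springs)
    for fid in face_ids:
        vs = net.faces[fid].vertex_nodes
        for t in range(len(vs)):
            u, v = vs[t], vs[(t + 1) % len(vs)]
            sid, adjoining = net.edge_map[(min(u, v), max(u, v))]
            if all(net.faces[g].removed for g in adjoining):
                to_break.append(sid)
    if to_break:
        net.break_springs(sorted(set(to_break)))
    return net


@dataclass
class Trajectory:
    """Per-step record of one destruction run plus its manifest."""

    data: pd.DataFrame
    manifest: dict

    @property
    def label(self) -> str:
        return self.manifest.get("label", "run")

    @property
    def moments(self) -> pd.DataFrame:
        return self.data[MOMENT_COLUMNS]

    @property
    def k_ratio(self) -> pd.Series:
        return self.data["K_over_K0"]

    def save(self, csv_path, manifest_path=None) -> None:
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        mpath = Path(manifest_path) if manifest_path else \
            csv_path.with_suffix(".manifest.json")
        mpath.write_text(json.dumps(self.manifest, indent=1))

    @classmethod
    def load(cls, csv_path, manifest_path=None) -> "Trajectory":
        csv_path = Path(csv_path)
        data = pd.read_csv(csv_path)
        mpath = Path(manifest_path) if manifest_path else \
            csv_path.with_suffix(".manifest.json")
        manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
        return cls(data, manifest)


def run_destruction(net: Network, policy: DestructionPolicy,
                    params: ConstitutiveParams | None = None,
                    criteria: EquilibriumCriteria | None = None,
                    delta_P: float | None = None,
                    method: str = "lbfgs",
                    stop_k_ratio: float = 0.3,
                    max_steps: int = 400,
                    max_faces: int | None = None,
                    measure_modulus: bool = True,
                    stop_at_single_cluster: bool = True,
                    label: str | None = None) -> Trajectory:
    """Run a full destruction simulation on a prestrained network.

    Per step: select walls → remove → re-equilibrate (fixed boundary) →
    measure airspace clusters, their volume moments and (optionally) the bulk
    modulus.  Stops when K/K0 <= ``stop_k_ratio``, when ``max_faces`` walls
    have been removed, when the eligible walls are exhausted, or when all
    cells have merged into a single airspace (no volume distribution is left
    to track).  The step-0 row records the intact pre-strained state.
    """
    params = params or ConstitutiveParams()
    criteria = criteria or EquilibriumCriteria()
    rng = np.random.default_rng(policy.seed)
    if delta_P is None:
        delta_P = default_probe_pressure(net, params)

    if net.needs_equilibration:
        equilibrate(net, BoundaryCondition.fixed(), criteria, params, method)

    v_ref = net.box_volume / net.n_cells  # initial single-cell volume scale
    rows = []
    K0 = None

    def measure(step, removed_step, removed_total, eq_ok):
        nonlocal K0
        clusters = airspace_clusters(net)
        mu, m2, m3, m4 = volume_moments(clusters, v_ref)
        row = {"step": step, "faces_removed_step": removed_step,
               "faces_removed_cumulative": removed_total,
               "n_clusters": len(clusters),
               "mu": mu, "m2": m2, "m3": m3, "m4": m4,
               "equilibrium_converged": eq_ok}
        if measure_modulus:
            meas = bulk_modulus(net, delta_P, criteria, params, method)
            if K0 is None:
                K0 = meas.K
            row["K"] = meas.K
            row["K_over_K0"] = meas.K / K0
            row["probe_converged"] = meas.converged
        rows.append(row)
        return row

    measure(0, 0, 0, True)
    removed_total = 0
    for step in range(1, max_steps + 1):
        try:
            fids = select_faces(net, policy, step - 1, rng, params)
        except NetworkExhausted:
            break
        remove_faces(net, fids)
        removed_total += len(fids)
        rep = equilibrate(net, BoundaryCondition.fixed(), criteria, params,
                          method)
        row = measure(step, len(fids), removed_total, rep.converged)
        if measure_modulus and row["K_over_K0"] <= stop_k_ratio:
            break
        if stop_at_single_cluster and row["n_clusters"] <= 1:
            break       # fully merged: no airspace-volume distribution left
        if max_faces is not None and removed_total >= max_faces:
            break

    manifest = {
        "label": label or f"{policy.pattern}-{policy.seed}",
        "policy": asdict(policy),
        "params": asdict(params),
        "lattice_type": net.lattice_type,
        "n_cells": net.n_cells,
        "prestrain": net.prestrain,
        "delta_P": delta_P,
        "stop_k_ratio": stop_k_ratio,
        "method": method,
    }
    return Trajectory(pd.DataFrame(rows), manifest)
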