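"""Standard simulation scenarios and the pooled structure-function analysis.

The base experiment is a 6-per-side cubic block at pre-strain 1.2 with
Nf = 4 walls removed per step, run to K/K0 ≈ 0.3, replicated with several
seeds for the random and the force-based patterns.  Held-out variants probe
the generality of the fitted stiffness plane: force-based destruction at 1.5×
higher pre-strain (strain 0.2 → 0.3), on a 14-hedral lattice, on a smaller
128-cell block, with nonlinear (power-law) springs, a mixed pattern with
force fraction r = 0.1 (Nf = 10 so that one wall per step is load-selected),
and random destruction at the higher pre-strain.

:func:`run_suite` executes the whole set reproducibly from one master seed;
:func:`standard_analysis` fits the KL basis and stiffness plane on the pooled
base runs and cross-evaluates every run against them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lattice import apply_prestrain, build_cubic_network, build_tkd_network
from .mechanics import (
    BoundaryCondition,
    ConstitutiveParams,
    EquilibriumCriteria,
    equilibrate,
)
from .destruction import DestructionPolicy, Trajectory, run_destruction
from .structfn import MomentMatrix, crossfit_evaluation, kl_basis

__all__ = [
    "ScenarioSpec",
    "base_scenarios",
    "heldout_scenarios",
    "build_scenario_network",
    "run_scenario",
    "run_suite",
    "standard_analysis",
    "contrast_ensemble",
    "destruction_contrast",
    "faces_to_reach",
]

BASE_PRESTRAIN = 1.2
HIGH_PRESTRAIN = 1.3          # 1.5x higher pre-strain: ε0 = 0.2 -> 0.3


@dataclass(frozen=True)
class ScenarioSpec:
    """One destruction experiment: lattice, pre-strain, springs and policy."""

    label: str
    lattice: str = "cubic"            # "cubic" or "tkd"
    dims: tuple = (6, 6, 6)
    prestrain: float = BASE_PRESTRAIN
    pattern: str = "force"
    faces_per_step: int = 4
    force_fraction: float = 1.0
    law: str = "linear"
    group: str = "base"               # base | heldout_correlated | heldout_random


def base_scenarios(n_random: int = 3, n_force: int = 3,
                   n_side: int = 6) -> list[ScenarioSpec]:
    """The pooled random + force-based ensemble the basis/plane is fit on."""
    out = []
    for i in range(n_random):
        out.append(ScenarioSpec(f"random-{i}", dims=(n_side,) * 3,
                                pattern="random", group="base"))
    for i in range(n_force):
        out.append(ScenarioSpec(f"force-{i}", dims=(n_side,) * 3,
                                pattern="force", group="base"))
    return out


def heldout_scenarios(n_side: int = 6) -> list[ScenarioSpec]:
    """Generalization variants projected onto the fixed base basis/plane."""
    d = (n_side,) * 3
    return [
        ScenarioSpec("force-hi-prestrain", dims=d, prestrain=HIGH_PRESTRAIN,
                     pattern="force", group="heldout_correlated"),
        ScenarioSpec("force-tkd", lattice="tkd", dims=(3, 3, 3),
                     pattern="force", group="heldout_correlated"),
        ScenarioSpec("force-128", dims=(4, 4, 8), pattern="force",
                     group="heldout_correlated"),
        ScenarioSpec("force-nonlinear", dims=d, law="power", pattern="force",
                     group="heldout_correlated"),
        ScenarioSpec("mixed-r0.1", dims=d, pattern="mixed",
                     faces_per_step=10, force_fraction=0.1,
                     group="heldout_correlated"),
        ScenarioSpec("random-hi-prestrain", dims=d, prestrain=HIGH_PRESTRAIN,
                     pattern="random", group="heldout_random"),
    ]


def build_scenario_network(spec: ScenarioSpec, criteria=None, params=None):
    """Build, pre-strain and equilibrate the scenario's intact network."""
    if spec.lattice == "cubic":
        net = build_cubic_network(spec.dims)
    elif spec.lattice == "tkd":
        net = build_tkd_network(spec.dims)
    else:
        raise ValueError(f"unknown lattice {spec.lattice!r}")
    apply_prestrain(net, spec.prestrain)
    equilibrate(net, BoundaryCondition.fixed(),
                criteria or EquilibriumCriteria(),
                params or ConstitutiveParams(law=spec.law))
    return net


def run_scenario(spec: ScenarioSpec, seed: int,
                 stop_k_ratio: float = 0.3, max_steps: int = 400,
                 criteria: EquilibriumCriteria | None = None) -> Trajectory:
    """Run one scenario end to end, reproducibly from ``seed``."""
    params = ConstitutiveParams(law=spec.law)
    criteria = criteria or EquilibriumCriteria()
    net = build_scenario_network(spec, criteria, params)
    policy = DestructionPolicy(pattern=spec.pattern,
                               faces_per_step=spec.faces_per_step,
                               force_fraction=spec.force_fraction,
                               seed=int(seed))
    return run_destruction(net, policy, params, criteria,
                           stop_k_ratio=stop_k_ratio, max_steps=max_steps,
                           label=spec.label)


def _scenario_seed(master_seed: int, label: str) -> int:
    """Stable per-scenario seed below 2**31 derived from the master seed."""
    import zlib
    h = np.random.SeedSequence(
        [int(master_seed) % (2 ** 31),
         zlib.crc32(label.encode()) % (2 ** 31)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def run_suite(seed: int, n_random: int = 3, n_force: int = 3,
              n_side: int = 6, include_heldout: bool = True,
              stop_k_ratio: float = 0.3, progress=None) -> dict[str, Trajectory]:
    """Run the base ensemble (and optionally the held-out variants).

    Every scenario gets its own sub-seed derived from ``seed``, so the whole
    suite is reproducible from a single integer.
    """
    specs = base_scenarios(n_random, n_force, n_side)
    if include_heldout:
        specs += heldout_scenarios(n_side)
    out: dict[str, Trajectory] = {}
    for spec in specs:
        if progress:
            progress(spec.label)
        out[spec.label] = run_scenario(spec, _scenario_seed(seed, spec.label),
                                       stop_k_ratio=stop_k_ratio)
    return out


def standard_analysis(runs: dict[str, Trajectory]) -> dict:
    """Basis + plane from the base runs, cross-evaluation of everything.

    Returns the crossfit result augmented with the pooled two-component
    explained-variance percentage and the per-group error bounds.
    """
    base = [lab for lab, t in runs.items()
            if t.manifest.get("label", lab).startswith(("random-", "force-"))
            and runs[lab] is not None and _group_of(lab) == "base"]
    if not base:
        raise ValueError("no base runs (labels random-i / force-i) found")
    res = crossfit_evaluation(runs, basis_source=base)
    explained = res["basis"].explained_fraction
    res["explained_two_pct"] = float(100.0 * explained[:2].sum())

    summary = res["summary"]
    correlated = [lab for lab in runs if _group_of(lab) == "heldout_correlated"]
    if correlated:
        res["max_error_correlated_pct"] = float(
            summary.loc[correlated, "max"].max())
    res["max_median_error_pct"] = float(summary["median"].max())
    return res


def contrast_ensemble(seed: int, n_each: int = 3, n_side: int = 6,
                      stop_k_ratio: float = 0.35,
                      progress=None) -> dict[str, Trajectory]:
    """Force vs random ensembles run far enough to cross K/K0 = 0.4.

    Unlike the structure-function suite these runs do not stop when the block
    merges into one airspace (random destruction typically does so while
    still fairly stiff), because the destruction-pattern contrast is about
    the stiffness-vs-walls-removed curve, not the volume distribution.
    """
    out = {}
    for pattern in ("force", "random"):
        for i in range(n_each):
            label = f"contrast-{pattern}-{i}"
            if progress:
                progress(label)
            spec = ScenarioSpec(label, dims=(n_side,) * 3, pattern=pattern)
            params = ConstitutiveParams()
            net = build_scenario_network(spec, params=params)
            policy = DestructionPolicy(pattern=pattern, faces_per_step=4,
                                       seed=_scenario_seed(seed, label))
            out[label] = run_destruction(
                net, policy, params, stop_k_ratio=stop_k_ratio,
                stop_at_single_cluster=False, label=label)
    return out


def faces_to_reach(traj: Trajectory, k_target: float) -> float | None:
    """Removed-wall count at which K/K0 first crosses ``k_target``
    (linear interpolation between steps); None if never reached."""
    k = traj.data["K_over_K0"].to_numpy()
    f = traj.data["faces_removed_cumulative"].to_numpy()
    below = np.flatnonzero(k <= k_target)
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return float(f[0])
    return float(f[i - 1] + (k[i - 1] - k_target) / (k[i - 1] - k[i])
                 * (f[i] - f[i - 1]))


def destruction_contrast(runs: dict[str, Trajectory], k_target: float = 0.4,
                         wall_fraction: float = 0.2) -> dict:
    """Pattern-contrast statistics on a force/random ensemble.

    Returns the ensemble-mean removed-wall counts at which each pattern
    reaches ``k_target``, their ratio (random / force), and the
    ensemble-mean airspace mean volume and volume variance at a matched
    wall count (``wall_fraction`` of the internal walls, i.e. within the
    growth phase, before random destruction merges the whole block).
    """
    force = [t for l, t in runs.items() if "force" in l]
    random_ = [t for l, t in runs.items() if "random" in l]
    f_cross = [faces_to_reach(t, k_target) for t in force]
    r_cross = [faces_to_reach(t, k_target) for t in random_]
    if any(c is None for c in f_cross + r_cross):
        raise ValueError("some runs never reached the target stiffness")

    def at_count(traj, n):
        d = traj.data
        i = int(np.argmin(np.abs(d["faces_removed_cumulative"].to_numpy() - n)))
        return d["mu"].iloc[i], d["m2"].iloc[i]

    n_internal = force[0].manifest.get("n_internal_faces")
    if n_internal is None:
        # 6-per-side cubic block: 3n^2(n+1) faces of which 6n^2 are boundary
        n = round(force[0].manifest["n_cells"] ** (1 / 3))
        n_internal = 3 * n * n * (n + 1) - 6 * n * n
    n_match = int(round(wall_fraction * n_internal))
    f_mu, f_m2 = np.mean([at_count(t, n_match) for t in force], axis=0)
    r_mu, r_m2 = np.mean([at_count(t, n_match) for t in random_], axis=0)
    return {
        "faces_force": float(np.mean(f_cross)),
        "faces_random": float(np.mean(r_cross)),
        "ratio": float(np.mean(r_cross) / np.mean(f_cross)),
        "matched_wall_count": n_match,
        "mu_force": float(f_mu), "mu_random": float(r_mu),
        "m2_force": float(f_m2), "m2_random": float(r_m2),
    }


def _group_of(label: str) -> str:
    if label.startswith(("random-hi", )):
        return "heldout_random"
    if label.startswith(("force-hi", "force-tkd", "force-128",
                         "force-nonlinear", "mixed")):
        return "heldout_correlated"
    return "base"
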