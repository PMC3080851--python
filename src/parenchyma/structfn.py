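"""Karhunen-Loève reduction of airspace-volume moments and the stiffness plane.

During a destruction run the four moments of the airspace-volume distribution
(mean μ and central moments m2-m4) evolve together; their cross-correlations
carry the signature of the spatial destruction pattern.  Stacking the moments
of one or more runs into a matrix M (one row per step), the eigenvectors of
the column covariance matrix give the KL (PCA) basis.  Empirically the first
two components capture essentially all the variability, so the structural
state reduces to the two projections (P1, P2), and the normalized bulk
modulus is estimated by the least-squares plane

    K̂/K0 = a·P1 + b·P2 + c.

Fitting the basis and the plane on base random + force-based trajectories and
projecting *new* runs (different lattice, prestrain, constitutive law or
mixed destruction) onto the same basis tests whether a single structure-
function plane generalizes; :func:`crossfit_evaluation` reproduces that
experiment and reports per-run relative-error summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOMENT_COLUMNS",
    "MomentMatrix",
    "KLBasis",
    "PlaneFit",
    "kl_basis",
    "project",
    "fit_plane",
    "estimation_error",
    "error_summary",
    "crossfit_evaluation",
    "StiffnessPlaneModel",
    "StiffnessPlaneResults",
]

MOMENT_COLUMNS = ["mu", "m2", "m3", "m4"]


@dataclass
class MomentMatrix:
    """Moment time-series matrix: one row per destruction step.

    ``data`` holds the four moment columns; ``run_ids`` tracks row provenance
    when several runs are pooled.
    """

    data: pd.DataFrame
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in MOMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"moment matrix lacks columns {missing}")
        self.data = self.data[MOMENT_COLUMNS].reset_index(drop=True)
        if self.data.isna().any().any():
            raise ValueError("moment matrix contains missing values")
        if not self.run_ids:
            self.run_ids = ["run"] * len(self.data)

    @classmethod
    def from_trajectories(cls, trajectories: dict) -> "MomentMatrix":
        frames, ids = [], []
        for label, traj in trajectories.items():
            m = traj.moments if hasattr(traj, "moments") else traj
            frames.append(m[MOMENT_COLUMNS])
            ids.extend([label] * len(m))
        return cls(pd.concat(frames, ignore_index=True), ids)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, MomentMatrix):
        return M.values
    if isinstance(M, pd.DataFrame):
        return M[MOMENT_COLUMNS].to_numpy(dtype=float)
    X = np.asarray(M, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2D moment matrix")
    return X


@dataclass
class KLBasis:
    """Eigenbasis of the moment covariance matrix.

    ``components[i]`` is the i-th eigenvector (descending eigenvalue order,
    sign fixed so each eigenvector's largest-magnitude entry is positive);
    ``means`` are the column means used for centering — projections of new
    data must reuse them.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    means: np.ndarray
    explained_fraction: np.ndarray


def kl_basis(M) -> KLBasis:
    """Column-centered covariance eigendecomposition of the moment matrix."""
    X = _as_matrix(M)
    if len(X) < 3:
        raise ValueError("need at least 3 rows to estimate the covariance")
    means = X.mean(axis=0)
    cov = np.cov(X - means, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    comps = evecs[:, order].T
    for i, v in enumerate(comps):            # deterministic sign convention
        if v[np.argmax(np.abs(v))] < 0:
            comps[i] = -v
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return KLBasis(comps, evals, means, frac)


def project(M, basis: KLBasis, n_components: int = 2) -> np.ndarray:
    """Project rows of M onto the leading basis vectors (centered with the
    basis means, which matters when projecting new runs on a fixed basis)."""
    X = _as_matrix(M)
    if X.shape[1] != basis.components.shape[1]:
        raise ValueError("column count does not match the basis")
    return (X - basis.means) @ basis.components[:n_components].T


@dataclass
class PlaneFit:
    """Least-squares plane K̂/K0 = a·P1 + b·P2 + c."""

    a: float
    b: float
    c: float
    rms_residual: float
    residuals: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def predict(self, P1, P2) -> np.ndarray:
        return self.a * np.asarray(P1) + self.b * np.asarray(P2) + self.c


def fit_plane(P1, P2, k_ratio) -> PlaneFit:
    """Minimum-mean-square-error plane through (P1, P2, K/K0)."""
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    y = np.asarray(k_ratio, dtype=float)
    if not (len(P1) == len(P2) == len(y)) or len(y) < 3:
        raise ValueError("need >= 3 equal-length series")
    A = np.column_stack([P1, P2, np.ones_like(P1)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("degenerate fit: (P1, P2) are collinear")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return PlaneFit(float(coef[0]), float(coef[1]), float(coef[2]),
                    float(np.sqrt(np.mean(resid ** 2))), resid)


def estimation_error(k_hat, k) -> np.ndarray:
    """Relative estimation error in percent: 100·|K̂ - K| / K."""
    k_hat = np.asarray(k_hat, dtype=float)
    k = np.asarray(k, dtype=float)
    if k_hat.shape != k.shape:
        raise ValueError("series must have equal length")
    if np.any(k <= 0):
        raise ValueError("true stiffness values must be positive")
    return 100.0 * np.abs(k_hat - k) / k


def error_summary(errors) -> dict:
    e = np.asarray(errors, dtype=float)
    return {"max": float(e.max()), "median": float(np.median(e)),
            "q1": float(np.percentile(e, 25)),
            "q3": float(np.percentile(e, 75)), "n": int(len(e))}


def _run_moments_k(run):
    if hasattr(run, "moments"):
        return run.moments, np.asarray(run.k_ratio, dtype=float)
    m, k = run
    return m, np.asarray(k, dtype=float)


def crossfit_evaluation(runs: dict, basis_source, fit_source=None) -> dict:
    """Fix basis and plane on some runs, evaluate the rest against them.

    ``runs`` maps labels to trajectories (or (moments, k_ratio) pairs);
    ``basis_source``/``fit_source`` are label subsets (fit defaults to the
    basis source).  Returns the basis, the plane and a per-run error-summary
    DataFrame (max/median/quartiles of the percent estimation error).
    """
    fit_source = list(fit_source or basis_source)
    basis_source = list(basis_source)
    for lab in set(basis_source) | set(fit_source):
        if lab not in runs:
            raise ValueError(f"unknown run label {lab!r}")

    pooled = pd.concat([_run_moments_k(runs[l])[0] for l in basis_source],
                       ignore_index=True)
    basis = kl_basis(pooled)

    P_fit, y_fit = [], []
    for lab in fit_source:
        m, k = _run_moments_k(runs[lab])
        P_fit.append(project(m, basis))
        y_fit.append(k)
    P_fit = np.vstack(P_fit)
    y_fit = np.concatenate(y_fit)
    plane = fit_plane(P_fit[:, 0], P_fit[:, 1], y_fit)

    records = []
    errors = {}
    for lab, run in runs.items():
        m, k = _run_moments_k(run)
        P = project(m, basis)
        err = estimation_error(plane.predict(P[:, 0], P[:, 1]), k)
        errors[lab] = err
        rec = {"run": lab, "in_fit": lab in fit_source, **error_summary(err)}
        records.append(rec)
    summary = pd.DataFrame(records).set_index("run")
    return {"basis": basis, "plane": plane, "summary": summary,
            "errors": errors}


# --------------------------------------------------------- model interface

class StiffnessPlaneModel:
    """Estimate normalized stiffness from airspace-volume moments.

    A thin model/results interface over :func:`kl_basis`, :func:`project` and
    :func:`fit_plane`: construct from the pooled moment matrix and the
    measured K/K0 series, call :meth:`fit`, then use the results object to
    predict the stiffness of new runs projected onto the same basis.
    """

    def __init__(self, moments, k_ratio, run_ids=None):
        self.M = moments if isinstance(moments, MomentMatrix) else \
            MomentMatrix(pd.DataFrame(np.asarray(moments, dtype=float),
                                      columns=MOMENT_COLUMNS)
                         if not isinstance(moments, pd.DataFrame) else moments,
                         list(run_ids) if run_ids is not None else [])
        self.k_ratio = np.asarray(k_ratio, dtype=float)
        if len(self.k_ratio) != len(self.M):
            raise ValueError("moments and k_ratio lengths differ")

    @classmethod
    def from_trajectories(cls, trajectories: dict) -> "StiffnessPlaneModel":
        M = MomentMatrix.from_trajectories(trajectories)
        k = np.concatenate([np.asarray(t.k_ratio, dtype=float)
                            for t in trajectories.values()])
        return cls(M, k, M.run_ids)

    def fit(self, n_components: int = 2) -> "StiffnessPlaneResults":
        if n_components != 2:
            raise ValueError("the stiffness estimator is a plane in (P1, P2)")
        basis = kl_basis(self.M)
        P = project(self.M, basis)
        plane = fit_plane(P[:, 0], P[:, 1], self.k_ratio)
        return StiffnessPlaneResults(self, basis, plane, P)


@dataclass
class StiffnessPlaneResults:
    model: StiffnessPlaneModel
    basis: KLBasis
    plane: PlaneFit
    projections: np.ndarray

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.plane.coefficients, index=["a", "b", "c"])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.plane.predict(self.projections[:, 0],
                                  self.projections[:, 1])

    @property
    def resid(self) -> np.ndarray:
        return self.plane.residuals

    @property
    def rsquared(self) -> float:
        y = self.model.k_ratio
        ss_res = float(np.sum(self.resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    def predict(self, moments) -> np.ndarray:
        P = project(moments, self.basis)
        return self.plane.predict(P[:, 0], P[:, 1])

    def summary(self) -> str:
        lines = [
            "Stiffness plane fit: K/K0 = a*P1 + b*P2 + c",
            "-" * 46,
            f"rows                 {len(self.model.M):>10d}",
            f"a (P1 slope)         {self.plane.a:>13.4e}",
            f"b (P2 slope)         {self.plane.b:>13.4e}",
            f"c (intercept)        {self.plane.c:>13.4e}",
            f"rms residual         {self.plane.rms_residual:>13.4e}",
            f"R^2                  {self.rsquared:>13.4f}",
            "explained variance   " + "  ".join(
                f"{f:.4f}" for f in self.basis.explained_fraction),
        ]
        return "\n".join(lines)
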