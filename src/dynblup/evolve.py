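"""Between-generation updating of mean reaction-norm parameters.

Four update rules produce the per-generation increment in the mean
intercepts and slopes:

``robertson``
    Robertson's secondary theorem of natural selection applied to the
    BLUP-estimated random effects: each increment is the population
    covariance of relative fitness with the corresponding estimated
    additive deviation.  This is the identifiable rule — it needs only
    phenotypes, fitness, cues and the relationship matrix.
``blup_closed``
    The closed-form equivalent of the Robertson/BLUP rule for A = I,
    expressed directly through cov(w, y).
``grad``
    The selection-gradient form of the multivariate breeder's equation,
    with the phenotypic covariance of the traits reconstructed from the
    reaction-norm parameter covariances at the current cues.  Identical
    to the BLUP rules when A = I; wrong (by design, as a comparator)
    when individuals are related.
``breeder``
    The multivariate breeder's equation applied to the true individual
    reaction-norm parameters.  Those are unobservable in the field, so
    this rule is a simulation-only comparator.

All rules share one covariance convention (population, 1/n) through
:func:`selection_cov`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blup_core import BlupFit, build_incidence, build_residual
from .popmodel import GeneticParams, MeanParams

__all__ = [
    "UpdateResult",
    "OverlapConfig",
    "selection_cov",
    "robertson_update",
    "blup_closed_update",
    "grad_update",
    "breeder_update",
    "overlap_scale",
    "apply_update",
    "shrinkage_variance",
]


@dataclass
class UpdateResult:
    """Incremental changes in the p(1+q) mean parameters (trait-major
    ordering: intercepts, then slopes by trait) and the rule that
    produced them."""

    delta: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.delta)):
            raise ValueError(f"non-finite update from method {self.method!r}")


@dataclass
class OverlapConfig:
    """Fraction f_t of each generation that are new offspring; with
    surviving parents (f_t < 1) the selection response is scaled down
    accordingly."""

    ft: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ft <= 1.0:
            raise ValueError("ft must be in (0, 1]")


def selection_cov(w: np.ndarray, v: np.ndarray) -> float:
    """Population covariance sum((w - wbar)(v - vbar)) / n.

    The 1/n normalization follows the Price-equation convention over the
    realized population; every update rule in this module uses this one
    implementation so the convention is consistent package-wide.
    """
    w = np.asarray(w, dtype=float).reshape(-1)
    v = np.asarray(v, dtype=float).reshape(-1)
    if w.shape[0] < 2:
        raise ValueError("selection covariance needs n >= 2 individuals")
    if w.shape != v.shape:
        raise ValueError(f"length mismatch: w has {w.shape[0]}, v has {v.shape[0]}")
    return float(np.mean((w - w.mean()) * (v - v.mean())))


def _cov_columns(w: np.ndarray, M: np.ndarray) -> np.ndarray:
    """selection_cov of w against each column of M, vectorized."""
    w = np.asarray(w, dtype=float).reshape(-1)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != w.shape[0]:
        raise ValueError("row count of values must match fitness vector length")
    if w.shape[0] < 2:
        raise ValueError("selection covariance needs n >= 2 individuals")
    wc = w - w.mean()
    Mc = M - M.mean(axis=0, keepdims=True)
    return (wc @ Mc) / w.shape[0]


def robertson_update(fit: BlupFit, w: np.ndarray) -> UpdateResult:
    """Robertson's secondary theorem on the BLUP random effects:
    delta_m = cov(w, xhat[:, m])."""
    return UpdateResult(delta=_cov_columns(w, fit.xhat), method="robertson")


def blup_closed_update(
    u: np.ndarray, gp: GeneticParams, w: np.ndarray, y: np.ndarray
) -> UpdateResult:
    """Closed-form Robertson/BLUP increment for unrelated individuals:

        delta = G (Z'R^-1 Z G + I)^-1 Z'R^-1 cov(w, y).

    Valid for A = I; agrees with :func:`robertson_update` on the Henderson
    solution for any n >= 2.
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    n = Y.shape[0]
    inc = build_incidence(u, gp.p, gp.q, n)
    res = build_residual(u, gp, n)
    rinv = 1.0 / res.r
    Zt = inc.Zt
    G = gp.G
    c = _cov_columns(w, Y)                         # (p,)
    k = gp.k
    inner = (Zt.T * rinv) @ Zt @ G + np.eye(k)
    try:
        delta = G @ np.linalg.solve(inner, (Zt.T * rinv) @ c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "closed-form BLUP update: inner matrix is singular"
        ) from err
    return UpdateResult(delta=delta, method="blup_closed")


def grad_update(
    u: np.ndarray, gp: GeneticParams, w: np.ndarray, y: np.ndarray
) -> UpdateResult:
    """Selection-gradient (GRAD) increment:

        delta = G Z' Pyy^-1 cov(w, y),
        Pyy = Paa + Gab Ut + (Gab Ut)' + Ut' Pbb Ut,

    where Pyy is the phenotypic covariance of the traits at the current
    cues (the cross term is symmetrized so Pyy is symmetric for
    nonzero Gab).
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    inc = build_incidence(u, gp.p, gp.q, Y.shape[0])
    Ut = inc.Ut
    cross = gp.Gab @ Ut
    Pyy = gp.Paa + cross + cross.T + Ut.T @ gp.Pbb @ Ut
    c = _cov_columns(w, Y)
    try:
        beta = np.linalg.solve(Pyy, c)             # selection gradient
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("GRAD update: Pyy is singular") from err
    return UpdateResult(delta=gp.G @ inc.Zt.T @ beta, method="grad")


def breeder_update(
    gp: GeneticParams,
    w: np.ndarray,
    x_true: np.ndarray,
    v: np.ndarray,
    eta: np.ndarray,
) -> UpdateResult:
    """Multivariate breeder's equation on the true individual parameters:

        delta = G P^-1 [cov(w, a_i); cov(w, b_i)],

    with a_i, b_i the individuals' realized intercepts and slopes
    (additive plus nonadditive deviations).  Simulation-only: these are
    not identifiable from field data.  Components with zero phenotypic
    variance (structurally absent parameters) are excluded before
    inverting P and receive no direct selection.
    """
    n, p = v.shape
    q = gp.q
    params = np.hstack([x_true[:, :p] + v, x_true[:, p:] + eta.reshape(n, p * q)])
    c = _cov_columns(w, params)
    P = gp.P
    active = np.diag(P) > 1e-12
    if not active.any():
        return UpdateResult(delta=np.zeros(gp.k), method="breeder")
    P_act = P[np.ix_(active, active)]
    try:
        sol = np.linalg.solve(P_act, c[active])
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("breeder update: P is singular") from err
    return UpdateResult(delta=gp.G[:, active] @ sol, method="breeder")


def overlap_scale(res: UpdateResult, oc: OverlapConfig) -> UpdateResult:
    """Scale the increment by the offspring fraction f_t."""
    return UpdateResult(delta=res.delta * oc.ft, method=res.method)


def apply_update(mean: MeanParams, res: UpdateResult) -> MeanParams:
    """Add the increments to the mean intercepts and slopes."""
    p, q = mean.p, mean.q
    if res.delta.shape[0] != p * (1 + q):
        raise ValueError(
            f"update has {res.delta.shape[0]} components, expected {p * (1 + q)}"
        )
    return MeanParams.from_vector(mean.vector() + res.delta, p, q)


def shrinkage_variance(Gjj: float, sigma_vj2: float) -> float:
    """Variance of a BLUP-estimated additive effect in the diagonal,
    no-plasticity case: Gjj^2 / (Gjj + sigma_v2) — strictly below the
    true additive variance whenever there is nonadditive noise.  This
    underestimation is exactly what makes the Robertson update correct.
    """
    denom = Gjj + sigma_vj2
    if not denom > 0:
        raise ValueError("Gjj + sigma_vj2 must be > 0")
    return Gjj**2 / denom
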