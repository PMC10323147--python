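"""Reaction-norm population model.

Each individual carries a linear reaction norm per trait: the phenotype of
trait ``j`` is the mean intercept plus the individual's additive and
nonadditive intercept deviations, plus cue-weighted slope terms,

    y_ji = abar_j + a'_ji + v_ji + sum_k (bbar_jk + b'_jk,i + eta_jk,i) u_k.

The additive deviations ``(a', b')`` are the heritable random effects with
covariance G across effects and, optionally, a relatedness matrix A across
individuals; ``v`` and ``eta`` are iid nonadditive noise.  Fitness is a
rounded Gaussian function of the distance between the phenotype vector and
the fitness peak ``theta`` (an integer number of surviving descendants).

Random-effect columns are ordered trait-major throughout the package:
``[a'_1 .. a'_p, b'_11 .. b'_1q, b'_21 .. , b'_pq]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .envgen import PSD_TOL, _check_psd, _psd_factor

__all__ = [
    "GeneticParams",
    "MeanParams",
    "RelMatrix",
    "Cohort",
    "FitnessConfig",
    "toy_genetic_params",
    "band_relatedness",
    "identity_relatedness",
    "sample_additive",
    "make_cohort",
    "fitness_values",
    "relative_fitness",
    "optimal_slope",
    "write_relmatrix_csv",
    "read_relmatrix_csv",
]


@dataclass
class GeneticParams:
    """Additive (G) and phenotypic (P) covariance structure.

    G blocks follow the trait-major effect ordering; ``Gab`` couples the p
    intercepts to the p*q slopes.  P is derived, never stored:
    ``Paa = Gaa + diag(sigma_v2)`` and ``Pbb = Gbb + diag(vec(sigma_eta2))``,
    i.e. the phenotypic covariance is the additive covariance inflated by
    the iid nonadditive variances on the diagonal.
    """

    p: int
    q: int
    Gaa: np.ndarray
    Gab: np.ndarray
    Gbb: np.ndarray
    sigma_v2: np.ndarray
    sigma_eta2: np.ndarray

    def __post_init__(self) -> None:
        self.Gaa = np.asarray(self.Gaa, dtype=float)
        self.Gab = np.asarray(self.Gab, dtype=float).reshape(self.p, self.p * self.q)
        self.Gbb = np.asarray(self.Gbb, dtype=float).reshape(
            self.p * self.q, self.p * self.q
        )
        self.sigma_v2 = np.asarray(self.sigma_v2, dtype=float).reshape(self.p)
        self.sigma_eta2 = np.asarray(self.sigma_eta2, dtype=float).reshape(self.p, self.q)
        self.validate()

    def validate(self) -> None:
        if self.Gaa.shape != (self.p, self.p):
            raise ValueError(f"Gaa must be {self.p}x{self.p}, got {self.Gaa.shape}")
        if np.any(self.sigma_v2 < 0) or np.any(self.sigma_eta2 < 0):
            raise ValueError("nonadditive variances must be nonnegative")
        _check_psd(self.G, "G")
        _check_psd(self.P, "P")

    @property
    def k(self) -> int:
        """Number of reaction-norm parameters per individual, p*(1+q)."""
        return self.p * (1 + self.q)

    @property
    def G(self) -> np.ndarray:
        return np.block([[self.Gaa, self.Gab], [self.Gab.T, self.Gbb]])

    @property
    def Paa(self) -> np.ndarray:
        return self.Gaa + np.diag(self.sigma_v2)

    @property
    def Pbb(self) -> np.ndarray:
        return self.Gbb + np.diag(self.sigma_eta2.ravel())

    @property
    def P(self) -> np.ndarray:
        return np.block([[self.Paa, self.Gab], [self.Gab.T, self.Pbb]])


def toy_genetic_params() -> GeneticParams:
    """Two traits, two cues; trait 1 responds only to cue 1 and trait 2
    only to cue 2 (the inactive slopes b12, b21 have zero variance).

    Additive: Gaa = [[0.2, 0.1], [0.1, 0.2]], Gab = 0, and the active
    slopes (b11, b22) have variance 0.05 with covariance 0.025.
    Nonadditive: intercept variance 0.2 per trait, active-slope variance
    0.05 (so Paa = [[0.4, 0.1], [0.1, 0.4]]).
    """
    p, q = 2, 2
    Gaa = np.array([[0.2, 0.1], [0.1, 0.2]])
    Gab = np.zeros((p, p * q))
    # slope ordering: b11, b12, b21, b22 -> active indices 0 and 3
    Gbb = np.zeros((p * q, p * q))
    Gbb[0, 0] = Gbb[3, 3] = 0.05
    Gbb[0, 3] = Gbb[3, 0] = 0.025
    sigma_v2 = np.array([0.2, 0.2])
    sigma_eta2 = np.array([[0.05, 0.0], [0.0, 0.05]])
    return GeneticParams(p=p, q=q, Gaa=Gaa, Gab=Gab, Gbb=Gbb,
                         sigma_v2=sigma_v2, sigma_eta2=sigma_eta2)


@dataclass
class MeanParams:
    """Evolving mean reaction-norm parameters: intercepts ``abar`` (p,)
    and slope matrix ``Bbar`` (p x q)."""

    abar: np.ndarray
    Bbar: np.ndarray

    def __post_init__(self) -> None:
        self.abar = np.atleast_1d(np.asarray(self.abar, dtype=float))
        p = self.abar.shape[0]
        self.Bbar = np.asarray(self.Bbar, dtype=float).reshape(p, -1)
        if not (np.all(np.isfinite(self.abar)) and np.all(np.isfinite(self.Bbar))):
            raise ValueError("mean reaction-norm parameters must be finite")

    @property
    def p(self) -> int:
        return self.abar.shape[0]

    @property
    def q(self) -> int:
        return self.Bbar.shape[1]

    def vector(self) -> np.ndarray:
        """Trait-major parameter vector [abar_1..abar_p, Bbar row-major]."""
        return np.concatenate([self.abar, self.Bbar.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray, p: int, q: int) -> "MeanParams":
        vec = np.asarray(vec, dtype=float)
        return cls(abar=vec[:p].copy(), Bbar=vec[p:].reshape(p, q).copy())

    def mean_traits(self, u: np.ndarray) -> np.ndarray:
        """Mean phenotypes ybar_j = abar_j + sum_k Bbar_jk u_k."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return self.abar + self.Bbar @ u

    def copy(self) -> "MeanParams":
        return MeanParams(abar=self.abar.copy(), Bbar=self.Bbar.copy())


class RelMatrix:
    """Additive genetic relationship matrix A and its symmetric square
    root A_M (A_M @ A_M = A).  For the unrelated case (``kind ==
    "identity"``) the dense matrices are built lazily, so large cohorts
    never materialize an n x n identity."""

    def __init__(self, A: np.ndarray | None, A_M: np.ndarray | None,
                 kind: str = "custom", n: int | None = None):
        if A is None and n is None:
            raise ValueError("either A or n must be given")
        self._A = None if A is None else np.asarray(A, dtype=float)
        self._A_M = None if A_M is None else np.asarray(A_M, dtype=float)
        self.kind = kind
        self._n = n if n is not None else self._A.shape[0]

    @property
    def A(self) -> np.ndarray:
        if self._A is None:
            self._A = np.eye(self._n)
        return self._A

    @property
    def A_M(self) -> np.ndarray:
        if self._A_M is None:
            self._A_M = np.eye(self._n)
        return self._A_M

    @property
    def n(self) -> int:
        return self._n

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity"

    def __repr__(self) -> str:
        return f"RelMatrix(kind={self.kind!r}, n={self.n})"


def identity_relatedness(n: int) -> RelMatrix:
    """Unrelated population: A = I (random mating, outbred)."""
    return RelMatrix(A=None, A_M=None, kind="identity", n=n)


def band_relatedness(n: int) -> RelMatrix:
    """Highly related population: A has 1 on the diagonal, 1/2 on the
    first off-diagonals and 1/4 everywhere else.  A_M is the symmetric
    PSD square root (eigendecomposition, negative eigenvalues clipped)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    A = np.full((n, n), 0.25)
    idx = np.arange(n)
    A[idx, idx] = 1.0
    A[idx[:-1], idx[:-1] + 1] = 0.5
    A[idx[:-1] + 1, idx[:-1]] = 0.5
    vals, vecs = np.linalg.eigh(A)
    vals = np.clip(vals, 0.0, None)
    A_M = (vecs * np.sqrt(vals)) @ vecs.T
    return RelMatrix(A=A, A_M=A_M, kind="band")


def make_relmatrix(A: np.ndarray, kind: str = "custom") -> RelMatrix:
    """Wrap an explicit relationship matrix, computing its square root."""
    A = np.asarray(A, dtype=float)
    _check_psd(A, "A")
    if not np.allclose(np.diag(A), 1.0, atol=1e-6):
        warnings.warn("relationship matrix diagonal differs from 1", stacklevel=2)
    vals, vecs = np.linalg.eigh(A)
    vals = np.clip(vals, 0.0, None)
    A_M = (vecs * np.sqrt(vals)) @ vecs.T
    if np.allclose(A, np.eye(A.shape[0])):
        kind = "identity"
    return RelMatrix(A=A, A_M=A_M, kind=kind)


def sample_additive(
    gp: GeneticParams, rel: RelMatrix, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the n x p(1+q) matrix of additive deviations.

    Effects are drawn jointly across columns from N(0, G) (independent
    across individuals), then each column is transformed as z = A_M z0 to
    impose the relatedness correlation, then mean-centered.  The centering
    (and, for A != I, the A_M transform) reduces the realized column
    variances below nominal; that reduction is a property of the sampling
    scheme, not an error.
    """
    if rel.n != n:
        raise ValueError(f"relatedness matrix is {rel.n}x{rel.n}, expected {n}x{n}")
    L = _psd_factor(gp.G)
    z0 = rng.standard_normal((n, gp.k)) @ L.T
    z = z0 if rel.is_identity else rel.A_M @ z0
    return z - z.mean(axis=0, keepdims=True)


@dataclass
class FitnessConfig:
    """Gaussian stabilizing selection: peak fitness W_max (integer number
    of descendants at the optimum) and width omega2 of the fitness
    function in squared trait units."""

    W_max: int = 4
    omega2: float = 10.0

    def __post_init__(self) -> None:
        if self.W_max < 1:
            raise ValueError("W_max must be >= 1")
        if not self.omega2 > 0:
            raise ValueError("omega2 must be > 0")


def fitness_values(y: np.ndarray, theta: np.ndarray, fit: FitnessConfig) -> np.ndarray:
    """Integer absolute fitness W_i = round(W_max * exp(-||y_i - theta||^2
    / (2 omega2))), rounding half away from zero."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    d2 = np.sum((y - theta[None, :]) ** 2, axis=1)
    raw = fit.W_max * np.exp(-d2 / (2.0 * fit.omega2))
    return np.floor(raw + 0.5).astype(int)  # raw >= 0, so this is half-away-from-zero


def relative_fitness(W: np.ndarray) -> np.ndarray:
    """w_i = W_i / mean(W); the mean of w is exactly 1."""
    W = np.asarray(W, dtype=float)
    Wbar = W.mean()
    if Wbar <= 0:
        raise ValueError("population extinct: mean absolute fitness is zero")
    return W / Wbar


def optimal_slope(var_u: float, cov_u_theta: float) -> float:
    """Mean slope minimizing E(y - theta)^2 in a stationary stochastic
    environment: the regression coefficient of the peak on the cue."""
    if not var_u > 0:
        raise ValueError("cue variance must be > 0")
    return cov_u_theta / var_u


@dataclass
class Cohort:
    """One generation: additive deviations ``x_true`` (n x p(1+q)),
    nonadditive draws ``v`` (n x p) and ``eta`` (n x p x q), phenotypes
    ``y`` (n x p), absolute fitness ``W`` and relative fitness ``w``."""

    x_true: np.ndarray
    v: np.ndarray
    eta: np.ndarray
    y: np.ndarray
    W: np.ndarray
    w: np.ndarray

    @property
    def n(self) -> int:
        return self.y.shape[0]


def phenotypes(
    mean: MeanParams,
    x_true: np.ndarray,
    v: np.ndarray,
    eta: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Assemble phenotypes from mean parameters, shared random draws, and
    the current cues (the reaction-norm sum, vectorized over individuals)."""
    p, q = mean.p, mean.q
    u = np.atleast_1d(np.asarray(u, dtype=float))
    n = x_true.shape[0]
    a_dev = x_true[:, :p] + v
    b_dev = x_true[:, p:].reshape(n, p, q) + eta
    return mean.abar[None, :] + a_dev + (mean.Bbar[None, :, :] + b_dev) @ u


def make_cohort(
    mean: MeanParams,
    gp: GeneticParams,
    rel: RelMatrix,
    u: np.ndarray,
    theta: np.ndarray,
    fit: FitnessConfig,
    n: int,
    rng: np.random.Generator,
) -> Cohort:
    """Draw a fresh cohort of n individuals and realize its fitness.

    Additive effects are relatedness-correlated and mean-centered;
    nonadditive effects are iid and are not centered.
    """
    x_true = sample_additive(gp, rel, n, rng)
    v = rng.standard_normal((n, gp.p)) * np.sqrt(gp.sigma_v2)[None, :]
    eta = rng.standard_normal((n, gp.p, gp.q)) * np.sqrt(gp.sigma_eta2)[None, :, :]
    y = phenotypes(mean, x_true, v, eta, u)
    W = fitness_values(y, theta, fit)
    w = relative_fitness(W)
    return Cohort(x_true=x_true, v=v, eta=eta, y=y, W=W, w=w)


def write_relmatrix_csv(path, rel: RelMatrix) -> None:
    """Dense no-header CSV, one row per individual."""
    np.savetxt(path, rel.A, delimiter=",")


def read_relmatrix_csv(path) -> RelMatrix:
    A = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return make_relmatrix(A, kind="file")
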