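"""Environment-dependent mixed model and the Henderson BLUP solve.

For a cohort of n individuals measured at cues ``u`` the model is

    y = X ybar + Z~ x + e,      Z~ = Z(u) (x) I_n,

with fixed effects the p mean traits, random effects the p(1+q) additive
reaction-norm deviations per individual (covariance G (x) A), and residual
covariance R(u) (x) I_n with per-trait variance
``r_j = sigma_v2_j + sum_k u_k^2 sigma_eta2_jk`` — both the incidence
matrix and the residual variances move with the environment, which is what
makes the model dynamical.  Solving Henderson's mixed-model equations
yields the estimated mean traits and the shrunken per-individual additive
deviations used downstream for the selection-response update.

Phenotype vectors are stacked trait-major (all individuals of trait 1,
then trait 2, ...) and random effects effect-major (all individuals of
effect 1, then effect 2, ...), consistent with ``X = I_p (x) 1_n`` and
``Z~ = Z (x) I_n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .popmodel import GeneticParams, RelMatrix, identity_relatedness

__all__ = [
    "IncidenceSet",
    "ResidualSet",
    "BlupFit",
    "build_incidence",
    "build_residual",
    "build_gtilde",
    "blup_solve",
    "fit_blup",
]

#: additive variances at or below this are treated as structural zeros
HERITABLE_TOL = 1e-12


@dataclass
class IncidenceSet:
    """Design matrices for one generation: per-individual incidence
    ``Zt = [I_p | Ut.T]`` (p x k), cue matrix ``Ut`` (pq x p), expanded
    incidence ``Ztilde = Zt (x) I_n`` and fixed-effect design ``X``."""

    Zt: np.ndarray
    Ut: np.ndarray
    n: int

    @property
    def Ztilde(self) -> np.ndarray:
        return np.kron(self.Zt, np.eye(self.n))

    @property
    def X(self) -> np.ndarray:
        p = self.Zt.shape[0]
        return np.kron(np.eye(p), np.ones((self.n, 1)))


def build_incidence(u: np.ndarray, p: int, q: int, n: int) -> IncidenceSet:
    """Incidence structure at cues ``u``: row j of Zt has 1 in intercept
    column j and u_1..u_q in trait j's slope columns."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.shape != (q,):
        raise ValueError(f"u must have shape ({q},), got {u.shape}")
    Ut = np.zeros((p * q, p))
    for j in range(p):
        Ut[j * q: (j + 1) * q, j] = u
    Zt = np.hstack([np.eye(p), Ut.T])
    return IncidenceSet(Zt=Zt, Ut=Ut, n=n)


@dataclass
class ResidualSet:
    """Per-individual residual variances r_j (length p) and their
    Kronecker expansion."""

    r: np.ndarray
    n: int

    @property
    def Rt(self) -> np.ndarray:
        return np.diag(self.r)

    @property
    def Rtilde(self) -> np.ndarray:
        return np.kron(self.Rt, np.eye(self.n))


def build_residual(u: np.ndarray, gp: GeneticParams, n: int) -> ResidualSet:
    """Residual variances r_j = sigma_v2_j + sum_k u_k^2 sigma_eta2_jk."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    r = gp.sigma_v2 + (gp.sigma_eta2 * u[None, :] ** 2).sum(axis=1)
    if np.any(r <= 0):
        bad = int(np.argmin(r))
        raise ValueError(
            f"residual variance r_{bad + 1} = {r[bad]:.3g} <= 0: the mixed model "
            "is unidentifiable without nonadditive variance on every trait"
        )
    return ResidualSet(r=r, n=n)


def build_gtilde(gp_or_G, rel: RelMatrix) -> np.ndarray:
    """Random-effect covariance G~ = G (x) A (effect-major ordering)."""
    G = gp_or_G.G if isinstance(gp_or_G, GeneticParams) else np.asarray(gp_or_G, float)
    return np.kron(G, rel.A)


@dataclass
class BlupFit:
    """Solution of the mixed-model equations: estimated mean traits
    ``ybar_hat`` (p,) and per-individual random effects ``xhat``
    (n x k, same column ordering as Cohort.x_true)."""

    ybar_hat: np.ndarray
    xhat: np.ndarray


def _inv_with_fallback(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        warnings.warn(f"{name} is singular; using pseudo-inverse", stacklevel=3)
        return np.linalg.pinv(mat)


def blup_solve(
    y: np.ndarray,
    inc: IncidenceSet,
    res: ResidualSet,
    G: np.ndarray,
    rel: RelMatrix,
) -> BlupFit:
    """Solve Henderson's mixed-model equations for one generation.

    Forms and solves the dense symmetric system

        [ X'R~^-1 X     X'R~^-1 Z~          ] [ybar_hat]   [X'R~^-1 y ]
        [ Z~'R~^-1 X    Z~'R~^-1 Z~ + G~^-1 ] [xhat    ] = [Z~'R~^-1 y]

    with ``G~^-1 = G^-1 (x) A^-1`` (pseudo-inverse fallback when A is
    singular).  ``G`` here covers exactly the effect columns present in
    ``inc.Zt``; pass a nonsingular G (use :func:`fit_blup` to drop
    zero-variance effects automatically).
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    n, p = Y.shape
    k = inc.Zt.shape[1]
    if inc.n != n or res.n != n or rel.n != n:
        raise ValueError("inconsistent cohort sizes across y, incidence, residual, A")
    rinv = 1.0 / res.r
    Zt = inc.Zt

    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G is singular in the Henderson solve; drop zero-variance effects "
            "(fit_blup does this) or regularize G"
        ) from err
    Ainv = _inv_with_fallback(rel.A, "relationship matrix A")

    ZtRZ = (Zt.T * rinv) @ Zt                      # k x k
    C11 = n * np.diag(rinv)                        # p x p
    C12 = np.kron((rinv[:, None] * Zt), np.ones((1, n)))   # p x kn
    C22 = np.kron(ZtRZ, np.eye(n)) + np.kron(Ginv, Ainv)   # kn x kn
    ybar_col = Y.mean(axis=0)
    rhs1 = n * rinv * ybar_col
    rhs2 = ((Zt.T * rinv) @ Y.T).ravel()           # effect-major

    C = np.block([[C11, C12], [C12.T, C22]])
    rhs = np.concatenate([rhs1, rhs2])
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "mixed-model equations are singular; increase the nonadditive "
            "variances or use a cohort with n >= 2"
        ) from err
    ybar_hat = sol[:p]
    xhat = sol[p:].reshape(k, n).T                 # back to n x k
    return BlupFit(ybar_hat=ybar_hat, xhat=xhat)


def _fast_identity_solve(
    Y: np.ndarray, Zt: np.ndarray, rinv: np.ndarray, G: np.ndarray
) -> BlupFit:
    """Closed-form Henderson solution for A = I.

    With A = I every block of the mixed-model equations is a Kronecker
    product with I_n, so the system decouples: the GLS fixed effects are
    the trait means, and each individual's random effects solve the same
    small k x k system S = Z'R^-1 Z + G^-1 against its centered record.
    """
    ybar_hat = Y.mean(axis=0)
    S = (Zt.T * rinv) @ Zt + np.linalg.inv(G)
    B = np.linalg.solve(S, Zt.T * rinv)            # k x p
    xhat = (Y - ybar_hat) @ B.T
    return BlupFit(ybar_hat=ybar_hat, xhat=xhat)


def fit_blup(
    y: np.ndarray,
    u: np.ndarray,
    gp: GeneticParams,
    rel: RelMatrix | None = None,
) -> BlupFit:
    """Assemble and solve the dynamical BLUP model at cues ``u``.

    Drops effect columns with zero additive variance (they are
    deterministically zero; e.g. the toy model's inactive slopes) before
    solving, uses the decoupled closed form when A = I and the dense
    Henderson solve otherwise, and returns ``xhat`` with the dropped
    columns re-embedded as zeros.
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    n = Y.shape[0]
    if rel is None:
        rel = identity_relatedness(n)
    G = gp.G
    mask = np.diag(G) > HERITABLE_TOL
    res = build_residual(u, gp, n)
    inc = build_incidence(u, gp.p, gp.q, n)

    if not mask.any():
        return BlupFit(ybar_hat=Y.mean(axis=0), xhat=np.zeros((n, gp.k)))

    G_r = G[np.ix_(mask, mask)]
    Zt_r = inc.Zt[:, mask]
    if rel.is_identity:
        fit_r = _fast_identity_solve(Y, Zt_r, 1.0 / res.r, G_r)
    else:
        inc_r = IncidenceSet(Zt=Zt_r, Ut=inc.Ut, n=n)
        fit_r = blup_solve(Y, inc_r, res, G_r, rel)

    xhat = np.zeros((n, gp.k))
    xhat[:, mask] = fit_r.xhat
    return BlupFit(ybar_hat=fit_r.ybar_hat, xhat=xhat)
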