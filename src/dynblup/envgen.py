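"""Stochastic environment and fitness-peak trajectories.

The simulated world is a population exposed to ``q`` environmental cues
(e.g. spring temperature and spring rainfall, expressed as deviations from
historical reference values) and ``p`` phenotypic optima ``theta`` (the
trait values that maximize fitness).  Cue means follow linear ramps that
start at a configurable generation, emulating the onset of a directional
climate trend; around the means, cues and optima fluctuate jointly as
white (uncorrelated in time) multivariate normal noise, so that within a
generation the optimum can covary with the cue an organism perceives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvConfig",
    "EnvTrajectory",
    "make_env_trajectory",
    "ls_line_endpoint_change",
    "write_env_csv",
    "read_env_csv",
]

#: relative tolerance used for symmetry / positive-semidefiniteness checks
PSD_TOL = 1e-8


def _check_psd(mat: np.ndarray, name: str) -> None:
    """Raise ValueError if *mat* is not symmetric positive semidefinite."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    scale = max(1.0, float(np.abs(mat).max()))
    if not np.allclose(mat, mat.T, atol=PSD_TOL * scale):
        raise ValueError(f"{name} is not symmetric")
    eigvals = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    if eigvals.min() < -PSD_TOL * scale:
        raise ValueError(
            f"{name} is not positive semidefinite (min eigenvalue {eigvals.min():.3g})"
        )


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """Symmetric factor L with L @ L.T = mat, negative eigenvalues clipped."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


@dataclass
class EnvConfig:
    """Configuration of the cue / fitness-peak process.

    Parameters
    ----------
    q, p
        Number of environmental cues and phenotypic traits.
    T
        Number of generations to simulate.
    ramp_start
        1-based generation at which the directional trend begins.
        For ``t < ramp_start`` the mean cue deviation is zero.
    cue_ramp_slopes
        Per-cue drift of the mean, in cue units per generation.
    theta_coupling
        ``p x q`` matrix mapping the mean cue deviation to the mean
        fitness-peak location (e.g. ``diag(-2, -2)``: a one-unit rise in
        the mean cue moves the optimum by -2 trait units).
    noise_cov
        ``(q+p) x (q+p)`` covariance of the white noise on
        ``(u_1..u_q, theta_1..theta_p)``, drawn jointly each generation.
    seed
        Seed for the trajectory's own random stream.
    """

    q: int = 2
    p: int = 2
    T: int = 60
    ramp_start: int = 10
    cue_ramp_slopes: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.015]))
    theta_coupling: np.ndarray = field(default_factory=lambda: np.diag([-2.0, -2.0]))
    noise_cov: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cue_ramp_slopes = np.asarray(self.cue_ramp_slopes, dtype=float).reshape(-1)
        self.theta_coupling = np.asarray(self.theta_coupling, dtype=float)
        if self.noise_cov is None:
            self.noise_cov = default_noise_cov()
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q < 0 or self.p < 1 or self.T < 1:
            raise ValueError("q >= 0, p >= 1 and T >= 1 required")
        if self.ramp_start < 1:
            raise ValueError("ramp_start must be >= 1")
        if self.cue_ramp_slopes.shape != (self.q,):
            raise ValueError(
                f"cue_ramp_slopes must have shape ({self.q},), "
                f"got {self.cue_ramp_slopes.shape}"
            )
        if self.theta_coupling.shape != (self.p, self.q):
            raise ValueError(
                f"theta_coupling must have shape ({self.p}, {self.q}), "
                f"got {self.theta_coupling.shape}"
            )
        k = self.q + self.p
        if self.noise_cov.shape != (k, k):
            raise ValueError(
                f"noise_cov must have shape ({k}, {k}), got {self.noise_cov.shape}"
            )
        _check_psd(self.noise_cov, "noise_cov")

    def stationary(self) -> "EnvConfig":
        """Copy of this config with the ramps switched off."""
        return EnvConfig(
            q=self.q,
            p=self.p,
            T=self.T,
            ramp_start=self.ramp_start,
            cue_ramp_slopes=np.zeros(self.q),
            theta_coupling=self.theta_coupling.copy(),
            noise_cov=self.noise_cov.copy(),
            seed=self.seed,
        )


def default_noise_cov() -> np.ndarray:
    """Joint white-noise covariance of (u1, u2, theta1, theta2) for the
    two-cue, two-trait toy system: cue variances 0.5 and 0.1875, peak
    variances 2 and 1, cue-cue covariance 0.25, and within-channel
    cue-peak covariances -0.25 and -0.09375 (unlisted cross terms are 0).
    """
    c = np.zeros((4, 4))
    np.fill_diagonal(c, [0.5, 0.1875, 2.0, 1.0])
    c[0, 1] = c[1, 0] = 0.25        # cov(u1, u2)
    c[0, 2] = c[2, 0] = -0.25       # cov(u1, theta1)
    c[1, 3] = c[3, 1] = -0.09375    # cov(u2, theta2)
    return c


@dataclass
class EnvTrajectory:
    """Realized cue deviations ``u`` (T x q) and peak locations ``theta``
    (T x p), generation-indexed from 1 (row 0 is generation 1)."""

    u: np.ndarray
    theta: np.ndarray

    @property
    def T(self) -> int:
        return self.u.shape[0]


def make_env_trajectory(cfg: EnvConfig, rng: np.random.Generator | None = None) -> EnvTrajectory:
    """Generate one realization of the cue / fitness-peak process.

    Mean parts are zero before ``ramp_start`` and rise linearly afterwards
    (``slope * (t - ramp_start)`` at 1-based generation ``t``); the mean
    peak is ``theta_coupling @ mean_cue``.  Noise is redrawn independently
    each generation from ``noise_cov``, jointly across all q+p channels.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = np.arange(1, cfg.T + 1)
    ramp = np.clip(t - cfg.ramp_start, 0, None).astype(float)  # (T,)
    mu_u = ramp[:, None] * cfg.cue_ramp_slopes[None, :]        # (T, q)
    mu_theta = mu_u @ cfg.theta_coupling.T                     # (T, p)

    L = _psd_factor(cfg.noise_cov)
    z = rng.standard_normal((cfg.T, cfg.q + cfg.p))
    noise = z @ L.T
    u = mu_u + noise[:, : cfg.q]
    theta = mu_theta + noise[:, cfg.q:]
    return EnvTrajectory(u=u, theta=theta)


def ls_line_endpoint_change(series: np.ndarray) -> float:
    """Endpoint change of an ordinary least-squares line fit.

    Fits value ~ generation index by OLS and returns the fitted value at
    ``t = T`` minus the fitted value at ``t = 1``, i.e. ``slope * (T - 1)``.
    Used as the drift diagnostic for a stationary cue series: even pure
    white noise produces an apparent linear trend of this magnitude.
    """
    y = np.asarray(series, dtype=float).reshape(-1)
    T = y.shape[0]
    if T < 2:
        raise ValueError("series must have length >= 2 for a least-squares line")
    t = np.arange(1.0, T + 1.0)
    slope = np.polyfit(t, y, 1)[0]
    return float(slope * (T - 1))


def write_env_csv(path, traj: EnvTrajectory) -> None:
    """Write a trajectory as CSV with columns t, u1..uq, theta1..thetap."""
    q = traj.u.shape[1]
    p = traj.theta.shape[1]
    df = pd.DataFrame({"t": np.arange(1, traj.T + 1)})
    for k in range(q):
        df[f"u{k + 1}"] = traj.u[:, k]
    for j in range(p):
        df[f"theta{j + 1}"] = traj.theta[:, j]
    df.to_csv(path, index=False)


def read_env_csv(path) -> EnvTrajectory:
    df = pd.read_csv(path)
    ucols = sorted((c for c in df.columns if c.startswith("u")), key=lambda c: int(c[1:]))
    tcols = sorted(
        (c for c in df.columns if c.startswith("theta")), key=lambda c: int(c[5:])
    )
    if not ucols or not tcols:
        raise ValueError(f"{path}: expected columns u1.. and theta1..")
    return EnvTrajectory(u=df[ucols].to_numpy(float), theta=df[tcols].to_numpy(float))
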