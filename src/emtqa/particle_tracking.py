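"""Sequential Monte Carlo (sampling-importance-resampling) sensor tracking.

The latent state is theta = (l, x, y, z, t): arc length along the catheter,
3D position and time.  The state evolution adds a configurable drift

    f(l, t) = R_A * L + s + a/2 + sum_{i=1..7} (b_i cos(w_i t) + c_i sin(w_i t))

plus Gaussian state noise; by default all drift coefficients are zero, which
reduces the model to a position random walk.  Observations are the measured
3D positions, h(theta) = theta + observation noise, and the likelihood is an
isotropic Gaussian on the position block only (l and t carry no measurement).

Particles with vanishing weights are replaced by copies of particles with
finite weight via systematic resampling, triggered when the effective sample
size drops below a configurable fraction of N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SensorRecording

__all__ = [
    "SensorState",
    "MotionModelParams",
    "ParticleSet",
    "DegenerateWeightsError",
    "propagate",
    "reweight",
    "resample",
    "effective_sample_size",
    "track",
]

logger = logging.getLogger("emtqa.tracking")


@dataclass(frozen=True)
class SensorState:
    """theta = (l, x, y, z, t): arc length (mm), position (mm), time (s)."""

    l: float
    x: float
    y: float
    z: float
    t: float

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.l, self.x, self.y, self.z, self.t])

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class MotionModelParams:
    """Coefficients of the drift model and the two noise scales.

    ``harmonics`` holds exactly seven ``(b_i, c_i, omega_i)`` triples
    (amplitudes in mm, angular frequencies in rad/s).  ``drift_direction``
    distributes the scalar arc-length drift over the position block; the
    zero default leaves the position a pure random walk.
    """

    R_A: float = 0.0
    L: float = 0.0
    s: float = 0.0
    a: float = 0.0
    harmonics: tuple[tuple[float, float, float], ...] = field(
        default_factory=lambda: ((0.0, 0.0, 0.0),) * 7
    )
    state_noise_sd: float = 0.5   # mm
    obs_noise_sd: float = 0.5     # mm
    drift_direction: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.harmonics) != 7:
            raise ValueError("exactly 7 harmonic (b, c, omega) triples required")
        if self.state_noise_sd <= 0 or self.obs_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")

    def drift(self, t: float) -> float:
        """Deterministic part of the state increment at time ``t``."""
        value = self.R_A * self.L + self.s + self.a / 2.0
        for b, c, omega in self.harmonics:
            value += b * np.cos(omega * t) + c * np.sin(omega * t)
        return float(value)


@dataclass
class ParticleSet:
    """N weighted state samples; weights sum to one."""

    particles: np.ndarray  # (N, 5) rows (l, x, y, z, t)
    weights: np.ndarray    # (N,)

    def __post_init__(self) -> None:
        self.particles = np.asarray(self.particles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.particles.ndim != 2 or self.particles.shape[1] != 5:
            raise ValueError("particles must be an (N, 5) array")
        if self.n < 2:
            raise ValueError("at least 2 particles are required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 (within 1e-12)")

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def positions(self) -> np.ndarray:
        return self.particles[:, 1:4]

    def posterior_mean(self) -> np.ndarray:
        """Weighted mean state (the filtering-density point estimate)."""
        return self.weights @ self.particles


class DegenerateWeightsError(RuntimeError):
    """All observation likelihoods are numerically zero."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def propagate(
    particles: ParticleSet,
    params: MotionModelParams,
    t: float,
    dt: float = 1.0 / 40.0,
    seed: int | np.random.Generator | None = None,
) -> ParticleSet:
    """Advance every particle through the state evolution; weights unchanged."""
    rng = _as_rng(seed)
    d = params.drift(t)
    new = particles.particles.copy()
    new[:, 0] += d + rng.normal(0.0, params.state_noise_sd, size=particles.n)
    new[:, 1:4] += d * np.asarray(params.drift_direction) + rng.normal(
        0.0, params.state_noise_sd, size=(particles.n, 3)
    )
    new[:, 4] += dt
    return ParticleSet(particles=new, weights=particles.weights.copy())


def reweight(
    particles: ParticleSet,
    observation: SensorState | np.ndarray,
    params: MotionModelParams,
) -> ParticleSet:
    """Multiply weights by the Gaussian observation likelihood and renormalise.

    Raises
    ------
    DegenerateWeightsError
        if every likelihood underflows to zero; the caller is expected to
        resample from the prior (the tracker reinitialises around the
        observation).
    """
    z = observation.position if isinstance(observation, SensorState) else np.asarray(
        observation, dtype=float
    )
    d2 = np.sum((particles.positions - z) ** 2, axis=1)
    lik = np.exp(-0.5 * d2 / params.obs_noise_sd**2)
    w = particles.weights * lik
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise DegenerateWeightsError(
            "all observation likelihoods vanished; resample from the prior"
        )
    return ParticleSet(particles=particles.particles.copy(), weights=w / total)


def resample(
    particles: ParticleSet, seed: int | np.random.Generator | None = None
) -> ParticleSet:
    """Systematic resampling; returns uniform weights 1/N.

    The expected copy count of particle n equals N * w_n.
    """
    rng = _as_rng(seed)
    n = particles.n
    u = (rng.random() + np.arange(n)) / n
    idx = np.searchsorted(np.cumsum(particles.weights), u, side="right")
    idx = np.clip(idx, 0, n - 1)
    return ParticleSet(
        particles=particles.particles[idx].copy(),
        weights=np.full(n, 1.0 / n),
    )


def effective_sample_size(weights: np.ndarray) -> float:
    return float(1.0 / np.sum(np.asarray(weights) ** 2))


def _init_particles(
    z0: np.ndarray, t0: float, n: int, spread: float, rng: np.random.Generator
) -> ParticleSet:
    p = np.zeros((n, 5))
    p[:, 1:4] = z0 + rng.normal(0.0, spread, size=(n, 3))
    p[:, 4] = t0
    return ParticleSet(particles=p, weights=np.full(n, 1.0 / n))


def track(
    recording: SensorRecording,
    params: MotionModelParams | None = None,
    N: int = 1000,
    resample_threshold: float = 0.5,
    seed: int = 0,
) -> SensorRecording:
    """Bootstrap-filter the solenoid channel sample by sample.

    Returns a copy of the recording whose solenoid channel holds the
    per-sample posterior-mean position estimate.  Deterministic under a
    fixed seed.
    """
    params = params or MotionModelParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    obs = recording.solenoid
    T = len(obs)
    estimates = np.empty((T, 3))
    pset = _init_particles(obs[0], recording.t[0], N, params.obs_noise_sd, rng)
    dt = recording.sample_period
    n_degenerate = 0
    for m in range(T):
        if m > 0:
            pset = propagate(pset, params, t=recording.t[m - 1], dt=dt, seed=rng)
        try:
            pset = reweight(pset, obs[m], params)
        except DegenerateWeightsError:
            n_degenerate += 1
            pset = _init_particles(obs[m], recording.t[m], N, params.obs_noise_sd, rng)
        estimates[m] = pset.posterior_mean()[1:4]
        if effective_sample_size(pset.weights) < resample_threshold * N:
            pset = resample(pset, seed=rng)
    if n_degenerate:
        logger.warning(
            "particle weights degenerated at %d of %d samples; particles were "
            "reinitialised around the observation (likely outliers)",
            n_degenerate, T,
        )
    return recording.replace_solenoid(estimates)
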