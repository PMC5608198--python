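"""Synthetic phantom recordings with the statistical structure of HDR-BT EMT data.

The generator emulates a stop-and-go solenoid sensor driven by an afterloader
through implanted catheters (2.5 mm dwell spacing, 5 mm tip margin, catheters
cut to at most 287.5 mm, dwell times 0.1-5 s, transit speed 25-500 mm/s,
40 Hz sampling), with three chest fiducial sensors, superimposed
quasi-periodic breathing (calm chest / calm belly / erratic speaking modes),
i.i.d. Gaussian measurement noise, and optional zero-dropout outliers where
the tracker writes all-zero rows.

Every stochastic element is driven by a seed recorded in the scenario, so a
scenario reproduces its recording bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    Catheter,
    DwellPoint,
    MOVE_IN,
    MOVE_OUT,
    STOP,
    SensorRecording,
    TreatmentPlan,
)

__all__ = [
    "BreathingModel",
    "PhantomScenario",
    "generate_plan",
    "generate_breathing",
    "generate_recording",
    "inject_outliers",
]

_CALM_MODES = ("chest", "belly")


@dataclass(frozen=True)
class BreathingModel:
    """Quasi-periodic chest-displacement model.

    A sum of ``harmonics`` sinusoids at multiples of ``base_frequency`` whose
    amplitude and instantaneous frequency wander slowly (Ornstein-Uhlenbeck
    modulation); the ``speaking`` mode additionally multiplies the series by
    a bursty random envelope, emulating the erratic breathing of a speaking
    patient.  ``amplitude`` is the per-axis peak displacement of the
    fundamental in mm.
    """

    mode: str = "chest"
    base_frequency: float = 0.30           # Hz
    amplitude: tuple[float, float, float] = (3.0, 1.5, 0.75)  # mm per axis
    amplitude_jitter: float = 0.08
    frequency_jitter: float = 0.04
    harmonics: int = 2

    def __post_init__(self) -> None:
        if self.mode not in (*_CALM_MODES, "speaking"):
            raise ValueError(f"unknown breathing mode {self.mode!r}")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be > 0")
        if any(a < 0 for a in self.amplitude):
            raise ValueError("per-axis amplitudes must be >= 0")
        if self.harmonics < 1:
            raise ValueError("at least one harmonic is required")

    @classmethod
    def for_mode(
        cls, mode: str, amplitude: tuple[float, float, float] = (3.0, 1.5, 0.75)
    ) -> "BreathingModel":
        """Defaults per breathing mode; speaking is strictly more jittery
        than either calm mode."""
        if mode == "chest":
            return cls(mode, 0.30, amplitude, 0.08, 0.04, 2)
        if mode == "belly":
            return cls(mode, 0.20, amplitude, 0.08, 0.04, 2)
        if mode == "speaking":
            return cls(mode, 0.35, amplitude, 0.45, 0.25, 3)
        raise ValueError(f"unknown breathing mode {mode!r}")


@dataclass(frozen=True)
class PhantomScenario:
    """Geometry, afterloader protocol and corruption levels of one phantom run."""

    n_catheters: int = 4
    catheter_shape: str = "arc"            # "straight" or "arc"
    curvature: float = 0.003               # 1/mm, used by the arc family
    catheter_length: float = 287.5         # mm, catheters are cut to <= 287.5
    dwell_spacing: float = 2.5             # mm
    tip_margin: float = 5.0                # mm
    n_dwells_per_catheter: int | None = None  # None -> fill the catheter
    dwell_time_range: tuple[float, float] = (0.1, 5.0)  # s
    sensor_speed: float = 50.0             # mm/s, afterloader range 25-500
    breathing: BreathingModel = field(default_factory=BreathingModel)
    noise_sd: float = 0.5                  # mm, Gaussian measurement noise
    outlier_rate: float = 0.0              # zero-dropout probability per sample
    sample_period: float = 1.0 / 40.0      # s
    origin: tuple[float, float, float] = (60.0, 80.0, 120.0)  # mm, implant site
    catheter_pitch: float = 7.5            # mm between neighbouring entries
    apply_session_transform: bool = True   # rigid CT->EMT frame change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_spacing <= 0:
            raise ValueError("dwell_spacing must be > 0")
        if not (0 < self.catheter_length <= 287.5):
            raise ValueError("catheter arc length must be in (0, 287.5] mm")
        if not (25.0 <= self.sensor_speed <= 500.0):
            raise ValueError("sensor speed must lie within [25, 500] mm/s")
        if self.catheter_shape not in ("straight", "arc"):
            raise ValueError(f"unknown catheter shape {self.catheter_shape!r}")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must be a probability")

    def replace(self, **kwargs) -> "PhantomScenario":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Catheter curve family
# ---------------------------------------------------------------------------

def _catheter_curve(scenario: PhantomScenario, index: int):
    """Arc-length parametrised curve of catheter ``index`` (0-based).

    ``s`` runs from 0 at the entry to ``catheter_length`` at the tip.
    Catheters sit on a two-row template grid; arcs bend in per-catheter
    planes so that a multi-catheter implant spans all three dimensions.
    """
    ncols = max(1, int(np.ceil(scenario.n_catheters / 2)))
    col, row = index % ncols, index // ncols
    entry = np.asarray(scenario.origin, dtype=float) + np.array(
        [col * scenario.catheter_pitch, row * scenario.catheter_pitch, 0.0]
    )
    if scenario.catheter_shape == "straight":
        def curve(s: np.ndarray) -> np.ndarray:
            s = np.atleast_1d(np.asarray(s, dtype=float))
            out = np.zeros((len(s), 3))
            out[:, 2] = s
            return entry + out
        return curve

    kappa = scenario.curvature
    phi = 2.0 * np.pi * index / max(scenario.n_catheters, 1) + 0.4
    bend = np.array([np.cos(phi), np.sin(phi), 0.0])

    def curve(s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if kappa == 0.0:
            out = np.zeros((len(s), 3))
            out[:, 2] = s
            return entry + out
        along = np.sin(kappa * s) / kappa
        across = (1.0 - np.cos(kappa * s)) / kappa
        return entry + along[:, None] * np.array([0.0, 0.0, 1.0]) + across[:, None] * bend

    return curve


# ---------------------------------------------------------------------------
# Plan generation
# ---------------------------------------------------------------------------

def generate_plan(scenario: PhantomScenario) -> TreatmentPlan:
    """Lay dwell points on each catheter curve.

    The first dwell point sits ``tip_margin`` from the tip; subsequent points
    follow every ``dwell_spacing`` mm of arc length back toward the entry.
    Dwell times are drawn uniformly from ``dwell_time_range`` (seeded) and
    quantised to the sample grid.
    """
    capacity = int(np.floor(
        (scenario.catheter_length - scenario.tip_margin) / scenario.dwell_spacing
    )) + 1
    n_dwells = capacity
    if scenario.n_dwells_per_catheter is not None:
        if scenario.n_dwells_per_catheter > capacity:
            raise ValueError(
                f"requested {scenario.n_dwells_per_catheter} dwell points but a "
                f"{scenario.catheter_length} mm catheter holds at most {capacity}"
            )
        n_dwells = scenario.n_dwells_per_catheter
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 101]))
    catheters = []
    for p in range(scenario.n_catheters):
        curve = _catheter_curve(scenario, p)
        # arc position measured from the entry; dwell 1 is deepest
        s_from_tip = scenario.tip_margin + scenario.dwell_spacing * np.arange(n_dwells)
        s = scenario.catheter_length - s_from_tip
        positions = curve(s)
        times = rng.uniform(*scenario.dwell_time_range, size=n_dwells)
        times = np.maximum(
            np.round(times / scenario.sample_period) * scenario.sample_period,
            scenario.sample_period,
        )
        catheters.append(Catheter(
            catheter_id=p + 1,
            dwell_points=tuple(
                DwellPoint(dwell_index=k + 1, position=positions[k],
                           dwell_time=float(times[k]))
                for k in range(n_dwells)
            ),
        ))
    return TreatmentPlan(catheters=tuple(catheters), frame_label="CT")


# ---------------------------------------------------------------------------
# Breathing generation
# ---------------------------------------------------------------------------

def _ou_process(n: int, dt: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck path (slow modulation driver)."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    a = max(0.0, 1.0 - dt / tau)
    b = np.sqrt(max(1.0 - a * a, 0.0))
    noise = rng.standard_normal(n)
    for k in range(1, n):
        x[k] = a * x[k - 1] + b * noise[k]
    return x


def generate_breathing(
    model: BreathingModel, duration: float, sample_period: float = 1.0 / 40.0,
    seed: int = 0,
) -> np.ndarray:
    """(T, 3) zero-mean quasi-periodic displacement series in mm."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / sample_period))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    t = np.arange(n) * sample_period

    amp_mod = 1.0
    freq_mod = np.ones(n)
    if model.amplitude_jitter > 0:
        amp_mod = 1.0 + model.amplitude_jitter * _ou_process(n, sample_period, 8.0, rng)
        amp_mod = np.clip(amp_mod, 0.0, None)
    if model.frequency_jitter > 0:
        freq_mod = 1.0 + model.frequency_jitter * _ou_process(n, sample_period, 8.0, rng)
        freq_mod = np.clip(freq_mod, 0.05, None)

    waveform = np.zeros(n)
    for h in range(1, model.harmonics + 1):
        phase0 = 0.0 if h == 1 else rng.uniform(0.0, 2.0 * np.pi)
        phase = 2.0 * np.pi * h * model.base_frequency * (
            np.cumsum(freq_mod) - freq_mod[0]
        ) * sample_period + phase0
        waveform += np.sin(phase) / h ** 2
    waveform *= amp_mod

    if model.mode == "speaking":
        # bursty envelope: smoothed random telegraph between quiet and loud
        burst = np.ones(n)
        k = 0
        while k < n:
            length = max(1, int(rng.uniform(0.5, 3.0) / sample_period))
            level = rng.uniform(0.3, 1.8)
            burst[k:k + length] = level
            k += length
        width = max(1, int(0.3 / sample_period))
        kernel = np.exp(-0.5 * (np.linspace(-2, 2, 2 * width + 1)) ** 2)
        kernel /= kernel.sum()
        burst = np.convolve(burst, kernel, mode="same")
        waveform *= burst

    series = waveform[:, None] * np.asarray(model.amplitude, dtype=float)[None, :]
    return series - series.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _rigid_transform(rng: np.random.Generator):
    """Random small rotation + translation emulating the CT->EMT frame change."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.3, 2.5)  # rad; FG and CT frames differ arbitrarily
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    translation = rng.uniform(-20.0, 20.0, size=3)
    return R, translation


def generate_recording(
    plan: TreatmentPlan, scenario: PhantomScenario
) -> tuple[SensorRecording, np.ndarray]:
    """Simulate the afterloader run of ``plan`` under ``scenario``.

    Returns the corrupted recording and the artifact-free ground-truth
    solenoid track (same frame as the recording).  The solenoid channel is
    stop-and-go motion along the catheters plus breathing displacement plus
    i.i.d. Gaussian noise; fiducial channels are fixed chest points plus the
    same breathing displacement plus independent noise.
    """
    dt = scenario.sample_period
    ss = np.random.SeedSequence([scenario.seed, 303])
    rng_noise, rng_transform = [np.random.default_rng(c) for c in ss.spawn(2)]

    positions: list[np.ndarray] = []
    commands: list[str] = []
    dwell_idx: list[int] = []
    cath_idx: list[int] = []

    def _transit(curve, s_from: float, s_to: float, command: str, cid: int) -> None:
        dist = abs(s_to - s_from)
        n = max(1, int(np.ceil(dist / (scenario.sensor_speed * dt))))
        s_path = s_from + (s_to - s_from) * (np.arange(1, n + 1) / n)
        positions.append(curve(s_path))
        commands.extend([command] * n)
        dwell_idx.extend([0] * n)
        cath_idx.extend([cid] * n)

    for cath in plan.catheters:
        cid = cath.catheter_id
        curve = _catheter_curve(scenario, cid - 1)
        s_of_dwell = [
            scenario.catheter_length
            - (scenario.tip_margin + (dp.dwell_index - 1) * scenario.dwell_spacing)
            for dp in cath.dwell_points
        ]
        if not s_of_dwell:
            continue
        _transit(curve, 0.0, s_of_dwell[0], MOVE_IN, cid)
        prev_s = s_of_dwell[0]
        for dp, s in zip(cath.dwell_points, s_of_dwell):
            if s != prev_s:
                _transit(curve, prev_s, s, MOVE_OUT, cid)
                prev_s = s
            n = max(1, int(round(dp.dwell_time / dt)))
            positions.append(np.repeat(curve(np.array([s])), n, axis=0))
            commands.extend([STOP] * n)
            dwell_idx.extend([dp.dwell_index] * n)
            cath_idx.extend([cid] * n)
        _transit(curve, prev_s, 0.0, MOVE_OUT, cid)

    track = np.concatenate(positions, axis=0)
    T = len(track)
    t = np.arange(T) * dt

    # frame change between the CT plan and the EMT session
    if scenario.apply_session_transform:
        R, trans = _rigid_transform(rng_transform)
    else:
        R, trans = np.eye(3), np.zeros(3)
    truth = track @ R.T + trans

    breathing = generate_breathing(
        scenario.breathing, duration=T * dt, sample_period=dt,
        seed=scenario.seed + 40_000,
    )[:T]

    solenoid = truth + breathing
    if scenario.noise_sd > 0:
        solenoid = solenoid + rng_noise.normal(0.0, scenario.noise_sd, size=(T, 3))

    # three fiducials on the chest, displaced by the same breathing motion
    fid_base = np.array([[0.0, 40.0, 60.0], [30.0, 10.0, 70.0], [-25.0, 20.0, 65.0]])
    fid_base = fid_base @ R.T + trans
    fiducials = np.empty((3, T, 3))
    for i in range(3):
        fiducials[i] = fid_base[i] + breathing
        if scenario.noise_sd > 0:
            fiducials[i] += rng_noise.normal(0.0, scenario.noise_sd, size=(T, 3))

    recording = SensorRecording(
        t=t, solenoid=solenoid, fiducials=fiducials,
        command=np.array(commands, dtype=object),
        dwell_index=np.array(dwell_idx, dtype=int),
        catheter_id=np.array(cath_idx, dtype=int),
        sample_period=dt,
    )
    if scenario.outlier_rate > 0:
        recording, _ = inject_outliers(
            recording, scenario.outlier_rate, seed=scenario.seed + 50_000
        )
    return recording, truth


def inject_outliers(
    recording: SensorRecording, rate: float, seed: int = 0
) -> tuple[SensorRecording, np.ndarray]:
    """Replace a Bernoulli(rate) subset of solenoid samples with zero rows.

    Emulates tracker dropouts where the measurement software writes zeros.
    Annotations are untouched.  Returns the corrupted recording and the
    indices of the corrupted samples.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be a probability")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    mask = rng.random(len(recording.t)) < rate
    solenoid = recording.solenoid.copy()
    solenoid[mask] = 0.0
    return recording.replace_solenoid(solenoid), np.flatnonzero(mask)
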