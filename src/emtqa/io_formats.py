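"""Canonical file formats for recordings, treatment plans and deviation reports.

All quantities are in millimetres and seconds.  Coordinates are treated as
arbitrary right-handed frames; no axis convention is imposed because the
downstream distance-based registration is frame-invariant.

Formats
-------
* treatment plan     -- JSON (catheters with numbered dwell points)
* sensor recording   -- CSV, one row per 40 Hz sample with columns
                        ``t,x,y,z,fid1_x..fid3_z,command,dwell_index,catheter_id``
* deviation report   -- CSV, one row per matched dwell pair plus a summary
                        block written as ``#``-comments
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DwellPoint",
    "Catheter",
    "TreatmentPlan",
    "SensorRecording",
    "DeviationReport",
    "PlanFormatError",
    "RecordingFormatError",
    "read_treatment_plan",
    "write_treatment_plan",
    "read_emt_recording",
    "write_emt_recording",
    "read_deviation_report",
    "write_deviation_report",
    "STOP",
    "MOVE_IN",
    "MOVE_OUT",
]

#: Afterloader command annotations attached to every sample.
STOP = "STOP"
MOVE_IN = "MOVE_IN"
MOVE_OUT = "MOVE_OUT"
_COMMANDS = (STOP, MOVE_IN, MOVE_OUT)

#: Canonical recording CSV columns, in order.
RECORDING_COLUMNS = (
    ["t", "x", "y", "z"]
    + [f"fid{i}_{a}" for i in (1, 2, 3) for a in ("x", "y", "z")]
    + ["command", "dwell_index", "catheter_id"]
)


class PlanFormatError(ValueError):
    """A treatment-plan file violates the documented schema."""


class RecordingFormatError(ValueError):
    """A recording file violates the documented schema."""


# ---------------------------------------------------------------------------
# Treatment plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellPoint:
    dwell_index: int
    position: np.ndarray  # shape (3,), mm
    dwell_time: float     # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class Catheter:
    catheter_id: int
    dwell_points: tuple[DwellPoint, ...]


@dataclass(frozen=True)
class TreatmentPlan:
    """Numbered 3D dwell positions grouped by catheter.

    The first dwell position of a catheter sits a default 5 mm margin from
    the catheter tip and subsequent positions follow in 2.5 mm arc-length
    steps, so consecutive points are separated by a strictly positive
    distance and dwell indices increase strictly within a catheter.
    """

    catheters: tuple[Catheter, ...]
    frame_label: str = "CT"

    def __post_init__(self) -> None:
        for cath in self.catheters:
            indices = [dp.dwell_index for dp in cath.dwell_points]
            if any(b <= a for a, b in zip(indices, indices[1:])):
                raise PlanFormatError(
                    f"catheter {cath.catheter_id}: dwell indices must be "
                    f"unique and strictly increasing, got {indices}"
                )
            for dp in cath.dwell_points:
                if not np.all(np.isfinite(dp.position)):
                    raise PlanFormatError(
                        f"catheter {cath.catheter_id}, dwell {dp.dwell_index}: "
                        "non-finite position"
                    )
            pos = np.array([dp.position for dp in cath.dwell_points])
            if len(pos) > 1:
                gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
                if np.any(gaps <= 0.0):
                    bad = int(np.argmin(gaps))
                    raise PlanFormatError(
                        f"catheter {cath.catheter_id}: consecutive dwell "
                        f"positions {bad + 1} and {bad + 2} coincide"
                    )

    @property
    def n_dwell_points(self) -> int:
        return sum(len(c.dwell_points) for c in self.catheters)

    def to_dict(self) -> dict:
        return {
            "frame_label": self.frame_label,
            "catheters": [
                {
                    "catheter_id": c.catheter_id,
                    "dwell_points": [
                        {
                            "dwell_index": dp.dwell_index,
                            "position": [float(v) for v in dp.position],
                            "dwell_time": float(dp.dwell_time),
                        }
                        for dp in c.dwell_points
                    ],
                }
                for c in self.catheters
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TreatmentPlan":
        try:
            catheters = tuple(
                Catheter(
                    catheter_id=int(c["catheter_id"]),
                    dwell_points=tuple(
                        DwellPoint(
                            dwell_index=int(dp["dwell_index"]),
                            position=np.asarray(dp["position"], dtype=float),
                            dwell_time=float(dp["dwell_time"]),
                        )
                        for dp in c["dwell_points"]
                    ),
                )
                for c in payload["catheters"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PlanFormatError(f"malformed treatment plan: {exc}") from exc
        return cls(catheters=catheters, frame_label=str(payload.get("frame_label", "CT")))


def read_treatment_plan(path: str | Path) -> TreatmentPlan:
    """Read a treatment plan from the canonical JSON schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"treatment plan not found: {path}")
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PlanFormatError(f"{path}: not valid JSON: {exc}") from exc
    return TreatmentPlan.from_dict(payload)


def write_treatment_plan(plan: TreatmentPlan, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(plan.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Sensor recording
# ---------------------------------------------------------------------------

@dataclass
class SensorRecording:
    """A 40 Hz multichannel EMT time series with afterloader annotations.

    Attributes
    ----------
    t : (T,) strictly increasing timestamps with constant step ``sample_period``.
    solenoid : (T, 3) positions of the in-catheter solenoid sensor, mm.
    fiducials : (3, T, 3) positions of the three chest fiducial sensors, mm.
    command : (T,) one of STOP / MOVE_IN / MOVE_OUT per sample.
    dwell_index : (T,) dwell number during a STOP run, 0 while moving.
    catheter_id : (T,) catheter the sensor currently traverses.

    Missing measurements appear as all-zero position rows; they are kept
    verbatim (the tracking software writes zeros on dropout) and handled by
    the downstream outlier stage.
    """

    t: np.ndarray
    solenoid: np.ndarray
    fiducials: np.ndarray
    command: np.ndarray
    dwell_index: np.ndarray
    catheter_id: np.ndarray
    sample_period: float = 1.0 / 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.solenoid = np.asarray(self.solenoid, dtype=float)
        self.fiducials = np.asarray(self.fiducials, dtype=float)
        self.command = np.asarray(self.command, dtype=object)
        self.dwell_index = np.asarray(self.dwell_index, dtype=int)
        self.catheter_id = np.asarray(self.catheter_id, dtype=int)
        T = len(self.t)
        if self.solenoid.shape != (T, 3):
            raise RecordingFormatError(
                f"solenoid channel shape {self.solenoid.shape} != ({T}, 3)"
            )
        if self.fiducials.shape != (3, T, 3):
            raise RecordingFormatError(
                "exactly 3 fiducial channels of the solenoid's length are "
                f"required, got array of shape {self.fiducials.shape}"
            )
        for arr, name in ((self.command, "command"), (self.dwell_index, "dwell_index"),
                          (self.catheter_id, "catheter_id")):
            if len(arr) != T:
                raise RecordingFormatError(f"annotation '{name}' length mismatch")
        if T > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise RecordingFormatError("timestamps must be strictly increasing")
            if not np.allclose(steps, self.sample_period, rtol=1e-6, atol=1e-9):
                raise RecordingFormatError(
                    "timestamps must advance by one sample_period per row"
                )
        bad = set(np.unique(self.command)) - set(_COMMANDS)
        if bad:
            raise RecordingFormatError(f"unknown afterloader commands: {sorted(bad)}")
        self._check_stop_runs()

    def _check_stop_runs(self) -> None:
        # every STOP sample must carry a dwell number; runs then hold exactly
        # one dwell_index by construction (stop_runs splits on changes)
        missing = (self.command == STOP) & (self.dwell_index < 1)
        if missing.any():
            raise RecordingFormatError(
                f"{int(missing.sum())} STOP samples carry no dwell index"
            )

    def stop_runs(self) -> list[tuple[int, int]]:
        """Half-open ``[start, stop)`` index ranges of contiguous STOP samples.

        A run is also broken at a change of dwell_index or catheter_id, so
        back-to-back dwells with no move sample in between stay distinct.
        """
        is_stop = self.command == STOP
        if not is_stop.any():
            return []
        key = np.stack([is_stop.astype(int), self.dwell_index, self.catheter_id])
        change = np.any(key[:, 1:] != key[:, :-1], axis=0)
        boundaries = np.flatnonzero(np.concatenate(([True], change, [True])))
        runs = []
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if is_stop[a]:
                runs.append((int(a), int(b)))
        return runs

    @property
    def duration(self) -> float:
        return len(self.t) * self.sample_period

    def fiducial_mean(self) -> np.ndarray:
        """(T, 3) average of the three fiducial channels."""
        return self.fiducials.mean(axis=0)

    def replace_solenoid(self, solenoid: np.ndarray) -> "SensorRecording":
        return SensorRecording(
            t=self.t.copy(),
            solenoid=np.asarray(solenoid, dtype=float),
            fiducials=self.fiducials.copy(),
            command=self.command.copy(),
            dwell_index=self.dwell_index.copy(),
            catheter_id=self.catheter_id.copy(),
            sample_period=self.sample_period,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t": self.t, "x": self.solenoid[:, 0], "y": self.solenoid[:, 1],
                "z": self.solenoid[:, 2]}
        for i in range(3):
            for j, a in enumerate(("x", "y", "z")):
                data[f"fid{i + 1}_{a}"] = self.fiducials[i, :, j]
        data["command"] = self.command
        data["dwell_index"] = self.dwell_index
        data["catheter_id"] = self.catheter_id
        return pd.DataFrame(data, columns=RECORDING_COLUMNS)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        sample_period: float = 1.0 / 40.0,
    ) -> "SensorRecording":
        """Build a recording from a dataframe in (a dialect of) the canonical
        layout.

        This is the converter entry point for adapting externally deposited
        recordings: pass ``column_map`` mapping canonical column names to the
        names used by the foreign table.
        """
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
        if missing:
            raise RecordingFormatError(f"recording is missing columns {missing}")
        fid = np.stack([
            df[[f"fid{i}_x", f"fid{i}_y", f"fid{i}_z"]].to_numpy(dtype=float)
            for i in (1, 2, 3)
        ])
        return cls(
            t=df["t"].to_numpy(dtype=float),
            solenoid=df[["x", "y", "z"]].to_numpy(dtype=float),
            fiducials=fid,
            command=df["command"].to_numpy(),
            dwell_index=df["dwell_index"].to_numpy(dtype=int),
            catheter_id=df["catheter_id"].to_numpy(dtype=int),
            sample_period=sample_period,
        )


def read_emt_recording(path: str | Path, sample_period: float = 1.0 / 40.0) -> SensorRecording:
    """Read a recording from the canonical CSV schema.

    All rows are conserved; all-zero position rows (tracker dropouts) are
    retained verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    df = pd.read_csv(path)
    return SensorRecording.from_dataframe(df, sample_period=sample_period)


def write_emt_recording(recording: SensorRecording, path: str | Path) -> None:
    recording.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Deviation report
# ---------------------------------------------------------------------------

@dataclass
class DeviationReport:
    """Per-dwell-position plan-vs-measurement deviation magnitudes.

    ``deviations`` holds one ``(catheter_id, dwell_index, deviation_mm)``
    entry per matched dwell pair.  Summaries are derived: per-catheter means
    and the global mean, which equals the entry-count-weighted mean of the
    per-catheter means.  ``unmatched`` lists plan keys that were never
    traversed; they are excluded from all means.
    """

    deviations: tuple[tuple[int, int, float], ...]
    unmatched: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.deviations = tuple(
            (int(c), int(d), float(v)) for c, d, v in self.deviations
        )
        if any(v < 0 for _, _, v in self.deviations):
            raise ValueError("deviations must be non-negative")
        self.unmatched = tuple((int(c), int(d)) for c, d in self.unmatched)

    @property
    def catheter_ids(self) -> list[int]:
        seen: list[int] = []
        for c, _, _ in self.deviations:
            if c not in seen:
                seen.append(c)
        return seen

    def per_catheter_mean(self) -> dict[int, float]:
        sums: dict[int, list[float]] = {}
        for c, _, v in self.deviations:
            sums.setdefault(c, []).append(v)
        return {c: float(np.mean(v)) for c, v in sums.items()}

    @property
    def global_mean(self) -> float:
        if not self.deviations:
            return 0.0
        return float(np.mean([v for _, _, v in self.deviations]))

    def catheter_boundaries(self) -> list[int]:
        """Row offsets where a new catheter starts (for plot separators)."""
        bounds = []
        for i in range(1, len(self.deviations)):
            if self.deviations[i][0] != self.deviations[i - 1][0]:
                bounds.append(i)
        return bounds


def write_deviation_report(report: DeviationReport, path: str | Path) -> None:
    """Write a deviation report as CSV plus a ``#``-comment summary block."""
    lines = ["catheter_id,dwell_index,deviation_mm"]
    for c, d, v in report.deviations:
        lines.append(f"{c},{d},{v!r}")
    for c, m in report.per_catheter_mean().items():
        lines.append(f"# catheter_mean,{c},{m!r}")
    lines.append(f"# global_mean,{report.global_mean!r}")
    for c, d in report.unmatched:
        lines.append(f"# unmatched,{c},{d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_deviation_report(path: str | Path) -> DeviationReport:
    path = Path(path)
    deviations: list[tuple[int, int, float]] = []
    unmatched: list[tuple[int, int]] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "catheter_id,dwell_index,deviation_mm":
            raise ValueError(f"{path}: not a deviation report (header {header!r})")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line.lstrip("# ").split(",")
                if fields[0] == "unmatched":
                    unmatched.append((int(fields[1]), int(fields[2])))
                continue
            c, d, v = line.split(",")
            deviations.append((int(c), int(d), float(v)))
    return DeviationReport(deviations=tuple(deviations), unmatched=tuple(unmatched))
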