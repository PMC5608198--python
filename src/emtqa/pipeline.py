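"""End-to-end orchestration of the EMT analysis chain.

Stage order (fixed): particle-filter tracking -> SSA outlier repair ->
fiducial averaging + first-SSA-component breathing reference -> EEMD of
sensor and breathing signals per spatial axis -> Fourier-area protection ->
similarity-flagged breathing-mode removal (optionally iterated) -> dwell
extraction -> MDS deviation report.

Every stage logs its seeds, thresholds and flagged/protected mode indices,
and ``run_pipeline(..., return_intermediates=True)`` keeps each stage's
output for audit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import eemd_core, mds_registration, particle_tracking, ssa_core
from .io_formats import DeviationReport, SensorRecording, TreatmentPlan

__all__ = [
    "TrackingConfig",
    "SSAConfig",
    "EEMDConfig",
    "MDSConfig",
    "PipelineConfig",
    "run_pipeline",
    "clean_recording",
    "baseline_deviation_report",
    "summarize",
]

logger = logging.getLogger("emtqa.pipeline")


@dataclass
class TrackingConfig:
    n_particles: int = 1000
    resample_threshold: float = 0.5
    state_noise_sd: float = 0.5   # mm
    obs_noise_sd: float = 0.5     # mm

    def motion_params(self) -> particle_tracking.MotionModelParams:
        return particle_tracking.MotionModelParams(
            state_noise_sd=self.state_noise_sd, obs_noise_sd=self.obs_noise_sd
        )


@dataclass
class SSAConfig:
    K: int | None = None          # None -> min(40, T // 4)
    neighbor_radius: int = 2      # samples patched around each outlier


@dataclass
class EEMDConfig:
    ensemble_size: int = 10       # E
    noise_sd: float = 0.2         # fraction of signal sd
    A_th: float = 0.04            # Fourier-area protection threshold
    measure: str = "pcc"          # pcc | kld | jsd
    threshold: float | None = None  # None -> per-measure default
    max_iterations: int = 1       # removal passes (re-decomposing each time)
    manual_drop_imfs: tuple[int, ...] = ()  # expert override, 0-based, axis-wide


@dataclass
class MDSConfig:
    method: str = "separate"      # separate | direct
    allow_reflection: bool = True


@dataclass
class PipelineConfig:
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    ssa: SSAConfig = field(default_factory=SSAConfig)
    eemd: EEMDConfig = field(default_factory=EEMDConfig)
    mds: MDSConfig = field(default_factory=MDSConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, klass in (("tracking", TrackingConfig), ("ssa", SSAConfig),
                               ("eemd", EEMDConfig), ("mds", MDSConfig)):
            if section in payload:
                values = dict(payload[section])
                if section == "eemd" and "manual_drop_imfs" in values:
                    values["manual_drop_imfs"] = tuple(values["manual_drop_imfs"])
                setattr(cfg, section, klass(**values))
        if "seed" in payload:
            cfg.seed = int(payload["seed"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["eemd"]["manual_drop_imfs"] = list(self.eemd.manual_drop_imfs)
        Path(path).write_text(yaml.safe_dump(payload))


def _catheter_segments(recording: SensorRecording) -> list[np.ndarray]:
    """Contiguous sample-index blocks, one per traversed catheter."""
    cid = recording.catheter_id
    change = np.flatnonzero(cid[1:] != cid[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(cid)]))
    return [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _slice_recording(recording: SensorRecording, idx: np.ndarray) -> SensorRecording:
    return SensorRecording(
        t=np.arange(len(idx)) * recording.sample_period,
        solenoid=recording.solenoid[idx],
        fiducials=recording.fiducials[:, idx, :],
        command=recording.command[idx],
        dwell_index=recording.dwell_index[idx],
        catheter_id=recording.catheter_id[idx],
        sample_period=recording.sample_period,
    )


def clean_recording(
    recording: SensorRecording, config: PipelineConfig | None = None,
    return_intermediates: bool = False,
):
    """Tracking, outlier repair and breathing removal, catheter by catheter.

    Each catheter's segment is processed separately -- its track is a single
    monotone staircase, so the breathing band is far less contaminated by
    transit structure than in the concatenated record.  Returns the cleaned
    recording (and, on request, every stage's intermediate output).
    """
    config = config or PipelineConfig()
    solenoid = np.empty_like(recording.solenoid)
    segments = _catheter_segments(recording)
    all_inter: list[dict[str, object]] = []
    for idx in segments:
        segment = _slice_recording(recording, idx)
        cleaned_seg, inter = _clean_segment(segment, config)
        solenoid[idx] = cleaned_seg
        all_inter.append(inter)
    cleaned_recording = recording.replace_solenoid(solenoid)
    if return_intermediates:
        merged: dict[str, object] = {"segments": all_inter}
        merged["tracked"] = recording.replace_solenoid(
            np.concatenate([i["tracked"] for i in all_inter])
        )
        merged["patched"] = np.concatenate([i["patched"] for i in all_inter])
        merged["outlier_indices"] = np.concatenate([
            seg_idx[i["outlier_indices"]] for seg_idx, i in zip(segments, all_inter)
        ]).astype(int)
        merged["breathing_reference"] = np.concatenate(
            [i["breathing_reference"] for i in all_inter]
        )
        merged["flagged_imfs"] = [i["flagged_imfs"] for i in all_inter]
        return cleaned_recording, merged
    return cleaned_recording


def _clean_segment(
    recording: SensorRecording, config: PipelineConfig
) -> tuple[np.ndarray, dict[str, object]]:
    intermediates: dict[str, object] = {}

    # 1. particle-filter tracking of the solenoid channel
    tracked = particle_tracking.track(
        recording,
        params=config.tracking.motion_params(),
        N=config.tracking.n_particles,
        resample_threshold=config.tracking.resample_threshold,
        seed=config.seed,
    )
    intermediates["tracked"] = tracked.solenoid
    logger.info("tracking done (N=%d, seed=%d)", config.tracking.n_particles, config.seed)

    # 2. outlier detection per axis, union of flagged indices, SSA patching
    flagged_idx: set[int] = set()
    for axis in range(3):
        flagged_idx.update(
            int(i) for i in ssa_core.detect_outliers(tracked.solenoid[:, axis])
        )
    outliers = np.array(sorted(flagged_idx), dtype=int)
    patched = tracked.solenoid.copy()
    for axis in range(3):
        patched[:, axis] = ssa_core.patch_outliers(
            tracked.solenoid[:, axis], outliers,
            neighbor_radius=config.ssa.neighbor_radius, K=config.ssa.K,
        )
    logger.info("outlier repair: %d samples patched", len(outliers))
    intermediates["outlier_indices"] = outliers
    intermediates["patched"] = patched

    # 3. breathing reference: fiducial average, first SSA component per axis
    breathing_ref = ssa_core.denoise_fiducial(recording.fiducials, K=config.ssa.K)
    intermediates["breathing_reference"] = breathing_ref

    # 4. per-axis EEMD, Fourier-area protection, similarity removal
    ecfg = config.eemd
    cleaned = np.empty_like(patched)
    flags_per_axis: list[list[set[int]]] = []
    for axis in range(3):
        signal = patched[:, axis]
        axis_flags: list[set[int]] = []
        segment_tag = int(recording.catheter_id[0])
        for iteration in range(max(1, ecfg.max_iterations)):
            seed = ((config.seed * 1000 + segment_tag * 100 + axis * 10 + iteration)
                    % (2**31 - 1))
            sensor_imfs = eemd_core.eemd(
                signal, E=ecfg.ensemble_size, noise_sd=ecfg.noise_sd,
                seed=seed, sample_period=recording.sample_period,
            )
            breathing_imfs = eemd_core.eemd(
                breathing_ref[:, axis], E=ecfg.ensemble_size,
                noise_sd=ecfg.noise_sd, seed=seed + 7,
                sample_period=recording.sample_period,
            )
            protected = eemd_core.select_protected_imfs(sensor_imfs, A_th=ecfg.A_th)
            # the trend carries the catheter track itself; never remove it
            protected.add(sensor_imfs.trend_index)
            flagged = eemd_core.identify_breathing_imfs(
                sensor_imfs, breathing_imfs, measure=ecfg.measure,
                threshold=ecfg.threshold, protected=protected,
            )
            flagged |= {
                j for j in ecfg.manual_drop_imfs if 0 <= j < sensor_imfs.n_imfs
            }
            logger.info(
                "axis %d pass %d: %d modes, protected %s, flagged %s",
                axis, iteration, sensor_imfs.n_imfs,
                sorted(protected), sorted(flagged),
            )
            axis_flags.append(flagged)
            if not flagged:
                break
            signal = eemd_core.remove_breathing(signal, flagged, sensor_imfs)
        cleaned[:, axis] = signal
        flags_per_axis.append(axis_flags)
    intermediates["flagged_imfs"] = flags_per_axis
    return cleaned, intermediates


def run_pipeline(
    plan: TreatmentPlan,
    recording: SensorRecording,
    config: PipelineConfig | None = None,
    return_intermediates: bool = False,
):
    """Full chain from raw recording to a plan-vs-measurement deviation report."""
    config = config or PipelineConfig()
    result = clean_recording(recording, config, return_intermediates=True)
    cleaned_recording, intermediates = result

    measured = mds_registration.extract_dwell_positions(cleaned_recording)
    plan_set = mds_registration.DwellPositionSet.from_plan(plan)
    report = mds_registration.align_and_deviate(
        plan_set, measured,
        method=config.mds.method,
        allow_reflection=config.mds.allow_reflection,
    )
    logger.info(
        "deviation report: %d pairs, global mean %.3f mm",
        len(report.deviations), report.global_mean,
    )
    intermediates["cleaned"] = cleaned_recording
    intermediates["measured_dwells"] = measured
    if return_intermediates:
        return report, intermediates
    return report


def baseline_deviation_report(
    plan: TreatmentPlan, recording: SensorRecording,
    mds: MDSConfig | None = None,
) -> DeviationReport:
    """Deviations of the *unprocessed* recording: dwell extraction straight
    from the raw solenoid channel.  The no-cleaning reference against which
    the pipeline is judged."""
    mds = mds or MDSConfig()
    measured = mds_registration.extract_dwell_positions(recording)
    plan_set = mds_registration.DwellPositionSet.from_plan(plan)
    return mds_registration.align_and_deviate(
        plan_set, measured, method=mds.method, allow_reflection=mds.allow_reflection
    )


def summarize(report: DeviationReport, figure_path: str | Path | None = None) -> str:
    """Plain-text per-catheter table; optionally a deviation-vs-dwell-pair
    plot with vertical separators between catheters."""
    if not report.deviations:
        raise ValueError("cannot summarize an empty report")
    lines = ["catheter  n_pairs  mean_deviation_mm"]
    per_cath = report.per_catheter_mean()
    counts: dict[int, int] = {}
    for c, _, _ in report.deviations:
        counts[c] = counts.get(c, 0) + 1
    for c in report.catheter_ids:
        lines.append(f"{c:>8d}  {counts[c]:>7d}  {per_cath[c]:>17.3f}")
    lines.append(f"global mean over {len(report.deviations)} pairs: "
                 f"{report.global_mean:.3f} mm")
    if report.unmatched:
        lines.append(f"unmatched plan positions (excluded from means): "
                     f"{len(report.unmatched)}")
    text = "\n".join(lines)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        values = [v for _, _, v in report.deviations]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(range(len(values)), values, ".", ms=3)
        for b in report.catheter_boundaries():
            ax.axvline(b - 0.5, color="black", lw=0.8)
        ax.set_xlabel("dwell pair")
        ax.set_ylabel("absolute deviation [mm]")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return text
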