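"""Dwell-position extraction and plan-vs-measurement deviation via MDS.

Each EMT session refers to its own coordinate frame, so plan and measured
dwell positions are compared through classical multidimensional scaling,
which relies on pairwise distances only: the matrix of dissimilarities
(D)_mm' = -1/2 d^2(x_m, x_m') is double-centered into a kernel whose
eigendecomposition yields principal coordinates X_hat = V Lambda^{1/2}.
The two embeddings are brought onto a common axis system by
correspondence-based orthogonal alignment over the matched
(catheter, dwell index) keys -- this resolves the per-axis sign/reflection
ambiguity inherent to any spectral embedding -- and the deviation of a
dwell pair is the Euclidean distance between the aligned embedded points,
in physical mm (no scaling is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import DeviationReport, SensorRecording, TreatmentPlan

__all__ = [
    "DwellPositionSet",
    "MDSEmbedding",
    "DegenerateGeometryError",
    "extract_dwell_positions",
    "mds_embed",
    "align_and_deviate",
]

logger = logging.getLogger("emtqa.mds")


class DegenerateGeometryError(ValueError):
    """The point set spans fewer than 3 dimensions."""


@dataclass
class DwellPositionSet:
    """One 3-vector per (catheter_id, dwell_index) key, with the number of
    averaged samples N_s per entry."""

    keys: tuple[tuple[int, int], ...]   # (catheter_id, dwell_index)
    positions: np.ndarray               # (M, 3) mm
    n_samples: np.ndarray               # (M,)
    frame_label: str = "EMT"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        self.keys = tuple((int(c), int(d)) for c, d in self.keys)
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("(catheter_id, dwell_index) keys must be unique")
        if np.any(self.n_samples < 1):
            raise ValueError("every entry must average at least one sample")
        if self.positions.shape != (len(self.keys), 3):
            raise ValueError("positions must be (M, 3)")

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_plan(cls, plan: TreatmentPlan) -> "DwellPositionSet":
        keys, positions = [], []
        for cath in plan.catheters:
            for dp in cath.dwell_points:
                keys.append((cath.catheter_id, dp.dwell_index))
                positions.append(dp.position)
        return cls(
            keys=tuple(keys),
            positions=np.array(positions).reshape(len(keys), 3),
            n_samples=np.ones(len(keys), dtype=int),
            frame_label=plan.frame_label,
        )


def extract_dwell_positions(cleaned: SensorRecording) -> DwellPositionSet:
    """Average the point cloud of every STOP run into one dwell position.

    The afterloader command stream identifies the samples belonging to each
    stop, so keeping the component-wise mean per (catheter, dwell index) is
    sufficient; N_s records how many samples entered each average.
    """
    sums: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    order: list[tuple[int, int]] = []
    for start, stop in cleaned.stop_runs():
        key = (int(cleaned.catheter_id[start]), int(cleaned.dwell_index[start]))
        if key not in sums:
            sums[key] = np.zeros(3)
            counts[key] = 0
            order.append(key)
        sums[key] += cleaned.solenoid[start:stop].sum(axis=0)
        counts[key] += stop - start
    if not order:
        raise ValueError("recording contains no STOP annotations")
    positions = np.array([sums[k] / counts[k] for k in order])
    return DwellPositionSet(
        keys=tuple(order),
        positions=positions,
        n_samples=np.array([counts[k] for k in order]),
        frame_label="EMT",
    )


@dataclass
class MDSEmbedding:
    """Classical-MDS spectral coordinates of one dwell-position set."""

    dissimilarity: np.ndarray   # (M, M), -1/2 squared distances
    kernel: np.ndarray          # (M, M), double-centered
    eigenvalues: np.ndarray     # (M,), descending
    eigenvectors: np.ndarray    # (M, M), columns
    coordinates: np.ndarray     # (M, 3), X_hat rows

    @property
    def retained_dimension(self) -> int:
        return self.coordinates.shape[1]


def mds_embed(points: DwellPositionSet | np.ndarray) -> MDSEmbedding:
    """Embed a point set from its pairwise distances.

    Raises ``DegenerateGeometryError`` when fewer than 3 eigenvalues are
    positive (collinear or coplanar configurations have no 3-D embedding).
    """
    X = points.positions if isinstance(points, DwellPositionSet) else np.asarray(points, dtype=float)
    M = len(X)
    if M < 4:
        raise ValueError("at least 4 points are required for a 3-D embedding")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(d2, 0.0, None, out=d2)
    np.fill_diagonal(d2, 0.0)
    D = -0.5 * d2
    J = np.eye(M) - np.full((M, M), 1.0 / M)
    K = J @ D @ J
    K = 0.5 * (K + K.T)
    lam, V = np.linalg.eigh(K)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    tol = max(1e-9 * max(lam[0], 0.0), 1e-12)
    if np.sum(lam > tol) < 3:
        raise DegenerateGeometryError(
            "point set spans fewer than 3 dimensions; cannot embed in 3-D"
        )
    coords = V[:, :3] * np.sqrt(lam[:3])
    return MDSEmbedding(
        dissimilarity=D, kernel=K, eigenvalues=lam, eigenvectors=V,
        coordinates=coords,
    )


def _orthogonal_align(
    source: np.ndarray, target: np.ndarray, allow_reflection: bool = True
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Least-squares R, t mapping source -> target over correspondences.

    A reflection (det R = -1) is accepted only when it strictly reduces the
    residual -- spectral embeddings carry an arbitrary per-axis sign, so
    this is frequently the case.
    """
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (source - mu_s).T @ (target - mu_t)
    U, S, Vt = np.linalg.svd(H)
    R_free = Vt.T @ U.T
    flip = np.diag([1.0, 1.0, -1.0])
    R_rot = Vt.T @ flip @ U.T if np.linalg.det(R_free) < 0 else R_free

    def residual(R: np.ndarray) -> float:
        t = mu_t - R @ mu_s
        return float(np.sum((target - (source @ R.T + t)) ** 2))

    reflected = False
    R = R_rot
    if allow_reflection and np.linalg.det(R_free) < 0:
        if residual(R_free) < residual(R_rot):
            R = R_free
            reflected = True
            logger.info("reflection accepted during alignment (reduces residual)")
    t = mu_t - R @ mu_s
    return R, t, reflected


def align_and_deviate(
    plan: DwellPositionSet,
    measured: DwellPositionSet,
    method: str = "separate",
    allow_reflection: bool = True,
) -> DeviationReport:
    """Deviation magnitude per matched dwell pair after MDS registration.

    ``method="separate"`` (default) embeds both sets independently and
    aligns the measured embedding onto the plan embedding over the matched
    keys.  ``method="direct"`` skips the spectral embedding and aligns the
    raw coordinates; for exactly Euclidean data both routes agree.  Plan
    keys never traversed are reported as unmatched and excluded from means.
    """
    if method not in ("separate", "direct"):
        raise ValueError(f"unknown method {method!r}")
    plan_index = {k: i for i, k in enumerate(plan.keys)}
    meas_index = {k: i for i, k in enumerate(measured.keys)}
    matched = [k for k in plan.keys if k in meas_index]
    unmatched = tuple(k for k in plan.keys if k not in meas_index)
    if len(matched) < 4:
        raise ValueError(
            f"only {len(matched)} matched dwell pairs; at least 4 are needed"
        )
    if method == "separate":
        plan_coords = mds_embed(plan).coordinates
        meas_coords = mds_embed(measured).coordinates
    else:
        plan_coords = plan.positions
        meas_coords = measured.positions
    src = np.array([meas_coords[meas_index[k]] for k in matched])
    dst = np.array([plan_coords[plan_index[k]] for k in matched])
    R, t, _ = _orthogonal_align(src, dst, allow_reflection)
    deviations = np.linalg.norm(dst - (src @ R.T + t), axis=1)
    return DeviationReport(
        deviations=tuple(
            (k[0], k[1], float(v)) for k, v in zip(matched, deviations)
        ),
        unmatched=unmatched,
    )
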