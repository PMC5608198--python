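"""Linear and distribution-based similarity between component time series.

The Pearson correlation coefficient compares two series pointwise; the
Kullback-Leibler and Jensen-Shannon divergences, Shannon entropy and mutual
information compare probability histograms derived from the series by
sample counting.  Histograms meant for divergence computations share equal
bin edges over the pooled range of the pair, and zero bins are replaced by
a small epsilon <= 1e-3 and renormalised so that the KLD stays finite.

Natural logarithms are used throughout, so the Jensen-Shannon divergence is
bounded by ln 2 and sqrt(JSD) is a metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbabilityHistogram",
    "pcc",
    "to_histogram",
    "histogram_pair",
    "kld",
    "jsd",
    "shannon_entropy",
    "mutual_information",
]


@dataclass(frozen=True)
class ProbabilityHistogram:
    """Equal-width binned probabilities summing to one.

    After epsilon-smoothing every probability is at least
    epsilon / (1 + n_bins * epsilon) > 0.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "probabilities",
                           np.asarray(self.probabilities, dtype=float))
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("need n_bins + 1 bin edges")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 (within 1e-12)")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)

    def same_binning(self, other: "ProbabilityHistogram") -> bool:
        return (self.n_bins == other.n_bins
                and np.allclose(self.bin_edges, other.bin_edges))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient in [-1, 1].

    PCC = (L*Sxy - Sx*Sy) / sqrt((L*Sxx - Sx^2)(L*Syy - Sy^2)).
    A zero-variance argument makes the coefficient undefined; by convention
    0 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D series of length >= 2")
    L = len(x)
    num = L * np.dot(x, y) - x.sum() * y.sum()
    den_x = L * np.dot(x, x) - x.sum() ** 2
    den_y = L * np.dot(y, y) - y.sum() ** 2
    if den_x <= 0 or den_y <= 0:
        warnings.warn("correlation undefined for a zero-variance series; returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip(num / np.sqrt(den_x * den_y), -1.0, 1.0))


def _default_bins(length: int) -> int:
    return max(2, int(np.ceil(np.sqrt(length))))


def to_histogram(
    x: np.ndarray,
    n_bins: int | None = None,
    epsilon: float = 1e-4,
    value_range: tuple[float, float] | None = None,
) -> ProbabilityHistogram:
    """Probability histogram of ``x`` by sample counting.

    Zero bins are replaced by ``epsilon`` and the histogram renormalised.
    ``value_range`` fixes the bin edges, which lets two series share a
    common binning (see ``histogram_pair``).
    """
    x = np.asarray(x, dtype=float)
    if n_bins is None:
        n_bins = _default_bins(len(x))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not (0.0 < epsilon <= 1e-3):
        raise ValueError("epsilon must lie in (0, 1e-3] (KLD needs positivity)")
    counts, edges = np.histogram(x, bins=n_bins, range=value_range)
    p = counts.astype(float)
    total = p.sum()
    if total > 0:
        p /= total
    else:
        p = np.full(n_bins, 1.0 / n_bins)
    p = np.where(p == 0.0, epsilon, p)
    p /= p.sum()
    return ProbabilityHistogram(bin_edges=edges, probabilities=p, epsilon=epsilon)


def histogram_pair(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int | None = None,
    epsilon: float = 1e-4,
) -> tuple[ProbabilityHistogram, ProbabilityHistogram]:
    """Histogram both series over their pooled min-max range with shared
    edges, as required for divergence comparisons."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins is None:
        n_bins = _default_bins(max(len(x), len(y)))
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        hi = lo + 1.0  # both constant: a single shared occupied bin
    rng = (lo, hi)
    return (to_histogram(x, n_bins, epsilon, rng),
            to_histogram(y, n_bins, epsilon, rng))


def _check_binning(p: ProbabilityHistogram, q: ProbabilityHistogram) -> None:
    if not p.same_binning(q):
        raise ValueError("histograms must share identical bin edges")


def _kld_arrays(p: np.ndarray, q: np.ndarray) -> float:
    # conventions: 0 ln(0/q) = 0; p ln(p/0) = +inf for p > 0
    total = 0.0
    for pi, qi in zip(p, q):
        if pi == 0.0:
            continue
        if qi == 0.0:
            return float("inf")
        total += pi * np.log(pi / qi)
    return max(0.0, float(total))


def kld(p: ProbabilityHistogram, q: ProbabilityHistogram) -> float:
    """Kullback-Leibler divergence sum p ln(p/q) >= 0; zero iff p == q.

    Not symmetric; infinite when q lacks support where p has mass (epsilon
    smoothing prevents this for histograms built by ``to_histogram``).
    """
    _check_binning(p, q)
    return _kld_arrays(p.probabilities, q.probabilities)


def jsd(p: ProbabilityHistogram, q: ProbabilityHistogram) -> float:
    """Jensen-Shannon divergence, symmetric and bounded by ln 2:
    JSD = (KLD(p || m) + KLD(q || m)) / 2 with m = (p + q) / 2."""
    _check_binning(p, q)
    m = 0.5 * (p.probabilities + q.probabilities)
    value = 0.5 * _kld_arrays(p.probabilities, m) + 0.5 * _kld_arrays(q.probabilities, m)
    return float(np.clip(value, 0.0, np.log(2.0)))


def shannon_entropy(p: ProbabilityHistogram | np.ndarray) -> float:
    """H = -sum p ln p (0 ln 0 = 0)."""
    probs = p.probabilities if isinstance(p, ProbabilityHistogram) else np.asarray(p, dtype=float)
    nz = probs[probs > 0]
    return float(-np.sum(nz * np.log(nz)))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """MI = KLD(joint || product of marginals), from a 2-D sample-count
    histogram; zero iff the binned variables are independent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_bins is None:
        n_bins = _default_bins(len(x))
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            pij = joint[i, j]
            if pij > 0:
                total += pij * np.log(pij / (px[i] * py[j]))
    return max(0.0, float(total))
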