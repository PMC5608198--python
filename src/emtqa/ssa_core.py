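"""Singular spectrum analysis: fiducial denoising and outlier repair.

A length-T series is embedded into K delayed coordinates, giving the L x K
Hankel trajectory matrix X (T = K + L - 1, L > K).  Eigendecomposition of
the K x K matrix X^T X yields an ordered eigenspectrum; projecting onto the
eigenvectors and anti-diagonal averaging of the rank-1 component matrices
returns additive component series whose sum reproduces the input exactly.

Two uses downstream:

* the averaged fiducial (breathing) signal is replaced by its first SSA
  component (denoising);
* tracker dropouts in the solenoid signal, flagged by the rule
  |x - median(x)| > 2 * std(x), are patched with first-SSA-component values
  while every other sample is kept bit-identical, preserving the
  stop-position information.

Series are decomposed without mean removal so that the first component
carries the local trend used as the replacement value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SSADecomposition",
    "decompose",
    "reconstruct",
    "denoise_fiducial",
    "detect_outliers",
    "patch_outliers",
    "default_embedding_dim",
]


def default_embedding_dim(series_length: int) -> int:
    """K = min(40, T // 4): captures breathing periods at 40 Hz while
    keeping the segment length L well above K."""
    return max(2, min(40, series_length // 4))


@dataclass
class SSADecomposition:
    """Eigenstructure and component series of one channel.

    ``components[k]`` is the length-T series obtained by anti-diagonal
    averaging of the rank-1 matrix z_k v_k^T; their sum over all k equals
    the original series (perfect reconstruction).
    """

    series: np.ndarray        # (T,)
    K: int                    # embedding dimension
    eigenvalues: np.ndarray   # (K,) descending, eigenvalues of X^T X
    eigenvectors: np.ndarray  # (K, K) columns v_k, orthonormal
    projections: np.ndarray   # (L, K) columns z_k = X v_k
    components: np.ndarray    # (K, T)

    @property
    def T(self) -> int:
        return len(self.series)

    @property
    def L(self) -> int:
        return self.T - self.K + 1

    def trajectory_matrix(self) -> np.ndarray:
        """The L x K Hankel matrix X with X[i, j] = x[i + j]."""
        return sliding_window_view(self.series, self.K)


def _antidiagonal_average(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    # anti-diagonal s of outer(z, v) collects pairs i + j = s, so the sums
    # are the full convolution of z with v; dividing by the pair count
    # Hankelises and unfolds (first row then last column) in one step
    L, K = len(z), len(v)
    counts = np.convolve(np.ones(L), np.ones(K), mode="full")
    return np.convolve(z, v, mode="full") / counts


def decompose(series: np.ndarray, K: int | None = None) -> SSADecomposition:
    """Embed, eigendecompose X^T X and return the ordered decomposition."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    T = len(x)
    if K is None:
        K = default_embedding_dim(T)
    if K < 2:
        raise ValueError("embedding dimension K must be >= 2")
    if T < 2 * K:
        raise ValueError(f"series of length {T} is too short for K={K} (need T >= 2K)")
    X = sliding_window_view(x, K)            # (L, K), Hankel
    R = X.T @ X
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    V = V[:, order]
    Z = X @ V
    components = np.empty((K, T))
    for k in range(K):
        components[k] = _antidiagonal_average(Z[:, k], V[:, k])
    return SSADecomposition(
        series=x.copy(), K=K, eigenvalues=lam, eigenvectors=V,
        projections=Z, components=components,
    )


def reconstruct(decomp: SSADecomposition, component_indices) -> np.ndarray:
    """Sum the selected component series (already Hankelised and unfolded).

    An empty index set yields the zero series.
    """
    idx = np.asarray(sorted(set(int(i) for i in component_indices)), dtype=int)
    if idx.size == 0:
        return np.zeros(decomp.T)
    if idx.min() < 0 or idx.max() >= decomp.K:
        raise IndexError(f"component indices must lie in [0, {decomp.K - 1}]")
    return decomp.components[idx].sum(axis=0)


def denoise_fiducial(fiducials: np.ndarray, K: int | None = None) -> np.ndarray:
    """Average the three fiducial channels and keep only the first SSA
    component per axis; returns the (T, 3) breathing reference."""
    fid = np.asarray(fiducials, dtype=float)
    if fid.ndim != 3 or fid.shape[0] < 3:
        raise ValueError("three fiducial channels of shape (3, T, 3) are required")
    mean = fid.mean(axis=0)
    out = np.empty_like(mean)
    for axis in range(3):
        out[:, axis] = decompose(mean[:, axis], K).components[0]
    return out


def detect_outliers(series: np.ndarray) -> np.ndarray:
    """Indices satisfying |x - median(x)| > 2 * std(x).

    The sample standard deviation and median are taken over the full series
    in a single pass.  A zero-variance series has no outliers (the rule is
    unsatisfiable).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    sd = np.std(x, ddof=1)
    if sd == 0.0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(x - np.median(x)) > 2.0 * sd)


def patch_outliers(
    series: np.ndarray,
    outliers: np.ndarray,
    neighbor_radius: int = 2,
    K: int | None = None,
) -> np.ndarray:
    """Replace flagged samples and their +-neighbor_radius neighbours with
    first-SSA-component values; all other samples are bit-identical."""
    x = np.asarray(series, dtype=float)
    idx = np.asarray(outliers, dtype=int)
    patched = x.copy()
    if idx.size == 0:
        return patched
    mask = np.zeros(len(x), dtype=bool)
    for i in idx:
        lo = max(0, i - neighbor_radius)
        hi = min(len(x), i + neighbor_radius + 1)
        mask[lo:hi] = True
    first = decompose(x, K).components[0]
    patched[mask] = first[mask]
    return patched
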