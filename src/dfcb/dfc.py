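"""Sliding-window dynamic functional connectivity (DFC).

A subject's N×R ROI time series is cut into K = floor((N−T)/S)+1
overlapping windows of length T advanced by step S; each window yields a
symmetric R×R Pearson-correlation matrix D(k). The K matrices are then
flattened into the edge×window matrix A whose row m tracks one ROI pair's
correlation over windows (row-major upper-triangle order). Window and edge
indices are 1-based in the public API, matching the usual presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "DFCSeries",
    "EdgeTimeMatrix",
    "num_windows",
    "slice_window",
    "pearson_corr",
    "fc_matrix",
    "build_dfc",
    "vectorize_upper",
    "devectorize",
    "edge_to_pair",
    "pair_to_edge",
    "n_edges",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length T, step S (in time points)."""

    T: int
    S: int

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"window length T must be ≥ 2, got {self.T}")
        if self.S < 1:
            raise ValueError(f"step S must be ≥ 1, got {self.S}")


@dataclass
class DFCSeries:
    """K windowed correlation matrices, stacked K×R×R."""

    matrices: np.ndarray  # (K, R, R)
    window_spec: WindowSpec

    @property
    def K(self) -> int:
        return self.matrices.shape[0]

    @property
    def R(self) -> int:
        return self.matrices.shape[1]


@dataclass
class EdgeTimeMatrix:
    """Edge×window matrix A: row m is edge m's correlation time course."""

    values: np.ndarray  # (n_edges, K)
    edge_pairs: np.ndarray  # (n_edges, 2), 1-based (i, j) with i < j
    R: int

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


def n_edges(R: int) -> int:
    return R * (R - 1) // 2


def num_windows(N: int, T: int, S: int) -> int:
    """K = floor((N−T)/S) + 1 full windows; trailing points are discarded."""
    if T < 2:
        raise ValueError(f"T must be ≥ 2, got {T}")
    if T > N:
        raise ValueError(f"window length T={T} exceeds series length N={N}")
    if S < 1:
        raise ValueError(f"S must be ≥ 1, got {S}")
    return (N - T) // S + 1


def slice_window(ts: np.ndarray, spec: WindowSpec, k: int) -> np.ndarray:
    """Rows (k−1)·S+1 … (k−1)·S+T (1-based, inclusive) of the series."""
    ts = np.asarray(ts)
    K = num_windows(ts.shape[0], spec.T, spec.S)
    if not (1 <= k <= K):
        raise IndexError(f"window index k={k} outside 1..{K}")
    start = (k - 1) * spec.S
    return ts[start : start + spec.T]


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length vectors.

    Raises on zero-variance input rather than silently returning 0: a
    constant window makes the correlation undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson_corr needs two equal-length 1-D vectors of length ≥ 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def fc_matrix(window: np.ndarray) -> np.ndarray:
    """Symmetric R×R correlation matrix of one T×R window, unit diagonal."""
    window = np.asarray(window, dtype=float)
    sd = window.std(axis=0)
    if np.any(sd == 0):
        rois = np.flatnonzero(sd == 0) + 1
        raise ValueError(f"constant column(s) in window for ROI(s) {rois.tolist()}")
    D = np.corrcoef(window, rowvar=False)
    D = np.clip(D, -1.0, 1.0)
    np.fill_diagonal(D, 1.0)
    return (D + D.T) / 2.0


def build_dfc(ts: np.ndarray, spec: WindowSpec) -> DFCSeries:
    """All K windowed FC matrices of one subject."""
    ts = np.asarray(ts, dtype=float)
    N, R = ts.shape
    K = num_windows(N, spec.T, spec.S)
    mats = np.empty((K, R, R))
    for k in range(1, K + 1):
        try:
            mats[k - 1] = fc_matrix(slice_window(ts, spec, k))
        except ValueError as exc:
            raise ValueError(f"window {k}: {exc}") from None
    return DFCSeries(mats, spec)


def _upper_indices(R: int) -> tuple[np.ndarray, np.ndarray]:
    # np.triu_indices is row-major: (0,1),(0,2),…,(0,R−1),(1,2),… — the
    # fixed edge ordering used throughout.
    return np.triu_indices(R, k=1)


def vectorize_upper(dfc: DFCSeries) -> EdgeTimeMatrix:
    """Stack each D(k)'s upper triangle as column k of A (n_edges×K)."""
    if dfc.K == 0:
        raise ValueError("empty DFC series")
    iu, ju = _upper_indices(dfc.R)
    A = dfc.matrices[:, iu, ju].T  # (n_edges, K)
    pairs = np.stack([iu + 1, ju + 1], axis=1)
    return EdgeTimeMatrix(np.ascontiguousarray(A), pairs, dfc.R)


def devectorize(column: np.ndarray, R: int) -> np.ndarray:
    """Rebuild a symmetric unit-diagonal R×R matrix from one column of A."""
    column = np.asarray(column, dtype=float)
    if column.size != n_edges(R):
        raise ValueError(f"expected {n_edges(R)} edge values for R={R}, got {column.size}")
    D = np.eye(R)
    iu, ju = _upper_indices(R)
    D[iu, ju] = column
    D[ju, iu] = column
    return D


def edge_to_pair(m: int, R: int) -> tuple[int, int]:
    """1-based row index m → 1-based ROI pair (i, j), i < j (row-major order)."""
    M = n_edges(R)
    if not (1 <= m <= M):
        raise IndexError(f"edge index m={m} outside 1..{M}")
    m0 = m - 1
    i = 0
    # row i (0-based) holds R−1−i edges
    while m0 >= R - 1 - i:
        m0 -= R - 1 - i
        i += 1
    return (i + 1, i + 2 + m0)


def pair_to_edge(i: int, j: int, R: int) -> int:
    """Inverse of :func:`edge_to_pair` (all 1-based)."""
    if not (1 <= i < j <= R):
        raise IndexError(f"invalid pair ({i}, {j}) for R={R}")
    i0, j0 = i - 1, j - 1
    return i0 * (2 * R - i0 - 1) // 2 + (j0 - i0 - 1) + 1
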