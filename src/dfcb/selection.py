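"""t-test feature selection and back-projection to ROI pairs/frequencies.

Projected feature matrices are flattened row-major into per-subject
vectors; each feature is screened with a two-sample t-test and those with
p below a raw threshold (no multiplicity correction — the screening is
deliberately liberal) are kept. A selected bilateral feature at position
(a, b) can be traced back to the ROI pair carrying the largest spatial
loading |Z[·, a]| and the frequency bin with the largest temporal loading
|X[·, b]|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bilateral_pca import ProjectionPair
from .dfc import edge_to_pair

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "BackProjectedFeature",
    "flatten_features",
    "unflatten_features",
    "two_sample_t",
    "select_features",
    "stable_features",
    "backproject",
]


@dataclass
class FeatureTable:
    """n_subjects×p feature matrix aligned with cohort order."""

    values: np.ndarray
    labels: np.ndarray
    feature_coords: list[tuple[int, int]] | None = None  # flat index → (a, b), 1-based


@dataclass
class SelectionResult:
    p_values: np.ndarray  # length p; NaN for zero-variance (excluded) features
    selected: np.ndarray  # sorted 0-based indices with p < alpha
    alpha: float

    @property
    def selected_set(self) -> frozenset[int]:
        return frozenset(int(j) for j in self.selected)


@dataclass
class BackProjectedFeature:
    flat_index: int  # 0-based position in the flattened feature vector
    coord: tuple[int, int]  # (a, b), 1-based position in C
    spatial_edge: tuple[int, int]  # 1-based ROI pair (i, j), i < j
    spatial_names: tuple[str, str] | None
    temporal_bin: int  # 1-based frequency bin
    p_value: float = field(default=float("nan"))


def flatten_features(C: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-major flattening of a q×d feature matrix with a coordinate map."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    q, d = C.shape
    coords = [(a + 1, b + 1) for a in range(q) for b in range(d)]
    return C.reshape(-1), coords


def unflatten_features(v: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return np.asarray(v, dtype=float).reshape(shape)


def two_sample_t(values: np.ndarray, labels: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p for one feature.

    Pooled-variance Student's t by default (df = n−2); Welch's correction
    optional. Zero pooled variance returns (0, 1) — a degenerate feature
    carries no evidence and is excluded upstream rather than crashing.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g0 = values[labels == 0]
    g1 = values[labels == 1]
    if g0.size < 2 or g1.size < 2:
        raise ValueError("each class needs ≥ 2 subjects for a t-test")
    n0, n1 = g0.size, g1.size
    v0 = g0.var(ddof=1)
    v1 = g1.var(ddof=1)
    diff = g1.mean() - g0.mean()
    if welch:
        se2 = v0 / n0 + v1 / n1
        if se2 == 0:
            return 0.0, 1.0
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        if sp2 == 0:
            return 0.0, 1.0
        t = diff / np.sqrt(sp2 * (1 / n0 + 1 / n1))
        df = n0 + n1 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def select_features(table: FeatureTable, alpha: float, welch: bool = False) -> SelectionResult:
    """Indices of features with two-sample p < alpha (zero-variance dropped).

    Vectorized pooled-t over all columns; matches :func:`two_sample_t`
    feature by feature.
    """
    X = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("feature table rows must align with labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    g0 = X[y == 0]
    g1 = X[y == 1]
    n0, n1 = g0.shape[0], g1.shape[0]
    v0 = g0.var(axis=0, ddof=1)
    v1 = g1.var(axis=0, ddof=1)
    diff = g1.mean(axis=0) - g0.mean(axis=0)
    p = np.full(X.shape[1], np.nan)
    if welch:
        se2 = v0 / n0 + v1 / n1
        ok = se2 > 0
        t = np.zeros_like(diff)
        t[ok] = diff[ok] / np.sqrt(se2[ok])
        df = np.ones_like(diff)
        df[ok] = se2[ok] ** 2 / (
            (v0[ok] / n0) ** 2 / (n0 - 1) + (v1[ok] / n1) ** 2 / (n1 - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        ok = sp2 > 0
        t = np.zeros_like(diff)
        t[ok] = diff[ok] / np.sqrt(sp2[ok] * (1 / n0 + 1 / n1))
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n0 + n1 - 2)
    selected = np.flatnonzero(np.nan_to_num(p, nan=np.inf) < alpha)
    return SelectionResult(p_values=p, selected=selected, alpha=alpha)


def stable_features(per_fold_selections: list[set[int] | frozenset[int]]) -> frozenset[int]:
    """Features selected in every fold (intersection across folds)."""
    if not per_fold_selections:
        raise ValueError("need at least one fold selection")
    out = set(per_fold_selections[0])
    for s in per_fold_selections[1:]:
        out &= set(s)
    return frozenset(out)


def backproject(
    selected: list[int] | np.ndarray,
    pair: ProjectionPair,
    R: int,
    roi_labels: list[str] | None = None,
    p_values: np.ndarray | None = None,
) -> list[BackProjectedFeature]:
    """Map selected flat features to their maximal-loading edge and bin.

    Flat index j (0-based, row-major over the q×d feature matrix) sits at
    coordinate (a, b); the spatial contributor is the edge maximizing
    |Z[m, a]| (ties → smallest edge index) and the temporal contributor
    the bin maximizing |X[u, b]| (ties → smallest bin).
    """
    out = []
    d = pair.d
    for j in np.asarray(selected, dtype=int):
        a0, b0 = divmod(int(j), d)
        if not (0 <= a0 < pair.q):
            raise IndexError(f"flat feature index {j} outside q·d = {pair.q * d}")
        m0 = int(np.argmax(np.abs(pair.Z[:, a0])))  # argmax takes the first max: smallest index wins ties
        u0 = int(np.argmax(np.abs(pair.X[:, b0])))
        edge = edge_to_pair(m0 + 1, R)
        names = None
        if roi_labels is not None:
            names = (roi_labels[edge[0] - 1], roi_labels[edge[1] - 1])
        out.append(
            BackProjectedFeature(
                flat_index=int(j),
                coord=(a0 + 1, b0 + 1),
                spatial_edge=edge,
                spatial_names=names,
                temporal_bin=u0 + 1,
                p_value=float(p_values[j]) if p_values is not None else float("nan"),
            )
        )
    return out
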