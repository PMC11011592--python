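"""Repeated stratified cross-validated evaluation of the feature methods.

Six feature methods share one evaluation harness:

* ``proposed`` — bilateral (2D)²PCA on grid-averaged DFT magnitude spectra
  of edge time courses;
* ``fourier_temporal`` / ``fourier_spatial`` — one-directional 2DPCA on the
  same spectra (A·X, resp. Zᵀ·A);
* ``temporal_spatial`` — bilateral (2D)²PCA on the raw (time-domain) edge
  time courses, no Fourier step;
* ``central`` — per-edge central-moment summaries;
* ``t_index`` — binary-graph topological indices per window.

Within every training fold the projection matrices and the t-test feature
screen are fitted on training subjects only (no leakage); a linear SVM
(C configurable, features standardized by training-fold mean/sd) is the
classifier. Per repeat, fold confusion counts are pooled into one metrics
report; the final report averages the per-repeat metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import bilateral_pca as bpca
from .baselines import central_moment_features, topo_features
from .dfc import WindowSpec, build_dfc, num_windows, vectorize_upper
from .io import METHODS, PipelineConfig
from .selection import FeatureTable, select_features, stable_features
from .spectral import SpectralMatrix, average_spectra, spectral_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "CVResult",
    "FoldModel",
    "make_folds",
    "confusion_metrics",
    "extract_method_inputs",
    "fit_fold",
    "predict_fold",
    "run_method",
    "compare_methods",
    "parameter_grid_run",
    "repeat_stable_features",
]

PCA_METHODS = ("proposed", "fourier_temporal", "fourier_spatial", "temporal_spatial")


@dataclass(frozen=True)
class FoldAssignment:
    repeat: int
    fold: int
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int


@dataclass
class MetricsReport:
    """Confusion counts and the six derived metrics, in percent.

    Undefined ratios (zero denominators) are NaN, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def acc(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def tpr(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.ppv, self.tpr
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2.0 * p * r / (p + r)

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc, "TPR": self.tpr, "TNR": self.tnr,
            "PPV": self.ppv, "NPV": self.npv, "F1": self.f1,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
        }


@dataclass
class MeanMetrics:
    """Metric averages across repeats (counts do not apply)."""

    ACC: float
    TPR: float
    TNR: float
    PPV: float
    NPV: float
    F1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.ACC, "TPR": self.TPR, "TNR": self.TNR,
            "PPV": self.PPV, "NPV": self.NPV, "F1": self.F1,
        }


@dataclass
class FoldModel:
    """Everything fitted on one training fold."""

    method: str
    pair: bpca.ProjectionPair | None
    selected: np.ndarray  # 0-based flat feature indices used by the SVM
    p_values: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    svm: SVC


@dataclass
class CVResult:
    method: str
    config: dict
    folds: list[FoldAssignment]
    per_fold_metrics: list[MetricsReport]
    per_fold_selected: list[frozenset[int]]
    per_fold_predictions: list[np.ndarray]
    per_repeat_metrics: list[MetricsReport]
    final: MeanMetrics  # mean over repeats
    pooled: MetricsReport  # all repeats' counts pooled (also reported)

    @property
    def accuracy(self) -> float:
        return self.final.ACC


def make_folds(labels: np.ndarray, k: int, repeats: int, seed: int) -> list[FoldAssignment]:
    """Stratified k-fold assignments for each repeat, reproducible from seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    out = []
    for rep in range(repeats):
        rep_seed = int((seed + 1000003 * rep) % (2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(labels.size), labels)):
            out.append(FoldAssignment(rep, fold, tuple(tr.tolist()), tuple(te.tolist()), rep_seed))
    return out


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Confusion counts and metrics; positive class is label 1 (patients)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


# ----------------------------------------------------------- extraction

def _grid_specs(config: PipelineConfig, N: int) -> list[WindowSpec]:
    specs = []
    for T in config.window_lengths:
        for S in config.step_sizes:
            if T > N:
                warnings.warn(f"window length T={T} exceeds N={N}; cell skipped")
                continue
            specs.append(WindowSpec(T, S))
    if not specs:
        raise ValueError("no feasible (T, S) cell for this cohort")
    return specs


def extract_method_inputs(
    ts_list: list[np.ndarray],
    config: PipelineConfig,
    methods: list[str] | tuple[str, ...] = ("proposed",),
) -> dict[str, object]:
    """Per-subject feature inputs for each requested method.

    For the PCA methods the input is one matrix per subject (grid-averaged
    edge spectra, or padded time-domain edge courses for
    ``temporal_spatial``); for ``central``/``t_index`` it is one feature
    vector per subject (per-setting features averaged across the grid).
    All requested methods share one pass over the (T, S) grid.

    Subject-level extraction is classifier-independent (no labels touched),
    so it can safely happen once, outside the CV folds.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    N = min(ts.shape[0] for ts in ts_list)
    specs = _grid_specs(config, N)
    # pad every (T, S) run — and every subject, if lengths differ — to one
    # common DFT length so spectra are bin-aligned before averaging
    max_k = max(
        num_windows(ts.shape[0], sp.T, sp.S) for ts in ts_list for sp in specs
    )
    need_spectral = bool({"proposed", "fourier_temporal", "fourier_spatial"} & set(methods))
    need_time = "temporal_spatial" in methods
    need_central = "central" in methods
    need_topo = "t_index" in methods
    partition = np.asarray(config.partition) if config.partition is not None else None

    spectral_in: list[np.ndarray] = []
    time_in: list[np.ndarray] = []
    central_in: list[np.ndarray] = []
    topo_in: list[np.ndarray] = []
    for ts in ts_list:
        spectra: list[SpectralMatrix] = []
        padded: list[np.ndarray] = []
        centrals: list[np.ndarray] = []
        topos: list[np.ndarray] = []
        for sp in specs:
            dfc = build_dfc(ts, sp)
            A = vectorize_upper(dfc)
            if need_spectral:
                spectra.append(
                    spectral_matrix(A, pad_to=max_k, half=config.half_spectrum,
                                    mode=config.spectrum_mode)
                )
            if need_time:
                pad = np.zeros((A.n_edges, max_k))
                pad[:, : A.K] = A.values
                padded.append(pad)
            if need_central:
                centrals.append(
                    central_moment_features(A, config.moment_order_max).reshape(-1)
                )
            if need_topo:
                topos.append(topo_features(dfc, config.binarize_fraction, partition))
        if need_spectral:
            spectral_in.append(average_spectra(spectra).values)
        if need_time:
            time_in.append(np.mean(padded, axis=0))
        if need_central:
            central_in.append(np.mean(centrals, axis=0))
        if need_topo:
            topo_in.append(np.mean(topos, axis=0))

    out: dict[str, object] = {}
    for m in methods:
        if m in ("proposed", "fourier_temporal", "fourier_spatial"):
            out[m] = spectral_in
        elif m == "temporal_spatial":
            out[m] = time_in
        elif m == "central":
            out[m] = np.asarray(central_in)
        elif m == "t_index":
            out[m] = np.asarray(topo_in)
    return out


def _fold_feature_rows(inputs, idx, method, pair) -> np.ndarray:
    """Flattened per-subject feature vectors for the given subject indices."""
    if method in PCA_METHODS:
        rows = []
        for i in idx:
            A = inputs[i]
            if method == "fourier_temporal":
                F = bpca.project_rows_only(A, pair)
            elif method == "fourier_spatial":
                F = bpca.project_cols_only(A, pair)
            else:  # proposed, temporal_spatial: bilateral projection
                F = bpca.project(A, pair)
            rows.append(F.reshape(-1))
        return np.asarray(rows)
    return np.asarray([inputs[i] for i in idx])


def fit_fold(
    inputs, train_idx, labels: np.ndarray, method: str, config: PipelineConfig
) -> FoldModel:
    """Fit projections, feature screen and classifier on training subjects only."""
    train_idx = list(train_idx)
    y_tr = np.asarray(labels)[train_idx]
    pair = None
    if method in PCA_METHODS:
        pair = bpca.fit([inputs[i] for i in train_idx], config.theta_row, config.theta_col)
    X_tr = _fold_feature_rows(inputs, train_idx, method, pair)
    sel = select_features(FeatureTable(X_tr, y_tr), config.alpha, welch=config.welch)
    selected = sel.selected
    if selected.size == 0:
        # degenerate screen: keep the single most discriminative feature
        finite = np.nan_to_num(sel.p_values, nan=np.inf)
        selected = np.array([int(np.argmin(finite))])
        logger.warning("%s: empty feature selection in fold; falling back to min-p feature", method)
    Xs = X_tr[:, selected]
    mean = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    svm = SVC(kernel="linear", C=config.svm_c)
    svm.fit((Xs - mean) / sd, y_tr)
    return FoldModel(method, pair, selected, sel.p_values, mean, sd, svm)


def predict_fold(model: FoldModel, inputs, test_idx) -> np.ndarray:
    X_te = _fold_feature_rows(inputs, list(test_idx), model.method, model.pair)
    Xs = (X_te[:, model.selected] - model.scaler_mean) / model.scaler_sd
    return model.svm.predict(Xs)


def _aggregate(
    method: str,
    config: PipelineConfig,
    folds: list[FoldAssignment],
    metrics: list[MetricsReport],
    selections: list[frozenset[int]],
    predictions: list[np.ndarray],
) -> CVResult:
    repeats = sorted({f.repeat for f in folds})
    per_repeat = []
    for rep in repeats:
        counts = [m for f, m in zip(folds, metrics) if f.repeat == rep]
        per_repeat.append(
            MetricsReport(
                tp=sum(c.tp for c in counts), fp=sum(c.fp for c in counts),
                tn=sum(c.tn for c in counts), fn=sum(c.fn for c in counts),
            )
        )
    final = MeanMetrics(
        *(float(np.mean([getattr(r, a) for r in per_repeat]))
          for a in ("acc", "tpr", "tnr", "ppv", "npv", "f1"))
    )
    pooled = MetricsReport(
        tp=sum(m.tp for m in metrics), fp=sum(m.fp for m in metrics),
        tn=sum(m.tn for m in metrics), fn=sum(m.fn for m in metrics),
    )
    return CVResult(
        method=method, config=config.to_dict(), folds=folds,
        per_fold_metrics=metrics, per_fold_selected=selections,
        per_fold_predictions=predictions, per_repeat_metrics=per_repeat,
        final=final, pooled=pooled,
    )


def _run_cv(inputs, labels, method, config, folds) -> CVResult:
    labels = np.asarray(labels)
    if config.paper_mode and method in PCA_METHODS:
        # fit projections on the full cohort (optimistically biased, for
        # comparability with whole-sample fitting protocols)
        full_pair = bpca.fit(list(inputs), config.theta_row, config.theta_col)
    metrics, selections, predictions = [], [], []
    for f in folds:
        if config.paper_mode and method in PCA_METHODS:
            X_tr = _fold_feature_rows(inputs, list(f.train_idx), method, full_pair)
            sel = select_features(FeatureTable(X_tr, labels[list(f.train_idx)]),
                                  config.alpha, welch=config.welch)
            selected = sel.selected if sel.selected.size else np.array(
                [int(np.argmin(np.nan_to_num(sel.p_values, nan=np.inf)))])
            Xs = X_tr[:, selected]
            mean, sd = Xs.mean(axis=0), Xs.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            svm = SVC(kernel="linear", C=config.svm_c)
            svm.fit((Xs - mean) / sd, labels[list(f.train_idx)])
            model = FoldModel(method, full_pair, selected, sel.p_values, mean, sd, svm)
        else:
            model = fit_fold(inputs, f.train_idx, labels, method, config)
        pred = predict_fold(model, inputs, f.test_idx)
        metrics.append(confusion_metrics(labels[list(f.test_idx)], pred))
        selections.append(frozenset(int(j) for j in model.selected))
        predictions.append(pred)
    return _aggregate(method, config, folds, metrics, selections, predictions)


def repeat_stable_features(result: CVResult) -> frozenset[int]:
    """Features selected in every CV repeat (in at least one of its folds).

    One repeat of k-fold CV is one cross-validation experiment; a feature
    is stable when every experiment selects it. Intersecting over all
    k·repeats individual folds instead is stricter and is available by
    passing ``result.per_fold_selected`` to
    :func:`dfcb.selection.stable_features` directly.
    """
    per_rep: dict[int, set[int]] = {}
    for f, s in zip(result.folds, result.per_fold_selected):
        per_rep.setdefault(f.repeat, set()).update(s)
    return stable_features([frozenset(v) for v in per_rep.values()])


def run_method(
    ts_list: list[np.ndarray],
    labels: np.ndarray,
    method: str | None = None,
    config: PipelineConfig | None = None,
    folds: list[FoldAssignment] | None = None,
) -> CVResult:
    """End-to-end repeated CV for one feature method."""
    config = config or PipelineConfig()
    method = method or config.method
    inputs = extract_method_inputs(ts_list, config, [method])[method]
    if folds is None:
        folds = make_folds(labels, config.cv_folds, config.cv_repeats, config.rng_seed)
    return _run_cv(inputs, labels, method, config, folds)


def compare_methods(
    ts_list: list[np.ndarray],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, CVResult]:
    """All methods on identical fold assignments (controlled comparison)."""
    config = config or PipelineConfig()
    inputs = extract_method_inputs(ts_list, config, methods)
    folds = make_folds(np.asarray(labels), config.cv_folds, config.cv_repeats, config.rng_seed)
    return {m: _run_cv(inputs[m], labels, m, config, folds) for m in methods}


def parameter_grid_run(
    ts_list: list[np.ndarray],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    method: str | None = None,
) -> list[dict]:
    """One CV result per (T, S) cell; infeasible cells skipped with a warning."""
    config = config or PipelineConfig()
    method = method or config.method
    N = min(ts.shape[0] for ts in ts_list)
    surface = []
    for T in config.window_lengths:
        for S in config.step_sizes:
            if T > N:
                warnings.warn(f"grid cell T={T}, S={S} skipped: T exceeds N={N}")
                continue
            cell_cfg = PipelineConfig(**{**config.to_dict(),
                                         "window_lengths": [T], "step_sizes": [S]})
            res = run_method(ts_list, labels, method, cell_cfg)
            surface.append({"T": T, "S": S, "ACC": res.final.ACC, "result": res})
    return surface
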