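"""Cohort, ROI time-series and configuration I/O.

Time-series files are delimited text with rows = time points and columns =
ROIs (the layout most connectome tools export). Manifests are delimited
tables with columns ``subject_id``, ``path``, ``label``. Configuration is
YAML (JSON is a subset and therefore also accepted); unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SubjectRecord",
    "Cohort",
    "PipelineConfig",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_manifest",
    "write_manifest",
    "load_config",
    "save_config",
    "load_cohort_timeseries",
]

METHODS = (
    "proposed",
    "fourier_temporal",
    "fourier_spatial",
    "temporal_spatial",
    "central",
    "t_index",
)


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member: id, binary group label (patient=1, control=0), file."""

    subject_id: str
    label: int
    source_path: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"label for subject {self.subject_id!r} must be 0 or 1, got {self.label!r}"
            )


@dataclass
class Cohort:
    """Ordered collection of subjects plus optional ROI names."""

    records: list[SubjectRecord]
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s) in cohort: {dupes}")

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PipelineConfig:
    """Run configuration with defaults mirroring the study design.

    ``window_lengths`` and ``step_sizes`` define the sliding-window grid;
    ``theta_row``/``theta_col`` are the cumulative eigenvalue-energy
    thresholds choosing how many spatial (q) and temporal (d) components
    are kept; ``alpha`` is the t-test selection threshold.
    """

    window_lengths: list[int] = field(default_factory=lambda: [20, 30, 40, 50, 60])
    step_sizes: list[int] = field(default_factory=lambda: [2, 4, 6, 8, 10])
    theta_row: float = 0.95
    theta_col: float = 0.95
    alpha: float = 0.01
    moment_order_max: int = 4
    binarize_fraction: float = 0.2
    cv_folds: int = 10
    cv_repeats: int = 10
    rng_seed: int = 0
    method: str = "proposed"
    # classifier / numerics knobs
    svm_c: float = 1.0
    welch: bool = False
    spectrum_mode: str = "magnitude"  # or "realimag"
    half_spectrum: bool = False
    paper_mode: bool = False  # fit projections/selection on all data (biased)
    partition: list[int] | None = None  # fixed module partition for topo metrics

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, grid, lo in (("window_lengths", self.window_lengths, 2),
                               ("step_sizes", self.step_sizes, 1)):
            if not grid or any((not isinstance(v, (int, np.integer))) or v < lo for v in grid):
                raise ValueError(f"{name} must be a nonempty list of integers ≥ {lo}")
        for name, v in (("theta_row", self.theta_row), ("theta_col", self.theta_col)):
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.binarize_fraction < 1):
            raise ValueError(
                f"binarize_fraction must be in (0, 1), got {self.binarize_fraction}"
            )
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be ≥ 2, got {self.cv_folds}")
        if self.cv_repeats < 1:
            raise ValueError(f"cv_repeats must be ≥ 1, got {self.cv_repeats}")
        if self.moment_order_max < 1:
            raise ValueError(f"moment_order_max must be ≥ 1, got {self.moment_order_max}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.spectrum_mode not in ("magnitude", "realimag"):
            raise ValueError(f"spectrum_mode must be 'magnitude' or 'realimag'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _detect_delimiter(first_line: str) -> str | None:
    """Pick among comma/tab/whitespace; None means any-whitespace split."""
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None


def read_roi_timeseries(path: str | Path) -> np.ndarray:
    """Read an N×R ROI time-series matrix from delimited text.

    Rows are time points (temporal order preserved), columns are ROIs.
    Raises a :class:`ValueError` naming the offending line on ragged or
    non-numeric input, and on matrices smaller than 2×2.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    delim: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delim is None and ncols is None:
                delim = _detect_delimiter(line)
            cells = line.split(delim) if delim else line.split()
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value on line {lineno}: {exc}") from None
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise ValueError(
                    f"{path}: ragged row on line {lineno}: expected {ncols} columns, got {len(row)}"
                )
            rows.append(row)
    values = np.asarray(rows, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(
            f"{path}: time-series matrix must be at least 2×2, got shape {values.shape}"
        )
    return values


def write_roi_timeseries(path: str | Path, values: np.ndarray) -> None:
    """Write a time-series matrix as tab-separated text (full precision)."""
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.17g")


def read_manifest(path: str | Path, label_map: dict[str, int] | None = None) -> Cohort:
    """Read a cohort manifest (columns subject_id, path, label).

    ``label_map`` optionally maps string labels (e.g. ``{"patient": 1,
    "control": 0}``); otherwise labels must already be 0/1. Row order is
    preserved. Relative paths are resolved against the manifest directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = row["label"]
        if label_map is not None and str(raw) in label_map:
            label = label_map[str(raw)]
        else:
            try:
                label = int(raw)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: unmappable label {raw!r}") from None
        if label not in (0, 1):
            raise ValueError(f"{path}: label {raw!r} is outside {{0,1}}")
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = path.parent / p
        records.append(SubjectRecord(str(row["subject_id"]), label, str(p)))
    return Cohort(records)


def write_manifest(path: str | Path, cohort: Cohort) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort.records],
            "path": [r.source_path for r in cohort.records],
            "label": [r.label for r in cohort.records],
        }
    )
    df.to_csv(path, index=False)


def load_cohort_timeseries(cohort: Cohort) -> list[np.ndarray]:
    """Load every subject's time-series matrix, enforcing a shared R."""
    mats = [read_roi_timeseries(r.source_path) for r in cohort.records]
    ncols = {m.shape[1] for m in mats}
    if len(ncols) > 1:
        raise ValueError(f"subjects disagree on ROI count: {sorted(ncols)}")
    return mats


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config; omitted fields take the documented defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "partition" in data and data["partition"] is not None:
        data["partition"] = [int(v) for v in data["partition"]]
    return PipelineConfig(**data)


def save_config(path: str | Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_roi_labels(path: str | Path) -> list[str]:
    """Read an ROI label table (index, abbreviation[, name]); 1-based order."""
    df = pd.read_csv(path, sep=None, engine="python")
    col = "abbreviation" if "abbreviation" in df.columns else df.columns[-1]
    return [str(v) for v in df[col]]
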