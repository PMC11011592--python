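"""Synthetic two-group cohorts with planted dynamic-connectivity effects.

Each subject's N×R time series is built from latent Gaussian signals with
deterministic mixing weights chosen so the *instantaneous* correlation of
chosen ROI pairs follows a known trajectory:

* every ROI carries a global shared signal at weight √base_corr, so all
  pairs share a constant baseline correlation;
* each planted edge (i, j) additionally shares its own latent signal
  whose weight is modulated sinusoidally in patients (group 1):
  target corr(t) = base_corr + effect·(1 + sin(2πt/period + φ))/2, with a
  subject-specific random phase φ — in controls the planted edges stay at
  baseline;
* per-ROI weights are renormalized so each clean signal has unit
  variance, then white observation noise is added (which attenuates all
  correlations by 1/(1+noise_sd²), uniformly across groups).

Subject-specific phases desynchronize the edge time courses across
subjects while leaving DFT magnitudes of the planted modulation nearly
invariant — exactly the temporal-mismatch situation the frequency-domain
features are designed for. Planted edges should be pairwise disjoint so
the target correlations compose exactly.

Defaults are the strong-effect study conditions: 40 subjects per group,
R=20 regions, N=200 time points, 3 planted edges, modulation period 40,
effect amplitude 0.5, observation noise sd 0.5, seed 7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import Cohort, SubjectRecord, write_manifest, write_roi_timeseries

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_subject",
    "generate_cohort",
    "generate_null_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_per_group: int = 40
    R: int = 20
    N: int = 200
    planted_edges: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6))
    base_corr: float = 0.2
    effect_amplitude: float = 0.5
    modulation_period: float = 40.0
    noise_sd: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        for i, j in self.planted_edges:
            if not (1 <= i < j <= self.R):
                raise ValueError(f"planted edge ({i}, {j}) invalid for R={self.R}")
        if not (0 <= self.base_corr and self.base_corr + self.effect_amplitude < 1):
            raise ValueError(
                "need 0 ≤ base_corr and base_corr + effect_amplitude < 1 "
                f"(got {self.base_corr} + {self.effect_amplitude})"
            )
        if self.N < 2 * self.modulation_period:
            raise ValueError("N must cover at least two modulation cycles")
        if self.n_per_group < 1 or self.R < 2:
            raise ValueError("need n_per_group ≥ 1 and R ≥ 2")


@dataclass
class SyntheticCohort:
    """Generated cohort: per-subject matrices, labels, ground truth."""

    timeseries: list[np.ndarray]
    labels: np.ndarray
    spec: SyntheticSpec
    cohort: Cohort | None = None  # populated when written to disk


def generate_subject(spec: SyntheticSpec, group: int, rng: np.random.Generator) -> np.ndarray:
    """One subject's N×R matrix with the group's planted correlation structure."""
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    N, R = spec.N, spec.R
    t = np.arange(N)
    b = np.sqrt(spec.base_corr)
    g = rng.standard_normal(N)  # global baseline signal
    eps = rng.standard_normal((N, R))  # per-ROI idiosyncratic signals

    # per-edge modulated weights c_e(t) with c_e² = planted extra correlation
    c = np.zeros((len(spec.planted_edges), N))
    for e in range(len(spec.planted_edges)):
        phase = rng.uniform(0, 2 * np.pi)
        if group == 1:
            extra = spec.effect_amplitude * (
                1.0 + np.sin(2 * np.pi * t / spec.modulation_period + phase)
            ) / 2.0
            c[e] = np.sqrt(extra)
    s = rng.standard_normal((len(spec.planted_edges), N))  # per-edge shared latents

    csum = np.zeros((N, R))  # Σ_e∋i c_e(t)² per ROI
    shared = np.zeros((N, R))  # Σ_e∋i c_e(t)·s_e(t) per ROI
    for e, (i, j) in enumerate(spec.planted_edges):
        for roi in (i - 1, j - 1):
            csum[:, roi] += c[e] ** 2
            shared[:, roi] += c[e] * s[e]
    resid = 1.0 - spec.base_corr - csum
    if np.any(resid < 0):
        raise ValueError("infeasible correlation target: weights exceed unit variance "
                         "(overlapping planted edges?)")
    x = b * g[:, None] + shared + np.sqrt(resid) * eps
    x += spec.noise_sd * rng.standard_normal((N, R))
    return x


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Reproducible two-group cohort; optionally written to disk.

    Subjects are ordered controls first, patients second. When ``out_dir``
    is given, per-subject time-series files, a manifest and a
    ground-truth sidecar (planted edges and parameters) are written.
    """
    rng = np.random.default_rng(spec.seed)
    timeseries, labels = [], []
    for group in (0, 1):
        for _ in range(spec.n_per_group):
            timeseries.append(generate_subject(spec, group, rng))
            labels.append(group)
    out = SyntheticCohort(timeseries, np.array(labels), spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for idx, (ts, label) in enumerate(zip(timeseries, labels)):
            sid = f"sub-{idx:03d}"
            fname = f"{sid}.tsv"
            write_roi_timeseries(out_dir / fname, ts)
            records.append(SubjectRecord(sid, int(label), str(out_dir / fname)))
        cohort = Cohort(records)
        write_manifest(out_dir / "manifest.csv", cohort)
        truth = {
            "planted_edges": [list(e) for e in spec.planted_edges],
            "n_per_group": spec.n_per_group,
            "R": spec.R,
            "N": spec.N,
            "base_corr": spec.base_corr,
            "effect_amplitude": spec.effect_amplitude,
            "modulation_period": spec.modulation_period,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        }
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        out.cohort = cohort
    return out


def generate_null_cohort(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Same cohort mechanism with the planted effect forced to zero."""
    return generate_cohort(replace(spec, effect_amplitude=0.0), out_dir)
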