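"""Frequency-domain representation of edge time courses.

Windows with the same index in different subjects need not correspond to
the same brain state, so comparing edge time courses point-by-point mixes
unrelated windows. Taking the DFT magnitude of each edge's correlation
series compares energy per frequency instead — magnitudes are invariant to
circular time shifts, which removes the ordering sensitivity.

When connectivity is built over a grid of (T, S) window settings the
number of windows K differs per setting; each edge series is zero-padded
to the grid's maximum K before the DFT so spectra are bin-aligned, then
averaged element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfc import EdgeTimeMatrix

__all__ = [
    "SpectralMatrix",
    "dft",
    "magnitude_spectrum",
    "spectral_matrix",
    "average_spectra",
]


@dataclass
class SpectralMatrix:
    """n_edges×U matrix of per-edge DFT magnitudes."""

    values: np.ndarray  # (n_edges, U), nonnegative
    dft_length: int
    edge_pairs: np.ndarray | None = None
    R: int | None = None

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def U(self) -> int:
        return self.values.shape[1]


def dft(x: np.ndarray) -> np.ndarray:
    """DFT of a length-K vector: f(u) = Σ_k x(k)·e^{−2πi(k−1)(u−1)/K}."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("dft expects a nonempty 1-D vector")
    return np.fft.fft(x)


def magnitude_spectrum(
    x: np.ndarray, pad_to: int | None = None, *, half: bool = False
) -> np.ndarray:
    """|DFT| of x, optionally zero-padded to length ``pad_to``.

    With ``half=True`` only bins 1..floor(U/2)+1 are kept (the rest are
    conjugate-redundant for real input).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("magnitude_spectrum expects a nonempty 1-D vector")
    K = x.size
    U = K if pad_to is None else int(pad_to)
    if U < K:
        raise ValueError(f"pad_to={U} is shorter than the series length {K}")
    mags = np.abs(np.fft.fft(x, n=U))
    if half:
        mags = mags[: U // 2 + 1]
    return mags


def spectral_matrix(
    A: EdgeTimeMatrix,
    pad_to: int | None = None,
    *,
    half: bool = False,
    mode: str = "magnitude",
) -> SpectralMatrix:
    """Row-wise spectrum of the edge×window matrix, edge order preserved.

    ``mode='realimag'`` concatenates real and imaginary parts instead of
    taking magnitudes (a sensitivity-analysis alternative; not shift
    invariant).
    """
    vals = np.asarray(A.values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty edge-time matrix")
    K = vals.shape[1]
    U = K if pad_to is None else int(pad_to)
    if U < K:
        raise ValueError(f"pad_to={U} is shorter than K={K}")
    F = np.fft.fft(vals, n=U, axis=1)
    if mode == "magnitude":
        out = np.abs(F)
    elif mode == "realimag":
        out = np.concatenate([F.real, F.imag], axis=1)
    else:
        raise ValueError(f"unknown spectrum mode {mode!r}")
    if half and mode == "magnitude":
        out = out[:, : U // 2 + 1]
    return SpectralMatrix(out, U, A.edge_pairs, A.R)


def average_spectra(spectra: list[SpectralMatrix]) -> SpectralMatrix:
    """Element-wise mean of bin-aligned spectral matrices (one per (T,S))."""
    if not spectra:
        raise ValueError("no spectra to average")
    shapes = {s.values.shape for s in spectra}
    if len(shapes) > 1:
        raise ValueError(f"spectral matrices disagree in shape: {sorted(shapes)}")
    mean = np.mean([s.values for s in spectra], axis=0)
    first = spectra[0]
    return SpectralMatrix(mean, first.dft_length, first.edge_pairs, first.R)
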