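# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `dfcb`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Pipeline model

**Dynamic connectivity.** A subject is an N×R matrix (rows = time points,
columns = ROIs). Windows of length T, step S (both in time points) give
K = ⌊(N−T)/S⌋+1 windowed Pearson-correlation matrices; trailing time
points not covered by a full window are discarded, windows are
rectangular (no taper), and correlations are used as-is (no Fisher
z-transform). A window with a constant ROI signal is an error, not a
silent zero: correlation is undefined there and silently imputing it
would leak a data-quality problem into the features.

**Edge ordering.** The upper triangle is vectorized row-major:
(1,2), (1,3), …, (1,R), (2,3), …, (R−1,R). Edge indices and window/bin
indices are 1-based in the public API. `edge_to_pair`/`pair_to_edge` are
exact inverses; the mapping is frozen because back-projection and all
reports depend on it.

**Spectra.** Edge time courses are transformed with the standard DFT
(negative exponent convention) and the *magnitude* is kept. Magnitudes
are invariant to circular shifts of the window sequence, which is the
operational cure for windows not corresponding across subjects; they are
also real and nonnegative, so downstream linear algebra stays real. A
`spectrum_mode="realimag"` switch keeps concatenated real/imaginary parts
instead (not shift-invariant; for sensitivity analysis), and
`half_spectrum=True` drops the conjugate-redundant upper bins. The full
spectrum is the default so the matrix keeps one column per window,
mirroring the time-domain shape.

**Grid averaging.** With a (T,S) grid, K differs per cell, so each cell's
edge series is zero-padded to the grid's maximum K before the DFT and
spectra are averaged bin-wise. This is one reading of "average the DFC
over the grid"; it is isolated in `spectral.average_spectra` so a
time-domain or score-level alternative can be swapped in. For the
no-Fourier variant the padded time-domain matrices are averaged; for the
central-moment and topology baselines, whose feature spaces are aligned
across cells, per-cell feature vectors are averaged instead. Caveat: after
padding to a common length, a fixed physical frequency lands in different
bins for different S, so bin-level physical interpretation is only exact
for single-cell runs — the frequency-recovery check below therefore uses
a single (T, S) = (20, 2) cell.

**Bilateral 2D PCA.** Column and row covariances are averaged (divide by
the number of training matrices, no small-sample correction), symmetrized,
and eigendecomposed densely. Eigenvalues are sorted descending ("the d
largest"); tiny negative eigenvalues from rounding are clipped at zero.
Retained dimensions d (columns/temporal) and q (rows/spatial) are the
smallest prefix whose eigenvalue mass reaches θ_col resp. θ_row; the
cumulative ratio is clamped to 1 at the last position so θ=1 always
selects the full (nonzero) spectrum. Defaults θ_row = θ_col = 0.95; these
are exposed in config and were not reported by any reference, so treat
them as tunables. Projection applies to the raw matrix (not mean-
centered): centering shifts every subject's feature matrix by the same
constant ZᵀĀX, which two-sample t-tests and linear decision rules ignore
(asserted numerically in the tests); the training mean is stored for
diagnostics. Eigenvector sign is fixed by making each vector's largest-
magnitude entry positive; ties in eigenvalues keep ascending original
index, and tied subspaces are documented as basis-dependent. At
R = 116 the row covariance is 6670×6670, which a dense `eigh` handles in
minutes; a truncated solver would be admissible but must match the dense
result on small instances.

**Selection.** Features are the row-major flattening of C. The screen is
a classical pooled-variance two-sample t-test, two-sided, df = n−2
(Welch optional), no multiplicity correction — the threshold p < 0.01 is
deliberately a raw screen. Zero-variance features are excluded (NaN
p-value), not errors. If a training fold selects nothing, the single
smallest-p feature is used and the event logged.

**Stability and back-projection.** A feature is *stable* when every CV
repeat selects it in at least one fold (`repeat_stable_features`); the
stricter all-folds intersection is also available. A selected feature at
position (a,b) is attributed to the edge maximizing |Z[·,a]| and the
frequency bin maximizing |X[·,b]|, ties to the smaller index. This is a
single-argmax attribution: when several edges load one component almost
equally, only one is reported (see Limitations).

**Evaluation.** Stratified 10-fold CV repeated 10 times (seeded,
reproducible); per repeat the fold confusion counts are pooled into one
metrics report and the final report averages the per-repeat metrics; the
all-repeats pooled counts are also kept. Positive class = patients
(label 1). Ratios with zero denominators are NaN, never 0. The classifier
is a linear SVM, C = 1, on features standardized by training-fold
mean/sd. Projections, screening, scaler and SVM are fitted strictly
inside the training fold; `paper_mode=True` instead fits projections on
the full sample (optimistically biased, for comparability with
whole-sample protocols) and is off by default.

## Baselines

**Central moments.** Per edge, m(d) = sign(μ_d)·|μ_d|^{1/d} of the
population central moments of the windowed-correlation series,
d = 1…D_max (default 4). The signed root keeps odd-order moments real
and preserves skew direction; m(1) is identically zero and is dropped by
the zero-variance screen downstream.

**Topological indices.** Each windowed matrix is binarized by keeping
exactly ⌊0.2·M⌋ strongest edges (ties to the smaller edge index, so the
graph is deterministic). Per window: mean clustering coefficient,
transitivity, characteristic path length (averaged over reachable pairs
only; 0 when no pair is reachable), global efficiency, and nodal
betweenness (raw pair counts), within-module degree z-score (population
sd; modules with constant degree give 0) and participation coefficient.
Standard graph computations are delegated to networkx; the two modular
metrics are implemented here. The module partition defaults to greedy
modularity maximization per window; supplying a fixed partition in config
is the recommended reproducible (and much faster) mode. Across windows
each index contributes its mean and standard deviation, giving
(4 + 3R)·2 features.

## Synthetic cohorts

`generate_subject` mixes latent unit-variance Gaussian signals so the
*pre-noise* instantaneous correlation is controlled exactly: a global
signal at weight √base_corr puts a constant baseline correlation on
every pair; each planted edge shares an extra latent whose squared weight
is effect·(1+sin(2πt/period+φ))/2 in patients (φ random per subject and
edge) and zero in controls; per-ROI weights renormalize to unit variance
(requires base_corr+effect < 1 and disjoint planted edges). White
observation noise of sd σ is then added, attenuating all observed
correlations by 1/(1+σ²) — with the default σ=0.5, an effect of 0.5 on a
0.2 baseline appears as observed correlations oscillating between 0.16
and 0.56 in patients versus a constant 0.16 in controls.

Defaults (the study conditions used throughout the tests and the
acceptance script): 40 subjects per group, R=20, N=200, planted edges
(1,2), (3,4), (5,6), base_corr=0.2, effect=0.5, period=40 time points,
noise sd 0.5, seed 7. R=20 rather than atlas scale keeps the suite fast;
atlas-scale shapes (6670 edges, 1334 binarized) are covered by
shape-level checks. What the generator does **not** emulate: hemodynamic
response and autocorrelated BOLD noise, scanner drift and motion
artifacts, heterogeneous effect sizes across subjects, and site effects —
so green tests demonstrate the pipeline's statistical correctness and
recovery behavior under its own assumptions, not clinical performance.

## Measured behavior at the default conditions

The suite verifies (tolerances in the tests): transform and eigen
decompositions against enumeration oracles (1e−9 / 1e−8), graph metrics
against exhaustive path/triangle enumeration on ≤6-node graphs, exact
binarization density, metric arithmetic, fold hygiene (fitted artifacts
are bit-identical when test subjects' data is corrupted or deleted), and
null calibration (selection rate ≈ 1% at p<0.01; CV accuracy at chance).

Three planted-recovery facts at the defaults are worth stating plainly
(all computed by `tests/test_acceptance.py` and `scripts/acceptance.py`):

* the bilateral method's mean CV accuracy is ≈ 86% (seed 7), below a
  naive expectation from the per-edge signal strength, because the three
  planted edges are *statistically exchangeable*: the row covariance
  merges them into one spatial component, collapsing three independent
  discriminative signals into one feature, and leakage-safe in-fold
  screening adds variance (an oracle SVM given the three planted-edge
  spectra directly reaches ≈ 97%);
* for the same reason the one-directional temporal variant, which keeps
  per-edge rows, *outperforms* the bilateral method on these cohorts —
  the bilateral advantage requires heterogeneous edge effects, which the
  generator deliberately does not plant;
* argmax back-projection then attributes stable features to one or two of
  the three exchangeable edges (the contrast directions among them carry
  no group-mean signal and are never selected), while the recovered
  modulation frequency is exact to within one bin once mirror
  (conjugate) bins are folded and the DC bin — which carries the real
  but rhythm-free mean-connectivity offset — is set aside.

## Limitations

* Single-argmax back-projection under-reports when several edges load a
  component comparably; a loading-profile report would be a natural
  extension.
* Frequency attribution is only physically meaningful for single-(T,S)
  runs (see grid averaging above).
* Greedy-modularity partitions are deterministic but can differ across
  networkx versions; pin a partition for archival runs.
* The t-screen's raw threshold controls per-feature error, not the
  family-wise rate; an FDR switch exists but is off by default to match
  the screening design.
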