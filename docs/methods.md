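# Methods

This note describes the models and procedures implemented in `mscurate`, the
choices made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Data model

The central object is an N × K matrix of non-negative chromatographic peak
areas (samples × features) with three attached tables: per-sample metadata
(class label, run order, batch, sample type), per-feature metadata (m/z in
Th, retention time in seconds), and a *sample mapping* that assigns classes
to the sample types `study`, `qc` (pooled/intrastudy QC) and `blank`. The
mapping gives every curation step its default behaviour — e.g. the variation
filter evaluates QC classes and removes features matrix-wide — so a pipeline
definition only needs per-step parameters.

Retention times are seconds everywhere. m/z tolerances are absolute Th by
default (0.005 Th default, matching centroiding at ~0.01 Th point spacing).
Zero areas are treated as data, not as missing: they enter dispersion
metrics, and missing cells become zeros (with a logged count) at load time,
since exported matrices generally do not distinguish the two. Metrics that
are undefined (zero median, zero study-sample MAD) propagate as NaN, and
every filter treats NaN as failing — curation is conservative.

## QC metrics

* **Detection rate**: a sample detects a feature iff area > threshold
  (strict). Intraclass mode computes the rate per class and takes the
  minimum — i.e. the feature must be consistently detected in *every* class;
  a `intraclass_max` mode (at least one class) is exposed as an option.
* **Robust RSD** = 1.4826 · MAD/median. The constant is the normal-
  consistency factor 1/Φ⁻¹(3/4), so for Gaussian data the estimate matches
  sd/mean (the test suite checks this at n = 10⁵ within 2 %).
* **D-ratio** = MAD(QC areas)/MAD(study areas), the plain MAD ratio (the
  consistency factor cancels).

## CWT peak picking

Peaks are detected on 1-D signals (EICs, ROI traces, accumulated spectra) by
the ridge-line scheme standard in chromatography:

1. The signal is convolved with Mexican-hat (Ricker) wavelets on a geometric
   width grid, default 1 to 0.5 × the expected maximum peak width in samples.
2. Local CWT maxima per scale are linked into ridges from the largest scale
   down (link tolerance width/2, gap tolerance 2 scales); ridges shorter than
   `min_length` scales are discarded.
3. The apex is the ridge position at its smallest scale, refined to the local
   raw-signal maximum; the best-responding scale sets a ±4·scale search
   window for boundaries, which are the raw-signal minima in that window,
   extended outward while the signal keeps descending so wide peaks are
   never truncated mid-slope.
4. The area is the trapezoidal integral above a straight baseline joining
   the boundary intensities (the simplest defensible baseline; clipped at
   zero). On noiseless Gaussians this recovers A·σ·√(2π) within 2 % across
   amplitudes 10²–10⁶.
5. SNR is the baseline-subtracted height over 1.4826 · MAD of the linearly
   detrended flanking signal (≥ 20 samples per side where available; the
   whole detrended signal as a conservative fallback). A noiseless signal
   gets infinite SNR. There is no community-standard SNR definition for
   CWT picking; this one is robust to neighbouring peaks.

Feature detection chains a centWave-style ROI stage — greedy scan-by-scan
extension of m/z traces within a tolerance of the running mean, one point
per scan per ROI, gaps up to `max_gap` scans (default 1), minimum 5 real
points and 500 max intensity by default — with the CWT picker run on each
ROI's zero-padded intensity trace. Feature m/z is the intensity-weighted
mean of the ROI m/z trace inside the peak bounds. Profile-mode spectra are
accepted by chromatogram/accumulation tools but rejected by the ROI builder,
which requires centroids. The two width-grid presets (chromatographic and
spectral) are package choices; reasonable alternatives exist.

## Blank correction

In the default `threshold_subtract` mode, per feature: let Bmax and Bmean be
the maximum and mean blank area. Sample areas ≤ `fold_threshold` × Bmax
(default 10) are set to 0; remaining areas have Bmean subtracted, clipped at
0. Unconditional `subtract_mean`/`subtract_max` modes are available. The
correction is applied to study and QC rows (pooled QCs are made of study
material, so they carry the same contaminants); blank rows are left as is.

## LOESS drift correction

Signal drift is estimated per feature and per batch from the pooled-QC
injections: LOESS is fitted to (run order, QC area), the fitted drift at QC
orders is interpolated (linear by default, cubic optional) to every
injection's order, and each area is multiplied by
`median(QC areas) / drift(order)`. The correction is multiplicative with a
QC-median reference — the standard arithmetic for QC-based LOESS correction
— so recovery is assessed against the drift-free signal *at that reference
level* (the planted truth times the median of the drift curve over QC
orders).

The LOESS span is either fixed or selected per feature by leave-one-out
cross-validation over the grid {0.3, 0.4, …, 1.0}: each QC point is left
out, the smoother is fitted to the rest and evaluated at the left-out order
by linear interpolation (edge points clamp to the nearest fitted value), and
the span with the smallest squared prediction error wins (ties take the
smaller span). Everything is deterministic given the inputs, and the chosen
span per feature is recorded in the step log.

Guard rails: at least 4 QC injections per batch are required; samples
outside the first/last QC order of their batch are an error (extrapolation
is forbidden — the QC-presence filter's bracket requirement exists to
guarantee this); features whose drift estimate is ≤ 0 or non-finite anywhere
are removed and logged. Batches are processed independently; no inter-batch
scaling is attempted.

## The default curation pipeline

Order and thresholds: retention time ≥ 90 s (closed interval) → feature
detected in 100 % of QCs including the first and last of each batch → blank
threshold-subtraction (10-fold rule) → LOESS drift correction (present by
default, switchable off) → robust RSD in QCs ≤ 20 % (features *strictly
above* are removed) → prevalence: areas < 5 zeroed matrix-wide, then 100 %
intraclass detection rate required → D-ratio *strictly below* 10 % →
total-area normalisation of study and QC rows (each row divided by its sum;
zero-total rows are an error naming the sample). Zeroed areas count as not
detected in all subsequent detection-rate computations. Every step logs the
features it removed, so the run yields the feature funnel alongside the
curated matrix.

A brute-force reference implementation of the same rules
(`synth.naive_default_curation`, plain Python loops, no shared code with the
pipeline) exists solely for validation: on seeded synthetic studies the
per-step surviving-feature sets of pipeline and reference must match
exactly. Both routes call the same statsmodels LOESS smoother — the smoother
itself is not re-derived — but the pipeline logic, LOOCV loop and
interpolation are coded independently on each side.

## System suitability and PCA

A suitability reference is built from ≥ 2 replicate injections of a standard
mixture: per analyte, the means of m/z, retention time and area, the
standard deviations of m/z and area, and closed acceptance intervals
mean ± k·SD (k = 2 by default) for m/z and area and mean ± 3 s for retention
time. A checked injection passes per analyte iff all three measured values
fall inside their intervals; undetected analytes fail all three checks.

PCA scores are computed by SVD on the column-mean-centred matrix (optional
autoscaling or Pareto scaling; none by default, since drift checks run on
areas that share a scale). Signs are fixed by forcing the largest-magnitude
loading of each component positive, so score plots are reproducible. For
drift assessment the scores carry the run order; on QC-only score plots the
Spearman correlation of PC1 with run order quantifies drift visibility.

## Feature correspondence

Observations (sample, m/z, rt, area) are clustered by DBSCAN in
standardised coordinates (m/z divided by the m/z tolerance, rt by the rt
tolerance) with eps = 1 and a two-point neighbourhood; same-sample
duplicates within a cluster keep the higher area (ties: earlier rt, logged);
clusters present in fewer than `min_fraction` of samples are dropped;
feature m/z/rt are cluster medians. With min neighbours = 2 every clustered
point is a core point, so the result is independent of observation order.
This is a standard density-based scheme honouring tolerance semantics, and —
like any correspondence step without retention-time warping — should be
validated on known standards before untargeted use.

## Synthetic data

`generate_raw_run` plants Gaussian elution profiles (one centroid point per
scan above a small intensity floor, optional per-scan m/z jitter, optional
uniform-m/z noise points with exponential intensities) and returns the
analytic truth (area = height · sd · √(2π)). Runs serialise to minimal
centroid MS1 mzML documents (uncompressed 64-bit float arrays, scan times in
seconds) so the mzML reader is exercised end-to-end.

`generate_study` emulates a reference-material batch: by default four plasma
materials × six process replicates, three process blanks at the start, and a
pooled-QC template of three leading QCs, a bracketing QC after every block
of four study injections and three trailing QCs (11 QCs over 38
injections). Drift-free areas are lognormal feature scales × lognormal
class effects × lognormal replicate variation; QC rows use the pooled (mean
of class means) profile. Observed areas are drift × (1 + proportional
noise), with multiplicative linear drift spanning 1.0 → 1.4 and 2 % noise by
default — the scale of drift the method is meant to remove. About 10 % of
features carry a blank-level baseline (present in blanks and all samples),
and about 15 % get 50 % dropout in one random class to exercise the
prevalence filter.

What the generator does **not** emulate: real plasma metabolome composition,
correlated features (adducts, isotopologues), retention-time shifts between
samples, heteroscedastic detector noise, batch-to-batch level changes, or
missingness that is intensity-dependent. Passing tests therefore demonstrate
that the algorithms implement their stated rules and recover planted
structure under realistic noise — not that any particular real data set
would be curated correctly.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: studies of ~38
injections × 50 features, drift batches of 40 injections × 10 features,
raw runs of 100–300 scans, 12–100 seeds per stochastic check. These sizes
are large enough for every property under test while keeping a full run in
minutes. All randomness is routed through seeded NumPy generators;
LOESS/LOOCV, ridge linking and clustering are deterministic, so repeated
runs are bit-identical.

Known limitations: no MS² handling beyond ignoring non-MS1 spectra, no
centroiding of profile data, no isotope/adduct grouping, no retention-time
alignment, no imputation beyond zeroing, and no inter-batch harmonisation.
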