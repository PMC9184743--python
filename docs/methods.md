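# Methods

This note documents the models and procedures implemented in `restdyn`,
the choices made where several defensible options existed, and what the
synthetic validation studies do and do not demonstrate.

## Overview

The package analyses resting-state EEG along two complementary axes and
relates both to a group-by-condition experimental design:

* **Multiscale entropy (MSE)** quantifies signal unpredictability across
  timescales. Fine scales index fast, local dynamics; coarse scales
  slow, distributed dynamics. It is sensitive to both linear and
  nonlinear temporal structure.
* **Spectral power density (SPD)** quantifies the linear frequency
  content as *relative* band power, deliberately blind to global
  amplitude differences between subjects or age groups.
* **Mean-centered task PLS** relates either feature grid (channels ×
  timescales, channels × frequency bins, or channels × timepoints for
  ERP data — the engine is agnostic) to the design in a single
  decomposition, assessed by permutation and bootstrap resampling.

## Preprocessing

Continuous multichannel records are band-pass filtered (default
0.5–40 Hz, zero-phase Hamming-window FIR applied forward–backward;
≥20 dB one octave outside the band), segmented into contiguous,
non-overlapping, left-aligned epochs (default 2500 ms; a trailing
remainder is discarded), and screened by a peak-to-peak criterion: an
epoch is rejected when **any** channel's max−min voltage exceeds the
threshold (default 100 µV). The same operations support ERP-style
segmentation with different windows, an 80 µV threshold and baseline
correction (`pipeline.erp_grid`).

Choices worth knowing:

* The rejection rule is per-channel-any, evaluated on the full montage
  *before* channel subsetting, so rejected-epoch counts refer to
  whole-montage epochs. Rejecting after subsetting would keep more
  epochs but is not commutative with it; the pipeline fixes the order.
* Rejecting every epoch raises an explicit error; downstream stages
  never silently receive zero epochs.
* ICA-based removal of ocular/muscle/cardiac components is an upstream
  responsibility; the package expects cleaned input.
* Time is sample-indexed, 0-based, with half-open windows
  `[start, start+len)`.
* On disk, epoched data live in a versioned HDF5 container (array plus
  a JSON-text header with fs, labels, provenance); EDF (read via MNE)
  and a CSV fallback are supported for continuous input. EDF cannot
  represent epoch structure losslessly, hence the container.

## Multiscale entropy

Scale *τ* replaces the series by means of non-overlapping windows of
length *τ* (scale 1 = the raw series). Sample entropy is

    SampEn(m, r) = −ln(A / B),

where *B* counts template pairs of length *m* within Chebyshev distance
*r* (self-matches excluded, pairs over *i < j*, both counts drawn from
the first *N−m* templates) and *A* the pairs still matching at length
*m+1*. Defaults: `m = 2`, `r = 0.5 × SD`, scales 1..50, with scales
capped so every coarse-grained series keeps ≥50 samples — for 2500-
sample epochs this yields exactly scales 1–50. Per-epoch grids are
averaged across epochs per subject.

Numerical conventions (all fixed, all tested against an independent
brute-force enumeration oracle):

* **Tolerance**: `r` is computed from the SD of the *original*
  (scale-1) series, per channel per epoch, with the population (1/N)
  normalizer, and reused unchanged at every scale. Recomputing SD per
  scale would systematically inflate coarse-scale entropy. A
  `sd_scope="recording"` switch computes the SD over the concatenated
  epochs instead; per-epoch is the default.
* **Undefined estimates** (zero matches at either length) become NaN
  sentinels, excluded from epoch averages with a logged count; dropping
  cells is less biased than clamping to an arbitrary ceiling.
* The pair-counting kernel is JIT-compiled (numba) with early abort;
  for iid Gaussian input it reproduces the analytic limit
  −ln(2Φ(r/(σ√2))−1) ≈ 1.286 at r = 0.5σ.

## Spectral power density

Each epoch is z-normalized (mean 0, SD 1, population normalizer — the
same convention as the entropy tolerance) and transformed by a single
rectangular-window FFT; no taper, no padding, no segmentation, so
2500 samples at 1000 Hz give exactly 0.4 Hz resolution. Powers are
restricted to the analysis range (default 0.4–40 Hz: the first nonzero
bin up to the filter edge; bin 0 is zeroed by mean removal) and divided
by the total within-range power, making each single-trial spectrum a
unit-sum vector invariant to global amplitude. Trial spectra are
averaged per subject (a mean of unit-sum vectors is unit-sum).

Default bands (closed intervals on bin centers): delta 1–3 Hz, theta
4–7 Hz, a delta+theta composite 1–7 Hz, alpha 8–14 Hz, beta 15–30 Hz,
gamma 30–40 Hz. The 7→8 and 14→15 Hz gaps are kept rather than merged,
and gamma is capped at the 40 Hz filter edge; all edges are
configurable through `BandSet`.

## Mean-centered task PLS

With rows ordered subjects-within-conditions-within-groups, the cell
mean of each group × condition cell is deviated from the *unweighted*
grand mean of cell means (so the deviation rows sum to zero even for
unequal group sizes), and the cells × features matrix is decomposed by
SVD. Each latent variable (LV) pairs a unit-norm design-salience vector
(a contrast over cells), a unit-norm feature-salience vector (a pattern
over channel × feature elements) and a singular value; Σsₖ² equals the
squared Frobenius norm of the centered matrix (tested). Sign
ambiguity is fixed by flipping each LV so its largest-magnitude feature
salience is positive, with design saliences flipped jointly.

**Permutation test** (default 500 permutations): whole subjects are
reassigned across groups without replacement and condition labels are
shuffled within subject, respecting the repeated-measures structure.
Permuted singular values are compared to observed ones LV-by-LV by rank
(default); a Procrustes mode that projects each permuted matrix onto
the original saliences is available as a flag. p uses the +1 correction
and is never exactly zero.

**Bootstrap ratios** (default 500 resamples): subjects are drawn with
replacement independently within each group, each carrying all its
condition rows. Every bootstrap decomposition is orthogonally
Procrustes-aligned to the original LVs before accumulation — the one
place alignment is mandatory, since sign/axis flips between resamples
would otherwise inflate the standard errors to meaninglessness. The
ratio is the original singular-value-scaled salience over the bootstrap
SE of the aligned, scaled saliences; |ratio| ≥ 2 (a configurable
threshold) is read as roughly p < 0.05 stability. Elements with zero
bootstrap SE become NaN with a logged count.

## Synthetic EEG generator

Each group × condition cell is a `SynthProfile`: a 1/f^α background
(frequency-domain amplitude shaping of white Gaussian noise — exact
slope control in O(n log n)), band-limited oscillations specified as
(center, bandwidth, amplitude relative to background SD) with Gaussian
spectral bumps (σ = bandwidth/2), white measurement noise (default
1 µV on a 6 µV background), and optional biphasic ~200 ms transients
injected into a known, exactly-counted fraction of epochs (their
indices are recorded so the rejection stage can be validated against
ground truth).

Default study profiles (tuning targets chosen once to reproduce the
qualitative aging/training signatures, not estimates of any real
recording):

| profile | α | delta 2 Hz | theta 5.5 Hz | alpha 10 Hz | beta 20 Hz |
|---|---|---|---|---|---|
| young | 1.6 | 0.8 | 0.8 | 1.0 | 0.25 |
| old | 1.0 | 0.35 | 0.35 | 1.0 | 0.75 |
| old, post-training | 1.3 | 0.35 | 0.63 | 1.8 | 0.75 |

The flatter old background with beta emphasis yields higher fine-scale
and lower coarse-scale entropy plus a higher beta / lower 1–7 Hz share;
the post-training profile (applied to one group only) steepens the
background (+0.3) and boosts the 3–14 Hz bands (×1.8), raising
coarse-scale entropy and theta/alpha power.

Between-subject variability is a Gaussian scaling of band amplitudes
(SD 10% of the mean), drawn once per subject and shared across that
subject's conditions to mimic the repeated-measures design. All
randomness flows through a seed hierarchy (study → subject → epoch), so
any subset regenerates bit-identically. Epochs are drawn independently
by default; a continuous mode exists for testing segmentation.

**What the generator does not emulate:** electrode geometry and volume
conduction (channels are i.i.d. given the profile — no spatial
correlation or topography), nonstationarity within recordings,
stereotyped blink/ECG waveforms (artifacts are generic transients), and
any nonlinear temporal structure beyond what 1/f-plus-oscillation
mixtures produce. Passing recovery tests therefore shows the *pipeline*
detects spectral/entropy differences of realistic size under realistic
trial noise; it does not certify performance on real, spatially
structured EEG.

## Validation studies and problem sizes

`restdyn.simulations` runs complete replicate studies end to end:

* **Null calibration**: 2 groups × 2 conditions × 10 subjects with
  identical profiles everywhere (1000 ms epochs at 250 Hz, 4 channels,
  entropy at scales 1–5, 99 permutations). Over 200 replicates the
  empirical type-I error at α = 0.05 should sit in roughly [0.02, 0.09]
  and the LV1 p-values should look uniform.
* **Aging recovery**: young vs old, 8 subjects per group, 2 epochs,
  4 channels, full 1–50 scale grids. Recovery = significant LV1 with
  the group contrast aligned to higher fine-scale / lower coarse-scale
  entropy in the old group, plus the beta-up / low-band-down spectral
  direction.
* **Training recovery**: 4 groups × pre/post, 6 subjects per group,
  with the effect in the old-training group only; checks the aligned
  coarse-scale entropy saliences (with positive signed bootstrap
  ratios, 50 resamples) and the 3–14 Hz spectral saliences.

These reduced study sizes were chosen so that a few hundred replicates
complete in minutes on one CPU while leaving the injected effects
comfortably but not trivially detectable; the recovery simulations skip
the amplitude-rejection stage since no artifacts are injected (at two
epochs per subject an ordinary background excursion can otherwise
occasionally void a subject). Rejection correctness is validated
separately against the generator's exact injection bookkeeping.

## Summary-statistics helpers

`one_sample_t_from_summary` computes t = (mean−μ₀)/(sd/√n), df = n−1,
from published summaries. `additive_two_way_F_from_cells` reconstructs
a data realization exactly matching each cell's (mean, sample SD, n) —
the additive least-squares fit depends only on these sufficient
statistics — and reports the Type II F of a main effect in the
no-interaction model, df = (levels−1, N−levels_A−levels_B+1). Note that
an F recomputed from *rounded* published cell summaries can differ from
the originally reported value by ~1%.

## Known limitations

* Sample entropy is O(N²) per series; full-scale studies (48 epochs ×
  20 channels × 50 scales × ~80 recordings) take tens of minutes, not
  seconds. The kernel is single-threaded by design (determinism).
* The permutation scheme assumes a complete repeated-measures design
  (every subject in every condition of its group); missing cells are
  rejected, not imputed.
* Bootstrap SEs are undefined for features with zero variance across
  resamples (NaN sentinel).
* Band-power intervals are closed on bin centers; with 0.4 Hz bins a
  band edge falling between bins excludes the straddling bin.
* No EDF export; continuous synthetic data can be written via the CSV
  fallback or segmented into the epoched container.
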