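# Methods

## Signal model of the synthetic generator

Each simulated recording is 86 s of 64-channel EEG at 500 Hz (1 s padding
around an 84-s stimulation train, onset marked by an event).  The
deterministic part is a sum of steady-state responses:

* an **oddball response** at multiples k·f_odd (k = 1…8, skipping
  multiples of 5, which coincide with the base rate) and
* a **base-rate response** at multiples of f_base = 5.77 Hz (4 harmonics),

each with a random phase per subject.  Configured amplitudes are
**totals**: the summed amplitude over all injected harmonics of that
response, matching the analysis' dependent measure (the summed
baseline-subtracted amplitude).  Harmonic k carries the fraction
`r^(k−1) / Σ r^(j−1)` of the total, with roll-off r = 0.6.

**Topography.**  Responses are spatial patterns over the montage: the
four electrodes of each analysis cluster respond at gain 1, six
surrounding electrodes per region at gain 0.5, and the remaining
electrodes share a uniform negative counterweight that makes every
pattern sum to zero across channels.  Two consequences are intended:
common-average re-referencing leaves the injected signal exactly
unchanged (so ground-truth amplitudes stay valid after preprocessing),
and cluster electrodes carry exactly the configured amplitude.  This is a
gain model, not a forward solution; no volume conduction is simulated.

**Grid snapping.**  By default injected frequencies are snapped to the
FFT grid of the integer-cycle analysis window (41 594 samples,
Δf ≈ 0.01202 Hz).  The steady-state idealisation behind rectangular-window
FFT quantification is exact periodicity over the analysis window; snapping
makes the simulation honour it (the shift is < 0.04% of f_odd).

**Stochastic components.**  1/f background noise (amplitude spectrum
∝ f^(−exponent/2), exponent 1, i.i.d. across channels) scaled to a
time-domain SD of `noise_scale`; 50 Hz mains with random per-channel gain
(0.5–1.5×) so that re-referencing cannot cancel it; and blinks — Poisson
events at 10/min, 300 ms raised-cosine waveforms of 80 µV at Fp1/Fp2 with
a frontally peaked topography — giving the ICA step a realistic,
detectable target.  Between-subject variability is a single Gaussian
offset (SD 0.15 µV, truncated so amplitudes stay non-negative) added to
each subject's totals, shared across conditions.

### Designed effect structure (defaults)

Summed oddball amplitudes (µV) in the parieto-occipital clusters:

| | Self | CloseOther | Stranger |
|---|---|---|---|
| NT, faces | 1.50 | 0.95 | 0.36 |
| autism, faces | 0.95 | 0.95 | 0.36 |
| both groups, names | 0.46 | 0.38 | 0.22 |

with smaller frontocentral values.  This encodes the target pattern: a
graded self > familiar > stranger profile for neurotypical faces, an
absent self-advantage (Self = CloseOther) for autistic faces, and a pure
familiarity effect with no group difference for names.  Magnitudes sit on
the µV scale typical of summed baseline-subtracted oddball responses.

### Choice of noise level

The default `noise_scale` is 0.15 µV, which puts the per-bin amplitude
noise near the oddball harmonics around 0.005 µV — small relative to the
weakest injected harmonic.  This is deliberate.  The baseline-subtracted
amplitude is only asymptotically unbiased: the signal bin combines with
noise in quadrature (a Rice distribution), while the subtracted neighbour
mean contributes its full expected amplitude (≈1.25 σ_bin per harmonic,
≈5 σ at the fundamental summed over seven harmonics).  At realistic
background levels (tens of µV) the summed measure is therefore
systematically conservative — every comparison remains valid, but
absolute amplitudes shrink toward zero and slope-1 parameter recovery is
unattainable by construction.  The default keeps the quantification in
its linear regime, where recovery of the injected ground truth is a sharp
end-to-end correctness check; the bias at higher noise is a property of
the measure itself, not of this implementation, and `noise_scale` is a
plain config field for anyone who wants to study it.

The direct ROI-table generator (`simulate_subject_table`), used for
power and type-I studies at replicate counts the raw-EEG chain cannot
reach, uses a *larger* residual cell noise (`table_noise_sd` = 0.4 µV),
chosen to reproduce effect sizes on the scale such studies report
(d ≈ 0.8–1 for group comparisons of difference scores).  Power results
from this generator are therefore conservative relative to the full
chain.

## Preprocessing

* **Re-reference**: subtract the instantaneous cross-channel mean;
  idempotent (a second call warns and no-ops).
* **Bad-channel interpolation**: distance-weighted local *linear* fit
  (intercept + 3-D gradient over the k = 6 nearest good electrodes on the
  unit sphere), evaluated at the bad electrode.  Unlike a weighted mean,
  this reproduces linearly varying potentials exactly, including at rim
  electrodes where all neighbours lie to one side.  More than two bad
  channels triggers a warning (such recordings would normally be
  excluded).
* **Band-pass**: 4th-order Butterworth 0.1–70 Hz, applied
  forward–backward (`sosfiltfilt`) so spectral peaks are not phase-shifted.
* **Segmentation**: 84 s from each condition's train-onset marker.
* **Ocular correction**: FastICA with as many components as the data rank
  (the common-average reference removes one dimension; the unmixing
  matrix is fitted on 3× temporally decimated data for speed — blink
  sources are broadband, so decimation does not affect their
  identifiability — and applied at the full rate).  Components whose
  absolute correlation with a virtual EOG (mean of Fp1/Fp2) exceeds 0.8
  are zeroed before back-projection.  Epochs whose EOG shows no
  blink-scale excursions (99th-percentile deviation < 30 µV) are returned
  unchanged: with nothing to correct, steady-state signal leaking into
  the frontal channels must not be regressed out.  If the decomposition
  fails, a regression-based EOG subtraction is the logged fallback.
* **Cropping**: floor(96/1.154 × 500) = 41 594 samples from the epoch
  start, i.e. exactly 96 oddball cycles (≈83.19 s).

## Spectral quantification

Amplitude spectra are |FFT|/(N/2) (DC and Nyquist halved), no taper —
integer-cycle cropping makes the targets bin-centred, so the rectangular
window is exact.  The noise surround of a target bin is ±10 bins with the
adjacent bin on each side excluded (18 noise bins ≈ ±0.12 Hz at
Δf ≈ 0.012 Hz); the same bins feed the baseline mean and the z-score's
sample SD (n−1).  A target's baseline-subtracted amplitude may be
negative (never clipped).  Windows that would cross a spectrum edge
shrink symmetrically with a warning.

Harmonic selection scans oddball multiples on the grand-average spectrum
(mean over channels, subjects, conditions): the retained set is the
maximal consecutive run of multiples with z > 2.32 starting at the
fundamental, skipping base-rate multiples without breaking the run; the
fundamental is always retained.  The per-condition response is the sum of
baseline-subtracted amplitudes over the intersection of the retained set
with the design's harmonic targets (multiples 1–8 except 5); per-harmonic
values are exported alongside.

A note on the z threshold: z > 2.32 corresponds to p < 0.01 only under a
known-variance normal reference.  With 18 estimated noise bins the
statistic is a scaled t (null exceedance ≈1.9% for Gaussian amplitudes)
and raw FFT amplitudes are Rayleigh-distributed (≈3.2%).  The validation
suite measures exactly this, and the spectral unit tests pin the
Monte-Carlo null to its analytic t-distribution prediction.  The
threshold is used as a selection heuristic, not as a calibrated test.

## ROI reduction

The fixed clusters are the default for statistics.  The collapsed
localizer — the automated stand-in for choosing electrodes by visual
inspection of the grand-average topography — selects, within each
predeclared scalp region, the k = 4 electrodes with the largest
grand-average summed response, collapsed across subjects, conditions and
stimulus types so the choice cannot bias condition contrasts; ties break
alphabetically.  TP9/TP10 are kept in the parieto-occipital regions to
match the cluster membership used in the statistics.  By default the
localizer pools across stimulus types; disagreement with the fixed
clusters changes nothing silently because the statistics stage uses the
fixed sets unless explicitly switched.

## Statistics

The mixed ANOVA evaluates each within effect on projections of the
per-subject cell vectors onto orthonormal contrast bases (Kronecker
products of Helmert contrasts and unit vectors).  Sums of squares are
Type III via model comparison on effect-coded group regressors — with
unequal group sizes this tests unweighted marginal means, matching the
behaviour of standard commercial ANOVA implementations, and was verified
against R's `car::Anova(type = 3)` to printed precision.  Mauchly's W
and the Greenhouse–Geisser ε come from the pooled within-group covariance
of the same contrast scores; the GG-corrected p is reported whenever the
effect has more than one numerator df, and the decision rule (used by the
follow-up plan) applies it when Mauchly's p < .05.  Balanced within-cell
data are required; unbalanced input is rejected rather than silently
re-weighted (between-group sizes may differ).

Follow-ups: per-stimulus-type ANOVAs, pairwise condition paired t-tests
(pooled across groups, collapsed over laterality), and independent
t-tests comparing the groups on condition difference scores
(Self−CloseOther, Self−Stranger, CloseOther−Stranger).  Cohen's dz
(paired, mean/SD of differences) and d (independent, Bessel-corrected
pooled SD) accompany every t; raw and Bonferroni-adjusted p-values are
both reported, since which follow-ups warrant correction is a reporting
choice, not a computation.

Degenerate cases: identical paired vectors are a true null (t = 0,
p = 1); a constant non-zero difference (zero variance) is an error;
single-group tables skip the group terms with an explicit note.

## Validation studies (scripts/acceptance.py)

* **Null z exceedance**: noise-only recordings through the full
  preprocessing chain; z computed at ≥10 000 bins across 2–45 Hz.
* **Type-I rate**: 1000 replicates of a flat-amplitude (null) design at
  n = 8 per group through the table generator and the headline
  Condition × Group test with the GG decision rule.
* **Parameter recovery**: 50 subjects × 3 Faces conditions at the default
  noise level; recovered cluster-mean summed amplitudes regressed on the
  injected ground truth (450 cluster-level points).  Blinks are disabled
  here so the regression isolates spectral quantification; ICA is
  validated separately.
* **Effect structure**: 100 replicates of the designed study at
  n = 24/20; counts of Faces and Names Condition × Group detections and
  of significantly *reversed* group differences (expected: none).

Problem sizes (replicate counts, reduced n for the type-I study, one
recording per subject-condition) were chosen so the whole script runs in
a few minutes on one CPU while keeping Monte-Carlo error well inside each
quantity's decision band.

## Known limitations

* Region-gain topography, no leadfield; no saccades or muscle artifacts;
  no notch filter (none is needed at the default line amplitude, and the
  study's band-pass retains 50 Hz by design).
* The summed baseline-subtracted measure is conservative at realistic
  noise levels (see "Choice of noise level").
* The table-level generator draws i.i.d. cell noise; it does not model
  condition-specific subject slopes, so sphericity violations are mild.
* Harmonic selection uses raw (not baseline-subtracted) grand-average
  amplitudes for its z-scores; the z's own noise normalisation makes the
  subtraction redundant there.
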