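# Methods

## Scope

`impedquant` implements, end to end, the analysis side of a
multi-frequency impedance-cytometry bead immunoassay: synthetic data
generation with ground truth, transit-pulse detection, the dataset
splitting / mock-experiment protocol, the two-layer bead → sample
classification framework, and its evaluation. Instrument control,
electrode electrostatics, Maxwell mixture theory, fluidics, and
image-based (CNN) peak classification are out of scope; no regression
model on concentration is built.

## Generative model

No public recording of the assay exists, so the synthetic generator is the
package's data source. It emulates the *statistical structure the
analysis assumes*, not the electrochemistry.

**Per-bead amplitudes.** A bead at concentration c is *bound* (carries
captured analyte) with probability f(c), the **bound-fraction curve**.
Its 8-channel peak-amplitude vector is drawn from

    x ~ Normal( base_mean + δ · b(c) · w + chip_offset , diag(σ²) ),   bound
    x ~ Normal( base_mean            + chip_offset , diag(σ²) ),   unbound

truncated at zero (amplitudes are magnitudes of the impedance deviation).
Here δ is the overall effect size (V), w the per-channel effect profile,
σ the within-class SD, and b(c) the **bound-degree curve**: the mean
surface occupancy of a bound bead, saturating with concentration. Both
f and b are non-decreasing tables over the assay concentrations
{0, 10, 25, 50, 100, 300, 500} pg/mL; f(0) > 0 models non-specific
binding. A graded b(c) is essential: with a fixed bound shift the
bead-level class posterior is monotone in f alone, per-bead predictions
collapse onto the two extreme classes, and the composition feature
degenerates to (effectively) a single binomial proportion — which caps
sample-level accuracy well below the regime this method operates in.
With occupancy grading, per-bead confusion spreads over all classes, as
observed in practice.

**Chips.** Each chip contributes an additive per-channel offset drawn
once per chip (`chip_offset_sd`, CRC-seeded from the chip id so all
experiments on a chip share it) — the minimal mechanism behind the need
to calibrate each chip individually.

**Traces.** Bead arrivals are Poisson (`arrival_rate_hz`), placed away
from the record edges so no pulse is clipped; each bead contributes a
Gaussian pulse (FWHM `pulse_width_s` ≥ the 10 ms minimum transit time)
scaled per channel by its amplitude vector. White noise (`noise_sd`) is
added, then each channel passes a first-order low-pass at 100 Hz
(exponential discretization, y[k] = a·y[k−1] + (1−a)·x[k],
a = exp(−dt/τ), τ = 1/(2π f_c), unit DC gain). The closed-form peak
attenuation of a Gaussian through this filter,
y(t) = (σ√(2π)/τ)·exp(σ²/2τ²)·exp(−t/τ)·Φ(t/σ − σ/τ), is exposed as
`lpf_gaussian_attenuation` and anchors all amplitude-accuracy bounds: a
15 ms pulse keeps ≈ 97 % of its height, a 1 ms artifact ≈ 42 %
(continuous) / ≈ 52 % (at the 900 Sa/s discrete filter) — the mechanism
by which sub-transit-time events are rejected.

### Default parameters (the frozen preset)

| parameter | default | units | why |
|---|---|---|---|
| frequencies | 500k, 700k, 1M, 1.5M, 2M, 5M, 10M, 20M | Hz | the instrument's 8-channel panel |
| excitation / gain | 0.4 / 1000 | V, V/A | instrument metadata; sets the volt scale |
| LPF cutoff | 100 | Hz | passes ≥ 10 ms transits only |
| sampling rate | 900 | Sa/s | Nyquist > 100 Hz; an 80-sample window spans ~89 ms ≈ several transits |
| base_mean | 0.25 … 0.10 (decreasing) | V | plausible peak amplitudes, largest at the lowest frequency |
| δ (effect_size) | 0.075 | V | see calibration below |
| w (effect_profile) | 0.14 … 0.56 … 0.09 | – | mid-frequency channels most analyte-sensitive |
| σ (within_class_sd) | 0.01 | V/channel | bead-to-bead variability |
| f(c) | 0.02, 0.33, 0.42, 0.52, 0.73, 0.86, 0.95 | – | saturating binding curve |
| b(c) | 0.20, 0.55, 0.62, 0.70, 0.84, 0.93, 1.00 | – | saturating occupancy of bound beads |
| arrival rate | 0.2 | beads/s | dilute single-particle regime: < 1 % of events within the 10 ms resolution limit |
| pulse width | 0.015 | s FWHM | ~1.5× the minimum transit |
| noise_sd | 0.002 | V | trace SNR ≳ 50 on the reference channel |
| chip_offset_sd | 0.003 | V | chip-to-chip calibration spread |
| beads / experiment | 1,000 | – | unreported in practice; free choice, 3 experiments per concentration |

The preset was calibrated **once** to the method's operating regime —
weak per-bead, strong per-sample classification: at the defaults,
five-way layer-1 bead accuracy is 44–46 % while sample accuracy over the
50 test mocks is ≥ 96 % on every one of 20 master seeds checked at freeze
(mean 98.8 %), and the binary pipeline classifies 10/10 mocks on all
seeds. Nothing was changed after freezing. The amplitude distribution
family is switchable to a moment-matched lognormal
(`amplitude_family="lognormal"`); truncated normal is the default.

## Peak detection

Detection runs on the lowest-frequency (reference) channel after
subtracting a per-channel running-median baseline (2 s window, centred,
shrinking at the edges). The noise scale is 1.4826 × MAD of the
baseline-subtracted reference channel (robust to peak contamination);
candidates are local maxima with **height and topographic prominence**
above 5 × that scale — the prominence requirement suppresses noise
ripples riding on pulse flanks, which stay above a height-only threshold
for tens of ms. Events closer than 10 ms are merged (larger amplitude
wins; earlier event on exact ties). Each accepted event is read out on
all channels as the maximum baseline-subtracted excursion within a
centred 80-sample window; events whose window overhangs the record edge
are dropped (incomplete windows bias amplitudes). All detector constants
are this package's own choices; the real assay's peak-calling software is
unreported.

On preset traces the detector achieves recall and precision ≥ 0.99 at
10 ms matching tolerance, with amplitude RMSE equal to the documented
filter attenuation (~2.8 % of pulse height) plus noise. At higher bead
rates recall is capped by coincidence physics — two beads inside one
10 ms resolution cell are one pulse — which is why the preset is dilute;
coincidence deconvolution is a non-goal.

## Splitting and mock experiments

All splits are stratified per class so every class survives every stage
(whether the original analysis stratified is unreported). Rounding:
round-half-up for the 70:30 and 30:70 splits, floor for mock sizes.
Training mocks partition each class ("divided", not bootstrapped) into
100 equal disjoint groups, dropping the remainder. Test mocks are 10
(quantification) or 5 (binary) disjoint mocks per class of
floor(10 % × class size) peaks each — disjointness chosen where the
original procedure is ambiguous. Balancing for the binary task happens
before the train/test split (configurable order); the undersampling is
proportionally stratified over (chip, concentration) strata because an
unstratified subsample's chip-mix fluctuation is shared between train and
test and — chips being identifiable from their offsets — lifts even a
zero-effect dataset measurably above chance. Every operation derives an
independent RNG stream from the `SplitSpec` seed, so stages can be rerun
in isolation.

## Classifiers

"Coarse kNN" is mapped to k = 100, Euclidean distance, per-feature
z-scoring (zero-variance features get unit scale); k, like everything
else, is configurable. The effective neighbour count is min(k, n) — for
layer 2 the 100-neighbour vote therefore spans one class's worth of
training mocks. Ties break toward the class with the smaller summed
neighbour distance, then the earlier class in `class_order`, making every
prediction reproducible. The linear discriminant stores per-class means,
the pooled within-class covariance (1/(n−C) normalisation; ridge of
1e-6 × mean diagonal added only if singular or condition number > 1e12) and
empirical priors; posteriors are exact Gaussian shared-covariance
posteriors via softmax of the linear discriminant scores. Both
classifiers are implemented in-package because the tie-break and ridge
conventions are part of the contract; tests verify them against exhaustive
brute-force oracles and (for the discriminant) scikit-learn.

Layer 2 is always coarse kNN on composition vectors; layer 1 defaults to
coarse kNN for quantification and the linear discriminant for the binary
screen. Models serialize to JSON (floats round-trip exactly) and reload
bit-identically.

## Evaluation

Confusion matrices (rows = true class) and one-vs-rest ROC/AUC are backed
by scikit-learn behind the package's interface; AUC uses the trapezoidal
rule, equivalent to the Mann–Whitney U with half-credit ties (verified
against an exhaustive pair-counting oracle). Plot functions always return
the numeric point set they draw.

## What passing tests do and do not show

The synthetic generator reproduces the *assumed* structure: a weakly
informative bead-level signal that becomes decisive at the sample level,
monotone amplitude–concentration response, chip offsets, Poisson
arrivals, and the instrument's filter selectivity. It does not model
electrode double-layer effects, bead aggregation, flow-rate variation,
coincident doublets, baseline drift beyond what the running median
absorbs, or the true (unknown) amplitude distribution family. Passing the
parameter-recovery suite therefore demonstrates that the pipeline
correctly implements and recovers the two-layer mechanism under its own
assumptions — not that those assumptions hold for any particular chip.

## Numerical and degenerate-input conventions

Flat traces yield zero detections (not an error); empty mock experiments,
unknown labels, mismatched panels and undersized classes raise labelled
errors naming the offending input. The detector guards the zero-MAD case
with a tiny positive threshold. Splits conserve rows exactly and never
duplicate; all pipeline randomness derives from a master seed via SHA-256
stage hashing, and a run's manifest (config echo, stage seeds, versions)
suffices to reproduce it byte-for-byte.

## Problem sizes

The committed study design is 3 experiments × 1,000 beads per
concentration (5 concentrations on chip 1; chip 2 adds 25 and
300 pg/mL), giving 50 test mocks of 90 beads for quantification and 10
test mocks of ~600 beads for the binary task. Null-control checks run 20
replicates at 200 beads/experiment. A full quantification run takes
roughly a second on one core; the whole test suite under a minute.
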