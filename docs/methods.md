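# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices embodied in `nacclfp`, in the spirit of a
package methods appendix. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Task design

The mixed-gamble task is the full factorial of gain levels × loss
multipliers × repetitions (default 5 × 20 × 2 = 200 trials). Gains default
to {25, 40, 55, 75, 100} euro cents; the loss of each offer is
`−gain × m`. The 20 multiplier values are not uniquely determined by the
published design description, which fixes only their range [0.5, 5] and the
expected-value sign counts (150 positive, 40 negative, 10 zero). The default
set — 15 values log-spaced over [0.5, 1), the value 1.0, and 4 values evenly
spaced over (1, 5] — is the simplest structured set reproducing those
counts, since EV = 0.5·gain·(1 − m) is positive iff m < 1. The set is
configurable. Losses are kept at exact fractional-cent precision
(25 × 0.5 = 12.5 cents); trial order is a uniform seeded permutation; the
gamble's screen side is counterbalanced exactly 50/50. The published loss
range "5–200 cents" is arithmetically inconsistent with a full factorial
over these gains and multipliers (which spans 12.5–500) and is not enforced.

## Choice models

All three models are Bernoulli likelihoods over accept/reject choices.
Utilities are in euro cents, so μ has units 1/cent; because models 2 and 3
apply the logistic to `μ(U + g)`, their bias g is also in cents, whereas the
model-1 bias is a pure logit. Fitting is by L-BFGS-B on the exact negative
log-likelihood with its analytic gradient, restarted from a deterministic
grid (g ∈ {−2, 0, 2}; μ ∈ {0.01, 0.1, 1}/cent; λ ∈ {0.5, 1, 2, 4}) with box
bounds μ ∈ [10⁻⁶, 10], λ ∈ [0.05, 20], g ∈ [−100, 100]; the best restart
wins. Degenerate data (one choice type, or < 10 trials) produce a flagged
boundary fit rather than an error. Model comparison is by
BIC = k·ln n − 2·ln L with ties broken toward the simpler model. Pseudo-r²
is McFadden's measure against the chance model (P = 0.5 every trial),
`1 − ln L / (n·ln ½)`, which is 0 for a coin-flip fit and approaches 1 as
fitted probabilities approach the choices. μ is refit independently in
models 2 and 3 (never shared).

The expected-value resampling test shuffles choices across trials
(zero-EV trials excluded) and reports the one-sided exceedance fraction of
the statistic P(gamble | EV > 0) − P(gamble | EV < 0) over 1000 seeded
shuffles. Permutations are sampled with replacement; uniqueness is not
enforced.

## Synthetic LFP generator

The generator emulates the structure of bilateral 4-contact accumbens
recordings at 512 Hz:

- **Background**: per-contact Gaussian noise spectrally shaped to
  1/f^α (α = 1 by default), SD 10 µV; plus an identical "reference"
  component per electrode (SD 10 µV) that the bipolar montage cancels
  exactly — this is what makes common-mode rejection testable.
- **Line noise**: 50 Hz and harmonics to 250 Hz with contact-specific
  amplitude jitter and phase (so it survives re-referencing and the notch
  filter's effect is observable), 5 µV at the fundamental.
- **Events**: options onset, response (log-normal latency, median 2.17 s,
  σ = 0.25 log-units), and — for accepted gambles only — outcome onset
  exactly 2 s after the response; inter-trial intervals jitter uniformly
  over 1.5–2 s.
- **Evoked responses**: sums of two Gabor atoms (~150 ms and ~400 ms
  latency). The options response is valence-free (8 µV). The outcome
  response's early atom is 14 µV for wins vs 5 µV for losses; with
  `erp_reversal` the late atom carries the same difference with opposite
  sign, emulating the later polarity flip of the valence effect.
- **Beta bursts**: Gaussian-windowed (σ = 200 ms, centered 400 ms after
  outcome) 15–30 Hz narrow-band noise with amplitude
  `12·√(1 + boost)` µV, boost 1.5 for wins vs 0.25 for losses by default.
- **Optional regressor effects**: band-limited power components whose
  power is `base²·max(0.05, 1 + slope·x)` for x = gamble EV or signed
  outcome magnitude, in a configurable band/window/lock.
  `rpe_positive_config()` freezes a positive-control subject: no valence
  asymmetry, magnitude slope +0.008/cent and EV slope −0.03/cent on
  15–30 Hz power in the first post-outcome second.
- **Artifacts**: `inject_artifacts` adds broadband noise at
  `scale × background SD` to exactly `round(rate·n)` seeded trials.

Trial-locked components are injected with a fixed ventral→dorsal contact
gain gradient (1.0, 0.5, 0.2, 0.05), emulating a source near the deepest
contact; without such a gradient every trial effect would cancel under the
bipolar montage exactly like the reference component.

No quantitative LFP effect sizes are published for this paradigm — only
statistical maps — so the generator's default amplitudes are this package's
own choices, set once so that the full pipeline detects the injected
effects with roughly 80–95% probability per subject at the study's trial
counts. They are deliberately *not* presented as physiological estimates.
What passing tests show is that the inferential machinery is calibrated
(correct false-positive rates) and sensitive (detects effects of plausible
signal-to-noise ratio); they cannot show that real accumbens recordings
contain such effects. The generator also omits several properties of real
data: nonstationary drift, interictal epileptiform activity, cross-trial
autocorrelation of background state, and volume-conducted far fields with
realistic geometry.

The default simulated chooser (`simulate_subject`) uses model 3 with
g = 30 cents, μ = 0.1/cent, λ = 2, which accepts roughly two thirds of
gambles — matching the observed average gamble rate and leaving ~65 win and
~65 loss epochs for outcome-locked analyses.

## Preprocessing

The bipolar montage subtracts each contact's dorsal neighbor (3 channels
per hemisphere). All filters are 4th-order Butterworth designs run
forward-backward (zero phase) as second-order sections: band-stops at
k·50 ± 1.5 Hz for k·50 ≤ 250 Hz, and a 0.5–25 Hz band-pass for evoked
potentials. Epochs use a closed-open sample window
`[e + round(t₀·fs), e + round(t₁·fs))` with t = 0 at the lock event.
Baseline correction subtracts the mean amplitude over the 100 ms before
options onset; for epochs locked to later events the per-trial baseline is
computed from the continuous recording (`pretrial_baseline`).

Trial rejection computes each trial × channel epoch variance and z-scores
it across trials within channel using the median and 1.4826 × MAD; a
trial's metric is its maximum z over channels, rejected above threshold 4.
The robust location/scale is a deliberate choice: with ~19% of trials
carrying 10× artifacts, a mean/SD z-score is inflated by the artifacts
themselves to the point where they fall below any reasonable threshold
(masking), whereas the median/MAD version keeps clean-data false-positive
rates below a few percent while catching essentially all injected
artifacts.

## Spectral estimation

Low frequencies (2.5–40 Hz, 2.5 Hz steps) use a single Hanning taper on
400 ms windows; high frequencies (30–250 Hz, 5 Hz steps) use 7 Slepian
tapers on 200 ms windows with time-half-bandwidth NW = 4 (±20 Hz
smoothing), power averaged over tapers. Both recipes step every 25 ms
(13 samples at 512 Hz, i.e. 25.4 ms); the high-frequency step is not
published and is taken equal to the low-frequency step. Time stamps are
window centers; bins whose windows overhang the epoch are NaN and excluded
from statistics via a validity mask. Coefficients are computed by direct
projection onto tapered complex exponentials at exactly the target
frequencies (no zero-padding). The low recipe is amplitude-normalized (a
unit sinusoid yields power ≈ 1 at its bin); statistics operate on raw
power — the inference compares conditions, so the overall scale cancels —
with a log transform available to the caller.

## Cluster-based permutation inference

Bin statistics are the pooled-variance independent-samples t, the
simple-regression slope t, or the paired/one-sample t; infinite t values
(perfect fits) are capped at ±10⁶ so cluster masses stay finite. Bins
exceeding the two-sided critical t at the cluster-forming α (0.05; 0.1 in
the liberal scan) are grouped into connected components separately for
positive and negative t, with 4-connectivity over the time(-frequency)
grid and optional adjacency between neighboring same-electrode bipolar
channels; disabling adjacency altogether reduces the procedure to max-|t|
correction, which is verified against a direct implementation in the
tests. Cluster mass is the sum of member t values. Permutations shuffle
condition labels, regressor values, or signs (for the paired statistic);
the identity permutation is always included, so p ≥ 1/n_permutations. The
null distribution is the per-permutation maximum cluster mass pooled
across all supplied maps — supplying both hemispheres therefore corrects
across hemispheres — kept separately for positive and negative clusters,
and each observed cluster's p is its exceedance fraction. The
activation-vs-baseline contrast uses the paired statistic on per-trial
(post-outcome − tiled baseline) differences with sign-flipping
permutations, which respects the within-trial pairing.

## RPE pipeline and disambiguation

Regressors per gamble trial: valence ±1, signed outcome magnitude (cents),
gamble EV (cents), and RPE = magnitude − EV (an exact identity, asserted).
The analysis windows are 0–2 s post outcome (valence contrasts), 0–1.5 s
(magnitude regressions per valence and the candidate scan), and the four
EV windows (0–1 s post options, −1.5–0 s pre response, 0–2 s post
response, 0–1.5 s post outcome); each named window is corrected internally
across its bins and hemispheres, with no additional correction across
windows. Channels are averaged within hemisphere by default, with a
per-channel mode that allows clusters to span adjacent bipolar pairs.

The candidate scan runs the RPE regression with both the cluster-forming
and the test level at 0.1 (the "liberal" setting, read as a 0.1
significance level). Disambiguation averages the measure over the
candidate's extent per trial and fits valence + magnitude + EV jointly by
OLS with per-coefficient two-sided t tests at 0.05. Classification:
`rpe_signal` iff magnitude and EV are both significant with opposite
signs; `valence_signal` iff valence is significant and neither other
regressor is; `magnitude_only` / `ev_only` iff exactly that regressor is
significant; otherwise `unclassified`. If the design matrix condition
number exceeds 10⁸, magnitude is orthogonalized against valence and the
adjustment recorded. Because valence and signed magnitude are strongly
collinear, a genuinely valence-driven signal will occasionally drag the
magnitude (or EV) coefficient over the 0.05 line; this is why the
end-to-end expectation is framed as a ≥ 90% rate across seeds rather than
a per-seed certainty, and why single-seed tests assert dominance of the
valence classification rather than its exclusivity.

The evoked-response quality gate requires at least one significant cluster
(0–800 ms, corrected across both hemispheres) in both the options-locked
and the outcome-locked average evoked response; subjects with a flat
response to either event are flagged for exclusion.

## Problem sizes and determinism

Statistical calibration runs use reduced sizes chosen as the package's own
defaults for desk-scale verification: 500 replicate datasets for parameter
recovery, 500 simulations for resampling-test calibration, 200 simulations
× 200 permutations on a 10 × 40 bin grid for the cluster type-I check, and
50 synthetic subjects at 200 permutations for the end-to-end conclusion.
Every stochastic component takes an explicit seed (NumPy `default_rng` /
`SeedSequence.spawn`), and identical seeds reproduce designs, choices,
recordings, and permutation draws bit for bit.

## Known limitations

- The generator's effect amplitudes are calibration targets, not
  physiology; absolute power units are arbitrary.
- Plain-EDF export quantizes to 16 bits over each channel's range and
  carries no event annotations (events travel in the HDF5 container or
  JSON sidecar).
- The paired baseline contrast and the robust rejection rule are specific
  readings of underdetermined published procedures; both are exposed as
  configuration.
- Group-level inference is deliberately out of scope; every analysis is
  within-subject.
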