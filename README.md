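# nacclfp

Decision-model fitting and cluster-permutation analysis of reward signals
in human nucleus-accumbens local field potentials (LFP), with a synthetic
data generator that makes the whole pipeline testable end to end.

## The problem

Deep-brain-stimulation electrodes occasionally give direct electrophysiological
access to the human ventral striatum while a patient performs an economic
choice task. A central question for such recordings is whether outcome-locked
LFP responses constitute a unified **reward-prediction-error (RPE)** signal —
one that scales positively with obtained reward magnitude and negatively with
the expected value of the chosen gamble — or merely an **outcome-valence**
signal that distinguishes wins from losses without scaling by either quantity.
Distinguishing the two requires a specific inferential sequence, which this
package implements as reusable, tested components:

1. **Task design** — a mixed-gamble task: 200 choices between a safe option
   worth 0 and a 50/50 gamble (gain `V_gain` ∈ {25, 40, 55, 75, 100} euro
   cents; loss `V_loss = −V_gain · m` for 20 multipliers `m` ∈ [0.5, 5]; each
   offer presented twice). The default design has 150 positive-, 40 negative-
   and 10 zero-expected-value trials.
2. **Choice models** — three nested logistic models fit by maximum likelihood
   and compared by BIC:
   - model 1: `P(gamble) = 1/(1+e^{−g})` (pure gamble bias),
   - model 2: `U = 0.5·V_gain + 0.5·V_loss`, `P = 1/(1+e^{−μ(U+g)})`,
   - model 3: `U = 0.5·V_gain + 0.5·λ·V_loss` (λ > 1 ⇒ loss aversion),
   plus a nonparametric resampling test for an expected-value effect on choice.
3. **Preprocessing** — bipolar montage (each contact referenced to its dorsal
   neighbor), zero-phase Butterworth band-stop at 50 Hz and harmonics up to
   250 Hz, event-locked epoching, robust variance-based trial rejection, and
   100 ms pre-trial baseline correction.
4. **Spectral analysis** — Hanning-taper time-frequency power (2.5–40 Hz,
   400 ms windows every 25 ms) and Slepian multitaper power (30–250 Hz,
   200 ms windows, ±20 Hz smoothing, 7 tapers), and 0.5–25 Hz evoked
   potentials.
5. **Cluster-based permutation inference** — bin-wise t statistics
   (independent-samples, simple-regression, or paired) thresholded at
   P < 0.05, summed over connected supra-threshold clusters, and compared to
   the permutation distribution of the maximum cluster mass pooled across
   both hemispheres.
6. **RPE identification and disambiguation** — a liberal (α = 0.1) scan for
   clusters correlating with the RPE regressor (outcome magnitude − gamble
   expected value), followed by a three-regressor model (valence, magnitude,
   expected value) on each candidate's extent-averaged signal. An RPE signal
   requires significant magnitude and expected-value coefficients of opposite
   sign; a valence signal loads on the win/loss distinction alone.

Because no patient recordings are publicly available, the package ships a
first-class synthetic generator (`nacclfp.synthetic_lfp`) producing 8-contact
recordings at 512 Hz with 1/f background, line noise, a shared per-electrode
reference component, valence-dependent evoked potentials, outcome-locked beta
bursts, optional expected-value/magnitude power modulations, and artifact
trials — all with ground truth returned for validation.

## Worked example

```python
import numpy as np
from nacclfp import behavior as bh, cluster_stats as cst
from nacclfp import rpe_pipeline as rp, task_design as td

design = td.generate_design(seed=1)
print(td.design_summary(design))

trials, recording = rp.simulate_subject(seed=1)   # model-3 chooser + synthetic LFP
fits = [bh.fit_model(trials, m) for m in (1, 2, 3)]
for f in fits:
    print(f"model {f.model_id}: g={f.params.g:7.3f} mu={f.params.mu:.4f} "
          f"lam={f.params.lam:.3f} BIC={f.bic:7.1f} pseudo-r2={f.pseudo_r2:.3f}")
print("preferred model:", bh.compare_models(fits))

cfg = cst.PermutationConfig(n_permutations=500, seed=1)
summary = rp.outcome_signal_summary(trials, recording, cfg)
print("classifications:", summary["classifications"])
```

prints

```
{'n_trials': 200, 'positive': 150, 'negative': 40, 'zero': 10, 'n_gain_levels': 5, 'n_multiplier_levels': 20}
model 1: g=  0.597  mu=1.0000  lam=1.000  BIC=  265.5  pseudo-r2=0.062
model 2: g=  4.513  mu=0.1206  lam=1.000  BIC=  168.6  pseudo-r2=0.430
model 3: g= 24.520  mu=0.1079  lam=1.805  BIC=  150.8  pseudo-r2=0.513
preferred model: 3
classifications: ['valence_signal', 'valence_signal', 'valence_signal', 'valence_signal', 'unclassified', 'unclassified']
```

The subject was simulated from model 3 (g = 30 cents, μ = 0.1/cent, λ = 2);
the fit recovers those values, BIC selects the generating model, and the
gain-vs-loss contrast finds a significant post-outcome beta-band cluster
(mass 579.1, p = 0.002 in this run). Although the liberal scan surfaces six
candidate "RPE" clusters — valence signals correlate with the RPE regressor
by construction — the disambiguation regression classifies them as valence
signals, not RPE signals: the computational restatement of the conclusion
that these outcome responses reflect valence rather than a unified
prediction error.

A thin CLI wraps the same functions:

```bash
nacclfp design --seed 1 --out design.csv
nacclfp simulate-behavior --seed 1 --out trials.csv
nacclfp simulate-lfp --trials trials.csv --seed 1 --out rec.h5
nacclfp analyze --trials trials.csv --recording rec.h5 --out report.json
```

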