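"""Reward-prediction-error analysis pipeline.

Runs the inferential sequence used to ask whether outcome-locked accumbens
LFP signals constitute a unified reward-prediction-error (RPE) signal or
merely an outcome-valence signal:

1. valence contrasts (per-valence activation vs pre-options baseline, and
   gains vs losses) on time-frequency power and on evoked potentials;
2. outcome-magnitude regressions separately within wins and within losses;
3. expected-value regressions in four peri-event time windows;
4. a liberal-threshold scan for candidate RPE signals (regression on
   RPE = outcome magnitude - gamble expected value);
5. disambiguation of every candidate with a three-regressor model
   (valence, magnitude, expected value): a genuine RPE signal must load on
   magnitude and expected value with opposite signs, whereas a valence
   signal loads on the gain/loss distinction alone.

All cluster inference is corrected across both hemispheres by pooling the
permutation null (see :mod:`nacclfp.cluster_stats`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import behavior, preprocess, spectral
from .cluster_stats import ClusterResult, PermutationConfig, permutation_test
from .preprocess import EpochSet
from .spectral import TFRPower
from .synthetic_lfp import LFPRecording

__all__ = [
    "build_regressors",
    "CandidateSignal",
    "DisambiguationResult",
    "valence_contrast",
    "magnitude_regression",
    "ev_regression",
    "candidate_rpe_scan",
    "disambiguate",
    "qc_evoked_response",
    "outcome_signal_summary",
    "simulate_subject",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

EV_WINDOWS = {
    "post_options": ("options_onset", (0.0, 1.0), "all"),
    "pre_response": ("response", (-1.5, 0.0), "all"),
    "post_response": ("response", (0.0, 2.0), "gamble"),
    "post_outcome": ("outcome_onset", (0.0, 1.5), "gamble"),
}


def build_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-gamble-trial regressors: valence, magnitude, ev, rpe.

    Valence is +1 for wins / -1 for losses, magnitude the signed outcome
    in cents, ev the gamble expected value, and rpe = magnitude - ev.
    """
    gamble = trials[trials["chose_gamble"] == 1].copy()
    out = pd.DataFrame({
        "trial": gamble["trial"].to_numpy(),
        "valence": np.sign(gamble["outcome_cents"].to_numpy(float)),
        "magnitude": gamble["outcome_cents"].to_numpy(float),
        "ev": gamble["ev_cents"].to_numpy(float),
    })
    out["rpe"] = out["magnitude"] - out["ev"]
    assert np.array_equal(out["rpe"], out["magnitude"] - out["ev"])
    return out


@dataclass
class CandidateSignal:
    """A liberal-threshold cluster put forward for disambiguation."""

    modality: str  # "tf_low" | "tf_high" | "erp"
    map_index: int  # hemisphere index within the analyzed maps
    bins: tuple  # member-bin indices within the analysis window
    direction: str  # "positive" | "negative"
    p_value: float


@dataclass
class DisambiguationResult:
    candidate: CandidateSignal
    coef: dict  # regressor -> coefficient
    t: dict
    p: dict
    classification: str
    orthogonalized: bool = False


# ------------------------------------------------------------ data access


def _tf_window_maps(tfr: TFRPower, window: tuple[float, float]):
    """Per-channel (trials x freq x time) maps restricted to a time window."""
    sel = (tfr.times >= window[0]) & (tfr.times < window[1]) & tfr.valid
    if not sel.any():
        raise ValueError(f"no valid TF bins inside window {window}")
    return [tfr.power[:, h][:, :, sel] for h in range(len(tfr.channels))], sel


def _erp_window_maps(epochs: EpochSet, window: tuple[float, float]):
    """Hemisphere-averaged (trials x time) maps within a time window."""
    sel = (epochs.times >= window[0]) & (epochs.times < window[1])
    if not sel.any():
        raise ValueError(f"no samples inside window {window}")
    maps = []
    for hemi in ("L", "R"):
        idx = [i for i, c in enumerate(epochs.channels) if c.startswith(hemi)]
        if idx:
            maps.append(epochs.data[:, idx][:, :, sel].mean(axis=1))
    return maps, sel


def _subset(maps, mask):
    return [m[mask] for m in maps]


# --------------------------------------------------------------- analyses


def valence_contrast(
    tfr: TFRPower,
    baseline: np.ndarray,
    config: PermutationConfig,
    window: tuple[float, float] = (0.0, 2.0),
) -> dict[str, ClusterResult]:
    """Valence analyses on outcome-locked TF power.

    Per valence, each trial's post-outcome power is compared with that
    trial's pre-options baseline (tiled across time) with sign-flipping
    permutations; gains vs losses uses the independent-samples statistic.
    ``tfr`` should be hemisphere-averaged; ``baseline`` is the matching
    trials x hemisphere x frequency array of pre-options power.
    """
    maps, _ = _tf_window_maps(tfr, window)
    valence = np.sign(tfr.metadata["outcome_cents"].to_numpy(float))
    results = {}
    for name, mask in (("gain_vs_baseline", valence > 0), ("loss_vs_baseline", valence < 0)):
        if mask.sum() < 10:
            logger.warning("skipping %s: only %d trials", name, mask.sum())
            continue
        diffs = [
            maps[h][mask] - baseline[mask, h][:, :, None]
            for h in range(len(maps))
        ]
        results[name] = permutation_test(diffs, None, "dep_t", config)
    if (valence > 0).sum() >= 10 and (valence < 0).sum() >= 10:
        results["gain_vs_loss"] = permutation_test(
            maps, (valence > 0).astype(float), "indep_t", config
        )
    else:
        logger.warning("skipping gain_vs_loss: insufficient trials per valence")
    return results


def erp_valence_contrast(
    epochs: EpochSet,
    config: PermutationConfig,
    window: tuple[float, float] = (0.0, 2.0),
) -> dict[str, ClusterResult]:
    """Gain-vs-loss contrast on outcome-evoked potentials."""
    maps, _ = _erp_window_maps(epochs, window)
    valence = np.sign(epochs.metadata["outcome_cents"].to_numpy(float))
    if (valence > 0).sum() < 10 or (valence < 0).sum() < 10:
        logger.warning("skipping ERP gain_vs_loss: insufficient trials")
        return {}
    return {"gain_vs_loss": permutation_test(maps, (valence > 0).astype(float), "indep_t", config)}


def magnitude_regression(
    maps: list[np.ndarray],
    regressors: pd.DataFrame,
    valence: str,
    config: PermutationConfig,
) -> ClusterResult | None:
    """Regression of the measure on |outcome| within one valence.

    ``maps`` are per-hemisphere trial x bins arrays over the post-outcome
    analysis window (0-1.5 s); ``valence`` is ``"win"`` or ``"loss"``.
    """
    mask = (regressors["valence"] > 0 if valence == "win" else regressors["valence"] < 0).to_numpy()
    x = np.abs(regressors.loc[mask, "magnitude"].to_numpy(float))
    if np.ptp(x) == 0 or mask.sum() < 4:
        logger.warning("skipping magnitude regression (%s): degenerate regressor", valence)
        return None
    return permutation_test(_subset(maps, mask), x, "regression_t", config)


def ev_regression(
    tfr_by_lock: dict[str, TFRPower],
    trials: pd.DataFrame,
    config: PermutationConfig,
) -> dict[str, ClusterResult]:
    """Expected-value regressions in the four peri-event windows.

    Windows: first second after options onset (all trials), 1.5 s before
    the response (all trials), the 2 s delay after a gamble response, and
    the first 1.5 s after outcome onset (gamble trials).  Each window is
    corrected internally across its bins and both hemispheres.
    """
    results = {}
    for name, (lock, window, which) in EV_WINDOWS.items():
        tfr = tfr_by_lock.get(lock)
        if tfr is None:
            continue
        maps, _ = _tf_window_maps(tfr, window)
        meta = tfr.metadata
        if which == "gamble":
            mask = meta["chose_gamble"].to_numpy() == 1
        else:
            mask = np.ones(len(meta), bool)
        ev = meta.loc[mask, "ev_cents"].to_numpy(float)
        if np.ptp(ev) == 0:
            raise ValueError("EV regressor has zero variance (single-offer design?)")
        results[name] = permutation_test(_subset(maps, mask), ev, "regression_t", config)
    return results


def candidate_rpe_scan(
    maps: list[np.ndarray],
    regressors: pd.DataFrame,
    config: PermutationConfig,
    modality: str,
) -> list[CandidateSignal]:
    """Liberal-threshold scan for candidate RPE signals (post outcome).

    Clusters are formed and tested at the liberal 0.1 level (both the
    bin threshold and the cluster test), so true valence signals — which
    correlate with RPE — surface as candidates for disambiguation.
    """
    liberal = replace(config, cluster_alpha=0.1, test_alpha=0.1)
    rpe = regressors["rpe"].to_numpy(float)
    result = permutation_test(maps, rpe, "regression_t", liberal)
    return [
        CandidateSignal(
            modality=modality, map_index=c.map_index, bins=c.bins,
            direction=c.sign, p_value=c.p_value,
        )
        for c in result.significant(liberal.test_alpha)
    ]


def _ols_tstats(X: np.ndarray, y: np.ndarray):
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * spstats.t.sf(np.abs(t), dof)
    return beta, t, p


def disambiguate(
    candidate: CandidateSignal,
    maps: list[np.ndarray],
    regressors: pd.DataFrame,
    alpha: float = 0.05,
) -> DisambiguationResult:
    """Classify a candidate signal as valence, RPE, or neither.

    The measure is averaged over the candidate's bin extent per trial and
    regressed on valence (+/-1), signed outcome magnitude (cents) and
    gamble expected value (cents) simultaneously.  An RPE signal requires
    significant magnitude and expected-value coefficients of opposite
    signs; a valence signal requires a significant valence coefficient
    with neither of the other two significant.
    """
    data = maps[candidate.map_index]
    flat_idx = (slice(None),) + candidate.bins
    y = data[flat_idx]
    if y.ndim > 1:
        y = y.mean(axis=tuple(range(1, y.ndim)))
    names = ["valence", "magnitude", "ev"]
    cols = [regressors[c].to_numpy(float) for c in names]
    X = np.column_stack([np.ones(len(y))] + cols)
    ortho = False
    if np.linalg.cond(X) > 1e8:
        v = X[:, 1]
        m = X[:, 2]
        X[:, 2] = m - v * (v @ m) / (v @ v)
        ortho = True
        logger.warning("collinear design: magnitude orthogonalized against valence")
    beta, t, p = _ols_tstats(X, y)
    coef = dict(zip(names, beta[1:]))
    tt = dict(zip(names, t[1:]))
    pp = dict(zip(names, p[1:]))

    sig = {k: pp[k] < alpha for k in names}
    opposite = sig["magnitude"] and sig["ev"] and np.sign(coef["magnitude"]) == -np.sign(coef["ev"])
    if opposite:
        cls = "rpe_signal"
    elif sig["valence"] and not sig["magnitude"] and not sig["ev"]:
        cls = "valence_signal"
    elif sig["magnitude"] and not sig["valence"] and not sig["ev"]:
        cls = "magnitude_only"
    elif sig["ev"] and not sig["valence"] and not sig["magnitude"]:
        cls = "ev_only"
    else:
        cls = "unclassified"
    return DisambiguationResult(
        candidate=candidate, coef=coef, t=tt, p=pp, classification=cls,
        orthogonalized=ortho,
    )


def qc_evoked_response(
    erp_options: EpochSet,
    erp_outcome: EpochSet,
    config: PermutationConfig,
    window: tuple[float, float] = (0.0, 0.8),
) -> dict:
    """Evoked-response quality gate for a subject.

    The trial-averaged evoked response must differ from zero (at least one
    significant cluster, corrected over 0-800 ms and both hemispheres) for
    both the options presentation and the gamble outcome; subjects with a
    flat response to either event are flagged for exclusion.
    """
    out = {}
    for name, ep in (("options", erp_options), ("outcome", erp_outcome)):
        maps, _ = _erp_window_maps(ep, window)
        res = permutation_test(maps, None, "dep_t", config)
        out[name] = {
            "n_significant": len(res.significant(0.05)),
            "result": res,
        }
    out["pass"] = all(out[k]["n_significant"] > 0 for k in ("options", "outcome"))
    return out


def outcome_signal_summary(
    trials: pd.DataFrame,
    recording: LFPRecording,
    config: PermutationConfig,
) -> dict:
    """Outcome-locked valence contrast, candidate-RPE scan and disambiguation.

    A focused version of the full pipeline covering only the outcome
    analyses: bipolar montage, line-noise removal, outcome-locked epochs
    (pre-options baseline-corrected), Hanning time-frequency power with
    hemisphere averaging, the gain-vs-loss contrast (0-2 s), the liberal
    candidate-RPE scan (0-1.5 s, TF and ERP), and the three-regressor
    disambiguation of every candidate.
    """
    bip = preprocess.notch_line_noise(preprocess.bipolar_montage(recording))
    ep = preprocess.epoch(bip, "outcome_onset", (-0.5, 2.5), trials)
    ep = preprocess.baseline_correct(ep, baselines=preprocess.pretrial_baseline(bip))
    tfr = spectral.tf_low(ep).average_channels()

    maps2, _ = _tf_window_maps(tfr, (0.0, 2.0))
    valence = np.sign(tfr.metadata["outcome_cents"].to_numpy(float))
    gvl = permutation_test(maps2, (valence > 0).astype(float), "indep_t", config)

    regs = build_regressors(tfr.metadata)
    maps15, _ = _tf_window_maps(tfr, (0.0, 1.5))
    candidates = candidate_rpe_scan(maps15, regs, config, "tf_low")
    erp = preprocess.bandpass_erp(ep)
    erp_maps, _ = _erp_window_maps(erp, (0.0, 1.5))
    candidates += candidate_rpe_scan(erp_maps, regs, config, "erp")

    disamb = [
        disambiguate(c, maps15 if c.modality == "tf_low" else erp_maps, regs)
        for c in candidates
    ]
    return {
        "gain_vs_loss": gvl,
        "candidates": candidates,
        "disambiguation": disamb,
        "classifications": [d.classification for d in disamb],
    }


# --------------------------------------------------------- synthetic subject


def simulate_subject(
    seed: int,
    lfp_config=None,
    model_id: int = 3,
    params: behavior.DecisionParams | None = None,
):
    """Simulate one subject: design, choices/outcomes, and LFP recording.

    The default chooser (model 3, g = 30 cents, mu = 0.1/cent, lam = 2)
    gambles on about two thirds of trials, matching the observed average
    gamble rate, so roughly 65 win and 65 loss epochs survive for the
    outcome-locked analyses.
    """
    from . import synthetic_lfp, task_design

    if params is None:
        params = behavior.DecisionParams(g=30.0, mu=0.1, lam=2.0)
    design = task_design.generate_design(seed=seed)
    trials = behavior.simulate_choices(design, model_id, params, seed=seed + 10_000)
    if lfp_config is None:
        lfp_config = synthetic_lfp.SyntheticConfig(seed=seed + 20_000)
    recording = synthetic_lfp.synthesize_recording(trials, lfp_config)
    return trials, recording


# ------------------------------------------------------------ full pipeline


@dataclass
class PipelineConfig:
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    z_threshold: float = 4.0
    include_high: bool = True
    seed: int = 0

    def stats(self, seed_offset: int = 0) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            cluster_alpha=self.cluster_alpha,
            seed=self.seed + seed_offset,
        )


def run_full_pipeline(
    trials: pd.DataFrame,
    recording: LFPRecording,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Behavior fits, preprocessing, QC and the full inferential sequence.

    Returns a structured report dict; a stage failure marks that stage
    failed in the report and the pipeline continues where possible.
    """
    report: dict = {"stages": {}, "config": config}

    def stage(name, fn):
        try:
            report[name] = fn()
            report["stages"][name] = "ok"
        except Exception as exc:  # pipeline must degrade gracefully
            logger.warning("stage %s failed: %s", name, exc)
            report["stages"][name] = f"failed: {exc}"
            report[name] = None
        return report[name]

    if len(trials) == 0:
        report["stages"]["input"] = "failed: empty trial table"
        return report

    def _behavior():
        fits = [behavior.fit_model(trials, m) for m in (1, 2, 3)]
        return {
            "fits": {f.model_id: f.to_dict() for f in fits},
            "preferred_model": behavior.compare_models(fits),
            "ev_choice_p": behavior.ev_choice_resampling_test(trials, seed=config.seed),
        }

    stage("behavior", _behavior)

    # ---- preprocessing
    bip = preprocess.bipolar_montage(recording)
    bip = preprocess.notch_line_noise(bip)

    ep_options = preprocess.epoch(bip, "options_onset", (-1.5, 3.0), trials)
    ep_options = preprocess.reject_artifacts(ep_options, config.z_threshold)
    kept_trials = set(ep_options.metadata.loc[ep_options.kept, "trial"])
    report["n_rejected"] = int((~ep_options.kept).sum())

    baselines = preprocess.pretrial_baseline(bip)

    def _locked(lock, window):
        ep = preprocess.epoch(bip, lock, window, trials)
        mask = ep.metadata["trial"].isin(kept_trials).to_numpy()
        ep = ep.select(mask)
        return preprocess.baseline_correct(ep, baselines=baselines)

    ep_opt = _locked("options_onset", (-1.5, 1.5))
    ep_resp = _locked("response", (-2.0, 2.5))
    ep_out = _locked("outcome_onset", (-0.5, 3.0))

    erp_opt = preprocess.bandpass_erp(ep_opt)
    erp_out = preprocess.bandpass_erp(ep_out)

    stats_cfg = config.stats()
    stage("qc", lambda: qc_evoked_response(erp_opt, erp_out, stats_cfg))

    # ---- time-frequency
    tf_opt = spectral.tf_low(ep_opt).average_channels()
    tf_resp = spectral.tf_low(ep_resp).average_channels()
    tf_out = spectral.tf_low(ep_out).average_channels()
    base = spectral.baseline_power(tf_opt)
    # align baseline rows to the outcome-locked trial subset
    opt_trials = tf_opt.metadata["trial"].to_numpy()
    out_trials = tf_out.metadata["trial"].to_numpy()
    row = {t: i for i, t in enumerate(opt_trials)}
    base_out = base[[row[t] for t in out_trials]]

    stage("valence_tf", lambda: valence_contrast(tf_out, base_out, stats_cfg))
    stage("valence_erp", lambda: erp_valence_contrast(erp_out, stats_cfg))

    regs = build_regressors(tf_out.metadata)
    maps_mag, _ = _tf_window_maps(tf_out, (0.0, 1.5))

    def _magnitude():
        return {
            v: magnitude_regression(maps_mag, regs, v, stats_cfg)
            for v in ("win", "loss")
        }

    stage("magnitude_tf", _magnitude)

    stage("ev", lambda: ev_regression(
        {"options_onset": tf_opt, "response": tf_resp, "outcome_onset": tf_out},
        trials, stats_cfg,
    ))

    def _candidates():
        cands = candidate_rpe_scan(maps_mag, regs, stats_cfg, "tf_low")
        erp_maps, _ = _erp_window_maps(erp_out, (0.0, 1.5))
        cands += candidate_rpe_scan(erp_maps, regs, stats_cfg, "erp")
        disamb = []
        for c in cands:
            source = maps_mag if c.modality == "tf_low" else erp_maps
            disamb.append(disambiguate(c, source, regs))
        return {
            "candidates": cands,
            "disambiguation": disamb,
            "classifications": [d.classification for d in disamb],
        }

    stage("rpe", _candidates)

    if config.include_high:
        def _high():
            tfh = spectral.tf_high(ep_out).average_channels()
            regs_h = build_regressors(tfh.metadata)
            maps_h, _ = _tf_window_maps(tfh, (0.0, 1.5))
            return {
                v: magnitude_regression(maps_h, regs_h, v, stats_cfg)
                for v in ("win", "loss")
            }

        stage("magnitude_tf_high", _high)

    return report
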