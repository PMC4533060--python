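"""Synthetic accumbens-like LFP with ground-truth effect structure.

Generates continuous 8-contact (2 electrodes x 4 contacts) recordings at
512 Hz emulating the mixed-gamble task: 1/f background noise, 50 Hz line
noise with harmonics, a reference component shared by all contacts of one
electrode (which the bipolar montage cancels exactly), valence-dependent
outcome-evoked potentials, outcome-locked beta-band bursts with a larger
power increase for gains, optional expected-value- and magnitude-
proportional band-limited power components, and optional high-variance
artifact trials.  Every injected component is returned as ground truth so
downstream stages can be validated quantitatively.

Trial-locked effect components are injected with a fixed ventral-to-dorsal
contact gain gradient, emulating a local source near the deepest contact;
this is what lets them survive bipolar re-referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EffectSpec",
    "SyntheticConfig",
    "LFPRecording",
    "synthesize_recording",
    "inject_artifacts",
]

# per-electrode gain of trial-locked components, ventral -> dorsal
CONTACT_PROFILE = np.array([1.0, 0.5, 0.2, 0.05])

EVENT_KINDS = ("options_onset", "response", "outcome_onset")


def rpe_positive_config(seed: int = 0) -> "SyntheticConfig":
    """Generator config for a positive-control subject with a true RPE signal.

    Valence asymmetries are switched off (equal beta boosts and evoked
    amplitudes for wins and losses) and post-outcome beta power is made to
    scale positively with outcome magnitude and negatively with gamble
    expected value — the defining signature of a reward-prediction-error
    signal.
    """
    return SyntheticConfig(
        seed=seed,
        beta_gain_boost=0.5,
        beta_loss_boost=0.5,
        erp_gain_amp=8.0,
        erp_loss_amp=8.0,
        magnitude_effect=EffectSpec(
            band=(15.0, 30.0), window=(0.0, 1.0), slope=0.008, base_amp=12.0
        ),
        ev_effect=EffectSpec(
            band=(15.0, 30.0), window=(0.0, 1.0), slope=-0.03, base_amp=12.0
        ),
    )


@dataclass(frozen=True)
class EffectSpec:
    """A band-limited power modulation tied to a per-trial regressor.

    Injected power in ``band`` within ``window`` (seconds relative to the
    ``lock`` event) is ``base_amp**2 * (1 + slope * x)`` where ``x`` is the
    trial's regressor value (EV or signed outcome magnitude, euro cents);
    the multiplier is floored at 0.05 so power stays positive.
    """

    band: tuple[float, float]
    window: tuple[float, float]
    lock: str = "outcome_onset"
    slope: float = 0.01
    base_amp: float = 4.0


@dataclass(frozen=True)
class SyntheticConfig:
    fs: float = 512.0
    n_contacts_per_hemisphere: int = 4
    noise_exponent: float = 1.0
    noise_scale: float = 10.0  # uV, background SD per contact
    reference_scale: float = 10.0  # uV, shared per-electrode component SD
    line_freq: float = 50.0
    line_amplitude: float = 5.0  # uV at the fundamental
    erp_options_amp: float = 8.0  # uV, options-evoked response (valence-free)
    erp_gain_amp: float = 14.0  # uV, early outcome-evoked peak for wins
    erp_loss_amp: float = 5.0  # uV, for losses
    erp_reversal: bool = True
    beta_band: tuple[float, float] = (15.0, 30.0)
    beta_base_amp: float = 12.0  # uV, burst amplitude before valence boost
    beta_gain_boost: float = 1.5  # fractional power increase for wins
    beta_loss_boost: float = 0.25
    ev_effect: EffectSpec | None = None
    magnitude_effect: EffectSpec | None = None
    artifact_rate: float = 0.0
    artifact_scale: float = 10.0
    response_median_s: float = 2.17
    response_sigma: float = 0.25  # log-normal shape of the response latency
    outcome_delay_s: float = 2.0
    iti_range_s: tuple[float, float] = (1.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        nyq = self.fs / 2.0
        for band in filter(None, [self.beta_band,
                                  self.ev_effect.band if self.ev_effect else None,
                                  self.magnitude_effect.band if self.magnitude_effect else None]):
            if band[1] >= nyq:
                raise ValueError(f"band {band} exceeds the Nyquist frequency {nyq}")
        if self.fs <= 2 * 250.0:
            raise ValueError("sampling rate must exceed twice the 250 Hz analysis limit")


@dataclass
class LFPRecording:
    """Continuous multichannel recording with trial event markers."""

    signal: np.ndarray  # channels x samples, uV
    fs: float
    labels: list  # e.g. "L1".."L4", "R1".."R4" (1 = most ventral)
    events: pd.DataFrame  # columns: trial, kind, sample
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def hemisphere_channels(self, hemi: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab.startswith(hemi)]

    def event_samples(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)


def _one_over_f_noise(n: int, exponent: float, fs: float, rng) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ~ 1/f**exponent, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()

def _band_noise(n: int, band: tuple[float, float], fs: float, rng) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (rFFT masking)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _erp_template(fs: float, gain_amp: float, loss_amp: float, reversal: bool):
    """Outcome-evoked templates (win, loss): two Gabor atoms, 0..1 s.

    The early (~150 ms) atom carries the valence amplitude difference; with
    ``reversal`` the later (~400 ms) atom carries the same difference with
    opposite sign, emulating the later polarity flip of the valence effect.
    """
    t = np.arange(int(round(1.0 * fs))) / fs
    atom1 = np.cos(2 * np.pi * 4.0 * (t - 0.15)) * np.exp(-0.5 * ((t - 0.15) / 0.06) ** 2)
    atom2 = np.cos(2 * np.pi * 3.0 * (t - 0.40)) * np.exp(-0.5 * ((t - 0.40) / 0.10) ** 2)
    mean_amp = 0.5 * (gain_amp + loss_amp)
    diff = gain_amp - loss_amp
    win = gain_amp * atom1
    loss = loss_amp * atom1
    if reversal:
        win = win + (mean_amp - 0.5 * diff) * atom2
        loss = loss + (mean_amp + 0.5 * diff) * atom2
    else:
        win = win + mean_amp * atom2
        loss = loss + mean_amp * atom2
    return win, loss


def _schedule_events(trials: pd.DataFrame, cfg: SyntheticConfig, rng):
    """Lay trials along the recording; returns (events df, total samples)."""
    fs = cfg.fs
    rows = []
    cursor = 2.0  # lead-in, seconds
    n = len(trials)
    latency = np.exp(np.log(cfg.response_median_s) + cfg.response_sigma * rng.standard_normal(n))
    iti = rng.uniform(*cfg.iti_range_s, size=n)
    chose = trials["chose_gamble"].to_numpy(bool)
    for i in range(n):
        opt = cursor
        resp = opt + latency[i]
        rows.append((i, "options_onset", int(round(opt * fs))))
        rows.append((i, "response", int(round(resp * fs))))
        if chose[i]:
            out = resp + cfg.outcome_delay_s
            rows.append((i, "outcome_onset", int(round(resp * fs)) + int(round(cfg.outcome_delay_s * fs))))
            cursor = out + 1.5 + iti[i]
        else:
            cursor = resp + iti[i]
    events = pd.DataFrame(rows, columns=["trial", "kind", "sample"])
    n_samples = int(round((cursor + 4.0) * fs))
    return events, n_samples


def _add_windowed(sig: np.ndarray, start: int, component: np.ndarray) -> None:
    """Add ``component`` to ``sig`` starting at sample ``start``, clipped."""
    n = sig.shape[-1]
    stop = min(start + len(component), n)
    if start >= n or stop <= max(start, 0):
        return
    lo = max(start, 0)
    sig[..., lo:stop] += component[lo - start : stop - start]


def synthesize_recording(trials: pd.DataFrame, config: SyntheticConfig) -> LFPRecording:
    """Generate a continuous recording for a simulated behavioral session.

    ``trials`` must carry ``chose_gamble``, ``outcome_cents`` and
    ``ev_cents`` columns (see :func:`nacclfp.behavior.simulate_choices`).
    The returned recording's ``ground_truth`` dict holds the injected
    per-trial effect parameters and the clean beta-burst amplitudes.
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    cfg = config
    fs = cfg.fs
    ss = np.random.SeedSequence(cfg.seed)
    rng_sched, rng_bg, rng_ref, rng_line, rng_burst, rng_fx = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]

    events, n_samples = _schedule_events(trials, cfg, rng_sched)
    n_per_hemi = cfg.n_contacts_per_hemisphere
    labels = [f"{h}{i + 1}" for h in ("L", "R") for i in range(n_per_hemi)]
    n_ch = len(labels)

    sig = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        sig[c] = cfg.noise_scale * _one_over_f_noise(n_samples, cfg.noise_exponent, fs, rng_bg)

    # shared reference per electrode: cancels exactly under bipolar montage
    for h in range(2):
        ref = cfg.reference_scale * _one_over_f_noise(n_samples, cfg.noise_exponent, fs, rng_ref)
        sig[h * n_per_hemi : (h + 1) * n_per_hemi] += ref[None, :]

    # line noise: fundamental + harmonics up to 250 Hz, contact-specific
    # amplitude jitter and phase so it survives re-referencing
    t = np.arange(n_samples) / fs
    k_max = int(250.0 // cfg.line_freq)
    for c in range(n_ch):
        for k in range(1, k_max + 1):
            amp = cfg.line_amplitude / k * (0.8 + 0.4 * rng_line.random())
            phase = rng_line.uniform(0, 2 * np.pi)
            sig[c] += amp * np.sin(2 * np.pi * k * cfg.line_freq * t + phase)

    profile = np.concatenate([CONTACT_PROFILE[:n_per_hemi]] * 2)

    outcome_events = events[events["kind"] == "outcome_onset"]
    outcome_by_trial = dict(zip(outcome_events["trial"], outcome_events["sample"]))
    outcomes = trials["outcome_cents"].to_numpy(float)
    evs = trials["ev_cents"].to_numpy(float)

    win_tpl, loss_tpl = _erp_template(fs, cfg.erp_gain_amp, cfg.erp_loss_amp, cfg.erp_reversal)

    burst_len = int(round(1.0 * fs))
    tb = np.arange(burst_len) / fs
    burst_env = np.exp(-0.5 * ((tb - 0.4) / 0.2) ** 2)

    # options-evoked response: same morphology on every trial, no valence
    if cfg.erp_options_amp != 0.0:
        opt_tpl, _ = _erp_template(fs, cfg.erp_options_amp, cfg.erp_options_amp, False)
        opt_events = events[events["kind"] == "options_onset"]
        for s in opt_events["sample"].to_numpy():
            for c in range(n_ch):
                _add_windowed(sig[c], int(s), profile[c] * opt_tpl)

    truth_beta = np.full(len(trials), np.nan)
    for i, out_sample in outcome_by_trial.items():
        won = outcomes[i] > 0
        tpl = win_tpl if won else loss_tpl
        boost = cfg.beta_gain_boost if won else cfg.beta_loss_boost
        amp = cfg.beta_base_amp * np.sqrt(1.0 + boost)
        truth_beta[i] = amp
        burst = amp * burst_env * _band_noise(burst_len, cfg.beta_band, fs, rng_burst)
        component = tpl + burst if len(tpl) == burst_len else tpl
        for c in range(n_ch):
            _add_windowed(sig[c], int(out_sample), profile[c] * component)

    # optional regressor-proportional band-power components
    lock_samples = {
        kind: dict(zip(events.loc[events["kind"] == kind, "trial"],
                       events.loc[events["kind"] == kind, "sample"]))
        for kind in EVENT_KINDS
    }
    for spec, x in ((cfg.ev_effect, evs), (cfg.magnitude_effect, outcomes)):
        if spec is None:
            continue
        locks = lock_samples[spec.lock]
        w_len = int(round((spec.window[1] - spec.window[0]) * fs))
        for i, lock in locks.items():
            if not np.isfinite(x[i]):
                continue
            mult = max(0.05, 1.0 + spec.slope * x[i])
            amp = spec.base_amp * np.sqrt(mult)
            comp = amp * _band_noise(w_len, spec.band, fs, rng_fx)
            start = int(lock) + int(round(spec.window[0] * fs))
            for c in range(n_ch):
                _add_windowed(sig[c], start, profile[c] * comp)

    truth = {
        "config": cfg,
        "beta_burst_amp": truth_beta,
        "contact_profile": profile,
        "artifact_trials": [],
    }
    return LFPRecording(signal=sig, fs=fs, labels=labels, events=events, ground_truth=truth)


def inject_artifacts(
    recording: LFPRecording,
    trials: pd.DataFrame,
    artifact_rate: float,
    artifact_scale: float,
    seed: int = 0,
) -> tuple[LFPRecording, list[int]]:
    """Add large-amplitude transient noise to a deterministic trial count.

    Exactly ``round(artifact_rate * n_trials)`` trials are selected (by
    seed) and receive Gaussian noise of ``artifact_scale`` times the
    background SD on all contacts across their epoch.  Returns the new
    recording and the ground-truth list of affected trial indices.
    """
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError("artifact_rate must lie in [0, 1)")
    n_trials = len(trials)
    n_art = int(round(artifact_rate * n_trials))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(n_trials, size=n_art, replace=False)) if n_art else []

    sig = recording.signal.copy()
    fs = recording.fs
    noise_sd = recording.ground_truth.get("config", SyntheticConfig()).noise_scale
    opts = dict(zip(
        recording.events.loc[recording.events["kind"] == "options_onset", "trial"],
        recording.events.loc[recording.events["kind"] == "options_onset", "sample"],
    ))
    span = int(round(6.0 * fs))  # covers options..post-outcome for any trial
    for i in chosen:
        start = int(opts[i]) - int(round(0.5 * fs))
        burst = artifact_scale * noise_sd * rng.standard_normal((sig.shape[0], span))
        stop = min(start + span, sig.shape[1])
        lo = max(start, 0)
        sig[:, lo:stop] += burst[:, lo - start : stop - start]

    truth = dict(recording.ground_truth)
    truth["artifact_trials"] = [int(i) for i in chosen]
    return (
        LFPRecording(
            signal=sig,
            fs=fs,
            labels=list(recording.labels),
            events=recording.events.copy(),
            ground_truth=truth,
        ),
        truth["artifact_trials"],
    )
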