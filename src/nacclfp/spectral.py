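"""Evoked responses and time-frequency power.

Two spectral recipes are used to account for different smoothing needs:

* low frequencies (2.5-40 Hz in 2.5 Hz steps): single Hanning taper on
  400 ms windows slid in 25 ms steps;
* high frequencies (30-250 Hz in 5 Hz steps): 7 orthogonal Slepian (DPSS)
  multitapers on 200 ms windows (time-half-bandwidth NW = 4, i.e. +/-20 Hz
  spectral smoothing), power averaged over tapers, same 25 ms step.

Time stamps are window centers; bins whose window overhangs the epoch edge
are marked invalid (NaN power) and excluded from statistics.  Power is in
raw squared-amplitude units (a unit-amplitude sinusoid yields power ~1 at
its bin under the low recipe); statistics run on raw power by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .preprocess import EpochSet

__all__ = [
    "TFRPower",
    "ERP",
    "tf_low",
    "tf_high",
    "erp_average",
    "baseline_power",
    "LOW_FREQS",
    "HIGH_FREQS",
]

LOW_FREQS = np.arange(2.5, 40.0 + 1e-9, 2.5)
HIGH_FREQS = np.arange(30.0, 250.0 + 1e-9, 5.0)
STEP_S = 0.025


@dataclass
class TFRPower:
    """Time-frequency power cube: trials x channels x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray  # per time bin: full window inside the epoch
    recipe: str  # "low" | "high"
    channels: list
    metadata: pd.DataFrame
    kept: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(self.power.shape[0], dtype=bool)

    def average_channels(self, groups: dict[str, list[int]] | None = None) -> "TFRPower":
        """Mean power over channel groups (default: one group per hemisphere)."""
        if groups is None:
            groups = {}
            for hemi in ("L", "R"):
                idx = [i for i, c in enumerate(self.channels) if c.startswith(hemi)]
                if idx:
                    groups[hemi] = idx
        pooled = np.stack(
            [self.power[:, idx].mean(axis=1) for idx in groups.values()], axis=1
        )
        return TFRPower(
            power=pooled, freqs=self.freqs, times=self.times, valid=self.valid,
            recipe=self.recipe, channels=list(groups), metadata=self.metadata,
            kept=self.kept,
        )

    def select_trials(self, mask: np.ndarray) -> "TFRPower":
        mask = np.asarray(mask, bool)
        return TFRPower(
            power=self.power[mask], freqs=self.freqs, times=self.times,
            valid=self.valid, recipe=self.recipe, channels=list(self.channels),
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            kept=self.kept[mask],
        )


@dataclass
class ERP:
    """Per-trial filtered time courses and their across-trial mean."""

    trials: np.ndarray  # trials x channels x time
    mean: np.ndarray  # channels x time
    times: np.ndarray
    channels: list
    n_trials: int


def _sliding_tf(epochs: EpochSet, freqs: np.ndarray, win_s: float, tapers: np.ndarray) -> TFRPower:
    fs = epochs.fs
    n_win = tapers.shape[-1]
    half_lo = n_win // 2
    half_hi = n_win - half_lo
    n_t = epochs.data.shape[2]
    step = max(1, int(round(STEP_S * fs)))

    centers = np.arange(0, n_t, step)
    valid = (centers - half_lo >= 0) & (centers + half_hi <= n_t)
    vcenters = centers[valid]

    n_trials, n_ch = epochs.data.shape[:2]
    power = np.full((n_trials, n_ch, len(freqs), len(centers)), np.nan)
    if vcenters.size and n_trials:
        offs = np.arange(n_win) - half_lo
        seg_idx = vcenters[:, None] + offs[None, :]  # n_valid x n_win
        segs = epochs.data[:, :, seg_idx]  # trials x ch x n_valid x n_win
        tsec = offs / fs
        # basis: taper x complex exponential, per taper and frequency
        pw = np.zeros((n_trials, n_ch, vcenters.size, len(freqs)))
        for taper in np.atleast_2d(tapers):
            basis = taper[:, None] * np.exp(-2j * np.pi * tsec[:, None] * freqs[None, :])
            coef = segs @ basis  # trials x ch x n_valid x n_freq
            norm = 2.0 / taper.sum() if tapers.ndim == 1 else np.sqrt(2.0 / fs)
            pw += np.abs(norm * coef) ** 2
        pw /= np.atleast_2d(tapers).shape[0]
        power[:, :, :, valid] = np.transpose(pw, (0, 1, 3, 2))

    times = epochs.times[0] + centers / fs
    return TFRPower(
        power=power, freqs=np.asarray(freqs, float), times=times, valid=valid,
        recipe="", channels=list(epochs.channels), metadata=epochs.metadata,
        kept=epochs.kept,
    )


def tf_low(epochs: EpochSet, freqs: np.ndarray | None = None) -> TFRPower:
    """Hanning-taper TF power, 400 ms windows every 25 ms, 2.5-40 Hz."""
    if freqs is None:
        freqs = LOW_FREQS
    win_s = 0.4
    n_win = int(round(win_s * epochs.fs))
    if epochs.data.shape[2] < n_win:
        raise ValueError("epoch shorter than the 400 ms analysis window")
    rayleigh = 1.0 / win_s
    if np.any(np.asarray(freqs) < rayleigh - 1e-9):
        raise ValueError(f"frequencies below the window resolution {rayleigh:.2f} Hz")
    taper = windows.hann(n_win, sym=False)
    out = _sliding_tf(epochs, np.asarray(freqs, float), win_s, taper)
    out.recipe = "low"
    return out


def tf_high(epochs: EpochSet, freqs: np.ndarray | None = None) -> TFRPower:
    """Slepian multitaper TF power: 200 ms windows, +/-20 Hz smoothing.

    Time-half-bandwidth NW = 0.2 s x 20 Hz = 4, giving 2*NW - 1 = 7
    orthogonal tapers.
    """
    if freqs is None:
        freqs = HIGH_FREQS
    win_s = 0.2
    n_win = int(round(win_s * epochs.fs))
    if epochs.data.shape[2] < n_win:
        raise ValueError("epoch shorter than the 200 ms analysis window")
    nw = 4.0
    tapers = windows.dpss(n_win, nw, Kmax=int(2 * nw - 1))
    out = _sliding_tf(epochs, np.asarray(freqs, float), win_s, tapers)
    out.recipe = "high"
    return out


def erp_average(epochs: EpochSet, mask: np.ndarray | None = None) -> ERP:
    """Arithmetic across-trial mean of (band-passed) epochs."""
    if mask is None:
        mask = np.ones(epochs.n_trials, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("condition mask selects no trials")
    sel = epochs.data[mask]
    return ERP(
        trials=sel, mean=sel.mean(axis=0), times=epochs.times,
        channels=list(epochs.channels), n_trials=int(mask.sum()),
    )


def baseline_power(tfr: TFRPower, window: tuple[float, float] = (-1.0, -0.2)) -> np.ndarray:
    """Per-trial mean power over pre-options time bins (trials x ch x freq).

    ``tfr`` must come from options-locked epochs covering the window; bins
    whose centers fall in [window) and whose analysis window is fully
    inside the epoch are averaged.
    """
    sel = (tfr.times >= window[0]) & (tfr.times < window[1]) & tfr.valid
    if not sel.any():
        raise ValueError("baseline window not covered by valid TF bins")
    return tfr.power[:, :, :, sel].mean(axis=3)
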