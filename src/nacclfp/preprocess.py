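"""Continuous-recording preprocessing: montage, filtering, epoching, QC.

All filters are Butterworth designs applied as second-order sections with
forward-backward (zero-phase) filtering.  Time conventions: seconds
relative to the lock event, 0-based sample indices, closed-open windows
[start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic_lfp import LFPRecording

__all__ = [
    "EpochSet",
    "bipolar_montage",
    "notch_line_noise",
    "epoch",
    "reject_artifacts",
    "baseline_correct",
    "bandpass_erp",
    "pretrial_baseline",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Trial-locked data cube with metadata and a kept-trial mask.

    ``data`` is trials x channels x time; ``times`` is seconds relative to
    the lock event (t = 0 at the event sample).
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: list
    lock: str
    metadata: pd.DataFrame  # one row per epoch; carries the trial index
    kept: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, bool)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            fs=self.fs,
            channels=list(self.channels),
            lock=self.lock,
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            kept=self.kept[mask],
        )

    def kept_only(self) -> "EpochSet":
        return self.select(self.kept)


def bipolar_montage(recording: LFPRecording) -> LFPRecording:
    """Re-reference each contact to its dorsal neighbor (3 ch/hemisphere).

    Contacts must be labeled ``<hemi><index>`` with index 1 most ventral.
    Any component common to all contacts of one electrode cancels exactly.
    """
    new_sig = []
    new_labels = []
    for hemi in ("L", "R"):
        idx = recording.hemisphere_channels(hemi)
        if not idx:
            continue
        idx = sorted(idx, key=lambda i: recording.labels[i])
        if len(idx) < 2:
            raise ValueError(f"hemisphere {hemi} needs >= 2 contacts for a bipolar montage")
        for a, b in zip(idx[:-1], idx[1:]):
            new_sig.append(recording.signal[a] - recording.signal[b])
            new_labels.append(f"{recording.labels[a]}-{recording.labels[b]}")
    if not new_sig:
        raise ValueError("recording has no recognizable contacts")
    return LFPRecording(
        signal=np.asarray(new_sig),
        fs=recording.fs,
        labels=new_labels,
        events=recording.events.copy(),
        ground_truth=dict(recording.ground_truth),
    )


def _sos_bandstop(low: float, high: float, fs: float):
    return sps.butter(4, [low, high], btype="bandstop", fs=fs, output="sos")


def notch_line_noise(
    recording: LFPRecording,
    line_freq: float = 50.0,
    half_width: float = 1.5,
    max_freq: float = 250.0,
) -> LFPRecording:
    """Band-stop the line frequency and its harmonics up to ``max_freq``.

    Each stop band is ``k*line_freq +/- half_width`` Hz, removed with a
    fourth-order two-pass Butterworth filter (applied as SOS, zero phase).
    """
    sig = recording.signal
    k = 1
    while k * line_freq <= max_freq:
        f0 = k * line_freq
        sos = _sos_bandstop(f0 - half_width, f0 + half_width, recording.fs)
        sig = sps.sosfiltfilt(sos, sig, axis=-1)
        k += 1
    return LFPRecording(
        signal=np.ascontiguousarray(sig),
        fs=recording.fs,
        labels=list(recording.labels),
        events=recording.events.copy(),
        ground_truth=dict(recording.ground_truth),
    )


def epoch(
    recording: LFPRecording,
    lock: str,
    window: tuple[float, float],
    trials: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut fixed-length epochs around every occurrence of a lock event.

    The epoch covers samples ``e + round(start*fs) .. e + round(end*fs)``
    (end exclusive).  Trials whose window exceeds the recording bounds are
    dropped with a logged warning.  ``trials`` metadata, if given, is
    joined on the trial index.
    """
    ev = recording.event_samples(lock)
    fs = recording.fs
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    n_samp = hi - lo
    if n_samp < 0:
        raise ValueError("window end must not precede window start")

    cubes, kept_rows = [], []
    for _, row in ev.iterrows():
        s = int(row["sample"])
        if s + lo < 0 or s + hi > recording.n_samples:
            logger.warning("trial %d: epoch exceeds recording bounds; dropped", row["trial"])
            continue
        cubes.append(recording.signal[:, s + lo : s + hi])
        kept_rows.append(int(row["trial"]))

    data = np.asarray(cubes) if cubes else np.empty((0, recording.signal.shape[0], n_samp))
    meta = pd.DataFrame({"trial": kept_rows})
    if trials is not None:
        meta = meta.merge(trials, left_on="trial", right_on="trial", how="left")
    times = (np.arange(lo, hi)) / fs
    return EpochSet(
        data=data, times=times, fs=fs, channels=list(recording.labels),
        lock=lock, metadata=meta,
    )


def reject_artifacts(epochs: EpochSet, z_threshold: float = 4.0) -> EpochSet:
    """Flag high-variance trials via a per-channel robust-z variance rule.

    Per trial and channel the epoch variance is computed and z-scored
    across trials within each channel using the median and the scaled
    median absolute deviation (robust to the artifact trials themselves,
    which would otherwise inflate a mean/SD z-score enough to mask them
    at realistic contamination rates).  A trial's metric is its maximum z
    over channels; trials with metric > ``z_threshold`` are marked
    rejected in the kept mask (data are not removed).
    """
    if epochs.n_trials < 10:
        raise ValueError("artifact rejection needs at least 10 trials")
    var = epochs.data.var(axis=2)  # trials x channels
    med = np.median(var, axis=0, keepdims=True)
    mad = 1.4826 * np.median(np.abs(var - med), axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(mad > 0, (var - med) / mad, 0.0)
    metric = z.max(axis=1)
    kept = metric <= z_threshold
    out = epochs.select(np.ones(epochs.n_trials, bool))
    out.kept = kept
    return out


def pretrial_baseline(
    recording: LFPRecording,
    window: tuple[float, float] = (-0.1, 0.0),
) -> pd.DataFrame:
    """Mean signal per trial/channel over a window before options onset.

    Returns a DataFrame indexed by trial with one column per channel,
    used to baseline-correct epochs locked to later events.
    """
    ev = recording.event_samples("options_onset")
    fs = recording.fs
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    rows, idx = [], []
    for _, row in ev.iterrows():
        s = int(row["sample"])
        if s + lo < 0 or s + hi > recording.n_samples:
            continue
        rows.append(recording.signal[:, s + lo : s + hi].mean(axis=1))
        idx.append(int(row["trial"]))
    return pd.DataFrame(rows, index=idx, columns=recording.labels)


def baseline_correct(
    epochs: EpochSet,
    baselines: pd.DataFrame | None = None,
    window: tuple[float, float] = (-0.1, 0.0),
) -> EpochSet:
    """Subtract the pre-trial mean amplitude from the entire epoch.

    If ``baselines`` (from :func:`pretrial_baseline`) is given, each
    trial's per-channel value is subtracted — required for epochs that do
    not contain the pre-options interval.  Otherwise the mean over
    ``window`` (relative to the epoch's own lock event, which must then be
    the options onset) is used.
    """
    out = epochs.select(np.ones(epochs.n_trials, bool))
    out.kept = epochs.kept.copy()
    if baselines is not None:
        for i, trial in enumerate(epochs.metadata["trial"]):
            if trial not in baselines.index:
                raise ValueError(f"no pre-trial baseline available for trial {trial}")
            out.data[i] -= baselines.loc[trial].to_numpy()[:, None]
        return out
    sel = (epochs.times >= window[0]) & (epochs.times < window[1])
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    out.data = epochs.data - epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


def bandpass_erp(
    epochs: EpochSet, band: tuple[float, float] = (0.5, 25.0)
) -> EpochSet:
    """Band-pass each trial/channel 0.5-25 Hz (4th order, zero phase)."""
    sos = sps.butter(4, band, btype="bandpass", fs=epochs.fs, output="sos")
    out = epochs.select(np.ones(epochs.n_trials, bool))
    out.kept = epochs.kept.copy()
    if epochs.n_trials:
        out.data = sps.sosfiltfilt(sos, epochs.data, axis=2)
    return out
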