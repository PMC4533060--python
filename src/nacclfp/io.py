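"""Persistence: HDF5 containers for recordings/epochs and EDF export."""

from __future__ import annotations

import io
import json

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .spectral import TFRPower
from .synthetic_lfp import LFPRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_tfr",
    "load_tfr",
    "rejection_report",
    "export_edf",
    "save_ground_truth",
]


def save_recording(recording: LFPRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal, compression="gzip")
        f.attrs["fs"] = recording.fs
        f.attrs["labels"] = json.dumps(list(recording.labels))
        ev = recording.events
        grp = f.create_group("events")
        grp.create_dataset("trial", data=ev["trial"].to_numpy(np.int64))
        grp.create_dataset("sample", data=ev["sample"].to_numpy(np.int64))
        grp.create_dataset(
            "kind", data=np.array(ev["kind"], dtype=h5py.string_dtype())
        )


def load_recording(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({
            "trial": f["events/trial"][:],
            "kind": [k.decode() for k in f["events/kind"][:]],
            "sample": f["events/sample"][:],
        })
        return LFPRecording(
            signal=f["signal"][:],
            fs=float(f.attrs["fs"]),
            labels=json.loads(f.attrs["labels"]),
            events=events,
        )


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("kept", data=epochs.kept)
        f.attrs["fs"] = epochs.fs
        f.attrs["lock"] = epochs.lock
        f.attrs["channels"] = json.dumps(list(epochs.channels))
        f.attrs["metadata"] = epochs.metadata.to_json(orient="split")


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][:],
            times=f["times"][:],
            fs=float(f.attrs["fs"]),
            channels=json.loads(f.attrs["channels"]),
            lock=str(f.attrs["lock"]),
            metadata=pd.read_json(io.StringIO(f.attrs["metadata"]), orient="split"),
            kept=f["kept"][:].astype(bool),
        )


def save_tfr(tfr: TFRPower, path) -> None:
    """Persist a time-frequency power cube (power + axes + validity mask)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power, compression="gzip")
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("valid", data=tfr.valid)
        f.create_dataset("kept", data=tfr.kept)
        f.attrs["recipe"] = tfr.recipe
        f.attrs["channels"] = json.dumps(list(tfr.channels))
        f.attrs["metadata"] = tfr.metadata.to_json(orient="split")


def load_tfr(path) -> TFRPower:
    with h5py.File(path, "r") as f:
        return TFRPower(
            power=f["power"][:],
            freqs=f["freqs"][:],
            times=f["times"][:],
            valid=f["valid"][:].astype(bool),
            recipe=str(f.attrs["recipe"]),
            channels=json.loads(f.attrs["channels"]),
            metadata=pd.read_json(io.StringIO(f.attrs["metadata"]), orient="split"),
            kept=f["kept"][:].astype(bool),
        )


def rejection_report(epochs: EpochSet, path) -> pd.DataFrame:
    """Write a TSV listing each trial's kept/rejected status; returns it."""
    report = pd.DataFrame({
        "trial": epochs.metadata["trial"].to_numpy(),
        "kept": epochs.kept.astype(int),
    })
    report.to_csv(path, sep="\t", index=False)
    return report


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def export_edf(recording: LFPRecording, path) -> None:
    """Write the recording as plain EDF (one channel per contact).

    Signals are scaled to 16-bit integers over each channel's physical
    range, in 1-second data records (the last record is zero-padded).
    Event markers are not representable in plain EDF; write them with
    :func:`save_ground_truth` / the HDF5 container alongside.  The output
    is readable by standard EDF tools (e.g. ``mne.io.read_raw_edf``).
    """
    sig = np.asarray(recording.signal, float)
    n_ch, n_samp = sig.shape
    spr = int(round(recording.fs))  # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    pad = n_rec * spr - n_samp
    if pad:
        sig = np.pad(sig, ((0, 0), (0, pad)))

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig = np.round(
        (sig - phys_min[:, None]) / span[:, None] * 65535.0 - 32768.0
    ).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X synthetic LFP", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    fields = [
        (16, [lab for lab in recording.labels]),
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{v:.1f}" for v in phys_min]),
        (8, [f"{v:.1f}" for v in phys_max]),
        (8, ["-32768"] * n_ch),
        (8, ["32767"] * n_ch),
        (80, [""] * n_ch),
        (8, [spr] * n_ch),
        (32, [""] * n_ch),
    ]
    for width, values in fields:
        header += b"".join(_edf_field(v, width) for v in values)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def save_ground_truth(recording: LFPRecording, path) -> None:
    """JSON sidecar with the generator's injected-effect ground truth."""
    truth = recording.ground_truth
    payload = {
        "artifact_trials": truth.get("artifact_trials", []),
        "beta_burst_amp": np.asarray(truth.get("beta_burst_amp", [])).tolist(),
        "contact_profile": np.asarray(truth.get("contact_profile", [])).tolist(),
    }
    cfg = truth.get("config")
    if cfg is not None:
        payload["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
            if isinstance(v, (int, float, bool, str, tuple))
        }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)
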