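"""Epoching, artifact rejection, channel handling and on-disk I/O.

The central container is :class:`EpochedRecording`: a 3-D array of
``epochs x channels x samples`` in microvolts together with the sampling
rate and ordered channel labels.  All signal stages (entropy, spectra)
consume this container; the synthetic generator produces it.

Conventions
-----------
* Time is sample-indexed, 0-based; epoch windows are half-open
  ``[start, start + n_samples)``.
* Epoch rejection uses the peak-to-peak (max minus min) amplitude within
  an epoch: an epoch is dropped when *any* channel's range exceeds the
  threshold.  The pipeline rejects on the full montage before channel
  subsetting, so rejected-epoch counts refer to whole-montage epochs.
* Re-referencing, bad-channel interpolation and ICA-based artifact
  removal are upstream responsibilities: this module expects data that
  are already referenced and free of stereotyped ocular/muscle/cardiac
  components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EpochedRecording",
    "RejectionReport",
    "MONTAGE_35",
    "TASK_CHANNELS_20",
    "segment_continuous",
    "reject_epochs",
    "select_channels",
    "bandpass_filter",
    "save_epochs",
    "load_epochs",
    "read_continuous_csv",
    "read_edf",
    "write_rejection_report",
]

#: Full 35-channel recording montage (10-10 labels, nose reference).
MONTAGE_35 = [
    "Fp1", "AFz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5",
    "FC1", "FC2", "FC6", "FT10", "T7", "C3", "Cz", "C4", "T8", "TP9",
    "CP5", "CP1", "CP2", "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
]

#: 20-channel task-related subset used for the resting-state analyses
#: (peripheral electrodes excluded).
TASK_CHANNELS_20 = [
    "F3", "Fz", "F4", "F8", "FC1", "FC2", "FC6", "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6", "P3", "Pz", "P4", "O1", "Oz", "O2",
]

_CONTAINER_VERSION = 1


class EmptyResultError(RuntimeError):
    """Raised when an operation would yield zero epochs."""


@dataclass
class EpochedRecording:
    """Epoched multichannel EEG: ``epochs x channels x samples`` in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    epoch_ms: float
    provenance: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        expected = self.epoch_ms * self.fs / 1000.0
        if abs(expected - round(expected)) > 1e-9 or int(round(expected)) != self.data.shape[2]:
            raise ValueError(
                f"epoch_ms={self.epoch_ms} at fs={self.fs} implies {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def log(self, step: str) -> None:
        self.provenance.append(step)


@dataclass
class RejectionReport:
    """Bookkeeping of a peak-to-peak epoch-rejection pass."""

    n_input: int
    n_rejected: int
    rejected_indices: list[int]
    threshold_uV: float

    def __post_init__(self) -> None:
        if self.n_rejected != len(self.rejected_indices):
            raise ValueError("n_rejected must equal len(rejected_indices)")
        if self.n_rejected > self.n_input:
            raise ValueError("cannot reject more epochs than provided")


def segment_continuous(
    signal: np.ndarray,
    fs: float,
    epoch_ms: float,
    channel_labels: list[str] | None = None,
) -> EpochedRecording:
    """Cut a continuous ``channels x samples`` record into fixed epochs.

    Windows are non-overlapping, contiguous and left-aligned; a trailing
    remainder shorter than one epoch is discarded.  Epoch order preserves
    time order.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim == 1:
        signal = signal[None, :]
    if signal.ndim != 2:
        raise ValueError("continuous signal must be 1-D or 2-D (channels x samples)")
    n_ch, n_total = signal.shape
    n_per = epoch_ms * fs / 1000.0
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"epoch_ms={epoch_ms} is not an integer number of samples at fs={fs}")
    n_per = int(round(n_per))
    n_epochs = n_total // n_per
    if n_epochs < 1:
        raise EmptyResultError(
            f"signal of {n_total} samples is shorter than one {n_per}-sample epoch"
        )
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    data = (
        signal[:, : n_epochs * n_per]
        .reshape(n_ch, n_epochs, n_per)
        .transpose(1, 0, 2)
        .copy()
    )
    rec = EpochedRecording(data, fs, channel_labels, epoch_ms)
    rec.log(f"segment_continuous(epoch_ms={epoch_ms}, n_epochs={n_epochs})")
    return rec


def reject_epochs(
    rec: EpochedRecording, threshold_uV: float = 100.0
) -> tuple[EpochedRecording, RejectionReport]:
    """Drop epochs whose min-max voltage range exceeds ``threshold_uV``.

    The criterion is per-channel-any: an epoch is rejected if any single
    channel's (max - min) within the epoch exceeds the threshold.
    Surviving epochs keep their original relative order.  Raises
    :class:`EmptyResultError` if nothing survives, so downstream stages
    never silently receive zero epochs.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold_uV must be positive")
    ptp = rec.data.max(axis=2) - rec.data.min(axis=2)  # epochs x channels
    bad = (ptp > threshold_uV).any(axis=1)
    rejected = np.flatnonzero(bad)
    report = RejectionReport(
        n_input=rec.n_epochs,
        n_rejected=int(bad.sum()),
        rejected_indices=[int(i) for i in rejected],
        threshold_uV=float(threshold_uV),
    )
    if bad.all():
        raise EmptyResultError(
            f"all {rec.n_epochs} epochs exceed the {threshold_uV} µV rejection threshold"
        )
    kept = EpochedRecording(
        rec.data[~bad],
        rec.fs,
        rec.channel_labels,
        rec.epoch_ms,
        provenance=list(rec.provenance),
        info=dict(rec.info),
    )
    kept.log(f"reject_epochs(threshold_uV={threshold_uV}, rejected={report.n_rejected})")
    return kept, report


def select_channels(rec: EpochedRecording, keep: list[str]) -> EpochedRecording:
    """Subset and reorder channels; output order follows ``keep``."""
    missing = [c for c in keep if c not in rec.channel_labels]
    if missing:
        raise KeyError(f"channel(s) not in recording: {missing}")
    idx = [rec.channel_labels.index(c) for c in keep]
    out = EpochedRecording(
        rec.data[:, idx, :],
        rec.fs,
        list(keep),
        rec.epoch_ms,
        provenance=list(rec.provenance),
        info=dict(rec.info),
    )
    out.log(f"select_channels(n={len(keep)})")
    return out


def bandpass_filter(
    signal: np.ndarray, fs: float, low_Hz: float = 0.5, high_Hz: float = 40.0
) -> np.ndarray:
    """Zero-phase FIR band-pass of a continuous ``channels x samples`` record.

    A linear-phase Hamming-window FIR (applied forward-backward, so the
    net phase is zero) with >=20 dB attenuation one octave outside the
    band and <=1 dB passband ripple.  Applied to continuous data before
    segmentation; filtering epoch-by-epoch would smear edge transients.
    """
    if not (0 < low_Hz < high_Hz < fs / 2):
        raise ValueError(f"invalid band edges ({low_Hz}, {high_Hz}) for fs={fs}")
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    # transition widths: half an octave each side keeps 20 dB at one octave
    trans_lo = low_Hz / 2
    trans_hi = min(high_Hz / 2, fs / 2 - high_Hz)
    numtaps = int(np.ceil(3.3 * fs / min(trans_lo, trans_hi)))
    numtaps |= 1  # odd length -> type I linear phase
    if numtaps >= signal.shape[1]:
        raise ValueError(
            f"signal too short ({signal.shape[1]} samples) for a {numtaps}-tap filter"
        )
    taps = sps.firwin(
        numtaps, [low_Hz, high_Hz], pass_zero=False, fs=fs, window="hamming"
    )
    padlen = min(3 * numtaps, signal.shape[1] - 1)
    return sps.filtfilt(taps, [1.0], signal, axis=1, padlen=padlen)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def save_epochs(rec: EpochedRecording, path: str) -> None:
    """Write an epoched container (HDF5 layout, version 1).

    One file per subject-condition: dataset ``data`` plus a JSON-text
    header attribute carrying fs, labels, epoch length, provenance and
    auxiliary info.  EDF cannot represent epoch structure losslessly,
    hence the dedicated container.
    """
    import h5py

    header = {
        "version": _CONTAINER_VERSION,
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "epoch_ms": rec.epoch_ms,
        "provenance": rec.provenance,
        "info": {k: _jsonable(v) for k, v in rec.info.items()},
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", compression_opts=4)
        f.attrs["header"] = json.dumps(header)


def load_epochs(path: str) -> EpochedRecording:
    """Read an epoched container written by :func:`save_epochs`."""
    import h5py

    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        if header.get("version") != _CONTAINER_VERSION:
            raise ValueError(f"unsupported container version {header.get('version')}")
        data = f["data"][...]
    return EpochedRecording(
        data,
        header["fs"],
        header["channel_labels"],
        header["epoch_ms"],
        provenance=list(header.get("provenance", [])),
        info=dict(header.get("info", {})),
    )


def read_continuous_csv(path: str) -> tuple[np.ndarray, list[str]]:
    """Plain-text fallback reader: CSV of samples x channels with a label header.

    Returns ``(channels x samples array, labels)``; the sampling rate is
    not stored in CSV and must be supplied by the caller.
    """
    df = pd.read_csv(path)
    return df.to_numpy(dtype=np.float64).T, [str(c) for c in df.columns]


def read_edf(path: str) -> tuple[np.ndarray, list[str], float]:
    """Read a continuous EDF record; returns (channels x samples in µV, labels, fs)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, list(raw.ch_names), float(raw.info["sfreq"])


def write_rejection_report(report: RejectionReport, path: str) -> None:
    """Serialize a RejectionReport as a two-line TSV."""
    df = pd.DataFrame(
        {
            "n_input": [report.n_input],
            "n_rejected": [report.n_rejected],
            "threshold_uV": [report.threshold_uV],
            "rejected_indices": [",".join(map(str, report.rejected_indices))],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v
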