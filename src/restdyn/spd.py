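"""Spectral power density: normalized single-trial FFT spectra and band shares.

Each epoch is z-normalized (mean 0, SD 1, population normalizer) before
a single rectangular-window FFT, so the resulting spectra are relative:
multiplying a raw epoch by any positive constant leaves them unchanged.
This deliberately removes global signal-power differences (e.g. between
age groups) and keeps only the *distribution* of variance over
frequency.  With 2500-sample epochs at 1000 Hz the bin spacing is
0.4 Hz.  Relative power divides each bin by the total power inside the
analysis range (default 0.4-40 Hz: the first nonzero bin up to the
band-pass cutoff; the 0 Hz bin is zeroed by mean removal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpdGrid",
    "BandSet",
    "DEFAULT_BANDS",
    "normalize_epoch",
    "power_spectrum",
    "relative_power",
    "band_power",
    "spd_average",
    "spd_grid",
    "band_summary",
    "save_spd_grid",
]


@dataclass(frozen=True)
class BandSet:
    """Named frequency bands in Hz; intervals are closed on bin centers."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 1.0, 3.0),
        ("theta", 4.0, 7.0),
        ("low", 1.0, 7.0),  # delta+theta composite
        ("alpha", 8.0, 14.0),
        ("beta", 15.0, 30.0),
        ("gamma", 30.0, 40.0),
    )

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name!r} has empty interval [{lo}, {hi}]")

    def __iter__(self):
        return iter(self.bands)

    def interval(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


DEFAULT_BANDS = BandSet()


@dataclass
class SpdGrid:
    """Trial-averaged relative power, channels x frequency bins."""

    values: np.ndarray
    freqs_Hz: np.ndarray
    channel_labels: list[str]
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs_Hz = np.asarray(self.freqs_Hz, dtype=np.float64)
        if self.values.shape != (len(self.channel_labels), len(self.freqs_Hz)):
            raise ValueError("values must be channels x bins")
        if np.any(self.values < 0):
            raise ValueError("relative power cannot be negative")


def normalize_epoch(series: np.ndarray) -> np.ndarray:
    """z-normalize one epoch series to mean 0, SD 1 (population SD)."""
    series = np.asarray(series, dtype=np.float64)
    sd = series.std()
    if sd == 0:
        raise ValueError("constant series cannot be normalized")
    return (series - series.mean()) / sd


def power_spectrum(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a single epoch series.

    No taper and no detrending beyond the mean removal done in
    :func:`normalize_epoch`; bins sit at k*fs/N.  Power is scaled so that
    the one-sided sum equals sum(x^2) = N*var for a zero-mean series
    (Parseval).  Returns ``(freqs_Hz, power)``.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    n = epoch.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    spec = np.fft.rfft(epoch)
    power = np.abs(spec) ** 2 / n
    # double the interior bins to fold negative frequencies in
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def relative_power(
    spectrum: np.ndarray,
    freqs: np.ndarray,
    range_Hz: tuple[float, float] = (0.4, 40.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a spectrum to ``range_Hz`` and normalize it to unit sum.

    Returns ``(freqs in range, fractions)``; fractions sum to 1 along the
    last axis.  The denominator is the total power inside the range, so
    the result is invariant to the overall signal scale.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    lo, hi = range_Hz
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not mask.any():
        raise ValueError(f"no bins inside range {range_Hz}")
    sub = spectrum[..., mask]
    total = sub.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power inside the analysis range")
    return freqs[mask], sub / total


def band_power(
    rel_spectrum: np.ndarray, freqs: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Share of relative power in ``band`` (closed interval on bin centers)."""
    freqs = np.asarray(freqs, dtype=np.float64)
    lo, hi = band
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bin")
    return np.asarray(rel_spectrum)[..., mask].sum(axis=-1)


def spd_average(per_epoch_spectra: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of single-trial relative spectra."""
    if len(per_epoch_spectra) == 0:
        raise ValueError("need at least one epoch spectrum")
    stack = np.stack([np.asarray(s, dtype=np.float64) for s in per_epoch_spectra])
    return stack.mean(axis=0)


def spd_grid(rec, range_Hz: tuple[float, float] = (0.4, 40.0)) -> SpdGrid:
    """Trial-averaged relative power grid for an :class:`EpochedRecording`.

    Per epoch and channel: z-normalize, FFT, restrict to ``range_Hz``,
    normalize to unit sum; then average the unit-sum spectra over epochs
    (a mean of unit-sum vectors is unit-sum).
    """
    if rec.n_epochs < 1:
        raise ValueError("recording has no epochs")
    per_epoch = []
    freqs_out = None
    for e in range(rec.n_epochs):
        z = np.stack([normalize_epoch(rec.data[e, c]) for c in range(rec.n_channels)])
        freqs, power = power_spectrum(z, rec.fs)
        freqs_sub, rel = relative_power(power, freqs, range_Hz)
        freqs_out = freqs_sub
        per_epoch.append(rel)
    return SpdGrid(
        values=spd_average(per_epoch),
        freqs_Hz=freqs_out,
        channel_labels=list(rec.channel_labels),
        n_epochs_averaged=rec.n_epochs,
    )


def band_summary(grid: SpdGrid, bands: BandSet = DEFAULT_BANDS) -> pd.DataFrame:
    """Per-channel band shares (rows=channels, columns=band names)."""
    out = {
        name: band_power(grid.values, grid.freqs_Hz, (lo, hi))
        for name, lo, hi in bands
    }
    return pd.DataFrame(out, index=grid.channel_labels)


def save_spd_grid(
    grid: SpdGrid, path: str, bands: BandSet = DEFAULT_BANDS
) -> None:
    """TSV of bins (Hz headers), a band-summary TSV, and a JSON sidecar."""
    df = pd.DataFrame(
        grid.values,
        index=grid.channel_labels,
        columns=[f"{f:.4g}" for f in grid.freqs_Hz],
    )
    df.to_csv(path, sep="\t", index_label="channel")
    band_summary(grid, bands).to_csv(str(path) + ".bands.tsv", sep="\t", index_label="channel")
    with open(str(path) + ".json", "w") as f:
        json.dump({"n_epochs_averaged": grid.n_epochs_averaged}, f)
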