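"""Multiscale entropy: coarse-graining plus sample entropy.

Sample entropy SampEn(m, r) of a series is -ln(A/B), where B counts
pairs of length-m templates whose Chebyshev (maximum coordinate-wise)
distance is at most r, and A counts the same pairs still matching when
extended by one point.  Self-matches are excluded and pairs are counted
over i < j, which is what distinguishes sample entropy from approximate
entropy.  Multiscale entropy evaluates SampEn on progressively
coarse-grained copies of the series: scale tau replaces the series by
means of non-overlapping windows of length tau, so fine scales index
fast local dynamics and coarse scales slow, distributed dynamics.

Tolerance convention
--------------------
``r_abs = r_frac * SD`` of the *original* (scale-1) series, computed per
channel per epoch with the population (1/N) normalizer, and reused
unchanged at every scale.  Recomputing the SD per scale would
systematically inflate coarse-scale entropy; holding r fixed at the
scale-1 value follows Costa's reference implementation.  A per-recording
SD is available via the ``sd_scope`` switch on :func:`mse_grid`.

Undefined estimates (zero template matches at either length) propagate
as NaN sentinels and are excluded from epoch averaging with a logged
count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MseParams",
    "MseGrid",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "mse_average",
    "mse_grid",
    "save_mse_grid",
    "load_mse_grid",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass(frozen=True)
class MseParams:
    """Sample-entropy parameters and the coarse-graining scale rule.

    Defaults are m=2, r=0.5*SD, scales 1..50 with at least 50 coarse
    samples retained per scale, i.e. the settings used for 2500-sample
    epochs at 1000 Hz where scale s corresponds to an s-ms window.
    """

    m: int = 2
    r_frac: float = 0.5
    max_scale: int = 50
    min_coarse_samples: int = 50

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("pattern length m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("tolerance fraction r_frac must be positive")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")
        if self.min_coarse_samples < self.m + 2:
            raise ValueError("min_coarse_samples must be >= m + 2")


@dataclass
class MseGrid:
    """Trial-averaged sample entropy, channels x timescales (nats)."""

    values: np.ndarray
    scales: np.ndarray
    channel_labels: list[str]
    n_epochs_averaged: int
    n_valid: np.ndarray | None = None  # per-cell count of defined epochs
    params: MseParams = field(default_factory=MseParams)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.int64)
        if self.values.shape != (len(self.channel_labels), len(self.scales)):
            raise ValueError("values must be channels x scales")
        if len(self.scales) and not (
            self.scales[0] == 1 and np.all(np.diff(self.scales) > 0)
        ):
            raise ValueError("scales must increase strictly from 1")


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Average a series within non-overlapping windows of length ``scale``.

    Element j of the output is the mean of samples [j*scale, (j+1)*scale);
    a trailing remainder shorter than one window is discarded.  Scale 1
    returns the original series.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    scale = int(scale)
    n = series.shape[0]
    if scale < 1 or scale > n:
        raise ValueError(f"scale={scale} invalid for series of length {n}")
    n_win = n // scale
    return series[: n_win * scale].reshape(n_win, scale).mean(axis=1)


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    """Template-pair counts (A, B) at lengths m+1 and m, Chebyshev metric.

    Pairs (i, j), i < j, run over the first N-m templates so that both
    the length-m and the length-(m+1) counts draw from the same template
    set.
    """
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(series: np.ndarray, m: int, r_abs: float) -> float:
    """SampEn(m, r_abs) in nats; NaN (with a logged warning) if undefined."""
    series = np.ascontiguousarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if series.shape[0] <= m + 1:
        raise ValueError(f"series of length {series.shape[0]} too short for m={m}")
    if r_abs <= 0:
        raise ValueError("tolerance r_abs must be positive")
    a, b = _sampen_counts(series, int(m), float(r_abs))
    if a == 0 or b == 0:
        logger.warning(
            "sample entropy undefined (A=%d, B=%d) for series of length %d",
            a, b, series.shape[0],
        )
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(
    epoch: np.ndarray,
    params: MseParams = MseParams(),
    fs: float = 1000.0,
    r_abs_per_channel: np.ndarray | None = None,
) -> np.ndarray:
    """Sample entropy per channel and scale for one epoch.

    The number of scales is ``min(max_scale, floor(N / min_coarse_samples))``
    so that every coarse-grained series keeps at least
    ``min_coarse_samples`` points.  The tolerance is ``r_frac`` times the
    per-channel population SD of the raw (scale-1) epoch unless absolute
    tolerances are supplied.  Returns a channels x scales array with NaN
    where the estimate is undefined.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n_ch, n = epoch.shape
    n_scales = min(params.max_scale, n // params.min_coarse_samples)
    if n_scales < 1:
        raise ValueError(
            f"epoch of {n} samples supports no scale with "
            f"min_coarse_samples={params.min_coarse_samples}"
        )
    if r_abs_per_channel is None:
        r_abs_per_channel = params.r_frac * epoch.std(axis=1)  # population SD
    r_abs_per_channel = np.asarray(r_abs_per_channel, dtype=np.float64)
    if np.any(r_abs_per_channel <= 0):
        raise ValueError("flat channel: tolerance would be zero")
    out = np.full((n_ch, n_scales), np.nan)
    for c in range(n_ch):
        r = float(r_abs_per_channel[c])
        for s in range(1, n_scales + 1):
            cg = coarse_grain(epoch[c], s) if s > 1 else epoch[c]
            a, b = _sampen_counts(np.ascontiguousarray(cg), params.m, r)
            if a > 0 and b > 0:
                out[c, s - 1] = -np.log(a / b)
    return out


def mse_average(per_epoch_grids: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean over epoch grids, ignoring NaN sentinels.

    Returns ``(mean grid, per-cell count of defined epochs)``.  Cells
    undefined in every epoch stay NaN.
    """
    if len(per_epoch_grids) == 0:
        raise ValueError("need at least one epoch grid")
    stack = np.stack([np.asarray(g, dtype=np.float64) for g in per_epoch_grids])
    if stack.ndim != 3:
        raise ValueError("epoch grids must share one channels x scales shape")
    n_valid = np.sum(~np.isnan(stack), axis=0)
    n_undefined = int(np.isnan(stack).sum())
    if n_undefined:
        logger.warning("%d undefined entropy cells excluded from averaging", n_undefined)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return mean, n_valid


def mse_grid(
    rec,
    params: MseParams = MseParams(),
    sd_scope: str = "epoch",
) -> MseGrid:
    """Trial-averaged MSE grid for an :class:`EpochedRecording`.

    ``sd_scope`` selects how the tolerance SD is computed: ``"epoch"``
    (default; per channel per epoch) or ``"recording"`` (per channel
    over the concatenated epochs).
    """
    if rec.n_epochs < 1:
        raise ValueError("recording has no epochs")
    if sd_scope not in ("epoch", "recording"):
        raise ValueError("sd_scope must be 'epoch' or 'recording'")
    fixed_r = None
    if sd_scope == "recording":
        pooled = rec.data.transpose(1, 0, 2).reshape(rec.n_channels, -1)
        fixed_r = params.r_frac * pooled.std(axis=1)
    grids = [
        mse_curve(rec.data[e], params, rec.fs, r_abs_per_channel=fixed_r)
        for e in range(rec.n_epochs)
    ]
    mean, n_valid = mse_average(grids)
    scales = np.arange(1, mean.shape[1] + 1)
    return MseGrid(
        values=mean,
        scales=scales,
        channel_labels=list(rec.channel_labels),
        n_epochs_averaged=rec.n_epochs,
        n_valid=n_valid,
        params=params,
    )


def save_mse_grid(grid: MseGrid, path: str) -> None:
    """TSV (rows=channels, columns=scales) plus a JSON sidecar of params."""
    df = pd.DataFrame(
        grid.values, index=grid.channel_labels, columns=[str(s) for s in grid.scales]
    )
    df.to_csv(path, sep="\t", index_label="channel")
    sidecar = {
        "n_epochs_averaged": grid.n_epochs_averaged,
        "params": {
            "m": grid.params.m,
            "r_frac": grid.params.r_frac,
            "max_scale": grid.params.max_scale,
            "min_coarse_samples": grid.params.min_coarse_samples,
        },
        "n_valid": None if grid.n_valid is None else grid.n_valid.tolist(),
    }
    with open(str(path) + ".json", "w") as f:
        json.dump(sidecar, f, indent=1)


def load_mse_grid(path: str) -> MseGrid:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    with open(str(path) + ".json") as f:
        sidecar = json.load(f)
    p = sidecar["params"]
    return MseGrid(
        values=df.to_numpy(),
        scales=np.array([int(c) for c in df.columns]),
        channel_labels=[str(i) for i in df.index],
        n_epochs_averaged=sidecar["n_epochs_averaged"],
        n_valid=None if sidecar["n_valid"] is None else np.array(sidecar["n_valid"]),
        params=MseParams(p["m"], p["r_frac"], p["max_scale"], p["min_coarse_samples"]),
    )
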