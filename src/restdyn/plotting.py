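"""Basic heatmaps for salience and bootstrap-ratio maps."""

from __future__ import annotations

import numpy as np

from .taskpls import LatentVariable, PLSResult


def plot_bootstrap_ratio_map(
    result: PLSResult,
    lv: LatentVariable,
    threshold: float | None = 2.0,
    ax=None,
    cmap: str = "RdBu_r",
):
    """Channel x feature heatmap of an LV's bootstrap ratios.

    Values with |ratio| below ``threshold`` are masked, mirroring the
    usual convention that |ratio| >= 2 marks stable contributions.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if lv.bootstrap_ratios is None:
        raise ValueError("LV has no bootstrap ratios")
    br = result.unflatten(lv.bootstrap_ratios)
    if threshold is not None:
        br = np.where(np.abs(br) >= threshold, br, np.nan)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    vmax = np.nanmax(np.abs(br)) if np.isfinite(br).any() else 1.0
    im = ax.imshow(br, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(result.channel_labels)))
    ax.set_yticklabels(result.channel_labels, fontsize=6)
    step = max(1, len(result.feature_labels) // 10)
    ax.set_xticks(range(0, len(result.feature_labels), step))
    ax.set_xticklabels(result.feature_labels[::step], fontsize=6, rotation=45)
    ax.figure.colorbar(im, ax=ax, label="bootstrap ratio")
    return ax
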