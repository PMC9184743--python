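"""Simulation studies: null calibration and parameter recovery.

These functions each run one complete replicate study — synthetic EEG
generation, entropy/spectral feature extraction and task-PLS inference —
and report whether the known generative structure was recovered.  They
are the package's main validation surface: repeated over seeds they
estimate the empirical type-I error of the permutation test on null
studies and the power/direction-accuracy on studies with injected aging
or training effects.

Problem sizes default to reduced-scale studies (fewer subjects, epochs
and channels than a full experiment) chosen so a few dozen replicates
run in minutes while the effects stay comfortably recoverable; the
injected effect profiles themselves are the package defaults from
:mod:`restdyn.synthgen`.
"""

from __future__ import annotations

import numpy as np

from .mse import MseParams
from .pipeline import analyze_study
from .synthgen import default_aging_spec, default_training_spec, generate_study, null_spec
from .taskpls import StudyDesign

__all__ = ["null_replicate", "aging_replicate", "training_replicate"]


def _design_for(spec) -> StudyDesign:
    subjects = {
        g: tuple(f"{g}_s{i:02d}" for i in range(spec.n_subjects_per_group))
        for g in spec.groups
    }
    return StudyDesign(spec.groups, spec.conditions, subjects)


def null_replicate(seed: int, n_perm: int = 99) -> float:
    """LV1 permutation p for one null study (identical profiles in all cells).

    Uses a small 2x2x10 study of short low-rate epochs with a coarse
    entropy grid (5 timescales) so hundreds of replicates are cheap;
    under the null the returned p should be uniform on (0, 1].
    """
    spec = null_spec(n_subjects_per_group=10, n_epochs=4, n_channels=4,
                     epoch_ms=1000.0, fs=250.0, seed=seed)
    recs = generate_study(spec)
    res, _ = analyze_study(
        recs, _design_for(spec), kind="mse",
        mse_params=MseParams(max_scale=5, min_coarse_samples=50),
        reject_uV=None, n_perm=n_perm, n_boot=0, seed=seed,
    )
    return float(res.lvs[0].perm_p)


def aging_replicate(
    seed: int,
    n_subjects: int = 8,
    n_epochs: int = 2,
    n_channels: int = 4,
    n_perm: int = 99,
) -> dict:
    """Recovery of the cross-sectional aging contrast in one replicate.

    Generates a young-vs-old study from the default profiles and checks,
    on the entropy side, that LV1 is significant with the group contrast
    aligned to higher fine-scale (1-10) and lower coarse-scale (41-50)
    entropy in the old group, and on the spectral side that the old
    group shows a larger beta (15-30 Hz) and smaller 1-7 Hz share.
    """
    channels = tuple(f"ch{i}" for i in range(n_channels))
    spec = default_aging_spec(
        n_subjects_per_group=n_subjects, n_epochs=n_epochs, channels=channels, seed=seed
    )
    recs = generate_study(spec)
    design = _design_for(spec)

    res, grids = analyze_study(
        recs, design, kind="mse", reject_uV=None, n_perm=n_perm, n_boot=0, seed=seed
    )
    lv = res.lvs[0]
    sal = res.unflatten(lv.feature_saliences)
    # design cells are [young, old]; sign of the contrast is arbitrary
    contrast = lv.design_saliences[1] - lv.design_saliences[0]
    fine = float(sal[:, :10].mean())
    coarse = float(sal[:, 40:].mean())
    mse_ok = (
        lv.perm_p < 0.05 and contrast * fine > 0 and contrast * coarse < 0
    )

    # spectral direction check on the same recordings (group means)
    from .spd import band_power, spd_grid

    beta, low = {}, {}
    for g in spec.groups:
        shares_beta, shares_low = [], []
        for s in design.subjects[g]:
            grid = spd_grid(recs[(g, "pre", s)])
            shares_beta.append(band_power(grid.values, grid.freqs_Hz, (15.0, 30.0)).mean())
            shares_low.append(band_power(grid.values, grid.freqs_Hz, (1.0, 7.0)).mean())
        beta[g], low[g] = np.mean(shares_beta), np.mean(shares_low)
    spd_ok = beta["old"] > beta["young"] and low["old"] < low["young"]

    return {
        "perm_p": float(lv.perm_p),
        "mse_recovered": bool(mse_ok),
        "spd_direction_ok": bool(spd_ok),
        "fine_salience_signed": contrast * fine,
        "coarse_salience_signed": contrast * coarse,
        "beta_old_minus_young": float(beta["old"] - beta["young"]),
        "low_old_minus_young": float(low["old"] - low["young"]),
    }


def training_replicate(
    seed: int,
    kind: str = "mse",
    n_subjects: int = 6,
    n_epochs: int = 2,
    n_channels: int = 4,
    n_perm: int = 99,
    n_boot: int = 50,
) -> dict:
    """Recovery of the pre/post training effect injected in one group only.

    The four-group (young/old x control/training) two-condition study
    raises coarse-timescale entropy and 3-14 Hz power post-training in
    the old-training group.  For ``kind="mse"`` the check is: LV1
    significant, coarse-scale (21-50) saliences aligned with the
    old-training post-minus-pre design contrast, and the signed
    bootstrap ratios at coarse scales positive.  For ``kind="spd"``:
    LV1 significant with the 3-14 Hz saliences aligned likewise.
    """
    channels = tuple(f"ch{i}" for i in range(n_channels))
    spec = default_training_spec(
        n_subjects_per_group=n_subjects, n_epochs=n_epochs, channels=channels, seed=seed
    )
    recs = generate_study(spec)
    design = _design_for(spec)
    res, _ = analyze_study(
        recs, design, kind=kind, reject_uV=None, n_perm=n_perm,
        n_boot=n_boot if kind == "mse" else 0, seed=seed,
    )
    lv = res.lvs[0]
    cells = res.design.cells
    eff = (
        lv.design_saliences[cells.index(("old_training", "post"))]
        - lv.design_saliences[cells.index(("old_training", "pre"))]
    )
    sal = res.unflatten(lv.feature_saliences)
    out = {"perm_p": float(lv.perm_p)}
    if kind == "mse":
        coarse = float(sal[:, 20:].mean())
        br_coarse = float("nan")
        if lv.bootstrap_ratios is not None:
            br = res.unflatten(lv.bootstrap_ratios)
            br_coarse = float(np.sign(eff) * br[:, 20:].mean())
        out["recovered"] = bool(lv.perm_p < 0.05 and eff * coarse > 0)
        out["coarse_salience_signed"] = eff * coarse
        out["coarse_bootstrap_ratio_signed"] = br_coarse
    else:
        freqs = np.array([float(f) for f in res.feature_labels])
        mid = float(sal[:, (freqs >= 3.0) & (freqs <= 14.0)].mean())
        out["recovered"] = bool(lv.perm_p < 0.05 and eff * mid > 0)
        out["mid_band_salience_signed"] = eff * mid
    return out
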