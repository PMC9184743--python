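"""End-to-end orchestration: ingest -> preprocess -> MSE/SPD -> task PLS -> reports.

A run is described by a :class:`RunConfig`: a manifest mapping
(group, condition, subject) to an epoched-container file, the analysis
kind (``mse``, ``spd`` or ``erp-grid``), preprocessing parameters
(2500 ms epochs, 100 µV rejection, channel subset), entropy/band
settings, and PLS resampling sizes (500 permutations, 500 bootstraps,
bootstrap-ratio threshold 2.0 by default).  One top-level seed drives
every stochastic stage through derived streams.

This module also carries the small summary-statistics helpers used for
participant tables: a one-sample t from (mean, SD, n) and the additive
(main-effects-only) two-way ANOVA F reconstructed from per-cell
sufficient statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess as pp
from .mse import MseParams, mse_grid, save_mse_grid
from .spd import DEFAULT_BANDS, BandSet, save_spd_grid, spd_grid
from .taskpls import FeatureGrid, PLSResult, StudyDesign, task_pls

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "GroupSummary",
    "run",
    "analyze_study",
    "erp_grid",
    "one_sample_t_from_summary",
    "additive_two_way_F_from_cells",
]

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Everything needed for one reproducible analysis run."""

    manifest: dict[tuple[str, str, str], str]  # (group, condition, subject) -> path
    groups: tuple[str, ...]
    conditions: tuple[str, ...]
    kind: str = "mse"  # mse | spd | erp-grid
    out_dir: str = "restdyn_out"
    epoch_ms: float = 2500.0
    reject_uV: float = 100.0
    channel_subset: tuple[str, ...] | None = tuple(pp.TASK_CHANNELS_20)
    mse_params: MseParams = field(default_factory=MseParams)
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)
    n_perm: int = 500
    n_boot: int = 500
    br_threshold: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("mse", "spd", "erp-grid"):
            raise ValueError(f"unknown analysis kind {self.kind!r}")
        missing = [str(p) for p in self.manifest.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest paths not found: {missing[:5]}")
        subjects_by_group: dict[str, set] = {}
        for (g, c, s) in self.manifest:
            subjects_by_group.setdefault(g, set()).add(s)
        for g in self.groups:
            for c in self.conditions:
                for s in subjects_by_group.get(g, ()):
                    if (g, c, s) not in self.manifest:
                        raise ValueError(f"manifest missing cell {(g, c, s)}")

    def design(self) -> StudyDesign:
        subjects: dict[str, list] = {g: [] for g in self.groups}
        for (g, c, s) in self.manifest:
            if c == self.conditions[0] and s not in subjects[g]:
                subjects[g].append(s)
        return StudyDesign(
            groups=tuple(self.groups),
            conditions=tuple(self.conditions),
            subjects={g: tuple(sorted(v)) for g, v in subjects.items()},
        )


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one scalar measure in one cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _subject_features(rec: pp.EpochedRecording, config: RunConfig):
    """Preprocess one recording and reduce it to a FeatureGrid."""
    rec, report = pp.reject_epochs(rec, config.reject_uV)
    if config.channel_subset is not None:
        rec = pp.select_channels(rec, list(config.channel_subset))
    if config.kind == "mse":
        grid = mse_grid(rec, config.mse_params)
        return FeatureGrid.from_mse(grid), grid, report
    elif config.kind == "spd":
        grid = spd_grid(rec)
        return FeatureGrid.from_spd(grid), grid, report
    raise ValueError(config.kind)


def analyze_study(
    recordings: dict[tuple[str, str, str], pp.EpochedRecording],
    design: StudyDesign,
    kind: str = "mse",
    mse_params: MseParams = MseParams(),
    reject_uV: float | None = 100.0,
    channel_subset: list[str] | None = None,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[PLSResult, dict[tuple[str, str, str], FeatureGrid]]:
    """Programmatic end-to-end path from in-memory recordings to PLS.

    Used by the command-line ``run`` as well as by simulation studies
    that never touch disk.  Returns the PLS result and the per-subject
    feature grids.
    """
    grids: dict[tuple[str, str, str], FeatureGrid] = {}
    for key, rec in recordings.items():
        if reject_uV is not None:
            rec, _ = pp.reject_epochs(rec, reject_uV)
        if channel_subset is not None:
            rec = pp.select_channels(rec, channel_subset)
        if kind == "mse":
            grids[key] = FeatureGrid.from_mse(mse_grid(rec, mse_params))
        elif kind == "spd":
            grids[key] = FeatureGrid.from_spd(spd_grid(rec))
        else:
            raise ValueError(f"unknown analysis kind {kind!r}")
    result = task_pls(grids, design, n_perm=n_perm, n_boot=n_boot, seed=seed)
    return result, grids


def run(config: RunConfig) -> PLSResult:
    """Execute a configured run and write the report bundle.

    Bundle contents: per-subject grid TSVs, per-LV design-salience and
    bootstrap-ratio tables, a JSON summary (singular values, covariance
    fractions, permutation p) and a provenance log echoing the config,
    seed and software version.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    grids: dict[tuple[str, str, str], FeatureGrid] = {}
    rejection_rows = []
    for key, path in sorted(config.manifest.items()):
        g, c, s = key
        try:
            rec = pp.load_epochs(path)
            fg, grid, report = _subject_features(rec, config)
        except Exception as err:
            raise RuntimeError(f"stage failure for cell {key}: {err}") from err
        grids[key] = fg
        rejection_rows.append(
            {"group": g, "condition": c, "subject": s,
             "n_input": report.n_input, "n_rejected": report.n_rejected}
        )
        gpath = out / f"grid_{g}_{c}_{s}.tsv"
        if config.kind == "mse":
            save_mse_grid(grid, str(gpath))
        else:
            save_spd_grid(grid, str(gpath), config.bands)
    pd.DataFrame(rejection_rows).to_csv(out / "rejection_summary.tsv", sep="\t", index=False)

    result = task_pls(
        grids, design, n_perm=config.n_perm, n_boot=config.n_boot, seed=config.seed
    )
    _write_reports(result, config, out)
    return result


def _write_reports(result: PLSResult, config: RunConfig, out: Path) -> None:
    summary = []
    for k, lv in enumerate(result.lvs):
        summary.append(
            {
                "lv": k + 1,
                "singular_value": lv.singular_value,
                "covariance_fraction": lv.covariance_fraction,
                "perm_p": lv.perm_p,
            }
        )
        cells = [f"{g}|{c}" for g, c in result.design.cells]
        pd.DataFrame(
            {"cell": cells, "design_salience": lv.design_saliences}
        ).to_csv(out / f"lv{k + 1}_design_saliences.tsv", sep="\t", index=False)
        if result.channel_labels and result.feature_labels:
            sal = result.unflatten(lv.feature_saliences)
            pd.DataFrame(
                sal, index=result.channel_labels, columns=result.feature_labels
            ).to_csv(out / f"lv{k + 1}_feature_saliences.tsv", sep="\t", index_label="channel")
            if lv.bootstrap_ratios is not None:
                br = result.unflatten(lv.bootstrap_ratios)
                pd.DataFrame(
                    br, index=result.channel_labels, columns=result.feature_labels
                ).to_csv(out / f"lv{k + 1}_bootstrap_ratios.tsv", sep="\t", index_label="channel")
    with open(out / "lv_summary.json", "w") as f:
        json.dump(summary, f, indent=1)
    provenance = {
        "software": f"restdyn {__version__}",
        "seed": config.seed,
        "kind": config.kind,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "br_threshold": config.br_threshold,
        "reject_uV": config.reject_uV,
        "epoch_ms": config.epoch_ms,
        "channel_subset": list(config.channel_subset) if config.channel_subset else None,
        "n_subjects": {g: len(result.design.subjects[g]) for g in result.design.groups},
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=1)


def erp_grid(
    rec: pp.EpochedRecording, baseline_ms: tuple[float, float] = (-100.0, 0.0),
    t0_ms: float = 100.0,
) -> FeatureGrid:
    """Plumbing for ERP-style analyses: baseline-corrected epoch average.

    ``t0_ms`` is the stimulus position measured from epoch onset; the
    baseline interval is given relative to the stimulus.  Returns a
    channel x timepoint grid suitable for the generic PLS engine.
    """
    t0 = int(round(t0_ms * rec.fs / 1000.0))
    b0 = t0 + int(round(baseline_ms[0] * rec.fs / 1000.0))
    b1 = t0 + int(round(baseline_ms[1] * rec.fs / 1000.0))
    if not (0 <= b0 < b1 <= rec.n_samples):
        raise ValueError("baseline interval outside the epoch")
    baseline = rec.data[:, :, b0:b1].mean(axis=2, keepdims=True)
    avg = (rec.data - baseline).mean(axis=0)
    times = (np.arange(rec.n_samples) - t0) / rec.fs * 1000.0
    return FeatureGrid(avg, list(rec.channel_labels), [f"{t:.0f}ms" for t in times])


# ---------------------------------------------------------------------------
# participant-table helpers
# ---------------------------------------------------------------------------

class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class FTestResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu0: float
) -> TTestResult:
    """One-sample t-test against mu0 from summary statistics alone.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, two-sided p.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))


def additive_two_way_F_from_cells(
    summaries: dict[tuple[str, str], GroupSummary],
    factor: str = "A",
) -> FTestResult:
    """Main-effects-only two-way ANOVA F from per-cell sufficient statistics.

    Reconstructs a data realization matching each cell's (mean, SD, n)
    exactly — any such realization gives the same F because the additive
    least-squares fit depends only on these sufficient statistics — and
    fits y ~ A + B without interaction.  ``factor`` selects which main
    effect's F to report ("A" = first key element, "B" = second).
    SDs are interpreted as sample SDs (ddof=1).
    """
    if factor not in ("A", "B"):
        raise ValueError("factor must be 'A' or 'B'")
    a_levels = sorted({k[0] for k in summaries})
    b_levels = sorted({k[1] for k in summaries})
    for a in a_levels:
        for b in b_levels:
            if (a, b) not in summaries:
                raise ValueError(f"missing cell {(a, b)}")
    ys, fa, fb = [], [], []
    for (a, b), s in summaries.items():
        z = np.linspace(-1.0, 1.0, s.n)
        z = z - z.mean()
        denom = z.std(ddof=1)
        z = z / denom if denom > 0 else z
        ys.append(s.mean + s.sd * z)
        fa.extend([a] * s.n)
        fb.extend([b] * s.n)
    df = pd.DataFrame({"y": np.concatenate(ys), "A": fa, "B": fb})

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("y ~ C(A) + C(B)", data=df).fit()
    table = anova_lm(model, typ=2)
    row = table.loc["C(A)"] if factor == "A" else table.loc["C(B)"]
    df1 = int(row["df"])
    df2 = int(model.df_resid)
    return FTestResult(float(row["F"]), df1, df2, float(row["PR(>F)"]))
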