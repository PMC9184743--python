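"""Mean-centered task partial least squares with permutation and bootstrap inference.

Task PLS relates a subjects-by-features data matrix to a group-by-
condition experimental design in one decomposition.  The cell means of
the data (one row per group x condition cell) are deviated from the
unweighted grand mean of cell means and the resulting matrix M is
factored by singular value decomposition,

    M = U S V^T,

giving latent variables (LVs): each LV pairs a *design salience* vector
(a contrast over cells, a column of U), a *feature salience* vector (a
pattern over channel x feature elements, a column of V) and a singular
value (the covariance strength the LV captures).  LVs come out in
decreasing order of covariance explained.

Inference is nonparametric and respects the repeated-measures design:

* **Permutation test** - subjects are reassigned across groups without
  replacement (a subject's condition rows travel together) and condition
  labels are shuffled within subject; the singular values of each
  permuted decomposition are compared to the observed ones LV-by-LV by
  rank.  p = (1 + #{s_perm >= s_obs}) / (1 + n_perm), never exactly 0.
* **Bootstrap ratios** - subjects are resampled with replacement within
  each group; each bootstrap decomposition is Procrustes-aligned to the
  original LVs (without alignment, sign flips between resamples inflate
  the standard errors to meaninglessness); the bootstrap ratio of a
  feature is its original (singular-value-scaled) salience divided by
  the bootstrap standard error.  |ratio| >= 2 is conventionally read as
  roughly p < 0.05 stability.

The engine is agnostic to what the feature axis means: channel x
timescale entropy grids, channel x frequency-bin power grids and
channel x timepoint ERP grids all go through identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "FeatureGrid",
    "LatentVariable",
    "PLSResult",
    "build_matrix",
    "mean_center",
    "extract_lvs",
    "permutation_test",
    "bootstrap_saliences",
    "project_brain_scores",
    "task_pls",
]


@dataclass(frozen=True)
class StudyDesign:
    """Groups, conditions and per-group subject ids defining the row order.

    Rows are subjects nested within conditions nested within groups:
    for each group, for each condition, the group's subjects in order.
    Every subject appears in every condition of its group (repeated
    measures).
    """

    groups: tuple[str, ...]
    conditions: tuple[str, ...]
    subjects: dict[str, tuple[str, ...]]  # group -> ordered subject ids

    def __post_init__(self) -> None:
        if not self.groups or not self.conditions:
            raise ValueError("need at least one group and one condition")
        for g in self.groups:
            if g not in self.subjects or len(self.subjects[g]) == 0:
                raise ValueError(f"group {g!r} has no subjects")
            if len(set(self.subjects[g])) != len(self.subjects[g]):
                raise ValueError(f"duplicate subject ids in group {g!r}")

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(g, c) for g in self.groups for c in self.conditions]

    @property
    def n_rows(self) -> int:
        return sum(len(self.subjects[g]) for g in self.groups) * len(self.conditions)

    def row_index(self, group: str, condition: str, subject: str) -> int:
        """Row of (group, condition, subject) in the stacked data matrix."""
        row = 0
        for g in self.groups:
            n_g = len(self.subjects[g])
            if g == group:
                c_idx = self.conditions.index(condition)
                s_idx = self.subjects[g].index(subject)
                return row + c_idx * n_g + s_idx
            row += n_g * len(self.conditions)
        raise KeyError(group)

    def cell_rows(self, group: str, condition: str) -> np.ndarray:
        """Row indices of one group x condition cell, in subject order."""
        return np.array(
            [self.row_index(group, condition, s) for s in self.subjects[group]]
        )


@dataclass
class FeatureGrid:
    """A channel x feature matrix for one subject/condition, flattenable.

    The feature axis may be timescales, frequency bins or timepoints;
    labels are retained so salience maps can be un-flattened.
    """

    values: np.ndarray
    channel_labels: list[str]
    feature_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.channel_labels), len(self.feature_labels)):
            raise ValueError("values must be channels x features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature grid contains non-finite entries")

    @classmethod
    def from_mse(cls, grid) -> "FeatureGrid":
        return cls(grid.values, list(grid.channel_labels), [str(s) for s in grid.scales])

    @classmethod
    def from_spd(cls, grid) -> "FeatureGrid":
        return cls(
            grid.values, list(grid.channel_labels), [f"{f:.4g}" for f in grid.freqs_Hz]
        )

    def flatten(self) -> np.ndarray:
        """Row-major (channel-major) flattening to one feature vector."""
        return self.values.reshape(-1)


@dataclass
class LatentVariable:
    """One latent variable with its inference fields."""

    singular_value: float
    design_saliences: np.ndarray  # one weight per group x condition cell
    feature_saliences: np.ndarray  # unit-norm, one weight per flattened feature
    perm_p: float | None = None
    bootstrap_ratios: np.ndarray | None = None
    threshold: float = 2.0
    covariance_fraction: float | None = None  # s_k^2 / sum s^2


@dataclass
class PLSResult:
    """Full decomposition plus the layout needed to un-flatten maps."""

    lvs: list[LatentVariable]
    design: StudyDesign
    channel_labels: list[str]
    feature_labels: list[str]
    X: np.ndarray = field(repr=False, default=None)

    def unflatten(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec).reshape(len(self.channel_labels), len(self.feature_labels))


def build_matrix(
    grids: dict[tuple[str, str, str], FeatureGrid | np.ndarray],
    design: StudyDesign,
) -> np.ndarray:
    """Stack per-subject grids into the rows x features data matrix.

    ``grids`` maps (group, condition, subject) to a FeatureGrid (or an
    already-flat vector).  Row order is fixed by the design, not by the
    dict's insertion order.  A missing cell raises an error naming it.
    """
    rows = []
    for g in design.groups:
        for c in design.conditions:
            for s in design.subjects[g]:
                key = (g, c, s)
                if key not in grids:
                    raise KeyError(f"missing feature grid for cell {key}")
                v = grids[key]
                rows.append(v.flatten() if isinstance(v, FeatureGrid) else np.ravel(v))
    X = np.asarray(rows, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    return X


def mean_center(X: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Cell-means deviation matrix M (cells x features).

    Row for cell (g, c) = mean over that cell's subjects minus the
    unweighted grand mean of all cell means, so M's rows sum to zero
    even when group sizes differ.
    """
    X = np.asarray(X, dtype=np.float64)
    cell_means = np.stack([X[design.cell_rows(g, c)].mean(axis=0) for g, c in design.cells])
    return cell_means - cell_means.mean(axis=0, keepdims=True)


def extract_lvs(M: np.ndarray) -> list[LatentVariable]:
    """SVD of the mean-centered cell matrix, with a fixed sign convention.

    LVs are ordered by decreasing singular value; numerically null
    components (s < max-dim * eps * s_max) are dropped.  Each feature-
    salience vector is flipped so its largest-magnitude element is
    positive, with the paired design saliences flipped jointly, removing
    the SVD sign ambiguity.
    """
    M = np.asarray(M, dtype=np.float64)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    lvs = []
    for k in range(s.size):
        if s[k] <= tol:
            break
        v = Vt[k].copy()
        u = U[:, k].copy()
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v, u = -v, -u
        lvs.append(
            LatentVariable(
                singular_value=float(s[k]),
                design_saliences=u,
                feature_saliences=v,
                covariance_fraction=float(s[k] ** 2 / total) if total > 0 else 0.0,
            )
        )
    return lvs


def _subject_row_table(design: StudyDesign) -> np.ndarray:
    """(n_subjects_total, n_conditions) row indices; subjects pooled over groups."""
    table = []
    for g in design.groups:
        for s in design.subjects[g]:
            table.append([design.row_index(g, c, s) for c in design.conditions])
    return np.asarray(table)


def permutation_test(
    X: np.ndarray,
    design: StudyDesign,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
    rotate: str = "none",
) -> np.ndarray:
    """Permutation p-value per LV by whole-subject label reassignment.

    Each permutation moves whole subjects (all their condition rows)
    across group slots without replacement and independently shuffles
    the condition labels within each subject, then recomputes the
    mean-centered SVD.  With ``rotate="none"`` (default) permuted
    singular values are compared to the observed ones LV-by-LV by rank;
    ``rotate="procrustes"`` instead projects each permuted M onto the
    original feature saliences before reading off singular values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 19:
        logger.warning("n_perm=%d cannot resolve alpha=0.05", n_perm)
    if rotate not in ("none", "procrustes"):
        raise ValueError("rotate must be 'none' or 'procrustes'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    obs_lvs = extract_lvs(mean_center(X, design))
    obs_s = np.array([lv.singular_value for lv in obs_lvs])
    if rotate == "procrustes":
        V = np.stack([lv.feature_saliences for lv in obs_lvs], axis=1)
    table = _subject_row_table(design)
    n_subj, n_cond = table.shape
    exceed = np.zeros(obs_s.size)
    for _ in range(n_perm):
        order = rng.permutation(n_subj)
        Xp = np.empty_like(X)
        for slot in range(n_subj):
            src = table[order[slot]]
            if n_cond > 1:
                src = src[rng.permutation(n_cond)]
            Xp[table[slot]] = X[src]
        Mp = mean_center(Xp, design)
        if rotate == "procrustes":
            s_perm = np.linalg.norm(Mp @ V, axis=0)
        else:
            s_perm = np.linalg.svd(Mp, compute_uv=False)[: obs_s.size]
            s_perm = np.pad(s_perm, (0, obs_s.size - s_perm.size))
        exceed += s_perm >= obs_s
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_saliences(
    X: np.ndarray,
    design: StudyDesign,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Bootstrap-ratio map per LV from within-group subject resampling.

    Each bootstrap draws subjects with replacement independently within
    each group (a drawn subject carries all its condition rows),
    recomputes the mean-centered SVD, Procrustes-aligns the bootstrap
    feature saliences (scaled by their singular values) to the original
    LVs, and accumulates per-element standard errors.  The returned
    ratio for LV k is ``original v_k * s_k / SE_k``; elements with zero
    bootstrap SE become NaN with a logged count.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    for g in design.groups:
        if len(design.subjects[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects for bootstrapping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    obs_lvs = extract_lvs(mean_center(X, design))
    K = len(obs_lvs)
    V = np.stack([lv.feature_saliences for lv in obs_lvs], axis=1)  # features x K
    s = np.array([lv.singular_value for lv in obs_lvs])
    orig_scaled = V * s  # features x K

    # per-group tables of (subject, condition) -> row
    group_tables = {}
    for g in design.groups:
        group_tables[g] = np.asarray(
            [[design.row_index(g, c, subj) for c in design.conditions]
             for subj in design.subjects[g]]
        )

    samples = np.empty((n_boot,) + orig_scaled.shape)
    for b in range(n_boot):
        Xb = np.empty_like(X)
        for g in design.groups:
            table = group_tables[g]
            n_g = table.shape[0]
            draw = rng.integers(0, n_g, size=n_g)
            for slot in range(n_g):
                Xb[table[slot]] = X[table[draw[slot]]]
        Mb = mean_center(Xb, design)
        Ub, sb, Vbt = np.linalg.svd(Mb, full_matrices=False)
        Vb = Vbt[:K].T  # features x K
        sb = sb[:K]
        # orthogonal Procrustes: align bootstrap saliences to the originals
        A, _, Bt = np.linalg.svd(Vb.T @ V, full_matrices=False)
        R = A @ Bt
        samples[b] = (Vb * sb) @ R

    se = samples.std(axis=0, ddof=1)  # features x K
    ratios = []
    n_degenerate = 0
    for k in range(K):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(se[:, k] > 0, orig_scaled[:, k] / se[:, k], np.nan)
        n_degenerate += int(np.sum(se[:, k] == 0))
        ratios.append(r)
    if n_degenerate:
        logger.warning("%d salience elements had zero bootstrap SE", n_degenerate)
    return ratios


def project_brain_scores(X: np.ndarray, lv: LatentVariable) -> np.ndarray:
    """Per-row brain score: the projection of each row onto the LV's pattern."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != lv.feature_saliences.shape[0]:
        raise ValueError(
            f"X has {X.shape[-1]} features, LV has {lv.feature_saliences.shape[0]}"
        )
    return X @ lv.feature_saliences


def task_pls(
    grids: dict[tuple[str, str, str], FeatureGrid],
    design: StudyDesign,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
    rotate: str = "none",
) -> PLSResult:
    """Full mean-centered task-PLS analysis of per-subject feature grids.

    Builds the data matrix, extracts LVs and attaches permutation
    p-values and bootstrap-ratio maps.  ``seed`` drives both resampling
    schemes through independent streams.
    """
    X = build_matrix(grids, design)
    lvs = extract_lvs(mean_center(X, design))
    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    if n_perm > 0:
        p = permutation_test(X, design, n_perm=n_perm, seed=perm_rng, rotate=rotate)
        for k, lv in enumerate(lvs):
            lv.perm_p = float(p[k])
    if n_boot > 0:
        ratios = bootstrap_saliences(X, design, n_boot=n_boot, seed=boot_rng)
        for k, lv in enumerate(lvs):
            lv.bootstrap_ratios = ratios[k]
    some = next(iter(grids.values()))
    ch = some.channel_labels if isinstance(some, FeatureGrid) else []
    feat = some.feature_labels if isinstance(some, FeatureGrid) else []
    return PLSResult(lvs=lvs, design=design, channel_labels=ch, feature_labels=feat, X=X)
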