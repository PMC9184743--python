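import numpy as np
import pytest

from restdyn.taskpls import StudyDesign


def brute_force_sampen(x, m, r):
    """Independent sample-entropy oracle: exhaustive vectorized pair counting.

    Counts matching template pairs (Chebyshev distance <= r, i < j) over
    the first N-m templates at lengths m and m+1 and returns
    (A, B, -ln(A/B)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(length):
        T = np.lib.stride_tricks.sliding_window_view(x, length)[: n - m]
        D = np.abs(T[:, None, :] - T[None, :, :]).max(axis=-1)
        iu = np.triu_indices(T.shape[0], 1)
        return int((D[iu] <= r).sum())

    B = count(m)
    A = count(m + 1)
    value = -np.log(A / B) if (A > 0 and B > 0) else np.nan
    return A, B, value


def design_for(spec):
    """StudyDesign matching the subject ids generate_study produces."""
    subjects = {
        g: tuple(f"{g}_s{i:02d}" for i in range(spec.n_subjects_per_group))
        for g in spec.groups
    }
    return StudyDesign(spec.groups, spec.conditions, subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_design():
    return StudyDesign(
        groups=("g1", "g2"),
        conditions=("pre", "post"),
        subjects={"g1": ("a", "b", "c"), "g2": ("d", "e", "f")},
    )
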