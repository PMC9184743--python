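import numpy as np
import pytest
import scipy.linalg

from restdyn.taskpls import (
    FeatureGrid,
    StudyDesign,
    bootstrap_saliences,
    build_matrix,
    extract_lvs,
    mean_center,
    permutation_test,
    project_brain_scores,
    task_pls,
)


def _grids_for(design, rng, n_features=4, offsets=None):
    """Random FeatureGrids (1 channel x n_features) per design cell."""
    grids = {}
    for g in design.groups:
        for c in design.conditions:
            for s in design.subjects[g]:
                v = rng.standard_normal(n_features)
                if offsets is not None:
                    v = v + offsets.get((g, c), 0.0)
                grids[(g, c, s)] = FeatureGrid(
                    v[None, :], ["ch0"], [f"f{i}" for i in range(n_features)]
                )
    return grids


class TestBuildMatrix:
    def test_shape_and_row_order(self, small_design, rng):
        grids = _grids_for(small_design, rng)
        X = build_matrix(grids, small_design)
        assert X.shape == (12, 4)
        i = small_design.row_index("g2", "post", "e")
        np.testing.assert_array_equal(X[i], grids[("g2", "post", "e")].flatten())

    def test_insertion_order_irrelevant(self, small_design, rng):
        grids = _grids_for(small_design, rng)
        shuffled = dict(reversed(list(grids.items())))
        np.testing.assert_array_equal(
            build_matrix(grids, small_design), build_matrix(shuffled, small_design)
        )

    def test_missing_cell_named_in_error(self, small_design, rng):
        grids = _grids_for(small_design, rng)
        del grids[("g1", "post", "b")]
        with pytest.raises(KeyError, match=r"g1.*post.*b"):
            build_matrix(grids, small_design)


class TestMeanCenter:
    def test_identical_subjects_give_zero(self, small_design):
        X = np.ones((12, 4)) * 3.3
        np.testing.assert_allclose(mean_center(X, small_design), 0.0, atol=1e-12)

    def test_symmetric_cells(self):
        design = StudyDesign(("g1", "g2"), ("c",), {"g1": ("a",), "g2": ("b",)})
        X = np.array([[1.0, 2.0], [-1.0, -2.0]])
        M = mean_center(X, design)
        np.testing.assert_allclose(M, [[1, 2], [-1, -2]])

    def test_rows_sum_to_zero_even_unbalanced(self, rng):
        design = StudyDesign(
            ("g1", "g2"), ("pre", "post"),
            {"g1": ("a", "b", "c", "d", "e"), "g2": ("x", "y")},
        )
        X = rng.standard_normal((design.n_rows, 6))
        M = mean_center(X, design)
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-12)


class TestExtractLvs:
    def test_rank_one_recovery(self):
        u = np.array([0.6, -0.8])
        v = np.array([0.0, 1.0, 0.0, 0.0])
        M = 5.0 * np.outer(u, v)
        lvs = extract_lvs(M)
        assert len(lvs) == 1
        assert lvs[0].singular_value == pytest.approx(5.0)
        np.testing.assert_allclose(np.abs(lvs[0].feature_saliences), v, atol=1e-12)
        # sign convention: largest-magnitude feature salience positive
        assert lvs[0].feature_saliences[1] > 0

    def test_energy_conservation(self, rng):
        M = rng.standard_normal((4, 50))
        M -= M.mean(axis=0)
        lvs = extract_lvs(M)
        total = sum(lv.singular_value**2 for lv in lvs)
        assert total == pytest.approx(np.linalg.norm(M) ** 2, rel=1e-10)

    def test_matches_independent_svd_oracle(self, rng):
        M = rng.standard_normal((4, 50))
        lvs = extract_lvs(M)
        s_oracle = scipy.linalg.svdvals(M)
        for k, lv in enumerate(lvs):
            assert lv.singular_value == pytest.approx(s_oracle[k], abs=1e-10)
            # salience vector matches the oracle's singular vector up to sign
            _, _, Vt = scipy.linalg.svd(M, full_matrices=False)
            dot = abs(float(Vt[k] @ lv.feature_saliences))
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_unit_norm_saliences(self, rng):
        M = rng.standard_normal((6, 20))
        for lv in extract_lvs(M):
            assert np.linalg.norm(lv.feature_saliences) == pytest.approx(1.0)
            assert np.linalg.norm(lv.design_saliences) == pytest.approx(1.0)


class TestPermutationTest:
    def test_determinism(self, small_design, rng):
        X = rng.standard_normal((12, 5))
        p1 = permutation_test(X, small_design, n_perm=50, seed=7)
        p2 = permutation_test(X, small_design, n_perm=50, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_huge_effect_reaches_minimum_p(self, small_design, rng):
        offsets = {("g1", "pre"): 0.0, ("g1", "post"): 0.0,
                   ("g2", "pre"): 50.0, ("g2", "post"): 50.0}
        grids = _grids_for(small_design, rng, offsets=offsets)
        X = build_matrix(grids, small_design)
        p = permutation_test(X, small_design, n_perm=99, seed=1)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_label_invariance_of_singular_values(self, small_design, rng):
        X = rng.standard_normal((12, 5))
        lvs = extract_lvs(mean_center(X, small_design))
        relabeled = StudyDesign(
            ("g2", "g1"), small_design.conditions,
            {"g1": small_design.subjects["g1"], "g2": small_design.subjects["g2"]},
        )
        # rows must be re-stacked to the relabeled order
        grids = {}
        for g in small_design.groups:
            for c in small_design.conditions:
                for s in small_design.subjects[g]:
                    grids[(g, c, s)] = X[small_design.row_index(g, c, s)]
        X2 = build_matrix(grids, relabeled)
        lvs2 = extract_lvs(mean_center(X2, relabeled))
        s1 = [lv.singular_value for lv in lvs]
        s2 = [lv.singular_value for lv in lvs2]
        np.testing.assert_allclose(s1, s2, rtol=1e-10)

    def test_procrustes_mode_runs_and_is_valid_p(self, small_design, rng):
        X = rng.standard_normal((12, 5))
        p = permutation_test(X, small_design, n_perm=50, seed=3, rotate="procrustes")
        assert np.all((p > 0) & (p <= 1))


class TestBootstrap:
    def test_determinism(self, small_design, rng):
        X = rng.standard_normal((12, 5))
        r1 = bootstrap_saliences(X, small_design, n_boot=30, seed=5)
        r2 = bootstrap_saliences(X, small_design, n_boot=30, seed=5)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a, b)

    def test_strong_feature_has_large_ratio_null_feature_small(self):
        """Feature 0 carries a strong group effect; feature 3 pure noise."""
        design = StudyDesign(
            ("g1", "g2"), ("c",),
            {"g1": tuple("abcdefgh"), "g2": tuple("ijklmnop")},
        )
        hits_strong, hits_null = 0, 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            grids = {}
            for g in design.groups:
                for s in design.subjects[g]:
                    v = rng.standard_normal(4) * 0.5
                    if g == "g2":
                        v[0] += 5.0
                    grids[(g, "c", s)] = v
            X = build_matrix(grids, design)
            ratios = bootstrap_saliences(X, design, n_boot=100, seed=rep)[0]
            hits_strong += abs(ratios[0]) > 2
            hits_null += abs(ratios[3]) < 2
        assert hits_strong >= 0.8 * n_rep
        assert hits_null >= 0.8 * n_rep

    def test_too_few_subjects_raises(self):
        design = StudyDesign(("g1",), ("c",), {"g1": ("a",)})
        with pytest.raises(ValueError):
            bootstrap_saliences(np.ones((1, 3)), design, n_boot=10, seed=0)


class TestBrainScores:
    def test_scores_of_cell_means_reproduce_design_pattern(self, small_design, rng):
        X = rng.standard_normal((12, 6))
        M = mean_center(X, small_design)
        lvs = extract_lvs(M)
        for lv in lvs:
            scores = project_brain_scores(M, lv)
            np.testing.assert_allclose(
                scores, lv.design_saliences * lv.singular_value, atol=1e-10
            )

    def test_orthogonal_lv_score_vectors(self, small_design, rng):
        X = rng.standard_normal((12, 6))
        M = mean_center(X, small_design)
        lvs = extract_lvs(M)
        s01 = project_brain_scores(M, lvs[0]) @ project_brain_scores(M, lvs[1])
        assert s01 == pytest.approx(0.0, abs=1e-9)

    def test_dimension_mismatch_raises(self, small_design, rng):
        X = rng.standard_normal((12, 6))
        lv = extract_lvs(mean_center(X, small_design))[0]
        with pytest.raises(ValueError):
            project_brain_scores(np.ones((3, 5)), lv)


class TestGenericFeatureAxes:
    @pytest.mark.parametrize("shape,feature_kind", [
        ((4, 50), "timescale"), ((4, 99), "freq_bin"), ((4, 80), "timepoint"),
    ])
    def test_engine_is_agnostic_to_feature_axis(self, shape, feature_kind, rng):
        """Entropy, spectral and ERP grids go through structurally identically."""
        design = StudyDesign(
            ("g1", "g2"), ("pre", "post"),
            {"g1": ("a", "b", "c"), "g2": ("d", "e", "f")},
        )
        grids = {
            (g, c, s): FeatureGrid(
                rng.standard_normal(shape),
                [f"ch{i}" for i in range(shape[0])],
                [f"{feature_kind}{j}" for j in range(shape[1])],
            )
            for g in design.groups
            for c in design.conditions
            for s in design.subjects[g]
        }
        res = task_pls(grids, design, n_perm=20, n_boot=10, seed=0)
        assert len(res.lvs) == 3  # 4 cells, grand mean removed
        lv = res.lvs[0]
        assert lv.design_saliences.shape == (4,)
        assert lv.feature_saliences.shape == (shape[0] * shape[1],)
        assert res.unflatten(lv.bootstrap_ratios).shape == shape
        assert 0 < lv.perm_p <= 1
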