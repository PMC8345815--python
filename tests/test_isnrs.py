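"""Intersubject neural representational similarity: item averaging,
PC-constrained geometry, pairwise comparison, averaging, and group splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tonelearn.isnrs import (
    hand_rdm,
    isnrs_matrix,
    isnrs_pair,
    item_patterns,
    median_split_compare,
    pc_constrain,
)
from tonelearn.rdm import partial_spearman_rdm, pattern_rdm, spearman_rdm
from tonelearn.simulate import CohortConfig, simulate_patterns

from .conftest import random_rdm


class TestItemPatterns:
    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(0)
        trial_items = np.repeat(["a", "b"], 12)
        maps = rng.normal(size=(24, 7))
        out = item_patterns(maps, trial_items, ["a", "b"])
        np.testing.assert_allclose(out[0], maps[:12].mean(axis=0))
        np.testing.assert_allclose(out[1], maps[12:].mean(axis=0))

    def test_single_trial_passthrough(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(3, 5))
        out = item_patterns(maps, ["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(out, maps)

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError):
            item_patterns(np.ones((2, 4)), ["a", "a"], ["a", "b"])


class TestPcConstrain:
    def test_full_rank_preserves_euclidean_geometry(self):
        rng = np.random.default_rng(2)
        pats = rng.normal(size=(10, 30))
        labels = [f"i{k}" for k in range(10)]
        full = pattern_rdm(pats - pats.mean(0), labels, metric="euclidean")
        scores = pc_constrain(pats, k=9)
        constrained = pattern_rdm(scores, labels, metric="euclidean")
        np.testing.assert_allclose(constrained.values, full.values, atol=1e-8)

    def test_rank_one_matrix_unchanged_at_k1(self):
        rng = np.random.default_rng(3)
        base = np.outer(rng.normal(size=8), rng.normal(size=20))
        labels = [f"i{k}" for k in range(8)]
        full = pattern_rdm(base - base.mean(0), labels, metric="euclidean")
        constrained = pattern_rdm(pc_constrain(base, 1), labels, metric="euclidean")
        np.testing.assert_allclose(constrained.values, full.values, atol=1e-8)

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            pc_constrain(np.ones((5, 10)), 0)
        with pytest.raises(ValueError):
            pc_constrain(np.random.default_rng(0).normal(size=(5, 10)), 5)

    def test_planted_two_component_geometry_peaks_at_k2(self):
        # truth recovery is best at the true dimensionality, Monte Carlo
        labels = [f"i{k}" for k in range(12)]
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=(12, 2)) * [3.0, 2.0]
            truth = pattern_rdm(z - z.mean(0), labels, metric="euclidean")
            q, _ = np.linalg.qr(rng.normal(size=(40, 2)))
            pats = z @ q.T + 0.35 * rng.normal(size=(12, 40))
            fits = {}
            for k in range(1, 7):
                rdm_k = pattern_rdm(pc_constrain(pats, k), labels, metric="euclidean")
                fits[k] = spearman_rdm(rdm_k, truth).rho
            if max(fits, key=fits.get) == 2:
                wins += 1
        assert wins >= 12

    def test_monotone_recovery_with_dimensionality(self):
        # on noiseless full-rank geometry, more PCs never hurt
        rng = np.random.default_rng(5)
        z = rng.normal(size=(10, 6)) * np.linspace(3, 1, 6)
        labels = [f"i{k}" for k in range(10)]
        q, _ = np.linalg.qr(rng.normal(size=(25, 6)))
        pats = z @ q.T
        full = pattern_rdm(pats - pats.mean(0), labels, metric="euclidean")
        fits = [
            spearman_rdm(
                pattern_rdm(pc_constrain(pats, k), labels, metric="euclidean"), full
            ).rho
            for k in range(1, 7)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(fits, fits[1:]))


class TestIsnrsPair:
    def test_identical_rdms_give_one(self, items):
        rng = np.random.default_rng(6)
        a = random_rdm(items, rng)
        conf = hand_rdm(0, items)
        assert isnrs_pair(a, a, [conf]).rho == pytest.approx(1.0)

    def test_delegates_to_partial_spearman(self, items):
        rng = np.random.default_rng(7)
        a, b = random_rdm(items, rng), random_rdm(items, rng)
        conf = hand_rdm(1, items)
        assert isnrs_pair(a, b, [conf]).rho == partial_spearman_rdm(a, b, [conf]).rho

    def test_independent_rdms_centered_on_zero(self, items):
        rhos = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rhos.append(
                isnrs_pair(random_rdm(items, rng), random_rdm(items, rng)).rho
            )
        assert abs(np.mean(rhos)) < 0.03


class TestHandRdm:
    def test_same_hand_pairs_zero(self, items):
        rdm = hand_rdm(0, items)  # T1,T2 left; T3,T4 right
        i, j = items.index("bu1"), items.index("bu2")
        assert rdm.values[i, j] == 0.0
        assert rdm.values[items.index("bu1"), items.index("bu3")] == 1.0

    def test_counterbalanced_maps_are_complementary(self, items):
        np.testing.assert_array_equal(hand_rdm(0, items).values, hand_rdm(1, items).values)
        # complementary assignment flips hands but same-hand structure is identical


class TestIsnrsMatrix:
    def test_averages_over_all_natives(self, small_cohort, small_config):
        _, patterns, _ = small_cohort
        mat = isnrs_matrix(patterns, "late")
        assert mat.n_natives == small_config.n_natives
        assert mat.values.shape == (small_config.n_learners, len(small_config.roi_names))
        assert np.all(np.abs(mat.values.to_numpy()) <= 1.0)

    def test_self_similarity_is_one(self, items):
        # a learner whose RDM equals the single native's RDM scores 1
        from tonelearn.simulate import CohortPatterns

        rng = np.random.default_rng(8)
        pats = rng.normal(size=(20, 15))
        cohort = CohortPatterns(
            data={
                ("learner", 0, "roi", "late"): pats,
                ("native", 0, "roi", "whole"): pats.copy(),
            },
            item_labels=items,
            roi_names=("roi",),
        )
        mat = isnrs_matrix(cohort, "late")
        assert mat.values.loc[0, "roi"] == pytest.approx(1.0)

    def test_mean_of_rhos_not_rho_of_mean(self, items):
        # averaging order matters: mean over pairwise rhos differs from the
        # rho against the averaged native RDM
        from tonelearn.simulate import CohortPatterns

        rng = np.random.default_rng(9)
        lp = rng.normal(size=(20, 15))
        n1, n2 = rng.normal(size=(20, 15)), rng.normal(size=(20, 15))
        cohort = CohortPatterns(
            data={
                ("learner", 0, "roi", "late"): lp,
                ("native", 0, "roi", "whole"): n1,
                ("native", 1, "roi", "whole"): n2,
            },
            item_labels=items,
            roi_names=("roi",),
        )
        mat = isnrs_matrix(cohort, "late", use_hand_confound=False)
        lrdm = pattern_rdm(lp, items)
        mean_rho = np.mean(
            [spearman_rdm(lrdm, pattern_rdm(n, items)).rho for n in (n1, n2)]
        )
        assert mat.values.loc[0, "roi"] == pytest.approx(mean_rho, abs=1e-12)
        from tonelearn.rdm import RDM

        mean_rdm = RDM(items, (pattern_rdm(n1, items).values + pattern_rdm(n2, items).values) / 2)
        rho_of_mean = spearman_rdm(lrdm, mean_rdm).rho
        assert mat.values.loc[0, "roi"] != pytest.approx(rho_of_mean, abs=1e-6)

    def test_scaling_invariance_of_correlation_path(self, small_cohort):
        _, patterns, _ = small_cohort
        scaled = {k: (7.5 * v if k[0] == "learner" else v) for k, v in patterns.data.items()}
        from tonelearn.simulate import CohortPatterns

        cohort2 = CohortPatterns(
            data=scaled, item_labels=patterns.item_labels, roi_names=patterns.roi_names
        )
        a = isnrs_matrix(patterns, "late").values
        b = isnrs_matrix(cohort2, "late").values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_planted_rois_track_ability(self, catalog):
        cfg = CohortConfig(
            n_learners=24, n_natives=8, seed=21,
            roi_names=("L.STG", "R.PreCG", "L.IPL", "R.AG"),
            planted_rois=("L.STG", "R.PreCG"),
        )
        patterns, truth = simulate_patterns(cfg, catalog)
        mat = isnrs_matrix(patterns, "late")
        planted = np.mean(
            [spearmanr(truth.ability, mat.values[r]).statistic for r in cfg.planted_rois]
        )
        assert planted > 0.5


class TestMedianSplit:
    def test_median_learners_excluded(self):
        from tonelearn.isnrs import IsnrsMatrix

        values = pd.DataFrame(
            {"roi": np.arange(6, dtype=float)}, index=range(6)
        )
        mat = IsnrsMatrix(values, "late", None, (), 1)
        outcomes = pd.Series([0.1, 0.2, 0.3, 0.3, 0.5, 0.6], index=range(6))
        out = median_split_compare(mat, outcomes)
        # two learners sit exactly at the median (0.3) and are removed
        assert out.loc[0, "n_successful"] + out.loc[0, "n_less_successful"] == 4

    def test_even_distinct_outcomes_split_in_half(self):
        from tonelearn.isnrs import IsnrsMatrix

        values = pd.DataFrame({"roi": [0.0, 1.0, 2.0, 3.0]}, index=range(4))
        mat = IsnrsMatrix(values, "late", None, (), 1)
        out = median_split_compare(mat, pd.Series([1.0, 2.0, 3.0, 4.0], index=range(4)))
        assert out.loc[0, "n_successful"] == 2
        assert out.loc[0, "n_less_successful"] == 2

    def test_successful_group_higher_in_planted_roi(self, small_cohort):
        table, patterns, truth = small_cohort
        mat = isnrs_matrix(patterns, "late")
        outcomes = pd.Series(truth.ability, index=mat.values.index)
        out = median_split_compare(mat, outcomes).set_index("roi")
        assert out.loc["L.STG", "difference"] > 0

    def test_identical_outcomes_rejected(self):
        from tonelearn.isnrs import IsnrsMatrix

        values = pd.DataFrame({"roi": [0.0, 1.0, 2.0, 3.0]}, index=range(4))
        mat = IsnrsMatrix(values, "late", None, (), 1)
        with pytest.raises(ValueError):
            median_split_compare(mat, pd.Series([1.0] * 4, index=range(4)))
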