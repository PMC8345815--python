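"""RDM construction, normalization, and comparison against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tonelearn.rdm import (
    RDM,
    build_categorical_rdm,
    build_feature_rdm,
    fisher_z,
    normalize_rdm,
    partial_spearman_rdm,
    pattern_rdm,
    spearman_rdm,
    vectorize,
)

from .conftest import random_rdm


class TestCategoricalRdm:
    def test_same_category_pairs_are_zero(self, items):
        tone_of = {it: it[-1] for it in items}
        rdm = build_categorical_rdm(tone_of)
        i, j = items.index("bu1"), items.index("di1")
        assert rdm.values[i, j] == 0.0
        assert rdm.values[items.index("bu1"), items.index("bu2")] == 1.0

    def test_single_category_gives_all_zero(self):
        rdm = build_categorical_rdm({f"i{k}": "same" for k in range(5)})
        assert np.all(rdm.values == 0.0)

    def test_zero_pair_count_matches_enumeration(self, items):
        # brute-force oracle: C(5,2) same-tone pairs per tone x 4 tones = 40
        tone_of = {it: it[-1] for it in items}
        rdm = build_categorical_rdm(tone_of)
        pairs = [
            (a, b)
            for i, a in enumerate(items)
            for b in items[i + 1 :]
            if tone_of[a] == tone_of[b]
        ]
        assert len(pairs) == 40
        assert int((vectorize(rdm) == 0).sum()) == 40


class TestFeatureRdm:
    def test_equal_features_zero_distance(self):
        rdm = build_feature_rdm({"a": 3.0, "b": 3.0, "c": 3.0})
        assert np.all(rdm.values == 0.0)

    def test_minmax_scaled_heights_hand_computed(self):
        # heights {100,150,200} min-max to {0,0.5,1}; |diffs| -> 0.5,1.0,0.5
        rdm = normalize_rdm(
            build_feature_rdm({"a": 100.0, "b": 150.0, "c": 200.0}, normalize_dims=True),
            anchor_zero=True,
        )
        np.testing.assert_allclose(vectorize(rdm), [0.5, 1.0, 0.5])

    def test_euclidean_identity(self):
        rdm = build_feature_rdm({"a": (0.0, 0.0), "b": (1.0, 1.0)}, metric="euclidean")
        assert rdm.values[0, 1] == pytest.approx(np.sqrt(2))

    def test_nonfinite_feature_rejected(self):
        with pytest.raises(ValueError):
            build_feature_rdm({"a": np.nan, "b": 1.0})


class TestNormalize:
    def test_linear_scaling_oracle(self):
        rdm = build_feature_rdm({"a": 0.0, "b": 2.0, "c": 6.0})
        # off-diagonals {2, 6, 4} -> {0, 1, 0.5}
        np.testing.assert_allclose(vectorize(normalize_rdm(rdm)), [0.0, 1.0, 0.5])

    def test_idempotent_on_unit_span(self):
        rdm = build_feature_rdm({"a": 0.0, "b": 0.5, "c": 1.0})
        once = normalize_rdm(rdm)
        np.testing.assert_allclose(normalize_rdm(once).values, once.values)

    def test_constant_rdm_rejected(self):
        vals = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            normalize_rdm(RDM(("a", "b", "c"), vals))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_preserves_offdiagonal_order(self, seed):
        rng = np.random.default_rng(seed)
        rdm = random_rdm([f"i{k}" for k in range(6)], rng)
        before = stats.rankdata(vectorize(rdm))
        after = stats.rankdata(vectorize(normalize_rdm(rdm)))
        np.testing.assert_array_equal(before, after)


class TestPatternRdm:
    def test_identical_patterns_zero_distance(self):
        pats = np.vstack([np.arange(5.0)] * 2 + [np.arange(5.0)[::-1]])
        rdm = pattern_rdm(pats, ["a", "b", "c"])
        assert rdm.values[0, 1] == pytest.approx(0.0)

    def test_orthogonal_centered_patterns_distance_one(self):
        pats = np.array(
            [[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0], [1.0, -1.0, -1.0, 1.0]]
        )
        rdm = pattern_rdm(pats, ["a", "b", "c"])
        assert rdm.values[0, 1] == pytest.approx(1.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        pats = rng.normal(size=(5, 10))
        rdm = pattern_rdm(pats, [f"i{k}" for k in range(5)])
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else 1 - stats.pearsonr(pats[i], pats[j])[0]
                assert rdm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pattern_rejected(self):
        pats = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError):
            pattern_rdm(pats, ["a", "b", "c"])

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_euclidean_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pats = rng.normal(size=(6, 8))
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        labels = [f"i{k}" for k in range(6)]
        a = pattern_rdm(pats, labels, metric="euclidean")
        b = pattern_rdm(pats @ q, labels, metric="euclidean")
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)


class TestVectorize:
    def test_twenty_items_gives_190(self, items):
        rng = np.random.default_rng(0)
        assert len(vectorize(random_rdm(items, rng))) == 190

    def test_two_items_gives_one(self):
        rdm = build_feature_rdm({"a": 0.0, "b": 1.0})
        assert len(vectorize(rdm)) == 1

    def test_transpose_invariant(self):
        rng = np.random.default_rng(3)
        rdm = random_rdm(["a", "b", "c", "d"], rng)
        transposed = RDM(rdm.labels, rdm.values.T.copy(), kind=rdm.kind)
        np.testing.assert_array_equal(vectorize(rdm), vectorize(transposed))


class TestSpearman:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(1)
        a = random_rdm(["a", "b", "c", "d", "e"], rng)
        b = RDM(a.labels, np.where(np.eye(5, dtype=bool), 0.0, a.values.max() - a.values))
        assert spearman_rdm(a, a).rho == pytest.approx(1.0)
        assert spearman_rdm(a, b).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, items):
        rng = np.random.default_rng(5)
        a, b = random_rdm(items, rng), random_rdm(items, rng)
        res = spearman_rdm(a, b)
        ra, rb = stats.rankdata(vectorize(a)), stats.rankdata(vectorize(b))
        assert res.rho == pytest.approx(stats.pearsonr(ra, rb)[0], abs=1e-12)
        assert res.n_pairs == 190

    def test_pairwise_complete_with_missing(self):
        rng = np.random.default_rng(6)
        a, b = random_rdm(["a", "b", "c", "d", "e"], rng), random_rdm(
            ["a", "b", "c", "d", "e"], rng
        )
        vals = a.values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        a_missing = RDM(a.labels, vals)
        res = spearman_rdm(a_missing, b)
        assert res.n_pairs == 9
        keep = ~np.isnan(vectorize(a_missing))
        oracle = stats.spearmanr(vectorize(a_missing)[keep], vectorize(b)[keep])[0]
        assert res.rho == pytest.approx(oracle, abs=1e-12)


class TestPartialSpearman:
    def test_empty_confounds_equals_plain_spearman(self, items):
        rng = np.random.default_rng(9)
        a, b = random_rdm(items, rng), random_rdm(items, rng)
        assert partial_spearman_rdm(a, b).rho == spearman_rdm(a, b).rho

    def test_identical_rdms_with_independent_confound(self, items):
        rng = np.random.default_rng(10)
        a = random_rdm(items, rng)
        conf = random_rdm(items, rng, kind="hand")
        assert partial_spearman_rdm(a, a, [conf]).rho == pytest.approx(1.0)

    def test_single_confound_closed_form(self):
        # closed-form oracle on ranks: (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))
        def rdm_from_vec(vec):
            vals = np.zeros((4, 4))
            vals[np.triu_indices(4, 1)] = vec
            return RDM(("a", "b", "c", "d"), vals + vals.T)

        x, y, z = [1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], [1, 3, 2, 4, 6, 5]
        rho = partial_spearman_rdm(
            rdm_from_vec(x), rdm_from_vec(y), [rdm_from_vec(z)]
        ).rho
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        r_xy, r_xz, r_yz = (
            stats.pearsonr(rx, ry)[0],
            stats.pearsonr(rx, rz)[0],
            stats.pearsonr(ry, rz)[0],
        )
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_confound_removal_drives_rho_to_zero(self, items):
        # a equals the confound; b is the confound plus tiny noise
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            conf = random_rdm(items, rng, kind="hand")
            noise = rng.normal(0, 1e-3, size=conf.values.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            b = RDM(conf.labels, np.abs(conf.values + noise))
            rhos.append(partial_spearman_rdm(conf, b, [conf]).rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_collinear_confounds_rejected(self, items):
        rng = np.random.default_rng(12)
        a, b = random_rdm(items, rng), random_rdm(items, rng)
        conf = random_rdm(items, rng)
        with pytest.raises(ValueError):
            partial_spearman_rdm(a, b, [conf, conf])


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected", [(0.0, 0.0), (0.5, 0.5493061443340549)]
    )
    def test_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-10)

    def test_odd_function_and_domain(self):
        assert fisher_z(-0.3) == -fisher_z(0.3)
        with pytest.raises(ValueError):
            fisher_z(1.0)


@settings(derandomize=True, max_examples=20)
@given(st.integers(0, 10_000))
def test_construction_commutes_with_relabelling(seed):
    """Permuting the item order permutes RDM rows and columns identically."""
    rng = np.random.default_rng(seed)
    items = [f"i{k}" for k in range(6)]
    feats = {it: float(v) for it, v in zip(items, rng.normal(size=6))}
    perm = rng.permutation(6)
    rdm = build_feature_rdm(feats)
    shuffled = build_feature_rdm({items[p]: feats[items[p]] for p in perm})
    np.testing.assert_allclose(
        shuffled.values, rdm.values[np.ix_(perm, perm)], atol=1e-12
    )
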