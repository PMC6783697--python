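"""Tests for the concordance statistics: CVs, ribosome estimates, two-sample
tests with multiple-testing control, ontology similarity and group screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from collections import Counter
from scipy import stats

from cytocomp import (
    OntologyProfile,
    cv_percent,
    estimate_ribosome_count,
    extra_ribosomal_comparison,
    mann_whitney_u,
    median_divergence,
    ontology_jaccard,
    ontology_profiles,
    pairwise_matrix,
    profile_pearson,
    ribosome_estimates,
    technique_group_cv,
    welch_t_test,
)


class TestCvPercent:
    @pytest.mark.parametrize("values, expected", [([2, 2, 2], 0.0), ([1, 2, 3], 50.0)])
    def test_values(self, values, expected):
        assert cv_percent(values) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([5])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([-1, 1])

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=50)
        for c in (0.1, 2.0, 1e6):
            assert cv_percent(c * x) == pytest.approx(cv_percent(x), rel=1e-9)


class TestRibosomeEstimates:
    def _matrix(self, col):
        return pd.DataFrame(
            {"DS1": col},
            index=pd.Index([f"R{i}" for i in range(len(col))], name="protein_id"),
        )

    def test_constant_column(self):
        (est,) = ribosome_estimates(self._matrix([100.0, 100.0, 100.0]), ["R0", "R1", "R2"])
        assert est.value == 100.0 and est.sd == 0.0 and est.available

    def test_mean_statistic(self):
        (est,) = ribosome_estimates(self._matrix([80.0, 100.0, 120.0]), ["R0", "R1", "R2"])
        assert est.value == pytest.approx(100.0)

    def test_all_missing_column_unavailable_and_excluded_from_tests(self):
        matrix = pd.DataFrame(
            {"DS1": [np.nan, np.nan], "DS2": [1.0, 2.0], "DS3": [1.5, 2.5]},
            index=pd.Index(["R0", "R1"], name="protein_id"),
        )
        ests = ribosome_estimates(matrix, ["R0", "R1"])
        assert not ests[0].available and ests[1].available
        samples = {c: matrix[c].dropna().to_numpy() for c in matrix.columns}
        result = pairwise_matrix(samples, test="welch")
        assert result.excluded == ["DS1"]
        assert result.n_pairs == 1

    def test_pooled_vs_per_protein_agree_without_noise(self):
        matrix = self._matrix([50.0, 50.0, 50.0])
        for method in ("pooled", "per_protein"):
            assert estimate_ribosome_count(matrix, ["R0", "R1", "R2"], method=method) == 50.0


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_example(self):
        # sd^2 = 1, n = 3 each: t = -3 / sqrt(2/3) ~ -3.674, df = 4
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [1, 2])

    def test_degenerate_variance_conventions(self):
        _, _, p_eq = welch_t_test([2, 2], [2, 2])
        assert p_eq == 1.0
        with pytest.warns(RuntimeWarning):
            t, _, p_ne = welch_t_test([2, 2], [3, 3])
        assert p_ne == 0.0 and np.isinf(t)


def _oracle_mwu(x, y):
    """Independent exact oracle: U by pair counting, p by labeling enumeration."""
    x, y = list(x), list(y)

    def u_first(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    pooled = x + y
    n1 = len(x)
    u_obs = u_first(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_first(xs, ys))
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_enumeration_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_rank_invariance(self):
        _, p1 = mann_whitney_u([1, 2, 3], [4, 5, 6])
        _, p2 = mann_whitney_u([1, 2, 3], [1001, 1002, 1003])
        assert p1 == p2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 2), (3, 5)])
    def test_matches_independent_oracle_with_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = _oracle_mwu(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_asymptotic_branch_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = rng.normal(1.0, size=11)  # combined 21 -> asymptotic
        u, p = mann_whitney_u(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == res.statistic and p == res.pvalue


class TestPairwiseMatrix:
    def _samples(self, k, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        return {f"D{i}": rng.normal(i * shift, 1.0, size=8) for i in range(k)}

    def test_twenty_datasets_give_190_pairs(self):
        result = pairwise_matrix(self._samples(20), test="welch", alpha=0.05)
        assert result.n_pairs == 190
        assert result.bonferroni_alpha == pytest.approx(0.05 / 190)

    def test_two_datasets_threshold_is_alpha(self):
        result = pairwise_matrix(self._samples(2), test="welch", alpha=0.05)
        assert result.n_pairs == 1
        assert result.bonferroni_alpha == 0.05

    def test_bh_adjustment_matches_step_up_oracle(self):
        result = pairwise_matrix(self._samples(6, seed=2, shift=0.7), test="welch")
        p = result.table["p_raw"].to_numpy()
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        assert result.table["p_bh"].to_numpy() == pytest.approx(adj)
        assert (result.table["p_bh"] >= result.table["p_raw"] - 1e-15).all()

    def test_bonferroni_set_subset_of_bh_set(self):
        for seed in range(5):
            result = pairwise_matrix(self._samples(8, seed=seed, shift=0.5), test="welch")
            tab = result.table
            assert (~tab["bonferroni_sig"] | tab["bh_sig"]).all()

    def test_symmetric_square_view(self):
        result = pairwise_matrix(self._samples(4), test="mannwhitney")
        sq = result.square("p_raw")
        assert np.allclose(sq.values, sq.values.T, equal_nan=True)
        assert sq.loc["D0", "D0"] != sq.loc["D0", "D0"]  # diagonal NaN


class TestOntology:
    def test_profile_counts(self):
        profiles = ontology_profiles(
            {"DS1": ["A", "B"]},
            {"A": {"glycolysis"}, "B": {"glycolysis", "folding"}},
        )
        assert profiles["DS1"].counts == {"glycolysis": 2, "folding": 1}

    def test_empty_class_sets_give_empty_profile(self):
        profiles = ontology_profiles({"DS1": ["A"]}, {"A": set()})
        assert profiles["DS1"].counts == {}
        assert profiles["DS1"].classes == frozenset()

    @pytest.mark.parametrize(
        "c1, c2, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 1, 2], 0.866),
        ],
    )
    def test_profile_pearson(self, c1, c2, expected):
        classes = ["a", "b", "c"]
        p1 = OntologyProfile("X", Counter(dict(zip(classes, c1))))
        p2 = OntologyProfile("Y", Counter(dict(zip(classes, c2))))
        assert profile_pearson(p1, p2) == pytest.approx(expected, abs=1e-3)

    def test_profile_pearson_zero_variance_is_missing(self):
        p1 = OntologyProfile("X", Counter({"a": 2, "b": 2}))
        p2 = OntologyProfile("Y", Counter({"a": 1, "b": 3}))
        assert profile_pearson(p1, p2) is None

    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), set(), 1.0),
        ],
    )
    def test_jaccard(self, s1, s2, expected):
        assert ontology_jaccard(s1, s2) == pytest.approx(expected)
        assert ontology_jaccard(s2, s1) == pytest.approx(expected)


class TestMedianDivergence:
    def test_identical_vectors(self):
        m = pd.Series([1.0, 2.0, 3.0])
        frac, flags = median_divergence(m, m.copy())
        assert frac == 0.0 and not flags.any()

    def test_hand_example(self):
        a = pd.Series([10.0, 10.0, 10.0, 10.0])
        b = pd.Series([10.0, 14.0, 20.0, 10.0])
        # symmetric relative differences: 0, 1/3, 2/3, 0 -> half exceed 0.25
        frac, flags = median_divergence(a, b, threshold=0.25)
        assert frac == pytest.approx(0.5)
        assert list(flags) == [False, True, True, False]

    def test_zero_threshold_flags_any_difference(self):
        a = pd.Series([1.0, 2.0])
        b = pd.Series([1.0, 2.1])
        frac, flags = median_divergence(a, b, threshold=0.0)
        assert list(flags) == [False, True]

    def test_both_zero_is_nondivergent(self):
        frac, flags = median_divergence(pd.Series([0.0]), pd.Series([0.0]))
        assert frac == 0.0

    def test_single_group_denominator(self):
        a = pd.Series([10.0])
        b = pd.Series([12.8])
        frac_mean, _ = median_divergence(a, b, threshold=0.25, denominator="mean")
        frac_a, _ = median_divergence(a, b, threshold=0.25, denominator="a")
        assert frac_mean == 0.0  # 2.8/11.4 ~ 0.246 <= 0.25
        assert frac_a == pytest.approx(1.0)  # 2.8/10 = 0.28 > 0.25

    def test_missing_pairs_skipped(self):
        a = pd.Series([1.0, np.nan, 5.0])
        b = pd.Series([1.0, 2.0, 10.0])
        frac, flags = median_divergence(a, b)
        assert len(flags) == 2


class TestExtraRibosomalComparison:
    def _matrix(self, rows):
        return pd.DataFrame(
            rows, index=pd.Index([f"R{i}" for i in range(len(rows))], name="protein_id")
        )

    def test_identical_sets_give_p_one(self):
        matrix = self._matrix([[10.0, 12.0], [20.0, 22.0], [30.0, 28.0], [40.0, 44.0]])
        p_means, p_medians = extra_ribosomal_comparison(
            ["R0", "R1"], ["R0", "R1"], matrix
        )
        assert p_means == 1.0 and p_medians == 1.0

    def test_far_apart_sets_highly_significant(self):
        rng = np.random.default_rng(4)
        low = rng.normal(100, 1, size=(10, 5))
        high = rng.normal(10_000, 1, size=(10, 5))
        matrix = self._matrix(np.vstack([low, high]).tolist())
        set_i = [f"R{i}" for i in range(10)]
        set_ii = [f"R{i}" for i in range(10, 20)]
        p_means, p_medians = extra_ribosomal_comparison(set_i, set_ii, matrix)
        assert p_means < 1e-3 and p_medians < 1e-3

    def test_null_p_values_uniform(self):
        """Under exchangeable groups the comparison p-value is ~Uniform(0,1)
        (Kolmogorov-Smirnov at the 1% level over 1,000 replicates)."""
        rng = np.random.default_rng(5)
        p_vals = []
        for _ in range(1000):
            data = rng.normal(100, 15, size=(12, 4))
            matrix = self._matrix(data.tolist())
            ids = [f"R{i}" for i in range(12)]
            p_means, _ = extra_ribosomal_comparison(ids[:6], ids[6:], matrix)
            p_vals.append(p_means)
        assert stats.kstest(p_vals, "uniform").pvalue > 0.01

    def test_small_set_rejected(self):
        matrix = self._matrix([[1.0, 2.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            extra_ribosomal_comparison(["R0"], ["R0", "R1"], matrix)


def test_group_cv_ordering_recovered_on_synthetic_data(default_study):
    """With GFP noise configured larger than MS noise, the estimated
    technique-group CVs reproduce that ordering."""
    from cytocomp import records_from_annotations
    from cytocomp.io_ingest import DatasetMeta

    params, matrix, ann, meta, _ = default_study
    metadata = [
        DatasetMeta(r.dataset_id, r.technique, r.medium, r.phase, r.units)
        for r in meta.itertuples()
    ]
    rib_ids = list(ann.loc[ann["is_ribosomal"] == 1, "protein_id"])
    group_cv = technique_group_cv(matrix, rib_ids, metadata)
    assert group_cv["GFP"] > group_cv["MS_absolute"]
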