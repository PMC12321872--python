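import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from dynconn.atlas import default_atlas
from dynconn.stats import (
    anova_tukey,
    chi_square_test,
    chord_aggregate,
    combat,
    differential_connections,
    scale_correlations,
    similarity_coefficient,
)


def zscore_cols(a):
    return (a - a.mean(axis=0)) / a.std(axis=0)


def offset_construction(n_per=40, p=6, offset=10.0, seed=0):
    """Two sites differing only by an additive offset; every feature's
    within-site first two moments are exactly (0,1) / (offset,1)."""
    rng = np.random.default_rng(seed)
    s1 = zscore_cols(rng.normal(size=(n_per, p)))
    s2 = zscore_cols(rng.normal(size=(n_per, p))) + offset
    Y = pd.DataFrame(np.vstack([s1, s2]))
    batch = np.array([0] * n_per + [1] * n_per)
    return Y, batch


class TestCombat:
    def test_additive_offset_harmonized_exactly(self):
        Y, batch = offset_construction()
        out = combat(Y, batch)
        m0 = out[batch == 0].mean(axis=0).to_numpy()
        m1 = out[batch == 1].mean(axis=0).to_numpy()
        assert np.allclose(m0, m1, rtol=1e-6, atol=1e-6)

    def test_single_site_identity_with_warning(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.warns(RuntimeWarning, match="single batch"):
            out = combat(Y, np.zeros(10, dtype=int))
        assert np.array_equal(out.to_numpy(), Y.to_numpy())

    def test_group_effect_preserved(self, rng):
        n = 60
        site = np.array([0] * n + [1] * n)
        group = np.tile(np.repeat([0, 1], n // 2), 2)
        X = rng.normal(size=(2 * n, 20))
        X[group == 1] += 2.0
        X[site == 1] += 5.0
        out = combat(pd.DataFrame(X), site, covariates=group.astype(float))
        d_before = X[group == 1].mean(axis=0) - X[group == 0].mean(axis=0)
        arr = out.to_numpy()
        d_after = arr[group == 1].mean(axis=0) - arr[group == 0].mean(axis=0)
        assert np.all(np.abs(d_after / d_before - 1) < 0.05)

    def test_idempotent(self):
        Y, batch = offset_construction(seed=3)
        once = combat(Y, batch)
        twice = combat(once, batch)
        denom = np.abs(once.to_numpy()).max()
        assert np.abs(twice.to_numpy() - once.to_numpy()).max() / denom < 1e-6

    def test_rank_deficient_design_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(20, 4)))
        batch = np.array([0] * 10 + [1] * 10)
        # covariate identical to batch indicator -> collinear with batch dummies
        with pytest.raises(ValueError, match="rank"):
            combat(Y, batch, covariates=batch.astype(float))

    def test_multiplicative_scale_removed(self, rng):
        n = 50
        site = np.array([0] * n + [1] * n)
        X = rng.normal(size=(2 * n, 10))
        X[site == 1] *= 3.0
        out = combat(pd.DataFrame(X), site).to_numpy()
        v0 = out[site == 0].std(axis=0)
        v1 = out[site == 1].std(axis=0)
        assert np.all(np.abs(v1 / v0 - 1) < 0.25)


class TestDifferentialConnections:
    def test_identical_groups_no_entries(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 30)))
        diff = differential_connections(X, X.copy(), alpha=0.05)
        assert diff.count == 0

    def test_type_one_error_calibrated(self, rng):
        # 1000-edge null, 50 replicates: rejection fraction near alpha
        fracs = []
        for _ in range(50):
            A = pd.DataFrame(rng.normal(size=(20, 1000)))
            B = pd.DataFrame(rng.normal(size=(20, 1000)))
            diff = differential_connections(A, B, alpha=0.05, correction="none")
            fracs.append(diff.count / 1000)
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_shift_power_matches_noncentral_t_oracle(self, rng):
        # closed-form oracle: two-sided equal-var t, n=50/50, shift 1 SD,
        # Bonferroni alpha 0.05/200 -> power = 0.8782 (noncentral t)
        oracle_power = 0.8781999050091059
        n, p, reps = 50, 200, 10
        rates = []
        for _ in range(reps):
            A = pd.DataFrame(rng.normal(size=(n, p)))
            B = pd.DataFrame(rng.normal(size=(n, p)))
            B.iloc[:, :10] += 1.0  # 1 SD shift on 10 designated edges
            diff = differential_connections(A, B, alpha=0.05, correction="bonferroni")
            recovered = {int(f) for f in diff.entries["feature"]}
            rates.append(len(recovered & set(range(10))) / 10)
        assert abs(np.mean(rates) - oracle_power) < 0.08
        assert np.mean(rates) > 0.8

    def test_monotone_in_alpha(self, rng):
        A = pd.DataFrame(rng.normal(size=(15, 100)))
        B = pd.DataFrame(rng.normal(0.3, 1.0, size=(15, 100)))
        counts = [
            differential_connections(A, B, alpha=a).count for a in (0.01, 0.05, 0.1, 0.5)
        ]
        assert counts == sorted(counts)

    def test_zero_variance_edge_flagged(self):
        A = pd.DataFrame({"e": np.ones(5)})
        B = pd.DataFrame({"e": np.ones(5)})
        diff = differential_connections(A, B)
        assert diff.count == 0
        assert bool(diff.all_tests["degenerate"].iloc[0])
        assert diff.all_tests["p"].iloc[0] == 1.0

    def test_welch_flag(self, rng):
        A = pd.DataFrame(rng.normal(0, 1, size=(30, 5)))
        B = pd.DataFrame(rng.normal(0, 5, size=(30, 5)))
        d1 = differential_connections(A, B, equal_var=True)
        d2 = differential_connections(A, B, equal_var=False)
        assert not np.allclose(d1.all_tests["p"], d2.all_tests["p"])

    def test_too_few_subjects_rejected(self, rng):
        A = pd.DataFrame(rng.normal(size=(1, 5)))
        B = pd.DataFrame(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError):
            differential_connections(A, B)


class TestChordAggregate:
    @pytest.fixture
    def atlas(self):
        return default_atlas(n_gray=14, n_white=12)

    def _diff(self, entries):
        table = pd.DataFrame(entries, columns=["feature", "t", "p", "p_corrected", "mean_diff"])
        from dynconn.stats import DifferentialConnectionSet

        return DifferentialConnectionSet(("CN", "CI"), table, 0.05, "none", table)

    def test_empty_diff_all_zero(self, atlas):
        chord = chord_aggregate(self._diff([]), atlas)
        assert (chord.to_numpy() == 0).all()
        assert chord.shape == (19, 19)

    def test_single_edge(self, atlas):
        # g013/g014 belong to the 7th gray network; w001 to WM1
        chord = chord_aggregate(self._diff([("g013-w001", 2.0, 0.01, 0.01, 0.3)]), atlas)
        assert chord.loc["SalienceVentralAttention", "WM1"] == pytest.approx(0.3)
        assert chord.loc["WM1", "SalienceVentralAttention"] == pytest.approx(0.3)

    def test_additivity_and_conservation(self, atlas):
        entries = [
            ("g013-w001", 2.0, 0.01, 0.01, 0.3),
            ("g014-w001", 2.0, 0.01, 0.01, -0.2),
            ("g001-g003", 2.0, 0.01, 0.01, 0.1),
        ]
        chord = chord_aggregate(self._diff(entries), atlas)
        assert chord.loc["SalienceVentralAttention", "WM1"] == pytest.approx(0.5)
        total = np.triu(chord.to_numpy()).sum()
        assert total == pytest.approx(0.3 + 0.2 + 0.1)

    def test_unknown_node_named_in_error(self, atlas):
        with pytest.raises(KeyError, match="zz9"):
            chord_aggregate(self._diff([("g001-zz9", 2.0, 0.01, 0.01, 0.3)]), atlas)


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        vals = np.tile(np.arange(5.0), 3)
        groups = np.repeat(["a", "b", "c"], 5)
        F, p, _ = anova_tukey(vals, groups)
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=30)
        g = np.repeat(["a", "b"], 15)
        x[g == "b"] += 0.7
        F, pF, _ = anova_tukey(x, g)
        t, pt = sst.ttest_ind(x[g == "a"], x[g == "b"])
        assert F == pytest.approx(t**2, rel=1e-10)
        assert pF == pytest.approx(pt, rel=1e-10)

    def test_large_shifts_all_pairs_significant(self, rng):
        vals = np.concatenate([
            rng.normal(0, 1, 20), rng.normal(10, 1, 20), rng.normal(20, 1, 20)
        ])
        groups = np.repeat(["a", "b", "c"], 20)
        F, p, table = anova_tukey(vals, groups)
        assert p < 1e-10
        assert table["reject"].astype(bool).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(np.arange(5.0), np.repeat("a", 5))


class TestChiSquare:
    def test_apoe_counts_significant(self):
        # 2x2 allele-frequency table (34.0% vs 56.7% carriers); frozen from
        # an independent chi2_contingency evaluation of the same counts
        stat, p = chi_square_test([[31, 16], [163, 213]])
        assert stat == pytest.approx(8.59906079773106, rel=1e-10)
        assert p == pytest.approx(0.0033633641050518364, rel=1e-10)
        assert p < 0.01

    def test_three_group_apoe_counts_below_point_001(self):
        # the 3-group r x c version of the same allele table does reach p<0.001
        stat, p = chi_square_test([[83, 56], [31, 16], [163, 213]])
        assert p < 0.001

    def test_independent_table_stat_zero(self):
        stat, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_transposition_invariance(self):
        t = [[31, 16], [163, 213]]
        s1, _ = chi_square_test(t)
        s2, _ = chi_square_test(np.asarray(t).T)
        assert s1 == pytest.approx(s2)

    def test_yates_flag_changes_statistic(self):
        s_raw, _ = chi_square_test([[12, 5], [7, 15]])
        s_yates, _ = chi_square_test([[12, 5], [7, 15]], yates=True)
        assert s_yates < s_raw

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[1.5, 2], [3, 4]])


class TestScaleCorrelations:
    def test_feature_equals_scale_r_one(self):
        x = np.arange(20.0)
        feats = pd.DataFrame({"f": x})
        scales = pd.DataFrame({"mmse": x})
        out = scale_correlations(feats, scales)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        n = 400
        feats = pd.DataFrame({"f": rng.normal(size=n)})
        scales = pd.DataFrame({"mmse": rng.normal(size=n)})
        out = scale_correlations(feats, scales)
        assert abs(out["r"].iloc[0]) < 0.15

    def test_bonferroni_scaling(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scales = pd.DataFrame(rng.normal(size=(50, 2)), columns=["mmse", "moca"])
        out = scale_correlations(feats, scales)
        assert len(out) == 8
        ok = ~out["degenerate"]
        assert np.allclose(
            out.loc[ok, "p_bonferroni"], np.minimum(out.loc[ok, "p"] * 8, 1.0)
        )

    def test_constant_scale_flagged(self):
        feats = pd.DataFrame({"f": np.arange(10.0)})
        scales = pd.DataFrame({"mmse": np.ones(10)})
        out = scale_correlations(feats, scales)
        assert bool(out["degenerate"].iloc[0]) and np.isnan(out["r"].iloc[0])

    def test_too_few_pairs_rejected(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        scales = pd.DataFrame({"mmse": [1.0, 2.0, np.nan]})
        with pytest.raises(ValueError):
            scale_correlations(feats, scales)


class TestSimilarityCoefficient:
    def test_identity(self, rng):
        A = rng.normal(size=(10, 10)); A = (A + A.T) / 2
        assert similarity_coefficient(A, A) == pytest.approx(1.0)

    def test_negation(self, rng):
        A = rng.normal(size=(10, 10)); A = (A + A.T) / 2
        assert similarity_coefficient(A, -A) == pytest.approx(-1.0)

    def test_null_similarity_small_at_328_nodes(self, rng):
        hits = 0
        for _ in range(20):
            A = rng.normal(size=(328, 328)); A = (A + A.T) / 2
            B = rng.normal(size=(328, 328)); B = (B + B.T) / 2
            if abs(similarity_coefficient(A, B)) < 0.02:
                hits += 1
        assert hits >= 18  # ~95% of replicates

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            similarity_coefficient(np.eye(4), np.eye(5))
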