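import numpy as np
import pytest
from scipy import stats

from pdxgem.dataio import DrugActivityTable, ExpressionMatrix
from pdxgem.discovery import (
    benjamini_hochberg,
    choose_method,
    correlation_per_feature,
    discover_biomarkers,
    split_by_activity,
    t_test_per_feature,
)


def _expr(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])], samples)


class TestSplitAndMethodChoice:
    @pytest.mark.parametrize("activity, sizes", [
        ([-10.0, -0.5, 3.0, 40.0], (2, 2)),
        ([5.0, 10.0], (0, 2)),
    ])
    def test_sign_split(self, activity, sizes):
        table = DrugActivityTable([f"s{i}" for i in range(len(activity))], activity)
        shrunken, grown = split_by_activity(table)
        assert (len(shrunken), len(grown)) == sizes

    def test_zero_activity_counts_as_grown(self):
        table = DrugActivityTable(["a", "b", "c"], [0.0, -1.0, 2.0])
        shrunken, grown = split_by_activity(table)
        assert "a" in grown and "b" in shrunken

    @pytest.mark.parametrize("shrunken_n, grown_n, expected", [
        (3, 10, "t_test"),       # paclitaxel-style panel
        (2, 4, "t_test"),        # gemcitabine-style panel (min group 2)
        (0, 13, "correlation"),  # trastuzumab-style panel
        (1, 12, "correlation"),
    ])
    def test_choice(self, shrunken_n, grown_n, expected):
        assert choose_method(shrunken_n, grown_n) == expected

    def test_min_group_size_knob(self):
        assert choose_method(2, 4, min_group_size=3) == "correlation"

    def test_too_few_pdx_rejected(self):
        with pytest.raises(ValueError):
            choose_method(1, 2)


class TestTTest:
    def test_identical_groups_null(self):
        expr = _expr([[1, 2, 3, 1, 2, 3]])
        t, p, deg = t_test_per_feature(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert t[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_degenerate_perfect_separation(self):
        expr = _expr([[0, 0, 0, 5, 5, 5]])
        t, p, deg = t_test_per_feature(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert p[0] == 0.0 and deg[0]

    def test_tied_constant_groups_flagged(self):
        expr = _expr([[2, 2, 2, 2, 2, 2]])
        t, p, deg = t_test_per_feature(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (t[0], p[0]) == (0.0, 1.0) and deg[0]

    def test_matches_hand_computed_pooled_t(self):
        """A = (2.1, 2.9, 2.5) vs B = (3.9, 4.1, 4.3, 3.7): pooled-variance
        Student's t with 5 df, computed by hand."""
        expr = _expr([[2.1, 2.9, 2.5, 3.9, 4.1, 4.3, 3.7]])
        shrunken = ["s0", "s1", "s2"]
        grown = ["s3", "s4", "s5", "s6"]
        t, p, _ = t_test_per_feature(expr, shrunken, grown)
        assert t[0] == pytest.approx(6.089984572, abs=1e-8)
        assert p[0] == pytest.approx(0.001726984, abs=1e-8)


class TestCorrelation:
    def test_self_correlation_pearson(self):
        act = DrugActivityTable([f"s{j}" for j in range(6)], [-3, -1, 0, 1, 2, 5])
        expr = _expr([act.activity])
        r, p, deg = correlation_per_feature(expr, act, flavor="pearson")
        assert r[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(0.0, abs=1e-12)

    def test_reverse_rank_spearman(self):
        act = DrugActivityTable([f"s{j}" for j in range(6)], [-3, -1, 0, 1, 2, 5])
        expr = _expr([[6, 5, 4, 3, 2, 1]])
        r, _, _ = correlation_per_feature(expr, act, flavor="spearman")
        assert r[0] == pytest.approx(-1.0)

    def test_matches_brute_force_spearman(self):
        """n=8 toy vectors against a from-scratch rank computation."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=8)

        def brute_rho(a, b):
            ra = np.array([sorted(a).index(v) + 1 for v in a], dtype=float)
            rb = np.array([sorted(b).index(v) + 1 for v in b], dtype=float)
            ca, cb = ra - ra.mean(), rb - rb.mean()
            return float((ca @ cb) / np.sqrt((ca @ ca) * (cb @ cb)))

        rho = brute_rho(x, y)
        t_stat = rho * np.sqrt(6 / (1 - rho ** 2))
        p_expect = 2 * stats.t.sf(abs(t_stat), 6)

        act = DrugActivityTable([f"s{j}" for j in range(8)], y)
        expr = _expr([x])
        r, p, _ = correlation_per_feature(expr, act, flavor="spearman")
        assert r[0] == pytest.approx(rho, abs=1e-12)
        assert p[0] == pytest.approx(p_expect, abs=1e-12)

    def test_constant_feature_flagged(self):
        act = DrugActivityTable([f"s{j}" for j in range(6)], [-3, -1, 0, 1, 2, 5])
        r, p, deg = correlation_per_feature(_expr([[1] * 6]), act, flavor="pearson")
        assert (r[0], p[0]) == (0.0, 1.0) and deg[0]


class TestBenjaminiHochberg:
    def test_permutation_invariance_and_range(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm], atol=1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_monotone_in_p_ranking(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        q = benjamini_hochberg(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)


class TestDiscoverBiomarkers:
    def test_planted_perfect_signal_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 12
        act = DrugActivityTable([f"s{j}" for j in range(n)],
                                rng.normal(scale=30, size=n))
        values = rng.normal(size=(20, n))
        values[7] = act.activity / 30.0
        expr = _expr(values)
        table = discover_biomarkers(expr, act, method="pearson")
        assert table.loc[7, "selected"]
        assert table["q_value"].idxmin() == 7

    def test_nominal_fallback_selects_exact_p_threshold_set(self):
        """When BH selects nothing, fallback must return exactly the
        features with nominal p < 0.05."""
        rng = np.random.default_rng(12)
        n = 10
        act = DrugActivityTable([f"s{j}" for j in range(n)],
                                rng.normal(scale=25, size=n))
        expr = _expr(rng.normal(size=(20, n)))
        table = discover_biomarkers(expr, act, method="pearson")
        if table["alpha_mode"].iloc[0] == "nominal":
            np.testing.assert_array_equal(table["selected"],
                                          table["p_value"] < 0.05)
            assert not (table["q_value"] < 0.05).any()

    def test_forced_nominal_selection(self):
        rng = np.random.default_rng(2)
        n = 12
        act = DrugActivityTable([f"s{j}" for j in range(n)],
                                rng.normal(scale=30, size=n))
        expr = _expr(rng.normal(size=(50, n)))
        table = discover_biomarkers(expr, act, method="pearson", selection="nominal")
        assert table["alpha_mode"].iloc[0] == "nominal"
        np.testing.assert_array_equal(table["selected"], table["p_value"] < 0.05)

    def test_row_order_matches_input(self, small_study):
        table = discover_biomarkers(small_study.pdx_expr, small_study.activity)
        assert table["feature_id"].tolist() == small_study.pdx_expr.feature_ids

    def test_direction_agrees_between_methods_on_monotone_data(self):
        """A feature increasing with tumor growth gets positive direction
        under both the t-test and the correlation branch."""
        n = 10
        act_vals = np.array([-40, -30, -20, -10, 5, 10, 20, 30, 40, 50], float)
        act = DrugActivityTable([f"s{j}" for j in range(n)], act_vals)
        rng = np.random.default_rng(9)
        up = np.linspace(0, 3, n) + rng.normal(scale=0.05, size=n)
        expr = _expr([up, -up])
        t_table = discover_biomarkers(expr, act, method="t_test")
        c_table = discover_biomarkers(expr, act, method="spearman")
        assert t_table.loc[0, "direction"] == c_table.loc[0, "direction"] == 1
        assert t_table.loc[1, "direction"] == c_table.loc[1, "direction"] == -1

    def test_null_rarely_selects_at_fdr(self):
        """Mini Monte-Carlo under the global null: the FDR screen should
        select anything in well under a quarter of replicates (the full
        calibration lives in the acceptance suite)."""
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            n = 12
            act = DrugActivityTable([f"s{j}" for j in range(n)],
                                    rng.normal(scale=25, size=n))
            expr = _expr(rng.normal(size=(200, n)))
            table = discover_biomarkers(expr, act, nominal_fallback=False)
            hits += int(table["selected"].any())
        assert hits <= 6
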