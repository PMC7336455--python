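import numpy as np
import pytest
from scipy import stats

from pdxgem.ccea import (
    CorrelationMatrixPair,
    ccec,
    ccec_all,
    ccec_pvalue,
    pairwise_correlations,
    run_ccea,
)
from pdxgem.dataio import ExpressionMatrix
from pdxgem.discovery import discover_biomarkers


def lin_ccc(x, y):
    """Independent moment-form oracle for Lin's concordance correlation
    coefficient: 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), biased
    (divisor-m) moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    return 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def random_pair(rng, n):
    """A random symmetric unit-diagonal matrix pair."""
    def corr_like(m):
        m = (m + m.T) / 2
        m = np.clip(m / (1.05 * np.abs(m).max()), -1, 1)
        np.fill_diagonal(m, 1.0)
        return m
    U = corr_like(rng.normal(size=(n, n)))
    V = corr_like(rng.normal(size=(n, n)))
    return U, V


class TestPairwiseCorrelations:
    def test_identical_and_anticorrelated_rows(self):
        base = np.array([0.0, 1.0, 2.0, 1.5, -0.5, 3.0])
        expr = ExpressionMatrix(np.vstack([base, base, -base]),
                                ["a", "b", "c"], [f"s{j}" for j in range(6)])
        m, deg = pairwise_correlations(expr)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        assert not deg.any()

    def test_matches_brute_force_double_loop(self, toy_expr):
        m, _ = pairwise_correlations(toy_expr)
        x = toy_expr.values
        for i in range(4):
            for j in range(4):
                ci = x[i] - x[i].mean()
                cj = x[j] - x[j].mean()
                expect = (ci @ cj) / np.sqrt((ci @ ci) * (cj @ cj))
                assert m[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_feature_flagged_and_zeroed(self):
        expr = ExpressionMatrix(
            np.vstack([np.arange(5.0), np.ones(5), np.arange(5.0) ** 2]),
            ["a", "b", "c"], [f"s{j}" for j in range(5)])
        m, deg = pairwise_correlations(expr)
        assert deg.tolist() == [False, True, False]
        assert m[1, 0] == 0.0 and m[1, 1] == 1.0

    def test_sample_minimum(self):
        expr = ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError):
            pairwise_correlations(expr)


class TestCcec:
    def test_equals_moment_form_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 30)
            U, V = random_pair(rng, int(n))
            c, _ = ccec_all(U, V)
            for g in range(int(n)):
                mask = np.arange(n) != g
                assert c[g] == pytest.approx(lin_ccc(U[mask, g], V[mask, g]),
                                             abs=1e-12)

    def test_perfect_concordance(self):
        rng = np.random.default_rng(1)
        U, _ = random_pair(rng, 10)
        c, deg = ccec_all(U, U.copy())
        np.testing.assert_allclose(c, 1.0, atol=1e-12)
        assert not deg.any()

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        U, V = random_pair(rng, 12)
        for g in (0, 5, 11):
            assert ccec(U, V, g) == pytest.approx(ccec(V, U, g), abs=1e-14)

    def test_reflected_row_is_negative(self):
        """V column reflected about the U column mean flips the covariance
        term, so the coefficient must be negative."""
        rng = np.random.default_rng(3)
        U, _ = random_pair(rng, 8)
        V = U.copy()
        g = 2
        mask = np.arange(8) != g
        ubar = U[mask, g].mean()
        V[mask, g] = 2 * ubar - U[mask, g]
        V[g, mask] = V[mask, g]
        c = ccec(U, V, g)
        assert c < 0
        assert c == pytest.approx(lin_ccc(U[mask, g], V[mask, g]), abs=1e-12)

    def test_never_exceeds_pearson_precision(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            U, V = random_pair(rng, 10)
            g = int(rng.integers(10))
            mask = np.arange(10) != g
            r = np.corrcoef(U[mask, g], V[mask, g])[0, 1]
            assert abs(ccec(U, V, g)) <= abs(r) + 1e-12

    def test_invariant_to_joint_permutation_of_partners(self):
        rng = np.random.default_rng(5)
        U, V = random_pair(rng, 9)
        g = 4
        others = [i for i in range(9) if i != g]
        perm = [g] + list(rng.permutation(others))
        Up = U[np.ix_(perm, perm)]
        Vp = V[np.ix_(perm, perm)]
        assert ccec(Up, Vp, 0) == pytest.approx(ccec(U, V, g), abs=1e-12)

    def test_degenerate_equal_constant_vectors(self):
        U = np.full((4, 4), 0.5)
        np.fill_diagonal(U, 1.0)
        c, deg = ccec_all(U, U.copy())
        assert np.all(c == 0.0) and deg.all()

    def test_pair_container_interface(self):
        rng = np.random.default_rng(6)
        U, V = random_pair(rng, 6)
        pair = CorrelationMatrixPair([f"g{i}" for i in range(6)], U, V)
        assert ccec(pair, 3) == pytest.approx(ccec(U, V, 3), abs=1e-14)


class TestCcecPvalue:
    def test_null_value_gives_one(self):
        assert ccec_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_closed_form_at_half(self):
        # 2 * (1 - Phi(atanh(0.5) * sqrt(101)))
        expect = 2 * stats.norm.sf(np.arctanh(0.5) * np.sqrt(101))
        assert ccec_pvalue(0.5, 103) == pytest.approx(expect, rel=1e-12)
        assert ccec_pvalue(0.5, 103) == pytest.approx(3.3811638e-08, rel=1e-6)

    def test_monotone_in_magnitude_and_m(self):
        assert ccec_pvalue(0.6, 20) < ccec_pvalue(0.4, 20)
        assert ccec_pvalue(0.4, 50) < ccec_pvalue(0.4, 20)
        assert ccec_pvalue(-0.4, 20) == pytest.approx(ccec_pvalue(0.4, 20))

    def test_boundary(self):
        assert ccec_pvalue(1.0, 10) == 0.0


class TestRunCcea:
    def _biomarkers(self, expr, features):
        import pandas as pd
        return pd.DataFrame({
            "feature_id": expr.feature_ids,
            "selected": [f in set(features) for f in expr.feature_ids],
        })

    def test_identical_cohorts_all_selected(self, small_study):
        expr = small_study.pdx_expr
        feats = expr.feature_ids[:10]
        table = run_ccea(expr, expr, self._biomarkers(expr, feats))
        assert table["ccec"].tolist() == pytest.approx([1.0] * 10)
        assert table["selected"].all()

    def test_planted_concordance_enriched(self, small_study):
        """Concordant features must dominate the selected set at >= 4:1 odds
        relative to their share among candidates."""
        bm = discover_biomarkers(small_study.pdx_expr, small_study.activity,
                                 method="pearson", selection="nominal")
        table = run_ccea(small_study.pdx_expr, small_study.patient_ref_expr, bm)
        conc = set(small_study.truth.concordant_feature_ids)
        sel = table.loc[table["selected"], "feature_id"]
        assert len(sel) >= 5
        in_sel = np.mean([f in conc for f in sel])
        in_all = np.mean([f in conc for f in table["feature_id"]])
        odds = (in_sel / (1 - in_sel + 1e-9)) / (in_all / (1 - in_all))
        assert odds >= 4.0

    def test_min_ccec_threshold_nests(self, small_study):
        bm = discover_biomarkers(small_study.pdx_expr, small_study.activity,
                                 method="pearson", selection="nominal")
        loose = run_ccea(small_study.pdx_expr, small_study.patient_ref_expr, bm)
        strict = run_ccea(small_study.pdx_expr, small_study.patient_ref_expr, bm,
                          min_ccec=0.3)
        loose_set = set(loose.loc[loose["selected"], "feature_id"])
        strict_set = set(strict.loc[strict["selected"], "feature_id"])
        assert strict_set <= loose_set

    def test_fdr_monotonicity(self, small_study):
        bm = discover_biomarkers(small_study.pdx_expr, small_study.activity,
                                 method="pearson", selection="nominal")
        tight = run_ccea(small_study.pdx_expr, small_study.patient_ref_expr, bm,
                         fdr=0.01)
        loose = run_ccea(small_study.pdx_expr, small_study.patient_ref_expr, bm,
                         fdr=0.10)
        assert set(tight.loc[tight["selected"], "feature_id"]) <= \
            set(loose.loc[loose["selected"], "feature_id"])

    def test_too_few_candidates_error(self, small_study):
        expr = small_study.pdx_expr
        bm = self._biomarkers(expr, expr.feature_ids[:2])
        with pytest.raises(ValueError, match="at least 3"):
            run_ccea(expr, small_study.patient_ref_expr, bm)

    def test_permutation_pvalues_available(self, small_study):
        expr = small_study.pdx_expr
        feats = expr.feature_ids[:8]
        table = run_ccea(expr, small_study.patient_ref_expr,
                         self._biomarkers(expr, feats),
                         p_method="permutation", n_permutations=99,
                         random_state=0)
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()
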