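import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from ihcflow import (
    ConfigurationError,
    DegenerateInputError,
    agreement_report,
    cohens_kappa,
    fleiss_kappa,
    kcc_chisq,
    kendalls_w,
    latin_design,
    levene_test,
    pearson_correlation,
    percent_concordance_ci,
    reproducibility_kcc,
    two_sample_t,
)
from ihcflow.agreement import contingency_table, format_p


# ---- independent textbook-formula oracles ---------------------------

def kendalls_w_oracle(ratings):
    """Tie-corrected W computed directly from the defining formula."""
    R = np.asarray(ratings, float)
    m, n = R.shape
    ranks = np.array([rankdata(r) for r in R])
    Rj = ranks.sum(axis=0)
    S = ((Rj - Rj.mean()) ** 2).sum()
    T = sum(
        (c**3 - c)
        for row in R
        for c in np.unique(row, return_counts=True)[1]
    )
    return 12 * S / (m**2 * (n**3 - n) - m * T)


def fleiss_kappa_oracle(ratings, k_cat=4):
    """Fleiss kappa from the defining P-bar / P-bar_e proportions."""
    R = np.asarray(ratings, int)
    n_items, n_raters = R.shape
    counts = np.zeros((n_items, k_cat))
    for i in range(n_items):
        for r in R[i]:
            counts[i, r] += 1
    p_cat = counts.sum(axis=0) / (n_items * n_raters)
    P_i = (np.sum(counts**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))
    P_bar, P_e = P_i.mean(), np.sum(p_cat**2)
    return (P_bar - P_e) / (1 - P_e)


class TestKendallsW:
    def test_identical_rankings(self):
        assert kendalls_w([[1, 2, 3, 0, 2, 1], [1, 2, 3, 0, 2, 1]]) == pytest.approx(1.0)

    def test_reversed_untied_rankings(self):
        assert kendalls_w([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]]) == pytest.approx(0.0)

    def test_matches_textbook_formula_with_ties(self, rng):
        for _ in range(20):
            R = rng.integers(0, 4, size=(3, 8))
            if np.all([len(np.unique(r)) == 1 for r in R]):
                continue
            assert kendalls_w(R) == pytest.approx(kendalls_w_oracle(R), abs=1e-12)

    def test_constant_raters_rejected(self):
        with pytest.raises(DegenerateInputError):
            kendalls_w([[2, 2, 2, 2], [1, 1, 1, 1]])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_invariant_to_monotone_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.integers(0, 4, size=(2, 10))
        if all(len(np.unique(r)) == 1 for r in R):
            return
        relabel = np.array([0, 5, 7, 20])  # strictly increasing recode
        assert kendalls_w(relabel[R]) == pytest.approx(kendalls_w(R), abs=1e-12)


class TestKCCChiSquare:
    def test_identity_reproduces_printed_chi2(self):
        """chi2 = m(n-1)W for two raters over 105 cases rounds to the
        reported per-biomarker chi-square values."""
        expected = {0.96: 200, 0.90: 187, 0.95: 198, 0.98: 204}
        for W, printed in expected.items():
            chi2, df, p = kcc_chisq(W, 2, 105)
            assert chi2 == pytest.approx(2 * 104 * W, abs=1e-9)
            assert round(chi2) == printed
            assert df == 104
            assert p < 1e-4

    def test_zero_w(self):
        chi2, df, p = kcc_chisq(0.0, 2, 10)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)


class TestKappa:
    def test_perfect_diagonal(self):
        kappa, _ = cohens_kappa(np.diag([10, 5, 3, 2]))
        assert kappa == pytest.approx(1.0)

    def test_chance_level(self):
        kappa, _ = cohens_kappa([[1, 1], [1, 1]])
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_2x2(self):
        # p_o = 35/50 = 0.7, p_e = (25*30 + 25*20)/50^2 = 0.5 -> kappa 0.4
        kappa, p = cohens_kappa([[20, 5], [10, 15]])
        assert kappa == pytest.approx(0.4, abs=1e-12)
        assert 0 < p < 1

    def test_both_raters_constant_rejected(self):
        table = np.zeros((4, 4))
        table[2, 2] = 30
        with pytest.raises(DegenerateInputError):
            cohens_kappa(table)

    def test_invariant_to_simultaneous_relabeling(self, rng):
        a = rng.integers(0, 4, size=40)
        b = rng.integers(0, 4, size=40)
        perm = rng.permutation(4)
        k1, _ = cohens_kappa(contingency_table(a, b))
        k2, _ = cohens_kappa(contingency_table(perm[a], perm[b]))
        assert k1 == pytest.approx(k2, abs=1e-12)


class TestFleissKappa:
    def test_unanimous_raters(self):
        R = np.array([[0, 0, 0], [2, 2, 2], [3, 3, 3], [1, 1, 1]])
        assert fleiss_kappa(R) == pytest.approx(1.0)

    def test_matches_defining_formula(self, rng):
        for _ in range(10):
            R = rng.integers(0, 4, size=(10, 4))
            assert fleiss_kappa(R) == pytest.approx(fleiss_kappa_oracle(R), abs=1e-10)

    def test_two_rater_special_case(self, rng):
        R = rng.integers(0, 4, size=(30, 2))
        assert fleiss_kappa(R) == pytest.approx(fleiss_kappa_oracle(R), abs=1e-10)

    def test_single_category_rejected(self):
        with pytest.raises(DegenerateInputError):
            fleiss_kappa(np.zeros((5, 3), dtype=int))


class TestConcordanceCI:
    def test_printed_percent(self):
        pct, lo, hi = percent_concordance_ci(103, 105)
        assert round(pct, 1) == 98.1
        assert lo == pytest.approx(93.29, abs=0.01)

    def test_full_agreement_boundary(self):
        pct, lo, hi = percent_concordance_ci(10, 10)
        assert pct == 100.0 and hi == 100.0

    def test_zero_agreement_boundary(self):
        pct, lo, hi = percent_concordance_ci(0, 10)
        assert pct == 0.0 and lo == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(1, 200), st.data())
    def test_ci_contains_point_estimate(self, n, data):
        matches = data.draw(st.integers(0, n))
        pct, lo, hi = percent_concordance_ci(matches, n)
        assert 0.0 <= lo <= pct <= hi <= 100.0


class TestQuantitativeComparisons:
    def test_pearson_perfect_linearity(self, rng):
        x = rng.normal(size=30)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=(2, 50))
        expected = np.cov(x, y, ddof=0)[0, 1] / (np.std(x) * np.std(y))
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_levene_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = levene_test([g, g])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_levene_matches_anova_on_deviations(self, rng):
        """Classic Levene W equals one-way ANOVA F on |x - group mean|."""
        from scipy.stats import f_oneway

        groups = [rng.normal(0, s, size=12) for s in (1.0, 3.0)]
        stat, p = levene_test(groups)
        devs = [np.abs(g - g.mean()) for g in groups]
        f_stat, f_p = f_oneway(*devs)
        assert stat == pytest.approx(f_stat, abs=1e-10)
        assert p == pytest.approx(f_p, abs=1e-10)

    def test_levene_detects_unequal_variance(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1.0, size=50)
            b = rng.normal(0, 10.0, size=50)
            _, p = levene_test([a, b])
            hits += p < 0.05
        assert hits >= 190

    def test_t_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 2.5])
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_t_matches_pooled_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, _ = two_sample_t(x, y)
        assert t == pytest.approx(expected, abs=1e-12)

    def test_t_detects_large_shift(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, size=30)
            y = rng.normal(3, 1, size=30)
            _, p = two_sample_t(x, y)
            hits += p < 0.001
        assert hits >= 198


class TestLatinDesign:
    def test_four_biomarker_square_rows(self):
        d = latin_design(4, "swap4")
        assert d.row_labels(0) == ("ER", "HER2", "PR", "Ki-67")
        assert d.row_labels(1) == ("HER2", "ER", "Ki-67", "PR")
        assert d.row_labels(2) == ("PR", "Ki-67", "ER", "HER2")
        assert d.row_labels(3) == ("Ki-67", "PR", "HER2", "ER")
        assert d.is_valid()

    def test_cyclic_rotation(self):
        d = latin_design(4, "cyclic")
        np.testing.assert_array_equal(d.square[1], [1, 2, 3, 0])
        assert d.is_valid()

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_cyclic_satisfies_latin_property(self, k):
        assert latin_design(k, "cyclic").is_valid()

    def test_swap4_requires_order_four(self):
        with pytest.raises(ConfigurationError):
            latin_design(5, "swap4")


class TestReproducibility:
    def test_identical_slides_give_w_one(self):
        slide = [0, 1, 2, 3, 1, 2]
        mat = np.tile(slide, (4, 1))
        out = reproducibility_kcc({"ER": mat})
        assert out["ER"] == pytest.approx(1.0)

    def test_single_discrepancy_drops_w(self):
        slide = [0, 1, 2, 3, 1, 2]
        mat = np.tile(slide, (4, 1))
        mat[3, 0] = 3
        assert reproducibility_kcc({"ER": mat})["ER"] < 1.0

    def test_tracks_generated_agreement(self, rng):
        """W over simulated repeated slides matches the brute-force formula."""
        for _ in range(100):
            base = rng.integers(0, 4, size=6)
            mat = np.tile(base, (4, 1))
            flip = rng.random(mat.shape) > 0.9
            mat[flip] = rng.integers(0, 4, size=flip.sum())
            if all(len(np.unique(r)) == 1 for r in mat):
                continue
            assert kendalls_w(mat) == pytest.approx(kendalls_w_oracle(mat), abs=1e-12)


class TestAgreementReport:
    def test_chi2_identity_holds(self, rng):
        a = rng.integers(0, 4, size=40)
        b = np.where(rng.random(40) < 0.9, a, rng.integers(0, 4, size=40))
        rep = agreement_report(a, b)
        assert rep.chi2 == pytest.approx(rep.m_raters * (rep.n_cases - 1) * rep.W, abs=1e-9)
        assert rep.ci95[0] <= rep.concordance_pct <= rep.ci95[1]

    def test_p_formatting(self):
        assert format_p(0.5) == "0.5000"
        assert format_p(5e-5) == "<0.0001"
        assert format_p(0.0123) == "0.0123"
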