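"""Fleiss' kappa, per-category collapse, bootstrap CIs, proportion tests."""

import numpy as np
import pytest

import scalafit as sf
from scalafit.agreement import RaterTable, _kappa_value
from scalafit.errors import ParameterError, UndefinedKappaError


def random_table(rng, n_items=None, n_raters=None, n_cats=3):
    n_items = n_items or int(rng.integers(3, 31))
    n_raters = n_raters or int(rng.integers(2, 7))
    assign = rng.integers(0, n_cats, (n_items, n_raters))
    counts = np.stack([(assign == c).sum(axis=1) for c in range(n_cats)], axis=1)
    return RaterTable(counts, tuple(f"c{j}" for j in range(n_cats)))


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        t = RaterTable(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5], [5, 0, 0]]))
        assert sf.fleiss_kappa(t).kappa == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # 3 items, 2 raters: P_i = (1, 1, 0), mean 2/3; p_j = (1/2, 1/2, 0)
        # so P_e = 1/2 and kappa = (2/3 - 1/2) / (1 - 1/2) = 1/3
        t = RaterTable(np.array([[2, 0, 0], [0, 2, 0], [1, 1, 0]]))
        assert sf.fleiss_kappa(t).kappa == pytest.approx(1 / 3, abs=1e-15)

    def test_matches_independent_implementation(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as oracle

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            t = random_table(rng)
            try:
                ours = sf.fleiss_kappa(t).kappa
            except UndefinedKappaError:
                continue
            assert ours == pytest.approx(oracle(t.counts), abs=1e-12)
            checked += 1

    def test_uniform_random_raters_near_zero(self):
        from scalafit.agreement import _asymptotic_ci

        rng = np.random.default_rng(3)
        t = random_table(rng, n_items=400, n_raters=5)
        res = sf.fleiss_kappa(t)
        lo, hi = _asymptotic_ci(t, alpha=0.05)
        se = (hi - lo) / (2 * 1.959963984540054)
        assert abs(res.kappa) < 3 * se

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedKappaError):
            sf.fleiss_kappa(RaterTable(np.array([[3, 0, 0], [3, 0, 0]])))

    def test_invariance_under_relabeling_and_reordering(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, n_items=12, n_raters=4)
        k = sf.fleiss_kappa(t).kappa
        perm_cats = RaterTable(t.counts[:, [2, 0, 1]])
        perm_items = RaterTable(t.counts[::-1])
        assert sf.fleiss_kappa(perm_cats).kappa == pytest.approx(k, abs=1e-15)
        assert sf.fleiss_kappa(perm_items).kappa == pytest.approx(k, abs=1e-15)


class TestPerCategoryKappa:
    def test_perfect_category_amid_shuffled_others(self):
        counts = np.array([
            [3, 1, 0], [2, 2, 0], [1, 3, 0], [4, 0, 0],
            [0, 0, 4], [0, 0, 4],
        ])
        t = RaterTable(counts)
        assert sf.per_category_kappa(t, "SV").kappa == pytest.approx(1.0)
        assert sf.fleiss_kappa(t).kappa < 1.0

    def test_binary_table_collapse_is_identity(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_items=15, n_raters=4, n_cats=2)
        overall = sf.fleiss_kappa(t).kappa
        for cat in t.categories:
            assert sf.per_category_kappa(t, cat).kappa == pytest.approx(
                overall, abs=1e-12)

    def test_hand_worked_collapse(self):
        counts = np.array([[2, 1, 0], [0, 3, 0], [1, 1, 1], [0, 0, 3]])
        t = RaterTable(counts)
        collapsed = np.column_stack([counts[:, 1], counts[:, 0] + counts[:, 2]])
        assert sf.per_category_kappa(t, "INT").kappa == pytest.approx(
            _kappa_value(collapsed), abs=1e-15)

    def test_unknown_category_rejected(self):
        t = RaterTable(np.array([[2, 1, 0], [0, 3, 0]]))
        with pytest.raises(ParameterError):
            sf.per_category_kappa(t, "XX")


class TestKappaCI:
    def test_perfect_agreement_interval_collapses(self):
        t = RaterTable(np.array([[4, 0, 0], [0, 4, 0], [0, 0, 4],
                                 [4, 0, 0], [0, 4, 0]]))
        lo, hi = sf.kappa_ci(t, seed=5)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, n_items=20, n_raters=4)
        assert sf.kappa_ci(t, seed=7) == sf.kappa_ci(t, seed=7)

    def test_too_few_items_refused(self):
        t = RaterTable(np.array([[2, 1, 0], [0, 3, 0], [1, 2, 0]]))
        with pytest.warns(UserWarning, match="too few items"):
            lo, hi = sf.kappa_ci(t)
        assert np.isnan(lo) and np.isnan(hi)

    def test_bootstrap_covers_population_kappa(self):
        """Items agree unanimously with probability q, otherwise at random:
        the large-sample kappa of that mixture should be covered by the
        95% bootstrap interval in >= 90% of simulated tables."""
        rng = np.random.default_rng(2024)
        q, n_raters, n_cats = 0.6, 4, 3

        def draw(n_items, r):
            rows = []
            for _ in range(n_items):
                if r.random() < q:
                    c = r.integers(n_cats)
                    row = np.zeros(n_cats, int)
                    row[c] = n_raters
                else:
                    assign = r.integers(0, n_cats, n_raters)
                    row = np.bincount(assign, minlength=n_cats)
                rows.append(row)
            return np.array(rows)

        pop_kappa = _kappa_value(draw(20000, rng))
        covered = total = 0
        for _ in range(200):
            t = RaterTable(draw(25, rng))
            try:
                lo, hi = sf.kappa_ci(t, seed=int(rng.integers(2 ** 31)),
                                     n_boot=400)
            except Exception:
                continue
            total += 1
            covered += lo <= pop_kappa <= hi
        assert total > 150
        assert covered / total >= 0.90


class TestProportionComparison:
    def test_study_counts_highly_significant(self):
        chi2, p = sf.compare_intermediate_proportions(13, 250, 50, 300)
        assert p < 0.001 and chi2 > 10

    def test_equal_proportions_null(self):
        chi2, p = sf.compare_intermediate_proportions(10, 100, 20, 200)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_pearson_formula(self):
        a, n1, b, n2 = 4, 20, 9, 25
        table = np.array([[a, n1 - a], [b, n2 - b]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        chi2, _ = sf.compare_intermediate_proportions(a, n1, b, n2)
        assert chi2 == pytest.approx(chi2_hand, abs=1e-12)

    def test_symmetry_in_groups(self):
        fwd = sf.compare_intermediate_proportions(13, 250, 50, 300)
        rev = sf.compare_intermediate_proportions(50, 300, 13, 250)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_small_expected_cell_warns(self):
        with pytest.warns(UserWarning, match="expected cell"):
            sf.compare_intermediate_proportions(0, 3, 1, 3)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            sf.compare_intermediate_proportions(5, 3, 1, 10)
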