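import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hsp70evo.clade_stats import (clade_comparison_report, cohens_d,
                                  compact_letter_display, holm_adjust,
                                  kruskal_wallis, pairwise_wilcoxon_holm,
                                  ranksum_p)
from hsp70evo.kaks import CladeKaKsSummary

from oracles import oracle_kruskal_wallis_h


class TestKruskalWallis:
    def test_two_small_groups_match_rank_formula(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)  # 3.857142...
        assert df == 1
        assert p == pytest.approx(float(sps.chi2.sf(27 / 7, 1)))

    def test_identical_groups_collapse_to_zero(self):
        h, df, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert h == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_explicit_ranking_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [list(rng.integers(0, 6, size=rng.integers(2, 8)).astype(float))
                      for _ in range(k)]
            if all(len(set(sum(groups, []))) == 1 for _ in [0]):
                continue
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_kruskal_wallis_h(groups), abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_on_continuous_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [list(rng.normal(size=12)) for _ in range(4)]
        h, df, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        assert ranksum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            x = list(rng.normal(size=int(rng.integers(2, 8))))
            y = list(rng.normal(size=int(rng.integers(2, 8))))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ranksum_p(x, y) == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = list(rng.integers(0, 8, size=15).astype(float))
            y = list(rng.integers(0, 8, size=18).astype(float))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            assert ranksum_p(x, y) == pytest.approx(ref.pvalue, rel=1e-9)

    def test_undersized_group_gives_nan(self):
        assert math.isnan(ranksum_p([1.0], [1.0, 2.0]))


class TestHolm:
    def test_stepdown_arithmetic(self):
        assert holm_adjust([0.01, 0.04, 0.02]) == pytest.approx([0.03, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(30):
            raw = rng.uniform(size=int(rng.integers(2, 10)))
            _, adj, _, _ = multipletests(raw, method="holm")
            assert holm_adjust(list(raw)) == pytest.approx(list(adj))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_order_invariant_and_bounded(self, raw):
        adj = holm_adjust(raw)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= r for a, r in zip(adj, raw))
        perm = list(reversed(range(len(raw))))
        adj_perm = holm_adjust([raw[i] for i in perm])
        assert [adj_perm[perm.index(i)] for i in range(len(raw))] == pytest.approx(adj)


class TestCohensD:
    def test_unit_pooled_sd_closed_form(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_degenerate_variance_flagged_infinite(self):
        assert cohens_d([0, 0], [1, 1]) == math.inf
        assert cohens_d([1, 1], [1, 1]) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        st.floats(0.5, 3.0),
        st.floats(-5, 5),
    )
    def test_symmetric_and_scale_invariant(self, x, y, a, b):
        d1 = cohens_d(x, y)
        assert cohens_d(y, x) == pytest.approx(d1, rel=1e-9, abs=1e-12) or (
            math.isinf(d1) and math.isinf(cohens_d(y, x))
        )
        xs = [a * v + b for v in x]
        ys = [a * v + b for v in y]
        d2 = cohens_d(xs, ys)
        if math.isinf(d1):
            assert math.isinf(d2)
        else:
            assert d2 == pytest.approx(d1, rel=1e-6, abs=1e-9)


class TestLettersAndReport:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(11)
        groups = {
            "g1": list(rng.normal(0, 0.05, size=15)),
            "g2": list(rng.normal(2, 0.05, size=15)),
            "g3": list(rng.normal(4, 0.05, size=15)),
        }
        _, letters = pairwise_wilcoxon_holm(groups)
        assert len({letters[g] for g in groups}) == 3

    def test_shared_list_split_in_two_is_null(self):
        values = [0.1, 0.2, 0.3, 0.4]
        report = clade_comparison_report(
            [CladeKaKsSummary("x", list(values)), CladeKaKsSummary("y", list(values))]
        )
        assert report.effect_sizes.loc["x", "y"] == 0.0
        assert report.adjusted_p.loc["x", "y"] == 1.0
        assert report.letters["x"] == report.letters["y"]

    def test_two_regimes_detected_with_large_effects(self):
        # six clades under two omega regimes: omnibus + large d in >=90% of 50 runs
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(50):
            low = [list(rng.normal(0.05, 0.02, size=20).clip(0.001)) for _ in range(3)]
            high = [list(rng.normal(0.2, 0.05, size=20).clip(0.001)) for _ in range(3)]
            groups = low + high
            _, _, p = kruskal_wallis(groups)
            d = cohens_d(groups[0], groups[3])
            hits += (p < 0.05) and (d > 0.8)
        assert hits >= 45

    def test_single_regime_shares_letters(self):
        # under the null all six clades should usually share a letter
        rng = np.random.default_rng(22)
        hits = 0
        for _ in range(50):
            groups = {f"g{i}": list(rng.normal(0.1, 0.03, size=20)) for i in range(6)}
            _, letters = pairwise_wilcoxon_holm(groups)
            common = set.intersection(*[set(letters[g]) for g in groups])
            hits += bool(common)
        assert hits >= 45

    def test_report_contract_on_fixture_pools(self, family):
        from hsp70evo.kaks import backtranslate, clade_pool, filter_saturated, pairwise_kaks_matrix

        coding = {c.id: c for c in family.codings}
        retained, _ = filter_saturated(
            pairwise_kaks_matrix(backtranslate(family.alignment, coding))
        )
        report = clade_comparison_report(clade_pool(retained, family.clades))
        assert report.kw_df == 3
        labels = list(report.group_sizes)
        assert list(report.adjusted_p.index) == labels
        assert np.allclose(report.adjusted_p.values, report.adjusted_p.values.T)
        assert (np.diag(report.adjusted_p.values) == 1).all()
        assert (report.effect_sizes.values >= 0).all()
        assert set(report.letters) == set(labels)

    def test_fewer_than_two_clades_errors(self):
        with pytest.raises(ValueError):
            clade_comparison_report([CladeKaKsSummary("x", [0.1, 0.2])])
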