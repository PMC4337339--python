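"""Audic-Claverie statistic, FDR adjustment, DEG calling and summaries."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biofilmdge.dge import (AudicClaverieDGE, ac_pmf, ac_two_sided_p,
                            adjust_fdr, call_degs, summarize_stage_counts)


def ac_pmf_rational(y: int, x: int, r: Fraction) -> Fraction:
    """Exact-rational oracle: p(y|x) = r^y C(x+y,y) / (1+r)^(x+y+1)."""
    return (r ** y) * math.comb(x + y, y) / ((1 + r) ** (x + y + 1))


class TestAcPmf:
    def test_equal_depth_zero_counts(self):
        assert ac_pmf(0, 0, 10**6, 10**6) == pytest.approx(0.5)

    def test_equal_depth_one_one(self):
        assert ac_pmf(1, 1, 10**6, 10**6) == pytest.approx(0.25)

    def test_matches_arbitrary_precision_evaluation(self):
        oracle = float(ac_pmf_rational(12, 5, Fraction(2)))
        assert ac_pmf(12, 5, 10**6, 2 * 10**6) == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("x", [0, 1, 10, 100])
    def test_normalizes_over_y(self, x):
        # negative-binomial law: sums to 1; truncation tail is negligible
        y = np.arange(0, 20 * (x + 5))
        total = ac_pmf(y, x, 10**6, 10**6).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    @given(x=st.integers(0, 200), y=st.integers(0, 200))
    @settings(max_examples=150, derandomize=True)
    def test_symmetry_at_equal_depth(self, x, y):
        assert ac_pmf(y, x, 10**6, 10**6) == pytest.approx(
            ac_pmf(x, y, 10**6, 10**6), rel=1e-12)

    def test_agrees_with_negative_binomial(self):
        # independent route: p(y|x) is NB(size x+1, prob N1/(N1+N2))
        x, n1, n2 = 17, 3 * 10**6, 10**7
        y = np.arange(0, 300)
        expected = stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2))
        np.testing.assert_allclose(ac_pmf(y, x, n1, n2), expected, rtol=1e-10)

    def test_numerical_stability_extreme_counts(self):
        val = ac_pmf(10**6, 10**6, 10**9, 10**9)
        assert 0 < val <= 1 and np.isfinite(val)

    @pytest.mark.parametrize("bad", [(-1, 0), (0, -2)])
    def test_negative_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            ac_pmf(bad[0], bad[1], 10**6, 10**6)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            ac_pmf(1, 1, 0, 10**6)


class TestAcTwoSidedP:
    def test_zero_zero_is_one(self):
        assert ac_two_sided_p(0, 0, 10**6, 10**6) == 1.0

    def test_matches_brute_force_tail_summation(self):
        x, y, n = 10, 40, 10**6
        i = np.arange(0, y + 1)
        s = ac_pmf(i, x, n, n).sum()
        expected = min(1.0, 2 * (1 - s + ac_pmf(y, x, n, n))) if s > 0.5 \
            else min(1.0, 2 * s)
        assert ac_two_sided_p(x, y, n, n) == pytest.approx(expected, rel=1e-9)

    @given(x=st.integers(0, 500), y=st.integers(0, 500),
           ratio=st.sampled_from([1, 2, 5]))
    @settings(max_examples=200, derandomize=True)
    def test_in_unit_interval(self, x, y, ratio):
        p = ac_two_sided_p(x, y, 10**6, ratio * 10**6)
        assert 0 < p <= 1

    def test_symmetric_under_extreme_imbalance(self):
        # more counts in the test library than expected -> small p either way
        assert ac_two_sided_p(1000, 10, 10**7, 10**7) < 1e-100
        assert ac_two_sided_p(10, 1000, 10**7, 10**7) < 1e-100

    def test_vectorized_matches_scalar(self):
        x = np.array([0, 3, 10, 250])
        y = np.array([0, 9, 10, 120])
        vec = ac_two_sided_p(x, y, 10**6, 2 * 10**6)
        for xi, yi, pi in zip(x, y, vec):
            assert pi == pytest.approx(ac_two_sided_p(int(xi), int(yi),
                                                      10**6, 2 * 10**6))


class TestAdjustFdr:
    def test_single_value_identity(self):
        assert adjust_fdr([0.03], method="BH")[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_example(self):
        # step-up: all four share min_i (m/i) p_(i) = 0.04
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04], "BH"),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_input_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        adj = adjust_fdr(p, "BH")
        assert list(adj) == [0.04, 0.04, 0.04, 0.04]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_by_dominates_bh_dominates_raw(self, p):
        bh = adjust_fdr(p, "BH")
        by = adjust_fdr(p, "BY")
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= np.asarray(p) - 1e-12)
        assert np.all(by <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5], method="bonferroni")


class TestCallDegs:
    @pytest.mark.parametrize("p_adj,lfc,expected_sig,expected_dir", [
        (0.0005, 1.5, True, "up"),
        (0.0005, -1.5, True, "down"),
        (0.0005, 0.5, False, "none"),   # effect-size gate
        (0.005, 3.0, False, "none"),    # FDR gate
        (0.001, 1.0, True, "up"),       # both cutoffs inclusive
    ])
    def test_gates(self, p_adj, lfc, expected_sig, expected_dir):
        frame = pd.DataFrame({"gene_id": ["g"], "p_adjusted": [p_adj],
                              "log2_ratio": [lfc]})
        out = call_degs(frame)
        assert bool(out["significant"][0]) is expected_sig
        assert out["direction"][0] == expected_dir


class TestSummarizeStageCounts:
    def _table(self, n_up, n_down):
        return pd.DataFrame({
            "significant": [True] * (n_up + n_down),
            "direction": ["up"] * n_up + ["down"] * n_down,
        })

    def test_published_arithmetic(self):
        summary = summarize_stage_counts({
            "FCP_vs_AP": self._table(522, 1576),
            "FCP_vs_BMP": self._table(472, 455),
        }).set_index("comparison")
        assert summary.loc["FCP_vs_AP", "total"] == 2098
        assert summary.loc["FCP_vs_BMP", "total"] == 927

    def test_empty_comparison(self):
        summary = summarize_stage_counts({"a_vs_b": self._table(0, 0)})
        assert summary.iloc[0][["up", "down", "total"]].tolist() == [0, 0, 0]


class TestStatisticalDesign:
    def test_planted_deg_recovery_sensitivity_and_fdp(self):
        """4-fold planted effects at 1e7 depth: sensitivity >= 0.9 and
        realized false-discovery proportion <= 0.01 at the default cutoffs."""
        from biofilmdge.synthetic import SyntheticConfig, simulate_de_experiment

        config = SyntheticConfig(n_genes=20_000,
                                 library_sizes={"lib1": 10**7, "lib2": 10**7},
                                 de_fraction=0.05, effect_sizes=(-2.0, 2.0),
                                 seed=0)
        counts, profiles, truth = simulate_de_experiment(config)
        res = AudicClaverieDGE(counts=counts, profiles=profiles,
                               comparison=("lib1", "lib2")).fit()
        planted = truth.planted_de_genes("lib1_vs_lib2")
        called = res.deg_genes
        sensitivity = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.9, sensitivity
        assert fdp <= 0.01, fdp

    def test_null_p_values_valid_and_near_uniform_at_small_thresholds(self):
        """Under the Poisson null the p-value distribution is sub-uniform at
        every threshold (validity: the exact test never anti-conservative)
        and close to uniform where rejections happen; the distribution is
        discrete, with an atom at p = 1, so exact continuous uniformity is
        not expected."""
        from biofilmdge.synthetic import SyntheticConfig, simulate_de_experiment

        config = SyntheticConfig(n_genes=20_000,
                                 library_sizes={"lib1": 10**7, "lib2": 10**7},
                                 de_fraction=0.0, seed=0)
        counts, _, _ = simulate_de_experiment(config)
        p = ac_two_sided_p(counts["lib1"].to_numpy(),
                           counts["lib2"].to_numpy(), 10**7, 10**7)
        grid = np.array([0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 0.9])
        ecdf = np.array([(p <= t).mean() for t in grid])
        se = np.sqrt(grid * (1 - grid) / p.size)
        assert np.all(ecdf <= grid + 3 * se)          # never anti-conservative
        small = grid <= 0.1
        assert np.all(np.abs(ecdf[small] - grid[small]) <= 0.01)


class TestModelResults:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(7)
        genes = pd.Index([f"g{i}" for i in range(300)], name="gene_id")
        base = rng.integers(20, 2000, size=300)
        counts = pd.DataFrame({"length_nt": rng.integers(300, 4000, size=300),
                               "ctrl": rng.poisson(base),
                               "test": rng.poisson(base)}, index=genes)
        counts.loc["g0", "test"] = counts.loc["g0", "ctrl"] * 20  # one clear DEG
        profiles = pd.DataFrame({"library_id": ["ctrl", "test"],
                                 "stage": ["FCP", "AP"],
                                 "total_reads": [10**6, 10**6]}
                                ).set_index("library_id", drop=False)
        return AudicClaverieDGE.from_dataframe(counts, profiles,
                                               control="ctrl", test="test").fit()

    def test_result_frame_contract(self, fitted):
        f = fitted.frame
        assert list(f.columns[:4]) == ["gene_id", "x", "y", "log2_ratio"]
        assert f["p_raw"].between(0, 1).all()
        assert (f.loc[f["significant"], "direction"] != "none").all()
        assert "g0" in set(f.loc[f["significant"], "gene_id"])

    def test_summary_mentions_comparison_and_counts(self, fitted):
        text = fitted.summary()
        assert "ctrl" in text and "test" in text
        assert f"genes tested:    {fitted.n_genes}" in text

    def test_undeclared_library_rejected(self, fitted):
        with pytest.raises(KeyError):
            AudicClaverieDGE(counts=fitted.model.counts,
                             profiles=fitted.model.profiles,
                             comparison=("ctrl", "nope"))

    def test_recall_at_looser_cutoffs_is_superset(self, fitted):
        strict = set(fitted.frame.loc[fitted.frame["significant"], "gene_id"])
        loose = fitted.call_degs(fdr_cutoff=0.05, lfc_cutoff=0.5)
        loose_set = set(loose.loc[loose["significant"], "gene_id"])
        assert strict <= loose_set
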