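import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from wormtx.de import (
    Contrast,
    DispersionEstimates,
    bh_adjust,
    consensus,
    estimate_dispersions,
    exact_test_nb,
    wald_test,
)
from wormtx.normalization import SizeFactors, size_factors_median_ratio
from wormtx.simulate import SimulationConfig, simulate_counts

from conftest import make_matrix


def unit_factors(matrix):
    return SizeFactors(
        factors=pd.Series(1.0, index=matrix.counts.columns), method="median_ratio"
    )


def zero_dispersions(matrix):
    genes = matrix.counts.index
    return DispersionEstimates(
        raw=pd.Series(0.0, index=genes), a0=0.0, a1=0.0, final=pd.Series(0.0, index=genes)
    )


class TestDispersions:
    def test_constant_gene_has_zero_raw_estimate(self):
        m = make_matrix(
            [[7, 7, 7, 7, 7, 7], [5, 9, 2, 30, 1, 8]],
            [("ecoli", 15)] * 3 + [("ecoli", 25)] * 3,
        )
        d = estimate_dispersions(m, unit_factors(m), [list(m.counts.columns[:3]), list(m.counts.columns[3:])])
        assert d.raw.iloc[0] == 0.0

    def test_poisson_data_yields_near_zero_final(self):
        cfg = SimulationConfig(
            n_genes=2000, class_counts={}, dispersion_a0=0.0, dispersion_a1=0.0, seed=13
        )
        m, _ = simulate_counts(cfg)
        f = size_factors_median_ratio(m)
        d = estimate_dispersions(m, f, list(m.condition_groups().values()))
        assert d.final.median() < 0.01

    def test_constant_dispersion_trend_intercept_recovered(self):
        cfg = SimulationConfig(
            n_genes=2000, class_counts={}, dispersion_a0=0.1, dispersion_a1=0.0, seed=14
        )
        m, _ = simulate_counts(cfg)
        f = size_factors_median_ratio(m)
        d = estimate_dispersions(m, f, list(m.condition_groups().values()))
        assert d.a0 == pytest.approx(0.1, abs=0.03)

    def test_trend_non_increasing_in_mean(self):
        d = DispersionEstimates(
            raw=pd.Series(dtype=float), a0=0.05, a1=5.0, final=pd.Series(dtype=float)
        )
        mus = np.linspace(1, 1000, 50)
        assert (np.diff(d.trend(mus)) <= 0).all()

    def test_single_replicate_everywhere_rejected(self):
        m = make_matrix([[1, 2]], [("ecoli", 15), ("ecoli", 25)])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(m, unit_factors(m), [["ecoli_15_r1"], ["ecoli_25_r1"]])


class TestWald:
    def _contrast(self, m):
        return Contrast.between(m, ("ecoli", 25), ("ecoli", 15))

    def test_identical_groups_null_identity(self):
        m = make_matrix(
            [[10, 20, 30, 10, 20, 30]], [("ecoli", 15)] * 3 + [("ecoli", 25)] * 3
        )
        t = wald_test(m, unit_factors(m), self._contrast(m), zero_dispersions(m))
        assert t["log2fc"].iloc[0] == 0.0
        assert t["p"].iloc[0] == 1.0

    def test_swapping_groups_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 400, size=(40, 6))
        conds = [("ecoli", 15)] * 3 + [("ecoli", 25)] * 3
        m = make_matrix(counts, conds)
        f = unit_factors(m)
        d = estimate_dispersions(m, f, [list(m.counts.columns[:3]), list(m.counts.columns[3:])])
        fwd = wald_test(m, f, Contrast.between(m, ("ecoli", 25), ("ecoli", 15)), d)
        rev = wald_test(m, f, Contrast.between(m, ("ecoli", 15), ("ecoli", 25)), d)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_call_rule_matches_padj_and_sign(self, planted_sim, planted_de):
        _, matrix, _ = planted_sim
        f, d = planted_de["mr"]
        t = wald_test(matrix, f, Contrast.between(matrix, ("ecoli", 25), ("ecoli", 15)), d)
        sig = t["padj"] < 0.05
        assert ((t["call"] == "up") == (sig & (t["log2fc"] > 0))).all()
        assert ((t["call"] == "down") == (sig & (t["log2fc"] < 0))).all()
        assert (t["padj"] >= t["p"] - 1e-15).all()


class TestExactTest:
    def _one_vs_one(self, counts):
        m = make_matrix(counts, [("ecoli", 25), ("ecoli", 15)])
        c = Contrast.between(m, ("ecoli", 25), ("ecoli", 15))
        return exact_test_nb(m, unit_factors(m), c, zero_dispersions(m))

    def test_balanced_split_is_modal_p_one(self):
        t = self._one_vs_one([[5, 5]])
        assert t["p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_split_matches_binomial_enumeration(self):
        # all 10 counts on one side of a fair binomial: p = 2 * (1/2)^10
        t = self._one_vs_one([[10, 0]])
        assert t["p"].iloc[0] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_all_zero_gene_convention(self):
        t = self._one_vs_one([[0, 0]])
        assert t["p"].iloc[0] == 1.0
        assert t["log2fc"].iloc[0] == 0.0

    def test_zero_dispersion_limit_equals_conditional_binomial(self):
        """With alpha=0 the conditional law is Binomial(t, n_a/(n_a+n_b))."""
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 60, size=(25, 5))
        conds = [("ecoli", 25)] * 2 + [("ecoli", 15)] * 3
        m = make_matrix(counts, conds)
        c = Contrast.between(m, ("ecoli", 25), ("ecoli", 15))
        t = exact_test_nb(m, unit_factors(m), c, zero_dispersions(m))
        y_a = counts[:, :2].sum(axis=1)
        tot = counts.sum(axis=1)
        for i in range(25):
            if tot[i] == 0:
                continue
            pmf = binom.pmf(np.arange(tot[i] + 1), tot[i], 2 / 5)
            expected = pmf[pmf <= pmf[y_a[i]] * (1 + 1e-9)].sum()
            assert t["p"].iloc[i] == pytest.approx(min(expected, 1.0), abs=1e-6)

    def test_detects_planted_signal(self, planted_sim, planted_de):
        _, matrix, truth = planted_sim
        f, d = planted_de["tmm"]
        c = Contrast.between(matrix, ("ecoli", 25), ("ecoli", 15))
        t = exact_test_nb(matrix, f, c, d)
        hot = truth.genes_in_class("exclusively_hot")
        strong = truth.expected_means.loc[sorted(hot), "ecoli_15"] > 100
        strong_hot = set(strong.index[strong])
        up = set(t.index[t["call"] == "up"])
        assert len(up & strong_hot) / len(strong_hot) > 0.9


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominate_raw_and_capped(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1).all()


class TestConsensus:
    def _table(self, calls):
        genes = list(calls)
        lfc = [1.0 if c == "up" else (-1.0 if c == "down" else 0.1) for c in calls.values()]
        padj = [0.01 if c in ("up", "down") else 0.5 for c in calls.values()]
        return pd.DataFrame(
            {"log2fc": lfc, "padj": padj}, index=pd.Index(genes, name="gene")
        )

    def test_intersection_rule(self):
        a = self._table({"g1": "up", "g2": "up", "g3": "ns"})
        b = self._table({"g1": "ns", "g2": "up", "g3": "up"})
        up, down = consensus(a, b)
        assert up == {"g2"} and down == set()

    def test_empty_table_absorbs(self):
        a = self._table({"g1": "ns", "g2": "ns"})
        b = self._table({"g1": "up", "g2": "down"})
        assert consensus(a, b) == (set(), set())

    def test_discordant_gene_excluded_from_both(self):
        a = self._table({"g1": "up"})
        b = self._table({"g1": "down"})
        assert consensus(a, b) == (set(), set())

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            consensus(self._table({"g1": "up"}), self._table({"g2": "up"}))

    def test_consensus_subset_of_each_engine(self, planted_sim, planted_de):
        _, matrix, _ = planted_sim
        f_mr, d_mr = planted_de["mr"]
        f_tmm, d_tmm = planted_de["tmm"]
        c = Contrast.between(matrix, ("ecoli", 25), ("ecoli", 15))
        tw = wald_test(matrix, f_mr, c, d_mr)
        te = exact_test_nb(matrix, f_tmm, c, d_tmm)
        up, down = consensus(tw, te)
        up_w = set(tw.index[tw["call"] == "up"])
        up_e = set(te.index[te["call"] == "up"])
        assert up <= up_w and up <= up_e
        assert len(up) <= min(len(up_w), len(up_e))
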