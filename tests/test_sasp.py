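import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovimmune.io import GeneSet
from ovimmune.sasp import (
    all_gene_fraction_diffs,
    analytic_fwer,
    expressed_fraction,
    fraction_set_cdf,
    fraction_test,
)

from conftest import make_counts, two_group_cells


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more likely than observed."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestExpressedFraction:
    def toy(self):
        # gene rows: g0 all-zero; g1 detected 1/4 young and 3/8 old; g2 everywhere
        young = np.array([[0] * 4, [2, 0, 0, 0], [1] * 4])
        old = np.array([[0] * 8, [1, 3, 0, 0, 2, 0, 0, 0], [1] * 8])
        dense = np.hstack([young, old])
        m = make_counts(dense, genes=["g0", "g1", "g2"])
        cells = two_group_cells(m.barcodes, 4)
        return m, cells

    def test_hand_counted_fractions(self):
        m, cells = self.toy()
        out = expressed_fraction(m, cells, "T", GeneSet("s", ("g1",))).iloc[0]
        assert out["frac_young"] == 0.25
        assert out["frac_old"] == 0.375
        assert out["diff"] == pytest.approx(0.125)

    def test_undetected_and_ubiquitous_genes(self):
        m, cells = self.toy()
        out = expressed_fraction(
            m, cells, "T", GeneSet("s", ("g0", "g2"))
        ).set_index("gene")
        assert out.loc["g0", ["frac_young", "frac_old", "diff"]].tolist() == [0, 0, 0]
        assert out.loc["g2", "frac_young"] == 1.0
        assert out.loc["g2", "frac_old"] == 1.0

    def test_cell_type_absent_in_one_age_rejected(self):
        m, cells = self.toy()
        cells.loc[cells["age_group"] == "old", "cell_type"] = "other"
        with pytest.raises(ValueError, match="absent"):
            expressed_fraction(m, cells, "T", GeneSet("s", ("g1",)))


class TestFractionTest:
    def records(self, ky, ny, ko, no):
        return pd.DataFrame(
            [{
                "gene": "g", "cell_type": "T", "k_young": ky, "n_young": ny,
                "k_old": ko, "n_old": no,
                "frac_young": ky / ny, "frac_old": ko / no,
                "diff": ko / no - ky / ny,
            }]
        )

    def test_identical_margins_give_p_one(self):
        out = fraction_test(self.records(5, 10, 5, 10))
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        out = fraction_test(self.records(10, 100, 50, 100))
        oracle = fisher_two_sided_oracle([[50, 50], [10, 90]])
        assert abs(out.loc[0, "p"] - oracle) < 1e-12

    def test_swapping_age_columns_leaves_p_unchanged(self):
        a = fraction_test(self.records(10, 100, 50, 100)).loc[0, "p"]
        b = fraction_test(self.records(50, 100, 10, 100)).loc[0, "p"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_pvalues_super_uniform_and_six_hits_never_seen(self):
        # 200 simulated null 24-gene panels; Fisher exactness keeps
        # P(p < alpha) <= alpha, so >= 6 significant genes is essentially
        # impossible (binomial tail ~1e-9)
        rng = np.random.default_rng(8)
        n_sig_01 = []
        all_p = []
        for _ in range(200):
            ky = rng.binomial(200, 0.3, size=24)
            ko = rng.binomial(200, 0.3, size=24)
            rec = pd.DataFrame(
                {
                    "gene": [f"g{i}" for i in range(24)],
                    "k_young": ky, "n_young": 200,
                    "k_old": ko, "n_old": 200,
                }
            )
            out = fraction_test(rec, alpha=0.01)
            n_sig_01.append(int(out["significant"].sum()))
            all_p.extend(out["p"].tolist())
        assert max(n_sig_01) < 6
        all_p = np.asarray(all_p)
        assert (all_p < 0.05).mean() <= 0.06
        assert (all_p < 0.01).mean() <= 0.015


class TestFractionSetCDF:
    def test_whole_universe_gives_zero_statistic(self):
        rng = np.random.default_rng(1)
        diffs = pd.Series(
            rng.normal(0, 0.05, size=100), index=[f"g{i}" for i in range(100)]
        )
        res = fraction_set_cdf(diffs, GeneSet("all", tuple(diffs.index)),
                               n_resample=200, seed=0)
        assert res.ks_D == 0.0

    def test_same_seed_gives_identical_percentile(self):
        rng = np.random.default_rng(2)
        diffs = pd.Series(
            rng.normal(0, 0.05, size=300), index=[f"g{i}" for i in range(300)]
        )
        gs = GeneSet("s", tuple(diffs.index[:24]))
        a = fraction_set_cdf(diffs, gs, n_resample=300, seed=9)
        b = fraction_set_cdf(diffs, gs, n_resample=300, seed=9)
        assert a.null_percentile == b.null_percentile

    def test_single_gene_set_rejected(self):
        diffs = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            fraction_set_cdf(diffs, GeneSet("s", ("a",)), n_resample=10, seed=0)

    def test_elevated_set_detected_in_simulated_counts(self):
        from ovimmune.simulate import SimConfig, simulate_counts
        from ovimmune.io import concat_cells

        genes = tuple(f"G{i:05d}" for i in range(24))
        cfg = SimConfig(
            n_cell_types=1,
            cells_per_type_young=(500,),
            cells_per_type_old=(500,),
            n_genes=500,
            seed=6,
            fraction_spec=tuple(("CT00", g, 0.3, 0.5) for g in genes),
        )
        young, old, cells = simulate_counts(cfg)
        combined = concat_cells(young, old)
        diffs = all_gene_fraction_diffs(combined, cells, "CT00")
        res = fraction_set_cdf(diffs, GeneSet("sasp", genes), n_resample=1000, seed=1)
        assert res.ks_p < 0.01
        assert res.null_percentile > 0.95


class TestAnalyticFWER:
    def test_six_of_24_at_alpha_01_designated_is_1e_minus_12(self):
        res = analytic_fwer(6, 24, 0.01)
        assert res.fwer_designated == pytest.approx(1e-12, rel=1e-9)

    def test_k_zero_gives_certainty(self):
        res = analytic_fwer(0, 24, 0.01)
        assert res.fwer_designated == 1.0
        assert res.fwer_tail == 1.0

    def test_single_gene_single_test_equals_alpha(self):
        res = analytic_fwer(1, 1, 0.01)
        assert res.fwer_designated == pytest.approx(0.01)
        assert res.fwer_tail == pytest.approx(0.01)

    def test_tail_matches_exhaustive_binomial_sum(self):
        for k, n, alpha in [(6, 24, 0.01), (3, 24, 0.05), (2, 10, 0.1)]:
            res = analytic_fwer(k, n, alpha)
            oracle = sum(
                math.comb(n, j) * alpha**j * (1 - alpha) ** (n - j)
                for j in range(k, n + 1)
            )
            assert abs(res.fwer_tail - oracle) <= 1e-15 * oracle

    def test_monotonicity_properties(self):
        # increasing in alpha and n; decreasing in k
        alphas = [0.001, 0.01, 0.05, 0.2]
        tails = [analytic_fwer(4, 24, a).fwer_tail for a in alphas]
        assert np.all(np.diff(tails) > 0)
        ns = [10, 24, 50, 100]
        tails = [analytic_fwer(4, n, 0.01).fwer_tail for n in ns]
        assert np.all(np.diff(tails) > 0)
        ks = [1, 2, 4, 8]
        tails = [analytic_fwer(k, 24, 0.01).fwer_tail for k in ks]
        assert np.all(np.diff(tails) < 0)
        assert all(
            analytic_fwer(k, 24, 0.01).fwer_tail
            >= analytic_fwer(k, 24, 0.01).fwer_designated
            for k in ks
        )

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            analytic_fwer(25, 24, 0.01)
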