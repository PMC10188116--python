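import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ovimmune.de import (
    call_degs,
    classify_terms,
    estimate_pi0,
    fold_change,
    storey_q,
    t_test,
    tail_restricted_degs,
)

from conftest import make_counts, make_norm, two_group_cells


def pooled_t_oracle(a, b):
    """Textbook two-sample pooled-variance t-test, two-tailed."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestFoldChange:
    def test_identical_groups_give_unit_fold(self):
        vals = np.tile([[1.0], [2.0], [0.5]], (1, 6))
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 3)
        fc = fold_change(norm, cells, "T")
        assert np.allclose(fc, 1.0)

    def test_doubled_old_means_give_fold_two(self):
        vals = np.hstack([np.full((4, 3), 1.0), np.full((4, 3), 2.0)])
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 3)
        fc = fold_change(norm, cells, "T")
        assert np.allclose(fc, 2.0, rtol=1e-6)

    def test_planted_quarter_fold_recovered_on_raw_scale(self):
        from ovimmune.simulate import SimConfig, simulate_counts
        from ovimmune.io import concat_cells

        cfg = SimConfig(
            n_cell_types=1,
            cells_per_type_young=(1000,),
            cells_per_type_old=(1000,),
            n_genes=50,
            baseline_mean=1.0,
            seed=17,
            de_spec=(("CT00", "G00000", 0.25),),
        )
        young, old, cells = simulate_counts(cfg)
        combined = concat_cells(young, old)
        fc = fold_change(combined, cells.assign(cell_type="CT00"), "CT00")
        assert abs(fc["G00000"] - 0.25) / 0.25 < 0.20

    def test_type_with_too_few_cells_rejected(self):
        norm = make_norm(np.ones((2, 3)))
        cells = two_group_cells(norm.barcodes, 1)
        with pytest.raises(ValueError, match="2 cells"):
            fold_change(norm, cells, "T")


class TestTTest:
    def test_equal_means_give_p_one(self):
        vals = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 3)
        p = t_test(norm, cells, "T")
        assert p.iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        young = [5.0, 6.0, 5.0, 6.0]
        old = [0.0, 0.0, 0.0, 1.0]
        vals = np.array([young + old])
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 4)
        p = t_test(norm, cells, "T")
        assert abs(p.iloc[0] - pooled_t_oracle(old, young)) < 1e-10

    def test_invariant_under_group_label_swap(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, size=(5, 10)).clip(min=0)
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 5)
        swapped = cells.copy()
        swapped["age_group"] = swapped["age_group"].map(
            {"young": "old", "old": "young"}
        )
        assert np.allclose(t_test(norm, cells, "T"), t_test(norm, swapped, "T"))

    def test_zero_variance_both_groups_gives_p_one(self):
        vals = np.array([[2.0] * 6, [2.0, 2.0, 3.0, 5.0, 5.0, 6.0]])
        norm = make_norm(vals)
        cells = two_group_cells(norm.barcodes, 3)
        p = t_test(norm, cells, "T")
        assert p.iloc[0] == 1.0
        assert p.iloc[1] < 0.01


class TestStoreyQ:
    def test_equals_bh_when_pi0_fixed_at_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = storey_q(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_uniform_grid_estimates_pi0_near_one(self):
        p = np.arange(0.01, 1.001, 0.01)
        pi0 = estimate_pi0(p)
        assert 0.85 <= pi0 <= 1.0
        q = storey_q(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, pi0 * bh, atol=1e-9)

    def test_all_unit_pvalues_give_q_equal_pi0(self):
        q = storey_q(np.ones(20), pi0=0.7)
        assert np.allclose(q, 0.7)

    def test_monotone_nondecreasing_in_p(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.beta(0.5, 3, size=rng.integers(10, 200))
            q = storey_q(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_calibrated_on_uniform_null(self):
        rng = np.random.default_rng(3)
        estimates = [estimate_pi0(rng.uniform(size=10000)) for _ in range(50)]
        assert 0.9 <= np.mean(estimates) <= 1.1

    def test_small_input_falls_back_to_bh(self):
        p = np.array([0.01, 0.5, 0.9])
        q = storey_q(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_q(np.array([0.5, 1.2]))


class TestCallDegs:
    def make(self, fc, p, q):
        idx = pd.Index([f"g{i}" for i in range(len(fc))], name="gene")
        return call_degs(
            pd.Series(fc, index=idx), pd.Series(p, index=idx), np.asarray(q)
        )

    def test_threshold_conjunction(self):
        out = self.make([2.5, 1.5, 3.0, 0.4], [0.01, 0.001, 0.04, 0.02],
                        [0.05, 0.001, 0.2, 0.08])
        assert out["is_deg"].tolist() == [True, False, False, True]
        assert out["direction"].tolist() == ["up", "none", "up", "down"]

    def test_direction_reflects_fold_only(self):
        out = self.make([4.0], [0.9], [0.9])
        assert out.loc[0, "direction"] == "up"
        assert not out.loc[0, "is_deg"]


class TestTailRestriction:
    def test_thousand_distinct_folds_flag_25_per_tail(self):
        rng = np.random.default_rng(5)
        fc = rng.lognormal(0, 0.5, size=1000)
        records = pd.DataFrame({"gene": range(1000), "fc": fc})
        out = tail_restricted_degs(records)
        low = out.loc[out["fc"] <= np.median(fc), "in_tail"].sum()
        high = out.loc[out["fc"] > np.median(fc), "in_tail"].sum()
        assert low == 25 and high == 25

    def test_degenerate_distribution_flags_none(self):
        records = pd.DataFrame({"gene": range(10), "fc": [1.0] * 10})
        assert not tail_restricted_degs(records)["in_tail"].any()

    def test_minimum_fold_always_in_tail_when_distinct(self):
        rng = np.random.default_rng(6)
        fc = rng.uniform(0.1, 10, size=50)
        records = pd.DataFrame({"gene": range(50), "fc": fc})
        out = tail_restricted_degs(records)
        assert bool(out.loc[out["fc"].idxmin(), "in_tail"])


class TestClassifyTerms:
    def test_shared_term_is_global(self):
        lists = pd.DataFrame(
            {
                "cell_type": ["Mph", "DC", "Mph"],
                "term": ["GO:1", "GO:1", "GO:2"],
                "direction": ["down", "down", "down"],
            }
        )
        out = classify_terms(lists).set_index("term")
        assert out.loc["GO:1", "label"] == "global"
        assert out.loc["GO:1", "n_cell_types"] == 2
        assert out.loc["GO:2", "label"] == "specific"

    def test_same_term_different_directions_counted_separately(self):
        lists = pd.DataFrame(
            {
                "cell_type": ["Mph", "DC"],
                "term": ["GO:1", "GO:1"],
                "direction": ["down", "up"],
            }
        )
        out = classify_terms(lists)
        assert (out["label"] == "specific").all()

    def test_empty_input_gives_empty_output(self):
        assert classify_terms(pd.DataFrame(columns=["cell_type", "term", "direction"])).empty
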