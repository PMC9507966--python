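import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hp5kit.differential import (
    class_comparison,
    expression_filter,
    matched_pairs_rank_biserial,
    median_of_ratios,
    prefilter_usage,
    select_alternative_tss,
    shrink_log2fc,
    stagewise_adjust,
)
from hp5kit.differential import test_differential_expression as nb_wald_de
from hp5kit.differential import test_usage as dm_usage_test

COLS = [f"A_rep{i}" for i in (1, 2, 3)] + [f"B_rep{i}" for i in (1, 2, 3)]
CONDS = pd.Series({c: c[0] for c in COLS})


class TestPrefilter:
    def _counts(self, rows, genes):
        df = pd.DataFrame(rows, columns=COLS[:len(rows[0])],
                          index=[f"t{i}" for i in range(len(rows))])
        return df, pd.Series(genes, index=df.index)

    def test_feature_thresholds_as_printed(self):
        # TSS with counts {5,5} of gene totals {50,50} -> kept
        counts, genes = self._counts(
            [[5, 5], [45, 45]], ["g", "g"])
        kept, kept_genes = prefilter_usage(counts, genes)
        assert "t0" in kept and "t1" in kept and "g" in kept_genes

    def test_low_proportion_everywhere_dropped(self):
        counts, genes = self._counts(
            [[4, 4, 4], [96, 96, 96]], ["g", "g"])
        kept, kept_genes = prefilter_usage(counts, genes)
        # 4% proportion fails min_feature_prop = 0.05 -> t0 out, gene degenerate
        assert len(kept) == 0 and len(kept_genes) == 0

    def test_gene_totals_below_twenty_dropped(self):
        counts, genes = self._counts(
            [[10, 10, 10], [9, 9, 9]], ["g", "g"])
        kept, kept_genes = prefilter_usage(counts, genes)
        assert len(kept_genes) == 0

    def test_expression_filter_more_than_one_sample(self):
        mat = pd.DataFrame({"s1": [20, 20], "s2": [19, 20], "s3": [0, 0]},
                           index=["g1", "g2"])
        kept = expression_filter(mat)
        assert list(kept) == ["g2"]


class TestUsage:
    def test_two_tss_per_tss_p_values_equal(self, rng):
        x = np.stack([rng.multinomial(400, [0.4, 0.6]) for _ in range(6)], axis=1)
        counts = pd.DataFrame(x, columns=COLS, index=["t1", "t2"])
        r = dm_usage_test(counts, CONDS)
        assert r.p_tss["t1"] == pytest.approx(r.p_tss["t2"], rel=1e-6)

    def test_planted_shift_detected(self, rng):
        x = np.stack(
            [rng.multinomial(1000, [0.3, 0.7]) for _ in range(3)]
            + [rng.multinomial(1000, [0.7, 0.3]) for _ in range(3)], axis=1)
        counts = pd.DataFrame(x, columns=COLS, index=["t1", "t2"])
        assert dm_usage_test(counts, CONDS).p_gene < 1e-3

    def test_null_p_values_roughly_uniform(self, rng):
        """Small-scale calibration check of the gene-level LRT (the full
        2,000-gene run lives in the acceptance suite)."""
        ps = []
        for _ in range(200):
            pi = 0.5 * rng.dirichlet(np.ones(3)) + 0.5 / 3
            x = np.stack([rng.multinomial(500, pi) for _ in range(6)], axis=1)
            counts = pd.DataFrame(x, columns=COLS,
                                  index=["t1", "t2", "t3"])
            ps.append(dm_usage_test(counts, CONDS).p_gene)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_tss_rejected(self):
        counts = pd.DataFrame([[10] * 6], columns=COLS, index=["t1"])
        with pytest.raises(ValueError, match="2 TSS"):
            dm_usage_test(counts, CONDS)

    def test_proportions_shrunk_by_uniform_pseudoprofile(self):
        counts = pd.DataFrame([[100, 100, 100, 0, 0, 0],
                               [0, 0, 0, 100, 100, 100]],
                              columns=COLS, index=["t1", "t2"])
        r = dm_usage_test(counts, CONDS)
        # one pseudo-read per TSS keeps zero proportions strictly positive
        assert (r.proportions > 0).all().all()
        assert r.proportions["A"].sum() == pytest.approx(1.0)


class TestStagewise:
    def test_all_ones_no_discoveries(self):
        gene_p = pd.Series({"g1": 1.0, "g2": 1.0})
        tss_p = pd.Series({"t1": 1.0, "t2": 1.0})
        tg = pd.Series({"t1": "g1", "t2": "g2"})
        gq, tq = stagewise_adjust(gene_p, tss_p, tg)
        assert (tq == 1.0).all()

    def test_single_strong_gene_among_nulls_discovered(self, rng):
        gene_p = pd.Series({f"g{i}": p for i, p in
                            enumerate(rng.uniform(0.2, 1, 99))})
        gene_p["hit"] = 1e-9
        tss_p = pd.Series({"t_hit": 1e-9, "t_null": 0.9})
        tg = pd.Series({"t_hit": "hit", "t_null": "hit"})
        gq, tq = stagewise_adjust(gene_p, tss_p, tg)
        assert tq["t_hit"] < 0.1
        assert tq["t_null"] > 0.1

    def test_no_discovery_outside_screened_genes(self, rng):
        gene_p = pd.Series(rng.uniform(0, 1, 50), index=[f"g{i}" for i in range(50)])
        tss_p = pd.Series(rng.uniform(0, 1e-8, 100),
                          index=[f"t{i}" for i in range(100)])
        tg = pd.Series([f"g{i % 50}" for i in range(100)], index=tss_p.index)
        gq, tq = stagewise_adjust(gene_p, tss_p, tg)
        screened = set(gq.index[gq <= 0.1])
        for t in tq.index[tq < 1.0]:
            assert tg[t] in screened

    def test_tss_q_never_below_gene_q(self, rng):
        gene_p = pd.Series(rng.uniform(0, 0.2, 20), index=[f"g{i}" for i in range(20)])
        tss_p = pd.Series(rng.uniform(0, 1, 60), index=[f"t{i}" for i in range(60)])
        tg = pd.Series([f"g{i % 20}" for i in range(60)], index=tss_p.index)
        gq, tq = stagewise_adjust(gene_p, tss_p, tg)
        for t in tq.index:
            assert tq[t] >= gq[tg[t]] - 1e-12

    def test_q_monotone_in_p_within_gene(self, rng):
        gene_p = pd.Series({"g": 1e-6})
        tss_p = pd.Series(rng.uniform(0, 1, 8),
                          index=[f"t{i}" for i in range(8)])
        tg = pd.Series("g", index=tss_p.index)
        _, tq = stagewise_adjust(gene_p, tss_p, tg)
        order = tss_p.sort_values().index
        assert (tq[order].diff().dropna() >= -1e-12).all()


class TestShrinkage:
    def test_shrunken_never_exceeds_raw_magnitude(self, rng):
        fc = pd.Series(rng.normal(0, 2, 50))
        se = pd.Series(rng.uniform(0.1, 1, 50))
        shrunk, sd = shrink_log2fc(fc, se)
        assert (shrunk.abs() <= fc.abs() + 1e-12).all()
        assert (sd > 0).all()

    def test_noisy_estimates_shrunk_harder(self):
        fc = pd.Series([2.0, 2.0])
        se = pd.Series([0.1, 2.0])
        shrunk, _ = shrink_log2fc(fc, se)
        assert abs(shrunk.iloc[1]) < abs(shrunk.iloc[0])


class TestSelectAlternative:
    def _table(self, **overrides):
        base = dict(
            tss_id=["t1", "t2", "t3"],
            gene_id=["g", "g", "g"],
            q=[0.01, 0.02, 0.5],
            shrunk_lfc=[2.0, -1.2, 0.1],
            shrunk_sd=[0.1, 0.1, 0.1],
            prop_ref=[0.2, 0.3, 0.5],
            prop_alt=[0.5, 0.2, 0.3],
        )
        base.update(overrides)
        return pd.DataFrame(base)

    def test_largest_abs_fold_change_wins(self):
        res = select_alternative_tss(self._table()).iloc[0]
        assert res["alternative_tss"] == "t1"
        assert res["base_tss"] == "t3"

    def test_prop_change_exactly_five_percent_fails(self):
        t = self._table(prop_alt=[0.25, 0.2, 0.3])  # delta = 0.05 exactly
        res = select_alternative_tss(t).iloc[0]
        assert not res["passes_stringency"]

    def test_overlapping_cis_fail_stringency(self):
        t = self._table(shrunk_lfc=[2.0, -1.2, 1.9], shrunk_sd=[1.0, 0.1, 1.0])
        res = select_alternative_tss(t).iloc[0]
        assert not res["passes_stringency"]

    def test_disjoint_cis_large_change_passes(self):
        res = select_alternative_tss(self._table()).iloc[0]
        assert res["passes_stringency"]

    def test_base_reassigned_when_equal_to_alternative(self):
        t = self._table(prop_ref=[0.6, 0.3, 0.1])  # base would be t1 == alt
        res = select_alternative_tss(t).iloc[0]
        assert res["base_tss"] == "t2"
        assert "reassigned" in res["note"]

    def test_invariant_to_row_order(self, rng):
        t = self._table()
        res1 = select_alternative_tss(t)
        res2 = select_alternative_tss(t.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(res1, res2)


class TestDifferentialExpression:
    def test_exact_threshold_fold_change_not_called(self):
        rngloc = np.random.default_rng(4)
        base = rngloc.integers(50, 500, 200).astype(float)
        rows = np.stack([np.repeat(base[:, None], 6, axis=1)])[0]
        counts = pd.DataFrame(rows, columns=COLS,
                              index=[f"g{i}" for i in range(200)])
        # one gene at exactly 1.5-fold with huge counts
        counts.loc["g0"] = [4000, 4000, 4000, 6000, 6000, 6000]
        res = nb_wald_de(counts, CONDS)
        assert res.loc["g0", "log2fc"] == pytest.approx(np.log2(1.5), abs=1e-6)
        assert res.loc["g0", "call"] == "ns"  # strict >

    def test_all_zero_gene_skipped(self):
        counts = pd.DataFrame(
            {c: [0, 100] for c in COLS}, index=["dead", "alive"])
        res = nb_wald_de(counts, CONDS)
        assert res.loc["dead", "call"] == "skipped"

    def test_planted_fold_changes_recovered(self, rng):
        mus = rng.lognormal(np.log(200), 0.5, 300)
        fcs = np.ones(300)
        fcs[:30] = 4.0
        rows = [np.concatenate([rng.poisson(m, 3), rng.poisson(m * f, 3)])
                for m, f in zip(mus, fcs)]
        counts = pd.DataFrame(rows, columns=COLS,
                              index=[f"g{i}" for i in range(300)])
        res = nb_wald_de(counts, CONDS)
        called = res["call"] == "up"
        assert called[:30].mean() >= 0.9


class TestMedianOfRatios:
    def test_depth_recovered(self, rng):
        base = rng.lognormal(5, 1, 300)
        counts = pd.DataFrame({
            "a": rng.poisson(base), "b": rng.poisson(3 * base)})
        sf = median_of_ratios(counts)
        assert sf["b"] / sf["a"] == pytest.approx(3.0, rel=0.05)


class TestClassComparison:
    def test_all_positive_pairs_r_plus_one(self):
        x = np.array([3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0])
        assert matched_pairs_rank_biserial(x, y) == 1.0

    def test_all_negative_pairs_r_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.0, 4.0, 5.0])
        assert matched_pairs_rank_biserial(x, y) == -1.0

    def test_signed_ranks_cancel_to_zero(self):
        # differences +1, +2, -3 -> (3 - 3) / 6 = 0
        x = np.array([1.0, 2.0, 0.0])
        y = np.array([0.0, 0.0, 3.0])
        assert matched_pairs_rank_biserial(x, y) == 0.0

    def test_paired_and_unpaired_families_holm_adjusted(self, rng):
        values = {
            "up": rng.normal(1, 1, 30),
            "down": rng.normal(-1, 1, 30),
            "ref": rng.normal(0, 1, 30),
        }
        res = class_comparison(values, reference="ref")
        assert set(res["class"]) == {"up", "down"}
        assert (res["p_holm"] >= res["p"] - 1e-12).all()
        paired = class_comparison(
            {"x": values["up"], "ref": values["ref"]}, reference="ref",
            paired=True)
        assert -1 <= paired["effect_size"].iloc[0] <= 1

    def test_tiny_class_skipped(self):
        res = class_comparison({"tiny": [1.0], "ref": [0.0, 1.0, 2.0]},
                               reference="ref")
        assert res.loc[res["class"] == "tiny", "skipped"].iloc[0] != ""


class TestPolysomeShift:
    def test_nonsignificant_genes_unclassified(self, rng):
        from hp5kit.benchmarks import _polysome_cohort
        counts, samples = _polysome_cohort(rng, 60, [False] * 60)
        from hp5kit.differential import test_polysome_shift
        res = test_polysome_shift(counts, samples)
        assert (res.loc[res["fdr"] >= 0.1, "class"] == "unclassified").all()

    def test_planted_shift_significant_and_hypersensitive(self, rng):
        from hp5kit.benchmarks import _polysome_cohort
        from hp5kit.differential import test_polysome_shift
        flags = [i < 5 for i in range(80)]
        counts, samples = _polysome_cohort(rng, 80, flags)
        res = test_polysome_shift(counts, samples)
        planted = res.iloc[:5]
        assert (planted["fdr"] < 0.1).all()
        assert (planted["class"] == "hypersensitive").all()


class TestIsoformVsRest:
    def _gene(self, rng, mrl_iso, mrl_rest, n_genes=40):
        from hp5kit.synthetic_data import fraction_weights
        cols = [f"{c}_rep{r}_f{f}" for c in "A" for r in (1, 2, 3)
                for f in range(1, 9)]
        samples = pd.DataFrame(
            [dict(sample=s, condition="A",
                  replicate=int(s.split("_rep")[1][0]),
                  fraction=int(s.split("_f")[1])) for s in cols])
        iso_rows, rest_rows = [], []
        for g in range(n_genes):
            mi = mrl_iso if g == 0 else rng.uniform(2, 7)
            mr = mrl_rest if g == 0 else mi
            yi, yr = {}, {}
            for r in (1, 2, 3):
                pi = rng.dirichlet(np.array(fraction_weights(mi)) / 0.002)
                pr = rng.dirichlet(np.array(fraction_weights(mr)) / 0.002)
                for f in range(1, 9):
                    s = f"A_rep{r}_f{f}"
                    yi[s] = rng.poisson(500 * pi[f - 1] * 8)
                    yr[s] = rng.poisson(2000 * pr[f - 1] * 8)
            iso_rows.append(yi)
            rest_rows.append(yr)
        iso = pd.DataFrame(iso_rows, columns=cols)
        rest = pd.DataFrame(rest_rows, columns=cols)
        sf = pd.Series(1.0, index=cols)
        return iso, rest, samples, sf

    def test_divergent_isoform_detected_null_isoforms_not(self, rng):
        from hp5kit.differential import test_isoform_vs_rest
        iso, rest, samples, sf = self._gene(rng, mrl_iso=2.0, mrl_rest=6.0)
        res = test_isoform_vs_rest(iso, rest, samples, sf)
        assert res["p"].iloc[0] < 1e-4  # planted divergent isoform
        assert (res["p"].iloc[1:] < 0.001).mean() < 0.1  # matched isoforms
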