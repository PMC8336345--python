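"""Association statistics: Fisher exact, FDR, meta-analysis, burden and
enrichment permutation tests, chi-square power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

from cnvrassoc import (
    CnvCall,
    Gene,
    GeneSet,
    burden_test,
    bh_adjust,
    cnv_enrichment_test,
    cnvr_association,
    fisher_combine,
    fisher_exact_two_tailed,
    meta_analyse,
    power_chi2_gof,
    sample_cnv_summaries,
)
from cnvrassoc.types import Cnvr


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher exact by full hypergeometric enumeration."""
    r1, n = a + b, a + b + c + d
    c1 = a + c

    def table_p(x):
        return (
            comb(c1, x, exact=True)
            * comb(n - c1, r1 - x, exact=True)
            / comb(n, r1, exact=True)
        )

    observed = table_p(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = table_p(x)
        if p <= observed * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestFisherExact:
    def test_severe_case_only_table(self):
        # 47/584 cases vs 0/655 controls (an 8.05% vs 0% contrast)
        assert fisher_exact_two_tailed(47, 537, 0, 655) == pytest.approx(
            1.60e-16, rel=0.05
        )

    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_tailed(1, 1, 1, 1) == 1.0
        assert fisher_exact_two_tailed(2, 3, 3, 2) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(0, 0, 0, 0)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9
        )


class TestBhAdjust:
    def test_monotone_ladder_collapses(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=50))
    def test_step_up_properties(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # adjusted values are non-decreasing in the order of sorted raw p
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCnvrAssociation:
    def test_published_deletion_contrast_pvalue(self):
        """49/131 vs 19/121 carriers gives p = 1.15e-4."""
        cnvr = Cnvr(13, 32_912_236, 32_921_033, "loss", set())
        (rec,) = cnvr_association([cnvr], [(49, 82, 19, 102)])
        assert rec.p_value == pytest.approx(1.15e-4, rel=0.01)
        assert rec.fdr_adjusted_p == rec.p_value  # single test

    def test_records_sorted_and_adjusted(self):
        cnvrs = [Cnvr(1, i * 1000, i * 1000 + 100, "loss", set()) for i in range(3)]
        counts = [(10, 90, 1, 99), (5, 95, 5, 95), (30, 70, 2, 98)]
        recs = cnvr_association(cnvrs, counts)
        assert recs[0].p_value <= recs[1].p_value <= recs[2].p_value
        for r in recs:
            assert r.fdr_adjusted_p >= r.p_value

    def test_empty_input(self):
        assert cnvr_association([], []) == []


class TestFisherCombine:
    def test_single_p_is_identity(self):
        for p in (0.5, 0.05, 1e-6):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_closed_form_two_studies(self):
        # k=2: combined p = exp(-X/2) (1 + X/2)
        x = -4 * np.log(0.05)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(
            np.exp(-x / 2) * (1 + x / 2), rel=1e-9
        )

    def test_monotone_in_each_argument(self):
        base = fisher_combine([0.01, 0.2])
        assert fisher_combine([0.02, 0.2]) > base
        assert fisher_combine([0.01, 0.3]) > base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.1])
        with pytest.raises(ValueError):
            fisher_combine([])


class TestMetaAnalyse:
    def test_shared_genes_combined(self):
        a = {"BRCA2": [("loss", 1.15e-4)], "ONLY_A": [("loss", 0.01)]}
        b = {"BRCA2": [("gain", 9.58e-13), ("loss", 9.27e-3)]}
        (rec,) = meta_analyse([a, b])
        assert rec.gene == "BRCA2"
        assert rec.combined_p == pytest.approx(
            fisher_combine([1.15e-4, 9.58e-13, 9.27e-3])
        )

    def test_combination_beats_each_study_when_both_small(self):
        a = {"G": [("loss", 0.03)]}
        b = {"G": [("loss", 0.04)]}
        (rec,) = meta_analyse([a, b])
        assert rec.combined_p < 0.03 and rec.combined_p < 0.04

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            meta_analyse([{"G": [("loss", 0.1)]}])


def _summaries(case_counts, control_counts):
    rows = {}
    for i, k in enumerate(case_counts):
        rows[f"case{i}"] = k
    for i, k in enumerate(control_counts):
        rows[f"ctrl{i}"] = k
    df = pd.DataFrame(
        {
            "n_cnvs": list(rows.values()),
            "has_cnv": [float(v > 0) for v in rows.values()],
            "total_kb": [v * 10.0 for v in rows.values()],
        },
        index=list(rows.keys()),
    )
    phenos = {s: ("case" if s.startswith("case") else "control") for s in rows}
    return df, phenos


class TestBurdenTest:
    def test_exchangeable_groups_not_significant(self):
        df, phenos = _summaries([5, 3, 2, 4], [4, 2, 3, 5])
        res = burden_test(df, phenos, n_perm=2000, seed=1)
        for m in res.metrics:
            assert res.p_value[m] >= 0.5

    def test_extreme_burden_contrast_detected(self):
        df, phenos = _summaries([5] * 20, [0] * 20)
        res = burden_test(df, phenos, n_perm=10_000, seed=2)
        assert res.p_value["n_cnvs"] <= 0.001

    def test_seed_reproducibility(self):
        df, phenos = _summaries([3, 1, 4, 1, 5], [2, 6, 5, 3, 5])
        a = burden_test(df, phenos, n_perm=500, seed=7)
        b = burden_test(df, phenos, n_perm=500, seed=7)
        assert a.p_value == b.p_value

    def test_p_never_zero(self):
        df, phenos = _summaries([100] * 5, [0] * 5)
        res = burden_test(df, phenos, n_perm=100, seed=3)
        assert min(res.p_value.values()) >= 1 / 101

    def test_single_class_rejected(self):
        df, phenos = _summaries([1, 2], [])
        with pytest.raises(ValueError):
            burden_test(df, phenos, n_perm=10, seed=0)


def _enrichment_setup(case_on_pathway):
    genes = [Gene(f"g{i}", 1, i * 100_000 + 1, i * 100_000 + 50_000) for i in range(20)]
    gene_set = GeneSet(genes)
    pathway = {f"g{i}" for i in range(10)}  # first half of the genome
    calls = {}
    phenos = {}
    for i in range(10):
        sid = f"case{i}"
        phenos[sid] = "case"
        target = genes[i % 10] if case_on_pathway else genes[10 + i % 10]
        calls[sid] = [CnvCall(sid, 1, target.start, target.end, 1, 5, 20.0, "hmm")]
    for i in range(10):
        sid = f"ctrl{i}"
        phenos[sid] = "control"
        target = genes[10 + i % 10]
        calls[sid] = [CnvCall(sid, 1, target.start, target.end, 1, 5, 20.0, "hmm")]
    return calls, gene_set, pathway, phenos


class TestCnvEnrichmentTest:
    def test_whole_genome_pathway_is_null(self):
        calls, gene_set, _, phenos = _enrichment_setup(True)
        p = cnv_enrichment_test(
            calls, gene_set, set(gene_set.names()), phenos, n_perm=500, seed=1
        )
        assert p == 1.0

    def test_case_specific_pathway_detected(self):
        calls, gene_set, pathway, phenos = _enrichment_setup(True)
        p = cnv_enrichment_test(calls, gene_set, pathway, phenos, n_perm=5000, seed=2)
        assert p <= 0.001

    def test_seed_reproducibility(self):
        calls, gene_set, pathway, phenos = _enrichment_setup(False)
        a = cnv_enrichment_test(calls, gene_set, pathway, phenos, n_perm=300, seed=5)
        b = cnv_enrichment_test(calls, gene_set, pathway, phenos, n_perm=300, seed=5)
        assert a == b

    def test_empty_pathway_rejected(self):
        calls, gene_set, _, phenos = _enrichment_setup(True)
        with pytest.raises(ValueError):
            cnv_enrichment_test(calls, gene_set, set(), phenos)


class TestPowerChi2Gof:
    def test_zero_effect_gives_alpha(self):
        assert power_chi2_gof(0.0, 100, 1, 0.05) == pytest.approx(0.05)

    def test_small_effect_large_cohort(self):
        # Cohen's w = 0.1 at n=1292: normal-approximation oracle
        # Phi(sqrt(lambda) - z_{0.975}) with lambda = 12.92
        from scipy.stats import norm

        lam = 1292 * 0.01
        approx = norm.cdf(np.sqrt(lam) - norm.ppf(0.975))
        power = power_chi2_gof(0.1, 1292, 1, 0.05)
        assert power == pytest.approx(0.949, abs=0.001)
        assert power == pytest.approx(approx, abs=0.02)

    def test_monotone_in_n(self):
        powers = [power_chi2_gof(0.1, n, 1, 0.05) for n in (100, 400, 1600)]
        assert powers[0] < powers[1] < powers[2]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            power_chi2_gof(0.1, 100, 1, 1.5)


class TestSampleSummaries:
    def test_counts_lengths_and_genes(self):
        genes = GeneSet([Gene("g1", 1, 5000, 15_000), Gene("g2", 1, 100_000, 120_000)])
        calls = {
            "s1": [CnvCall("s1", 1, 1000, 11_000, 1, 6, 20.0, "hmm")],
            "s2": [],
        }
        df = sample_cnv_summaries(calls, genes)
        assert df.loc["s1", "n_cnvs"] == 1
        assert df.loc["s1", "total_kb"] == pytest.approx(10.001)
        assert df.loc["s1", "n_genes"] == 1
        assert df.loc["s2", "has_cnv"] == 0.0
        assert df.loc["s2", "genes_per_kb"] == 0.0
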