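"""Case-control statistics: Fisher exact association with FDR, Fisher's
combined probability meta-analysis, permutation burden and pathway
enrichment tests, and chi-square goodness-of-fit power.

Standard distributions and corrections are delegated to scipy and
statsmodels; the permutation machinery (label permutation with the +1
finite-sample correction, so an empirical p-value is never zero) is
implemented here.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import (
    AssociationRecord,
    BurdenResult,
    Cnvr,
    CnvCall,
    Gene,
    GeneSet,
    MetaRecord,
)

__all__ = [
    "fisher_exact_two_tailed",
    "bh_adjust",
    "cnvr_association",
    "fisher_combine",
    "sample_cnv_summaries",
    "burden_test",
    "cnv_enrichment_test",
    "power_chi2_gof",
    "meta_analyse",
]

BURDEN_METRICS = (
    "n_cnvs",
    "has_cnv",
    "total_kb",
    "n_genes",
    "has_gene",
    "genes_per_kb",
)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (with the
    conventional 1+1e-7 relative slack).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cnvr_association(
    cnvrs: Sequence[Cnvr],
    counts: Sequence[tuple[int, int, int, int]],
    genes: Sequence[list[str]] | None = None,
) -> list[AssociationRecord]:
    """Per-CNVR two-tailed Fisher test with BH-FDR over all tested CNVRs.

    ``counts`` rows are (case carriers, cases without, control carriers,
    controls without), aligned with ``cnvrs``.  Records come back sorted by
    raw p-value.
    """
    if len(cnvrs) != len(counts):
        raise ValueError("cnvrs and counts must align")
    if not cnvrs:
        return []
    records = []
    for i, (r, (a, b, c, d)) in enumerate(zip(cnvrs, counts)):
        p = fisher_exact_two_tailed(a, b, c, d)
        rec = AssociationRecord(cnvr=r, a=a, b=b, c=c, d=d, p_value=p)
        if genes is not None:
            rec.genes = list(genes[i])
        records.append(rec)
    adjusted = bh_adjust([r.p_value for r in records])
    for rec, adj in zip(records, adjusted):
        rec.fdr_adjusted_p = float(adj)
    records.sort(key=lambda r: r.p_value)
    return records


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X = -2 sum(ln p) ~ chi2(2k)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x, 2 * p.size))


def meta_analyse(
    per_cohort: Sequence[Mapping[str, list[tuple[str, float]]]],
) -> list[MetaRecord]:
    """Combine per-gene association p-values across cohorts.

    Each cohort is a mapping gene -> [(copy_type, p), ...].  Only genes
    present in every cohort are combined; every listed (type, p) row of a
    shared gene enters the combination, and the degrees of freedom are
    twice the number of p-values combined.  Combined p-values get a BH
    adjustment over the shared genes.
    """
    if len(per_cohort) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    shared = set(per_cohort[0])
    for cohort in per_cohort[1:]:
        shared &= set(cohort)
    records = []
    for gene in sorted(shared):
        ps: list[float] = []
        typs: list[str] = []
        for cohort in per_cohort:
            for typ, p in cohort[gene]:
                ps.append(p)
                typs.append(typ)
        records.append(
            MetaRecord(gene=gene, cohort_p=ps, cohort_types=typs, combined_p=fisher_combine(ps))
        )
    adjusted = bh_adjust([r.combined_p for r in records])
    for rec, adj in zip(records, adjusted):
        rec.combined_adjusted_p = float(adj)
    records.sort(key=lambda r: r.combined_p)
    return records


def _genes_overlapped(calls: Sequence[CnvCall], gene_set: GeneSet) -> set[str]:
    hit: set[str] = set()
    for g in gene_set.genes:
        for c in calls:
            if c.chrom == g.chrom and c.start <= g.end and c.end >= g.start:
                hit.add(g.name)
                break
    return hit


def sample_cnv_summaries(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    gene_set: GeneSet | None = None,
) -> pd.DataFrame:
    """Per-sample burden summaries (one row per sample).

    Columns: n_cnvs, has_cnv, total_kb, n_genes, has_gene, genes_per_kb.
    Gene metrics are zero when no gene list is supplied.
    """
    rows = []
    for sid, calls in calls_by_sample.items():
        total_kb = sum(c.length for c in calls) / 1000.0
        n_genes = len(_genes_overlapped(calls, gene_set)) if gene_set else 0
        rows.append(
            {
                "sample_id": sid,
                "n_cnvs": len(calls),
                "has_cnv": float(len(calls) > 0),
                "total_kb": total_kb,
                "n_genes": n_genes,
                "has_gene": float(n_genes > 0),
                "genes_per_kb": n_genes / total_kb if total_kb > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _permutation_pvalues(
    values: np.ndarray, is_case: np.ndarray, n_perm: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided (case mean > control mean) label-permutation p-values for
    each column of ``values``; returns (case means, control means, p)."""
    rng = np.random.default_rng(seed)
    n_cases = int(is_case.sum())
    case_mean = values[is_case].mean(axis=0)
    control_mean = values[~is_case].mean(axis=0)
    observed = case_mean - control_mean
    n = len(is_case)
    exceed = np.zeros(values.shape[1], dtype=np.int64)
    # column totals let one group mean imply the other
    total = values.sum(axis=0)
    for _ in range(n_perm):
        idx = rng.permutation(n)[:n_cases]
        pc = values[idx].mean(axis=0)
        pm = (total - values[idx].sum(axis=0)) / (n - n_cases)
        # tiny slack so exact ties survive float summation-order noise
        exceed += (pc - pm) >= observed - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return case_mean, control_mean, p


def burden_test(
    summaries: pd.DataFrame,
    phenotypes: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> BurdenResult:
    """Genome-wide burden comparison via one-sided label permutation.

    For each metric the statistic is (case mean - control mean); the
    empirical p-value is (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    metrics = [m for m in BURDEN_METRICS if m in summaries.columns]
    if not metrics:
        raise ValueError("no burden metrics in summaries")
    labels = np.array([phenotypes[s] for s in summaries.index])
    is_case = labels == "case"
    if is_case.all() or not is_case.any():
        raise ValueError("both phenotypes must be present")
    values = summaries[metrics].to_numpy(dtype=float)
    case_mean, control_mean, p = _permutation_pvalues(values, is_case, n_perm, seed)
    return BurdenResult(
        metrics=metrics,
        case_mean=dict(zip(metrics, case_mean)),
        control_mean=dict(zip(metrics, control_mean)),
        p_value=dict(zip(metrics, p)),
        n_perm=n_perm,
        seed=seed,
    )


def cnv_enrichment_test(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    gene_set: GeneSet,
    pathway_genes: set[str],
    phenotypes: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Pathway enrichment of case CNVs controlling gene/CNV size and rate.

    Per sample the statistic is the fraction of its CNV-overlapped genes
    that belong to the pathway; samples overlapping no gene are left out
    (the ratio is undefined for them).  The group statistic is the case
    mean minus the control mean of these per-sample fractions, tested by
    one-sided label permutation.  Normalizing within sample is what
    controls for differences in gene and CNV size/rate distributions.
    """
    if not pathway_genes:
        raise ValueError("pathway gene set is empty")
    ratios, labels = [], []
    for sid, calls in calls_by_sample.items():
        hit = _genes_overlapped(calls, gene_set)
        if not hit:
            continue
        ratios.append(len(hit & pathway_genes) / len(hit))
        labels.append(phenotypes[sid])
    values = np.asarray(ratios, dtype=float)[:, None]
    is_case = np.array(labels) == "case"
    if values.size == 0 or is_case.all() or not is_case.any():
        raise ValueError("both phenotypes must contribute gene-overlapping samples")
    _, _, p = _permutation_pvalues(values, is_case, n_perm, seed)
    return float(p[0])


def power_chi2_gof(w: float, n: int, df: int = 1, alpha: float = 0.05) -> float:
    """Power of a chi-square goodness-of-fit test at effect size Cohen's w.

    The test statistic is noncentral chi-square with noncentrality
    lambda = n * w^2; power is its upper tail beyond the central
    chi-square(df) critical value at level alpha.
    """
    if w < 0:
        raise ValueError("effect size w must be non-negative")
    if n < 1 or df < 1:
        raise ValueError("n and df must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    crit = sps.chi2.ppf(1 - alpha, df)
    if w == 0:
        return float(alpha)
    return float(sps.ncx2.sf(crit, df, n * w * w))
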