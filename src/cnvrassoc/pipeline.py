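"""End-to-end pipeline: call -> sample QC -> call QC -> exclusion -> merge
-> consensus -> CNVR -> frequency filter -> burden + association -> FDR ->
annotation -> enrichment -> meta-analysis (with two cohorts).

Every stage logs its input/output counts; all randomness flows from the
single configuration seed, so a rerun writes byte-identical tables.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from .callers import CallerParams, call_cohort, sample_qc_metrics
from .config import PipelineConfig
from .consensus import build_cnvrs, carrier_table, consensus_calls, frequency_filter
from .io import read_signal_tsv
from .qc import QcThresholds, SampleLimits, exclude_regions, filter_calls, filter_samples, merge_adjacent
from .regions import RegionSet
from .stats import burden_test, cnvr_association, meta_analyse, sample_cnv_summaries
from .synthetic import build_snp_map, simulate_cohort
from .types import (
    AssociationRecord,
    BurdenResult,
    CnvCall,
    CohortTruth,
    GeneSet,
    MetaRecord,
    SignalTrack,
    SnpMap,
)

logger = logging.getLogger("cnvrassoc")

__all__ = ["CohortResult", "PipelineResult", "run_pipeline", "thresholds_from_config"]


@dataclass
class CohortResult:
    name: str
    snp_map: SnpMap
    n_cases: int
    n_controls: int
    cnvrs: list
    association: list[AssociationRecord]
    burden: BurdenResult
    truth: CohortTruth | None = None
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)
    cnvr_table: pd.DataFrame | None = None
    association_table: pd.DataFrame | None = None
    enrichment_table: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    cohorts: list[CohortResult]
    meta: list[MetaRecord] = field(default_factory=list)
    meta_table: pd.DataFrame | None = None


def thresholds_from_config(cfg: PipelineConfig) -> QcThresholds:
    q = cfg.qc
    return QcThresholds(
        sample_limits={
            "hmm": SampleLimits(
                max_sd_lrr=q.hmm_max_sd_lrr,
                max_baf_drift=q.hmm_max_baf_drift,
                max_gcwf=q.hmm_max_gcwf,
                max_calls=q.max_calls,
            ),
            "bayes": SampleLimits(
                max_sd_lrr=q.bayes_max_sd_lrr,
                max_sd_baf=q.bayes_max_sd_baf,
                max_outlier_rate=q.bayes_max_outlier_rate,
                max_calls=q.max_calls,
            ),
            "gaussian": SampleLimits(max_calls=10**9),
        },
        min_probes=q.min_probes,
        min_length_bp=q.min_length_bp,
        min_confidence={
            "hmm": (q.hmm_min_confidence, False),
            "bayes": (q.bayes_min_confidence, True),
            "gaussian": (q.gaussian_min_confidence, False),
        },
        exclusion_overlap_fraction=q.exclusion_overlap_fraction,
    )


def _merge_sample_calls(calls: Sequence[CnvCall], snp_map: SnpMap) -> list[CnvCall]:
    """Apply the gap-merging rule within each sample/chrom/copy-type group."""
    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample_id, c.caller, c.chrom, c.copy_type)].append(c)
    out: list[CnvCall] = []
    for group in groups.values():
        out.extend(merge_adjacent(group, snp_map))
    return out


def analyse_cohort(
    name: str,
    snp_map: SnpMap,
    tracks: Sequence[SignalTrack],
    *,
    params: CallerParams | None = None,
    thresholds: QcThresholds | None = None,
    regions: RegionSet | None = None,
    gene_set: GeneSet | None = None,
    reciprocal_overlap: float = 0.5,
    min_freq: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    truth: CohortTruth | None = None,
) -> CohortResult:
    """Run the per-cohort stages on in-memory tracks.

    This is the library entry point that the config-driven
    :func:`run_pipeline` and the simulation studies share.
    """
    if not tracks:
        raise ValueError("empty cohort")
    params = params or CallerParams()
    thresholds = thresholds or QcThresholds()

    raw = call_cohort(tracks, snp_map, params)
    qcs = []
    for i, t in enumerate(tracks):
        qc = sample_qc_metrics(t, snp_map)
        qc.n_calls = {caller: len(raw[caller][i]) for caller in raw}
        qcs.append(qc)

    kept_by_caller: dict[str, set[str]] = {}
    dropped_reasons: dict[str, list[str]] = defaultdict(list)
    for caller in raw:
        kept, dropped = filter_samples(qcs, thresholds, caller)
        kept_by_caller[caller] = set(kept)
        for sid, reasons in dropped.items():
            dropped_reasons[sid].extend(f"{caller}:{r}" for r in reasons)
        logger.info("%s: sample QC [%s]: kept %d / dropped %d", name, caller, len(kept), len(dropped))

    # a sample that fails >=2 callers can never reach consensus: drop it
    fail_counts = {
        t.sample_id: sum(t.sample_id not in kept_by_caller[c] for c in raw)
        for t in tracks
    }
    cohort_ids = [sid for sid, nf in fail_counts.items() if nf < 2]
    excluded = {sid: dropped_reasons[sid] for sid, nf in fail_counts.items() if nf >= 2}
    logger.info("%s: cohort after sample QC: %d of %d samples", name, len(cohort_ids), len(tracks))

    phenotypes = {t.sample_id: t.phenotype for t in tracks if t.sample_id in set(cohort_ids)}
    n_cases = sum(1 for p in phenotypes.values() if p == "case")
    n_controls = sum(1 for p in phenotypes.values() if p == "control")

    pooled: list[CnvCall] = []
    for caller, per_sample in raw.items():
        for i, t in enumerate(tracks):
            if t.sample_id in kept_by_caller[caller] and t.sample_id in phenotypes:
                pooled.extend(per_sample[i])
    logger.info("%s: raw calls after sample QC: %d", name, len(pooled))

    pooled = filter_calls(pooled, thresholds)
    logger.info("%s: calls after call-level QC: %d", name, len(pooled))
    if regions is not None:
        pooled = exclude_regions(pooled, regions, thresholds.exclusion_overlap_fraction)
        logger.info("%s: calls after exclusion regions: %d", name, len(pooled))
    pooled = _merge_sample_calls(pooled, snp_map)
    logger.info("%s: calls after gap merging: %d", name, len(pooled))

    by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in pooled:
        by_sample[c.sample_id].append(c)
    consensus = []
    for sid in sorted(by_sample):
        consensus.extend(consensus_calls(by_sample[sid], reciprocal_overlap))
    logger.info("%s: consensus calls: %d", name, len(consensus))

    cnvrs = build_cnvrs(consensus)
    cnvrs = frequency_filter(cnvrs, n_cases, n_controls, min_freq)
    logger.info("%s: CNVRs after frequency filter: %d", name, len(cnvrs))

    counts = carrier_table(cnvrs, phenotypes)
    genes = None
    if gene_set is not None:
        genes, _ = ann.annotate_genes([(r.chrom, r.start, r.end) for r in cnvrs], gene_set)
    association = cnvr_association(cnvrs, counts, genes)

    consensus_by_sample = {sid: [] for sid in phenotypes}
    for c in consensus:
        consensus_by_sample[c.sample_id].append(
            CnvCall(c.sample_id, c.chrom, c.start, c.end,
                    1 if c.copy_type == "loss" else 3,
                    max(1, snp_map.n_probes(c.chrom, c.start, c.end)), 0.0, "hmm")
        )
    summaries = sample_cnv_summaries(consensus_by_sample, gene_set)
    burden = burden_test(summaries, phenotypes, n_perm=n_perm, seed=seed)
    logger.info("%s: burden p (n_cnvs) = %.3g", name, burden.p_value["n_cnvs"])

    return CohortResult(
        name=name,
        snp_map=snp_map,
        n_cases=n_cases,
        n_controls=n_controls,
        cnvrs=cnvrs,
        association=association,
        burden=burden,
        truth=truth,
        dropped_samples=excluded,
    )


def _association_frame(result: CohortResult) -> pd.DataFrame:
    rows = []
    for rec in result.association:
        rows.append(
            {
                "chrom": rec.cnvr.chrom,
                "start": rec.cnvr.start,
                "end": rec.cnvr.end,
                "length": rec.cnvr.length,
                "type": rec.cnvr.copy_type,
                "p_value": f"{rec.p_value:.3g}",
                "fdr_adjusted_p": f"{rec.fdr_adjusted_p:.3g}",
                "genes": ",".join(rec.genes),
                "case_carriers": rec.a,
                "control_carriers": rec.c,
                "case_pct": f"{rec.case_pct:.3g}",
                "control_pct": f"{rec.control_pct:.3g}",
            }
        )
    return pd.DataFrame(rows)


def _cnvr_frame(result: CohortResult) -> pd.DataFrame:
    rows = []
    for rec in sorted(
        result.association, key=lambda x: (x.cnvr.chrom, x.cnvr.start, x.cnvr.copy_type)
    ):
        r = rec.cnvr
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "type": r.copy_type,
                "n_case_carriers": rec.a,
                "n_control_carriers": rec.c,
                "case_pct": f"{rec.case_pct:.3g}",
                "control_pct": f"{rec.control_pct:.3g}",
            }
        )
    return pd.DataFrame(rows)


def _dropped_frame(result: CohortResult) -> pd.DataFrame:
    rows = [
        {"sample_id": sid, "reasons": ";".join(reasons)}
        for sid, reasons in sorted(result.dropped_samples.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "reasons"])


def _burden_frame(b: BurdenResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": b.metrics,
            "case_mean": [f"{b.case_mean[m]:.6g}" for m in b.metrics],
            "control_mean": [f"{b.control_mean[m]:.6g}" for m in b.metrics],
            "p_value": [f"{b.p_value[m]:.3g}" for m in b.metrics],
        }
    )


def _meta_frame(records: Sequence[MetaRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene,
                "cohort_p": ",".join(f"{p:.3g}" for p in r.cohort_p),
                "types": ",".join(r.cohort_types),
                "combined_p": f"{r.combined_p:.3g}",
                "combined_adjusted_p": f"{r.combined_adjusted_p:.3g}",
            }
        )
    return pd.DataFrame(rows)


def gene_pvalues(result: CohortResult) -> dict[str, list[tuple[str, float]]]:
    """Per-gene (copy type, p) rows of a cohort's association records."""
    out: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for rec in result.association:
        for gene in rec.genes:
            out[gene].append((rec.cnvr.copy_type, rec.p_value))
    return dict(out)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full configured pipeline, writing result tables when
    ``out_dir`` is set."""
    params = CallerParams(
        lrr_sd=cfg.callers.lrr_sd,
        min_lrr_sd=cfg.callers.min_lrr_sd,
        baf_sd=cfg.callers.baf_sd,
        p_stay=cfg.callers.p_stay,
        d_scale=cfg.callers.d_scale,
        gaussian_confidence=cfg.callers.gaussian_confidence,
    )
    thresholds = thresholds_from_config(cfg)
    regions = (
        RegionSet.from_bed(cfg.paths.exclusion_bed) if cfg.paths.exclusion_bed else None
    )
    gene_set = ann.read_glist(cfg.paths.glist) if cfg.paths.glist else None

    results: list[CohortResult] = []
    for k, cohort_cfg in enumerate(cfg.cohorts):
        cohort_seed = (cfg.seed + 7919 * k) % (2**31)
        truth = None
        if cohort_cfg.simulate is not None:
            sim = cohort_cfg.simulate
            snp_map = build_snp_map(
                sim.n_chromosomes,
                sim.markers_per_chromosome,
                sim.mean_spacing,
                sim.gc_wavelength,
                seed=cohort_seed,
            )
            from .types import CnvLocus

            loci = [
                CnvLocus(l.chrom, l.start, l.end, l.copy_number, l.case_frequency, l.control_frequency)
                for l in sim.loci
            ]
            tracks, truth = simulate_cohort(
                snp_map,
                loci,
                sim.n_cases,
                sim.n_controls,
                sd_lrr=sim.sd_lrr,
                baf_noise=sim.baf_noise,
                gc_wave_amplitude=sim.gc_wave_amplitude,
                seed=cohort_seed + 1,
            )
        else:
            phenotypes = {}
            if cohort_cfg.phenotypes_tsv:
                ph = pd.read_csv(cohort_cfg.phenotypes_tsv, sep="\t")
                phenotypes = dict(zip(ph.iloc[:, 0], ph.iloc[:, 1]))
            snp_map, tracks = read_signal_tsv(cohort_cfg.signal_tsv, phenotypes)

        result = analyse_cohort(
            cohort_cfg.name,
            snp_map,
            tracks,
            params=params,
            thresholds=thresholds,
            regions=regions,
            gene_set=gene_set,
            reciprocal_overlap=cfg.consensus.reciprocal_overlap,
            min_freq=cfg.consensus.min_freq,
            n_perm=cfg.association.n_perm,
            seed=cohort_seed + 2,
            truth=truth,
        )
        result.cnvr_table = _cnvr_frame(result)
        result.association_table = _association_frame(result)
        if cfg.paths.gmt and gene_set is not None:
            terms = ann.read_gmt(cfg.paths.gmt)
            reference = set(gene_set.names())
            query = {
                g
                for rec in result.association
                if rec.p_value < cfg.association.alpha
                for g in rec.genes
            } & reference
            if query and terms:
                enr = ann.overrepresentation_test(query, terms, reference)
                result.enrichment_table = pd.DataFrame(
                    {
                        "term": [e.term for e in enr],
                        "n_query_in_term": [e.n_query_in_term for e in enr],
                        "fold_enrichment": [f"{e.fold_enrichment:.3g}" for e in enr],
                        "direction": [e.direction for e in enr],
                        "p_value": [f"{e.p_value:.3g}" for e in enr],
                        "bonferroni_p": [f"{e.bonferroni_p:.3g}" for e in enr],
                    }
                )
                logger.info(
                    "%s: enrichment over %d terms (query %d genes)",
                    result.name, len(terms), len(query),
                )
        results.append(result)

    out = PipelineResult(cohorts=results)
    if len(results) == 2 and gene_set is not None:
        per_cohort = [gene_pvalues(r) for r in results]
        if all(per_cohort):
            out.meta = meta_analyse(per_cohort)
            out.meta_table = _meta_frame(out.meta)

    if cfg.out_dir:
        root = Path(cfg.out_dir)
        root.mkdir(parents=True, exist_ok=True)
        for result in results:
            d = root / result.name
            d.mkdir(exist_ok=True)
            result.cnvr_table.to_csv(d / "cnvr.tsv", sep="\t", index=False)
            result.association_table.to_csv(d / "association.tsv", sep="\t", index=False)
            _burden_frame(result.burden).to_csv(d / "burden.tsv", sep="\t", index=False)
            _dropped_frame(result).to_csv(d / "qc_dropped.tsv", sep="\t", index=False)
            if result.enrichment_table is not None:
                result.enrichment_table.to_csv(d / "enrichment.tsv", sep="\t", index=False)
        if out.meta_table is not None:
            out.meta_table.to_csv(root / "meta.tsv", sep="\t", index=False)
    return out
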