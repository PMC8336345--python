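"""Sample-level and call-level exclusion rules, exclusion-region overlap,
and adjacent-call merging.

Boundary semantics follow the usual phrasing of array-CNV quality criteria:
"less than five probes" removes calls with n_probes < 5 (so exactly five is
kept), "less than 5 kb" keeps length >= 5000, and the confidence rule is
inclusive (>= 10) for the HMM caller but strict (> 10) for the Bayes-factor
caller, whose threshold is stated as "greater than ten".  The Gaussian
caller has no sample-level limits; its calls carry a confidence floor of 35.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .regions import RegionSet
from .types import CnvCall, SampleQc, SnpMap

__all__ = ["QcThresholds", "filter_samples", "filter_calls", "exclude_regions", "merge_adjacent"]

_INF = float("inf")


@dataclass(frozen=True)
class SampleLimits:
    max_sd_lrr: float = _INF
    max_baf_drift: float = _INF
    max_gcwf: float = _INF
    max_sd_baf: float = _INF
    max_outlier_rate: float = _INF
    max_calls: int = 50


@dataclass(frozen=True)
class QcThresholds:
    """Per-caller sample limits and call limits; defaults are the standard
    stringent values for each caller family."""

    sample_limits: dict[str, SampleLimits] = field(
        default_factory=lambda: {
            "hmm": SampleLimits(max_sd_lrr=0.35, max_baf_drift=0.01, max_gcwf=0.05),
            "bayes": SampleLimits(max_sd_lrr=0.25, max_sd_baf=0.3, max_outlier_rate=0.01),
            "gaussian": SampleLimits(max_calls=10**9),
        }
    )
    min_probes: int = 5
    min_length_bp: int = 5000
    #: (threshold, strict) per caller, on the log10 confidence scale
    min_confidence: dict[str, tuple[float, bool]] = field(
        default_factory=lambda: {
            "hmm": (10.0, False),
            "bayes": (10.0, True),
            "gaussian": (35.0, False),
        }
    )
    exclusion_overlap_fraction: float = 0.5


def filter_samples(
    qcs: Sequence[SampleQc], thresholds: QcThresholds, caller: str
) -> tuple[list[str], dict[str, list[str]]]:
    """Split samples into kept ids and dropped ids with violation reasons.

    A sample is dropped iff it violates at least one limit for the given
    caller; every violated limit is reported as a reason code.
    """
    if caller not in thresholds.sample_limits:
        raise ValueError(f"unknown caller {caller!r}")
    lim = thresholds.sample_limits[caller]
    kept: list[str] = []
    dropped: dict[str, list[str]] = {}
    for qc in qcs:
        reasons = []
        if qc.sd_lrr > lim.max_sd_lrr:
            reasons.append("sd_lrr")
        if qc.baf_drift > lim.max_baf_drift:
            reasons.append("baf_drift")
        if abs(qc.gc_wave_factor) > lim.max_gcwf:
            reasons.append("gc_wave_factor")
        if qc.sd_baf > lim.max_sd_baf:
            reasons.append("sd_baf")
        if qc.outlier_rate > lim.max_outlier_rate:
            reasons.append("outlier_rate")
        if qc.n_calls.get(caller, 0) > lim.max_calls:
            reasons.append("n_calls")
        if reasons:
            dropped[qc.sample_id] = reasons
        else:
            kept.append(qc.sample_id)
    return kept, dropped


def _confidence_ok(call: CnvCall, thresholds: QcThresholds) -> bool:
    threshold, strict = thresholds.min_confidence.get(call.caller, (0.0, False))
    return call.confidence > threshold if strict else call.confidence >= threshold


def filter_calls(calls: Sequence[CnvCall], thresholds: QcThresholds) -> list[CnvCall]:
    """Keep calls with >= min probes, >= min length and caller-specific
    confidence at or above threshold."""
    return [
        c
        for c in calls
        if c.n_probes >= thresholds.min_probes
        and c.length >= thresholds.min_length_bp
        and _confidence_ok(c, thresholds)
    ]


def exclude_regions(
    calls: Sequence[CnvCall], regions: RegionSet, fraction: float = 0.5
) -> list[CnvCall]:
    """Remove calls whose overlap with the region union is at least
    ``fraction`` of the call length.

    Calls are 1-based inclusive; regions are half-open, so the call
    [start, end] maps to [start-1, end) for the overlap computation.
    """
    kept = []
    for c in calls:
        overlap = regions.overlap_bp(c.chrom, c.start - 1, c.end)
        if overlap / c.length < fraction:
            kept.append(c)
    return kept


def merge_adjacent(
    calls: Sequence[CnvCall], snp_map: SnpMap | None = None
) -> list[CnvCall]:
    """Merge neighbouring calls separated by a gap smaller than half their
    combined length; repeats until a fixpoint.

    All calls must share sample, chromosome and copy type (the caller
    groups them).  The merged call spans min start .. max end, confidence
    is the sum, and n_probes is recomputed from the map when provided
    (otherwise summed).
    """
    if len(calls) <= 1:
        return list(calls)
    key = {(c.sample_id, c.chrom, c.copy_type) for c in calls}
    if len(key) != 1:
        raise ValueError("merge_adjacent expects one sample/chromosome/copy-type group")
    merged = sorted(calls, key=lambda c: (c.start, c.end))
    changed = True
    while changed:
        changed = False
        out: list[CnvCall] = [merged[0]]
        for nxt in merged[1:]:
            cur = out[-1]
            gap = nxt.start - cur.end - 1
            if gap < (cur.length + nxt.length) / 2:
                start, end = min(cur.start, nxt.start), max(cur.end, nxt.end)
                n_probes = (
                    snp_map.n_probes(cur.chrom, start, end)
                    if snp_map is not None
                    else cur.n_probes + nxt.n_probes
                )
                out[-1] = CnvCall(
                    sample_id=cur.sample_id,
                    chrom=cur.chrom,
                    start=start,
                    end=end,
                    copy_number=cur.copy_number,
                    n_probes=n_probes,
                    confidence=cur.confidence + nxt.confidence,
                    caller=cur.caller,
                )
                changed = True
            else:
                out.append(nxt)
        merged = out
    return merged
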