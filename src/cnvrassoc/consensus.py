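"""Multi-caller consensus calls and cross-sample CNV regions.

A consensus call needs the same event type found by at least two distinct
callers with reciprocal overlap (the overlap must be at least the given
fraction of *both* intervals); its interval is the common intersection.
CNV regions (CNVRs) are then built per chromosome and copy type by the
innermost-boundary rule: a left-to-right sweep accumulates overlapping
consensus calls while their running intersection (max start, min end) is
non-empty, and emits the intersection as a CNVR when it empties.  Every
contributing call therefore fully covers its CNVR, which makes "carrier of
the CNVR" well defined.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Mapping, Sequence

from .types import CnvCall, ConsensusCall, Cnvr

__all__ = ["consensus_calls", "build_cnvrs", "frequency_filter", "carrier_table"]


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    """min over both intervals of (overlap bp / interval length)."""
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return min(overlap / a.length, overlap / b.length)


def consensus_calls(
    calls: Sequence[CnvCall], reciprocal_overlap: float = 0.5
) -> list[ConsensusCall]:
    """Build consensus calls for one sample from QC-filtered per-caller calls.

    Groups are formed greedily by leftmost start (ties broken by longest):
    the anchor call collects same-type calls from other callers that
    reciprocally overlap it and every call already in the group; a call
    contributes to at most one consensus call.
    """
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError("consensus_calls expects calls from a single sample")
    out: list[ConsensusCall] = []
    by_key: dict[tuple[int, str], list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_key[(c.chrom, c.copy_type)].append(c)
    for (chrom, copy_type), group in sorted(by_key.items()):
        pool = sorted(group, key=lambda c: (c.start, -c.length))
        used = [False] * len(pool)
        for i, anchor in enumerate(pool):
            if used[i]:
                continue
            members = [anchor]
            member_idx = [i]
            for j in range(i + 1, len(pool)):
                if used[j]:
                    continue
                cand = pool[j]
                if cand.caller in {m.caller for m in members}:
                    if any(
                        _reciprocal_overlap(cand, m) >= reciprocal_overlap
                        for m in members
                    ):
                        warnings.warn(
                            f"multiple overlapping {cand.caller} calls in one "
                            f"consensus group on chr{chrom}; extra call skipped",
                            stacklevel=2,
                        )
                    continue
                if all(
                    _reciprocal_overlap(cand, m) >= reciprocal_overlap for m in members
                ):
                    members.append(cand)
                    member_idx.append(j)
            if len(members) >= 2:
                start = max(m.start for m in members)
                end = min(m.end for m in members)
                out.append(
                    ConsensusCall(
                        sample_id=anchor.sample_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        copy_type=copy_type,
                        callers=frozenset(m.caller for m in members),
                    )
                )
                for j in member_idx:
                    used[j] = True
    return sorted(out, key=lambda c: (c.chrom, c.copy_type, c.start, c.end))


def build_cnvrs(calls: Sequence[ConsensusCall]) -> list[Cnvr]:
    """Pool consensus calls across samples into innermost-boundary CNVRs."""
    by_key: dict[tuple[int, str], list[ConsensusCall]] = defaultdict(list)
    for c in calls:
        by_key[(c.chrom, c.copy_type)].append(c)
    out: list[Cnvr] = []
    for (chrom, copy_type), group in sorted(by_key.items()):
        group.sort(key=lambda c: (c.start, c.end, c.sample_id))
        acc: list[ConsensusCall] = []
        lo, hi = 0, 0
        for c in group:
            if not acc:
                acc, lo, hi = [c], c.start, c.end
                continue
            new_lo, new_hi = max(lo, c.start), min(hi, c.end)
            if new_lo <= new_hi:
                acc.append(c)
                lo, hi = new_lo, new_hi
            else:
                out.append(
                    Cnvr(chrom, lo, hi, copy_type, {m.sample_id for m in acc})
                )
                # restart at the breaking call, carrying over accumulated
                # calls that still overlap it (they cover the new region)
                acc = [m for m in acc if m.end >= c.start] + [c]
                lo = c.start
                hi = min(m.end for m in acc)
        if acc:
            out.append(Cnvr(chrom, lo, hi, copy_type, {m.sample_id for m in acc}))
    return sorted(out, key=lambda r: (r.chrom, r.start, r.end, r.copy_type))


def frequency_filter(
    cnvrs: Sequence[Cnvr], n_cases: int, n_controls: int, min_freq: float = 0.01
) -> list[Cnvr]:
    """Keep CNVRs carried by at least ``min_freq`` of the whole cohort."""
    total = n_cases + n_controls
    if total <= 0:
        raise ValueError("cohort size must be positive")
    return [r for r in cnvrs if len(r.carriers) / total >= min_freq]


def carrier_table(
    cnvrs: Sequence[Cnvr], phenotypes: Mapping[str, str]
) -> list[tuple[int, int, int, int]]:
    """Per-CNVR 2x2 counts (case carriers, cases without, control carriers,
    controls without), aligned with ``cnvrs``."""
    n_cases = sum(1 for p in phenotypes.values() if p == "case")
    n_controls = sum(1 for p in phenotypes.values() if p == "control")
    rows = []
    for r in cnvrs:
        a = c = 0
        for sid in r.carriers:
            if sid not in phenotypes:
                raise ValueError(f"sample {sid!r} has unknown phenotype")
            if phenotypes[sid] == "case":
                a += 1
            else:
                c += 1
        rows.append((a, n_cases - a, c, n_controls - c))
    return rows
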