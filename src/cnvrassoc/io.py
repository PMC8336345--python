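"""File formats: final-report-style signal TSV and rawcnv-style call lists.

The signal TSV mirrors the GenomeStudio final-report layout — a header of
``Name  Chr  Position`` followed by paired ``<sample>.LRR`` / ``<sample>.BAF``
columns, one row per marker.  Calls round-trip through a rawcnv-like line
format with 1-based inclusive coordinates::

    chr1:100-200  numsnp=5  length=101  state,cn=1  s1  conf=12.5  caller=hmm
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CnvCall, SignalTrack, SnpMap

__all__ = ["write_signal_tsv", "read_signal_tsv", "write_calls", "read_calls"]


def write_signal_tsv(
    path: str | Path, snp_map: SnpMap, tracks: Sequence[SignalTrack]
) -> None:
    data: dict[str, object] = {
        "Name": snp_map.names,
        "Chr": snp_map.chrom,
        "Position": snp_map.pos,
        "PFB": snp_map.pfb,
        "GC": snp_map.gc,
    }
    for t in tracks:
        data[f"{t.sample_id}.LRR"] = t.lrr
        data[f"{t.sample_id}.BAF"] = t.baf
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signal_tsv(
    path: str | Path, phenotypes: dict[str, str] | None = None
) -> tuple[SnpMap, list[SignalTrack]]:
    """Read a signal TSV back into a map and tracks.

    ``phenotypes`` maps sample id to 'case'/'control'; samples not listed
    default to 'control'.  Malformed files raise ``ValueError`` naming the
    offending column or line.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["Name", "Chr", "Position", "PFB", "GC"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in df.columns[len(required):]:
        if not re.fullmatch(r".+\.(LRR|BAF)", col):
            raise ValueError(f"{path}: unexpected column {col!r}")
    lrr_samples = [c[:-4] for c in df.columns if c.endswith(".LRR")]
    baf_samples = [c[:-4] for c in df.columns if c.endswith(".BAF")]
    if lrr_samples != baf_samples:
        odd = set(lrr_samples) ^ set(baf_samples)
        raise ValueError(f"{path}: unpaired LRR/BAF columns for {sorted(odd)}")
    chrom_arr = df["Chr"].to_numpy()
    pos_arr = df["Position"].to_numpy()
    same_chrom = chrom_arr[1:] == chrom_arr[:-1]
    bad = np.flatnonzero(same_chrom & (np.diff(pos_arr) <= 0))
    if bad.size:
        line = int(bad[0]) + 3  # +1 header, +1 zero-based, +1 second row of pair
        raise ValueError(f"{path}:{line}: positions not strictly increasing")
    snp_map = SnpMap(
        names=df["Name"].to_numpy(dtype=object),
        chrom=df["Chr"].to_numpy(dtype=np.int64),
        pos=df["Position"].to_numpy(dtype=np.int64),
        pfb=df["PFB"].to_numpy(dtype=float),
        gc=df["GC"].to_numpy(dtype=float),
    )
    tracks = []
    for sid in lrr_samples:
        lrr = df[f"{sid}.LRR"].to_numpy(dtype=float)
        baf = df[f"{sid}.BAF"].to_numpy(dtype=float)
        if np.any(~np.isfinite(lrr)) or np.any(~np.isfinite(baf)):
            raise ValueError(f"{path}: non-numeric signal value for sample {sid!r}")
        if np.any((baf < 0) | (baf > 1)):
            bad = int(np.flatnonzero((baf < 0) | (baf > 1))[0]) + 2
            raise ValueError(f"{path}:{bad}: BAF out of range for sample {sid!r}")
        phenotype = (phenotypes or {}).get(sid, "control")
        tracks.append(SignalTrack(sid, phenotype, lrr, baf))
    return snp_map, tracks


_CALL_RE = re.compile(
    r"chr(?P<chrom>\d+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>\d+)\s+"
    r"state,cn=(?P<cn>\d+)\s+(?P<sample>\S+)\s+"
    r"conf=(?P<conf>[-+0-9.eE]+)\s+caller=(?P<caller>\w+)"
)


def write_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_probes}\t"
                f"length={c.length}\tstate,cn={c.copy_number}\t{c.sample_id}\t"
                f"conf={c.confidence!r}\tcaller={c.caller}\n"
            )


def read_calls(path: str | Path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _CALL_RE.fullmatch(line)
            if m is None:
                raise ValueError(f"{path}:{lineno}: malformed call line: {line!r}")
            cn = int(m["cn"])
            if cn == 2:
                raise ValueError(f"{path}:{lineno}: diploid state is not a call")
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    chrom=int(m["chrom"]),
                    start=int(m["start"]),
                    end=int(m["end"]),
                    copy_number=cn,
                    n_probes=int(m["numsnp"]),
                    confidence=float(m["conf"]),
                    caller=m["caller"],
                )
            )
    return calls
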