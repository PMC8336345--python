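"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the package; BED files are the
only place where 0-based half-open intervals appear, and conversion happens
at the read/write boundary (see :mod:`cnvrassoc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SnpMap",
    "CnvLocus",
    "SignalTrack",
    "CohortTruth",
    "CnvCall",
    "SampleQc",
    "ConsensusCall",
    "Cnvr",
    "AssociationRecord",
    "BurdenResult",
    "MetaRecord",
    "Gene",
    "GeneSet",
    "EnrichmentRecord",
]

#: Mean LRR per copy-number state 0..4.  Diploid is centred at zero; the
#: non-diploid means follow the convention shared by the SNP-array callers
#: (a homozygous deletion is essentially signal-free, hence the large
#: negative value).
STATE_LRR_MEAN = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}

COPY_TYPES = ("loss", "gain")
CALLERS = ("hmm", "bayes", "gaussian")


def copy_type_of(copy_number: int) -> str:
    """'loss' for CN<2, 'gain' for CN>2; diploid has no type."""
    if copy_number < 2:
        return "loss"
    if copy_number > 2:
        return "gain"
    raise ValueError("diploid copy number has no copy type")


@dataclass(frozen=True)
class SnpMap:
    """An ordered autosomal marker map.

    Attributes
    ----------
    names : array of str
        Marker identifiers, unique.
    chrom : array of int
        Chromosome (1..22) per marker.
    pos : array of int
        1-based base-pair position, strictly increasing within a chromosome.
    pfb : array of float
        Population frequency of the B allele, in [0, 1].
    gc : array of float
        Local GC fraction around the marker, in [0, 1].
    """

    names: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pfb: np.ndarray
    gc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.chrom, self.pos, self.pfb, self.gc):
            if len(arr) != n:
                raise ValueError("SnpMap arrays must have equal length")
        if n == 0:
            raise ValueError("SnpMap must contain at least one marker")
        if not (np.all(self.chrom >= 1) and np.all(self.chrom <= 22)):
            raise ValueError("chromosomes must be autosomal (1..22)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chr{c}")
        if np.any((self.pfb < 0) | (self.pfb > 1)):
            raise ValueError("population B-allele frequencies must be in [0,1]")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("GC fractions must be in [0,1]")

    def __len__(self) -> int:
        return len(self.names)

    def standardized_gc(self) -> np.ndarray:
        """Local GC standardized to zero mean / unit variance over the map."""
        sd = float(np.std(self.gc))
        if sd == 0:
            return np.zeros(len(self))
        return (self.gc - np.mean(self.gc)) / sd

    def marker_slice(self, chrom: int, start: int, end: int) -> slice:
        """Index slice of the markers on ``chrom`` with start<=pos<=end."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise ValueError(f"chromosome {chrom} not on the map")
        p = self.pos[idx]
        lo = int(np.searchsorted(p, start, side="left"))
        hi = int(np.searchsorted(p, end, side="right"))
        return slice(int(idx[0]) + lo, int(idx[0]) + hi)

    def n_probes(self, chrom: int, start: int, end: int) -> int:
        s = self.marker_slice(chrom, start, end)
        return s.stop - s.start


@dataclass(frozen=True)
class CnvLocus:
    """A ground-truth CNV locus to implant into a simulated cohort."""

    chrom: int
    start: int
    end: int
    copy_number: int
    case_frequency: float
    control_frequency: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must be <= end")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("implanted copy number must be in {0,1,3,4}")
        for f in (self.case_frequency, self.control_frequency):
            if not 0 <= f <= 1:
                raise ValueError("carrier frequencies must be in [0,1]")

    @property
    def copy_type(self) -> str:
        return copy_type_of(self.copy_number)


@dataclass
class SignalTrack:
    """One sample's LRR/BAF signal over a :class:`SnpMap`."""

    sample_id: str
    phenotype: str  # 'case' | 'control'
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValueError("phenotype must be 'case' or 'control'")
        if len(self.lrr) != len(self.baf):
            raise ValueError("lrr and baf must have equal length")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise ValueError("BAF values must lie in [0,1]")


@dataclass
class CohortTruth:
    """Implanted loci and their carriers, kept for recovery testing."""

    loci: list[CnvLocus]
    carriers: dict[int, set[str]]  # locus index -> carrier sample ids
    seed: int


@dataclass
class CnvCall:
    """One contiguous copy-number event called in one sample."""

    sample_id: str
    chrom: int
    start: int
    end: int
    copy_number: int
    n_probes: int
    confidence: float
    caller: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("call start must be <= end")
        if self.n_probes < 1:
            raise ValueError("a call must span at least one probe")
        if self.copy_number == 2:
            raise ValueError("diploid segments are not calls")
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")

    @property
    def copy_type(self) -> str:
        return copy_type_of(self.copy_number)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleQc:
    """Per-sample signal-quality metrics."""

    sample_id: str
    sd_lrr: float
    baf_drift: float
    gc_wave_factor: float
    sd_baf: float
    outlier_rate: float
    n_calls: dict[str, int] = field(default_factory=dict)


@dataclass
class ConsensusCall:
    """A per-sample call supported by >=2 callers; interval is the
    intersection of the supporting calls."""

    sample_id: str
    chrom: int
    start: int
    end: int
    copy_type: str
    callers: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.callers) < 2:
            raise ValueError("consensus requires at least two callers")
        if self.start > self.end:
            raise ValueError("empty consensus interval")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Cnvr:
    """A cross-sample CNV region (innermost boundaries of overlapping
    consensus calls of one copy type)."""

    chrom: int
    start: int
    end: int
    copy_type: str
    carriers: set[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssociationRecord:
    """Per-CNVR case-control association result."""

    cnvr: Cnvr
    a: int  # case carriers
    b: int  # cases without
    c: int  # control carriers
    d: int  # controls without
    p_value: float
    fdr_adjusted_p: float = float("nan")
    genes: list[str] = field(default_factory=list)

    @property
    def case_pct(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    @property
    def control_pct(self) -> float:
        return 100.0 * self.c / (self.c + self.d)


@dataclass
class BurdenResult:
    """Genome-wide CNV burden comparison, one row per metric."""

    metrics: list[str]
    case_mean: dict[str, float]
    control_mean: dict[str, float]
    p_value: dict[str, float]
    n_perm: int
    seed: int


@dataclass
class MetaRecord:
    """Cross-cohort meta-analysis record for one gene."""

    gene: str
    cohort_p: list[float]
    cohort_types: list[str]
    combined_p: float
    combined_adjusted_p: float = float("nan")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: int
    start: int
    end: int


@dataclass
class GeneSet:
    """A glist-style gene coordinate list with unique names."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        for g in self.genes:
            if g.start > g.end:
                raise ValueError(f"invalid interval for gene {g.name}")

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> list[str]:
        return [g.name for g in self.genes]


@dataclass
class EnrichmentRecord:
    """One term of an overrepresentation test."""

    term: str
    n_query_in_term: int
    n_query: int
    n_term_in_reference: int
    n_reference: int
    fold_enrichment: float
    direction: str  # '+' | '-'
    p_value: float
    bonferroni_p: float
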