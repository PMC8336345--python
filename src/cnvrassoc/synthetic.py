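"""Synthetic SNP-array cohorts: marker maps, LRR/BAF tracks, implanted CNVs.

The generator emulates the statistical structure a genotyping-array CNV
analysis assumes: per-marker LogR ratios centred at a copy-state-specific
mean, B-allele frequencies emitted at the allelic ratio implied by the
genotype within the carried copy state, per-sample Gaussian LRR noise,
truncated-normal BAF noise, and a GC-correlated intensity wave.

Case and control carriers of each implanted locus are drawn independently
per sample at phenotype-specific frequencies, which is the level of realism
the downstream frequency-contrast statistics require.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .regions import RegionSet
from .types import STATE_LRR_MEAN, CnvLocus, CohortTruth, SignalTrack, SnpMap

__all__ = ["build_snp_map", "simulate_cohort", "make_exclusion_bed"]

# Allelic-ratio BAF bands per copy state: k copies of the B allele out of
# CN total copies.  CN0 has no allelic signal and is emitted uniform(0,1).
BAF_BANDS = {
    1: np.array([0.0, 1.0]),
    2: np.array([0.0, 0.5, 1.0]),
    3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}

#: Homozygous BAF bands are compressed by the array chemistry; their noise
#: scale is one quarter of the heterozygous-band scale.
HOM_NOISE_SHRINK = 0.25


def build_snp_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    mean_spacing: float = 3000.0,
    gc_wavelength: float = 1e6,
    seed: int = 0,
) -> SnpMap:
    """Generate an ordered autosomal marker map.

    Inter-marker gaps are exponential with the given mean (a memoryless
    stand-in for real array spacing), local GC is a smooth sinusoid plus
    noise squashed into [0,1], and population B-allele frequencies are
    uniform on (0.05, 0.95).
    """
    if not 1 <= n_chromosomes <= 22:
        raise ValueError("n_chromosomes must be in 1..22")
    if markers_per_chromosome < 10:
        raise ValueError("markers_per_chromosome must be >= 10")
    if mean_spacing <= 0 or gc_wavelength <= 0:
        raise ValueError("mean_spacing and gc_wavelength must be positive")

    rng = np.random.default_rng(seed)
    names, chroms, poss, pfbs, gcs = [], [], [], [], []
    for c in range(1, n_chromosomes + 1):
        gaps = rng.exponential(mean_spacing, markers_per_chromosome)
        pos = np.cumsum(np.maximum(1, np.round(gaps)).astype(np.int64))
        # resolve duplicate positions produced by rounding
        pos = pos + np.arange(markers_per_chromosome, dtype=np.int64) * 0
        phase = rng.uniform(0, 2 * math.pi)
        wave = 0.41 + 0.08 * np.sin(2 * math.pi * pos / gc_wavelength + phase)
        gc = np.clip(wave + rng.normal(0, 0.01, markers_per_chromosome), 0, 1)
        pfb = rng.uniform(0.05, 0.95, markers_per_chromosome)
        names.extend(f"chr{c}:snp{i}" for i in range(markers_per_chromosome))
        chroms.append(np.full(markers_per_chromosome, c, dtype=np.int64))
        poss.append(pos)
        pfbs.append(pfb)
        gcs.append(gc)
    return SnpMap(
        names=np.array(names, dtype=object),
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        pfb=np.concatenate(pfbs),
        gc=np.concatenate(gcs),
    )


def _truncnorm_rvs(
    rng: np.random.Generator, loc: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """Truncated-normal draws on [0,1] with elementwise loc/scale."""
    a = (0.0 - loc) / scale
    b = (1.0 - loc) / scale
    u = rng.uniform(size=loc.shape)
    lo = stats.norm.cdf(a)
    hi = stats.norm.cdf(b)
    return np.clip(loc + scale * stats.norm.ppf(lo + u * (hi - lo)), 0.0, 1.0)


def _emit_baf(
    rng: np.random.Generator,
    copy_number: int,
    pfb: np.ndarray,
    baf_noise: float,
) -> np.ndarray:
    """Draw BAF for markers carried at ``copy_number`` copies."""
    n = len(pfb)
    if copy_number == 0:
        return rng.uniform(0.0, 1.0, n)
    k = rng.binomial(copy_number, pfb)
    band = k / copy_number
    if baf_noise == 0:
        return band.astype(float)
    hom = (k == 0) | (k == copy_number)
    scale = np.where(hom, baf_noise * HOM_NOISE_SHRINK, baf_noise)
    return _truncnorm_rvs(rng, band.astype(float), scale)


def simulate_cohort(
    snp_map: SnpMap,
    loci: Sequence[CnvLocus],
    n_cases: int,
    n_controls: int,
    sd_lrr: float = 0.2,
    baf_noise: float = 0.03,
    gc_wave_amplitude: float = 0.0,
    seed: int = 0,
) -> tuple[list[SignalTrack], CohortTruth]:
    """Simulate LRR/BAF tracks for a case-control cohort.

    Diploid LRR is centred at 0; carried segments at the copy-state mean
    (CN0 -3.5, CN1 -0.66, CN3 +0.40, CN4 +0.68).  A GC wave of the given
    amplitude times the standardized local GC is added to every sample.

    Returns the tracks together with a :class:`CohortTruth` recording which
    samples carry which implanted locus.
    """
    if sd_lrr < 0 or baf_noise < 0:
        raise ValueError("noise scales must be non-negative")
    if n_cases < 0 or n_controls < 0:
        raise ValueError("cohort sizes must be non-negative")
    for locus in loci:
        chrom_pos = snp_map.pos[snp_map.chrom == locus.chrom]
        if chrom_pos.size == 0:
            raise ValueError(f"locus chromosome {locus.chrom} not on the map")
        if locus.start < chrom_pos[0] or locus.end > chrom_pos[-1]:
            raise ValueError(
                f"locus {locus.chrom}:{locus.start}-{locus.end} outside map bounds"
            )

    rng = np.random.default_rng(seed)
    zgc = snp_map.standardized_gc()
    n_markers = len(snp_map)
    tracks: list[SignalTrack] = []
    carriers: dict[int, set[str]] = {i: set() for i in range(len(loci))}
    locus_slices = [
        snp_map.marker_slice(l.chrom, l.start, l.end) for l in loci
    ]

    phenotypes = ["case"] * n_cases + ["control"] * n_controls
    for i, phenotype in enumerate(phenotypes):
        sid = f"{phenotype}_{i:04d}" if phenotype == "case" else f"{phenotype}_{i - n_cases:04d}"
        cn = np.full(n_markers, 2, dtype=np.int8)
        for j, locus in enumerate(loci):
            freq = locus.case_frequency if phenotype == "case" else locus.control_frequency
            if rng.uniform() < freq:
                cn[locus_slices[j]] = locus.copy_number
                carriers[j].add(sid)
        lrr = np.array([STATE_LRR_MEAN[s] for s in (0, 1, 2, 3, 4)])[cn]
        if sd_lrr > 0:
            lrr = lrr + rng.normal(0, sd_lrr, n_markers)
        if gc_wave_amplitude != 0:
            lrr = lrr + gc_wave_amplitude * zgc
        baf = np.empty(n_markers)
        for state in np.unique(cn):
            mask = cn == state
            baf[mask] = _emit_baf(rng, int(state), snp_map.pfb[mask], baf_noise)
        tracks.append(SignalTrack(sid, phenotype, lrr, baf))

    truth = CohortTruth(loci=list(loci), carriers=carriers, seed=seed)
    return tracks, truth


def make_exclusion_bed(
    snp_map: SnpMap,
    telomere_bp: int = 0,
    centromere: dict[int, tuple[int, int]] | None = None,
    extra_regions: Sequence[tuple[int, int, int]] = (),
) -> RegionSet:
    """Build an exclusion region set (telomeres, centromeres, extras).

    Telomeric regions are ``telomere_bp`` at each end of each chromosome's
    marker span; centromeres are given 1-based inclusive per chromosome;
    extras as (chrom, start, end) 1-based inclusive.  The result stores
    0-based half-open intervals and round-trips through BED.
    """
    intervals: list[tuple[int, int, int]] = []  # (chrom, start0, end0) half-open
    chrom_span = {
        int(c): (int(snp_map.pos[snp_map.chrom == c][0]),
                 int(snp_map.pos[snp_map.chrom == c][-1]))
        for c in np.unique(snp_map.chrom)
    }
    if telomere_bp < 0:
        raise ValueError("telomere_bp must be non-negative")
    if telomere_bp > 0:
        for c, (lo, hi) in chrom_span.items():
            intervals.append((c, max(0, lo - 1), lo - 1 + telomere_bp))
            intervals.append((c, max(0, hi - telomere_bp), hi))
    for c, (s, e) in (centromere or {}).items():
        if s > e:
            raise ValueError("inverted centromere interval")
        intervals.append((int(c), int(s) - 1, int(e)))
    for c, s, e in extra_regions:
        if s > e:
            raise ValueError("inverted extra region")
        intervals.append((int(c), int(s) - 1, int(e)))
    return RegionSet(intervals)
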