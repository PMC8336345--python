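"""Three CNV callers over LRR/BAF signal, plus per-sample QC metrics.

The callers re-create the decision structure of the three detection
strategies used in array-CNV studies — a hidden-Markov decoder (``hmm``),
the same segmentation scored by a log Bayes factor after GC correction
(``bayes``), and a Gaussian-partition scan that calls maximal segments
whose cumulative log-likelihood advantage over diploid exceeds a confidence
threshold (``gaussian``).  All three share one emission model:

* LRR ~ Normal(state mean, sigma) with state means (-3.5, -0.66, 0, 0.40,
  0.68) for CN0..CN4;
* BAF ~ mixture over genotype bands (k of CN copies B) weighted by the
  marker's population B-allele frequency, each band a truncated normal on
  [0,1]; CN0 is uniform (no allelic signal).

Confidence scores are log10 likelihood ratios against diploid, so the
conventional per-caller thresholds (10, >10, 35) are on one scale.

Decoding is vectorized across samples: :func:`viterbi_paths` decodes a
whole cohort in one pass over markers, which is what makes whole-cohort
simulation studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, ndtr

from .types import STATE_LRR_MEAN, CnvCall, SampleQc, SignalTrack, SnpMap
from .synthetic import BAF_BANDS, HOM_NOISE_SHRINK

__all__ = [
    "CallerParams",
    "sample_qc_metrics",
    "gc_correct",
    "call_hmm",
    "call_bayes",
    "call_gaussian",
    "call_cohort",
    "viterbi_paths",
]

_LN10 = np.log(10.0)
_STATES = np.arange(5)
_STATE_MEANS = np.array([STATE_LRR_MEAN[s] for s in range(5)])


@dataclass(frozen=True)
class CallerParams:
    """Tunable decoding parameters shared by the callers.

    ``lrr_sd=None`` estimates a robust per-sample noise scale from the
    track (1.4826 x median absolute deviation, floored at ``min_lrr_sd``),
    which keeps the emission model honest for samples of differing quality.
    ``d_scale`` is the distance constant of the distance-dependent
    self-transition 1 - (1-p_stay) * (1-exp(-d/D)).
    """

    lrr_sd: float | None = None
    min_lrr_sd: float = 0.02
    baf_sd: float = 0.05
    p_stay: float = 0.999
    d_scale: float = 100_000.0
    state_prior: tuple[float, ...] = (0.0025, 0.0025, 0.99, 0.0025, 0.0025)
    gaussian_confidence: float = 35.0

    def __post_init__(self) -> None:
        prior = np.asarray(self.state_prior, dtype=float)
        if prior.shape != (5,) or np.any(prior <= 0) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("state_prior must be 5 positive values summing to 1")
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must be in (0,1)")
        if self.d_scale <= 0:
            raise ValueError("d_scale must be positive")


def sample_qc_metrics(track: SignalTrack, snp_map: SnpMap) -> SampleQc:
    """Compute per-sample signal-quality metrics.

    * ``sd_lrr`` — standard deviation of the autosomal LRR;
    * ``baf_drift`` — fraction of markers with BAF in (0.2,0.25)u(0.75,0.8),
      the off-cluster bands empty in a clean sample;
    * ``gc_wave_factor`` — OLS slope of LRR on standardized local GC,
      computed over markers within 3 robust SDs of the median LRR so that
      genuine CNV segments do not masquerade as waves;
    * ``sd_baf`` — standard deviation of BAF within the heterozygous band
      [0.25, 0.75];
    * ``outlier_rate`` — fraction of markers with |LRR| > 1.
    """
    if len(track.lrr) == 0:
        raise ValueError("empty signal track")
    if len(track.lrr) != len(snp_map):
        raise ValueError("track length does not match the marker map")
    lrr, baf = track.lrr, track.baf
    zgc = snp_map.standardized_gc()
    drift = np.mean(((baf > 0.2) & (baf < 0.25)) | ((baf > 0.75) & (baf < 0.8)))
    med = np.median(lrr)
    mad_sd = 1.4826 * np.median(np.abs(lrr - med))
    mask = np.abs(lrr - med) <= max(3 * mad_sd, 1e-12)
    zm, lm = zgc[mask], lrr[mask]
    zm = zm - zm.mean()
    denom = float(np.sum(zm**2))
    slope = float(np.sum(zm * (lm - lm.mean())) / denom) if denom > 0 else 0.0
    het = baf[(baf >= 0.25) & (baf <= 0.75)]
    sd_baf = float(np.std(het)) if het.size else 0.0
    return SampleQc(
        sample_id=track.sample_id,
        sd_lrr=float(np.std(lrr)),
        baf_drift=float(drift),
        gc_wave_factor=slope,
        sd_baf=sd_baf,
        outlier_rate=float(np.mean(np.abs(lrr) > 1.0)),
    )


def gc_correct(track: SignalTrack, snp_map: SnpMap) -> SignalTrack:
    """Residualize LRR on standardized local GC (genomic-wave correction).

    Only the GC-linear component is removed; the track mean (diploid
    baseline) is preserved.  Idempotent up to numerical tolerance.
    """
    zgc = snp_map.standardized_gc()
    denom = float(np.sum(zgc**2))
    if denom == 0:
        return replace(track, lrr=track.lrr.copy())
    slope = float(np.sum(zgc * (track.lrr - track.lrr.mean())) / denom)
    return replace(track, lrr=track.lrr - slope * zgc)


# ---------------------------------------------------------------- emissions


#: Small uniform outlier weight mixed into every BAF emission, so a single
#: off-model marker (genotyping artifact) cannot assign -inf likelihood to
#: the true state and break a segment.
BAF_OUTLIER_WEIGHT = 1e-4


def _truncnorm_pdf(x: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Density of a normal truncated to [0,1]."""
    z = (x - loc) / scale
    mass = ndtr((1.0 - loc) / scale) - ndtr((0.0 - loc) / scale)
    return np.exp(-0.5 * z * z) / (scale * np.sqrt(2 * np.pi) * mass)


def _baf_loglik(baf: np.ndarray, pfb: np.ndarray, cn: int, baf_sd: float) -> np.ndarray:
    """Log-likelihood of BAF under copy number ``cn``; shapes broadcast over
    (..., n_markers).

    The emission is a genotype mixture: k of cn copies carry the B allele
    with binomial weight at the marker's population B-allele frequency, and
    each genotype's BAF band is a truncated normal on [0,1] (homozygous
    bands compressed by the array chemistry).  CN0 carries no allelic
    signal and is uniform.
    """
    shape = np.broadcast_shapes(baf.shape, pfb.shape)
    if cn == 0:
        return np.zeros(shape)
    bands = BAF_BANDS[cn]
    density = np.full(shape, BAF_OUTLIER_WEIGHT)
    from math import comb

    for k, mu in enumerate(bands):
        w = comb(cn, k) * pfb**k * (1.0 - pfb) ** (cn - k)
        sd = baf_sd * HOM_NOISE_SHRINK if mu in (0.0, 1.0) else baf_sd
        density = density + w * _truncnorm_pdf(baf, float(mu), sd)
    return np.log(density)


def _estimate_sd(lrr: np.ndarray, params: CallerParams) -> np.ndarray:
    """Per-sample robust LRR noise scale, shape (n_samples,)."""
    if params.lrr_sd is not None:
        return np.full(lrr.shape[0], params.lrr_sd)
    mad = np.median(np.abs(lrr - np.median(lrr, axis=1, keepdims=True)), axis=1)
    return np.maximum(params.min_lrr_sd, 1.4826 * mad)


def _lrr_loglik(lrr: np.ndarray, params: CallerParams) -> np.ndarray:
    """Gaussian LRR log-likelihood per state, shape (S, M, 5)."""
    sd = _estimate_sd(lrr, params)[:, None, None]
    z = (lrr[:, :, None] - _STATE_MEANS[None, None, :]) / sd
    return -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(sd)


def _baf_loglik_all(baf: np.ndarray, snp_map: SnpMap, params: CallerParams) -> np.ndarray:
    """BAF log-likelihood per state, shape (S, M, 5)."""
    out = np.empty(baf.shape + (5,))
    pfb = snp_map.pfb[None, :]
    for s in range(5):
        out[:, :, s] = _baf_loglik(baf, pfb, s, params.baf_sd)
    return out


def emission_loglik(
    lrr: np.ndarray, baf: np.ndarray, snp_map: SnpMap, params: CallerParams
) -> np.ndarray:
    """Per-marker log-likelihood under each copy state.

    ``lrr``/``baf`` have shape (n_samples, n_markers); the result has shape
    (n_samples, n_markers, 5).
    """
    return _lrr_loglik(lrr, params) + _baf_loglik_all(baf, snp_map, params)


# ------------------------------------------------------------------ decoding


def _log_transitions(snp_map: SnpMap, params: CallerParams) -> np.ndarray:
    """Log transition matrices per inter-marker step, shape (M-1, 5, 5).

    Self-transition probability decays with marker distance d as
    1 - (1-p_stay)(1-exp(-d/D)); the leaving mass is split over the other
    states proportionally to the state prior.  Chromosome boundaries get
    d = +inf (maximal reset toward the prior).
    """
    pos = snp_map.pos.astype(float)
    d = np.diff(pos)
    d[np.diff(snp_map.chrom) != 0] = np.inf
    p_self = 1.0 - (1.0 - params.p_stay) * (1.0 - np.exp(-d / params.d_scale))
    prior = np.asarray(params.state_prior)
    T = np.empty((len(d), 5, 5))
    for i in range(5):
        w = prior.copy()
        w[i] = 0.0
        w = w / w.sum()
        T[:, i, :] = (1.0 - p_self)[:, None] * w[None, :]
        T[:, i, i] = p_self
    return np.log(T)


def viterbi_paths(
    emissions: np.ndarray, logT: np.ndarray, log_pi: np.ndarray
) -> np.ndarray:
    """Maximum-likelihood state paths, vectorized over samples.

    Parameters
    ----------
    emissions : (S, M, K) log-likelihoods
    logT : (M-1, K, K) per-step log transition matrices
    log_pi : (K,) log initial distribution

    Returns the decoded paths, shape (S, M), dtype int8.
    """
    S, M, K = emissions.shape
    score = log_pi[None, :] + emissions[:, 0, :]
    back = np.empty((S, M, K), dtype=np.int8)
    for m in range(1, M):
        cand = score[:, :, None] + logT[m - 1][None, :, :]  # (S, K_from, K_to)
        back[:, m, :] = np.argmax(cand, axis=1)
        score = np.max(cand, axis=1) + emissions[:, m, :]
    paths = np.empty((S, M), dtype=np.int8)
    paths[:, -1] = np.argmax(score, axis=1)
    rows = np.arange(S)
    for m in range(M - 1, 0, -1):
        paths[:, m - 1] = back[rows, m, paths[:, m]]
    return paths


def _segments_from_path(path: np.ndarray, diploid: int = 2) -> list[tuple[int, int, int]]:
    """Contiguous same-value runs of ``path`` not equal to ``diploid``, as
    (value, first, last) marker indices; runs never cross chromosome
    boundaries (handled by caller)."""
    segs = []
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(path) - 1]])
    for s, e in zip(starts, ends):
        if path[s] != diploid:
            segs.append((int(path[s]), int(s), int(e)))
    return segs


def _chromosome_bounds(snp_map: SnpMap) -> list[tuple[int, int]]:
    """(first, last) marker index per chromosome, in map order."""
    breaks = np.flatnonzero(np.diff(snp_map.chrom) != 0)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(snp_map) - 1]])
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


def maximal_scoring_segments(
    scores: np.ndarray, min_score: float
) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences with total score >= ``min_score``.

    Ruzzo-Tompa linear sweep over sign-compressed blocks: consecutive
    markers of equal sign collapse into one block, then the standard
    maximal-subsequence stack runs over blocks.  Returned tuples are
    (first index, last index, score); segments are disjoint and always
    start and end on positive markers.
    """
    pos_mask = scores > 0
    if not pos_mask.any():
        return []
    # compress runs of equal sign into blocks: (start, end, total)
    change = np.flatnonzero(np.diff(pos_mask))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(scores) - 1]])
    cum = np.concatenate([[0.0], np.cumsum(scores)])
    block_sum = cum[ends + 1] - cum[starts]
    # stack entries: [start_block, end_block, L (cum before), R (cum after)]
    stack: list[list[float]] = []
    for b in range(len(starts)):
        if block_sum[b] <= 0:
            continue
        cand = [b, b, float(cum[starts[b]]), float(cum[ends[b] + 1])]
        while True:
            j = None
            for idx in range(len(stack) - 1, -1, -1):
                if stack[idx][2] < cand[2]:
                    j = idx
                    break
            if j is None or stack[j][3] >= cand[3]:
                stack.append(cand)
                break
            cand = [stack[j][0], cand[1], stack[j][2], cand[3]]
            del stack[j:]
    out = []
    for b0, b1, L, R in stack:
        if R - L >= min_score:
            out.append((int(starts[int(b0)]), int(ends[int(b1)]), R - L))
    return out


def _split_by_chrom(snp_map: SnpMap, first: int, last: int) -> list[tuple[int, int]]:
    chroms = snp_map.chrom[first : last + 1]
    if chroms[0] == chroms[-1]:
        return [(first, last)]
    out = []
    breaks = np.flatnonzero(np.diff(chroms) != 0)
    lo = first
    for b in breaks:
        out.append((lo, first + int(b)))
        lo = first + int(b) + 1
    out.append((lo, last))
    return out


def _calls_from_paths(
    paths: np.ndarray,
    emissions: np.ndarray,
    snp_map: SnpMap,
    sample_ids: Sequence[str],
    caller: str,
    confidence_mode: str,
) -> list[list[CnvCall]]:
    """Turn decoded paths into per-sample call lists.

    ``confidence_mode='state'`` scores the called state against diploid;
    ``'maxbf'`` takes the best non-diploid state (MaxLogBF).  Both are
    log10 likelihood ratios summed over the segment.
    """
    out: list[list[CnvCall]] = []
    for s, sid in enumerate(sample_ids):
        calls: list[CnvCall] = []
        for state, first, last in _segments_from_path(paths[s]):
            for lo, hi in _split_by_chrom(snp_map, first, last):
                seg = emissions[s, lo : hi + 1, :]
                if confidence_mode == "maxbf":
                    lr = (seg.sum(axis=0) - seg[:, 2].sum()) / _LN10
                    conf = float(np.max(np.delete(lr, 2)))
                else:
                    conf = float((seg[:, state].sum() - seg[:, 2].sum()) / _LN10)
                calls.append(
                    CnvCall(
                        sample_id=sid,
                        chrom=int(snp_map.chrom[lo]),
                        start=int(snp_map.pos[lo]),
                        end=int(snp_map.pos[hi]),
                        copy_number=state,
                        n_probes=hi - lo + 1,
                        confidence=conf,
                        caller=caller,
                    )
                )
        out.append(calls)
    return out


def _stack_tracks(tracks: Sequence[SignalTrack]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    lrr = np.stack([t.lrr for t in tracks])
    baf = np.stack([t.baf for t in tracks])
    return lrr, baf, [t.sample_id for t in tracks]


def _decode_hmm(
    em: np.ndarray,
    snp_map: SnpMap,
    params: CallerParams,
    ids: Sequence[str],
    caller: str,
    confidence_mode: str,
) -> list[list[CnvCall]]:
    logT = _log_transitions(snp_map, params)
    log_pi = np.log(np.asarray(params.state_prior))
    paths = viterbi_paths(em, logT, log_pi)
    return _calls_from_paths(paths, em, snp_map, ids, caller, confidence_mode)


def _call_hmm_batch(
    tracks: Sequence[SignalTrack],
    snp_map: SnpMap,
    params: CallerParams,
    caller: str,
    confidence_mode: str,
) -> list[list[CnvCall]]:
    lrr, baf, ids = _stack_tracks(tracks)
    if lrr.shape[1] != len(snp_map):
        raise ValueError("track length does not match the marker map")
    em = emission_loglik(lrr, baf, snp_map, params)
    return _decode_hmm(em, snp_map, params, ids, caller, confidence_mode)


def call_hmm(
    track: SignalTrack, snp_map: SnpMap, params: CallerParams | None = None
) -> list[CnvCall]:
    """Hidden-Markov caller: Viterbi decoding over CN0..CN4 with
    distance-dependent transitions; confidence is the log10 likelihood
    ratio of the called state vs diploid over the segment."""
    params = params or CallerParams()
    return _call_hmm_batch([track], snp_map, params, "hmm", "state")[0]


def call_bayes(
    track: SignalTrack, snp_map: SnpMap, params: CallerParams | None = None
) -> list[CnvCall]:
    """Bayes-factor caller: GC-corrects the track, decodes with the same
    HMM machinery, and scores each segment by MaxLogBF — the log10 Bayes
    factor of the best non-diploid state vs diploid.  Calls with
    MaxLogBF <= 10 are emitted but dropped by the call-level QC."""
    params = params or CallerParams()
    corrected = gc_correct(track, snp_map)
    return _call_hmm_batch([corrected], snp_map, params, "bayes", "maxbf")[0]


def call_gaussian(
    track: SignalTrack, snp_map: SnpMap, params: CallerParams | None = None
) -> list[CnvCall]:
    """Gaussian-partition caller: classifies each marker by its best
    bivariate (LRR, BAF-band) Gaussian state and calls maximal same-state
    non-diploid runs whose cumulative log10-likelihood advantage over
    diploid reaches the confidence threshold (default 35)."""
    params = params or CallerParams()
    return _call_gaussian_batch([track], snp_map, params)[0]


def _call_gaussian_batch(
    tracks: Sequence[SignalTrack],
    snp_map: SnpMap,
    params: CallerParams,
    em: np.ndarray | None = None,
) -> list[list[CnvCall]]:
    lrr, baf, ids = _stack_tracks(tracks)
    if lrr.shape[1] != len(snp_map):
        raise ValueError("track length does not match the marker map")
    if em is None:
        em = emission_loglik(lrr, baf, snp_map, params)
    # per-marker log10 advantage of the best loss (CN0/CN1) and best gain
    # (CN3/CN4) state over diploid
    adv_loss = (np.maximum(em[:, :, 0], em[:, :, 1]) - em[:, :, 2]) / _LN10
    adv_gain = (np.maximum(em[:, :, 3], em[:, :, 4]) - em[:, :, 2]) / _LN10
    chrom_bounds = _chromosome_bounds(snp_map)
    out: list[list[CnvCall]] = []
    for s, sid in enumerate(ids):
        calls: list[CnvCall] = []
        for adv, candidates in ((adv_loss[s], (0, 1)), (adv_gain[s], (3, 4))):
            for c_lo, c_hi in chrom_bounds:
                for lo, hi, conf in maximal_scoring_segments(
                    adv[c_lo : c_hi + 1], params.gaussian_confidence
                ):
                    lo, hi = lo + c_lo, hi + c_lo
                    seg = em[s, lo : hi + 1, :]
                    state = max(candidates, key=lambda k: seg[:, k].sum())
                    calls.append(
                        CnvCall(
                            sample_id=sid,
                            chrom=int(snp_map.chrom[lo]),
                            start=int(snp_map.pos[lo]),
                            end=int(snp_map.pos[hi]),
                            copy_number=state,
                            n_probes=hi - lo + 1,
                            confidence=float(conf),
                            caller="gaussian",
                        )
                    )
        calls.sort(key=lambda c: (c.chrom, c.start, c.end))
        out.append(calls)
    return out


def call_cohort(
    tracks: Sequence[SignalTrack],
    snp_map: SnpMap,
    params: CallerParams | None = None,
    callers: Sequence[str] = ("hmm", "bayes", "gaussian"),
) -> dict[str, list[list[CnvCall]]]:
    """Run the requested callers over a whole cohort in batched mode.

    Returns a mapping caller -> per-sample call lists, aligned with
    ``tracks``.  Decoding each caller over all samples at once avoids
    per-sample Python overhead, so full simulation studies stay fast.
    """
    params = params or CallerParams()
    lrr, baf, ids = _stack_tracks(tracks)
    if lrr.shape[1] != len(snp_map):
        raise ValueError("track length does not match the marker map")
    # the BAF likelihood is shared by all three callers (GC correction only
    # touches LRR), so compute it once for the whole cohort
    baf_ll = _baf_loglik_all(baf, snp_map, params)
    out: dict[str, list[list[CnvCall]]] = {}
    em = None
    if "hmm" in callers or "gaussian" in callers:
        em = _lrr_loglik(lrr, params) + baf_ll
    if "hmm" in callers:
        out["hmm"] = _decode_hmm(em, snp_map, params, ids, "hmm", "state")
    if "bayes" in callers:
        corrected = np.stack([gc_correct(t, snp_map).lrr for t in tracks])
        em_b = _lrr_loglik(corrected, params) + baf_ll
        out["bayes"] = _decode_hmm(em_b, snp_map, params, ids, "bayes", "maxbf")
    if "gaussian" in callers:
        out["gaussian"] = _call_gaussian_batch(tracks, snp_map, params, em=em)
    return out
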