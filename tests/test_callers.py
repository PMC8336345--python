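"""CNV callers: QC metrics, GC correction, decoding accuracy and the
exhaustive-enumeration Viterbi oracle."""

import itertools

import numpy as np
import pytest

from cnvrassoc import (
    CallerParams,
    SignalTrack,
    build_snp_map,
    call_bayes,
    call_cohort,
    call_gaussian,
    call_hmm,
    gc_correct,
    sample_qc_metrics,
    simulate_cohort,
)
from cnvrassoc.callers import _log_transitions, emission_loglik, viterbi_paths


def diploid_track(snp_map, sample_id="s1"):
    baf = np.where(snp_map.pfb > 0.5, 1.0, 0.0)
    return SignalTrack(sample_id, "control", np.zeros(len(snp_map)), baf)


class TestSampleQc:
    def test_clean_track_all_zero(self, small_map):
        m = sample_qc_metrics(diploid_track(small_map), small_map)
        assert m.sd_lrr == 0.0
        assert m.baf_drift == 0.0
        assert m.outlier_rate == 0.0

    def test_sd_lrr_estimator_consistency(self):
        big = build_snp_map(1, 10000, 3000, 1e6, seed=5)
        tracks, _ = simulate_cohort(big, [], 1, 0, sd_lrr=0.40, seed=8)
        m = sample_qc_metrics(tracks[0], big)
        assert 0.38 < m.sd_lrr < 0.42

    def test_gc_wave_factor_recovers_slope(self, small_map):
        t = diploid_track(small_map)
        t.lrr = 0.05 * small_map.standardized_gc()
        m = sample_qc_metrics(t, small_map)
        assert m.gc_wave_factor == pytest.approx(0.05, abs=1e-12)

    def test_baf_drift_counts_off_cluster_bands(self, small_map):
        t = diploid_track(small_map)
        t.baf = t.baf.copy()
        t.baf[:120] = 0.22  # 10% of markers in the drift band
        m = sample_qc_metrics(t, small_map)
        assert m.baf_drift == pytest.approx(0.1)

    def test_empty_track_rejected(self, small_map):
        t = SignalTrack("x", "case", np.array([]), np.array([]))
        with pytest.raises(ValueError):
            sample_qc_metrics(t, small_map)


class TestGcCorrect:
    def test_no_wave_is_identity(self, small_map):
        t = diploid_track(small_map)
        out = gc_correct(t, small_map)
        assert np.max(np.abs(out.lrr - t.lrr)) < 1e-9

    def test_removes_injected_wave(self, small_map):
        tracks, _ = simulate_cohort(
            small_map, [], 1, 0, sd_lrr=0.1, gc_wave_amplitude=0.05, seed=3
        )
        before = sample_qc_metrics(tracks[0], small_map).gc_wave_factor
        after = sample_qc_metrics(gc_correct(tracks[0], small_map), small_map).gc_wave_factor
        assert abs(before) > 0.04
        assert abs(after) < 0.005

    def test_idempotent(self, small_map):
        tracks, _ = simulate_cohort(
            small_map, [], 1, 0, sd_lrr=0.2, gc_wave_amplitude=0.08, seed=4
        )
        once = gc_correct(tracks[0], small_map)
        twice = gc_correct(once, small_map)
        assert np.max(np.abs(twice.lrr - once.lrr)) < 1e-9


class TestCallers:
    @pytest.mark.parametrize("caller", [call_hmm, call_bayes, call_gaussian])
    def test_noise_free_diploid_yields_no_calls(self, small_map, caller):
        assert caller(diploid_track(small_map), small_map) == []

    def test_hmm_recovers_deletion(self, small_map, deletion_locus):
        tracks, _ = simulate_cohort(
            small_map, [deletion_locus], 1, 0, sd_lrr=0.15, seed=3
        )
        calls = call_hmm(tracks[0], small_map)
        assert len(calls) == 1
        c = calls[0]
        assert c.copy_type == "loss"
        overlap = min(c.end, deletion_locus.end) - max(c.start, deletion_locus.start) + 1
        truth_len = deletion_locus.end - deletion_locus.start + 1
        assert overlap / truth_len >= 0.9

    def test_bayes_strong_deletion_exceeds_bf_threshold(self, small_map, deletion_locus):
        tracks, _ = simulate_cohort(
            small_map, [deletion_locus], 1, 0, sd_lrr=0.15, seed=3
        )
        calls = call_bayes(tracks[0], small_map)
        assert len(calls) == 1
        assert calls[0].confidence > 10

    def test_bayes_maxbf_matches_direct_computation(self, small_map, deletion_locus):
        tracks, _ = simulate_cohort(
            small_map, [deletion_locus], 1, 0, sd_lrr=0.15, seed=3
        )
        params = CallerParams()
        corrected = gc_correct(tracks[0], small_map)
        call = call_bayes(tracks[0], small_map, params)[0]
        em = emission_loglik(
            corrected.lrr[None, :], corrected.baf[None, :], small_map, params
        )[0]
        sl = small_map.marker_slice(call.chrom, call.start, call.end)
        lr = (em[sl].sum(axis=0) - em[sl, 2].sum()) / np.log(10)
        expected = max(lr[s] for s in (0, 1, 3, 4))
        assert call.confidence == pytest.approx(expected)

    def test_gaussian_recovers_duplication_with_high_confidence(
        self, small_map, duplication_locus
    ):
        tracks, _ = simulate_cohort(
            small_map, [duplication_locus], 1, 0, sd_lrr=0.15, seed=5
        )
        calls = call_gaussian(tracks[0], small_map)
        assert len(calls) == 1
        assert calls[0].copy_type == "gain"
        assert calls[0].confidence >= 35

    def test_gaussian_boundaries_tight_at_low_noise(self, small_map, duplication_locus):
        tracks, _ = simulate_cohort(
            small_map, [duplication_locus], 1, 0, sd_lrr=0.10, seed=6
        )
        calls = call_gaussian(tracks[0], small_map)
        assert len(calls) == 1
        c = calls[0]
        pos = small_map.pos
        start_i = int(np.searchsorted(pos, c.start))
        end_i = int(np.searchsorted(pos, c.end))
        assert abs(start_i - 700) <= 5
        assert abs(end_i - 799) <= 5

    @pytest.mark.parametrize("caller", [call_hmm, call_bayes, call_gaussian])
    def test_deterministic(self, small_map, deletion_locus, caller):
        tracks, _ = simulate_cohort(
            small_map, [deletion_locus], 1, 0, sd_lrr=0.2, seed=7
        )
        assert caller(tracks[0], small_map) == caller(tracks[0], small_map)

    def test_calls_lie_on_map_markers(self, small_map, deletion_locus):
        tracks, _ = simulate_cohort(
            small_map, [deletion_locus], 5, 0, sd_lrr=0.2, seed=8
        )
        for per_sample in call_cohort(tracks, small_map).values():
            for calls in per_sample:
                for c in calls:
                    assert c.start in small_map.pos and c.end in small_map.pos
                    assert c.n_probes == small_map.n_probes(c.chrom, c.start, c.end)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CallerParams(state_prior=(0.2, 0.2, 0.2, 0.2, 0.1))
        with pytest.raises(ValueError):
            CallerParams(p_stay=1.5)


class TestViterbiOracle:
    def test_decoder_matches_exhaustive_enumeration(self):
        """Viterbi path equals the argmax over every possible 5-state path
        on small instances (brute force over 5^M paths)."""
        snp_map = build_snp_map(1, 10, 5000, 1e6, seed=13)
        params = CallerParams(lrr_sd=0.3)
        logT = _log_transitions(snp_map, params)
        log_pi = np.log(np.asarray(params.state_prior))
        rng = np.random.default_rng(99)
        for trial in range(3):
            n = 8
            em = rng.normal(0, 2.0, size=(1, n, 5))
            decoded = viterbi_paths(em, logT[: n - 1], log_pi)[0]
            # enumerate all 5^8 paths vectorized
            paths = np.array(list(itertools.product(range(5), repeat=n)), dtype=np.int8)
            scores = log_pi[paths[:, 0]] + em[0, np.arange(n), paths].sum(axis=1)
            scores += logT[np.arange(n - 1), paths[:, :-1], paths[:, 1:]].sum(axis=1)
            best = scores.max()
            decoded_score = (
                log_pi[decoded[0]]
                + em[0, np.arange(n), decoded].sum()
                + logT[np.arange(n - 1), decoded[:-1], decoded[1:]].sum()
            )
            assert decoded_score == pytest.approx(best, abs=1e-9)


class TestCallerOperatingCharacteristics:
    def test_sensitivity_and_specificity_at_reference_noise(self, small_map):
        """Each caller finds >=90% of 50-probe implanted events at LRR noise
        0.2 over 200 carriers, and makes <=2 false calls per diploid sample."""
        from cnvrassoc import CnvLocus

        locus = CnvLocus(
            1, int(small_map.pos[400]), int(small_map.pos[449]), 1, 1.0, 0.0
        )
        tracks, _ = simulate_cohort(small_map, [locus], 200, 100, sd_lrr=0.2, seed=21)
        raw = call_cohort(tracks, small_map)
        for caller, per_sample in raw.items():
            hits = 0
            false_calls = 0
            for t, calls in zip(tracks, per_sample):
                overlapping = [
                    c
                    for c in calls
                    if c.copy_type == "loss" and c.start <= locus.end and c.end >= locus.start
                ]
                if t.phenotype == "case":
                    hits += bool(overlapping)
                else:
                    false_calls += len(calls)
            assert hits / 200 >= 0.9, caller
            assert false_calls / 100 <= 2, caller


class TestMaximalScoringSegments:
    def test_properties_on_random_scores(self):
        """Segments are disjoint, start/end on positive markers, have the
        reported score, and clear the threshold."""
        from cnvrassoc.callers import maximal_scoring_segments

        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.normal(-0.3, 1.0, 300)
            segs = maximal_scoring_segments(scores, 2.0)
            last_end = -1
            for lo, hi, score in segs:
                assert lo > last_end
                last_end = hi
                assert scores[lo] > 0 and scores[hi] > 0
                assert score == pytest.approx(scores[lo : hi + 1].sum())
                assert score >= 2.0

    def test_bridges_interior_dip(self):
        from cnvrassoc.callers import maximal_scoring_segments

        scores = np.array([4.0, -1.0, 5.0])
        assert maximal_scoring_segments(scores, 2.0) == [(0, 2, 8.0)]

    def test_keeps_separated_peaks_apart(self):
        from cnvrassoc.callers import maximal_scoring_segments

        scores = np.array([5.0, -10.0, 3.0])
        assert maximal_scoring_segments(scores, 2.0) == [(0, 0, 5.0), (2, 2, 3.0)]
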