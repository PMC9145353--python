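"""Beat detection, SPWVD maps, template-matching quality scores."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgsync import (
    QualityUndefinedError,
    RhythmSpec,
    SamplePair,
    Signal,
    SqiConfig,
    beat_scores,
    beat_tfmap,
    detect_beats,
    generate_record_pair,
    resample,
    sample_sqi,
    sqi_filter,
)
from ecgsync.sqi import QualityReport
from ecgsync.synth import LEAD_I, render_lead


class TestDetectBeats:
    def test_clean_60bpm_recall_and_precision(self, clean_record, clean_lead_250):
        _, _, r_true = clean_record
        beats = detect_beats(clean_lead_250)
        assert abs(len(beats) - len(r_true)) <= 1
        # precision: every detection matches a true beat within 50 ms
        for t in beats.times:
            assert np.min(np.abs(r_true - t)) < 0.05
        # recall: every interior true beat is detected within 50 ms
        interior = r_true[(r_true > 1) & (r_true < clean_lead_250.duration - 1)]
        for t in interior:
            assert np.min(np.abs(beats.times - t)) < 0.05

    def test_flat_signal_yields_empty_annotation(self):
        beats = detect_beats(Signal(np.zeros(5000), fs=250.0))
        assert len(beats) == 0

    def test_premature_beat_increases_count_by_one(self):
        rhythm = RhythmSpec(mean_hr=60, rr_jitter_sd=0.0, ectopy_rate=0.0)
        lead_i, _, r_times = generate_record_pair(30, rhythm, seed=3)
        base = len(detect_beats(resample(lead_i, 250.0)))
        # re-render with one premature beat squeezed between two beats
        inserted = np.sort(np.append(r_times, r_times[10] + 0.45))
        sig = render_lead(inserted, 30, 257.0, LEAD_I)
        withx = len(detect_beats(resample(sig, 250.0)))
        assert withx == base + 1

    def test_refractory_period_enforced(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        assert np.all(np.diff(beats.r_samples) >= 0.2 * beats.fs)


class TestBeatTFMap:
    def test_pure_tone_ridge_at_10hz(self):
        fs = 250.0
        t = np.arange(int(5 * fs)) / fs
        sig = Signal(np.sin(2 * np.pi * 10.0 * t), fs=fs)
        tf = beat_tfmap(sig, int(2.5 * fs))
        ridge = tf.freqs[np.argmax(tf.values, axis=0)]
        interior = slice(20, tf.values.shape[1] - 20)
        assert np.all(np.abs(ridge[interior] - 10.0) < 1.0)

    def test_bilinear_scaling(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        r = int(beats.r_samples[5])
        base = beat_tfmap(clean_lead_250, r).values
        doubled = beat_tfmap(
            Signal(2 * clean_lead_250.samples, fs=250.0), r).values
        npt.assert_allclose(doubled, 4 * base, rtol=1e-9, atol=1e-12)

    def test_deterministic_for_identical_beats(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        a = beat_tfmap(clean_lead_250, int(beats.r_samples[4])).values
        b = beat_tfmap(clean_lead_250, int(beats.r_samples[4])).values
        npt.assert_array_equal(a, b)

    def test_window_out_of_bounds_signals_skip(self, clean_lead_250):
        from ecgsync.sqi import _WindowOutOfBounds, _beat_window
        with pytest.raises(_WindowOutOfBounds):
            _beat_window(clean_lead_250, 3, SqiConfig())

    def test_nonnegative_fixed_shape(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        shapes = set()
        for r in beats.r_samples[2:6]:
            v = beat_tfmap(clean_lead_250, int(r)).values
            assert np.all(v >= 0) and np.all(np.isfinite(v))
            shapes.add(v.shape)
        assert len(shapes) == 1


class TestBeatScores:
    def test_identical_beats_score_one(self, clean_lead_250):
        report = beat_scores(clean_lead_250, detect_beats(clean_lead_250))
        # regular no-jitter rhythm: every beat matches its template exactly
        npt.assert_allclose(report.beat_scores, 1.0, atol=1e-9)
        assert sample_sqi(report, 0.9) == 1.0

    def test_first_three_beats_unscored(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        report = beat_scores(clean_lead_250, beats)
        # beats at the record edge lack a full window and are also skipped
        assert report.n_scored <= len(beats) - 3

    def test_noise_corrupted_beat_scores_low(self, clean_record):
        lead_i = resample(clean_record[0], 250.0)
        beats = detect_beats(lead_i)
        x = lead_i.samples.copy()
        r = int(beats.r_samples[10])
        lo, hi = r - int(0.25 * 250), r + int(0.45 * 250)
        rms = np.sqrt(np.mean(x[lo:hi] ** 2))
        rng = np.random.default_rng(8)
        x[lo:hi] = rng.normal(scale=rms, size=hi - lo)
        report = beat_scores(Signal(x, fs=250.0), beats)
        scores = dict(zip(report.scored_beat_indices, report.beat_scores))
        assert scores[10] < 0.5
        assert scores[8] > 0.9 and scores[14] > 0.9

    def test_scores_invariant_to_global_amplitude(self, clean_lead_250):
        beats = detect_beats(clean_lead_250)
        a = beat_scores(clean_lead_250, beats).beat_scores
        b = beat_scores(Signal(3.7 * clean_lead_250.samples, fs=250.0),
                        beats).beat_scores
        npt.assert_allclose(a, b, atol=1e-9)

    def test_too_few_beats_rejected(self):
        fs = 250.0
        t = np.arange(int(6 * fs)) / fs
        sig = Signal(np.sin(2 * np.pi * 1.0 * t), fs=fs)
        beats = detect_beats(Signal(np.zeros(int(6 * fs)), fs=fs))
        with pytest.raises(QualityUndefinedError):
            beat_scores(sig, beats)


def _report(scores):
    scores = np.asarray(scores, dtype=float)
    return QualityReport(
        beat_scores=scores,
        scored_beat_indices=np.arange(3, 3 + scores.size),
        r_samples=np.arange(3, 3 + scores.size) * 250,
        fs=250.0,
    )


class TestSampleSqi:
    def test_fraction_of_good_beats(self):
        rep = _report([0.95] * 4 + [0.5] * 6)
        assert sample_sqi(rep, 0.9) == pytest.approx(0.4)

    def test_all_good(self):
        assert sample_sqi(_report([0.99] * 5), 0.9) == 1.0

    def test_empty_report_rejected(self):
        with pytest.raises(QualityUndefinedError):
            sample_sqi(_report([]), 0.9)

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=30),
           st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, scores, t1, t2):
        lo, hi = sorted([t1, t2])
        rep = _report(scores)
        assert sample_sqi(rep, hi) <= sample_sqi(rep, lo)


class TestSqiFilter:
    def _pairs(self, sqis, jittered_record):
        lead_i, lead_v2, _ = jittered_record
        pair = SamplePair(lead_i.slice_seconds(30, 60),
                          lead_v2.slice_seconds(0, 90))
        return [(pair, q) for q in sqis]

    def test_threshold_zero_retains_all(self, jittered_record):
        kept, ratio = sqi_filter(self._pairs([0.1, 0.5, 0.9], jittered_record), 0.0)
        assert len(kept) == 3 and ratio == 1.0

    def test_threshold_one_keeps_perfect_only(self, jittered_record):
        kept, ratio = sqi_filter(self._pairs([1.0, 0.8, 1.0], jittered_record), 1.0)
        assert len(kept) == 2 and ratio == pytest.approx(2 / 3)

    def test_boundary_is_inclusive(self, jittered_record):
        kept, _ = sqi_filter(self._pairs([0.49, 0.50], jittered_record), 0.5)
        assert len(kept) == 1

    def test_retained_count_monotone_in_threshold(self, jittered_record):
        pairs = self._pairs(np.linspace(0, 1, 11), jittered_record)
        sizes = [len(sqi_filter(pairs, t)[0]) for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestSpwvdQuality:
    def test_sqi_degrades_with_snr(self):
        """Mean sample SQI increases with SNR (electrode-motion noise)."""
        from scipy.stats import spearmanr
        from ecgsync.synth import add_noise_kind

        rhythm = RhythmSpec(mean_hr=70, rr_jitter_sd=0.04, ectopy_rate=0.0)
        snrs = [24, 12, 0, -6]
        means = []
        for snr in snrs:
            vals = []
            for seed in range(5):
                lead_i, _, _ = generate_record_pair(30, rhythm, seed=seed)
                noisy = resample(add_noise_kind(lead_i, "EM", snr, seed=seed + 50),
                                 250.0)
                try:
                    rep = beat_scores(noisy, detect_beats(noisy))
                    vals.append(sample_sqi(rep, 0.9))
                except (QualityUndefinedError, ValueError):
                    vals.append(0.0)
            means.append(np.mean(vals))
        rho = spearmanr(snrs, means).statistic
        assert rho > 0
        assert means[0] > means[-1]
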