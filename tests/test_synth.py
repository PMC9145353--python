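"""Synthetic generator: rhythm, morphology, sampling design, noise calibration."""

import numpy as np
import numpy.testing as npt
import pytest
from scipy.signal import periodogram

from ecgsync import (
    LEAD_I,
    LEAD_V2,
    RhythmSpec,
    Signal,
    add_noise,
    generate_noise,
    generate_record_pair,
    select_samples,
)
from ecgsync.synth import generate_rhythm


class TestRhythm:
    def test_half_hour_beat_count_at_60bpm(self):
        rhythm = RhythmSpec(mean_hr=60, rr_jitter_sd=0.0, ectopy_rate=0.0)
        lead_i, _, r_times = generate_record_pair(1800, rhythm, seed=0)
        assert abs(len(r_times) - 1800) <= 1
        assert len(lead_i) == 1800 * 257

    def test_ectopy_inserts_short_then_compensatory_interval(self):
        rng = np.random.default_rng(0)
        rhythm = RhythmSpec(mean_hr=60, rr_jitter_sd=0.0, ectopy_rate=0.3)
        times = generate_rhythm(120, rhythm, rng)
        rr = np.diff(times)
        short = rr < 0.8
        assert short.any()
        after = rr[1:][short[:-1]]
        assert np.all(after > 1.1)  # every premature beat is followed by a pause

    def test_af_mode_rr_within_band(self):
        rng = np.random.default_rng(1)
        times = generate_rhythm(300, RhythmSpec(af_mode=True), rng)
        rr = np.diff(times)
        assert rr.min() >= 0.4 - 1e-9 and rr.max() <= 1.2 + 1e-9
        assert np.std(rr) > 0.1  # irregularly irregular

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RhythmSpec(mean_hr=20)
        with pytest.raises(ValueError):
            RhythmSpec(ectopy_rate=1.5)


class TestRecordPair:
    def test_same_seed_bit_identical(self):
        a = generate_record_pair(30, seed=5)
        b = generate_record_pair(30, seed=5)
        npt.assert_array_equal(a[0].samples, b[0].samples)
        npt.assert_array_equal(a[1].samples, b[1].samples)
        npt.assert_array_equal(a[2], b[2])

    def test_leads_share_beat_positions(self):
        lead_i, lead_v2, r_times = generate_record_pair(30, seed=2)
        fs = 257.0
        for t in r_times[1:-1]:
            k = int(round(t * fs))
            w = slice(max(0, k - 5), k + 6)
            assert abs(np.argmax(lead_i.samples[w]) - np.argmax(lead_v2.samples[w])) <= 1

    def test_r_wave_dominates_both_leads(self):
        for morph in (LEAD_I, LEAD_V2):
            r_amp = abs(morph.waves["R"].amplitude)
            assert all(abs(w.amplitude) < r_amp
                       for k, w in morph.waves.items() if k != "R")

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_record_pair(5, seed=0)


class TestSelectSamples:
    def test_search_is_sixty_seconds_longer(self, jittered_record):
        lead_i, lead_v2, _ = jittered_record
        pairs = select_samples(lead_i, lead_v2, m=30, n_samples=3, seed=0)
        for p in pairs:
            assert p.search.duration - p.reference.duration == pytest.approx(60.0, abs=0.01)
            assert p.true_lag == 30.0

    def test_requested_count_honored(self, jittered_record):
        lead_i, lead_v2, _ = jittered_record
        assert len(select_samples(lead_i, lead_v2, m=30, n_samples=100, seed=1)) == 100

    def test_short_record_rejected_with_minimum_duration(self, clean_record):
        lead_i, lead_v2, _ = clean_record  # 60 s record
        with pytest.raises(ValueError, match="90.0 s"):
            select_samples(lead_i, lead_v2, m=30, n_samples=1, margin=30)

    def test_reference_matches_search_window_in_v2_geometry(self, jittered_record):
        """Ground-truth consistency: cutting lead V2 at the reference's own
        indices reproduces the search window at true_lag exactly."""
        lead_i, lead_v2, _ = jittered_record
        for p in select_samples(lead_i, lead_v2, m=20, n_samples=5, seed=3):
            s = p.meta["start_s"]
            v2_cut = lead_v2.slice_seconds(
                p.search.t0 + p.true_lag, p.search.t0 + p.true_lag + 20)
            k0 = int(round(p.true_lag * p.search.fs))
            npt.assert_array_equal(
                p.search.samples[k0: k0 + len(v2_cut)], v2_cut.samples)


class TestNoise:
    @pytest.mark.parametrize("kind", ["BW", "EM", "MA"])
    def test_unit_rms(self, kind):
        sig = generate_noise(kind, 30, 257.0, seed=4)
        assert np.sqrt(np.mean(sig.samples**2)) == pytest.approx(1.0, abs=1e-9)

    def test_bw_power_below_1hz(self):
        sig = generate_noise("BW", 120, 257.0, seed=0)
        f, p = periodogram(sig.samples, fs=257.0)
        assert p[f < 1.0].sum() / p.sum() >= 0.95

    def test_ma_power_above_15hz(self):
        sig = generate_noise("MA", 120, 257.0, seed=0)
        f, p = periodogram(sig.samples, fs=257.0)
        assert p[f > 15.0].sum() / p.sum() >= 0.90

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown noise kind"):
            generate_noise("powerline", 10, 257.0)

    def test_deterministic(self):
        a = generate_noise("EM", 20, 257.0, seed=9)
        b = generate_noise("EM", 20, 257.0, seed=9)
        npt.assert_array_equal(a.samples, b.samples)


class TestAddNoise:
    @pytest.fixture
    def ecg(self, jittered_record):
        return jittered_record[0].slice_seconds(10, 40)

    def test_zero_db_equalizes_powers(self, ecg):
        noise = generate_noise("MA", 30, 257.0, seed=1)
        noise = Signal(noise.samples[: len(ecg)], fs=257.0)
        out = add_noise(ecg, noise, 0.0)
        added = out.samples - ecg.samples
        npt.assert_allclose(np.var(added), np.var(ecg.samples), rtol=1e-6)

    @pytest.mark.parametrize("snr", [-6, 0, 6, 12, 18, 24])
    @pytest.mark.parametrize("kind", ["BW", "EM", "MA"])
    def test_round_trip_snr_within_001_db(self, ecg, kind, snr):
        noise = generate_noise(kind, 30, 257.0, seed=2)
        noise = Signal(noise.samples[: len(ecg)], fs=257.0)
        out = add_noise(ecg, noise, snr)
        added = out.samples - ecg.samples
        achieved = 10 * np.log10(np.var(ecg.samples) / np.var(added))
        assert abs(achieved - snr) < 0.01

    def test_minus_six_db_noise_power_ratio(self, ecg):
        noise = generate_noise("EM", 30, 257.0, seed=3)
        noise = Signal(noise.samples[: len(ecg)], fs=257.0)
        out = add_noise(ecg, noise, -6.0)
        added = out.samples - ecg.samples
        ratio = np.var(added) / np.var(ecg.samples)
        npt.assert_allclose(ratio, 10 ** 0.6, rtol=1e-6)  # ~3.981

    def test_zero_power_inputs_rejected(self, ecg):
        flat = Signal(np.zeros(len(ecg)), fs=257.0)
        with pytest.raises(ValueError, match="zero-power"):
            add_noise(flat, ecg, 0.0)
        with pytest.raises(ValueError, match="zero-power"):
            add_noise(ecg, flat, 0.0)
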