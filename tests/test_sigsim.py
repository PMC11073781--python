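"""Simulator: beat trains, lead mixing, cohort generation."""

import numpy as np
import pytest

from fetalpeaks.sigsim import (FETAL_MORPHOLOGY, MATERNAL_MORPHOLOGY,
                               BeatMorphology, SimConfig, SimConfigError,
                               WaveParams, generate_cohort, mix_abdominal,
                               simulate_record, synth_beat_train)


def _unit_rms(x):
    return x / np.sqrt(np.mean(x ** 2))


class TestSynthBeatTrain:
    def test_zero_amplitude_gives_flat_trace_with_scheduled_peaks(self):
        trace, peaks = synth_beat_train(
            120, 0, BeatMorphology.zero(), fs=1000, duration=10,
            rng=np.random.default_rng(0))
        assert np.all(trace == 0)
        assert len(peaks) > 0

    def test_constant_rate_gives_exact_half_second_intervals(self):
        _, peaks = synth_beat_train(
            120, 0, MATERNAL_MORPHOLOGY, fs=1000, duration=10,
            rng=np.random.default_rng(0))
        assert len(peaks) in (19, 20, 21)
        assert np.all(np.diff(peaks) == 500)

    def test_trace_length_matches_duration(self):
        trace, _ = synth_beat_train(140, 5, FETAL_MORPHOLOGY, fs=1000,
                                    duration=7.3,
                                    rng=np.random.default_rng(1))
        assert len(trace) == 7300

    def test_peak_count_matches_renewal_process_oracle(self):
        """Count beats by stepping cumulative truncated-normal R-R sums with
        the same seed path, independently of the waveform synthesis."""
        seed, hr_mean, hr_sd, duration = 7, 140.0, 5.0, 60.0
        _, peaks = synth_beat_train(hr_mean, hr_sd, FETAL_MORPHOLOGY,
                                    fs=1000, duration=duration,
                                    rng=np.random.default_rng(seed))
        rng = np.random.default_rng(seed)
        rr_mean = 60.0 / hr_mean
        rr_sd = 60.0 * hr_sd / hr_mean ** 2
        lo, hi = max(0.2, rr_mean - 3 * rr_sd), rr_mean + 3 * rr_sd
        intervals = []
        total = 0.0
        while total < duration + rr_mean:
            rr = rng.normal(rr_mean, rr_sd)
            while not (lo <= rr <= hi):
                rr = rng.normal(rr_mean, rr_sd)
            intervals.append(rr)
            total += rr
        t = 0.5 * intervals[0]
        count = 0
        for k in range(len(intervals)):
            if t >= duration:
                break
            count += 1
            if k + 1 < len(intervals):
                t += intervals[k + 1]
        assert len(peaks) == count

    def test_peaks_sit_on_local_maxima_of_clean_trace(self):
        trace, peaks = synth_beat_train(140, 5, FETAL_MORPHOLOGY, fs=1000,
                                        duration=30,
                                        rng=np.random.default_rng(3))
        for p in peaks:
            lo, hi = max(0, p - 2), min(len(trace), p + 3)
            assert trace[p] == pytest.approx(trace[lo:hi].max())

    def test_invalid_config_rejected(self):
        with pytest.raises(SimConfigError):
            synth_beat_train(120, 0, FETAL_MORPHOLOGY, fs=-1, duration=10)
        with pytest.raises(SimConfigError):
            synth_beat_train(120, 0, FETAL_MORPHOLOGY, fs=1000, duration=0.1)


class TestMorphologyInvariants:
    def test_r_wave_must_dominate(self):
        with pytest.raises(SimConfigError):
            BeatMorphology(P=WaveParams(1.2, 0.2, -1.0),
                           Q=WaveParams(-0.1, 0.1, -0.3),
                           R=WaveParams(1.0, 0.1, 0.0),
                           S=WaveParams(-0.1, 0.1, 0.3),
                           T=WaveParams(0.3, 0.4, 1.5))

    def test_width_must_be_positive(self):
        with pytest.raises(SimConfigError):
            WaveParams(0.5, 0.0, 0.0)


class TestMixAbdominal:
    def _sources(self, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        m, _ = synth_beat_train(80, 3, MATERNAL_MORPHOLOGY, 1000, n / 1000,
                                rng=rng)
        f, _ = synth_beat_train(140, 5, FETAL_MORPHOLOGY, 1000, n / 1000,
                                rng=rng)
        return _unit_rms(m), _unit_rms(f)

    def test_zero_fetal_zero_noise_is_scalar_multiple_of_maternal(self):
        m, _ = self._sources()
        cfg = SimConfig(duration=20, noise_baseline=0, noise_powerline=0,
                        noise_white=0, rng_seed=5, full_scale=20.0)
        rec, _ = mix_abdominal(m, np.zeros_like(m), cfg)
        step = 2 * cfg.full_scale / 2 ** cfg.quantization_bits
        gains = rec.meta["gains_maternal"]
        for ch in range(rec.n_channels):
            assert np.max(np.abs(rec.signal[ch] - gains[ch] * m)) <= step

    def test_mixing_is_linear_up_to_quantization(self):
        m, f = self._sources()
        # generous full scale so no sample clips and pure superposition holds
        cfg = SimConfig(duration=20, rng_seed=11, full_scale=20.0)
        r_ab, _ = mix_abdominal(m, f, cfg)
        r_cd, _ = mix_abdominal(0.3 * m, 0.5 * f, cfg)
        r_sum, _ = mix_abdominal(1.3 * m, 1.5 * f, cfg)
        # both runs share the seed, hence gains and noise; subtracting the
        # common noise once leaves the pure superposition
        r_zero, _ = mix_abdominal(np.zeros_like(m), np.zeros_like(f), cfg)
        lhs = r_ab.signal + r_cd.signal - r_zero.signal
        step = 2 * cfg.full_scale / 2 ** cfg.quantization_bits
        assert np.max(np.abs(lhs - r_sum.signal)) <= 3 * step

    def test_white_noise_rms_calibration(self):
        cfg = SimConfig(duration=60, noise_baseline=0, noise_powerline=0,
                        noise_white=0.25, rng_seed=2)
        z = np.zeros(60_000)
        rec, _ = mix_abdominal(z, z, cfg)
        rms = np.sqrt(np.mean(rec.signal ** 2, axis=1))
        assert np.all(np.abs(rms - 0.25) / 0.25 < 0.05)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mix_abdominal(np.zeros(100), np.zeros(99), SimConfig())

    def test_amplitude_ratio_on_each_channel(self):
        m, f = self._sources(60_000)
        cfg = SimConfig(duration=60, fetal_to_maternal_amplitude_ratio=0.3,
                        noise_baseline=0, noise_powerline=0, noise_white=0,
                        rng_seed=4)
        rec, _ = mix_abdominal(m, f, cfg)
        g_m = np.asarray(rec.meta["gains_maternal"])
        g_f = np.asarray(rec.meta["gains_fetal"])
        ratio = (np.abs(g_f) * np.sqrt(np.mean(f ** 2))
                 / (np.abs(g_m) * np.sqrt(np.mean(m ** 2))))
        assert np.all(np.abs(ratio - 0.3) / 0.3 <= 0.10)

    def test_quantized_values_lie_on_grid(self):
        m, f = self._sources()
        cfg = SimConfig(duration=20, rng_seed=9)
        rec, _ = mix_abdominal(m, f, cfg)
        step = 2 * cfg.full_scale / 2 ** cfg.quantization_bits
        frac = rec.signal / step
        assert np.allclose(frac, np.round(frac), atol=1e-6)


class TestSimulateRecord:
    def test_fetal_peaks_are_local_maxima_of_clean_source(self):
        cfg = SimConfig(duration=30, rng_seed=21)
        _, gt = simulate_record(cfg)
        src = gt.fetal_source
        for p in gt.fetal_peak_samples:
            lo, hi = max(0, p - 2), min(len(src), p + 3)
            assert src[p] == pytest.approx(src[lo:hi].max())

    def test_ground_truth_peaks_strictly_increasing_and_in_bounds(self):
        cfg = SimConfig(duration=30, rng_seed=22)
        rec, gt = simulate_record(cfg)
        for peaks in (gt.fetal_peak_samples, gt.maternal_peak_samples):
            assert np.all(np.diff(peaks) > 0)
            assert peaks.min() >= 0 and peaks.max() < rec.n_samples


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(2, SimConfig(duration=5), seed=3)
        b = generate_cohort(2, SimConfig(duration=5), seed=3)
        for (ra, ga), (rb, gb) in zip(a, b):
            assert np.array_equal(ra.signal, rb.signal)
            assert np.array_equal(ga.fetal_peak_samples, gb.fetal_peak_samples)

    def test_26_subjects_have_distinct_ids(self):
        cohort = generate_cohort(26, SimConfig(duration=2), seed=0)
        ids = [rec.subject_id for rec, _ in cohort]
        assert len(ids) == 26 and len(set(ids)) == 26

    def test_fetal_hr_means_within_configured_range(self):
        cohort = generate_cohort(100, SimConfig(duration=2), seed=1)
        hrs = [rec.meta["fetal_hr_mean"] for rec, _ in cohort]
        assert all(110.0 <= h <= 160.0 for h in hrs)

    def test_n_subjects_must_be_positive(self):
        with pytest.raises(SimConfigError):
            generate_cohort(0, SimConfig(duration=2), seed=0)
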