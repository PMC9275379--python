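"""Synthetic generator: determinism, shape contracts, planted effects."""
import numpy as np
import pytest
from scipy import signal as sps

from microfusion.synth import (
    EFFECT_HALFSPAN_SECONDS,
    GeneratorConfig,
    GroundTruth,
    ParameterError,
    default_face_box,
    generate_dataset,
    generate_eeg,
    generate_frames,
    generate_gsr,
    generate_ppg,
    me_region_for,
    plant_micro_expression,
)


def tiny_config(**kw):
    base = dict(n_subjects=2, trials_per_subject=2, trial_seconds=4.0,
                frame_size=(64, 64), seed=3)
    base.update(kw)
    return GeneratorConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_subjects": 0},
            {"fps": 0.0},
            {"trial_seconds": 1.0},  # under 60 frames at 30 fps
            {"noise_sd": -0.1},
            {"rating_fidelity": 1.5},
            {"frame_size": (8, 8)},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ParameterError):
            tiny_config(**kw)

    def test_trial_counts(self):
        assert tiny_config().n_trials == 4
        assert GeneratorConfig(n_subjects=23, trials_per_subject=10).n_trials == 230


class TestDataset:
    def test_same_seed_is_bit_identical(self):
        cfg = tiny_config()
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.frames, tb.frames)
            assert np.array_equal(ta.eeg, tb.eeg)
            assert np.array_equal(ta.gsr, tb.gsr)
            assert np.array_equal(ta.ppg, tb.ppg)
            assert (ta.rating_arousal, ta.rating_valence) == (
                tb.rating_arousal, tb.rating_valence)

    def test_shapes_and_ranges(self, small_dataset, small_config):
        cfg = small_config
        assert len(small_dataset) == cfg.n_trials
        for t in small_dataset:
            assert t.frames.shape == (cfg.n_frames, *cfg.frame_size)
            assert t.frames.min() >= 0.0 and t.frames.max() <= 1.0
            assert t.eeg.shape == (cfg.eeg_channels, cfg.n_eeg_samples)
            assert t.gsr.shape == (cfg.n_physio_samples,)
            assert t.ppg.shape == (cfg.n_physio_samples,)
            assert 1 <= t.rating_arousal <= 9 and 1 <= t.rating_valence <= 9
            assert 0 <= t.truth.apex_frame < cfg.n_frames
            # micro-expression duration corresponds to 65-500 ms
            assert 0.065 * cfg.fps <= t.truth.me_duration_frames + 1
            assert t.truth.me_duration_frames <= 0.5 * cfg.fps

    def test_latent_states_balanced(self):
        cfg = tiny_config(n_subjects=4, trials_per_subject=4)
        trials = generate_dataset(cfg)
        combos = [(t.truth.latent_arousal, t.truth.latent_valence) for t in trials]
        counts = {c: combos.count(c) for c in set(combos)}
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_rating_fidelity(self):
        # physiology-light config so many trials stay cheap
        cfg = GeneratorConfig(n_subjects=10, trials_per_subject=10, trial_seconds=2.0,
                              frame_size=(48, 48), eeg_channels=2, seed=21)
        trials = generate_dataset(cfg)
        match_a = np.mean([
            (t.rating_arousal > 5) == bool(t.truth.latent_arousal) for t in trials
        ])
        match_v = np.mean([
            (t.rating_valence > 5) == bool(t.truth.latent_valence) for t in trials
        ])
        se = np.sqrt(0.95 * 0.05 / len(trials))
        assert match_a >= 0.95 - 3 * se
        assert match_v >= 0.95 - 3 * se


class TestPlanting:
    def test_zero_amplitude_is_identity(self, rng):
        frames = rng.random((10, 32, 32)).astype(np.float32)
        out = plant_micro_expression(frames, 5, 4, 0.0, (2, 2, 5, 5))
        assert np.array_equal(out, frames)

    def test_region_outside_frame_rejected(self, rng):
        frames = rng.random((10, 32, 32))
        with pytest.raises(ValueError):
            plant_micro_expression(frames, 5, 4, 0.1, (30, 30, 5, 5))

    def test_difference_curve_peaks_at_apex(self):
        """Brute-force per-pixel mean |frame - first| is maximal at the apex."""
        frames = np.zeros((60, 32, 32), dtype=np.float32)
        region = (4, 6, 8, 8)
        out = plant_micro_expression(frames, 30, 15, 0.2, region)
        top, left, h, w = region
        scores = np.abs(out - out[0])[:, top : top + h, left : left + w].mean(axis=(1, 2))
        assert int(np.argmax(scores)) == 30

    def test_duration_converts_at_30fps(self):
        # 15 frames at 30 fps is a 0.5 s event
        assert 15 / 30.0 == pytest.approx(0.5)

    def test_untouched_pixels(self, rng):
        frames = rng.random((20, 32, 32))
        region = (4, 6, 8, 8)
        out = plant_micro_expression(frames, 10, 6, 0.3, region)
        mask = np.ones((32, 32), dtype=bool)
        mask[4:12, 6:14] = False
        assert np.array_equal(out[:, mask], frames[:, mask])


def _truth(arousal=1, valence=1, apex=60, dur=8):
    return GroundTruth(latent_arousal=arousal, latent_valence=valence,
                       apex_frame=apex, me_duration_frames=dur)


class TestEeg:
    def _band_power(self, x, rate, lo, hi):
        f, p = sps.periodogram(x, fs=rate, axis=-1)
        return p[..., (f >= lo) & (f < hi)].mean()

    def test_shape_contract(self):
        cfg = tiny_config(trial_seconds=80.0)
        eeg = generate_eeg(_truth(apex=1200), cfg, np.random.default_rng(0))
        assert eeg.shape == (cfg.eeg_channels, round(80 * cfg.eeg_rate))

    def test_beta_power_localized_to_roi(self):
        """High-arousal beta boost sits inside the apex window only."""
        cfg = tiny_config(trial_seconds=40.0, band_shift_strength=1.5)
        truth = _truth(arousal=1, apex=int(20 * cfg.fps))
        eeg = generate_eeg(truth, cfg, np.random.default_rng(2))
        rate = cfg.eeg_rate
        mid = int(20 * rate)
        span = int(EFFECT_HALFSPAN_SECONDS * rate)
        inside = eeg[:, mid - span : mid + span]
        outside = eeg[:, : mid - span]
        beta_in = self._band_power(inside, rate, 12, 30)
        beta_out = self._band_power(outside, rate, 12, 30)
        assert beta_in > 2 * beta_out

    def test_zero_strength_is_stationary(self):
        cfg = tiny_config(trial_seconds=40.0, band_shift_strength=0.0)
        truth = _truth(arousal=1, apex=int(20 * cfg.fps))
        eeg = generate_eeg(truth, cfg, np.random.default_rng(2))
        rate = cfg.eeg_rate
        mid, span = int(20 * rate), int(EFFECT_HALFSPAN_SECONDS * rate)
        beta_in = self._band_power(eeg[:, mid - span : mid + span], rate, 12, 30)
        beta_out = self._band_power(eeg[:, : mid - span], rate, 12, 30)
        assert beta_in == pytest.approx(beta_out, rel=0.5)

    def test_valence_alpha_contrast(self):
        cfg = tiny_config(trial_seconds=40.0, band_shift_strength=1.5)
        apex = int(20 * cfg.fps)
        hi = generate_eeg(_truth(valence=1, apex=apex), cfg, np.random.default_rng(3))
        lo = generate_eeg(_truth(valence=0, apex=apex), cfg, np.random.default_rng(3))
        rate = cfg.eeg_rate
        mid, span = int(20 * rate), int(EFFECT_HALFSPAN_SECONDS * rate)
        a_hi = self._band_power(hi[:, mid - span : mid + span], rate, 8, 12)
        a_lo = self._band_power(lo[:, mid - span : mid + span], rate, 8, 12)
        assert a_hi > 1.5 * a_lo


class TestPhysio:
    def test_gsr_arousal_contrast(self):
        """After cleaning, first-difference activity separates arousal groups."""
        from microfusion.signals import clean_gsr

        cfg = tiny_config(trial_seconds=30.0, physio_effect_strength=1.5)
        stats = {0: [], 1: []}
        for i in range(50):
            for arousal in (0, 1):
                g = generate_gsr(_truth(arousal=arousal, apex=450), cfg,
                                 np.random.default_rng(100 + 2 * i + arousal))
                g = clean_gsr(g, cfg.physio_rate)
                stats[arousal].append(np.abs(np.diff(g)).mean())
        lo, hi = np.asarray(stats[0]), np.asarray(stats[1])
        se = np.sqrt(lo.var() / lo.size + hi.var() / hi.size)
        # direction is not asserted: whole-trial z-scoring rescales trials
        # with large responses, but the groups must be clearly separated
        assert abs(hi.mean() - lo.mean()) > 3 * se

    def test_zero_strength_gsr_has_no_apex_cluster(self):
        cfg0 = tiny_config(trial_seconds=30.0, physio_effect_strength=0.0)
        cfg1 = tiny_config(trial_seconds=30.0, physio_effect_strength=2.0)
        t = _truth(arousal=1, apex=450)
        g0 = generate_gsr(t, cfg0, np.random.default_rng(7))
        g1 = generate_gsr(t, cfg1, np.random.default_rng(7))
        assert g1.max() - g1.min() > g0.max() - g0.min()

    def test_ppg_pulse_survives_its_passband(self):
        """Band-passing 0.7-2.5 Hz keeps most of the pulse power."""
        from microfusion.signals import bandpass

        cfg = tiny_config(trial_seconds=30.0)
        ppg = generate_ppg(_truth(arousal=1, apex=450), cfg, np.random.default_rng(9))
        filtered = bandpass(ppg, cfg.physio_rate, 0.7, 2.5)
        # fundamental is ~1.4 Hz for high arousal; most variance survives
        assert filtered.std() > 0.6 * ppg.std()


class TestZeroEffectFrames:
    def test_no_planted_peak(self):
        from microfusion.spotting import FacialRegionSet, difference_curve

        cfg0 = tiny_config(apex_effect_amplitude=0.0)
        cfg1 = tiny_config(apex_effect_amplitude=0.2)
        truth = _truth(apex=60, dur=10)
        rng0, rng1 = np.random.default_rng(5), np.random.default_rng(5)
        f0 = generate_frames(truth, cfg0, rng0)
        f1 = generate_frames(truth, cfg1, rng1)
        top, left, h, w = default_face_box(cfg0.frame_size)
        regions = FacialRegionSet.default(h, w).shifted(top, left)
        c0 = difference_curve(f0, regions)
        c1 = difference_curve(f1, regions)
        # the curve rides on a flat noise floor; compare peak prominence
        prom0 = c0.values.max() - np.median(c0.values)
        prom1 = c1.values.max() - np.median(c1.values)
        assert prom1 > 5 * prom0
        assert int(np.argmax(c1.values)) == 60


class TestFaceGeometry:
    def test_me_region_depends_on_latent_state(self):
        shape = (96, 96)
        regions = {
            (a, v): me_region_for(_truth(arousal=a, valence=v), shape)
            for a in (0, 1) for v in (0, 1)
        }
        assert len(set(regions.values())) == 4
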