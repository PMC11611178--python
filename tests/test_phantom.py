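"""Phantom generator: waveform composition, rendering fidelity, cohort
determinism."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import find_peaks

import lumenflow as lf
from lumenflow.errors import ConfigError
from lumenflow.phantom import cardiac_pulse_shape


class TestAcquisitionSpec:
    def test_defaults_consistent(self, spec):
        assert spec.depth_samples == 1020
        assert spec.frame_rate_hz == 500.0
        # pulse-echo sampling distance: c / (2 f_rf)
        assert spec.sound_speed_m_s / (2 * spec.rf_sampling_hz) * 1e6 == pytest.approx(
            spec.depth_scale_um, abs=0.1)
        assert 0 < spec.carrier_cycles_per_sample < 0.5

    def test_inconsistent_depth_scale_rejected(self):
        with pytest.raises(ConfigError):
            lf.AcquisitionSpec(depth_scale_um=50.0)

    def test_mm_to_samples(self, spec):
        # 7.5 mm at 24.65 um/sample
        assert spec.mm_to_samples(7.5) == pytest.approx(304.26, abs=0.01)


class TestDiameterWaveform:
    def test_all_modulations_off_gives_constant(self):
        cfg = lf.PhantomSubjectConfig(pulse_amplitude_mm=0, resp_amplitude_mm=0,
                                      trend_amplitude_mm=0)
        d = lf.diameter_waveform(cfg, 100)
        assert np.allclose(d, cfg.mean_diameter_mm)

    def test_mean_matches_quadrature_of_pulse_shape(self):
        """Over whole cardiac+respiratory cycles the mean diameter equals
        D0 + A_p * mean(pulse shape), the latter by numeric quadrature."""
        cfg = lf.PhantomSubjectConfig(heart_rate_bpm=60, resp_rate_cpm=7.5)
        spec = lf.AcquisitionSpec()
        # 8 s = 8 cardiac cycles = 1 respiratory cycle at 7.5 cpm
        n = int(8 * spec.frame_rate_hz)
        d = lf.diameter_waveform(cfg, n, spec)
        pulse_mean, _ = quad(lambda p: cardiac_pulse_shape(np.array([p]))[0], 0, 1,
                             limit=200)
        expected = cfg.mean_diameter_mm + cfg.pulse_amplitude_mm * pulse_mean
        assert d.mean() == pytest.approx(expected, abs=2e-3)

    def test_deterministic(self):
        cfg = lf.PhantomSubjectConfig(seed=42)
        assert np.array_equal(lf.diameter_waveform(cfg, 500),
                              lf.diameter_waveform(cfg, 500))

    def test_positivity_violation_names_field(self):
        with pytest.raises(ConfigError, match="mean_diameter_mm"):
            lf.diameter_waveform(
                lf.PhantomSubjectConfig(mean_diameter_mm=0.5,
                                        pulse_amplitude_mm=0.4,
                                        resp_amplitude_mm=0.2), 10)

    def test_pulse_shape_normalized(self):
        p = cardiac_pulse_shape(np.linspace(0, 1, 1000, endpoint=False))
        assert p.min() >= 0 and p.max() == pytest.approx(1.0, abs=1e-6)


class TestRenderRecording:
    def test_noiseless_frame_has_two_wall_peaks(self):
        cfg = lf.PhantomSubjectConfig(speckle_sigma=0, lumen_echo_sigma=0,
                                      noise_sigma=0, seed=1)
        rec, ann = lf.render_recording(cfg, 3)
        for j in range(3):
            env = lf.hilbert_envelope(rec.samples[:, j])
            peaks, _ = find_peaks(env, height=0.5 * env.max())
            assert len(peaks) == 2
            assert abs(peaks[0] - ann.anterior[j]) <= 1.0
            assert abs(peaks[1] - ann.posterior[j]) <= 1.0

    def test_annotation_identities_exact(self):
        _, ann = lf.render_recording(lf.PhantomSubjectConfig(seed=2), 50)
        assert np.array_equal(ann.center, (ann.anterior + ann.posterior) / 2)
        assert np.array_equal(ann.diameter, ann.posterior - ann.anterior)
        assert np.all(ann.posterior > ann.anterior)

    def test_same_seed_identical(self):
        cfg = lf.PhantomSubjectConfig(seed=9)
        rec1, _ = lf.render_recording(cfg, 20)
        rec2, _ = lf.render_recording(cfg, 20)
        assert np.array_equal(rec1.samples, rec2.samples)

    def test_lumen_hypoechoic(self):
        """Mean envelope amplitude in the central lumen under 10% of the
        wall-echo peak for the default configuration."""
        cfg = lf.PhantomSubjectConfig(seed=5)
        rec, ann = lf.render_recording(cfg, 50)
        env = lf.hilbert_envelope(rec.samples)
        ratios = []
        for j in range(50):
            a, p = ann.anterior[j], ann.posterior[j]
            lo = int(a + 0.25 * (p - a))
            hi = int(a + 0.75 * (p - a))
            wall = max(env[int(a) - 4:int(a) + 5, j].max(),
                       env[int(p) - 4:int(p) + 5, j].max())
            ratios.append(env[lo:hi, j].mean() / wall)
        assert np.mean(ratios) < 0.1

    def test_wall_excursion_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            lf.render_recording(
                lf.PhantomSubjectConfig(lumen_center_baseline=100.0), 10)

    def test_rendered_diameter_matches_waveform(self):
        cfg = lf.PhantomSubjectConfig(seed=3)
        spec = lf.AcquisitionSpec()
        _, ann = lf.render_recording(cfg, 400, spec)
        expected = spec.mm_to_samples(lf.diameter_waveform(cfg, 400, spec))
        assert np.abs(ann.diameter - expected).max() < 1e-9


class TestMakeCohort:
    def test_reproducible(self):
        c1 = lf.make_cohort(2, 40, master_seed=7)
        c2 = lf.make_cohort(2, 40, master_seed=7)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.rf.samples, s2.rf.samples)
            assert np.array_equal(s1.annotation.diameter, s2.annotation.diameter)

    def test_shape_contract(self):
        c = lf.make_cohort(2, 10, master_seed=0)
        assert c.n_subjects == 2
        assert all(s.rf.n_frames == 10 for s in c.subjects)

    def test_single_subject_rejected(self):
        with pytest.raises(ConfigError, match="leave-one-subject-out"):
            lf.make_cohort(1, 10, master_seed=0)

    def test_baselines_in_range(self):
        c = lf.make_cohort(6, 5, master_seed=7)
        for s in c.subjects:
            assert 350 <= s.config.lumen_center_baseline <= 650

    def test_artifact_bands_outside_lumen(self):
        c = lf.make_cohort(4, 5, master_seed=3)
        for s in c.subjects:
            lo = s.annotation.anterior.min()
            hi = s.annotation.posterior.max()
            for depth, amp in s.config.artifact_bands:
                assert not lo <= depth <= hi
                assert amp <= 0.8
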