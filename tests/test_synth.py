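"""Tests for the synthetic generators: determinism, ground-truth
bookkeeping, and construction-level statistics."""

import numpy as np
import pytest

from tbikit import synth
from tbikit.presets import InjuryCondition, InjuryPreset, default_presets
from tbikit.synth import FiringModel, RecordingConfig


class TestSimulateRecording:
    def test_silent_limit_is_all_zero(self):
        cfg = RecordingConfig(
            sampling_rate_hz=5000.0, duration_s=2.0, n_wells=1,
            noise_sd_uv=0.0, seed=0,
        )
        rec, truth = synth.simulate_recording(cfg, FiringModel(tonic_rate_hz=0.0))
        assert np.all(rec.traces == 0.0)
        assert all(len(t) == 0 for t in truth)

    def test_same_seed_bit_identical(self):
        cfg = RecordingConfig(
            sampling_rate_hz=5000.0, duration_s=3.0, n_wells=1, seed=7
        )
        firing = FiringModel(tonic_rate_hz=3.0, burst_event_rate_per_5min=20.0)
        rec1, truth1 = synth.simulate_recording(cfg, firing)
        rec2, truth2 = synth.simulate_recording(cfg, firing)
        assert rec1.traces.tobytes() == rec2.traces.tobytes()
        assert all(np.array_equal(a, b) for a, b in zip(truth1, truth2))

    def test_poisson_count_statistics(self):
        """9 electrodes at 2 Hz for 300 s: total ground-truth count within
        3 sigma of the Poisson mean 5400."""
        cfg = RecordingConfig(
            sampling_rate_hz=5000.0, duration_s=300.0, n_wells=1,
            noise_sd_uv=0.001, seed=42,
        )
        _, truth = synth.simulate_recording(cfg, FiringModel(tonic_rate_hz=2.0))
        total = sum(len(t) for t in truth)
        assert abs(total - 5400) <= 3 * np.sqrt(5400)

    def test_rendered_trough_matches_amplitude_and_truth_count(self):
        cfg = RecordingConfig(
            sampling_rate_hz=20000.0, duration_s=5.0, n_wells=1,
            noise_sd_uv=0.0, seed=3,
        )
        rec, truth = synth.simulate_recording(cfg, FiringModel(tonic_rate_hz=2.0))
        # noiseless trace: each trough reaches the configured amplitude
        assert rec.traces.min() == pytest.approx(cfg.spike_amplitude_uv, rel=0.02)
        below = rec.traces[0] < 0.5 * cfg.spike_amplitude_uv
        n_excursions = np.sum(np.diff(below.astype(int)) == 1) + below[0]
        assert n_excursions == len(truth[0])

    def test_preset_scales_rates(self, presets):
        cfg = RecordingConfig(
            sampling_rate_hz=5000.0, duration_s=200.0, n_wells=2,
            noise_sd_uv=0.001, seed=5,
        )
        firing = FiringModel(tonic_rate_hz=4.0)
        _, truth_base = synth.simulate_recording(cfg, firing)
        _, truth_hit = synth.simulate_recording(
            cfg, firing, presets[("hit3", 24.0)]
        )
        ratio = sum(len(t) for t in truth_hit) / sum(len(t) for t in truth_base)
        assert ratio == pytest.approx(0.642, abs=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RecordingConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            RecordingConfig(spike_amplitude_uv=10.0)
        with pytest.raises(ValueError):
            FiringModel(tonic_rate_hz=-1.0)
        with pytest.raises(ValueError):
            FiringModel(intra_burst_isi_ms=400.0)


class TestSimulateViabilityImage:
    def test_label_bookkeeping_exact(self):
        _, truth = synth.simulate_viability_image(100, 0.8, seed=1)
        assert truth["n_live"] == 80 and truth["n_dead"] == 20
        assert truth["is_live"].sum() == 80

    def test_all_viable_leaves_dead_channel_noise_only(self):
        img, _ = synth.simulate_viability_image(50, 1.0, seed=2, noise_sd=0.01)
        assert img.channels["dead"].max() < 0.2
        assert img.channels["live"].max() == pytest.approx(1.0, abs=0.1)

    def test_noiseless_live_channel_has_expected_components(self):
        from skimage import measure

        img, truth = synth.simulate_viability_image(10, 1.0, seed=3, noise_sd=0.0)
        labels = measure.label(img.channels["live"] > 0.5)
        assert labels.max() == 10

    def test_determinism(self):
        img1, t1 = synth.simulate_viability_image(30, 0.5, seed=9)
        img2, t2 = synth.simulate_viability_image(30, 0.5, seed=9)
        for k in img1.channels:
            assert np.array_equal(img1.channels[k], img2.channels[k])
        assert np.array_equal(t1["centers_px"], t2["centers_px"])

    def test_impossible_density_raises(self):
        with pytest.raises(RuntimeError, match="density"):
            synth.simulate_viability_image(
                500, 1.0, field_um=50.0, cell_radius_um=5.0, seed=0
            )


class TestSimulateTeer:
    def test_zero_sd_inverts_normalization_exactly(self, presets):
        preset = presets[("control", 1.0)].with_(
            teer_mean_ohm_cm2=50.73, teer_sd_ohm_cm2=0.0
        )
        records = synth.simulate_teer(
            preset, n_inserts=3, blank_ohm=300.0, area_cm2=0.336, seed=0
        )
        for r in records:
            assert r.raw_ohm == pytest.approx(300.0 + 50.73 / 0.336)

    def test_zero_inserts_empty(self, presets):
        assert synth.simulate_teer(presets[("control", 1.0)], n_inserts=0) == []

    def test_experiment_and_insert_ids(self, presets):
        records = synth.simulate_teer(
            presets[("hit1", 24.0)], n_inserts=2, n_experiments=3, seed=1
        )
        assert len(records) == 6
        assert {r.experiment_id for r in records} == {0, 1, 2}
        assert {r.insert_id for r in records} == {0, 1}


class TestSimulateBubbleTrace:
    def test_growth_phase_duration(self):
        trace = synth.simulate_bubble_trace(
            growth_speed_mm_s=40.0, r_max_mm=2.0, noise_sd_mm=0.0
        )
        i_max = int(np.argmax(trace.radius_m))
        assert trace.times_s[i_max] == pytest.approx(0.050)
        assert trace.radius_m[i_max] == pytest.approx(2e-3)

    def test_collapse_duration_is_growth_over_factor(self):
        trace = synth.simulate_bubble_trace(collapse_factor=100.0, noise_sd_mm=0.0)
        i_max = int(np.argmax(trace.radius_m))
        t_grow = trace.times_s[i_max]
        t_coll = trace.times_s[-1] - t_grow
        assert t_coll == pytest.approx(t_grow / 100.0, rel=0.05)

    def test_halved_dt_samples_same_envelope(self):
        a = synth.simulate_bubble_trace(dt_s=2e-4, noise_sd_mm=0.0)
        b = synth.simulate_bubble_trace(dt_s=1e-4, noise_sd_mm=0.0)
        n = min(len(a.radius_m), len(b.radius_m[::2]))
        assert np.allclose(b.radius_m[::2][:n], a.radius_m[:n])

    def test_collapse_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_bubble_trace(collapse_factor=0.5)


class TestPresets:
    def test_default_table_covers_grid(self, presets):
        for label in ("control", "hit1", "hit3"):
            for tp in (0.0, 1.0, 24.0):
                assert (label, tp) in presets

    def test_printed_effect_sizes_encoded(self, presets):
        assert presets[("hit1", 24.0)].rate_multiplier == pytest.approx(0.840)
        assert presets[("hit3", 24.0)].rate_multiplier == pytest.approx(0.642)
        assert presets[("control", 24.0)].rate_multiplier == pytest.approx(1.0143)
        assert presets[("control", 24.0)].burst_rate_per_5min == 53.0
        assert presets[("hit1", 24.0)].burst_rate_per_5min == 38.4
        assert presets[("control", 24.0)].viable_fraction - presets[
            ("hit3", 24.0)
        ].viable_fraction == pytest.approx(0.215)
        assert presets[("control", 1.0)].teer_mean_ohm_cm2 == 50.73
        assert presets[("hit3", 24.0)].teer_mean_ohm_cm2 == 28.31

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError):
            InjuryPreset(condition=InjuryCondition("hit1"), viable_fraction=1.5)
        with pytest.raises(ValueError):
            InjuryCondition("hit5")
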