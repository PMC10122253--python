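"""Unit and property tests for the MEA spike/burst analysis chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbikit import mea, synth
from tbikit.mea import DetectionParams, Recording, SpikeTrain, WellSummary
from tbikit.presets import InjuryCondition

from conftest import burst_oracle


def _recording_from_trace(x, fs=20000.0):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return Recording(
        traces=x,
        sampling_rate_hz=fs,
        well_map=np.zeros(x.shape[0], dtype=int),
        duration_s=x.shape[1] / fs,
    )


class TestBandpassFilter:
    @pytest.mark.parametrize(
        "freq_hz, keep",
        [(50.0, False), (700.0, True), (150.0, False), (2200.0, False)],
    )
    def test_frequency_response_against_sine_oracle(self, freq_hz, keep):
        """In-band tones pass nearly unchanged; tones one octave outside
        the 300-1100 Hz band are attenuated by >= 40 dB (RMS oracle)."""
        fs = 20000.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * freq_hz * t)
        rec = _recording_from_trace(x, fs)
        y = mea.bandpass_filter(rec, DetectionParams()).traces[0]
        # discard edge transients before measuring RMS
        sl = slice(int(0.2 * fs), int(1.8 * fs))
        ratio = np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2))
        if keep:
            assert ratio > 0.95
        else:
            assert ratio < 10 ** (-40 / 20)

    def test_zero_trace_stays_zero_and_length_preserved(self):
        rec = _recording_from_trace(np.zeros(4000))
        out = mea.bandpass_filter(rec, DetectionParams())
        assert out.traces.shape == rec.traces.shape
        assert np.allclose(out.traces, 0.0)

    def test_linearity(self, rng):
        a = rng.standard_normal(20000)
        b = rng.standard_normal(20000)
        p = DetectionParams()
        fa = mea.bandpass_filter(_recording_from_trace(a), p).traces[0]
        fb = mea.bandpass_filter(_recording_from_trace(b), p).traces[0]
        fab = mea.bandpass_filter(_recording_from_trace(a + b), p).traces[0]
        assert np.allclose(fab, fa + fb, rtol=1e-9, atol=1e-12)

    def test_band_edge_beyond_nyquist_rejected(self):
        rec = _recording_from_trace(np.zeros(1000), fs=2000.0)
        with pytest.raises(ValueError):
            mea.bandpass_filter(rec, DetectionParams())


class TestDetectSpikes:
    def test_zero_variance_trace_gives_empty_train(self):
        rec = _recording_from_trace(np.zeros(20000))
        (train,) = mea.detect_spikes(rec, DetectionParams())
        assert len(train) == 0

    def test_single_deep_sample_detected_against_bruteforce(self, rng):
        """One isolated sample below -4.5 x SD forces exactly one event,
        matching a brute-force scan for sub-threshold samples."""
        x = rng.standard_normal(20000)
        x /= x.std()
        x[7000] = -6.0  # well past 4.5 after the SD inflates slightly
        rec = _recording_from_trace(x)
        (train,) = mea.detect_spikes(rec, DetectionParams())
        thr = 4.5 * x.std()
        brute = np.flatnonzero(x < -thr)
        assert len(brute) == 1 and brute[0] == 7000
        assert len(train) == 1
        assert train.times_s[0] == pytest.approx(7000 / 20000.0)

    def test_injected_templates_recovered_within_half_ms(self, presets):
        """Ground-truth troughs at 15x noise SD are each matched by one
        detection within 0.5 ms (generator-oracle check)."""
        cfg = synth.RecordingConfig(
            sampling_rate_hz=20000.0, duration_s=20.0, n_wells=1, seed=11
        )
        rec, truth = synth.simulate_recording(
            cfg, synth.FiringModel(tonic_rate_hz=0.5)
        )
        trains = mea.detect_spikes(
            mea.bandpass_filter(rec, DetectionParams()), DetectionParams()
        )
        for t_true, train in zip(truth, trains):
            assert len(train) == len(t_true)
            assert np.all(np.abs(train.times_s - t_true) <= 0.0005)

    def test_raising_threshold_never_adds_spikes(self, rng):
        x = rng.standard_normal(50000) * 3.0
        rec = _recording_from_trace(x)
        counts = [
            len(mea.detect_spikes(rec, DetectionParams(threshold_k=k))[0])
            for k in (2.0, 2.5, 3.0, 3.5, 4.0, 4.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_refractory_suppresses_later_crossing(self):
        fs = 20000.0
        x = np.zeros(20000)
        x[1000] = -10.0
        x[1010] = -9.0  # 0.5 ms later: inside the dead time
        x[1200] = -9.5  # 10 ms later: a separate event
        rec = _recording_from_trace(x, fs)
        (train,) = mea.detect_spikes(rec, DetectionParams())
        assert np.allclose(train.times_s, [1000 / fs, 1200 / fs])


class TestActiveElectrodes:
    @pytest.mark.parametrize("n_spikes, kept", [(75, True), (74, False), (0, False)])
    def test_quarter_hertz_boundary_inclusive(self, n_spikes, kept):
        """>= 15 spikes/min means 75 spikes in 300 s is active, 74 is not."""
        train = SpikeTrain(0, np.linspace(1.0, 299.0, n_spikes))
        result = mea.active_electrodes([train], duration_s=300.0)
        assert (len(result) == 1) is kept


class TestDetectBursts:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ([0.0, 0.1, 0.2], [(0.0, 0.2, 3)]),
            ([0.0, 0.1], []),
            # gaps of exactly 300 ms stay in-burst; the lone 7th spike stays out
            (
                [0.0, 0.30, 0.60, 1.5, 1.6, 1.7, 2.5],
                [(0.0, 0.60, 3), (1.5, 1.7, 3)],
            ),
            ([], []),
        ],
    )
    def test_worked_groupings_match_bruteforce_oracle(self, times, expected):
        result = mea.detect_bursts(SpikeTrain(0, np.asarray(times)))
        got = [(b.start_s, b.end_s, b.n_spikes) for b in result.bursts]
        assert got == pytest.approx(expected)
        assert got == pytest.approx(burst_oracle(times))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(
            st.one_of(
                st.floats(0.01, 0.29),
                st.just(0.300),
                st.floats(0.31, 2.0),
            ),
            min_size=0,
            max_size=30,
        )
    )
    def test_equals_bruteforce_oracle_on_random_trains(self, gaps):
        times = np.cumsum(np.asarray(gaps))
        result = mea.detect_bursts(SpikeTrain(0, times))
        got = [(b.start_s, b.end_s, b.n_spikes) for b in result.bursts]
        assert got == pytest.approx(burst_oracle(times))


class TestSummaries:
    def _summaries(self):
        trains = [
            SpikeTrain(0, np.linspace(0.5, 299.5, 100)),
            SpikeTrain(1, np.linspace(0.5, 299.5, 200)),
            SpikeTrain(2, np.asarray([1.0, 150.0])),  # inactive
        ]
        bursts = [mea.detect_bursts(t) for t in trains]
        return mea.summarize_wells(
            trains, bursts, np.zeros(3, dtype=int), 300.0
        )

    def test_spikes_per_active_electrode_mean(self):
        (summary,) = self._summaries()
        assert summary.n_active_electrodes == 2
        assert summary.spikes_per_active_electrode == 150.0

    def test_no_active_electrodes_flags_missing_rates(self):
        trains = [SpikeTrain(0, np.asarray([1.0]))]
        (summary,) = mea.summarize_wells(trains, [], np.zeros(1, int), 300.0)
        assert summary.n_active_electrodes == 0
        assert np.isnan(summary.spikes_per_active_electrode)
        assert np.isnan(summary.bursts_per_5min)

    def test_burst_rate_scales_to_five_minutes(self):
        train = SpikeTrain(0, np.linspace(0.0, 59.0, 100))
        bursts = mea.detect_bursts(train)
        (summary,) = mea.summarize_wells(
            [train], [bursts], np.zeros(1, int), 60.0
        )
        assert summary.bursts_per_5min == pytest.approx(len(bursts) * 5.0)


class TestPercentChange:
    def _well(self, well, rate, label=None, tp=0.0):
        cond = InjuryCondition(label, tp) if label else None
        return WellSummary(well, 9, rate, 0.0, cond)

    @pytest.mark.parametrize(
        "base, post, expected",
        [(100.0, 84.0, -16.0), (100.0, 100.0, 0.0), (100.0, 101.43, 1.43)],
    )
    def test_signed_percent_change(self, base, post, expected):
        out = mea.percent_change(
            [self._well("A", base)], [self._well("A", post, "hit1", 24.0)]
        )
        assert out["hit1"] == pytest.approx(expected)

    def test_zero_baseline_flagged_undefined(self):
        with pytest.warns(UserWarning):
            out = mea.percent_change(
                [self._well("A", 0.0)], [self._well("A", 10.0, "hit1", 24.0)]
            )
        assert np.isnan(out["hit1"])

    def test_condition_averaging_over_wells(self):
        base = [self._well("A", 100.0), self._well("B", 200.0)]
        post = [
            self._well("A", 90.0, "hit1", 24.0),
            self._well("B", 160.0, "hit1", 24.0),
        ]
        assert mea.percent_change(base, post)["hit1"] == pytest.approx(-15.0)
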