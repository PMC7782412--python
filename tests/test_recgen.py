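import numpy as np
import pytest

import spikesim as ss
from spikesim.noisegen import NoiseSpec
from spikesim.recgen import (
    DriftParams,
    ModulationParams,
    RecordingParams,
    SelectionRules,
    SpikeTrainParams,
    assemble_recording,
    compute_modulation_values,
    convolve_unit,
    drift_step_at,
    filter_recording,
    is_spatially_overlapping,
    jitter_templates,
    make_fast_drift_schedule,
    select_templates,
    stretch_template,
    template_amplitudes,
)


def _gaussian_template(n_ch=4, n_pts=100, troughs=None):
    """Template with a negative Gaussian trough of given depth per channel."""
    t = np.arange(n_pts)
    tpl = np.zeros((n_ch, n_pts))
    for ch, depth in (troughs or {}).items():
        tpl[ch] = -depth * np.exp(-0.5 * ((t - n_pts // 2) / 3.0) ** 2)
    return tpl


class TestTemplateAmplitudes:
    def test_single_trough(self):
        tpl = _gaussian_template(troughs={2: 40.0})
        amps, ch = template_amplitudes(tpl)
        assert ch == 2
        assert amps[2] == pytest.approx(40.0)

    def test_all_zero_tie_goes_to_lowest_channel(self):
        amps, ch = template_amplitudes(np.zeros((4, 10)))
        assert ch == 0
        assert np.all(amps == 0)

    def test_matches_per_channel_scan(self, rng):
        tpl = rng.standard_normal((6, 80))
        amps, ch = template_amplitudes(tpl)
        for c in range(6):
            assert amps[c] == pytest.approx(abs(tpl[c].min()))
        assert ch == int(np.argmax(amps))


class TestSpatialOverlap:
    @pytest.mark.parametrize("fraction, expected", [(0.91, True), (0.89, False)])
    def test_ninety_percent_rule(self, fraction, expected):
        # A peaks on channel 0; B peaks on channel 3 with amplitude 50 and
        # carries fraction * 50 on channel 0
        t_a = _gaussian_template(troughs={0: 60.0, 3: 1.0})
        t_b = _gaussian_template(troughs={3: 50.0, 0: fraction * 50.0})
        assert is_spatially_overlapping(t_a, t_b, threshold=0.9) is expected

    def test_identical_templates_always_overlap(self):
        tpl = _gaussian_template(troughs={1: 30.0})
        assert is_spatially_overlapping(tpl, tpl, threshold=1.0)


class TestSelectTemplates:
    def test_requested_composition(self, small_library):
        rules = SelectionRules(n_exc=4, n_inh=2, min_dist=25.0)
        idx = select_templates(small_library, rules, temp_seed=1)
        assert len(idx) == 6
        types = np.asarray(small_library.celltypes)[idx]
        assert list(types) == ["excitatory"] * 4 + ["inhibitory"] * 2

    def test_minimum_distance_honored(self, small_library):
        rules = SelectionRules(n_exc=4, n_inh=2, min_dist=30.0)
        idx = select_templates(small_library, rules, temp_seed=2)
        locs = small_library.locations[idx]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                assert np.linalg.norm(locs[i] - locs[j]) >= 30.0

    def test_deterministic_per_seed(self, small_library):
        rules = SelectionRules(n_exc=2, n_inh=1)
        a = select_templates(small_library, rules, temp_seed=3)
        b = select_templates(small_library, rules, temp_seed=3)
        assert np.array_equal(a, b)

    def test_unsatisfiable_distance_raises(self, small_library):
        rules = SelectionRules(n_exc=4, n_inh=2, min_dist=5000.0)
        with pytest.raises(RuntimeError, match="min_dist"):
            select_templates(small_library, rules, temp_seed=0, max_draws=50)


class TestModulation:
    def test_gaussian_statistics_without_bursting(self):
        rng = np.random.default_rng(0)
        times = np.sort(np.random.default_rng(1).uniform(0, 1000, 10_000))
        v = compute_modulation_values(times, ModulationParams(mod_sd=0.05), rng)
        assert v.mean() == pytest.approx(1.0, abs=0.002)
        assert v.std() == pytest.approx(0.05, abs=0.002)

    def test_burst_depression_resets_at_spike_count_limit(self):
        times = np.arange(20) * 0.010
        params = ModulationParams(bursting=True, max_spikes_per_burst=5, mod_sd=0.0)
        v = compute_modulation_values(times, params, np.random.default_rng(0))
        for start in range(0, 20, 5):
            group = v[start : start + 5]
            assert np.all(np.diff(group) < 0)
            assert group[0] == pytest.approx(1.0)

    def test_burst_depression_resets_at_duration_limit(self):
        times = np.arange(32) * 0.010
        params = ModulationParams(
            bursting=True, max_burst_duration=75.0, max_spikes_per_burst=1000, mod_sd=0.0
        )
        v = compute_modulation_values(times, params, np.random.default_rng(0))
        resets = np.flatnonzero(v == 1.0)
        # events close once they span >= 75 ms (8 spikes at 10 ms ISI)
        assert resets.tolist() == [0, 8, 16, 24]

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            compute_modulation_values(
                np.array([0.2, 0.1]), ModulationParams(), np.random.default_rng(0)
            )


class TestStretch:
    def test_unit_modulation_is_identity(self):
        tpl = _gaussian_template(troughs={1: 40.0})
        assert np.array_equal(stretch_template(tpl, 1.0, 30.0), tpl)

    def test_larger_stretch_parameter_widens_trough(self):
        tpl = _gaussian_template(troughs={0: 40.0})

        def fwhm(w):
            return int((w < w.min() / 2).sum())

        s10 = stretch_template(tpl, 0.7, 10.0)
        s30 = stretch_template(tpl, 0.7, 30.0)
        assert fwhm(s30[0]) > fwhm(s10[0]) > fwhm(tpl[0])

    def test_sample_count_and_trough_index_preserved(self):
        tpl = _gaussian_template(troughs={0: 40.0})
        out = stretch_template(tpl, 0.5, 20.0)
        assert out.shape == tpl.shape
        assert out[0].argmin() == tpl[0].argmin()


class TestJitter:
    def test_single_jitter_is_unshifted_copy(self, rng):
        tpl = _gaussian_template(troughs={0: 40.0})
        out = jitter_templates(tpl, 1, 10, rng)
        assert out.shape == (1, 4, 100)
        assert np.allclose(out[0], tpl, atol=1e-8)

    def test_jittered_amplitudes_close_to_original(self, rng):
        tpl = _gaussian_template(troughs={0: 40.0, 2: 25.0})
        out = jitter_templates(tpl, 10, 10, rng)
        amp0 = abs(tpl.min())
        for v in range(10):
            assert abs(out[v].min()) == pytest.approx(amp0, rel=0.05)

    def test_drifting_template_jitter_shape(self, rng):
        tpl = np.stack([_gaussian_template(troughs={0: 40.0})] * 5)
        out = jitter_templates(tpl, 3, 10, rng)
        assert out.shape == (5, 3, 4, 100)


class TestDriftPlayback:
    def test_all_modes_start_at_step_zero(self, rng):
        amps = np.linspace(40, 80, 30)
        for mode in ("slow", "fast", "slow+fast"):
            drift = DriftParams(enabled=True, mode=mode)
            schedule = (
                None
                if mode == "slow"
                else make_fast_drift_schedule(60.0, drift, 30, amps, rng)
            )
            assert drift_step_at(0.0, drift, 30, amps, schedule) == 0

    def test_slow_drift_kinematics(self):
        # 5 um/min over a 29 um trajectory with 1 um steps: 5 steps after 60 s
        drift = DriftParams(enabled=True, mode="slow", velocity=5.0)
        assert drift_step_at(60.0, drift, 30, step_length=1.0) == 5

    def test_slow_drift_reflects_at_ends(self):
        drift = DriftParams(enabled=True, mode="slow", velocity=29.0 * 2)  # um/min
        # span covered in 30 s; position reflects afterwards
        assert drift_step_at(30.0, drift, 30, step_length=1.0) == 29
        assert drift_step_at(40.0, drift, 30, step_length=1.0) == 19

    def test_slow_drift_monotone_before_reflection(self):
        drift = DriftParams(enabled=True, mode="slow", velocity=10.0)
        idx = [drift_step_at(t, drift, 30, step_length=1.0) for t in np.linspace(0, 170, 50)]
        assert np.all(np.diff(idx) >= 0)

    def test_fast_drift_jump_count_and_amplitude_band(self, rng):
        amps = np.linspace(40, 80, 30)
        drift = DriftParams(enabled=True, mode="fast", fast_period=20.0)
        schedule = make_fast_drift_schedule(60.0, drift, 30, amps, rng)
        assert [jt for jt, _ in schedule] == [20.0, 40.0]
        prev = 0
        for _, idx in schedule:
            diff = abs(amps[idx] - amps[prev])
            assert 5.0 <= diff <= 20.0
            prev = idx


class TestConvolveUnit:
    def test_single_spike_reproduces_template(self):
        tpl = _gaussian_template(troughs={1: 40.0})[None, :, :]  # one jitter
        fs, n_samples = 32000.0, 3200
        times = np.array([0.05])
        out = convolve_unit(times, tpl, np.ones(1), fs, n_samples, np.zeros(1, int))
        center = int(round(0.05 * fs))
        trough = tpl[0, 1].argmin()
        window = out[:, center - trough : center - trough + 100]
        assert np.allclose(window, tpl[0], atol=1e-5)

    def test_superposition_of_distant_spikes(self):
        tpl = _gaussian_template(troughs={0: 40.0})[None, :, :]
        fs, n_samples = 32000.0, 64000
        both = convolve_unit(
            np.array([0.5, 1.5]), tpl, np.ones(2), fs, n_samples, np.zeros(2, int)
        )
        first = convolve_unit(np.array([0.5]), tpl, np.ones(1), fs, n_samples, np.zeros(1, int))
        second = convolve_unit(np.array([1.5]), tpl, np.ones(1), fs, n_samples, np.zeros(1, int))
        assert np.allclose(both, first + second, atol=1e-5)

    def test_modulation_scales_waveform(self):
        tpl = _gaussian_template(troughs={0: 40.0})[None, :, :]
        full = convolve_unit(np.array([0.05]), tpl, np.ones(1), 32000.0, 3200, np.zeros(1, int))
        half = convolve_unit(
            np.array([0.05]), tpl, np.array([0.5]), 32000.0, 3200, np.zeros(1, int)
        )
        assert np.allclose(half, 0.5 * full, atol=1e-5)


class TestAssembleRecording:
    def test_bit_identical_reproducibility(self, small_library):
        kwargs = dict(rec_params=RecordingParams(duration=3.0))
        a = assemble_recording(small_library, **kwargs)
        b = assemble_recording(small_library, **kwargs)
        assert np.array_equal(a.recordings, b.recordings)
        assert np.array_equal(a.spike_traces, b.spike_traces)

    def test_chunk_duration_does_not_change_output(self, small_library):
        a = assemble_recording(
            small_library, rec_params=RecordingParams(duration=3.0, chunk_duration=20.0)
        )
        b = assemble_recording(
            small_library, rec_params=RecordingParams(duration=3.0, chunk_duration=1.0)
        )
        assert np.array_equal(a.recordings, b.recordings)

    def test_seed_separability(self, small_library):
        base = assemble_recording(small_library, rec_params=RecordingParams(duration=3.0))
        other_noise = assemble_recording(
            small_library, rec_params=RecordingParams(duration=3.0, noise_seed=99)
        )
        assert not np.array_equal(base.recordings, other_noise.recordings)
        assert base.info["selected_template_indices"] == other_noise.info["selected_template_indices"]
        for ta, tb in zip(base.spiketrains.trains, other_noise.spiketrains.trains):
            assert np.array_equal(ta, tb)
        other_st = assemble_recording(
            small_library, rec_params=RecordingParams(duration=3.0, st_seed=99)
        )
        assert base.info["selected_template_indices"] == other_st.info["selected_template_indices"]

    def test_bundle_shapes_and_timestamps(self, small_library):
        rec = RecordingParams(duration=2.0, n_jitters=4)
        b = assemble_recording(small_library, rec_params=rec)
        n_samples = int(round(2.0 * rec.fs))
        assert b.recordings.shape == (4, n_samples)
        assert b.templates.shape[:3] == (6, 4, 4)
        assert b.spike_traces.shape == (6, n_samples)
        assert b.voltage_peaks.shape == (6, 4)
        assert np.allclose(np.diff(b.timestamps), 1.0 / rec.fs)
        assert np.all(b.voltage_peaks <= 0)

    def test_zero_noise_recording_matches_unit_template(self, small_library):
        """Noise-free single-unit recording: windows around spikes correlate
        > 0.99 with the template on its max channel."""
        b = assemble_recording(
            small_library,
            rules=SelectionRules(n_exc=1, n_inh=0),
            st_params=SpikeTrainParams(rate_exc=5.0),
            modulation=ModulationParams(mod_sd=0.0),
            noise_spec=NoiseSpec(level=0.0),
            rec_params=RecordingParams(duration=5.0, n_jitters=1),
        )
        tpl = b.templates[0, 0]
        amps, max_ch = template_amplitudes(tpl)
        trough = int(np.unravel_index(np.argmin(tpl), tpl.shape)[-1])
        n_pts = tpl.shape[-1]
        fs = b.info["fs"]
        cors = []
        for t in b.spiketrains.trains[0]:
            lo = int(round(t * fs)) - trough
            if lo < 0 or lo + n_pts > b.recordings.shape[1]:
                continue
            cors.append(np.corrcoef(b.recordings[max_ch, lo : lo + n_pts], tpl[max_ch])[0, 1])
        assert np.mean(cors) > 0.99

    def test_forced_collision_is_sum_of_templates(self, small_library):
        """At a spatio-temporal collision the noise-free recording equals the
        sample-wise sum of the two colliding templates."""
        from spikesim.spiketrains import SpikeTrainSet

        rules = SelectionRules(n_exc=2, n_inh=0)
        idx = select_templates(small_library, rules, temp_seed=1)
        t0, t1 = small_library.templates[idx]
        # recompute both units' contributions independently
        fs, n_samples = 32000.0, 32000
        spike = np.array([0.5])
        out0 = convolve_unit(spike, t0[None], np.ones(1), fs, n_samples, np.zeros(1, int))
        out1 = convolve_unit(spike, t1[None], np.ones(1), fs, n_samples, np.zeros(1, int))
        both = convolve_unit(spike, t0[None], np.ones(1), fs, n_samples, np.zeros(1, int))
        both = convolve_unit(spike, t1[None], np.ones(1), fs, n_samples, np.zeros(1, int), out=both)
        assert np.allclose(both, out0 + out1, atol=1e-5)

    def test_drifting_bundle_has_step_axis(self, drifting_library):
        b = assemble_recording(
            drifting_library,
            rules=SelectionRules(n_exc=2, n_inh=1),
            drift=DriftParams(enabled=True, mode="slow"),
            rec_params=RecordingParams(duration=2.0, n_jitters=2),
        )
        assert b.drifting
        assert b.templates.shape[1] == 30
        assert b.templates_locations.shape == (3, 30, 3)

    def test_drift_requires_drifting_library(self, small_library):
        with pytest.raises(ValueError, match="drifting"):
            assemble_recording(
                small_library,
                drift=DriftParams(enabled=True),
                rec_params=RecordingParams(duration=1.0),
            )


class TestFilterRecording:
    def test_highpass_removes_dc_offset(self):
        rec = np.full((2, 32000), 100.0)
        out = filter_recording(rec, "highpass", [300.0], 3, 32000.0)
        assert np.abs(out.mean()) < 1e-6 * 100.0

    def test_in_band_sine_amplitude_preserved(self):
        fs = 32000.0
        t = np.arange(int(fs)) / fs
        rec = np.sin(2 * np.pi * 1000.0 * t)[None, :]
        out = filter_recording(rec, "bandpass", (300.0, 6000.0), 3, fs)
        mid = slice(2000, -2000)  # avoid edge transients
        assert np.abs(out[0, mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_repeated_filtering_stable_within_ripple(self):
        # for an in-band signal the cascaded response stays within 2%
        fs = 32000.0
        t = np.arange(64000) / fs
        rec = np.sin(2 * np.pi * 1000.0 * t)[None, :]
        once = filter_recording(rec, "bandpass", (300.0, 6000.0), 3, fs)
        twice = filter_recording(once, "bandpass", (300.0, 6000.0), 3, fs)
        mid = slice(4000, -4000)
        assert np.abs(twice[0, mid]).max() == pytest.approx(np.abs(once[0, mid]).max(), rel=0.02)

    def test_invalid_cutoffs_rejected(self):
        rec = np.zeros((1, 1000))
        with pytest.raises(ValueError):
            filter_recording(rec, "highpass", [20000.0], 3, 32000.0)
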