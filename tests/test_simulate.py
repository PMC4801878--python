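"""Synthetic recordings: event trains, response morphologies, noise, round trips."""

import numpy as np
import pytest
from dataclasses import replace

from nirsdot.events import EventSet
from nirsdot.preprocess import bandpass, to_optical_density
from nirsdot.simulate import (
    HRSpec,
    NoiseSpec,
    calibrate_amplitude,
    fit_response_params,
    hr_waveform,
    make_event_train,
    noise_od_sd,
    simulate_null,
    simulate_recording,
)


class TestEventTrain:
    def test_zero_rate_empty(self):
        assert len(make_event_train(600, 0.0, 5, seed=0)) == 0

    def test_poisson_count_property(self):
        rate, dur = 6.0, 600.0
        counts = [len(make_event_train(dur, rate, 0.0, seed=s)) for s in range(100)]
        expected = rate / 60 * dur
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 100)

    def test_refractory_enforced(self):
        ev = make_event_train(1200, 6.0, 7.5, seed=3)
        assert np.diff(ev.times).min() >= 7.5

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="refractory"):
            make_event_train(600, 30.0, 7.5, seed=0)


class TestWaveform:
    def test_zero_amplitude_zero_traces(self):
        t = np.linspace(-20, 40, 500)
        w = hr_waveform(HRSpec(hbo_amplitude_uM=0.0), t)
        np.testing.assert_array_equal(w, 0.0)

    def test_no_undershoot_single_nonnegative_lobe(self):
        t = np.linspace(-20, 40, 2000)
        w = hr_waveform(HRSpec(undershoot_ratio=0.0), t)
        assert (w[0] >= 0).all()

    def test_peak_time_matches_spec_within_sample(self):
        t = np.arange(-20, 40, 0.05)
        for spec in (HRSpec(), HRSpec(onset_shift_s=0, time_to_peak_s=20, duration_s=35)):
            w = hr_waveform(spec, t)
            got = t[np.argmax(np.abs(w[0]))]
            assert got == pytest.approx(spec.onset_shift_s + spec.time_to_peak_s, abs=0.05)

    def test_support_matches_onset_and_duration(self):
        t = np.arange(-20, 40, 0.05)
        spec = HRSpec(onset_shift_s=-9.5, time_to_peak_s=14.5, duration_s=30)
        w = hr_waveform(spec, t)[0]
        sup = t[np.abs(w) >= 0.05 * np.abs(w).max()]
        assert sup[0] == pytest.approx(-9.5, abs=0.1)
        assert sup[-1] == pytest.approx(20.5, abs=0.1)

    def test_hbr_is_scaled_flipped_hbo(self):
        t = np.linspace(-20, 40, 500)
        w = hr_waveform(HRSpec(undershoot_ratio=0.4), t)
        np.testing.assert_allclose(w[1], -w[0] / 3.0)

    @pytest.mark.parametrize(
        "spec, first_sign",
        [
            (HRSpec(undershoot_ratio=0.5), +1),  # HbO up then down
            (HRSpec(polarity="inverted", undershoot_ratio=0.5), -1),  # down then up
            (HRSpec(), +1),  # monophasic up
        ],
    )
    def test_cohort_morphologies_expressible(self, spec, first_sign):
        t = np.arange(spec.onset_shift_s, spec.onset_shift_s + spec.duration_s, 0.05)
        hbo = hr_waveform(spec, t)[0]
        assert np.sign(hbo[np.abs(hbo) > 0.2 * np.abs(hbo).max()][0]) == first_sign
        if spec.undershoot_ratio > 0:
            assert hbo.min() < 0 < hbo.max()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            HRSpec(duration_s=-1)
        with pytest.raises(ValueError):
            HRSpec(time_to_peak_s=30, duration_s=20)
        with pytest.raises(ValueError):
            HRSpec(polarity="sideways")


class TestFitResponseParams:
    def test_band_deformation_compensated(self):
        # through the analysis band a 22 s bump reads ~17 s at 5 % of peak;
        # the template fit recovers the generating parameters instead
        from scipy import signal

        fs = 20.0
        ts = np.arange(-20, 40, 1 / fs)
        t_ext = np.arange(-140, 160, 1 / fs)
        w = hr_waveform(HRSpec(), t_ext)[0]
        sos = signal.butter(4, [0.005, 0.3], btype="bandpass", fs=fs, output="sos")
        filt = signal.sosfiltfilt(sos, w)
        sel = (t_ext >= -20) & (t_ext < 40)
        fit = fit_response_params(filt[sel], t_ext[sel], fs)
        assert fit["onset_s"] == pytest.approx(-5.0, abs=0.5)
        assert fit["duration_s"] == pytest.approx(22.0, rel=0.05)
        assert fit["model_correlation"] > 0.99


@pytest.fixture(scope="module")
def sim_setup(toy_scene):
    ev = EventSet(
        times=np.array([60.0, 150.0, 240.0]),
        labels=np.array(["ied", "ied", "control"], object),
    )
    return toy_scene, ev


class TestSimulateRecording:
    def test_zero_hr_zero_noise_constant_intensity(self, sim_setup):
        scene, ev = sim_setup
        silent = NoiseSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0, pink_sd=0, white_sd=0)
        raw, _ = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=0.0), silent, seed=0, duration_s=300.0,
        )
        assert np.ptp(raw.intensity) == 0.0

    def test_noise_free_od_round_trip_1e10(self, sim_setup):
        scene, ev = sim_setup
        silent = NoiseSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0, pink_sd=0, white_sd=0)
        raw, truth = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=2.0), silent, seed=0, duration_s=300.0,
        )
        od = to_optical_density(raw)
        expected = truth["od_signal"] + np.log(
            np.exp(-truth["od_signal"]).mean(axis=-1, keepdims=True)
        )
        np.testing.assert_allclose(od.values, expected, atol=1e-10)

    def test_amplitude_linearity(self, sim_setup):
        scene, ev = sim_setup
        silent = NoiseSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0, pink_sd=0, white_sd=0)
        kw = dict(seed=0, duration_s=300.0)
        _, t1 = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=1.0), silent, **kw,
        )
        _, t2 = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=2.0), silent, **kw,
        )
        np.testing.assert_allclose(t2["od_signal"], 2.0 * t1["od_signal"], atol=1e-14)

    def test_controls_do_not_evoke_responses(self, sim_setup):
        scene, ev = sim_setup
        silent = NoiseSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0, pink_sd=0, white_sd=0)
        raw, truth = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=1.0), silent, seed=0, duration_s=300.0,
        )
        ctl = ev.select("control")[0]
        # the control marker at 240 s is >60 s from both IEDs: flat there
        k = slice(int((ctl - 2) * raw.fs), int((ctl + 20) * raw.fs))
        assert np.abs(truth["od_signal"][:, :, k]).max() == 0.0

    def test_event_outside_run_raises(self, sim_setup):
        scene, ev = sim_setup
        bad = EventSet(times=np.array([500.0]), labels=np.array(["ied"], object))
        with pytest.raises(ValueError, match="outside"):
            simulate_recording(
                scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
                bad, HRSpec(), NoiseSpec(), seed=0, duration_s=300.0,
            )

    def test_motion_artifacts_annotated(self, sim_setup):
        scene, ev = sim_setup
        noisy = NoiseSpec(motion_rate_per_min=4.0)
        raw, _ = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=0.0), noisy, seed=5, duration_s=300.0,
        )
        assert len(raw.artifact_segments) > 0
        assert all(0 <= a < b <= 300.0 for a, b in raw.artifact_segments)


class TestSimulateNull:
    def test_identical_to_zero_amplitude_recording(self, sim_setup):
        scene, ev = sim_setup
        kw = dict(seed=9, duration_s=300.0)
        a, _ = simulate_null(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=5.0), NoiseSpec(), **kw,
        )
        b, _ = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(hbo_amplitude_uM=0.0), NoiseSpec(), **kw,
        )
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_event_locked_average_vanishes_with_many_events(self, sim_setup):
        scene, _ = sim_setup
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(30, 1970, 200))
        ev = EventSet(times=times, labels=np.array(["ied"] * 200, object))
        raw, _ = simulate_null(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(), NoiseSpec(), seed=1, duration_s=2000.0,
        )
        od = to_optical_density(raw)
        from nirsdot.events import epoch

        eps, _ = epoch(od.values, od.fs, times, window=(-2, 2))
        avg = eps.data.mean(axis=0)
        assert np.abs(avg).max() < 3 * noise_od_sd(NoiseSpec(), band=None) / np.sqrt(200) * 4

    def test_physiological_peaks_present_then_filtered(self, sim_setup):
        scene, _ = sim_setup
        from scipy.signal import periodogram

        ev = EventSet(times=np.array([100.0]), labels=np.array(["ied"], object))
        raw, _ = simulate_null(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, HRSpec(), NoiseSpec(), seed=2, duration_s=600.0,
        )
        od = to_optical_density(raw).values[0, 0]
        f, p = periodogram(od, fs=20.0)
        cardiac = p[(f > 0.9) & (f < 1.3)].sum()
        flat = p[(f > 3.0) & (f < 5.0)].sum()
        assert cardiac > 20 * flat
        filt = bandpass(od, 20.0)
        f2, p2 = periodogram(filt, fs=20.0)
        assert p2[(f2 > 0.9) & (f2 < 1.3)].sum() < 0.01 * cardiac


class TestCalibration:
    def test_peak_to_noise_convention(self, toy_scene):
        scene = toy_scene
        hr, noise = HRSpec(), NoiseSpec()
        amp = calibrate_amplitude(
            scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask, hr, noise,
            peak_to_noise=0.5,
        )
        hr2 = replace(hr, hbo_amplitude_uM=amp)
        ev = EventSet(times=np.array([100.0]), labels=np.array(["ied"], object))
        silent = NoiseSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0, pink_sd=0, white_sd=0)
        _, truth = simulate_recording(
            scene.head, scene.channels, scene.smaps, scene.voi_mask, scene.mirror_mask,
            ev, hr2, silent, seed=0, duration_s=300.0,
        )
        got = np.abs(truth["od_signal"]).max()
        assert got == pytest.approx(0.5 * noise_od_sd(noise), rel=0.02)

    def test_in_band_sd_below_broadband(self):
        n = NoiseSpec()
        assert noise_od_sd(n) < noise_od_sd(n, band=None)
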