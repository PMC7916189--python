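"""Forward model: synthetic spectra, frames, recordings and cohorts."""

import numpy as np
import pytest

import ldflow
from ldflow import (
    Band,
    ScattererModel,
    cmbc,
    compute_power_spectrum,
    default_grid,
    extract_features,
    make_profile,
    mean_speed,
    scaled_heating_plan,
    synth_breath_hold,
    synth_cohort,
    synth_frame,
    synth_occlusion,
    synth_recording,
    synth_spectrum,
)
from ldflow.cumsum import average_curve
from ldflow.errors import ConfigurationError
from ldflow.spectral import spectra_to_series
from ldflow.synthetic import line_shape, model_spectrum


class TestSynthSpectrum:
    def test_zero_concentration_and_floor_give_null_spectrum(self):
        model = ScattererModel(conc=0.0, noise_floor=0.0)
        spec = synth_spectrum(model)
        assert np.all(spec.S == 0.0)

    def test_doubling_concentration_doubles_expected_spectrum(self):
        f = default_grid()
        s1 = model_spectrum(ScattererModel(conc=1.0), f)
        s2 = model_spectrum(ScattererModel(conc=2.0), f)
        assert np.allclose(s2, 2.0 * s1)

    def test_cmbc_exactly_proportional_to_concentration(self):
        # the line shape is unit-area on the grid, so the zeroth moment
        # tracks conc linearly (r^2 > 0.999 with noise off)
        f = default_grid()
        concs = np.linspace(0.5, 5.0, 10)
        vals = [cmbc(synth_spectrum(ScattererModel(conc=float(c)), f),
                     Band(20.0, 12_800.0)) for c in concs]
        r = np.corrcoef(concs, vals)[0, 1]
        assert r**2 > 0.999

    def test_mean_speed_monotone_in_v_scale(self):
        f = default_grid()
        speeds = [mean_speed(synth_spectrum(ScattererModel(v_scale=v), f),
                             Band(60.0, 12_800.0))
                  for v in [200.0, 400.0, 800.0]]
        assert speeds[0] < speeds[1] < speeds[2]

    def test_sampling_noise_is_mean_preserving(self, rng):
        model = ScattererModel()
        f = default_grid()
        target = model_spectrum(model, f)
        draws = np.mean([synth_spectrum(model, f, rng=rng).S for _ in range(400)],
                        axis=0)
        rel = np.linalg.norm(draws - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_gaussian_and_mixture_shapes(self):
        f = default_grid()
        for shape in ("gaussian", {"lorentzian": 0.6, "gaussian": 0.4}):
            s = synth_spectrum(ScattererModel(shape=shape), f)
            assert np.all(s.S >= 0)
            assert np.trapezoid(s.S, f) == pytest.approx(1.0, rel=1e-9)

    def test_invalid_models_rejected(self):
        with pytest.raises(ConfigurationError):
            ScattererModel(v_scale=-1.0)
        with pytest.raises(ConfigurationError):
            ScattererModel(shape={"lorentzian": 0.5, "gaussian": 0.2})


class TestSynthFrame:
    def test_common_mode_artefact_cancels_in_the_differential(self, rng):
        # artefact amplitude 10x the Doppler component leaves the averaged
        # differential spectrum unchanged within estimation error
        model = ScattererModel(conc=1.0, v_scale=800.0, noise_floor=0.0)
        rms = np.std(synth_frame(model, rng=rng).differential)
        spectra_clean, spectra_cm = [], []
        for i in range(100):
            fr1 = synth_frame(model, rng=np.random.default_rng(1000 + i))
            fr2 = synth_frame(model, rng=np.random.default_rng(1000 + i),
                              common_mode_amplitude=10.0 * rms)
            spectra_clean.append(compute_power_spectrum(fr1).S)
            spectra_cm.append(compute_power_spectrum(fr2).S)
        m_clean = np.mean(spectra_clean, axis=0)
        m_cm = np.mean(spectra_cm, axis=0)
        rel = np.linalg.norm(m_cm - m_clean) / np.linalg.norm(m_clean)
        assert rel < 0.05

    def test_zero_doppler_component_leaves_only_channel_noise(self, rng):
        model = ScattererModel(conc=0.0, noise_floor=1e-4)
        spectra = [compute_power_spectrum(synth_frame(model, rng=rng)).S
                   for _ in range(200)]
        mean_S = np.mean(spectra, axis=0)
        assert np.mean(mean_S) == pytest.approx(1e-4, rel=0.05)
        # flat: no systematic tilt across the band
        lo, hi = mean_S[:320].mean(), mean_S[320:].mean()
        assert lo == pytest.approx(hi, rel=0.05)

    def test_empirical_mean_spectrum_matches_target_shape(self):
        model = ScattererModel(conc=1.0, v_scale=600.0, noise_floor=0.0)
        fs, n = 50_000.0, 2500
        acc = np.zeros(640)
        for i in range(1000):
            fr = synth_frame(model, fs=fs, n_samples=n,
                             rng=np.random.default_rng(i))
            acc += compute_power_spectrum(fr).S
        mean_S = acc / 1000
        freqs = np.fft.rfftfreq(n, 1 / fs)[1:]
        target = model.conc * line_shape(freqs, model.v_scale)[:640]
        rel = np.linalg.norm(mean_S - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_too_short_frame_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_frame(ScattererModel(), n_samples=1)


class TestSynthRecording:
    def test_amplitude_responder_has_zero_abc_and_positive_dbp(self):
        profile = make_profile("amplitude")  # conc x3, v_scale x1, no jitter
        plan = scaled_heating_plan(0.1)
        specs = synth_recording(profile, plan=plan, rng=None)  # noise off
        fv = extract_features(specs, plan=plan)
        assert fv.abc == 0.0
        assert fv.dbp > 0
        assert fv.dv31 == pytest.approx(0.0, abs=1e-9)

    def test_broadening_responder_has_positive_abc_and_dv31(self):
        profile = make_profile("broadening")
        plan = scaled_heating_plan(0.1)
        specs = synth_recording(profile, plan=plan, rng=None)
        fv = extract_features(specs, plan=plan)
        assert fv.abc > 0
        assert fv.dv31 > 0

    def test_non_responder_features_are_small(self):
        plan = scaled_heating_plan(0.1)
        quiet = extract_features(
            synth_recording(make_profile("non-responder"), plan=plan,
                            rng=np.random.default_rng(5)), plan=plan)
        loud = extract_features(
            synth_recording(make_profile("mixed"), plan=plan,
                            rng=np.random.default_rng(5)), plan=plan)
        assert abs(quiet.dbp) < 0.25 * abs(loud.dbp)
        assert quiet.abc < 0.5 * loud.abc

    def test_tick_rate_and_duration(self):
        plan = scaled_heating_plan(0.1)
        specs = synth_recording(make_profile("mixed"), plan=plan)
        assert len(specs) == int(round(plan.duration / 0.05))
        assert specs[1].t0 - specs[0].t0 == pytest.approx(0.05)


class TestSynthCohort:
    def test_same_seed_reproduces_the_table(self):
        plan = scaled_heating_plan(0.02)
        t1 = synth_cohort(n_per_group=3, seed=42, plan=plan)
        t2 = synth_cohort(n_per_group=3, seed=42, plan=plan)
        assert t1.equals(t2)

    def test_groups_and_columns(self):
        plan = scaled_heating_plan(0.02)
        t = synth_cohort(n_per_group=2, seed=0, plan=plan)
        assert set(t["group"]) == {"responder", "patient"}
        assert {"abc", "dbp", "dv31", "subject_id"} <= set(t.columns)

    def test_too_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_cohort(n_per_group=0)


class TestProvocations:
    def band_pu(self, specs, band, window):
        sel = [s for s in specs if window[0] <= s.t0 < window[1]]
        return np.mean([p.pu for p in spectra_to_series(sel, band=band)])

    def test_baseline_only_series_is_stationary(self):
        profile = make_profile("mixed")
        specs = synth_breath_hold(profile, timings=(60.0, 1e-9, 0.0),
                                  rng=None)  # no hold, noise off
        low = Band(60.0, 400.0)
        first = self.band_pu(specs, low, (0.0, 30.0))
        second = self.band_pu(specs, low, (30.0, 60.0))
        assert second == pytest.approx(first, rel=0.05)  # oscillations only

    def test_breath_hold_redistributes_band_perfusion(self):
        # during the hold the low band (60-400 Hz) rises while the broad
        # band (60-6400 Hz) falls
        profile = make_profile("mixed")
        rng = np.random.default_rng(3)
        specs = synth_breath_hold(profile, timings=(30.0, 20.0, 30.0), rng=rng)
        low, broad = Band(60.0, 400.0), Band(60.0, 6400.0)
        before, hold = (0.0, 28.0), (34.0, 46.0)
        assert self.band_pu(specs, low, hold) > self.band_pu(specs, low, before)
        assert self.band_pu(specs, broad, hold) < self.band_pu(specs, broad, before)

    def test_occlusion_lifts_the_cumulative_curve_pointwise(self):
        profile = make_profile("mixed")
        rng = np.random.default_rng(9)
        specs = synth_occlusion(profile, timings=(30.0, 30.0, 30.0), rng=rng)
        baseline = average_curve(specs, (0.0, 28.0))
        occluded = average_curve(specs, (36.0, 56.0))
        assert np.all(occluded.C >= baseline.C - 1e-12)
        assert np.max(occluded.C - baseline.C) > 0.01


class TestIdentifiability:
    def test_extracted_mean_speed_monotone_in_generating_v_scale(self):
        f = default_grid()
        grid = np.linspace(200.0, 2000.0, 10)
        extracted = [mean_speed(synth_spectrum(ScattererModel(v_scale=float(v)), f),
                                Band(60.0, 12_800.0)) for v in grid]
        assert np.all(np.diff(extracted) > 0)

    def test_extracted_cmbc_linear_in_concentration(self):
        f = default_grid()
        concs = np.linspace(0.2, 4.0, 10)
        vals = np.array([cmbc(synth_spectrum(ScattererModel(conc=float(c)), f),
                              Band(20.0, 12_800.0)) for c in concs])
        slope, intercept = np.polyfit(concs, vals, 1)
        pred = slope * concs + intercept
        ss_res = np.sum((vals - pred) ** 2)
        ss_tot = np.sum((vals - vals.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_randomness_flows_through_the_supplied_generator(self):
        model = ScattererModel()
        s1 = synth_spectrum(model, rng=np.random.default_rng(5))
        s2 = synth_spectrum(model, rng=np.random.default_rng(5))
        assert np.array_equal(s1.S, s2.S)
        assert ldflow.synth_spectrum is synth_spectrum
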