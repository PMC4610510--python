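"""Generator contracts: frequency grid, dispersion shape, culture dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capsense.simulate import (CloneProfile, CultureParams, DisturbanceSpec, SamplingSpec,
                               dispersion_response, generate_clone_pair,
                               make_frequency_grid, simulate_run)

from conftest import EXACT_SAMPLING, NOISELESS, clean_clone, short_culture


class TestFrequencyGrid:
    def test_endpoints_and_log_spacing(self):
        f = make_frequency_grid(17, 0.3, 10.0)
        assert f[0] == pytest.approx(0.3)
        assert f[-1] == pytest.approx(10.0)
        # log-spaced: constant ratio between neighbours
        assert np.allclose(np.diff(np.log(f)), np.log(f[1] / f[0]))
        # the 10th frequency is the published upper window bound
        assert f[9] == pytest.approx(0.3 * (10 / 0.3) ** (9 / 16))
        assert round(f[9], 2) == 2.16

    def test_two_point_grid(self):
        assert np.allclose(make_frequency_grid(2, 1.0, 10.0), [1.0, 10.0])

    @pytest.mark.parametrize("args", [(1, 0.3, 10), (17, 0, 10), (17, -1, 10), (17, 5, 5),
                                      (17, 10, 0.3)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_frequency_grid(*args)


class TestDispersion:
    def test_debye_midpoint_and_plateau(self):
        assert dispersion_response(1.2, 1.2, 0.0) == pytest.approx(0.5)
        assert dispersion_response(0.012, 1.2, 0.0) == pytest.approx(1.0, abs=2e-4)

    @given(fc=st.floats(0.1, 10.0), alpha=st.floats(0.0, 0.9),
           f=st.floats(0.01, 100.0))
    def test_bounded_and_monotone(self, fc, alpha, f):
        r1 = dispersion_response(f, fc, alpha)
        r2 = dispersion_response(2 * f, fc, alpha)
        assert 0.0 < r1 <= 1.0
        assert r2 < r1

    def test_limits(self):
        assert dispersion_response(1e-6, 2.0, 0.3) == pytest.approx(1.0, abs=1e-3)
        assert dispersion_response(1e6, 2.0, 0.3) == pytest.approx(0.0, abs=1e-3)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            dispersion_response(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            dispersion_response(1.0, 1.0, -0.1)


class TestSimulateRun:
    def test_seed_determinism(self):
        kw = dict(clone=CloneProfile(), culture=short_culture(),
                  disturb=DisturbanceSpec(), sampling=SamplingSpec(), seed=11)
        a, b = simulate_run(**kw), simulate_run(**kw)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.vcc_offline, b.vcc_offline)
        assert np.array_equal(a.ground_truth_debris, b.ground_truth_debris)

    def test_exact_proportionality_without_interferents(self, noiseless_run):
        """With zero noise/debris/drift every channel is a scalar multiple of VCC."""
        run = noiseless_run
        v = run.ground_truth_vcc
        r = np.corrcoef(run.spectra[:, 0], v)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        # channel ratios equal dispersion-response ratios (closed form)
        clone = clean_clone()
        disp = dispersion_response(run.frequencies, clone.critical_frequency_cells,
                                   clone.cole_cole_alpha)
        ratio = run.spectra[50] / run.spectra[50, 0]
        assert np.allclose(ratio, disp / disp[0], rtol=1e-9)

    def test_growth_then_decline_shape(self, noiseless_run):
        v = noiseless_run.ground_truth_vcc
        peak = int(np.argmax(v))
        assert 0 < peak < len(v) - 1
        assert v[-1] < 0.5 * v[peak]
        assert v[peak] > 3 * v[0]

    def test_cell_conservation_without_growth(self):
        """d(VCC + dead + debris)/dt is the growth term alone."""
        culture = CultureParams(mu_max=0.0, duration=120, death_onset=30, inoculum=5.0)
        run = simulate_run(clean_clone(), culture, NOISELESS, EXACT_SAMPLING, seed=0)
        total = run.ground_truth_tcc + run.ground_truth_debris
        assert np.allclose(total, culture.inoculum, rtol=1e-9)

    def test_tcc_viability_bookkeeping(self, debris_heavy_run):
        run = debris_heavy_run
        assert np.all(run.tcc_offline >= run.vcc_offline)
        assert np.all((run.viability_offline > 0) & (run.viability_offline <= 100))
        assert np.all(np.diff(run.ground_truth_debris) >= -1e-12)
        assert np.all(run.spectra >= 0)

    def test_debris_dominates_high_frequency_late(self, debris_heavy_run):
        """Normalized top channel stays high after normalized VCC has declined."""
        run = debris_heavy_run
        fq17 = run.spectra[:, -1] / run.spectra[:, -1].max()
        vcc = run.ground_truth_vcc / run.ground_truth_vcc.max()
        assert fq17[-1] > vcc[-1]

    def test_debris_amplitude_monotone_effect(self):
        ends = []
        for amp in (0.5, 1.0, 2.0):
            run = simulate_run(CloneProfile(debris_amplitude=amp), CultureParams(),
                               NOISELESS, EXACT_SAMPLING, seed=1)
            ends.append((run.spectra[-1, -1], run.ground_truth_vcc[-1]))
        caps, vccs = zip(*ends)
        assert caps[0] < caps[1] < caps[2]
        assert vccs[0] == vccs[1] == vccs[2]

    def test_bolus_dilutes_state(self):
        disturb = DisturbanceSpec(bolus_times=((48.0, 0.2),), noise_cv=0.0)
        run = simulate_run(clean_clone(), short_culture(), disturb, EXACT_SAMPLING, seed=0)
        i = int(np.searchsorted(run.times_online, 48.0))
        assert run.ground_truth_vcc[i + 1] < 0.9 * run.ground_truth_vcc[i - 1]

    def test_offline_must_be_sparser_than_online(self):
        with pytest.raises(ValueError):
            SamplingSpec(online_interval=1.0, offline_interval=0.5)

    @pytest.mark.parametrize("bad", [
        dict(per_cell_capacitance=-1.0),
        dict(cole_cole_alpha=1.2),
        dict(debris_critical_frequency=0.5),  # below the cell dispersion
    ])
    def test_clone_profile_validation(self, bad):
        with pytest.raises(ValueError):
            CloneProfile(**bad)

    def test_culture_validation(self):
        with pytest.raises(ValueError):
            CultureParams(duration=100, death_onset=150)
        with pytest.raises(ValueError):
            CultureParams(inoculum=1.0)


class TestClonePair:
    def test_empty_fleet(self):
        a, b = generate_clone_pair(CloneProfile(), 1.0, CultureParams(), 0, seed=0)
        assert a == [] and b == []

    def test_amplitude_ratio_scales_spectra_only(self):
        a, b = generate_clone_pair(clean_clone(), 2.0, short_culture(), 2, seed=4,
                                   disturb=NOISELESS, sampling=EXACT_SAMPLING,
                                   culture_jitter=0.0, fc_debris_jitter=0.0)
        # identical culture kinetics, doubled dielectric amplitude
        assert np.allclose(a[0].ground_truth_vcc, b[0].ground_truth_vcc)
        assert np.allclose(b[0].spectra, 2.0 * a[0].spectra, rtol=1e-9)

    def test_unit_ratio_fleets_are_exchangeable(self):
        a, b = generate_clone_pair(CloneProfile(), 1.0, CultureParams(), 3, seed=9)
        peak_a = np.mean([r.ground_truth_vcc.max() for r in a])
        peak_b = np.mean([r.ground_truth_vcc.max() for r in b])
        cap_a = np.mean([r.spectra[:, 0].max() for r in a])
        cap_b = np.mean([r.spectra[:, 0].max() for r in b])
        assert peak_b == pytest.approx(peak_a, rel=0.15)
        assert cap_b == pytest.approx(cap_a, rel=0.15)

    def test_base_model_overestimates_brighter_clone(self):
        """Amplitude ratio 1/0.69 inflates the foreign estimate by ~1.449."""
        from capsense.dataio import spline_align
        from capsense.model import fit_pls, predict_vcc

        ratio = 1 / 0.69
        a, b = generate_clone_pair(clean_clone(), ratio, CultureParams(), 1, seed=2)
        run_a = a[0].to_fermentation_run("A1")
        run_b = b[0].to_fermentation_run("B1")
        model = fit_pls(spline_align(run_a))
        y_hat = predict_vcc(model, run_b.spectra)
        factor = np.mean(y_hat[100:]) / np.mean(b[0].ground_truth_vcc[100:])
        assert factor == pytest.approx(ratio, rel=0.05)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            generate_clone_pair(CloneProfile(), -0.5, CultureParams(), 1, seed=0)
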