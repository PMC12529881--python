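"""Histogram construction, peak fitting and fraction conventions."""

import numpy as np
import pytest

from oligomp import (
    Condition,
    NoiseModel,
    build_histogram,
    calibrate,
    fit_peaks,
    fractions_from_counts,
    mass_accuracy,
    simulate_calibration_standard,
    simulate_events,
    species_fractions,
)
from oligomp.histogram import _window_counts
from oligomp.synthetic import EventList


class TestBuildHistogram:
    def test_counts_conserved(self, params):
        ev = simulate_events(params, None, Condition(c_tot=1e-6), n_events=8000, seed=1)
        h = build_histogram(ev)
        assert h.n_total == 8000

    def test_single_mass_single_bin(self):
        ev = EventList(masses=np.full(50, 100.0), condition=Condition(c_tot=1e-9), seed=0)
        h = build_histogram(ev, bin_width=4.0)
        assert (h.counts > 0).sum() == 1

    def test_noise_free_three_bins(self, params, clean_noise):
        ev = simulate_events(params, None, Condition(c_tot=1e-6), n_events=8000,
                             noise=clean_noise, seed=1)
        h = build_histogram(ev, bin_width=4.0)
        assert (h.counts > 0).sum() == 3

    def test_empty_raises(self):
        ev = EventList(masses=np.array([]), condition=Condition(c_tot=1e-9), seed=0)
        with pytest.raises(ValueError):
            build_histogram(ev)


class TestFitPeaks:
    def test_recovers_species_means(self, params):
        ev = simulate_events(params, None, Condition(c_tot=1e-6), n_events=8000,
                             noise=NoiseModel(peak_cv=0.08, background_rate=0.02), seed=8)
        pf = fit_peaks(ev)
        assert pf.converged and pf.method == "em"
        np.testing.assert_allclose(pf.means, [46.4, 92.8, 185.6], rtol=0.02)

    def test_noise_free_falls_back_to_exact_window_counts(self, params, clean_noise):
        cond = Condition(c_tot=1e-6)
        ev = simulate_events(params, None, cond, n_events=8000, noise=clean_noise, seed=8)
        pf = fit_peaks(ev)
        assert not pf.converged and pf.method == "window"
        expected = np.array([np.sum(ev.masses == m) for m in (46.4, 92.8, 185.6)])
        np.testing.assert_array_equal(pf.counts, expected)

    def test_absent_tetramer_gets_near_zero_count(self, params):
        # deep dilution: essentially no tetramer particles
        ev = simulate_events(params, None, Condition(c_tot=2e-9), n_events=8000,
                             noise=NoiseModel(peak_cv=0.08, background_rate=0.0), seed=8)
        pf = fit_peaks(ev)
        assert pf.counts[2] / pf.counts.sum() < 0.005

    def test_posterior_and_window_counts_agree(self, params):
        ev = simulate_events(params, None, Condition(c_tot=1e-6), n_events=8000,
                             noise=NoiseModel(peak_cv=0.08, background_rate=0.0), seed=3)
        pf = fit_peaks(ev)
        win, _ = _window_counts(ev.masses, np.array([46.4, 92.8, 185.6]),
                                0.08 * np.array([46.4, 92.8, 185.6]), 2.5)
        np.testing.assert_allclose(pf.counts, win, rtol=0.02, atol=8)

    def test_too_few_events_raises(self):
        ev = EventList(masses=np.full(50, 46.4), condition=Condition(c_tot=1e-9), seed=0)
        with pytest.raises(ValueError):
            fit_peaks(ev)


class TestFractions:
    def test_low_concentration_worked_example(self):
        # count ratio 18:31:1 -> monomer-equivalent fractions 21.4/73.8/4.8 %
        fr = fractions_from_counts([18, 31, 1])
        assert fr.conc_fractions == pytest.approx((0.2143, 0.7381, 0.0476), abs=1e-4)

    def test_high_concentration_worked_example(self):
        # count ratio 4:18:7 -> 5.9/52.9/41.2 %
        fr = fractions_from_counts([4, 18, 7])
        assert fr.conc_fractions == pytest.approx((0.0588, 0.5294, 0.4118), abs=1e-4)

    def test_pure_monomer(self):
        fr = fractions_from_counts([123, 0, 0])
        assert fr.count_fractions == (1.0, 0.0, 0.0)
        assert fr.conc_fractions == (1.0, 0.0, 0.0)

    def test_conventions_consistent(self, rng):
        for _ in range(20):
            c = rng.integers(1, 1000, size=3).astype(float)
            fr = fractions_from_counts(c)
            w = np.array(fr.count_fractions) * [1, 2, 4]
            np.testing.assert_allclose(fr.conc_fractions, w / w.sum(), rtol=1e-12)
            assert sum(fr.count_fractions) == pytest.approx(1.0, abs=1e-9)
            assert sum(fr.conc_fractions) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            fractions_from_counts([0, 0, 0])

    def test_end_to_end_fraction_recovery(self, params):
        # pipeline recovers the generator's concentration fractions to ~3 pp
        for c_tot in (50e-9, 800e-9, 50e-6):
            cond = Condition(c_tot=c_tot)
            ev = simulate_events(params, None, cond, n_events=8000, seed=17)
            fr = fractions_from_counts(fit_peaks(ev).counts)
            truth = species_fractions(params, None, cond).conc_fractions()
            np.testing.assert_allclose(fr.conc_fractions, truth, atol=0.03)


class TestMassAccuracy:
    @pytest.mark.parametrize(
        "obs,exp,acc",
        [(50.0, 46.4, 92.8), (90.0, 92.8, 96.98), (180.0, 185.6, 96.98), (100.0, 100.0, 100.0)],
    )
    def test_worked_examples(self, obs, exp, acc):
        assert mass_accuracy(obs, exp) == pytest.approx(acc, abs=0.01)

    def test_symmetry(self):
        assert mass_accuracy(50, 46.4) == mass_accuracy(46.4, 50)


class TestCalibrate:
    def test_identity_when_already_in_kda(self):
        ev = simulate_calibration_standard(n_events=8000, noise=NoiseModel(peak_cv=0.05,
                                                                           background_rate=0.0),
                                           seed=6)
        cal = calibrate(ev, known_masses=(160, 320, 480, 640))
        assert cal.slope == pytest.approx(1.0, abs=0.02)
        assert abs(cal.intercept) < 8.0

    def test_recovers_linear_distortion(self):
        ev = simulate_calibration_standard(n_events=8000, noise=NoiseModel(peak_cv=0.05,
                                                                           background_rate=0.0),
                                           seed=6)
        distorted = EventList(masses=0.5 * ev.masses + 10.0, condition=ev.condition, seed=6)
        cal = calibrate(distorted, known_masses=(160, 320, 480, 640))
        assert cal.slope == pytest.approx(2.0, rel=0.01)
        assert cal.intercept == pytest.approx(-20.0, rel=0.05)
        np.testing.assert_allclose(cal.apply([90.0]), [160.0], rtol=0.02)

    def test_mixture_means_recovered(self):
        ev = simulate_calibration_standard(n_events=8000, noise=NoiseModel(peak_cv=0.05,
                                                                           background_rate=0.0),
                                           seed=9)
        pf = fit_peaks(ev, init_masses=[160, 320, 480, 640], init_cv=0.05, background=False)
        np.testing.assert_allclose(pf.means, [160, 320, 480, 640], rtol=0.02)

    def test_single_species_raises(self):
        ev = EventList(masses=np.random.default_rng(0).normal(160, 8, 1000),
                       condition=Condition(c_tot=1e-9), seed=0)
        with pytest.raises(ValueError):
            calibrate(ev, known_masses=(160, 320))
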