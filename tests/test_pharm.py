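"""Cheng-Prusoff conversion, Schild analysis and the OMAM global fit."""

import numpy as np
import pytest

from oligomp import (
    OMAMParams,
    PharmacologyConfig,
    calibrate_lambda,
    ic50_to_ki,
    omam_response,
    omam_global_fit,
    schild_analysis,
    schild_nonlinear,
)
from oligomp.reference import INHIBITOR_TABLE

# measured IC50 (molar) / Ki (molar) pairs of the three inhibitors
TABLE_PAIRS = [(row["ic50"], row["ki"]) for row in INHIBITOR_TABLE.values()]


class TestIc50ToKi:
    def test_classical_constructed_identity(self):
        cfg = PharmacologyConfig(mode="classical", s=100e-6, k_s=34.6e-6)
        ic50 = (1 + 100 / 34.6) * 1e-6
        assert ic50_to_ki(ic50, cfg)["ki"] == pytest.approx(1e-6, rel=1e-12)

    def test_classical_no_substrate_is_identity(self):
        cfg = PharmacologyConfig(mode="classical", s=0.0)
        assert ic50_to_ki(3.1e-6, cfg)["ki"] == pytest.approx(3.1e-6)

    def test_hill_equals_classical_at_n1(self):
        c1 = PharmacologyConfig(mode="classical", s=100e-6, k_s=34.6e-6)
        c2 = PharmacologyConfig(mode="hill", s=100e-6, k_s=34.6e-6, n=1.0)
        assert ic50_to_ki(5e-6, c1)["ki"] == pytest.approx(ic50_to_ki(5e-6, c2)["ki"])

    def test_empirical_mode_reproduces_reference_ki(self):
        lam = calibrate_lambda(TABLE_PAIRS).lam
        cfg = PharmacologyConfig(mode="empirical_lambda", lam=lam)
        ki = ic50_to_ki(3.1e-6, cfg)["ki"]
        assert ki == pytest.approx(82.6e-9, rel=0.02)

    def test_empirical_mode_requires_lambda(self):
        with pytest.raises(ValueError):
            ic50_to_ki(1e-6, PharmacologyConfig(mode="empirical_lambda"))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            PharmacologyConfig(mode="something")


class TestCalibrateLambda:
    def test_reference_table_is_consistent(self):
        cal = calibrate_lambda(TABLE_PAIRS)
        assert cal.lam == pytest.approx(37.9, abs=0.1)
        assert max(cal.residuals) < 0.02
        assert cal.consistent

    def test_single_pair(self):
        cal = calibrate_lambda([(2.0, 1.0)])
        assert cal.lam == 2.0

    def test_inconsistent_pairs_flagged(self):
        cal = calibrate_lambda([(2.0, 1.0), (200.0, 1.0)])
        assert not cal.consistent

    def test_nonpositive_pair_raises(self):
        with pytest.raises(ValueError):
            calibrate_lambda([(1.0, 0.0)])


def competitive_ec50s(k_b, b_values, ec50_control=34.6e-6):
    return {b: ec50_control * (1 + b / k_b) for b in b_values}


class TestSchildLinear:
    @pytest.mark.parametrize("k_b", [7e-9, 0.7e-6, 70e-6])
    def test_competitive_antagonist_gives_unit_slope(self, k_b):
        ec50s = competitive_ec50s(k_b, np.array([1, 2.5, 6, 15]) * k_b)
        res = schild_analysis(ec50s, 34.6e-6)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.k_b_app == pytest.approx(k_b, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_atcm_ratios_flatten_at_high_concentration(self):
        # saturating CR from the allosteric ternary-complex model: the
        # high-concentration window regresses with slope below 1
        k_b, alpha = 0.7e-6, 0.05
        b = np.geomspace(5e-6, 100e-6, 5)
        cr = (1 + b / k_b) / (1 + alpha * b / k_b)
        res = schild_analysis({bi: 34.6e-6 * c for bi, c in zip(b, cr)}, 34.6e-6)
        assert res.slope < 1.0

    def test_no_effect_region_only_raises(self):
        with pytest.raises(ValueError, match="no-effect"):
            schild_analysis({1e-9: 34.6e-6, 2e-9: 34.5e-6}, 34.6e-6)

    def test_single_usable_point_raises(self):
        ec50s = {1e-9: 34.6e-6 * 1.01, 1e-6: 34.6e-6 * 3.0}
        with pytest.raises(ValueError):
            schild_analysis(ec50s, 34.6e-6)

    def test_explicit_linear_region_bounds(self):
        k_b = 0.7e-6
        b = np.array([0.2, 0.8, 2, 5, 10, 50]) * 1e-6
        ec50s = competitive_ec50s(k_b, b)
        res = schild_analysis(ec50s, 34.6e-6, linear_region=(0.8e-6, 10e-6))
        assert res.n_used == 4
        assert res.slope == pytest.approx(1.0, abs=1e-9)


class TestSchildNonlinear:
    def test_recovers_atcm_truth(self):
        k_b, alpha = 25.2e-9, 0.02
        b = np.geomspace(1e-9, 100e-6, 12)
        cr = (1 + b / k_b) / (1 + alpha * b / k_b)
        res = schild_nonlinear({bi: 34.6e-6 * c for bi, c in zip(b, cr)}, 34.6e-6)
        assert not res["flagged"]
        assert res["k_b"] == pytest.approx(k_b, rel=1e-6)
        assert res["alpha"] == pytest.approx(alpha, rel=1e-6)

    def test_null_modulator_flagged_unidentifiable(self):
        b = np.geomspace(1e-9, 100e-6, 6)
        res = schild_nonlinear({bi: 34.6e-6 for bi in b}, 34.6e-6)  # CR = 1 throughout
        assert res["flagged"]

    def test_competitive_limit_has_unit_schild_slope(self):
        # alpha = 0 reduces the ATCM to pure competition
        k_b = 1e-6
        b = np.geomspace(2e-6, 50e-6, 5)
        ec50s = competitive_ec50s(k_b, b)
        res = schild_analysis(ec50s, 34.6e-6)
        assert res.slope == pytest.approx(1.0, abs=1e-9)


TRUTH = OMAMParams(e_max=68.3, k_s=34.6e-6, k_b=25.2e-9,
                   tau_s=17.6, tau_i=0.02, alpha=0.02, beta=0.0, n=1.3)
S_GRID = 800e-6 / 2.0 ** np.arange(14)[::-1]
B_GRID = [0.0, 2e-9, 20e-9, 0.2e-6, 0.8e-6, 2e-6, 5e-6, 10e-6, 50e-6, 200e-6]


def truth_curves(noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for b in B_GRID:
        y = omam_response(S_GRID, b, TRUTH)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, size=len(y))
        out.append((b, S_GRID, y))
    return out


class TestOmamGlobalFit:
    def test_control_only_flags_inhibitor_parameters(self):
        res = omam_global_fit([(0.0, S_GRID, omam_response(S_GRID, 0.0, TRUTH))],
                              e_max=68.3, k_s=34.6e-6)
        assert res.flagged
        assert set(res.unidentifiable) == {"k_b", "tau_i", "alpha", "beta"}
        assert res.params.tau_s == pytest.approx(17.6, rel=0.01)

    def test_missing_control_curve_raises(self):
        curves = [(b, S_GRID, omam_response(S_GRID, b, TRUTH)) for b in (1e-6, 1e-5)]
        with pytest.raises(ValueError, match="control"):
            omam_global_fit(curves, e_max=68.3, k_s=34.6e-6)

    def test_idempotent_on_own_predictions(self):
        first = omam_global_fit(truth_curves(), e_max=68.3, k_s=34.6e-6)
        pred = [(b, s, omam_response(s, b, first.params)) for b, s, _ in truth_curves()]
        second = omam_global_fit(pred, e_max=68.3, k_s=34.6e-6)
        for name in ("k_b", "tau_s", "tau_i", "alpha", "n"):
            assert getattr(second.params, name) == pytest.approx(
                getattr(first.params, name), rel=1e-6, abs=1e-9
            )

    def test_noisy_recovery_of_substrate_efficacy(self):
        curves = truth_curves(noise_sd=0.05 * 68.3 / np.sqrt(3), seed=4)
        res = omam_global_fit(curves, e_max=68.3, k_s=34.6e-6)
        assert res.params.tau_s == pytest.approx(17.6, rel=0.25)
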