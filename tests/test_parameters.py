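"""Parameter loading, validation, scaling round trips, calibration formulas."""

import dataclasses
import math

import numpy as np
import pytest

from il35sim import (
    InfeasibleCalibration,
    ParameterError,
    ScalingSystem,
    audit_parameter_table,
    calibrate_il35_production,
    calibrate_mdsc_production,
    load_scenario,
    nondimensionalize,
    redimensionalize,
)
from il35sim.parameters import (
    SCALE_EXPONENTS,
    _il35_calibration_bracket_oracle,
    _il35_forward,
    _mdsc_scenario_ratio_ode,
    scale_factor,
)


class TestScenarios:
    def test_presets_differ_only_in_tumor_il35_production(self, params_il35, params_ctrl):
        d35, dc = params_il35.as_dict(), params_ctrl.as_dict()
        diffs = [k for k in d35 if d35[k] != dc[k]]
        assert diffs == ["lambda_rho_c"]
        assert d35["lambda_rho_c"] > dc["lambda_rho_c"]

    def test_reload_is_idempotent(self, params_il35):
        again = load_scenario("J558-IL-35")
        assert dataclasses.asdict(again) == dataclasses.asdict(params_il35)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ParameterError, match="unknown scenario"):
            load_scenario("J558-nonsense")

    def test_override_applies_and_validates(self, params_il35):
        p = load_scenario("J558-IL-35", overrides={"d_c": 0.2})
        assert p.d_c == 0.2
        with pytest.raises(ParameterError, match="strictly positive"):
            load_scenario("J558-IL-35", overrides={"d_c": -1.0})
        with pytest.raises(ParameterError, match="unknown override"):
            load_scenario("J558-IL-35", overrides={"nope": 1.0})

    def test_threshold_ordering_enforced(self, params_il35):
        with pytest.raises(ParameterError, match="w_nec < w_hyp"):
            params_il35.replace(w_nec=2 * params_il35.w_hyp)
        with pytest.raises(ParameterError, match="w_star"):
            params_il35.replace(w_star=2 * params_il35.w_normal)
        with pytest.raises(ParameterError, match="eps_c"):
            params_il35.replace(eps_c=1.5)


class TestScaling:
    def test_identity_scaling_is_identity(self, params_il35):
        refs = {k: 1.0 for k in
                ("c", "q", "M", "rho", "R_treg", "beta", "T", "h", "e", "w", "A")}
        one = ScalingSystem(length=1.0, time=1.0, refs=refs)
        pn = nondimensionalize(params_il35, one)
        for k, v in params_il35.as_dict().items():
            assert pn.as_dict()[k] == v

    def test_round_trip_default_scaling(self, params_il35, scaling):
        back = redimensionalize(nondimensionalize(params_il35, scaling), scaling)
        for k, v in params_il35.as_dict().items():
            assert back.as_dict()[k] == pytest.approx(v, rel=1e-12)

    def test_round_trip_random_parameter_vectors(self, params_il35, rng):
        """100 random positive parameter sets survive the round trip to 1e-12."""
        base = params_il35.as_dict()
        worst = 0.0
        for _ in range(100):
            refs = {k: 10 ** rng.uniform(-9, 0) for k in
                    ("c", "q", "M", "rho", "R_treg", "beta", "T", "h", "e", "w", "A")}
            s = ScalingSystem(length=10 ** rng.uniform(-2, 1),
                              time=10 ** rng.uniform(-1, 1), refs=refs)
            perturbed = params_il35.replace(
                **{k: base[k] * 10 ** rng.uniform(-0.3, 0.3)
                   for k in ("lambda_c", "eta", "chi_M", "D_w", "s_q")})
            back = redimensionalize(nondimensionalize(perturbed, s), s)
            for k, v in perturbed.as_dict().items():
                worst = max(worst, abs(back.as_dict()[k] - v) / abs(v))
        assert worst < 1e-12

    def test_same_units_map_identically(self, params_il35, scaling):
        p = params_il35.replace(d_n=params_il35.d_c)
        pn = nondimensionalize(p, scaling)
        assert pn.d_n == pn.d_c  # both are 1/day rates

    def test_zero_scale_factor_rejected(self):
        with pytest.raises(ParameterError):
            ScalingSystem(length=0.0)
        with pytest.raises(ParameterError):
            ScalingSystem(refs={"c": -1.0})

    def test_scale_factor_unknown_name(self, scaling):
        with pytest.raises(ParameterError):
            scale_factor("not_a_parameter", scaling)


def test_parameter_table_audit_is_clean():
    """Dimensional and frozen dimensionless columns agree under the scaling."""
    assert audit_parameter_table() == []


class TestMdscCalibration:
    def test_unit_ratio_gives_zero(self):
        assert calibrate_mdsc_production(1.0, d_M=0.2, horizon=14.0) == 0.0

    def test_monotone_in_observed_ratio(self):
        vals = [calibrate_mdsc_production(r, 0.2, 14.0, s_M=0.004)
                for r in np.linspace(1.0, 4.0, 25)]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("ratio", [1.5, 2.5, 4.0])
    def test_against_ode_oracle(self, ratio):
        """Closed form reproduces the horizon-time ratio of the two-ODE system."""
        lam = calibrate_mdsc_production(ratio, d_M=0.2, horizon=14.0,
                                        s_M=0.004, saturation=0.5)
        got = _mdsc_scenario_ratio_ode(lam, d_M=0.2, horizon=14.0,
                                       s_M=0.004, saturation=0.5)
        assert got == pytest.approx(ratio, rel=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            calibrate_mdsc_production(0.5, 0.2, 14.0)
        with pytest.raises(ParameterError):
            calibrate_mdsc_production(math.nan, 0.2, 14.0)


class TestIl35Calibration:
    def test_long_time_limit_is_steady_state_formula(self):
        lam = calibrate_il35_production(2e-9, c_bar=0.8, d_rho=10.0, t=1e6)
        assert lam == pytest.approx(10.0 * 2e-9 / 0.8, rel=1e-12)

    def test_forward_inverse_consistency(self):
        lam = calibrate_il35_production(1.5e-9, c_bar=0.6, d_rho=8.0, t=0.4)
        assert _il35_forward(lam, 0.6, 8.0, 0.4) == pytest.approx(1.5e-9, rel=1e-10)

    def test_against_root_finder_oracle(self, rng):
        """50 random inputs: closed form matches brute-force inversion."""
        for _ in range(50):
            c_bar = 10 ** rng.uniform(-2, 0)
            d_rho = 10 ** rng.uniform(-1, 2)
            t = 10 ** rng.uniform(-2, 2)
            rho_t = 10 ** rng.uniform(-12, -8)
            lam = calibrate_il35_production(rho_t, c_bar, d_rho, t)
            oracle = _il35_calibration_bracket_oracle(rho_t, c_bar, d_rho, t)
            assert lam == pytest.approx(oracle, rel=1e-9)

    def test_infeasible_target_flagged(self):
        with pytest.raises(InfeasibleCalibration):
            calibrate_il35_production(1e-6, c_bar=0.8, d_rho=10.0, t=15.0,
                                      lambda_max=1e-9)
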