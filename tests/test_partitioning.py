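"""The two-pool mixing model, mass balances, priming and uncertainty."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primesplit.errors import DegenerateMixingError, ValidationError
from primesplit.partitioning import (
    ABOVE_RANGE,
    BELOW_RANGE,
    IN_RANGE,
    JarObservation,
    PartitionResult,
    litter_released_c,
    partition_jar,
    partition_litter_c,
    priming_effect,
    priming_efficiency,
    propagate_uncertainty,
    soc_final,
    soc_mineralization,
    summarize_treatment,
)

D_NATIVE = -16.54
D_LITTER = -28.59  # Ah litter


def make_jar(**kw):
    base = dict(
        jar_id="J1",
        treatment_code="Ah",
        replicate=1,
        soil_mass=200.0,
        litter_mass=2.0,
        litter_C_added=4415.9,
        SOC_initial=8000.0,
        TOC_final=10000.0,
        d13C_final=-20.0,
        d13C_native=D_NATIVE,
        d13C_litter=D_LITTER,
    )
    base.update(kw)
    return JarObservation(**base)


def make_result(code, soc_min, jar_id="x"):
    return PartitionResult(
        jar_id=jar_id,
        treatment_code=code,
        C_litter_remaining=0.0,
        SOC_final=0.0,
        SOC_mineralized=soc_min,
        litter_released_C=0.0,
    )


class TestMixingModel:
    def test_pure_soil_end_member(self):
        c, flag = partition_litter_c(10000.0, D_NATIVE, D_NATIVE, D_LITTER)
        assert c == 0.0 and flag == IN_RANGE

    def test_pure_litter_end_member(self):
        c, flag = partition_litter_c(10000.0, D_LITTER, D_NATIVE, D_LITTER)
        assert c == pytest.approx(10000.0) and flag == IN_RANGE

    def test_worked_mixture(self):
        c, _ = partition_litter_c(10000.0, -20.0, D_NATIVE, D_LITTER)
        assert c == pytest.approx(10000.0 * 3.46 / 12.05)

    def test_degenerate_end_members(self):
        with pytest.raises(DegenerateMixingError):
            partition_litter_c(10000.0, -20.0, -25.0, -25.0)

    def test_out_of_range_flags_not_clamped(self):
        c_hi, f_hi = partition_litter_c(1000.0, -10.0, D_NATIVE, D_LITTER)
        assert f_hi == ABOVE_RANGE and c_hi < 0
        c_lo, f_lo = partition_litter_c(1000.0, -30.0, D_NATIVE, D_LITTER)
        assert f_lo == BELOW_RANGE and c_lo > 1000.0

    @given(
        toc=st.floats(100.0, 50000.0),
        d_native=st.floats(-18.0, -14.0),
        d_litter=st.floats(-30.0, -26.0),
        mix=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_two_by_two_linear_system(self, toc, d_native, d_litter, mix):
        """The closed form equals the solution of the pool/isotope system."""
        d_final = d_native + mix * (d_litter - d_native)
        c, _ = partition_litter_c(toc, d_final, d_native, d_litter)
        a = np.array([[1.0, 1.0], [d_native, d_litter]])
        b = np.array([toc, d_final * toc])
        soc_lin, c_lin = np.linalg.solve(a, b)
        assert c == pytest.approx(c_lin, rel=1e-9, abs=1e-9)
        assert soc_final(toc, c) == pytest.approx(soc_lin, rel=1e-9, abs=1e-6)

    @given(
        d_final=st.floats(-28.0, -17.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_common_delta_shift(self, d_final, shift):
        c0, _ = partition_litter_c(5000.0, d_final, D_NATIVE, D_LITTER)
        c1, _ = partition_litter_c(
            5000.0, d_final + shift, D_NATIVE + shift, D_LITTER + shift
        )
        assert c1 == pytest.approx(c0, rel=1e-9)

    def test_strictly_decreasing_in_d13c_final(self):
        grid = np.linspace(D_LITTER, D_NATIVE, 50)
        values = [partition_litter_c(5000.0, d, D_NATIVE, D_LITTER)[0] for d in grid]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestPools:
    @pytest.mark.parametrize(
        "toc,c_lit,expected",
        [(10000.0, 0.0, 10000.0), (10000.0, 10000.0, 0.0), (10000.0, 2871.4, 7128.6)],
    )
    def test_soc_final(self, toc, c_lit, expected):
        assert soc_final(toc, c_lit) == pytest.approx(expected)

    def test_soc_mineralization(self):
        assert soc_mineralization(8000.0, 7128.6) == pytest.approx(871.4)
        assert soc_mineralization(5.0, 5.0) == 0.0
        assert soc_mineralization(8000.0, 8200.0) == pytest.approx(-200.0)

    def test_litter_released(self):
        assert litter_released_c(0.0, 0.0) == 0.0
        assert litter_released_c(4400.0, 2871.4) == pytest.approx(1528.6)
        assert litter_released_c(100.0, 150.0) == pytest.approx(-50.0)

    def test_partition_jar_mass_balance_and_flags(self):
        res = partition_jar(make_jar())
        assert res.SOC_final + res.C_litter_remaining == pytest.approx(
            10000.0, rel=1e-12
        )
        assert res.end_member_flag == IN_RANGE and res.flags == ()

    def test_negative_mineralization_flagged(self):
        res = partition_jar(make_jar(SOC_initial=6000.0, d13C_final=-20.0))
        assert res.SOC_mineralized < 0
        assert "negative_SOC_mineralization" in res.flags

    def test_control_jar_contract(self):
        ctrl = make_jar(
            treatment_code="CK", litter_mass=0.0, litter_C_added=0.0,
            d13C_final=D_NATIVE, d13C_litter=D_NATIVE,
        )
        res = partition_jar(ctrl)
        assert res.C_litter_remaining == 0.0
        assert res.SOC_final == ctrl.TOC_final
        with pytest.raises(ValidationError, match="control"):
            make_jar(treatment_code="CK", litter_mass=2.0)


class TestPriming:
    def test_zero_when_equal_to_control(self):
        ctrl = [make_result("CK", 321.0, f"c{i}") for i in range(5)]
        trt = [make_result("Ah", 321.0, f"t{i}") for i in range(5)]
        pr = priming_effect(trt, ctrl, litter_mass=2.0, soil_mass=200.0)
        assert pr.priming_effect == pytest.approx(0.0)

    def test_worked_contrast(self):
        ctrl = [make_result("CK", 321.0)]
        trt = [make_result("Ah", 900.0, "a"), make_result("Ah", 950.0, "b")]
        pr = priming_effect(trt, ctrl)
        assert pr.per_jar_pe == pytest.approx((579.0, 629.0))
        assert pr.priming_effect == pytest.approx(604.0)
        assert pr.n == 2

    def test_empty_control_rejected(self):
        with pytest.raises(ValidationError):
            priming_effect([make_result("Ah", 900.0)], [])

    def test_control_self_contrast_zero(self):
        ctrl = [make_result("CK", v, str(v)) for v in (300.0, 320.0, 340.0)]
        pr = priming_effect(ctrl, ctrl)
        assert pr.priming_effect == pytest.approx(0.0, abs=1e-9)

    def test_share_equals_pe_over_mineralization(self):
        ctrl = [make_result("CK", 300.0)]
        trt = [make_result("Ah", 600.0)]
        pr = priming_effect(trt, ctrl)
        assert pr.priming_share == pytest.approx(300.0 / 600.0)

    def test_control_uncertainty_widens_se(self):
        ctrl = [make_result("CK", v, str(v)) for v in (280.0, 321.0, 360.0)]
        trt = [make_result("Ah", v, "t" + str(v)) for v in (800.0, 900.0, 1000.0)]
        plain = priming_effect(trt, ctrl)
        folded = priming_effect(trt, ctrl, include_control_uncertainty=True)
        assert folded.priming_effect_se > plain.priming_effect_se


class TestPrimingEfficiency:
    def test_zero_pe(self):
        assert priming_efficiency(0.0, 2.0, 200.0) == 0.0

    def test_paper_scale_and_raw_scale(self):
        assert priming_efficiency(500.0, 2.0, 200.0, scale="milli") == pytest.approx(50.0)
        assert priming_efficiency(500.0, 2.0, 200.0, scale="micro") == pytest.approx(50000.0)

    def test_inverse_proportional_to_litter_mass(self):
        one = priming_efficiency(500.0, 2.0, 200.0)
        two = priming_efficiency(500.0, 4.0, 200.0)
        assert two == pytest.approx(one / 2)

    def test_control_undefined(self):
        assert math.isnan(priming_efficiency(100.0, 0.0, 200.0))


class TestSummaries:
    def test_constant_values(self):
        s = summarize_treatment([1.0, 1.0, 1.0], "Ah", "x")
        assert s.mean == 1.0 and s.se == 0.0 and s.n == 3

    def test_mean_of_extremes(self):
        s = summarize_treatment([447.8, 808.9], "Ah", "SOC_mineralized")
        assert s.mean == pytest.approx(628.35)

    def test_single_jar_se_missing(self):
        assert summarize_treatment([5.0], "Ah", "x").se is None


class TestUncertaintyPropagation:
    def test_zero_ses_give_zero_spread(self):
        df = propagate_uncertainty(make_jar(), {}, n_draws=200, seed=0)
        assert (df["se"] <= 1e-9).all()  # identical draws up to summation rounding
        assert (df["n_excluded"] == 0).all()

    def test_deterministic_given_seed(self):
        jar = make_jar()
        ses = {"d13C_final": 0.1, "TOC_final": 50.0}
        a = propagate_uncertainty(jar, ses, n_draws=500, seed=42)
        b = propagate_uncertainty(jar, ses, n_draws=500, seed=42)
        assert a.equals(b)

    def test_se_scales_linearly_with_delta_se(self):
        """Doubling the δ13C_final SE ≈ doubles the litter-C SE (delta method)."""
        jar = make_jar()
        one = propagate_uncertainty(jar, {"d13C_final": 0.05}, n_draws=4000, seed=1)
        two = propagate_uncertainty(jar, {"d13C_final": 0.10}, n_draws=4000, seed=1)
        se1 = one.set_index("quantity").loc["C_litter_remaining", "se"]
        se2 = two.set_index("quantity").loc["C_litter_remaining", "se"]
        assert se2 / se1 == pytest.approx(2.0, rel=0.1)
        # delta method: |∂C/∂δ_final| × SE = TOC/(δn−δl) × SE
        expect = jar.TOC_final / (D_NATIVE - D_LITTER) * 0.05
        assert se1 == pytest.approx(expect, rel=0.1)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValidationError):
            propagate_uncertainty(make_jar(), {}, n_draws=10, seed=0)
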