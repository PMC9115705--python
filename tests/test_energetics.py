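"""Core energetic model: coupling, isovolumic/stroke power, efficiency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rvenergetics import (
    DEFAULT_CONSTANTS as C,
    BeatWindow,
    HemodynamicState,
    InventedFlowParams,
    ModelConstants,
    OxygenState,
    PressureTrace,
    calibrate_amplitude,
    invented_flow,
    isovolumic_power_adjusted,
    isovolumic_power_elbeery,
    o2_rate_from_power,
    oxygen_delivery_rate,
    power_from_o2_rate,
    rv_efficiency,
    stroke_power_adjusted,
    stroke_power_integrated,
    total_mechanical_energy,
    total_power_output,
    useful_stroke_power,
)
from rvenergetics.errors import InvalidArgumentError, InvalidInputError


def make_state(HR=80.0, mPAP=50.0, PP=30.0, CO=4800.0, EF=0.4,
               mRV_EP=53.0, RV_EDP=10.0, V0=0.0):
    return HemodynamicState.from_measurements(
        HR=HR, mPAP=mPAP, PP=PP, CO=CO, EF=EF, mRV_EP=mRV_EP, RV_EDP=RV_EDP, V0=V0
    )


physiologic_states = st.builds(
    make_state,
    HR=st.floats(50.0, 130.0),
    mPAP=st.floats(20.0, 90.0),
    PP=st.floats(5.0, 60.0),
    CO=st.floats(2000.0, 8000.0),
    EF=st.floats(0.10, 0.70),
    RV_EDP=st.floats(1.0, 18.0),
).filter(lambda h: h.mRV_EP > h.RV_EDP + 1.0)


def test_state_invariants_enforced():
    with pytest.raises(InvalidArgumentError):
        HemodynamicState(
            HR=80, mPAP=50, PP=30, SV=60, CO=9999.0,  # CO != HR*SV
            mRV_EP=53, RV_EDP=10, RV_EDV=150, RV_ESV=90, EF=0.4,
        )
    with pytest.raises(InvalidArgumentError):
        make_state(mRV_EP=9.0, RV_EDP=10.0)
    with pytest.raises(InvalidArgumentError):
        OxygenState(Sa=0.0, OEF=0.5, Q_RCA=47.5, Chb=0.1)


class TestOxygenCoupling:
    def test_energy_per_ml_oxygen(self):
        assert total_mechanical_energy(0.0) == 0.0
        assert total_mechanical_energy(1.0) == pytest.approx(20.2)
        assert total_mechanical_energy(0.05) == pytest.approx(1.01)

    def test_rate_conversion_and_round_trip(self):
        assert o2_rate_from_power(20.2) == pytest.approx(1.0)
        assert o2_rate_from_power(101.0) == pytest.approx(5.0)
        x = 137.3
        assert power_from_o2_rate(o2_rate_from_power(x)) == pytest.approx(
            x, rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        for fn in (total_mechanical_energy, o2_rate_from_power, power_from_o2_rate):
            with pytest.raises(InvalidArgumentError):
                fn(-1.0)

    def test_delivery_rate(self):
        ox = OxygenState(Sa=1.0, OEF=0.5, Q_RCA=47.5, Chb=0.10)
        assert oxygen_delivery_rate(ox) == pytest.approx(1.34 * 0.5 * 47.5 * 0.10)
        doubled = OxygenState(Sa=1.0, OEF=0.5, Q_RCA=95.0, Chb=0.10)
        assert oxygen_delivery_rate(doubled) == pytest.approx(
            2 * oxygen_delivery_rate(ox)
        )


class TestIsovolumicPower:
    def test_elbeery_hand_arithmetic(self):
        h = make_state(HR=80, mRV_EP=50.0, CO=80 * 60.0, EF=0.4, RV_EDP=10.0)
        # RV_EDV = 60/0.4 = 150 ml
        assert isovolumic_power_elbeery(h) == pytest.approx(
            80 * 50.0 * 150.0 * 1.33e-4
        )

    def test_zero_at_dead_volume_limit(self):
        h = make_state()
        h2 = HemodynamicState(
            HR=h.HR, mPAP=h.mPAP, PP=h.PP, SV=h.SV, CO=h.CO, mRV_EP=h.mRV_EP,
            RV_EDP=h.RV_EDP, RV_EDV=h.RV_EDV, RV_ESV=h.RV_ESV, EF=h.EF,
            V0=h.RV_EDV * (1 - 1e-12),
        )
        assert isovolumic_power_elbeery(h2) == pytest.approx(0.0, abs=1e-6)

    def test_linear_in_heart_rate(self):
        h1 = make_state(HR=60.0, CO=60 * 60.0)
        h2 = make_state(HR=120.0, CO=120 * 60.0)
        # same SV/volumes, doubled HR -> doubled power
        assert isovolumic_power_elbeery(h2) == pytest.approx(
            2 * isovolumic_power_elbeery(h1)
        )

    def test_adjusted_hand_arithmetic(self):
        # SV = 66.67, EF chosen so RV_ESV = 100
        h = make_state(HR=80, mRV_EP=50.0, RV_EDP=10.0, CO=80 * 66.0, EF=66 / 166)
        assert isovolumic_power_adjusted(h) == pytest.approx(
            80 * 40.0 * 100.0 * 1.33e-4
        )

    def test_adjusted_reduces_to_elbeery_in_degenerate_limit(self):
        """With RV_EDP -> 0 and RV_ESV -> RV_EDV the two formulas
        coincide (checked in the near-degenerate limit EF -> 0)."""
        h = make_state(EF=1e-6, RV_EDP=1e-9, V0=0.0)
        assert isovolumic_power_adjusted(h) == pytest.approx(
            isovolumic_power_elbeery(h), rel=1e-4
        )

    @settings(derandomize=True, max_examples=100)
    @given(h=physiologic_states)
    def test_adjusted_is_lower_bound(self, h):
        assert isovolumic_power_adjusted(h) <= isovolumic_power_elbeery(h)


class TestStrokePower:
    def test_adjusted_closed_form_hand_arithmetic(self):
        h = make_state(HR=75, mPAP=47.4, PP=30.0, CO=75 * 74.7)
        useful, pulsatile = stroke_power_adjusted(h)
        assert useful == pytest.approx(75 * 47.4 * 74.7 * 1.33e-4)
        assert pulsatile == pytest.approx(0.156 * 30.0)

    def test_useful_stroke_power(self):
        h = make_state(mPAP=47.4, CO=5600.0, HR=75.0)
        assert useful_stroke_power(h) == pytest.approx(47.4 * 5600 * 1.33e-4)
        # identity with the HR·mPAP·SV form since CO = HR·SV
        assert useful_stroke_power(h) == pytest.approx(
            float(h.HR * h.mPAP * h.SV) * 1.33e-4
        )

    def test_integrated_constant_integrand(self):
        """Trapezoid is exact for constant P·Q: power = P·Q·k."""
        rate, p_val, q_val = 1000.0, 20.0, 3000.0
        n = int(5.5 * rate)
        p = PressureTrace(np.full(n, p_val), rate, "PA_pressure")
        q = PressureTrace(np.full(n, q_val), rate, "PA_flow")
        wins = [BeatWindow(k + 0.1, k + 0.4, k + 1.0) for k in range(5)]
        sp = stroke_power_integrated(p, q, wins, tail=0.0)
        assert sp == pytest.approx(p_val * q_val * 1.33e-4, rel=1e-12)

    def test_integrated_zero_flow(self):
        rate = 1000.0
        n = int(5.5 * rate)
        p = PressureTrace(np.full(n, 40.0), rate, "PA_pressure")
        q = PressureTrace(np.zeros(n), rate, "PA_flow")
        wins = [BeatWindow(k + 0.1, k + 0.4, k + 1.0) for k in range(5)]
        assert stroke_power_integrated(p, q, wins) == 0.0

    def test_integrated_matches_fine_grid_oracle(self):
        """Invented-flow beat against 10 kHz quadrature, within 0.1%."""
        co, t_es, t_ed, p_const = 4500.0, 0.30, 0.80, 35.0
        prof = calibrate_amplitude(
            InventedFlowParams(A=1.0, SV=60.0, t_es=t_es, t_ed=t_ed), co
        )
        rate = 1000.0
        t = np.arange(0.0, 5 * t_ed + 0.2, 1 / rate)
        q = np.asarray(invented_flow(np.mod(t, t_ed), prof))
        p = PressureTrace(np.full(t.size, p_const), rate, "PA_pressure")
        qt = PressureTrace(q, rate, "PA_flow")
        wins = [BeatWindow(k * t_ed, k * t_ed + t_es, (k + 1) * t_ed) for k in range(5)]
        # window starts at ejection onset == cycle start here, so use
        # a half-open first window shifted off zero by one sample
        sp = stroke_power_integrated(p, qt, wins)
        # oracle: 10 kHz trapezoid over one beat's window [0, t_es+0.04]
        tf = np.linspace(0.0, t_es + 0.04, int((t_es + 0.04) * 10_000) + 1)
        oracle = (
            np.trapezoid(p_const * np.asarray(invented_flow(tf, prof)), tf)
            / t_es
            * 1.33e-4
        )
        assert sp == pytest.approx(oracle, rel=1e-3)

    def test_mismatched_time_bases_rejected(self):
        p = PressureTrace(np.full(6000, 20.0), 1000.0, "PA_pressure")
        q = PressureTrace(np.full(1500, 100.0), 250.0, "PA_flow")
        wins = [BeatWindow(k + 0.1, k + 0.4, k + 1.0) for k in range(5)]
        with pytest.raises(InvalidInputError):
            stroke_power_integrated(p, q, wins)


class TestTotalPowerAndEfficiency:
    def test_components_sum_to_total(self):
        h = make_state()
        for variant in ("elbeery", "adjusted"):
            pb = total_power_output(h, variant, "closed_form")
            assert pb.total == pytest.approx(pb.isovolumic + pb.stroke, rel=1e-12)

    def test_closed_form_matches_independent_script(self):
        """Adjusted-model total against a literal transcription of the
        closed-form expressions with plain floats."""
        h = make_state(HR=75, mPAP=47.4, PP=30.0, CO=5600.0, EF=0.46,
                       mRV_EP=50.4, RV_EDP=8.0)
        sv = 5600.0 / 75
        esv = sv / 0.46 - sv
        expected = (
            75 * (50.4 - 8.0) * esv * 1.33e-4
            + 75 * 47.4 * sv * 1.33e-4
            + 0.156 * 30.0
        )
        pb = total_power_output(h, "adjusted", "closed_form")
        assert pb.total == pytest.approx(expected, rel=1e-12)
        eff = rv_efficiency(pb, h)
        assert eff == pytest.approx(47.4 * 5600 * 1.33e-4 / expected, rel=1e-12)

    def test_efficiency_bounds_and_monotonicity(self):
        h = make_state()
        pb = total_power_output(h, "adjusted", "closed_form")
        eff = rv_efficiency(pb, h)
        assert 0 < eff <= 1
        # inflating isovolumic power strictly decreases efficiency
        from rvenergetics import PowerBreakdown
        worse = PowerBreakdown(
            variant="adjusted", isovolumic=2 * pb.isovolumic, stroke=pb.stroke,
            total=2 * pb.isovolumic + pb.stroke,
        )
        assert rv_efficiency(worse, h) < eff

    def test_all_useful_power_means_unit_efficiency(self):
        h = make_state(PP=1e-9)  # degenerate: no pulse pressure
        from rvenergetics import PowerBreakdown
        pb = PowerBreakdown(
            variant="adjusted", isovolumic=0.0,
            stroke=float(useful_stroke_power(h)), total=float(useful_stroke_power(h)),
        )
        assert rv_efficiency(pb, h) == pytest.approx(1.0, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(h=physiologic_states)
    def test_conservation_and_efficiency_range(self, h):
        pb = total_power_output(h, "adjusted", "closed_form")
        assert pb.total - pb.isovolumic - pb.stroke == pytest.approx(
            0.0, abs=1e-12 * float(pb.total)
        )
        assert 0 < rv_efficiency(pb, h) <= 1


def test_pressure_volume_conversion_matches_si():
    """1 mmHg·ml = 133.322 Pa × 1e-6 m³ = 1.333e-4 J; the model constant
    1.33e-4 agrees to 3 significant figures."""
    si = 133.322387415 * 1e-6
    assert abs(C.k_mmhgml - si) / si < 5e-3
    assert float(f"{si:.3g}") == C.k_mmhgml


def test_constants_defaults():
    c = ModelConstants()
    assert (c.k_o2, c.k_hb, c.k_mmhgml, c.k_osc, c.t_reg) == (
        20.2, 1.34, 1.33e-4, 0.156, 0.04
    )
    with pytest.raises(InvalidArgumentError):
        ModelConstants(k_o2=-1.0)
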