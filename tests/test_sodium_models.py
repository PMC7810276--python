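import math

import pytest
from hypothesis import given, settings, strategies as st

from natremia.errors import InvalidInputError
from natremia.infusates import infusate_from_percent
from natremia.sodium_models import (
    InfusionEvent,
    PatientState,
    PredictionResult,
    adrogue_madias_delta_na,
    adrogue_madias_original,
    critical_urine_osmolality,
    predict,
    round_display,
    voets_delta_na,
)

NS = infusate_from_percent(0.9)   # 154 / 308
HS = infusate_from_percent(2.5)   # 428 / 856


def _state(tbw, na, ou=500.0):
    return PatientState(tbw=tbw, na_plasma=na, urine_osm=ou)


# strategies over clinically spanning but numerically tame ranges
states = st.builds(
    PatientState,
    tbw=st.floats(10, 80),
    na_plasma=st.floats(100, 160),
    urine_osm=st.floats(50, 1400),
)
volumes = st.floats(0.05, 3.0)
infusates = st.sampled_from([NS, HS])


class TestVoets:
    def test_cohort_row_1(self):
        delta = voets_delta_na(_state(34, 133, 766), InfusionEvent(1.5, NS))
        assert math.isclose(delta, 133 * 1.5 / 34 * (1.7 * 308 / 766 - 1))
        assert round_display(delta) == -1.9

    def test_cohort_row_9(self):
        delta = voets_delta_na(_state(25, 127, 677), InfusionEvent(0.10, HS))
        assert round_display(delta) == 0.6

    def test_cohort_row_15(self):
        delta = voets_delta_na(_state(29, 122, 345), InfusionEvent(0.15, HS))
        assert round_display(delta) == 2.0

    def test_zero_at_critical_osmolality(self):
        delta = voets_delta_na(_state(34, 133, 1.7 * 308), InfusionEvent(1.0, NS))
        assert delta == pytest.approx(0.0, abs=1e-12)

    @given(states, volumes, infusates, st.floats(0.1, 10.0))
    def test_linear_in_volume(self, state, vi, inf, k):
        d1 = voets_delta_na(state, InfusionEvent(vi, inf))
        dk = voets_delta_na(state, InfusionEvent(k * vi, inf))
        assert math.isclose(dk, k * d1, rel_tol=1e-9, abs_tol=1e-9)

    @given(states, volumes, infusates)
    def test_sign_rule(self, state, vi, inf):
        delta = voets_delta_na(state, InfusionEvent(vi, inf))
        threshold = 1.7 * inf.tonicity
        if state.urine_osm < threshold:
            assert delta > 0
        elif state.urine_osm > threshold:
            assert delta < 0

    @given(states, volumes, infusates, st.floats(10, 1300))
    def test_strictly_decreasing_in_urine_osm(self, state, vi, inf, ou_hi_extra):
        ou_lo = state.urine_osm
        ou_hi = ou_lo + ou_hi_extra
        d_lo = voets_delta_na(state, InfusionEvent(vi, inf))
        d_hi = voets_delta_na(
            PatientState(tbw=state.tbw, na_plasma=state.na_plasma, urine_osm=ou_hi),
            InfusionEvent(vi, inf),
        )
        assert d_hi < d_lo

    def test_invalid_state_rejected(self):
        with pytest.raises(InvalidInputError):
            PatientState(tbw=0, na_plasma=133, urine_osm=500)
        with pytest.raises(InvalidInputError):
            PatientState(tbw=34, na_plasma=133, urine_osm=0)
        with pytest.raises(InvalidInputError):
            InfusionEvent(volume=-1, infusate=NS)

    def test_invalid_factor_rejected(self):
        with pytest.raises(InvalidInputError):
            voets_delta_na(_state(34, 133), InfusionEvent(1.0, NS), tonicity_factor=0)


class TestAdrogueMadias:
    def test_cohort_row_1(self):
        delta = adrogue_madias_delta_na(_state(34, 133), InfusionEvent(1.5, NS))
        assert round_display(delta) == 0.9

    def test_cohort_row_9(self):
        delta = adrogue_madias_delta_na(_state(25, 127), InfusionEvent(0.10, HS))
        assert round_display(delta) == 1.2

    def test_isotonic_to_plasma_gives_zero(self):
        delta = adrogue_madias_delta_na(_state(34, 154.0), InfusionEvent(1.0, NS))
        assert delta == 0.0

    @given(states, volumes, infusates)
    def test_mass_balance_oracle(self, state, vi, inf):
        """Modified form == two-compartment mixing, derived independently."""
        delta = adrogue_madias_delta_na(state, InfusionEvent(vi, inf))
        mixed = (state.tbw * state.na_plasma + vi * inf.na_conc) / (state.tbw + vi)
        assert math.isclose(delta, mixed - state.na_plasma, rel_tol=1e-12, abs_tol=1e-12)

    @given(states, infusates)
    def test_original_is_modified_at_one_litre(self, state, inf):
        assert adrogue_madias_original(state, inf) == adrogue_madias_delta_na(
            state, InfusionEvent(1.0, inf)
        )

    def test_original_cohort_rows(self):
        # rows with Vi = 1.0 L of normal saline
        assert round_display(adrogue_madias_original(_state(37, 132), NS)) == 0.6
        assert round_display(adrogue_madias_original(_state(25, 128), NS)) == 1.0

    @given(states, volumes, infusates)
    def test_final_sodium_bounded_between_plasma_and_infusate(self, state, vi, inf):
        delta = adrogue_madias_delta_na(state, InfusionEvent(vi, inf))
        na_final = state.na_plasma + delta
        lo, hi = sorted((state.na_plasma, inf.na_conc))
        if lo != hi:
            assert lo < na_final < hi

    @given(states, volumes, infusates, st.floats(0.1, 5.0))
    def test_strictly_sublinear_in_volume(self, state, vi, inf, k):
        if abs(inf.na_conc - state.na_plasma) < 1e-6 or abs(k - 1) < 1e-6:
            return
        d1 = adrogue_madias_delta_na(state, InfusionEvent(vi, inf))
        dk = adrogue_madias_delta_na(state, InfusionEvent(k * vi, inf))
        if k > 1:
            assert abs(dk) < k * abs(d1)
        else:
            assert abs(dk) > k * abs(d1)


class TestCriticalUrineOsmolality:
    def test_normal_saline(self):
        assert critical_urine_osmolality(NS) == pytest.approx(523.6)

    def test_hypertonic(self):
        assert critical_urine_osmolality(HS) == pytest.approx(1455.2)

    def test_identity_factor(self):
        # percent chosen so tonicity lands exactly on 300 mmol/L
        inf = infusate_from_percent(150 * 58.44 / 10000, label="x")
        assert inf.tonicity == 300
        assert critical_urine_osmolality(inf, tonicity_factor=1.0) == 300

    @given(infusates, st.floats(500, 1500))
    def test_voets_vanishes_at_threshold(self, inf, na_osm_seed):
        threshold = critical_urine_osmolality(inf)
        state = PatientState(tbw=40, na_plasma=130, urine_osm=threshold)
        assert voets_delta_na(state, InfusionEvent(1.0, inf)) == pytest.approx(0, abs=1e-12)


class TestPredict:
    def test_voets_dispatch_row_1(self):
        result = predict(_state(34, 133, 766), InfusionEvent(1.5, NS), "voets")
        assert isinstance(result, PredictionResult)
        assert result.na_final == pytest.approx(133 - 1.857, abs=0.001)
        assert result.na_final == 133 + result.delta_na

    def test_zero_delta_keeps_sodium(self):
        result = predict(_state(34, 133, 1.7 * 308), InfusionEvent(1.0, NS), "voets")
        assert result.na_final == pytest.approx(133.0)

    def test_row_15_display(self):
        result = predict(_state(29, 122, 345), InfusionEvent(0.15, HS), "voets")
        assert round_display(result.delta_na) == 2.0

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidInputError, match="unknown model"):
            predict(_state(34, 133), InfusionEvent(1.0, NS), "nguyen_kurtz")

    def test_nonphysical_result_warns_not_clamps(self):
        # tiny TBW + huge volume of very hypotonic-urine-dominated case
        state = PatientState(tbw=0.5, na_plasma=140, urine_osm=5000)
        with pytest.warns(RuntimeWarning):
            result = predict(state, InfusionEvent(3.0, NS), "voets")
        assert result.na_final < 0  # returned as-is


class TestRoundDisplay:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.25, 0.3), (-0.25, -0.3), (1.849, 1.8), (-1.857, -1.9), (0.0, 0.0), (2.04, 2.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_display(value) == expected
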