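"""Formula-level oracles for the VILI indices, frozen from hand evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ardsim.indices import (FRCReference, UndefinedIndexError, c_rs, do2,
                            dynamic_strain, mean_alveolar_pressure,
                            mechanical_power, r_aw, recruitment_fraction,
                            static_strain, tidal_recruitment, vd_vt)
from ardsim.simulator import BreathRecord

TOL = 1e-9


def frc(v=1250.0):
    return FRCReference("P", v, np.full(100, v / 100))


def make_breath(open_insp, open_exp, dv=5.0, p_insp_alv=None):
    n = open_insp.size
    v_exp = np.full(n, 10.0)
    v_insp = v_exp + np.where(open_insp, dv, 0.0)
    return BreathRecord(
        v_alv_insp=v_insp, v_alv_exp=v_exp,
        p_alv_insp=p_insp_alv if p_insp_alv is not None else np.full(n, 20.0),
        p_alv_exp=np.full(n, 8.0),
        open_insp=open_insp, open_exp=open_exp,
        p_peak=30.0, p_plat=25.0, peep_total=10.0,
        v_t=float(np.where(open_insp, dv, 0.0).sum()), t_insp=1.6,
        vr=12.5, ie=0.5, series={},
    )


@pytest.mark.parametrize("vt,pplat,peep,expected", [
    (420.0, 25.0, 10.0, 28.0),
    (0.0, 25.0, 10.0, 0.0),
    (500.0, 30.0, 5.0, 20.0),
])
def test_static_compliance_examples(vt, pplat, peep, expected):
    assert c_rs(vt, pplat, peep) == pytest.approx(expected, rel=TOL)


def test_static_compliance_undefined_when_no_driving_pressure():
    with pytest.raises(UndefinedIndexError):
        c_rs(400.0, 10.0, 10.0)


@pytest.mark.parametrize("dv,vfrc,expected", [
    (0.0, 1250.0, 0.0),
    (1250.0, 1250.0, 1.0),
    (500.0, 1250.0, 0.4),
])
def test_dynamic_strain_examples(dv, vfrc, expected):
    assert dynamic_strain(dv, frc(vfrc)) == pytest.approx(expected, rel=TOL)


@pytest.mark.parametrize("vexp,vfrc,expected", [
    (1875.0, 1250.0, 1.5),
    (1250.0, 1250.0, 1.0),
    (0.0, 1250.0, 0.0),
])
def test_static_strain_examples(vexp, vfrc, expected):
    assert static_strain(vexp, frc(vfrc)) == pytest.approx(expected, rel=TOL)


def test_strain_additivity():
    # (V_insp / V_frc) = static + dynamic when dV = V_insp - V_exp
    r = frc(1250.0)
    v_exp, dv = 1875.0, 500.0
    total = static_strain(v_exp, r) + dynamic_strain(dv, r)
    assert total == pytest.approx((v_exp + dv) / 1250.0, rel=TOL)


def test_tidal_recruitment_counting():
    oi = np.zeros(100, dtype=bool)
    oi[:60] = True
    oe = np.zeros(100, dtype=bool)
    oe[:44] = True
    breath = make_breath(oi, oe)
    assert tidal_recruitment(breath) == pytest.approx(16.0, rel=TOL)
    # brute-force equivalence on the same record
    brute = 100.0 * (breath.ventilated_insp.sum()
                     - breath.ventilated_exp.sum()) / 100.0
    assert tidal_recruitment(breath) == pytest.approx(max(brute, 0.0), rel=TOL)


def test_tidal_recruitment_degenerate_states():
    all_open = np.ones(100, dtype=bool)
    none_open = np.zeros(100, dtype=bool)
    assert tidal_recruitment(make_breath(all_open, all_open)) == 0.0
    assert tidal_recruitment(make_breath(none_open, none_open)) == 0.0


def test_recruitment_fraction_counting():
    before_open = np.ones(100, dtype=bool)
    before_open[:30] = False          # 30 silent units
    after_open = before_open.copy()
    after_open[:12] = True            # 12 of them gain ventilation
    before = make_breath(before_open, before_open)
    after = make_breath(after_open, after_open)
    assert recruitment_fraction(before, after) == pytest.approx(0.12, rel=TOL)
    assert recruitment_fraction(before, before) == 0.0
    none = make_breath(np.zeros(100, bool), np.zeros(100, bool))
    everything = make_breath(np.ones(100, bool), np.ones(100, bool))
    assert recruitment_fraction(none, everything) == pytest.approx(1.0, rel=TOL)


@pytest.mark.parametrize("pressures,expected", [
    (np.full(100, 17.3), 17.3),
    (np.arange(1.0, 101.0), 90.5),
    (np.concatenate([[50.0], np.zeros(99)]), 2.5),
])
def test_mean_alveolar_pressure_examples(pressures, expected):
    assert mean_alveolar_pressure(pressures) == pytest.approx(expected, rel=TOL)


@pytest.mark.parametrize("vr,vt,e,ie,raw,peep,expected", [
    (15.0, 0.42, 45.45, 0.5, 10.0, 10.0, None),   # hand value below
    (10.0, 0.0, 20.0, 0.5, 5.0, 8.0, 0.0),
    (10.0, 0.5, 20.0, 1.0, 0.0, 0.0, 2.45),
])
def test_mechanical_power_examples(vr, vt, e, ie, raw, peep, expected):
    got = mechanical_power(vr, vt, e, ie, raw, peep)
    if expected is None:
        # 0.098*15*{0.42^2*[45.45/2 + 15*1.5/30*10] + 0.42*10}
        expected = 0.098 * 15 * (0.42**2 * (45.45 / 2 + 15 * 1.5 / 30 * 10)
                                 + 0.42 * 10)
        assert got == pytest.approx(14.011, abs=5e-3)
    assert got == pytest.approx(expected, rel=TOL)


@settings(derandomize=True, max_examples=60)
@given(st.floats(5, 30), st.floats(0.1, 1.0), st.floats(5, 80),
       st.floats(0.2, 2.0), st.floats(0.5, 30), st.floats(0.5, 20),
       st.floats(1.01, 1.5))
def test_mechanical_power_monotone_in_each_input(vr, vt, e, ie, raw, peep, f):
    base = mechanical_power(vr, vt, e, ie, raw, peep)
    assert mechanical_power(vr * f, vt, e, ie, raw, peep) > base
    assert mechanical_power(vr, vt * f, e, ie, raw, peep) > base
    assert mechanical_power(vr, vt, e * f, ie, raw, peep) > base
    assert mechanical_power(vr, vt, e, ie, raw * f, peep) > base
    assert mechanical_power(vr, vt, e, ie, raw, peep * f) > base


@pytest.mark.parametrize("ppeak,pplat,vt,tinsp,expected", [
    (30.0, 25.0, 0.5, 1.0, 10.0),
    (30.0, 30.0, 0.5, 1.0, 0.0),
    (28.0, 24.0, 0.4, 0.8, 8.0),
])
def test_airway_resistance_examples(ppeak, pplat, vt, tinsp, expected):
    assert r_aw(ppeak, pplat, vt, tinsp) == pytest.approx(expected, rel=TOL)


@pytest.mark.parametrize("co,sao2,pao2,hb,expected", [
    (0.0, 0.9, 90.0, 10.0, 0.0),
    (5.0, 1.0, 100.0, 15.0, 1020.0),
    (5.0, 0.0, 0.0, 15.0, 0.0),
])
def test_oxygen_delivery_examples(co, sao2, pao2, hb, expected):
    assert do2(co, sao2, pao2, hb) == pytest.approx(expected, rel=TOL)


@pytest.mark.parametrize("paco2,peco2,expected", [
    (40.0, 40.0, 0.0),
    (40.0, 0.0, 1.0),
    (40.0, 20.0, 0.5),
])
def test_deadspace_fraction_examples(paco2, peco2, expected):
    assert vd_vt(paco2, peco2) == pytest.approx(expected, rel=TOL)


@settings(derandomize=True, max_examples=50)
@given(st.floats(100, 800), st.floats(1, 40), st.floats(0.1, 30))
def test_compliance_roundtrip_reconstructs_tidal_volume(vt, dp, peep):
    crs = c_rs(vt, peep + dp, peep)
    assert crs * dp == pytest.approx(vt, rel=1e-12)
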