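"""Lung-mechanics physics: analytic RC oracle, mass balance, recruitment."""

import numpy as np
import pytest

from ardsim.mechanics import recruitment_rule, simulate_mechanics
from conftest import make_single_compartment


def analytic_end_volumes(c, r_total, peep, p_insp, vr, ie):
    """Closed-form periodic end-inspiratory/-expiratory volumes of one
    linear RC unit driven by a square pressure wave."""
    tau = r_total * c / 1000.0
    t_total = 60.0 / vr
    ti = t_total * ie / (1 + ie)
    te = t_total - ti
    a, b = np.exp(-ti / tau), np.exp(-te / tau)
    vi_inf, ve_inf = c * p_insp, c * peep
    vei = (vi_inf * (1 - a) + a * ve_inf * (1 - b)) / (1 - a * b)
    vee = ve_inf + (vei - ve_inf) * b
    return vei, vee


def test_single_compartment_matches_rc_charging_solution():
    c, rb, rc = 30.0, 1200.0, 3.0
    lung = make_single_compartment(c_ml_cmh2o=c, rb=rb, rc=rc)
    mech = simulate_mechanics(lung, peep=5.0, p_insp=25.0, vr=12.5, ie=0.5,
                              conv_tol=1e-5, max_breaths=60)
    vei, vee = analytic_end_volumes(c, rb + rc, 5.0, 25.0, 12.5, 0.5)
    assert mech.v_insp[0] == pytest.approx(vei, rel=5e-3)
    assert mech.v_exp[0] == pytest.approx(vee, rel=5e-3)
    assert mech.vt == pytest.approx(vei - vee, rel=5e-3)


def test_step_halving_changes_tidal_volume_by_less_than_two_permille(mid_lung):
    lung, _ = mid_lung
    m1 = simulate_mechanics(lung, 8.0, 26.0, 12.5, 0.5, dt=1e-3)
    m2 = simulate_mechanics(lung, 8.0, 26.0, 12.5, 0.5, dt=5e-4)
    assert abs(m1.vt - m2.vt) / m2.vt < 2e-3


def test_gas_volume_mass_balance_is_exact(mid_lung):
    lung, _ = mid_lung
    mech = simulate_mechanics(lung, 8.0, 26.0, 12.5, 0.5, conv_tol=1e-6,
                              max_breaths=80)
    # no gas compression: delivered VT == summed compartment excursion
    assert mech.vt_delivered == pytest.approx(
        float((mech.v_insp - mech.v_start).sum()), abs=1e-9)
    assert mech.vt == pytest.approx(mech.vt_delivered, rel=1e-3)
    # per-compartment monotonicity within the breath
    assert np.all(mech.v_insp - mech.v_exp > -1e-9)
    assert mech.p_peak >= mech.p_plat >= mech.peep - 1e-12


def test_zero_driving_pressure_gives_zero_tidal_volume(mid_lung):
    lung, _ = mid_lung
    mech = simulate_mechanics(lung, 10.0, 10.0, 12.5, 0.5)
    assert mech.vt == pytest.approx(0.0, abs=1e-6)


def test_nothing_opens_when_top_exceeds_peak_pressure():
    lung = make_single_compartment(top=50.0)
    mech = simulate_mechanics(lung, 5.0, 25.0, 12.5, 0.5)
    assert not mech.open_insp[0] and not mech.open_exp[0]
    assert mech.vt == pytest.approx(0.0, abs=1e-9)


def test_tidal_volume_monotone_in_driving_pressure(mid_lung):
    lung, _ = mid_lung
    vts = [simulate_mechanics(lung, 8.0, 8.0 + dp, 12.5, 0.5).vt
           for dp in (6.0, 12.0, 18.0, 24.0)]
    assert np.all(np.diff(vts) >= -1e-9)


def test_open_fraction_monotone_in_peep(mid_lung):
    lung, _ = mid_lung
    fr = [simulate_mechanics(lung, peep, peep + 15.0, 12.5, 0.5).open_exp.mean()
          for peep in (0.0, 5.0, 10.0, 15.0)]
    assert np.all(np.diff(fr) >= 0.0)


class TestRecruitmentRule:
    def test_zero_top_always_open(self):
        for paw in (0.0, 5.0, 30.0):
            assert recruitment_rule(False, paw, top=0.0)

    def test_tie_opens(self):
        assert recruitment_rule(False, 12.0, top=12.0)
        assert not recruitment_rule(False, 11.999, top=12.0)

    def test_hysteresis_band(self):
        # open compartment survives down to top - delta
        assert recruitment_rule(True, 10.5, top=12.0, delta_close=2.0)
        assert not recruitment_rule(True, 9.9, top=12.0, delta_close=2.0)

    def test_intra_tidal_cycling_over_one_breath(self):
        # square wave peaking above TOP, closing pressure above PEEP:
        # the unit must open during inspiration and close during expiration
        top, delta, peep, p_insp = 12.0, 2.0, 5.0, 26.0
        state = False
        trajectory = []
        for paw in [peep, p_insp, p_insp, peep, peep]:
            state = recruitment_rule(state, paw, top=top, delta_close=delta)
            trajectory.append(state)
        assert trajectory == [False, True, True, False, False]

    def test_cycling_seen_in_full_simulation(self):
        lung = make_single_compartment(top=12.0)
        mech = simulate_mechanics(lung, 5.0, 26.0, 12.5, 0.5)
        assert mech.open_insp[0] and not mech.open_exp[0]


def test_breath_series_writer_roundtrip(tmp_path, mid_lung):
    import pandas as pd
    from ardsim.simulator import BreathRecord, write_breath_series

    lung, _ = mid_lung
    mech = simulate_mechanics(lung, 8.0, 26.0, 12.5, 0.5)
    breath = BreathRecord(
        v_alv_insp=mech.v_insp, v_alv_exp=mech.v_exp,
        p_alv_insp=mech.p_insp_alv, p_alv_exp=mech.p_exp_alv,
        open_insp=mech.open_insp, open_exp=mech.open_exp,
        p_peak=mech.p_peak, p_plat=mech.p_plat, peep_total=8.0,
        v_t=mech.vt, t_insp=mech.t_insp, vr=12.5, ie=0.5,
        series=mech.series)
    series_csv = tmp_path / "series.csv"
    summary_csv = tmp_path / "summary.csv"
    write_breath_series(breath, series_csv, summary_csv)
    series = pd.read_csv(series_csv)
    assert list(series.columns) == ["time_s", "variable", "value"]
    assert {"p_airway", "p_vent", "v_total", "flow"} <= set(series.variable)
    # 10-ms cadence
    t = series[series.variable == "p_airway"]["time_s"].to_numpy()
    assert abs(t[1] - t[0] - 0.01) < 1e-9
    summary = pd.read_csv(summary_csv)
    assert summary.loc[0, "v_t"] == pytest.approx(mech.vt)
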