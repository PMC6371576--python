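"""Correlation machinery and sweep summaries (no heavy simulation here)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ardsim.sweep as sweep_mod
from ardsim.cohort import ConfigurationError, generate_risk_table
from ardsim.sweep import (InterventionGrid, correlate, default_grids,
                          run_intervention, summarize)


class TestCorrelate:
    def test_perfect_positive_linearity(self):
        r, p = correlate([1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0, 9.0])
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative_linearity(self):
        r, _ = correlate([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_product_moment_example(self):
        # means (1..5) vs risks (1,2,2,4,5): cov = 10, sxx = 10, syy = 10.8
        r, p = correlate([1, 2, 3, 4, 5], [1, 2, 2, 4, 5])
        assert r == pytest.approx(10.0 / np.sqrt(10.0 * 10.8), rel=1e-12)
        t = r * np.sqrt(3 / (1 - r * r))
        assert p == pytest.approx(2 * sps.t.sf(t, 3), rel=1e-9)

    def test_matches_brute_force_two_pass_computation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r, p = correlate(x, y)
            # brute force: explicit two-pass covariance / variance
            xm, ym = x.mean(), y.mean()
            num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
            den = np.sqrt(sum((a - xm) ** 2 for a in x)
                          * sum((b - ym) ** 2 for b in y))
            assert r == pytest.approx(num / den, abs=1e-12)
            r_sp, p_sp = sps.pearsonr(x, y)
            assert r == pytest.approx(r_sp, abs=1e-12)
            assert p == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_is_explicitly_undefined(self):
        r, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlate([1.0, np.inf, 2.0], [1.0, 2.0, 3.0])


class TestGridValidation:
    def test_intervention1_requires_constant_peep(self):
        with pytest.raises(ConfigurationError):
            InterventionGrid(1, [(12.0, 8.0), (15.0, 9.0)])

    def test_intervention2_requires_constant_delta_p(self):
        with pytest.raises(ConfigurationError):
            InterventionGrid(2, [(12.0, 8.0), (15.0, 11.0)])

    def test_intervention3_requires_opposing_trends(self):
        with pytest.raises(ConfigurationError):
            InterventionGrid(3, [(21.0, 5.0), (22.0, 8.0)])
        InterventionGrid(3, [(21.0, 5.0), (18.0, 8.0)])  # valid

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            InterventionGrid(1, [])
        with pytest.raises(ConfigurationError):
            run_intervention([], default_grids()[1])


def _fake_per_patient(power_means, n_pat=4, iid=1):
    rows = []
    rng = np.random.default_rng(1)
    for k, (dp, mp) in enumerate(power_means):
        for j in range(n_pat):
            row = {name: 1.0 for name in sweep_mod.SWEEP_INDICES}
            row.update({"patient_id": f"P{j}", "intervention_id": iid,
                        "delta_p": dp, "peep": 8.0,
                        "mechanical_power": mp + 0.01 * (j - 1.5),
                        "dynamic_strain": 0.02 * dp + 0.001 * j})
            rows.append(row)
    return pd.DataFrame(rows)


class TestSummarize:
    conditions = [(12.0, 8.0), (15.0, 8.0), (18.0, 8.0), (21.0, 8.0)]

    def test_risk_affine_in_power_flags_power_strong(self):
        per_patient = _fake_per_patient([(dp, 0.5 * dp) for dp, _ in
                                         self.conditions])
        risk = generate_risk_table({1: self.conditions}, monotone_slope=0.08,
                                   noise=0.0)
        res = summarize(per_patient, risk)
        row = res.correlation_table.set_index("index").loc["mechanical_power"]
        assert row["r"] == pytest.approx(1.0, abs=1e-9)
        assert bool(row["strong"])

    def test_constant_risk_flags_nothing(self):
        per_patient = _fake_per_patient([(dp, 0.5 * dp) for dp, _ in
                                         self.conditions])
        risk = generate_risk_table({1: self.conditions}, monotone_slope=0.0,
                                   noise=0.0)
        res = summarize(per_patient, risk)
        assert not res.correlation_table["strong"].any()
        assert res.correlation_table["r"].isna().all()

    def test_strong_flag_strict_at_threshold(self, monkeypatch):
        per_patient = _fake_per_patient([(dp, 0.5 * dp) for dp, _ in
                                         self.conditions])
        risk = generate_risk_table({1: self.conditions}, monotone_slope=0.08,
                                   noise=0.0)
        monkeypatch.setattr(sweep_mod, "correlate", lambda x, y: (0.85, 0.001))
        res = summarize(per_patient, risk)
        assert not res.correlation_table["strong"].any()
        monkeypatch.setattr(sweep_mod, "correlate",
                            lambda x, y: (0.8501, 0.001))
        res = summarize(per_patient, risk)
        assert res.correlation_table["strong"].all()

    def test_every_index_appears_with_mean_and_sd(self):
        per_patient = _fake_per_patient([(dp, 0.5 * dp) for dp, _ in
                                         self.conditions])
        res = summarize(per_patient, None)
        got = set(res.condition_table["index"].unique())
        assert got == set(sweep_mod.SWEEP_INDICES)
        assert (res.condition_table["sd"] >= 0).all()
        assert (res.condition_table["n"] == 4).all()
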