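"""Cox fits, the linear risk score, median split, and log-rank/KM."""

import numpy as np
import pandas as pd
import pytest
from lifelines.exceptions import ConvergenceError
from scipy import stats

from lnceqtm.survival import (fit_cox, logrank_and_km, median_split,
                              risk_score)


def _clinical(times, events, ids=None):
    ids = ids or [f"P{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events},
                      index=pd.Index(ids, name="sample_id"))
    return df.astype({"time": float, "event": int})


def _beta(rows, ids):
    return pd.DataFrame(rows, index=ids,
                        columns=[f"P{i}" for i in range(len(rows[0]))])


class TestRiskScore:
    def test_hand_arithmetic(self):
        coefs = pd.Series([1.0, -2.0], index=["cg0", "cg1"])
        beta = _beta([[0.5], [0.25]], ["cg0", "cg1"])
        assert risk_score(coefs, beta).tolist() == [0.0]

    def test_single_probe(self):
        coefs = pd.Series([2.0], index=["cg0"])
        assert risk_score(coefs, _beta([[0.3]], ["cg0"])).tolist() == \
            pytest.approx([0.6])

    def test_zero_coefs_give_zero_scores(self):
        coefs = pd.Series([0.0, 0.0], index=["cg0", "cg1"])
        beta = _beta([[0.5, 0.9], [0.25, 0.1]], ["cg0", "cg1"])
        assert risk_score(coefs, beta).tolist() == [0.0, 0.0]

    def test_probe_order_invariant(self):
        rng = np.random.default_rng(0)
        beta = _beta(rng.random((3, 8)), ["cg0", "cg1", "cg2"])
        coefs = pd.Series([1.5, -0.5, 2.0], index=["cg0", "cg1", "cg2"])
        s1 = risk_score(coefs, beta)
        s2 = risk_score(coefs.loc[["cg2", "cg0", "cg1"]], beta)
        pd.testing.assert_series_equal(s1, s2)

    def test_adding_zero_coefficient_probe_changes_nothing(self):
        rng = np.random.default_rng(1)
        beta = _beta(rng.random((2, 6)), ["cg0", "cg1"])
        s1 = risk_score(pd.Series([1.0], index=["cg0"]), beta)
        s2 = risk_score(pd.Series([1.0, 0.0], index=["cg0", "cg1"]), beta)
        pd.testing.assert_series_equal(s1, s2)

    def test_missing_beta_excludes_patient(self):
        beta = _beta([[0.5, np.nan]], ["cg0"])
        scores = risk_score(pd.Series([1.0], index=["cg0"]), beta)
        assert list(scores.index) == ["P0"]


class TestMedianSplit:
    def test_even_split(self):
        groups = median_split(pd.Series([1, 2, 3, 4],
                                        index=list("abcd")).astype(float))
        assert groups.tolist() == ["low", "low", "high", "high"]

    def test_scores_at_median_go_low(self):
        groups = median_split(pd.Series([1, 2, 2, 3],
                                        index=list("abcd")).astype(float))
        assert groups.tolist() == ["low", "low", "low", "high"]

    def test_constant_scores_skip(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.Series([1.0] * 6))

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match=">= 4"):
            median_split(pd.Series([1.0, 2.0, 3.0]))


class TestLogrankAndKm:
    def test_identical_groups_give_p1(self):
        clin = _clinical([5, 10, 15, 5, 10, 15], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=clin.index)
        p, curves = logrank_and_km(groups, clin)
        assert p == pytest.approx(1.0)
        pd.testing.assert_frame_equal(curves["high"], curves["low"])

    def test_toy_table_matches_observed_expected_oracle(self):
        """Hand-computed log-rank on a 6-patient table (all events)."""
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        clin = _clinical(times, events)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=clin.index)
        p, _ = logrank_and_km(groups, clin)

        # oracle: chi2 = (O1-E1)^2 / V from the risk tables
        o1 = e1 = v = 0.0
        at_risk = list(zip(times, events, groups))
        for t in sorted({t for t, e, _ in at_risk if e}):
            risk = [(tt, ee, g) for tt, ee, g in at_risk if tt >= t]
            n = len(risk)
            n1 = sum(1 for _, _, g in risk if g == "high")
            d = sum(1 for tt, ee, _ in risk if tt == t and ee)
            d1 = sum(1 for tt, ee, g in risk if tt == t and ee and g == "high")
            o1 += d1
            e1 += d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        p_hand = float(stats.chi2.sf((o1 - e1) ** 2 / v, df=1))
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_group_label_exchange_symmetric(self):
        rng = np.random.default_rng(2)
        clin = _clinical(rng.exponential(100, 20), rng.integers(0, 2, 20))
        clin.iloc[:4, clin.columns.get_loc("event")] = 1  # ensure events
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=clin.index)
        p1, _ = logrank_and_km(groups, clin)
        p2, _ = logrank_and_km(groups.map({"high": "low", "low": "high"}),
                               clin)
        assert p1 == pytest.approx(p2)

    def test_no_events_anywhere_raises(self):
        clin = _clinical([5, 6, 7, 8], [0, 0, 0, 0])
        groups = pd.Series(["high", "high", "low", "low"], index=clin.index)
        with pytest.raises(ValueError, match="no events"):
            logrank_and_km(groups, clin)

    def test_km_curves_are_monotone_product_limit(self):
        rng = np.random.default_rng(3)
        clin = _clinical(rng.exponential(50, 30), np.ones(30, dtype=int))
        groups = pd.Series(["high"] * 15 + ["low"] * 15, index=clin.index)
        _, curves = logrank_and_km(groups, clin)
        for c in curves.values():
            assert (np.diff(c["survival"]) <= 1e-12).all()
            assert c["survival"].iloc[0] == 1.0


class TestFitCox:
    def _simulate(self, rng, n=150, coef=4.0):
        beta = _beta(rng.beta(5, 5, size=(2, n)), ["cg0", "cg1"])
        lam = 0.01 * np.exp(coef * (beta.loc["cg0"].to_numpy() - 0.5))
        clin = _clinical(rng.exponential(1 / lam), np.ones(n, dtype=int),
                         ids=list(beta.columns))
        return beta, clin

    def test_recovers_positive_hazard_sign(self):
        rng = np.random.default_rng(4)
        beta, clin = self._simulate(rng)
        coefs = fit_cox(beta, ["cg0", "cg1"], clin)
        assert coefs["cg0"] > 0
        assert abs(coefs["cg1"]) < abs(coefs["cg0"])

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(5)
        beta = _beta(rng.beta(5, 5, size=(1, 400)), ["cg0"])
        clin = _clinical(rng.exponential(100, 400), np.ones(400, dtype=int),
                         ids=list(beta.columns))
        coef = fit_cox(beta, ["cg0"], clin)["cg0"]
        # sd of betahat ~ 1/(sd_x * sqrt(n)) ~ 0.33; allow 3 sd
        assert abs(coef) < 3 * (1 / (beta.loc["cg0"].std() * np.sqrt(400)))

    def test_duplicate_covariates_raise_collinearity(self):
        rng = np.random.default_rng(6)
        row = rng.beta(5, 5, size=20)
        beta = _beta([row, row], ["cg0", "cg1"])
        clin = _clinical(rng.exponential(100, 20), np.ones(20, dtype=int),
                         ids=list(beta.columns))
        with pytest.raises(ConvergenceError):
            fit_cox(beta, ["cg0", "cg1"], clin)

    def test_no_events_raise(self):
        rng = np.random.default_rng(7)
        beta = _beta(rng.beta(5, 5, size=(1, 10)), ["cg0"])
        clin = _clinical(rng.exponential(100, 10), np.zeros(10, dtype=int),
                         ids=list(beta.columns))
        with pytest.raises(ValueError, match="events"):
            fit_cox(beta, ["cg0"], clin)
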