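"""Unit and property tests for the weighted product-limit core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fgmrisk as fr
from fgmrisk.km import RiskTableError

from conftest import brute_force_km, random_event_frame


def make_frame(times, events, weights=None):
    n = len(times)
    return pd.DataFrame(
        {
            "time": times,
            "event": events,
            "weight": weights if weights is not None else np.ones(n),
            "stratum_id": "s1",
            "psu_id": [str(i) for i in range(n)],
        }
    )


class TestRiskTable:
    def test_hand_tally(self, hand_fixture):
        rt = fr.risk_table(hand_fixture)
        assert rt.n[4] == 5 and rt.d[4] == 1
        assert rt.n[6] == 3 and rt.d[6] == 1
        assert rt.c[5] == 1 and rt.c[7] == 1 and rt.c[8] == 1

    def test_single_weighted_event_at_birth(self):
        rt = fr.risk_table(make_frame([0], [True], [2.0]))
        assert rt.n[0] == 2.0 and rt.d[0] == 2.0
        assert rt.n_unw[0] == 1 and rt.d_unw[0] == 1

    def test_empty_input_all_zero(self):
        rt = fr.risk_table(pd.DataFrame(columns=["time", "event", "weight"]))
        assert not rt.n.any() and not rt.d.any() and not rt.c.any()

    def test_conservation(self, rng):
        for _ in range(20):
            rt = fr.risk_table(random_event_frame(rng, weighted=True))
            np.testing.assert_allclose(rt.n[1:], (rt.n - rt.d - rt.c)[:-1], atol=1e-12)
            np.testing.assert_array_equal(rt.n_unw[1:], (rt.n_unw - rt.d_unw - rt.c_unw)[:-1])

    def test_rejects_bad_times_and_weights(self):
        with pytest.raises(RiskTableError):
            fr.risk_table(make_frame([55], [True]))
        with pytest.raises(RiskTableError):
            fr.risk_table(make_frame([5], [True], [-1.0]))
        with pytest.raises(RiskTableError, match="missing required"):
            fr.risk_table(pd.DataFrame({"time": [1]}))


class TestKmEstimate:
    def test_no_events_flat_one(self, rng):
        df = random_event_frame(rng)
        df["event"] = False
        curve = fr.km_estimate(fr.risk_table(df))
        assert (curve.s == 1.0).all()

    def test_hand_example(self, hand_fixture):
        s = fr.km_estimate(fr.risk_table(hand_fixture)).s
        assert s[4] == pytest.approx(0.8, abs=1e-15)
        assert s[6] == pytest.approx(0.8 * (2 / 3), abs=1e-15)
        assert s[8] == pytest.approx(8 / 15, abs=1e-15)

    def test_weighted_hand_example(self):
        # weights {(2,e,w=2),(3,c,w=1),(5,e,w=1)}: S(2) = 1 - 2/4; S(5) = 0
        df = make_frame([2, 3, 5], [True, False, True], [2.0, 1.0, 1.0])
        s = fr.km_estimate(fr.risk_table(df)).s
        assert s[2] == pytest.approx(0.5, abs=1e-15)
        assert s[5] == pytest.approx(0.0, abs=1e-15)
        assert s[49] == 0.0  # flat extension past exhaustion

    def test_matches_lifelines_oracle(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(10):
            df = random_event_frame(rng)
            kmf = lifelines.KaplanMeierFitter().fit(df["time"], df["event"])
            ours = fr.km_estimate(fr.risk_table(df)).s
            theirs = kmf.survival_function_at_times(np.arange(50)).to_numpy()
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_inconsistent_risk_table_raises(self):
        rt = fr.risk_table(make_frame([3], [True]))
        rt.d[3] = 5.0
        with pytest.raises(RiskTableError):
            fr.km_estimate(rt)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 49), st.booleans(), st.floats(0.1, 10.0)),
            min_size=1,
            max_size=40,
        ),
        scale=st.floats(0.01, 100.0),
    )
    def test_monotone_bounded_and_scale_invariant(self, data, scale):
        times, events, weights = map(list, zip(*data))
        df = make_frame(times, events, weights)
        s = fr.km_estimate(fr.risk_table(df)).s
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))
        df2 = df.assign(weight=df["weight"] * scale)
        s2 = fr.km_estimate(fr.risk_table(df2)).s
        np.testing.assert_allclose(s, s2, atol=1e-10)


class TestVariance:
    def test_zero_events_zero_se(self, rng):
        df = random_event_frame(rng)
        df["event"] = False
        curve = fr.km_variance(df)
        assert np.allclose(curve.se, 0.0)

    def test_srs_se_close_to_binomial(self):
        # SRS, no censoring before t: SE(S_hat) ~ sqrt(S(1-S)/n)
        rng = np.random.default_rng(7)
        n = 100
        h = 1 - 0.5 ** (1 / 11)  # S(10) = 0.5 under constant hazard over 0..10
        haz = np.zeros(50)
        haz[:11] = h
        hit = rng.random((n, 50)) < haz
        has = hit.any(axis=1)
        times = np.where(has, hit.argmax(axis=1), 30)
        df = make_frame(times, has)
        curve = fr.km_variance(df)
        binom = np.sqrt(curve.s[10] * (1 - curve.s[10]) / n)
        assert curve.se[10] == pytest.approx(binom, rel=0.15)

    def test_lonely_psu_error_names_stratum(self):
        df = make_frame([3, 4, 5], [True, True, False])
        df["stratum_id"] = ["s1", "s1", "lonely"]
        df["psu_id"] = ["a", "b", "c"]
        with pytest.raises(ValueError, match="lonely"):
            fr.km_variance(df)
        curve = fr.km_variance(df, lonely_psu="collapse")
        assert curve.se is not None

    def test_linearized_tracks_bootstrap(self, clean_spec):
        tables = fr.simulate_survey(clean_spec)
        records, _ = fr.build_event_table(tables.women, tables.daughters, survey_id="A")
        curve = fr.km_variance(records)
        boot = fr.bootstrap_se(records, n_replicates=200, rng=5)
        mask = (curve.s[1:16] > 0.05) & (boot[1:16] > 0)
        ratio = curve.se[1:16][mask].mean() / boot[1:16][mask].mean()
        assert 0.8 < ratio < 1.25


class TestConfidenceInterval:
    def test_zero_se_degenerate_interval(self, hand_fixture):
        curve = fr.km_estimate(fr.risk_table(hand_fixture))
        curve.se = np.zeros(50)
        fr.confidence_interval(curve)
        np.testing.assert_array_equal(curve.ci_low, curve.s)
        np.testing.assert_array_equal(curve.ci_high, curve.s)

    def test_log_scale_arithmetic(self):
        # S=0.8, SE(log S)=0.05 -> 0.8 * exp(-/+ 1.959964*0.05)
        curve = fr.SurvivalCurve(s=np.full(50, 0.8), se=np.full(50, 0.8 * 0.05))
        fr.confidence_interval(curve, level=0.95)
        assert curve.ci_low[0] == pytest.approx(0.7254, abs=2e-4)
        assert curve.ci_high[0] == pytest.approx(0.8823, abs=2e-4)

    def test_bounds_respect_unit_interval(self):
        curve = fr.SurvivalCurve(s=np.full(50, 0.99), se=np.full(50, 0.05))
        fr.confidence_interval(curve)
        assert np.all(curve.ci_high <= 1.0)
        fr.confidence_interval(curve, method="loglog")
        assert np.all(curve.ci_high <= 1.0) and np.all(curve.ci_low <= curve.s)

    def test_invalid_level_rejected(self, hand_fixture):
        curve = fr.km_variance(hand_fixture)
        with pytest.raises(ValueError):
            fr.confidence_interval(curve, level=1.5)


class TestCompareCurves:
    @staticmethod
    def _curve(s, se):
        return fr.SurvivalCurve(s=np.full(50, float(s)), se=np.full(50, float(se)))

    def test_identical_curves_null(self):
        a = self._curve(0.7, 0.02)
        out = fr.compare_curves(a, self._curve(0.7, 0.02), [5, 15])
        assert (out["diff"] == 0).all() and (out["z"] == 0).all() and (out["p"] == 1).all()

    def test_z_arithmetic(self):
        out = fr.compare_curves(self._curve(0.8, 0.02), self._curve(0.7, 0.02), [10])
        assert out["z"].iloc[0] == pytest.approx(0.10 / np.sqrt(0.0008), rel=1e-6)

    def test_age_out_of_range_rejected(self):
        a = self._curve(0.7, 0.02)
        with pytest.raises(ValueError):
            fr.compare_curves(a, a, [60])

    def test_power_exceeds_normal_approximation(self):
        # two SRS arms with a true survival gap; observed rejection rate at
        # alpha=.05 should reach the closed-form normal-approximation power
        rng = np.random.default_rng(99)
        n, p_a, p_b, t_eval = 400, 0.40, 0.55, 10
        se_true = np.sqrt(p_a * (1 - p_a) / n + p_b * (1 - p_b) / n)
        from scipy.stats import norm

        power = norm.cdf(abs(p_a - p_b) / se_true - norm.ppf(0.975))
        reps, rej = 150, 0
        for _ in range(reps):
            arms = []
            for p in (p_a, p_b):
                cut = rng.random(n) < 1 - p  # event by t_eval with prob 1-p
                times = np.where(cut, rng.integers(0, t_eval + 1, n), 30)
                arms.append(fr.km_variance(make_frame(times, cut)))
            out = fr.compare_curves(arms[0], arms[1], [t_eval])
            rej += out["p"].iloc[0] < 0.05
        mc_se = np.sqrt(power * (1 - power) / reps)
        assert rej / reps >= power - 4 * mc_se
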