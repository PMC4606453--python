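"""Tap assay: response scoring, background correction, logistic fit, F test."""

import numpy as np
import pandas as pd
import pytest

from larvasleep.arousal_assay import (
    DoseResponseFit,
    TapResponseTable,
    background_probability,
    compare_fits,
    corrected_response_table,
    fit_dose_response,
    logistic_response,
    percent_change,
    score_responses,
)
from larvasleep.errors import AnalysisError, FitError
from larvasleep.io_tracking import ActivityMatrix, StimulusEvent, StimulusLog
from larvasleep.synthetic_data import (
    TapSimParams,
    default_tap_powers,
    simulate_tap_experiment,
    simulate_tap_tables,
)


def second_matrix(values):
    v = np.atleast_2d(np.asarray(values, dtype=float))
    return ActivityMatrix(
        larva_ids=tuple(f"L{i}" for i in range(v.shape[0])),
        bin_start_times=np.arange(v.shape[1], dtype=float),
        bin_width=1.0,
        values=v,
    )


def tap_log(times, powers=None):
    powers = powers if powers is not None else [3.0] * len(times)
    return StimulusLog(tuple(StimulusEvent(float(t), "tap", float(p)) for t, p in zip(times, powers)))


def exact_table(powers, bottom, top, etp50, slope, n_trials=30):
    c = logistic_response(np.asarray(powers), bottom, top, np.log10(etp50), slope)
    df = pd.DataFrame(
        {
            "power": powers,
            "n_trials": n_trials,
            "raw_response": np.clip(c, 0, 1),
            "corrected_response": c,
        }
    )
    return TapResponseTable(table=df, background=0.0)


class TestScoreResponses:
    def test_zero_trace_never_responds(self):
        m = second_matrix(np.zeros((2, 120)))
        out = score_responses(m, tap_log([30.0, 90.0]))
        assert (out["response"] == 0).all() and len(out) == 4

    def test_window_boundary(self):
        v = np.zeros(60)
        v[32] = 1.0  # movement 2 s after the tap at t=30
        m = second_matrix(v)
        assert score_responses(m, tap_log([30.0]), 5.0)["response"].iloc[0] == 1
        assert score_responses(m, tap_log([30.0]), 1.0)["response"].iloc[0] == 0

    def test_overlapping_windows_rejected(self):
        m = second_matrix(np.zeros(60))
        with pytest.raises(AnalysisError, match="closer together"):
            score_responses(m, tap_log([10.0, 12.0]), 5.0)

    def test_event_outside_recording_rejected(self):
        m = second_matrix(np.zeros(20))
        with pytest.raises(AnalysisError, match="response window"):
            score_responses(m, tap_log([18.0]), 5.0)

    def test_equals_brute_force_window_scan(self, rng):
        n_ev, window = 12, 5.0
        times = 10.0 + np.arange(n_ev) * 20.0
        v = (rng.random((3, 300)) < 0.05).astype(float)
        m = second_matrix(v)
        out = score_responses(m, tap_log(times), window).pivot(
            index="larva_id", columns="event_index", values="response"
        )
        for li, lid in enumerate(m.larva_ids):
            for k, t in enumerate(times):
                expect = int(any(v[li, s] > 0 for s in range(300) if t <= s < t + window))
                assert out.loc[lid, k] == expect


class TestBackground:
    def test_motionless_larva(self):
        m = second_matrix(np.zeros(200))
        b = background_probability(m, tap_log([30.0, 90.0, 150.0]))
        assert b.iloc[0] == 0.0

    def test_always_moving_larva(self):
        m = second_matrix(np.ones(200))
        b = background_probability(m, tap_log([30.0, 90.0, 150.0]))
        assert b.iloc[0] == 1.0

    def test_planted_bernoulli_rate_recovered(self):
        """b ~ Bernoulli(0.1) pre-window movement over 420 events per larva."""
        params = TapSimParams(background=0.10, n_larvae=20, seed=3)
        m, log = simulate_tap_experiment(params)
        b = background_probability(m, log)
        n = 420 * 20
        ci_half = 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(b.mean() - 0.10) < ci_half


class TestCorrectedTable:
    def test_r_equal_b_gives_zero(self):
        resp = pd.DataFrame({"power": [1.0, 1.0, 2.0, 2.0] * 5, "response": [1, 0] * 10})
        table = corrected_response_table(resp, 0.5)
        assert np.allclose(table.corrected, 0.0)

    def test_forced_by_formula(self):
        resp = pd.DataFrame({"power": [2.0] * 100, "response": [1] * 43 + [0] * 57})
        table = corrected_response_table(resp, 0.05)
        assert table.table["corrected_response"].iloc[0] == pytest.approx(0.38)

    def test_full_assay_equals_hand_aggregation(self):
        m, log = simulate_tap_experiment(TapSimParams(n_larvae=12, seed=9))
        resp = score_responses(m, log)
        b = background_probability(m, log)
        table = corrected_response_table(resp, b)
        # hand aggregation from the flat response list
        hand = resp.groupby("power")["response"].mean()
        assert np.allclose(table.table["raw_response"], hand.values)
        assert np.allclose(table.corrected, hand.values - b.mean())
        assert (table.table["n_trials"] == 30 * 12).all()


class TestDoseResponseFit:
    def test_noiseless_identifiability(self):
        table = exact_table(default_tap_powers(), 0.0, 0.4, 3.0, 2.0)
        fit = fit_dose_response(table)
        assert fit.ss_residual <= 1e-10
        assert fit.etp50 == pytest.approx(3.0, rel=1e-4)
        assert fit.top == pytest.approx(0.4, rel=1e-4)
        assert fit.hill_slope == pytest.approx(2.0, rel=1e-3)

    def test_matches_grid_search_oracle_on_noisy_data(self, rng):
        """Brute-force grid over (top, logEC50, slope) agrees within grid step."""
        powers = default_tap_powers()
        c = logistic_response(powers, 0.0, 0.35, np.log10(3.1), 2.0) + rng.normal(
            0, 0.02, powers.size
        )
        df = pd.DataFrame(
            {
                "power": powers,
                "n_trials": 30,
                "raw_response": np.clip(c, 0, 1),
                "corrected_response": c,
            }
        )
        fit = fit_dose_response(TapResponseTable(table=df, background=0.0))
        tops = np.linspace(0.2, 0.5, 61)
        les = np.linspace(np.log10(1.0), np.log10(36.31), 157)
        slopes = np.linspace(0.5, 4.0, 71)
        logp = np.log10(powers)
        best = (np.inf, None)
        for t in tops:
            for h in slopes:
                pred = t / (1.0 + 10.0 ** ((les[:, None] - logp[None, :]) * h))
                ss = ((pred - c[None, :]) ** 2).sum(axis=1)
                k = int(np.argmin(ss))
                if ss[k] < best[0]:
                    best = (ss[k], (t, les[k], h))
        _, (t_b, le_b, h_b) = best
        assert fit.top == pytest.approx(t_b, abs=0.006)
        assert fit.log_etp50 == pytest.approx(le_b, abs=0.011)
        assert fit.hill_slope == pytest.approx(h_b, abs=0.05)
        assert fit.ss_residual <= best[0] + 1e-12

    def test_fitted_curve_monotone_with_positive_slope(self):
        table = simulate_tap_tables(TapSimParams(seed=21))
        fit = fit_dose_response(table)
        grid = np.linspace(1.0, 36.31, 200)
        pred = np.asarray(fit.predict(grid))
        if fit.hill_slope > 0:
            assert (np.diff(pred) >= -1e-12).all()

    def test_etp50_equivariant_under_power_rescaling(self):
        table = simulate_tap_tables(TapSimParams(seed=22))
        fit1 = fit_dose_response(table)
        k = 2.5
        df = table.table.copy()
        df["power"] = df["power"] * k
        fit2 = fit_dose_response(TapResponseTable(table=df, background=table.background))
        assert fit2.etp50 == pytest.approx(k * fit1.etp50, rel=1e-6)

    def test_degenerate_all_equal_rejected(self):
        df = pd.DataFrame(
            {
                "power": default_tap_powers(),
                "n_trials": 30,
                "raw_response": 0.2,
                "corrected_response": 0.2,
            }
        )
        with pytest.raises(FitError, match="degenerate"):
            fit_dose_response(TapResponseTable(table=df, background=0.0))

    def test_too_few_powers_rejected(self):
        with pytest.raises(FitError, match=">= 5"):
            fit_dose_response(exact_table([1.0, 2.0, 4.0, 8.0], 0, 0.4, 3.0, 2.0))


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,val,expected",
        [(3.1, 2.1, -32), (5.7, 2.6, -54), (4.0, 4.0, 0)],
    )
    def test_reported_etp50_changes(self, ref, val, expected):
        assert round(percent_change(ref, val)) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestCompareFits:
    def test_identical_datasets_give_null_f(self):
        table = simulate_tap_tables(TapSimParams(seed=30))
        res = compare_fits(table, table, shared="all")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_f_equals_oracle_from_refit_ss(self):
        ta = simulate_tap_tables(TapSimParams(seed=31))
        tb = simulate_tap_tables(TapSimParams(etp50=2.1, seed=32))
        res = compare_fits(ta, tb, shared="etp50")
        fa, fb = fit_dose_response(ta), fit_dose_response(tb)
        ss_sep = fa.ss_residual + fb.ss_residual
        df_sep = fa.df + fb.df
        df_sh = (fa.n_points + fb.n_points) - 5  # shared logEC50 + 2x(top, slope)
        f_oracle = ((res.ss_shared - ss_sep) / (df_sh - df_sep)) / (ss_sep / df_sep)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.df_numerator == 1 and res.df_denominator == df_sep

    def test_shift_detected_at_study_scale(self):
        """Planted ETP50 3.1 vs 2.1 at the study's trial design is detected."""
        ta = simulate_tap_tables(TapSimParams(etp50=3.1, seed=33))
        tb = simulate_tap_tables(TapSimParams(etp50=2.1, seed=34))
        assert compare_fits(ta, tb, shared="etp50").p_value < 1e-3

    def test_top_difference_detected(self):
        ta = simulate_tap_tables(TapSimParams(top=0.34, seed=35))
        tb = simulate_tap_tables(TapSimParams(top=0.43, seed=36))
        assert compare_fits(ta, tb, shared="top").p_value < 1e-3
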