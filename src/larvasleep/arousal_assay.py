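"""Arousal-threshold (tap) assay: response scoring, background correction,
dose-response fitting and nested-curve comparison.

Mechano-acoustic taps of graded power are delivered at 1-min intervals while
larvae are videotracked.  A larva "responds" to a tap when it moves within a
short window after the stimulus.  Because larvae also move spontaneously,
the per-power response fraction r(p) is corrected by the background
probability b of movement in an equal-length window *before* the stimulus:

    corrected response  c(p) = r(p) - b

The corrected dose-response data are fit by ordinary least squares to a
four-parameter logistic in log10 power (the "variable-slope" model):

    c(p) = bottom + (top - bottom) / (1 + 10^((logETP50 - log10 p) * h))

ETP50 — the effective tap power at which half the larvae respond — is the
assay's arousal-threshold summary.  Groups are compared with the extra
sum-of-squares F test on nested fits: a shared-parameter joint fit versus
independent per-group fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError, FitError, ValidationError
from .io_tracking import ActivityMatrix, StimulusLog

__all__ = [
    "TapResponseTable",
    "DoseResponseFit",
    "FTestResult",
    "logistic_response",
    "score_responses",
    "background_probability",
    "corrected_response_table",
    "fit_dose_response",
    "percent_change",
    "compare_fits",
]


def logistic_response(
    power: np.ndarray | float,
    bottom: float,
    top: float,
    log_etp50: float,
    hill_slope: float,
) -> np.ndarray | float:
    """Variable-slope logistic dose-response model evaluated at linear power."""
    logp = np.log10(power)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_etp50 - logp) * hill_slope))


@dataclass(frozen=True)
class TapResponseTable:
    """Per-power response fractions for one group of larvae.

    ``table`` has one row per tap power (sorted ascending) with columns
    ``power``, ``n_trials``, ``raw_response`` and ``corrected_response``;
    ``background`` is the group-mean spontaneous-movement probability that
    was subtracted.  Negative corrected responses are retained.
    """

    table: pd.DataFrame
    background: float

    def __post_init__(self) -> None:
        df = self.table
        needed = {"power", "n_trials", "raw_response", "corrected_response"}
        if not needed.issubset(df.columns):
            raise ValidationError(f"response table needs columns {sorted(needed)}")
        if (df["n_trials"] <= 0).any():
            raise ValidationError("every power must have n_trials > 0")
        if ((df["raw_response"] < 0) | (df["raw_response"] > 1)).any():
            raise ValidationError("raw response fractions must lie in [0, 1]")
        if not df["power"].is_monotonic_increasing:
            raise ValidationError("powers must be sorted ascending")

    @property
    def powers(self) -> np.ndarray:
        return self.table["power"].to_numpy(dtype=float)

    @property
    def corrected(self) -> np.ndarray:
        return self.table["corrected_response"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class DoseResponseFit:
    """Ordinary-least-squares fit of the variable-slope logistic."""

    bottom: float
    top: float
    log_etp50: float
    hill_slope: float
    ss_residual: float
    n_points: int
    fixed: tuple[str, ...]  # names of parameters held fixed
    converged: bool

    @property
    def etp50(self) -> float:
        """Half-maximal tap power on the linear power-setting scale."""
        return float(10.0**self.log_etp50)

    @property
    def n_free(self) -> int:
        return 4 - len(self.fixed)

    @property
    def df(self) -> int:
        return self.n_points - self.n_free

    def predict(self, power: np.ndarray | float) -> np.ndarray | float:
        return logistic_response(power, self.bottom, self.top, self.log_etp50, self.hill_slope)


@dataclass(frozen=True)
class FTestResult:
    """Extra sum-of-squares F test between nested dose-response models."""

    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    shared: str  # which parameter(s) the null model shares across groups
    ss_shared: float
    ss_separate: float


def _window_indices(matrix: ActivityMatrix, t0: float, t1: float) -> slice:
    """Bins whose start time falls in [t0, t1)."""
    starts = matrix.bin_start_times
    return slice(
        int(np.searchsorted(starts, t0 - 1e-9)), int(np.searchsorted(starts, t1 - 1e-9))
    )


def score_responses(
    activity_fine: ActivityMatrix,
    stimulus_log: StimulusLog,
    response_window_s: float = 5.0,
) -> pd.DataFrame:
    """Binary response per (larva, tap event).

    A response is any movement (activity value > 0) in the
    ``response_window_s`` seconds following the tap.  The activity matrix
    must be binned finer than the window (e.g. 1-s bins).  Overlapping
    response windows (taps closer together than the window) and events
    whose window leaves the recording are errors.

    Returns a long DataFrame with columns ``larva_id``, ``event_index``,
    ``time_s``, ``power``, ``response``.
    """
    taps = stimulus_log.of_kind("tap")
    if not taps:
        raise AnalysisError("stimulus log contains no tap events")
    if activity_fine.bin_width > response_window_s:
        raise AnalysisError(
            f"activity bin width {activity_fine.bin_width:g} s coarser than "
            f"the {response_window_s:g}-s response window"
        )
    times = np.array([e.time_s for e in taps])
    if (np.diff(times) < response_window_s - 1e-9).any():
        raise AnalysisError("tap events closer together than the response window")
    t_end = activity_fine.t_end
    rows = []
    moved = activity_fine.values > 0
    for k, ev in enumerate(taps):
        if ev.time_s < activity_fine.bin_start_times[0] or ev.time_s + response_window_s > t_end:
            raise AnalysisError(
                f"tap at t={ev.time_s:g} s has no full response window in the recording"
            )
        sl = _window_indices(activity_fine, ev.time_s, ev.time_s + response_window_s)
        resp = moved[:, sl].any(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "larva_id": activity_fine.larva_ids,
                    "event_index": k,
                    "time_s": ev.time_s,
                    "power": float(ev.payload),  # type: ignore[arg-type]
                    "response": resp.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def background_probability(
    activity_fine: ActivityMatrix,
    stimulus_log: StimulusLog,
    pre_window_s: float = 5.0,
) -> pd.Series:
    """Per-larva probability of spontaneous movement before a stimulus.

    For each larva: the fraction of tap events with any movement in the
    ``pre_window_s`` seconds preceding the stimulus (all events pooled, so
    with the standard design of 14 powers x 30 trials each larva
    contributes 420 observations).
    """
    taps = stimulus_log.of_kind("tap")
    if not taps:
        raise AnalysisError("stimulus log contains no tap events")
    moved = activity_fine.values > 0
    counts = np.zeros(activity_fine.n_larvae)
    for ev in taps:
        if ev.time_s - pre_window_s < activity_fine.bin_start_times[0] - 1e-9:
            raise AnalysisError(
                f"tap at t={ev.time_s:g} s has no full {pre_window_s:g}-s pre-window"
            )
        sl = _window_indices(activity_fine, ev.time_s - pre_window_s, ev.time_s)
        counts += moved[:, sl].any(axis=1)
    return pd.Series(
        counts / len(taps), index=pd.Index(activity_fine.larva_ids, name="larva_id"), name="background"
    )


def corrected_response_table(
    responses: pd.DataFrame, background: pd.Series | float
) -> TapResponseTable:
    """Aggregate scored responses by power and subtract background.

    The raw response fraction at each power averages over all (larva,
    event) observations at that power; the background term is the group
    mean of the per-larva spontaneous-movement probabilities.  Corrected
    values are *not* clipped: small negative values are legitimate noise
    around a true zero and clipping them would bias the fitted bottom.
    """
    b = float(np.mean(background)) if not np.isscalar(background) else float(background)
    grp = responses.groupby("power")["response"]
    df = pd.DataFrame(
        {
            "power": grp.mean().index.to_numpy(dtype=float),
            "n_trials": grp.size().to_numpy(),
            "raw_response": grp.mean().to_numpy(dtype=float),
        }
    ).sort_values("power", ignore_index=True)
    df["corrected_response"] = df["raw_response"] - b
    return TapResponseTable(table=df, background=b)


# Parameter order used by the optimizer.
_PARAM_NAMES = ("bottom", "top", "log_etp50", "hill_slope")


def _start_points(powers: np.ndarray, c: np.ndarray, n_starts: int, seed: int) -> np.ndarray:
    """Deterministic multi-start initializations spanning the power range."""
    logp = np.log10(powers)
    rng = np.random.default_rng(seed)
    mids = np.linspace(logp.min(), logp.max(), n_starts)
    tops = np.full(n_starts, max(float(c.max()), 0.05))
    slopes = np.full(n_starts, 2.0)
    starts = np.column_stack(
        [np.full(n_starts, min(float(c.min()), 0.0)), tops, mids, slopes]
    )
    starts[1:] += rng.normal(scale=[0.01, 0.05, 0.1, 0.5], size=(n_starts - 1, 4))
    return starts


def fit_dose_response(
    table: TapResponseTable,
    fix_bottom: float | None = 0.0,
    n_starts: int = 5,
    seed: int = 0,
    ss_tol: float = 1e-10,
) -> DoseResponseFit:
    """OLS fit of the variable-slope logistic to a corrected response table.

    The bottom is fixed at 0 by default because responses are already
    background-corrected; pass ``fix_bottom=None`` to free all four
    parameters.  Initialization is multi-start (``n_starts`` deterministic
    starts spanning the log-power range) and the best sum of squares wins.
    """
    if len(table) < 5:
        raise FitError(f"need >= 5 distinct powers to fit, got {len(table)}")
    powers = table.powers
    if (powers <= 0).any():
        raise FitError("powers must be > 0 for log-scale fitting")
    c = table.corrected
    if np.ptp(c) == 0:
        raise FitError("all corrected responses identical; dose-response fit is degenerate")
    logp = np.log10(powers)

    fixed = () if fix_bottom is None else ("bottom",)

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        if fixed:
            return (float(fix_bottom), *theta)  # type: ignore[arg-type]
        return tuple(theta)  # type: ignore[return-value]

    def residuals(theta: np.ndarray) -> np.ndarray:
        bot, top, le, h = unpack(theta)
        return bot + (top - bot) / (1.0 + 10.0 ** ((le - logp) * h)) - c

    best: optimize.OptimizeResult | None = None
    for x0 in _start_points(powers, c, n_starts, seed):
        theta0 = x0[1:] if fixed else x0
        try:
            res = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 0.0):
            best = res
    if best is None:
        raise FitError("dose-response fit failed to converge from all starts")
    bot, top, le, h = unpack(best.x)
    ss = float(2.0 * best.cost)
    return DoseResponseFit(
        bottom=float(bot),
        top=float(top),
        log_etp50=float(le),
        hill_slope=float(h),
        ss_residual=ss,
        n_points=len(table),
        fixed=fixed,
        converged=True,
    )


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``.

    ``percent_change(3.1, 2.1)`` is about -32 (a 32% decrease).
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def _fit_joint(
    tables: Sequence[TapResponseTable],
    shared: Sequence[str],
    fix_bottom: float | None,
    n_starts: int,
    seed: int,
) -> float:
    """Best joint SS with the named parameters tied across groups."""
    free_names = [n for n in _PARAM_NAMES if fix_bottom is None or n != "bottom"]
    shared_free = [n for n in free_names if n in shared]
    group_free = [n for n in free_names if n not in shared]
    logps = [np.log10(t.powers) for t in tables]
    cs = [t.corrected for t in tables]

    def model(params: dict[str, float], logp: np.ndarray) -> np.ndarray:
        bot = params["bottom"]
        return bot + (params["top"] - bot) / (
            1.0 + 10.0 ** ((params["log_etp50"] - logp) * params["hill_slope"])
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        pos = 0
        shared_vals = dict(zip(shared_free, theta[: len(shared_free)]))
        pos = len(shared_free)
        out = []
        for g in range(len(tables)):
            vals = dict(shared_vals)
            for n in group_free:
                vals[n] = theta[pos]
                pos += 1
            if fix_bottom is not None:
                vals["bottom"] = fix_bottom
            out.append(model(vals, logps[g]) - cs[g])
        return np.concatenate(out)

    best_ss = np.inf
    all_p = np.concatenate([t.powers for t in tables])
    all_c = np.concatenate(cs)
    for x0 in _start_points(all_p, all_c, n_starts, seed):
        start_map = dict(zip(_PARAM_NAMES, x0))
        theta0 = np.array(
            [start_map[n] for n in shared_free]
            + [start_map[n] for _ in tables for n in group_free]
        )
        try:
            res = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if res.success:
            best_ss = min(best_ss, float(2.0 * res.cost))
    if not np.isfinite(best_ss):
        raise FitError("joint dose-response fit failed to converge from all starts")
    return best_ss


def compare_fits(
    table_a: TapResponseTable,
    table_b: TapResponseTable,
    shared: str = "etp50",
    fix_bottom: float | None = 0.0,
    n_starts: int = 5,
    seed: int = 0,
) -> FTestResult:
    """Extra sum-of-squares F test between two groups' dose-response curves.

    ``shared`` names the parameter(s) constrained equal in the null model:
    ``"etp50"`` tests for an arousal-threshold shift, ``"top"`` for a change
    in maximal response fraction, ``"all"`` for any curve difference.  With
    SSs and residual dfs of the shared (null) and separate (alternative)
    fits,

        F = ((SS_shared - SS_separate) / (df_shared - df_separate))
            / (SS_separate / df_separate)

    and p comes from the F distribution with that df pair.
    """
    shared_map = {
        "all": [n for n in _PARAM_NAMES if fix_bottom is None or n != "bottom"],
        "etp50": ["log_etp50"],
        "top": ["top"],
    }
    if shared not in shared_map:
        raise ValueError(f"shared must be one of {sorted(shared_map)}, got {shared!r}")
    shared_names = shared_map[shared]

    fit_a = fit_dose_response(table_a, fix_bottom=fix_bottom, n_starts=n_starts, seed=seed)
    fit_b = fit_dose_response(table_b, fix_bottom=fix_bottom, n_starts=n_starts, seed=seed)
    ss_sep = fit_a.ss_residual + fit_b.ss_residual
    df_sep = fit_a.df + fit_b.df

    n_free_per_group = len([n for n in _PARAM_NAMES if fix_bottom is None or n != "bottom"])
    n_shared_model = len(shared_names) + 2 * (n_free_per_group - len(shared_names))
    df_sh = (fit_a.n_points + fit_b.n_points) - n_shared_model
    if df_sh - df_sep <= 0:
        raise AnalysisError("shared model must have fewer free parameters than separate fits")
    if ss_sep <= 0:
        raise FitError("separate fits have zero residual; F test degenerate")

    ss_sh = _fit_joint([table_a, table_b], shared_names, fix_bottom, n_starts, seed)
    # joint optimum can never beat the unconstrained separate fits except by
    # numerical noise; clamp so F >= 0
    ss_sh = max(ss_sh, ss_sep)
    f_stat = ((ss_sh - ss_sep) / (df_sh - df_sep)) / (ss_sep / df_sep)
    p = float(stats.f.sf(f_stat, df_sh - df_sep, df_sep))
    return FTestResult(
        f_statistic=float(f_stat),
        df_numerator=df_sh - df_sep,
        df_denominator=df_sep,
        p_value=p,
        shared=shared,
        ss_shared=ss_sh,
        ss_separate=ss_sep,
    )
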