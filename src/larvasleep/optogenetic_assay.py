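"""Optogenetic light-stimulation analysis on 10-s-binned activity.

Freely behaving larvae are exposed to 30-min blocks of red or blue light
(three trials per night, 3-h inter-trial interval) while activity is
recorded in 10-s bins.  Light transitions trigger startle bursts in every
genotype, so the minute around light onset and everything from light
offset onward are excluded.  The retained windows are:

* baseline:  30 min before onset, minus the final minute;
* response:  30 min after onset, minus the first minute.

Each larva's total response-window activity is divided by the mean
baseline activity of its genotype (baseline normalization), trials are
pooled by averaging the per-trial ratios, and genotype means are expressed
as a percentage of a reference genotype.  Response dynamics are summarized
by A, the maximum of the smoothed genotype-mean activity trace, and T_A,
the time from light onset to reach it.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_tracking import ActivityMatrix, PlateMap, StimulusLog

__all__ = [
    "TrialWindows",
    "OptoWindows",
    "extract_windows",
    "normalize_light_activity",
    "genotype_percent",
    "response_dynamics",
]


@dataclass(frozen=True)
class TrialWindows:
    onset_s: float
    offset_s: float
    baseline_idx: np.ndarray  # bin indices into the activity matrix
    response_idx: np.ndarray
    excluded_idx: np.ndarray  # onset/offset exclusion bins inside [t0, offset)


@dataclass(frozen=True)
class OptoWindows:
    trials: tuple[TrialWindows, ...]

    def __len__(self) -> int:
        return len(self.trials)


def extract_windows(
    matrix_10s: ActivityMatrix,
    stimulus_log: StimulusLog,
    pre_s: float = 1800.0,
    post_s: float = 1800.0,
    exclusion_s: float = 60.0,
) -> OptoWindows:
    """Baseline/response bin indices per light trial, exclusions applied.

    Each ``light_on`` event must be matched by the next ``light_off``; the
    recording must fully cover ``pre_s`` before onset and ``post_s`` after.
    The minute (``exclusion_s``) before and after onset is excluded, and
    the response window ends at light offset so the offset burst never
    enters any statistic.
    """
    ons = stimulus_log.of_kind("light_on")
    offs = stimulus_log.of_kind("light_off")
    if not ons:
        raise AnalysisError("stimulus log contains no light_on events")
    if len(ons) != len(offs):
        raise AnalysisError(f"{len(ons)} light_on but {len(offs)} light_off events")
    starts = matrix_10s.bin_start_times
    width = matrix_10s.bin_width

    def idx_range(t0: float, t1: float) -> np.ndarray:
        return np.arange(
            int(np.searchsorted(starts, t0 - 1e-9)), int(np.searchsorted(starts, t1 - 1e-9))
        )

    trials = []
    prev_end = -np.inf
    for k, (on, off) in enumerate(zip(ons, offs)):
        if off.time_s <= on.time_s:
            raise AnalysisError(f"trial {k}: light_off at {off.time_s:g} precedes light_on")
        t0 = on.time_s - pre_s
        t1 = min(on.time_s + post_s, off.time_s)
        if t0 < starts[0] - 1e-9 or t1 > matrix_10s.t_end + 1e-9:
            raise AnalysisError(
                f"trial {k}: window [{t0:g}, {t1:g}) s not fully covered by the recording"
            )
        if t0 < prev_end:
            raise AnalysisError(f"trial {k} overlaps the previous trial")
        prev_end = off.time_s
        baseline = idx_range(t0, on.time_s - exclusion_s)
        response = idx_range(on.time_s + exclusion_s, t1)
        excluded = idx_range(on.time_s - exclusion_s, on.time_s + exclusion_s)
        trials.append(
            TrialWindows(
                onset_s=on.time_s,
                offset_s=off.time_s,
                baseline_idx=baseline,
                response_idx=response,
                excluded_idx=excluded,
            )
        )
    return OptoWindows(tuple(trials))


def normalize_light_activity(
    windows: OptoWindows, matrix: ActivityMatrix, plate_map: PlateMap
) -> pd.DataFrame:
    """Per-larva baseline-normalized light response, averaged over trials.

    For each trial, a larva's ratio is its total response-window activity
    divided by the *genotype-mean* total baseline activity for that trial;
    the per-larva value is the mean ratio across trials.
    """
    genotype = plate_map.genotype_map(matrix.larva_ids)
    geno = genotype.to_numpy()
    ratios = np.zeros((matrix.n_larvae, len(windows)))
    for t, tw in enumerate(windows.trials):
        baseline_tot = matrix.values[:, tw.baseline_idx].sum(axis=1)
        response_tot = matrix.values[:, tw.response_idx].sum(axis=1)
        base_mean = pd.Series(baseline_tot).groupby(geno).mean()
        if (base_mean <= 0).any():
            bad = base_mean[base_mean <= 0].index.tolist()
            raise AnalysisError(f"zero genotype baseline activity in trial {t}: {bad}")
        ratios[:, t] = response_tot / pd.Series(geno).map(base_mean).to_numpy()
    return pd.DataFrame(
        {
            "larva_id": matrix.larva_ids,
            "genotype": geno,
            "normalized_activity": ratios.mean(axis=1),
        }
    )


def genotype_percent(ratios: pd.DataFrame, reference_genotype: str) -> pd.Series:
    """Genotype-mean normalized activity as percent of a reference genotype."""
    needed = {"genotype", "normalized_activity"}
    if not needed.issubset(ratios.columns):
        raise AnalysisError(f"ratio table needs columns {sorted(needed)}")
    means = ratios.groupby("genotype")["normalized_activity"].mean()
    ref = str(reference_genotype).casefold()
    if ref not in means.index:
        raise AnalysisError(f"reference genotype {reference_genotype!r} not present")
    return 100.0 * means / means[ref]


def response_dynamics(
    matrix: ActivityMatrix,
    windows: OptoWindows,
    plate_map: PlateMap,
    smoothing_bins: int = 5,
) -> pd.DataFrame:
    """Maximum genotype-mean activity A and time-to-maximum T_A.

    The genotype-mean 10-s-bin trace over the response window (averaged
    across trials, aligned on light onset) is smoothed with a centered
    moving average of ``smoothing_bins`` bins; A is its maximum
    (seconds-active per bin) and T_A the minutes from light onset to the
    first bin attaining A (ties broken earliest).  Edge bins lost to the
    'valid' smoothing kernel do not compete for the maximum.
    """
    if smoothing_bins < 1 or smoothing_bins % 2 == 0:
        raise AnalysisError("smoothing_bins must be a positive odd integer")
    n_resp = min(tw.response_idx.size for tw in windows.trials)
    if n_resp < smoothing_bins:
        raise AnalysisError(
            f"response window of {n_resp} bins shorter than the {smoothing_bins}-bin kernel"
        )
    genotype = plate_map.genotype_map(matrix.larva_ids).to_numpy()
    kernel = np.ones(smoothing_bins) / smoothing_bins
    half = smoothing_bins // 2
    rows = []
    for g in pd.unique(genotype):
        sel = genotype == g
        # mean across trials and larvae, aligned bins-from-onset
        trace = np.mean(
            [matrix.values[sel][:, tw.response_idx[:n_resp]].mean(axis=0) for tw in windows.trials],
            axis=0,
        )
        smooth = np.convolve(trace, kernel, mode="valid")
        k = int(np.argmax(smooth))  # argmax takes the earliest on ties
        # bin k of the valid-smoothed trace is centered on response bin k+half
        first_offset_s = (
            matrix.bin_start_times[windows.trials[0].response_idx[0]] - windows.trials[0].onset_s
        )
        t_a_min = (first_offset_s + (k + half) * matrix.bin_width + matrix.bin_width / 2) / 60.0
        rows.append({"genotype": g, "A": float(smooth[k]), "T_A_min": t_a_min})
    return pd.DataFrame(rows)
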