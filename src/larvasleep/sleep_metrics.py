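"""Sleep/wake measures from minute-binned locomotor activity.

A sleep bout is one or more consecutive 60-s bins with zero locomotor
activity — the standard behavioral rest criterion for larval zebrafish.
From that single definition this module derives the six per-larva,
per-epoch measures reported in larval sleep studies:

* total activity (seconds of movement in the epoch),
* waking activity (seconds of movement per minute spent awake),
* sleep (minutes asleep),
* sleep bout number,
* mean sleep bout length (minutes),
* sleep latency (minutes from epoch start to the first bout; censored at
  the epoch length when the larva never sleeps).

It also implements the heat-shock overexpression ratio: each larva's
post-heat-shock night sleep divided by the mean pre-heat-shock night sleep
of its genotype, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .io_tracking import ActivityMatrix, EpochSchedule, PlateMap

__all__ = [
    "SleepBout",
    "SleepSummary",
    "rebin",
    "detect_sleep_bouts",
    "summarize_epoch",
    "summarize_all",
    "heat_shock_sleep_change",
]

MINUTE = 60.0


@dataclass(frozen=True)
class SleepBout:
    start_bin: int  # index into the (epoch-relative) minute series
    duration: int  # minutes

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValidationError("sleep bout duration must be >= 1 minute")


@dataclass(frozen=True)
class SleepSummary:
    larva_id: str
    epoch: str
    total_activity: float  # seconds of movement in the epoch
    waking_activity: float  # seconds of movement per waking minute
    sleep: float  # minutes
    bout_count: int
    mean_bout_length: float  # minutes; 0 when no bouts
    sleep_latency: float  # minutes from epoch start to first bout start
    latency_censored: bool  # True when the larva never slept in the epoch
    waking_defined: bool  # False when the larva slept the whole epoch


def rebin(matrix: ActivityMatrix, target_bin_width: float) -> ActivityMatrix:
    """Sum activity into wider bins; total activity is conserved.

    ``target_bin_width`` must be an integer multiple of the source width and
    the record length must divide evenly into the new bins.
    """
    ratio = target_bin_width / matrix.bin_width
    factor = int(round(ratio))
    if not np.isclose(ratio, factor) or factor < 1:
        raise AnalysisError(
            f"target bin width {target_bin_width:g} is not an integer multiple "
            f"of source width {matrix.bin_width:g}"
        )
    if factor == 1:
        return matrix
    if matrix.n_bins % factor:
        raise AnalysisError(
            f"{matrix.n_bins} bins do not divide evenly into windows of {factor}"
        )
    vals = matrix.values.reshape(matrix.n_larvae, matrix.n_bins // factor, factor).sum(axis=2)
    return ActivityMatrix(
        larva_ids=matrix.larva_ids,
        bin_start_times=matrix.bin_start_times[::factor],
        bin_width=float(target_bin_width),
        values=vals,
    )


def detect_sleep_bouts(
    minute_values: Sequence[float] | np.ndarray, zero_threshold: float = 0.0
) -> list[SleepBout]:
    """Maximal runs of consecutive zero-activity minutes, one bout per run.

    ``zero_threshold`` exposes the inactivity criterion as a knob; a minute
    counts as sleep when its activity is <= the threshold (default: exactly
    zero seconds of movement).
    """
    v = np.asarray(minute_values, dtype=float)
    asleep = v <= zero_threshold
    if not asleep.any():
        return []
    padded = np.concatenate(([False], asleep, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [SleepBout(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _epoch_bin_slice(matrix: ActivityMatrix, start_s: float, end_s: float) -> slice:
    starts = matrix.bin_start_times
    if start_s < starts[0] - 1e-9 or end_s > starts[-1] + matrix.bin_width + 1e-9:
        raise AnalysisError(
            f"epoch [{start_s:g}, {end_s:g}) s extends beyond the recording "
            f"[{starts[0]:g}, {starts[-1] + matrix.bin_width:g}) s"
        )
    i0 = int(np.searchsorted(starts, start_s - 1e-9))
    i1 = int(np.searchsorted(starts, end_s - 1e-9))
    return slice(i0, i1)


def summarize_epoch(
    matrix: ActivityMatrix,
    schedule: EpochSchedule,
    epoch_label: str,
    larva_id: str,
    zero_threshold: float = 0.0,
) -> SleepSummary:
    """All six sleep/wake measures for one larva over one day/night epoch.

    Bouts spanning the epoch boundary are clipped at the boundary: only the
    portion inside the epoch is counted, so a bout crossing midnight
    contributes to both adjacent epochs.
    """
    if not np.isclose(matrix.bin_width, MINUTE):
        raise AnalysisError(
            f"sleep scoring requires 60-s bins (got {matrix.bin_width:g} s); "
            "rebin the matrix first"
        )
    epoch = schedule.epoch(epoch_label)
    sl = _epoch_bin_slice(matrix, epoch.start_s, epoch.end_s)
    v = matrix.row(larva_id)[sl]
    n_min = v.size
    bouts = detect_sleep_bouts(v, zero_threshold)
    sleep = float(sum(b.duration for b in bouts))
    total_activity = float(v.sum())
    waking_min = n_min - sleep
    waking_defined = waking_min > 0
    waking_activity = total_activity / waking_min if waking_defined else 0.0
    if bouts:
        latency = float(bouts[0].start_bin)
        censored = False
    else:
        latency = float(n_min)
        censored = True
    return SleepSummary(
        larva_id=str(larva_id),
        epoch=epoch_label,
        total_activity=total_activity,
        waking_activity=waking_activity,
        sleep=sleep,
        bout_count=len(bouts),
        mean_bout_length=sleep / len(bouts) if bouts else 0.0,
        sleep_latency=latency,
        latency_censored=censored,
        waking_defined=waking_defined,
    )


def summarize_all(
    matrix: ActivityMatrix,
    schedule: EpochSchedule,
    epoch_labels: Sequence[str] | None = None,
    zero_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-larva x per-epoch summary table (one row per combination)."""
    if epoch_labels is None:
        epoch_labels = [
            e.label
            for e in schedule.epochs(matrix.t_end)
            if e.start_s >= matrix.bin_start_times[0] - 1e-9 and e.end_s <= matrix.t_end + 1e-9
        ]
    rows = [
        summarize_epoch(matrix, schedule, label, larva, zero_threshold)
        for label in epoch_labels
        for larva in matrix.larva_ids
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def heat_shock_sleep_change(
    summaries: pd.DataFrame,
    pre_night: str,
    post_night: str,
    grouping: PlateMap | Mapping[str, str],
) -> pd.DataFrame:
    """Per-larva sleep change after heat-shock induction, as a percentage.

    For each larva: 100 x (sleep on ``post_night``) / (mean sleep on
    ``pre_night`` over all larvae of the same genotype).  100% means no
    change; 40% means sleep was reduced to 40% of the pre-induction level.
    """
    needed = {"larva_id", "epoch", "sleep"}
    if not needed.issubset(summaries.columns):
        raise AnalysisError(f"summary table needs columns {sorted(needed)}")
    pre = summaries[summaries["epoch"] == pre_night].set_index("larva_id")["sleep"]
    post = summaries[summaries["epoch"] == post_night].set_index("larva_id")["sleep"]
    missing = post.index.difference(pre.index).tolist() + pre.index.difference(post.index).tolist()
    if missing:
        raise AnalysisError(f"larvae missing one of the two nights: {missing[:5]}")
    if isinstance(grouping, PlateMap):
        genotype = grouping.genotype_map(list(post.index))
    else:
        genotype = pd.Series({k: grouping[k] for k in post.index}, name="genotype")
    genotype.index = post.index
    pre_mean = pre.groupby(genotype).mean()
    zero = pre_mean[pre_mean == 0].index.tolist()
    if zero:
        raise AnalysisError(
            f"genotype(s) with zero mean pre-night sleep, ratio undefined: {zero}"
        )
    pct = 100.0 * post / genotype.map(pre_mean)
    return pd.DataFrame(
        {
            "larva_id": post.index,
            "genotype": genotype.values,
            "pre_sleep": pre.loc[post.index].values,
            "post_sleep": post.values,
            "sleep_change_pct": pct.values,
        }
    ).reset_index(drop=True)
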