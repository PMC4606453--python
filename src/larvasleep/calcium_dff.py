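"""Stimulus-locked ΔF/F₀ analysis for single-neuron calcium-imaging trials.

Each trial is a fluorescence time series around one stimulation: baseline
F₀ is the mean of the 10 frames immediately preceding the stimulation
marker and F the mean of the 10 frames after it, giving

    ΔF/F₀ = (F - F₀) / F₀   (reported in percent).

Trials (typically 8 stimulation/imaging cycles per neuron at 4 Hz) are
aggregated to per-neuron and per-condition means ± s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

__all__ = [
    "CalciumTrial",
    "DffResult",
    "dff_trial",
    "aggregate_dff",
    "read_calcium_table",
    "write_calcium_table",
]


@dataclass(frozen=True)
class CalciumTrial:
    """One stimulation/imaging cycle for one neuron.

    ``frames`` holds raw fluorescence values (arbitrary units, > 0) and
    ``marker_index`` the frame index of stimulation: frames before it are
    pre-stimulation baseline, frames from it onward are post-stimulation.
    """

    neuron_id: str
    condition: str  # e.g. "chr2" vs "control"
    trial_index: int
    frames: np.ndarray
    marker_index: int
    frame_rate_hz: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame rate must be positive")
        if not 0 < self.marker_index < self.frames.size:
            raise ValidationError("marker index must lie strictly inside the trial")


@dataclass(frozen=True)
class DffResult:
    """ΔF/F₀ aggregate with the trial count behind each mean."""

    table: pd.DataFrame  # columns: group, mean_dff_pct, sem_dff_pct, n_trials


def dff_trial(trial: CalciumTrial, n_baseline: int = 10, n_post: int = 10) -> float:
    """Percent ΔF/F₀ for one trial from 10-frame pre/post window means."""
    if trial.marker_index < n_baseline:
        raise AnalysisError(
            f"trial {trial.neuron_id}/{trial.trial_index}: only {trial.marker_index} "
            f"frames before the marker, need {n_baseline}"
        )
    if trial.frames.size - trial.marker_index < n_post:
        raise AnalysisError(
            f"trial {trial.neuron_id}/{trial.trial_index}: only "
            f"{trial.frames.size - trial.marker_index} frames after the marker, need {n_post}"
        )
    f0 = float(trial.frames[trial.marker_index - n_baseline : trial.marker_index].mean())
    f = float(trial.frames[trial.marker_index : trial.marker_index + n_post].mean())
    if f0 <= 0:
        raise AnalysisError(f"non-positive baseline fluorescence F0={f0:g}")
    return 100.0 * (f - f0) / f0


def aggregate_dff(
    trials: Sequence[CalciumTrial],
    by: str = "condition",
    n_baseline: int = 10,
    n_post: int = 10,
) -> DffResult:
    """Mean ± s.e.m. ΔF/F₀ per neuron or per condition.

    ``by`` is ``"neuron"`` or ``"condition"``; n is the number of trials
    entering each mean, and s.e.m. = sd / sqrt(n) with n-1 ddof.  Every
    group needs at least 2 trials for a defined s.e.m.
    """
    if by not in ("neuron", "condition"):
        raise ValueError("by must be 'neuron' or 'condition'")
    if not trials:
        raise AnalysisError("no trials to aggregate")
    key = (lambda t: t.neuron_id) if by == "neuron" else (lambda t: t.condition)
    df = pd.DataFrame(
        {
            "group": [key(t) for t in trials],
            "dff_pct": [dff_trial(t, n_baseline, n_post) for t in trials],
        }
    )
    counts = df.groupby("group")["dff_pct"].size()
    small = counts[counts < 2].index.tolist()
    if small:
        raise AnalysisError(f"group(s) with < 2 trials, s.e.m. undefined: {small}")
    agg = df.groupby("group")["dff_pct"].agg(
        mean_dff_pct="mean", sem_dff_pct=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n_trials="size"
    )
    return DffResult(table=agg.reset_index())


_CAL_COLS = ["neuron", "condition", "trial", "frame", "value", "marker_index", "frame_rate_hz"]


def read_calcium_table(path: str | Path) -> list[CalciumTrial]:
    """Read per-trial fluorescence traces from the canonical long format."""
    df = pd.read_csv(path)
    missing = [c for c in _CAL_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: calcium table missing column(s) {missing}")
    trials = []
    for (neuron, cond, trial), g in df.groupby(["neuron", "condition", "trial"], sort=True):
        g = g.sort_values("frame")
        if not (g["frame"].to_numpy() == np.arange(len(g))).all():
            raise ValidationError(f"{path}: non-contiguous frames for trial {neuron}/{trial}")
        trials.append(
            CalciumTrial(
                neuron_id=str(neuron),
                condition=str(cond),
                trial_index=int(trial),
                frames=g["value"].to_numpy(dtype=float),
                marker_index=int(g["marker_index"].iloc[0]),
                frame_rate_hz=float(g["frame_rate_hz"].iloc[0]),
            )
        )
    return trials


def write_calcium_table(trials: Sequence[CalciumTrial], path: str | Path) -> None:
    parts = []
    for t in trials:
        parts.append(
            pd.DataFrame(
                {
                    "neuron": t.neuron_id,
                    "condition": t.condition,
                    "trial": t.trial_index,
                    "frame": np.arange(t.frames.size),
                    "value": t.frames,
                    "marker_index": t.marker_index,
                    "frame_rate_hz": t.frame_rate_hz,
                }
            )
        )
    pd.concat(parts, ignore_index=True)[_CAL_COLS].to_csv(path, index=False)
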