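"""Synthetic behavioral and imaging data with each assay's assumed structure.

The study's raw recordings are not redistributable, so every pipeline stage
is exercised on generated data whose ground truth is planted:

* sleep/wake — an alternating-renewal (semi-Markov) process at 1-min
  resolution: wake and sleep bout lengths are geometric with day/night-
  dependent means, waking minutes receive positive activity draws and
  sleep minutes are exactly zero.  This is the simplest process whose
  summaries reproduce the assay's measures; it is not a claim about fish.
* tap assay — responses Bernoulli with probability given by the
  variable-slope logistic in log power, OR-composed with spontaneous
  background movement at rate b in any window.
* optogenetic trials — 10-s-binned activity with onset/offset bursts and a
  ramp-to-peak light response followed by a mild decline (a perfectly flat
  plateau would leave the time-to-maximum unidentifiable under noise).
* calcium trials — baseline fluorescence plus a stimulus-locked
  exponentially decaying transient; the amplitude parameter is defined as
  the expected ΔF/F over the standard 10-frame post window, so planted and
  recovered amplitudes are directly comparable.

Every generator is a pure function of (params, seed): same inputs, same
output, no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .arousal_assay import TapResponseTable, logistic_response
from .calcium_dff import CalciumTrial
from .io_tracking import (
    ActivityMatrix,
    EpochSchedule,
    PlateMap,
    StimulusEvent,
    StimulusLog,
)

__all__ = [
    "EpochSleepParams",
    "SleepSimParams",
    "TapSimParams",
    "OptoGenotypeParams",
    "OptoSimParams",
    "CalciumSimParams",
    "simulate_sleep_wake",
    "simulate_tap_experiment",
    "simulate_tap_tables",
    "simulate_opto_night",
    "simulate_calcium",
    "default_tap_powers",
]


def _larva_ids(n: int, prefix: str = "L") -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1:03d}" for i in range(n))


# ---------------------------------------------------------------------------
# sleep/wake


@dataclass(frozen=True)
class EpochSleepParams:
    """Bout structure for one epoch type (all means in minutes)."""

    mean_wake_bout_min: float
    mean_sleep_bout_min: float
    waking_activity_mean_s: float  # seconds-active per waking minute
    waking_activity_shape: float = 4.0  # gamma shape; larger = less dispersed

    def __post_init__(self) -> None:
        if min(self.mean_wake_bout_min, self.mean_sleep_bout_min) <= 0:
            raise ValidationError("bout-length means must be positive")
        if not 0 < self.waking_activity_mean_s <= 60:
            raise ValidationError("waking activity mean must be in (0, 60] s/min")


@dataclass(frozen=True)
class SleepSimParams:
    """Alternating-renewal sleep/wake simulation over a light/dark schedule.

    Defaults are order-of-magnitude choices for larval zebrafish: long
    active wake bouts and rare short sleep bouts by day; shorter wake
    bouts, longer sleep bouts and lower waking activity by night.
    """

    day: EpochSleepParams = EpochSleepParams(40.0, 1.5, 10.0)
    night: EpochSleepParams = EpochSleepParams(8.0, 4.0, 6.0)
    n_larvae: int = 96
    duration_h: float = 24.0
    schedule: EpochSchedule = field(default_factory=EpochSchedule)
    overrides: Mapping[str, EpochSleepParams] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae < 1 or self.duration_h <= 0:
            raise ValidationError("need n_larvae >= 1 and positive duration")


def simulate_sleep_wake(params: SleepSimParams, seed: int | None = None) -> ActivityMatrix:
    """Minute-binned activity from alternating geometric wake/sleep bouts.

    Bout lengths are geometric (minute-discretized, minimum 1 min) with the
    mean of the epoch in force at bout onset; waking minutes get gamma
    activity draws clipped to (0, 60] and sleep minutes are exactly 0.
    Specific epochs can be overridden by label (e.g. to plant a
    post-heat-shock sleep change on one night).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_min = int(round(params.duration_h * 60))
    # per-minute epoch parameters
    epoch_of_min = np.empty(n_min, dtype=object)
    for ep in params.schedule.epochs(n_min * 60.0):
        i0 = max(0, int(np.ceil(ep.start_s / 60.0)))
        i1 = min(n_min, int(np.ceil(ep.end_s / 60.0)))
        if ep.label in params.overrides:
            p = params.overrides[ep.label]
        else:
            p = params.day if ep.label.startswith("day") else params.night
        epoch_of_min[i0:i1] = p
    values = np.zeros((params.n_larvae, n_min))
    for i in range(params.n_larvae):
        t = 0
        awake = bool(rng.integers(0, 2))
        while t < n_min:
            p: EpochSleepParams = epoch_of_min[t]
            mean = p.mean_wake_bout_min if awake else p.mean_sleep_bout_min
            length = int(rng.geometric(min(1.0, 1.0 / mean)))
            end = min(t + length, n_min)
            if awake:
                k = p.waking_activity_shape
                draws = rng.gamma(k, p.waking_activity_mean_s / k, size=end - t)
                values[i, t:end] = np.clip(draws, 0.5, 60.0)
            t = end
            awake = not awake
    return ActivityMatrix(
        larva_ids=_larva_ids(params.n_larvae),
        bin_start_times=np.arange(n_min) * 60.0,
        bin_width=60.0,
        values=values,
    )


# ---------------------------------------------------------------------------
# tap (arousal threshold) assay


def default_tap_powers(n: int = 14, lo: float = 1.0, hi: float = 36.31) -> np.ndarray:
    """Log-spaced tap power settings spanning the range used in the assay."""
    return np.round(np.logspace(np.log10(lo), np.log10(hi), n), 2)


@dataclass(frozen=True)
class TapSimParams:
    """Generative model of the tap assay (defaults match the study design:
    14 powers spanning 1-36.31, 30 trials per power, 1-min inter-trial
    interval, ~90 larvae per group)."""

    etp50: float = 3.1
    hill_slope: float = 2.0
    top: float = 0.34
    bottom: float = 0.0
    background: float = 0.05
    powers: tuple[float, ...] = tuple(default_tap_powers())
    trials_per_power: int = 30
    n_larvae: int = 90
    iti_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bottom <= self.top <= 1:
            raise ValidationError("need 0 <= bottom <= top <= 1")
        if not 0 <= self.background <= 1:
            raise ValidationError("background probability must be in [0, 1]")
        if self.etp50 <= 0:
            raise ValidationError("etp50 must be positive")
        if min(self.powers) <= 0:
            raise ValidationError("powers must be positive")


def _tap_schedule(params: TapSimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Tap times and powers: each power repeated trials_per_power times, in
    random order, one tap per inter-trial interval."""
    powers = np.repeat(np.asarray(params.powers, dtype=float), params.trials_per_power)
    powers = rng.permutation(powers)
    t0 = 30.0  # leave room for the first 5-s pre-window
    times = t0 + np.arange(powers.size) * params.iti_s
    return times, powers


def simulate_tap_experiment(
    params: TapSimParams, seed: int | None = None
) -> tuple[ActivityMatrix, StimulusLog]:
    """Full tap experiment: 1-s-binned activity traces plus a stimulus log.

    In the 5-s window after each tap a larva moves if it responds to the
    stimulus (Bernoulli with the logistic probability at that power) OR
    moves spontaneously (Bernoulli ``background``); in the 5-s pre-window
    movement is spontaneous only.  Movement outside these windows is not
    simulated — it does not enter any assay statistic.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    times, powers = _tap_schedule(params, rng)
    n_ev = times.size
    n_bins = int(times[-1] + params.iti_s)
    values = np.zeros((params.n_larvae, n_bins))
    r = logistic_response(
        powers, params.bottom, params.top, np.log10(params.etp50), params.hill_slope
    )
    responds = rng.random((params.n_larvae, n_ev)) < r[None, :]
    bg_post = rng.random((params.n_larvae, n_ev)) < params.background
    bg_pre = rng.random((params.n_larvae, n_ev)) < params.background
    post = responds | bg_post
    pre_cols = (times - 3.0).astype(int)  # inside [t-5, t)
    post_cols = (times + 2.0).astype(int)  # inside [t, t+5)
    li, ev = np.nonzero(bg_pre)
    values[li, pre_cols[ev]] = 1.0
    li, ev = np.nonzero(post)
    values[li, post_cols[ev]] = 1.0
    matrix = ActivityMatrix(
        larva_ids=_larva_ids(params.n_larvae),
        bin_start_times=np.arange(n_bins, dtype=float),
        bin_width=1.0,
        values=values,
    )
    log = StimulusLog(
        tuple(StimulusEvent(float(t), "tap", float(p)) for t, p in zip(times, powers))
    )
    return matrix, log


def simulate_tap_tables(params: TapSimParams, seed: int | None = None) -> TapResponseTable:
    """Corrected response table sampled at the aggregate (binomial) level.

    Statistically equivalent to running :func:`simulate_tap_experiment`
    through response scoring and background correction, but without
    materializing second-resolution traces — the right tool for
    calibration studies needing hundreds of replicates.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    powers = np.sort(np.asarray(params.powers, dtype=float))
    n_per_power = params.trials_per_power * params.n_larvae
    r = logistic_response(
        powers, params.bottom, params.top, np.log10(params.etp50), params.hill_slope
    )
    p_move = r + params.background - r * params.background  # response OR background
    raw = rng.binomial(n_per_power, p_move) / n_per_power
    n_bg = params.trials_per_power * len(powers) * params.n_larvae
    b_hat = rng.binomial(n_bg, params.background) / n_bg
    df = pd.DataFrame(
        {
            "power": powers,
            "n_trials": n_per_power,
            "raw_response": raw,
            "corrected_response": raw - b_hat,
        }
    )
    return TapResponseTable(table=df, background=float(b_hat))


# ---------------------------------------------------------------------------
# optogenetic night


@dataclass(frozen=True)
class OptoGenotypeParams:
    """Light-response profile for one genotype.

    Rates are expected seconds-active per 10-s bin.  The response ramps
    from baseline to ``peak_rate`` over ``rise_time_min`` and then
    declines linearly to ``end_fraction * peak_rate`` at light offset,
    making the maximum (and hence T_A) identifiable.
    """

    n_larvae: int = 48
    baseline_rate: float = 1.0
    peak_rate: float = 2.0
    rise_time_min: float = 12.0
    end_fraction: float = 0.9
    burst_rate: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_rate <= 10 or not 0 < self.peak_rate <= 10:
            raise ValidationError("rates must be in (0, 10] s per 10-s bin")
        if not 0 < self.end_fraction <= 1:
            raise ValidationError("end_fraction must be in (0, 1]")


@dataclass(frozen=True)
class OptoSimParams:
    """One night of light-stimulation trials for several genotypes."""

    genotypes: Mapping[str, OptoGenotypeParams] = field(
        default_factory=lambda: {
            "wt": OptoGenotypeParams(),
            "chr2": OptoGenotypeParams(peak_rate=3.0),
        }
    )
    n_trials: int = 3
    iti_s: float = 10800.0  # 3 h between light onsets
    light_s: float = 1800.0  # 30-min illumination
    burst_s: float = 30.0
    bin_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iti_s < self.light_s + 3600:
            raise ValidationError("inter-trial interval too short for disjoint windows")


def _opto_rate_profile(g: OptoGenotypeParams, p: OptoSimParams, n_bins: int, onsets: np.ndarray) -> np.ndarray:
    """Expected seconds-active per bin over the whole night for one genotype."""
    width = p.bin_width
    t = np.arange(n_bins) * width  # bin start times
    rate = np.full(n_bins, g.baseline_rate)
    rise_s = max(g.rise_time_min * 60.0, p.burst_s)
    for onset in onsets:
        rel = t - onset
        in_burst = (rel >= 0) & (rel < p.burst_s)
        in_rise = (rel >= p.burst_s) & (rel < rise_s)
        in_decay = (rel >= rise_s) & (rel < p.light_s)
        off_burst = (rel >= p.light_s) & (rel < p.light_s + p.burst_s)
        rate[in_burst] = g.burst_rate
        if rise_s > p.burst_s:
            frac = (rel[in_rise] - p.burst_s) / (rise_s - p.burst_s)
            rate[in_rise] = g.baseline_rate + (g.peak_rate - g.baseline_rate) * frac
        frac = (rel[in_decay] - rise_s) / (p.light_s - rise_s)
        rate[in_decay] = g.peak_rate * (1.0 - (1.0 - g.end_fraction) * frac)
        rate[off_burst] = g.burst_rate
    return rate


def simulate_opto_night(
    params: OptoSimParams, seed: int | None = None
) -> tuple[ActivityMatrix, StimulusLog, PlateMap]:
    """10-s-binned activity for one night of light trials, plus log and map.

    Per-bin activity is binomial(bin width, rate/bin width) seconds, so
    values always respect the activity bounds.  Light onsets occur every
    ``iti_s`` starting 30 min into the night.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    width = params.bin_width
    onsets = 1800.0 + np.arange(params.n_trials) * params.iti_s
    duration = onsets[-1] + params.light_s + 600.0
    n_bins = int(np.ceil(duration / width))
    values = []
    ids: list[str] = []
    geno_rows = []
    for gi, (name, g) in enumerate(params.genotypes.items()):
        rate = _opto_rate_profile(g, params, n_bins, onsets)
        counts = rng.binomial(int(width), np.clip(rate / width, 0, 1), size=(g.n_larvae, n_bins))
        values.append(counts.astype(float))
        gids = _larva_ids(g.n_larvae, prefix=f"G{gi}L")
        ids.extend(gids)
        geno_rows += [
            {"well": f"W{len(geno_rows) + j + 1:03d}", "larva_id": lid, "genotype": name}
            for j, lid in enumerate(gids)
        ]
    events = []
    for onset in onsets:
        events.append(StimulusEvent(float(onset), "light_on", "blue"))
        events.append(StimulusEvent(float(onset + params.light_s), "light_off", "blue"))
    matrix = ActivityMatrix(
        larva_ids=tuple(ids),
        bin_start_times=np.arange(n_bins) * width,
        bin_width=width,
        values=np.vstack(values),
    )
    return matrix, StimulusLog(tuple(events)), PlateMap.from_records(geno_rows)


# ---------------------------------------------------------------------------
# calcium imaging


@dataclass(frozen=True)
class CalciumSimParams:
    """Stimulus-locked GCaMP-like trial generator.

    ``amplitude_pct`` is the expected ΔF/F (percent) measured over the
    standard 10-frame post-stimulation window; the underlying exponential
    transient (decay constant ``tau_s``) is scaled so that this window
    mean equals the planted value.  Noise is i.i.d. Gaussian per frame
    with sd ``noise_sd_pct`` percent of baseline.
    """

    f0: float = 100.0
    amplitude_pct: float = 30.0
    tau_s: float = 4.0
    noise_sd_pct: float = 2.0
    n_trials: int = 8
    n_neurons: int = 1
    frame_rate_hz: float = 4.0
    imaging_s: float = 30.0
    pre_s: float = 10.0
    condition: str = "chr2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.tau_s <= 0 or self.frame_rate_hz <= 0:
            raise ValidationError("f0, tau_s and frame rate must be positive")
        if self.n_trials < 1:
            raise ValidationError("need at least one trial")


def simulate_calcium(params: CalciumSimParams, seed: int | None = None) -> list[CalciumTrial]:
    """Generate per-trial fluorescence traces for ``n_neurons`` neurons."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_pre = int(round(params.pre_s * params.frame_rate_hz))
    n_post = int(round(params.imaging_s * params.frame_rate_hz))
    t_post = np.arange(n_post) / params.frame_rate_hz
    window = np.exp(-t_post[:10] / params.tau_s)
    scale = (params.amplitude_pct / 100.0) / window.mean()  # calibrate 10-frame window mean
    transient = params.f0 * scale * np.exp(-t_post / params.tau_s)
    sd = params.f0 * params.noise_sd_pct / 100.0
    trials = []
    for n in range(params.n_neurons):
        for k in range(params.n_trials):
            frames = np.concatenate(
                [np.full(n_pre, params.f0), params.f0 + transient]
            ) + rng.normal(scale=sd, size=n_pre + n_post)
            trials.append(
                CalciumTrial(
                    neuron_id=f"N{n + 1:02d}",
                    condition=params.condition,
                    trial_index=k,
                    frames=frames,
                    marker_index=n_pre,
                    frame_rate_hz=params.frame_rate_hz,
                )
            )
    return trials
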