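"""Tabular I/O and experiment metadata for videotracker behavioral data.

The pipeline's universal input is a dense per-larva, per-time-bin table of
seconds-active exported by a videotracking system in quantization mode.  This
module defines the validated in-memory containers (:class:`ActivityMatrix`,
:class:`PlateMap`, :class:`EpochSchedule`, :class:`StimulusLog`) and the
delimited-text readers/writers that move them to and from disk.

Time is stored as seconds since experiment start throughout; clock-time
anchoring (lights on/off, day/night epoch labels) comes only from
:class:`EpochSchedule`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, StructuralError, ValidationError

__all__ = [
    "ActivityMatrix",
    "TableDialect",
    "PlateMap",
    "EpochSchedule",
    "Epoch",
    "StimulusEvent",
    "StimulusLog",
    "read_activity_table",
    "write_activity_table",
    "read_plate_map",
    "write_plate_map",
    "read_stimulus_log",
    "write_stimulus_log",
    "write_summary",
    "read_summary",
]

# Tap driver hardware range: 4095 settings spanning 0.01-40.95.
TAP_POWER_MIN = 0.01
TAP_POWER_MAX = 40.95

EVENT_KINDS = frozenset(
    {"tap", "light_on", "light_off", "heat_shock_start", "heat_shock_end", "chr2_pulse"}
)


@dataclass(frozen=True)
class ActivityMatrix:
    """Dense per-larva, per-bin seconds-active time series.

    Parameters
    ----------
    larva_ids
        One identifier per row of ``values``.
    bin_start_times
        Bin start times in seconds since experiment start; strictly
        increasing with constant spacing equal to ``bin_width``.
    bin_width
        Bin width in seconds (60 for the sleep assay, 10 for the
        optogenetic assay, 1 for tap-response scoring).
    values
        Array of shape ``(n_larvae, n_bins)``; each cell is the number of
        seconds the larva was in motion during that bin, in
        ``[0, bin_width]``.
    """

    larva_ids: tuple[str, ...]
    bin_start_times: np.ndarray
    bin_width: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "larva_ids", tuple(str(x) for x in self.larva_ids))
        starts = np.asarray(self.bin_start_times, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "bin_start_times", starts)
        object.__setattr__(self, "values", vals)
        if len(set(self.larva_ids)) != len(self.larva_ids):
            raise ValidationError("duplicate larva ids")
        if vals.shape != (len(self.larva_ids), starts.size):
            raise StructuralError(
                f"values shape {vals.shape} does not match "
                f"{len(self.larva_ids)} larvae x {starts.size} bins"
            )
        if self.bin_width <= 0:
            raise ValidationError(f"bin_width must be positive, got {self.bin_width}")
        if starts.size > 1:
            diffs = np.diff(starts)
            bad = np.flatnonzero(~np.isclose(diffs, self.bin_width, rtol=0, atol=1e-9))
            if bad.size:
                i = int(bad[0])
                raise StructuralError(
                    f"non-constant bin spacing: gap of {diffs[i]:g} s before bin "
                    f"starting at t={starts[i + 1]:g} s (expected {self.bin_width:g} s)"
                )
        if vals.size:
            out = np.argwhere((vals < 0) | (vals > self.bin_width + 1e-9))
            if out.size:
                cells = ", ".join(
                    f"({self.larva_ids[i]}, t={starts[j]:g}s)={vals[i, j]:g}"
                    for i, j in out[:10]
                )
                raise ValidationError(
                    f"{out.shape[0]} activity value(s) outside [0, {self.bin_width:g}]: {cells}"
                )

    @property
    def n_larvae(self) -> int:
        return len(self.larva_ids)

    @property
    def n_bins(self) -> int:
        return int(self.bin_start_times.size)

    @property
    def t_end(self) -> float:
        """End time of the final bin (seconds since experiment start)."""
        if self.n_bins == 0:
            return 0.0
        return float(self.bin_start_times[-1] + self.bin_width)

    def row(self, larva_id: str) -> np.ndarray:
        try:
            i = self.larva_ids.index(str(larva_id))
        except ValueError:
            raise KeyError(f"unknown larva id {larva_id!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns (larva, bin_start, value)."""
        n_l, n_b = self.values.shape
        return pd.DataFrame(
            {
                "larva": np.repeat(self.larva_ids, n_b),
                "bin_start": np.tile(self.bin_start_times, n_l),
                "value": self.values.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:  # value equality for round-trip tests
        if not isinstance(other, ActivityMatrix):
            return NotImplemented
        return (
            self.larva_ids == other.larva_ids
            and np.isclose(self.bin_width, other.bin_width)
            and np.allclose(self.bin_start_times, other.bin_start_times)
            and np.allclose(self.values, other.values)
        )


@dataclass(frozen=True)
class TableDialect:
    """Column mapping + delimiter for a vendor's long-format activity export."""

    larva: str = "larva"
    time: str = "bin_start"
    value: str = "value"
    delimiter: str = ","


def read_activity_table(path: str | Path, dialect: TableDialect | None = None) -> ActivityMatrix:
    """Read a long-format activity table into a validated :class:`ActivityMatrix`.

    Rows may appear in any order; they are sorted by time.  Bin width is
    inferred from the time column and verified constant.  Missing bins are an
    error (the tracker emits dense bins), as are duplicated (larva, bin)
    pairs and values outside ``[0, bin_width]``.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter)
    missing = [c for c in (dialect.larva, dialect.time, dialect.value) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    df = df.rename(
        columns={dialect.larva: "larva", dialect.time: "bin_start", dialect.value: "value"}
    )
    if df.duplicated(["larva", "bin_start"]).any():
        dup = df[df.duplicated(["larva", "bin_start"])].iloc[0]
        raise StructuralError(
            f"{path}: duplicated (larva, bin) pair ({dup['larva']}, t={dup['bin_start']})"
        )
    wide = df.pivot(index="larva", columns="bin_start", values="value")
    if wide.isna().any().any():
        larva = wide.index[wide.isna().any(axis=1)][0]
        raise StructuralError(f"{path}: larva {larva} is missing bins (dense bins required)")
    starts = wide.columns.to_numpy(dtype=float)
    order = np.argsort(starts)
    starts = starts[order]
    values = wide.to_numpy(dtype=float)[:, order]
    if starts.size < 2:
        raise StructuralError(f"{path}: at least two bins required to infer bin width")
    width = float(np.diff(starts)[0])
    return ActivityMatrix(
        larva_ids=tuple(str(x) for x in wide.index),
        bin_start_times=starts,
        bin_width=width,
        values=values,
    )


def write_activity_table(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write an :class:`ActivityMatrix` in the canonical long format."""
    matrix.to_frame().to_csv(path, index=False)


def _normalize_genotype(s: str) -> str:
    return " ".join(str(s).split()).casefold()


@dataclass(frozen=True)
class PlateMap:
    """Well -> (larva, genotype, treatment, transgene flags, include) mapping.

    Genotype and treatment labels are normalized (whitespace-collapsed,
    case-folded) so that e.g. ``"DBH-/-"`` and ``"dbh-/-"`` group together.
    """

    table: pd.DataFrame  # index well; columns larva_id, genotype, treatment, transgenes, include

    def __post_init__(self) -> None:
        df = self.table
        for col in ("larva_id", "genotype"):
            if col not in df.columns:
                raise FormatError(f"plate map missing column {col!r}")
        if df.index.duplicated().any():
            well = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate well {well!r} in plate map")
        if df["larva_id"].duplicated().any():
            lid = df.loc[df["larva_id"].duplicated(), "larva_id"].iloc[0]
            raise ValidationError(f"larva id {lid!r} mapped from multiple wells")

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping[str, object]],
    ) -> "PlateMap":
        df = pd.DataFrame(list(records))
        if "well" not in df.columns:
            raise FormatError("plate map records need a 'well' field")
        df = df.set_index("well")
        if "treatment" not in df.columns:
            df["treatment"] = "none"
        if "transgenes" not in df.columns:
            df["transgenes"] = ""
        if "include" not in df.columns:
            df["include"] = True
        df["larva_id"] = df["larva_id"].astype(str)
        df["genotype"] = df["genotype"].map(_normalize_genotype)
        df["treatment"] = df["treatment"].map(_normalize_genotype)
        df["include"] = df["include"].astype(bool)
        return cls(df[["larva_id", "genotype", "treatment", "transgenes", "include"]])

    def __len__(self) -> int:
        return len(self.table)

    def genotype_of(self, larva_id: str) -> str:
        sel = self.table[self.table["larva_id"] == str(larva_id)]
        if len(sel) != 1:
            raise ValidationError(
                f"larva id {larva_id!r} resolves to {len(sel)} plate-map rows (need exactly 1)"
            )
        return str(sel["genotype"].iloc[0])

    def genotype_map(self, larva_ids: Sequence[str]) -> pd.Series:
        """Genotype per larva id, erroring on unmapped or ambiguous ids."""
        lut = self.table.set_index("larva_id")["genotype"]
        missing = [x for x in larva_ids if str(x) not in lut.index]
        if missing:
            raise ValidationError(f"larva id(s) not in plate map: {missing[:5]}")
        return lut.loc[[str(x) for x in larva_ids]]


def read_plate_map(path: str | Path, delimiter: str = ",") -> PlateMap:
    df = pd.read_csv(path, sep=delimiter)
    needed = {"well", "genotype"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: plate map needs columns {sorted(needed)}")
    if "larva_id" not in df.columns:
        df["larva_id"] = df["well"]
    return PlateMap.from_records(df.to_dict("records"))


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    plate_map.table.reset_index().rename(columns={"index": "well"}).to_csv(path, index=False)


def _parse_clock(hhmm: str) -> float:
    """'HH:MM' -> seconds past midnight."""
    try:
        h, m = hhmm.split(":")
        sec = int(h) * 3600 + int(m) * 60
    except (ValueError, AttributeError):
        raise FormatError(f"clock time must be 'HH:MM', got {hhmm!r}") from None
    if not 0 <= sec < 86400:
        raise ValidationError(f"clock time out of range: {hhmm!r}")
    return float(sec)


@dataclass(frozen=True)
class Epoch:
    label: str  # e.g. "day5" or "night5"
    start_s: float  # seconds since experiment start
    end_s: float

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def length_min(self) -> float:
        return self.length_s / 60.0


@dataclass(frozen=True)
class EpochSchedule:
    """Light/dark schedule anchoring experiment time to day/night epochs.

    Default is the standard larval-zebrafish 14 h:10 h LD cycle with lights
    on at 9 am and off at 11 pm.  ``start_day`` gives the developmental day
    (dpf) at the experiment start; epoch "day N" runs lights-on to
    lights-off of day N, "night N" runs lights-off of day N to the next
    lights-on.
    """

    lights_on: str = "09:00"
    lights_off: str = "23:00"
    experiment_start: str = "09:00"
    start_day: int = 4

    def __post_init__(self) -> None:
        on = _parse_clock(self.lights_on)
        off = _parse_clock(self.lights_off)
        if on == off:
            raise ValidationError("lights_on and lights_off must differ")
        _parse_clock(self.experiment_start)

    def epochs(self, t_end_s: float, t_start_s: float = 0.0) -> list[Epoch]:
        """All day/night epochs overlapping [t_start_s, t_end_s)."""
        on = _parse_clock(self.lights_on)
        off = _parse_clock(self.lights_off)
        exp0 = _parse_clock(self.experiment_start)
        day_len = (off - on) % 86400
        out: list[Epoch] = []
        # walk whole days from one day before start to cover partial overlap
        d = -1
        while True:
            day_offset = d * 86400.0
            day_n = self.start_day + d
            day_start = day_offset + on - exp0
            day_end = day_start + day_len
            night_end = day_start + 86400.0
            if day_start >= t_end_s:
                break
            if day_end > t_start_s:
                out.append(Epoch(f"day{day_n}", day_start, day_end))
            if night_end > t_start_s and day_end < t_end_s:
                out.append(Epoch(f"night{day_n}", day_end, night_end))
            d += 1
        return [e for e in out if e.end_s > t_start_s and e.start_s < t_end_s]

    def epoch(self, label: str, horizon_days: int = 60) -> Epoch:
        """Look up an epoch by label (e.g. ``"night5"``)."""
        for e in self.epochs(horizon_days * 86400.0, -86400.0):
            if e.label == label:
                return e
        raise KeyError(f"no epoch labelled {label!r} within {horizon_days} days")


@dataclass(frozen=True)
class StimulusEvent:
    time_s: float
    kind: str  # tap | light_on | light_off | heat_shock_start | heat_shock_end | chr2_pulse
    payload: float | str | None = None  # tap power setting, or light color

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "tap":
            p = float(self.payload)  # type: ignore[arg-type]
            if not TAP_POWER_MIN <= p <= TAP_POWER_MAX:
                raise ValidationError(
                    f"tap power {p} outside driver range [{TAP_POWER_MIN}, {TAP_POWER_MAX}]"
                )


@dataclass(frozen=True)
class StimulusLog:
    """Time-ordered stimulus event list (taps, light transitions, heat shock)."""

    events: tuple[StimulusEvent, ...]

    def __post_init__(self) -> None:
        evs = tuple(self.events)
        object.__setattr__(self, "events", evs)
        times = [e.time_s for e in evs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("stimulus event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "payload": [e.payload for e in self.events],
            }
        )


def read_stimulus_log(path: str | Path, delimiter: str = ",") -> StimulusLog:
    df = pd.read_csv(path, sep=delimiter)
    needed = {"time_s", "kind"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: stimulus log needs columns {sorted(needed)}")
    events = []
    for rec in df.to_dict("records"):
        payload = rec.get("payload")
        if payload is not None and pd.isna(payload):
            payload = None
        elif rec["kind"] == "tap":
            payload = float(payload)
        events.append(StimulusEvent(float(rec["time_s"]), str(rec["kind"]), payload))
    return StimulusLog(tuple(events))


def write_stimulus_log(log: StimulusLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)


def write_summary(rows: Sequence[object] | pd.DataFrame, path: str | Path) -> None:
    """Write result records (dataclasses or a DataFrame) as delimited text.

    Column order is deterministic (dataclass field order, or the frame's own
    order) and floats are serialized at full shortest-round-trip precision,
    so ``read_summary(write_summary(x)) == x``.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and dataclasses.is_dataclass(rows[0]):
            cols = [f.name for f in dataclasses.fields(rows[0])]
            df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=cols)
        else:
            df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
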