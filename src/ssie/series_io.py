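"""Daily greenhouse series: data model, CSV I/O and day-to-cycle aggregation.

The observational unit is one calendar day of greenhouse records (solar
radiation, temperature, humidity, pressure and per-plant water consumption).
The plant-growth machinery runs on Cycles of Development (CD), the interval
between two successive phytomer appearances; with a stable phyllochron of two
days, consecutive day pairs are merged into one cycle record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date as _date
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ssie")

__all__ = [
    "DailyRecord",
    "CycleRecord",
    "SeriesError",
    "SchemaError",
    "DuplicateDateError",
    "RowParseError",
    "InconsistentMeasurementError",
    "water_consumption",
    "read_daily_series",
    "write_daily_series",
    "aggregate_to_cycles",
    "write_cycle_table",
]


class SeriesError(ValueError):
    """Base class for daily-series validation and I/O errors."""


class SchemaError(SeriesError):
    """A mandatory column is missing from the input file."""


class DuplicateDateError(SeriesError):
    """Two rows carry the same calendar date."""


class RowParseError(SeriesError):
    """A row holds an unparseable numeric value; carries the line number."""


class InconsistentMeasurementError(SeriesError):
    """Runoff exceeds irrigation, or an invalid station configuration."""


@dataclass(frozen=True)
class DailyRecord:
    """One day of greenhouse observations.

    ``w_c`` (per-plant water consumption, liters) may be ``None`` for
    forecast-only days where only meteorology is available.  Humidity fields
    are fractions in [0, 1]; radiation in W/m^2; temperature in Celsius;
    pressure in hPa.
    """

    date: _date
    e_avg: float
    e_max: Optional[float] = None
    t_avg: Optional[float] = None
    t_min: Optional[float] = None
    t_max: Optional[float] = None
    rh_avg: Optional[float] = None
    rh_min: Optional[float] = None
    rh_max: Optional[float] = None
    p_avg: Optional[float] = None
    w_c: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_avg) or self.e_avg < 0:
            raise SeriesError(f"{self.date}: e_avg must be finite and >= 0, got {self.e_avg}")
        if self.e_max is not None and self.e_max < self.e_avg:
            raise SeriesError(f"{self.date}: e_max ({self.e_max}) < e_avg ({self.e_avg})")
        for name in ("rh_avg", "rh_min", "rh_max"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise SeriesError(f"{self.date}: {name}={v} outside [0, 1]")
        if self.w_c is not None and self.w_c < 0:
            raise SeriesError(f"{self.date}: w_c must be >= 0, got {self.w_c}")
        if self.t_avg is not None:
            if self.t_min is not None and self.t_min > self.t_avg:
                raise SeriesError(f"{self.date}: t_min > t_avg")
            if self.t_max is not None and self.t_max < self.t_avg:
                raise SeriesError(f"{self.date}: t_max < t_avg")


@dataclass(frozen=True)
class CycleRecord:
    """Aggregation of ``phyllochron`` consecutive days into one development cycle."""

    cycle_index: int
    e_cd: float
    w_cd: Optional[float]
    day_span: tuple[_date, ...]

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise SeriesError(f"cycle_index must be >= 1, got {self.cycle_index}")


def water_consumption(v_irr: float, r_off: float, n_plants: int) -> float:
    """Per-plant water consumption of a station: (V_irr - R_off) / n.

    ``v_irr`` is the applied irrigation volume (L) and ``r_off`` the runoff
    collected until the next morning (L); ``n_plants`` plants share one slab.
    """
    if n_plants is None or int(n_plants) != n_plants or n_plants < 1:
        raise InconsistentMeasurementError(
            f"invalid station: n_plants must be a positive integer, got {n_plants}"
        )
    if r_off < 0 or v_irr < 0:
        raise InconsistentMeasurementError("volumes must be nonnegative")
    if r_off > v_irr:
        raise InconsistentMeasurementError(
            f"inconsistent measurement: runoff {r_off} L exceeds irrigation {v_irr} L"
        )
    return (v_irr - r_off) / n_plants


# Default column names; remappable through read_daily_series(schema=...).
_DEFAULT_SCHEMA = {
    "date": "date",
    "e_avg": "e_avg",
    "e_max": "e_max",
    "t_avg": "t_avg",
    "t_min": "t_min",
    "t_max": "t_max",
    "rh_avg": "rh_avg",
    "rh_min": "rh_min",
    "rh_max": "rh_max",
    "p_avg": "p_avg",
    "w_c": "w_c",
}
_MANDATORY = ("date", "e_avg")


def read_daily_series(path, schema: Optional[dict] = None) -> list[DailyRecord]:
    """Read a delimited daily-series file into sorted ``DailyRecord`` objects.

    The file must have a header row with at least a date column and an average
    solar-radiation column; a water-consumption column is optional (its absence
    flags a forecast-only series).  ``schema`` maps field names to column names
    for files with different headers.  Records are returned sorted by date;
    calendar gaps are reported through the package logger.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=None, engine="python")
    for fieldname in _MANDATORY:
        if colmap[fieldname] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[fieldname]!r} in {path}")
    has_wc = colmap["w_c"] in df.columns
    if not has_wc:
        logger.warning("%s has no %r column: forecast-only series", path, colmap["w_c"])

    try:
        dates = pd.to_datetime(df[colmap["date"]], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise RowParseError(f"unparseable date in {path}: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise DuplicateDateError(f"duplicate date {dup} in {path}")

    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        kwargs = {"date": dates.iloc[pos]}
        for fieldname, col in colmap.items():
            if fieldname == "date" or col not in df.columns:
                continue
            raw = row[col]
            if pd.isna(raw):
                kwargs[fieldname] = None
                continue
            try:
                kwargs[fieldname] = float(raw)
            except (TypeError, ValueError) as exc:
                # +2: header line plus 1-based numbering
                raise RowParseError(
                    f"line {pos + 2}: cannot parse {col}={raw!r} as a number"
                ) from exc
        records.append(DailyRecord(**kwargs))

    records.sort(key=lambda r: r.date)
    gaps = [
        (a.date, b.date)
        for a, b in zip(records, records[1:])
        if (b.date - a.date).days > 1
    ]
    if gaps:
        logger.warning("calendar gaps in %s: %s", path, gaps)
    return records


def write_daily_series(records: Sequence[DailyRecord], path) -> None:
    """Write records to CSV with the default column names (ISO dates)."""
    rows = []
    for r in records:
        rows.append({col: getattr(r, fieldname) for fieldname, col in _DEFAULT_SCHEMA.items()})
    pd.DataFrame(rows).to_csv(path, index=False)


def aggregate_to_cycles(
    days: Sequence[DailyRecord],
    phyllochron: int = 2,
    *,
    e_mode: str = "sum",
    w_mode: str = "weighted",
    trailing: str = "drop",
    first_cycle_index: int = 1,
) -> list[CycleRecord]:
    """Aggregate consecutive day blocks into development-cycle records.

    Within each block of ``phyllochron`` days, water consumption is combined
    with weights proportional to each day's average radiation (``w_mode:
    'weighted'``; ``'mean'`` gives the plain average) while radiation is summed
    so that ``e_cd`` is the cycle's total radiative input (``e_mode: 'sum'``;
    ``'mean'`` averages instead).  A block whose radiation is all zero falls
    back to the unweighted mean with a warning.  The trailing partial block is
    dropped by default (``trailing='keep-partial'`` retains it).
    """
    if e_mode not in ("sum", "mean"):
        raise SeriesError(f"e_mode must be 'sum' or 'mean', got {e_mode!r}")
    if w_mode not in ("weighted", "mean"):
        raise SeriesError(f"w_mode must be 'weighted' or 'mean', got {w_mode!r}")
    if trailing not in ("drop", "keep-partial"):
        raise SeriesError(f"trailing must be 'drop' or 'keep-partial', got {trailing!r}")
    if len(days) < phyllochron:
        raise SeriesError(
            f"need at least {phyllochron} days for one cycle, got {len(days)}"
        )

    cycles: list[CycleRecord] = []
    n_full = len(days) // phyllochron
    blocks = [days[i * phyllochron : (i + 1) * phyllochron] for i in range(n_full)]
    if trailing == "keep-partial" and len(days) % phyllochron:
        blocks.append(days[n_full * phyllochron :])

    for bi, block in enumerate(blocks):
        e = np.array([d.e_avg for d in block], dtype=float)
        e_cd = float(e.sum()) if e_mode == "sum" else float(e.mean())
        wc_vals = [d.w_c for d in block]
        if any(w is None for w in wc_vals):
            w_cd: Optional[float] = None
        else:
            w = np.array(wc_vals, dtype=float)
            if w_mode == "weighted":
                if e.sum() <= 0:
                    logger.warning(
                        "cycle %d: all-zero radiation, using unweighted mean",
                        first_cycle_index + bi,
                    )
                    w_cd = float(w.mean())
                else:
                    w_cd = float(np.sum(e * w) / e.sum())
            else:
                w_cd = float(w.mean())
        cycles.append(
            CycleRecord(
                cycle_index=first_cycle_index + bi,
                e_cd=e_cd,
                w_cd=w_cd,
                day_span=tuple(d.date for d in block),
            )
        )
    return cycles


def write_cycle_table(cycles: Sequence[CycleRecord], path) -> None:
    """Write cycle records as ``cycle_index,e_cd,w_cd,first_day,last_day`` CSV."""
    pd.DataFrame(
        {
            "cycle_index": [c.cycle_index for c in cycles],
            "e_cd": [c.e_cd for c in cycles],
            "w_cd": [c.w_cd for c in cycles],
            "first_day": [c.day_span[0] for c in cycles],
            "last_day": [c.day_span[-1] for c in cycles],
        }
    ).to_csv(path, index=False)
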