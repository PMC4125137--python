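"""Restructure cow event records into two-day risk-period (person-period) data.

Each lactation is expanded into a sequence of two-day periods between 20 and
220 days in milk (DIM) during which the cow was at risk of conceiving; the
binary outcome marks the period in which conception occurred.  This
person-period table is the unit of analysis for the discrete-time survival
model: logistic regression on it estimates the per-period conception hazard.

Bins are half-open ``[20, 22), [22, 24), ..., [218, 220)`` so a lactation at
risk for the whole window contributes exactly 100 periods.  Clinical lameness
events recorded within 7 days of a previously retained event are treated as
duplicate records of the same disease episode and dropped.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    LAMENESS_WINDOWS,
    PARITY_CATEGORIES,
    SEASON_CATEGORIES,
    WINDOW_DAY_BOUNDS,
    YEAR_CATEGORIES,
)

__all__ = [
    "LactationRecord",
    "RiskPeriod",
    "dedupe_lameness_events",
    "build_risk_periods",
    "flag_lameness_windows",
    "compute_covariates",
    "build_risk_period_table",
    "read_lactation_tables",
    "write_risk_period_table",
    "season_of",
    "year_category",
    "parity_category",
]

RISK_WINDOW_START = 20
RISK_WINDOW_END = 220  # exclusive
BIN_DAYS = 2
DEDUPE_GAP_DAYS = 7

END_REASONS = ("pregnant", "culled", "censored")


@dataclass
class LactationRecord:
    """One cow-lactation: identifiers, calving anchor and event history."""

    herd_id: str
    cow_id: str
    lactation_no: int
    calving_date: _dt.date
    yield_305d: float
    lameness_dims: list[int] = field(default_factory=list)
    end_dim: int = 0
    end_reason: str = "censored"

    def __post_init__(self) -> None:
        if self.lactation_no < 1:
            raise ValueError("lactation_no must be a positive integer")
        if self.end_dim < 1:
            raise ValueError("end_dim must be >= 1")
        if self.end_reason not in END_REASONS:
            raise ValueError(f"end_reason must be one of {END_REASONS}")


@dataclass
class RiskPeriod:
    """One two-day at-risk unit with outcome flag and covariates."""

    herd_id: str
    cow_id: str
    lactation_id: str
    dim_start: int
    outcome: int
    parity_cat: str
    year_cat: str
    season: str
    yield_centred: float
    lame_flags: dict[str, int]


def dedupe_lameness_events(event_dims: Sequence[int]) -> list[int]:
    """Drop lameness events recorded within 7 days of the last retained event.

    A sequential scan: an event is removed iff it occurs <= 7 days after the
    most recently *retained* event, so output gaps are always > 7 days.
    """
    dims = sorted(int(d) for d in event_dims)
    if dims and dims[0] < 0:
        raise ValueError("lameness event DIM must be non-negative")
    kept: list[int] = []
    for d in dims:
        if not kept or d - kept[-1] > DEDUPE_GAP_DAYS:
            kept.append(d)
    return kept


def parity_category(lactation_no: int) -> str:
    return str(lactation_no) if lactation_no <= 4 else ">4"


def year_category(calving_date: _dt.date) -> str:
    y = calving_date.year
    if y <= 2002:
        return "<=2002"
    if y >= 2007:
        return "2007-8"
    return str(y)


def season_of(calving_date: _dt.date, dim: int) -> str:
    """Calendar-quarter season of the day falling ``dim`` days after calving."""
    date = calving_date + _dt.timedelta(days=int(dim))
    return SEASON_CATEGORIES[(date.month - 1) // 3]


def flag_lameness_windows(
    dim_start: int,
    lameness_dims: Sequence[int],
    anchor: str = "start",
) -> dict[str, int]:
    """Binary flags for lameness events in each time window around a period.

    ``anchor`` fixes the reference day the offsets are measured from:
    ``"start"`` (bin start, the default), ``"mid"`` (bin midpoint, start+1)
    or ``"overlap"`` (flag if either day of the bin falls in the window).
    """
    if anchor == "start":
        refs = (dim_start,)
    elif anchor == "mid":
        refs = (dim_start + 1,)
    elif anchor == "overlap":
        refs = (dim_start, dim_start + 1)
    else:
        raise ValueError("anchor must be 'start', 'mid' or 'overlap'")
    flags = dict.fromkeys(LAMENESS_WINDOWS, 0)
    for e in lameness_dims:
        for ref in refs:
            delta = e - ref
            for w, (lo, hi) in WINDOW_DAY_BOUNDS.items():
                if lo <= delta <= hi:
                    flags[w] = 1
    return flags


def compute_covariates(
    lac: LactationRecord, dim_start: int, yield_centre: float
) -> tuple[str, str, str, float]:
    """Parity/year/season categories and centred yield for one risk period."""
    if lac.yield_305d is None or not np.isfinite(lac.yield_305d):
        raise ValueError(f"missing 305-day yield for cow {lac.cow_id}")
    return (
        parity_category(lac.lactation_no),
        year_category(lac.calving_date),
        season_of(lac.calving_date, dim_start),
        (lac.yield_305d - yield_centre) / 1000.0,
    )


def _last_bin_start(end_dim: int) -> int:
    """Start of the bin containing end_dim, capped at the final bin."""
    start = end_dim - (end_dim - RISK_WINDOW_START) % BIN_DAYS
    return min(start, RISK_WINDOW_END - BIN_DAYS)


def build_risk_periods(
    lac: LactationRecord,
    yield_centre: float = 0.0,
    anchor: str = "start",
) -> list[RiskPeriod]:
    """Expand one lactation into its sequence of two-day risk periods.

    Bins run ``[20,22) ... [218,220)``; a bin is emitted while the cow is
    still at risk at the bin start, up to and including the bin containing
    ``end_dim``.  The final bin carries outcome 1 iff the lactation ended in
    conception before 220 DIM.
    """
    if lac.end_dim < RISK_WINDOW_START:
        return []
    parity_cat, year_cat, _, yield_centred = compute_covariates(
        lac, RISK_WINDOW_START, yield_centre
    )
    last_start = _last_bin_start(lac.end_dim)
    lact_id = f"{lac.herd_id}/{lac.cow_id}/{lac.lactation_no}"
    event_bin = (
        last_start
        if lac.end_reason == "pregnant" and lac.end_dim < RISK_WINDOW_END
        else None
    )
    periods = []
    for start in range(RISK_WINDOW_START, last_start + 1, BIN_DAYS):
        periods.append(
            RiskPeriod(
                herd_id=lac.herd_id,
                cow_id=lac.cow_id,
                lactation_id=lact_id,
                dim_start=start,
                outcome=int(start == event_bin),
                parity_cat=parity_cat,
                year_cat=year_cat,
                season=season_of(lac.calving_date, start),
                yield_centred=yield_centred,
                lame_flags=flag_lameness_windows(
                    start, lac.lameness_dims, anchor=anchor
                ),
            )
        )
    return periods


def build_risk_period_table(
    records: Iterable[LactationRecord],
    yield_centre: float | None = None,
    anchor: str = "start",
) -> pd.DataFrame:
    """Risk-period table (one row per two-day period) for a set of lactations.

    ``yield_centre`` defaults to the grand mean 305-day yield of the input
    records, so ``yield_centred`` has mean ~0 over lactations.
    """
    records = list(records)
    if yield_centre is None:
        if not records:
            raise ValueError("no lactation records supplied")
        yield_centre = float(np.mean([r.yield_305d for r in records]))
    rows = []
    for lac in records:
        for rp in build_risk_periods(lac, yield_centre, anchor=anchor):
            row = {
                "herd_id": rp.herd_id,
                "cow_id": rp.cow_id,
                "lactation_id": rp.lactation_id,
                "dim_start": rp.dim_start,
                "outcome": rp.outcome,
                "parity_cat": rp.parity_cat,
                "year_cat": rp.year_cat,
                "season": rp.season,
                "yield_centred": rp.yield_centred,
            }
            row.update(rp.lame_flags)
            rows.append(row)
    cols = [
        "herd_id",
        "cow_id",
        "lactation_id",
        "dim_start",
        "outcome",
        "parity_cat",
        "year_cat",
        "season",
        "yield_centred",
        *LAMENESS_WINDOWS,
    ]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["yield_centre"] = yield_centre
    return df


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Lactation table columns: herd_id, cow_id, lactation_no, calving_date
# (ISO-8601), yield_305d, end_dim, end_reason.
# Lameness table columns: herd_id, cow_id, lactation_no, and either dim
# (days in milk) or event_date (ISO-8601, converted using calving_date).
# ---------------------------------------------------------------------------

def read_lactation_tables(
    lactations_csv, lameness_csv=None
) -> list[LactationRecord]:
    """Read lactation and lameness-event CSVs into deduped records."""
    lact = pd.read_csv(lactations_csv, dtype={"herd_id": str, "cow_id": str})
    lact["calving_date"] = pd.to_datetime(lact["calving_date"]).dt.date
    events: dict[tuple, list[int]] = {}
    if lameness_csv is not None:
        lame = pd.read_csv(lameness_csv, dtype={"herd_id": str, "cow_id": str})
        if "dim" in lame.columns:
            dims = lame["dim"].astype(int)
        else:
            dates = pd.to_datetime(lame["event_date"]).dt.date
            calving = lact.set_index(["herd_id", "cow_id", "lactation_no"])[
                "calving_date"
            ]
            keys = list(
                zip(lame["herd_id"], lame["cow_id"], lame["lactation_no"])
            )
            dims = pd.Series(
                [(d - calving.loc[k]).days for d, k in zip(dates, keys)]
            )
        if (dims < 0).any():
            raise ValueError("lameness event before calving (negative DIM)")
        for (h, c, ln), grp in pd.DataFrame(
            {
                "herd_id": lame["herd_id"],
                "cow_id": lame["cow_id"],
                "lactation_no": lame["lactation_no"],
                "dim": dims,
            }
        ).groupby(["herd_id", "cow_id", "lactation_no"]):
            events[(h, c, int(ln))] = grp["dim"].tolist()

    records = []
    for row in lact.itertuples(index=False):
        key = (row.herd_id, row.cow_id, int(row.lactation_no))
        records.append(
            LactationRecord(
                herd_id=row.herd_id,
                cow_id=row.cow_id,
                lactation_no=int(row.lactation_no),
                calving_date=row.calving_date,
                yield_305d=float(row.yield_305d),
                lameness_dims=dedupe_lameness_events(events.get(key, [])),
                end_dim=int(row.end_dim),
                end_reason=row.end_reason,
            )
        )
    return records


def write_risk_period_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
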