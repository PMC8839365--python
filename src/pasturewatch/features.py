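"""Aggregation of hourly converter output into daily behavioral variables.

The noseband-sensor converter emits per-hour summaries (bite frequency,
rumination chews, rumination time, bouts started, ...); the pedometer adds
lying bouts.  Daily variables are built from these as follows:

* hour-based rates (``BITEFREQ``, ``RUMICHEWBOLUS``, ``HACTIVITY``) are the
  mean over the hours of the day;
* counts and durations (``RUMINATECHEW``, ``RUMIBOUTTIME``,
  ``GRAZINGSTART``, ``LAYDOWN``) are the daily sum;
* ``RUMIBOUTLENGTH`` is daily rumination time divided by the number of
  rumination bouts started that day.

Missing hourly values are skipped in means and treated as 0 in sums.
Days with an implausibly short daily rumination time (below 117 min, the
minimum observed in the training data this pipeline emulates) are removed
by :func:`plausibility_filter`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, UndefinedBoutLengthError
from .variables import BEHAVIOR_VARS

__all__ = [
    "HOURLY_COLUMNS",
    "RUMINATION_PLAUSIBILITY_MIN",
    "aggregate_daily",
    "aggregate_table",
    "plausibility_filter",
    "split_by_location",
]

#: Mapping hourly column -> daily variable for mean-type variables.
MEAN_MAP: dict[str, str] = {
    "bite_freq": "BITEFREQ",
    "chews_per_bolus": "RUMICHEWBOLUS",
    "head_activity": "HACTIVITY",
}

#: Mapping hourly column -> daily variable for sum-type variables.
SUM_MAP: dict[str, str] = {
    "rum_chews": "RUMINATECHEW",
    "rum_time": "RUMIBOUTTIME",
    "eating_bouts_started": "GRAZINGSTART",
    "lying_bouts": "LAYDOWN",
}

#: Required columns of an hourly converter table.
HOURLY_COLUMNS: tuple[str, ...] = (
    "cow_id",
    "day",
    "hour",
    "bite_freq",
    "rum_chews",
    "rum_time",
    "rum_bouts_started",
    "eating_bouts_started",
    "chews_per_bolus",
    "head_activity",
    "lying_bouts",
)

#: Daily rumination times below this (min/day) are considered implausible.
RUMINATION_PLAUSIBILITY_MIN: float = 117.0


def _check_hourly_schema(hours: pd.DataFrame) -> None:
    missing = set(HOURLY_COLUMNS) - set(hours.columns)
    if missing:
        raise SchemaError(f"hourly table missing columns: {sorted(missing)}")


def _aggregate_group(g: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    for src, dst in MEAN_MAP.items():
        out[dst] = float(g[src].mean())  # skips NaN
    for src, dst in SUM_MAP.items():
        out[dst] = float(g[src].sum())  # NaN treated as 0
    n_bouts = float(g["rum_bouts_started"].sum())
    rum_time = out["RUMIBOUTTIME"]
    if n_bouts == 0:
        if rum_time > 0:
            raise UndefinedBoutLengthError(
                "positive rumination time with zero rumination bouts"
            )
        out["RUMIBOUTLENGTH"] = 0.0
    else:
        out["RUMIBOUTLENGTH"] = rum_time / n_bouts
    return out


def aggregate_daily(hours: pd.DataFrame) -> pd.Series:
    """Aggregate the hourly records of a single cow-day.

    All rows must share one ``cow_id`` and one ``day``.  Returns a Series
    with the cow/day identifiers and the eight daily variables.
    """
    _check_hourly_schema(hours)
    if hours.empty:
        raise EmptyInputError("no hourly records for this cow-day")
    if hours["cow_id"].nunique() != 1 or hours["day"].nunique() != 1:
        raise ValueError("aggregate_daily expects records of exactly one cow-day")
    out = {"cow_id": hours["cow_id"].iloc[0], "day": hours["day"].iloc[0]}
    out.update(_aggregate_group(hours))
    return pd.Series(out)[["cow_id", "day", *BEHAVIOR_VARS]]


def aggregate_table(hours: pd.DataFrame, by: tuple[str, ...] = ("cow_id", "day")) -> pd.DataFrame:
    """Aggregate an hourly table to one row per group of ``by`` columns."""
    _check_hourly_schema(hours)
    if hours.empty:
        raise EmptyInputError("empty hourly table")
    rows = []
    for key, g in hours.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row.update(_aggregate_group(g))
        rows.append(row)
    return pd.DataFrame(rows)[[*by, *BEHAVIOR_VARS]]


def plausibility_filter(
    days: pd.DataFrame, threshold: float = RUMINATION_PLAUSIBILITY_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split daily features into (kept, removed) on daily rumination time.

    Records with ``RUMIBOUTTIME`` strictly below ``threshold`` minutes are
    removed; a value exactly at the threshold is kept.  Row order is
    preserved in both outputs.
    """
    if "RUMIBOUTTIME" not in days.columns:
        raise SchemaError("daily feature table missing RUMIBOUTTIME")
    implausible = days["RUMIBOUTTIME"] < threshold
    return days.loc[~implausible].copy(), days.loc[implausible].copy()


def split_by_location(hours: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate hourly data separately for pasture and barn hours.

    Returns ``(pasture, barn)`` daily tables.  Sum-type variables of the
    two tables add up to the whole-day sums exactly.  A cow-day with no
    hours in one location is simply absent from that table.
    """
    _check_hourly_schema(hours)
    if "location" not in hours.columns or hours["location"].isna().any():
        raise SchemaError("every hourly record needs a 'location' tag (pasture/barn)")
    bad = set(hours["location"].unique()) - {"pasture", "barn"}
    if bad:
        raise ValueError(f"unknown locations: {sorted(bad)}")
    parts = {}
    for loc in ("pasture", "barn"):
        sub = hours[hours["location"] == loc]
        parts[loc] = (
            aggregate_table(sub)
            if not sub.empty
            else pd.DataFrame(columns=["cow_id", "day", *BEHAVIOR_VARS])
        )
    return parts["pasture"], parts["barn"]
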