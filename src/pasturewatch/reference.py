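"""Reference classification of herbage availability from milk and rumen fill.

Each cow-day of a grazing cycle is labelled ``0`` (sufficient herbage) or
``1`` (scarce) per indicator:

1. *Day attribution*: milk responds to a feed deficit with roughly one day
   of delay when cows graze during the day, so in day-grazing months the
   milk yield of day ``d+1`` evaluates grazing day ``d``; in night-grazing
   months the same-day yield is used.  Rumen fill is scored right after
   grazing and always evaluates the same day.
2. *Baselines*: per cow and cycle, rumen baseline = mean score of days 1-2;
   milk baseline = mean attributed yield of days 2-3.
3. *Reduction limits*: per cow and month, the SD of the baseline-day values
   across both cycles (n = 4) is computed; limits are ``k`` (default 3,
   the 99.73% band of a normal) times the average SD — absolute score
   units for rumen fill, percent of the cow-month mean for milk.
4. *Classes*: on days 3-6 a decline strictly beyond the limit is labelled
   scarce (1); smaller declines, increases, and the baseline days 1-2 are
   labelled sufficient (0).
5. *Combination*: a cow-day is combined-positive if either indicator is
   positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import DAY_GRAZING, NIGHT_GRAZING

__all__ = [
    "ReductionLimits",
    "attribute_milk_day",
    "compute_baselines",
    "compute_limits",
    "limits_from_mean_sds",
    "classify_days",
    "combine",
]

CYCLE_KEY = ["cow_id", "month", "cycle"]
DAY_KEY = CYCLE_KEY + ["day"]

#: Cycle days whose outcomes define the baselines.
RUMEN_BASELINE_DAYS = (1, 2)
MILK_BASELINE_DAYS = (2, 3)
#: Cycle days on which scarcity is evaluated.
EVALUATION_DAYS = (3, 4, 5, 6)


@dataclass
class ReductionLimits:
    """Scarcity thresholds derived from baseline-day variability.

    ``rumen_abs_limit`` is in score units, ``milk_rel_limit`` in percent of
    the baseline.  The per-cow-month SD tables used to derive them are kept
    for inspection; ``outliers_excluded`` counts milk relative SDs dropped
    by the outlier rule (above Q3 + 3*IQR).
    """

    rumen_abs_limit: float
    milk_rel_limit: float
    k: float = 3.0
    rumen_sd_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    milk_sd_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers_excluded: int = 0

    def __post_init__(self) -> None:
        if self.rumen_abs_limit < 0 or self.milk_rel_limit < 0:
            raise ValueError("reduction limits must be >= 0")


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} missing columns: {sorted(missing)}")


def attribute_milk_day(outcomes: pd.DataFrame, grazing_mode: str | None = None) -> pd.DataFrame:
    """Attach the evaluation milk yield ``milk_attr`` to each cow-day.

    ``grazing_mode`` is ``"day_grazing"`` or ``"night_grazing"``; if None,
    a per-row ``grazing_mode`` column is used.  In day-grazing mode the
    next day's milk is taken from a ``milk_next_kg`` column if present,
    otherwise by shifting ``milk_kg`` within each cow-cycle (then the last
    cycle day has no next-day milk and is flagged).  Adds a boolean
    ``milk_attr_missing`` column.
    """
    _require(outcomes, DAY_KEY + ["milk_kg"], "outcome table")
    df = outcomes.copy()
    if grazing_mode is not None:
        if grazing_mode not in (DAY_GRAZING, NIGHT_GRAZING):
            raise ValueError(f"unknown grazing mode: {grazing_mode}")
        df["grazing_mode"] = grazing_mode
    elif "grazing_mode" not in df.columns:
        raise SchemaError("no grazing_mode column and no mode argument given")

    if "milk_next_kg" in df.columns:
        next_milk = df["milk_next_kg"]
    else:
        df = df.sort_values(DAY_KEY, kind="stable")
        next_milk = df.groupby(CYCLE_KEY, sort=False)["milk_kg"].shift(-1)

    is_day = df["grazing_mode"] == DAY_GRAZING
    df["milk_attr"] = np.where(is_day, next_milk, df["milk_kg"])
    df["milk_attr_missing"] = df["milk_attr"].isna()
    return df


def compute_baselines(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per cow-cycle baselines for both indicators.

    Requires an attributed table (see :func:`attribute_milk_day`).  Returns
    one row per (cow, month, cycle) with ``rumen_baseline``,
    ``milk_baseline`` and per-indicator validity flags ``rumen_ok`` /
    ``milk_ok`` (False when a baseline day is missing or excluded).
    """
    _require(outcomes, DAY_KEY + ["rumen_fill", "milk_attr"], "attributed outcome table")
    df = outcomes.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False

    rows = []
    for key, g in df.groupby(CYCLE_KEY, sort=True):
        g = g.set_index("day")

        def _baseline(col: str, days: tuple[int, ...]) -> tuple[float, bool]:
            vals = []
            for d in days:
                if d not in g.index:
                    return np.nan, False
                row = g.loc[d]
                if bool(row["excluded"]) or pd.isna(row[col]):
                    return np.nan, False
                vals.append(float(row[col]))
            return float(np.mean(vals)), True

        rumen_baseline, rumen_ok = _baseline("rumen_fill", RUMEN_BASELINE_DAYS)
        milk_baseline, milk_ok = _baseline("milk_attr", MILK_BASELINE_DAYS)
        rows.append(
            dict(
                zip(CYCLE_KEY, key),
                rumen_baseline=rumen_baseline,
                rumen_ok=rumen_ok,
                milk_baseline=milk_baseline,
                milk_ok=milk_ok,
            )
        )
    return pd.DataFrame(rows)


def _sd_tables(outcomes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cow-month SDs of the baseline-day values (both cycles pooled)."""
    df = outcomes.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df = df[~df["excluded"]]

    def _table(col: str, days: tuple[int, ...], relative: bool) -> pd.DataFrame:
        sub = df[df["day"].isin(days)].dropna(subset=[col])
        rows = []
        for (cow, month), g in sub.groupby(["cow_id", "month"], sort=True):
            vals = g[col].to_numpy(dtype=float)
            if vals.size < 2:
                warnings.warn(
                    f"cow {cow} month {month}: only {vals.size} baseline value(s); skipped",
                    stacklevel=3,
                )
                continue
            sd = float(np.std(vals, ddof=1))
            if relative:
                mean = float(np.mean(vals))
                if mean <= 0:
                    warnings.warn(
                        f"cow {cow} month {month}: non-positive mean; skipped", stacklevel=3
                    )
                    continue
                sd = 100.0 * sd / mean
            rows.append(dict(cow_id=cow, month=month, n=int(vals.size), sd=sd))
        return pd.DataFrame(rows)

    rumen = _table("rumen_fill", RUMEN_BASELINE_DAYS, relative=False)
    milk = _table("milk_attr", MILK_BASELINE_DAYS, relative=True)
    return rumen, milk


def compute_limits(outcomes: pd.DataFrame, k: float = 3.0) -> ReductionLimits:
    """Derive the scarcity reduction limits from baseline-day variability.

    Per cow and month, the SD over the baseline-day values of both cycles
    is computed (absolute for rumen fill; percent of the cow-month mean for
    milk).  Extreme milk relative SDs above Q3 + 3*IQR are excluded.  The
    limits are ``k`` times the respective average SD.
    """
    _require(outcomes, DAY_KEY + ["rumen_fill", "milk_attr"], "attributed outcome table")
    rumen_tab, milk_tab = _sd_tables(outcomes)
    if rumen_tab.empty or milk_tab.empty:
        raise ValueError("not enough baseline data to derive limits")

    sds = milk_tab["sd"].to_numpy()
    q1, q3 = np.percentile(sds, [25, 75])
    cutoff = q3 + 3.0 * (q3 - q1)
    keep = sds <= cutoff
    n_out = int((~keep).sum())
    milk_kept = milk_tab.loc[keep].reset_index(drop=True)

    return ReductionLimits(
        rumen_abs_limit=k * float(rumen_tab["sd"].mean()),
        milk_rel_limit=k * float(milk_kept["sd"].mean()),
        k=k,
        rumen_sd_table=rumen_tab,
        milk_sd_table=milk_tab.assign(outlier=~keep),
        outliers_excluded=n_out,
    )


def limits_from_mean_sds(
    mean_rumen_sd: float, mean_milk_rel_sd: float, k: float = 3.0
) -> ReductionLimits:
    """Reduction limits from already-averaged SDs.

    ``mean_rumen_sd`` in score units, ``mean_milk_rel_sd`` in percent.
    The limit is ``k`` times the average SD, e.g. 3 x 0.38 = 1.14 score
    units and 3 x 5.9% = 17.7%.
    """
    return ReductionLimits(
        rumen_abs_limit=k * mean_rumen_sd, milk_rel_limit=k * mean_milk_rel_sd, k=k
    )


def classify_days(
    outcomes: pd.DataFrame,
    baselines: pd.DataFrame,
    limits: ReductionLimits,
) -> pd.DataFrame:
    """Label every available cow-day per indicator.

    Returns a long table with columns ``cow_id, month, cycle, day,
    indicator, baseline, delta, cls`` where ``indicator`` is ``"milk"`` or
    ``"rumen"``; ``delta`` is the change versus baseline (percent for milk,
    score units for rumen; negative = decline) and ``cls`` is 1 when the
    decline strictly exceeds the limit on days 3-6.  Days 1-2 are always
    class 0.  Cow-days with a missing or excluded outcome, or an
    unlabelable baseline on evaluation days, are omitted.
    """
    _require(outcomes, DAY_KEY + ["rumen_fill", "milk_attr"], "attributed outcome table")
    df = outcomes.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df = df.merge(baselines, on=CYCLE_KEY, how="left", validate="many_to_one")
    df = df[~df["excluded"] & df["day"].isin((1, 2) + EVALUATION_DAYS)]
    on_eval = df["day"].isin(EVALUATION_DAYS)
    out_cols = DAY_KEY + ["indicator", "baseline", "delta", "cls"]

    def _indicator(name: str, value_col: str, base_col: str, ok_col: str,
                   limit: float, relative: bool) -> pd.DataFrame:
        sub = df[df[value_col].notna() & df[ok_col].fillna(False).astype(bool)].copy()
        if relative:
            delta = 100.0 * (sub[value_col] - sub[base_col]) / sub[base_col]
        else:
            delta = sub[value_col] - sub[base_col]
        sub["indicator"] = name
        sub["baseline"] = sub[base_col]
        sub["delta"] = delta
        sub["cls"] = (on_eval.loc[sub.index] & (-delta > limit)).astype(int)
        return sub[out_cols]

    milk = _indicator("milk", "milk_attr", "milk_baseline", "milk_ok",
                      limits.milk_rel_limit, relative=True)
    rumen = _indicator("rumen", "rumen_fill", "rumen_baseline", "rumen_ok",
                       limits.rumen_abs_limit, relative=False)
    labels = pd.concat([milk, rumen], ignore_index=True)
    if labels.empty:
        return pd.DataFrame(columns=out_cols)
    return labels.sort_values(DAY_KEY + ["indicator"], kind="stable").reset_index(drop=True)


def combine(milk_labels: pd.DataFrame, rumen_labels: pd.DataFrame) -> pd.DataFrame:
    """OR-combine the milk and rumen label tables on cow-day.

    A cow-day present in only one table uses that indicator alone; a
    cow-day is positive as soon as either available indicator is positive.
    """
    m = milk_labels[DAY_KEY + ["cls"]].rename(columns={"cls": "cls_milk"})
    r = rumen_labels[DAY_KEY + ["cls"]].rename(columns={"cls": "cls_rumen"})
    merged = m.merge(r, on=DAY_KEY, how="outer")
    both_missing = merged["cls_milk"].isna() & merged["cls_rumen"].isna()
    merged = merged.loc[~both_missing]
    merged["cls"] = (
        (merged["cls_milk"].fillna(0) > 0) | (merged["cls_rumen"].fillna(0) > 0)
    ).astype(int)
    merged["indicator"] = "combined"
    return merged[DAY_KEY + ["indicator", "cls"]].sort_values(DAY_KEY).reset_index(drop=True)
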