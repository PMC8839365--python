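"""Confusion-matrix evaluation of predicted against reference classes.

Class 1 ("scarce") is the positive class throughout.  For hard 0/1
predictions the ROC curve has a single interior point, so its area equals
the mean of sensitivity and specificity (balanced accuracy); that identity
is what :func:`auc_hard_label` computes.  A probability-ranked AUC is
available separately via :func:`ranked_auc` for predictors that emit
probabilities.

Metrics with a zero denominator (e.g. PPV of a predictor that never fires)
are reported as explicitly undefined (``None`` plus a flag), never as a
silent 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "ConfusionMetrics",
    "SubgroupSpec",
    "DEFAULT_SUBGROUPS",
    "confusion",
    "metrics",
    "evaluate",
    "auc_hard_label",
    "ranked_auc",
    "evaluate_subgroups",
    "milk_as_predictor",
    "positives_by_day",
]

DAY_KEY = ["cow_id", "month", "cycle", "day"]


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts with derived proportions.

    ``sensitivity = tp/(tp+fn)``, ``specificity = tn/(tn+fp)``,
    ``ppv = tp/(tp+fp)``, ``auc = (sensitivity + specificity)/2``.
    Undefined proportions are ``None`` and listed in ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred, ref) -> ConfusionMetrics:
    """Cross-tabulate 0/1 prediction and reference vectors (counts only)."""
    p = np.asarray(pred, dtype=int)
    r = np.asarray(ref, dtype=int)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    if not (set(np.unique(p)) <= {0, 1} and set(np.unique(r)) <= {0, 1}):
        raise ValueError("classes must be 0/1")
    return ConfusionMetrics(
        tp=int(((p == 1) & (r == 1)).sum()),
        tn=int(((p == 0) & (r == 0)).sum()),
        fp=int(((p == 1) & (r == 0)).sum()),
        fn=int(((p == 0) & (r == 1)).sum()),
    )


def metrics(counts: ConfusionMetrics) -> ConfusionMetrics:
    """Fill sensitivity, specificity, PPV and hard-label AUC from counts."""
    undefined: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    ppv = _ratio(counts.tp, counts.tp + counts.fp, "ppv")
    if sens is None or spec is None:
        undefined.append("auc")
        auc = None
    else:
        auc = auc_hard_label(sens, spec)
    return replace(
        counts,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        auc=auc,
        undefined=tuple(undefined),
    )


def evaluate(pred, ref) -> ConfusionMetrics:
    """Counts plus derived metrics in one call."""
    return metrics(confusion(pred, ref))


def auc_hard_label(sensitivity: float, specificity: float) -> float:
    """ROC area of a single-threshold (hard-label) classifier.

    Equal to the mean of sensitivity and specificity: the ROC polygon of a
    0/1 predictor has the single interior vertex (1-specificity,
    sensitivity).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def ranked_auc(p_hat, ref) -> float:
    """Probability-ranked ROC AUC (for comparison with the hard-label AUC)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(ref, dtype=int), np.asarray(p_hat, dtype=float)))


@dataclass(frozen=True)
class SubgroupSpec:
    """A named cow subgroup defined by a predicate over the cow profile row."""

    name: str
    predicate: Callable[[pd.Series], bool]


#: The standard animal subgroups: parity, grazing experience, milk
#: performance band, gestation, and body condition band.  Milk and BCS
#: bands are mutually exclusive and exhaustive on their grids.
DEFAULT_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec("primiparous", lambda c: c["parity"] == 1),
    SubgroupSpec("multiparous", lambda c: c["parity"] > 1),
    SubgroupSpec("grazing_experience", lambda c: bool(c["grazing_experience"])),
    SubgroupSpec("no_grazing_experience", lambda c: not c["grazing_experience"]),
    SubgroupSpec("high_milk", lambda c: c["mean_milk_yield"] > 27.0),
    SubgroupSpec("medium_milk", lambda c: 20.0 <= c["mean_milk_yield"] <= 27.0),
    SubgroupSpec("low_milk", lambda c: c["mean_milk_yield"] < 20.0),
    SubgroupSpec("gestating", lambda c: bool(c["gestation"])),
    SubgroupSpec("not_gestating", lambda c: not c["gestation"]),
    SubgroupSpec("high_bcs", lambda c: c["bcs"] >= 3.25),
    SubgroupSpec("medium_bcs", lambda c: 2.75 <= c["bcs"] <= 3.00),
    SubgroupSpec("low_bcs", lambda c: c["bcs"] <= 2.5),
)


def _metrics_row(cm: ConfusionMetrics) -> dict:
    return dict(
        n=cm.n,
        tp=cm.tp,
        tn=cm.tn,
        fp=cm.fp,
        fn=cm.fn,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        ppv=cm.ppv,
        auc=cm.auc,
    )


def evaluate_subgroups(
    compared: pd.DataFrame,
    profiles: pd.DataFrame,
    specs: tuple[SubgroupSpec, ...] = DEFAULT_SUBGROUPS,
) -> pd.DataFrame:
    """Metric table per cow subgroup.

    ``compared`` holds aligned cow-day rows with ``cow_id``, ``pred`` and
    ``ref`` columns; ``profiles`` holds one row per cow (as from
    ``herd_to_frame``).  Empty subgroups are omitted with a warning.
    """
    if not {"cow_id", "pred", "ref"} <= set(compared.columns):
        raise SchemaError("compared table needs cow_id, pred, ref columns")
    prof = profiles.set_index("cow_id")
    rows = []
    for spec in specs:
        members = {cid for cid, row in prof.iterrows() if spec.predicate(row)}
        sub = compared[compared["cow_id"].isin(members)]
        if sub.empty:
            warnings.warn(f"subgroup '{spec.name}' is empty; omitted", stacklevel=2)
            continue
        cm = evaluate(sub["pred"], sub["ref"])
        rows.append(dict(subgroup=spec.name, **_metrics_row(cm)))
    return pd.DataFrame(rows)


def milk_as_predictor(milk_labels: pd.DataFrame, rumen_labels: pd.DataFrame) -> ConfusionMetrics:
    """Evaluate the milk-yield labels against the rumen-fill reference.

    The milk indicator plays the role of the prediction, rumen fill the
    role of the truth; cow-days present in both tables are compared.
    """
    m = milk_labels[DAY_KEY + ["cls"]].rename(columns={"cls": "pred"})
    r = rumen_labels[DAY_KEY + ["cls"]].rename(columns={"cls": "ref"})
    merged = m.merge(r, on=DAY_KEY, how="inner")
    if merged.empty:
        raise ValueError("no overlapping cow-days between the two label tables")
    return evaluate(merged["pred"], merged["ref"])


def positives_by_day(labels: pd.DataFrame, cls_col: str = "cls") -> pd.DataFrame:
    """Per-cycle-day counts of observations and positive classifications.

    Returns one row per day plus a ``total`` row, with columns ``n``,
    ``positives`` and ``share_pct`` (positives as percent of that day's
    observations).
    """
    if "day" not in labels.columns or cls_col not in labels.columns:
        raise SchemaError(f"label table needs 'day' and '{cls_col}' columns")
    rows = []
    for day, g in labels.groupby("day", sort=True):
        pos = int((g[cls_col] == 1).sum())
        rows.append(dict(day=str(day), n=len(g), positives=pos, share_pct=100.0 * pos / len(g)))
    total_pos = int((labels[cls_col] == 1).sum())
    rows.append(
        dict(
            day="total",
            n=len(labels),
            positives=total_pos,
            share_pct=100.0 * total_pos / len(labels),
        )
    )
    return pd.DataFrame(rows)
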