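"""Binary feed-status classifiers: logistic GLM and random forest.

Both models predict, from the eight (or reduced five) daily behavioral
variables, whether a cow-day reflects sufficient (0) or scarce (1) herbage
availability.  They are trained once on a two-class training table and
applied unchanged to test cow-days; the decision threshold is a predicted
probability of 0.5, with a probability of exactly 0.5 mapped to the
negative class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from .errors import SchemaError
from .variables import FULL8, PREDICTOR_SETS, PredictorSet

__all__ = ["FeedStatusModel", "fit_glm", "fit_rfm", "predict_status", "save_model", "load_model"]

DEFAULT_THRESHOLD = 0.5


@dataclass
class FeedStatusModel:
    """A fitted feed-status classifier with its predictor set and threshold."""

    kind: str  # "GLM" or "RFM"
    predictors: PredictorSet
    threshold: float = DEFAULT_THRESHOLD
    coefficients: dict[str, float] | None = None  # GLM: {"const": b0, var: b, ...}
    forest: RandomForestClassifier | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.kind not in ("GLM", "RFM"):
            raise ValueError("kind must be 'GLM' or 'RFM'")
        if self.kind == "GLM" and self.coefficients is not None:
            if len(self.coefficients) != len(self.predictors.names) + 1:
                raise ValueError("GLM needs one coefficient per predictor plus intercept")


def _design(table: pd.DataFrame, predictors: PredictorSet) -> pd.DataFrame:
    missing = set(predictors.names) - set(table.columns)
    if missing:
        raise SchemaError(f"feature table missing predictors: {sorted(missing)}")
    X = table[list(predictors.names)].astype(float)
    if X.isna().any().any():
        raise ValueError("missing predictor values; impute or drop before fitting")
    return X


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if not set(classes) <= {0, 1}:
        raise ValueError("class labels must be 0/1")


def fit_glm(training: pd.DataFrame, predictors: PredictorSet = FULL8) -> FeedStatusModel:
    """Fit the binomial GLM with logit link by maximum likelihood.

    ``training`` needs a 0/1 ``cls`` column and the predictor columns.
    Complete separation is flagged in the metadata (coefficients are still
    returned) rather than raised.
    """
    y = training["cls"].to_numpy(dtype=int)
    _check_two_classes(y)
    X = sm.add_constant(_design(training, predictors), has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    if np.abs(res.params.to_numpy()).max() > 1e3:
        separation = True
    if separation:
        warnings.warn("possible complete separation in GLM training data", stacklevel=2)

    coef = {"const": float(res.params["const"])}
    coef.update({v: float(res.params[v]) for v in predictors.names})
    meta = {
        "n": int(len(y)),
        "class_counts": {int(c): int((y == c).sum()) for c in np.unique(y)},
        "converged": bool(res.converged),
        "separation_flag": separation,
        "deviance": float(res.deviance),
    }
    return FeedStatusModel(kind="GLM", predictors=predictors, coefficients=coef, metadata=meta)


def fit_rfm(
    training: pd.DataFrame,
    predictors: PredictorSet = FULL8,
    n_trees: int = 500,
    vars_per_split: int | None = None,
    seed: int = 0,
) -> FeedStatusModel:
    """Fit the random forest classifier (500 trees, sqrt(p) vars per split).

    Out-of-bag accuracy is recorded in the metadata; the fit is
    deterministic for a fixed ``seed``.
    """
    y = training["cls"].to_numpy(dtype=int)
    _check_two_classes(y)
    X = _design(training, predictors)
    max_features = vars_per_split if vars_per_split is not None else "sqrt"
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X.to_numpy(), y)
    meta = {
        "n": int(len(y)),
        "class_counts": {int(c): int((y == c).sum()) for c in np.unique(y)},
        "oob_accuracy": float(rf.oob_score_),
        "n_trees": int(n_trees),
        "seed": int(seed),
    }
    return FeedStatusModel(kind="RFM", predictors=predictors, forest=rf, metadata=meta)


def predict_status(model: FeedStatusModel, features: pd.DataFrame) -> pd.DataFrame:
    """Predicted probability and class for each row of ``features``.

    Returns the input identifiers (any non-predictor columns are carried
    through) plus ``p_hat`` and ``cls``; class 1 iff ``p_hat`` strictly
    exceeds the threshold, so a probability of exactly 0.5 is negative.
    """
    X = _design(features, model.predictors)
    if model.kind == "GLM":
        beta = np.array(
            [model.coefficients["const"]]
            + [model.coefficients[v] for v in model.predictors.names]
        )
        eta = beta[0] + X.to_numpy() @ beta[1:]
        p = expit(eta)
    else:
        if model.forest is None:
            raise ValueError("random forest model has no fitted ensemble")
        proba = model.forest.predict_proba(X.to_numpy())
        pos_col = int(np.where(model.forest.classes_ == 1)[0][0])
        p = proba[:, pos_col]
    out = features.copy()
    out["p_hat"] = p
    out["cls"] = (p > model.threshold).astype(int)
    return out


def save_model(model: FeedStatusModel, path: str | Path) -> Path:
    """Persist a model: JSON for GLM coefficients, joblib for the forest."""
    path = Path(path)
    if model.kind == "GLM":
        payload = {
            "kind": model.kind,
            "variant": model.predictors.variant,
            "predictors": list(model.predictors.names),
            "threshold": model.threshold,
            "coefficients": model.coefficients,
            "metadata": model.metadata,
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        import joblib

        joblib.dump(
            {
                "kind": model.kind,
                "variant": model.predictors.variant,
                "predictors": list(model.predictors.names),
                "threshold": model.threshold,
                "forest": model.forest,
                "metadata": model.metadata,
            },
            path,
        )
    return path


def load_model(path: str | Path) -> FeedStatusModel:
    """Load a model saved by :func:`save_model` (format sniffed from content)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (UnicodeDecodeError, json.JSONDecodeError):
        import joblib

        payload = joblib.load(path)
        return FeedStatusModel(
            kind=payload["kind"],
            predictors=_predictor_set(payload),
            threshold=payload["threshold"],
            forest=payload["forest"],
            metadata=payload["metadata"],
        )
    return FeedStatusModel(
        kind=payload["kind"],
        predictors=_predictor_set(payload),
        threshold=payload["threshold"],
        coefficients=payload["coefficients"],
        metadata=payload["metadata"],
    )


def _predictor_set(payload: dict) -> PredictorSet:
    names = tuple(payload["predictors"])
    canonical = PREDICTOR_SETS.get(payload["variant"])
    if canonical is not None and canonical.names == names:
        return canonical
    return PredictorSet(names=names, variant=payload["variant"])
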