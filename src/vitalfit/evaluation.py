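"""Scoring of fitted candidate survival-prediction models.

Metrics follow the conventions of clinical risk-prediction reporting:

* Brier score, reported x100: ``100 * mean((p - y)^2)`` where ``p`` is
  the predicted death probability and ``y`` the observed outcome
  (lower is better; 25.0 for a constant 0.5 forecast).
* Index of Prediction Accuracy (IPA): ``100 * (1 - Brier_model /
  Brier_null)`` against the null (intercept-only) model; 0 for the null
  model itself, 100 for perfect prediction, negative when worse than
  the null.
* Confusion matrix at a probability cutoff (default 0.5) with survivors
  as the positive class: TP = correctly predicted survivors, TN =
  correctly predicted non-survivors, accuracy = (TP + TN) / n.
* Survival ratios: observed and predicted mean survival per trip, and
  per gear the mean (min-max) across that gear's trips, with a high/low
  call at the 0.5 management line (high means strictly above 0.50).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .records_io import RecordSet


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclasses.dataclass
class EvaluationReport:
    """Per-model metric bundle (one row of a model-comparison table)."""

    model_id: str
    aic: float
    brier: float                    # x100
    ipa: float | None
    confusion: ConfusionMatrix
    per_trip: pd.DataFrame          # observed/predicted SR and |diff| per trip
    per_gear: pd.DataFrame          # mean/min/max SR and high-low call per gear

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


def _check_inputs(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs p {p.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities outside [0, 1]")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    return y, p


def brier(y: np.ndarray, p: np.ndarray) -> float:
    """Brier score x100 of predicted death probabilities against outcomes."""
    y, p = _check_inputs(y, p)
    return float(100.0 * np.mean((p - y) ** 2))


def ipa(bs_model: float, bs_null: float) -> float:
    """Index of Prediction Accuracy from two x100 Brier scores."""
    if bs_null == 0:
        raise ValueError("IPA undefined: null-model Brier score is 0")
    return float(100.0 * (1.0 - bs_model / bs_null))


def confusion(y: np.ndarray, p: np.ndarray,
              threshold: float = 0.5) -> ConfusionMatrix:
    """Classify at ``threshold`` on the death probability and tabulate.

    A fish is called a survivor (class 0) when its predicted death
    probability is below the threshold.  Survivors are the positive
    class: TP counts correctly predicted survivors, TN correctly
    predicted deaths.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    y, p = _check_inputs(y, p)
    pred_dead = p >= threshold
    obs_dead = y == 1
    return ConfusionMatrix(
        tp=int((~pred_dead & ~obs_dead).sum()),
        fp=int((~pred_dead & obs_dead).sum()),
        fn=int((pred_dead & ~obs_dead).sum()),
        tn=int((pred_dead & obs_dead).sum()),
    )


def classify_high_low(sr: float) -> str:
    """Management call on a survival ratio: ``high`` iff sr > 0.50."""
    if not 0.0 <= sr <= 1.0:
        raise ValueError(f"survival ratio {sr} outside [0, 1]")
    return "high" if sr > 0.50 else "low"


def survival_ratios(rs: RecordSet,
                    p: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed and predicted survival ratios per trip and per gear.

    ``p`` holds predicted death probabilities aligned with the records.
    Per trip: observed SR = mean(1 - y), predicted SR = mean(1 - p), and
    their absolute difference.  Per gear: mean, min and max of the
    trip-level SRs plus high/low calls on the gear means.
    """
    y, p = _check_inputs(rs.mortality(), np.asarray(p, dtype=float))
    df = pd.DataFrame({
        "trip_id": rs.df["trip_id"].to_numpy(),
        "gear_type": rs.df["gear_type"].to_numpy(),
        "survived": 1.0 - y,
        "pred_survival": 1.0 - p,
    })
    sizes = df.groupby("trip_id", sort=False).size()
    if (sizes == 0).any():  # pragma: no cover - groupby cannot produce this
        raise ValueError("trip with zero fish")
    per_trip = (
        df.groupby(["trip_id", "gear_type"], sort=False)
        .agg(n=("survived", "size"),
             observed_sr=("survived", "mean"),
             predicted_sr=("pred_survival", "mean"))
        .reset_index()
    )
    per_trip["abs_diff"] = (per_trip["observed_sr"]
                            - per_trip["predicted_sr"]).abs()
    per_trip["observed_call"] = per_trip["observed_sr"].map(classify_high_low)
    per_trip["predicted_call"] = per_trip["predicted_sr"].map(classify_high_low)

    per_gear = (
        per_trip.groupby("gear_type", sort=False)
        .agg(n_trips=("trip_id", "size"),
             observed_mean=("observed_sr", "mean"),
             observed_min=("observed_sr", "min"),
             observed_max=("observed_sr", "max"),
             predicted_mean=("predicted_sr", "mean"),
             predicted_min=("predicted_sr", "min"),
             predicted_max=("predicted_sr", "max"))
        .reset_index()
    )
    per_gear["observed_call"] = per_gear["observed_mean"].map(classify_high_low)
    per_gear["predicted_call"] = per_gear["predicted_mean"].map(classify_high_low)
    return per_trip, per_gear


def evaluate_model(
    model_id: str,
    rs: RecordSet,
    p: np.ndarray,
    aic: float,
    bs_null: float | None = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Full metric bundle for one fitted model's predictions."""
    y = rs.mortality()
    bs = brier(y, p)
    per_trip, per_gear = survival_ratios(rs, p)
    return EvaluationReport(
        model_id=model_id,
        aic=aic,
        brier=bs,
        ipa=None if bs_null is None else ipa(bs, bs_null),
        confusion=confusion(y, p, threshold),
        per_trip=per_trip,
        per_gear=per_gear,
    )
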