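"""Candidate vitality indicators computed from the ten binary attributes.

Seven indicator families are supported as predictors of mortality:

* ``RI`` — the reflex-and-injury index, the arithmetic mean of the ten
  binary scores (equal weight 0.1 each), in [0, 1];
* ``RI_opt_fish`` / ``RI_opt_trip`` — the same index as a weighted mean
  with per-attribute weights found by fish-level (AIC) or trip-level
  (prediction error) optimization;
* ``n_reflex`` / ``n_injury`` / ``n_both`` — counts of impaired
  reflexes, present injuries, and their sum;
* ``categorical`` — the four-level A-D vitality grade as an unordered
  factor (reference level A);
* ``partitioned`` — the ten attributes entered individually;
* ``null`` — no indicator (constant-only model).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .records_io import ATTRIBUTES, REFLEXES, VITALITY_LEVELS, RecordSet

N_ATTRIBUTES = len(ATTRIBUTES)

#: Valid indicator specification names.
INDICATOR_SPECS: tuple[str, ...] = (
    "RI",
    "RI_opt_fish",
    "RI_opt_trip",
    "n_reflex",
    "n_injury",
    "n_both",
    "categorical",
    "partitioned",
    "null",
)

# Printed weight tables are rounded to two decimals, so a valid vector
# may sum to 0.99-1.01; accept that slack without renormalizing.
SIMPLEX_ATOL = 0.015


@dataclasses.dataclass(frozen=True)
class WeightVector:
    """Non-negative attribute weights on the unit simplex.

    ``weights`` follows the canonical attribute order (six reflexes then
    four injuries).  ``level`` records how the weights were obtained:
    ``"uniform"`` (all 0.1), ``"fish"`` (AIC-optimized) or ``"trip"``
    (trip-error-optimized).
    """

    weights: np.ndarray
    level: str = "uniform"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (N_ATTRIBUTES,):
            raise ValueError(f"expected {N_ATTRIBUTES} weights, got {w.shape}")
        if (w < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.4f})")
        if self.level not in ("fish", "trip", "uniform"):
            raise ValueError(f"unknown weight level {self.level!r}")

    @classmethod
    def uniform(cls) -> "WeightVector":
        return cls(np.full(N_ATTRIBUTES, 1.0 / N_ATTRIBUTES), "uniform")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(ATTRIBUTES))


def _scores(record: pd.Series | dict) -> np.ndarray:
    vals = np.array([record[a] for a in ATTRIBUTES], dtype=float)
    if np.isnan(vals).any():
        missing = [a for a, v in zip(ATTRIBUTES, vals) if np.isnan(v)]
        raise ValueError(f"missing attribute score(s): {missing}")
    return vals


def ri_index(record: pd.Series | dict) -> float:
    """Equal-weight reflex-and-injury index: mean of the ten binary scores.

    0 is a fully responsive, uninjured fish; 1 a fully impaired and
    injured one.  Missing attribute scores are an error — the
    denominator is never silently reduced.
    """
    return float(_scores(record).mean())


def weighted_index(record: pd.Series | dict, w: WeightVector) -> float:
    """Weighted reflex-and-injury index ``sum_a w_a * attr_a``.

    Equal weights are evaluated as the plain arithmetic mean, so the
    reduction to :func:`ri_index` is exact in floating point, not just
    mathematically.
    """
    scores = _scores(record)
    if np.ptp(w.weights) == 0.0:
        return float(scores.mean())
    return float(scores @ w.weights)


def count_indicators(record: pd.Series | dict) -> tuple[int, int, int]:
    """(impaired reflexes, present injuries, both) for one fish."""
    vals = _scores(record)
    n_reflex = int(vals[: len(REFLEXES)].sum())
    n_injury = int(vals[len(REFLEXES):].sum())
    return n_reflex, n_injury, n_reflex + n_injury


def indicator_matrix(
    rs: RecordSet,
    spec: str,
    w: WeightVector | None = None,
) -> pd.DataFrame:
    """Numeric design columns for one indicator over a record set.

    Returns one column for the scalar indicators, three dummy columns
    for the categorical vitality grade (reference level A), ten binary
    columns for the partitioned indicator, and no columns for the null
    model.  Optimized-index specs require a weight vector.
    """
    if spec not in INDICATOR_SPECS:
        raise ValueError(f"unknown indicator spec {spec!r}")
    A = rs.attribute_matrix()
    if np.isnan(A).any():
        raise ValueError("attribute scores contain missing values; "
                         "apply complete_cases first")
    if spec in ("RI_opt_fish", "RI_opt_trip"):
        if w is None:
            raise ValueError(f"indicator {spec!r} requires a WeightVector")
        return pd.DataFrame({spec: A @ w.weights})
    if w is not None and spec not in ("RI_opt_fish", "RI_opt_trip"):
        raise ValueError(f"indicator {spec!r} does not take weights")
    if spec == "RI":
        return pd.DataFrame({"RI": A.mean(axis=1)})
    if spec == "n_reflex":
        return pd.DataFrame({"n_reflex": A[:, : len(REFLEXES)].sum(axis=1)})
    if spec == "n_injury":
        return pd.DataFrame({"n_injury": A[:, len(REFLEXES):].sum(axis=1)})
    if spec == "n_both":
        return pd.DataFrame({"n_both": A.sum(axis=1)})
    if spec == "categorical":
        vit = rs.df["vitality"]
        bad = ~vit.isin(VITALITY_LEVELS)
        if bad.any():
            raise ValueError(
                f"vitality level(s) outside A-D: {sorted(vit[bad].unique())}")
        return pd.DataFrame(
            {f"vitality_{lv}": (vit == lv).astype(float).to_numpy()
             for lv in VITALITY_LEVELS[1:]})
    if spec == "partitioned":
        return pd.DataFrame(A, columns=list(ATTRIBUTES))
    # null model: constant only
    return pd.DataFrame(index=pd.RangeIndex(rs.n))
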