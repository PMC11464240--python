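"""Binomial logistic GLM fitting for mortality models.

Models are of the form ``logit P(dead_i = 1) = alpha + x_i' beta`` with
an indicator column and optional covariate main effects / interactions.
Fitting is maximum likelihood via iteratively reweighted least squares
(IRLS, the canonical Fisher-scoring algorithm for canonical-link GLMs).
The implementation is intentionally lean: the weight-optimization stage
refits the same small GLM thousands of times inside its objective
function, so per-fit overhead dominates the pipeline's runtime.

No random effects are used: the aim is prediction, not inference on
cluster variance, and predictions to new random levels are not wanted.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .indicators import WeightVector, indicator_matrix
from .records_io import RecordSet

#: Named covariate sets; ``gear:sea_temp`` style entries are product terms
#: and always come with both main effects.
COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "none": (),
    "Length": ("length",),
    "SeaTemp": ("sea_temp",),
    "Gear": ("gear",),
    "Depth": ("depth",),
    "Duration": ("duration",),
    "TotalCatch": ("total_catch",),
    "AirExp": ("air_exposure",),
    "Gear*SeaTemp": ("gear", "sea_temp", "gear:sea_temp"),
    "SeaTemp*AirExp": ("sea_temp", "air_exposure", "sea_temp:air_exposure"),
}

MAX_ITER = 100
SCORE_TOL = 1e-8
DEVIANCE_RTOL = 1e-10
SEPARATION_EPS = 1e-8


class RankDeficientError(ValueError):
    """The design matrix is numerically rank deficient."""


@dataclasses.dataclass
class DesignMatrix:
    """Response and predictor matrix aligned with a RecordSet."""

    y: np.ndarray              # 1 = dead
    X: np.ndarray              # includes the intercept column
    columns: list[str]
    trips: np.ndarray          # trip id per row
    gears: np.ndarray          # gear type per row

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class FittedModel:
    coef: np.ndarray
    columns: list[str]
    llf: float
    aic: float
    k: int
    converged: bool
    separated: bool
    n_iter: int

    def params(self) -> pd.Series:
        return pd.Series(self.coef, index=self.columns)


def covariate_requirements(covariate_set: str) -> list[str]:
    """Covariate names needed for complete-case filtering of a set."""
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate set {covariate_set!r}; "
                         f"expected one of {sorted(COVARIATE_SETS)}")
    return [t for t in COVARIATE_SETS[covariate_set] if ":" not in t]


def _covariate_columns(rs: RecordSet, covariate_set: str) -> pd.DataFrame:
    terms = COVARIATE_SETS[covariate_set]
    base: dict[str, np.ndarray] = {}
    gear_dummy = (rs.df["gear_type"] == "OTB").astype(float).to_numpy()
    for term in terms:
        if term == "gear":
            if rs.df["gear_type"].nunique() < 2:
                raise RankDeficientError(
                    "gear term requested but only one gear type present")
            base["gear_OTB"] = gear_dummy
        elif ":" not in term:
            base[term] = rs.df[term].to_numpy(dtype=float)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            col_a = gear_dummy if a == "gear" else rs.df[a].to_numpy(dtype=float)
            col_b = gear_dummy if b == "gear" else rs.df[b].to_numpy(dtype=float)
            name_a = "gear_OTB" if a == "gear" else a
            name_b = "gear_OTB" if b == "gear" else b
            base[f"{name_a}:{name_b}"] = col_a * col_b
    out = pd.DataFrame(base)
    if out.isna().any().any():
        bad = [c for c in out.columns if out[c].isna().any()]
        raise ValueError(f"missing covariate values in {bad}; "
                         "apply complete_cases first")
    return out


def build_design(
    rs: RecordSet,
    indicator: str,
    covariate_set: str = "none",
    weights: WeightVector | None = None,
) -> DesignMatrix:
    """Assemble intercept + indicator columns + covariate terms.

    The gear factor is coded as one dummy (OTB vs the BT2 reference);
    interaction sets expand to both main effects plus the product term.
    The response is mortality coded 1 = dead.
    """
    ind = indicator_matrix(rs, indicator, weights)
    cov = _covariate_columns(rs, covariate_set)
    n = rs.n
    cols = ["intercept"] + list(ind.columns) + list(cov.columns)
    X = np.column_stack(
        [np.ones(n)]
        + [ind[c].to_numpy(dtype=float) for c in ind.columns]
        + [cov[c].to_numpy(dtype=float) for c in cov.columns]
    ) if cols != ["intercept"] else np.ones((n, 1))
    if len(set(cols)) != len(cols):
        raise ValueError(f"duplicate design columns in {cols}")
    return DesignMatrix(
        y=rs.mortality(),
        X=X,
        columns=cols,
        trips=rs.df["trip_id"].to_numpy(),
        gears=rs.df["gear_type"].to_numpy(),
    )


def _collinear_columns(X: np.ndarray, columns: Sequence[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [columns[i] for i in range(len(columns)) if diag[i] <= tol]


def fit_logistic(d: DesignMatrix, check_rank: bool = True) -> FittedModel:
    """Maximum-likelihood logistic fit by IRLS.

    Convergence when the largest score component is below 1e-8 or the
    relative deviance change is below 1e-10, within 100 iterations.
    Complete or quasi-separation is flagged when fitted probabilities
    sit within 1e-8 of 0 or 1 (the resolution the score tolerance can
    reach) on the matching outcome class; such fits are excluded from model ranking by
    the callers.  A rank-deficient design raises
    :class:`RankDeficientError` naming the collinear columns.
    """
    X, y = d.X, d.y
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more rows ({n}) than columns ({k})")
    if check_rank and np.linalg.matrix_rank(X) < k:
        raise RankDeficientError(
            f"design is rank deficient; suspect columns: "
            f"{_collinear_columns(X, d.columns)}")

    beta = np.zeros(k)
    eta = X @ beta
    p = expit(eta)
    deviance = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-10)
        score = X.T @ (y - p)
        XtWX = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        # |eta| capped at 30: expit is then within 1e-13 of 0/1, which is
        # beyond the separation threshold but keeps the logs finite.
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        new_deviance = -2.0 * float(
            np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        score_max = np.abs(X.T @ (y - p)).max()
        rel_change = abs(deviance - new_deviance) / (abs(new_deviance) + 0.1)
        deviance = new_deviance
        if score_max < SCORE_TOL or rel_change < DEVIANCE_RTOL:
            converged = True
            break

    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    separated = bool(
        ((p >= 1 - SEPARATION_EPS) & (y == 1)).any()
        or ((p <= SEPARATION_EPS) & (y == 0)).any()
    )
    return FittedModel(
        coef=beta,
        columns=list(d.columns),
        llf=llf,
        aic=2.0 * k - 2.0 * llf,
        k=k,
        converged=converged,
        separated=separated,
        n_iter=n_iter,
    )


def predict(m: FittedModel, d: DesignMatrix) -> np.ndarray:
    """Per-fish predicted death probability ``expit(X beta)``.

    Predicted survival is ``1 - predict(m, d)``.
    """
    if list(d.columns) != list(m.columns):
        raise ValueError(
            f"design columns {d.columns} do not match model {m.columns}")
    return expit(np.clip(d.X @ m.coef, -30, 30))


def fit_arrays(y: np.ndarray, X: np.ndarray,
               columns: Sequence[str] | None = None,
               check_rank: bool = True) -> FittedModel:
    """Fit directly from arrays (fast path for the optimizer objectives)."""
    d = DesignMatrix(
        y=np.asarray(y, dtype=float),
        X=np.asarray(X, dtype=float),
        columns=list(columns or [f"x{i}" for i in range(X.shape[1])]),
        trips=np.empty(len(y), dtype=object),
        gears=np.empty(len(y), dtype=object),
    )
    return fit_logistic(d, check_rank=check_rank)
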