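"""Optimization of the attribute weights of the weighted reflex-and-injury index.

The weighted index ``RI_w = sum_a w_a * attr_a`` replaces the
equal-weight index inside a logistic mortality GLM, and the weights are
chosen by nested optimization: the outer search moves the weight vector
on the unit simplex, the inner step refits the GLM and returns one of
two objectives —

* fish level: the AIC of the fitted model (lower is better), or
* trip level: the mean over trips of the absolute difference between
  predicted mean survival (averaging the per-fish predictions of the
  trip) and observed mean survival.

Twelve named optimization methods are run from the same uniform start
(every weight 0.1); if the converged methods agree the weighting is
considered trustworthy.  Because the named methods are unconstrained
optimizers while the weights live on the simplex, the search runs over
ten unconstrained parameters mapped through a softmax; near-zero
weights (< 5e-3) are snapped to exactly 0 and the vector renormalized
for reporting.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .glm_engine import (
    RankDeficientError,
    _covariate_columns,
    covariate_requirements,
    fit_arrays,
)
from .indicators import N_ATTRIBUTES, WeightVector
from .records_io import ATTRIBUTES, RecordSet

#: Objective value recorded when the inner GLM fails to converge (or
#: separates); keeps the outer search alive while marking the point bad.
FAILED_OBJECTIVE = float("inf")

SNAP_TOL = 5e-3

#: The twelve named optimization methods, mapped onto SciPy minimizers.
#: Derivative-free originals map to derivative-free equivalents
#: (Nelder-Mead simplex, Powell direction set, COBYLA); quasi-Newton and
#: gradient originals use finite-difference gradients.  Method-for-method
#: parity with the original routines is not promised — consistency
#: across this registry is what the consensus check relies on.
METHOD_REGISTRY: dict[str, dict] = {
    "Nelder-Mead": {"method": "Nelder-Mead", "nm_step": 0.5,
                    "options": {"xatol": 1e-3, "fatol": 1e-8,
                                "adaptive": False}},
    "BFGS": {"method": "BFGS", "options": {"gtol": 1e-4, "eps": 1e-5}},
    "CG": {"method": "CG", "options": {"gtol": 1e-4, "eps": 1e-5}},
    "L-BFGS-B": {"method": "L-BFGS-B",
                 "options": {"ftol": 1e-10, "gtol": 1e-5, "eps": 1e-5}},
    "ucminf": {"method": "BFGS",
               "options": {"gtol": 5e-5, "eps": 1e-5, "norm": np.inf}},
    "nlm": {"method": "Newton-CG", "options": {"xtol": 1e-6, "maxiter": 50},
            "numeric_jac": True},
    "nlminb": {"method": "TNC",
               "options": {"ftol": 1e-10, "xtol": 1e-8, "gtol": 1e-5,
                           "eps": 1e-5}},
    "spg": {"method": "SLSQP", "options": {"ftol": 1e-9, "eps": 1e-5}},
    "bobyqa": {"method": "Powell",
               "options": {"xtol": 1e-4, "ftol": 1e-8}},
    "newuoa": {"method": "COBYLA",
               "options": {"rhobeg": 0.5, "tol": 1e-8}},
    "nmkb": {"method": "Nelder-Mead", "nm_step": 0.25,
             "options": {"xatol": 1e-3, "fatol": 1e-8, "adaptive": True}},
    "hjkb": {"method": "Powell",
             "options": {"xtol": 1e-6, "ftol": 1e-10}},
}

DEFAULT_METHODS: tuple[str, ...] = tuple(METHOD_REGISTRY)


@dataclasses.dataclass
class OptimizationResult:
    """One (method x covariate-set x level) weight-optimization run."""

    method: str
    level: str                      # "fish" or "trip"
    covariate_set: str
    weights: WeightVector
    objective: float                # AIC (fish) or error term (trip)
    start_objective: float
    converged: bool
    n_evaluations: int
    wall_time: float                # seconds
    message: str = ""


@dataclasses.dataclass
class ConsensusReport:
    """Agreement of converged methods for one (level, covariate set)."""

    status: str                     # "trusted" | "not_trusted" | "insufficient"
    n_converged: int
    max_linf: float                 # largest pairwise weight distance
    spread: np.ndarray              # per-attribute max - min across methods
    best: OptimizationResult | None


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def snap_weights(w: np.ndarray, tol: float = SNAP_TOL) -> np.ndarray:
    """Zero out weights below ``tol`` and renormalize.

    Softmax outputs are never exactly zero; reported weight tables carry
    exact zeros for irrelevant attributes, and this reproduces them.
    """
    out = np.where(w < tol, 0.0, w)
    s = out.sum()
    if s <= 0:
        return w
    return out / s


def _objective_factory(
    rs: RecordSet,
    covariate_set: str,
    level: str,
) -> Callable[[np.ndarray], float]:
    """Build a fast objective over weight vectors.

    The attribute matrix, covariate columns and response are extracted
    once; each call assembles the design (intercept, weighted index,
    covariates), refits the GLM by IRLS and scores it.  Inner fits that
    fail to converge, or that separate, return ``FAILED_OBJECTIVE``.
    """
    if level not in ("fish", "trip"):
        raise ValueError(f"level must be 'fish' or 'trip', got {level!r}")
    needed = covariate_requirements(covariate_set)
    df = rs.df
    for col in ("gear_type" if c == "gear" else c for c in needed):
        if df[col].isna().any():
            raise ValueError(
                f"missing values in covariate {col!r}; apply complete_cases")
    A = rs.attribute_matrix()
    y = rs.mortality()
    cov = _covariate_columns(rs, covariate_set).to_numpy(dtype=float)
    n = len(y)
    ncov = cov.shape[1]
    X = np.empty((n, 2 + ncov))
    X[:, 0] = 1.0
    if ncov:
        X[:, 2:] = cov
    if level == "trip":
        trip_codes, trip_index = _trip_codes(df["trip_id"].to_numpy())
        n_trips = len(trip_index)
        if n_trips < 2:
            raise ValueError("trip-level objective needs at least 2 trips")
        trip_sizes = np.bincount(trip_codes, minlength=n_trips)
        obs_surv = np.bincount(trip_codes, weights=1.0 - y,
                               minlength=n_trips) / trip_sizes

    from scipy.special import expit

    def objective(w: np.ndarray) -> float:
        # equal weights reduce exactly to the arithmetic-mean index
        if np.ptp(w) == 0.0:
            X[:, 1] = A.mean(axis=1)
        else:
            X[:, 1] = A @ w
        # a constant index column (e.g. every attribute identical) is
        # collinear with the intercept; fit without it instead
        Xf = X if np.ptp(X[:, 1]) > 1e-12 else np.delete(X, 1, axis=1)
        try:
            m = fit_arrays(y, Xf, check_rank=False)
        except (RankDeficientError, np.linalg.LinAlgError, ValueError):
            return FAILED_OBJECTIVE
        if not m.converged or m.separated or not np.isfinite(m.llf):
            return FAILED_OBJECTIVE
        if level == "fish":
            return m.aic
        p = expit(np.clip(Xf @ m.coef, -30, 30))
        pred_surv = np.bincount(trip_codes, weights=1.0 - p,
                                minlength=n_trips) / trip_sizes
        return float(np.mean(np.abs(pred_surv - obs_surv)))

    return objective


def _trip_codes(trips: np.ndarray) -> tuple[np.ndarray, list]:
    index = list(dict.fromkeys(trips))
    lookup = {t: i for i, t in enumerate(index)}
    return np.array([lookup[t] for t in trips]), index


def fish_objective(w: WeightVector | np.ndarray, rs: RecordSet,
                   covariate_set: str = "none") -> float:
    """AIC of the mortality GLM using the weighted index as indicator."""
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    return _objective_factory(rs, covariate_set, "fish")(wv)


def trip_objective(w: WeightVector | np.ndarray, rs: RecordSet,
                   covariate_set: str = "none") -> float:
    """Mean absolute trip-level survival prediction error.

    Per trip, predicted mean survival is the average of the per-fish
    predicted survival probabilities; the objective is the mean over
    trips of |predicted - observed| mean survival.
    """
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    return _objective_factory(rs, covariate_set, "trip")(wv)


def _numeric_grad(f: Callable[[np.ndarray], float],
                  h: float = 1e-5) -> Callable[[np.ndarray], np.ndarray]:
    def grad(z: np.ndarray) -> np.ndarray:
        g = np.empty_like(z)
        for i in range(len(z)):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            g[i] = (f(zp) - f(zm)) / (2 * h)
        return g
    return grad


def optimize_weights(
    rs: RecordSet,
    covariate_set: str = "none",
    level: str = "fish",
    methods: Sequence[str] | None = None,
    start: WeightVector | None = None,
    max_evaluations: int = 4000,
) -> list[OptimizationResult]:
    """Run the method registry on one objective; one result per method.

    The outer search is over ten unconstrained parameters mapped through
    a softmax to the simplex; the default start is the uniform weight
    vector (softmax of zeros).  A run is recorded as converged when the
    minimizer reports success, the final objective is finite, and it
    does not exceed the start objective (descent contract).  All runs,
    converged or not, are returned.
    """
    if methods is None:
        methods = DEFAULT_METHODS
    if not methods:
        raise ValueError("empty method list")
    unknown = [m for m in methods if m not in METHOD_REGISTRY]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; registry has "
                         f"{sorted(METHOD_REGISTRY)}")
    start = start or WeightVector.uniform()
    f_w = _objective_factory(rs, covariate_set, level)
    start_objective = f_w(start.weights)
    # Normalize the outer objective by its start value so AIC-scale
    # (~1e3) and trip-error-scale (~1e-1) problems present comparable
    # gradients and tolerances to the minimizers.
    scale = abs(start_objective)
    if not np.isfinite(scale) or scale < 1e-8:
        scale = 1.0

    results: list[OptimizationResult] = []
    failures: dict[str, str] = {}
    for name in methods:
        spec = METHOD_REGISTRY[name]
        n_eval = 0
        best_seen: list = [np.inf, None]  # [objective, z]

        def f_z(z: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            if n_eval > max_evaluations:
                raise _BudgetExhausted
            val = f_w(softmax(z))
            if np.isfinite(val) and val < best_seen[0]:
                best_seen[0] = val
                best_seen[1] = np.array(z, dtype=float)
            # inf breaks several line searches; a large finite penalty
            # keeps them moving while staying far above any real value.
            return 1e12 if not np.isfinite(val) else val / scale

        # softmax(0) is the uniform vector; shift the start to match a
        # non-uniform starting weight when one is given.
        z0 = np.log(np.maximum(start.weights, 1e-8))
        z0 = z0 - z0.mean()
        kwargs = {k: (dict(v) if isinstance(v, dict) else v)
                  for k, v in spec.items()}
        numeric_jac = kwargs.pop("numeric_jac", False)
        nm_step = kwargs.pop("nm_step", None)
        # Let each backend run up to the shared evaluation budget instead
        # of its (often much smaller) built-in default cap.
        budget_keys = {"Nelder-Mead": ("maxfev",), "Powell": ("maxfev",),
                       "COBYLA": ("maxiter",), "L-BFGS-B": ("maxfun",),
                       "TNC": ("maxfun",)}
        for key in budget_keys.get(kwargs["method"], ()):
            kwargs["options"].setdefault(key, max_evaluations)
        if nm_step is not None:
            # simplex methods need a start simplex wide enough to sense
            # the objective; the default perturbation at z0 = 0 is tiny
            simplex = np.vstack([z0] + [z0 + nm_step * e
                                        for e in np.eye(len(z0))])
            kwargs["options"]["initial_simplex"] = simplex
        t0 = time.perf_counter()
        try:
            res = minimize(
                f_z, z0,
                jac=_numeric_grad(f_z) if numeric_jac else None,
                **kwargs,
            )
            success = bool(res.success)
            z_final = np.asarray(res.x, dtype=float)
            message = str(res.message)
        except _BudgetExhausted:
            success = False
            z_final = best_seen[1] if best_seen[1] is not None else z0
            message = f"evaluation budget ({max_evaluations}) exhausted"
        except Exception as exc:  # pragma: no cover - defensive
            success = False
            z_final = best_seen[1] if best_seen[1] is not None else z0
            message = f"{type(exc).__name__}: {exc}"
        wall = time.perf_counter() - t0

        w_raw = softmax(z_final)
        w_snap = snap_weights(w_raw)
        obj_snap = f_w(w_snap)
        obj_raw = f_w(w_raw)
        # Snapping tiny weights to zero must not break the descent
        # contract; fall back to the raw softmax weights if it would.
        if obj_snap <= obj_raw + 1e-9:
            w_final, obj_final = w_snap, obj_snap
        else:
            w_final, obj_final = w_raw, obj_raw
        converged = (success and np.isfinite(obj_final)
                     and obj_final <= start_objective + 1e-9)
        if not converged and not success:
            failures[name] = message
        results.append(OptimizationResult(
            method=name,
            level=level,
            covariate_set=covariate_set,
            weights=WeightVector(w_final, level),
            objective=float(obj_final),
            start_objective=float(start_objective),
            converged=converged,
            n_evaluations=n_eval,
            wall_time=wall,
            message=message,
        ))
    if len(failures) == len(methods):
        raise RuntimeError(f"all optimization methods failed: {failures}")
    return results


class _BudgetExhausted(Exception):
    pass


def check_consistency(
    results: Sequence[OptimizationResult],
    tol: float = 0.05,
) -> ConsensusReport:
    """Compare converged runs of one (level, covariate set) batch.

    The weighting is flagged ``trusted`` when every pair of converged
    methods agrees within L-infinity distance ``tol``.  The best result
    is the converged run with the lowest objective (ties broken by
    shortest wall time, then registry order).
    """
    conv = [r for r in results if r.converged]
    if len({(r.level, r.covariate_set) for r in results}) > 1:
        raise ValueError("results mix levels or covariate sets")
    if len(conv) < 2:
        best = _select_best(conv)
        return ConsensusReport("insufficient", len(conv), float("nan"),
                               np.full(N_ATTRIBUTES, np.nan), best)
    W = np.stack([r.weights.weights for r in conv])
    diffs = np.abs(W[:, None, :] - W[None, :, :]).max(axis=2)
    max_linf = float(diffs.max())
    status = "trusted" if max_linf <= tol else "not_trusted"
    return ConsensusReport(
        status=status,
        n_converged=len(conv),
        max_linf=max_linf,
        spread=W.max(axis=0) - W.min(axis=0),
        best=_select_best(conv),
    )


def _select_best(conv: Sequence[OptimizationResult]) -> OptimizationResult | None:
    if not conv:
        return None
    order = {name: i for i, name in enumerate(METHOD_REGISTRY)}
    return min(conv, key=lambda r: (r.objective, r.wall_time,
                                    order.get(r.method, len(order))))


def classify_relevance(
    weight: float,
    wall_time: float = 0.0,
    time_threshold: float = float("inf"),
) -> str:
    """Relevance class of one attribute weight.

    ``little`` for weights at or below the uniform 0.10, ``medium`` up
    to 0.20, ``high`` above 0.20; weights above 0.30 produced by runs
    with unusually long optimization times are flagged ``outlier``.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight {weight} outside [0, 1]")
    if weight > 0.30 and wall_time > time_threshold:
        return "outlier"
    if weight <= 0.10:
        return "little"
    if weight <= 0.20:
        return "medium"
    return "high"


def relevance_classes(
    w: WeightVector,
    wall_time: float = 0.0,
    time_threshold: float = float("inf"),
) -> dict[str, str]:
    """Relevance class per attribute, canonical order."""
    return {a: classify_relevance(float(x), wall_time, time_threshold)
            for a, x in zip(ATTRIBUTES, w.weights)}
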