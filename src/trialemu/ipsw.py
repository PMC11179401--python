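"""Inverse propensity score weighting for the registry arms.

A self-contained maximum-likelihood logistic regression (IRLS) predicts
trial membership from age, female indicator and baseline letters.  Registry
eyes receive ATT odds weights ``p / (1 - p)``, rescaled to sum to the
registry arm size so weighted tallies are directly comparable to cohort N.

The estimand choice (trial arm as the target population, odds weights on
registry eyes only) is an interpretation: the source analysis names the
model but not its weight formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityFit",
    "WeightSet",
    "SeparationError",
    "fit_logistic",
    "predict_proba",
    "att_weights",
    "weighted_mean_sd",
    "smd",
    "effective_n",
    "balance_report",
    "design_matrix",
]

#: Covariates used throughout: age (years, top-coded), female flag, letters.
COVARIATES = ("age", "female", "baseline_letters")


class SeparationError(RuntimeError):
    """The likelihood has no finite maximiser (quasi-complete separation)."""


@dataclass
class PropensityFit:
    coefficients: dict[str, float]  # intercept first, then feature names
    converged: bool
    log_likelihood: float
    n_iterations: int
    feature_names: tuple[str, ...]

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array(
            [self.coefficients["intercept"]]
            + [self.coefficients[f] for f in self.feature_names]
        )


@dataclass
class WeightSet:
    eye_ids: list[str]
    weights: np.ndarray  # positive, sums to n_target
    n_target: float
    n_capped: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.eye_ids, name="weight")


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    covariates,
    labels,
    feature_names: Optional[Sequence[str]] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PropensityFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``covariates`` is an (n, p) design *without* the intercept column; the
    intercept is added internally.  Convergence is declared when the
    coefficient max-change drops to ``tol``; separation or a singular
    information matrix leaves ``converged=False``.
    """
    X0 = np.asarray(covariates, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one row of each label")
    if np.any(X0.std(axis=0) == 0):
        raise ValueError("constant covariate column is collinear with intercept")
    names = tuple(feature_names or (f"x{i}" for i in range(X0.shape[1])))
    X = np.column_stack([np.ones(len(X0)), X0])

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        # singular information signals separation along some direction
        try:
            delta = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            converged = False
            break
        beta = beta + delta
        if not np.all(np.isfinite(beta)):
            converged = False
            break
        if np.max(np.abs(delta)) <= tol:
            converged = True
            break

    # quasi-complete separation: fitted probabilities pinned at 0/1
    eta = X @ beta
    p = expit(eta)
    if converged and (np.max(np.abs(beta[1:])) > 1e6 or np.all((p > 1 - 1e-12) == (y == 1))):
        if np.all(p[y == 1] > 1 - 1e-8) and np.all(p[y == 0] < 1e-8):
            converged = False

    coefs = {"intercept": float(beta[0])}
    coefs.update({name: float(b) for name, b in zip(names, beta[1:])})
    fit = PropensityFit(
        coefficients=coefs,
        converged=converged,
        log_likelihood=_log_likelihood(X, y, beta),
        n_iterations=it,
        feature_names=names,
    )
    if not converged:
        logger.warning("logistic fit did not converge after %d iterations", it)
    return fit


def predict_proba(fit: PropensityFit, covariates) -> np.ndarray:
    X0 = np.asarray(covariates, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    X = np.column_stack([np.ones(len(X0)), X0])
    return expit(X @ fit.coef_vector)


def design_matrix(frame: pd.DataFrame) -> np.ndarray:
    """(age, female, baseline_letters) design rows from a cohort/trial table."""
    age_col = "age" if "age" in frame.columns else "age_at_index"
    return np.column_stack(
        [
            frame[age_col].to_numpy(dtype=float),
            (frame["gender"] == "F").to_numpy(dtype=float),
            frame["baseline_letters"].to_numpy(dtype=float),
        ]
    )


def att_weights(
    fit: PropensityFit,
    registry_rows: pd.DataFrame,
    p_max: float = 0.999,
) -> WeightSet:
    """ATT odds weights ``p / (1 - p)`` for registry eyes, rescaled to N.

    ``p`` is the predicted probability of trial membership.  Probabilities
    above ``p_max`` are capped (count reported, never silent) to guard the
    odds transform.
    """
    if not fit.converged:
        raise SeparationError("refusing weights from a non-converged fit")
    X = design_matrix(registry_rows)
    p = predict_proba(fit, X)
    n_capped = int(np.sum(p > p_max))
    if n_capped:
        logger.warning("capped %d propensity values at %g", n_capped, p_max)
    p = np.minimum(p, p_max)
    raw = p / (1.0 - p)
    n = len(registry_rows)
    weights = raw * (n / raw.sum())
    ids = [
        f"{r.patient_id}:{r.laterality}"
        for r in registry_rows.itertuples(index=False)
    ]
    return WeightSet(eye_ids=ids, weights=weights, n_target=float(n), n_capped=n_capped)


def weighted_mean_sd(values, weights) -> tuple[float, float]:
    """Weighted mean and SD under the frequency-weight convention.

    The SD denominator is ``sum(w) - 1`` so uniform unit weights reproduce
    the ordinary sample SD exactly.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    if sw <= 1:
        raise ValueError("sum of weights must exceed 1")
    mean = float((w * x).sum() / sw)
    var = float((w * (x - mean) ** 2).sum() / (sw - 1.0))
    return mean, float(np.sqrt(var))


def smd(
    group_a,
    group_b,
    weights_b=None,
) -> float:
    """Standardized mean difference ``(mean_a - mean_b) / pooled SD``.

    ``weights_b`` reweights group B (the registry side).  Returns ``nan``
    when the pooled SD degenerates to zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    mean_a, sd_a = float(a.mean()), float(a.std(ddof=1))
    if weights_b is None:
        mean_b, sd_b = float(b.mean()), float(b.std(ddof=1))
    else:
        mean_b, sd_b = weighted_mean_sd(b, weights_b)
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0:
        return float("nan")
    return (mean_a - mean_b) / pooled


def effective_n(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight set")
    return float(w.sum() ** 2 / (w**2).sum())


def balance_report(
    trial_rows: pd.DataFrame,
    registry_rows: pd.DataFrame,
    weights: WeightSet,
) -> pd.DataFrame:
    """Per-covariate SMD before/after weighting plus the effective n."""
    Xa = design_matrix(trial_rows)
    Xb = design_matrix(registry_rows)
    rows = []
    for j, name in enumerate(COVARIATES):
        rows.append(
            {
                "covariate": name,
                "smd_before": smd(Xa[:, j], Xb[:, j]),
                "smd_after": smd(Xa[:, j], Xb[:, j], weights_b=weights.weights),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["effective_n"] = effective_n(weights.weights)
    return report
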