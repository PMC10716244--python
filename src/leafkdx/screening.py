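"""Influence-factor feature screening via multiple linear regression.

Each feature's influence factor is the magnitude of its standardized
regression coefficient: both the 22 features and the response (measured
leaf potassium content by default) are z-scored, an ordinary
least-squares fit is taken, and factor(f) = |coef(f)|.  Features whose
factor falls below the arithmetic mean of all factors are dropped; the
mean plays the role of the 0.35 cutoff reported for the original field
data, and a fixed threshold can be supplied to reproduce that behavior.

The transformer is sklearn-compatible: ``fit(X, y)`` computes the
:class:`InfluenceReport`, ``transform(X)`` keeps the retained columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = [
    "InfluenceReport",
    "InfluenceScreen",
    "standardize",
    "fit_mlr",
    "influence_factors",
    "screen",
]


class ConstantColumnError(ValueError):
    pass


class RankDeficientError(ValueError):
    pass


@dataclass
class InfluenceReport:
    """Per-feature influence factors and the mean-threshold retention rule."""

    factors: dict[str, float]
    threshold: float
    retained: list[str]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "factors": self.factors,
            "threshold": self.threshold,
            "retained": self.retained,
            "n_samples": self.n_samples,
        }


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns (population sd); returns (Z, means, sds) for reuse."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ConstantColumnError(f"constant column(s) at index {bad.tolist()}")
    return (X - mu) / sd, mu, sd


def fit_mlr(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordinary least squares of y on Z (with intercept).

    Returns (coefficients, intercept).  Residuals are orthogonal to the
    design columns; rank deficiency raises with the offending columns.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need n_samples > n_features, got n={n}, p={p}")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < p + 1:
        # columns that do not increase the rank of the preceding ones
        dep, rank = [], 1
        for j in range(p):
            r = np.linalg.matrix_rank(design[:, : j + 2])
            if r == rank:
                dep.append(j)
            rank = r
        raise RankDeficientError(f"rank-deficient design; dependent column(s): {dep}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:], float(beta[0])


def fit_mlr_minnorm(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-norm OLS (pseudoinverse): tolerant of exact collinearity.

    The 22-feature table is structurally rank-deficient — the
    chromaticity coordinates satisfy NRI+NGI+NBI = 1 — so screening uses
    this solver; the minimum-norm solution shares a collinear group's
    weight symmetrically and is deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(Z)), Z])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:], float(beta[0])


def influence_factors(coefficients: np.ndarray, names: list[str] | None = None) -> dict[str, float]:
    """Influence factor = |standardized coefficient|, keyed by feature name."""
    coefs = np.abs(np.asarray(coefficients, dtype=float))
    if names is None:
        names = [f"x{i}" for i in range(len(coefs))]
    return dict(zip(names, coefs.tolist()))


def screen(factors: dict[str, float], threshold: float | None = None) -> InfluenceReport:
    """Retain features whose factor reaches the (mean) threshold.

    The retained set is never empty: the maximum factor is always ≥ the
    mean.  Canonical (input) feature order is preserved.
    """
    if not factors:
        raise ValueError("need at least one factor")
    vals = np.asarray(list(factors.values()), dtype=float)
    thr = float(vals.mean()) if threshold is None else float(threshold)
    # tolerance keeps the max >= mean guarantee under float summation error
    tol = 1e-9 * max(1.0, abs(thr))
    retained = [f for f, v in factors.items() if v >= thr - tol]
    if not retained:  # only reachable with an explicit too-high override
        raise ValueError(f"threshold {thr} retains no feature")
    return InfluenceReport(factors=dict(factors), threshold=thr, retained=retained, n_samples=0)


class InfluenceScreen(TransformerMixin, BaseEstimator):
    """Mean-threshold influence-factor feature selector.

    Parameters
    ----------
    response : {"k_content", "label"} or None
        Which response the MLR regresses on when ``fit`` receives a
        DataFrame carrying both; with a plain array, ``y`` is used as-is.
    threshold : float or None
        Fixed cutoff overriding the mean-of-factors rule (e.g. 0.35).

    Attributes
    ----------
    report_ : InfluenceReport
    retained_ : list of retained feature names
    support_ : boolean mask over input columns
    """

    def __init__(self, response: str = "k_content", threshold: float | None = None):
        self.response = response
        self.threshold = threshold

    def fit(self, X, y):
        X_arr, names = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X_arr.shape[0]:
            raise ValueError("X and y length mismatch")
        Z, self.feature_means_, self.feature_sds_ = standardize(X_arr)
        y_sd = y.std()
        if y_sd == 0:
            raise ConstantColumnError("response is constant")
        zy = (y - y.mean()) / y_sd
        try:
            coefs, _ = fit_mlr(Z, zy)
        except RankDeficientError as exc:
            log.warning("collinear features (%s); using minimum-norm OLS", exc)
            coefs, _ = fit_mlr_minnorm(Z, zy)
        factors = influence_factors(coefs, names)
        self.report_ = screen(factors, self.threshold)
        self.report_.n_samples = X_arr.shape[0]
        self.feature_names_in_ = np.asarray(names)
        self.retained_ = list(self.report_.retained)
        self.support_ = np.asarray([n in set(self.retained_) for n in names])
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.retained_ if n not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            return X[self.retained_]
        return np.asarray(X, dtype=float)[:, self.support_]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]
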