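"""Fisher linear discriminant projection.

Maximizes the generalized Rayleigh quotient wᵀS_B w / wᵀS_W w, where S_W
and S_B are the (unnormalized) within- and between-class scatter
matrices.  For a two-class problem the between-class scatter has rank 1,
so only the leading discriminant carries class information; a 2-D output
is still supported for visualization, padding with the next generalized
eigenvector (near-zero eigenvalue) under an ε-ridge on S_W — an explicit
convention, flagged with a warning, not a claim that a second genuine
discriminant exists.

Deterministic by construction: eigenvectors are unit-normalized with the
first nonzero component forced positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = ["LDAProjection", "FisherLDA", "scatter_matrices", "lda_fit", "lda_transform"]


def scatter_matrices(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter; S_W + S_B = total scatter.

    S_W = Σ_c Σ_{i∈c} (x_i − μ_c)(x_i − μ_c)ᵀ,
    S_B = Σ_c n_c (μ_c − μ)(μ_c − μ)ᵀ.
    Every class needs ≥ 2 samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    p = X.shape[1]
    mu = X.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mc = Xc.mean(axis=0)
        d = Xc - mc
        s_w += d.T @ d
        dm = (mc - mu)[:, None]
        s_b += Xc.shape[0] * (dm @ dm.T)
    return s_w, s_b


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Unit columns with the first nonzero component positive."""
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    for j in range(V.shape[1]):
        nz = np.nonzero(np.abs(V[:, j]) > 1e-12)[0]
        if nz.size and V[nz[0], j] < 0:
            V[:, j] = -V[:, j]
    return V


@dataclass
class LDAProjection:
    within_scatter: np.ndarray
    between_scatter: np.ndarray
    eigenvalues: np.ndarray  # descending
    projection: np.ndarray  # p × d, unit columns
    class_means: dict[int, np.ndarray]
    feature_names: list[str] | None = None
    period: str | None = None

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "projection": self.projection.tolist(),
            "class_means": {str(k): v.tolist() for k, v in self.class_means.items()},
            "feature_names": self.feature_names,
            "period": self.period,
        }


def lda_fit(
    X: np.ndarray,
    labels: np.ndarray,
    d: int = 2,
    feature_names: list[str] | None = None,
) -> LDAProjection:
    """Top-d generalized eigenvectors of (S_W, S_B) by descending eigenvalue.

    A singular S_W is regularized by adding εI with ε = 1e-6·trace(S_W)/p
    (logged).  When d exceeds rank(S_B) — always the case for d=2 with two
    classes — the extra directions are the padding convention described in
    the module docstring and a warning is raised.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    s_w, s_b = scatter_matrices(X, labels)
    p = s_w.shape[0]
    if d > p:
        raise ValueError(f"cannot extract d={d} directions from p={p} features")

    sw = s_w
    try:
        np.linalg.cholesky(sw)
    except np.linalg.LinAlgError:
        eps = 1e-6 * np.trace(sw) / p
        log.warning("singular within-class scatter; adding ridge eps=%.3g", eps)
        sw = sw + eps * np.eye(p)

    evals, evecs = scipy.linalg.eigh(s_b, sw)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)  # clip eigenvalue noise at zero

    rank_b = int(np.linalg.matrix_rank(s_b))
    if d > rank_b:
        warnings.warn(
            f"requested {d} discriminants but between-class scatter has rank "
            f"{rank_b}; dimensions beyond {rank_b} are near-zero-eigenvalue padding",
            stacklevel=2,
        )
    W = _fix_signs(evecs[:, :d].copy())

    classes = np.unique(labels)
    means = {int(c): X[labels == c].mean(axis=0) for c in classes}
    return LDAProjection(
        within_scatter=s_w,
        between_scatter=s_b,
        eigenvalues=evals[:d],
        projection=W,
        class_means=means,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def lda_transform(proj: LDAProjection, X, feature_names: list[str] | None = None) -> np.ndarray:
    """Project samples: X · W.  Feature names, when given, must match the fit."""
    if feature_names is not None and proj.feature_names is not None:
        if list(feature_names) != list(proj.feature_names):
            extra = sorted(set(feature_names) - set(proj.feature_names))
            missing = sorted(set(proj.feature_names) - set(feature_names))
            raise ValueError(f"feature mismatch: missing={missing}, unexpected={extra}")
    return np.asarray(X, dtype=float) @ proj.projection


class FisherLDA(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`lda_fit` / :func:`lda_transform`.

    Parameters
    ----------
    n_components : int, default 2
        Output dimensionality; values above rank(S_B) are padded (see
        module docstring) with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
        self.projection_ = lda_fit(
            np.asarray(X, dtype=float), np.asarray(y), d=self.n_components, feature_names=names
        )
        self.eigenvalues_ = self.projection_.eigenvalues
        return self

    def transform(self, X):
        check_is_fitted(self, "projection_")
        names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
        return lda_transform(self.projection_, np.asarray(X, dtype=float), names)
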