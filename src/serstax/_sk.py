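"""Shared scikit-learn building blocks."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.pipeline import Pipeline
from sklearn.svm import SVR


class FlooredScaler(BaseEstimator, TransformerMixin):
    """Standardize features, flooring tiny scales.

    A feature that is (near-)constant in training — e.g. a fit parameter
    pinned at its bound — would otherwise receive an enormous scale factor
    and dominate every distance downstream.  Scales below ``floor_frac``
    of the median feature scale are clamped to that floor.
    """

    def __init__(self, floor_frac: float = 1e-3):
        self.floor_frac = floor_frac

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        positive = scale[scale > 0]
        ref = np.median(positive) if positive.size else 1.0
        floor = self.floor_frac * ref
        self.scale_ = np.where(scale < floor, floor, scale)
        return self

    def transform(self, X):
        return (np.asarray(X, float) - self.mean_) / self.scale_


class CappedPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the components explaining ``variance`` of the total,
    capped at ``cap`` components (overfitting guard ahead of SVR)."""

    def __init__(self, variance: float = 0.99, cap: int = 15):
        self.variance = variance
        self.cap = cap

    def fit(self, X, y=None):
        X = np.asarray(X)
        limit = min(X.shape[0], X.shape[1])
        probe = PCA(n_components=limit, svd_solver="full").fit(X)
        cum = np.cumsum(probe.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance) + 1)
        k = max(1, min(k, self.cap, limit))
        self.pca_ = PCA(n_components=k, svd_solver="full").fit(X)
        self.n_components_ = k
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X))


def make_screened_svr(c: float, epsilon: float, k: int = 8) -> Pipeline:
    """Standardize -> univariate screening -> linear SVR.

    Keeps the ``k`` features most correlated with the target (univariate F
    test) before the regression.  Features carrying no target information
    get exactly zero weight, so a shift along such a feature at prediction
    time — e.g. a concentration-driven intensity change in a band that is
    class-independent — cannot bias the estimate.  Used for the
    chain-length regressors, whose deployment regime includes inputs far
    from the training concentration.
    """
    from sklearn.feature_selection import SelectKBest, f_regression

    return Pipeline([
        ("scale", FlooredScaler()),
        ("screen", SelectKBest(f_regression, k=k)),
        ("svr", SVR(kernel="linear", C=c, epsilon=epsilon)),
    ])


def make_linear_svr(c: float, epsilon: float) -> Pipeline:
    """Standardize (floored) -> linear support vector regression.

    The regression targets (chain length, log concentration, mol fraction)
    enter the peak parameters linearly by construction of the measurement,
    so a linear epsilon-SVR projects onto the informative direction and is
    insensitive to the many orthogonal noise dimensions that dominate
    sample-to-sample distances in the 95-feature space.
    """
    return Pipeline([
        ("scale", FlooredScaler()),
        ("svr", SVR(kernel="linear", C=c, epsilon=epsilon)),
    ])
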