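"""Phylogenetic principal component analysis under Pagel's lambda.

The analysis estimates lambda by maximum likelihood for the joint
multivariate Brownian model, computes the generalized-least-squares
(phylogenetic) trait means and the evolutionary covariance matrix

    R = (X - 1 a')' C(lambda)^-1 (X - 1 a') / (n - 1),

and eigendecomposes R.  Scores are the centred data projected on the
eigenvectors; loadings are the evolutionary correlations between traits and
scores.  On a star phylogeny (C proportional to I) everything reduces to
ordinary PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .tree import PhyloTree
from .traits import TraitMatrix


def _as_frame(traits, sex: str | None = None) -> pd.DataFrame:
    if isinstance(traits, TraitMatrix):
        if traits.scale != "log":
            raise ValueError("phylogenetic PCA expects log-scale traits")
        if sex is None:
            raise ValueError("pass sex= when supplying a TraitMatrix")
        frame = traits.sex_table(sex)
    else:
        frame = pd.DataFrame(traits)
    if frame.isna().to_numpy().any():
        raise ValueError("trait matrix must be complete (impute first)")
    return frame.astype(float)


def _loglik(lam: float, X: np.ndarray, C0: np.ndarray, diag: np.ndarray) -> float:
    """Joint multivariate-Brownian log-likelihood at a given lambda.

    Per-trait rates are profiled out through the ML covariance estimate:
    logL = -1/2 [ n p ln 2pi + p ln|C| + n ln|R_ml| + n p ].
    """
    n, p = X.shape
    C = lam * C0
    np.fill_diagonal(C, diag)
    cf = cho_factor(C, lower=True)
    logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (Ci1 @ X) / (one @ Ci1)
    Xc = X - a
    R_ml = Xc.T @ cho_solve(cf, Xc) / n
    sign, logdet_R = np.linalg.slogdet(R_ml)
    if sign <= 0:
        return -np.inf
    return -0.5 * (n * p * np.log(2 * np.pi) + p * logdet_C + n * logdet_R + n * p)


def estimate_lambda(
    traits, tree: PhyloTree, sex: str | None = None, tol: float = 1e-6
) -> tuple[float, float]:
    """ML estimate of Pagel's lambda on [0, 1] for a complete log matrix.

    Returns (lambda_hat, log-likelihood at the optimum).
    """
    frame = _as_frame(traits, sex)
    if len(frame) < 3:
        raise ValueError("need at least 3 species")
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric; lambda transform still defined",
                      stacklevel=2)
    sub = tree.prune(frame.index)
    C0 = sub.covariance().loc[frame.index, frame.index].to_numpy().copy()
    diag = np.diag(C0).copy()
    X = frame.to_numpy()

    res = minimize_scalar(
        lambda lam: -_loglik(lam, X, C0.copy(), diag),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    lam = float(res.x)
    ll = float(-res.fun)
    # the bounded optimizer never evaluates the exact endpoints; snap if better
    for edge in (0.0, 1.0):
        ll_edge = _loglik(edge, X, C0.copy(), diag)
        if ll_edge > ll:
            lam, ll = edge, float(ll_edge)
    return lam, ll


@dataclass
class PCAResult:
    """Phylogenetic PCA output (one sex at a time)."""

    lam: float
    loglik: float
    scores: pd.DataFrame        # species x axes
    loadings: pd.DataFrame      # traits x axes, evolutionary correlations
    variance_pct: pd.Series     # per axis, sums to 100
    phylo_mean: pd.Series       # GLS ancestral trait means
    eigenvalues: np.ndarray


class PhylogeneticPCA(BaseEstimator):
    """sklearn-style estimator for lambda-transformed phylogenetic PCA.

    Parameters
    ----------
    tree : PhyloTree
        Ultrametric phylogeny covering the analysed species.
    lam : "ml" or float in [0, 1]
        Pagel's lambda; "ml" (default) estimates it by maximum likelihood.

    Fitted attributes: ``lambda_``, ``loglik_``, ``phylo_mean_``,
    ``eigenvalues_``, ``components_`` (eigenvectors, traits x axes),
    ``loadings_``, ``variance_pct_``, ``scores_``.
    """

    def __init__(self, tree: PhyloTree, lam: str | float = "ml"):
        self.tree = tree
        self.lam = lam

    def fit(self, X, y=None, sex: str | None = None) -> "PhylogeneticPCA":
        frame = _as_frame(X, sex)
        sub = self.tree.prune(frame.index)
        order = frame.index
        C0 = sub.covariance().loc[order, order].to_numpy().copy()
        diag = np.diag(C0).copy()
        M = frame.to_numpy()
        n, p = M.shape

        if self.lam == "ml":
            lam, ll = estimate_lambda(frame, sub)
        else:
            lam = float(self.lam)
            ll = _loglik(lam, M, C0.copy(), diag)

        C = lam * C0
        np.fill_diagonal(C, diag)
        cf = cho_factor(C, lower=True)
        one = np.ones(n)
        Ci1 = cho_solve(cf, one)
        a = (Ci1 @ M) / (one @ Ci1)
        Mc = M - a
        R = Mc.T @ cho_solve(cf, Mc) / (n - 1)
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        order_ax = np.argsort(vals)[::-1]
        vals, vecs = vals[order_ax], vecs[:, order_ax]

        sd = np.sqrt(np.diag(R))
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = vecs * np.sqrt(np.clip(vals, 0.0, None)) / sd[:, None]
        # orientation: largest-|loading| trait positive on every axis
        for j in range(p):
            i = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i, j] < 0:
                loadings[:, j] = -loadings[:, j]
                vecs[:, j] = -vecs[:, j]
        scores = Mc @ vecs

        axes = [f"PC{j + 1}" for j in range(p)]
        self.lambda_ = lam
        self.loglik_ = ll
        self.phylo_mean_ = pd.Series(a, index=frame.columns)
        self.eigenvalues_ = vals
        self.components_ = pd.DataFrame(vecs, index=frame.columns, columns=axes)
        self.loadings_ = pd.DataFrame(loadings, index=frame.columns, columns=axes)
        self.variance_pct_ = pd.Series(
            100.0 * vals / vals.sum(), index=axes, name="variance_pct"
        )
        self.scores_ = pd.DataFrame(scores, index=frame.index, columns=axes)
        return self

    def transform(self, X, sex: str | None = None) -> pd.DataFrame:
        frame = _as_frame(X, sex)
        Mc = frame[self.phylo_mean_.index].to_numpy() - self.phylo_mean_.to_numpy()
        return pd.DataFrame(
            Mc @ self.components_.to_numpy(),
            index=frame.index,
            columns=self.components_.columns,
        )

    def fit_transform(self, X, y=None, sex: str | None = None) -> pd.DataFrame:
        return self.fit(X, sex=sex).scores_

    def result_(self) -> PCAResult:
        return PCAResult(
            lam=self.lambda_,
            loglik=self.loglik_,
            scores=self.scores_,
            loadings=self.loadings_,
            variance_pct=self.variance_pct_,
            phylo_mean=self.phylo_mean_,
            eigenvalues=self.eigenvalues_,
        )


def phylo_pca(
    traits, tree: PhyloTree, sex: str | None = None, lam: str | float = "ml"
) -> PCAResult:
    """Functional wrapper: lambda-transformed phylogenetic PCA."""
    return PhylogeneticPCA(tree, lam=lam).fit(traits, sex=sex).result_()
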