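"""Polynomial functional space of mechanical-advantage curves.

Each MA curve is summarised by the coefficients of a polynomial in the
normalized edge position s in [0, 1], fitted by ordinary least squares.  A
single polynomial order is chosen for all specimens by minimising a pooled
Gaussian AIC; the per-specimen coefficients then form a specimens x
descriptors matrix — the functional space — which is ordinated by principal
component analysis.  In this space the leading axis typically codes for the
vertical position (overall force-transmission level) of the curve and the
second for its curvature (linear versus gently exponential decrease).

The AIC uses the conventional least-squares form: per curve, a Gaussian
likelihood with the maximum-likelihood error variance rss/n, pooled by
summation over curves, with ``order + 2`` parameters per curve (the
coefficients plus one error variance).  Ties are broken toward the lower
order (parsimony).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SklearnPCA

from .mechanics import MACurve

DESCRIPTOR_POLICIES = ("exclude_intercept", "include_intercept")


@dataclass
class PolynomialFit:
    """Least-squares polynomial summary of one MA curve."""

    specimen_id: str
    order: int
    coefficients: np.ndarray  # intercept first, then increasing powers of s
    rss: float
    n: int

    def predict(self, s: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(s, float),
                                                self.coefficients)


@dataclass
class FunctionalSpace:
    """Coefficient matrix of a set of curves, with optional PCA ordination."""

    specimen_ids: list[str]
    coefficient_matrix: np.ndarray  # specimens x descriptors
    descriptor_policy: str
    order: int
    pc_scores: np.ndarray | None = None
    pc_loadings: np.ndarray | None = None  # components x descriptors
    eigenvalues: np.ndarray | None = None
    variance_explained: np.ndarray | None = None  # percentages, sum to 100


def fit_polynomial(curve: MACurve, order: int) -> PolynomialFit:
    """OLS fit of ma on powers of s up to `order` (deterministic).

    Raises if the design is rank deficient or has more parameters than
    points.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order + 1 > curve.n_points:
        raise ValueError(
            f"{curve.specimen_id}: order {order} needs at least {order + 1} "
            f"points, curve has {curve.n_points}")
    design = np.vander(curve.s, order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise ValueError(f"{curve.specimen_id}: rank-deficient design for order {order}")
    coef, _, _, _ = np.linalg.lstsq(design, curve.ma, rcond=None)
    resid = curve.ma - design @ coef
    return PolynomialFit(curve.specimen_id, order, coef,
                         float(resid @ resid), curve.n_points)


def _pooled_aic(fits: list[PolynomialFit]) -> float:
    """Least-squares AIC pooled over curves.

    Per curve: logLik = -n/2 (log(2 pi rss/n) + 1) at the MLE variance
    rss/n; parameters = coefficients + one variance.  rss is clamped away
    from zero so that numerically perfect fits do not produce -inf.
    """
    loglik = 0.0
    k_total = 0
    for f in fits:
        sigma2 = max(f.rss, 1e-300) / f.n
        loglik += -0.5 * f.n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        k_total += f.order + 2
    return 2.0 * k_total - 2.0 * loglik


def select_order_by_aic(curves: list[MACurve],
                        candidate_orders: Iterable[int],
                        ) -> tuple[int, dict[int, float]]:
    """Choose one polynomial order for all curves by pooled AIC.

    Every candidate order is fitted to every curve; the pooled AIC is
    minimised, ties broken toward the lower order.  Returns the selected
    order and the full order -> AIC table.
    """
    if not curves:
        raise ValueError("no curves supplied")
    orders = sorted(set(int(q) for q in candidate_orders))
    if not orders:
        raise ValueError("no candidate orders supplied")
    aic_by_order = {
        q: _pooled_aic([fit_polynomial(c, q) for c in curves]) for q in orders}
    best = min(orders, key=lambda q: (aic_by_order[q], q))
    return best, aic_by_order


def build_coefficient_matrix(fits: list[PolynomialFit],
                             policy: str = "exclude_intercept",
                             ) -> FunctionalSpace:
    """Stack per-specimen coefficients into the functional-space matrix.

    Under ``exclude_intercept`` (default) the descriptors are the ``order``
    non-intercept coefficients — five shape descriptors at order 5; the
    intercept is near-collinear with the curve level already carried by the
    slope coefficients on [0, 1].  ``include_intercept`` keeps all
    ``order + 1`` coefficients.
    """
    if policy not in DESCRIPTOR_POLICIES:
        raise ValueError(f"unknown descriptor policy {policy!r}")
    if not fits:
        raise ValueError("no fits supplied")
    orders = {f.order for f in fits}
    if len(orders) > 1:
        raise ValueError(f"heterogeneous polynomial orders {sorted(orders)}; "
                         f"refit all curves at a common order")
    order = orders.pop()
    start = 1 if policy == "exclude_intercept" else 0
    matrix = np.vstack([f.coefficients[start:] for f in fits])
    return FunctionalSpace(
        specimen_ids=[f.specimen_id for f in fits],
        coefficient_matrix=matrix,
        descriptor_policy=policy,
        order=order,
    )


def fix_component_signs(loadings: np.ndarray,
                        scores: np.ndarray | None = None):
    """Fix PC sign ambiguity: largest-magnitude loading of each PC positive.

    Operates on a components x descriptors loading matrix; flips the
    matching score columns when given.
    """
    loadings = loadings.copy()
    scores = None if scores is None else scores.copy()
    for i, row in enumerate(loadings):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            loadings[i] = -loadings[i]
            if scores is not None:
                scores[:, i] = -scores[:, i]
    return (loadings, scores) if scores is not None else loadings


class FunctionalPCA(BaseEstimator, TransformerMixin):
    """PCA of the polynomial-coefficient matrix with a fixed sign convention.

    Thin layer over :class:`sklearn.decomposition.PCA` (full SVD solver)
    that optionally standardizes the descriptors (correlation-matrix PCA),
    reports variance explained in percent, and resolves the sign ambiguity
    of each component by forcing its largest-magnitude loading positive.

    By default the covariance matrix is used: all descriptors share the same
    (dimensionless) units.

    Attributes
    ----------
    mean_ : ndarray of shape (n_descriptors,)
    scale_ : ndarray of shape (n_descriptors,)
        Per-column standard deviation under ``scale_to_correlation``, else 1.
    components_ : ndarray of shape (n_components, n_descriptors)
    eigenvalues_ : ndarray
        Variances along the components (ddof = 1).
    variance_explained_ : ndarray
        Percent of total variance per component; sums to 100.
    """

    def __init__(self, scale_to_correlation: bool = False):
        self.scale_to_correlation = scale_to_correlation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("PCA needs a 2D matrix with at least 3 specimens")
        self.mean_ = X.mean(axis=0)
        if self.scale_to_correlation:
            scale = X.std(axis=0, ddof=1)
            if np.any(scale == 0):
                bad = list(np.where(scale == 0)[0])
                raise ValueError(f"zero-variance descriptor(s) at column(s) {bad} "
                                 f"cannot be standardized")
            self.scale_ = scale
        else:
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_
        pca = _SklearnPCA(svd_solver="full").fit(Z)
        scores = pca.transform(Z)
        loadings, scores = fix_component_signs(pca.components_, scores)
        self.components_ = loadings
        self.eigenvalues_ = pca.explained_variance_
        self.variance_explained_ = 100.0 * pca.explained_variance_ratio_
        self._fit_scores = scores
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("FunctionalPCA is not fitted")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X)._fit_scores


def pca(space: FunctionalSpace, scale_to_correlation: bool = False) -> FunctionalSpace:
    """Ordinate a functional space by PCA; returns a populated copy."""
    est = FunctionalPCA(scale_to_correlation=scale_to_correlation)
    scores = est.fit_transform(space.coefficient_matrix)
    return replace(
        space,
        pc_scores=scores,
        pc_loadings=est.components_,
        eigenvalues=est.eigenvalues_,
        variance_explained=est.variance_explained_,
    )
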