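"""Unsupervised stratification: PCA, confidence ellipses, normality screen.

PCA is the basis both for score-plot stratification of the groups and for
the T2/Q outlier charts in :mod:`serofir.qc`.  Loadings carry a fixed sign
convention (largest-magnitude element of each row positive) so runs are
bit-reproducible; explained-variance fractions use *all* eigenvalues in the
denominator, matching the "PC-1 73 %" style of reporting.

Group clouds in (PC-1, PC-2) are summarised by chi-square confidence
ellipses, and Mardia's multivariate skewness/kurtosis test provides the
normality screen that decides parametric vs nonparametric framing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset

__all__ = [
    "SpectralPCA",
    "Ellipse",
    "MardiaResult",
    "fit_pca",
    "project",
    "confidence_ellipse",
    "mardia_test",
]


class UnsupervisedError(ValueError):
    pass


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectralDataset):
        return data.intensities
    return check_array(data)


class SpectralPCA(BaseEstimator):
    """PCA of mean-centered spectra via SVD (sklearn backend).

    Fitted attributes: ``mean_`` (vector subtracted before projection, also
    for new data), ``components_`` (orthonormal loading rows with the fixed
    sign convention), ``explained_variance_`` (eigenvalues, ddof=1) and
    ``explained_variance_ratio_`` (fractions of the total variance over all
    eigenvalues).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, data, y=None):
        X = _as_matrix(data)
        n, p = X.shape
        limit = min(n - 1, p)
        if not 1 <= self.n_components <= limit:
            raise UnsupervisedError(
                f"n_components={self.n_components} exceeds min(n-1, p)={limit}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        comps = pca.components_.copy()
        # sign convention: largest-|.| element of each loading row positive
        flip = np.sign(comps[np.arange(comps.shape[0]),
                             np.argmax(np.abs(comps), axis=1)])
        comps *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.total_variance_ = float(pca.explained_variance_.sum()
                                     / pca.explained_variance_ratio_.sum())
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    def transform(self, data) -> np.ndarray:
        """Scores of new data: subtract the *model* mean, apply loadings."""
        check_is_fitted(self, "components_")
        X = _as_matrix(data)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, data, y=None) -> np.ndarray:
        return self.fit(data).transform(data)

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(scores) @ self.components_ + self.mean_


def fit_pca(data, n_components: int = 2) -> SpectralPCA:
    """Fit a :class:`SpectralPCA` on a dataset or matrix."""
    return SpectralPCA(n_components=n_components).fit(data)


def project(model: SpectralPCA, data) -> np.ndarray:
    """Scores of (possibly new) data under a fitted model."""
    return model.transform(data)


# ---------------------------------------------------------------------------
# confidence ellipses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """A 2-D confidence ellipse in score space."""

    center: tuple
    semi_axes: tuple
    angle: float       # radians, orientation of the major axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2) points."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> Ellipse:
    """Chi-square confidence ellipse of a 2-column score cloud.

    Center is the group mean; the semi-axes are ``sqrt(lambda_i * q)`` with
    ``lambda_i`` the eigenvalues of the 2x2 sample covariance and ``q`` the
    chi-square(2) quantile at ``level``; the orientation follows the leading
    eigenvector.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != 2:
        raise UnsupervisedError("confidence_ellipse expects a 2-column score matrix")
    if scores.shape[0] < 3:
        raise UnsupervisedError("need at least 3 points for a confidence ellipse")
    if not 0.0 < level < 1.0:
        raise UnsupervisedError("level must be in (0, 1)")
    cov = np.cov(scores, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise UnsupervisedError("singular score covariance; ellipse undefined")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(
        center=tuple(scores.mean(axis=0)),
        semi_axes=tuple(np.sqrt(evals * q)),
        angle=angle,
        level=level,
    )


# ---------------------------------------------------------------------------
# Mardia multivariate normality test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MardiaResult:
    b1: float            # multivariate skewness
    b2: float            # multivariate kurtosis
    skew_stat: float     # n*b1/6, ~ chi2(d(d+1)(d+2)/6) under normality
    skew_df: int
    skew_p: float
    kurt_z: float        # z of b2 against d(d+2) with variance 8d(d+2)/n
    kurt_p: float

    @property
    def normal(self) -> bool:
        """Both component tests non-significant at the 5 % level."""
        return self.skew_p > 0.05 and self.kurt_p > 0.05


def mardia_test(X: np.ndarray, max_components: int | None = None) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis test.

    ``b1`` is the mean over all ordered observation pairs of ``g_ij**3`` and
    ``b2`` the mean of ``g_ii**2``, with ``g`` the centered Mahalanobis
    inner-product matrix using the maximum-likelihood covariance.  If the
    covariance is singular and ``max_components`` is given, the test runs on
    that many leading PCA scores instead (an affine-invariant reduction);
    otherwise a labelled error is raised.
    """
    X = check_array(np.asarray(X, dtype=float))
    n, d = X.shape
    if n <= d:
        if max_components is None:
            raise UnsupervisedError(
                f"n={n} observations <= d={d} variables; covariance singular. "
                "Pass max_components to run on leading PCA scores."
            )
        X = SpectralPCA(n_components=min(max_components, n - 1)).fit_transform(X)
        n, d = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n  # ML covariance, the classical Mardia normalisation
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        if max_components is None:
            raise UnsupervisedError(
                "singular covariance; pass max_components to fall back to PCA scores"
            ) from None
        return mardia_test(
            SpectralPCA(n_components=min(max_components, n - 1)).fit_transform(X)
        )
    G = Xc @ Sinv @ Xc.T
    b1 = float((G ** 3).sum()) / n**2
    b2 = float((np.diag(G) ** 2).sum()) / n
    skew_df = d * (d + 1) * (d + 2) // 6
    skew_stat = n * b1 / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, df=skew_df))
    kurt_z = (b2 - d * (d + 2)) / np.sqrt(8.0 * d * (d + 2) / n)
    kurt_p = float(2.0 * stats.norm.sf(abs(kurt_z)))
    return MardiaResult(b1, b2, skew_stat, skew_df, skew_p, float(kurt_z), kurt_p)
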