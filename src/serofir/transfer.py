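"""Piecewise Direct Standardization (PDS) between measurement batches.

Spectra acquired in different batches/experiments differ by small grid
shifts and detector gain.  PDS learns, for every target wavenumber j on the
master batch, a least-squares map from a small window of slave wavenumbers
[j-h, j+h] (plus intercept) onto the master value at j, using paired
measurements of the same transfer samples.  The per-window problems are
solved by truncated SVD (singular values below ``rank_tol`` times the
largest are discarded, guarding collinearity) and assembled into one banded
linear operator, so standardized slave spectra can be pooled with master
spectra.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectralDataset

__all__ = ["PiecewiseDirectStandardization", "fit_pds", "apply_pds"]


class TransferError(ValueError):
    pass


def _matrix(data) -> np.ndarray:
    if isinstance(data, SpectralDataset):
        return data.intensities
    return np.atleast_2d(np.asarray(data, dtype=float))


def _grid(data) -> np.ndarray | None:
    return data.wavenumbers if isinstance(data, SpectralDataset) else None


class PiecewiseDirectStandardization(TransformerMixin, BaseEstimator):
    """PDS transfer map from a slave batch onto a master batch.

    Parameters
    ----------
    half_width : int, default 7
        Window half-width in grid points; the coefficient band has width
        ``2*half_width + 1`` (clipped at the grid edges).
    rank_tol : float, default 1e-6
        Relative singular-value cutoff of the truncated-SVD solver.

    Fitted attributes
    -----------------
    operator_ : ndarray (p, p)
        Banded transfer operator; standardized = X @ operator_ + intercept_.
    intercept_ : ndarray (p,)
    grid_ : ndarray or None
        Training grid when datasets were supplied.
    rms_before_, rms_after_ : float
        Slave-vs-master RMS on the training pairs, raw and standardized.
    """

    def __init__(self, half_width: int = 7, rank_tol: float = 1e-6):
        self.half_width = half_width
        self.rank_tol = rank_tol

    def fit(self, slave, master):
        S, M = _matrix(slave), _matrix(master)
        if S.shape[0] != M.shape[0]:
            raise TransferError(
                f"pairing error: {S.shape[0]} slave rows vs {M.shape[0]} master rows"
            )
        if S.shape[1] != M.shape[1]:
            raise TransferError("master and slave must share one grid")
        if S.shape[0] < 3:
            raise TransferError("need at least 3 paired transfer samples")
        gs, gm = _grid(slave), _grid(master)
        if gs is not None and gm is not None and not np.allclose(gs, gm):
            raise TransferError("master and slave grids differ")
        if self.half_width < 0:
            raise TransferError("half_width must be >= 0")

        n, p = S.shape
        h = self.half_width
        B = np.zeros((p, p))
        c = np.zeros(p)
        mean_s = S.mean(axis=0)
        mean_m = M.mean(axis=0)
        n_degenerate = 0
        for j in range(p):
            lo, hi = max(0, j - h), min(p, j + h + 1)
            W = S[:, lo:hi] - mean_s[lo:hi]
            m = M[:, j] - mean_m[j]
            U, sv, Vt = np.linalg.svd(W, full_matrices=False)
            keep = (sv > 0) & (sv >= self.rank_tol * (sv[0] if sv.size else 0.0))
            if not keep.any():
                # all-constant window: intercept-only map onto the master mean
                n_degenerate += 1
                c[j] = mean_m[j]
                continue
            beta = Vt[keep].T @ ((U[:, keep].T @ m) / sv[keep])
            B[lo:hi, j] = beta
            c[j] = mean_m[j] - mean_s[lo:hi] @ beta
        if n_degenerate:
            warnings.warn(
                f"{n_degenerate} degenerate (constant) windows mapped by "
                "intercept only",
                RuntimeWarning,
            )

        self.operator_ = B
        self.intercept_ = c
        self.grid_ = None if gs is None else np.asarray(gs, float).copy()
        fitted = S @ B + c
        self.rms_before_ = float(np.sqrt(np.mean((S - M) ** 2)))
        self.rms_after_ = float(np.sqrt(np.mean((fitted - M) ** 2)))
        self.n_features_in_ = p
        return self

    def transform(self, data):
        check_is_fitted(self, "operator_")
        X = _matrix(data)
        if X.shape[1] != self.operator_.shape[0]:
            raise TransferError(
                f"grid mismatch: {X.shape[1]} points vs model {self.operator_.shape[0]}"
            )
        g = _grid(data)
        if g is not None and self.grid_ is not None and not np.allclose(g, self.grid_):
            raise TransferError("dataset grid differs from the model grid")
        out = X @ self.operator_ + self.intercept_
        if isinstance(data, SpectralDataset):
            result = data.with_intensities(out)
            result.metadata["batch"] = "std:" + result.metadata["batch"].astype(str)
            return result
        return out


def fit_pds(master, slave, half_width: int = 7,
            rank_tol: float = 1e-6) -> PiecewiseDirectStandardization:
    """Fit a PDS model from paired (same rows, same order) measurements."""
    return PiecewiseDirectStandardization(half_width, rank_tol).fit(slave, master)


def apply_pds(model: PiecewiseDirectStandardization, data):
    """Map spectra through a fitted PDS model; metadata untouched except the
    batch id, which is annotated as standardized."""
    return model.transform(data)
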