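"""The five-step chemometric preprocessing chain.

Order is fixed: (i) truncation to the fingerprint window (default
1800-900 cm^-1), (ii) Savitzky-Golay second derivative (default 15-point
window), (iii) multiplicative scatter correction against a reference
spectrum, (iv) unit vector normalization, (v) scaling (mean-centering or
per-wavenumber standardization) fitted on training data only when used
inside cross-validation.

Two surfaces are provided: scikit-learn-style array transformers
(:class:`SavitzkyGolayDerivative`, :class:`MultiplicativeScatterCorrection`,
:class:`VectorNormalizer`, :class:`SpectrumScaler`) that compose with
sklearn pipelines, and dataset-level functions mirroring them.  The
stateful chain is bundled in :class:`PreprocessModel` (fit on training
spectra, apply to held-out spectra with no refit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset

__all__ = [
    "PreprocessParams",
    "PreprocessModel",
    "SavitzkyGolayDerivative",
    "MultiplicativeScatterCorrection",
    "VectorNormalizer",
    "SpectrumScaler",
    "truncate",
    "sg_second_derivative",
    "msc",
    "vector_normalize",
    "fit_scaler",
    "apply_scaler",
    "preprocess_pipeline",
]


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    ``sg_points`` must be odd and at least ``sg_polyorder + 2``; the
    derivative order is fixed at 2.  ``scale_mode`` is 'mean-center',
    'standardize' or 'none'; set ``apply_scaling=False`` to defer step (v)
    to a consumer stage (the classifier fits its own train-only scaler).
    """

    window_low: float = 900.0
    window_high: float = 1800.0
    sg_points: int = 15
    sg_polyorder: int = 3
    sg_deriv: int = 2
    msc_reference: np.ndarray | None = None
    scale_mode: str = "mean-center"
    apply_scaling: bool = True

    def __post_init__(self) -> None:
        if self.window_low >= self.window_high:
            raise PreprocessError(
                f"window [{self.window_low}, {self.window_high}] is reversed"
            )
        if self.sg_points % 2 == 0 or self.sg_points < self.sg_polyorder + 2:
            raise PreprocessError(
                "sg_points must be odd and >= sg_polyorder + 2 "
                f"(got {self.sg_points}/{self.sg_polyorder})"
            )
        if self.sg_deriv > self.sg_polyorder:
            raise PreprocessError("sg_deriv must be <= sg_polyorder")
        if self.scale_mode not in ("mean-center", "standardize", "none"):
            raise PreprocessError(f"unknown scale_mode {self.scale_mode!r}")


# ---------------------------------------------------------------------------
# array-level transformers (sklearn API)
# ---------------------------------------------------------------------------

class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative along rows, physical-step aware.

    Parameters
    ----------
    window_length : int, default 15
        Odd filter length in points.
    polyorder : int, default 3
        Order of the local fitting polynomial.
    deriv : int, default 2
        Derivative order; output units are AU/(cm^-1)^deriv when ``delta``
        is the grid step in cm^-1.
    delta : float, default 1.0
        Grid spacing used to scale the derivative.
    drop_edges : bool, default True
        Drop ``(window_length-1)/2`` points at each end instead of padding,
        so no fabricated values enter later stages.
    """

    def __init__(self, window_length: int = 15, polyorder: int = 3,
                 deriv: int = 2, delta: float = 1.0, drop_edges: bool = True):
        self.window_length = window_length
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta
        self.drop_edges = drop_edges

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] < self.window_length:
            raise PreprocessError(
                f"need >= {self.window_length} points, got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        out = savgol_filter(
            X, self.window_length, self.polyorder, deriv=self.deriv,
            delta=self.delta, axis=1, mode="interp",
        )
        if self.drop_edges:
            h = (self.window_length - 1) // 2
            out = out[:, h : X.shape[1] - h]
        return out


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC: regress each spectrum on a reference, remove offset and gain.

    Per spectrum the OLS fit ``x = a + b * ref`` is solved in closed form
    and the corrected spectrum is ``(x - a) / b``.  The reference is the
    mean of the fitted data unless given explicitly; applying a fitted
    instance to held-out data reuses the fit-time reference (no leakage).
    Fitted coefficients of the last ``transform`` call are exposed as
    ``coefficients_`` (columns: offset a, slope b).
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = check_array(X)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise PreprocessError(
                    f"reference length {ref.size} != n_points {X.shape[1]}"
                )
            self.reference_ = ref
        else:
            self.reference_ = X.mean(axis=0)
        if np.var(self.reference_) < 1e-300:
            raise PreprocessError("MSC reference has zero variance")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        ref = self.reference_
        rc = ref - ref.mean()
        denom = float(rc @ rc)
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        a = X.mean(axis=1) - b * ref.mean()
        if np.any(np.abs(b) < 1e-12):
            bad = int(np.argmin(np.abs(b)))
            raise PreprocessError(
                f"degenerate scatter fit (|b| < 1e-12) for spectrum row {bad}"
            )
        self.coefficients_ = np.column_stack([a, b])
        return (X - a[:, None]) / b[:, None]


class VectorNormalizer(TransformerMixin, BaseEstimator):
    """Scale every row to unit Euclidean norm."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise PreprocessError(f"zero-norm spectrum at row {bad}")
        return X / norms[:, None]


class SpectrumScaler(TransformerMixin, BaseEstimator):
    """Per-wavenumber mean-centering or standardization with train statistics.

    ``mode`` is 'mean-center', 'standardize' or 'none'.  Statistics are
    fitted once and reused on held-out data (no refit), the behaviour
    cross-validated classification requires.
    """

    def __init__(self, mode: str = "mean-center", wavenumbers: np.ndarray | None = None):
        self.mode = mode
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        if self.mode not in ("mean-center", "standardize", "none"):
            raise PreprocessError(f"unknown scale mode {self.mode!r}")
        X = check_array(X)
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        if self.mode == "standardize" and np.any(self.sds_ == 0):
            bad = int(np.flatnonzero(self.sds_ == 0)[0])
            w = None if self.wavenumbers is None else self.wavenumbers[bad]
            raise PreprocessError(
                f"zero standard deviation at column {bad}"
                + (f" (wavenumber {w} cm^-1)" if w is not None else "")
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X)
        if self.mode == "none":
            return X.copy()
        out = X - self.means_
        if self.mode == "standardize":
            out = out / self.sds_
        return out


# ---------------------------------------------------------------------------
# dataset-level operations
# ---------------------------------------------------------------------------

def truncate(dataset: SpectralDataset, window_low: float = 900.0,
             window_high: float = 1800.0) -> SpectralDataset:
    """Keep exactly the grid points in the closed interval [low, high]."""
    if window_low >= window_high:
        raise PreprocessError(
            f"window [{window_low}, {window_high}] is reversed or empty"
        )
    mask = dataset.window_mask(window_low, window_high)
    if not mask.any():
        raise PreprocessError(
            f"window [{window_low}, {window_high}] does not intersect the grid "
            f"[{dataset.wavenumbers[0]}, {dataset.wavenumbers[-1]}]"
        )
    return dataset.with_intensities(
        dataset.intensities[:, mask], wavenumbers=dataset.wavenumbers[mask]
    )


def _grid_step(wavenumbers: np.ndarray) -> float:
    steps = np.diff(wavenumbers)
    step = float(steps.mean())
    if np.any(np.abs(steps - step) > 1e-6 * abs(step)):
        raise PreprocessError(
            "grid is not uniform; interpolate to a uniform grid before the "
            "Savitzky-Golay derivative"
        )
    return step


def sg_second_derivative(dataset: SpectralDataset, sg_points: int = 15,
                         sg_polyorder: int = 3, deriv: int = 2) -> SpectralDataset:
    """Savitzky-Golay derivative of every spectrum, edge points dropped."""
    step = _grid_step(dataset.wavenumbers)
    tr = SavitzkyGolayDerivative(
        window_length=sg_points, polyorder=sg_polyorder, deriv=deriv,
        delta=step, drop_edges=True,
    ).fit(dataset.intensities)
    out = tr.transform(dataset.intensities)
    h = (sg_points - 1) // 2
    return dataset.with_intensities(
        out, wavenumbers=dataset.wavenumbers[h : dataset.n_points - h]
    )


def msc(dataset: SpectralDataset, reference: np.ndarray | None = None):
    """MSC against a reference (dataset mean by default).

    Returns ``(corrected dataset, coefficients)`` with coefficients columns
    (offset a, slope b), one row per spectrum.
    """
    tr = MultiplicativeScatterCorrection(reference=reference).fit(dataset.intensities)
    out = tr.transform(dataset.intensities)
    return dataset.with_intensities(out), tr.coefficients_


def vector_normalize(dataset: SpectralDataset) -> SpectralDataset:
    """Unit Euclidean norm per spectrum."""
    tr = VectorNormalizer().fit(dataset.intensities)
    return dataset.with_intensities(tr.transform(dataset.intensities))


def fit_scaler(dataset: SpectralDataset, scale_mode: str = "mean-center") -> SpectrumScaler:
    return SpectrumScaler(mode=scale_mode, wavenumbers=dataset.wavenumbers).fit(
        dataset.intensities
    )


def apply_scaler(scaler: SpectrumScaler, dataset: SpectralDataset) -> SpectralDataset:
    return dataset.with_intensities(scaler.transform(dataset.intensities))


class PreprocessModel(BaseEstimator):
    """The full stateful chain, fit on one dataset and applicable to another.

    ``fit`` runs truncation and derivative on the fit data, then learns the
    MSC reference (mean of the fit data after the derivative, unless an
    explicit reference is supplied) and the scaler statistics.  ``transform``
    applies the identical steps to any dataset on the same raw grid,
    reusing the fitted reference and statistics.
    """

    def __init__(self, params: PreprocessParams | None = None):
        self.params = params

    def _params(self) -> PreprocessParams:
        return self.params if self.params is not None else PreprocessParams()

    def fit(self, dataset: SpectralDataset, y=None):
        p = self._params()
        stageA = sg_second_derivative(
            truncate(dataset, p.window_low, p.window_high),
            p.sg_points, p.sg_polyorder, p.sg_deriv,
        )
        self.grid_ = stageA.wavenumbers.copy()
        self.msc_ = MultiplicativeScatterCorrection(reference=p.msc_reference).fit(
            stageA.intensities
        )
        normed = VectorNormalizer().fit(stageA.intensities).transform(
            self.msc_.transform(stageA.intensities)
        )
        self.scaler_ = SpectrumScaler(mode=p.scale_mode, wavenumbers=self.grid_).fit(normed)
        self.steps_ = [
            ("truncate", {"window_low": p.window_low, "window_high": p.window_high}),
            ("sg_derivative", {"points": p.sg_points, "polyorder": p.sg_polyorder,
                               "deriv": p.sg_deriv}),
            ("msc", {"reference": "fitted mean" if p.msc_reference is None else "explicit"}),
            ("vector_normalize", {}),
            ("scale", {"mode": p.scale_mode, "applied": p.apply_scaling}),
        ]
        return self

    def transform(self, dataset: SpectralDataset) -> SpectralDataset:
        check_is_fitted(self, "msc_")
        p = self._params()
        out = sg_second_derivative(
            truncate(dataset, p.window_low, p.window_high),
            p.sg_points, p.sg_polyorder, p.sg_deriv,
        )
        if out.wavenumbers.shape != self.grid_.shape or not np.allclose(
            out.wavenumbers, self.grid_
        ):
            raise PreprocessError("dataset grid differs from the fitted grid")
        x = self.msc_.transform(out.intensities)
        x = VectorNormalizer().fit(x).transform(x)
        if p.apply_scaling:
            x = self.scaler_.transform(x)
        return out.with_intensities(x)

    def fit_transform(self, dataset: SpectralDataset, y=None) -> SpectralDataset:
        return self.fit(dataset).transform(dataset)


def preprocess_pipeline(dataset: SpectralDataset,
                        params: PreprocessParams | None = None) -> SpectralDataset:
    """One-shot preprocessing of a dataset (fit and apply on the same data)."""
    return PreprocessModel(params).fit_transform(dataset)
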