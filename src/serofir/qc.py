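"""Two-stage spectral quality assessment.

Stage one re-specifies the classical per-spectrum quality checks with
explicit windows and configurable thresholds: absorbance level (maximum in
the 1800-900 cm^-1 fingerprint window inside a band of acceptable optical
densities), signal-to-noise ratio (amide-I signal in 1700-1600 against the
detrended noise floor in the band-free 2200-1900 region), and water-vapour
line intensity (peak-to-peak second derivative in 1847-1837 cm^-1).

Stage two fits a PCA model to the mean-centered raw spectra and flags
outliers on the Hotelling T2 versus Q-residual chart: T2 measures distance
inside the model subspace (F-distribution threshold), Q the off-model
residual (Jackson-Mudholkar threshold).  A spectrum passes QC iff it passes
all three quality checks and sits under both chart thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from .dataset import SpectralDataset
from .unsupervised import SpectralPCA

__all__ = [
    "QualityThresholds",
    "OutlierModel",
    "quality_test",
    "fit_outlier_model",
    "t2_q",
    "qc_report",
    "apply_outlier_filter",
]

# Fixed scoring windows (cm^-1), the declared surrogate re-specification.
FINGERPRINT_WINDOW = (900.0, 1800.0)
SIGNAL_WINDOW = (1600.0, 1700.0)
NOISE_WINDOW = (1900.0, 2200.0)
WATER_WINDOW = (1837.0, 1847.0)


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QualityThresholds:
    """Thresholds of the three per-spectrum quality checks.

    Defaults are calibrated to the synthetic generator's default artifact
    levels (see the methods note): serum films with amide-I peaks of roughly
    0.3-3 AU, an SNR floor of 50 and a water-vapour second-derivative
    ceiling about five times the clean-data score.
    """

    absorbance_min: float = 0.05
    absorbance_max: float = 3.0
    snr_min: float = 50.0
    water_vapor_max: float = 5e-4

    def __post_init__(self) -> None:
        if self.absorbance_min >= self.absorbance_max:
            raise QCError("absorbance_min must be < absorbance_max")
        if self.snr_min <= 0 or self.water_vapor_max <= 0:
            raise QCError("snr_min and water_vapor_max must be > 0")


def _require_window(dataset: SpectralDataset, window: tuple, name: str) -> np.ndarray:
    mask = dataset.window_mask(*window)
    if mask.sum() < 3:
        raise QCError(
            f"grid does not cover the {name} window {window[0]}-{window[1]} cm^-1"
        )
    return mask


def _linear_detrend(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Residual of an OLS line fit over a window (rows of x)."""
    A = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(A, x.T, rcond=None)
    return x - (A @ coef).T


def quality_test(dataset: SpectralDataset,
                 thresholds: QualityThresholds | None = None) -> pd.DataFrame:
    """Per-spectrum quality checks (stage one only).

    Returns a DataFrame with columns ``spectrum_id, max_absorbance,
    absorbance_ok, snr, snr_ok, water_score, water_ok, quality_ok``.
    """
    thr = thresholds or QualityThresholds()
    fp = _require_window(dataset, FINGERPRINT_WINDOW, "fingerprint")
    sig = _require_window(dataset, SIGNAL_WINDOW, "signal")
    noi = _require_window(dataset, NOISE_WINDOW, "noise")
    wat = _require_window(dataset, WATER_WINDOW, "water-vapour")

    X = dataset.intensities
    w = dataset.wavenumbers

    max_abs = X[:, fp].max(axis=1)
    absorbance_ok = (max_abs >= thr.absorbance_min) & (max_abs <= thr.absorbance_max)

    # signal: peak height above a straight baseline through the window edges
    ws = w[sig]
    Xs = X[:, sig]
    edge = max(3, Xs.shape[1] // 10)
    x0, x1 = ws[:edge].mean(), ws[-edge:].mean()
    y0 = Xs[:, :edge].mean(axis=1)
    y1 = Xs[:, -edge:].mean(axis=1)
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0[:, None] + slope[:, None] * (ws - x0)
    signal = (Xs - baseline).max(axis=1)

    noise = _linear_detrend(X[:, noi], w[noi]).std(axis=1, ddof=2)
    noise = np.where(noise > 0, noise, np.finfo(float).tiny)
    snr = signal / noise
    snr_ok = snr >= thr.snr_min

    # water-vapour score: SG second derivative, peak-to-peak inside the window
    d2 = savgol_filter(X, 15, 3, deriv=2,
                       delta=float(np.diff(w).mean()), axis=1, mode="interp")
    water = d2[:, wat].max(axis=1) - d2[:, wat].min(axis=1)
    water_ok = water <= thr.water_vapor_max

    return pd.DataFrame(
        {
            "spectrum_id": dataset.metadata["spectrum_id"].to_numpy(),
            "max_absorbance": max_abs,
            "absorbance_ok": absorbance_ok,
            "snr": snr,
            "snr_ok": snr_ok,
            "water_score": water,
            "water_ok": water_ok,
            "quality_ok": absorbance_ok & snr_ok & water_ok,
        }
    )


# ---------------------------------------------------------------------------
# Hotelling T2 / Q residual chart
# ---------------------------------------------------------------------------

@dataclass
class OutlierModel:
    """Fitted T2/Q chart: PCA model, retained rank and both thresholds."""

    pca: SpectralPCA
    eigenvalues: np.ndarray     # all eigenvalues (ddof=1)
    k: int
    alpha: float
    t2_threshold: float
    q_threshold: float


def _jackson_mudholkar(residual_eigenvalues: np.ndarray, alpha: float) -> float:
    lam = residual_eigenvalues[residual_eigenvalues > 0]
    if lam.size == 0 or lam.sum() <= 0:
        raise QCError(
            "residual eigenvalues are ~0; Q threshold undefined — lower "
            "variance_fraction"
        )
    t1, t2, t3 = (float((lam ** i).sum()) for i in (1, 2, 3))
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2 ** 2)
    if h0 <= 0:
        h0 = 1e-4
    c = stats.norm.ppf(1.0 - alpha)
    inner = c * np.sqrt(2.0 * t2 * h0 ** 2) / t1 + 1.0 + t2 * h0 * (h0 - 1.0) / t1 ** 2
    return float(t1 * inner ** (1.0 / h0))


def fit_outlier_model(dataset: SpectralDataset | np.ndarray,
                      variance_fraction: float = 0.95,
                      alpha: float = 0.05) -> OutlierModel:
    """Fit the T2/Q chart on mean-centered intensities.

    The retained rank ``k`` is the smallest component count whose cumulative
    explained variance reaches ``variance_fraction``; the T2 control limit is
    ``k(n-1)/(n-k) * F_{1-alpha}(k, n-k)``, the Q limit follows
    Jackson-Mudholkar on the residual eigenvalues.
    """
    X = dataset.intensities if isinstance(dataset, SpectralDataset) else np.asarray(dataset)
    n = X.shape[0]
    if not 0.0 < variance_fraction < 1.0:
        raise QCError("variance_fraction must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise QCError("alpha must be in (0, 1)")
    rank = min(n - 1, X.shape[1])
    full = SpectralPCA(n_components=rank).fit(X)
    lam = full.explained_variance_
    frac = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(frac, variance_fraction) + 1)
    if k >= n:
        raise QCError("retained rank k equals n; lower variance_fraction")
    if k >= rank:
        raise QCError(
            "variance_fraction retains every component; Q threshold undefined "
            "— lower variance_fraction"
        )
    pca = SpectralPCA(n_components=k).fit(X)
    t2_thr = k * (n - 1) / (n - k) * stats.f.ppf(1.0 - alpha, k, n - k)
    q_thr = _jackson_mudholkar(lam[k:], alpha)
    return OutlierModel(pca=pca, eigenvalues=lam, k=k, alpha=alpha,
                        t2_threshold=float(t2_thr), q_threshold=q_thr)


def t2_q(model: OutlierModel, dataset: SpectralDataset | np.ndarray):
    """Hotelling T2 and Q residual of every row under a fitted chart."""
    X = dataset.intensities if isinstance(dataset, SpectralDataset) else np.asarray(dataset)
    scores = model.pca.transform(X)
    lam = model.eigenvalues[: model.k]
    t2 = ((scores ** 2) / lam).sum(axis=1)
    resid = (X - model.pca.mean_) - scores @ model.pca.components_
    q = (resid ** 2).sum(axis=1)
    return t2, q


def qc_report(dataset: SpectralDataset,
              thresholds: QualityThresholds | None = None,
              variance_fraction: float = 0.95,
              alpha: float = 0.05) -> pd.DataFrame:
    """Full QC report: quality checks plus the T2/Q chart, one row per spectrum.

    ``pass`` is the conjunction of the three quality booleans and both chart
    conditions (T2 and Q at or under their thresholds).
    """
    report = quality_test(dataset, thresholds)
    model = fit_outlier_model(dataset, variance_fraction, alpha)
    t2, q = t2_q(model, dataset)
    report["T2"] = t2
    report["Q"] = q
    report["T2_threshold"] = model.t2_threshold
    report["Q_threshold"] = model.q_threshold
    report["pass"] = (
        report["quality_ok"]
        & (t2 <= model.t2_threshold)
        & (q <= model.q_threshold)
    )
    return report


def apply_outlier_filter(dataset: SpectralDataset, report: pd.DataFrame):
    """Keep exactly the rows with ``pass == True``; order preserved.

    Returns ``(filtered dataset, list of excluded spectrum ids)``.
    """
    if len(report) != dataset.n_spectra:
        raise QCError(
            f"report has {len(report)} rows for {dataset.n_spectra} spectra"
        )
    keep = report["pass"].to_numpy(dtype=bool)
    excluded = list(report.loc[~keep, "spectrum_id"])
    if not keep.any():
        raise QCError("QC excluded every spectrum; nothing left for analysis")
    return dataset.select_rows(keep), excluded
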