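"""Synthetic serum FTIR dataset generator.

Emulates the statistical structure a serum-fingerprinting analysis assumes,
so every downstream stage (QC, preprocessing, calibration transfer, PCA,
CNN classification) is testable without instrument data:

* a three-class group structure (non-allergic / allergic / SIT-tolerized)
  whose class differences are multiplicative amplitude changes on a few
  absorption bands inside the 1800-900 cm^-1 fingerprint window;
* >= 20 replicate spectra per subject with subject-level biological
  variability (log-normal per-band factors, larger for the human preset);
* multiplicative scatter (gain/offset), slow polynomial baseline drift,
  additive white noise and a fixed water-vapour line comb;
* between-batch effects (small grid shift plus detector gain) motivating
  piecewise direct standardization;
* an optional fraction of gross outlier spectra motivating QC.

Bands are Gaussians truncated to compact support at +/- 4 sigma, so class
differences are *exactly* zero outside the bands that differ - a property
the test suite relies on.

All randomness is keyed hierarchically: subject-level draws depend only on
(seed, class index, subject index) and replicate-level draws additionally on
the replicate index, so enlarging the design never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SpectralDataset

__all__ = [
    "BandSpec",
    "SimConfig",
    "default_bands",
    "preset",
    "make_base_spectrum",
    "inject_artifacts",
    "inject_outliers",
    "generate_dataset",
    "paired_transfer_set",
]

#: Fixed class order used throughout: healthy controls, allergic, treated.
DEFAULT_CLASSES = ("non_allergic", "allergic", "sit")

#: Water-vapour line positions (cm^-1).  Artifact plumbing, not physics:
#: twelve narrow lines spanning the 1845-1400 region, two of them inside
#: the 1847-1837 window the QC water score inspects.
WATER_LINES = (
    1844.2, 1838.9, 1790.1, 1751.7, 1716.9, 1684.3,
    1652.5, 1616.9, 1576.2, 1540.3, 1497.8, 1456.1,
)
WATER_LINE_SIGMA = 2.0  # cm^-1

# Gross-outlier corruption levels (absorbance units / factors).
OUTLIER_SCALE = 10.0
OUTLIER_SATURATION = 6.0
OUTLIER_SLOPE_MAX = 6.0


class SimulationError(ValueError):
    """Raised for invalid simulator configuration or arguments."""


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: truncated Gaussian with per-class amplitude factors.

    Parameters
    ----------
    center, width : float
        Band position and Gaussian sigma, cm^-1.
    amplitude : float
        Peak absorbance (AU) for a reference subject of a class with factor 1.
    class_effects : dict
        Multiplicative amplitude factor per class label; classes absent from
        the dict get factor 1.  All factors must be positive.
    """

    center: float
    width: float
    amplitude: float
    class_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SimulationError(f"band width must be > 0 (got {self.width})")
        if self.amplitude < 0:
            raise SimulationError("band amplitude must be >= 0")
        for cls, fac in self.class_effects.items():
            if fac <= 0:
                raise SimulationError(f"class effect for {cls!r} must be > 0")

    def effect(self, class_label: str) -> float:
        return float(self.class_effects.get(class_label, 1.0))

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude truncated-Gaussian profile on a grid."""
        z = (wavenumbers - self.center) / self.width
        prof = np.exp(-0.5 * z * z)
        prof[np.abs(z) > 4.0] = 0.0
        return prof


def default_bands(separation: str = "moderate") -> list[BandSpec]:
    """Serum band set with class effects scaled by a separation level.

    Band centres sit inside the canonical fingerprint assignments
    (ester 1710-1760, amide 1500-1720, collagen 1190-1350, phosphate
    diester 1220-1250, carbohydrates 950-1200 cm^-1) plus two broad
    out-of-window bands (amide A, CH stretch) for realism.  The allergic
    class perturbs the ester and amide bands (+10 % / -8 %); the treated
    (SIT/tolerized) class perturbs the carbohydrate bands (+8 %).  The
    ``separation`` knob scales those deviations from unity.
    """
    scale = {"low": 0.5, "moderate": 1.0, "high": 2.0}
    try:
        s = scale[separation]
    except KeyError:
        raise SimulationError(
            f"unknown separation level {separation!r}; choose from {sorted(scale)}"
        ) from None

    def fx(delta: float) -> float:
        return 1.0 + delta * s

    allergic_up = {"allergic": fx(+0.10)}
    allergic_down = {"allergic": fx(-0.08)}
    sit_up = {"sit": fx(+0.08)}
    return [
        BandSpec(3300.0, 80.0, 0.60),
        BandSpec(2930.0, 30.0, 0.15),
        BandSpec(1740.0, 12.0, 0.35, allergic_up),       # ester carbonyl
        BandSpec(1655.0, 18.0, 0.90, allergic_down),     # amide I
        BandSpec(1545.0, 16.0, 0.55, allergic_down),     # amide II
        BandSpec(1455.0, 12.0, 0.25),                    # CH2 bend
        BandSpec(1400.0, 12.0, 0.18),
        BandSpec(1310.0, 14.0, 0.15),                    # collagen / amide III
        BandSpec(1240.0, 14.0, 0.22),                    # phosphate diester
        BandSpec(1165.0, 12.0, 0.12, sit_up),            # carbohydrates ...
        BandSpec(1120.0, 12.0, 0.10, sit_up),
        BandSpec(1080.0, 14.0, 0.18, sit_up),
        BandSpec(1030.0, 12.0, 0.15, sit_up),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration (defaults define the reference conditions)."""

    grid_start: float = 500.0
    grid_end: float = 4000.0
    grid_step: float = 1.5
    classes: tuple = DEFAULT_CLASSES
    n_subjects_per_class: int = 20
    n_replicates_per_subject: int = 20
    bands: tuple = None  # type: ignore[assignment]
    subject_sd: float = 0.10
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.01
    baseline_degree: int = 2
    baseline_sd: float = 0.005
    noise_sd: float = 0.0015
    water_vapor_amplitude: float = 0.001
    n_batches: int = 1
    batch_shift: float = 1.5
    batch_gain: float = 1.05
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bands is None:
            object.__setattr__(self, "bands", tuple(default_bands("moderate")))
        else:
            object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.grid_start >= self.grid_end:
            raise SimulationError("grid_start must be < grid_end")
        if self.grid_step <= 0:
            raise SimulationError("grid_step must be > 0")
        if self.n_replicates_per_subject < 1:
            raise SimulationError("n_replicates_per_subject must be >= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise SimulationError("outlier_fraction must be in [0, 1)")
        for name in ("subject_sd", "scatter_slope_sd", "scatter_offset_sd",
                     "baseline_sd", "noise_sd", "water_vapor_amplitude"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise SimulationError("n_batches must be >= 1")

    def grid(self) -> np.ndarray:
        """Ascending grid of integer multiples of the step inside the span.

        Anchoring the grid at multiples of the step makes 900 and 1800 cm^-1
        exact grid points at the default 1.5 cm^-1 spacing, so the closed
        fingerprint window holds exactly 601 points.
        """
        k0 = int(np.ceil(self.grid_start / self.grid_step - 1e-9))
        k1 = int(np.floor(self.grid_end / self.grid_step + 1e-9))
        return self.grid_step * np.arange(k0, k1 + 1, dtype=float)


def preset(name: str, separation: str = "moderate", **overrides) -> SimConfig:
    """Shipped study presets.

    ``mouse``: 3 groups x 10 subjects, 2 measurement batches (two independent
    experiments), tighter subject variability (genetically identical animals).
    ``human``: 3 groups x 20 subjects, 1 batch, larger subject variability
    (heterogeneous cohort).
    """
    if name == "mouse":
        settings = dict(n_subjects_per_class=10, subject_sd=0.05, n_batches=2)
    elif name == "human":
        settings = dict(n_subjects_per_class=20, subject_sd=0.10, n_batches=1)
    else:
        raise SimulationError(f"unknown preset {name!r}; choose 'mouse' or 'human'")
    settings["bands"] = tuple(default_bands(separation))
    settings.update(overrides)
    return SimConfig(**settings)


# ---------------------------------------------------------------------------
# Deterministic RNG keying
# ---------------------------------------------------------------------------

def _rng(*key: int) -> np.random.Generator:
    """Generator keyed by a tuple of non-negative integers."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


_SUBJECT_STREAM = 1
_REPLICATE_STREAM = 2
_OUTLIER_STREAM = 3


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------

def make_base_spectrum(
    config: SimConfig, class_label: str, subject_factors: np.ndarray
) -> np.ndarray:
    """Noiseless absorbance spectrum for one subject of one class.

    ``sum_b amplitude_b * class_effect_b(class) * subject_factor_b *
    TruncGauss(center_b, width_b)`` on the config grid; non-negative
    everywhere because every term is.
    """
    if class_label not in config.classes:
        raise SimulationError(
            f"unknown class label {class_label!r}; expected one of {config.classes}"
        )
    subject_factors = np.asarray(subject_factors, dtype=float)
    if subject_factors.shape != (len(config.bands),):
        raise SimulationError(
            f"need one subject factor per band ({len(config.bands)}), "
            f"got shape {subject_factors.shape}"
        )
    if np.any(subject_factors <= 0):
        raise SimulationError("subject factors must be positive")
    grid = config.grid()
    out = np.zeros_like(grid)
    for band, f in zip(config.bands, subject_factors):
        out += band.amplitude * band.effect(class_label) * f * band.profile(grid)
    return out


def _water_comb(grid: np.ndarray) -> np.ndarray:
    """Fixed unit-amplitude water-vapour comb (alternating line signs)."""
    comb = np.zeros_like(grid)
    for i, center in enumerate(WATER_LINES):
        z = (grid - center) / WATER_LINE_SIGMA
        prof = np.exp(-0.5 * z * z)
        prof[np.abs(z) > 4.0] = 0.0
        comb += (1.0 if i % 2 == 0 else -1.0) * prof
    return comb


def inject_artifacts(
    spectrum: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    batch_index: int = 0,
) -> np.ndarray:
    """Measured spectrum: scatter, baseline, water vapour, noise, batch effects.

    Returns ``b*x + a + poly_baseline + water_comb + noise`` where
    ``(a, b)`` come from the scatter model, the baseline is a random
    polynomial of the configured degree, and batch effects (grid shift by
    ``batch_index * batch_shift`` via linear interpolation, gain
    ``batch_gain ** batch_index``) act on the clean spectrum first.  With all
    sd/amplitude parameters zero and batch 0 this is the identity.
    """
    grid = config.grid()
    x = np.asarray(spectrum, dtype=float)
    if x.shape != grid.shape:
        raise SimulationError("spectrum is not on the config grid")

    # Batch response: the slave instrument reports x(w - shift) * gain.
    if batch_index > 0:
        shift = batch_index * config.batch_shift
        gain = config.batch_gain ** batch_index
        if shift != 0.0:
            x = np.interp(grid - shift, grid, x)
        x = gain * x

    b = 1.0 + config.scatter_slope_sd * rng.standard_normal()
    a = config.scatter_offset_sd * rng.standard_normal()
    out = b * x + a

    if config.baseline_degree >= 0 and config.baseline_sd > 0:
        t = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
        coeffs = config.baseline_sd * rng.standard_normal(config.baseline_degree + 1)
        out += np.polynomial.polynomial.polyval(t, coeffs)
    if config.water_vapor_amplitude > 0:
        out += config.water_vapor_amplitude * rng.standard_normal() * _water_comb(grid)
    if config.noise_sd > 0:
        out += config.noise_sd * rng.standard_normal(grid.size)
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def n_outliers(fraction: float, n: int) -> int:
    """Deterministic outlier count: floor(fraction*n), at least 1 if fraction>0."""
    if not 0.0 <= fraction < 1.0:
        raise SimulationError("outlier fraction must be in [0, 1)")
    if fraction == 0.0:
        return 0
    return max(1, int(np.floor(fraction * n)))


def inject_outliers(
    dataset: SpectralDataset, fraction: float, rng: np.random.Generator
) -> tuple[SpectralDataset, np.ndarray]:
    """Corrupt a deterministic fraction of spectra into gross outliers.

    Each selected spectrum suffers one of three corruptions: 10x amplitude
    scaling, a saturated flat-top segment, or a strong sloped baseline.
    Returns the corrupted dataset and a boolean mask of corrupted rows.
    """
    n = dataset.n_spectra
    k = n_outliers(fraction, n)
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return dataset.copy(), mask
    rows = rng.choice(n, size=k, replace=False)
    mask[rows] = True
    out = dataset.intensities.copy()
    grid = dataset.wavenumbers
    for i in rows:
        mode = rng.integers(3)
        if mode == 0:
            out[i] = OUTLIER_SCALE * out[i]
        elif mode == 1:
            # saturated detector: a flat-top segment pinned at a high level
            lo = rng.integers(0, max(1, grid.size - grid.size // 4))
            hi = lo + grid.size // 4
            out[i, lo:hi] = OUTLIER_SATURATION
        else:
            out[i] = out[i] + OUTLIER_SLOPE_MAX * (grid - grid[0]) / (grid[-1] - grid[0])
    return dataset.with_intensities(out), mask


def _subject_table(config: SimConfig) -> list[tuple[str, str, str, int, int]]:
    """(subject_id, class, batch, class_idx, subject_idx) rows; batches
    round-robin over subjects within each class so every batch sees every
    class."""
    rows = []
    for ci, cls in enumerate(config.classes):
        for si in range(config.n_subjects_per_class):
            batch = si % config.n_batches
            rows.append((f"{cls}_s{si:03d}", cls, f"b{batch}", ci, si))
    return rows


def generate_dataset(config: SimConfig) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate the full synthetic dataset plus its ground-truth table.

    Returns ``(dataset, truth)`` where ``truth`` has one row per spectrum:
    spectrum_id, subject_id, group, batch, replicate, is_outlier.  Identical
    config (including seed) gives bit-identical output.
    """
    grid = config.grid()
    rows, meta = [], []
    for subject_id, cls, batch, ci, si in _subject_table(config):
        srng = _rng(config.seed, _SUBJECT_STREAM, ci, si)
        factors = np.exp(config.subject_sd * srng.standard_normal(len(config.bands)))
        base = make_base_spectrum(config, cls, factors)
        batch_index = int(batch[1:])
        for ri in range(config.n_replicates_per_subject):
            rrng = _rng(config.seed, _REPLICATE_STREAM, ci, si, ri)
            rows.append(inject_artifacts(base, config, rrng, batch_index))
            meta.append(
                {
                    "spectrum_id": f"{subject_id}_r{ri:03d}",
                    "subject_id": subject_id,
                    "group": cls,
                    "batch": batch,
                    "replicate": ri,
                }
            )
    dataset = SpectralDataset(
        wavenumbers=grid,
        intensities=np.vstack(rows),
        metadata=pd.DataFrame(meta),
    )
    orng = _rng(config.seed, _OUTLIER_STREAM)
    dataset, mask = inject_outliers(dataset, config.outlier_fraction, orng)
    truth = dataset.metadata.copy()
    truth["is_outlier"] = mask
    return dataset, truth


def paired_transfer_set(
    config: SimConfig, n_subjects: int = 10, n_replicates: int = 4,
    seed: int | None = None,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Paired master/slave measurements of the same subjects for PDS fitting.

    The same noiseless subject spectra are measured ``n_replicates`` times
    under batch-0 (master) and batch-1 (slave) response, with fresh
    measurement artifacts each; rows are paired by position.  The pair count
    ``n_subjects * n_replicates`` should comfortably exceed the PDS window
    width (2*half_width+1) or the windowed regressions overfit.
    """
    seed = config.seed if seed is None else seed
    grid = config.grid()
    master_rows, slave_rows, meta_m, meta_s = [], [], [], []
    table = _subject_table(config)[:n_subjects]
    if len(table) < n_subjects:
        raise SimulationError("not enough subjects in the design for the transfer set")
    for subject_id, cls, _batch, ci, si in table:
        srng = _rng(seed, _SUBJECT_STREAM, ci, si)
        factors = np.exp(config.subject_sd * srng.standard_normal(len(config.bands)))
        base = make_base_spectrum(config, cls, factors)
        for ri in range(n_replicates):
            mrng = _rng(seed, _REPLICATE_STREAM, ci, si, 10_000 + 2 * ri)
            srng2 = _rng(seed, _REPLICATE_STREAM, ci, si, 10_001 + 2 * ri)
            master_rows.append(inject_artifacts(base, config, mrng, batch_index=0))
            slave_rows.append(inject_artifacts(base, config, srng2, batch_index=1))
            for meta, tag in ((meta_m, "m"), (meta_s, "s")):
                meta.append(
                    {
                        "spectrum_id": f"{subject_id}_xfer_{tag}{ri}",
                        "subject_id": subject_id,
                        "group": cls,
                        "batch": "b0" if tag == "m" else "b1",
                        "replicate": ri,
                    }
                )
    make = lambda rows, meta: SpectralDataset(  # noqa: E731
        wavenumbers=grid, intensities=np.vstack(rows), metadata=pd.DataFrame(meta)
    )
    return make(master_rows, meta_m), make(slave_rows, meta_s)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Config copy with a different seed."""
    return replace(config, seed=seed)
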