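"""In-memory containers for serum FTIR spectra.

A :class:`SpectralDataset` is the object every pipeline stage consumes and
produces: one shared, strictly ascending wavenumber grid (cm^-1), an
``(n_spectra, n_points)`` absorbance matrix, and a metadata table aligned
row-for-row with the matrix.

The internal grid convention is ascending wavenumbers everywhere; readers
normalise descending input on ingestion and nothing downstream ever
re-reverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required metadata columns, in canonical order.
META_COLUMNS = ("spectrum_id", "subject_id", "group", "batch", "replicate")


class SpectralDataError(ValueError):
    """Raised when spectral data violate a structural contract."""


@dataclass
class Spectrum:
    """A single spectrum: ascending wavenumber grid plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    subject_id: str = ""
    group: str = ""
    batch: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectralDataError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise SpectralDataError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectralDataError("wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectralDataError("intensities must be finite")


@dataclass
class SpectralDataset:
    """A stack of spectra on one common grid with aligned metadata.

    Parameters
    ----------
    wavenumbers : ndarray, shape (n_points,)
        Strictly ascending common grid in cm^-1.
    intensities : ndarray, shape (n_spectra, n_points)
        Absorbance matrix; one spectrum per row.
    metadata : DataFrame
        One row per spectrum with at least the columns in
        :data:`META_COLUMNS`.  ``subject_id -> group`` must be single-valued.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectralDataError("common grid must be strictly ascending")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise SpectralDataError(
                f"matrix has {self.intensities.shape[1]} columns but grid has "
                f"{self.wavenumbers.size} points"
            )
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {
                    "spectrum_id": [f"s{i:05d}" for i in range(self.n_spectra)],
                    "subject_id": [f"subj{i:05d}" for i in range(self.n_spectra)],
                    "group": "",
                    "batch": "b0",
                    "replicate": 0,
                }
            )
        self.metadata = self.metadata.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise SpectralDataError(f"metadata lacks required columns: {missing}")
        if len(self.metadata) != self.n_spectra:
            raise SpectralDataError(
                f"metadata has {len(self.metadata)} rows for "
                f"{self.n_spectra} spectra"
            )
        groups_per_subject = self.metadata.groupby("subject_id")["group"].nunique()
        bad = groups_per_subject[groups_per_subject > 1]
        if len(bad):
            raise SpectralDataError(
                f"subject->group mapping not single-valued for: {list(bad.index)}"
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def __len__(self) -> int:
        return self.n_spectra

    # -- helpers ----------------------------------------------------------
    def window_mask(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of grid points inside the closed interval [low, high]."""
        if low >= high:
            raise SpectralDataError(f"window [{low}, {high}] is reversed or empty")
        return (self.wavenumbers >= low) & (self.wavenumbers <= high)

    def select_rows(self, index) -> "SpectralDataset":
        """Row subset (boolean mask or integer index), order preserved."""
        index = np.asarray(index)
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[index].copy(),
            metadata=self.metadata.iloc[np.flatnonzero(index) if index.dtype == bool else index]
            .reset_index(drop=True)
            .copy(),
        )

    def with_intensities(self, intensities: np.ndarray, wavenumbers: np.ndarray | None = None) -> "SpectralDataset":
        """Same metadata, new matrix (and optionally new grid)."""
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy() if wavenumbers is None else np.asarray(wavenumbers, float),
            intensities=np.asarray(intensities, float),
            metadata=self.metadata.copy(),
        )

    def copy(self) -> "SpectralDataset":
        return self.with_intensities(self.intensities.copy())

    def spectrum(self, i: int) -> Spectrum:
        row = self.metadata.iloc[i]
        return Spectrum(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[i].copy(),
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            batch=str(row["batch"]),
            replicate=int(row["replicate"]),
        )

    def equals(self, other: "SpectralDataset", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.wavenumbers.shape == other.wavenumbers.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, rtol=rtol, atol=atol)
            and self.intensities.shape == other.intensities.shape
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol)
            and self.metadata[list(META_COLUMNS)].astype(str).equals(
                other.metadata[list(META_COLUMNS)].astype(str)
            )
        )


def stack(datasets: list[SpectralDataset]) -> SpectralDataset:
    """Concatenate datasets sharing one grid."""
    if not datasets:
        raise SpectralDataError("nothing to stack")
    grid = datasets[0].wavenumbers
    for d in datasets[1:]:
        if d.wavenumbers.shape != grid.shape or not np.array_equal(d.wavenumbers, grid):
            raise SpectralDataError("grid mismatch while stacking datasets")
    return SpectralDataset(
        wavenumbers=grid.copy(),
        intensities=np.vstack([d.intensities for d in datasets]),
        metadata=pd.concat([d.metadata for d in datasets], ignore_index=True),
    )
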