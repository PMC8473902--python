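"""Containers for FTIR absorbance spectra.

A :class:`Spectrum` is a single absorbance trace on a wavenumber grid; a
:class:`SpectrumSet` holds many spectra that share one grid, together with
sample metadata (strain, species, replicate).  Grids are stored in the
mid-IR instrument convention: strictly monotone *descending* wavenumbers
(e.g. 4000 -> 600 cm^-1) with uniform spacing.

On-disk format is a wide CSV: first column ``wavenumber_cm-1``, one column
per sample id; metadata travels in a companion CSV with columns
``sample,strain,species,replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectrumSet", "read_spectra_csv", "write_spectra_csv"]

#: relative tolerance for uniform-grid validation
_GRID_RTOL = 1e-6

META_COLUMNS = ("strain", "species", "replicate")


def _validate_grid(wavenumbers: np.ndarray) -> float:
    """Check strict descent and uniform spacing; return the (positive) step."""
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise ValueError("wavenumber grid needs at least two points")
    steps = np.diff(wn)
    if not np.all(steps < 0):
        raise ValueError("wavenumber grid must be strictly descending")
    step = -float(steps.mean())
    if np.max(np.abs(-steps - step)) > _GRID_RTOL * step:
        raise ValueError("wavenumber grid must be uniformly spaced")
    return step


@dataclass
class Spectrum:
    """One absorbance spectrum on a uniform descending wavenumber grid."""

    sample_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        _validate_grid(self.wavenumbers)

    @property
    def grid_step(self) -> float:
        return -float(np.diff(self.wavenumbers).mean())

    def __len__(self) -> int:
        return self.wavenumbers.size


class SpectrumSet:
    """A collection of spectra on one shared grid, plus sample metadata.

    Parameters
    ----------
    wavenumbers : 1-D array, descending, uniformly spaced (cm^-1).
    intensities : 2-D array, one row per sample.
    ids : sample identifiers, one per row.
    meta : optional DataFrame indexed by sample id with columns
        ``strain``, ``species``, ``replicate`` (missing columns allowed).
    """

    def __init__(self, wavenumbers, intensities, ids, meta: pd.DataFrame | None = None):
        self.wavenumbers = np.asarray(wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        self.ids = list(ids)
        _validate_grid(self.wavenumbers)
        if self.intensities.shape != (len(self.ids), self.wavenumbers.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.ids)} samples x {self.wavenumbers.size} grid points"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        if meta is None:
            meta = pd.DataFrame(index=pd.Index(self.ids, name="sample"))
        else:
            meta = meta.copy()
            if "sample" in meta.columns:
                meta = meta.set_index("sample")
            missing = set(self.ids) - set(meta.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
            meta = meta.loc[self.ids]
        self.meta = meta

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        for i, sid in enumerate(self.ids):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        sid = self.ids[i]
        return Spectrum(sid, self.wavenumbers, self.intensities[i],
                        meta=dict(self.meta.loc[sid].dropna()))

    @property
    def grid_step(self) -> float:
        return -float(np.diff(self.wavenumbers).mean())

    def labels(self, column: str) -> pd.Series:
        """Metadata column (e.g. ``strain``) aligned to the sample order."""
        if column not in self.meta.columns:
            raise KeyError(f"metadata has no column {column!r}")
        return self.meta[column]

    def with_data(self, wavenumbers, intensities) -> "SpectrumSet":
        """New set with the same samples/metadata but transformed data."""
        return SpectrumSet(wavenumbers, intensities, self.ids, self.meta.reset_index())

    # -- IO ----------------------------------------------------------------
    def to_csv(self, spectra_path, meta_path=None) -> None:
        write_spectra_csv(self, spectra_path, meta_path)

    @classmethod
    def from_csv(cls, spectra_path, meta_path=None) -> "SpectrumSet":
        return read_spectra_csv(spectra_path, meta_path)


def write_spectra_csv(sset: SpectrumSet, spectra_path, meta_path=None) -> None:
    """Write the wide spectra CSV (and optionally the metadata CSV)."""
    df = pd.DataFrame(sset.intensities.T, columns=sset.ids)
    df.insert(0, "wavenumber_cm-1", sset.wavenumbers)
    df.to_csv(spectra_path, index=False)
    if meta_path is not None:
        sset.meta.reset_index().to_csv(meta_path, index=False)


def read_spectra_csv(spectra_path, meta_path=None) -> SpectrumSet:
    """Read the wide spectra CSV dialect (first column ``wavenumber_cm-1``)."""
    df = pd.read_csv(spectra_path)
    first = df.columns[0]
    if not first.startswith("wavenumber"):
        raise ValueError(f"first column must be the wavenumber axis, got {first!r}")
    wn = df[first].to_numpy(dtype=float)
    ids = list(df.columns[1:])
    if not ids:
        raise ValueError(f"no sample columns in {Path(spectra_path)}")
    intens = df[ids].to_numpy(dtype=float).T
    meta = pd.read_csv(meta_path) if meta_path is not None else None
    return SpectrumSet(wn, intens, ids, meta)
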