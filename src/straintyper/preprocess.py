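"""Spectral preprocessing: Savitzky-Golay second derivative, window cut,
vector normalization.

The analysis representation of an FTIR spectrum is produced by three steps
applied in this order:

1. second derivative d^2 A / d nu^2, estimated with a Savitzky-Golay filter
   (local least-squares polynomial fit, default 9 points / order 3), which
   resolves overlapping absorption bands and annihilates additive linear
   baselines;
2. restriction to the carbohydrate fingerprint window (default
   1300-800 cm^-1), the region that carries cell-wall composition signal;
3. scaling to unit Euclidean norm, which removes pathlength / biomass
   amount effects.

Derivatives are taken with respect to wavenumber (physical units,
absorbance * cm^2), not sample index, so results do not depend on the grid
spacing.  The (window-1)/2 edge points on each side of the grid are dropped
rather than padded; the fingerprint window is interior so the edges never
reach the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "PreprocessParams",
    "sg_second_derivative",
    "cut_range",
    "vector_normalize",
    "preprocess_set",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    sg_window : odd number of points in the Savitzky-Golay fit (default 9).
    sg_polyorder : polynomial order of the local fit (default 3).
    cut_hi, cut_lo : retained wavenumber window in cm^-1, inclusive
        (defaults 1300 and 800).
    """

    sg_window: int = 9
    sg_polyorder: int = 3
    cut_hi: float = 1300.0
    cut_lo: float = 800.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if self.sg_polyorder < 2:
            raise ValueError("sg_polyorder must be >= 2 for a second derivative")
        if not self.cut_hi > self.cut_lo:
            raise ValueError("cut_hi must exceed cut_lo")


def _sg_arrays(wn: np.ndarray, y: np.ndarray, p: PreprocessParams):
    half = (p.sg_window - 1) // 2
    if wn.size < p.sg_window:
        raise ValueError(
            f"spectrum has {wn.size} points, fewer than the "
            f"{p.sg_window}-point filter window"
        )
    step = -float(np.diff(wn).mean())
    # savgol assumes ascending sample order along the array; the grid is
    # descending in nu, but a second derivative is invariant to axis flip.
    d2 = savgol_filter(y, p.sg_window, p.sg_polyorder, deriv=2, delta=step, axis=-1)
    return wn[half:-half], d2[..., half:-half]


def sg_second_derivative(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber.

    Each output point is the second derivative at the center of a local
    least-squares polynomial of order ``sg_polyorder`` fitted to
    ``sg_window`` consecutive points.  The (window-1)/2 edge points at each
    end are dropped.
    """
    wn, d2 = _sg_arrays(s.wavenumbers, s.intensities, p)
    return Spectrum(s.sample_id, wn, d2, meta=dict(s.meta))


def _cut_mask(wn: np.ndarray, p: PreprocessParams, step: float) -> np.ndarray:
    # inclusive bounds, matched by value with half-a-step tolerance
    tol = 0.5 * step
    return (wn >= p.cut_lo - tol) & (wn <= p.cut_hi + tol)


def cut_range(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Retain the points with cut_lo <= nu <= cut_hi (both ends inclusive)."""
    mask = _cut_mask(s.wavenumbers, p, s.grid_step)
    if mask.sum() < 2:
        raise ValueError(
            f"window [{p.cut_lo}, {p.cut_hi}] cm^-1 does not overlap the grid "
            f"[{s.wavenumbers.min():g}, {s.wavenumbers.max():g}]"
        )
    return Spectrum(s.sample_id, s.wavenumbers[mask], s.intensities[mask],
                    meta=dict(s.meta))


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise ValueError(f"spectrum {s.sample_id!r} is identically zero")
    return Spectrum(s.sample_id, s.wavenumbers, s.intensities / norm,
                    meta=dict(s.meta))


def preprocess_set(sset: SpectrumSet, p: PreprocessParams = PreprocessParams()) -> SpectrumSet:
    """Apply derivative -> cut -> normalize to every spectrum of a set.

    All spectra share one grid, so the whole set is transformed with
    vectorized array operations; the result equals the per-spectrum
    composition of :func:`sg_second_derivative`, :func:`cut_range` and
    :func:`vector_normalize`.
    """
    wn, d2 = _sg_arrays(sset.wavenumbers, sset.intensities, p)
    mask = _cut_mask(wn, p, sset.grid_step)
    if not mask.any():
        raise ValueError("cut window does not overlap the derivative grid")
    wn = wn[mask]
    d2 = d2[:, mask]
    norms = np.linalg.norm(d2, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        bad = [sset.ids[i] for i in np.flatnonzero(norms[:, 0] == 0.0)]
        raise ValueError(f"zero spectra after preprocessing: {bad[:5]}")
    return sset.with_data(wn, d2 / norms)
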