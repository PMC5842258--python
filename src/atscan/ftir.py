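"""FTIR spectrum preprocessing and difference spectra.

Cell-wall FTIR spectra of macerated stem tissue are compared over the
fingerprint region (800–1800 cm⁻¹).  Preprocessing follows the usual
recipe: truncate to the fingerprint window, anchor the baseline at
1800 cm⁻¹ (subtract the absorbance there as a constant offset), and
normalize each spectrum to unit trapezoidal area so tissue loading
cancels.  Genotype groups are then compared by a pointwise mean
difference spectrum.

The diagnostic contrast for pectin methylesterification is the pair of
carbonyl bands near 1740 cm⁻¹ (methyl-esterified, C=O ester stretch) and
1600–1630 cm⁻¹ (de-esterified carboxylate); their ratio tracks the
esterification state of the pectin fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "DifferenceSpectrum",
    "preprocess_spectrum",
    "difference_spectrum",
    "band_ratio",
    "FINGERPRINT_WINDOW",
    "ESTER_BAND",
    "CARBOXYLATE_BAND",
]

FINGERPRINT_WINDOW = (800.0, 1800.0)
BASELINE_ANCHOR = 1800.0
ESTER_BAND = 1740.0        # methyl-esterified pectin C=O
CARBOXYLATE_BAND = 1624.0  # de-esterified pectin COO-


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber/absorbance series with processing-state flags."""

    wavenumber: np.ndarray   # cm^-1, strictly monotone
    absorbance: np.ndarray   # arbitrary units
    truncated: bool = False
    baselined: bool = False
    normalized: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumber, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise ValueError("wavenumber and absorbance must be 1-D and equal length")
        if w.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        dw = np.diff(w)
        if np.all(dw > 0):
            pass
        elif np.all(dw < 0):  # descending instruments: store ascending
            w, a = w[::-1], a[::-1]
        else:
            raise ValueError("wavenumbers must be strictly monotone")
        object.__setattr__(self, "wavenumber", w)
        object.__setattr__(self, "absorbance", a)

    def value_at(self, wn: float) -> float:
        """Absorbance at ``wn`` (linear interpolation between grid points)."""
        w = self.wavenumber
        if not (w[0] <= wn <= w[-1]):
            raise ValueError(f"{wn} cm^-1 outside spectral range [{w[0]}, {w[-1]}]")
        return float(np.interp(wn, w, self.absorbance))

    def area(self) -> float:
        """Trapezoidal integral over the stored range."""
        return float(np.trapezoid(self.absorbance, self.wavenumber))


@dataclass(frozen=True)
class DifferenceSpectrum:
    """Pointwise mean(group A) − mean(group B) with band read-outs."""

    wavenumber: np.ndarray
    delta: np.ndarray
    band_values: dict
    convention: str = "A-minus-B"

    def value_at(self, wn: float) -> float:
        return float(np.interp(wn, self.wavenumber, self.delta))


class ZeroAreaError(ValueError):
    """Normalization impossible: zero integral after baseline anchoring."""


def preprocess_spectrum(
    s: Spectrum,
    window: tuple[float, float] = FINGERPRINT_WINDOW,
    anchor: float = BASELINE_ANCHOR,
) -> Spectrum:
    """Truncate, anchor the baseline and area-normalize one spectrum.

    The spectrum is cut to ``window``, the absorbance at ``anchor``
    (linearly interpolated when off-grid) is subtracted as a constant
    offset, and the result is divided by its trapezoidal integral so the
    retained window has unit area.  Already-normalized spectra are
    returned unchanged (flags make the operation idempotent).
    """
    if s.normalized:
        return s
    lo, hi = window
    w = s.wavenumber
    if w[0] > lo or w[-1] < min(hi, anchor):
        raise ValueError(
            f"spectrum [{w[0]}, {w[-1]}] does not cover the {lo}-{max(hi, anchor)} cm^-1 window"
        )
    base = s.value_at(anchor)
    mask = (w >= lo) & (w <= hi)
    wt = w[mask]
    # make sure the window edges themselves are on the grid
    if wt[0] > lo:
        wt = np.concatenate([[lo], wt])
    if wt[-1] < hi:
        wt = np.concatenate([wt, [hi]])
    at = np.interp(wt, w, s.absorbance) - base
    area = float(np.trapezoid(at, wt))
    if abs(area) < 1e-12 * max(float(np.max(np.abs(at)) * (hi - lo)), 1e-30) or area == 0.0:
        raise ZeroAreaError("zero integral after baseline anchoring")
    return Spectrum(
        wavenumber=wt,
        absorbance=at / area,
        truncated=True,
        baselined=True,
        normalized=True,
        meta=dict(s.meta, baseline_anchor=anchor, window=window),
    )


def _common_grid(spectra: list[Spectrum]) -> np.ndarray:
    lo = max(s.wavenumber[0] for s in spectra)
    hi = min(s.wavenumber[-1] for s in spectra)
    if lo >= hi:
        raise ValueError("spectra have disjoint wavenumber ranges")
    ref = spectra[0].wavenumber
    grid = ref[(ref >= lo) & (ref <= hi)]
    if grid.size < 3:
        raise ValueError("common wavenumber range too narrow")
    return grid


def difference_spectrum(
    group_a: list[Spectrum],
    group_b: list[Spectrum],
    bands: tuple[float, ...] = (ESTER_BAND, CARBOXYLATE_BAND),
) -> DifferenceSpectrum:
    """Mean spectrum of group A minus mean spectrum of group B.

    Raw inputs are preprocessed first; all spectra are resampled onto the
    common grid by linear interpolation.  The convention is ``A − B``
    (e.g. A = wild type, B = mutant: a band where the mutant is enriched
    comes out negative).  Signed values at ``bands`` are reported in
    ``band_values``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one spectrum")
    ga = [preprocess_spectrum(s) for s in group_a]
    gb = [preprocess_spectrum(s) for s in group_b]
    grid = _common_grid(ga + gb)
    mean_a = np.mean([np.interp(grid, s.wavenumber, s.absorbance) for s in ga], axis=0)
    mean_b = np.mean([np.interp(grid, s.wavenumber, s.absorbance) for s in gb], axis=0)
    delta = mean_a - mean_b
    band_values = {b: float(np.interp(b, grid, delta)) for b in bands}
    return DifferenceSpectrum(wavenumber=grid, delta=delta, band_values=band_values)


def band_ratio(
    s: Spectrum,
    band1: float = ESTER_BAND,
    band2: float = CARBOXYLATE_BAND,
    halfwidth: float = 8.0,
) -> float:
    """Integrated-absorbance ratio of two bands (band1 / band2).

    The spectrum is preprocessed if raw, then each band is integrated
    over ``band ± halfwidth`` by the trapezoid rule.  Area normalization
    makes the ratio invariant to global positive scaling of the raw
    spectrum.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if abs(band1 - band2) < 2 * halfwidth:
        raise ValueError("band windows overlap; reduce halfwidth")
    sp = preprocess_spectrum(s)
    w = sp.wavenumber
    for b in (band1, band2):
        if b - halfwidth < w[0] or b + halfwidth > w[-1]:
            raise ValueError(f"band {b} ± {halfwidth} outside spectral window")

    def integrate(center: float) -> float:
        grid = np.union1d(
            w[(w >= center - halfwidth) & (w <= center + halfwidth)],
            [center - halfwidth, center + halfwidth],
        )
        vals = np.interp(grid, w, sp.absorbance)
        return float(np.trapezoid(vals, grid))

    i1, i2 = integrate(band1), integrate(band2)
    if i2 == 0.0:
        raise ZeroDivisionError("zero integrated absorbance in reference band")
    return i1 / i2
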