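"""Stem mechanical-strength traits from three-point-bend tests.

A dried stem section rests on two supports a span ``L`` apart and a probe
descends at its midpoint (``a = L/2``), recording a force–displacement
trace.  Two *absolute* strength traits are read off the trace:

* ``Fmax`` — the peak force, the stem's absolute resistance to breaking;
* ``F/V`` — the slope of the initial elastic segment, its absolute
  resistance to bending.

Combining these with the cross-section's second moment of area

    I = pi * (D2**4 - d1a**4) / 64

(``D2``/``d1a`` the whole-stem and hollow diameters, both derived from
areas) gives the *material* strength traits

    MOR = Fmax * a * D2 / I
    MOE = (F/V) * (a**2 / 12) * (3L - 4a) / I

which with the midpoint load ``a = L/2`` reduces MOE to the textbook
three-point-bend form ``(F/V) * L**3 / (48 I)``.

Forces are carried in whatever units the instrument records; no unit
conversion is applied (callers may scale inputs themselves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BendCurve",
    "StemGeometry",
    "StrengthTraits",
    "NoElasticRegionError",
    "extract_curve_features",
    "diameter_from_area",
    "second_moment_of_area",
    "modulus_of_rupture",
    "modulus_of_elasticity",
    "derive_stem_traits",
    "derive_trait_table",
    "accession_means",
]

DEFAULT_SPAN_MM = 70.0      # rapeseed stem sections: supports 7 cm apart
ARABIDOPSIS_SPAN_MM = 12.0  # razor-blade rig for thin stems: 1.2 cm


class NoElasticRegionError(ValueError):
    """The trace has no usable rising elastic segment."""


@dataclass(frozen=True)
class BendCurve:
    """A force–displacement trace from a three-point bend test."""

    displacement: np.ndarray  # mm, strictly increasing
    force: np.ndarray         # instrument force units

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if d.ndim != 1 or f.ndim != 1 or d.size != f.size:
            raise ValueError("displacement and force must be 1-D and equal length")
        if d.size < 3:
            raise ValueError("a bend curve needs at least 3 samples")
        if not np.all(np.diff(d) > 0):
            raise ValueError("displacement must be strictly increasing")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in bend curve")


@dataclass(frozen=True)
class StemGeometry:
    """Cross-section measurements of a stem sample.

    Whole-stem and hollow diameters are always *derived* from the measured
    areas (``d = 2 sqrt(area/pi)``), never supplied directly.
    """

    whole_area: float                 # mm^2
    hollow_area: float = 0.0          # mm^2
    parenchyma_area: float = float("nan")  # mm^2
    cortex_thickness: float = float("nan")  # mm

    def __post_init__(self) -> None:
        if self.whole_area < 0 or self.hollow_area < 0:
            raise ValueError("areas must be non-negative")
        if self.hollow_area >= self.whole_area and self.whole_area > 0:
            raise ValueError("hollow_area must be smaller than whole_area")

    @property
    def D2(self) -> float:
        """Whole-stem diameter (mm), from the whole cross-section area."""
        return diameter_from_area(self.whole_area)

    @property
    def d1a(self) -> float:
        """Hollow diameter (mm), from the central-cavity area."""
        return diameter_from_area(self.hollow_area)


@dataclass(frozen=True)
class StrengthTraits:
    """Per-sample strength trait bundle."""

    fmax: float
    f_over_v: float
    I: float
    MOR: float
    MOE: float
    span: float
    a: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.a):
            object.__setattr__(self, "a", self.span / 2.0)


def _unimodal_fit(y: np.ndarray) -> np.ndarray:
    """Project a sequence onto the closest rise-then-fall (unimodal) shape.

    Least-squares unimodal regression: for every candidate mode position the
    best fit is the isotonic (increasing) regression of the prefix joined to
    the antitonic regression of the suffix; the mode with the smallest
    residual sum of squares wins.  A clean unimodal trace is reproduced
    exactly; under noise, neighbouring samples are pooled, which keeps the
    fitted peak close to the true one instead of riding the largest noise
    excursion.
    """
    n = y.size
    inc_fits, inc_sse = _pava_prefix(y)
    dec_fits, dec_sse = _pava_prefix(y[::-1])
    # split after index m: y[0..m] non-decreasing, y[m+1..n-1] non-increasing
    best_m, best_sse = n - 1, np.inf
    for m in range(n):
        sse = inc_sse[m] + (dec_sse[n - 2 - m] if m < n - 1 else 0.0)
        if sse < best_sse - 1e-12:
            best_sse, best_m = sse, m
    out = np.empty(n)
    out[: best_m + 1] = inc_fits[best_m]
    if best_m < n - 1:
        out[best_m + 1 :] = dec_fits[n - 2 - best_m][::-1]
    return out


def _pava_prefix(y: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Isotonic (non-decreasing) fits of every prefix of ``y`` via PAVA.

    Returns ``(fits, sse)`` where ``fits[m]`` is the fitted prefix ``y[:m+1]``
    and ``sse[m]`` its residual sum of squares.  Runs the pool-adjacent-
    violators pass once, snapshotting each prefix in O(n^2) total.
    """
    n = y.size
    fits: list[np.ndarray] = []
    sse = np.empty(n)
    # active blocks: (level, weight, sum_sq) with implicit contiguity
    levels: list[float] = []
    weights: list[int] = []
    ssq: list[float] = []
    for i in range(n):
        levels.append(float(y[i]))
        weights.append(1)
        ssq.append(float(y[i]) ** 2)
        while len(levels) > 1 and levels[-2] >= levels[-1]:
            w = weights[-2] + weights[-1]
            lv = (levels[-2] * weights[-2] + levels[-1] * weights[-1]) / w
            sq = ssq[-2] + ssq[-1]
            levels[-2:] = [lv]
            weights[-2:] = [w]
            ssq[-2:] = [sq]
        fit = np.repeat(levels, weights)
        fits.append(fit)
        sse[i] = sum(sq - lv * lv * w for lv, w, sq in zip(levels, weights, ssq))
    return fits, np.maximum(sse, 0.0)


def estimate_trace_noise(force: np.ndarray) -> float:
    """Robust white-noise SD of a trace from its second differences.

    Second differences annihilate any locally linear signal, so for a
    piecewise-linear mechanical profile the median absolute second
    difference reflects measurement noise only (scaled by sqrt(6) for the
    variance of a second difference and 1.4826 for MAD-to-SD).
    """
    if force.size < 4:
        return 0.0
    d2 = np.diff(np.asarray(force, dtype=float), 2)
    return float(1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0))


def extract_curve_features(
    curve: BendCurve,
    window: tuple[float, float] = (0.10, 0.75),
) -> tuple[float, float]:
    """Read ``(fmax, f_over_v)`` off a force–displacement trace.

    ``fmax`` is the peak of the unimodal projection of the force trace:
    identical to ``max(force)`` on a noise-free trace.  When measurement
    noise is detected (see :func:`estimate_trace_noise`), the trace is
    first smoothed with a quadratic Savitzky–Golay filter so the peak
    estimate does not ride the largest noise excursion.  ``f_over_v`` is
    the least-squares slope over the pre-peak samples whose (fitted) force
    lies between ``window[0]`` and ``window[1]`` of ``fmax`` — skipping the
    toe-in region near zero load and the final approach to failure.

    Raises
    ------
    NoElasticRegionError
        If the trace is flat, monotonically decreasing, or leaves fewer
        than two samples in the elastic window.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    f = curve.force
    if np.ptp(f) == 0.0:
        raise NoElasticRegionError("constant-force trace has no elastic region")
    sigma = estimate_trace_noise(f)
    if sigma > 1e-9 * np.ptp(f) and f.size >= 9:
        from scipy.signal import savgol_filter

        w = min(max(2 * (f.size // 24) + 1, 5), 101, f.size - (1 - f.size % 2))
        fitted = _unimodal_fit(savgol_filter(f, w, 2))
    else:
        fitted = _unimodal_fit(f)
    peak_idx = int(np.argmax(fitted))
    fmax = float(fitted[peak_idx])
    if fmax <= 0 or peak_idx == 0:
        raise NoElasticRegionError("trace has no rising segment before its peak")
    pre = np.arange(curve.force.size) <= peak_idx
    mask = pre & (fitted >= lo * fmax) & (fitted <= hi * fmax)
    if mask.sum() < 2:
        raise NoElasticRegionError(
            f"fewer than 2 samples with force in [{lo:.0%}, {hi:.0%}] of fmax"
        )
    x = curve.displacement[mask]
    y = curve.force[mask]
    slope = float(np.polyfit(x, y, 1)[0])
    if slope <= 0:
        raise NoElasticRegionError("elastic-window slope is not positive")
    return fmax, slope


def diameter_from_area(area: float) -> float:
    """Diameter of the circle with the given area: ``2 sqrt(area/pi)``."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    out = 2.0 * np.sqrt(area / math.pi)
    return float(out) if out.ndim == 0 else out


def second_moment_of_area(D2: float, d1a: float = 0.0) -> float:
    """Second moment of area of an annulus: ``pi (D2^4 - d1a^4) / 64``."""
    D2 = np.asarray(D2, dtype=float)
    d1a = np.asarray(d1a, dtype=float)
    if np.any(d1a < 0) or np.any(D2 < 0):
        raise ValueError("diameters must be non-negative")
    if np.any(d1a > D2):
        raise ValueError("hollow diameter d1a cannot exceed whole diameter D2")
    out = math.pi * (D2**4 - d1a**4) / 64.0
    return float(out) if out.ndim == 0 else out


def modulus_of_rupture(fmax: float, a: float, D2: float, I: float) -> float:
    """Material resistance to breakage: ``Fmax * a * D2 / I``."""
    if np.any(np.asarray(I) <= 0):
        raise ValueError("second moment of area I must be positive")
    out = np.asarray(fmax, dtype=float) * a * D2 / I
    return float(out) if np.ndim(out) == 0 else out


def modulus_of_elasticity(f_over_v: float, a: float, L: float, I: float) -> float:
    """Material flexural stiffness: ``(F/V) * (a^2/12) * (3L - 4a) / I``."""
    if np.any(np.asarray(I) <= 0):
        raise ValueError("second moment of area I must be positive")
    out = np.asarray(f_over_v, dtype=float) * (a**2 / 12.0) * (3.0 * L - 4.0 * a) / I
    return float(out) if np.ndim(out) == 0 else out


def derive_stem_traits(
    curve: BendCurve,
    geometry: StemGeometry,
    span: float = DEFAULT_SPAN_MM,
) -> StrengthTraits:
    """Chain curve extraction and the beam equations for one sample."""
    if span <= 0:
        raise ValueError("span must be positive")
    fmax, f_over_v = extract_curve_features(curve)
    a = span / 2.0
    I = second_moment_of_area(geometry.D2, geometry.d1a)
    if I <= 0:
        raise ValueError("degenerate cross-section: I = 0")
    mor = modulus_of_rupture(fmax, a, geometry.D2, I)
    moe = modulus_of_elasticity(f_over_v, a, span, I)
    return StrengthTraits(fmax=fmax, f_over_v=f_over_v, I=I, MOR=mor, MOE=moe, span=span, a=a)


def derive_trait_table(
    curves: dict[str, BendCurve],
    geometry: pd.DataFrame,
    span: float = DEFAULT_SPAN_MM,
) -> pd.DataFrame:
    """Batch-mode trait derivation.

    ``geometry`` has one row per sample with columns ``sample``,
    ``accession``, ``whole_area_mm2``, ``hollow_area_mm2`` and optionally
    ``parenchyma_area_mm2``, ``cortex_thickness_mm``.  Returns a tidy table
    with one row per sample; failures are re-raised tagged with the sample
    id.  Use :func:`accession_means` for the accession-mean table.
    """
    required = {"sample", "accession", "whole_area_mm2", "hollow_area_mm2"}
    missing = required - set(geometry.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    rows = []
    for rec in geometry.to_dict("records"):
        sid = rec["sample"]
        try:
            geo = StemGeometry(
                whole_area=float(rec["whole_area_mm2"]),
                hollow_area=float(rec["hollow_area_mm2"]),
                parenchyma_area=float(rec.get("parenchyma_area_mm2", float("nan"))),
                cortex_thickness=float(rec.get("cortex_thickness_mm", float("nan"))),
            )
            tr = derive_stem_traits(curves[sid], geo, span=span)
        except Exception as exc:
            raise type(exc)(f"sample {sid!r}: {exc}") from exc
        rows.append(
            {
                "sample": sid,
                "accession": rec["accession"],
                "fmax": tr.fmax,
                "f_over_v": tr.f_over_v,
                "stem_diameter": geo.D2,
                "second_moment": tr.I,
                "MOR": tr.MOR,
                "MOE": tr.MOE,
                "parenchyma_area": geo.parenchyma_area,
                "cortex_thickness": geo.cortex_thickness,
                "hollow_area": geo.hollow_area,
            }
        )
    return pd.DataFrame(rows)


def accession_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic accession means of every numeric trait column."""
    return (
        trait_table.drop(columns=["sample"], errors="ignore")
        .groupby("accession", sort=True)
        .mean(numeric_only=True)
    )
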