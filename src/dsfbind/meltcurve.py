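"""Melt-curve processing: normalization, smoothing, derivative, Tm, peaks.

A DSF melt curve records reporter-dye fluorescence as a protein sample is
heated through its unfolding transition.  The melting temperature Tm is
defined here, as is conventional for thermal-shift assays, as the temperature
of the maximal rate of fluorescence change — the global maximum of dF/dT.
With a constant instrument ramp rate the derivative with respect to time is
proportional to the derivative with respect to temperature, so everything is
reported per °C.

The processing chain for one well is typically::

    curve -> smooth_curve -> derivative_curve -> find_tm / detect_peaks

Biphasic melts (two coexisting unfolding transitions, e.g. a ligand-bound and
a ligand-free population) appear as two derivative peaks; ``detect_peaks``
attributes the positive-derivative area to each transition by a
nearest-minimum watershed, which downstream code uses to estimate the
fraction of protein in the shifted (bound) population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import peak_prominences, savgol_filter

from .errors import DegenerateCurveError, NoTransitionError, ParameterError

__all__ = [
    "MeltCurve",
    "DerivativeCurve",
    "Peak",
    "PeakSet",
    "normalize_curve",
    "smooth_curve",
    "derivative_curve",
    "find_tm",
    "detect_peaks",
]


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-vs-temperature trace.

    Parameters
    ----------
    temperatures
        Temperature grid in °C, strictly increasing.
    fluorescence
        Raw (or smoothed) fluorescence in RFU, same length as the grid.
    well_id
        Instrument well identifier, e.g. ``"A1"``.
    normalized
        Optional normalized trace on a 0–100 scale (see
        :func:`normalize_curve`).
    annotations
        Free-form metadata (plate id, smoothing descriptor, ...).
    """

    temperatures: np.ndarray
    fluorescence: np.ndarray
    well_id: str = ""
    normalized: np.ndarray | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or f.shape != t.shape:
            raise ParameterError(
                f"well {self.well_id!r}: temperature and fluorescence arrays "
                f"must be 1-D and equal length (got {t.shape} vs {f.shape})"
            )
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if self.normalized is not None:
            n = np.asarray(self.normalized, dtype=float)
            if n.shape != t.shape:
                raise ParameterError("normalized trace length mismatch")
            object.__setattr__(self, "normalized", n)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class DerivativeCurve:
    """dF/dT of a melt curve on the same temperature grid."""

    temperatures: np.ndarray
    dfdt: np.ndarray
    smoothing: str = "none"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        d = np.asarray(self.dfdt, dtype=float)
        if t.ndim != 1 or d.shape != t.shape:
            raise ParameterError("derivative length inconsistent with grid")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "dfdt", d)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class Peak:
    """One derivative peak: a candidate unfolding transition."""

    tm_C: float
    height: float
    prominence: float
    area_fraction: float


@dataclass(frozen=True)
class PeakSet:
    """Derivative peaks sorted by temperature; area fractions sum to ≤ 1."""

    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        tms = [p.tm_C for p in self.peaks]
        if tms != sorted(tms):
            raise ParameterError("peaks must be sorted by temperature")
        total = sum(p.area_fraction for p in self.peaks)
        if total > 1.0 + 1e-9:
            raise ParameterError(f"peak area fractions sum to {total} > 1")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]


def normalize_curve(curve: MeltCurve, mode: str = "minmax") -> MeltCurve:
    """Return a copy of *curve* with a 0–100 normalized trace attached.

    ``mode="minmax"`` (default) rescales to ``100 * (F - min) / (max - min)``
    so the normalized trace spans exactly [0, 100]; ``mode="max"`` divides by
    the maximum only (``100 * F / max``), matching the "percentage maximum
    fluorescence" convention some instruments use.

    Raises
    ------
    DegenerateCurveError
        If the trace is constant (no signal to normalize).
    """
    f = curve.fluorescence
    fmin, fmax = float(np.min(f)), float(np.max(f))
    if fmax == fmin:
        raise DegenerateCurveError(
            f"well {curve.well_id!r}: constant fluorescence trace cannot be normalized"
        )
    if mode == "minmax":
        # ratio first so the extrema map to exactly 0 and 100
        norm = ((f - fmin) / (fmax - fmin)) * 100.0
    elif mode == "max":
        if fmax == 0:
            raise DegenerateCurveError("max-normalization of an all-zero trace")
        norm = 100.0 * f / fmax
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return replace(curve, normalized=norm)


def smooth_curve(curve: MeltCurve, window: int = 7, polyorder: int = 3) -> MeltCurve:
    """Savitzky–Golay smooth the fluorescence trace.

    A polynomial of order *polyorder* is fitted in a sliding window of
    *window* points; near the edges the filter falls back to a polynomial fit
    over the terminal window, so no points are dropped.

    Raises
    ------
    ParameterError
        If *window* is even, < 5, ≥ the number of points, or ≤ *polyorder*.
    """
    n = len(curve)
    if window % 2 == 0 or window < 5:
        raise ParameterError(f"smoothing window must be odd and >= 5, got {window}")
    if window >= n:
        raise ParameterError(f"smoothing window {window} >= number of points {n}")
    if polyorder >= window:
        raise ParameterError(f"polyorder {polyorder} must be < window {window}")
    smoothed = savgol_filter(curve.fluorescence, window, polyorder, mode="interp")
    ann = dict(curve.annotations)
    ann["smoothing"] = f"savgol(window={window}, polyorder={polyorder})"
    return replace(curve, fluorescence=smoothed, annotations=ann)


def derivative_curve(curve: MeltCurve) -> DerivativeCurve:
    """Numerical dF/dT: central differences inside, one-sided at the ends.

    Raises
    ------
    ParameterError
        If the curve has fewer than 3 points.
    """
    if len(curve) < 3:
        raise ParameterError("derivative requires at least 3 points")
    dfdt = np.gradient(curve.fluorescence, curve.temperatures)
    return DerivativeCurve(
        temperatures=curve.temperatures,
        dfdt=dfdt,
        smoothing=curve.annotations.get("smoothing", "none"),
    )


def _refine_quadratic(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid vertex of the parabola through points i-1, i, i+1.

    Falls back to the grid point at the ends or when the three points are
    collinear; the offset is clamped to half a grid step so refinement can
    never leave the argmax cell.
    """
    if i == 0 or i == len(y) - 1:
        return float(t[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(t[i])
    offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    step = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + offset * step)


def find_tm(deriv: DerivativeCurve) -> float:
    """Melting temperature: location of the global derivative maximum.

    The grid argmax is refined by quadratic interpolation through the three
    surrounding points, which recovers sub-grid Tm resolution on the coarse
    temperature grids typical of plate readers.  Ties are broken toward the
    lower temperature.

    Raises
    ------
    NoTransitionError
        If the derivative is flat (no transition).
    """
    y = deriv.dfdt
    if y.size == 0:
        raise NoTransitionError("empty derivative curve")
    if float(np.ptp(y)) == 0.0:
        raise NoTransitionError("flat derivative: no unfolding transition")
    i = int(np.argmax(y))  # first occurrence = lowest-temperature tie
    return _refine_quadratic(deriv.temperatures, y, i)


def detect_peaks(
    deriv: DerivativeCurve,
    min_prominence_frac: float = 0.1,
    min_separation_C: float = 2.0,
    presmooth_window: int | None = 25,
) -> PeakSet:
    """Locate unfolding transitions as local maxima of dF/dT.

    Parameters
    ----------
    deriv
        Derivative curve to analyze.
    min_prominence_frac
        Minimum peak prominence as a fraction of the global derivative
        maximum; peaks below it are ignored.  A value > 1 therefore yields an
        empty :class:`PeakSet`.
    min_separation_C
        Minimum separation between reported peaks in °C; of two closer peaks
        only the higher is kept.
    presmooth_window
        Width (points) of a quadratic Savitzky–Golay filter applied to the
        derivative before peak finding.  Unfolding transitions are several
        °C wide, so aggressive pre-smoothing suppresses noise ripple without
        moving genuine peaks; reported heights refer to the pre-smoothed
        derivative.  ``None`` disables.

    Each reported peak is assigned an *area fraction*: the share of the total
    positive-derivative area lying in its watershed cell, where cell
    boundaries sit at the derivative minimum between adjacent peaks.  Area
    beyond the point where the derivative first turns negative after the last
    peak (high-temperature dye-dissociation decay) is excluded.  For a
    two-population biphasic melt the high-temperature peak's area fraction
    estimates the shifted (ligand-bound) population fraction.
    """
    t = deriv.temperatures
    y = deriv.dfdt
    if y.size == 0:
        raise NoTransitionError("empty derivative curve")
    if presmooth_window is not None and y.size > presmooth_window >= 5:
        y = savgol_filter(y, presmooth_window, 2)
    ymax = float(np.max(y))
    if ymax <= 0.0 or float(np.ptp(y)) == 0.0:
        return PeakSet(peaks=())
    step = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    distance = max(1, int(math.ceil(min_separation_C / step)))
    # Both a prominence and an absolute-height floor: in a flat noisy
    # baseline a small bump can have ~2x-noise prominence (peak-to-dip)
    # while its height stays near zero, so height alone separates noise
    # bumps from genuine minor transitions.
    idx, props = _scipy_find_peaks(
        y,
        prominence=min_prominence_frac * ymax,
        height=min_prominence_frac * ymax,
        distance=distance,
    )
    if idx.size == 0:
        return PeakSet(peaks=())
    prominences = props["prominence"] if "prominence" in props else peak_prominences(y, idx)[0]

    # Watershed boundaries: minimum of the derivative between adjacent peaks.
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(int(a + np.argmin(y[a : b + 1])))
    # Truncate after the last peak where the derivative first goes negative
    # (dye-dissociation region contributes no transition area).
    last = idx[-1]
    after = np.nonzero(y[last:] < 0.0)[0]
    end = int(last + after[0]) if after.size else y.size - 1
    bounds.append(end)

    pos = np.clip(y, 0.0, None)
    total = float(np.trapezoid(pos[: end + 1], t[: end + 1]))
    peaks = []
    for k, i in enumerate(idx):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(pos[lo : hi + 1], t[lo : hi + 1])) if hi > lo else 0.0
        frac = area / total if total > 0 else 0.0
        peaks.append(
            Peak(
                tm_C=_refine_quadratic(t, y, int(i)),
                height=float(y[i]),
                prominence=float(prominences[k]),
                area_fraction=frac,
            )
        )
    peaks.sort(key=lambda p: p.tm_C)
    # Numerical guard: trapezoid cell areas can overshoot the clipped total
    # by float error only; renormalize if the sum exceeds 1.
    s = sum(p.area_fraction for p in peaks)
    if s > 1.0:
        peaks = [replace(p, area_fraction=p.area_fraction / s) for p in peaks]
    return PeakSet(peaks=tuple(peaks))
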