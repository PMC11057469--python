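"""Binding-affinity estimation from thermal-shift dose–response data.

The thermal shift ΔTm(c) = Tm(ligand at c) − Tm(vehicle) grows with ligand
occupancy of the protein.  Two models are fitted:

* single-site hyperbolic isotherm (the standard thermal-shift model)::

      ΔTm(c) = ΔTm_max · c / (Kd + c)

  Kd is the ligand concentration at half-maximal shift; ΔTm_max the
  saturating shift.  Fits are performed per replicate series and the
  reported Kd is the mean ± SEM over replicate estimates, with n the number
  of replicate Kd values — the convention used in thermal-shift affinity
  tables.

* Hill equation for cooperative, biphasic melts::

      φ(c) = c^h / (K_half^h + c^h)

  where φ is the fraction of protein in the shifted (ligand-bound)
  transition, estimated from the area fraction of the high-temperature
  derivative peak.  h > 1 indicates positive cooperativity.

Ligands producing no shift beyond a threshold (default 1.0 °C) are
classified nonbinding and reported with N/A affinity fields.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DSFError,
    FitError,
    NotBiphasicError,
    ParameterError,
    PlateValidationError,
)
from .meltcurve import derivative_curve, detect_peaks, find_tm, smooth_curve
from .plate_io import AnnotatedCurve

__all__ = [
    "DosePoint",
    "DoseResponseSeries",
    "BindingFit",
    "OccupancySeries",
    "extract_tm",
    "build_delta_tm_series",
    "fit_single_site",
    "classify_binder",
    "nonbinding_fit",
    "biphasic_occupancy",
    "fit_hill",
    "aggregate_replicates",
    "single_site_model",
    "hill_model",
    "DEFAULT_NONBINDER_THRESHOLD_C",
]

DEFAULT_NONBINDER_THRESHOLD_C = 1.0


def single_site_model(c, dtm_max, kd):
    """Hyperbolic single-site isotherm ΔTm(c) = ΔTm_max·c/(Kd + c)."""
    c = np.asarray(c, dtype=float)
    return dtm_max * c / (kd + c)


def hill_model(c, k_half, h):
    """Hill occupancy φ(c) = c^h / (K_half^h + c^h); φ(0) = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, c**h / (k_half**h + c**h), 0.0)
    return out


@dataclass(frozen=True)
class DosePoint:
    concentration_mM: float
    value: float
    replicate: int
    plate_id: str = ""


@dataclass(frozen=True)
class DoseResponseSeries:
    """Per protein–ligand dose–response points (ΔTm or occupancy)."""

    protein: str
    ligand: str
    points: tuple[DosePoint, ...]
    value_kind: str = "delta_tm"  # "delta_tm" | "occupancy"

    def __post_init__(self) -> None:
        if self.value_kind not in ("delta_tm", "occupancy"):
            raise ParameterError(f"unknown value kind {self.value_kind!r}")
        for p in self.points:
            if p.concentration_mM < 0:
                raise ParameterError("negative concentration in dose-response series")
            if self.value_kind == "occupancy" and not (-1e-9 <= p.value <= 1 + 1e-9):
                raise ParameterError(f"occupancy {p.value} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration_mM for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])

    def nonzero_concentration_count(self) -> int:
        return len({p.concentration_mM for p in self.points if p.concentration_mM > 0})

    def by_replicate(self) -> dict[int, list[DosePoint]]:
        groups: dict[int, list[DosePoint]] = defaultdict(list)
        for p in self.points:
            groups[p.replicate].append(p)
        return dict(groups)

    def mean_by_concentration(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique concentrations and the mean value at each."""
        conc = sorted({p.concentration_mM for p in self.points})
        means = [
            float(np.mean([p.value for p in self.points if p.concentration_mM == c]))
            for c in conc
        ]
        return np.array(conc), np.array(means)


@dataclass(frozen=True)
class BindingFit:
    """Fitted binding parameters for one protein–ligand combination."""

    protein: str
    ligand: str
    model: str  # "single_site" | "hill" | "nonbinding"
    kd_mM: float = float("nan")  # K_half for the hill model
    kd_se_mM: float = float("nan")
    dtm_max_C: float = float("nan")  # fitted plateau
    dtm_max_se_C: float = float("nan")
    observed_dtm_max_C: float = float("nan")  # max mean ΔTm actually observed
    hill_h: float = float("nan")
    hill_h_se: float = float("nan")
    r2: float = float("nan")
    n_replicates: int = 0
    residuals: tuple[float, ...] = ()
    destabilizing: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("single_site", "hill", "nonbinding"):
            raise ParameterError(f"unknown model {self.model!r}")
        if self.model != "nonbinding" and not self.kd_mM > 0:
            raise FitError(
                f"{self.protein}/{self.ligand}: non-positive Kd {self.kd_mM}"
            )
        if not np.isnan(self.r2) and self.r2 > 1 + 1e-12:
            raise FitError(f"r2 {self.r2} > 1")
        if not np.isnan(self.hill_h) and self.hill_h <= 0:
            raise FitError(f"non-positive Hill coefficient {self.hill_h}")


@dataclass(frozen=True)
class OccupancySeries:
    """Shifted-population fraction per well vs ligand concentration."""

    protein: str
    ligand: str
    points: tuple[DosePoint, ...]
    baseline_tm_C: float = float("nan")
    shifted_tm_C: float = float("nan")

    def __post_init__(self) -> None:
        for p in self.points:
            if not (-1e-9 <= p.value <= 1 + 1e-9):
                raise ParameterError(f"occupancy {p.value} outside [0, 1]")
            if p.concentration_mM == 0 and p.value != 0:
                raise ParameterError("occupancy at concentration 0 must be 0")

    def to_series(self) -> DoseResponseSeries:
        return DoseResponseSeries(
            protein=self.protein,
            ligand=self.ligand,
            points=self.points,
            value_kind="occupancy",
        )


def extract_tm(
    curve, smooth: bool = True, window: int = 7, polyorder: int = 3
) -> float:
    """Tm of one well: (optionally smoothed) derivative maximum."""
    mc = curve.curve if isinstance(curve, AnnotatedCurve) else curve
    if smooth:
        mc = smooth_curve(mc, window=window, polyorder=polyorder)
    return find_tm(derivative_curve(mc))


def build_delta_tm_series(
    curves: list[AnnotatedCurve],
    smooth: bool = True,
    window: int = 7,
    polyorder: int = 3,
) -> DoseResponseSeries:
    """Build the ΔTm dose–response series for one protein–ligand group.

    *curves* must contain the sample wells of a single (protein, ligand)
    group plus the vehicle wells of that protein (any plate).  The baseline
    for each sample well is the mean vehicle Tm of the same protein **on the
    same plate**, so plate-to-plate baseline drift cancels.

    Wells whose Tm extraction fails are excluded with a warning; a plate
    carrying sample wells but no vehicle wells is an error.
    """
    samples = [c for c in curves if c.role == "sample"]
    vehicles = [c for c in curves if c.role == "vehicle"]
    if not samples:
        raise PlateValidationError("no sample wells in group")
    proteins = {c.protein for c in samples}
    ligands = {c.ligand for c in samples}
    if len(proteins) > 1 or len(ligands) > 1:
        raise PlateValidationError(
            f"build_delta_tm_series expects one (protein, ligand) group, got "
            f"{sorted(proteins)} x {sorted(ligands)}"
        )
    protein = samples[0].protein
    ligand = samples[0].ligand

    def tm_or_none(c: AnnotatedCurve) -> float | None:
        try:
            return extract_tm(c, smooth=smooth, window=window, polyorder=polyorder)
        except DSFError as exc:
            warnings.warn(
                f"well {c.well} (plate {c.plate_id}): Tm extraction failed, "
                f"excluded ({exc})",
                stacklevel=3,
            )
            return None

    baseline: dict[str, float] = {}
    for plate_id in {c.plate_id for c in samples}:
        tms = [
            tm
            for c in vehicles
            if c.plate_id == plate_id and c.protein == protein
            if (tm := tm_or_none(c)) is not None
        ]
        if not tms:
            raise PlateValidationError(
                f"plate {plate_id!r}: no vehicle wells for protein {protein!r}"
            )
        baseline[plate_id] = float(np.mean(tms))

    points = []
    for c in samples:
        tm = tm_or_none(c)
        if tm is None:
            continue
        points.append(
            DosePoint(
                concentration_mM=c.concentration_mM,
                value=tm - baseline[c.plate_id],
                replicate=c.replicate,
                plate_id=c.plate_id,
            )
        )
    return DoseResponseSeries(
        protein=protein, ligand=ligand, points=tuple(points), value_kind="delta_tm"
    )


def _fit_isotherm(conc: np.ndarray, vals: np.ndarray) -> tuple[float, float]:
    """Least-squares (dtm_max, kd) for one series; raises FitError on failure."""
    vmax = float(np.max(np.abs(vals)))
    if vmax == 0:
        raise FitError("all-zero response cannot be fitted")
    p0 = (float(vals[np.argmax(conc)]), float(np.median(conc[conc > 0])))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                single_site_model,
                conc,
                vals,
                p0=p0,
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"single-site fit did not converge: {exc}")
    return float(popt[0]), float(popt[1])


def fit_single_site(series: DoseResponseSeries) -> BindingFit:
    """Fit the single-site isotherm to a ΔTm dose–response series.

    Each replicate series is fitted independently; reported Kd and ΔTm_max
    are the mean ± SEM across replicate estimates (n = number of replicate
    fits).  r² comes from a pooled fit over all points.  A negative fitted
    plateau is flagged as a destabilizing ligand rather than reported as an
    affinity.

    Raises
    ------
    ParameterError
        Wrong value kind or fewer than 4 distinct nonzero concentrations.
    FitError
        Non-convergence of the pooled or every replicate fit.
    """
    if series.value_kind != "delta_tm":
        raise ParameterError("fit_single_site expects a delta_tm series")
    if series.nonzero_concentration_count() < 4:
        raise ParameterError(
            "single-site fit needs >= 4 distinct nonzero concentrations "
            f"(got {series.nonzero_concentration_count()})"
        )
    conc_all = series.concentrations
    vals_all = series.values

    kds, plateaus = [], []
    for rep, pts in sorted(series.by_replicate().items()):
        conc = np.array([p.concentration_mM for p in pts])
        vals = np.array([p.value for p in pts])
        if len({c for c in conc if c > 0}) < 4:
            continue
        try:
            dtm_max, kd = _fit_isotherm(conc, vals)
        except FitError:
            warnings.warn(f"replicate {rep}: single-site fit failed, excluded")
            continue
        kds.append(kd)
        plateaus.append(dtm_max)
    if not kds:
        # No replicate had enough points on its own; fall back to pooled.
        dtm_max, kd = _fit_isotherm(conc_all, vals_all)
        kds, plateaus = [kd], [dtm_max]

    pooled_dtm, pooled_kd = _fit_isotherm(conc_all, vals_all)
    pred = single_site_model(conc_all, pooled_dtm, pooled_kd)
    resid = vals_all - pred
    ss_tot = float(np.sum((vals_all - vals_all.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    n = len(kds)
    kd_mean = float(np.mean(kds))
    kd_sem = float(np.std(kds, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    dtm_mean = float(np.mean(plateaus))
    dtm_sem = float(np.std(plateaus, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    destabilizing = dtm_mean < 0
    _, mean_by_c = series.mean_by_concentration()
    fit = BindingFit(
        protein=series.protein,
        ligand=series.ligand,
        model="single_site",
        kd_mM=kd_mean,
        kd_se_mM=kd_sem,
        dtm_max_C=dtm_mean,
        dtm_max_se_C=dtm_sem,
        observed_dtm_max_C=float(np.max(np.abs(mean_by_c))),
        r2=r2,
        n_replicates=n,
        residuals=tuple(float(r) for r in resid),
        destabilizing=destabilizing,
        notes="destabilizing ligand: negative fitted plateau" if destabilizing else "",
    )
    return fit


def classify_binder(
    series: DoseResponseSeries,
    min_shift_C: float = DEFAULT_NONBINDER_THRESHOLD_C,
) -> bool:
    """True if the ligand binds: max |mean ΔTm per concentration| ≥ threshold.

    Vehicle (zero-concentration) points are ignored; a threshold of 0
    classifies everything as binding.
    """
    nz = [p for p in series.points if p.concentration_mM > 0]
    if not nz:
        return False
    conc = sorted({p.concentration_mM for p in nz})
    max_shift = max(
        abs(float(np.mean([p.value for p in nz if p.concentration_mM == c])))
        for c in conc
    )
    return max_shift >= min_shift_C


def nonbinding_fit(series: DoseResponseSeries) -> BindingFit:
    """The N/A result row for a ligand classified as nonbinding."""
    reps = len(series.by_replicate())
    _, mean_by_c = series.mean_by_concentration()
    return BindingFit(
        protein=series.protein,
        ligand=series.ligand,
        model="nonbinding",
        observed_dtm_max_C=float(np.max(np.abs(mean_by_c))) if len(series) else float("nan"),
        n_replicates=reps,
        notes="no thermal shift above nonbinder threshold",
    )


def biphasic_occupancy(
    curves: list[AnnotatedCurve],
    smooth: bool = True,
    window: int = 7,
    polyorder: int = 3,
    min_prominence_frac: float = 0.1,
    min_separation_C: float = 3.0,
) -> OccupancySeries:
    """Estimate the shifted-population fraction per well of a biphasic group.

    The two transition temperatures are anchored from the data: the baseline
    center is the vehicle Tm, the saturating center the dominant peak of the
    highest-concentration wells.  Each well's positive-derivative area is
    then split by a watershed cut at the derivative minimum between the two
    anchors, and the occupancy is the share of area on the high-temperature
    side — the anchored form of the peak-area attribution, which stays
    well-defined even when the minor transition is too small to register as
    a separate peak.  Vehicle wells enter as occupancy 0 at concentration 0.

    Raises
    ------
    NotBiphasicError
        If no sample well resolves two transitions (use the single-site
        ΔTm path instead).
    """
    samples = [c for c in curves if c.role == "sample"]
    vehicles = [c for c in curves if c.role == "vehicle"]
    if not samples:
        raise PlateValidationError("no sample wells in group")
    if not vehicles:
        raise PlateValidationError("biphasic analysis requires vehicle wells")
    protein = samples[0].protein
    ligand = samples[0].ligand

    def mean_curve(group: list[AnnotatedCurve]):
        mc = group[0].curve
        f = np.mean([g.curve.fluorescence for g in group], axis=0)
        from dataclasses import replace as _replace

        mc = _replace(mc, fluorescence=f)
        if smooth:
            mc = smooth_curve(mc, window=window, polyorder=polyorder)
        return mc

    def peaks_of_mean(group: list[AnnotatedCurve]):
        return detect_peaks(
            derivative_curve(mean_curve(group)),
            min_prominence_frac=min_prominence_frac,
            min_separation_C=min_separation_C,
        )

    baseline_tm = float(np.mean([extract_tm(c, smooth, window, polyorder) for c in vehicles]))

    # Detection on per-concentration replicate means (per plate): averaging
    # suppresses point noise so a spurious noise bump is not mistaken for a
    # second transition.
    by_conc: dict[tuple[str, float], list[AnnotatedCurve]] = defaultdict(list)
    for c in samples:
        by_conc[(c.plate_id, c.concentration_mM)].append(c)
    conc_peaks = {key: peaks_of_mean(grp) for key, grp in by_conc.items()}
    if not any(len(ps) >= 2 for ps in conc_peaks.values()):
        raise NotBiphasicError(
            f"{protein}/{ligand}: no concentration resolves two transitions; "
            "use the single-site ΔTm analysis"
        )

    top_conc = max(c.concentration_mM for c in samples)
    top_tms = []
    for (plate_id, conc), ps in conc_peaks.items():
        if conc == top_conc and len(ps):
            # dominant (largest-area) peak of the saturating wells
            top_tms.append(max(ps, key=lambda p: p.area_fraction).tm_C)
    if not top_tms:
        raise NotBiphasicError(f"{protein}/{ligand}: saturating wells show no peaks")
    shifted_tm = float(np.mean(top_tms))
    if abs(shifted_tm - baseline_tm) < min_separation_C:
        raise NotBiphasicError(
            f"{protein}/{ligand}: saturating transition ({shifted_tm:.2f} °C) is "
            f"not resolved from baseline ({baseline_tm:.2f} °C)"
        )

    def shifted_area_fraction(c: AnnotatedCurve) -> float:
        mc = c.curve
        if smooth:
            mc = smooth_curve(mc, window=window, polyorder=polyorder)
        deriv = derivative_curve(mc)
        t, y = deriv.temperatures, deriv.dfdt
        # watershed cut: derivative minimum between the two anchors
        window_mask = (t >= baseline_tm) & (t <= shifted_tm)
        if not window_mask.any():
            raise NotBiphasicError("anchors outside the temperature grid")
        idx = np.nonzero(window_mask)[0]
        cut = idx[int(np.argmin(y[idx]))]
        # truncate where the derivative first turns negative past the
        # shifted transition (dye-decay region carries no transition area)
        past = np.nonzero((t > shifted_tm) & (y < 0))[0]
        end = int(past[0]) if past.size else y.size
        pos = np.clip(y[:end], 0.0, None)
        total = float(np.trapezoid(pos, t[:end]))
        if total <= 0:
            return 0.0
        high = float(np.trapezoid(pos[cut:], t[cut:end]))
        return min(max(high / total, 0.0), 1.0)

    points = []
    for c in samples:
        points.append(
            DosePoint(
                concentration_mM=c.concentration_mM,
                value=shifted_area_fraction(c),
                replicate=c.replicate,
                plate_id=c.plate_id,
            )
        )
    for c in vehicles:
        points.append(
            DosePoint(
                concentration_mM=0.0,
                value=0.0,
                replicate=c.replicate,
                plate_id=c.plate_id,
            )
        )
    return OccupancySeries(
        protein=protein,
        ligand=ligand,
        points=tuple(points),
        baseline_tm_C=baseline_tm,
        shifted_tm_C=shifted_tm,
    )


def fit_hill(series: OccupancySeries | DoseResponseSeries) -> BindingFit:
    """Fit the Hill equation to an occupancy series.

    Reports K_half in the Kd field, the Hill coefficient h, and standard
    errors from the fit covariance.  The series must actually traverse the
    transition (span below 0.2 and above 0.8 occupancy).

    Raises
    ------
    ParameterError
        Insufficient dynamic range.
    FitError
        Non-convergence or inadmissible (h ≤ 0) estimates.
    """
    if isinstance(series, OccupancySeries):
        protein, ligand = series.protein, series.ligand
        points = series.points
    else:
        if series.value_kind != "occupancy":
            raise ParameterError("fit_hill expects an occupancy series")
        protein, ligand = series.protein, series.ligand
        points = series.points
    conc = np.array([p.concentration_mM for p in points])
    occ = np.array([p.value for p in points])
    if occ.min() >= 0.2 or occ.max() <= 0.8:
        raise ParameterError(
            "occupancy series must span below 0.2 and above 0.8 "
            f"(got [{occ.min():.3f}, {occ.max():.3f}])"
        )
    nz = conc > 0
    mid_guess = float(np.interp(0.5, np.sort(occ[nz]), np.sort(conc[nz])))
    p0 = (max(mid_guess, 1e-6), 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                hill_model,
                conc,
                occ,
                p0=p0,
                bounds=([1e-12, 1e-6], [np.inf, 50.0]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Hill fit did not converge: {exc}")
    k_half, h = float(popt[0]), float(popt[1])
    if h <= 0:
        raise FitError(f"inadmissible Hill coefficient {h}")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    pred = hill_model(conc, k_half, h)
    resid = occ - pred
    ss_tot = float(np.sum((occ - occ.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    reps = len({p.replicate for p in points})
    return BindingFit(
        protein=protein,
        ligand=ligand,
        model="hill",
        kd_mM=k_half,
        kd_se_mM=float(perr[0]),
        hill_h=h,
        hill_h_se=float(perr[1]),
        r2=r2,
        n_replicates=reps,
        residuals=tuple(float(r) for r in resid),
    )


def aggregate_replicates(fits: list[BindingFit]) -> BindingFit:
    """Combine ≥ 2 replicate fits of one protein–ligand: mean ± SEM, n.

    Raises
    ------
    ParameterError
        Fewer than 2 fits, or mixed models/groups in the input.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ParameterError("aggregate_replicates needs >= 2 replicate fits")
    models = {f.model for f in fits}
    if len(models) > 1:
        raise ParameterError(f"mixed models in replicate fits: {sorted(models)}")
    groups = {(f.protein, f.ligand) for f in fits}
    if len(groups) > 1:
        raise ParameterError(f"mixed protein-ligand groups: {sorted(groups)}")
    n = len(fits)
    if fits[0].model == "nonbinding":
        return replace(fits[0], n_replicates=n, notes=f"aggregated from {n} replicate fits")
    kds = np.array([f.kd_mM for f in fits])
    dtms = np.array([f.dtm_max_C for f in fits])

    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    return replace(
        fits[0],
        kd_mM=float(np.mean(kds)),
        kd_se_mM=sem(kds),
        dtm_max_C=float(np.mean(dtms)),
        dtm_max_se_C=sem(dtms) if np.all(np.isfinite(dtms)) else float("nan"),
        n_replicates=n,
        residuals=(),
        notes=f"aggregated from {n} replicate fits",
    )
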