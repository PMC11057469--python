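"""Parameter-recovery experiments under the study's design conditions.

These functions regenerate synthetic data with the plate design the assay
used (half-log dilution series spanning 0.1–10 × Kd, 6 replicates,
replicate ΔTm scatter ≈ 0.3 °C) and measure how well the estimators recover
the generating parameters.  They are the package's own validation surface:
the acceptance script and the test suite both call them.

All experiments are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding import (
    biphasic_occupancy,
    build_delta_tm_series,
    classify_binder,
    extract_tm,
    fit_hill,
    fit_single_site,
    hill_model,
    DosePoint,
    DoseResponseSeries,
    OccupancySeries,
)
from .plate_io import join_plate
from .synthetic import (
    ALBUMIN_PRESETS,
    DEFAULT_NOISE_SD_RFU,
    SimBindingParams,
    SimProteinParams,
    simulate_melt_curve,
    simulate_nonbinder_plate,
    simulate_plate,
)

__all__ = [
    "SingleSiteRecovery",
    "single_site_recovery_experiment",
    "tm_recovery_experiment",
    "HillRecovery",
    "hill_recovery_experiment",
    "cooperative_h_experiment",
    "nonbinder_experiment",
]


def _grouped(plate, pmap):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves = join_plate(plate, pmap)
    return [c for c in curves if c.role in ("sample", "vehicle")]


def half_log_concentrations(kd_mM: float, n: int = 8) -> list[float]:
    """Half-log dilution series spanning 0.1–10 × Kd, plus the vehicle 0."""
    return [0.0] + list(kd_mM * np.logspace(-1.0, 1.0, n))


@dataclass(frozen=True)
class SingleSiteRecovery:
    median_rel_err_kd: float
    mean_bias_kd: float
    median_rel_err_dtm: float
    n_plates: int


def single_site_recovery_experiment(
    n_plates: int = 100,
    seed: int = 0,
    kd_true_mM: float = 0.79,
    dtm_max_true_C: float = 13.0,
    n_replicates: int = 6,
    noise_sd: float = DEFAULT_NOISE_SD_RFU,
    protein: SimProteinParams | None = None,
) -> SingleSiteRecovery:
    """Simulate plates and measure single-site Kd / ΔTm_max recovery.

    Defaults reproduce the study design: 8 half-log concentrations spanning
    0.1–10 × Kd, 6 replicates per concentration, point noise giving ~0.3 °C
    replicate Tm scatter.
    """
    protein = protein or ALBUMIN_PRESETS["HSA"]
    conc = half_log_concentrations(kd_true_mM)
    binding = SimBindingParams(
        ligand="L", kd_true_mM=kd_true_mM, dtm_max_true_C=dtm_max_true_C
    )
    rel_err_kd, signed_err_kd, rel_err_dtm = [], [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_plates):
        plate_seed = int(rng.integers(0, 2**31 - 1))
        plate, pmap, _ = simulate_plate(
            protein, binding, conc, n_replicates=n_replicates,
            noise_sd=noise_sd, seed=plate_seed,
        )
        series = build_delta_tm_series(_grouped(plate, pmap))
        fit = fit_single_site(series)
        rel_err_kd.append(abs(fit.kd_mM - kd_true_mM) / kd_true_mM)
        signed_err_kd.append((fit.kd_mM - kd_true_mM) / kd_true_mM)
        rel_err_dtm.append(abs(fit.dtm_max_C - dtm_max_true_C) / dtm_max_true_C)
    return SingleSiteRecovery(
        median_rel_err_kd=float(np.median(rel_err_kd)),
        mean_bias_kd=float(np.mean(signed_err_kd)),
        median_rel_err_dtm=float(np.median(rel_err_dtm)),
        n_plates=n_plates,
    )


def tm_recovery_experiment(n_draws: int = 50, seed: int = 0) -> tuple[float, int]:
    """Max |Tm_hat − Tm_true| over noiseless two-state curves, random params.

    Draws Tm in 58–82 °C and transition steepness ΔH in 120–250 kcal/mol on
    the default 0.3 °C grid; returns (max absolute error in °C, n_draws).
    """
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_draws):
        tm = float(rng.uniform(58.0, 82.0))
        dh = float(rng.uniform(120.0, 250.0))
        protein = SimProteinParams(name="sim", tm0_C=tm, vanthoff_dh_kcal=dh)
        curve = simulate_melt_curve(protein, tm, noise_sd=0.0)
        errs.append(abs(extract_tm(curve) - tm))
    return float(np.max(errs)), n_draws


@dataclass(frozen=True)
class HillRecovery:
    frac_within_half: float
    n_runs: int


def hill_recovery_experiment(
    n_runs: int = 100,
    seed: int = 0,
    occupancy_noise_sd: float = 0.05,
    h_range: tuple[float, float] = (1.5, 4.5),
    k_half_mM: float = 0.6,
) -> HillRecovery:
    """Hill-coefficient recovery from noisy occupancy series.

    Each run draws a true h, generates a 10-point half-log occupancy series
    (3 replicates) from the Hill equation with Gaussian occupancy noise
    clipped to [0, 1], fits, and scores whether the recovered h lies within
    ±0.5 of truth.
    """
    rng = np.random.default_rng(seed)
    conc = k_half_mM * np.logspace(-1.0, 1.0, 10)
    hits = 0
    for _ in range(n_runs):
        h_true = float(rng.uniform(*h_range))
        points = [DosePoint(0.0, 0.0, rep) for rep in (1, 2, 3)]
        for rep in (1, 2, 3):
            occ = hill_model(conc, k_half_mM, h_true)
            occ = np.clip(occ + rng.normal(0.0, occupancy_noise_sd, occ.size), 0.0, 1.0)
            points += [DosePoint(float(c), float(o), rep) for c, o in zip(conc, occ)]
        series = OccupancySeries(protein="sim", ligand="L", points=tuple(points))
        try:
            fit = fit_hill(series)
        except Exception:
            continue
        if abs(fit.hill_h - h_true) <= 0.5:
            hits += 1
    return HillRecovery(frac_within_half=hits / n_runs, n_runs=n_runs)


def cooperative_h_experiment(
    n_runs: int = 100,
    seed: int = 0,
    h_true: float = 3.5,
    k_half_mM: float = 0.6,
    noise_sd: float = DEFAULT_NOISE_SD_RFU,
) -> tuple[float, int]:
    """End-to-end biphasic pipeline: fraction of runs recovering h > 1.

    Simulates full biphasic plates at the reported cooperative slope,
    extracts occupancy via the anchored watershed, fits the Hill equation
    and counts runs with fitted h > 1 (the qualitative cooperativity call).
    Returns (fraction with h > 1, n_runs).
    """
    protein = ALBUMIN_PRESETS["BSA"]
    binding = SimBindingParams(
        ligand="L", mode="biphasic", hill_h=h_true, k_half_mM=k_half_mM
    )
    conc = [0.0] + list(k_half_mM * np.logspace(-0.8, 0.8, 9))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        plate_seed = int(rng.integers(0, 2**31 - 1))
        plate, pmap, _ = simulate_plate(
            protein, binding, conc, n_replicates=3, noise_sd=noise_sd,
            seed=plate_seed,
        )
        occ = biphasic_occupancy(_grouped(plate, pmap))
        fit = fit_hill(occ)
        if fit.hill_h > 1.0:
            hits += 1
    return hits / n_runs, n_runs


def nonbinder_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD_RFU,
) -> tuple[float, int]:
    """Fraction of nonbinder plates correctly classified nonbinding.

    Each run simulates a plate with zero true thermal shift, builds the ΔTm
    series and applies the 1.0 °C nonbinder threshold; a correct run yields
    a nonbinding (N/A) classification.  Returns (fraction correct, n_seeds).
    """
    protein = ALBUMIN_PRESETS["HSA"]
    conc = [0.0, 0.1, 0.3, 1.0, 3.0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        plate_seed = int(rng.integers(0, 2**31 - 1))
        plate, pmap, _ = simulate_nonbinder_plate(
            protein, conc, seed=plate_seed, noise_sd=noise_sd
        )
        series = build_delta_tm_series(_grouped(plate, pmap))
        if not classify_binder(series):
            hits += 1
    return hits / n_seeds, n_seeds
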