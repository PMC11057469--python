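"""Ground-truthed synthetic DSF plates.

The generator emulates the raw output of a 96-well thermal-shift experiment
so the whole analysis chain can be exercised against known truth:

* each well's fluorescence follows a two-state van 't Hoff unfolding model:
  the unfolded fraction is ``f_u(T) = 1 / (1 + exp[(ΔH/R)(1/T − 1/Tm)])``
  (temperatures in Kelvin inside the formula only), mixed between linear
  folded and unfolded baselines, with optional post-transition exponential
  decay emulating dye dissociation, plus additive Gaussian point noise;
* ligand binding is modeled phenomenologically as a Tm shift following the
  single-site isotherm ``Tm(c) = Tm0 + ΔTm_max·c/(Kd + c)`` — i.e. the data
  are generated from the same response model the estimators fit, which is
  the right construction for testing estimator correctness;
* biphasic (cooperative) binding mixes an unshifted and a shifted melt with
  bound fraction ``φ(c) = c^h/(K_half^h + c^h)`` (Hill);
* plates carry vehicle (concentration 0) and no-protein control wells, and
  every simulated plate is accompanied by a ground-truth manifest.

Replicate-to-replicate Tm scatter is *not* injected directly: it emerges
from point noise propagating through Tm extraction, as in a real instrument.
Protein presets for the four study albumins use their published ligand-free
melting temperatures so simulated output is directly comparable to real
traces.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .meltcurve import MeltCurve
from .plate_io import PlateData, PlateMap, PlateMapRow

__all__ = [
    "GAS_CONSTANT_KCAL",
    "SimProteinParams",
    "SimBindingParams",
    "SimTruth",
    "ALBUMIN_PRESETS",
    "DEFAULT_GRID",
    "DEFAULT_NOISE_SD_RFU",
    "two_state_fraction",
    "simulate_melt_curve",
    "simulate_plate",
    "simulate_nonbinder_plate",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)

#: Temperature grid matching the published assay range (°C): start, stop, step.
DEFAULT_GRID = (50.0, 90.0, 0.3)

#: Point noise (RFU) calibrated so that per-well Tm scatter through the
#: default extraction pipeline is ~0.3 °C — the replicate ΔTm noise level
#: the recovery analyses assume.
DEFAULT_NOISE_SD_RFU = 12.0


@dataclass(frozen=True)
class SimProteinParams:
    """Two-state melt-shape parameters for one protein.

    ``vanthoff_dh_kcal`` sets the transition steepness (larger = sharper
    derivative peak); baselines are linear in temperature; ``decay_per_C``
    adds post-transition signal decay (0 = none).
    """

    name: str
    tm0_C: float
    vanthoff_dh_kcal: float = 180.0
    folded_intercept: float = 200.0
    folded_slope: float = 0.2
    unfolded_intercept: float = 2000.0
    unfolded_slope: float = -1.0
    decay_per_C: float = 0.0

    def __post_init__(self) -> None:
        if self.vanthoff_dh_kcal <= 0:
            raise ParameterError("van 't Hoff ΔH must be positive")
        if self._unfolded(self.tm0_C) <= self._folded(self.tm0_C):
            raise ParameterError(
                "unfolded baseline must exceed folded baseline at Tm0"
            )

    def _folded(self, t):
        return self.folded_intercept + self.folded_slope * np.asarray(t, float)

    def _unfolded(self, t):
        return self.unfolded_intercept + self.unfolded_slope * np.asarray(t, float)


#: Presets for the four study albumins at their ligand-free melting
#: temperatures (HSA 71.3, BSA 62.6, PSA 71.3, RSA 66.8 °C).
ALBUMIN_PRESETS: dict[str, SimProteinParams] = {
    "HSA": SimProteinParams(name="HSA", tm0_C=71.3),
    "BSA": SimProteinParams(name="BSA", tm0_C=62.6),
    "PSA": SimProteinParams(name="PSA", tm0_C=71.3),
    "RSA": SimProteinParams(name="RSA", tm0_C=66.8),
}


@dataclass(frozen=True)
class SimBindingParams:
    """Ground-truth binding behavior of the simulated ligand."""

    ligand: str
    mode: str = "single_site"  # "single_site" | "biphasic"
    kd_true_mM: float = 1.0
    dtm_max_true_C: float = 10.0
    hill_h: float = 3.5
    k_half_mM: float = 0.6
    shifted_tm_offset_C: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("single_site", "biphasic"):
            raise ParameterError(f"unknown binding mode {self.mode!r}")
        if self.kd_true_mM <= 0:
            raise ParameterError("Kd_true must be positive")
        if self.mode == "biphasic" and self.hill_h <= 0:
            raise ParameterError("biphasic mode requires hill_h > 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth manifest emitted with every simulated plate."""

    plate_id: str
    seed: int
    protein: dict
    binding: dict
    grid: tuple[float, float, float]
    noise_sd_rfu: float
    wells: tuple[dict, ...]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["wells"] = list(payload["wells"])
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["grid"] = tuple(payload["grid"])
        payload["wells"] = tuple(payload["wells"])
        return cls(**payload)


def _kelvin(t_C):
    return np.asarray(t_C, float) + 273.15


def two_state_fraction(t_C, tm_C: float, dh_kcal: float):
    """Unfolded fraction f_u(T) of the two-state van 't Hoff model.

    Exactly 0.5 at T = Tm; approaches 0 well below and 1 well above.
    """
    a = dh_kcal / GAS_CONSTANT_KCAL
    arg = a * (1.0 / _kelvin(t_C) - 1.0 / _kelvin(tm_C))
    # clip to avoid overflow in exp; saturates f_u at 0/1 far from Tm
    return 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))


def transition_width_C(protein: SimProteinParams, tm_C: float) -> float:
    """Characteristic width R·Tm²/ΔH of the unfolding transition (°C)."""
    tk = float(_kelvin(tm_C))
    return GAS_CONSTANT_KCAL * tk * tk / protein.vanthoff_dh_kcal


def _grid_array(grid: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = grid
    if step <= 0 or stop <= start:
        raise ParameterError(f"bad temperature grid {grid}")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _noiseless_trace(protein: SimProteinParams, tm_C: float, t: np.ndarray) -> np.ndarray:
    fu = two_state_fraction(t, tm_C, protein.vanthoff_dh_kcal)
    decay = np.exp(-protein.decay_per_C * np.clip(t - tm_C, 0.0, None))
    return (1.0 - fu) * protein._folded(t) + fu * protein._unfolded(t) * decay


def simulate_melt_curve(
    protein: SimProteinParams,
    tm_C: float,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> MeltCurve:
    """Simulate one well's melt curve with the transition centered at *tm_C*.

    Deterministic given (parameters, seed).

    Raises
    ------
    ParameterError
        If the grid does not span Tm ± 3 transition widths.
    """
    t = _grid_array(grid)
    w = transition_width_C(protein, tm_C)
    if tm_C - 3 * w < t[0] or tm_C + 3 * w > t[-1]:
        raise ParameterError(
            f"grid {grid} too narrow for Tm {tm_C} (needs ±{3 * w:.2f} °C)"
        )
    f = _noiseless_trace(protein, tm_C, t)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    return MeltCurve(
        temperatures=t,
        fluorescence=f,
        annotations={"simulated": True, "true_tm_C": tm_C, "protein": protein.name},
    )


def _well_ids(n: int) -> list[str]:
    ids = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
    if n > len(ids):
        raise ParameterError(f"layout needs {n} wells; a 96-well plate has 96")
    return ids[:n]


def simulate_plate(
    protein: SimProteinParams,
    binding: SimBindingParams,
    concentrations_mM,
    n_replicates: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD_RFU,
    seed: int = 0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    plate_id: str | None = None,
) -> tuple[PlateData, PlateMap, SimTruth]:
    """Simulate a full plate for one protein–ligand combination.

    Layout: for every concentration in *concentrations_mM* (which must
    include 0, the vehicle) there are *n_replicates* wells; the zero
    concentration becomes the vehicle wells.  Two no-protein control wells
    (dye background only) are appended.  The returned :class:`SimTruth`
    records the per-well true Tm (single-site) or true bound fraction and
    component transition temperatures (biphasic).

    Raises
    ------
    ParameterError
        If 0 is not among the concentrations, or the layout exceeds 96 wells.
    """
    conc = sorted(float(c) for c in concentrations_mM)
    if not any(c == 0.0 for c in conc):
        raise ParameterError("concentrations must include 0 (the vehicle wells)")
    if any(c < 0 for c in conc):
        raise ParameterError("negative concentration")
    rng = np.random.default_rng(seed)
    t = _grid_array(grid)
    n_wells = len(conc) * n_replicates + 2
    ids = _well_ids(n_wells)
    pid = plate_id or f"sim-{protein.name}-{binding.ligand}-{seed}"

    wells: dict[str, np.ndarray] = {}
    map_rows: list[PlateMapRow] = []
    truth_rows: list[dict] = []
    k = 0
    for c in conc:
        for rep in range(1, n_replicates + 1):
            wid = ids[k]
            k += 1
            if binding.mode == "single_site":
                tm = protein.tm0_C + binding.dtm_max_true_C * c / (
                    binding.kd_true_mM + c
                )
                f = _noiseless_trace(protein, tm, t)
                truth = {"well": wid, "concentration_mM": c, "replicate": rep,
                         "true_tm_C": tm, "true_occupancy": c / (binding.kd_true_mM + c)}
            else:
                phi = (
                    c**binding.hill_h
                    / (binding.k_half_mM**binding.hill_h + c**binding.hill_h)
                    if c > 0
                    else 0.0
                )
                tm_shifted = protein.tm0_C + binding.shifted_tm_offset_C
                f = (1.0 - phi) * _noiseless_trace(protein, protein.tm0_C, t) + (
                    phi
                ) * _noiseless_trace(protein, tm_shifted, t)
                truth = {"well": wid, "concentration_mM": c, "replicate": rep,
                         "true_occupancy": phi, "baseline_tm_C": protein.tm0_C,
                         "shifted_tm_C": tm_shifted}
            if noise_sd > 0:
                f = f + rng.normal(0.0, noise_sd, size=t.size)
            wells[wid] = f
            role = "vehicle" if c == 0.0 else "sample"
            map_rows.append(
                PlateMapRow(
                    well=wid,
                    protein=protein.name,
                    ligand="none" if c == 0.0 else binding.ligand,
                    concentration_mM=c,
                    role=role,
                    replicate=rep,
                )
            )
            truth_rows.append(truth)
    # no-protein controls: flat dye background
    for rep in range(1, 3):
        wid = ids[k]
        k += 1
        f = np.full(t.size, 100.0)
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=t.size)
        wells[wid] = f
        map_rows.append(
            PlateMapRow(
                well=wid,
                protein="none",
                ligand="none",
                concentration_mM=0.0,
                role="no_protein",
                replicate=rep,
            )
        )
        truth_rows.append({"well": wid, "concentration_mM": 0.0, "replicate": rep,
                           "true_occupancy": 0.0, "no_protein": True})

    plate = PlateData(plate_id=pid, temperatures=t, wells=wells)
    pmap = PlateMap(rows=tuple(map_rows))
    truth = SimTruth(
        plate_id=pid,
        seed=int(seed),
        protein=asdict(protein),
        binding=asdict(binding),
        grid=tuple(grid),
        noise_sd_rfu=float(noise_sd),
        wells=tuple(truth_rows),
    )
    return plate, pmap, truth


def simulate_nonbinder_plate(
    protein: SimProteinParams,
    concentrations_mM,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD_RFU,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    ligand: str = "nonbinder",
) -> tuple[PlateData, PlateMap, SimTruth]:
    """Plate for a ligand with no thermal-shift effect (all wells at Tm0)."""
    binding = SimBindingParams(
        ligand=ligand, mode="single_site", kd_true_mM=1.0, dtm_max_true_C=0.0
    )
    plate, pmap, truth = simulate_plate(
        protein,
        binding,
        concentrations_mM,
        noise_sd=noise_sd,
        seed=seed,
        grid=grid,
    )
    wells = tuple(
        {**w, "true_occupancy": 0.0} for w in truth.wells
    )
    return plate, pmap, SimTruth(**{**asdict(truth), "wells": wells})
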