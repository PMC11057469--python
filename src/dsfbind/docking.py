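"""Docking free-energy aggregation and correlation with measured affinity.

Docking runs score many candidate poses (modes) in several binding sites of
a protein structure.  The aggregation protocol here is:

1. per (structure, ligand, site): arithmetic mean ΔG over the top modes
   (up to 9);
2. per (structure, ligand): geometric mean over the site means.

A geometric mean of uniformly *negative* energies is undefined in the reals,
so step 2 is computed on the magnitudes and the favorable sign restored:
``-(∏|ΔG_i|)^(1/k)``.  This is the only reading under which a geometric mean
across uniformly favorable sites is computable, and it reduces to the common
value when all sites agree.  Mixed-sign site means are rejected.

The aggregated per-ligand ΔG is then correlated (Pearson) with the
experimentally measured dissociation constants, pairing by ligand, with an
optional exclusion list; the two-sided p-value comes from the t transform
with n − 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, PlateFormatError, PlateValidationError

__all__ = [
    "CorrelationResult",
    "read_docking_csv",
    "site_mean_dg",
    "ligand_dg",
    "aggregate_structures",
    "correlate_kd_dg",
]

_DOCKING_COLUMNS = ["structure", "ligand", "site", "mode", "dg_kcal_mol"]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between Kd and aggregated ΔG."""

    r: float
    p: float
    n: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ParameterError(f"|r| > 1: {self.r}")
        if self.n < 3:
            raise ParameterError("correlation requires n >= 3 pairs")


def read_docking_csv(path: str | Path) -> pd.DataFrame:
    """Read a docking ΔG table.

    Expected columns: ``structure, ligand, site, mode, dg_kcal_mol``.
    Mode ranks must be unique within (structure, ligand, site) and ΔG finite.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DOCKING_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: docking table lacks columns {missing}")
    if not np.isfinite(df["dg_kcal_mol"]).all():
        raise PlateValidationError(f"{path}: non-finite ΔG values")
    if df.duplicated(subset=["structure", "ligand", "site", "mode"]).any():
        raise PlateValidationError(
            f"{path}: duplicate mode ranks within a (structure, ligand, site)"
        )
    return df


def site_mean_dg(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean ΔG per (structure, ligand, site) over available modes.

    Groups with no modes cannot occur in a tidy table; empty input is
    reported with a warning and yields an empty frame.
    """
    if table.empty:
        warnings.warn("site_mean_dg: empty docking table")
        return pd.DataFrame(columns=["structure", "ligand", "site", "dg_kcal_mol"])
    return (
        table.groupby(["structure", "ligand", "site"], as_index=False)["dg_kcal_mol"]
        .mean()
    )


def ligand_dg(site_means: Sequence[float] | Iterable[float]) -> float:
    """Geometric mean of per-site ΔG magnitudes, favorable sign restored.

    Raises
    ------
    ParameterError
        Empty input or any non-negative site mean (geometric mean of
        mixed-sign energies is undefined).
    """
    vals = np.asarray(list(site_means), dtype=float)
    if vals.size == 0:
        raise ParameterError("ligand_dg: no site means")
    if np.any(vals >= 0):
        raise ParameterError(
            f"ligand_dg requires uniformly negative (favorable) site means, got {vals}"
        )
    return -float(np.exp(np.mean(np.log(-vals))))


def aggregate_structures(table: pd.DataFrame) -> pd.DataFrame:
    """Full aggregation: site means, then per-(structure, ligand) geometric mean."""
    sm = site_mean_dg(table)
    rows = [
        {"structure": s, "ligand": l, "dg_kcal_mol": ligand_dg(g["dg_kcal_mol"])}
        for (s, l), g in sm.groupby(["structure", "ligand"])
    ]
    return pd.DataFrame(rows, columns=["structure", "ligand", "dg_kcal_mol"])


def correlate_kd_dg(
    kd_by_ligand: Mapping[str, float],
    dg_by_ligand: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> CorrelationResult:
    """Pearson correlation between Kd and aggregated ΔG, paired by ligand.

    Ligands in *exclude* are removed before pairing; only ligands present in
    both mappings are used.

    Raises
    ------
    ParameterError
        Fewer than 3 pairs after exclusion, or zero variance in either
        variable.
    """
    excl = set(exclude)
    labels = sorted((set(kd_by_ligand) & set(dg_by_ligand)) - excl)
    if len(labels) < 3:
        raise ParameterError(
            f"correlation requires >= 3 paired ligands, got {len(labels)}"
        )
    kd = np.array([float(kd_by_ligand[l]) for l in labels])
    dg = np.array([float(dg_by_ligand[l]) for l in labels])
    if np.ptp(kd) == 0 or np.ptp(dg) == 0:
        raise ParameterError("correlation undefined: zero variance input")
    res = stats.pearsonr(kd, dg)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(labels), labels=tuple(labels)
    )
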