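"""Cross-species and cross-congener affinity contrasts.

All contrasts operate on a tidy Kd table (one row per protein–ligand pair)
and use the symmetric percent difference

    100 · |a − b| / ((a + b) / 2)  =  200 · |a − b| / (a + b)

as the canonical contrast statistic.  "Higher affinity" always means *lower*
Kd; the direction of each contrast is reported explicitly to keep that
inversion out of the caller's hands.

Effect sizes are classical Cohen's d computed from replicate-level spread
(SD recovered from SEM as SD = SEM·√n) with the pooled-SD denominator, and
classified small/medium/large at the conventional 0.2/0.5/0.8 cut points
(boundaries inclusive upward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, PlateValidationError

__all__ = [
    "KdTable",
    "ComparisonResult",
    "percent_difference",
    "species_contrasts",
    "chain_length_contrast",
    "cohens_d",
    "classify_effect_size",
    "rank_order",
    "read_kd_table",
    "DEFAULT_CHAIN_PAIRS",
]

#: 4-carbon vs 8-carbon congener pairs contrasted within each species.
DEFAULT_CHAIN_PAIRS = (("PFBA", "PFOA"), ("PFBS", "PFOS"))

_KD_COLUMNS = ["protein", "ligand", "chain_length", "kd_mM", "kd_sem_mM"]


@dataclass(frozen=True)
class KdTable:
    """Tidy affinity table: one row per (protein, ligand).

    Nonbinding pairs are kept as rows with NaN Kd so that rank matrices and
    contrast listings can report their exclusion explicitly.  The optional
    ``n`` column is the number of replicate Kd estimates behind each row.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _KD_COLUMNS if c not in df.columns]
        if missing:
            raise PlateValidationError(f"Kd table lacks columns {missing}")
        if df.duplicated(subset=["protein", "ligand"]).any():
            dupes = df[df.duplicated(subset=["protein", "ligand"], keep=False)]
            raise PlateValidationError(
                "duplicate (protein, ligand) rows: "
                + ", ".join(f"{p}/{l}" for p, l in zip(dupes.protein, dupes.ligand))
            )
        bound = df["kd_mM"].dropna()
        if (bound <= 0).any():
            raise PlateValidationError("Kd values must be positive")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.frame["protein"]))

    @property
    def ligands(self) -> list[str]:
        return list(dict.fromkeys(self.frame["ligand"]))

    def kd(self, protein: str, ligand: str) -> float:
        sel = self.frame[
            (self.frame["protein"] == protein) & (self.frame["ligand"] == ligand)
        ]
        if sel.empty:
            raise KeyError(f"no row for ({protein}, {ligand})")
        return float(sel["kd_mM"].iloc[0])


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise affinity contrast."""

    pair: tuple[str, str]
    ligand: str
    percent_difference: float
    direction: str  # "<label>-higher-affinity" or "tie"
    cohens_d: float | None = None
    effect_size_class: str | None = None
    note: str = ""


def percent_difference(kd_a: float, kd_b: float) -> float:
    """Symmetric percent difference 200·|a − b|/(a + b).

    Bounded in [0, 200) for positive inputs; the direction of the affinity
    ordering is reported separately (lower Kd = higher affinity).
    """
    if not (kd_a > 0 and kd_b > 0):
        raise ParameterError(
            f"percent_difference requires positive Kd values, got ({kd_a}, {kd_b})"
        )
    return 200.0 * abs(kd_a - kd_b) / (kd_a + kd_b)


def _direction(label_a: str, kd_a: float, label_b: str, kd_b: float) -> str:
    if kd_a == kd_b:
        return "tie"
    return f"{label_a if kd_a < kd_b else label_b}-higher-affinity"


def species_contrasts(table: KdTable, reference: str = "HSA") -> list[ComparisonResult]:
    """Contrast every species against *reference*, per ligand.

    Nonbinding rows (NaN Kd) are skipped.  Returns an empty list when the
    table holds a single species.

    Raises
    ------
    ParameterError
        If *reference* is absent from the table.
    """
    df = table.frame
    if reference not in set(df["protein"]):
        raise ParameterError(f"reference species {reference!r} not in Kd table")
    out: list[ComparisonResult] = []
    for ligand in table.ligands:
        sub = df[df["ligand"] == ligand].dropna(subset=["kd_mM"])
        ref_rows = sub[sub["protein"] == reference]
        if ref_rows.empty:
            continue
        kd_ref = float(ref_rows["kd_mM"].iloc[0])
        for _, row in sub[sub["protein"] != reference].iterrows():
            kd_other = float(row["kd_mM"])
            out.append(
                ComparisonResult(
                    pair=(reference, row["protein"]),
                    ligand=ligand,
                    percent_difference=percent_difference(kd_ref, kd_other),
                    direction=_direction(reference, kd_ref, row["protein"], kd_other),
                )
            )
    return out


def chain_length_contrast(
    table: KdTable,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_CHAIN_PAIRS,
) -> list[ComparisonResult]:
    """Within each species, contrast short- vs long-chain congener Kd.

    A species missing either congener of a pair (or with a nonbinding entry)
    is skipped with a note-carrying result omitted — i.e. the pair is simply
    absent from the output for that species.
    """
    df = table.frame
    out: list[ComparisonResult] = []
    for protein in table.proteins:
        sub = df[df["protein"] == protein]
        for short, long in pairs:
            kd = {}
            ok = True
            for lig in (short, long):
                rows = sub[sub["ligand"] == lig].dropna(subset=["kd_mM"])
                if rows.empty:
                    import warnings

                    warnings.warn(
                        f"{protein}: missing congener {lig}, pair ({short}, {long}) skipped"
                    )
                    ok = False
                    break
                kd[lig] = float(rows["kd_mM"].iloc[0])
            if not ok:
                continue
            note = "equal Kd" if kd[short] == kd[long] else ""
            out.append(
                ComparisonResult(
                    pair=(short, long),
                    ligand=protein,  # the grouping label here is the species
                    percent_difference=percent_difference(kd[short], kd[long]),
                    direction=_direction(short, kd[short], long, kd[long]),
                    note=note,
                )
            )
    return out


def classify_effect_size(d: float) -> str:
    """Conventional Cohen's d classes; boundaries inclusive upward."""
    if d >= 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    return "small"


def cohens_d(
    mean_a: float,
    sem_a: float,
    n_a: int,
    mean_b: float,
    sem_b: float,
    n_b: int,
) -> tuple[float, str]:
    """Cohen's d from group means and SEMs with the pooled-SD denominator.

    Group SDs are recovered as SD = SEM·√n; pooled SD uses the usual
    (n−1)-weighted formula.  Equal means give d = 0; a zero pooled SD with
    unequal means gives +inf (flagged by the returned class "large").
    """
    if n_a < 2 or n_b < 2:
        raise ParameterError("cohens_d requires n >= 2 in each group")
    if sem_a < 0 or sem_b < 0:
        raise ParameterError("SEMs must be non-negative")
    s_a = sem_a * math.sqrt(n_a)
    s_b = sem_b * math.sqrt(n_b)
    pooled = math.sqrt(
        ((n_a - 1) * s_a**2 + (n_b - 1) * s_b**2) / (n_a + n_b - 2)
    )
    diff = abs(mean_a - mean_b)
    if pooled == 0:
        d = 0.0 if diff == 0 else float("inf")
    else:
        d = diff / pooled
    return d, classify_effect_size(d)


def rank_order(table: KdTable) -> pd.DataFrame:
    """Affinity rank matrix: ligands × species, rank 1 = lowest Kd.

    Ties share the mean rank; ligands bound by fewer than 2 species (or by
    none — nonbinders) are excluded.
    """
    df = table.frame.dropna(subset=["kd_mM"])
    wide = df.pivot(index="ligand", columns="protein", values="kd_mM")
    wide = wide[wide.notna().sum(axis=1) >= 2]
    ranks = wide.rank(axis=1, method="average", ascending=True)
    # keep input ligand order
    order = [l for l in table.ligands if l in ranks.index]
    return ranks.loc[order]


def read_kd_table(path: str | Path) -> KdTable:
    """Read a Kd table CSV (``N/A`` marks nonbinding entries).

    Accepts either the reference-table shape (with a ``chain_length``
    column) or the results CSV written by the fitting pipeline (which has
    none — a NaN chain-length column is inserted so chain contrasts are
    simply unavailable).
    """
    df = pd.read_csv(path, na_values=["N/A", "NA", ""])
    if "chain_length" not in df.columns:
        df["chain_length"] = np.nan
    return KdTable(frame=df)
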