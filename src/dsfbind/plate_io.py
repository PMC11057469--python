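"""Plate-reader file I/O.

Reads the wide melt-export dialect common to qPCR instruments (one
``temperature_C`` column followed by one fluorescence column per well), the
plate-map CSV assigning wells to protein/ligand/concentration/role, and
writes the tidy per-fit results table.

All files are UTF-8 CSV with ``.`` as decimal separator.  Temperatures are
°C, concentrations mM, fluorescence RFU.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PlateFormatError, PlateValidationError
from .meltcurve import MeltCurve

__all__ = [
    "PlateData",
    "PlateMapRow",
    "PlateMap",
    "AnnotatedCurve",
    "ROLES",
    "read_plate_csv",
    "write_plate_csv",
    "read_plate_map",
    "write_plate_map",
    "join_plate",
    "write_results",
    "read_results",
]

ROLES = ("sample", "vehicle", "no_protein", "positive_control")

#: Column order of the results CSV written by :func:`write_results`.
RESULT_COLUMNS = [
    "protein",
    "ligand",
    "n",
    "kd_mM",
    "kd_sem_mM",
    "dtm_max_C",
    "dtm_max_sem_C",
    "model",
    "r2",
    "binder_flag",
]


@dataclass(frozen=True)
class PlateData:
    """One plate's melt export: a shared temperature grid plus well traces."""

    plate_id: str
    temperatures: np.ndarray
    wells: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2:
            raise PlateValidationError("plate needs at least 2 temperature points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise PlateValidationError(
                f"plate {self.plate_id!r}: temperatures must be strictly increasing"
            )
        step = float(np.median(dt))
        if not np.allclose(dt, step, rtol=1e-6, atol=1e-9 * max(1.0, step)):
            raise PlateValidationError(
                f"plate {self.plate_id!r}: temperature grid is not uniform"
            )
        object.__setattr__(self, "temperatures", t)
        wells = {}
        for well, series in self.wells.items():
            s = np.asarray(series, dtype=float)
            if s.shape != t.shape:
                raise PlateValidationError(
                    f"plate {self.plate_id!r} well {well!r}: series length "
                    f"{s.size} != grid length {t.size}"
                )
            wells[str(well)] = s
        object.__setattr__(self, "wells", wells)

    @property
    def step_C(self) -> float:
        return float(np.median(np.diff(self.temperatures)))

    def curve(self, well: str) -> MeltCurve:
        """The melt curve of one well."""
        return MeltCurve(
            temperatures=self.temperatures,
            fluorescence=self.wells[well],
            well_id=well,
            annotations={"plate_id": self.plate_id},
        )


@dataclass(frozen=True)
class PlateMapRow:
    well: str
    protein: str
    ligand: str
    concentration_mM: float
    role: str
    replicate: int


@dataclass(frozen=True)
class PlateMap:
    """Validated well annotations for one plate."""

    rows: tuple[PlateMapRow, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.well in seen:
                raise PlateValidationError(f"duplicate well {row.well!r} in plate map")
            seen.add(row.well)
            if row.role not in ROLES:
                raise PlateValidationError(
                    f"well {row.well!r}: unknown role {row.role!r} "
                    f"(expected one of {ROLES})"
                )
            if row.concentration_mM < 0:
                raise PlateValidationError(
                    f"well {row.well!r}: negative concentration"
                )
            if row.role == "vehicle" and row.concentration_mM != 0:
                raise PlateValidationError(
                    f"well {row.well!r}: vehicle wells must have concentration 0"
                )
            if row.replicate < 1:
                raise PlateValidationError(f"well {row.well!r}: replicate must be >= 1")
        # Every (protein, ligand) sample group needs a vehicle for that protein.
        vehicle_proteins = {r.protein for r in self.rows if r.role == "vehicle"}
        for row in self.rows:
            if row.role == "sample" and row.protein not in vehicle_proteins:
                raise PlateValidationError(
                    f"sample group ({row.protein}, {row.ligand}) has no vehicle "
                    f"well for protein {row.protein!r}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def by_well(self) -> dict[str, PlateMapRow]:
        return {r.well: r for r in self.rows}


@dataclass(frozen=True)
class AnnotatedCurve:
    """A melt curve joined with its plate-map annotation."""

    curve: MeltCurve
    well: str
    protein: str
    ligand: str
    concentration_mM: float
    role: str
    replicate: int
    plate_id: str


def _fmt(x: float) -> str:
    """Canonical number formatting for written CSVs (10 significant digits)."""
    if isinstance(x, float) and math.isnan(x):
        return "N/A"
    s = f"{x:.10g}"
    return s


def read_plate_csv(path: str | Path, plate_id: str | None = None) -> PlateData:
    """Read a wide melt-export CSV into :class:`PlateData`.

    The first column must be named ``temperature_C``; every remaining column
    is taken as a well trace.  The plate id defaults to the file stem.

    Raises
    ------
    PlateFormatError
        Missing/odd header, duplicated well columns, ragged rows, or
        non-numeric cells.
    PlateValidationError
        Non-monotone or non-uniform temperature grid.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise PlateFormatError(f"{path}: empty file")
        header = next(csv.reader(io.StringIO(header_line)))
        if not header or header[0] != "temperature_C":
            raise PlateFormatError(
                f"{path}: first column must be 'temperature_C' "
                f"(got {header[0]!r})" if header else f"{path}: empty header"
            )
        wells = header[1:]
        if len(set(wells)) != len(wells):
            dupes = sorted({w for w in wells if wells.count(w) > 1})
            raise PlateFormatError(f"{path}: duplicated well columns {dupes}")
        if not wells:
            raise PlateFormatError(f"{path}: no well columns")
        rows = []
        for lineno, rec in enumerate(csv.reader(fh), start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise PlateFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}"
                )
            try:
                rows.append([float(x) for x in rec])
            except ValueError as exc:
                raise PlateFormatError(f"{path}:{lineno}: non-numeric cell ({exc})")
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise PlateFormatError(f"{path}: no data rows")
    return PlateData(
        plate_id=plate_id if plate_id is not None else path.stem,
        temperatures=data[:, 0],
        wells={w: data[:, j + 1] for j, w in enumerate(wells)},
    )


def write_plate_csv(plate: PlateData, path: str | Path) -> None:
    """Write a plate in the canonical wide dialect (round-trips losslessly)."""
    path = Path(path)
    wells = list(plate.wells)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["temperature_C", *wells])
        cols = [plate.temperatures] + [plate.wells[w] for w in wells]
        for rec in zip(*cols):
            writer.writerow([_fmt(float(x)) for x in rec])


_MAP_HEADER = ["well", "protein", "ligand", "concentration_mM", "role", "replicate"]


def read_plate_map(path: str | Path) -> PlateMap:
    """Read and validate a plate-map CSV.

    Expected header: ``well,protein,ligand,concentration_mM,role,replicate``.

    Raises
    ------
    PlateFormatError
        Wrong header or unparsable fields.
    PlateValidationError
        Duplicate wells, unknown roles, nonzero vehicle concentration, or a
        sample group with no vehicle well for its protein.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise PlateFormatError(f"{path}: cannot parse plate map ({exc})")
    if list(df.columns) != _MAP_HEADER:
        raise PlateFormatError(
            f"{path}: plate map header must be {','.join(_MAP_HEADER)}"
        )
    rows = []
    for i, rec in df.iterrows():
        try:
            conc = float(rec["concentration_mM"])
            rep = int(rec["replicate"])
        except ValueError as exc:
            raise PlateFormatError(f"{path}: row {i + 2}: {exc}")
        rows.append(
            PlateMapRow(
                well=rec["well"].strip(),
                protein=rec["protein"].strip(),
                ligand=rec["ligand"].strip(),
                concentration_mM=conc,
                role=rec["role"].strip(),
                replicate=rep,
            )
        )
    return PlateMap(rows=tuple(rows))


def write_plate_map(pmap: PlateMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_MAP_HEADER)
        for r in pmap:
            writer.writerow(
                [r.well, r.protein, r.ligand, _fmt(r.concentration_mM), r.role, r.replicate]
            )


def join_plate(plate: PlateData, pmap: PlateMap) -> list[AnnotatedCurve]:
    """Join plate traces with their map rows.

    Every mapped well must exist on the plate; wells present on the plate but
    absent from the map are reported with a single summary warning, never
    silently dropped from the user's attention.

    Raises
    ------
    PlateValidationError
        If the map references wells not on the plate (all offenders listed).
    """
    missing = sorted(r.well for r in pmap if r.well not in plate.wells)
    if missing:
        raise PlateValidationError(
            f"plate {plate.plate_id!r}: map references absent wells {missing}"
        )
    unmapped = sorted(set(plate.wells) - {r.well for r in pmap})
    if unmapped:
        warnings.warn(
            f"plate {plate.plate_id!r}: {len(unmapped)} unmapped wells "
            f"ignored: {', '.join(unmapped[:8])}"
            + ("..." if len(unmapped) > 8 else ""),
            stacklevel=2,
        )
    return [
        AnnotatedCurve(
            curve=plate.curve(r.well),
            well=r.well,
            protein=r.protein,
            ligand=r.ligand,
            concentration_mM=r.concentration_mM,
            role=r.role,
            replicate=r.replicate,
            plate_id=plate.plate_id,
        )
        for r in pmap
    ]


def _result_cell(value, sig: int = 6) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "N/A"
    return f"{value:.{sig}g}"


def write_results(fits, path: str | Path) -> None:
    """Write a tidy results CSV, one row per binding fit.

    Non-binders are written with ``N/A`` Kd/ΔTm fields and
    ``binder_flag=False``, mirroring how nonbinding congeners are reported in
    affinity summary tables.  Numeric values carry 6 significant digits.
    """
    fits = list(fits)
    if not fits:
        raise PlateValidationError("write_results: no fits to write")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for fit in fits:
            binder = fit.model != "nonbinding"
            writer.writerow(
                [
                    fit.protein,
                    fit.ligand,
                    fit.n_replicates,
                    _result_cell(fit.kd_mM if binder else None),
                    _result_cell(fit.kd_se_mM if binder else None),
                    _result_cell(fit.dtm_max_C if binder else None),
                    _result_cell(fit.dtm_max_se_C if binder else None),
                    fit.model,
                    _result_cell(fit.r2 if binder else None),
                    binder,
                ]
            )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, na_values=["N/A"])
    if list(df.columns) != RESULT_COLUMNS:
        raise PlateFormatError(f"{path}: unexpected results header")
    return df
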