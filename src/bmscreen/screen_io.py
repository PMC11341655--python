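"""Domain types, 1536-well plate geometry, and tabular readers/writers.

All tables are plain UTF-8 text with a single header row:

* plate reads: comma-separated, columns
  ``plate_id,well,role,compound_id,conc_um,cell_model_id,signal``
* compound library: tab-separated, columns
  ``compound_id,name,target_genes,target_family,clinical_status``
  (``target_genes`` is a semicolon-delimited gene-symbol list)
* variant calls: tab-separated, columns
  ``sample_id,source,gene,c_hgvs,p_hgvs,af_percent``

Concentrations are µM throughout; signals are dimensionless luminescence
counts (CellTiter-Glo style, proportional to viable cell number).
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "ValidationError",
    "ModelClass",
    "WellRole",
    "VariantSource",
    "ClinicalStatus",
    "CellModel",
    "CompoundRecord",
    "WellMeasurement",
    "VariantCall",
    "N_ROWS",
    "N_COLS",
    "parse_well",
    "format_well",
    "read_plate_table",
    "write_plate_table",
    "read_compound_library",
    "write_compound_library",
    "read_variant_table",
    "write_variant_table",
]


class ValidationError(ValueError):
    """Raised when a record or table row violates its invariants."""


class ModelClass(str, enum.Enum):
    TUMOR = "TUMOR"
    HFB = "HFB"  # human fibroblasts, non-neoplastic control
    PBC = "PBC"  # peripheral blood cells, non-neoplastic control


class WellRole(str, enum.Enum):
    SAMPLE = "SAMPLE"
    DMSO = "DMSO"
    POS_CTRL = "POS_CTRL"


class VariantSource(str, enum.Enum):
    TISSUE = "TISSUE"
    CULTURE = "CULTURE"


class ClinicalStatus(str, enum.Enum):
    FDA_APPROVED = "FDA_APPROVED"
    CLINICAL_EVALUATION = "CLINICAL_EVALUATION"


# ---------------------------------------------------------------------------
# Plate geometry: 1536-well = 32 rows x 48 columns, rows A-Z then AA-AF.
# ---------------------------------------------------------------------------

N_ROWS = 32
N_COLS = 48

_WELL_RE = re.compile(r"^([A-Z]{1,2})(\d{1,2})$")


def _row_number(letters: str) -> int:
    n = 0
    for ch in letters:
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n


def parse_well(label: str) -> tuple[int, int]:
    """Parse a well label like ``"A1"`` or ``"AF48"`` to 1-based (row, column).

    Raises :class:`ValidationError` for labels outside the 1536-well grid.
    """
    m = _WELL_RE.match(label.strip())
    if not m:
        raise ValidationError(f"malformed well label: {label!r}")
    row = _row_number(m.group(1))
    col = int(m.group(2))
    if not (1 <= row <= N_ROWS and 1 <= col <= N_COLS):
        raise ValidationError(
            f"well {label!r} outside 1536-well grid ({N_ROWS} rows x {N_COLS} columns)"
        )
    return row, col


def format_well(row: int, col: int) -> str:
    """Inverse of :func:`parse_well`: (row, col) -> label."""
    if not (1 <= row <= N_ROWS and 1 <= col <= N_COLS):
        raise ValidationError(f"well position ({row}, {col}) outside 1536-well grid")
    if row <= 26:
        letters = chr(ord("A") + row - 1)
    else:
        letters = "A" + chr(ord("A") + row - 27)
    return f"{letters}{col}"


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellModel:
    """A screened cell model: one patient-derived tumor culture, or one of the
    two non-neoplastic controls (human fibroblasts, peripheral blood cells)."""

    model_id: str
    model_class: ModelClass
    patient_id: str = ""
    entity: str = ""  # tumor entity, e.g. "NSCLC", "ESCA"

    def __post_init__(self) -> None:
        if self.model_class is ModelClass.TUMOR and not self.patient_id:
            raise ValidationError(
                f"tumor cell model {self.model_id!r} requires a patient_id"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound with its target annotation."""

    compound_id: str
    name: str
    target_genes: tuple[str, ...]
    target_family: str
    clinical_status: ClinicalStatus

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class WellMeasurement:
    """One plate well: location, role, dose and raw luminescence signal."""

    plate_id: str
    well: str
    role: WellRole
    compound_id: str
    conc_um: float
    cell_model_id: str
    signal: float

    def __post_init__(self) -> None:
        parse_well(self.well)  # validates geometry
        if self.conc_um < 0:
            raise ValidationError(f"negative concentration in well {self.well}")
        if self.signal < 0:
            raise ValidationError(f"negative signal in well {self.well}")
        if self.role is WellRole.DMSO:
            if self.conc_um != 0:
                raise ValidationError(
                    f"DMSO well {self.well} has nonzero concentration {self.conc_um}"
                )
            if self.compound_id:
                raise ValidationError(
                    f"DMSO well {self.well} has a compound_id ({self.compound_id!r})"
                )
        elif not self.compound_id:
            raise ValidationError(f"{self.role.value} well {self.well} lacks a compound_id")


@dataclass(frozen=True)
class VariantCall:
    """A gene-panel variant call with its mutant allele fraction (percent)."""

    sample_id: str
    source: VariantSource
    gene: str
    c_hgvs: str
    p_hgvs: str = ""
    af_percent: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("variant call lacks a gene symbol")
        if not (0.0 <= self.af_percent <= 100.0):
            raise ValidationError(
                f"allele fraction {self.af_percent} outside [0, 100] "
                f"({self.gene} {self.c_hgvs})"
            )

    @property
    def match_key(self) -> tuple[str, str]:
        # exact-string matching on (gene, cDNA HGVS) after whitespace stripping
        return self.gene.strip(), re.sub(r"\s+", "", self.c_hgvs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["plate_id", "well", "role", "compound_id", "conc_um", "cell_model_id", "signal"]
LIBRARY_COLUMNS = ["compound_id", "name", "target_genes", "target_family", "clinical_status"]
VARIANT_COLUMNS = ["sample_id", "source", "gene", "c_hgvs", "p_hgvs", "af_percent"]


def _check_header(header: list[str] | None, expected: list[str], path: Path) -> None:
    if header is None or [h.strip() for h in header] != expected:
        raise ValidationError(
            f"{path}: header {header!r} does not match expected columns {expected}"
        )


def _parse_float(text: str, what: str, row_no: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"row {row_no}: {what} is not a number: {text!r}") from None


def read_plate_table(path: str | Path) -> list[WellMeasurement]:
    """Read a plate-reads CSV into validated :class:`WellMeasurement` records.

    Row order is preserved. Any invariant violation raises
    :class:`ValidationError` naming the 1-based data-row number.
    """
    path = Path(path)
    wells: list[WellMeasurement] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, PLATE_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(PLATE_COLUMNS):
                raise ValidationError(f"row {i}: expected {len(PLATE_COLUMNS)} fields, got {len(row)}")
            plate_id, well, role, compound_id, conc, model, signal = (c.strip() for c in row)
            try:
                rec = WellMeasurement(
                    plate_id=plate_id,
                    well=well,
                    role=WellRole(role),
                    compound_id=compound_id,
                    conc_um=_parse_float(conc, "conc_um", i),
                    cell_model_id=model,
                    signal=_parse_float(signal, "signal", i),
                )
            except ValueError as exc:  # includes ValidationError and bad enum
                raise ValidationError(f"row {i}: {exc}") from None
            wells.append(rec)
    return wells


def write_plate_table(wells: Iterable[WellMeasurement], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for w in wells:
            writer.writerow(
                [w.plate_id, w.well, w.role.value, w.compound_id,
                 repr(float(w.conc_um)), w.cell_model_id, repr(float(w.signal))]
            )


def read_compound_library(path: str | Path) -> dict[str, CompoundRecord]:
    """Read the compound-annotation TSV into a map ``compound_id -> record``.

    Duplicate compound IDs are rejected with an error listing them.
    """
    path = Path(path)
    library: dict[str, CompoundRecord] = {}
    duplicates: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        _check_header(header, LIBRARY_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(LIBRARY_COLUMNS):
                raise ValidationError(f"row {i}: expected {len(LIBRARY_COLUMNS)} fields, got {len(row)}")
            compound_id, name, genes, family, status = (c.strip() for c in row)
            try:
                rec = CompoundRecord(
                    compound_id=compound_id,
                    name=name,
                    target_genes=tuple(g for g in genes.split(";") if g),
                    target_family=family,
                    clinical_status=ClinicalStatus(status),
                )
            except ValueError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
            if compound_id in library:
                duplicates.append(compound_id)
            else:
                library[compound_id] = rec
    if duplicates:
        raise ValidationError(f"duplicate compound IDs: {sorted(set(duplicates))}")
    return library


def write_compound_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LIBRARY_COLUMNS)
        for r in records:
            writer.writerow(
                [r.compound_id, r.name, ";".join(r.target_genes),
                 r.target_family, r.clinical_status.value]
            )


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a variant-call TSV into validated :class:`VariantCall` records."""
    path = Path(path)
    calls: list[VariantCall] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        _check_header(header, VARIANT_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(VARIANT_COLUMNS):
                raise ValidationError(f"row {i}: expected {len(VARIANT_COLUMNS)} fields, got {len(row)}")
            sample_id, source, gene, c_hgvs, p_hgvs, af = (c.strip() for c in row)
            try:
                rec = VariantCall(
                    sample_id=sample_id,
                    source=VariantSource(source),
                    gene=gene,
                    c_hgvs=c_hgvs,
                    p_hgvs=p_hgvs,
                    af_percent=_parse_float(af, "af_percent", i),
                )
            except ValueError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
            calls.append(rec)
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(VARIANT_COLUMNS)
        for v in calls:
            writer.writerow(
                [v.sample_id, v.source.value, v.gene, v.c_hgvs, v.p_hgvs,
                 repr(float(v.af_percent))]
            )
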