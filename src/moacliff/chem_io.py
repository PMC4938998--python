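"""Reading, writing and canonicalization of screening data.

Ingests bioassay result tables in the style of PubChem BioAssay CSV
exports (one row per tested substance: SID, CID, structure, outcome
annotation, optional potency) and normalizes them into
:class:`CompoundRecord` / :class:`AssayDataset` containers that the rest
of the pipeline operates on.  Structures are carried as SMILES strings
throughout; every key that has to compare equal downstream (scaffolds,
MMP cores, fragments) goes through :func:`canonical_smiles`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem, RDLogger

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "OTHER",
    "MISSING",
    "AGONIST",
    "ANTAGONIST",
    "ChemParseError",
    "DialectError",
    "CompoundRecord",
    "AuditRow",
    "AssayDataset",
    "Dialect",
    "read_bioassay_table",
    "canonical_smiles",
    "mol_from_smiles",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable structure; we log those ourselves.
RDLogger.DisableLog("rdApp.error")

# Outcome vocabulary.  Anything that is neither Active nor Inactive maps
# to Other (e.g. "Inconclusive"); an absent annotation maps to Missing.
ACTIVE = "Active"
INACTIVE = "Inactive"
OTHER = "Other"
MISSING = "Missing"

AGONIST = "agonist"
ANTAGONIST = "antagonist"


class ChemParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class DialectError(ValueError):
    """The column-mapping configuration does not match the input table."""


@dataclass(frozen=True)
class CompoundRecord:
    """One screened substance: identifiers, structure, outcome, potencies.

    ``sid`` identifies the deposited sample, ``cid`` the unique chemical
    structure; several SIDs may share a CID.  ``potencies`` holds raw
    IC50 values in micromolar (possibly empty).
    """

    sid: str
    cid: str
    smiles: str
    outcome: str
    potencies: tuple[float, ...] = ()
    source_assay: str = AGONIST

    def with_outcome(self, outcome: str) -> "CompoundRecord":
        return replace(self, outcome=outcome)


@dataclass(frozen=True)
class AuditRow:
    stage: str
    n_before: int
    n_removed: int
    n_after: int


@dataclass
class AssayDataset:
    """A collection of compound records for one assay plus a filter audit trail.

    The audit counts *records*; unique-CID counts (the unit the published
    per-stage numbers are reported in) are available via :meth:`n_cids`.
    """

    records: list[CompoundRecord] = field(default_factory=list)
    audit: list[AuditRow] = field(default_factory=list)
    name: str = AGONIST

    def __len__(self) -> int:
        return len(self.records)

    def cids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.cid, None)
        return list(seen)

    def n_cids(self) -> int:
        return len({r.cid for r in self.records})

    def outcome_by_cid(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for r in self.records:
            out.setdefault(r.cid, r.outcome)
        return out

    def smiles_by_cid(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for r in self.records:
            out.setdefault(r.cid, r.smiles)
        return out

    def potencies_by_cid(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for r in self.records:
            out.setdefault(r.cid, []).extend(r.potencies)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sid": [r.sid for r in self.records],
                "cid": [r.cid for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "outcome": [r.outcome for r in self.records],
                "ic50_um": [
                    ";".join(repr(v) for v in r.potencies) for r in self.records
                ],
            }
        )

    def audit_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [a.stage for a in self.audit],
                "n_before": [a.n_before for a in self.audit],
                "n_removed": [a.n_removed for a in self.audit],
                "n_after": [a.n_after for a in self.audit],
            }
        )


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a bioassay export.

    The defaults match the CSV dialect this package itself writes; set
    the fields to the exporting database's column headers otherwise
    (e.g. ``PUBCHEM_SID``).  ``potency_col`` may be ``None`` when the
    table carries no potency readout.  A potency cell may contain a
    single number or a ``;``-separated list.
    """

    sid_col: str = "sid"
    cid_col: str = "cid"
    smiles_col: str = "smiles"
    outcome_col: str = "outcome"
    potency_col: str | None = "ic50_um"
    sep: str = ","

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "Dialect":
        allowed = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise DialectError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def normalize_outcome(value: object) -> str:
    """Map a raw outcome annotation to the four-term vocabulary."""
    if value is None:
        return MISSING
    if isinstance(value, float) and math.isnan(value):
        return MISSING
    text = str(value).strip()
    if not text:
        return MISSING
    low = text.lower()
    if low == "active":
        return ACTIVE
    if low == "inactive":
        return INACTIVE
    if low in {"missing", "na", "n/a", "nan"}:
        return MISSING
    return OTHER


def _parse_potency_cell(value: object, sid: str) -> tuple[float, ...]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    vals: list[float] = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            vals.append(float(part))
        except ValueError:
            logger.warning("SID %s: unparseable potency %r ignored", sid, part)
            return ()
    return tuple(vals)


def read_bioassay_table(
    path: str | Path,
    dialect: Dialect | Mapping[str, object] | None = None,
    source_assay: str = AGONIST,
) -> AssayDataset:
    """Read a bioassay result table into an :class:`AssayDataset`.

    The reader is non-destructive: one record per row, duplicates and
    discrepancies included (curation happens in :mod:`moacliff.preprocess`).
    An empty file yields an empty dataset; a missing mandatory column
    raises :class:`DialectError`.
    """
    if dialect is None:
        dialect = Dialect()
    elif not isinstance(dialect, Dialect):
        dialect = Dialect.from_dict(dialect)
    try:
        df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    except pd.errors.EmptyDataError:
        return AssayDataset(records=[], name=source_assay)
    mandatory = [dialect.sid_col, dialect.cid_col, dialect.smiles_col, dialect.outcome_col]
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise DialectError(f"missing mandatory columns: {missing_cols}")
    has_potency = dialect.potency_col is not None and dialect.potency_col in df.columns
    records = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        sid = str(row_d[dialect.sid_col])
        potencies = (
            _parse_potency_cell(row_d[dialect.potency_col], sid) if has_potency else ()
        )
        cid_raw = row_d[dialect.cid_col]
        smiles_raw = row_d[dialect.smiles_col]
        records.append(
            CompoundRecord(
                sid=sid,
                cid="" if cid_raw is None or (isinstance(cid_raw, float) and math.isnan(cid_raw)) else str(cid_raw),
                smiles="" if smiles_raw is None or (isinstance(smiles_raw, float) and math.isnan(smiles_raw)) else str(smiles_raw),
                outcome=normalize_outcome(row_d[dialect.outcome_col]),
                potencies=potencies,
                source_assay=source_assay,
            )
        )
    return AssayDataset(records=records, name=source_assay)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`ChemParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemParseError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Return the canonical form of a SMILES string (idempotent)."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_table(rows: pd.DataFrame | Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write tabular data as CSV/TSV (by extension) with a mandatory header."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_dataset(ds: AssayDataset, path: str | Path) -> None:
    write_table(ds.to_dataframe(), path)
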