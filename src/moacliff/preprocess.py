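"""Six-step curation of raw HTS exports and potency aggregation.

The curation pipeline mirrors the standard cleanup applied to paired
PubChem Tox21 screens before structural analysis:

1. drop records with missing readouts;
2. collapse redundant records (same CID, same outcome, different SID);
3. drop CIDs with discrepant outcomes across their SIDs;
4. keep only binary (Active/Inactive) outcome annotations;
5. drop mixtures (multi-component structures);
6. drop ring-less (acyclic) structures.

Each stage appends an audit row so removed + kept always reconciles.
Potencies are converted from IC50 (µM) to pIC50 (molar): values within
one log order are averaged, wider spreads disqualify the compound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from rdkit import Chem

from .chem_io import (
    ACTIVE,
    INACTIVE,
    MISSING,
    AssayDataset,
    AuditRow,
    CompoundRecord,
)

__all__ = [
    "PotencyRecord",
    "STAGE_ORDER",
    "filter_missing_readouts",
    "collapse_redundant",
    "drop_discrepant",
    "keep_binary_outcomes",
    "remove_mixtures",
    "remove_ringless",
    "run_pipeline",
    "aggregate_potency",
    "aggregate_dataset_potencies",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "missing_readouts",
    "redundant_sids",
    "discrepant_outcomes",
    "non_binary_outcomes",
    "mixtures",
    "ringless",
)


@dataclass(frozen=True)
class PotencyRecord:
    """Aggregated potency for one compound, in pIC50 (−log10 molar) units."""

    cid: str
    pic50: float
    n_merged: int


def _stage(ds: AssayDataset, name: str, kept: list[CompoundRecord]) -> AssayDataset:
    n_before = len(ds.records)
    n_after = len(kept)
    audit = ds.audit + [AuditRow(name, n_before, n_before - n_after, n_after)]
    return AssayDataset(records=kept, audit=audit, name=ds.name)


def filter_missing_readouts(ds: AssayDataset) -> AssayDataset:
    """Stage 1: remove records without an outcome readout."""
    kept = [r for r in ds.records if r.outcome != MISSING]
    return _stage(ds, STAGE_ORDER[0], kept)


def collapse_redundant(ds: AssayDataset) -> AssayDataset:
    """Stage 2: merge same-CID, same-outcome records into one.

    CIDs whose records disagree in outcome are left untouched here;
    stage 3 removes them wholesale.  Potency lists of merged records are
    concatenated in input order, so the unique-CID count is unchanged.
    """
    outcomes_by_cid: dict[str, set[str]] = {}
    for r in ds.records:
        outcomes_by_cid.setdefault(r.cid, set()).add(r.outcome)
    kept: list[CompoundRecord] = []
    merged: dict[str, int] = {}
    for r in ds.records:
        if len(outcomes_by_cid[r.cid]) > 1:
            kept.append(r)
            continue
        if r.cid in merged:
            i = merged[r.cid]
            prev = kept[i]
            kept[i] = CompoundRecord(
                sid=prev.sid,
                cid=prev.cid,
                smiles=prev.smiles,
                outcome=prev.outcome,
                potencies=prev.potencies + r.potencies,
                source_assay=prev.source_assay,
            )
        else:
            merged[r.cid] = len(kept)
            kept.append(r)
    return _stage(ds, STAGE_ORDER[1], kept)


def drop_discrepant(ds: AssayDataset) -> AssayDataset:
    """Stage 3: remove every CID reported with conflicting outcomes."""
    outcomes_by_cid: dict[str, set[str]] = {}
    for r in ds.records:
        outcomes_by_cid.setdefault(r.cid, set()).add(r.outcome)
    kept = [r for r in ds.records if len(outcomes_by_cid[r.cid]) == 1]
    return _stage(ds, STAGE_ORDER[2], kept)


def keep_binary_outcomes(ds: AssayDataset) -> AssayDataset:
    """Stage 4: keep only Active/Inactive annotations."""
    kept = [r for r in ds.records if r.outcome in (ACTIVE, INACTIVE)]
    return _stage(ds, STAGE_ORDER[3], kept)


def remove_mixtures(ds: AssayDataset) -> AssayDataset:
    """Stage 5: remove multi-component structures.

    A mixture is a structure graph with more than one covalently
    connected component (dot-disconnected SMILES).  Unparseable
    structures are removed here too, with a logged warning, rather than
    aborting the run.
    """
    kept = []
    for r in ds.records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            logger.warning("CID %s: unparseable structure removed: %r", r.cid, r.smiles)
            continue
        if len(Chem.GetMolFrags(mol)) == 1:
            kept.append(r)
    return _stage(ds, STAGE_ORDER[4], kept)


def remove_ringless(ds: AssayDataset) -> AssayDataset:
    """Stage 6: remove structures without any ring."""
    kept = []
    for r in ds.records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is not None and len(Chem.GetSymmSSSR(mol)) > 0:
            kept.append(r)
    return _stage(ds, STAGE_ORDER[5], kept)


def run_pipeline(ds: AssayDataset) -> AssayDataset:
    """Apply the six curation stages in their fixed order."""
    for fn in (
        filter_missing_readouts,
        collapse_redundant,
        drop_discrepant,
        keep_binary_outcomes,
        remove_mixtures,
        remove_ringless,
    ):
        ds = fn(ds)
    return ds


def pic50_from_um(ic50_um: float) -> float:
    """Convert an IC50 in micromolar to pIC50 in −log10(molar)."""
    if ic50_um <= 0:
        raise ValueError(f"IC50 must be strictly positive, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)


def aggregate_potency(values_um: list[float] | tuple[float, ...]) -> float | None:
    """Aggregate raw IC50 values (µM) into one pIC50, or disqualify.

    Values within one log order (max − min of pIC50 ≤ 1, inclusive) are
    averaged; a wider spread returns ``None`` — the compound is dropped
    from potency-based analyses.  The result is invariant to input
    order.  An empty list returns ``None``.
    """
    if not values_um:
        return None
    pic50s = [pic50_from_um(v) for v in values_um]
    if max(pic50s) - min(pic50s) > 1.0:
        return None
    return sum(pic50s) / len(pic50s)


def aggregate_dataset_potencies(
    ds: AssayDataset, outcome: str = ACTIVE
) -> tuple[dict[str, PotencyRecord], set[str]]:
    """Aggregate per-CID potencies for compounds with the given outcome.

    Returns ``(records, dropped)``: ``records`` maps CID to its
    aggregated :class:`PotencyRecord`; ``dropped`` holds CIDs whose
    potency spread exceeded one log order.  CIDs without any potency
    value appear in neither.
    """
    records: dict[str, PotencyRecord] = {}
    dropped: set[str] = set()
    outcome_by_cid = ds.outcome_by_cid()
    for cid, values in ds.potencies_by_cid().items():
        if outcome_by_cid[cid] != outcome or not values:
            continue
        agg = aggregate_potency(values)
        if agg is None:
            dropped.add(cid)
        else:
            records[cid] = PotencyRecord(cid=cid, pic50=agg, n_merged=len(values))
    return records, dropped
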