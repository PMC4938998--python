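"""Bemis–Murcko scaffolds, cyclic skeletons (CSKs) and their statistics.

The Bemis–Murcko scaffold of a molecule keeps every ring system, every
linker connecting ring systems, and atoms attached to ring or linker
atoms by bonds of order > 1 (an exocyclic carbonyl oxygen stays, a
methyl group goes).  The cyclic skeleton abstracts the scaffold one
step further: every atom becomes carbon and every bond becomes single,
so topologically equivalent scaffolds collapse onto one CSK.

Statistics over a curated assay dataset include per-scaffold compound
counts, per-CSK scaffold counts, the singleton fraction, a ring-count
histogram, and the partition of the scaffold universe into
exclusively-active / overlapping / exclusively-inactive sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import ACTIVE, INACTIVE, AssayDataset, mol_from_smiles
from .preprocess import PotencyRecord

__all__ = [
    "ScaffoldAssignment",
    "ScaffoldSummary",
    "bm_scaffold",
    "csk_of",
    "ring_count",
    "assign_scaffolds",
    "summarize_scaffolds",
    "exclusive_potency_profile",
]


@dataclass(frozen=True)
class ScaffoldAssignment:
    cid: str
    scaffold: str
    csk: str
    n_rings: int


@dataclass
class ScaffoldSummary:
    """Scaffold/CSK statistics for one curated dataset."""

    scaffold_to_cids: dict[str, tuple[str, ...]]
    csk_to_scaffolds: dict[str, tuple[str, ...]]
    ring_histogram: Counter = field(default_factory=Counter)
    exclusive_active: frozenset[str] = frozenset()
    exclusive_inactive: frozenset[str] = frozenset()
    overlap: frozenset[str] = frozenset()

    @property
    def n_compounds(self) -> int:
        return sum(len(v) for v in self.scaffold_to_cids.values())

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffold_to_cids)

    @property
    def n_csks(self) -> int:
        return len(self.csk_to_scaffolds)

    @property
    def scaffold_counts(self) -> Counter:
        return Counter({s: len(v) for s, v in self.scaffold_to_cids.items()})

    @property
    def singleton_fraction(self) -> float:
        if not self.scaffold_to_cids:
            return 0.0
        n_single = sum(1 for v in self.scaffold_to_cids.values() if len(v) == 1)
        return n_single / self.n_scaffolds


def _n_rings(mol: Chem.Mol) -> int:
    # force SSSR perception: lazily initialized ring info can be absent
    # on molecules touched after partially sanitized intermediates
    return len(Chem.GetSymmSSSR(mol))


def bm_scaffold(smiles: str) -> str:
    """Canonical Bemis–Murcko scaffold of a molecule.

    Raises ``ValueError`` for acyclic molecules: a scaffold needs at
    least one ring, and ring-less structures are filtered upstream.
    """
    mol = mol_from_smiles(smiles)
    if _n_rings(mol) == 0:
        raise ValueError(f"acyclic molecule has no scaffold: {smiles!r}")
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def csk_of(scaffold_smiles: str) -> str:
    """Cyclic skeleton: all atoms to carbon, all bonds to single.

    Aromaticity, charges, isotopes and stereochemistry are erased.
    Idempotent; scaffolds differing only in heteroatoms or bond orders
    map to the same CSK.
    """
    mol = mol_from_smiles(scaffold_smiles)
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetIsotope(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    out = rw.GetMol()
    # Hypervalent origins (e.g. a sulfone S) can leave a carbon with
    # more than four neighbours; skip the valence check on purpose.
    Chem.SanitizeMol(
        out, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
    )
    out.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(out)


def ring_count(smiles: str) -> int:
    """Number of rings (smallest set of smallest rings)."""
    return _n_rings(mol_from_smiles(smiles))


def assign_scaffolds(ds: AssayDataset) -> list[ScaffoldAssignment]:
    """Scaffold and CSK for every compound in a curated dataset."""
    out = []
    for cid, smiles in ds.smiles_by_cid().items():
        scaf = bm_scaffold(smiles)
        out.append(
            ScaffoldAssignment(
                cid=cid, scaffold=scaf, csk=csk_of(scaf), n_rings=ring_count(scaf)
            )
        )
    return out


def summarize_scaffolds(
    assignments: list[ScaffoldAssignment], outcomes: dict[str, str]
) -> ScaffoldSummary:
    """Aggregate scaffold statistics and the activity-exclusivity partition.

    A scaffold is *exclusively active* when every compound carrying it
    is Active, *exclusively inactive* when all are Inactive, and
    *overlapping* when it covers at least one of each.
    """
    scaffold_to_cids: dict[str, list[str]] = {}
    csk_to_scaffolds: dict[str, set[str]] = {}
    ring_hist: Counter = Counter()
    for a in assignments:
        scaffold_to_cids.setdefault(a.scaffold, []).append(a.cid)
        csk_to_scaffolds.setdefault(a.csk, set()).add(a.scaffold)
    for scaf in scaffold_to_cids:
        ring_hist[ring_count(scaf)] += 1
    excl_act, excl_inact, overlap = set(), set(), set()
    for scaf, cids in scaffold_to_cids.items():
        outs = {outcomes[c] for c in cids}
        if outs == {ACTIVE}:
            excl_act.add(scaf)
        elif outs == {INACTIVE}:
            excl_inact.add(scaf)
        else:
            overlap.add(scaf)
    return ScaffoldSummary(
        scaffold_to_cids={s: tuple(v) for s, v in scaffold_to_cids.items()},
        csk_to_scaffolds={c: tuple(sorted(v)) for c, v in csk_to_scaffolds.items()},
        ring_histogram=ring_hist,
        exclusive_active=frozenset(excl_act),
        exclusive_inactive=frozenset(excl_inact),
        overlap=frozenset(overlap),
    )


def exclusive_potency_profile(
    summary: ScaffoldSummary, potencies: dict[str, PotencyRecord]
) -> pd.DataFrame:
    """Potency range per exclusively-active scaffold.

    Compounds disqualified by the one-log-order rule (or lacking any
    potency) are excluded; a scaffold that loses all its compounds this
    way drops out of the profile entirely, so the number of profiled
    scaffolds can shrink relative to the exclusivity partition.
    """
    rows = []
    for scaf in sorted(summary.exclusive_active):
        vals = [
            potencies[c].pic50 for c in summary.scaffold_to_cids[scaf] if c in potencies
        ]
        if not vals:
            continue
        rows.append(
            {
                "scaffold": scaf,
                "n_compounds": len(vals),
                "pic50_min": min(vals),
                "pic50_max": max(vals),
            }
        )
    return pd.DataFrame(rows, columns=["scaffold", "n_compounds", "pic50_min", "pic50_max"])
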