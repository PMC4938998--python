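"""Size-restricted matched molecular pairs (MMPs) and activity cliffs.

A matched molecular pair is two molecules that differ only by a small
structural change at one site: they share an invariant *core* and swap
an *exchanged fragment*.  Pairs are found by fragment-and-index: every
acyclic single bond of every molecule is cut, each (core, fragment)
split is canonicalized, and compounds sharing a core with different
fragments become candidate pairs.

Candidates are size-restricted so the exchange stays a small, local
edit (all sizes in heavy atoms):

1. the core must be at least twice the size of each exchanged fragment;
2. an exchanged fragment may have at most 13 heavy atoms;
3. the two exchanged fragments may differ by at most 8 heavy atoms.

A compound pair connected by several admissible cuts is reduced to one
MMP: the cut with the smallest |size difference| between exchanged
fragments wins, remaining ties are broken by a seeded random draw (the
surviving pair *count* does not depend on the seed, only the chosen
representative cut may).

With binary screen outcomes, an MMP whose members disagree (one Active,
one Inactive) is an activity cliff — a point of SAR discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from rdkit import Chem

from .chem_io import ACTIVE, INACTIVE, mol_from_smiles

__all__ = [
    "Fragmentation",
    "MatchedPair",
    "INACTIVE_MMP",
    "ACTIVE_MMP",
    "ACTIVITY_CLIFF",
    "enumerate_fragmentations",
    "index_pairs",
    "size_filter",
    "apply_size_filter",
    "deduplicate",
    "classify",
    "generate_mmps",
    "build_network",
    "write_graphml",
    "write_sif",
]

INACTIVE_MMP = "inactive_mmp"
ACTIVE_MMP = "active_mmp"
ACTIVITY_CLIFF = "activity_cliff"

# Size-restriction defaults, in heavy atoms.
CORE_RATIO = 2.0
MAX_FRAGMENT_ATOMS = 13
MAX_DELTA_ATOMS = 8


@dataclass(frozen=True)
class Fragmentation:
    """One cut of one molecule: invariant core + exchanged fragment.

    Attachment points are written as dummy atoms (``[*]``, numbered for
    double cuts) and never count as heavy atoms; for single cuts the
    core is the larger side (ties emit both orientations).
    """

    parent_cid: str
    core: str
    fragment: str
    core_heavy: int
    frag_heavy: int
    n_cuts: int = 1


@dataclass(frozen=True)
class MatchedPair:
    """Two compounds sharing a core; unordered, stored with cid_left < cid_right."""

    cid_left: str
    cid_right: str
    core: str
    frag_left: str
    frag_right: str
    core_heavy: int
    frag_left_heavy: int
    frag_right_heavy: int
    category: str | None = None

    @property
    def delta_heavy(self) -> int:
        return abs(self.frag_left_heavy - self.frag_right_heavy)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cid_left, self.cid_right)


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds between heavy atoms (hydrogens are implicit)."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() == 0 or bond.GetEndAtom().GetAtomicNum() == 0:
            continue
        out.append(bond.GetIdx())
    return out


def _single_cut(mol: Chem.Mol, cid: str, bond_idx: int) -> list[Fragmentation]:
    cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - cutting an acyclic bond always splits
        return []
    (sa, ha), (sb, hb) = ((Chem.MolToSmiles(p), _heavy(p)) for p in pieces)
    if ha > hb:
        splits = [(sa, ha, sb, hb)]
    elif hb > ha:
        splits = [(sb, hb, sa, ha)]
    else:  # tie: both orientations are candidate (core, fragment) splits
        splits = [(sa, ha, sb, hb), (sb, hb, sa, ha)]
    return [
        Fragmentation(
            parent_cid=cid, core=core, fragment=frag, core_heavy=ch, frag_heavy=fh
        )
        for core, ch, frag, fh in splits
    ]


def _relabel(smiles: str, mapping: dict[int, int]) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(mapping[atom.GetIsotope()])
    return Chem.MolToSmiles(mol)


def _double_cut(mol: Chem.Mol, cid: str, b1: int, b2: int) -> list[Fragmentation]:
    cut = Chem.FragmentOnBonds(
        mol, [b1, b2], addDummies=True, dummyLabels=[(1, 1), (2, 2)]
    )
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    if len(pieces) != 3:
        return []
    linker = None
    outer = []
    for p in pieces:
        labels = [a.GetIsotope() for a in p.GetAtoms() if a.GetAtomicNum() == 0]
        if len(labels) == 2:
            linker = p
        else:
            outer.append(p)
    if linker is None or len(outer) != 2:
        return []
    frag = Chem.MolToSmiles(linker)
    core = Chem.MolToSmiles(Chem.CombineMols(outer[0], outer[1]))
    # Attachment numbering 1/2 is arbitrary; normalize to the labelling
    # that gives the lexicographically smaller core string.
    swap = {1: 2, 2: 1}
    core_alt = _relabel(core, swap)
    if core_alt < core:
        core, frag = core_alt, _relabel(frag, swap)
    return [
        Fragmentation(
            parent_cid=cid,
            core=core,
            fragment=frag,
            core_heavy=_heavy(outer[0]) + _heavy(outer[1]),
            frag_heavy=_heavy(linker),
            n_cuts=2,
        )
    ]


def enumerate_fragmentations(
    smiles: str, cid: str = "", max_cuts: int = 1
) -> list[Fragmentation]:
    """All single-cut (and optionally double-cut) fragmentations.

    Every acyclic single bond between heavy atoms is cut once; with
    ``max_cuts=2``, every unordered pair of such bonds additionally
    yields a two-attachment core and a linker fragment.
    """
    if max_cuts not in (1, 2):
        raise ValueError("max_cuts must be 1 or 2")
    mol = mol_from_smiles(smiles)
    bonds = _cuttable_bonds(mol)
    frags: list[Fragmentation] = []
    for b in bonds:
        frags.extend(_single_cut(mol, cid, b))
    if max_cuts == 2:
        for i in range(len(bonds)):
            for j in range(i + 1, len(bonds)):
                frags.extend(_double_cut(mol, cid, bonds[i], bonds[j]))
    return frags


def index_pairs(
    fragmentations: Iterable[Fragmentation],
) -> list[MatchedPair]:
    """Group fragmentations by core and emit candidate pairs.

    For each canonical core, every unordered pair of distinct compounds
    with different exchanged fragments yields one candidate; a compound
    never pairs with itself, and identical (pair, core, fragments)
    duplicates are collapsed.
    """
    by_core: dict[tuple[str, int], list[Fragmentation]] = {}
    for f in fragmentations:
        by_core.setdefault((f.core, f.n_cuts), []).append(f)
    seen: set[tuple] = set()
    pairs: list[MatchedPair] = []
    for (core, _n_cuts), group in by_core.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a.parent_cid == b.parent_cid or a.fragment == b.fragment:
                    continue
                if a.parent_cid > b.parent_cid:
                    a, b = b, a
                key = (a.parent_cid, b.parent_cid, core, a.fragment, b.fragment)
                if key in seen:
                    continue
                seen.add(key)
                pairs.append(
                    MatchedPair(
                        cid_left=a.parent_cid,
                        cid_right=b.parent_cid,
                        core=core,
                        frag_left=a.fragment,
                        frag_right=b.fragment,
                        core_heavy=a.core_heavy,
                        frag_left_heavy=a.frag_heavy,
                        frag_right_heavy=b.frag_heavy,
                    )
                )
    return pairs


def size_filter(
    pair: MatchedPair,
    core_ratio: float = CORE_RATIO,
    max_fragment_atoms: int = MAX_FRAGMENT_ATOMS,
    max_delta_atoms: int = MAX_DELTA_ATOMS,
) -> tuple[bool, str | None]:
    """Apply the three size restrictions; returns (retained, failed_rule).

    All boundaries are inclusive: a core exactly twice the fragment
    size passes rule 1, a 13-atom fragment passes rule 2, an 8-atom
    size difference passes rule 3.
    """
    if pair.frag_left_heavy > max_fragment_atoms or pair.frag_right_heavy > max_fragment_atoms:
        return False, "fragment_max_atoms"
    if pair.delta_heavy > max_delta_atoms:
        return False, "fragment_delta_atoms"
    if pair.core_heavy < core_ratio * pair.frag_left_heavy or (
        pair.core_heavy < core_ratio * pair.frag_right_heavy
    ):
        return False, "core_twice_fragment"
    return True, None


def apply_size_filter(
    pairs: Iterable[MatchedPair], **kwargs
) -> tuple[list[MatchedPair], list[tuple[MatchedPair, str]]]:
    kept, rejected = [], []
    for p in pairs:
        ok, reason = size_filter(p, **kwargs)
        if ok:
            kept.append(p)
        else:
            rejected.append((p, reason))
    return kept, rejected


def deduplicate(pairs: Iterable[MatchedPair], seed: int = 0) -> list[MatchedPair]:
    """One MMP per compound pair: smallest fragment-size deviation wins.

    Remaining ties are broken by a seeded random draw over a
    deterministically sorted candidate list, so results are reproducible
    and the number of surviving pairs never depends on the seed.
    """
    rng = np.random.default_rng(seed)
    by_pair: dict[tuple[str, str], list[MatchedPair]] = {}
    for p in pairs:
        by_pair.setdefault(p.key, []).append(p)
    out = []
    for key in sorted(by_pair):
        group = by_pair[key]
        best = min(p.delta_heavy for p in group)
        ties = sorted(
            (p for p in group if p.delta_heavy == best),
            key=lambda p: (p.core, p.frag_left, p.frag_right),
        )
        out.append(ties[int(rng.integers(len(ties)))])
    return out


def classify(pair: MatchedPair, outcomes: Mapping[str, str]) -> str:
    """Category from the two binary outcomes (order-independent)."""
    try:
        left, right = outcomes[pair.cid_left], outcomes[pair.cid_right]
    except KeyError as exc:
        raise KeyError(f"no outcome for compound {exc.args[0]!r}") from exc
    for o in (left, right):
        if o not in (ACTIVE, INACTIVE):
            raise ValueError(f"non-binary outcome {o!r} in pair {pair.key}")
    if left == right:
        return ACTIVE_MMP if left == ACTIVE else INACTIVE_MMP
    return ACTIVITY_CLIFF


@dataclass
class MmpResult:
    pairs: list[MatchedPair]
    rejections: list[tuple[MatchedPair, str]]

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {INACTIVE_MMP: 0, ACTIVE_MMP: 0, ACTIVITY_CLIFF: 0}
        for p in self.pairs:
            counts[p.category] += 1
        return counts


def generate_mmps(
    smiles_by_cid: Mapping[str, str],
    outcomes: Mapping[str, str] | None = None,
    max_cuts: int = 1,
    seed: int = 0,
    core_ratio: float = CORE_RATIO,
    max_fragment_atoms: int = MAX_FRAGMENT_ATOMS,
    max_delta_atoms: int = MAX_DELTA_ATOMS,
) -> MmpResult:
    """Full chain: fragment, index, size-filter, deduplicate, classify."""
    frags: list[Fragmentation] = []
    for cid in sorted(smiles_by_cid):
        frags.extend(enumerate_fragmentations(smiles_by_cid[cid], cid=cid, max_cuts=max_cuts))
    candidates = index_pairs(frags)
    kept, rejected = apply_size_filter(
        candidates,
        core_ratio=core_ratio,
        max_fragment_atoms=max_fragment_atoms,
        max_delta_atoms=max_delta_atoms,
    )
    pairs = deduplicate(kept, seed=seed)
    if outcomes is not None:
        pairs = [replace(p, category=classify(p, outcomes)) for p in pairs]
    return MmpResult(pairs=pairs, rejections=rejected)


def build_network(
    pairs: Iterable[MatchedPair], outcomes: Mapping[str, str] | None = None
) -> nx.Graph:
    """MMP network: compounds as nodes (outcome-annotated), MMPs as edges."""
    g = nx.Graph()
    for p in pairs:
        for cid in (p.cid_left, p.cid_right):
            if not g.has_node(cid):
                g.add_node(cid, outcome=(outcomes or {}).get(cid, ""))
        g.add_edge(p.cid_left, p.cid_right, category=p.category or "", core=p.core)
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: one ``node<TAB>category<TAB>node`` line per edge."""
    with open(path, "w") as fh:
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{data.get('category') or 'mmp'}\t{v}\n")
        for n in g.nodes:
            if g.degree[n] == 0:
                fh.write(f"{n}\n")
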