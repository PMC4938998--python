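"""Scaffold/CSK decomposition against an independent pruning oracle."""

import pytest
from rdkit import Chem

from moacliff.chem_io import ACTIVE, INACTIVE
from moacliff.preprocess import PotencyRecord
from moacliff.scaffolds import (
    ScaffoldAssignment,
    assign_scaffolds,
    bm_scaffold,
    csk_of,
    exclusive_potency_profile,
    ring_count,
    summarize_scaffolds,
)

TESTOSTERONE = "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O"
STEROID_SCAFFOLD = "O=C1CCC2C(=C1)CCC1C2CCC2C1CCC2"


def pruning_oracle(smiles: str) -> str:
    """Two-phase reference decomposition.

    Phase 1: iteratively delete degree-1 heavy atoms regardless of bond
    order, to a fixed point — what survives is the ring systems plus the
    linkers between them.  Phase 2: re-add atoms attached to a surviving
    atom by a bond of order > 1 (the exocyclic carbonyl rule).
    """
    mol = Chem.MolFromSmiles(smiles)
    keep = {a.GetIdx() for a in mol.GetAtoms()}
    changed = True
    while changed:
        changed = False
        for idx in sorted(keep):
            atom = mol.GetAtomWithIdx(idx)
            degree = sum(1 for n in atom.GetNeighbors() if n.GetIdx() in keep)
            if degree <= 1 and not atom.IsInRing():
                keep.discard(idx)
                changed = True
    skeleton = set(keep)
    for idx in skeleton:
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            other = bond.GetOtherAtom(mol.GetAtomWithIdx(idx)).GetIdx()
            if other not in skeleton and bond.GetBondTypeAsDouble() > 1.0:
                keep.add(other)
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


class TestBmScaffold:
    @pytest.mark.parametrize(
        "molecule,expected",
        [
            ("Cc1ccccc1", "c1ccccc1"),
            ("Oc1ccc(-c2ccccc2)cc1", Chem.CanonSmiles("c1ccc(-c2ccccc2)cc1")),
            (TESTOSTERONE, Chem.CanonSmiles(STEROID_SCAFFOLD)),
        ],
    )
    def test_known_scaffolds(self, molecule, expected):
        assert bm_scaffold(molecule) == expected

    def test_exocyclic_carbonyl_retained(self):
        # cyclohexanone with a methyl substituent: the =O stays, the C goes
        assert bm_scaffold("CC1CCCCC1=O") == Chem.CanonSmiles("O=C1CCCCC1")

    def test_acyclic_molecule_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            bm_scaffold("CCCCCC")

    @pytest.mark.parametrize(
        "molecule",
        [
            "Cc1ccccc1",            # toluene
            "Oc1ccccc1",            # phenol
            "O=Cc1ccccc1",          # benzaldehyde: whole CHO removed
            "C=Cc1ccccc1",          # styrene: vinyl removed
            "CC(=O)c1ccccc1",       # acetophenone
            "O=C(c1ccccc1)c1ccccc1",  # benzophenone: linker carbonyl kept
            "c1ccc(Cc2ccccc2)cc1",  # diphenylmethane
            "OCC1CCC(N)CC1",
            "CC1CCCCC1=O",
            "Clc1ccc(F)cc1",
            "CCOc1ccncc1",
            "NC1CC1C=O",
        ],
    )
    def test_matches_pruning_oracle(self, molecule):
        assert bm_scaffold(molecule) == pruning_oracle(molecule)

    def test_idempotent_on_library(self, small_curated):
        datasets, _ = small_curated
        for ds in datasets.values():
            for smiles in list(ds.smiles_by_cid().values())[:40]:
                scaf = bm_scaffold(smiles)
                assert bm_scaffold(scaf) == scaf


class TestCsk:
    @pytest.mark.parametrize(
        "scaffold,expected",
        [
            ("c1ccncc1", "C1CCCCC1"),
            ("c1ccccc1", "C1CCCCC1"),
        ],
    )
    def test_reduction(self, scaffold, expected):
        assert csk_of(scaffold) == Chem.CanonSmiles(expected)

    def test_steroid_csk_derived_by_string_surgery(self):
        # independent derivation: drop the double bonds and turn O into C
        # directly on the scaffold string, then canonicalize
        by_hand = Chem.CanonSmiles("CC1CCC2C(C1)CCC1C2CCC2C1CCC2")
        assert csk_of(STEROID_SCAFFOLD) == by_hand

    def test_idempotent_and_heteroatom_invariant(self):
        for scaf in ["c1ccncc1", STEROID_SCAFFOLD, "O=C1CCOC1", "c1ccc2[nH]ccc2c1"]:
            reduced = csk_of(scaf)
            assert csk_of(reduced) == reduced
        # swapping a ring N for C changes the scaffold, not the CSK
        assert csk_of("c1ccc2ncccc2c1") == csk_of("c1ccc2ccccc2c1")

    def test_hypervalent_atom_survives_reduction(self):
        # a sulfone ring: the 6-valent S becomes a carbon without crashing
        out = csk_of("O=S1(=O)CCCC1")
        assert Chem.MolFromSmiles(out) is not None


class TestRingCount:
    @pytest.mark.parametrize(
        "smiles,n",
        [("c1ccccc1", 1), (STEROID_SCAFFOLD, 4), ("c1ccc2ccccc2c1", 2)],
    )
    def test_counts(self, smiles, n):
        assert ring_count(smiles) == n


class TestSummary:
    def test_exclusivity_partition_small_case(self):
        assignments = [
            ScaffoldAssignment("a", "c1ccccc1", "C1CCCCC1", 1),
            ScaffoldAssignment("b", "c1ccccc1", "C1CCCCC1", 1),
            ScaffoldAssignment("c", "c1ccncc1", "C1CCCCC1", 1),
            ScaffoldAssignment("d", "c1ccncc1", "C1CCCCC1", 1),
        ]
        outcomes = {"a": ACTIVE, "b": ACTIVE, "c": ACTIVE, "d": INACTIVE}
        s = summarize_scaffolds(assignments, outcomes)
        assert s.exclusive_active == {"c1ccccc1"}
        assert s.overlap == {"c1ccncc1"}
        assert not s.exclusive_inactive
        assert s.n_csks == 1
        assert s.singleton_fraction == 0.0

    def test_single_scaffold_counts(self):
        assignments = [
            ScaffoldAssignment(str(i), "c1ccccc1", "C1CCCCC1", 1) for i in range(5)
        ]
        s = summarize_scaffolds(assignments, {str(i): ACTIVE for i in range(5)})
        assert s.scaffold_counts["c1ccccc1"] == 5
        assert s.singleton_fraction == 0.0

    def test_partition_and_count_invariants_on_library(self, small_curated):
        datasets, truth = small_curated
        for assay, ds in datasets.items():
            assignments = assign_scaffolds(ds)
            outcomes = ds.outcome_by_cid()
            s = summarize_scaffolds(assignments, outcomes)
            assert s.n_compounds == ds.n_cids()
            universe = s.exclusive_active | s.exclusive_inactive | s.overlap
            assert universe == set(s.scaffold_to_cids)
            assert len(s.exclusive_active) + len(s.exclusive_inactive) + len(s.overlap) == s.n_scaffolds
            # scaffolds recovered from decorated compounds equal the clean templates
            for a in assignments:
                assert a.scaffold == truth.scaffold_by_cid[a.cid]
                assert a.csk == truth.csk_by_cid[a.cid]
                assert a.n_rings >= 1

    def test_exclusive_potency_profile_rules(self):
        S1, S2, S3 = "c1ccccc1", "c1ccncc1", "c1ccsc1"
        assignments = [
            ScaffoldAssignment("a", S1, "K", 1),
            ScaffoldAssignment("b", S1, "K", 1),
            ScaffoldAssignment("c", S2, "K", 1),
            ScaffoldAssignment("d", S3, "K", 1),
        ]
        outcomes = {k: ACTIVE for k in "abcd"}
        s = summarize_scaffolds(assignments, outcomes)
        potencies = {
            "a": PotencyRecord("a", 5.67, 1),
            "b": PotencyRecord("b", 9.10, 1),
            "c": PotencyRecord("c", 9.19, 1),
            # "d" was dropped by the one-log-order rule: S3 must vanish
        }
        prof = exclusive_potency_profile(s, potencies).set_index("scaffold")
        assert prof.loc[S1, "pic50_min"] == pytest.approx(5.67)
        assert prof.loc[S1, "pic50_max"] == pytest.approx(9.10)
        assert prof.loc[S2, "n_compounds"] == 1
        assert prof.loc[S2, "pic50_min"] == pytest.approx(9.19)
        assert S3 not in prof.index
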