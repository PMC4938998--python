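"""Fragment-and-index MMP generation, size rules, dedup and cliffs."""

import itertools

import pytest
from rdkit import Chem

from moacliff.chem_io import ACTIVE, INACTIVE
from moacliff.mmp import (
    ACTIVE_MMP,
    ACTIVITY_CLIFF,
    INACTIVE_MMP,
    MatchedPair,
    build_network,
    classify,
    deduplicate,
    enumerate_fragmentations,
    generate_mmps,
    index_pairs,
    size_filter,
    write_graphml,
    write_sif,
)
from moacliff.synthetic import DEFAULT_VOCABULARY, _attach


def canon(s):
    return Chem.CanonSmiles(s)


def mp(left="A", right="B", core_heavy=10, fl=1, fr=2, **kw):
    return MatchedPair(
        cid_left=left, cid_right=right, core="[*]C", frag_left="[*]F1",
        frag_right="[*]F2", core_heavy=core_heavy, frag_left_heavy=fl,
        frag_right_heavy=fr, **kw,
    )


class TestFragmentation:
    def test_ethylbenzene_single_cuts(self):
        frags = enumerate_fragmentations("CCc1ccccc1", cid="x")
        splits = {(f.core, f.fragment) for f in frags}
        assert (canon("*c1ccccc1"), canon("*CC")) in splits
        assert (canon("*Cc1ccccc1"), canon("*C")) in splits
        assert len(frags) == 2

    def test_benzene_has_no_cuts(self):
        assert enumerate_fragmentations("c1ccccc1") == []

    def test_pentylbenzene_five_cuts(self):
        frags = enumerate_fragmentations("CCCCCc1ccccc1")
        assert len(frags) == 5

    def test_tie_emits_both_orientations(self):
        frags = enumerate_fragmentations("c1ccc(-c2ccccc2)cc1")
        assert len(frags) == 2
        assert {f.core for f in frags} == {canon("*c1ccccc1")}
        assert all(f.core_heavy == f.frag_heavy == 6 for f in frags)

    def test_heavy_atom_conservation(self):
        for smiles in ["CCc1ccccc1", "CC(=O)Nc1ccc(O)cc1", "CCCCCc1ccccc1"]:
            parent = Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()
            for f in enumerate_fragmentations(smiles, max_cuts=2):
                assert f.core_heavy + f.frag_heavy == parent

    def test_double_cut_produces_linker_fragment(self):
        # ring-CH2-CH2-ring: cutting both attachment bonds exchanges the linker
        frags = enumerate_fragmentations("c1ccc(CCc2ccccc2)cc1", max_cuts=2)
        doubles = [f for f in frags if f.n_cuts == 2]
        assert any(f.frag_heavy == 2 and f.core_heavy == 12 for f in doubles)

    def test_invalid_max_cuts(self):
        with pytest.raises(ValueError):
            enumerate_fragmentations("CC", max_cuts=3)

    def test_parse_error_propagates(self):
        with pytest.raises(ValueError):
            enumerate_fragmentations("not_a_molecule")


class TestIndexing:
    def test_toluene_ethylbenzene_pair(self):
        frags = enumerate_fragmentations("Cc1ccccc1", cid="T") + enumerate_fragmentations(
            "CCc1ccccc1", cid="E"
        )
        pairs = index_pairs(frags)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.key == ("E", "T")
        assert p.core == canon("*c1ccccc1")
        assert {p.frag_left, p.frag_right} == {canon("*C"), canon("*CC")}

    def test_single_compound_never_pairs(self):
        frags = enumerate_fragmentations("CCCCc1ccccc1", cid="A")
        assert index_pairs(frags) == []

    def test_planted_series_yields_all_pairs(self):
        template = "[*:1]c1ccc2ccccc2c1"
        cids = {}
        frags = []
        for i, sub in enumerate(DEFAULT_VOCABULARY[:10]):
            cid = f"S{i}"
            cids[cid] = _attach(template, sub)
            frags.extend(enumerate_fragmentations(cids[cid], cid=cid))
        pairs = index_pairs(frags)
        assert len({p.key for p in pairs}) == 45  # C(10,2)
        core = canon(template.replace("[*:1]", "*"))
        attachment_pairs = [p for p in pairs if p.core == core]
        assert len(attachment_pairs) == 45


class TestSizeFilter:
    @pytest.mark.parametrize(
        "core,fl,fr,retained,reason",
        [
            (10, 5, 5, True, None),           # boundary: exactly twice
            (20, 14, 2, False, "fragment_max_atoms"),
            (30, 1, 10, False, "fragment_delta_atoms"),  # diff 9 > 8
            (30, 13, 13, True, None),         # 13-atom fragments allowed
            (9, 5, 1, False, "core_twice_fragment"),
            (30, 5, 13, True, None),          # diff exactly 8 allowed
        ],
    )
    def test_rules(self, core, fl, fr, retained, reason):
        ok, why = size_filter(mp(core_heavy=core, fl=fl, fr=fr))
        assert ok is retained
        assert why == reason


class TestDeduplication:
    def test_smallest_deviation_wins(self):
        a = mp(fl=3, fr=5)  # delta 2
        b = mp(fl=4, fr=4)  # delta 0
        assert deduplicate([a, b], seed=0) == [b]

    def test_tie_broken_reproducibly(self):
        a = mp(fl=3, fr=4)
        b = MatchedPair("A", "B", "[*]CC", "[*]X", "[*]Y", 10, 4, 5)
        first = deduplicate([a, b], seed=11)
        assert deduplicate([a, b], seed=11) == first
        assert len(first) == 1

    def test_count_independent_of_seed(self):
        groups = [
            mp("A", "B", fl=1, fr=2), mp("A", "B", fl=2, fr=3),
            mp("C", "D", fl=1, fr=1),
            MatchedPair("C", "D", "[*]N", "[*]X", "[*]Y", 8, 2, 2),
        ]
        counts = {len(deduplicate(groups, seed=s)) for s in range(10)}
        assert counts == {2}


class TestClassification:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (INACTIVE, INACTIVE, INACTIVE_MMP),
            (ACTIVE, ACTIVE, ACTIVE_MMP),
            (ACTIVE, INACTIVE, ACTIVITY_CLIFF),
            (INACTIVE, ACTIVE, ACTIVITY_CLIFF),
        ],
    )
    def test_categories(self, left, right, expected):
        assert classify(mp(), {"A": left, "B": right}) == expected

    def test_missing_outcome_raises(self):
        with pytest.raises(KeyError):
            classify(mp(), {"A": ACTIVE})


class TestNetwork:
    def test_nodes_edges_and_files(self, tmp_path):
        pairs = [
            mp("A", "B", category=ACTIVITY_CLIFF),
            mp("A", "C", category=INACTIVE_MMP),
            mp("C", "D", category=ACTIVE_MMP),
        ]
        g = build_network(pairs, {"A": ACTIVE, "B": INACTIVE, "C": INACTIVE, "D": ACTIVE})
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3
        assert g.nodes["A"]["outcome"] == ACTIVE
        write_graphml(g, tmp_path / "net.graphml")
        write_sif(g, tmp_path / "net.sif")
        assert len((tmp_path / "net.sif").read_text().splitlines()) == 3

    def test_empty_network(self, tmp_path):
        g = build_network([])
        assert g.number_of_nodes() == 0
        write_graphml(g, tmp_path / "empty.graphml")
        assert (tmp_path / "empty.graphml").exists()

    def test_planted_hub_degree(self):
        pairs = [mp("HUB", f"N{i}", category=ACTIVITY_CLIFF) for i in range(6)]
        g = build_network(pairs)
        assert max(dict(g.degree).values()) == g.degree["HUB"] == 6


class TestPipelineProperties:
    def test_index_equals_bruteforce_on_small_library(self):
        """Fragment-and-index must agree with all-pairs comparison."""
        smiles_by_cid = {}
        templates = ["[*:1]c1ccc2ccccc2c1", "[*:1]c1ccc2c(c1)CCO2"]
        i = 0
        for t in templates:
            for sub in DEFAULT_VOCABULARY[:8]:
                smiles_by_cid[f"M{i:02d}"] = _attach(t, sub)
                i += 1
        frags = {
            cid: enumerate_fragmentations(s, cid=cid)
            for cid, s in smiles_by_cid.items()
        }
        indexed = {p.key for p in index_pairs(itertools.chain.from_iterable(frags.values()))}
        brute = set()
        for a, b in itertools.combinations(sorted(smiles_by_cid), 2):
            if any(
                fa.core == fb.core and fa.fragment != fb.fragment
                for fa in frags[a]
                for fb in frags[b]
            ):
                brute.add((a, b))
        assert indexed == brute

    def test_pair_set_invariant_under_input_order(self, small_curated):
        datasets, _ = small_curated
        ds = datasets["agonist"]
        smiles = ds.smiles_by_cid()
        reversed_smiles = dict(reversed(list(smiles.items())))
        a = {p.key for p in generate_mmps(smiles, seed=3).pairs}
        b = {p.key for p in generate_mmps(reversed_smiles, seed=3).pairs}
        assert a == b

    def test_category_partition(self, small_curated):
        datasets, _ = small_curated
        ds = datasets["agonist"]
        result = generate_mmps(ds.smiles_by_cid(), outcomes=ds.outcome_by_cid(), seed=0)
        counts = result.category_counts
        assert sum(counts.values()) == len(result.pairs)
        assert set(counts) == {INACTIVE_MMP, ACTIVE_MMP, ACTIVITY_CLIFF}
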