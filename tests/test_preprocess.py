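"""Curation pipeline stages, audit trail and potency aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moacliff.chem_io import (
    ACTIVE,
    INACTIVE,
    MISSING,
    OTHER,
    AssayDataset,
    CompoundRecord,
)
from moacliff.preprocess import (
    STAGE_ORDER,
    aggregate_dataset_potencies,
    aggregate_potency,
    collapse_redundant,
    drop_discrepant,
    filter_missing_readouts,
    keep_binary_outcomes,
    remove_mixtures,
    remove_ringless,
    run_pipeline,
)


def rec(sid, cid, smiles="c1ccccc1", outcome=ACTIVE, potencies=()):
    return CompoundRecord(sid=sid, cid=cid, smiles=smiles, outcome=outcome,
                          potencies=tuple(potencies))


def ds(*records):
    return AssayDataset(records=list(records))


class TestStages:
    def test_missing_readouts_removed_with_audit(self):
        out = filter_missing_readouts(
            ds(rec("1", "A"), rec("2", "B", outcome=MISSING), rec("3", "C"))
        )
        assert [r.cid for r in out.records] == ["A", "C"]
        a = out.audit[0]
        assert (a.stage, a.n_before, a.n_removed, a.n_after) == (STAGE_ORDER[0], 3, 1, 2)

    def test_no_missing_is_identity_with_zero_audit(self):
        out = filter_missing_readouts(ds(rec("1", "A"), rec("2", "B")))
        assert out.audit[0].n_removed == 0
        assert len(out) == 2

    def test_redundant_sids_collapse_and_merge_potencies(self):
        out = collapse_redundant(
            ds(rec("1", "A", potencies=(1.0,)), rec("2", "A", potencies=(2.0,)),
               rec("3", "B", outcome=INACTIVE))
        )
        assert len(out) == 2
        merged = next(r for r in out.records if r.cid == "A")
        assert merged.potencies == (1.0, 2.0)
        assert out.n_cids() == 2  # unique-CID count unchanged

    def test_discrepant_cid_removed_entirely(self):
        out = drop_discrepant(
            ds(rec("1", "A"), rec("2", "A", outcome=INACTIVE),
               rec("3", "B"), rec("4", "B"))
        )
        assert {r.cid for r in out.records} == {"B"}
        assert out.audit[0].n_removed == 2

    def test_other_outcomes_removed(self):
        out = keep_binary_outcomes(
            ds(rec("1", "A"), rec("2", "B", outcome=OTHER), rec("3", "C", outcome=INACTIVE))
        )
        assert {r.outcome for r in out.records} == {ACTIVE, INACTIVE}

    def test_mixtures_removed(self):
        out = remove_mixtures(ds(rec("1", "A", smiles="CCO.Cl"), rec("2", "B", smiles="CCO")))
        assert [r.cid for r in out.records] == ["B"]

    def test_unparseable_structure_removed_at_mixture_stage(self, caplog):
        with caplog.at_level("WARNING"):
            out = remove_mixtures(ds(rec("1", "A", smiles="not_a_molecule"), rec("2", "B")))
        assert [r.cid for r in out.records] == ["B"]
        assert "A" in caplog.text

    def test_ringless_removed(self):
        out = remove_ringless(ds(rec("1", "A", smiles="CCCCCC"), rec("2", "B")))
        assert [r.cid for r in out.records] == ["B"]


class TestPipeline:
    def make_library(self):
        """21 records: 2 missing, 1 discrepant CID (2 records), 1 mixture,
        1 acyclic; 15 clean survivors by hand count (21 - 6 removals)."""
        records = [rec(str(i), f"C{i:02d}", outcome=INACTIVE) for i in range(15)]
        records += [
            rec("15", "C15"),  # active survivor -> 16 ring compounds, 1 acyclic below
            rec("m1", "M1", outcome=MISSING),
            rec("m2", "M2", outcome=MISSING),
            rec("d1", "D1", outcome=ACTIVE),
            rec("d2", "D1", outcome=INACTIVE),
            rec("x1", "X1", smiles="CCO.Cl"),
        ]
        # swap one clean record to an acyclic structure
        records[0] = rec("0", "C00", smiles="CCCCCC", outcome=INACTIVE)
        return ds(*records)

    def test_hand_counted_removals(self):
        out = run_pipeline(self.make_library())
        assert len(out) == 15
        removed = {a.stage: a.n_removed for a in out.audit}
        assert removed == {
            STAGE_ORDER[0]: 2, STAGE_ORDER[1]: 0, STAGE_ORDER[2]: 2,
            STAGE_ORDER[3]: 0, STAGE_ORDER[4]: 1, STAGE_ORDER[5]: 1,
        }

    def test_clean_library_is_identity(self):
        out = run_pipeline(ds(rec("1", "A"), rec("2", "B", outcome=INACTIVE)))
        assert len(out) == 2
        assert len(out.audit) == 6
        assert all(a.n_removed == 0 for a in out.audit)

    def test_audit_conservation_monotonicity_and_stage_order(self, small_curated):
        datasets, _ = small_curated
        for out in datasets.values():
            assert tuple(a.stage for a in out.audit) == STAGE_ORDER
            for a in out.audit:
                assert a.n_before - a.n_removed == a.n_after
            n_afters = [a.n_after for a in out.audit]
            assert all(x >= y for x, y in zip(n_afters, n_afters[1:]))
            assert len(out) == out.audit[-1].n_after


class TestPotency:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1.0], 6.0),
            ([1.0, 0.316227766], 6.25),
            ([10.0, 0.1], None),            # spread 2.0 > 1 log order
            ([1.0, 10.0], 5.5),             # spread exactly 1.0: inclusive
            ([1.0, 10.000001], None),       # just past the boundary
        ],
    )
    def test_aggregation_branches(self, values, expected):
        got = aggregate_potency(values)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_potency([1.0, -2.0])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=-3.0, max_value=3.0,
                           allow_nan=False, allow_infinity=False),
                 min_size=1, max_size=6),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, logs, rnd):
        values = [10.0 ** x for x in logs]
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a, b = aggregate_potency(values), aggregate_potency(shuffled)
        if a is None or b is None:
            assert a is None and b is None
        else:
            assert math.isclose(a, b, rel_tol=1e-12)

    def test_dataset_aggregation_on_toy(self, toy):
        ag, _, truth = toy
        clean = run_pipeline(ag)
        records, dropped = aggregate_dataset_potencies(clean)
        assert records["P1"].pic50 == pytest.approx(6.25)
        assert records["P1"].n_merged == 2
        assert dropped == truth["dropped_potency"]
        # only Active compounds are profiled
        assert all(clean.outcome_by_cid()[c] == ACTIVE for c in records)
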