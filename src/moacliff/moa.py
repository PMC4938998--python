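"""Cross-assay mechanism-of-action (MOA) analysis and MOA-cliffs.

Compounds screened in both an agonist and an antagonist assay carry a
pair of binary outcomes, reduced to a *label set*: {agonist} for
agonist-only actives, {antagonist} for antagonist-only actives, and
{agonist, antagonist} for dual-action compounds.  Compounds inactive in
both screens are removed first — they carry no mechanism label.

An MMP between two labelled compounds is classified by the relation of
the two label sets:

* equal sets      → same MOA;
* overlapping but unequal (one member is dual-action) → weak MOA-cliff;
* disjoint sets   → strong MOA-cliff (fully opposite mechanism).

The classification is symmetric in the pair by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem_io import ACTIVE, INACTIVE, AssayDataset
from .mmp import MatchedPair, generate_mmps

__all__ = [
    "SAME_MOA",
    "WEAK_CLIFF",
    "STRONG_CLIFF",
    "MoaProfile",
    "MoaPair",
    "intersect",
    "drop_both_inactive",
    "dual_action",
    "classify_moa",
    "moa_mmp_pipeline",
]

SAME_MOA = "same_moa"
WEAK_CLIFF = "weak_cliff"
STRONG_CLIFF = "strong_cliff"

AGONIST_LABEL = "agonist"
ANTAGONIST_LABEL = "antagonist"


@dataclass(frozen=True)
class MoaProfile:
    """A common compound's outcome pair across the two screens."""

    cid: str
    agonist_outcome: str
    antagonist_outcome: str

    @property
    def label_set(self) -> frozenset[str]:
        labels = set()
        if self.agonist_outcome == ACTIVE:
            labels.add(AGONIST_LABEL)
        if self.antagonist_outcome == ACTIVE:
            labels.add(ANTAGONIST_LABEL)
        return frozenset(labels)


@dataclass(frozen=True)
class MoaPair:
    pair: MatchedPair
    left: MoaProfile
    right: MoaProfile
    moa_category: str

    @property
    def outcome_pattern(self) -> tuple[str, str, str, str]:
        """(left agonist, left antagonist, right agonist, right antagonist),
        with the two sides ordered canonically so patterns aggregate."""
        a = (self.left.agonist_outcome, self.left.antagonist_outcome)
        b = (self.right.agonist_outcome, self.right.antagonist_outcome)
        lo, hi = sorted([a, b])
        return (*hi, *lo)


def intersect(agonist: AssayDataset, antagonist: AssayDataset) -> list[MoaProfile]:
    """One profile per CID present, with a binary outcome, in both curated sets."""
    ag = agonist.outcome_by_cid()
    ant = antagonist.outcome_by_cid()
    profiles = []
    for cid in ag:
        if cid not in ant:
            continue
        if ag[cid] in (ACTIVE, INACTIVE) and ant[cid] in (ACTIVE, INACTIVE):
            profiles.append(
                MoaProfile(cid=cid, agonist_outcome=ag[cid], antagonist_outcome=ant[cid])
            )
    return profiles


def drop_both_inactive(profiles: list[MoaProfile]) -> list[MoaProfile]:
    """Remove compounds inactive in both screens (empty label set)."""
    return [p for p in profiles if p.label_set]


def dual_action(profiles: list[MoaProfile]) -> list[MoaProfile]:
    """Compounds reported active in both screens simultaneously."""
    return [p for p in profiles if len(p.label_set) == 2]


def classify_moa(left: frozenset[str], right: frozenset[str]) -> str:
    """Classify a pair of non-empty label sets (symmetric)."""
    if not left or not right:
        raise ValueError("label sets must be non-empty after both-inactive removal")
    if left == right:
        return SAME_MOA
    if left & right:
        return WEAK_CLIFF
    return STRONG_CLIFF


def moa_mmp_pipeline(
    profiles: list[MoaProfile],
    smiles_by_cid: dict[str, str],
    max_cuts: int = 1,
    seed: int = 0,
    **mmp_kwargs,
) -> tuple[list[MoaPair], pd.DataFrame]:
    """MMPs over the labelled common compounds, classified by MOA relation.

    Runs the standard size-restricted MMP generation (same filters and
    dedup rule as the per-assay analysis) on the profiled compounds
    only, then classifies each pair.  Returns the pairs and a summary
    table of counts per MOA category and outcome pattern.
    """
    by_cid = {p.cid: p for p in profiles}
    subset = {cid: smiles_by_cid[cid] for cid in by_cid}
    result = generate_mmps(subset, outcomes=None, max_cuts=max_cuts, seed=seed, **mmp_kwargs)
    moa_pairs = []
    for mp in result.pairs:
        left, right = by_cid[mp.cid_left], by_cid[mp.cid_right]
        moa_pairs.append(
            MoaPair(
                pair=mp,
                left=left,
                right=right,
                moa_category=classify_moa(left.label_set, right.label_set),
            )
        )
    counts: dict[tuple[str, tuple[str, str, str, str]], int] = {}
    for p in moa_pairs:
        counts[(p.moa_category, p.outcome_pattern)] = (
            counts.get((p.moa_category, p.outcome_pattern), 0) + 1
        )
    order = {SAME_MOA: 0, WEAK_CLIFF: 1, STRONG_CLIFF: 2}
    rows = [
        {
            "moa_category": cat,
            "left_agonist": pat[0],
            "left_antagonist": pat[1],
            "right_agonist": pat[2],
            "right_antagonist": pat[3],
            "n_mmps": n,
        }
        for (cat, pat), n in sorted(
            counts.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
        )
    ]
    summary = pd.DataFrame(
        rows,
        columns=[
            "moa_category",
            "left_agonist",
            "left_antagonist",
            "right_agonist",
            "right_antagonist",
            "n_mmps",
        ],
    )
    return moa_pairs, summary
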