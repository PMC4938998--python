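"""Published summary counts of the PubChem AR Tox21 screens.

The agonist screen is PubChem AID 743053, the antagonist screen AID
743063.  The numbers below are the published per-stage and per-category
counts for those deposits; they serve as inputs for consistency
identities (ratios, partitions, differences) that the pipeline's own
summaries must satisfy on any dataset.  Reproducing the counts
themselves requires the deposited data, which this package reads from
local files but does not ship.
"""

from __future__ import annotations

REPORTED = {
    "agonist": {
        "n_compounds": 4162,
        "n_active": 172,
        "n_inactive": 3990,
        "n_scaffolds": 1571,
        "n_scaffolds_active": 72,
        "n_scaffolds_inactive": 1521,
        "n_csks": 895,
        "n_mmps": 9695,
        "n_inactive_mmps": 9462,
        "n_active_mmps": 141,
        "n_activity_cliffs": 92,
        "n_overlap_scaffolds": 22,
        "n_exclusive_active_scaffolds": 50,
    },
    "antagonist": {
        "n_compounds": 3563,
        "n_active": 322,
        "n_inactive": 3241,
        "n_scaffolds": 1384,
        "n_csks": 814,
        "n_mmps": 8049,
        "n_inactive_mmps": 7623,
        "n_active_mmps": 94,
        "n_activity_cliffs": 332,
    },
    "combined": {
        "n_common": 3293,
        "n_both_inactive": 3008,
        "n_labelled": 285,
        "n_single_moa": 240,
        "n_dual_active": 45,
        "n_moa_mmps": 78,
        "n_same_moa": 64,
        "n_same_moa_patterns": (17, 26, 21),
        "n_weak_cliffs": 13,
        "n_weak_cliff_patterns": (7, 6),
        "n_strong_cliffs": 1,
    },
}


def mean_compounds_per_scaffold(assay: str = "agonist") -> float:
    r = REPORTED[assay]
    return r["n_compounds"] / r["n_scaffolds"]


def inactive_to_active_ratio(assay: str = "agonist") -> float:
    r = REPORTED[assay]
    return r["n_inactive"] / r["n_active"]


def labelled_common_compounds() -> int:
    c = REPORTED["combined"]
    return c["n_common"] - c["n_both_inactive"]


def dual_active_count() -> int:
    c = REPORTED["combined"]
    return c["n_labelled"] - c["n_single_moa"]


def moa_mmp_total() -> int:
    c = REPORTED["combined"]
    return c["n_same_moa"] + c["n_weak_cliffs"] + c["n_strong_cliffs"]


def weak_cliff_total() -> int:
    return sum(REPORTED["combined"]["n_weak_cliff_patterns"])
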