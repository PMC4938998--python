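"""Scaffold, cyclic-skeleton and diversity statistics of the curated sets.

Decomposes every curated compound into its Bemis–Murcko scaffold and
CSK, summarizes scaffold frequency, singleton fraction, ring counts and
the active/inactive exclusivity partition, profiles potencies over the
exclusively-active scaffolds, and computes per-group diversity indices.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from moacliff.chem_io import ACTIVE, AGONIST, ANTAGONIST, INACTIVE, read_bioassay_table
from moacliff.diversity import FINGERPRINT_DIALECT, diversity_index, fingerprint
from moacliff.preprocess import aggregate_dataset_potencies
from moacliff.scaffolds import assign_scaffolds, exclusive_potency_profile, summarize_scaffolds

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    rows = []
    for assay in (AGONIST, ANTAGONIST):
        ds = read_bioassay_table(OUT / f"{assay}_clean.csv", source_assay=assay)
        outcomes = ds.outcome_by_cid()
        assignments = assign_scaffolds(ds)
        pd.DataFrame([asdict(a) for a in assignments]).to_csv(
            OUT / f"{assay}_scaffolds.csv", index=False
        )
        s = summarize_scaffolds(assignments, outcomes)
        smiles = ds.smiles_by_cid()
        dis = {}
        for split in (ACTIVE, INACTIVE):
            cids = [c for c, o in outcomes.items() if o == split]
            dis[split] = diversity_index([fingerprint(smiles[c]) for c in cids]) if len(cids) > 1 else float("nan")
        potencies, dropped = aggregate_dataset_potencies(ds)
        profile = exclusive_potency_profile(s, potencies)
        profile.to_csv(OUT / f"{assay}_exclusive_scaffolds.csv", index=False)
        rows.append(
            {
                "assay": assay,
                "n_compounds": ds.n_cids(),
                "n_scaffolds": s.n_scaffolds,
                "n_csks": s.n_csks,
                "singleton_fraction": round(s.singleton_fraction, 3),
                "n_exclusive_active": len(s.exclusive_active),
                "n_overlap": len(s.overlap),
                "di_active": round(dis[ACTIVE], 3),
                "di_inactive": round(dis[INACTIVE], 3),
            }
        )
        print(
            f"{assay}: {ds.n_cids()} compounds on {s.n_scaffolds} scaffolds "
            f"({s.n_csks} CSKs); {s.singleton_fraction:.0%} singleton scaffolds; "
            f"{len(s.exclusive_active)} exclusively active "
            f"({len(profile)} with usable potency, {len(dropped)} compounds "
            f"potency-disqualified); DI[{FINGERPRINT_DIALECT}] "
            f"active={dis[ACTIVE]:.2f} inactive={dis[INACTIVE]:.2f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "table1_summary.csv", index=False)


if __name__ == "__main__":
    main()
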