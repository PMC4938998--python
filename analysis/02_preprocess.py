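"""Curate both raw assay exports through the six-stage filter chain.

Reads the raw CSVs from step 01, applies the curation pipeline
(missing readouts, redundant SIDs, discrepant CIDs, non-binary
outcomes, mixtures, ring-less structures) and checks the audit trail
against the injected-artifact ground truth.
"""

import json
from pathlib import Path

from moacliff.chem_io import AGONIST, ANTAGONIST, read_bioassay_table, write_dataset, write_table
from moacliff.preprocess import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    truth = json.loads((OUT / "ground_truth.json").read_text())
    for assay in (AGONIST, ANTAGONIST):
        raw = read_bioassay_table(OUT / f"{assay}_raw.csv", source_assay=assay)
        clean = run_pipeline(raw)
        write_dataset(clean, OUT / f"{assay}_clean.csv")
        write_table(clean.audit_dataframe(), OUT / f"{assay}_audit.csv")
        expected = [tuple(x) for x in truth["expected_audit"][assay]]
        got = [(a.stage, a.n_removed) for a in clean.audit]
        status = "matches" if got == expected else "DIVERGES FROM"
        print(f"{assay}: {len(raw)} records -> {clean.n_cids()} compounds; "
              f"audit {status} injected artifacts")
        for row in clean.audit:
            print(f"  {row.stage:22s} {row.n_before:4d} -> {row.n_after:4d} "
                  f"(removed {row.n_removed})")


if __name__ == "__main__":
    main()
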