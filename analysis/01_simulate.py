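"""Generate the synthetic paired agonist/antagonist screen.

Builds a seeded two-assay screening library at study-condition scale
(500 ring compounds over 50 scaffold templates, artifact rates mirroring
the attrition of the published AR Tox21 screens) and writes the raw
exports plus the analytic ground truth that the later steps are judged
against.
"""

import json
from pathlib import Path

from moacliff.chem_io import write_dataset
from moacliff.synthetic import SimulationConfig, generate_library

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    ag, ant, truth = generate_library(config)
    write_dataset(ag, OUT / "agonist_raw.csv")
    write_dataset(ant, OUT / "antagonist_raw.csv")
    gt = {
        "seed": SEED,
        "expected_audit": truth.expected_audit,
        "final_cids": {a: sorted(s) for a, s in truth.final_cids.items()},
        "mmp_pairs": {a: sorted(map(list, s)) for a, s in truth.mmp_pairs.items()},
        "activity_cliffs": {a: sorted(map(list, s)) for a, s in truth.activity_cliffs.items()},
        "dual_active_cids": sorted(truth.dual_active_cids),
        "moa_pairs": [[a, b, c] for (a, b), c in sorted(truth.moa_pairs.items())],
        "planted_strong": [list(p) for p in truth.planted_strong],
        "planted_weak": [list(p) for p in truth.planted_weak],
    }
    (OUT / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    print(f"wrote {len(ag)} agonist and {len(ant)} antagonist records to {OUT}")
    print(f"library: {len(truth.compounds)} compounds, "
          f"{len(truth.dual_active_cids)} dual actives, "
          f"{len(truth.planted_strong)} planted strong and "
          f"{len(truth.planted_weak)} planted weak MOA-cliff pairs")


if __name__ == "__main__":
    main()
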