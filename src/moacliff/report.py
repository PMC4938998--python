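"""End-to-end orchestration: curation → scaffolds → MMPs → MOA → tables.

``run_all`` drives the whole pipeline over a pair of assay inputs
(local CSV exports or the synthetic generator) and writes the summary
tables underpinning the analysis: a dataset/scaffold/diversity summary,
per-assay MMP category tables, the MOA category table, scaffold ring
histograms, exclusive-scaffold potency profiles, dual-action compounds,
MMP networks, per-stage audit trails and a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .chem_io import (
    ACTIVE,
    AGONIST,
    ANTAGONIST,
    INACTIVE,
    AssayDataset,
    Dialect,
    read_bioassay_table,
    write_table,
)
from .diversity import FINGERPRINT_DIALECT, diversity_index, fingerprint
from .mmp import build_network, generate_mmps, write_graphml, write_sif
from .moa import drop_both_inactive, dual_action, intersect, moa_mmp_pipeline
from .preprocess import aggregate_dataset_potencies, run_pipeline
from .scaffolds import (
    assign_scaffolds,
    exclusive_potency_profile,
    summarize_scaffolds,
)
from .synthetic import SimulationConfig, generate_library

__all__ = ["run_all", "summarize_table1"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarize_table1(
    datasets: dict[str, AssayDataset],
    summaries: dict,
    dis: dict[str, dict[str, float | None]],
) -> pd.DataFrame:
    """Dataset summary: compounds, scaffolds, CSKs and DI per assay,
    split into total / Active / Inactive."""
    rows = []
    for assay, ds in datasets.items():
        outcomes = ds.outcome_by_cid()
        summary = summaries[assay]["all"]
        for split in ("total", ACTIVE, INACTIVE):
            if split == "total":
                sub = summary
                n_comp = ds.n_cids()
            else:
                sub = summaries[assay][split]
                n_comp = sum(1 for o in outcomes.values() if o == split)
            rows.append(
                {
                    "assay": assay,
                    "split": split,
                    "n_compounds": n_comp,
                    "n_scaffolds": sub.n_scaffolds,
                    "n_csks": sub.n_csks,
                    "diversity_index": dis[assay].get(split),
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: dict) -> tuple[AssayDataset, AssayDataset, object | None]:
    inputs = config.get("inputs", {})
    if "agonist" in inputs and "antagonist" in inputs:
        dialect = (
            Dialect.from_dict(config["dialect"]) if "dialect" in config else Dialect()
        )
        ag = read_bioassay_table(inputs["agonist"], dialect, source_assay=AGONIST)
        ant = read_bioassay_table(inputs["antagonist"], dialect, source_assay=ANTAGONIST)
        return ag, ant, None
    sim_kwargs = dict(config.get("simulation", {}))
    sim_kwargs.setdefault("seed", config.get("seed", 0))
    sim = SimulationConfig(**sim_kwargs)
    ag, ant, truth = generate_library(sim)
    return ag, ant, truth


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    ``config`` keys: ``inputs`` (paths to agonist/antagonist CSVs) or
    ``simulation`` (:class:`SimulationConfig` fields); ``dialect``;
    ``seed`` (MMP tie-break and default simulation seed); ``max_cuts``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    max_cuts = int(config.get("max_cuts", 1))

    raw_ag, raw_ant, _truth = _load_inputs(config)
    datasets: dict[str, AssayDataset] = {}
    stage_log: list[dict] = []
    for assay, raw in ((AGONIST, raw_ag), (ANTAGONIST, raw_ant)):
        ds = run_pipeline(raw)
        datasets[assay] = ds
        for row in ds.audit:
            logger.info(
                "%s/%s: %d -> %d (removed %d)",
                assay, row.stage, row.n_before, row.n_after, row.n_removed,
            )
        write_table(ds.audit_dataframe(), out / f"audit_{assay}.csv")
        write_table(ds.to_dataframe(), out / f"clean_{assay}.csv")
        stage_log.append({"stage": f"preprocess_{assay}", "n_records": len(ds)})

    # Scaffolds, CSKs, diversity.
    summaries: dict = {}
    dis: dict = {}
    hist_rows = []
    excl_frames = []
    for assay, ds in datasets.items():
        outcomes = ds.outcome_by_cid()
        assignments = assign_scaffolds(ds)
        write_table(
            pd.DataFrame([asdict(a) for a in assignments]),
            out / f"scaffolds_{assay}.csv",
        )
        summary = summarize_scaffolds(assignments, outcomes)
        by_split = {"all": summary}
        for split in (ACTIVE, INACTIVE):
            sub = [a for a in assignments if outcomes[a.cid] == split]
            by_split[split] = summarize_scaffolds(sub, outcomes)
        summaries[assay] = by_split
        for n_rings, count in sorted(summary.ring_histogram.items()):
            hist_rows.append({"assay": assay, "n_rings": n_rings, "n_scaffolds": count})

        smiles = ds.smiles_by_cid()
        dis[assay] = {}
        for split in (ACTIVE, INACTIVE):
            cids = [c for c, o in outcomes.items() if o == split]
            dis[assay][split] = (
                diversity_index([fingerprint(smiles[c]) for c in cids])
                if len(cids) >= 2
                else None
            )

        potencies, dropped = aggregate_dataset_potencies(ds)
        profile = exclusive_potency_profile(summary, potencies)
        profile.insert(0, "assay", assay)
        excl_frames.append(profile)
        stage_log.append(
            {"stage": f"scaffolds_{assay}", "n_scaffolds": summary.n_scaffolds,
             "n_csks": summary.n_csks, "n_potency_dropped": len(dropped)}
        )
    write_table(pd.DataFrame(hist_rows), out / "fig1_hist.csv")
    non_empty = [f for f in excl_frames if not f.empty]
    write_table(
        pd.concat(non_empty, ignore_index=True) if non_empty else excl_frames[0],
        out / "exclusive_scaffolds.csv",
    )
    write_table(summarize_table1(datasets, summaries, dis), out / "table1.csv")

    # Per-assay MMPs and activity cliffs.
    table2_rows = []
    for assay, ds in datasets.items():
        outcomes = ds.outcome_by_cid()
        result = generate_mmps(
            ds.smiles_by_cid(), outcomes=outcomes, max_cuts=max_cuts, seed=seed
        )
        pairs_df = pd.DataFrame(
            [
                {
                    "cid_left": p.cid_left,
                    "cid_right": p.cid_right,
                    "core": p.core,
                    "frag_left": p.frag_left,
                    "frag_right": p.frag_right,
                    "delta_heavy": p.delta_heavy,
                    "category": p.category,
                }
                for p in result.pairs
            ]
        )
        write_table(pairs_df, out / f"mmps_{assay}.csv")
        g = build_network(result.pairs, outcomes)
        write_graphml(g, out / f"network_{assay}.graphml")
        write_sif(g, out / f"network_{assay}.sif")
        for category, n in result.category_counts.items():
            table2_rows.append({"assay": assay, "category": category, "n_mmps": n})
        stage_log.append({"stage": f"mmp_{assay}", "n_mmps": len(result.pairs)})
    write_table(pd.DataFrame(table2_rows), out / "table2.csv")

    # Cross-assay MOA analysis.
    profiles = drop_both_inactive(intersect(datasets[AGONIST], datasets[ANTAGONIST]))
    smiles_all = {**datasets[ANTAGONIST].smiles_by_cid(), **datasets[AGONIST].smiles_by_cid()}
    write_table(
        pd.DataFrame(
            [{"cid": p.cid, "agonist_outcome": p.agonist_outcome,
              "antagonist_outcome": p.antagonist_outcome} for p in dual_action(profiles)]
        ),
        out / "dual_action.csv",
    )
    moa_pairs, table3 = moa_mmp_pipeline(profiles, smiles_all, max_cuts=max_cuts, seed=seed)
    write_table(
        pd.DataFrame(
            [
                {
                    "cid_left": p.pair.cid_left,
                    "cid_right": p.pair.cid_right,
                    "core": p.pair.core,
                    "frag_left": p.pair.frag_left,
                    "frag_right": p.pair.frag_right,
                    "moa_category": p.moa_category,
                }
                for p in moa_pairs
            ]
        ),
        out / "moa_pairs.csv",
    )
    write_table(table3, out / "table3.csv")
    stage_log.append({"stage": "moa", "n_profiles": len(profiles), "n_mmps": len(moa_pairs)})

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "max_cuts": max_cuts,
        "fingerprint_dialect": FINGERPRINT_DIALECT,
        "stages": stage_log,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
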