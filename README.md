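# moacliff

Cheminformatics analysis of paired agonist/antagonist high-throughput
screens: compound curation, Bemis–Murcko scaffold and cyclic-skeleton
statistics, size-restricted matched-molecular-pair (MMP) generation,
activity-cliff calling, and classification of cross-assay
mechanism-of-action (MOA) cliffs.

## Who this is for

Screens such as the Tox21 androgen-receptor pair (PubChem AID 743053,
agonist mode; AID 743063, antagonist mode) test one compound library in
two opposing-mechanism assays.  `moacliff` turns a pair of such
bioassay exports into the structural summaries a medicinal chemist asks
for: which scaffolds are exclusively active, where the
structure–activity relationship is discontinuous (activity cliffs), and
which near-identical compound pairs flip between agonism and antagonism
(MOA-cliffs).

## The methods at the core

**Curation.** Six filters in fixed order: records with missing
readouts; redundant records (same CID, same outcome, different SID —
collapsed, potency lists merged); CIDs with discrepant outcomes
(removed wholesale); non-binary annotations; mixtures (more than one
covalently connected component); ring-less structures.  Every stage
appends an audit row, so removed + kept always reconciles.

**Scaffolds.** The Bemis–Murcko scaffold keeps ring systems, linkers,
and atoms attached to them by bonds of order > 1; the cyclic skeleton
(CSK) additionally maps every atom to carbon and every bond to single
order, so topologically equivalent scaffolds coincide.  Potencies are
converted as pIC50 = −log10(IC50 [M]) = 6 − log10(IC50 [µM]); multiple
readings within one log order are averaged, wider spreads disqualify
the compound.

**MMPs.** Fragment-and-index: every acyclic single bond is cut, splits
are canonicalized, and compounds sharing an invariant core with
different exchanged fragments form candidate pairs, size-restricted so
that (1) the core has at least twice the heavy atoms of each exchanged
fragment, (2) a fragment has at most 13 heavy atoms, and (3) the two
fragments differ by at most 8 heavy atoms.  Multiple cuts for one
compound pair are reduced to the cut with the smallest fragment-size
deviation (seeded random tie-break).  With binary outcomes, a pair with
one Active and one Inactive member is an **activity cliff**.

**MOA-cliffs.** Compounds present in both curated screens carry a label
set ⊆ {agonist, antagonist} (both-inactive compounds are removed).  An
MMP between labelled compounds is *same-MOA* if the label sets are
equal, a *weak MOA-cliff* if they overlap but differ (one member is
dual-action), and a *strong MOA-cliff* if they are disjoint — a small
structural change flipping the mechanism outright.

## Worked example

The package ships a seeded synthetic generator that emulates the
paired-screen design with exact ground truth (`moacliff.synthetic`).
The numbered scripts under `analysis/` narrate the full pipeline over
one such screen:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_scaffolds_diversity.py
python analysis/04_mmp_cliffs.py
python analysis/05_moa_cliffs.py
```

which prints, among other lines:

```
agonist: 871 records -> 444 compounds; audit matches injected artifacts
  missing_readouts        871 ->  869 (removed 2)
  redundant_sids          869 ->  744 (removed 125)
  discrepant_outcomes     744 ->  714 (removed 30)
  non_binary_outcomes     714 ->  669 (removed 45)
  mixtures                669 ->  569 (removed 100)
  ringless                569 ->  444 (removed 125)
agonist: 1848 MMPs (1656 inactive / 7 active / 185 cliffs); recovery exact
389 common compounds -> 56 with a mechanism label (11 dual-action); 29 MMPs:
  11 same-MOA, 7 weak and 11 strong MOA-cliffs; recovery exact vs ground truth
  planted strong cliff CIDS000A / CIDS000B: classified strong_cliff
```

Each audit line is one curation stage (records before → after); the MMP
line partitions all matched pairs by outcome pattern; the MOA lines
count common compounds surviving both screens, their mechanism labels,
and the classification of every cross-assay MMP — including the
deliberately planted strong cliff, recovered exactly.

The same pipeline runs from the shell on real exports:

```bash
moacliff preprocess --input aid743053.csv --config dialect.yaml \
    --out clean_agonist.csv --audit audit_agonist.csv
moacliff mmp --input clean_agonist.csv --seed 7 --out mmps.csv --network mmps.graphml
moacliff moa --agonist clean_agonist.csv --antagonist clean_antagonist.csv \
    --out moa_pairs.csv --summary table3.csv --dual dual.csv
```

`dialect.yaml` maps the export's column names (SID, CID, SMILES,
outcome, potency) onto the reader; `moacliff run --config run.yaml`
drives everything at once and writes a checksummed manifest.

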