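# Methods

## Pipeline model and assumptions

The package analyses a pair of bioassay result tables — one agonist
screen, one antagonist screen — over a shared compound library.  A
*substance* (SID) is a deposited sample; a *compound* (CID) is a unique
chemical structure; several SIDs may map to one CID.  All analysis is
CID-based after curation.  Outcomes are reduced to a four-term
vocabulary at read time: `Active`, `Inactive`, `Other` (any other
annotation, e.g. "Inconclusive"), `Missing` (absent).  Identifiers are
opaque strings throughout; no PubChem semantics are assumed beyond the
SID/CID distinction.

### Curation

Six record-level filters in fixed order: (1) missing readouts;
(2) redundant records — same CID and outcome under different SIDs are
collapsed into one record with concatenated potency lists, leaving the
unique-CID count unchanged; (3) discrepant CIDs — conflicting outcomes
across a CID's records remove the CID entirely; (4) non-binary
outcomes; (5) mixtures; (6) ring-less structures.  "Mixture" is
operationalized as more than one covalently connected component in the
structure graph (dot-disconnected SMILES); no salt-stripping or other
standardization is attempted.  Unparseable structures are removed at
the mixture stage with a logged warning rather than aborting — HTS
exports routinely contain a few broken structure strings, and the
audit trail records the loss.

Audit rows count *records*; unique-CID counts (the unit in which
per-stage attrition of public deposits is usually quoted) are exposed
separately on the dataset object.  Two invariants are enforced by
construction and property-tested: `n_before − n_removed = n_after` at
every stage, and record counts never increase.

### Potency

IC50 values arrive in micromolar and are converted to
pIC50 = 6 − log10(IC50 µM), i.e. −log10 of the molar concentration.
A compound with several readings keeps their mean if the pIC50 spread
is at most 1.0 (inclusive — "within one log order"); a wider spread
disqualifies the compound from potency-based summaries.  The boundary
case (exactly 1.0) is retained and explicitly tested.  Aggregation is
applied to Active compounds only, and is permutation-invariant in its
input list.

### Scaffolds and cyclic skeletons

`bm_scaffold` delegates to RDKit's Murcko scaffold: ring systems,
linkers between them, and atoms attached to ring/linker atoms by bonds
of order > 1 (an exocyclic carbonyl oxygen on a ring stays; a methyl
group goes).  An independent two-phase pruning oracle — delete
degree-1 atoms to a fixed point, then re-attach multiply-bonded
neighbours of the survivors — is used in the test suite to check this
definition on small molecules.  The CSK is computed from the scaffold
*as stored* (including retained exocyclic atoms): every atom becomes
carbon, every bond single, aromaticity/charges/stereo erased.  Because
a hypervalent origin atom (e.g. a sulfone sulfur) can leave a carbon
with more than four neighbours, CSK sanitization deliberately skips
the valence check.  Ring counting uses the smallest set of smallest
rings.  Scaffold identity is canonical-string equality; there is no
graph-isomorphism fallback.

Ring queries force explicit SSSR perception (`GetSymmSSSR`) rather
than trusting lazily initialized ring info; with RDKit 2024.09 we
observed rare, non-deterministic "RingInfo not initialized" failures
on freshly parsed molecules when partially sanitized CSK intermediates
had been processed earlier in the same session, and forcing perception
removes the failure mode.

### Diversity index

DI of a compound set = mean over all unordered pairs of
(1 − Tanimoto similarity), on MACCS 166-key substructure fingerprints
(167 bits as implemented in RDKit; an 881-key PubChem-style dialect is
not available in the installed stack).  DI is 0 for a homogeneous set,
1 for pairwise-disjoint fingerprints, order-invariant, and only
comparable within one fingerprint dialect — the dialect is recorded in
run metadata.  A nearest-neighbour variant (mean of 1 − max similarity
to any other member) is available behind a flag.  All-pairs work is
capped at 5 000 members by default (≈12.5 M comparisons, desk scale);
published screen partitions are below 4 000.

### Matched molecular pairs

Fragment-and-index with single cuts by default: every acyclic single
bond between heavy atoms is cut once (bonds to hydrogen never), the
larger side is the invariant core (exact ties emit both orientations),
and attachment points are dummy atoms that never count as heavy.
Compounds sharing a canonical core with different fragments become
candidates.  A double-cut mode (unordered bond pairs; the middle piece
is the exchanged linker, attachment numbering normalized to the
lexicographically smaller core string) exists because the classic
fragment-and-index formulation supports it, but all headline
statistics use single cuts — "a structural change at a single site" —
and the two modes never mix during indexing.

Size restrictions (heavy atoms, all boundaries inclusive): core ≥ 2 ×
each fragment; fragment ≤ 13; fragment size difference ≤ 8.  The
rejection log records which rule failed, checked in the order
fragment-cap, size-difference, core-ratio so the most specific
violation is named.  Per compound pair, the admissible cut with the
smallest fragment-size deviation is kept; remaining ties are broken by
a seeded random draw over a deterministically sorted candidate list,
so the surviving pair *count* is seed-independent (tested) and the
representative cut is reproducible.  Stored pairs are ordered
lexicographically by CID; classification (inactive MMP / active MMP /
activity cliff) is symmetric.

### MOA classification

A common compound's label set is {agonist} ∪ {antagonist} according to
its Active outcomes in the two screens; both-inactive compounds are
removed before any MOA analysis, so label sets are non-empty.  The
pair taxonomy is a set relation: equal → same MOA; overlapping but
unequal (exactly one member dual-action) → weak MOA-cliff; disjoint →
strong MOA-cliff.  This single rule reproduces every outcome-pattern
row of the published taxonomy and is verified against brute-force
enumeration of all nine ordered label-set combinations (three same,
two weak, one strong unordered pattern).  Compounds dropped during
either screen's curation are absent from the intersection — there is
no rescue from the other assay.  MMP generation over the labelled
common compounds uses exactly the same size filters and dedup rule as
the per-assay analysis.

## Synthetic screens and what they do (not) show

The generator builds compounds by attaching one small substituent
(≤ 4 heavy atoms, single bond) to a ring-system template.  Templates
are constructed to be their own Murcko scaffolds and to contain no
acyclic single bonds; a pool of ~90 is derived from 12 hand-validated
fused/plain ring systems by aromatic C→N substitution.  Three
consequences make the ground truth analytic, independent of the
machinery under test:

* the true scaffold of every compound is the plain canonical form of
  its clean template, and the true CSK is the reduction of that
  template — so the pipeline's per-compound output is checked as a
  decoration-invariance property;
* the MMP set is exactly the set of within-template compound pairs
  (cores from any cut contain the full template, so cross-template
  cores can never coincide), and every such pair passes the size
  rules by construction (template ≥ 9 ≥ 2 × 4 heavy atoms);
* activity cliffs, dual actives and MOA categories follow from the
  assigned outcome tuples by the same set arithmetic the taxonomy
  defines.

Default study conditions mirror the published AR screens: active
fractions 0.04 (agonist) and 0.09 (antagonist); duplicate-SID rate
0.25 (≈ 10 486 substances over 8 111 compounds); discrepant 0.03,
inconclusive 0.09, mixture 0.20 and acyclic 0.25 matching the
published per-stage attrition; missing 0.005 (the deposits lost a
single compound to this filter; the rate is set to keep the stage
exercised at n = 500); true pIC50 drawn uniformly on 4.2–9.2, the
potency range reported for the exclusive scaffolds.  Duplicated
active records carry a second potency reading, concordant (within one
log order) with probability 0.8, so both aggregation branches occur
naturally.  One seeded NumPy generator drives everything; a fixed
seed gives byte-identical libraries.

What the generator does *not* emulate: realistic scaffold frequency
distributions (every template carries a series, so the ~77 % singleton
fraction and the long-tailed compounds-per-scaffold histogram of real
screens do not appear), medicinal-chemistry property distributions,
tautomer/salt noise beyond simple `.Cl` mixtures, and potency-outcome
correlation.  Passing the recovery suite therefore demonstrates
correctness of the bookkeeping and the pairing/classification logic
under the stated conditions, not statistical realism of the library.

## Problem sizes and numerical choices

The test suite and the acceptance script run the synthetic screen at
500 base compounds over 50 templates (≈ 870 records per assay after
artifact injection), the scale at which every planted feature is
recovered with precision = recall = 1 in a few seconds; the oracle
equivalence check uses a 30-compound library, and unit tests use a
120-compound variant.  Tie-breaks: dedup ties are sorted by
(core, fragment, fragment) before the seeded draw; equal-size
fragmentation ties emit both orientations rather than choosing one.
Degenerate inputs: an empty input file is an empty dataset, not an
error; a dataset with no admissible pairs yields empty tables and a
valid (node-only or empty) network file; Tanimoto of two all-zero
fingerprints is defined as 0 with a warning; DI of fewer than two
fingerprints is an error.

## Known limitations

* Reproducing the published per-deposit counts (e.g. 4 162/172/3 990
  curated agonist compounds, 9 695 MMPs, 92 cliffs) requires the
  AID 743053/743063 exports, which are read from local files and not
  shipped.  Whether the published MMP totals used single or also
  multi-cut fragmentations is not stated in the source material; the
  default here is single-cut, and totals on real data may shift with
  that choice.
* The printed diversity indices of the original screens depend on the
  PubChem fingerprint dialect; MACCS-based DI values are internally
  consistent but not directly comparable to them.
* Scaffold analysis reports terminal Bemis–Murcko scaffolds and CSKs
  only; no hierarchical scaffold network is built.
* The curated-count arithmetic treats the published outcome
  annotations as ground truth; dual-action compounds may reflect
  assay artifacts rather than genuine dual mechanism, and nothing
  here adjudicates that.
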