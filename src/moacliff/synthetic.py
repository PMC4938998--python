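"""Seeded synthetic screening libraries with exact ground truth.

Emulates a shared compound library screened in two opposing-mechanism
assays (agonist / antagonist): compounds are built by attaching small
substituents to ring-system templates, so every series sharing a
template forms clean, size-restricted matched molecular pairs whose
full list is known analytically.  Curation artifacts (missing
readouts, duplicate SIDs, discrepant CIDs, inconclusive annotations,
mixtures, acyclic decoys) are injected at configured rates with their
identities recorded, so each preprocessing stage has an exact expected
removal count.

Templates are constructed to be their own Bemis–Murcko scaffolds and to
contain no acyclic single bonds, which makes the ground truth
independent of the fragment-and-index machinery under test: MMPs are
exactly the within-template compound pairs, and the true scaffold of a
decorated compound is the plain canonical form of its clean template.

Default rates mirror the per-stage attrition and activity prevalence of
the published PubChem AR Tox21 screens (AID 743053 / AID 743063).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import (
    ACTIVE,
    AGONIST,
    ANTAGONIST,
    INACTIVE,
    MISSING,
    OTHER,
    AssayDataset,
    CompoundRecord,
)
from .moa import SAME_MOA, STRONG_CLIFF, WEAK_CLIFF, classify_moa
from .preprocess import STAGE_ORDER
from .scaffolds import csk_of

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "generate_library",
    "paper_toy_fixture",
    "BASE_TEMPLATES",
    "DEFAULT_VOCABULARY",
]


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


# Ring-system templates with one attachment point.  Each is its own
# Murcko scaffold and has no acyclic single bonds (exocyclic carbonyls
# are double bonds), so the only cuttable bonds of a decorated compound
# lie in its substituent.
BASE_TEMPLATES = (
    "[*:1]c1ccc2ccccc2c1",                # naphthalene
    "[*:1]C1CCc2ccccc2C1",                # tetralin
    "[*:1]c1ccc2c(c1)oc1ccccc12",         # dibenzofuran
    "[*:1]c1ccc2c(c1)[nH]c1ccccc12",      # carbazole
    "[*:1]c1ccc2c(c1)CCC2=O",             # indanone
    "[*:1]C1CCC2(CC1)CCCC2",              # spiro[4.5]decane
    "[*:1]c1ccc2c(c1)CCO2",               # dihydrobenzofuran
    "[*:1]c1cc2ccccc2s1",                 # benzothiophene
    "[*:1]c1cc2ccccc2o1",                 # benzofuran
    "[*:1]C1CCC2CCCCC2C1",                # decalin
    "[*:1]c1ccc2c(c1)C(=O)c1ccccc1C2=O",  # anthraquinone
    "[*:1]c1ccc2ccc3ccccc3c2c1",          # anthracene
)

# Exchanged-fragment vocabulary: acyclic substituents of ≤ 4 heavy
# atoms attached by a single bond, so every within-template pair
# satisfies the three MMP size restrictions by construction.
DEFAULT_VOCABULARY = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]C(C)C",
    "[*:1]CCCC",
    "[*:1]O",
    "[*:1]OC",
    "[*:1]OCC",
    "[*:1]CO",
    "[*:1]CCO",
    "[*:1]N",
    "[*:1]NC",
    "[*:1]CN",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]C=O",
    "[*:1]CC=O",
    "[*:1]C(C)=O",
    "[*:1]CF",
)

DEFAULT_ARTIFACT_RATES = {
    "missing": 0.005,
    "duplicate_sid": 0.25,
    "discrepant": 0.03,
    "inconclusive": 0.09,
    "mixture": 0.20,
    "acyclic": 0.25,
}

ASSAYS = (AGONIST, ANTAGONIST)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scaffold_templates: int = 50
    n_compounds: int = 500
    substituent_vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    fraction_active_agonist: float = 0.04
    fraction_active_antagonist: float = 0.09
    n_dual_active: int = 8
    n_planted_strong_cliffs: int = 1
    n_planted_weak_cliffs: int = 2
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES)
    )
    pic50_range: tuple[float, float] = (4.2, 9.2)
    # among duplicated-SID actives: chance the second reading agrees
    # within one log order (the rest are discordant and get dropped by
    # the potency aggregation rule)
    concordant_duplicate_fraction: float = 0.8

    def validate(self) -> None:
        for name in ("fraction_active_agonist", "fraction_active_antagonist"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        unknown = set(self.artifact_rates) - set(DEFAULT_ARTIFACT_RATES)
        if unknown:
            raise ConfigError(f"unknown artifact rates: {sorted(unknown)}")
        for k, v in self.artifact_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"artifact rate {k} must be in [0,1], got {v}")
        if min(self.n_compounds, self.n_scaffold_templates, self.n_dual_active) < 0:
            raise ConfigError("counts must be non-negative")
        n_planted = self.n_planted_strong_cliffs + self.n_planted_weak_cliffs
        if self.n_scaffold_templates <= n_planted:
            raise ConfigError("need more templates than planted-cliff templates")
        n_base_templates = self.n_scaffold_templates - n_planted
        if self.n_compounds > n_base_templates * len(self.substituent_vocabulary):
            raise ConfigError(
                "n_compounds exceeds distinct (template, substituent) combinations"
            )
        if self.n_dual_active > self.n_compounds:
            raise ConfigError("more dual actives than compounds")


@dataclass
class Compound:
    cid: str
    smiles: str
    template_id: int  # -1 for mixtures / acyclic decoys
    role: str  # base | dual | strong | weak | mixture | acyclic
    outcomes: dict[str, str] = field(default_factory=dict)  # assay -> truth
    pic50: dict[str, float] = field(default_factory=dict)  # assay -> true potency


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover, by construction."""

    compounds: list[Compound]
    templates: list[str]  # clean canonical template structures
    expected_audit: dict[str, list[tuple[str, int]]]  # assay -> (stage, n_removed)
    final_cids: dict[str, set[str]]
    outcomes: dict[str, dict[str, str]]  # assay -> cid -> outcome
    scaffold_by_cid: dict[str, str]
    csk_by_cid: dict[str, str]
    mmp_pairs: dict[str, set[tuple[str, str]]]
    activity_cliffs: dict[str, set[tuple[str, str]]]
    expected_potency: dict[str, dict[str, float | None]]  # None = dropped
    common_cids: set[str]
    labelled_cids: set[str]  # common minus both-inactive
    dual_active_cids: set[str]
    moa_pairs: dict[tuple[str, str], str]  # pair -> category
    planted_strong: list[tuple[str, str]]
    planted_weak: list[tuple[str, str]]

    def moa_category_counts(self) -> dict[str, int]:
        counts = {SAME_MOA: 0, WEAK_CLIFF: 0, STRONG_CLIFF: 0}
        for cat in self.moa_pairs.values():
            counts[cat] += 1
        return counts


def _strip_dummy(template: str) -> str:
    rw = Chem.RWMol(Chem.MolFromSmiles(template))
    for atom in list(rw.GetAtoms()):
        if atom.GetAtomicNum() == 0:
            rw.RemoveAtom(atom.GetIdx())
            break
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _template_pool(n_needed: int) -> list[str]:
    """Base templates plus aromatic C→N variants, canonically deduplicated."""
    pool: list[str] = []
    seen: set[str] = set()

    def add(smi: str) -> None:
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if canon not in seen:
            seen.add(canon)
            pool.append(canon)

    for base in BASE_TEMPLATES:
        add(base)
    for base in BASE_TEMPLATES:
        mol = Chem.MolFromSmiles(base)
        for atom in mol.GetAtoms():
            if (
                atom.GetIsAromatic()
                and atom.GetAtomicNum() == 6
                and atom.GetTotalNumHs() == 1
            ):
                rw = Chem.RWMol(mol)
                rw.GetAtomWithIdx(atom.GetIdx()).SetAtomicNum(7)
                rw.GetAtomWithIdx(atom.GetIdx()).SetNumExplicitHs(0)
                try:
                    variant = rw.GetMol()
                    Chem.SanitizeMol(variant)
                except Exception:
                    continue
                add(Chem.MolToSmiles(variant))
                if len(pool) >= n_needed:
                    return pool
    if len(pool) < n_needed:
        raise ConfigError(
            f"template pool exhausted: {len(pool)} available, {n_needed} requested"
        )
    return pool


def _attach(template: str, substituent: str) -> str:
    mol = Chem.molzip(Chem.MolFromSmiles(template), Chem.MolFromSmiles(substituent))
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _acyclic_decoys(n: int) -> list[str]:
    """Distinct acyclic structures: linear chains with 0 or 1 oxygen."""
    if n <= 0:
        return []
    out: list[str] = []
    seen: set[str] = set()
    for length in itertools.count(2):
        candidates = ["C" * length] + [
            "C" * i + "O" + "C" * (length - i) for i in range(1, length + 1)
        ]
        for smi in candidates:
            canon = Chem.CanonSmiles(smi)
            if canon not in seen:
                seen.add(canon)
                out.append(canon)
                if len(out) == n:
                    return out
    return out


def _pairs_within_templates(
    compounds: list[Compound], cids: set[str]
) -> set[tuple[str, str]]:
    by_template: dict[int, list[str]] = {}
    for c in compounds:
        if c.template_id >= 0 and c.cid in cids:
            by_template.setdefault(c.template_id, []).append(c.cid)
    pairs: set[tuple[str, str]] = set()
    for members in by_template.values():
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add((a, b))
    return pairs


def generate_library(
    config: SimulationConfig | None = None,
) -> tuple[AssayDataset, AssayDataset, GroundTruth]:
    """Generate the two raw assay datasets and their ground truth.

    Deterministic for a fixed seed.  With all artifact rates at zero the
    preprocessing pipeline is the identity on the generated sets.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_planted = config.n_planted_strong_cliffs + config.n_planted_weak_cliffs
    templates = _template_pool(config.n_scaffold_templates)
    base_templates = list(range(config.n_scaffold_templates - n_planted))
    planted_templates = list(range(len(base_templates), config.n_scaffold_templates))
    clean_templates = [_strip_dummy(t) for t in templates]

    # Per-template substituent order: a seeded permutation of the vocabulary.
    vocab_order = {
        t: [config.substituent_vocabulary[k] for k in rng.permutation(len(config.substituent_vocabulary))]
        for t in range(config.n_scaffold_templates)
    }
    used_per_template: dict[int, int] = {t: 0 for t in range(config.n_scaffold_templates)}

    def next_compound(template_id: int, cid: str, role: str) -> Compound:
        sub = vocab_order[template_id][used_per_template[template_id]]
        used_per_template[template_id] += 1
        return Compound(
            cid=cid,
            smiles=_attach(templates[template_id], sub),
            template_id=template_id,
            role=role,
        )

    compounds: list[Compound] = []
    for i in range(config.n_compounds):
        compounds.append(
            next_compound(base_templates[i % len(base_templates)], f"CID{i:05d}", "base")
        )

    # True outcomes for the base library.
    frac = {AGONIST: config.fraction_active_agonist, ANTAGONIST: config.fraction_active_antagonist}
    for c in compounds:
        for assay in ASSAYS:
            c.outcomes[assay] = ACTIVE if rng.random() < frac[assay] else INACTIVE

    # Dual actives: a seeded subset of base compounds set active in both screens.
    dual_idx = rng.choice(len(compounds), size=config.n_dual_active, replace=False)
    for i in sorted(int(k) for k in dual_idx):
        compounds[i].role = "dual"
        compounds[i].outcomes = {AGONIST: ACTIVE, ANTAGONIST: ACTIVE}

    # Planted MOA-cliff pairs on reserved templates, two compounds each.
    planted_strong: list[tuple[str, str]] = []
    planted_weak: list[tuple[str, str]] = []
    for j in range(config.n_planted_strong_cliffs):
        t = planted_templates[j]
        a = next_compound(t, f"CIDS{j:03d}A", "strong")
        b = next_compound(t, f"CIDS{j:03d}B", "strong")
        a.outcomes = {AGONIST: ACTIVE, ANTAGONIST: INACTIVE}
        b.outcomes = {AGONIST: INACTIVE, ANTAGONIST: ACTIVE}
        compounds += [a, b]
        planted_strong.append(tuple(sorted((a.cid, b.cid))))
    for j in range(config.n_planted_weak_cliffs):
        t = planted_templates[config.n_planted_strong_cliffs + j]
        a = next_compound(t, f"CIDW{j:03d}A", "weak")
        b = next_compound(t, f"CIDW{j:03d}B", "weak")
        a.outcomes = {AGONIST: ACTIVE, ANTAGONIST: ACTIVE}
        if j % 2 == 0:
            b.outcomes = {AGONIST: ACTIVE, ANTAGONIST: INACTIVE}
        else:
            b.outcomes = {AGONIST: INACTIVE, ANTAGONIST: ACTIVE}
        compounds += [a, b]
        planted_weak.append(tuple(sorted((a.cid, b.cid))))

    # True potencies for active readouts.
    lo, hi = config.pic50_range
    for c in compounds:
        for assay in ASSAYS:
            if c.outcomes[assay] == ACTIVE:
                c.pic50[assay] = float(lo + (hi - lo) * rng.random())

    # Structural decoys shared by both assays.
    rates = {**DEFAULT_ARTIFACT_RATES, **config.artifact_rates}
    n_mixture = int(round(rates["mixture"] * config.n_compounds))
    n_acyclic = int(round(rates["acyclic"] * config.n_compounds))
    vocab = config.substituent_vocabulary
    for m in range(n_mixture):
        t = base_templates[m % len(base_templates)] if base_templates else 0
        sub = vocab[(m // len(base_templates)) % len(vocab)]
        mix = Chem.CanonSmiles(_attach(templates[t], sub) + ".Cl")
        comp = Compound(cid=f"CIDX{m:04d}", smiles=mix, template_id=-1, role="mixture")
        compounds.append(comp)
    for a, smi in enumerate(_acyclic_decoys(n_acyclic)):
        compounds.append(
            Compound(cid=f"CIDA{a:04d}", smiles=smi, template_id=-1, role="acyclic")
        )
    for c in compounds:
        if c.role in ("mixture", "acyclic"):
            for assay in ASSAYS:
                c.outcomes[assay] = ACTIVE if rng.random() < frac[assay] else INACTIVE
                if c.outcomes[assay] == ACTIVE:
                    c.pic50[assay] = float(lo + (hi - lo) * rng.random())

    if len({c.cid for c in compounds}) != len(compounds):
        raise ConfigError("internal error: duplicate CIDs generated")
    if len({c.smiles for c in compounds}) != len(compounds):
        raise ConfigError("internal error: duplicate structures generated")

    # Outcome-level artifacts, drawn independently per assay over plain
    # base compounds (never dual actives or planted-cliff members, so
    # those always survive curation).
    n_missing = int(round(rates["missing"] * config.n_compounds))
    n_duplicate = int(round(rates["duplicate_sid"] * config.n_compounds))
    n_discrepant = int(round(rates["discrepant"] * config.n_compounds))
    n_inconclusive = int(round(rates["inconclusive"] * config.n_compounds))
    eligible = [i for i, c in enumerate(compounds) if c.role == "base"]
    need = n_missing + n_discrepant + n_inconclusive + n_duplicate
    if need > len(eligible):
        raise ConfigError(
            f"artifact rates need {need} victims but only {len(eligible)} plain compounds"
        )
    victims: dict[str, dict[str, list[int]]] = {}
    for assay in ASSAYS:
        order = [eligible[int(k)] for k in rng.permutation(len(eligible))]
        victims[assay] = {
            "missing": order[:n_missing],
            "discrepant": order[n_missing : n_missing + n_discrepant],
            "inconclusive": order[
                n_missing + n_discrepant : n_missing + n_discrepant + n_inconclusive
            ],
            "duplicate_sid": order[
                n_missing
                + n_discrepant
                + n_inconclusive : n_missing
                + n_discrepant
                + n_inconclusive
                + n_duplicate
            ],
        }

    # Assemble the raw records.
    datasets: dict[str, AssayDataset] = {}
    expected_potency: dict[str, dict[str, float | None]] = {a: {} for a in ASSAYS}
    for assay in ASSAYS:
        v = victims[assay]
        missing_set = set(v["missing"])
        discrepant_set = set(v["discrepant"])
        inconclusive_set = set(v["inconclusive"])
        duplicate_set = set(v["duplicate_sid"])
        records: list[CompoundRecord] = []
        sid_counter = itertools.count(1)
        prefix = "SAG" if assay == AGONIST else "SAN"

        def emit(c: Compound, outcome: str, potency: tuple[float, ...]) -> None:
            records.append(
                CompoundRecord(
                    sid=f"{prefix}{next(sid_counter):06d}",
                    cid=c.cid,
                    smiles=c.smiles,
                    outcome=outcome,
                    potencies=potency,
                    source_assay=assay,
                )
            )

        for i, c in enumerate(compounds):
            if i in missing_set:
                emit(c, MISSING, ())
                continue
            if i in inconclusive_set:
                emit(c, OTHER, ())
                continue
            outcome = c.outcomes[assay]
            base_pot: tuple[float, ...] = ()
            if outcome == ACTIVE:
                base_pot = (10.0 ** (6.0 - c.pic50[assay]),)
            emit(c, outcome, base_pot)
            if i in duplicate_set:
                # Same CID, same outcome, different SID; duplicated
                # actives carry a second potency reading.
                dup_pot: tuple[float, ...] = ()
                if outcome == ACTIVE:
                    if rng.random() < config.concordant_duplicate_fraction:
                        second = c.pic50[assay] + float(rng.uniform(-0.45, 0.45))
                    else:
                        second = c.pic50[assay] + 1.5 * (1 if rng.random() < 0.5 else -1)
                    dup_pot = (10.0 ** (6.0 - second),)
                    spread_ok = abs(second - c.pic50[assay]) <= 1.0
                    expected_potency[assay][c.cid] = (
                        (c.pic50[assay] + second) / 2.0 if spread_ok else None
                    )
                emit(c, outcome, dup_pot)
            elif outcome == ACTIVE:
                expected_potency[assay][c.cid] = c.pic50[assay]
            if i in discrepant_set:
                flipped = INACTIVE if outcome == ACTIVE else ACTIVE
                emit(c, flipped, ())
                expected_potency[assay].pop(c.cid, None)
        datasets[assay] = AssayDataset(records=records, name=assay)

    # Expected curation outcome, per assay.
    expected_audit: dict[str, list[tuple[str, int]]] = {}
    final_cids: dict[str, set[str]] = {}
    outcomes_truth: dict[str, dict[str, str]] = {}
    for assay in ASSAYS:
        v = victims[assay]
        expected_audit[assay] = [
            (STAGE_ORDER[0], len(v["missing"])),
            (STAGE_ORDER[1], len(v["duplicate_sid"])),
            (STAGE_ORDER[2], 2 * len(v["discrepant"])),
            (STAGE_ORDER[3], len(v["inconclusive"])),
            (STAGE_ORDER[4], n_mixture),
            (STAGE_ORDER[5], n_acyclic),
        ]
        removed = set(v["missing"]) | set(v["discrepant"]) | set(v["inconclusive"])
        final = {
            c.cid
            for i, c in enumerate(compounds)
            if c.role not in ("mixture", "acyclic") and i not in removed
        }
        final_cids[assay] = final
        outcomes_truth[assay] = {
            c.cid: c.outcomes[assay] for c in compounds if c.cid in final
        }
        expected_potency[assay] = {
            cid: p for cid, p in expected_potency[assay].items() if cid in final
        }

    scaffold_by_cid: dict[str, str] = {}
    csk_by_cid: dict[str, str] = {}
    for c in compounds:
        if c.template_id >= 0:
            scaffold_by_cid[c.cid] = clean_templates[c.template_id]
            csk_by_cid[c.cid] = csk_of(clean_templates[c.template_id])

    mmp_pairs: dict[str, set[tuple[str, str]]] = {}
    activity_cliffs: dict[str, set[tuple[str, str]]] = {}
    for assay in ASSAYS:
        pairs = _pairs_within_templates(compounds, final_cids[assay])
        mmp_pairs[assay] = pairs
        activity_cliffs[assay] = {
            (a, b)
            for a, b in pairs
            if outcomes_truth[assay][a] != outcomes_truth[assay][b]
        }

    common = final_cids[AGONIST] & final_cids[ANTAGONIST]
    labelled = {
        cid
        for cid in common
        if outcomes_truth[AGONIST][cid] == ACTIVE
        or outcomes_truth[ANTAGONIST][cid] == ACTIVE
    }
    dual = {
        cid
        for cid in labelled
        if outcomes_truth[AGONIST][cid] == ACTIVE
        and outcomes_truth[ANTAGONIST][cid] == ACTIVE
    }

    def label_set(cid: str) -> frozenset[str]:
        labels = set()
        if outcomes_truth[AGONIST][cid] == ACTIVE:
            labels.add(AGONIST)
        if outcomes_truth[ANTAGONIST][cid] == ACTIVE:
            labels.add(ANTAGONIST)
        return frozenset(labels)

    moa_pairs = {
        (a, b): classify_moa(label_set(a), label_set(b))
        for a, b in _pairs_within_templates(compounds, labelled)
    }

    truth = GroundTruth(
        compounds=compounds,
        templates=clean_templates,
        expected_audit=expected_audit,
        final_cids=final_cids,
        outcomes=outcomes_truth,
        scaffold_by_cid=scaffold_by_cid,
        csk_by_cid=csk_by_cid,
        mmp_pairs=mmp_pairs,
        activity_cliffs=activity_cliffs,
        expected_potency=expected_potency,
        common_cids=common,
        labelled_cids=labelled,
        dual_active_cids=dual,
        moa_pairs=moa_pairs,
        planted_strong=planted_strong,
        planted_weak=planted_weak,
    )
    return datasets[AGONIST], datasets[ANTAGONIST], truth


# ---------------------------------------------------------------------------


def paper_toy_fixture() -> tuple[AssayDataset, AssayDataset, dict]:
    """A small hand-written two-assay fixture with in-study structures.

    Contains testosterone (CID 10631), whose Bemis–Murcko scaffold is
    the classic 4-ring steroid enone "O=C1CCC2C(=C1)CCC1C2CCC2C1CCC2";
    a naphthalene MMP series forming an agonist activity cliff; a
    strong-MOA-cliff pair and a weak pair (the strong pair uses
    synthetic stand-in structures, since the deposited structures of the
    published strong-cliff CIDs are not reproduced here); potency lists
    exercising both aggregation branches; and one of each curation
    artifact.
    """
    testosterone = "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O"
    sca_1 = "O=C1CCC2C(=C1)CCC1C2CCC2C1CCC2"

    def rec(sid, cid, smiles, outcome, potencies=(), assay=AGONIST):
        return CompoundRecord(
            sid=sid, cid=cid, smiles=smiles, outcome=outcome,
            potencies=tuple(potencies), source_assay=assay,
        )

    naph_me = "Cc1ccc2ccccc2c1"
    naph_et = "CCc1ccc2ccccc2c1"
    carb_a = _attach("[*:1]c1ccc2c(c1)[nH]c1ccccc12", "[*:1]CCO")
    carb_b = _attach("[*:1]c1ccc2c(c1)[nH]c1ccccc12", "[*:1]CCC")
    dhbf_a = _attach("[*:1]c1ccc2c(c1)CCO2", "[*:1]C")
    dhbf_b = _attach("[*:1]c1ccc2c(c1)CCO2", "[*:1]CC")

    common = [
        ("10631", testosterone, ACTIVE, INACTIVE, (0.01,)),
        ("TOY1", naph_me, ACTIVE, INACTIVE, (0.5,)),
        ("TOY2", naph_et, INACTIVE, INACTIVE, ()),
        ("STRONG_A", carb_a, ACTIVE, INACTIVE, (20.4,)),
        ("STRONG_B", carb_b, INACTIVE, ACTIVE, ()),
        ("WEAK_A", dhbf_a, ACTIVE, ACTIVE, (1.0,)),
        ("WEAK_B", dhbf_b, ACTIVE, INACTIVE, (2.0,)),
    ]
    ag_records: list[CompoundRecord] = []
    ant_records: list[CompoundRecord] = []
    for i, (cid, smi, ag_out, ant_out, pot) in enumerate(common):
        ag_records.append(rec(f"SAG{i:03d}", cid, smi, ag_out, pot))
        ant_records.append(
            rec(f"SAN{i:03d}", cid, smi, ant_out,
                pot if ant_out == ACTIVE else (), assay=ANTAGONIST)
        )

    # Potency aggregation branches (agonist only): P1 merges within one
    # log order to a 6.25 mean; P2 spans two log orders and is dropped.
    ag_records += [
        rec("SAGP1A", "P1", "Cc1cc2ccccc2o1", ACTIVE, (1.0,)),
        rec("SAGP1B", "P1", "Cc1cc2ccccc2o1", ACTIVE, (0.316227766,)),
        rec("SAGP2A", "P2", "CCc1cc2ccccc2o1", ACTIVE, (10.0,)),
        rec("SAGP2B", "P2", "CCc1cc2ccccc2o1", ACTIVE, (0.1,)),
    ]
    # Curation artifacts (agonist assay).
    ag_records += [
        rec("SAGM01", "MISS1", "Oc1ccc2ccccc2c1", MISSING),
        rec("SAGX01", "MIX1", "CCO.Cl", INACTIVE),
        rec("SAGA01", "ACYC1", "CCCC", INACTIVE),
        rec("SAGD01", "DISC1", "NCc1ccc2ccccc2c1", ACTIVE, (5.0,)),
        rec("SAGD02", "DISC1", "NCc1ccc2ccccc2c1", INACTIVE),
        rec("SAGI01", "INC1", "OCc1ccc2ccccc2c1", OTHER),
    ]

    truth = {
        "sca_1": sca_1,
        "steroid_cid": "10631",
        "agonist_cliff_pair": ("TOY1", "TOY2"),
        "strong_pair": ("STRONG_A", "STRONG_B"),
        "weak_pair": ("WEAK_A", "WEAK_B"),
        "merged_potency": {"P1": 6.25},
        "dropped_potency": {"P2"},
        "artifact_cids": {"MISS1", "MIX1", "ACYC1", "DISC1", "INC1"},
    }
    return (
        AssayDataset(records=ag_records, name=AGONIST),
        AssayDataset(records=ant_records, name=ANTAGONIST),
        truth,
    )
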