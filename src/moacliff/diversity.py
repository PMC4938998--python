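"""Substructure fingerprints and the diversity index (DI) of compound sets.

The DI of a set is the mean pairwise Tanimoto *distance* (1 − similarity)
over all unordered pairs: 0 for a homogeneous set, approaching 1 for a
set of pairwise-dissimilar structures.  A nearest-neighbour variant
(mean over compounds of 1 − max similarity to any other member) is
available for comparison.  Fingerprints are MACCS 167 substructure keys,
a fixed-length binary key dialect; DI values are comparable only within
one dialect.
"""

from __future__ import annotations

import logging

from rdkit import DataStructs
from rdkit.Chem import MACCSkeys
from rdkit.DataStructs import ExplicitBitVect

from .chem_io import mol_from_smiles

__all__ = [
    "FINGERPRINT_DIALECT",
    "FINGERPRINT_BITS",
    "fingerprint",
    "tanimoto",
    "diversity_index",
]

logger = logging.getLogger(__name__)

FINGERPRINT_DIALECT = "MACCS-167"
FINGERPRINT_BITS = 167

# All-pairs DI is quadratic; this cap keeps a misconfigured call from
# silently consuming hours.  Screens of a few thousand members are fine.
DEFAULT_MAX_SET_SIZE = 5000


def fingerprint(smiles: str) -> ExplicitBitVect:
    """Binary substructure-key fingerprint of a molecule."""
    return MACCSkeys.GenMACCSKeys(mol_from_smiles(smiles))


def tanimoto(a: ExplicitBitVect, b: ExplicitBitVect) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length fingerprints.

    Two all-zero fingerprints are defined to have similarity 0 (with a
    warning): they share no substructure evidence.
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(
            f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}"
        )
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        logger.warning("Tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return DataStructs.TanimotoSimilarity(a, b)


def diversity_index(
    fps: list[ExplicitBitVect],
    method: str = "mean_pairwise",
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> float:
    """Diversity index of a fingerprint set, in [0, 1].

    ``mean_pairwise`` (default): mean of (1 − Tanimoto) over all
    unordered pairs.  ``nearest_neighbor``: mean over members of
    (1 − similarity to the nearest other member).  Both are invariant
    to input order.  Fewer than two members is undefined.
    """
    n = len(fps)
    if n < 2:
        raise ValueError("diversity index needs at least two fingerprints")
    if n > max_set_size:
        raise ValueError(f"set size {n} exceeds cap {max_set_size}")
    lengths = {fp.GetNumBits() for fp in fps}
    if len(lengths) != 1:
        raise ValueError(f"mixed fingerprint lengths: {sorted(lengths)}")
    if method == "mean_pairwise":
        total = 0.0
        n_pairs = 0
        for i in range(1, n):
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
            total += sum(1.0 - s for s in sims)
            n_pairs += i
        return total / n_pairs
    if method == "nearest_neighbor":
        total = 0.0
        for i in range(n):
            others = fps[:i] + fps[i + 1 :]
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], others)
            total += 1.0 - max(sims)
        return total / n
    raise ValueError(f"unknown method: {method!r}")
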