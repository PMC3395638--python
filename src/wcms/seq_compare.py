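"""Pairwise comparison of aligned 16S rRNA sequences.

Identity is computed over columns where both sequences carry an unambiguous
base: alignment gaps are not considered in the similarity calculation, and
ambiguity codes (N, R, Y, ...) are excluded the same way.  The Kimura
two-parameter distance corrects separately for transitions and
transversions over the same gap-excluded columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .types import SequenceSet, SimilarityMatrix

_UNAMBIGUOUS = set("ACGTU")
_PURINES = set("AG")
_PYRIMIDINES = set("CT")


@dataclass
class PairwiseIdentity:
    id_a: str
    id_b: str
    compared_columns: int
    matches: int

    @property
    def similarity(self) -> float:
        """Percent identity over the compared (both-unambiguous) columns."""
        return 100.0 * self.matches / self.compared_columns


@dataclass
class K2PDistance:
    P: float  # transition proportion
    Q: float  # transversion proportion

    @property
    def d(self) -> float:
        """Substitutions per site, -0.5*ln(1-2P-Q) - 0.25*ln(1-2Q)."""
        w1 = 1.0 - 2.0 * self.P - self.Q
        w2 = 1.0 - 2.0 * self.Q
        if w1 <= 0 or w2 <= 0:
            raise ValueError("K2P distance undefined (saturation)")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _comparable(a: str, b: str):
    if len(a) != len(b):
        raise ValueError(f"aligned length mismatch: {len(a)} != {len(b)}")
    for x, y in zip(a.upper().replace("U", "T"), b.upper().replace("U", "T")):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            yield x, y


def identity_gap_excluded(aligned_a: str, aligned_b: str,
                          id_a: str = "a", id_b: str = "b") -> PairwiseIdentity:
    """Percent identity skipping any column with a gap or ambiguous base."""
    compared = matches = 0
    for x, y in _comparable(aligned_a, aligned_b):
        compared += 1
        matches += x == y
    if compared == 0:
        raise ValueError(f"{id_a}/{id_b}: no comparable columns")
    return PairwiseIdentity(id_a, id_b, compared, matches)


def k2p_distance(aligned_a: str, aligned_b: str) -> K2PDistance:
    """Kimura two-parameter distance over gap-excluded columns."""
    compared = transitions = transversions = 0
    for x, y in _comparable(aligned_a, aligned_b):
        compared += 1
        if x == y:
            continue
        same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return K2PDistance(transitions / compared, transversions / compared)


def similarity_matrix_16s(seqs: SequenceSet) -> SimilarityMatrix:
    """All-pairs gap-excluded identity, in input order.

    Returned in the same labels-and-square-values layout the Mantel test
    consumes.  Values are identity fractions in [0, 1] (identity percent
    divided by 100) with a unit diagonal; multiply by 100 for the percent
    convention when writing reports.
    """
    if seqs.alphabet != "nucleotide":
        raise ValueError("nucleotide sequences required")
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = len(seqs)
    values = np.eye(n)
    for (i, (ida, a)), (j, (idb, b)) in combinations(enumerate(seqs.records), 2):
        sim = identity_gap_excluded(a, b, ida, idb).similarity / 100.0
        values[i, j] = values[j, i] = sim
    return SimilarityMatrix(seqs.ids, values)
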