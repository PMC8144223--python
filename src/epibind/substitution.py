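"""Amino-acid substitution matrices (BLOSUM62 by default).

BLOSUM62 drives three distinct steps in the pipeline: local-alignment
scoring when epitopes are mapped back onto their source proteins,
similarity-constrained data augmentation during training, and the
single-substitution neighborhoods used by the majority-vote postprocessor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from epibind.alphabet import AA_INDEX, AA_ORDER


@dataclass(frozen=True, eq=False)
class SubstitutionMatrix:
    """A symmetric 20x20 integer score table over the canonical alphabet.

    The diagonal must strictly dominate every off-diagonal entry of its row
    (true of all BLOSUM/PAM matrices restricted to the canonical 20), which
    guarantees that "the most similar residue" is always a *different*
    residue with a strictly lower score than identity.
    """

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.int64)
        n = len(AA_ORDER)
        if scores.shape != (n, n):
            raise ValueError(f"score table must be {n}x{n}, got {scores.shape}")
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        off = scores - np.diag(np.diag(scores))
        if not np.all(np.diag(scores) > off.max(axis=1)):
            raise ValueError("diagonal must strictly dominate each row")
        object.__setattr__(self, "scores", scores)

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.scores[AA_INDEX[a], AA_INDEX[b]])
        except KeyError as exc:
            raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None

    def row(self, a: str) -> np.ndarray:
        if a not in AA_INDEX:
            raise ValueError(f"non-canonical residue {a!r}")
        return self.scores[AA_INDEX[a]]

    @classmethod
    def from_biopython(cls, array, name: str) -> "SubstitutionMatrix":
        """Restrict a biopython substitution array to the canonical 20."""
        n = len(AA_ORDER)
        scores = np.zeros((n, n), dtype=np.int64)
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                scores[i, j] = int(array[a][b])
        return cls(scores=scores, name=name)

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "SubstitutionMatrix":
        """Load an NCBI-format matrix file (as written by makeblastdb et al.)."""
        arr = substitution_matrices.read(str(path))
        return cls.from_biopython(arr, name=name or str(path))


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """The BLOSUM62 matrix restricted to the canonical alphabet (cached)."""
    return SubstitutionMatrix.from_biopython(
        substitution_matrices.load("BLOSUM62"), name="BLOSUM62"
    )


def most_similar_residue(a: str, matrix: SubstitutionMatrix | None = None) -> str:
    """The distinct residue maximizing ``score(a, b)``; ties break alphabetically.

    Under BLOSUM62 e.g. W -> Y, V -> I, and L -> I (I and M tie at 2; the
    alphabetical rule selects I).
    """
    matrix = matrix or blosum62()
    if a not in AA_INDEX:
        raise ValueError(f"non-canonical residue {a!r}")
    row = matrix.row(a)
    best_b, best_s = None, None
    for j, b in enumerate(AA_ORDER):  # AA_ORDER is alphabetical, first win = tie-break
        if b == a:
            continue
        if best_s is None or row[j] > best_s:
            best_b, best_s = b, row[j]
    return best_b
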