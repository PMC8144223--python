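"""Canonical amino-acid alphabet and one-hot peptide encoding.

Every residue is represented as a length-20 indicator vector under the fixed
ordering ``ACDEFGHIKLMNPQRSTVWY`` (alphabetical one-letter codes). The
ordering is part of the model contract: checkpoints store it and refuse to
load under a different one.
"""

from __future__ import annotations

import numpy as np

#: Fixed alphabet ordering used by every encoder in the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Residue codes that are legal FASTA symbols but outside the canonical 20.
NON_CANONICAL = frozenset("XUBZJO*")


def validate_peptide(seq: str, length: int | None = None, name: str = "peptide") -> str:
    """Check that ``seq`` is a non-empty canonical residue string.

    Raises ``ValueError`` naming the first offending position. Returns the
    (unchanged) sequence for chaining.
    """
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError(f"{name} must be a non-empty residue string, got {seq!r}")
    for i, aa in enumerate(seq):
        if aa not in AA_INDEX:
            raise ValueError(
                f"{name} {seq!r} has non-canonical residue {aa!r} at position {i + 1}"
            )
    if length is not None and len(seq) != length:
        raise ValueError(f"{name} {seq!r} has length {len(seq)}, expected {length}")
    return seq


def one_hot_encode(pep: str) -> np.ndarray:
    """Encode a canonical peptide as an ``L x 20`` binary matrix.

    Row ``i`` holds a single 1 in the column of residue ``i`` under
    :data:`AA_ORDER`.
    """
    validate_peptide(pep)
    mat = np.zeros((len(pep), len(AA_ORDER)), dtype=np.float64)
    for i, aa in enumerate(pep):
        mat[i, AA_INDEX[aa]] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`; requires exactly one 1 per row."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != len(AA_ORDER):
        raise ValueError(f"expected an L x {len(AA_ORDER)} matrix, got shape {mat.shape}")
    if not np.array_equal(mat.sum(axis=1), np.ones(mat.shape[0])):
        raise ValueError("not a valid one-hot matrix: rows must each sum to 1")
    return "".join(AA_ORDER[j] for j in mat.argmax(axis=1))


def encode_batch(peptides) -> np.ndarray:
    """Stack one-hot matrices for equal-length peptides into ``B x L x 20``."""
    peptides = list(peptides)
    if not peptides:
        return np.zeros((0, 0, len(AA_ORDER)), dtype=np.float64)
    L = len(peptides[0])
    out = np.zeros((len(peptides), L, len(AA_ORDER)), dtype=np.float64)
    for b, pep in enumerate(peptides):
        validate_peptide(pep, length=L)
        for i, aa in enumerate(pep):
            out[b, i, AA_INDEX[aa]] = 1.0
    return out
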