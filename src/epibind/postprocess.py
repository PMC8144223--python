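"""Threshold calls, similarity majority-vote smoothing, and union ensembling.

The majority vote re-examines each call through the peptide's L
single-substitution neighbors — position i replaced by its most similar
residue under BLOSUM62 — and flips the call only when a strict majority of
neighbor calls disagrees. Ties keep the original call, which also makes the
vote idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from epibind.alphabet import validate_peptide
from epibind.substitution import SubstitutionMatrix, blosum62, most_similar_residue


@dataclass(frozen=True)
class PredictionRecord:
    seq: str
    score: float
    call: int
    call_post: int | None = None


def binary_call(score: float, threshold: float = 0.5) -> int:
    """1 iff ``score >= threshold`` (boundary counts as positive)."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return int(score >= threshold)


def neighbor_peptides(pep: str, matrix: SubstitutionMatrix | None = None) -> list[str]:
    """The L most-akin peptides: one best substitution per position."""
    validate_peptide(pep)
    matrix = matrix or blosum62()
    out = []
    for i, a in enumerate(pep):
        out.append(pep[:i] + most_similar_residue(a, matrix) + pep[i + 1 :])
    return out


def _as_scorer(model):
    if callable(model) and not hasattr(model, "predict_scores"):
        return model
    return model.predict_scores


def majority_vote(
    model,
    record: PredictionRecord,
    matrix: SubstitutionMatrix | None = None,
    threshold: float = 0.5,
) -> PredictionRecord:
    """Flip ``record.call`` when a strict majority of neighbors disagrees."""
    scorer = _as_scorer(model)
    neighbors = neighbor_peptides(record.seq, matrix)
    calls = [binary_call(float(s), threshold) for s in scorer(neighbors)]
    disagree = sum(1 for c in calls if c != record.call)
    flipped = disagree > len(neighbors) / 2
    return replace(record, call_post=1 - record.call if flipped else record.call)


def postprocess_records(
    model,
    records,
    matrix: SubstitutionMatrix | None = None,
    threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Vectorized majority vote: scores all neighbors in one model call."""
    records = list(records)
    if not records:
        return []
    matrix = matrix or blosum62()
    scorer = _as_scorer(model)
    all_neighbors, offsets = [], [0]
    for rec in records:
        nb = neighbor_peptides(rec.seq, matrix)
        all_neighbors.extend(nb)
        offsets.append(len(all_neighbors))
    scores = np.asarray(scorer(all_neighbors), dtype=float)
    out = []
    for rec, lo, hi in zip(records, offsets[:-1], offsets[1:]):
        calls = (scores[lo:hi] >= threshold).astype(int)
        disagree = int(np.sum(calls != rec.call))
        flipped = disagree > (hi - lo) / 2
        out.append(replace(rec, call_post=1 - rec.call if flipped else rec.call))
    return out


def ensemble_union(calls_a, calls_b) -> np.ndarray:
    """Join predictive positives from two methods: elementwise logical OR."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    return (a | b).astype(int)
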