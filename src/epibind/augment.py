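"""BLOSUM62 data augmentation and on-batch class balancing.

Positive peptides are rare (prevalence near 1:40 in real binding tables),
so training batches are resampled to a chosen "virtual" prevalence, and the
oversampled positives are diversified by substituting a bounded number of
residues with similar ones: a replacement ``a -> b`` is allowed only when
``BLOSUM62(a, b) >= tolerance``. Negatives pass through unaugmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from epibind.alphabet import AA_ORDER, encode_batch, validate_peptide
from epibind.substitution import SubstitutionMatrix, blosum62


@dataclass(frozen=True)
class AugmentConfig:
    """Number of substituted positions and the minimum allowed score.

    ``n_sub=0`` disables augmentation. Note no BLOSUM62 off-diagonal entry
    reaches 4, so ``tolerance=4`` also yields the identity map.
    """

    n_sub: int = 2
    tolerance: int = 0

    def __post_init__(self):
        if self.n_sub < 0:
            raise ValueError("n_sub must be >= 0")


@dataclass
class Batch:
    inputs: np.ndarray  # (batch, L, 20) one-hot stack
    labels: np.ndarray  # (batch,) in {0,1}
    seqs: list
    virtual_prevalence: float


_ALLOWED_CACHE: dict = {}


def allowed_substitutions(matrix: SubstitutionMatrix, tolerance: int) -> dict:
    """Map residue -> list of distinct residues scoring >= tolerance."""
    key = (matrix.name, tolerance)
    if key not in _ALLOWED_CACHE:
        _ALLOWED_CACHE[key] = {
            a: [b for b in AA_ORDER if b != a and matrix.score(a, b) >= tolerance]
            for a in AA_ORDER
        }
    return _ALLOWED_CACHE[key]


def augment_peptide(
    pep: str,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    matrix: SubstitutionMatrix | None = None,
) -> str:
    """Randomly substitute up to ``cfg.n_sub`` residues with similar ones.

    Positions are drawn uniformly without replacement; each drawn position
    receives a replacement drawn uniformly from its allowed set, or is left
    unchanged when the set is empty. Length is always preserved.
    """
    validate_peptide(pep)
    if cfg.n_sub == 0:
        return pep
    matrix = matrix or blosum62()
    table = allowed_substitutions(matrix, cfg.tolerance)
    n = min(cfg.n_sub, len(pep))
    positions = rng.choice(len(pep), size=n, replace=False)
    out = list(pep)
    for pos in positions:
        allowed = table[out[pos]]
        if not allowed:
            continue
        out[pos] = allowed[rng.integers(len(allowed))]
    return "".join(out)


def positive_count(batch_size: int, virtual_prevalence: float) -> int:
    """Round-half-up positive count; guarantees >= 1 when prevalence > 0 and batch >= 2."""
    if not 0 <= virtual_prevalence <= 1:
        raise ValueError("virtual_prevalence must be in [0, 1]")
    return int(np.floor(batch_size * virtual_prevalence + 0.5))


def sample_balanced_batch(
    train,
    batch_size: int,
    virtual_prevalence: float,
    aug: AugmentConfig,
    rng: np.random.Generator,
    matrix: SubstitutionMatrix | None = None,
) -> Batch:
    """Sample a class-balanced, augmentation-diversified training batch.

    Exactly ``round(batch_size * virtual_prevalence)`` positives are drawn
    with replacement and passed through :func:`augment_peptide`; the rest
    are negatives drawn with replacement, unaugmented; the batch order is
    shuffled.
    """
    pos = [p.seq for p in train if p.label == 1]
    neg = [p.seq for p in train if p.label == 0]
    n_pos = positive_count(batch_size, virtual_prevalence)
    n_neg = batch_size - n_pos
    if n_pos > 0 and not pos:
        raise ValueError("training set has no positives")
    if n_neg > 0 and not neg:
        raise ValueError("training set has no negatives")
    matrix = matrix or blosum62()
    seqs, labels = [], []
    for _ in range(n_pos):
        seqs.append(augment_peptide(pos[rng.integers(len(pos))], aug, rng, matrix))
        labels.append(1)
    for _ in range(n_neg):
        seqs.append(neg[rng.integers(len(neg))])
        labels.append(0)
    order = rng.permutation(batch_size)
    seqs = [seqs[i] for i in order]
    labels = np.array([labels[i] for i in order], dtype=np.float64)
    return Batch(
        inputs=encode_batch(seqs),
        labels=labels,
        seqs=seqs,
        virtual_prevalence=virtual_prevalence,
    )
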