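"""Smith-Waterman local alignment with affine gap penalties (Gotoh).

Used to map epitope sequences back onto their source proteins so that the
occupied span can be labeled positive and the remaining sequence tiled into
negatives. Scoring is BLOSUM62 with affine gaps (open 11, extend 1: a gap of
length k costs 11 + (k-1)). Ties between equal-scoring optima are broken
deterministically in favor of the alignment whose target span ends left-most
(row-major scan order), so repeated runs always return the same span.
"""

from __future__ import annotations

from dataclasses import dataclass

from epibind.alphabet import validate_peptide
from epibind.substitution import SubstitutionMatrix, blosum62

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a target.

    Coordinates are 1-based inclusive on both sequences. ``aligned`` is
    False when the optimal local score is 0 (no positive-scoring segment),
    in which case the coordinate fields are 0.
    """

    score: int
    target_start: int = 0
    target_end: int = 0
    query_start: int = 0
    query_end: int = 0
    aligned: bool = False
    identity: float = 0.0
    gapped: bool = False


def sw_align(
    query: str,
    target: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal local alignment score and span of ``query`` within ``target``.

    Three-state affine DP: M (residue pair), Ix (gap in target, consumes
    query), Iy (gap in query, consumes target); all states floor at the
    local-alignment zero. The best-scoring M cell is selected with a strict
    ``>`` under row-major scanning, which keeps the left-most optimum.
    """
    matrix = matrix or blosum62()
    validate_peptide(query, name="query")
    validate_peptide(target, name="target")
    n, m = len(query), len(target)

    sub = matrix.scores
    from epibind.alphabet import AA_INDEX

    q = [AA_INDEX[a] for a in query]
    t = [AA_INDEX[a] for a in target]

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi = Iy[i]
        srow = sub[q[i - 1]]
        for j in range(1, m + 1):
            ix = max(Mi1[j] - gap_open, Ixi1[j] - gap_extend)
            iy = max(Mi[j - 1] - gap_open, Iyi[j - 1] - gap_extend)
            Ixi[j] = ix
            Iyi[j] = iy
            diag = max(Mi1[j - 1], Ixi1[j - 1], Iy[i - 1][j - 1])
            sc = (diag if diag > 0 else 0.0) + srow[t[j - 1]]
            if sc < 0:
                sc = 0.0
            Mi[j] = sc
            if sc > best:
                best, bi, bj = sc, i, j

    if best <= 0:
        return AlignmentResult(score=0)

    # Traceback from the best M cell to recover spans and identity.
    i, j, state = bi, bj, "M"
    matches = 0
    aligned_cols = 0
    gapped = False
    while True:
        if state == "M":
            aligned_cols += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            diag_m, diag_x, diag_y = M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]
            prev = max(diag_m, diag_x, diag_y)
            i, j = i - 1, j - 1
            if prev <= 0:
                break
            state = "M" if diag_m == prev else ("X" if diag_x == prev else "Y")
        elif state == "X":
            gapped = True
            aligned_cols += 1
            came_open = M[i - 1][j] - gap_open
            came_ext = Ix[i - 1][j] - gap_extend
            state = "M" if came_open >= came_ext else "X"
            i -= 1
        else:  # Y
            gapped = True
            aligned_cols += 1
            came_open = M[i][j - 1] - gap_open
            came_ext = Iy[i][j - 1] - gap_extend
            state = "M" if came_open >= came_ext else "Y"
            j -= 1

    return AlignmentResult(
        score=int(best),
        target_start=j + 1,
        target_end=bj,
        query_start=i + 1,
        query_end=bi,
        aligned=True,
        identity=matches / aligned_cols if aligned_cols else 0.0,
        gapped=gapped,
    )
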