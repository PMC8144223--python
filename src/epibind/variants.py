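"""Missense variants to scored, expression-annotated candidate peptides.

A missense single-nucleotide variant substitutes one residue in a protein;
the candidate neoantigen is the length-L window of the mutated protein
centered at the substituted position (shifted, never padded, at the
termini). Candidates are scored by a trained binder and reported ranked by
probability with the gene's FPKM attached for the user's examination —
expression is never used for filtering or ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from epibind.alphabet import AA_INDEX
from epibind.dataset import ProteinRecord
from epibind.postprocess import PredictionRecord, postprocess_records

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MissenseVariant:
    protein_acc: str
    pos: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    gene: str = ""

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt residues are identical: {self.ref_aa}")


@dataclass(frozen=True)
class VariantPeptide:
    variant: MissenseVariant
    seq: str
    mut_offset: int  # 0-based index of the substituted residue in seq
    start: int  # 1-based window start on the protein


@dataclass(frozen=True)
class RankedCandidate:
    rank: int
    seq: str
    gene: str
    probability: float
    fpkm: float
    call_post: int | None = None


DEFAULT_VEP_COLUMNS = {
    "consequence": "Consequence",
    "accession": "ENSP",
    "position": "Protein_position",
    "amino_acids": "Amino_acids",
    "gene": "SYMBOL",
}


def parse_missense_table(source, columns: dict | None = None) -> list[MissenseVariant]:
    """Parse a VEP-style TSV (or DataFrame), keeping only missense rows.

    The amino-acid change field ``"R/Q"`` is split into ref/alt; malformed
    rows are skipped with a logged warning. ``Protein_position`` ranges like
    ``"57-57"`` collapse to their first coordinate.
    """
    cols = dict(DEFAULT_VEP_COLUMNS)
    if columns:
        cols.update(columns)
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    out = []
    for _, row in df.iterrows():
        if "missense_variant" not in str(row[cols["consequence"]]):
            continue
        change = str(row[cols["amino_acids"]])
        parts = change.split("/")
        if len(parts) != 2 or not all(len(p) == 1 and p in AA_INDEX for p in parts):
            logger.warning("skipping malformed amino-acid change %r", change)
            continue
        ref, alt = parts
        if ref == alt:
            logger.warning("skipping non-substitution change %r", change)
            continue
        try:
            pos = int(str(row[cols["position"]]).split("-")[0])
        except ValueError:
            logger.warning("skipping malformed protein position %r", row[cols["position"]])
            continue
        out.append(
            MissenseVariant(
                protein_acc=str(row[cols["accession"]]),
                pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                gene=str(row[cols["gene"]]) if cols["gene"] in df.columns else "",
            )
        )
    return out


def mutant_window(protein: ProteinRecord, v: MissenseVariant, L: int = 12) -> VariantPeptide:
    """Length-L mutant window centered at the substituted residue.

    The window start is ``pos - floor(L/2)`` (1-based), clamped into
    ``[1, len - L + 1]``; for even L the mutation sits at 0-based offset
    ``L // 2`` away from the start when no clamping occurs. The reference
    residue is checked against the protein before substituting.
    """
    n = len(protein.seq)
    if n < L:
        raise ValueError(
            f"protein {protein.acc} (length {n}) shorter than window length {L}"
        )
    if not 1 <= v.pos <= n:
        raise ValueError(f"position {v.pos} outside protein {protein.acc} (length {n})")
    found = protein.seq[v.pos - 1]
    if found != v.ref_aa:
        raise ValueError(
            f"reference mismatch at {protein.acc}:{v.pos}: expected {v.ref_aa}, found {found}"
        )
    mutated = protein.seq[: v.pos - 1] + v.alt_aa + protein.seq[v.pos :]
    start = min(max(1, v.pos - L // 2), n - L + 1)
    seq = mutated[start - 1 : start - 1 + L]
    return VariantPeptide(variant=v, seq=seq, mut_offset=v.pos - start, start=start)


def rank_candidates(
    peptides: list[VariantPeptide],
    model,
    fpkm: dict[str, float] | None = None,
    matrix=None,
    threshold: float = 0.5,
) -> list[RankedCandidate]:
    """Score, annotate with FPKM, and rank variant peptides.

    Sorted by probability descending with the sequence string as a stable
    tie-break; ranks run 1..n. A gene absent from the FPKM table gets 0.0
    with a logged warning. When ``matrix`` is given, the majority-vote
    postprocessed call is included.
    """
    peptides = list(peptides)
    if not peptides:
        return []
    fpkm = fpkm or {}
    scores = model.predict_scores([p.seq for p in peptides])
    call_posts = [None] * len(peptides)
    if matrix is not None:
        records = [
            PredictionRecord(seq=p.seq, score=float(s), call=int(s >= threshold))
            for p, s in zip(peptides, scores)
        ]
        call_posts = [r.call_post for r in postprocess_records(model, records, matrix, threshold)]
    rows = []
    for p, s, cp in zip(peptides, scores, call_posts):
        gene = p.variant.gene
        if gene in fpkm:
            expr = float(fpkm[gene])
        else:
            logger.warning("gene %r absent from expression table; FPKM set to 0", gene)
            expr = 0.0
        rows.append((float(s), p.seq, gene, expr, cp))
    rows.sort(key=lambda r: (-r[0], r[1]))
    return [
        RankedCandidate(rank=i + 1, seq=seq, gene=gene, probability=prob, fpkm=expr, call_post=cp)
        for i, (prob, seq, gene, expr, cp) in enumerate(rows)
    ]


def read_fpkm_table(path) -> dict[str, float]:
    """Two-column TSV gene<TAB>FPKM -> dict."""
    df = pd.read_csv(path, sep="\t")
    gene_col, fpkm_col = df.columns[:2]
    return {str(r[gene_col]): float(r[fpkm_col]) for _, r in df.iterrows()}


def write_candidates_csv(candidates, path) -> None:
    pd.DataFrame(
        [
            {
                "rank": c.rank,
                "sequence": c.seq,
                "gene": c.gene,
                "probability": c.probability,
                "fpkm": c.fpkm,
                "call_post": c.call_post,
            }
            for c in candidates
        ]
    ).to_csv(path, index=False)
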