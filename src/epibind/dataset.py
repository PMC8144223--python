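"""Labeled fixed-length peptide datasets from epitope/protein tables.

Positive examples are every length-L protein window that fully contains a
mapped epitope ("the epitope region extended through the original sequence
to a regular size"); negatives are length-L windows tiled over the regions
of the same proteins that do not overlap any known epitope span by even one
residue. Coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import train_test_split

from epibind.align import sw_align
from epibind.alphabet import AA_INDEX
from epibind.substitution import SubstitutionMatrix, blosum62

logger = logging.getLogger(__name__)

#: IEDB qualitative labels mapped to the binary binder class.
POSITIVE_LABELS = frozenset(
    {"Positive High", "Positive Intermediate", "Positive Low", "Positive"}
)
NEGATIVE_LABELS = frozenset({"Negative"})


@dataclass(frozen=True)
class EpitopeEntry:
    epitope_seq: str
    qual_label: str
    protein_acc: str
    haplotype: str = ""


@dataclass(frozen=True)
class ProteinRecord:
    acc: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def is_canonical(self) -> bool:
        return len(self.seq) >= 1 and all(a in AA_INDEX for a in self.seq)


@dataclass(frozen=True)
class WindowConfig:
    """Window length and negative-tiling parameters.

    ``L`` is the fixed peptide length (8, 10 or 12 residues, matching the
    lengths the binder models accept); ``negative_step`` is the tiling
    stride over epitope-free regions; ``dedup`` collapses identical peptide
    strings.
    """

    L: int = 12
    negative_step: int = 1
    dedup: bool = True

    def __post_init__(self):
        if self.L not in (8, 10, 12):
            raise ValueError(f"window length must be 8, 10 or 12, got {self.L}")
        if self.negative_step < 1:
            raise ValueError("negative_step must be >= 1")


@dataclass(frozen=True)
class LabeledPeptide:
    seq: str
    label: int
    protein_acc: str
    start: int
    end: int


@dataclass
class DatasetSplit:
    train: list
    test: list
    seed: int


@dataclass
class BuildStats:
    """Bookkeeping for entries dropped during dataset construction."""

    n_entries: int = 0
    n_positive_entries: int = 0
    n_negative_entries: int = 0
    n_unresolved_accession: int = 0
    n_non_canonical: int = 0
    n_too_long: int = 0
    n_unmappable: int = 0
    n_positive_windows: int = 0
    n_negative_windows: int = 0
    per_protein_spans: dict = field(default_factory=dict)


def binarize_label(qual_label: str) -> int:
    """Binarize an IEDB qualitative binding label (1 = binder)."""
    if qual_label in POSITIVE_LABELS:
        return 1
    if qual_label in NEGATIVE_LABELS:
        return 0
    raise ValueError(f"unknown qualitative label {qual_label!r}")


def positive_windows(
    protein: ProteinRecord, epitope_span: tuple[int, int], cfg: WindowConfig
) -> list[LabeledPeptide]:
    """All length-L windows of ``protein`` fully containing ``epitope_span``.

    Start positions run from ``max(1, end - L + 1)`` to
    ``min(start, len - L + 1)``; the count therefore has the closed form
    ``min(start, len - L + 1) - max(1, end - L + 1) + 1``.
    """
    s, e = epitope_span
    n, L = len(protein.seq), cfg.L
    if not (1 <= s <= e <= n):
        raise ValueError(f"span ({s},{e}) outside protein {protein.acc} of length {n}")
    if e - s + 1 > L:
        raise ValueError(f"span ({s},{e}) longer than window length {L}")
    if n < L:
        raise ValueError(f"protein {protein.acc} shorter than window length {L}")
    lo = max(1, e - L + 1)
    hi = min(s, n - L + 1)
    out = []
    for w in range(lo, hi + 1):
        out.append(
            LabeledPeptide(
                seq=protein.seq[w - 1 : w - 1 + L],
                label=1,
                protein_acc=protein.acc,
                start=w,
                end=w + L - 1,
            )
        )
    return out


def _free_segments(n: int, spans) -> list[tuple[int, int]]:
    """Maximal runs of positions 1..n not covered by any span."""
    covered = [False] * (n + 2)
    for s, e in spans:
        for p in range(max(1, s), min(n, e) + 1):
            covered[p] = True
    segs, start = [], None
    for p in range(1, n + 2):
        if p <= n and not covered[p]:
            if start is None:
                start = p
        else:
            if start is not None:
                segs.append((start, p - 1))
                start = None
    return segs


def negative_windows(
    protein: ProteinRecord, positive_spans, cfg: WindowConfig
) -> list[LabeledPeptide]:
    """Length-L windows tiled over the epitope-free regions of ``protein``.

    A window is emitted only if it overlaps no positive span by any residue;
    tiling restarts at the left edge of each free segment with stride
    ``cfg.negative_step``. With ``cfg.dedup`` identical strings collapse to
    their first occurrence.
    """
    n, L = len(protein.seq), cfg.L
    out, seen = [], set()
    for a, b in _free_segments(n, positive_spans):
        if b - a + 1 < L:
            continue
        for w in range(a, b - L + 2, cfg.negative_step):
            pep = protein.seq[w - 1 : w - 1 + L]
            if cfg.dedup:
                if pep in seen:
                    continue
                seen.add(pep)
            out.append(
                LabeledPeptide(seq=pep, label=0, protein_acc=protein.acc, start=w, end=w + L - 1)
            )
    return out


def build_dataset(
    entries,
    proteins: dict[str, ProteinRecord],
    cfg: WindowConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    min_identity: float = 0.9,
) -> tuple[list[LabeledPeptide], BuildStats]:
    """Map epitopes onto proteins and emit the labeled window dataset.

    Each positive entry is located on its source protein by Smith-Waterman
    local alignment; the alignment is accepted only if it covers the whole
    epitope without gaps (target span length equals epitope length) at
    >= ``min_identity`` identity, otherwise the entry is dropped as
    unmappable. Negatives come from the remaining sequence of proteins
    hosting at least one accepted epitope. No emitted negative string ever
    equals a positive window string from the same build.
    """
    cfg = cfg or WindowConfig()
    matrix = matrix or blosum62()
    stats = BuildStats()
    spans_by_protein: dict[str, list[tuple[int, int]]] = {}

    for entry in entries:
        stats.n_entries += 1
        label = binarize_label(entry.qual_label)
        if label == 0:
            stats.n_negative_entries += 1
            continue  # negatives come from remaining sequence, not from entries
        stats.n_positive_entries += 1
        protein = proteins.get(entry.protein_acc)
        if protein is None:
            stats.n_unresolved_accession += 1
            continue
        if not protein.is_canonical() or any(a not in AA_INDEX for a in entry.epitope_seq):
            stats.n_non_canonical += 1
            continue
        if len(entry.epitope_seq) > cfg.L:
            stats.n_too_long += 1
            continue
        res = sw_align(entry.epitope_seq, protein.seq, matrix, gap_open, gap_extend)
        span_len = res.target_end - res.target_start + 1
        full_query = res.query_start == 1 and res.query_end == len(entry.epitope_seq)
        if not (
            res.aligned
            and span_len == len(entry.epitope_seq)
            and full_query
            and res.identity >= min_identity
        ):
            stats.n_unmappable += 1
            logger.warning(
                "epitope %s unmappable on %s (aligned=%s identity=%.2f)",
                entry.epitope_seq,
                entry.protein_acc,
                res.aligned,
                res.identity,
            )
            continue
        spans_by_protein.setdefault(entry.protein_acc, []).append(
            (res.target_start, res.target_end)
        )

    if not spans_by_protein:
        raise ValueError("no usable entries: every entry was dropped or negative")

    dataset: list[LabeledPeptide] = []
    pos_strings: set[str] = set()
    positives: list[LabeledPeptide] = []
    for acc, spans in spans_by_protein.items():
        protein = proteins[acc]
        seen = set()
        for span in spans:
            if len(protein.seq) < cfg.L or span[1] - span[0] + 1 > cfg.L:
                stats.n_too_long += 1
                continue
            for pep in positive_windows(protein, span, cfg):
                if cfg.dedup and pep.seq in seen:
                    continue
                seen.add(pep.seq)
                positives.append(pep)
                pos_strings.add(pep.seq)
        stats.per_protein_spans[acc] = list(spans)

    negatives: list[LabeledPeptide] = []
    for acc, spans in spans_by_protein.items():
        for pep in negative_windows(proteins[acc], spans, cfg):
            if pep.seq in pos_strings:
                continue
            negatives.append(pep)

    dataset = positives + negatives
    stats.n_positive_windows = len(positives)
    stats.n_negative_windows = len(negatives)
    return dataset, stats


def split_train_test(dataset, test_frac: float = 0.1, seed: int = 0) -> DatasetSplit:
    """Label-stratified random split, disjoint by peptide string.

    Unique peptide strings (not window instances) are assigned to the two
    sides, so a peptide occurring in several proteins never leaks across
    the split. A string's label is the maximum over its instances, though
    :func:`build_dataset` already guarantees label consistency per string.
    """
    if not 0 < test_frac < 1:
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    dataset = list(dataset)
    by_string: dict[str, int] = {}
    for pep in dataset:
        by_string[pep.seq] = max(by_string.get(pep.seq, 0), pep.label)
    strings = sorted(by_string)
    labels = [by_string[s] for s in strings]
    for cls in (0, 1):
        if labels.count(cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 unique peptides; cannot split")
    train_s, test_s = train_test_split(
        strings, test_size=test_frac, random_state=seed, stratify=labels
    )
    test_set = set(test_s)
    train = [p for p in dataset if p.seq not in test_set]
    test = [p for p in dataset if p.seq in test_set]
    return DatasetSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# file interfaces

DEFAULT_EPITOPE_COLUMNS = {
    "epitope_seq": "epitope_seq",
    "qual_label": "qual_label",
    "protein_acc": "protein_acc",
    "haplotype": "haplotype",
}


def read_epitope_csv(path, columns: dict | None = None) -> list[EpitopeEntry]:
    """Read an IEDB-style epitope table; column names are configurable."""
    cols = dict(DEFAULT_EPITOPE_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        entries.append(
            EpitopeEntry(
                epitope_seq=str(row[cols["epitope_seq"]]).strip().upper(),
                qual_label=str(row[cols["qual_label"]]).strip(),
                protein_acc=str(row[cols["protein_acc"]]).strip(),
                haplotype=str(row[cols["haplotype"]]).strip()
                if cols["haplotype"] in df.columns
                else "",
            )
        )
    return entries


def read_protein_fasta(path) -> dict[str, ProteinRecord]:
    """Read proteins from FASTA; accession = first whitespace token of header."""
    proteins = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        seq = str(rec.seq).upper().rstrip("*")
        proteins[acc] = ProteinRecord(acc=acc, seq=seq)
    return proteins


def write_protein_fasta(proteins, path) -> None:
    with open(path, "w") as fh:
        for p in proteins.values() if isinstance(proteins, dict) else proteins:
            fh.write(f">{p.acc}\n{p.seq}\n")


def write_dataset_csv(dataset, path) -> None:
    pd.DataFrame(
        [
            {"seq": p.seq, "label": p.label, "protein_acc": p.protein_acc, "start": p.start, "end": p.end}
            for p in dataset
        ]
    ).to_csv(path, index=False)


def read_dataset_csv(path) -> list[LabeledPeptide]:
    df = pd.read_csv(path)
    return [
        LabeledPeptide(
            seq=str(r.seq), label=int(r.label), protein_acc=str(r.protein_acc),
            start=int(r.start), end=int(r.end),
        )
        for r in df.itertuples()
    ]
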