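"""Synthetic proteome/epitope/variant fixtures with a known motif truth.

The generator emulates the shape of the real inputs — a protein FASTA, an
IEDB-style epitope table, a VEP-style missense table, and an FPKM table —
while replacing assay-derived binding labels with a deterministic
anchor-motif ground truth, the way MHC class I binding is governed by a few
anchor residues in the bound core. An 8-mer core is a binder iff its anchor
positions carry allowed residues; implanted epitopes satisfy the motif by
construction and, under the default model, the background distribution
assigns zero probability to the anchor residues, so background sequence can
never form a binder. Noise-free datasets are therefore perfectly separable
by :func:`oracle_score`, which is what makes parameter-recovery tests of
the learning stack meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from epibind.alphabet import AA_ORDER
from epibind.dataset import EpitopeEntry, ProteinRecord
from epibind.variants import MissenseVariant

_DEFAULT_ANCHORS = {5: frozenset("WY"), 8: frozenset("CM")}


def _default_background() -> np.ndarray:
    """Uniform over the 16 residues outside the default anchor sets."""
    excluded = set().union(*_DEFAULT_ANCHORS.values())
    freqs = np.array([0.0 if aa in excluded else 1.0 for aa in AA_ORDER])
    return freqs / freqs.sum()


@dataclass(frozen=True)
class MotifModel:
    """Anchor-motif ground truth over an 8-mer binding core.

    ``anchor_positions`` maps 1-based core positions to allowed residue
    sets; ``background_freqs`` is the residue distribution of non-anchor
    sequence; ``noise_rate`` is the probability of flipping an implanted
    entry's qualitative label.
    """

    core_length: int = 8
    anchor_positions: dict = field(default_factory=lambda: dict(_DEFAULT_ANCHORS))
    background_freqs: np.ndarray = field(default_factory=_default_background)
    noise_rate: float = 0.0

    def __post_init__(self):
        freqs = np.asarray(self.background_freqs, dtype=float)
        if freqs.shape != (len(AA_ORDER),) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("background_freqs must be a 20-vector summing to 1")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        for pos, allowed in self.anchor_positions.items():
            if not 1 <= pos <= self.core_length:
                raise ValueError(f"anchor position {pos} outside core")
            if not allowed:
                raise ValueError(f"anchor position {pos} has an empty residue set")
        object.__setattr__(self, "background_freqs", freqs)

    def sample_core(self, rng: np.random.Generator) -> str:
        core = [
            AA_ORDER[j]
            for j in rng.choice(len(AA_ORDER), size=self.core_length, p=self.background_freqs)
        ]
        for pos, allowed in self.anchor_positions.items():
            opts = sorted(allowed)
            core[pos - 1] = opts[rng.integers(len(opts))]
        return "".join(core)

    def core_matches(self, core: str) -> bool:
        return all(core[p - 1] in allowed for p, allowed in self.anchor_positions.items())


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 200
    protein_length_range: tuple = (300, 500)
    n_positive_entries: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_positive_entries < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.protein_length_range
        if lo > hi or lo < 8:
            raise ValueError("protein_length_range must be sane and >= core length")


def sample_proteome(
    cfg: SyntheticConfig, rng: np.random.Generator, motif: MotifModel | None = None
) -> list[ProteinRecord]:
    """i.i.d. background proteins with accessions SYN000001, SYN000002, ..."""
    motif = motif or MotifModel()
    lo, hi = cfg.protein_length_range
    out = []
    for i in range(cfg.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(
            AA_ORDER[j] for j in rng.choice(len(AA_ORDER), size=n, p=motif.background_freqs)
        )
        out.append(ProteinRecord(acc=f"SYN{i + 1:06d}", seq=seq))
    return out


def implant_epitopes(
    proteome: list[ProteinRecord],
    motif: MotifModel,
    n_pos: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[list[ProteinRecord], list[EpitopeEntry], dict]:
    """Write motif-consistent cores into the proteome at random positions.

    Cores never overlap a previously implanted span on the same protein.
    Returns the modified proteome, IEDB-style entries labeled
    "Positive High" (flipped to "Negative" with probability
    ``motif.noise_rate``), and the true span map ``acc -> [(start, end)]``.
    """
    seqs = {p.acc: list(p.seq) for p in proteome}
    spans: dict[str, list] = {p.acc: [] for p in proteome}
    accs = [p.acc for p in proteome]
    entries = []
    k = motif.core_length
    for _ in range(n_pos):
        placed = False
        for _attempt in range(max_attempts):
            acc = accs[rng.integers(len(accs))]
            n = len(seqs[acc])
            if n < k:
                continue
            start = int(rng.integers(1, n - k + 2))
            end = start + k - 1
            if any(not (end < s or start > e) for s, e in spans[acc]):
                continue
            core = motif.sample_core(rng)
            seqs[acc][start - 1 : end] = list(core)
            spans[acc].append((start, end))
            label = "Positive High"
            if motif.noise_rate > 0 and rng.random() < motif.noise_rate:
                label = "Negative"
            entries.append(EpitopeEntry(epitope_seq=core, qual_label=label, protein_acc=acc))
            placed = True
            break
        if not placed:
            raise ValueError("insufficient proteome capacity to implant epitopes")
    new_proteome = [ProteinRecord(acc=p.acc, seq="".join(seqs[p.acc])) for p in proteome]
    truth = {acc: sorted(sp) for acc, sp in spans.items() if sp}
    return new_proteome, entries, truth


def oracle_score(pep: str, motif: MotifModel, soft: bool = False) -> float:
    """Ground-truth score: does any core-length subwindow satisfy the motif?

    Hard variant returns 1.0/0.0; the soft variant returns the fraction of
    anchors satisfied by the best subwindow.
    """
    k = motif.core_length
    if len(pep) < k:
        raise ValueError(f"peptide shorter than the {k}-residue core")
    best = 0.0
    n_anchors = len(motif.anchor_positions)
    for s in range(len(pep) - k + 1):
        core = pep[s : s + k]
        hits = sum(1 for p, allowed in motif.anchor_positions.items() if core[p - 1] in allowed)
        best = max(best, hits / n_anchors)
        if best == 1.0:
            break
    return best if soft else float(best == 1.0)


def random_negative_sampler(
    n: int, L: int, background_freqs, rng: np.random.Generator
) -> list[str]:
    """n i.i.d. background peptides of length L (blind-test style negatives)."""
    freqs = np.asarray(background_freqs, dtype=float)
    out = []
    for _ in range(n):
        out.append("".join(AA_ORDER[j] for j in rng.choice(len(AA_ORDER), size=L, p=freqs)))
    return out


def synth_variants(
    proteome: list[ProteinRecord],
    n: int,
    rng: np.random.Generator,
    min_protein_length: int = 12,
) -> tuple[list[MissenseVariant], dict[str, float]]:
    """Random missense variants plus a log-normal FPKM table.

    Each variant substitutes one residue of a randomly chosen protein with
    a uniformly drawn different canonical residue; gene symbols derive from
    the accession (SYN000007 -> Gsyn7). FPKM ~ LogNormal(1, 1).
    """
    eligible = [p for p in proteome if len(p.seq) >= min_protein_length]
    if not eligible:
        raise ValueError("no protein long enough for variant windows")
    variants = []
    genes = set()
    for _ in range(n):
        p = eligible[rng.integers(len(eligible))]
        pos = int(rng.integers(1, len(p.seq) + 1))
        ref = p.seq[pos - 1]
        alts = [a for a in AA_ORDER if a != ref]
        alt = alts[rng.integers(len(alts))]
        gene = _gene_symbol(p.acc)
        genes.add(gene)
        variants.append(
            MissenseVariant(protein_acc=p.acc, pos=pos, ref_aa=ref, alt_aa=alt, gene=gene)
        )
    fpkm = {g: float(rng.lognormal(mean=1.0, sigma=1.0)) for g in sorted(genes)}
    return variants, fpkm


def _gene_symbol(acc: str) -> str:
    return "Gsyn" + str(int(acc.removeprefix("SYN")))


# ---------------------------------------------------------------------------
# fixture emission (the `simulate` subcommand)


def variants_to_vep_frame(variants):
    import pandas as pd

    return pd.DataFrame(
        {
            "Consequence": ["missense_variant"] * len(variants),
            "ENSP": [v.protein_acc for v in variants],
            "Protein_position": [v.pos for v in variants],
            "Amino_acids": [f"{v.ref_aa}/{v.alt_aa}" for v in variants],
            "SYMBOL": [v.gene for v in variants],
        }
    )


def write_fixture_dir(
    outdir,
    cfg: SyntheticConfig,
    motif: MotifModel | None = None,
    n_variants: int = 50,
) -> dict:
    """Emit proteins.fasta, epitopes.csv, variants.tsv, fpkm.tsv, truth.json."""
    import os

    import pandas as pd

    from epibind.dataset import write_protein_fasta

    motif = motif or MotifModel()
    rng = np.random.default_rng(cfg.seed)
    proteome = sample_proteome(cfg, rng, motif)
    proteome, entries, truth = implant_epitopes(proteome, motif, cfg.n_positive_entries, rng)
    variants, fpkm = synth_variants(proteome, n_variants, rng)

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "proteins": os.path.join(outdir, "proteins.fasta"),
        "epitopes": os.path.join(outdir, "epitopes.csv"),
        "variants": os.path.join(outdir, "variants.tsv"),
        "fpkm": os.path.join(outdir, "fpkm.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_protein_fasta(proteome, paths["proteins"])
    pd.DataFrame(
        {
            "epitope_seq": [e.epitope_seq for e in entries],
            "qual_label": [e.qual_label for e in entries],
            "protein_acc": [e.protein_acc for e in entries],
            "haplotype": ["SYN" for _ in entries],
        }
    ).to_csv(paths["epitopes"], index=False)
    variants_to_vep_frame(variants).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame({"gene": list(fpkm), "FPKM": [fpkm[g] for g in fpkm]}).to_csv(
        paths["fpkm"], sep="\t", index=False
    )
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "spans": truth,
                "anchors": {str(p): sorted(a) for p, a in motif.anchor_positions.items()},
                "core_length": motif.core_length,
                "noise_rate": motif.noise_rate,
            },
            fh,
            indent=2,
        )
    return paths
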