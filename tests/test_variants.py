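"""Variant parsing, mutant window geometry, and candidate ranking."""

import logging

import numpy as np
import pandas as pd
import pytest

from epibind.dataset import ProteinRecord
from epibind.variants import (
    MissenseVariant,
    VariantPeptide,
    mutant_window,
    parse_missense_table,
    rank_candidates,
    write_candidates_csv,
)


def _vep_frame(rows):
    return pd.DataFrame(
        rows, columns=["Consequence", "ENSP", "Protein_position", "Amino_acids", "SYMBOL"]
    )


def test_parse_keeps_only_missense_and_skips_malformed(caplog):
    df = _vep_frame(
        [
            ("missense_variant", "P1", 57, "E/K", "GeneA"),
            ("synonymous_variant", "P1", 12, "L/L", "GeneA"),
            ("missense_variant,splice_region_variant", "P2", "9-9", "R/Q", "GeneB"),
            ("missense_variant", "P3", 5, "E=", "GeneC"),
        ]
    )
    with caplog.at_level(logging.WARNING):
        variants = parse_missense_table(df)
    assert len(variants) == 2
    assert variants[0] == MissenseVariant("P1", 57, "E", "K", "GeneA")
    assert variants[1].pos == 9 and variants[1].ref_aa == "R"
    assert any("E=" in r.message for r in caplog.records)


def test_variant_requires_distinct_residues():
    with pytest.raises(ValueError):
        MissenseVariant("P1", 5, "A", "A")


# ---------------------------------------------------------------------------
# mutant windows


PROT = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY")  # length 20, all distinct


def test_centering_example():
    v = MissenseVariant("P1", 10, PROT.seq[9], "W" if PROT.seq[9] != "W" else "A")
    p = mutant_window(PROT, v, 12)
    assert (p.start, p.start + 11) == (4, 15)
    assert p.mut_offset == 6
    assert p.seq[p.mut_offset] == v.alt_aa


def test_left_clamp_example():
    v = MissenseVariant("P1", 2, PROT.seq[1], "A")
    p = mutant_window(PROT, v, 12)
    assert p.start == 1
    assert p.mut_offset == 1


def test_protein_shorter_than_window_rejected():
    short = ProteinRecord("P2", "ACDEFGHIKL")
    with pytest.raises(ValueError, match="shorter"):
        mutant_window(short, MissenseVariant("P2", 3, "D", "E"), 12)


def test_reference_mismatch_reports_expected_and_found():
    v = MissenseVariant("P1", 10, "W", "A")  # position 10 is actually L
    with pytest.raises(ValueError, match="expected W, found L"):
        mutant_window(PROT, v, 12)


@pytest.mark.parametrize("L", [8, 10, 12])
def test_window_geometry_exhaustive(L):
    n = len(PROT.seq)
    for pos in range(1, n + 1):
        ref = PROT.seq[pos - 1]
        alt = "A" if ref != "A" else "C"
        p = mutant_window(PROT, MissenseVariant("P1", pos, ref, alt), L)
        assert len(p.seq) == L
        assert 1 <= p.start <= n - L + 1
        assert 0 <= p.mut_offset < L  # clamping keeps the mutation inside
        assert p.seq[p.mut_offset] == alt
        # removing the substitution reproduces the wild-type window
        wt = p.seq[: p.mut_offset] + ref + p.seq[p.mut_offset + 1 :]
        assert wt == PROT.seq[p.start - 1 : p.start - 1 + L]
        # unclamped windows are centered with the mutation at offset L//2
        if L // 2 < pos <= n - (L - L // 2 - 1):
            assert p.mut_offset == L // 2


# ---------------------------------------------------------------------------
# ranking


class _StubModel:
    def predict_scores(self, peps):
        # deterministic score from the first residue
        return np.array([ord(p[0]) / 200 for p in peps])


def _candidates():
    out = []
    for i, (seq0, gene) in enumerate([("Y", "G1"), ("A", "G2"), ("M", "G3")]):
        seq = seq0 + "CDEFGHIKLMN"
        v = MissenseVariant(f"P{i}", 1, "A" if seq0 != "A" else "C", seq0, gene)
        out.append(VariantPeptide(variant=v, seq=seq, mut_offset=0, start=1))
    return out


def test_rank_is_probability_sorted_permutation(caplog):
    peps = _candidates()
    with caplog.at_level(logging.WARNING):
        ranked = rank_candidates(peps, _StubModel(), fpkm={"G1": 3.04, "G3": 0.5})
    assert [c.rank for c in ranked] == [1, 2, 3]
    assert sorted(c.seq for c in ranked) == sorted(p.seq for p in peps)
    probs = [c.probability for c in ranked]
    assert probs == sorted(probs, reverse=True)
    assert ranked[0].gene == "G1" and ranked[0].fpkm == 3.04
    missing = [c for c in ranked if c.gene == "G2"]
    assert missing[0].fpkm == 0.0
    assert any("G2" in r.message for r in caplog.records)


def test_rank_tie_break_is_sequence_alphabetical():
    class Const:
        def predict_scores(self, peps):
            return np.full(len(peps), 0.7)

    ranked = rank_candidates(_candidates(), Const(), fpkm={})
    seqs = [c.seq for c in ranked]
    assert seqs == sorted(seqs)


def test_empty_input_gives_empty_report():
    assert rank_candidates([], _StubModel()) == []


def test_report_csv_schema(tmp_path):
    ranked = rank_candidates(_candidates(), _StubModel(), fpkm={"G1": 1.0})
    path = tmp_path / "report.csv"
    write_candidates_csv(ranked, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["rank", "sequence", "gene", "probability", "fpkm", "call_post"]
    assert df["rank"].tolist() == [1, 2, 3]
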