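"""Dataset construction: label binarization, window enumeration, splitting."""

import numpy as np
import pytest

from epibind.dataset import (
    EpitopeEntry,
    LabeledPeptide,
    ProteinRecord,
    WindowConfig,
    binarize_label,
    build_dataset,
    negative_windows,
    positive_windows,
    split_train_test,
)


@pytest.mark.parametrize(
    "label,expected",
    [
        ("Positive High", 1),
        ("Positive Intermediate", 1),
        ("Positive Low", 1),
        ("Positive", 1),
        ("Negative", 0),
    ],
)
def test_binarize_known_labels(label, expected):
    assert binarize_label(label) == expected


def test_binarize_rejects_unknown_label():
    with pytest.raises(ValueError, match="Positiv"):
        binarize_label("Positiv")


# ---------------------------------------------------------------------------
# window enumeration


def _protein(n, acc="P1"):
    rng = np.random.default_rng(n)
    from epibind.alphabet import AA_ORDER

    return ProteinRecord(acc=acc, seq="".join(rng.choice(list(AA_ORDER), size=n)))


def test_positive_windows_enumeration_example():
    prot = _protein(20)
    wins = positive_windows(prot, (5, 12), WindowConfig(L=12))
    assert len(wins) == 5
    assert [w.start for w in wins] == [1, 2, 3, 4, 5]
    for w in wins:
        assert w.label == 1
        assert w.seq == prot.seq[w.start - 1 : w.end]


def test_positive_windows_single_placement():
    prot = _protein(12)
    wins = positive_windows(prot, (1, 12), WindowConfig(L=12))
    assert len(wins) == 1
    assert wins[0].seq == prot.seq


def test_positive_windows_protein_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="shorter"):
        positive_windows(_protein(11), (1, 8), WindowConfig(L=12))


def test_positive_windows_span_outside_protein_rejected():
    with pytest.raises(ValueError, match="outside"):
        positive_windows(_protein(20), (15, 22), WindowConfig(L=12))


def test_positive_window_count_matches_closed_form_and_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(300):
        L = int(rng.choice([8, 10, 12]))
        n = int(rng.integers(L, 60))
        e_len = int(rng.integers(1, L + 1))
        s = int(rng.integers(1, n - e_len + 2))
        e = s + e_len - 1
        prot = _protein(n)
        wins = positive_windows(prot, (s, e), WindowConfig(L=L))
        # independent enumeration: every start whose window contains the span
        brute = [
            w for w in range(1, n - L + 2) if w <= s and w + L - 1 >= e
        ]
        closed = min(s, n - L + 1) - max(1, e - L + 1) + 1
        assert [w.start for w in wins] == brute
        assert len(wins) == max(0, closed)


def test_negative_windows_tiling_examples():
    prot = _protein(36)
    stride1 = negative_windows(prot, [(13, 20)], WindowConfig(L=12, negative_step=1, dedup=False))
    assert len(stride1) == 6
    assert [w.start for w in stride1] == [1, 21, 22, 23, 24, 25]
    stride12 = negative_windows(prot, [(13, 20)], WindowConfig(L=12, negative_step=12, dedup=False))
    assert [w.start for w in stride12] == [1, 21]


def test_negative_windows_fully_covered_protein_is_empty():
    prot = _protein(30)
    assert negative_windows(prot, [(1, 30)], WindowConfig(L=12)) == []


def test_negative_windows_never_overlap_spans_property():
    rng = np.random.default_rng(17)
    for _ in range(300):
        L = int(rng.choice([8, 10, 12]))
        n = int(rng.integers(L, 80))
        spans = []
        for _ in range(rng.integers(0, 3)):
            a = int(rng.integers(1, n + 1))
            b = min(n, a + int(rng.integers(0, L)))
            spans.append((a, b))
        step = int(rng.integers(1, L + 1))
        wins = negative_windows(_protein(n), spans, WindowConfig(L=L, negative_step=step, dedup=False))
        covered = set()
        for a, b in spans:
            covered.update(range(a, b + 1))
        all_clear = [
            w for w in range(1, n - L + 2)
            if not (set(range(w, w + L)) & covered)
        ]
        starts = [w.start for w in wins]
        # emitted windows are clear of all spans and form a subset of the stride-1 set
        assert set(starts) <= set(all_clear)
        # the first window of every maximal clear segment is always emitted
        for w in all_clear:
            if w - 1 not in all_clear and (w == 1 or w - 1 not in all_clear):
                assert w in starts
        # within a segment, consecutive emitted starts differ by the stride
        for w1, w2 in zip(starts, starts[1:]):
            if w2 - w1 < L and w2 - w1 > 0 and all(
                x in all_clear for x in range(w1, w2 + 1)
            ):
                assert w2 - w1 == step


# ---------------------------------------------------------------------------
# build_dataset


def test_build_dataset_pooled_spans_and_no_label_leakage(small_dataset, small_world):
    dataset = small_dataset["dataset"]
    proteins = small_dataset["proteins"]
    pos_strings = {p.seq for p in dataset if p.label == 1}
    neg_strings = {p.seq for p in dataset if p.label == 0}
    assert pos_strings and neg_strings
    assert not pos_strings & neg_strings
    # round trip: every window matches its protein at the recorded span
    for p in dataset:
        assert p.seq == proteins[p.protein_acc].seq[p.start - 1 : p.end]
    # negatives exclude every true epitope span (pooled across entries)
    truth = small_world["truth"]
    for p in dataset:
        if p.label == 0 and p.protein_acc in truth:
            for s, e in truth[p.protein_acc]:
                assert p.end < s or p.start > e


def test_build_dataset_two_entries_one_protein_disjoint_epitopes():
    prot = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY")
    entries = [
        EpitopeEntry("ACDEFGHI", "Positive High", "P1"),
        EpitopeEntry("MNPQRSTV", "Positive Low", "P1"),
    ]
    dataset, stats = build_dataset(entries, {"P1": prot}, WindowConfig(L=12, negative_step=1))
    assert stats.n_positive_entries == 2
    spans = stats.per_protein_spans["P1"]
    assert len(spans) == 2
    for p in dataset:
        if p.label == 0:
            for s, e in spans:
                assert p.end < s or p.start > e


def test_build_dataset_rejects_when_nothing_usable():
    prot = ProteinRecord("P1", "ACDEFGHIKLMN")
    entries = [EpitopeEntry("ACDEFGHI", "Positive High", "MISSING")]
    with pytest.raises(ValueError, match="no usable"):
        build_dataset(entries, {"P1": prot}, WindowConfig(L=12))


def test_build_dataset_drops_overlong_and_unmappable_entries(small_world):
    proteins = {p.acc: p for p in small_world["proteome"]}
    acc = small_world["entries"][0].protein_acc
    entries = list(small_world["entries"][:10]) + [
        EpitopeEntry("A" * 13, "Positive High", acc),  # longer than L
        EpitopeEntry("WWWWWWWW", "Positive High", acc),  # cannot map
    ]
    dataset, stats = build_dataset(entries, proteins, WindowConfig(L=12, negative_step=4))
    assert stats.n_too_long >= 1
    assert stats.n_unmappable >= 1


# ---------------------------------------------------------------------------
# splitting


def _unique_dataset(n_pos, n_neg):
    from epibind.alphabet import AA_ORDER

    rng = np.random.default_rng(0)
    items, seen = [], set()
    while len(items) < n_pos + n_neg:
        seq = "".join(rng.choice(list(AA_ORDER), size=12))
        if seq in seen:
            continue
        seen.add(seq)
        label = 1 if len(items) < n_pos else 0
        items.append(LabeledPeptide(seq, label, "P", 1, 12))
    return items


def test_split_stratification_arithmetic():
    split = split_train_test(_unique_dataset(100, 900), test_frac=0.10, seed=0)
    assert len(split.test) == 100
    assert sum(p.label for p in split.test) == 10


def test_split_deterministic_and_disjoint(small_dataset):
    a = split_train_test(small_dataset["dataset"], 0.1, seed=3)
    b = split_train_test(small_dataset["dataset"], 0.1, seed=3)
    assert [p.seq for p in a.test] == [p.seq for p in b.test]
    assert not {p.seq for p in a.train} & {p.seq for p in a.test}


def test_split_rejects_bad_fraction_and_tiny_class():
    data = _unique_dataset(10, 10)
    with pytest.raises(ValueError):
        split_train_test(data, 0.0, seed=0)
    with pytest.raises(ValueError):
        split_train_test(_unique_dataset(1, 10), 0.5, seed=0)
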