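"""Reproducible end-to-end benchmark on synthetic motif data.

Generates the default synthetic study (200 proteins of 300-500 residues,
500 implanted anchor-motif epitopes, no label noise), builds the stride-1
window dataset, trains the default Bi-LSTM binder at a reduced step budget,
and evaluates on the held-out 10% split with and without the majority-vote
postprocessor. This is the package's parameter-recovery experiment: the
labels are a deterministic function of sequence, so a correctly wired
learning stack must recover near-perfect ranking.
"""

from __future__ import annotations

import numpy as np

from epibind.dataset import WindowConfig, build_dataset, split_train_test
from epibind.metrics import compute_metrics
from epibind.model import BiLSTMBinder
from epibind.postprocess import PredictionRecord, postprocess_records
from epibind.substitution import blosum62
from epibind.synthetic import MotifModel, SyntheticConfig, implant_epitopes, sample_proteome


def synthetic_end_to_end(
    seed: int = 0,
    n_proteins: int = 200,
    protein_length_range: tuple = (300, 500),
    n_epitopes: int = 500,
    noise_rate: float = 0.0,
    window_length: int = 12,
    negative_step: int = 1,
    epochs: int = 5,
    steps_per_epoch: int = 150,
    threshold: float = 0.5,
) -> dict:
    """Run simulate -> build -> split -> train -> evaluate -> postprocess.

    Returns a flat dict of the headline quantities plus the problem sizes.
    All randomness derives from ``seed``.
    """
    seed = int(seed) % (2**31)
    motif = MotifModel(noise_rate=noise_rate)
    cfg = SyntheticConfig(
        n_proteins=n_proteins,
        protein_length_range=protein_length_range,
        n_positive_entries=n_epitopes,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    proteome = sample_proteome(cfg, rng, motif)
    proteome, entries, _truth = implant_epitopes(proteome, motif, n_epitopes, rng)
    proteins = {p.acc: p for p in proteome}
    dataset, stats = build_dataset(
        entries, proteins, WindowConfig(L=window_length, negative_step=negative_step)
    )
    split = split_train_test(dataset, test_frac=0.10, seed=seed)

    model = BiLSTMBinder(
        peptide_length=window_length,
        epochs=epochs,
        steps_per_epoch=steps_per_epoch,
        validation_fraction=0.0,
        patience=0,
        random_state=seed,
    )
    model.fit([p.seq for p in split.train], [p.label for p in split.train])

    X_test = [p.seq for p in split.test]
    y_test = [p.label for p in split.test]
    scores = model.predict_scores(X_test)
    records = [
        PredictionRecord(seq=s, score=float(p), call=int(p >= threshold))
        for s, p in zip(X_test, scores)
    ]
    records = postprocess_records(model, records, blosum62(), threshold)
    raw = compute_metrics(y_test, scores, [r.call for r in records], threshold)
    post = compute_metrics(y_test, scores, [r.call_post for r in records], threshold)

    return {
        "n_positive_windows": stats.n_positive_windows,
        "n_negative_windows": stats.n_negative_windows,
        "n_test": len(X_test),
        "prevalence": raw.prevalence,
        "auc_roc": raw.auc_roc,
        "pr_auc": raw.pr_auc,
        "accuracy": raw.acc,
        "f1": raw.f1,
        "accuracy_postprocessed": post.acc,
        "ppv": raw.ppv,
        "ppv_postprocessed": post.ppv,
        "sensitivity": raw.sensitivity,
        "specificity": raw.specificity,
        "final_train_loss": model.history_[-1]["loss"],
    }
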