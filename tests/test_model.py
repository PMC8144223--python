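"""Estimator contracts, training behavior, and cross-validated grid search."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from epibind.model import BiLSTMBinder, cross_validate, make_folds, n_models_trained


@pytest.fixture(scope="module")
def fast_params():
    return dict(
        lstm_units=(6, 6, 6), dense_units=(8, 4, 1), dropout_rates=(0.0, 0.0),
        epochs=1, steps_per_epoch=5, batch_size=16,
        validation_fraction=0.0, patience=0, random_state=0,
    )


def _toy_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    from epibind.alphabet import AA_ORDER

    X, y = [], []
    for i in range(n):
        pep = list(rng.choice(list(AA_ORDER), size=12))
        lab = i % 2
        pep[3] = "W" if lab else "A"
        X.append("".join(pep))
        y.append(lab)
    return X, y


def test_sklearn_param_contract(fast_params):
    est = BiLSTMBinder(**fast_params)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.set_params(epochs=2)
    assert est.epochs == 2


def test_untrained_model_scores_in_unit_interval(fast_params):
    est = BiLSTMBinder(**fast_params)
    net = est.build_network()
    from epibind.alphabet import encode_batch

    X, _ = _toy_data(100)
    p, _ = net.forward(encode_batch(X))
    assert np.all((p >= 0) & (p <= 1))


def test_fit_predict_contracts(fast_params):
    X, y = _toy_data()
    est = BiLSTMBinder(**fast_params).fit(X, y)
    assert est.predict_scores([]).shape == (0,)
    scores = est.predict_scores(X[:10])
    perm = [9, 3, 0, 7, 1, 2, 8, 4, 6, 5]
    permuted = est.predict_scores([X[i] for i in perm])
    assert np.allclose(permuted, scores[perm], atol=1e-10)
    dup = est.predict_scores([X[0], X[0]])
    assert dup[0] == dup[1]
    proba = est.predict_proba(X[:4])
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert set(est.predict(X[:4])) <= {0, 1}


def test_wrong_length_peptide_rejected(fast_params):
    X, y = _toy_data()
    est = BiLSTMBinder(**fast_params).fit(X, y)
    with pytest.raises(ValueError, match="SHORT"):
        est.predict_scores(["SHORT"])


def test_fit_requires_both_classes(fast_params):
    X, _ = _toy_data(20)
    with pytest.raises(ValueError, match="both classes"):
        BiLSTMBinder(**fast_params).fit(X, [1] * 20)


def test_same_seed_reproduces_training_exactly(fast_params):
    X, y = _toy_data()
    a = BiLSTMBinder(**fast_params).fit(X, y)
    b = BiLSTMBinder(**fast_params).fit(X, y)
    assert a.history_ == b.history_
    assert np.array_equal(a.predict_scores(X[:8]), b.predict_scores(X[:8]))


def test_training_separates_clean_signal(small_split, trained_tiny_binder):
    """A fixed-anchor motif is learnable to near-perfect held-out ranking."""
    X_test = [p.seq for p in small_split.test]
    y_test = [p.label for p in small_split.test]
    auc = roc_auc_score(y_test, trained_tiny_binder.predict_scores(X_test))
    assert auc > 0.99
    losses = [h["loss"] for h in trained_tiny_binder.history_]
    assert losses[-1] < losses[0]


def test_checkpoint_round_trip(tmp_path, trained_tiny_binder, small_split):
    path = tmp_path / "binder.npz"
    trained_tiny_binder.save(path)
    loaded = BiLSTMBinder.load(path)
    X = [p.seq for p in small_split.test[:16]]
    assert np.array_equal(loaded.predict_scores(X), trained_tiny_binder.predict_scores(X))


def test_checkpoint_alphabet_mismatch_fails_loudly(tmp_path, trained_tiny_binder):
    path = tmp_path / "binder.npz"
    trained_tiny_binder.save(path)
    with np.load(path, allow_pickle=False) as data:
        payload = {k: data[k] for k in data.files}
    import ast

    meta = ast.literal_eval(str(payload["__meta__"][0]))
    meta["alphabet"] = "".join(reversed(meta["alphabet"]))
    payload["__meta__"] = np.array([repr(meta)])
    np.savez(path, **payload)
    with pytest.raises(ValueError, match="alphabet"):
        BiLSTMBinder.load(path)


# ---------------------------------------------------------------------------
# cross-validation


def test_fold_partition_depends_only_on_data_k_seed():
    _, y = _toy_data(40)
    a = make_folds(y, k=4, seed=1)
    b = make_folds(y, k=4, seed=1)
    c = make_folds(y, k=4, seed=2)
    for (tr1, va1), (tr2, va2) in zip(a, b):
        assert np.array_equal(va1, va2)
    assert any(not np.array_equal(v1, v2) for (_, v1), (_, v2) in zip(a, c))


def test_grid_search_bookkeeping_and_determinism(fast_params):
    X, y = _toy_data(48)
    grid = [{"learning_rate": 1e-3}, {"learning_rate": 1e-3}]
    results, best = cross_validate(
        X, y, grid, k=2, seed=0, base_estimator=BiLSTMBinder(**fast_params)
    )
    assert len(results) == 2
    assert all(len(r.fold_aucs) == 2 for r in results)
    # identical configs on identical folds give identical fold AUCs
    assert results[0].fold_aucs == results[1].fold_aucs
    for r in results:
        assert min(r.fold_aucs) <= r.mean_auc <= max(r.fold_aucs)
        assert np.isclose(r.mean_auc, np.mean(r.fold_aucs))
        assert np.isclose(r.std_auc, np.std(r.fold_aucs))
    assert best == grid[0]


def test_grid_search_model_count_arithmetic():
    assert n_models_trained(16, 5) == 80
    assert n_models_trained(1, 5) == 5


def test_cross_validate_rejects_degenerate_inputs(fast_params):
    X, y = _toy_data(20)
    with pytest.raises(ValueError):
        cross_validate(X, y, [], k=2, seed=0)
    with pytest.raises(ValueError):
        cross_validate(X, y, [{}], k=1, seed=0)
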