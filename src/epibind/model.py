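"""The bidirectional-LSTM peptide binder as a scikit-learn estimator.

:class:`BiLSTMBinder` maps fixed-length peptides to binding probabilities
in [0, 1]. The architecture is three stacked bidirectional LSTM layers
followed by three dense layers with two intermediate dropouts; the output
head is a single sigmoid unit (equivalent to a 2-way softmax) trained with
binary cross-entropy. Training consumes on-batch balanced, BLOSUM62-
augmented batches rather than raw epochs over the imbalanced dataset: one
"epoch" is ``steps_per_epoch`` freshly resampled batches at the configured
virtual prevalence.

The estimator follows scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``clone``
compatibility) so it composes with sklearn model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from epibind.alphabet import AA_ORDER, encode_batch, validate_peptide
from epibind.augment import AugmentConfig, sample_balanced_batch
from epibind.dataset import LabeledPeptide
from epibind.nn import Adam, BinderNetwork, bce_loss
from epibind.substitution import blosum62

logger = logging.getLogger(__name__)

_CHECKPOINT_VERSION = 1


def _as_peptides(X) -> list[str]:
    if hasattr(X, "tolist"):
        X = X.tolist()
    return [p.seq if isinstance(p, LabeledPeptide) else str(p) for p in X]


class BiLSTMBinder(ClassifierMixin, BaseEstimator):
    """Bidirectional-LSTM binary classifier over fixed-length peptides.

    Parameters
    ----------
    peptide_length : accepted input length L (8, 10 or 12 residues).
    lstm_units : units per bidirectional recurrent layer (3-tuple).
    dense_units : neurons per dense layer; the last entry is the 1-unit head.
    dropout_rates : rates for the two intermediate dropouts.
    learning_rate, batch_size, epochs, steps_per_epoch : Adam/loop settings.
        ``steps_per_epoch=None`` uses ``ceil(n_train / batch_size)``.
    virtual_prevalence : positive fraction enforced inside each batch.
    n_sub, tolerance : BLOSUM62 augmentation settings for sampled positives.
    validation_fraction, patience : early stopping on validation loss;
        ``patience=0`` or ``validation_fraction=0`` disables it.
    random_state : seed for the single generator driving initialization,
        sampling, augmentation and dropout. Fixed seed => identical runs.

    Attributes (after ``fit``)
    --------------------------
    net_ : the underlying NumPy network.
    history_ : per-epoch records (loss, val_loss, val_auc).
    classes_ : ``array([0, 1])``.
    """

    def __init__(
        self,
        peptide_length: int = 12,
        lstm_units: tuple = (64, 64, 64),
        dense_units: tuple = (64, 32, 1),
        dropout_rates: tuple = (0.3, 0.3),
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 20,
        steps_per_epoch: int | None = None,
        virtual_prevalence: float = 0.5,
        n_sub: int = 2,
        tolerance: int = 0,
        validation_fraction: float = 0.1,
        patience: int = 5,
        random_state: int | None = 0,
    ):
        self.peptide_length = peptide_length
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.dropout_rates = dropout_rates
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.virtual_prevalence = virtual_prevalence
        self.n_sub = n_sub
        self.tolerance = tolerance
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    # -- core API ---------------------------------------------------------

    def _validate_peptides(self, X) -> list[str]:
        peps = _as_peptides(X)
        for p in peps:
            validate_peptide(p, length=self.peptide_length)
        return peps

    def build_network(self, rng: np.random.Generator | None = None) -> BinderNetwork:
        """Construct the untrained network for the current configuration."""
        rng = rng or np.random.default_rng(self.random_state)
        return BinderNetwork(
            L=self.peptide_length,
            d_in=len(AA_ORDER),
            lstm_units=self.lstm_units,
            dense_units=self.dense_units,
            dropout_rates=self.dropout_rates,
            rng=rng,
        )

    def fit(self, X, y):
        """Train on peptides ``X`` (strings or LabeledPeptides) with labels ``y``."""
        peps = self._validate_peptides(X)
        y = np.asarray(y, dtype=int)
        if len(peps) != len(y):
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training set must contain both classes")

        rng = np.random.default_rng(self.random_state)
        items = [LabeledPeptide(p, int(lab), "", 0, 0) for p, lab in zip(peps, y)]

        use_val = self.validation_fraction > 0 and self.patience > 0
        if use_val:
            idx = np.arange(len(items))
            tr_idx, va_idx = train_test_split(
                idx,
                test_size=self.validation_fraction,
                random_state=int(rng.integers(2**31)),
                stratify=y,
            )
            train_items = [items[i] for i in tr_idx]
            val_peps = [peps[i] for i in va_idx]
            val_y = y[va_idx]
        else:
            train_items = items
            val_peps, val_y = [], np.array([])

        self.net_ = self.build_network(rng)
        opt = Adam(self.net_.param_layers, lr=self.learning_rate)
        aug = AugmentConfig(n_sub=self.n_sub, tolerance=self.tolerance)
        matrix = blosum62()
        steps = self.steps_per_epoch or max(1, int(np.ceil(len(train_items) / self.batch_size)))

        self.history_ = []
        best_val, best_weights, stall = np.inf, None, 0
        for epoch in range(self.epochs):
            losses = []
            for _ in range(steps):
                batch = sample_balanced_batch(
                    train_items, self.batch_size, self.virtual_prevalence, aug, rng, matrix
                )
                p, cache = self.net_.forward(batch.inputs, train=True, rng=rng)
                losses.append(bce_loss(p, batch.labels))
                opt.zero_grad()
                self.net_.backward(p, batch.labels, cache)
                opt.step()
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if use_val:
                val_p = self._score_network(val_peps)
                rec["val_loss"] = bce_loss(val_p, val_y.astype(float))
                if len(np.unique(val_y)) == 2:
                    rec["val_auc"] = float(roc_auc_score(val_y, val_p))
                if rec["val_loss"] < best_val:
                    best_val, best_weights, stall = rec["val_loss"], self.net_.get_weights(), 0
                else:
                    stall += 1
            self.history_.append(rec)
            logger.info("epoch %d: %s", epoch, rec)
            if use_val and stall >= self.patience:
                break
        if best_weights is not None:
            self.net_.set_weights(best_weights)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.peptide_length
        return self

    def _score_network(self, peptides, chunk: int = 256) -> np.ndarray:
        out = np.zeros(len(peptides))
        for lo in range(0, len(peptides), chunk):
            block = peptides[lo : lo + chunk]
            x = encode_batch(block)
            p, _ = self.net_.forward(x, train=False)
            out[lo : lo + len(block)] = p
        return out

    def predict_scores(self, X) -> np.ndarray:
        """Binding probability in [0, 1] per peptide, order-preserving."""
        self._check_fitted()
        peps = self._validate_peptides(X)
        if not peps:
            return np.zeros(0)
        return self._score_network(peps)

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit() or load()")

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config + alphabet + version."""
        self._check_fitted()
        meta = dict(
            version=_CHECKPOINT_VERSION,
            alphabet=AA_ORDER,
            params=self.get_params(),
        )
        np.savez(path, __meta__=np.array([repr(meta)]), **self.net_.get_weights())

    @classmethod
    def load(cls, path) -> "BiLSTMBinder":
        """Load a checkpoint; fails loudly on alphabet or version mismatch."""
        import ast

        with np.load(path, allow_pickle=False) as data:
            meta = ast.literal_eval(str(data["__meta__"][0]))
            if meta["alphabet"] != AA_ORDER:
                raise ValueError(
                    f"checkpoint alphabet {meta['alphabet']!r} does not match {AA_ORDER!r}"
                )
            if meta["version"] != _CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            est = cls(**meta["params"])
            est.net_ = est.build_network(np.random.default_rng(0))
            est.net_.set_weights({k: data[k] for k in data.files if k != "__meta__"})
        est.classes_ = np.array([0, 1])
        est.history_ = []
        return est


@dataclass
class CVResult:
    """Per-configuration cross-validation record."""

    params: dict
    fold_aucs: list
    mean_auc: float
    std_auc: float


def n_models_trained(n_configs: int, k: int) -> int:
    """Models a grid search will fit: one per (configuration, fold) pair."""
    return n_configs * k


def make_folds(y, k: int = 5, seed: int = 0):
    """Label-stratified k-fold partition depending only on (y, k, seed)."""
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    for _, va in folds:
        if len(np.unique(y[va])) < 2:
            raise ValueError("a fold lacks one of the classes; reduce k or add data")
    return folds


def cross_validate(
    X,
    y,
    grid: list[dict],
    k: int = 5,
    seed: int = 0,
    base_estimator: BiLSTMBinder | None = None,
) -> tuple[list[CVResult], dict]:
    """Grid search by stratified k-fold cross-validation on mean AUC ROC.

    The fold partition is computed once from ``(y, k, seed)`` and reused for
    every configuration, so configs compete on identical splits. Returns the
    per-config fold AUCs and the parameter dict with the highest mean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not grid:
        raise ValueError("grid must be non-empty")
    peps = _as_peptides(X)
    y = np.asarray(y, dtype=int)
    folds = make_folds(y, k=k, seed=seed)
    base = base_estimator or BiLSTMBinder()
    results = []
    for params in grid:
        fold_aucs = []
        for tr, va in folds:
            est = BiLSTMBinder(**{**base.get_params(), **params})
            est.set_params(random_state=seed)
            est.fit([peps[i] for i in tr], y[tr])
            scores = est.predict_scores([peps[i] for i in va])
            fold_aucs.append(float(roc_auc_score(y[va], scores)))
        results.append(
            CVResult(
                params=dict(params),
                fold_aucs=fold_aucs,
                mean_auc=float(np.mean(fold_aucs)),
                std_auc=float(np.std(fold_aucs)),
            )
        )
    best = max(results, key=lambda r: r.mean_auc)
    return results, best.params
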