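import numpy as np
import pytest

from epibind.dataset import WindowConfig, build_dataset, split_train_test
from epibind.substitution import blosum62
from epibind.synthetic import (
    MotifModel,
    SyntheticConfig,
    implant_epitopes,
    sample_proteome,
)


@pytest.fixture(scope="session")
def b62():
    return blosum62()


@pytest.fixture(scope="session")
def motif():
    return MotifModel()


@pytest.fixture(scope="session")
def small_world(motif):
    """A small synthetic proteome with implanted epitopes and its truth map."""
    cfg = SyntheticConfig(
        n_proteins=40, protein_length_range=(120, 200), n_positive_entries=80, seed=11
    )
    rng = np.random.default_rng(cfg.seed)
    proteome = sample_proteome(cfg, rng, motif)
    proteome, entries, truth = implant_epitopes(proteome, motif, cfg.n_positive_entries, rng)
    return {"proteome": proteome, "entries": entries, "truth": truth, "cfg": cfg}


@pytest.fixture(scope="session")
def small_dataset(small_world):
    proteins = {p.acc: p for p in small_world["proteome"]}
    dataset, stats = build_dataset(
        small_world["entries"], proteins, WindowConfig(L=12, negative_step=2)
    )
    return {"dataset": dataset, "stats": stats, "proteins": proteins}


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_train_test(small_dataset["dataset"], test_frac=0.1, seed=5)


@pytest.fixture(scope="session")
def tiny_binder_params():
    """A deliberately small network for fast training in unit tests."""
    return dict(
        lstm_units=(12, 12, 12),
        dense_units=(16, 8, 1),
        dropout_rates=(0.1, 0.1),
        epochs=3,
        steps_per_epoch=60,
        batch_size=32,
        validation_fraction=0.0,
        patience=0,
        random_state=42,
    )


@pytest.fixture(scope="session")
def trained_tiny_binder(small_split, tiny_binder_params):
    from epibind.model import BiLSTMBinder

    model = BiLSTMBinder(**tiny_binder_params)
    model.fit([p.seq for p in small_split.train], [p.label for p in small_split.train])
    return model
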