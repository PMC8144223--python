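"""End-to-end experiment orchestration from a single YAML configuration.

Runs build-dataset -> (optional) cross-validate -> train-final -> evaluate
-> (optional) variants-to-peptides -> rank, writing every intermediate as
CSV/JSON plus a manifest carrying the configuration hash and package
version. Each stage failure aborts with the stage name and a
machine-readable error record on disk, so partial runs are diagnosable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import yaml

import epibind
from epibind.dataset import (
    WindowConfig,
    build_dataset,
    read_epitope_csv,
    read_protein_fasta,
    split_train_test,
    write_dataset_csv,
)
from epibind.metrics import compute_metrics
from epibind.model import BiLSTMBinder, cross_validate
from epibind.postprocess import PredictionRecord, postprocess_records
from epibind.substitution import blosum62
from epibind.variants import (
    mutant_window,
    parse_missense_table,
    rank_candidates,
    read_fpkm_table,
    write_candidates_csv,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _model_params(config: dict) -> dict:
    params = dict(config.get("model", {}))
    for key in ("lstm_units", "dense_units", "dropout_rates"):
        if key in params:
            params[key] = tuple(params[key])
    return params


def run_experiment(config: dict, outdir: str) -> dict:
    """Execute the configured pipeline; returns the manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    manifest = {
        "config_hash": chash,
        "version": epibind.__version__,
        "seed": seed,
        "outputs": [],
    }

    def emit(name, path):
        manifest["outputs"].append({"name": name, "path": os.path.basename(path)})

    def fail(stage, exc):
        record = {"stage": stage, "error": str(exc), "config_hash": chash}
        with open(os.path.join(outdir, "error.json"), "w") as fh:
            json.dump(record, fh, indent=2)
        raise StageError(stage, exc) from exc

    paths = config.get("paths", {})
    for key in ("epitopes", "proteins"):
        if key not in paths or not os.path.exists(paths[key]):
            fail("validate", FileNotFoundError(f"missing input path for {key!r}"))

    wc = config.get("window", {})
    cfg = WindowConfig(
        L=int(wc.get("length", 12)),
        negative_step=int(wc.get("step", 1)),
        dedup=bool(wc.get("dedup", True)),
    )

    try:
        logger.info("stage=build-dataset seed=%d hash=%s", seed, chash)
        entries = read_epitope_csv(paths["epitopes"])
        proteins = read_protein_fasta(paths["proteins"])
        dataset, stats = build_dataset(entries, proteins, cfg)
        dataset_path = os.path.join(outdir, "dataset.csv")
        write_dataset_csv(dataset, dataset_path)
        emit("dataset", dataset_path)
        split = split_train_test(dataset, config.get("test_frac", 0.1), seed)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("build-dataset", exc)

    X_train = [p.seq for p in split.train]
    y_train = [p.label for p in split.train]
    X_test = [p.seq for p in split.test]
    y_test = [p.label for p in split.test]

    params = _model_params(config)
    grid = config.get("grid")
    try:
        if grid:
            logger.info("stage=cross-validate seed=%d hash=%s", seed, chash)
            results, best = cross_validate(
                X_train, y_train, [dict(g) for g in grid],
                k=int(config.get("folds", 5)), seed=seed,
                base_estimator=BiLSTMBinder(**params),
            )
            cv_path = os.path.join(outdir, "cv_results.json")
            with open(cv_path, "w") as fh:
                json.dump(
                    [
                        {"params": r.params, "fold_aucs": r.fold_aucs,
                         "mean_auc": r.mean_auc, "std_auc": r.std_auc}
                        for r in results
                    ],
                    fh, indent=2, default=str,
                )
            emit("cv_results", cv_path)
            params.update(best)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("cross-validate", exc)

    try:
        logger.info("stage=train seed=%d hash=%s", seed, chash)
        params.setdefault("random_state", seed)
        model = BiLSTMBinder(**params)
        model.fit(X_train, y_train)
        ckpt = os.path.join(outdir, "model.npz")
        model.save(ckpt)
        emit("model", ckpt)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("train", exc)

    try:
        logger.info("stage=evaluate seed=%d hash=%s", seed, chash)
        threshold = float(config.get("threshold", 0.5))
        scores = model.predict_scores(X_test)
        records = [
            PredictionRecord(seq=s, score=float(p), call=int(p >= threshold))
            for s, p in zip(X_test, scores)
        ]
        records = postprocess_records(model, records, blosum62(), threshold)
        metrics = compute_metrics(y_test, scores, [r.call for r in records], threshold)
        metrics_post = compute_metrics(y_test, scores, [r.call_post for r in records], threshold)
        metrics_path = os.path.join(outdir, "metrics.json")
        with open(metrics_path, "w") as fh:
            json.dump(
                {"raw": metrics.to_dict(), "postprocessed": metrics_post.to_dict()},
                fh, indent=2, sort_keys=True,
            )
        emit("metrics", metrics_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("evaluate", exc)

    if "variants" in paths:
        try:
            logger.info("stage=rank seed=%d hash=%s", seed, chash)
            variants = parse_missense_table(paths["variants"])
            proteins = read_protein_fasta(paths["proteins"])
            peptides = []
            for v in variants:
                if v.protein_acc not in proteins:
                    logger.warning("variant accession %s unresolved", v.protein_acc)
                    continue
                try:
                    peptides.append(mutant_window(proteins[v.protein_acc], v, cfg.L))
                except ValueError as exc:
                    logger.warning("variant skipped: %s", exc)
            fpkm = read_fpkm_table(paths["fpkm"]) if "fpkm" in paths else {}
            ranked = rank_candidates(peptides, model, fpkm, matrix=blosum62())
            rank_path = os.path.join(outdir, "candidates.csv")
            write_candidates_csv(ranked, rank_path)
            emit("candidates", rank_path)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("rank", exc)

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
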