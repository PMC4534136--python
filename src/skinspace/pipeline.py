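"""End-to-end pipeline: scenes -> features -> selection -> reduction ->
training -> evaluation, with per-stage artifact persistence and resume."""

from __future__ import annotations

import json
import logging
import pickle
import time
from pathlib import Path

import numpy as np

from . import _seeds
from .classifiers import ClassifierSpec, train
from .colorspaces import ComponentRegistry, build_feature_matrix
from .config import RunConfig
from .evaluation import evaluate_pairs, roc
from .ga import GaConfig, run_ga
from .manifest import Manifest, split_manifest
from .pca import fit_pca, make_space
from .skn import HybridSpace
from .synth import SceneConfig, generate_dataset

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("skinspace")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - reported with stage context
                raise PipelineError(name, e) from e
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("synth")
def _ensure_manifest(config: RunConfig, out_dir: Path) -> Manifest:
    if config.manifest:
        manifest = Manifest.load(config.manifest)
    else:
        scene = SceneConfig(
            height=config.synth.height,
            width=config.synth.width,
            n_regions=config.synth.n_regions,
            background_mode=config.synth.background_mode,
            skin_fraction_target=config.synth.skin_fraction_target,
            seed=_seeds.substream_seed(config.seed, "synth"),
        )
        path = generate_dataset(
            config.synth.n_images, scene, out_dir=out_dir / "data"
        )
        manifest = Manifest.load(path)
    if not any(r.split for r in manifest.rows):
        manifest = split_manifest(
            manifest, config.train_fraction, _seeds.substream_seed(config.seed, "split")
        )
    manifest.save(out_dir / "manifest.csv")
    return manifest


@_stage("derive")
def _derive_space(config: RunConfig, manifest: Manifest, out_dir: Path) -> HybridSpace:
    space_path = out_dir / "space.json"
    if space_path.exists():
        return HybridSpace.from_dict(json.loads(space_path.read_text()))
    registry = ComponentRegistry.default()
    pairs = list(manifest.load_pairs("train"))
    data = build_feature_matrix(pairs, registry)
    if data.n_pixels > config.ga.feature_subsample:
        rng = _seeds.substream(config.seed, "feature_subsample")
        idx = np.sort(
            rng.choice(data.n_pixels, size=config.ga.feature_subsample, replace=False)
        )
        from .colorspaces import PixelFeatureMatrix

        data = PixelFeatureMatrix(data.values[idx], data.labels[idx], data.column_ids)
    ga_config = GaConfig(
        population_size=config.ga.population_size,
        mutation_prob=config.ga.mutation_prob,
        crossover_prob=config.ga.crossover_prob,
        max_generations=config.ga.max_generations,
        stall_window=config.ga.stall_window,
        elite_fraction=config.ga.elite_fraction,
        model_sample_fraction=config.ga.model_sample_fraction,
        random_fraction=config.ga.random_fraction,
        cv_folds=config.ga.cv_folds,
        fitness_subsample=config.ga.fitness_subsample,
        seed=_seeds.substream_seed(config.seed, "ga"),
    )
    result = run_ga(data, ga_config)
    subset_ids = [data.column_ids[i] for i in result.best.subset.indices()]
    (out_dir / "best_subset.json").write_text(
        json.dumps(
            {
                "component_ids": subset_ids,
                "f_score": result.best.f_score,
                "error_rate": result.best.error_rate,
                "generations": result.n_generations,
            },
            indent=2,
        )
    )
    with open(out_dir / "ga_history.csv", "w") as fh:
        fh.write("generation,best_f,mean_f,error_rate\n")
        for h in result.history:
            fh.write(
                f"{h['generation']},{h['best_f']:.6f},{h['mean_f']:.6f},{h['error_rate']:.6f}\n"
            )
    cols = result.best.subset.indices()
    model = fit_pca(data.values[:, cols], [data.column_ids[i] for i in cols])
    space = make_space(model, min(config.pca.n_components, model.d), name="derived")
    space_path.write_text(json.dumps(space.to_dict(), indent=2))
    return space


@_stage("train")
def _train_model(config: RunConfig, manifest: Manifest, space, out_dir: Path):
    from .classifiers import pixel_features

    model_path = out_dir / "model.bin"
    if model_path.exists():
        with open(model_path, "rb") as fh:
            return pickle.load(fh)
    X_parts, y_parts = [], []
    for image, mask in manifest.load_pairs("train"):
        X, ids = pixel_features(image, space)
        X_parts.append(X)
        y_parts.append(mask.labels.reshape(-1))
    spec = ClassifierSpec(
        kind=config.classifier.kind,
        params=config.classifier.params,
        seed=_seeds.substream_seed(config.seed, "classifier"),
    )
    model = train(spec, np.vstack(X_parts), np.concatenate(y_parts), feature_ids=ids)
    with open(model_path, "wb") as fh:
        pickle.dump(model, fh)
    return model


@_stage("evaluate")
def _evaluate(config: RunConfig, manifest: Manifest, space, model, out_dir: Path) -> dict:
    pairs = list(manifest.load_pairs("test"))
    avg, per_image = evaluate_pairs(model, pairs, space, config.evaluation.threshold)
    report = {
        "config": config.model_dump(),
        "n_train": len(manifest.subset("train")),
        "n_test": len(manifest.subset("test")),
        "metrics": {
            "FPR": avg.FPR,
            "precision": avg.precision,
            "TPR": avg.TPR,
            "f_score": avg.f_score,
        },
        "per_image": [m.as_dict() for m in per_image],
    }
    if config.evaluation.roc:
        curve = roc(model, pairs, space, config.evaluation.n_thresholds)
        report["auc"] = curve.auc
        with open(out_dir / "roc.csv", "w") as fh:
            fh.write("threshold,tpr,fpr\n")
            for t, tp, fp in zip(curve.thresholds, curve.tpr, curve.fpr):
                fh.write(f"{t:.6f},{tp:.6f},{fp:.6f}\n")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the evaluation report.

    Stage artifacts (manifest, subset, space, model, report) are persisted in
    ``config.out_dir``; existing artifacts are reused, so a run is resumable
    from any completed stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")
    log.info("pipeline starting (seed=%d, space=%s)", config.seed, config.space)
    manifest = _ensure_manifest(config, out_dir)
    if config.space == "derive":
        space = _derive_space(config, manifest, out_dir)
    else:
        space = config.space
    model = _train_model(config, manifest, space, out_dir)
    return _evaluate(config, manifest, space, model, out_dir)
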