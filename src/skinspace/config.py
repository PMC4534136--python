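"""Structured run configuration (strict: unknown keys are rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_images: int = 30
    height: int = 64
    width: int = 64
    n_regions: int = 3
    background_mode: str = "uniform_noise"
    skin_fraction_target: float = 0.3


class GaSection(_Strict):
    enabled: bool = False
    population_size: int = 25
    mutation_prob: float = 0.035
    crossover_prob: float = 0.55
    max_generations: int = 500
    stall_window: int = 100
    elite_fraction: float = 0.4
    model_sample_fraction: float = 0.5
    random_fraction: float = 0.2
    cv_folds: int = 10
    fitness_subsample: int = 20_000
    feature_subsample: int = 20_000  # pixels used to build the GA feature matrix


class PcaSection(_Strict):
    n_components: int = 3


class ClassifierSection(_Strict):
    kind: str = "random_forest"
    params: dict = Field(default_factory=dict)


class EvaluationSection(_Strict):
    threshold: float = 0.5
    roc: bool = True
    n_thresholds: int = 50


class TransformSection(_Strict):
    chroma_center: float = 0.5


class RunConfig(_Strict):
    """Top-level pipeline configuration; one master seed feeds all stages."""

    seed: int = 0
    space: str = "skn"  # "skn", a registry space name, or "derive"
    train_fraction: float = 0.75
    manifest: Optional[str] = None
    out_dir: str = "runs/latest"
    log_level: str = "INFO"
    transforms: TransformSection = Field(default_factory=TransformSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    ga: GaSection = Field(default_factory=GaSection)
    pca: PcaSection = Field(default_factory=PcaSection)
    classifier: ClassifierSection = Field(default_factory=ClassifierSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
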