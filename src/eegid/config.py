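"""Run configuration: one YAML file drives simulation, preprocessing, and
the study grid.  Serialization is canonical (sorted keys) so a config
round-trips parse -> serialize byte-identically and can be content-hashed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .model import TrainConfig
from .preprocess import FilterSpec


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 21
    seed: int = 7
    preset: str = "strong"  # separability preset: "strong" | "weak"
    duration_s: float = 60.0
    level3_completion_prob: float = 13.0 / 21.0
    fs_hz: float = 1000.0
    powerline_amp: float = 2.0
    sim_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfigError("cohort.n_subjects must be >= 2")
        if self.preset not in ("strong", "weak"):
            raise InvalidConfigError(f"cohort.preset must be strong|weak, got {self.preset!r}")


@dataclass(frozen=True)
class SegmentationConfig:
    window: int = 1000
    step: int = 500


@dataclass(frozen=True)
class StudyConfig:
    variants: tuple[str, ...] = ("A", "B")
    scenarios: tuple[str, ...] = ()  # empty = all
    regions: tuple[str, ...] = ()  # empty = all subsets; else e.g. ("C+O", "all")
    train_fraction: float = 0.8
    k: int = 5
    split_seed: int = 0
    model_seed: int = 0
    split_by_record: bool = False
    finalize_variant: str = "B"


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "eegid_out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @staticmethod
    def from_dict(payload: dict) -> "RunConfig":
        try:
            def tup(d, key):
                if key in d and isinstance(d[key], list):
                    d[key] = tuple(d[key])
            cohort = CohortConfig(**payload.get("cohort", {}))
            filters = FilterSpec(**payload.get("filters", {}))
            seg = SegmentationConfig(**payload.get("segmentation", {}))
            sd = dict(payload.get("study", {}))
            for key in ("variants", "scenarios", "regions"):
                tup(sd, key)
            study = StudyConfig(**sd)
            training = TrainConfig(**payload.get("training", {}))
        except TypeError as exc:
            raise InvalidConfigError(f"bad config field: {exc}") from exc
        return RunConfig(
            cohort=cohort,
            filters=filters,
            segmentation=seg,
            study=study,
            training=training,
            output_dir=payload.get("output_dir", "eegid_out"),
        )

    @staticmethod
    def load(path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise InvalidConfigError(f"cannot read config {path}: {exc}") from exc
        return RunConfig.from_dict(payload)

    def quick(self) -> "RunConfig":
        """CI-scale shrink: small cohort, short recordings, few epochs.

        Not faithful to the full protocol — for smoke runs only.
        """
        return RunConfig(
            cohort=CohortConfig(
                n_subjects=4,
                seed=self.cohort.seed,
                preset=self.cohort.preset,
                duration_s=12.0,
                level3_completion_prob=1.0,
                fs_hz=self.cohort.fs_hz,
                powerline_amp=self.cohort.powerline_amp,
                sim_seed=self.cohort.sim_seed,
            ),
            filters=self.filters,
            segmentation=self.segmentation,
            study=StudyConfig(
                variants=("A",),
                scenarios=("rest",),
                regions=("all",),
                train_fraction=self.study.train_fraction,
                k=3,
                split_seed=self.study.split_seed,
                model_seed=self.study.model_seed,
                split_by_record=self.study.split_by_record,
                finalize_variant="A",
            ),
            training=TrainConfig(
                max_epochs=3,
                batch_size=self.training.batch_size,
                learning_rate=self.training.learning_rate,
                seed=self.training.seed,
            ),
            output_dir=self.output_dir,
        )
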