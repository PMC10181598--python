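"""End-to-end orchestration: synth → wavelet scan → features → train → evaluate.

A pipeline run is driven by one flat YAML config with per-stage sections and
persists every stage's artifact as plain CSV/JSON so stages can be re-run
independently.  Identical configs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, ClassVar, Mapping

import yaml

from . import io as eog_io
from .classifiers import KernelParams, save_model
from .evaluation import ModelConfigs, SplitSpec, evaluate_all
from .features import build_feature_matrix
from .synth import SyntheticConfig, generate_recording, perturb_separability
from .wavelets import (
    DEFAULT_CANDIDATES,
    WaveletSpec,
    scan_families,
    select_mother,
)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "load_config", "run_pipeline"]

log = logging.getLogger("eogwave")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``problems`` lists every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated parameters of one full run."""

    input_path: str | None = None          # read a recording instead of synthesizing
    output_dir: str = "eogwave_run"
    seed: int = 4
    overlap: float = 0.0                   # class-overlap perturbation, 0 = none
    samples_per_segment: int = 6500
    sampling_rate: float = 650.0
    noise_sd: float = 0.004
    families: list[str] = field(
        default_factory=lambda: [spec.name for spec in DEFAULT_CANDIDATES]
    )
    mother: str | None = None              # override the entropy-scan selection
    level: int = 4
    window_width: int = 4
    k: int = 4
    C: float = 14.5
    gamma: float | None = None
    r: float = 1.0
    degree: int = 3
    max_nodes: int = 10
    train_fraction: float = 0.8
    jaccard_mode: str = "micro"
    verbosity: str = "info"

    _FIELD_TYPES: ClassVar[tuple[tuple[str, tuple[type, ...]], ...]] = (
        ("input_path", (str, type(None))),
        ("output_dir", (str,)),
        ("seed", (int,)),
        ("overlap", (int, float)),
        ("samples_per_segment", (int,)),
        ("sampling_rate", (int, float)),
        ("noise_sd", (int, float)),
        ("families", (list,)),
        ("mother", (str, type(None))),
        ("level", (int,)),
        ("window_width", (int,)),
        ("k", (int,)),
        ("C", (int, float)),
        ("gamma", (int, float, type(None))),
        ("r", (int, float)),
        ("degree", (int,)),
        ("max_nodes", (int,)),
        ("train_fraction", (int, float)),
        ("jaccard_mode", (str,)),
        ("verbosity", (str,)),
    )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a mapping, reporting every problem at once."""
        problems: list[str] = []
        known = dict(cls._FIELD_TYPES)
        for key in data:
            if key not in known:
                problems.append(f"unknown config key {key!r}")
        values: dict[str, Any] = {}
        for key, types in cls._FIELD_TYPES:
            if key not in data:
                continue
            value = data[key]
            if isinstance(value, bool) or not isinstance(value, types):
                problems.append(
                    f"key {key!r} has type {type(value).__name__}, expected "
                    + "/".join(t.__name__ for t in types)
                )
            else:
                values[key] = value
        if problems:
            raise ConfigError(problems)
        config = cls(**values)
        config.validate()
        return config

    def validate(self) -> None:
        problems = []
        if not 0.0 <= self.overlap <= 1.0:
            problems.append("overlap must lie in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            problems.append("train_fraction must lie strictly between 0 and 1")
        if self.window_width < 2:
            problems.append("window_width must be >= 2")
        if not 1 <= self.level <= 5:
            problems.append("level must lie in 1..5")
        for name in self.families:
            try:
                WaveletSpec.parse(name)
            except ValueError as exc:
                problems.append(str(exc))
        if self.mother is not None:
            try:
                WaveletSpec.parse(self.mother)
            except ValueError as exc:
                problems.append(str(exc))
        if self.jaccard_mode not in ("micro", "macro"):
            problems.append("jaccard_mode must be 'micro' or 'macro'")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["config file must contain a YAML mapping"])
    return PipelineConfig.from_dict(data)


def _json_dump(payload: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in order and persist every artifact.

    Writes ``recording.csv`` (when synthesized), ``entropy.csv``,
    ``features.csv``, one JSON model per classifier and ``report.json`` in
    ``config.output_dir``.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    config.validate()
    logging.basicConfig(level=config.verbosity.upper(), format="%(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "acquire"
    try:
        if config.input_path:
            log.info("reading recording from %s", config.input_path)
            recording = eog_io.read_recording(
                config.input_path, sampling_rate=config.sampling_rate
            )
        else:
            log.info(
                "synthesizing recording (seed=%d, samples_per_segment=%d)",
                config.seed,
                config.samples_per_segment,
            )
            recording = generate_recording(
                SyntheticConfig(
                    samples_per_segment=config.samples_per_segment,
                    sampling_rate=config.sampling_rate,
                    noise_sd=config.noise_sd,
                    seed=config.seed,
                )
            )
            if config.overlap > 0:
                log.info("applying separability perturbation overlap=%.3f", config.overlap)
                recording = perturb_separability(
                    recording, config.overlap, seed=config.seed
                )
            eog_io.write_recording(recording, out / "recording.csv", overwrite=True)

        stage = "wavelet-scan"
        candidates = [WaveletSpec.parse(name) for name in config.families]
        scan = scan_families(recording, candidates)
        scan.to_frame().to_csv(out / "entropy.csv", index=False)
        mother = (
            WaveletSpec.parse(config.mother) if config.mother else select_mother(scan)
        )
        log.info("mother wavelet: %s", mother.name)

        stage = "features"
        matrix = build_feature_matrix(
            recording, mother, level=config.level, width=config.window_width
        )
        matrix.to_csv(out / "features.csv")
        log.info("feature matrix: %d windows x %d features", *matrix.X.shape)

        stage = "train-evaluate"
        kernel = (
            KernelParams(config.gamma, config.r, config.degree)
            if config.gamma is not None
            else KernelParams(1.0 / matrix.X.shape[1], config.r, config.degree)
        )
        report = evaluate_all(
            matrix,
            SplitSpec(config.train_fraction, config.seed),
            ModelConfigs(
                k=config.k,
                C=config.C,
                kernel=kernel,
                max_nodes=config.max_nodes,
                svm_seed=config.seed,
                jaccard_mode=config.jaccard_mode,
            ),
        )

        stage = "persist"
        for name, model in report.models.items():
            save_model(model, out / f"model_{name}.json")
        run_report = {
            "config": config.to_dict(),
            "mother_wavelet": mother.name,
            "n_windows": matrix.n_windows,
            "evaluation": report.as_dict(),
        }
        _json_dump(run_report, out / "report.json")
        for name, result in report.algorithms.items():
            log.info(
                "%s: train Jaccard %.4f, test Jaccard %.4f",
                name,
                result.train_jaccard,
                result.test_jaccard,
            )
        return run_report
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError(stage, exc) from exc
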