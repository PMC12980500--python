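"""Run configuration: one YAML mapping drives the whole pipeline.

All randomness funnels through a single global ``seed`` that each stage
expands with fixed offsets, so one number reproduces a full run. Unknown keys
and invalid values are rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .attribution import METHODS
from .exceptions import ConfigurationError
from .synth import CLASSES, DEFAULT_PREVALENCES


def _from_mapping(cls, mapping: dict, where: str):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {unknown}")
    return cls(**mapping)


@dataclass
class DataBlock:
    n_patients: int = 120
    mean_records_per_patient: float = 4.5
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    noise_sd: float = 0.03
    record_length_s: float = 1.2
    sampling_rate: float = 500.0
    n_val_patients: int = 20
    n_test_patients: int = 25

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("data.n_patients must be >= 1")
        bad = [c for c in self.prevalences if c not in CLASSES]
        if bad:
            raise ConfigurationError(f"data.prevalences: unknown class(es) {bad}")


@dataclass
class ModelBlock:
    n_conv_layers: int = 8
    kernel_size: int = 7
    base_channels: int = 16
    halve_every: int = 2
    dropout_rate: float = 0.1
    epochs: int = 12
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 5


@dataclass
class GridBlock:
    classes: list = field(default_factory=lambda: list(CLASSES))
    n_seeds: int = 2

    def __post_init__(self):
        bad = [c for c in self.classes if c not in CLASSES]
        if bad:
            raise ConfigurationError(f"grid.classes: unknown class(es) {bad}")
        if not self.classes:
            raise ConfigurationError("grid.classes must be non-empty")
        if self.n_seeds < 1:
            raise ConfigurationError("grid.n_seeds must be >= 1")


@dataclass
class MethodsBlock:
    names: list = field(default_factory=lambda: list(METHODS))
    ig_steps: int = 64
    sg_samples: int = 32
    sg_noise: float = 0.1
    shapley_segments: int = 32
    shapley_samples: int = 256
    shap_baselines: int = 16
    gradcam_tap: int = -1

    def __post_init__(self):
        bad = [m for m in self.names if m not in METHODS]
        if bad:
            raise ConfigurationError(f"methods.names: unknown method(s) {bad}")
        if not self.names:
            raise ConfigurationError("methods.names must be non-empty")


@dataclass
class ExperimentsBlock:
    which: list = field(default_factory=lambda: [1, 2, 3, 4])
    n_records: int = 24
    smooth: bool = True
    smooth_window: int = 31
    smooth_polyorder: int = 3
    corr_kind: str = "pearson"
    randomization_class: str = "atrial_fibrillation"
    perturb_steps: int = 30
    perturb_step_frac: float = 0.01
    perturb_noise_sd: float = 0.25
    perturb_noise_mode: str = "multiplicative"

    def __post_init__(self):
        bad = [w for w in self.which if w not in (1, 2, 3, 4)]
        if bad:
            raise ConfigurationError(f"experiments.which: unknown experiment(s) {bad}")
        if self.randomization_class not in CLASSES:
            raise ConfigurationError(
                f"experiments.randomization_class: unknown class {self.randomization_class}")
        if self.corr_kind not in ("pearson", "spearman"):
            raise ConfigurationError("experiments.corr_kind must be pearson|spearman")
        if self.perturb_noise_mode not in ("multiplicative", "additive"):
            raise ConfigurationError(
                "experiments.perturb_noise_mode must be multiplicative|additive")
        if self.perturb_steps * self.perturb_step_frac > 1 + 1e-9:
            raise ConfigurationError("experiments: perturb_steps * perturb_step_frac > 1")


_BLOCKS = {"data": DataBlock, "model": ModelBlock, "grid": GridBlock,
           "methods": MethodsBlock, "experiments": ExperimentsBlock}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/desk"
    data: DataBlock = field(default_factory=DataBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    grid: GridBlock = field(default_factory=GridBlock)
    methods: MethodsBlock = field(default_factory=MethodsBlock)
    experiments: ExperimentsBlock = field(default_factory=ExperimentsBlock)

    def as_dict(self) -> dict:
        return asdict(self)

    # fixed per-stage seed offsets: one global number reproduces everything
    def seed_for(self, stage: str, index: int = 0) -> int:
        offsets = {"data": 1, "split": 2, "train": 1000, "baselines": 3,
                   "exp": 5000, "perturb": 7000}
        return int((self.seed * 9973 + offsets[stage] + index) % (2 ** 31))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration, materializing defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    known = {"seed", "output_dir"} | set(_BLOCKS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {unknown}")
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    for name, cls in _BLOCKS.items():
        kwargs[name] = _from_mapping(cls, raw.get(name), name)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))
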