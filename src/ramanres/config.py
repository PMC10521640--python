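"""One YAML file drives the whole pipeline.

A single ``global_seed`` deterministically derives every module seed by a
fixed additive offset, so one integer reproduces the simulation, the
augmentation draws, the parameter initialization and the training
shuffles:

    simulate  seed = global_seed + 11
    augment   seed = global_seed + 23
    model     seed = global_seed + 37
    train     seed = global_seed + 53
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .augment import AugmentConfig, IntensifyConfig
from .preprocess import PreprocessConfig
from .resnet import ModelConfig
from .simulate import Peak, SimConfig
from .train import EnsembleConfig, TrainConfig

__all__ = ["RunConfig", "SEED_OFFSETS", "load_run_config"]

SEED_OFFSETS = {"simulate": 11, "augment": 23, "model": 37, "train": 53}


@dataclass
class RunConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    intensify: IntensifyConfig = field(default_factory=IntensifyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    output_dir: str = "runs"
    log_level: str = "info"
    global_seed: int = 0

    def apply_global_seed(self, seed: Optional[int] = None) -> "RunConfig":
        """Derive all module seeds from ``global_seed`` (or ``seed``)."""
        if seed is not None:
            self.global_seed = int(seed)
        g = self.global_seed
        self.simulate.seed = g + SEED_OFFSETS["simulate"]
        self.augment.seed = g + SEED_OFFSETS["augment"]
        self.model.seed = g + SEED_OFFSETS["model"]
        self.train.seed = g + SEED_OFFSETS["train"]
        return self

    def to_dict(self) -> dict:
        def plain(obj: Any) -> Any:
            if hasattr(obj, "__dict__") and not isinstance(obj, type):
                return {k: plain(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = {name: plain(getattr(self, name)) for name in
             ("simulate", "preprocess", "augment", "intensify", "model", "train", "ensemble")}
        d["simulate"]["peak_table"] = [
            [p.center, p.width, p.base_amplitude, p.class_delta]
            for p in self.simulate.peak_table
        ]
        d.update(output_dir=self.output_dir, log_level=self.log_level,
                 global_seed=self.global_seed)
        return d


def _build(cls, data: dict, **convert):
    kwargs = dict(data or {})
    for key, fn in convert.items():
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = fn(kwargs[key])
    known = set(cls.__dataclass_fields__)
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**kwargs)


def load_run_config(path: Optional[str | Path] = None,
                    overrides: Optional[dict[str, Any]] = None) -> RunConfig:
    """Load a RunConfig from YAML; ``overrides`` maps dotted paths
    (e.g. ``train.epochs``) to values and wins over the file."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: top level of the config must be a mapping")
        data = loaded
    for dotted, value in (overrides or {}).items():
        node = data
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value

    def tup(v):
        return tuple(v)

    cfg = RunConfig(
        simulate=_build(
            SimConfig, data.get("simulate", {}),
            grid=tup,
            peak_table=lambda rows: [Peak(*row) for row in rows],
        ),
        preprocess=_build(PreprocessConfig, data.get("preprocess", {}), grid=tup),
        augment=_build(AugmentConfig, data.get("augment", {}), intensity_range=tup),
        intensify=_build(IntensifyConfig, data.get("intensify", {})),
        model=_build(ModelConfig, data.get("model", {}), channel_schedule=list),
        train=_build(TrainConfig, data.get("train", {}), split_fractions=tup),
        ensemble=_build(
            EnsembleConfig, data.get("ensemble", {}),
            weights=tup,
            split_windows=lambda ws: tuple(tuple(w) for w in ws),
        ),
        output_dir=str(data.get("output_dir", "runs")),
        log_level=str(data.get("log_level", "info")),
        global_seed=int(data.get("global_seed", 0)),
    )
    return cfg.apply_global_seed()
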