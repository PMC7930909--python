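"""Experiment configuration: YAML (or JSON) files resolved into typed objects.

A config file has three sections (architecture, data, training)::

    arch:
      preset: conv_small            # scalar | fc_small | conv_small
      coupling: bidirectional       # or unidirectional
      loss_mode: ce_readout         # or mse_output_layer
      n_classes: 4
      seed: 0                       # parameter initialization seed
    data:
      n_classes: 4
      image_size: [1, 8, 8]
      n_train: 256
      n_test: 256
      template_snr: 3.0
      seed: 0
    train:
      T: 30
      K: 10
      batch_size: 64
      lr_per_layer: [0.25, 0.15, 0.1]
      lr_final: 1.0e-5
      weight_decay: 3.0e-4
      momentum: 0.9
      epochs: 10
      cosine_decay_epochs: 10
      dropout_p: 0.0
      seed: 1
      estimator: {kind: symmetric, beta: 1.0, leakage: 0.0}

Unknown keys raise; missing keys fall back to defaults except the ones listed
in ``REQUIRED``.  ``resolve`` materializes every default so a resolved copy
written next to the outputs replays the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .data import FIXTURE_KINDS, ToyDatasetSpec, make_fixture_net
from .estimators import EstimatorConfig
from .model import ArchitectureSpec, Parameters
from .training import TrainConfig

__all__ = ["ConfigError", "load_config", "resolve", "dump_resolved", "build_model"]

REQUIRED = {"arch": ("preset",), "train": ("lr_per_layer",)}

_ARCH_DEFAULTS = {
    "preset": None,
    "coupling": "bidirectional",
    "loss_mode": "ce_readout",
    "n_classes": 4,
    "seed": 0,
}


class ConfigError(ValueError):
    """Invalid or incomplete experiment configuration."""


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return resolve(cfg)


def resolve(cfg: dict) -> dict:
    """Validate and materialize all defaults; returns a plain-dict config."""
    _check_keys("<root>", cfg, {"arch", "data", "train"})
    for section, keys in REQUIRED.items():
        if section not in cfg:
            raise ConfigError(f"missing required section '{section}'")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigError(f"missing required key '{section}.{key}'")

    arch = dict(_ARCH_DEFAULTS)
    _check_keys("arch", cfg["arch"], set(arch))
    arch.update(cfg["arch"])
    if arch["preset"] not in FIXTURE_KINDS:
        raise ConfigError(f"arch.preset must be one of {FIXTURE_KINDS}, got {arch['preset']!r}")

    data_in = dict(cfg.get("data", {}))
    allowed = {f.name for f in dataclasses.fields(ToyDatasetSpec)}
    _check_keys("data", data_in, allowed)
    if "image_size" in data_in:
        data_in["image_size"] = tuple(data_in["image_size"])
    data = dataclasses.asdict(ToyDatasetSpec(**data_in))

    train_in = dict(cfg["train"])
    allowed = {f.name for f in dataclasses.fields(TrainConfig)}
    _check_keys("train", train_in, allowed)
    est_in = dict(train_in.pop("estimator", {"kind": "symmetric", "beta": 1.0}))
    _check_keys("train.estimator", est_in, {f.name for f in dataclasses.fields(EstimatorConfig)})
    try:
        est = EstimatorConfig(**est_in)
        train_in["lr_per_layer"] = tuple(train_in["lr_per_layer"])
        tc = TrainConfig(estimator=est, **train_in)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    train = dataclasses.asdict(tc)
    return {"arch": arch, "data": data, "train": train}


def dump_resolved(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(cfg), sort_keys=False))


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: list(o) if isinstance(o, tuple) else o))


def build_model(cfg: dict) -> tuple[ArchitectureSpec, Parameters]:
    a = cfg["arch"]
    return make_fixture_net(
        a["preset"],
        coupling=a["coupling"],
        loss_mode=a["loss_mode"],
        seed=a["seed"],
        n_classes=a["n_classes"],
    )


def build_train_config(cfg: dict, seed: int | None = None) -> TrainConfig:
    t = dict(cfg["train"])
    est = EstimatorConfig(**t.pop("estimator"))
    t["lr_per_layer"] = tuple(t["lr_per_layer"])
    if seed is not None:
        t["seed"] = seed
    return TrainConfig(estimator=est, **t)


def build_dataset_spec(cfg: dict) -> ToyDatasetSpec:
    d = dict(cfg["data"])
    d["image_size"] = tuple(d["image_size"])
    return ToyDatasetSpec(**d)
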