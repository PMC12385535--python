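"""YAML configuration: a single file with model/loss/activation/augment/
train/data sections whose defaults mirror the reference training setup."""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import ModelConfig, test_scale_config
from .train import TrainConfig

DEFAULTS: dict = {
    "model": {
        "hidden_dim": 30,
        "embed_dim": 180,
        "head_num": 30,
        "attention_layer_num": 6,
        "classes_num": 9,
        "input_height": 784,
        "input_width": 1216,
        "linear_bias": True,
    },
    "activation": {"name": "starprelu", "conv_stem": "starprelu"},
    "loss": {"name": "efloss", "beta": 3.0, "gamma": 0.3},
    "augment": {"enabled": True, "gamma_range": [0.7, 1.3], "flip_p": 0.5},
    "train": {
        "epochs": 50,
        "batch_size": 10,
        "learning_rate": 0.001,
        "adam_beta1": 0.9,
        "adam_beta2": 0.999,
        "seed": 0,
        "preset": "full",
    },
    "data": {"root": "data", "counts": None, "image_height": 64, "image_width": 96},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with the YAML file at `path` (if given)."""
    cfg = DEFAULTS
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg


def model_config_from(cfg: dict) -> ModelConfig:
    m, a = cfg["model"], cfg["activation"]
    return ModelConfig(
        hidden_dim=m["hidden_dim"],
        embed_dim=m["embed_dim"],
        head_num=m["head_num"],
        atten_layer_num=m["attention_layer_num"],
        classes_num=m["classes_num"],
        input_height=m["input_height"],
        input_width=m["input_width"],
        activation=a["name"],
        conv_stem_activations=a["conv_stem"],
        linear_bias=m["linear_bias"],
    )


def train_config_from(cfg: dict, **overrides) -> TrainConfig:
    t, loss = cfg["train"], cfg["loss"]
    kwargs = dict(
        epochs=t["epochs"],
        batch_size=t["batch_size"],
        learning_rate=t["learning_rate"],
        adam_beta1=t["adam_beta1"],
        adam_beta2=t["adam_beta2"],
        seed=t["seed"],
        preset=t["preset"],
        efloss_beta=loss["beta"],
        efloss_gamma=loss["gamma"],
        augment=cfg["augment"]["enabled"],
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def test_scale_yaml() -> dict:
    """Resolved config for the reduced test-scale preset."""
    ts = test_scale_config()
    return _merge(
        DEFAULTS,
        {
            "model": {
                "hidden_dim": ts.hidden_dim,
                "embed_dim": ts.embed_dim,
                "head_num": ts.head_num,
                "attention_layer_num": ts.atten_layer_num,
                "input_height": ts.input_height,
                "input_width": ts.input_width,
            }
        },
    )
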