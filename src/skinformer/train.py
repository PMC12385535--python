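"""Training and evaluation loops.

Training follows the reference protocol: Adam (lr 1e-3, betas 0.9/0.999),
mini-batches, on-the-fly augmentation on the training split only, and
EFLoss class scaling factors computed from training-split counts.  A
checkpoint of the best-validation-accuracy parameters is kept alongside
the final-epoch parameters.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .metrics import MacroReport, ConfusionMatrix, build_confusion, macro_report
from .model import HybridSkinFormer, ModelConfig
from .nn.losses import EFLossConfig, efloss_batch, efloss_grad, make_loss
from .nn.optim import Adam
from .preprocess import Augmenter, standardize_resolution, to_network_input
from .synthetic import LesionDataset

#: ablation presets: (activation, loss)
PRESETS = {
    "base1": ("relu", "ce"),
    "base2": ("relu", "efloss"),
    "base3": ("starprelu", "ce"),
    "full": ("starprelu", "efloss"),
}


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 10
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0
    preset: str = "full"
    efloss_beta: float = 3.0
    efloss_gamma: float = 0.3
    augment: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")

    @property
    def activation(self) -> str:
        return PRESETS[self.preset][0]

    @property
    def loss_name(self) -> str:
        return PRESETS[self.preset][1]


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float
    alpha_layers: list[float] = field(default_factory=list)
    star_prelu_params: list[list[float]] = field(default_factory=list)


@dataclass
class TrainResult:
    model: HybridSkinFormer
    history: list[EpochRecord]
    best_state: dict[str, np.ndarray]
    best_val_accuracy: float
    final_state: dict[str, np.ndarray]
    loss_config: EFLossConfig


def _prepare_images(images, model_cfg: ModelConfig) -> list[np.ndarray]:
    h, w = model_cfg.input_height, model_cfg.input_width
    return [
        img if img.shape[:2] == (h, w) else standardize_resolution(img, h, w)
        for img in images
    ]


def _forward_batches(model, images, batch_size: int):
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        yield start, to_network_input(chunk)


def _eval_split(model, images, labels, loss_cfg, batch_size):
    losses, preds = [], []
    for start, x in _forward_batches(model, images, batch_size):
        probs = model.forward(x)
        y = labels[start : start + len(probs)]
        losses.append(efloss_batch(probs, y, loss_cfg) * len(probs))
        preds.append(np.argmax(probs, axis=1))
    preds = np.concatenate(preds) if preds else np.zeros(0, dtype=int)
    loss = float(np.sum(losses) / max(len(images), 1))
    acc = float((preds == labels).mean()) if len(labels) else 0.0
    return loss, acc, preds


def _snapshot_learnables(model: HybridSkinFormer) -> tuple[list[float], list[list[float]]]:
    alphas = [layer.alpha for layer in model.layers]
    triples = [
        [float(p.slope.value), float(p.psi.value), float(p.beta.value)]
        for _, p in _star_prelu_modules(model)
    ]
    return alphas, triples


def _star_prelu_modules(model):
    from .nn.activations import StarPRelu

    seen = []
    def walk(mod, prefix):
        for name, attr in vars(mod).items():
            if isinstance(attr, StarPRelu):
                seen.append((f"{prefix}{name}", attr))
            elif hasattr(attr, "__dict__") and not isinstance(attr, np.ndarray):
                if attr.__class__.__module__.startswith("skinformer"):
                    walk(attr, f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, StarPRelu):
                        seen.append((f"{prefix}{name}.{i}", item))
                    elif item is not None and item.__class__.__module__.startswith("skinformer"):
                        walk(item, f"{prefix}{name}.{i}.")
    walk(model, "")
    return seen


def train(
    model_cfg: ModelConfig,
    dataset: LesionDataset,
    train_cfg: TrainConfig,
    log_path: str | Path | None = None,
) -> TrainResult:
    """Train on the dataset's train split, validating each epoch."""
    for split in ("train", "validation"):
        if split not in dataset.splits or len(dataset.splits[split]) == 0:
            raise ValueError(f"dataset has no {split!r} split")

    model_cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "activation": train_cfg.activation,
                                       "conv_stem_activations":
                                       train_cfg.activation if model_cfg.conv_stem_activations != "none"
                                       else "none"})
    model = HybridSkinFormer(model_cfg, seed=train_cfg.seed)
    opt = Adam(list(model.parameters()), lr=train_cfg.learning_rate,
               beta1=train_cfg.adam_beta1, beta2=train_cfg.adam_beta2)

    train_images, train_labels = dataset.subset("train")
    val_images, val_labels = dataset.subset("validation")
    train_images = _prepare_images(train_images, model_cfg)
    val_images = _prepare_images(val_images, model_cfg)

    counts = np.bincount(train_labels, minlength=model_cfg.classes_num)
    loss_cfg = make_loss(train_cfg.loss_name, counts,
                         beta=train_cfg.efloss_beta, gamma=train_cfg.efloss_gamma)

    rng = np.random.default_rng(np.random.SeedSequence([int(train_cfg.seed), 0xB0]))
    augmenter = Augmenter(rng, enabled=train_cfg.augment)

    history: list[EpochRecord] = []
    best_state = model.state_dict()
    best_val = -1.0
    log_file = open(log_path, "a") if log_path else None
    try:
        n = len(train_images)
        for epoch in range(1, train_cfg.epochs + 1):
            order = rng.permutation(n)
            epoch_loss, correct = 0.0, 0
            for start in range(0, n, train_cfg.batch_size):
                idx = order[start : start + train_cfg.batch_size]
                batch_imgs = [augmenter(train_images[i]) for i in idx]
                x = to_network_input(batch_imgs)
                y = train_labels[idx]
                probs = model.forward(x)
                loss = efloss_batch(probs, y, loss_cfg)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch starting at {start}"
                    )
                epoch_loss += loss * len(idx)
                correct += int((np.argmax(probs, axis=1) == y).sum())
                opt.zero_grad()
                model.backward(efloss_grad(probs, y, loss_cfg))
                opt.step()
            val_loss, val_acc, _ = _eval_split(model, val_images, val_labels,
                                               loss_cfg, train_cfg.batch_size)
            alphas, triples = _snapshot_learnables(model)
            rec = EpochRecord(
                epoch=epoch,
                train_loss=epoch_loss / n,
                train_accuracy=correct / n,
                val_loss=val_loss,
                val_accuracy=val_acc,
                alpha_layers=alphas,
                star_prelu_params=triples,
            )
            history.append(rec)
            if log_file:
                log_file.write(json.dumps(asdict(rec)) + "\n")
            if val_acc > best_val:
                best_val = val_acc
                best_state = model.state_dict()
    finally:
        if log_file:
            log_file.close()
    return TrainResult(
        model=model,
        history=history,
        best_state=best_state,
        best_val_accuracy=best_val,
        final_state=model.state_dict(),
        loss_config=loss_cfg,
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _config_hash(cfg: ModelConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def save_checkpoint(path: str | Path, model: HybridSkinFormer,
                    state: dict[str, np.ndarray] | None = None) -> Path:
    """Serialize parameters plus the config (and its hash) that built them."""
    path = Path(path)
    state = state or model.state_dict()
    meta = {"config": model.config.to_dict(), "config_hash": _config_hash(model.config)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{k.replace(".", "/"): v for k, v in state.items()})
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path, expected_config: ModelConfig | None = None) -> HybridSkinFormer:
    """Rebuild a model; refuses a checkpoint whose config hash mismatches."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    if _config_hash(cfg) != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch: file corrupted or edited")
    if expected_config is not None and _config_hash(expected_config) != meta["config_hash"]:
        raise ValueError("checkpoint was built from a different model configuration")
    model = HybridSkinFormer(cfg, seed=0)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    model: HybridSkinFormer,
    dataset: LesionDataset,
    split: str = "test",
    batch_size: int = 10,
    include_empty_classes: bool = False,
) -> tuple[MacroReport, ConfusionMatrix]:
    """Deterministic evaluation: no augmentation, argmax predictions."""
    images, labels = dataset.subset(split)
    images = _prepare_images(images, model.config)
    preds = predict(model, images, batch_size)
    cm = build_confusion(labels, preds, model.config.classes_num, dataset.class_names)
    return macro_report(cm, include_empty_classes=include_empty_classes), cm


def predict(model: HybridSkinFormer, images, batch_size: int = 10) -> np.ndarray:
    preds = [
        np.argmax(model.forward(x), axis=1)
        for _, x in _forward_batches(model, list(images), batch_size)
    ]
    return np.concatenate(preds) if preds else np.zeros(0, dtype=int)
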