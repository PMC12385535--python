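"""Ablation runs comparing activation/loss presets on one dataset.

Presets: base1 = (relu, cross-entropy), base2 = (relu, EFLoss),
base3 = (StarPRelu, cross-entropy), full = (StarPRelu, EFLoss).
Each preset trains with the identical seed and data, then is evaluated on
the same split, yielding a side-by-side macro report that includes
per-class (hence minority-class) recall.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import MacroReport
from .model import ModelConfig
from .train import PRESETS, TrainConfig, TrainResult, evaluate, train
from .synthetic import LesionDataset


@dataclass
class AblationEntry:
    preset: str
    report: MacroReport
    result: TrainResult


def run_ablation(
    dataset: LesionDataset,
    presets: list[str],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    split: str = "test",
) -> dict[str, AblationEntry]:
    """Train and evaluate each preset under identical conditions."""
    if len(presets) < 2:
        raise ValueError("need at least two presets to compare")
    for p in presets:
        if p not in PRESETS:
            raise ValueError(f"unknown preset {p!r}")
    out: dict[str, AblationEntry] = {}
    for preset in presets:
        cfg = replace(train_cfg, preset=preset)
        result = train(model_cfg, dataset, cfg)
        report, _ = evaluate(result.model, dataset, split=split, batch_size=cfg.batch_size)
        out[preset] = AblationEntry(preset=preset, report=report, result=result)
    return out


def ablation_table(entries: dict[str, AblationEntry], minority_class: int | None = None) -> str:
    lines = [f"{'preset':<8}{'acc(%)':>8}{'prec(%)':>9}{'rec(%)':>8}{'F1':>7}{'MCC':>7}"
             + ("{:>14}".format("min.recall(%)") if minority_class is not None else "")]
    for preset, e in entries.items():
        r = e.report
        row = (f"{preset:<8}{100 * r.overall_accuracy:>8.1f}{100 * r.macro_precision:>9.1f}"
               f"{100 * r.macro_recall:>8.1f}{r.macro_f1:>7.3f}{r.macro_mcc:>7.3f}")
        if minority_class is not None:
            row += f"{100 * r.per_class.recall[minority_class]:>14.1f}"
        lines.append(row)
    return "\n".join(lines)
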