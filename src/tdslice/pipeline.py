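"""Reproducible train / evaluate / ablate workflow.

Protocol: one exam per optimisation step (Adam), per-epoch validation AUC,
model selection at the best-validation-AUC epoch (earliest tie), an
accuracy-maximising decision threshold fitted on the validation split only,
and final metrics reported on the held-out test split.  The ablation grid
crosses {attention off/on} x {cross-entropy, penalty-weight loss}; the four
variants share the seed, splits and every other hyperparameter, and the loss
choice changes no learned parameters.

All randomness (model initialisation, epoch shuffling) derives from the
config seed, so identical config + seed reproduces the loss trajectory,
selected epoch and confusion counts exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace

import numpy as np

from .attention import TFitConfig
from .metrics import (EvalReport, adaptive_threshold, evaluate_scores, roc_auc,
                      select_best_epoch)
from .model import BackboneSpec, SliceClassifier
from .nn import Adam
from .penalty import (balanced_binary_overrides, build_penalty_matrix,
                      cross_entropy_grad_logits,
                      penalty_loss_grad_logits)
from .synthetic import DatasetSplit, SliceStack, stratified_split

__all__ = ["TrainConfig", "RunRecord", "train", "evaluate", "ablate",
           "ablation_table", "VARIANTS"]

logger = logging.getLogger(__name__)

# ablation grid: variant suffix -> (attention on, loss)
VARIANTS = {
    "CE": (False, "cross_entropy"),
    "Slice-CE": (True, "cross_entropy"),
    "Weight": (False, "penalty_weight"),
    "Slice-Weight": (True, "penalty_weight"),
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    The default learning rate (3e-3) suits the small randomly initialised
    backbones used here; large pretrained networks conventionally train at
    1e-5, which remains the documented choice for full-scale runs.
    """

    backbone: str = "tiny"
    attention: bool = False
    loss: str = "cross_entropy"  # or "penalty_weight"
    penalty_n: int = 2
    penalty_base_rule: str = "absolute-distance"
    penalty_overrides: dict | None = None
    # with no explicit overrides, match the binary cost ratio to the
    # training-split class ratio (linear expected cost otherwise pulls an
    # imbalanced model into the majority corner; see penalty module docs)
    penalty_balanced: bool = True
    learning_rate: float = 3e-3
    weight_decay: float = 0.0  # decoupled (AdamW-style), shared by all variants
    batch_size: int = 1
    max_epochs: int = 50
    early_stop_epsilon: float = 1e-4  # on the epoch-mean training loss
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    image_size: int = 64
    nu: float | None = None  # fix the Student-t dof instead of moment matching

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.loss not in ("cross_entropy", "penalty_weight"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class RunRecord:
    """Everything one run produced, enough to reproduce and audit it."""

    variant: str
    train_losses: list[float]
    val_aucs: list[float]
    selected_epoch: int  # 1-based
    threshold: float
    report: EvalReport
    config: TrainConfig
    seed: int
    early_stopped: bool = False

    def as_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "train_losses": self.train_losses,
            "val_aucs": self.val_aucs,
            "selected_epoch": self.selected_epoch,
            "threshold": self.threshold,
            "report": self.report.as_dict(),
            "config": asdict(self.config),
            "seed": self.seed,
            "early_stopped": self.early_stopped,
        }
        return d


def _index(stacks: list[SliceStack]) -> dict[str, SliceStack]:
    return {s.exam_id: s for s in stacks}


def _check_split(by_id: dict[str, SliceStack], split: DatasetSplit) -> None:
    for name, ids in (("train", split.train), ("val", split.val), ("test", split.test)):
        labels = {by_id[i].label for i in ids}
        if labels != {0, 1}:
            raise ValueError(f"{name} split must contain both classes, has labels {labels}")


def _scores(model: SliceClassifier, stacks: list[SliceStack]) -> np.ndarray:
    return np.array([model.predict_score(s.slices) for s in stacks])


def variant_name(config: TrainConfig) -> str:
    suffix = {v: k for k, v in VARIANTS.items()}[(config.attention, config.loss)]
    return f"{config.backbone}-{suffix}"


def train(config: TrainConfig, stacks: list[SliceStack],
          split: DatasetSplit | None = None) -> tuple[SliceClassifier, RunRecord]:
    """Train one model; returns it (at its best-validation-AUC weights)
    together with the run record evaluated on the test split."""
    by_id = _index(stacks)
    if split is None:
        split = stratified_split({s.exam_id: s.label for s in stacks},
                                 config.split_ratios, seed=config.seed)
    _check_split(by_id, split)
    train_stacks = [by_id[i] for i in split.train]
    val_stacks = [by_id[i] for i in split.val]
    test_stacks = [by_id[i] for i in split.test]

    model = SliceClassifier(
        backbone=BackboneSpec(name=config.backbone, image_size=config.image_size),
        attention=config.attention,
        tfit=TFitConfig(nu=config.nu),
        seed=config.seed,
    )
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    overrides = config.penalty_overrides
    if (overrides is None and config.penalty_balanced and config.penalty_n == 2
            and config.loss == "penalty_weight"):
        overrides = balanced_binary_overrides([s.label for s in train_stacks])
    pm = build_penalty_matrix(config.penalty_n, config.penalty_base_rule, overrides)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    train_losses: list[float] = []
    val_aucs: list[float] = []
    best_state = model.state_copy()
    best_auc = -np.inf
    early_stopped = False

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(train_stacks))
        epoch_loss = 0.0
        opt.zero_grad()
        pending = 0
        for step, idx in enumerate(order):
            ex = train_stacks[idx]
            pred, _ = model.forward(ex.slices, train=True)
            logits = np.log(np.maximum(pred.probs, 1e-300))  # recover log-probs scale
            if config.loss == "penalty_weight":
                loss, dlogits = penalty_loss_grad_logits(logits, ex.label, pm)
            else:
                loss, dlogits = cross_entropy_grad_logits(logits, ex.label)
            epoch_loss += loss
            model.backward(dlogits)
            pending += 1
            if pending == config.batch_size or step == len(order) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
        epoch_loss /= len(train_stacks)
        train_losses.append(epoch_loss)

        auc = roc_auc(_scores(model, val_stacks), [s.label for s in val_stacks]).auc
        val_aucs.append(auc)
        logger.info("epoch %d: train loss %.4f, val AUC %.4f", epoch + 1, epoch_loss, auc)
        if auc > best_auc:
            best_auc = auc
            best_state = model.state_copy()
        if epoch_loss < config.early_stop_epsilon:
            early_stopped = True
            logger.info("early stop: epoch-mean train loss %.2e < epsilon", epoch_loss)
            break

    selected = select_best_epoch(val_aucs)  # 0-based, earliest tie
    model.load_state(best_state)
    report, threshold = evaluate(model, val_stacks, test_stacks)
    record = RunRecord(
        variant=variant_name(config),
        train_losses=train_losses,
        val_aucs=val_aucs,
        selected_epoch=selected + 1,
        threshold=threshold,
        report=report,
        config=config,
        seed=config.seed,
        early_stopped=early_stopped,
    )
    return model, record


def evaluate(model: SliceClassifier, val_stacks: list[SliceStack],
             test_stacks: list[SliceStack]) -> tuple[EvalReport, float]:
    """Fit the decision threshold on validation, report on test.

    The threshold provenance is structural: only validation scores ever reach
    :func:`adaptive_threshold`, so no test information can leak into it.
    """
    val_scores = _scores(model, val_stacks)
    val_labels = [s.label for s in val_stacks]
    threshold = adaptive_threshold(val_scores, val_labels)
    test_scores = _scores(model, test_stacks)
    report = evaluate_scores(test_scores, [s.label for s in test_stacks], threshold)
    return report, threshold


def ablate(config: TrainConfig, stacks: list[SliceStack],
           split: DatasetSplit | None = None) -> dict[str, RunRecord]:
    """Run the 2x2 {attention} x {loss} grid with shared seed and splits."""
    if split is None:
        split = stratified_split({s.exam_id: s.label for s in stacks},
                                 config.split_ratios, seed=config.seed)
    records: dict[str, RunRecord] = {}
    for suffix, (attn, loss) in VARIANTS.items():
        cfg = replace(config, attention=attn, loss=loss)
        _, rec = train(cfg, stacks, split)
        records[f"{config.backbone}-{suffix}"] = rec
    return records


def ablation_table(records: dict[str, RunRecord]) -> str:
    """Tab-separated comparison of the four variants (AUC..F1 columns)."""
    lines = ["Model\tAUC\tACC\tPrecision\tRecall\tSpecificity\tF1"]
    for name, rec in records.items():
        r = rec.report
        lines.append(
            f"{name}\t{r.auc:.4f}\t{r.acc:.4f}\t{r.precision:.4f}"
            f"\t{r.recall:.4f}\t{r.specificity:.4f}\t{r.f1:.4f}"
        )
    return "\n".join(lines) + "\n"


def save_run(record: RunRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(record.as_dict(), fh, indent=2)
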