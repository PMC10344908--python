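"""Two-stage training with knowledge transfer.

Stage 1 pretrains the whole network on the data-rich, coarsely-labelled
task: binary short- vs long-lived classification, which censored patients
with a long enough follow-up can join (their follow-up time lower-bounds
survival). Stage 2 re-uses the pretrained expression and drug encoders —
copied exactly from the best stage-1 checkpoint — discards the
classification head and trains a fresh regression head (plus the encoders,
fine-tuned) on exact log months-to-death of deceased patients. The
``single_stage`` switch trains stage 2 from random initialization instead,
the ablation baseline for measuring what the transfer buys.

Losses: binary cross-entropy (stage 1), mean squared error on log months
(stage 2). Optimizer: Adam. Model selection: the epoch with the best
validation metric (accuracy / Pearson r) is checkpointed. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from ._autograd import Adam, Tensor
from .cohort import TrainingExample
from .vnn import ModelState, build_model, forward_batch

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "StageResult", "train_stage1",
           "initialize_stage2", "transfer_and_train_stage2", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 12
    weight_decay: float = 3.0
    #: multiplier on weight_decay for everything that is not a dense
    #: weight matrix (attention scorers, normalization, biases). 1.0
    #: regularizes hardest and predicts best; 0.0 leaves the attention
    #: scorers free, which is what makes attention weights informative
    #: about planted pathway importance (see the methods note).
    attention_decay_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("all training settings must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")


@dataclass
class StageResult:
    model: ModelState
    history: list[dict]            # per-epoch train/val metrics
    best_epoch: int
    best_metric: float
    stage: str


def _stack(examples: list[TrainingExample]):
    X = np.stack([ex.expression for ex in examples]).astype(np.float64)
    FP = np.stack([ex.fingerprint for ex in examples]).astype(np.float64)
    y = np.array([ex.label for ex in examples], dtype=np.float64)
    return X, FP, y


def evaluate(model: ModelState, examples: list[TrainingExample]) -> float:
    """Accuracy at threshold 0.5 (stage 1) or Pearson r on log months
    (stage 2), in inference mode."""
    if not examples:
        raise ValueError("cannot evaluate on an empty example list")
    X, FP, y = _stack(examples)
    pred = forward_batch(model, X, FP, train_mode=False).data.ravel()
    if model.stage == "stage1":
        return float(((pred >= 0.5) == (y >= 0.5)).mean())
    if np.std(pred) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined: zero-variance predictions "
                         "or labels")
    return float(stats.pearsonr(pred, y).statistic)


def _loss(model: ModelState, X, FP, y) -> tuple[Tensor, Tensor]:
    out = forward_batch(model, X, FP, train_mode=True)
    target = Tensor(y[:, None])
    if model.stage == "stage1":
        eps = 1e-12
        p = out
        bce = (target * (p + eps).log()
               + (1.0 - target) * (1.0 - p + eps).log())
        return bce.mean() * -1.0, out
    diff = out - target
    return (diff * diff).mean(), out


def _fit(model: ModelState, train: list[TrainingExample],
         val: list[TrainingExample], config: TrainConfig) -> StageResult:
    Xtr, FPtr, ytr = _stack(train)
    rng = np.random.default_rng(config.seed)
    names = [k for k, v in model.params.items() if v.requires_grad]
    params = [model.params[k] for k in names]
    mask = [1.0 if k.endswith("/W") else config.attention_decay_scale
            for k in names]
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay, decay_mask=mask)
    best_metric = -np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] | None = None
    history: list[dict] = []
    n = len(train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        batch_pred, batch_y = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss, out = _loss(model, Xtr[idx], FPtr[idx], ytr[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            batch_pred.append(out.data.ravel())
            batch_y.append(ytr[idx])
        # training metric from the accumulated batch outputs (train mode),
        # the usual running estimate; validation gets a proper eval pass
        pred = np.concatenate(batch_pred)
        y = np.concatenate(batch_y)
        if model.stage == "stage1":
            train_metric = float(((pred >= 0.5) == (y >= 0.5)).mean())
        elif np.std(pred) > 0 and np.std(y) > 0:
            train_metric = float(stats.pearsonr(pred, y).statistic)
        else:
            train_metric = float("nan")
        val_metric = evaluate(model, val)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                        "train_metric": train_metric,
                        "val_metric": val_metric})
        if val_metric > best_metric:
            best_metric = val_metric
            best_epoch = epoch
            best_params = {k: v.data.copy()
                           for k, v in model.params.items()}
        if epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    assert best_params is not None
    for k in model.params:
        model.params[k].data = best_params[k]
    model.metadata.update({"seed": config.seed, "epochs_run": len(history),
                           "best_epoch": best_epoch,
                           "best_val_metric": best_metric})
    return StageResult(model=model, history=history, best_epoch=best_epoch,
                       best_metric=best_metric, stage=model.stage)


def train_stage1(model: ModelState, train: list[TrainingExample],
                 val: list[TrainingExample],
                 config: TrainConfig) -> StageResult:
    """Pretrain on binary long-/short-lived labels (binary cross-entropy)."""
    labels = {ex.label for ex in train}
    if labels <= {0.0} or labels <= {1.0}:
        raise ValueError("stage-1 training set contains a single class")
    if not labels <= {0.0, 1.0}:
        raise ValueError("stage-1 labels must be binary 0/1")
    model.stage = "stage1"
    return _fit(model, train, val, config)


def initialize_stage2(stage1: StageResult | None,
                      single_stage: bool = False,
                      model: ModelState | None = None) -> ModelState:
    """Build the epoch-0 stage-2 model.

    With transfer (default): encoder and drug-encoder weights equal the
    stage-1 best weights exactly; the classification head is discarded and
    a fresh regression head is drawn. With ``single_stage=True`` every
    weight is freshly initialized (the ablation baseline); `stage1` (or a
    `model` template) then only supplies the DAG and config.
    """
    src = stage1.model if stage1 is not None else model
    if src is None:
        raise ValueError("need a stage-1 result or a model template")
    fresh = build_model(src.dag, src.config, stage="stage2")
    # a fresh head either way; different derived seed so the regression head
    # is not the sigmoid head's initialization
    head_rng = np.random.default_rng((src.config.seed * 2654435761 + 17)
                                     % (2 ** 31))
    for name in ("head/0/W", "head/1/W"):
        fresh.params[name].data = head_rng.uniform(
            -1, 1, fresh.params[name].shape) * np.sqrt(
                6.0 / sum(fresh.params[name].shape))
    if not single_stage:
        if stage1 is None:
            raise ValueError("two-stage training needs a stage-1 result")
        if fresh.dag_hash() != stage1.model.dag_hash():
            raise ValueError("stage-1 checkpoint was built on a different "
                             "DAG/config (hash mismatch)")
        for name in fresh.encoder_param_names():
            fresh.params[name].data = stage1.model.params[name].data.copy()
    fresh.metadata["transfer"] = not single_stage
    return fresh


def transfer_and_train_stage2(stage1: StageResult | None,
                              train: list[TrainingExample],
                              val: list[TrainingExample],
                              config: TrainConfig,
                              single_stage: bool = False,
                              model: ModelState | None = None) -> StageResult:
    """Fine-tune log-months regression from the stage-1 checkpoint.

    See :func:`initialize_stage2` for the epoch-0 weight contract; model
    selection checkpoints the best validation Pearson r.
    """
    fresh = initialize_stage2(stage1, single_stage=single_stage, model=model)
    return _fit(fresh, train, val, config)
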