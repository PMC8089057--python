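"""Training protocol: loss, two-phase optimizer schedule, checkpoint selection.

One protein per optimization step (batch size 1, as feature maps scale with
L^2). Epochs below the switch epoch use Adam at learning rate 0.001; from the
switch epoch (default 30) on, SGD with learning rate 0.01 and momentum 0.9;
training stops at the stop epoch (default 60). After every epoch the weights
are checkpointed and the precision of the top L/2 long-range contacts on the
validation set is recorded; the epoch maximizing that metric is selected
(ties broken by the earliest epoch).

The loss is mean binary cross-entropy over pairs with sequence separation
|i - j| >= 6 (trivially-near pairs excluded), computed from logits for
numerical stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn.tensor import Tensor
from .nn.optim import Adam, SGD
from .features import ContactMap, FeatureSet, ProteinRecord, range_mask
from .network import (
    ModelConfig, SequenceModule, RegionalModule, build_model, save_model,
    symmetrize,
)
from .evaluation import top_ln_precision

__all__ = [
    "TrainSchedule", "OptimizerSpec", "TrainState", "optimizer_phase",
    "contact_loss", "loss_mask", "train",
]

Item = tuple[ProteinRecord, FeatureSet, ContactMap]


@dataclass(frozen=True)
class TrainSchedule:
    adam_lr: float = 0.001
    sgd_lr: float = 0.01
    sgd_momentum: float = 0.9
    switch_epoch: int = 30
    stop_epoch: int = 60
    batch_size: int = 1  # fixed: one protein per step

    def __post_init__(self):
        if self.stop_epoch < 1 or self.switch_epoch < 1:
            raise ValueError("epochs must be positive")
        if self.adam_lr <= 0 or self.sgd_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size != 1:
            raise ValueError("the protocol trains one protein per step")


@dataclass(frozen=True)
class OptimizerSpec:
    kind: str                  # "adam" | "sgd" | "stop"
    lr: float | None = None
    momentum: float | None = None


def optimizer_phase(epoch: int, schedule: TrainSchedule = TrainSchedule()
                    ) -> OptimizerSpec:
    """Which optimizer a given (0-based) epoch uses."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= schedule.stop_epoch:
        return OptimizerSpec(kind="stop")
    if epoch < schedule.switch_epoch:
        return OptimizerSpec(kind="adam", lr=schedule.adam_lr)
    return OptimizerSpec(kind="sgd", lr=schedule.sgd_lr,
                         momentum=schedule.sgd_momentum)


def loss_mask(L: int, min_separation: int = 6,
              validity: np.ndarray | None = None) -> np.ndarray:
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    mask = sep >= min_separation
    if validity is not None:
        mask &= validity
    return mask


def contact_loss(pred: ContactMap, true: ContactMap,
                 mask: np.ndarray | None = None, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over unmasked pairs (probabilities clipped)."""
    if pred.values.shape != true.values.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mask = loss_mask(pred.length, validity=true.validity)
    if not mask.any():
        raise ValueError("all pairs masked")
    p = np.clip(pred.values[mask], eps, 1.0 - eps)
    t = true.values[mask]
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def _loss_from_logits(logits: Tensor, true: np.ndarray, mask: np.ndarray) -> Tensor:
    """BCE-with-logits, masked mean: mean(softplus(x) - t*x) over the mask."""
    m = Tensor(mask.astype(np.float64))
    t = Tensor(true)
    absx = logits.relu() + (-logits).relu()
    softplus = logits.relu() + ((-absx).exp() + 1.0).log()
    per_pair = (softplus - t * logits) * m
    return per_pair.sum() * (1.0 / float(mask.sum()))


@dataclass
class EpochLog:
    epoch: int
    loss: float
    val_precision: float
    phase: str
    checkpoint: str


@dataclass
class TrainState:
    epochs: list[EpochLog] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_checkpoint(self) -> str:
        return self.epochs[self.best_epoch].checkpoint

    def select_best(self) -> None:
        scores = [e.val_precision for e in self.epochs]
        self.best_epoch = int(np.argmax(scores))  # argmax takes earliest tie


def validation_precision(model: SequenceModule | RegionalModule,
                         valset: list[Item]) -> float:
    """Mean top-L/2 long-range precision of symmetrized predictions."""
    scores = []
    for _, fs, contacts in valset:
        pred = symmetrize(model.predict(fs).contacts)
        p = top_ln_precision(pred, contacts, "long", 2)
        if p is not None:
            scores.append(p)
    return float(np.mean(scores)) if scores else 0.0


def train(dataset: list[Item], valset: list[Item], config: ModelConfig,
          schedule: TrainSchedule = TrainSchedule(), seed: int = 0,
          out_dir: str | Path = "checkpoints",
          log_path: str | Path | None = None) -> TrainState:
    """Run the full protocol and return the state with the best epoch chosen.

    Fully seeded: weight initialization comes from ``config.init_seed`` and
    the per-epoch data order from ``seed``. One checkpoint is written per
    completed epoch.
    """
    if not dataset or not valset:
        raise ValueError("dataset and valset must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = build_model(config)
    order_rng = np.random.default_rng(seed)
    state = TrainState()
    optimizer = None
    current_kind = None
    log_fh = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(schedule.stop_epoch):
            spec = optimizer_phase(epoch, schedule)
            if spec.kind == "stop":
                break
            if spec.kind != current_kind:
                if spec.kind == "adam":
                    optimizer = Adam(model.parameters(), lr=spec.lr)
                else:
                    optimizer = SGD(model.parameters(), lr=spec.lr,
                                    momentum=spec.momentum)
                current_kind = spec.kind
            order = order_rng.permutation(len(dataset))
            losses = []
            for idx in order:
                record, fs, contacts = dataset[idx]
                mask = loss_mask(fs.length, validity=contacts.validity)
                optimizer.zero_grad()
                logits, _ = model.forward_logits(fs)
                loss = _loss_from_logits(logits, contacts.values, mask)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, protein {record.id}")
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            ckpt = out_dir / f"epoch_{epoch:03d}.npz"
            save_model(model, ckpt)
            val = validation_precision(model, valset)
            entry = EpochLog(epoch=epoch, loss=float(np.mean(losses)),
                             val_precision=val, phase=spec.kind,
                             checkpoint=str(ckpt))
            state.epochs.append(entry)
            if log_fh is not None:
                log_fh.write(json.dumps(vars(entry)) + "\n")
                log_fh.flush()
    finally:
        if log_fh is not None:
            log_fh.close()
    state.select_best()
    return state
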