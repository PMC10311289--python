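"""NLL training loop with the published learning-rate schedule.

Adam, initial lr 1e-4; after 5 consecutive non-improving validations the lr
is multiplied by 0.6 and clamped at 1e-5; training stops after 20
consecutive non-improving validations. Validation runs every
`validate_every` training iterations and the best-validation parameters are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import tensor as T
from .nn.optim import Adam, clip_grad_norm, iter_params


@dataclass
class TrainingConfig:
    batch_size: int = 4
    lr_init: float = 1e-4
    lr_decay_factor: float = 0.6
    lr_floor: float = 1e-5
    decay_patience: int = 5  # validations
    validate_every: int = 1000  # training iterations
    stop_patience: int = 20  # validations
    seed: int = 0
    max_steps: int | None = None
    grad_clip: float = 1.0
    dropout_enabled: bool = False
    # progressive unfreezing of the decoder's pocket pathway: the
    # cross-attention output projections start at zero and stay frozen for
    # this many steps, letting the property-conditioning circuit form before
    # pocket information joins; 0 disables.
    cross_warmup_steps: int = 0

    def __post_init__(self):
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("decay factor must be in (0, 1)")
        if self.lr_floor >= self.lr_init:
            raise ValueError("lr_floor must be below lr_init")


class LrSchedule:
    """Validation-driven decay/early-stop state machine."""

    def __init__(self, cfg: TrainingConfig):
        self.cfg = cfg
        self.lr = cfg.lr_init
        self.best: float | None = None
        self.decay_wait = 0
        self.stop_wait = 0

    def update(self, val_loss: float) -> tuple[float, bool]:
        """Feed one validation loss; returns (current lr, should_stop)."""
        if self.best is None or val_loss < self.best:
            self.best = val_loss
            self.decay_wait = 0
            self.stop_wait = 0
            return self.lr, False
        self.decay_wait += 1
        self.stop_wait += 1
        if self.decay_wait >= self.cfg.decay_patience:
            self.lr = max(self.lr * self.cfg.lr_decay_factor, self.cfg.lr_floor)
            self.decay_wait = 0
        return self.lr, self.stop_wait >= self.cfg.stop_patience


@dataclass
class TrainingResult:
    log: list[dict]  # one row per validation event
    best_val_loss: float
    best_state: dict[str, np.ndarray]
    steps_run: int


def evaluate_nll(model, items, batch_size: int = 8) -> float:
    total, count = 0.0, 0
    with T.no_grad():
        for start in range(0, len(items), batch_size):
            batch = items[start : start + batch_size]
            loss = model.loss_on_batch(batch, reduction="sum")
            total += float(loss.data)
            count += sum(len(rec.token_ids) + 1 for _, rec in batch)
    return total / count


def train(model, train_items, val_items, cfg: TrainingConfig,
          progress=None) -> TrainingResult:
    """Seeded mini-batch training of a :class:`~pockmol.model.GeneratorModel`.

    `train_items` / `val_items` are lists of (PocketInputs, MoleculeRecord).
    """
    if not train_items or not val_items:
        raise ValueError("training and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    params = iter_params(model.params)
    cross_out: list = []
    if cfg.cross_warmup_steps > 0:
        cross_out = [t for name, t in model.flat_params().items()
                     if "decoder" in name and name.endswith("cross/wo")]
        for t in cross_out:
            t.data[:] = 0.0
    optimizer = Adam(model.params, lr=cfg.lr_init)
    schedule = LrSchedule(cfg)
    log: list[dict] = []
    best_state = model.state_arrays()
    best_val = float("inf")
    step = 0
    running = 0.0
    order = rng.permutation(len(train_items))
    cursor = 0
    while True:
        if cfg.max_steps is not None and step >= cfg.max_steps:
            break
        if cursor + cfg.batch_size > len(order):
            order = rng.permutation(len(train_items))
            cursor = 0
        batch = [train_items[i] for i in order[cursor : cursor + cfg.batch_size]]
        cursor += cfg.batch_size
        step += 1
        if cfg.dropout_enabled:
            with T.dropout_mode(drop_rng):
                loss = model.loss_on_batch(batch)
        else:
            loss = model.loss_on_batch(batch)
        optimizer.zero_grad()
        loss.backward()
        if step <= cfg.cross_warmup_steps:
            for t in cross_out:
                t.grad = None
        if cfg.grad_clip > 0:
            clip_grad_norm(params, cfg.grad_clip)
        optimizer.lr = schedule.lr
        optimizer.step()
        running += float(loss.data)
        if step % cfg.validate_every == 0:
            val_loss = evaluate_nll(model, val_items)
            lr, should_stop = schedule.update(val_loss)
            row = {
                "step": step,
                "train_loss": running / cfg.validate_every,
                "val_loss": val_loss,
                "lr": lr,
            }
            log.append(row)
            running = 0.0
            if progress is not None:
                progress(row)
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state_arrays()
            if should_stop:
                break
    model.load_state_arrays(best_state)
    return TrainingResult(log=log, best_val_loss=best_val,
                          best_state=best_state, steps_run=step)
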