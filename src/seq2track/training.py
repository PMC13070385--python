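"""Training recipe: Poisson NLL, AdamW, linear warm-up/decay, batch size 1.

Supports four modes — ``pretrain`` and ``scratch`` (full training from random
initialization or on the pretraining corpus), ``finetune`` (load checkpoint,
swap the head, train everything) and ``finetune_frozen`` (same, but the trunk
is frozen and only the head learns).  Multi-track training averages the
Poisson NLL over all tracks; single-track mode trains and reports on one
selected track.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .evaluation import evaluate
from .model import (TrackPredictor, build_model, load_checkpoint, replace_head,
                    save_checkpoint, set_trunk_frozen)

logger = logging.getLogger(__name__)

MODES = ("pretrain", "scratch", "finetune", "finetune_frozen")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 3e-5
    weight_decay: float = 1e-4
    epochs: int = 10
    batch_size: int = 1
    mode: str = "scratch"
    track_selection: str | int | None = None  # None = all tracks
    seed: int = 0
    grad_clip: float | None = None
    validate_each_epoch: bool = True
    checkpoint_each_epoch: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclasses.dataclass
class TrainLog:
    steps: list = dataclasses.field(default_factory=list)   # (step, epoch, loss, lr)
    val_metric: list = dataclasses.field(default_factory=list)  # per epoch mean r
    wall_time: float = 0.0
    checkpoint: str | None = None

    @property
    def losses(self):
        return np.array([s[2] for s in self.steps])

    @property
    def lrs(self):
        return np.array([s[3] for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "epoch", "loss", "lr"])

    def write(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "train_log.tsv", sep="\t", index=False)
        (directory / "train_summary.json").write_text(json.dumps({
            "val_metric": self.val_metric, "wall_time": self.wall_time,
            "checkpoint": self.checkpoint, "n_steps": len(self.steps)}, indent=2))


def poisson_nll(predicted_rates, target_counts, full=False) -> float:
    """Mean over bins x tracks of lambda - y*log(lambda).

    The y-only constant log(y!) is omitted (it does not affect optimization);
    ``full=True`` adds it for likelihood reporting.
    """
    lam = np.asarray(predicted_rates, dtype=float)
    y = np.asarray(target_counts, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson rates must be strictly positive")
    if np.any(y < 0):
        raise ValueError("target counts must be non-negative")
    nll = lam - y * np.log(lam)
    if full:
        from scipy.special import gammaln
        nll = nll + gammaln(y + 1.0)
    return float(nll.mean())


def lr_at_step(config: TrainConfig, step: int, steps_per_epoch: int) -> float:
    """Piecewise-linear schedule: 0 -> peak across epoch 1, then peak -> 0
    across the remaining epochs.  `step` counts completed optimizer steps."""
    total = config.epochs * steps_per_epoch
    if step < 0 or step > total:
        raise ValueError(f"step {step} outside [0, {total}]")
    peak = config.learning_rate
    warm = steps_per_epoch
    if step <= warm:
        return peak * step / warm
    return peak * (total - step) / (total - warm)


class AdamW:
    """Decoupled weight-decay Adam (bias-corrected), skipping frozen params."""

    def __init__(self, params, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps) \
                + lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _resolve_track(dataset, selection):
    if selection is None:
        return None
    if isinstance(selection, str):
        if selection not in dataset.track_names:
            raise ValueError(f"track {selection!r} not in dataset "
                             f"(available: {dataset.track_names[:5]}...)")
        return dataset.track_names.index(selection)
    if not 0 <= int(selection) < dataset.n_tracks:
        raise ValueError(f"track index {selection} out of range")
    return int(selection)


def _clip_gradients(params, max_norm):
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train(model: TrackPredictor, dataset, config: TrainConfig, run_dir=None):
    """Run the full training loop; returns (model, TrainLog).

    Deterministic given config.seed: data order, dropout and every update
    are driven by seeds derived from it.
    """
    track = _resolve_track(dataset, config.track_selection)
    n_model_tracks = model.config.head_track_counts[0]
    n_target = 1 if track is not None else dataset.n_tracks
    if n_model_tracks != n_target:
        raise ValueError(
            f"model head outputs {n_model_tracks} tracks but the objective "
            f"has {n_target}; rebuild or replace_head first")
    train_idx = dataset.indices("train")
    if train_idx.size == 0:
        raise ValueError("dataset has no training windows")
    steps_per_epoch = int(np.ceil(train_idx.size / config.batch_size))
    opt = AdamW([p for p in model.parameters()], weight_decay=config.weight_decay)
    log = TrainLog()
    t0 = time.time()
    step = 0
    model.set_training(True)
    run_dir = Path(run_dir) if run_dir else None
    for epoch in range(config.epochs):
        order_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, epoch]))
        order = order_rng.permutation(train_idx)
        drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, epoch, 1]))
        for lo in range(0, order.size, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            x = dataset.X[sel].astype(float)
            y = dataset.Y[sel]
            if track is not None:
                y = y[:, :, track:track + 1]
            lr = lr_at_step(config, step + 1, steps_per_epoch)
            opt.zero_grad()
            out = model.forward(x, rng=drop_rng)[0]
            nll = ad.reduce_mean(out - ad.Tensor(y) * ad.log(out))
            nll.backward()
            if config.grad_clip:
                _clip_gradients(opt.params, config.grad_clip)
            opt.step(lr)
            step += 1
            log.steps.append((step, epoch, float(nll.data), lr))
        if config.validate_each_epoch and dataset.indices("validation").size:
            ds = dataset if track is None else dataset.select_tracks([track])
            report = evaluate(model, ds, "validation")
            log.val_metric.append(report.mean_r)
            model.set_training(True)
        if run_dir and config.checkpoint_each_epoch:
            save_checkpoint(model, run_dir / f"epoch_{epoch:03d}", epoch=epoch)
    model.set_training(False)
    log.wall_time = time.time() - t0
    if run_dir:
        ckpt = save_checkpoint(model, run_dir / "final", epoch=config.epochs - 1)
        log.checkpoint = str(ckpt)
        log.write(run_dir)
    return model, log


def finetune(checkpoint, dataset, n_tracks, config: TrainConfig, run_dir=None):
    """Load -> replace_head -> (optionally freeze) -> train."""
    if config.mode not in ("finetune", "finetune_frozen"):
        raise ValueError("finetune requires mode 'finetune' or 'finetune_frozen'")
    model = checkpoint if isinstance(checkpoint, TrackPredictor) else load_checkpoint(checkpoint)
    replace_head(model, n_tracks, seed=config.seed)
    set_trunk_frozen(model, config.mode == "finetune_frozen")
    model, log = train(model, dataset, config, run_dir=run_dir)
    if run_dir and not isinstance(checkpoint, TrackPredictor):
        meta_path = Path(run_dir) / "final" / "checkpoint.json"
        meta = json.loads(meta_path.read_text())
        meta["parent"] = str(checkpoint)
        meta_path.write_text(json.dumps(meta, indent=2))
    return model, log


def grid_search(model_factory, datasets, lr_grid, wd_grid,
                base_config: TrainConfig | None = None):
    """Full-factorial (lr, wd) search; best = argmax mean validation r,
    ties broken toward the smaller learning rate."""
    base = base_config or TrainConfig()
    lrs = sorted(set(lr_grid))
    wds = sorted(set(wd_grid))
    if len(lrs) != len(lr_grid) or len(wds) != len(wd_grid):
        logger.warning("duplicate grid values were deduplicated")
    if not lrs or not wds:
        raise ValueError("grids must be non-empty")
    rows = []
    for i, ds in enumerate(datasets):
        for lr in lrs:
            for wd in wds:
                cfg = dataclasses.replace(base, learning_rate=lr, weight_decay=wd)
                model = model_factory()
                _, log = train(model, ds, cfg)
                score = log.val_metric[-1] if log.val_metric else float("nan")
                rows.append({"dataset": i, "learning_rate": lr,
                             "weight_decay": wd, "mean_validation_r": score})
    table = pd.DataFrame(rows)
    agg = table.groupby(["learning_rate", "weight_decay"])["mean_validation_r"].mean()
    best_score = agg.max()
    candidates = agg[agg == best_score].reset_index()
    best = candidates.sort_values(["learning_rate", "weight_decay"]).iloc[0]
    return table, {"learning_rate": float(best["learning_rate"]),
                   "weight_decay": float(best["weight_decay"]),
                   "mean_validation_r": float(best_score)}
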