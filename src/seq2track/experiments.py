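"""Scripted, seeded experiment designs at desk scale.

Three workflows mirror the study designs the package exists to support:

* architecture comparison — the four ablation combinations plus the
  reduced-attention variant, trained with paired seeds and data order so
  differences are attributable to the architecture alone;
* transfer experiment — pretrain on the reference corpus, then compare
  fine-tuning, frozen fine-tuning, training from scratch and the
  frozen-scratch control on a transfer-species dataset;
* track-count tradeoff sweep — train on a track of interest plus N randomly
  sampled additional tracks, then fine-tune on the single track of interest,
  recording both per-track and averaged correlations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import evaluate
from .model import (ModelConfig, build_model, count_parameters,
                    save_checkpoint, set_trunk_frozen)
from .training import TrainConfig, finetune, train

ARCHITECTURE_VARIANTS = {
    "baseline": {},
    "no_linear": {"include_attention_linear": False},
    "no_pointwise": {"include_final_pointwise": False},
    "no_linear_no_pointwise": {"include_attention_linear": False,
                               "include_final_pointwise": False},
    "5_blocks_no_linear_no_pointwise": {"include_attention_linear": False,
                                        "include_final_pointwise": False,
                                        "n_attention_blocks": 5},
}


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


@dataclasses.dataclass
class ExperimentPlan:
    name: str
    arms: list                    # (arm name, model config dict, train config)
    replicate_seeds: list
    output_dir: str | None = None

    def __post_init__(self):
        names = [a[0] for a in self.arms]
        if len(names) != len(set(names)):
            raise ValueError("arm names must be unique")


def run_architecture_comparison(variants, dataset, base_model_config: ModelConfig,
                                train_config: TrainConfig, out_dir=None) -> pd.DataFrame:
    """Train each architecture variant with identical seed and data order;
    returns per-epoch validation correlation plus parameter counts."""
    if len(variants) != len(set(variants)):
        raise ValueError("duplicate variants in comparison")
    unknown = set(variants) - set(ARCHITECTURE_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    rows = []
    for name in variants:
        overrides = ARCHITECTURE_VARIANTS[name]
        cfg = dataclasses.replace(base_model_config, **overrides)
        model = build_model(cfg, seed=train_config.seed)
        n_params = count_parameters(model).trainable_count
        model, log = train(model, dataset, train_config)
        for epoch, r in enumerate(log.val_metric):
            rows.append({"variant": name, "epoch": epoch, "validation_r": r,
                         "n_parameters": n_params,
                         "config_hash": _config_hash(cfg.to_dict()),
                         "seed": train_config.seed})
    table = pd.DataFrame(rows)
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "architecture_comparison.tsv",
                     sep="\t", index=False)
    return table


TRANSFER_MODES = ("pretrain", "no_pretrain", "pretrain_freeze", "no_pretrain_freeze")


def run_transfer_experiment(pretrain_checkpoint, species_dataset, mode_set,
                            seeds, model_config: ModelConfig,
                            finetune_config: TrainConfig,
                            scratch_config: TrainConfig,
                            eval_split="test", out_dir=None):
    """Four-arm pretraining comparison on one transfer-species dataset.

    Fine-tuned arms start from `pretrain_checkpoint` (required for the
    pretrain modes); scratch arms use fresh seed-derived initializations.
    Returns (per-run table, summary dict with percent improvement of the
    pretrain arm over the no-pretrain arm).
    """
    mode_set = list(mode_set)
    if not set(mode_set) <= set(TRANSFER_MODES):
        raise ValueError(f"modes must be drawn from {TRANSFER_MODES}")
    if pretrain_checkpoint is None and any(m.startswith("pretrain") for m in mode_set):
        raise ValueError("a pretrained checkpoint is required for pretrain modes")
    n_tracks = species_dataset.n_tracks
    rows = []
    for seed in seeds:
        for mode in mode_set:
            if mode == "pretrain":
                cfg = dataclasses.replace(finetune_config, mode="finetune", seed=seed)
                model, _ = finetune(pretrain_checkpoint, species_dataset, n_tracks, cfg)
            elif mode == "pretrain_freeze":
                cfg = dataclasses.replace(finetune_config, mode="finetune_frozen", seed=seed)
                model, _ = finetune(pretrain_checkpoint, species_dataset, n_tracks, cfg)
            else:
                cfg = dataclasses.replace(scratch_config, mode="scratch", seed=seed)
                mcfg = dataclasses.replace(model_config, head_track_counts=(n_tracks,))
                model = build_model(mcfg, seed=seed + 1000)
                if mode == "no_pretrain_freeze":
                    set_trunk_frozen(model, True)
                model, _ = train(model, species_dataset, cfg)
            report = evaluate(model, species_dataset, eval_split)
            rows.append({"mode": mode, "seed": seed, "mean_r": report.mean_r,
                         **{f"r_{t}": v for t, v in report.per_track_r.items()}})
    table = pd.DataFrame(rows)
    summary = {}
    by_mode = table.groupby("mode")["mean_r"]
    summary["mean_r"] = by_mode.mean().to_dict()
    summary["median_r"] = by_mode.median().to_dict()
    if {"pretrain", "no_pretrain"} <= set(mode_set):
        r_pre = by_mode.mean()["pretrain"]
        r_scr = by_mode.mean()["no_pretrain"]
        summary["improvement_percent"] = 100.0 * (r_pre - r_scr) / abs(r_scr)
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "transfer_experiment.tsv", sep="\t", index=False)
        (Path(out_dir) / "transfer_summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
    return table, summary


def run_tradeoff_sweep(dataset, track_of_interest, additional_counts, replicates,
                       model_config: ModelConfig, train_config: TrainConfig,
                       finetune_config: TrainConfig, eval_split="test",
                       out_dir=None) -> pd.DataFrame:
    """Track-count tradeoff: for each count, train on the track of interest
    plus that many randomly sampled additional tracks (redrawn per
    replicate), then fine-tune on the single track of interest.

    Records, per (count, replicate): r on the track of interest before and
    after fine-tuning, and the mean r over all trained tracks.
    """
    all_tracks = list(range(dataset.n_tracks))
    toi = (dataset.track_names.index(track_of_interest)
           if isinstance(track_of_interest, str) else int(track_of_interest))
    pool = [t for t in all_tracks if t != toi]
    if max(additional_counts) > len(pool):
        raise ValueError(
            f"requested {max(additional_counts)} additional tracks, "
            f"only {len(pool)} available")
    rows = []
    for count in additional_counts:
        for rep in range(replicates):
            rep_seed = train_config.seed + 1000 * rep + count
            rng = np.random.default_rng(np.random.SeedSequence([rep_seed, count]))
            extra = sorted(rng.choice(pool, size=count, replace=False).tolist())
            tracks = [toi] + extra
            ds = dataset.select_tracks(tracks)
            mcfg = dataclasses.replace(model_config, head_track_counts=(len(tracks),))
            model = build_model(mcfg, seed=rep_seed)
            cfg = dataclasses.replace(train_config, seed=rep_seed)
            model, _ = train(model, ds, cfg)
            rep_all = evaluate(model, ds, eval_split)
            r_toi_pre = list(rep_all.per_track_r.values())[0]
            # fine-tune on the single track of interest
            ft_cfg = dataclasses.replace(finetune_config, mode="finetune",
                                         seed=rep_seed)
            ds_toi = dataset.select_tracks([toi])
            model_ft, _ = finetune(model, ds_toi, 1, ft_cfg)
            r_toi_post = evaluate(model_ft, ds_toi, eval_split).mean_r
            rows.append({"track_count": count, "replicate": rep,
                         "sampled_tracks": json.dumps(extra),
                         "r_interest_pre": r_toi_pre,
                         "r_interest_post": r_toi_post,
                         "mean_r_all_tracks": rep_all.mean_r,
                         "seed": rep_seed})
    table = pd.DataFrame(rows)
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "tradeoff_sweep.tsv", sep="\t", index=False)
    return table
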