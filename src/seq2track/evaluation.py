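"""Pearson-correlation evaluation, per track and stratified by homology bin.

The reported metric is the per-track Pearson r between predictions and
labels over the concatenation of all bins of all evaluated windows, averaged
(unweighted) over tracks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Standard Pearson correlation (square-root denominator).

    If both vectors are constant the correlation is undefined; batch
    evaluation must not crash, so 0.0 is returned with a logged warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("pearson requires vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        logger.warning("pearson undefined for constant input; returning 0.0")
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@dataclasses.dataclass
class EvalReport:
    per_track_r: dict
    mean_r: float
    n_examples: int
    n_bins: int
    n_tracks: int
    per_homology_bin_r: dict | None = None
    per_homology_bin_n: dict | None = None

    def to_json(self, path=None):
        d = dataclasses.asdict(self)
        if self.per_homology_bin_r is not None:
            d["per_homology_bin_r"] = {str(k): v for k, v in self.per_homology_bin_r.items()}
            d["per_homology_bin_n"] = {str(k): v for k, v in self.per_homology_bin_n.items()}
        text = json.dumps(d, indent=2)
        if path:
            Path(path).write_text(text)
        return text

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"track": list(self.per_track_r),
                             "pearson_r": list(self.per_track_r.values())})


def _mean_r_over_tracks(pred, target):
    rs = [pearson(pred[:, :, j].ravel(), target[:, :, j].ravel())
          for j in range(pred.shape[2])]
    return rs


def evaluate_arrays(pred: np.ndarray, target: np.ndarray, track_names=None,
                    groups: dict | None = None) -> EvalReport:
    """Evaluate prediction/label arrays of shape (N, n_bins, n_tracks)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    names = track_names or [f"track_{j}" for j in range(pred.shape[2])]
    rs = _mean_r_over_tracks(pred, target)
    per_track = dict(zip(names, rs))
    bin_r = bin_n = None
    if groups is not None:
        bin_r, bin_n = {}, {}
        for key, idx in groups.items():
            bin_n[key] = len(idx)
            if len(idx) == 0:
                bin_r[key] = float("nan")
                continue
            sub = _mean_r_over_tracks(pred[idx], target[idx])
            bin_r[key] = float(np.mean(sub))
    return EvalReport(per_track_r=per_track, mean_r=float(np.mean(rs)),
                      n_examples=pred.shape[0], n_bins=pred.shape[1],
                      n_tracks=pred.shape[2], per_homology_bin_r=bin_r,
                      per_homology_bin_n=bin_n)


def evaluate(model, dataset, split_label, assignments=None,
             bin_edges=(0.0, 0.1, 0.5, 1.0), batch_size=8) -> EvalReport:
    """Evaluate a model on one split of a dataset.

    With homology `assignments` supplied, additionally reports mean r per
    homology-proportion bin over the evaluated windows.
    """
    idx = dataset.indices(split_label)
    if idx.size == 0:
        raise ValueError(f"no windows under split {split_label!r}")
    preds = []
    for lo in range(0, idx.size, batch_size):
        batch = dataset.X[idx[lo:lo + batch_size]].astype(float)
        preds.append(model.predict(batch)[0])
    pred = np.concatenate(preds, axis=0)
    target = dataset.Y[idx]
    groups = None
    if assignments is not None:
        prop = {a.window_id: a.homology_proportion for a in assignments}
        ids = [dataset.manifest.records[i]["id"] for i in idx]
        edges = list(bin_edges)
        groups = {}
        for b in range(len(edges) - 1):
            key = (edges[b], edges[b + 1])
            members = []
            for pos, wid in enumerate(ids):
                p = prop.get(wid, 0.0)
                j = min(int(np.searchsorted(edges, p, side="right")) - 1, len(edges) - 2)
                if j == b:
                    members.append(pos)
            groups[key] = np.array(members, dtype=int)
    return evaluate_arrays(pred, target, dataset.track_names, groups)
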