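"""Accuracy metrics and summaries for layerwise decoding.

Two scores per layer: the Pearson correlation ``r(y, yhat)`` between
pooled out-of-fold predictions and the group-average ratings, and the
noise-corrected "explainable variance explained",

    r2_EVE = r(y, yhat)^2 / r_split^2,

where ``r_split`` is the Spearman-Brown-corrected split-half reliability of
the matching ratings cell.  EVE is deliberately not clipped at 1 — sampling
noise in either numerator or ceiling can push it above — and the signed r
is always carried alongside so that squaring cannot hide an anticorrelated
prediction.

Layer position is expressed as relative depth, ``(index - 1)/(n_layers -
1)``: 0 for the shallowest layer, 1 for the deepest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rand import child_rng

__all__ = [
    "LayerScore",
    "ModelScore",
    "DepthAnalysis",
    "pearson_accuracy",
    "eve",
    "relative_depth",
    "layer_scores",
    "best_layer",
    "depth_profile",
    "representativeness",
    "score_by_group",
    "score_model",
]

logger = logging.getLogger(__name__)


def pearson_accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation across images between targets and predictions.

    Returns NaN (with a warning) if either vector is constant — undefined,
    flagged, never coerced to 0.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("y and yhat must be equal-length vectors of size >= 3")
    if y.std() == 0.0 or yhat.std() == 0.0:
        logger.warning("pearson_accuracy undefined: constant vector")
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def eve(r: float, r_split: float) -> float:
    """Explainable variance explained: ``r^2 / r_split^2`` (not clipped)."""
    if r_split == 0.0:
        raise ValueError("r_split is 0: explainable variance undefined")
    return float(r**2 / r_split**2)


def relative_depth(layer_index: int, n_layers: int) -> float:
    """Relative depth of 1-based ``layer_index``: 0 = shallowest, 1 = deepest."""
    if not 1 <= layer_index <= n_layers:
        raise ValueError(f"layer_index {layer_index} outside 1..{n_layers}")
    if n_layers == 1:
        logger.warning("single-layer model: relative depth set to 0 by convention")
        return 0.0
    return (layer_index - 1) / (n_layers - 1)


@dataclass
class LayerScore:
    """Accuracy of one layer's out-of-fold predictions."""

    layer_id: str
    depth: float
    r: float
    eve: float
    n_images: int


@dataclass
class ModelScore:
    """Best-layer summary for one model."""

    model_id: str
    best_layer_id: str
    best_depth: float
    max_r: float
    eve_at_best: float
    tie: bool = False
    by_group: pd.DataFrame | None = None


@dataclass
class DepthAnalysis:
    """Depth-on-accuracy summary: bin means and per-model OLS slopes."""

    bin_edges: np.ndarray
    bin_mean_r: np.ndarray
    coefficients: pd.Series  # slope of r on depth, per model
    mean_coefficient: float
    ci: tuple[float, float]


def layer_scores(
    predictions: Sequence, y: np.ndarray, r_split: float
) -> list[LayerScore]:
    """Score a set of per-layer predictions against one target vector."""
    y = np.asarray(y, float)
    out = []
    for pred in predictions:
        r = pearson_accuracy(y, pred.yhat)
        out.append(
            LayerScore(
                layer_id=pred.layer_id,
                depth=pred.depth,
                r=r,
                eve=eve(r, r_split) if np.isfinite(r) else float("nan"),
                n_images=y.size,
            )
        )
    return out


def best_layer(scores: Sequence[LayerScore], model_id: str = "") -> ModelScore:
    """Argmax of r over layers; exact ties break toward the shallowest layer."""
    if not scores:
        raise ValueError("no layer scores")
    rs = np.array([s.r for s in scores])
    finite = np.isfinite(rs)
    if not finite.any():
        raise ValueError("all layer accuracies undefined")
    max_r = rs[finite].max()
    winners = [s for s, ok in zip(scores, finite) if ok and s.r == max_r]
    tie = len(winners) > 1
    if tie:
        logger.warning("best-layer tie at r=%.6g; keeping the shallowest", max_r)
        winners.sort(key=lambda s: s.depth)
    best = winners[0]
    return ModelScore(
        model_id=model_id,
        best_layer_id=best.layer_id,
        best_depth=best.depth,
        max_r=best.r,
        eve_at_best=best.eve,
        tie=tie,
    )


def depth_profile(
    scores: pd.DataFrame, n_bins: int = 10, B: int = 1000, seed: int = 0
) -> DepthAnalysis:
    """Depth-on-accuracy regression across models.

    ``scores`` is a tidy frame with columns ``model, depth, r``.  Per model
    an OLS slope of r on depth is fit on the unbinned layer scores; equal-
    width depth bins (default 10) summarize r for display.  The mean slope
    gets a bootstrap-over-models percentile CI.
    """
    req = {"model", "depth", "r"}
    if not req.issubset(scores.columns):
        raise ValueError(f"scores frame needs columns {sorted(req)}")
    if scores["depth"].nunique() < 2:
        raise ValueError("need >= 2 distinct depths for a depth profile")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(scores["depth"], edges[1:-1]), 0, n_bins - 1)
    bin_mean = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            bin_mean[b] = scores.loc[sel, "r"].mean()

    def _slope(sub: pd.DataFrame) -> float:
        if sub["depth"].nunique() < 2:
            return np.nan
        return float(np.polyfit(sub["depth"], sub["r"], 1)[0])

    coefs = scores.groupby("model").apply(_slope, include_groups=False).dropna()
    coefs.name = "depth_coefficient"
    vals = coefs.to_numpy()
    rng = child_rng(seed, "depth_profile_ci")
    boots = vals[rng.integers(0, vals.size, size=(B, vals.size))].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DepthAnalysis(
        bin_edges=edges,
        bin_mean_r=bin_mean,
        coefficients=coefs,
        mean_coefficient=float(vals.mean()),
        ci=(float(lo), float(hi)),
    )


def representativeness(model_mean_r: float, mm1_values) -> float:
    """Fraction of respondents whose r_MM1 is strictly below the model's r."""
    vals = np.asarray(mm1_values, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite mm1 values")
    return float(np.mean(vals < model_mean_r))


def score_by_group(
    predictions: pd.DataFrame,
    table: pd.DataFrame,
    grouping: str = "image_category",
    n_splits: int = 1000,
    seed: int = 0,
    min_images: int = 3,
) -> pd.DataFrame:
    """Recompute r and EVE within image groups, with group-specific ceilings.

    ``predictions`` has columns ``image_id, y, yhat``; ``table`` is the
    matching ratings cell, whose ``grouping`` column (e.g. image_category
    or dataset_id) labels each image.  The split-half ceiling of each group
    is computed on that group's own rating rows only.  Groups with fewer
    than ``min_images`` images are skipped with a log line.
    """
    from .reliability import split_half  # local import to avoid cycle at import time

    if grouping not in table.columns:
        raise ValueError(f"grouping column {grouping!r} not in ratings table")
    labels = table[[grouping, "image_id"]].drop_duplicates()
    multi = labels.groupby("image_id")[grouping].nunique()
    if (multi > 1).any():
        raise ValueError(f"image(s) carry more than one {grouping} label")
    img_to_grp = labels.set_index("image_id")[grouping]
    rows = []
    for grp, ids in img_to_grp.groupby(img_to_grp).groups.items():
        sub = predictions[predictions["image_id"].isin(set(ids))]
        if len(sub) < min_images:
            logger.info("group %r skipped: only %d image(s)", grp, len(sub))
            continue
        r = pearson_accuracy(sub["y"].to_numpy(), sub["yhat"].to_numpy())
        ceil = split_half(table[table[grouping] == grp], n_splits=n_splits, seed=seed)
        rows.append(
            {
                "group": grp,
                "n_images": len(sub),
                "r": r,
                "r_split": ceil.mean,
                "eve": eve(r, ceil.mean) if np.isfinite(r) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def score_model(
    bank,
    table: pd.DataFrame,
    ridge_spec=None,
    proj_spec=None,
    n_splits: int = 200,
    seed: int = 0,
) -> tuple[list[LayerScore], ModelScore, pd.DataFrame]:
    """End-to-end pipeline for one model and one ratings cell.

    group-average the table, decode every layer of the bank, and score
    against the cell's split-half ceiling.  Returns the per-layer scores,
    the best-layer summary, and the best layer's prediction frame.
    """
    from .decoder import decode_bank
    from .reliability import group_average, split_half

    grp = group_average(table)
    if grp.image_ids != list(bank.image_ids):
        raise ValueError("ratings table and feature bank cover different images")
    preds = decode_bank(bank, grp.mean, grp.image_ids, ridge_spec, proj_spec)
    ceiling = split_half(table, n_splits=n_splits, seed=seed)
    scores = layer_scores(preds, grp.mean, ceiling.mean)
    summary = best_layer(scores, model_id=bank.model_id)
    best_pred = next(p for p in preds if p.layer_id == summary.best_layer_id)
    pred_frame = pd.DataFrame(
        {"image_id": grp.image_ids, "y": grp.mean, "yhat": best_pred.yhat}
    )
    return scores, summary, pred_frame
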