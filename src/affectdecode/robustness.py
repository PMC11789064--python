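"""Inferential suite: bootstrap rankings, paired comparisons, individual
and cross-dataset decoding.

* ``bootstrap_scores`` resamples the respondent pool, recomputes group
  means, rescores (or refits) each model's best layer per replicate, and
  tabulates pairwise score differences, sign-fraction bootstrap p-values
  (Holm-corrected over the declared family), and per-replicate model ranks.
* ``paired_ttest_holm`` runs paired t tests across condition cells with
  Holm step-down correction and paired Hedge's g (SD of the differences,
  small-sample correction ``1 - 3/(4 df - 1)``).
* ``mann_whitney`` wraps the rank-sum test (exact for tiny samples).
* ``decode_individual`` refits a layer's features to each respondent's own
  ratings and relates per-respondent accuracy to taste-typicality (r_MM1).
* ``cross_decode`` fits on one image subset and tests on another; the
  diagonal of the resulting matrix is the within-subset LOO accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rand import child_rng
from .bank import FeatureBank
from .decoder import RidgeSpec, ridge_fit, ridge_loo, standardize, decode_bank
from .projection import ProjectionSpec
from .reliability import bootstrap_group, group_average, mm1
from .scoring import pearson_accuracy

__all__ = [
    "holm_adjust",
    "BootstrapResult",
    "bootstrap_scores",
    "ComparisonResult",
    "paired_ttest_holm",
    "mann_whitney",
    "IndividualDecodeResult",
    "decode_individual",
    "cross_decode",
    "cross_decode_matrix",
    "CrossDecodeMatrix",
]

logger = logging.getLogger(__name__)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class BootstrapResult:
    """Respondent-pool bootstrap of model scores and rankings."""

    B: int
    scores: pd.DataFrame  # B x models, per-replicate accuracy r
    deltas: dict[tuple[str, str], np.ndarray]
    delta_ci: dict[tuple[str, str], tuple[float, float]]
    p_raw: dict[tuple[str, str], float]
    p_holm: dict[tuple[str, str], float]
    rank_counts: pd.DataFrame  # models x rank positions, counts summing to B
    seed: int
    mode: str = "rescore"


def _sign_fraction_p(delta: np.ndarray) -> float:
    """Two-sided bootstrap p: 2 * min(frac <= 0, frac >= 0), capped at 1."""
    return float(min(1.0, 2.0 * min(np.mean(delta <= 0), np.mean(delta >= 0))))


def bootstrap_scores(
    banks: Mapping[str, FeatureBank],
    table: pd.DataFrame,
    ridge_spec: RidgeSpec | None = None,
    proj_spec: ProjectionSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    mode: str = "rescore",
) -> BootstrapResult:
    """Bootstrap best-layer accuracies over the respondent pool.

    The best layer per model is selected once on the full pool.  Per
    replicate the group means are recomputed from a respondent resample
    and each model is either rescored against them with its fixed
    predictions (``mode="rescore"``, cheap) or its best-layer regression is
    refit to the resampled means (``mode="refit"``).  Pairwise differences
    over all model pairs form the comparison family for Holm correction.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for bootstrap p-value reporting")
    if mode not in ("rescore", "refit"):
        raise ValueError("mode must be 'rescore' or 'refit'")
    ridge_spec = ridge_spec or RidgeSpec()
    proj_spec = proj_spec or ProjectionSpec()
    grp = group_average(table)
    y = grp.mean
    base_preds: dict[str, object] = {}
    for name, bank in banks.items():
        preds = decode_bank(bank, y, grp.image_ids, ridge_spec, proj_spec)
        rs = [pearson_accuracy(y, p.yhat) for p in preds]
        base_preds[name] = preds[int(np.nanargmax(rs))]
    boot = bootstrap_group(table, B=B, seed=seed)
    names = list(banks)
    mat = np.empty((B, len(names)))
    for j, name in enumerate(names):
        pred = base_preds[name]
        if mode == "rescore":
            yhat = pred.yhat
            for b in range(B):
                mat[b, j] = pearson_accuracy(boot.means[b], yhat)
        else:
            bank = banks[name]
            layer = next(l for l in bank.layers if l.layer_id == pred.layer_id)
            sub = FeatureBank(bank.model_id, bank.image_ids, [layer], bank.provenance)
            for b in range(B):
                preds_b = decode_bank(sub, boot.means[b], grp.image_ids, ridge_spec, proj_spec)
                mat[b, j] = pearson_accuracy(boot.means[b], preds_b[0].yhat)
    scores = pd.DataFrame(mat, columns=names)

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    deltas = {pair: mat[:, names.index(pair[0])] - mat[:, names.index(pair[1])] for pair in pairs}
    delta_ci = {
        pair: tuple(float(v) for v in np.percentile(d, [2.5, 97.5]))
        for pair, d in deltas.items()
    }
    p_raw = {pair: _sign_fraction_p(d) for pair, d in deltas.items()}
    adj = holm_adjust(list(p_raw.values()))
    p_holm = dict(zip(p_raw, adj))

    order = np.argsort(-mat, axis=1)  # rank 0 = best score
    counts = np.zeros((len(names), len(names)), dtype=int)
    for pos in range(len(names)):
        idx, cnt = np.unique(order[:, pos], return_counts=True)
        counts[idx, pos] = cnt
    rank_counts = pd.DataFrame(
        counts, index=names, columns=[f"rank_{k + 1}" for k in range(len(names))]
    )
    return BootstrapResult(
        B=B,
        scores=scores,
        deltas=deltas,
        delta_ci=delta_ci,
        p_raw=p_raw,
        p_holm=p_holm,
        rank_counts=rank_counts,
        seed=seed,
        mode=mode,
    )


@dataclass
class ComparisonResult:
    """One family of frequentist comparisons (paired t or rank-sum)."""

    table: pd.DataFrame
    kind: str


def hedges_g_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Hedge's g: mean(d)/SD(d) times ``1 - 3/(4 df - 1)``, df=n-1.

    Zero-variance differences: g = 0 if the samples are identical, NaN
    (flagged) for a nonzero constant shift.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0
        logger.warning("Hedge's g undefined: constant nonzero paired difference")
        return float("nan")
    df = n - 1
    return float(d.mean() / sd * (1.0 - 3.0 / (4.0 * df - 1.0)))


def paired_ttest_holm(cells: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> ComparisonResult:
    """Paired t tests per condition cell, Holm-corrected over the family.

    ``cells`` maps a cell label (e.g. "arousal/scene") to the paired score
    vectors (x, y), one entry per model.  Fewer than 3 pairs in a cell is
    an error.
    """
    rows = []
    for name, (x, y) in cells.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape or x.size < 3:
            raise ValueError(f"cell {name!r}: need >= 3 complete pairs")
        d = x - y
        if d.std(ddof=1) == 0.0:
            t, p = (np.nan, 1.0) if np.allclose(d, 0.0) else (np.nan, np.nan)
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append(
            {
                "cell": name,
                "n_pairs": x.size,
                "mean_delta": float(d.mean()),
                "t": float(t) if np.isfinite(t) else np.nan,
                "df": x.size - 1,
                "p_raw": float(p) if np.isfinite(p) else np.nan,
                "hedges_g": hedges_g_paired(x, y),
            }
        )
    frame = pd.DataFrame(rows)
    finite = frame["p_raw"].notna()
    adjusted = np.full(len(frame), np.nan)
    adjusted[finite.to_numpy()] = holm_adjust(frame.loc[finite, "p_raw"].to_numpy())
    frame["p_holm"] = adjusted
    return ComparisonResult(table=frame, kind="paired_t")


def mann_whitney(x: np.ndarray, y: np.ndarray) -> ComparisonResult:
    """Two-sided Mann-Whitney rank-sum test (exact for tiny tie-free samples)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need size >= 2")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    frame = pd.DataFrame(
        [{"W": float(res.statistic), "p": float(res.pvalue), "n_x": x.size, "n_y": y.size}]
    )
    return ComparisonResult(table=frame, kind="mann_whitney")


@dataclass
class IndividualDecodeResult:
    """Per-respondent decoding accuracies and their link to taste-typicality."""

    r_individual: pd.Series
    r_mm1: pd.Series
    corr_with_mm1: float
    skipped: list[str] = field(default_factory=list)


def decode_individual(
    features: np.ndarray,
    image_ids: Sequence[str],
    table: pd.DataFrame,
    ridge_spec: RidgeSpec | None = None,
    min_images: int = 20,
) -> IndividualDecodeResult:
    """Refit a layer's features to each respondent's own ratings.

    ``features`` is the (typically best) layer matrix aligned to
    ``image_ids``.  For each respondent rating at least ``min_images``
    images, the feature rows of their viewed images are standardized and
    LOO-ridge-fit against their own ratings; negative accuracies are
    reported as-is.  Also returns the Pearson correlation across
    respondents between r_MM1 and individual decoding accuracy.
    """
    ridge_spec = ridge_spec or RidgeSpec()
    features = np.asarray(features, float)
    row_of = {img: i for i, img in enumerate(image_ids)}
    r_mm1 = mm1(table)
    out: dict[str, float] = {}
    skipped: list[str] = []
    for resp, sub in table.groupby("respondent_id"):
        if len(sub) < min_images:
            skipped.append(str(resp))
            continue
        rows = np.array([row_of[i] for i in sub["image_id"]])
        y = sub["rating"].to_numpy(float)
        if y.std() == 0.0:
            out[str(resp)] = np.nan
            continue
        Pz, yz, params = standardize(features[rows], y)
        out[str(resp)] = pearson_accuracy(y, params.inverse_y(ridge_loo(Pz, yz, ridge_spec.lam)))
    if skipped:
        logger.info("decode_individual: skipped %d respondent(s) below the %d-image floor",
                    len(skipped), min_images)
    r_ind = pd.Series(out, name="r_individual")
    joined = pd.concat([r_ind, r_mm1], axis=1, join="inner").dropna()
    corr = (
        float(np.corrcoef(joined["r_individual"], joined["r_mm1"])[0, 1])
        if len(joined) >= 3
        else float("nan")
    )
    return IndividualDecodeResult(r_individual=r_ind, r_mm1=r_mm1, corr_with_mm1=corr, skipped=skipped)


def cross_decode(
    features: np.ndarray,
    targets: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    ridge_spec: RidgeSpec | None = None,
) -> float:
    """One cross-decoding cell: fit on train rows, score r on test rows.

    If train and test rows are identical the within-set LOO accuracy is
    returned (the matrix diagonal); partially overlapping sets are an
    error.  Standardization parameters come from the training rows only
    and are applied unchanged to the test rows.
    """
    ridge_spec = ridge_spec or RidgeSpec()
    features = np.asarray(features, float)
    targets = np.asarray(targets, float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    train_set, test_set = set(train_idx.tolist()), set(test_idx.tolist())
    if train_set == test_set:
        Pz, yz, params = standardize(features[train_idx], targets[train_idx])
        yhat = params.inverse_y(ridge_loo(Pz, yz, ridge_spec.lam))
        return pearson_accuracy(targets[train_idx], yhat)
    if train_set & test_set:
        raise ValueError("off-diagonal cross-decoding requires disjoint train/test rows")
    Pz, yz, params = standardize(features[train_idx], targets[train_idx])
    beta = ridge_fit(Pz, yz, ridge_spec.lam)
    P_test = params.transform(features[test_idx])
    yhat = params.inverse_y(P_test @ beta)
    return pearson_accuracy(targets[test_idx], yhat)


@dataclass
class CrossDecodeMatrix:
    """Train-subset x test-subset accuracies; diagonal = within-set LOO."""

    accuracy: pd.DataFrame


def cross_decode_matrix(
    features: np.ndarray,
    targets: np.ndarray,
    labels: Sequence[str],
    ridge_spec: RidgeSpec | None = None,
) -> CrossDecodeMatrix:
    """All train x test subset combinations for one common feature space.

    ``labels`` assigns each image (row) to a subset, e.g.
    ``"dataset_a:landscape"``.
    """
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels.tolist()))
    idx = {g: np.flatnonzero(labels == g) for g in groups}
    acc = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for gtr in groups:
        for gte in groups:
            acc.loc[gtr, gte] = cross_decode(features, targets, idx[gtr], idx[gte], ridge_spec)
    return CrossDecodeMatrix(accuracy=acc)
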