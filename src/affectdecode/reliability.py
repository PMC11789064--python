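"""Inter-rater variability ceilings for sparse rating tables.

Two ceilings contextualize decoding accuracy:

* ``r_MM1`` (mean-minus-one): for each respondent, the Pearson correlation
  between their ratings and the group mean computed without them, over
  exactly the images that respondent rated — a "ceiling of shared taste".
* ``r_split`` (split-half reliability): respondents are repeatedly split
  into two halves, per-image half means are correlated across images, and
  each split's correlation is Spearman-Brown corrected, ``2r/(1+r)`` — the
  noise ceiling on any model of the group average.

Tables are long-format DataFrames with columns ``respondent_id, image_id,
rating, affect, image_category, dataset_id``.  The reliability operations
work on one (affect, dataset) cell at a time and raise on mixed tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rand import child_rng

__all__ = [
    "RATING_COLUMNS",
    "validate_ratings",
    "GroupRatings",
    "group_average",
    "mm1",
    "spearman_brown",
    "split_half",
    "SplitHalfResult",
    "bootstrap_group",
    "BootstrapGroupResult",
    "ReliabilityReport",
    "reliability_report",
]

logger = logging.getLogger(__name__)

RATING_COLUMNS = ("respondent_id", "image_id", "rating", "affect", "image_category", "dataset_id")
_KEY = ["dataset_id", "affect", "respondent_id", "image_id"]


def validate_ratings(
    table: pd.DataFrame, scale: tuple[float, float] = (0.0, 7.0)
) -> pd.DataFrame:
    """Validate a long-format ratings table; returns the table unchanged.

    Rejects missing columns, out-of-scale ratings, and duplicate
    (dataset, affect, respondent, image) keys, naming offending rows.
    """
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table is missing column(s): {missing}")
    lo, hi = scale
    bad = table.index[(table["rating"] < lo) | (table["rating"] > hi) | table["rating"].isna()]
    if len(bad):
        raise ValueError(
            f"{len(bad)} rating(s) outside the [{lo}, {hi}] scale; first offending row index: {bad[0]}"
        )
    dup = table.duplicated(subset=_KEY)
    if dup.any():
        key = table.loc[dup.idxmax(), _KEY].tolist()
        raise ValueError(f"duplicate (dataset, affect, respondent, image) key: {key}")
    return table


def _single_cell(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("affect", "dataset_id"):
        if col in table.columns and table[col].nunique() > 1:
            raise ValueError(
                f"table mixes multiple {col} values; filter to one (affect, dataset) cell first"
            )
    return table


@dataclass
class GroupRatings:
    """Per-image group-average ratings with rater counts."""

    image_ids: list[str]
    mean: np.ndarray
    n_raters: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.mean, index=self.image_ids, name="group_mean")


def group_average(table: pd.DataFrame) -> GroupRatings:
    """Arithmetic mean rating per image over all respondents who rated it.

    Images are returned in sorted image_id order.  An image with fewer than
    two raters is an error.
    """
    _single_cell(table)
    agg = table.groupby("image_id", sort=True)["rating"].agg(["mean", "count"])
    thin = agg.index[agg["count"] < 2]
    if len(thin):
        raise ValueError(f"image {thin[0]!r} has fewer than 2 raters ({int(agg.loc[thin[0], 'count'])})")
    return GroupRatings(list(agg.index), agg["mean"].to_numpy(), agg["count"].to_numpy())


def mm1(table: pd.DataFrame, min_images: int = 3) -> pd.Series:
    """Mean-minus-one correlation per respondent.

    For each respondent: Pearson correlation, over the images that
    respondent rated, between their ratings and the leave-that-respondent-
    out group mean.  Respondents with zero rating variance (or degenerate
    leave-out means) get NaN — flagged, never coerced to 0 or dropped.
    """
    _single_cell(table)
    counts = table.groupby("respondent_id")["image_id"].count()
    thin = counts.index[counts < min_images]
    if len(thin):
        raise ValueError(
            f"respondent {thin[0]!r} rated only {int(counts[thin[0]])} image(s); "
            f"mm1 requires >= {min_images}"
        )
    grp = table.groupby("image_id")["rating"]
    tot = grp.transform("sum")
    cnt = grp.transform("count")
    if (cnt < 2).any():
        bad = table.loc[cnt < 2, "image_id"].iloc[0]
        raise ValueError(f"image {bad!r} has fewer than 2 raters; leave-one-out mean undefined")
    loo_mean = (tot - table["rating"]) / (cnt - 1)
    work = pd.DataFrame(
        {"respondent_id": table["respondent_id"], "own": table["rating"], "rest": loo_mean}
    )

    def _corr(sub: pd.DataFrame) -> float:
        x = sub["own"].to_numpy(float)
        y = sub["rest"].to_numpy(float)
        if x.std() == 0.0 or y.std() == 0.0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    out = work.groupby("respondent_id").apply(_corr, include_groups=False)
    out.name = "r_mm1"
    n_undef = int(out.isna().sum())
    if n_undef:
        logger.warning("mm1 undefined (zero variance) for %d respondent(s)", n_undef)
    return out


def spearman_brown(r_half):
    """Spearman-Brown prophecy correction ``2r / (1 + r)``.

    Projects a half-sample reliability to the full sample.  Fixed points at
    0 and 1; undefined at r = -1.
    """
    r = np.asarray(r_half, dtype=np.float64)
    if np.any(r <= -1.0):
        raise ValueError("Spearman-Brown correction undefined for r_half <= -1")
    out = 2.0 * r / (1.0 + r)
    return float(out) if np.isscalar(r_half) or out.ndim == 0 else out


def _pivot(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Respondents x images value and indicator matrices (NaN -> 0/absent)."""
    wide = table.pivot(index="respondent_id", columns="image_id", values="rating")
    V = wide.to_numpy(float)
    seen = np.isfinite(V)
    return np.where(seen, V, 0.0), seen.astype(np.float64), list(wide.index), list(wide.columns)


def _rowwise_corr(A: np.ndarray, B: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row pair of A, B over the `valid` columns."""
    n = valid.sum(axis=1)
    A = np.where(valid, A, 0.0)
    B = np.where(valid, B, 0.0)
    sa, sb = A.sum(1), B.sum(1)
    saa, sbb, sab = (A * A).sum(1), (B * B).sum(1), (A * B).sum(1)
    cov = sab - sa * sb / n
    va = saa - sa**2 / n
    vb = sbb - sb**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / np.sqrt(va * vb)


@dataclass
class SplitHalfResult:
    """Distribution of Spearman-Brown-corrected split-half reliabilities."""

    values: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_splits: int
    seed: int
    n_images_excluded: int  # total image-split exclusions (unrated in a half)


def split_half(
    table: pd.DataFrame,
    n_splits: int = 10_000,
    seed: int = 0,
    batch: int = 500,
) -> SplitHalfResult:
    """Split-half reliability of the group-average ratings.

    Respondents are partitioned into two equal halves ``n_splits`` times
    (odd pools drop one respondent at random per split); per-image means are
    computed within each half over available raters, the two mean vectors
    are correlated across images, and each split's r is Spearman-Brown
    corrected.  Images unrated in one half are excluded from that split's
    correlation, with a logged total.
    """
    _single_cell(table)
    S, C, _, _ = _pivot(table)
    n_r = S.shape[0]
    if n_r < 2:
        raise ValueError("split-half reliability needs at least 2 respondents")
    half = n_r // 2
    rng = child_rng(seed, "split_half")
    vals = np.empty(n_splits)
    excluded = 0
    for start in range(0, n_splits, batch):
        b = min(batch, n_splits - start)
        # ranks of uniforms give a fresh random permutation per split
        order = np.argsort(rng.random((b, n_r)), axis=1)
        in_a = np.zeros((b, n_r))
        np.put_along_axis(in_a, order[:, :half], 1.0, axis=1)
        in_b = np.zeros((b, n_r))
        np.put_along_axis(in_b, order[:, half : 2 * half], 1.0, axis=1)
        sum_a, cnt_a = in_a @ S, in_a @ C
        sum_b, cnt_b = in_b @ S, in_b @ C
        valid = (cnt_a > 0) & (cnt_b > 0)
        excluded += int((~valid).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_a = np.where(valid, sum_a / np.maximum(cnt_a, 1.0), 0.0)
            mean_b = np.where(valid, sum_b / np.maximum(cnt_b, 1.0), 0.0)
        vals[start : start + b] = _rowwise_corr(mean_a, mean_b, valid)
    if excluded:
        logger.info("split_half: %d image-split exclusions (image unrated in one half)", excluded)
    corrected = spearman_brown(vals)
    lo, hi = np.percentile(corrected, [2.5, 97.5])
    return SplitHalfResult(
        values=corrected,
        mean=float(np.mean(corrected)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_splits=n_splits,
        seed=seed,
        n_images_excluded=excluded,
    )


@dataclass
class BootstrapGroupResult:
    """Respondent-pool bootstrap replicates of the group-average ratings."""

    image_ids: list[str]
    means: np.ndarray  # B x n_images
    carried_forward: np.ndarray  # B x n_images bool: no raters in replicate
    B: int
    seed: int


def bootstrap_group(
    table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> BootstrapGroupResult:
    """Resample the respondent pool with replacement B times.

    Each replicate draws respondents with replacement (keeping their full
    rating rows) and recomputes per-image means.  An image left with no
    raters in a replicate carries the original full-pool mean, flagged in
    ``carried_forward``.  ``weights`` (B x n_respondents multiplicities,
    respondents in sorted id order) may be supplied for diagnostics — e.g.
    a row of ones reproduces the plain group average.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _single_cell(table)
    S, C, _, image_ids = _pivot(table)
    n_r = S.shape[0]
    if weights is None:
        rng = child_rng(seed, "bootstrap_group")
        W = rng.multinomial(n_r, np.full(n_r, 1.0 / n_r), size=B).astype(np.float64)
    else:
        W = np.asarray(weights, dtype=np.float64)
        if W.shape != (B, n_r):
            raise ValueError(f"weights must have shape ({B}, {n_r})")
    sums, cnts = W @ S, W @ C
    empty = cnts == 0
    base = np.where(C.sum(0) > 0, S.sum(0) / np.maximum(C.sum(0), 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(empty, base, sums / np.maximum(cnts, 1.0))
    if empty.any():
        logger.info("bootstrap_group: %d image-replicate cells carried the original mean", int(empty.sum()))
    return BootstrapGroupResult(image_ids, means, empty, B, seed)


@dataclass
class ReliabilityReport:
    """Both ceilings plus bootstrap CIs for one (affect, dataset) cell."""

    r_mm1: pd.Series
    mm1_mean: float
    mm1_ci: tuple[float, float]
    split: SplitHalfResult
    seed: int

    def to_dict(self) -> dict:
        return {
            "mm1_mean": self.mm1_mean,
            "mm1_ci": list(self.mm1_ci),
            "n_respondents": int(self.r_mm1.size),
            "n_mm1_undefined": int(self.r_mm1.isna().sum()),
            "r_split_mean": self.split.mean,
            "r_split_ci": [self.split.ci_low, self.split.ci_high],
            "n_splits": self.split.n_splits,
            "seed": self.seed,
        }


def reliability_report(
    table: pd.DataFrame,
    n_splits: int = 10_000,
    B: int = 1000,
    seed: int = 0,
) -> ReliabilityReport:
    """Compute r_MM1 (with a respondent-pool bootstrap CI of its mean) and
    the split-half reliability distribution for one table cell."""
    r = mm1(table)
    vals = r.dropna().to_numpy()
    rng = child_rng(seed, "mm1_ci")
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    split = split_half(table, n_splits=n_splits, seed=seed)
    return ReliabilityReport(
        r_mm1=r,
        mm1_mean=float(vals.mean()),
        mm1_ci=(float(lo), float(hi)),
        split=split,
        seed=seed,
    )
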