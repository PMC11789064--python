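"""Synthetic rater pools and hierarchical feature banks with known truth.

The generator exists so every downstream stage — ceilings, projection,
decoding, scoring, robustness statistics — can be tested by parameter
recovery without any external behavioral data.

Rating model.  Respondent ``i``'s rating of image ``j`` is

    x_ij = t_j + u_ij + e_ij,

with an image-level latent affect ``t_j ~ N(0, var_shared)`` common to all
raters, a stable rater-idiosyncratic preference ``u_ij ~ N(0, var_idio)``,
and trial noise ``e_ij ~ N(0, var_noise)``.  Ratings are affinely mapped
onto the 0-7 scale (and optionally rounded to integers).  With ``m`` raters
per image the Spearman-Brown-corrected split-half reliability of the group
mean is analytically

    r_split = s / (s + (v_i + v_e) / m),

which the generator records as ground truth for recovery tests.

Feature model.  A bank of ``L`` layers carries a designed, depth-graded
trace of the latent: the deepest layer's best linear read-out reaches a
decodable fraction ``f`` of the explainable (noise-ceiling) variance, i.e.
its designed decoding accuracy is ``r(y, yhat)^2 = f * r_split^2`` so that
the explainable-variance-explained score recovers ``f``.  Shallower layers
mix the decodable signal with exactly-orthogonalized noise according to a
monotone depth profile ``alpha(d)``; ``alpha == 0`` yields the signal-free
"untrained" analog.  The depth gain is applied by signal mixing rather than
by scaling the signal block, because column standardization in the decoder
removes any purely multiplicative gain.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rand import child_rng
from .bank import FeatureBank, LayerFeatures
from .scoring import relative_depth

__all__ = [
    "RaterSimConfig",
    "FeatureSimConfig",
    "SimTruth",
    "simulate_ratings",
    "simulate_feature_bank",
    "make_paired_banks",
    "simulate_two_datasets",
    "TwoDatasetSim",
    "DEPTH_PROFILES",
]

#: Named monotone depth-gain profiles alpha(d), d in [0, 1].
DEPTH_PROFILES: dict[str, Callable[[float], float]] = {
    "linear": lambda d: d,
    "quadratic": lambda d: d**2,
    "cubic": lambda d: d**3,
    "zero": lambda d: 0.0,
}


@dataclass
class RaterSimConfig:
    """Rater-pool generative parameters (defaults: 900 images, 40 raters,
    variance split 1 shared / 2 idiosyncratic / 2 trial noise)."""

    n_images: int = 900
    n_raters: int = 40
    var_shared: float = 1.0
    var_idio: float = 2.0
    var_noise: float = 2.0
    coverage: float = 1.0
    scale_min: float = 0.0
    scale_max: float = 7.0
    discretize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.var_shared, self.var_idio, self.var_noise) < 0:
            raise ValueError("variances must be >= 0")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.n_images < 1 or self.n_raters < 2:
            raise ValueError("need n_images >= 1 and n_raters >= 2")


@dataclass
class FeatureSimConfig:
    """Feature-hierarchy generative parameters.

    ``decodable_fraction`` is the designed deepest-layer EVE score;
    ``n_signal_dims`` the number of feature dimensions carrying the signal;
    ``noise_scale`` the SD of the i.i.d. feature noise overlaid on every
    dimension; ``depth_profile`` a name from :data:`DEPTH_PROFILES` or a
    nondecreasing callable [0,1] -> [0,1].
    """

    n_layers: int = 8
    dims_per_layer: Sequence[int] | None = None
    n_signal_dims: int = 16
    depth_profile: str | Callable[[float], float] = "linear"
    decodable_fraction: float = 0.5
    noise_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims_per_layer is None:
            self.dims_per_layer = tuple([64] * self.n_layers)
        self.dims_per_layer = tuple(int(d) for d in self.dims_per_layer)
        if len(self.dims_per_layer) != self.n_layers:
            raise ValueError("dims_per_layer length must equal n_layers")
        k = self.n_signal_dims
        if k < 1 or any(d < k for d in self.dims_per_layer):
            raise ValueError("need every layer width D >= n_signal_dims >= 1")
        if not 0.0 <= self.decodable_fraction <= 1.0:
            raise ValueError("decodable_fraction must be in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        alpha = self.alpha
        grid = [alpha(d) for d in np.linspace(0, 1, 21)]
        if grid[0] < 0 or any(b < a - 1e-12 for a, b in zip(grid, grid[1:])):
            raise ValueError("depth_profile must be nondecreasing with alpha(0) >= 0")
        if max(grid) > 1 + 1e-12:
            raise ValueError("depth_profile must map into [0, 1]")

    @property
    def alpha(self) -> Callable[[float], float]:
        if callable(self.depth_profile):
            return self.depth_profile
        try:
            return DEPTH_PROFILES[self.depth_profile]
        except KeyError:
            raise ValueError(
                f"unknown depth_profile {self.depth_profile!r}; "
                f"choose from {sorted(DEPTH_PROFILES)} or pass a callable"
            ) from None


@dataclass
class SimTruth:
    """Generative ground truth recorded for parameter-recovery tests."""

    image_ids: list[str]
    latent: np.ndarray
    m_per_image: np.ndarray
    expected_rsplit: float
    rater_config: RaterSimConfig
    affine_scale: float
    affine_offset: float
    n_clipped: int = 0
    weights: np.ndarray | None = None
    feature_config: FeatureSimConfig | None = None
    expected_max_r2: float | None = None
    signal: np.ndarray | None = None  # designed decodable per-image signal g

    def to_dict(self) -> dict:
        return {
            "image_ids": self.image_ids,
            "latent": self.latent.tolist(),
            "m_per_image": self.m_per_image.tolist(),
            "expected_rsplit": self.expected_rsplit,
            "expected_max_r2": self.expected_max_r2,
            "affine_scale": self.affine_scale,
            "affine_offset": self.affine_offset,
            "n_clipped": self.n_clipped,
            "weights": None if self.weights is None else self.weights.tolist(),
        }


def _expected_rsplit(cfg: RaterSimConfig, m_bar: float) -> float:
    s, v = cfg.var_shared, cfg.var_idio + cfg.var_noise
    if s == 0.0:
        return 0.0
    if v == 0.0:
        return 1.0
    return s / (s + v / m_bar)


def simulate_ratings(
    config: RaterSimConfig,
    *,
    affect: str = "beauty",
    dataset_id: str = "synthetic",
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a long-format ratings table plus its generative ground truth.

    Each rater views a uniform random subset of ``round(coverage *
    n_images)`` images (a fixed per-rater count, mirroring fixed-quota
    viewing designs).  Raises if any image ends up with fewer than 2
    raters, naming the image.
    """
    n, R = config.n_images, config.n_raters
    image_ids = [f"img{j:04d}" for j in range(n)]
    rater_ids = [f"sub{i:04d}" for i in range(R)]
    if categories is not None and len(categories) != n:
        raise ValueError("categories must have one label per image")

    rng_lat = child_rng(config.seed, "ratings", "latent")
    rng_view = child_rng(config.seed, "ratings", "views")
    rng_obs = child_rng(config.seed, "ratings", "observe")

    t = rng_lat.standard_normal(n) * math.sqrt(config.var_shared)
    n_view = int(round(config.coverage * n))
    if n_view < 1:
        raise ValueError("coverage too low: raters would view 0 images")

    rater_idx = np.repeat(np.arange(R), n_view)
    img_idx = np.concatenate([rng_view.choice(n, size=n_view, replace=False) for _ in range(R)])
    m = np.bincount(img_idx, minlength=n)
    if (m < 2).any():
        j = int(np.argmin(m))
        raise ValueError(
            f"image {image_ids[j]!r} has {int(m[j])} rater(s) under coverage="
            f"{config.coverage}; every image needs >= 2"
        )

    u = rng_obs.standard_normal(img_idx.size) * math.sqrt(config.var_idio)
    e = rng_obs.standard_normal(img_idx.size) * math.sqrt(config.var_noise)
    x = t[img_idx] + u + e

    sd_tot = math.sqrt(config.var_shared + config.var_idio + config.var_noise)
    lo, hi = config.scale_min, config.scale_max
    scale = (hi - lo) / (8.0 * sd_tot) if sd_tot > 0 else 1.0  # +/- 4 SD spans the scale
    offset = (lo + hi) / 2.0
    rating = offset + scale * x
    n_clipped = int(((rating < lo) | (rating > hi)).sum())
    rating = np.clip(rating, lo, hi)
    if config.discretize:
        rating = np.clip(np.rint(rating), lo, hi)

    table = pd.DataFrame(
        {
            "respondent_id": np.array(rater_ids, dtype=object)[rater_idx],
            "image_id": np.array(image_ids, dtype=object)[img_idx],
            "rating": rating,
            "affect": affect,
            "image_category": (
                "all" if categories is None else np.array(categories, dtype=object)[img_idx]
            ),
            "dataset_id": dataset_id,
        }
    )
    truth = SimTruth(
        image_ids=image_ids,
        latent=t,
        m_per_image=m,
        expected_rsplit=_expected_rsplit(config, float(m.mean())),
        rater_config=config,
        affine_scale=scale,
        affine_offset=offset,
        n_clipped=n_clipped,
    )
    return table, truth


def _standardized(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _orthonormal_noise(rng: np.random.Generator, basis: np.ndarray | None, n: int) -> np.ndarray:
    """A standardized vector exactly orthogonal to the columns of ``basis``."""
    v = rng.standard_normal(n)
    v -= v.mean()
    if basis is not None and basis.size:
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        v = v - basis @ coef
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate noise draw; n too small for orthogonalization")
    return v / sd


def simulate_feature_bank(
    config: FeatureSimConfig,
    truth: SimTruth,
    *,
    model_id: str = "simnet",
    stream: str = "trained",
) -> FeatureBank:
    """Generate a layerwise feature bank carrying the designed affect signal.

    Updates ``truth`` in place with the read-out weights, the feature
    config, the designed per-image signal, and the designed ceiling
    ``expected_max_r2 = f * r_split^2``.
    """
    n = len(truth.image_ids)
    k = config.n_signal_dims
    if n < k + 3:
        raise ValueError(f"n_images={n} too small for n_signal_dims={k}")
    rng = child_rng(config.seed, "feature_bank", stream)

    z = _standardized(truth.latent) if truth.latent.std() > 0 else np.zeros(n)
    q = config.decodable_fraction * truth.expected_rsplit
    eta = _orthonormal_noise(rng, z[:, None], n)
    g = math.sqrt(q) * z + math.sqrt(1.0 - q) * eta  # unit variance, corr(g, z) = sqrt(q)
    basis = np.column_stack([z, eta])

    w = (rng.integers(0, 2, size=k) * 2 - 1).astype(np.float64)
    alpha = config.alpha
    layers = []
    for ell in range(config.n_layers):
        d = relative_depth(ell + 1, config.n_layers)
        a = float(alpha(d))
        if a > 0:
            xi = _orthonormal_noise(rng, basis, n)
            g_layer = a * g + math.sqrt(max(0.0, 1.0 - a * a)) * xi
        else:
            g_layer = _orthonormal_noise(rng, basis, n)
        D = config.dims_per_layer[ell]
        X = rng.standard_normal((n, D)) * config.noise_scale
        X[:, :k] += np.outer(g_layer, w)
        layers.append(LayerFeatures(layer_id=f"layer{ell:02d}", depth=d, array=X))

    truth.weights = w
    truth.feature_config = config
    truth.signal = g
    truth.expected_max_r2 = config.decodable_fraction * truth.expected_rsplit**2
    return FeatureBank(
        model_id=model_id,
        image_ids=list(truth.image_ids),
        layers=layers,
        provenance=f"synthetic-{stream}",
    )


def make_paired_banks(
    config: FeatureSimConfig, truth: SimTruth, *, model_id: str = "simnet"
) -> tuple[FeatureBank, FeatureBank]:
    """A trained bank and its signal-free (``alpha == 0``) counterpart.

    Shapes and depths are identical layer-by-layer; only the presence of
    the designed signal differs — the synthetic analog of comparing a model
    to its randomly initialized twin.
    """
    trained = simulate_feature_bank(config, truth, model_id=model_id, stream="trained")
    untrained_cfg = replace(config, depth_profile="zero")
    untrained_truth = copy.copy(truth)
    untrained = simulate_feature_bank(
        untrained_cfg, untrained_truth, model_id=f"{model_id}-untrained", stream="untrained"
    )
    return trained, untrained


@dataclass
class TwoDatasetSim:
    """Two rating tables + feature banks with category-structured read-outs."""

    tables: tuple[pd.DataFrame, pd.DataFrame]
    banks: tuple[FeatureBank, FeatureBank]
    truths: tuple[SimTruth, SimTruth]
    categories: tuple[tuple[str, ...], tuple[str, ...]]
    shared_category: str | None


def simulate_two_datasets(
    shared_category_overlap: bool = True,
    rater_config: RaterSimConfig | None = None,
    feature_config: FeatureSimConfig | None = None,
    seed: int = 0,
    categories_a: tuple[str, ...] = ("landscape", "object"),
    categories_b: tuple[str, ...] | None = None,
) -> TwoDatasetSim:
    """Two datasets whose shared image category (if any) shares its read-out.

    Every category owns a dedicated block of ``n_signal_dims`` feature
    columns; the read-out weights of a category are drawn from a stream
    keyed by the category *name*, so a category present in both datasets
    automatically uses a common weight vector while non-shared categories
    draw independent ones.  Cross-decoding between the shared category of
    the two datasets therefore transfers; between disjoint categories it
    does not.
    """
    rater_config = rater_config or RaterSimConfig(n_images=400, n_raters=30)
    # Wide layers with substantial per-dimension feature noise: transfer between
    # categories must be carried by the shared read-out, not by a low-rank
    # signal structure dominating the prediction variance.
    feature_config = feature_config or FeatureSimConfig(
        n_layers=3, dims_per_layer=(512, 512, 512), noise_scale=1.5, decodable_fraction=0.75
    )
    if categories_b is None:
        categories_b = ("landscape", "face") if shared_category_overlap else ("art", "face")
    shared = sorted(set(categories_a) & set(categories_b))
    if shared_category_overlap and not shared:
        raise ValueError("shared_category_overlap=True but the category sets are disjoint")

    all_cats = sorted(set(categories_a) | set(categories_b))
    k = feature_config.n_signal_dims
    if any(D < k * len(all_cats) for D in feature_config.dims_per_layer):
        raise ValueError(
            f"layer widths must be >= n_signal_dims * n_categories = {k * len(all_cats)}"
        )
    block = {c: slice(i * k, (i + 1) * k) for i, c in enumerate(all_cats)}
    weights = {
        c: (child_rng(seed, "category_weights", c).integers(0, 2, size=k) * 2 - 1).astype(float)
        for c in all_cats
    }

    tables, banks, truths = [], [], []
    for idx, (ds, cats) in enumerate([("dataset_a", categories_a), ("dataset_b", categories_b)]):
        cfg = replace(rater_config, seed=int(child_rng(seed, ds, "cfg").integers(0, 2**31 - 1)))
        n = cfg.n_images
        per = n // len(cats)
        labels = np.array(
            [cats[min(j // per, len(cats) - 1)] for j in range(n)], dtype=object
        )
        table, truth = simulate_ratings(cfg, dataset_id=ds, categories=labels)
        rng = child_rng(seed, ds, "features")
        z = _standardized(truth.latent)
        q = feature_config.decodable_fraction * truth.expected_rsplit
        eta = _orthonormal_noise(rng, z[:, None], n)
        g = math.sqrt(q) * z + math.sqrt(1.0 - q) * eta
        basis = np.column_stack([z, eta])
        alpha = feature_config.alpha
        layers = []
        for ell in range(feature_config.n_layers):
            d = relative_depth(ell + 1, feature_config.n_layers)
            a = float(alpha(d))
            if a > 0:
                xi = _orthonormal_noise(rng, basis, n)
                g_layer = a * g + math.sqrt(max(0.0, 1.0 - a * a)) * xi
            else:
                g_layer = _orthonormal_noise(rng, basis, n)
            D = feature_config.dims_per_layer[ell]
            X = rng.standard_normal((n, D)) * feature_config.noise_scale
            for c in cats:
                rows = labels == c
                X[np.ix_(rows, np.arange(D)[block[c]])] += np.outer(g_layer[rows], weights[c])
            layers.append(LayerFeatures(layer_id=f"layer{ell:02d}", depth=d, array=X))
        truth.feature_config = feature_config
        truth.signal = g
        truth.expected_max_r2 = feature_config.decodable_fraction * truth.expected_rsplit**2
        tables.append(table)
        banks.append(
            FeatureBank(
                model_id=f"simnet-{ds}",
                image_ids=list(truth.image_ids),
                layers=layers,
                provenance="synthetic-trained",
            )
        )
        truths.append(truth)

    return TwoDatasetSim(
        tables=(tables[0], tables[1]),
        banks=(banks[0], banks[1]),
        truths=(truths[0], truths[1]),
        categories=(tuple(categories_a), tuple(categories_b)),
        shared_category=shared[0] if shared else None,
    )
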