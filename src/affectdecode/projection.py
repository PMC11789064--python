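"""Sparse random projection with the Johnson-Lindenstrauss dimension bound.

High-dimensional layer activations are reduced to a fixed width ``p`` with a
very sparse random sign matrix.  For ``n`` points, an embedding dimension

    p >= 4 ln(n) / (eps^2/2 - eps^3/3)

suffices to preserve all pairwise squared distances within a ``(1 +/- eps)``
factor.  The projection matrix ``R`` (shape ``D x p``) has i.i.d. entries

    +sqrt(sqrt(D)/p)  with probability 1/(2 sqrt(D)),
    -sqrt(sqrt(D)/p)  with probability 1/(2 sqrt(D)),
     0                otherwise,

i.e. density ``1/sqrt(D)``, which keeps ``E ||u R||^2 = ||u||^2`` for any
fixed vector ``u``.  Projection is only applied to layers wider than a
threshold; narrower layers pass through unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

from ._rand import child_rng

__all__ = ["ProjectionSpec", "ProjectionMatrix", "jl_min_dim", "build_projection", "project"]

logger = logging.getLogger(__name__)

#: Default embedding width: the JL minimum dimension for 900 points at
#: distortion 0.1, floored (the unrounded bound is ~5830.6).
DEFAULT_P = 5830


def jl_min_dim(n: int, epsilon: float, rounding: Literal["floor", "ceil"] = "floor") -> int:
    """Minimum embedding dimension preserving pairwise distances of ``n`` points.

    Evaluates ``4 ln(n) / (eps^2/2 - eps^3/3)`` and rounds.  The default
    ``floor`` reproduces the conventional printed value of 5,830 for
    ``n=900, eps=0.1``; ``ceil`` is exposed for conventions that round up.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    value = 4.0 * math.log(n) / (epsilon**2 / 2.0 - epsilon**3 / 3.0)
    if rounding == "floor":
        return math.floor(value)
    if rounding == "ceil":
        return math.ceil(value)
    raise ValueError(f"rounding must be 'floor' or 'ceil', got {rounding!r}")


@dataclass
class ProjectionSpec:
    """Configuration for the dimensionality-reduction stage.

    ``p`` is the target width, ``apply_threshold`` the input width above
    which projection is applied (narrower layers pass through), and
    ``epsilon`` the distortion the defaults were derived from.
    """

    epsilon: float = 0.1
    p: int = DEFAULT_P
    apply_threshold: int = DEFAULT_P
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")


@dataclass
class ProjectionMatrix:
    """A sparse ``D x p`` random sign matrix with its generation metadata."""

    matrix: sparse.csc_array
    D: int
    p: int
    density: float
    magnitude: float
    seed_tags: tuple = field(default_factory=tuple)

    @property
    def nnz_fraction(self) -> float:
        return self.matrix.nnz / (self.D * self.p)


def build_projection(D: int, p: int, seed: int, *tags: object) -> ProjectionMatrix:
    """Draw the sparse projection matrix for ``(seed, *tags)``.

    Entries are i.i.d.: ``+/- sqrt(sqrt(D)/p)`` each with probability
    ``1/(2 sqrt(D))``, zero otherwise.  The draw is deterministic given the
    seed and tags.
    """
    if D < 1 or p < 1:
        raise ValueError(f"D and p must be >= 1, got D={D}, p={p}")
    rng = child_rng(seed, "projection", *tags)
    density = 1.0 / math.sqrt(D)
    magnitude = math.sqrt(math.sqrt(D) / p)

    # Exact i.i.d. Bernoulli entries per column: binomial count of nonzeros,
    # then a uniform subset of rows; built column-wise to bound memory.
    counts = rng.binomial(D, density, size=p)
    indptr = np.zeros(p + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    for j in range(p):
        k = counts[j]
        if k:
            indices[indptr[j] : indptr[j + 1]] = rng.choice(D, size=k, replace=False)
    signs = rng.integers(0, 2, size=indptr[-1]) * 2 - 1
    data = magnitude * signs.astype(np.float64)
    matrix = sparse.csc_array((data, indices, indptr), shape=(D, p))
    return ProjectionMatrix(matrix, D, p, density, magnitude, seed_tags=(seed, *tags))


def project(F: np.ndarray, spec: ProjectionSpec, *tags: object) -> np.ndarray:
    """Project ``F`` (images x D) to width ``spec.p`` if D exceeds the threshold.

    Layers at or below ``spec.apply_threshold`` are returned unchanged
    (identity pass-through); the decision is logged.  ``tags`` (typically
    model and layer ids) select the per-layer random stream so distinct
    layers get independent projection matrices and reruns are reproducible.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("F must be a 2-D images x D matrix")
    if not np.all(np.isfinite(F)):
        raise ValueError(f"non-finite features in layer {tags or '<unnamed>'}")
    D = F.shape[1]
    if D <= spec.apply_threshold:
        logger.debug("projection pass-through for %s (D=%d <= %d)", tags, D, spec.apply_threshold)
        return F
    pm = build_projection(D, spec.p, spec.seed, *tags)
    logger.debug("projecting %s: D=%d -> p=%d (density %.4g)", tags, D, spec.p, pm.density)
    return F @ pm.matrix
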