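"""Leave-one-out cross-validated ridge decoding of group-average ratings.

For every image ``i`` a ridge regression is fit on the remaining images,

    beta_i = (P_-i' P_-i + lambda I)^-1 P_-i' Y_-i,

and used to predict the held-out rating ``yhat_i = P_i beta_i``.  The loop
is never run explicitly: because ridge is a linear smoother the exact LOO
prediction follows from the full-data hat matrix ``H``,

    yhat_loo_i = y_i - (y_i - yhat_i) / (1 - H_ii),

computed in the primal (``p <= n``) or dual/Gram (``p > n``) form, whichever
is cheaper.  The identity is exact; tests check it against a naive per-fold
refit to 1e-8 relative tolerance.

Targets and feature columns are standardized (mean 0, SD 1, population SD)
once on the full data before cross-validation by default, mirroring the
usual decoding practice; a ``per_fold`` mode that re-standardizes inside
each fold is available for leakage-sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .bank import FeatureBank, flatten_features
from .projection import ProjectionSpec, project

__all__ = [
    "RidgeSpec",
    "Standardizer",
    "standardize",
    "ridge_loo",
    "ridge_fit",
    "grid_search_lambda",
    "decode_bank",
    "DecodePrediction",
]

logger = logging.getLogger(__name__)

#: Default logarithmic penalty grid, 1e-1 ... 1e6.
DEFAULT_GRID = tuple(10.0**k for k in range(-1, 7))

_VAR_TOL = 1e-12


@dataclass
class RidgeSpec:
    """Ridge decoding configuration: penalty, search grid, standardization."""

    lam: float = 1e4
    grid: Sequence[float] = DEFAULT_GRID
    standardization_mode: Literal["whole-data", "per-fold"] = "whole-data"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        g = list(self.grid)
        if any(v <= 0 for v in g) or sorted(g) != g:
            raise ValueError("grid must be strictly positive and sorted ascending")


@dataclass
class Standardizer:
    """Column/target standardization parameters (population SD convention)."""

    col_mean: np.ndarray
    col_sd: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns
    n_dropped: int
    y_mean: float
    y_sd: float

    def transform(self, P: np.ndarray) -> np.ndarray:
        return (P[:, self.kept] - self.col_mean) / self.col_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def inverse_y(self, yz: np.ndarray) -> np.ndarray:
        return yz * self.y_sd + self.y_mean


def standardize(P: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, Standardizer]:
    """Standardize feature columns and target to mean 0, SD 1.

    Zero-variance columns are dropped with a logged count; a constant target
    is an error (the target is undecodable).
    """
    P = np.asarray(P, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    col_mean = P.mean(axis=0)
    col_sd = P.std(axis=0)  # population SD
    kept = np.flatnonzero(col_sd > _VAR_TOL)
    n_dropped = P.shape[1] - kept.size
    if n_dropped:
        logger.warning("dropping %d zero-variance feature column(s)", n_dropped)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd <= _VAR_TOL:
        raise ValueError("target Y is constant: undecodable")
    params = Standardizer(col_mean[kept], col_sd[kept], kept, n_dropped, y_mean, y_sd)
    return params.transform(P), params.transform_y(y), params


@dataclass
class DecodePrediction:
    """Out-of-fold predictions for one layer, on the original rating scale."""

    layer_id: str
    depth: float
    yhat: np.ndarray
    lam: float
    standardizer: Standardizer | None = None
    projected: bool = False
    p_used: int = 0
    extras: dict = field(default_factory=dict)


def _hat(Pz: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Full-data ridge fitted values operator: returns (yhat_map, diag H).

    Primal form for p <= n, Gram (dual) form otherwise; both give the hat
    matrix H = P (P'P + lam I)^-1 P' = K (K + lam I)^-1 with K = P P'.
    """
    n, p = Pz.shape
    if lam == 0.0 and p >= n:
        raise np.linalg.LinAlgError(
            "ridge system is singular at lambda=0 with p >= n; use lambda > 0"
        )
    if p <= n:
        G = Pz.T @ Pz + lam * np.eye(p)
        A = np.linalg.solve(G, Pz.T)  # p x n
        h = np.einsum("ij,ji->i", Pz, A)
        H_apply = Pz @ A
    else:
        K = Pz @ Pz.T
        H_apply = np.linalg.solve(K + lam * np.eye(n), K)  # symmetric: commutes
        h = np.diag(H_apply)
    return H_apply, h


def ridge_fit(P_train: np.ndarray, y_train: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients ``(P'P + lam I)^-1 P'y`` (primal or dual by shape)."""
    n, p = P_train.shape
    if lam == 0.0 and p >= n:
        raise np.linalg.LinAlgError(
            "ridge system is singular at lambda=0 with p >= n; use lambda > 0"
        )
    if p <= n:
        G = P_train.T @ P_train + lam * np.eye(p)
        return np.linalg.solve(G, P_train.T @ y_train)
    K = P_train @ P_train.T + lam * np.eye(n)
    return P_train.T @ np.linalg.solve(K, y_train)


def ridge_loo(Pz: np.ndarray, yz: np.ndarray, lam: float) -> np.ndarray:
    """Exact leave-one-out ridge predictions (standardized space).

    Equivalent to refitting ``beta_i`` on the data minus image ``i`` for
    every ``i``, via the hat-matrix identity.
    """
    Pz = np.asarray(Pz, dtype=np.float64)
    yz = np.asarray(yz, dtype=np.float64)
    if Pz.shape[0] < 3:
        raise ValueError("need at least 3 images for leave-one-out decoding")
    H_apply, h = _hat(Pz, lam)
    yhat = H_apply @ yz
    denom = 1.0 - h
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("leverage >= 1 encountered; increase lambda")
    return yz - (yz - yhat) / denom


def ridge_loo_naive(
    Pz: np.ndarray, yz: np.ndarray, lam: float, *, per_fold_standardize: bool = False
) -> np.ndarray:
    """Reference LOO by explicit per-fold refitting (slow; used as oracle and
    as the implementation of the ``per-fold`` standardization mode)."""
    n = Pz.shape[0]
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Ptr, ytr = Pz[mask], yz[mask]
        Pte = Pz[i]  # 1-D test row
        if per_fold_standardize:
            mu, sd = Ptr.mean(axis=0), Ptr.std(axis=0)
            keep = sd > _VAR_TOL
            ymu, ysd = ytr.mean(), ytr.std()
            beta = ridge_fit((Ptr[:, keep] - mu[keep]) / sd[keep], (ytr - ymu) / ysd, lam)
            out[i] = float(((Pte[keep] - mu[keep]) / sd[keep]) @ beta * ysd + ymu)
        else:
            beta = ridge_fit(Ptr, ytr, lam)
            out[i] = float(Pte @ beta)
    return out


def grid_search_lambda(
    Pz: np.ndarray, yz: np.ndarray, grid: Sequence[float] = DEFAULT_GRID
) -> float:
    """The grid penalty minimizing mean LOO squared error.

    Uses one eigendecomposition of the Gram matrix so the whole grid costs a
    single O(n^3) factorization.  Ties break toward the smaller penalty.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    Pz = np.asarray(Pz, dtype=np.float64)
    yz = np.asarray(yz, dtype=np.float64)
    K = Pz @ Pz.T
    evals, Q = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    Qty = Q.T @ yz
    Q2 = Q**2
    best_lam, best_mse = None, np.inf
    for lam in grid:
        shrink = evals / (evals + lam)
        yhat = Q @ (shrink * Qty)
        h = Q2 @ shrink
        loo = yz - (yz - yhat) / (1.0 - h)
        mse = float(np.mean((yz - loo) ** 2))
        if mse < best_mse - 1e-15:
            best_lam, best_mse = lam, mse
    return float(best_lam)


def decode_bank(
    bank: FeatureBank,
    y: np.ndarray,
    image_ids: Sequence[str],
    ridge_spec: RidgeSpec | None = None,
    proj_spec: ProjectionSpec | None = None,
) -> list[DecodePrediction]:
    """Run flatten -> project -> standardize -> LOO ridge for every layer.

    ``y`` are the per-image targets (e.g. group-average ratings) ordered as
    ``image_ids``, which must match the bank's image list exactly.
    """
    ridge_spec = ridge_spec or RidgeSpec()
    proj_spec = proj_spec or ProjectionSpec()
    if list(image_ids) != list(bank.image_ids):
        raise ValueError("image order of targets does not match the feature bank")
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != bank.n_images:
        raise ValueError(
            f"target length {y.shape[0]} does not match bank image count {bank.n_images}"
        )
    preds: list[DecodePrediction] = []
    for layer in bank.layers:
        F = flatten_features(layer.array)
        P = project(F, proj_spec, bank.model_id, layer.layer_id)
        projected = P.shape[1] != F.shape[1]
        Pz, yz, params = standardize(P, y)
        if ridge_spec.standardization_mode == "per-fold":
            yhat = ridge_loo_naive(np.asarray(P, float), y, ridge_spec.lam, per_fold_standardize=True)
        else:
            yhat = params.inverse_y(ridge_loo(Pz, yz, ridge_spec.lam))
        preds.append(
            DecodePrediction(
                layer_id=layer.layer_id,
                depth=layer.depth,
                yhat=yhat,
                lam=ridge_spec.lam,
                standardizer=params,
                projected=projected,
                p_used=Pz.shape[1],
            )
        )
    return preds
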