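"""Training objective: prediction + reconstruction + interpretability terms.

The composite loss is

    L = L_pred + lam_recons * L_recons + lam_mask * sum(m) + lam_group * I(G)

where the paper-form objective is the unweighted sum (all lambdas 1); the
weights exist because the raw terms scale very differently with the feature
count and batch size.  ``I(G)`` is an entropy-style penalty on the raw group
entries that is zero exactly when every entry is 0 or 1, pushing groups
toward crisp memberships.  Mask pre-training minimizes the squared distance
between masks and inputs so that training starts from masks that mirror the
observed features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "prediction_loss",
    "reconstruction_loss",
    "mask_sparsity",
    "group_entropy",
    "pretrain_loss",
    "total_loss",
    "PROB_CLIP",
]

PROB_CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_recons: float = 1.0
    lambda_mask: float = 1.0
    lambda_group: float = 1.0

    def __post_init__(self):
        if min(self.lambda_recons, self.lambda_mask, self.lambda_group) < 0:
            raise ValueError("loss weights must be non-negative")


def _check_same_shape(a: np.ndarray, b: np.ndarray, what: str):
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def prediction_loss(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Mean (over instances) summed binary cross-entropy.

    Handles both the single-output mortality head (c = 1) and wide
    multi-label heads (one output per diagnosis group).  Probabilities are
    clipped to [PROB_CLIP, 1 - PROB_CLIP] before the logs.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=np.float64))
    _check_same_shape(Y, Yhat, "prediction_loss")
    P = np.clip(Yhat, PROB_CLIP, 1.0 - PROB_CLIP)
    n = Y.shape[0]
    return float(-(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)).sum() / n)


def reconstruction_loss(X: np.ndarray, Xmasked: np.ndarray, reconstructor) -> float:
    """Sum over instances of the Euclidean distance ||X_i - phi(Xmasked_i)||_2.

    `reconstructor` maps an (n x d) array to an (n x d) array (a two-layer
    MLP in the trained models; any callable with that contract here).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Xmasked = np.atleast_2d(np.asarray(Xmasked, dtype=np.float64))
    _check_same_shape(X, Xmasked, "reconstruction_loss")
    R = np.asarray(reconstructor(Xmasked), dtype=np.float64)
    _check_same_shape(X, R, "reconstruction_loss output")
    return float(np.linalg.norm(X - R, axis=1).sum())


def mask_sparsity(m: np.ndarray) -> float:
    """Sum of all mask entries (L1 penalty on masks in [0, 1])."""
    m = np.asarray(m, dtype=np.float64)
    return float(m.sum())


def group_entropy(G: np.ndarray) -> float:
    """Entropy-style penalty I(G) on raw group entries.

    I(G) = -(1/d) sum(G^T log G^T) - (1/k) sum(G log G), natural log, with
    0 log 0 := 0.  Both sums run over the same k*d entries, so
    I(G) = (1/d + 1/k) * sum(-G log G); it vanishes iff G is binary.
    """
    G = np.atleast_2d(np.asarray(G, dtype=np.float64))
    if G.min() < 0 or G.max() > 1:
        raise ValueError("group entries must lie in [0, 1]")
    k, d = G.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(G > 0, -G * np.log(np.where(G > 0, G, 1.0)), 0.0)
    return float((1.0 / d + 1.0 / k) * ent.sum())


def pretrain_loss(m: np.ndarray, X: np.ndarray) -> float:
    """Sum of squared element-wise differences between masks and inputs."""
    m = np.asarray(m, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    _check_same_shape(m, X, "pretrain_loss")
    return float(((m - X) ** 2).sum())


def total_loss(
    pred: float,
    recons: float,
    mask_reg: float,
    group_reg: float,
    weights: LossWeights = LossWeights(),
) -> float:
    """Weighted composite objective; unit weights give the plain sum."""
    return float(
        pred
        + weights.lambda_recons * recons
        + weights.lambda_mask * mask_reg
        + weights.lambda_group * group_reg
    )
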