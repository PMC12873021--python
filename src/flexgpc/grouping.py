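"""Feature groups and instance-wise feature masks.

A feature group is a soft membership vector over the ``d`` features: entry
``G[j, f]`` in [0, 1] is the importance of feature ``f`` within group ``j``.
A per-instance mask is built by combining the ``k`` group rows with
selection weights ``s`` under one of two schemes:

* **CC** (convex combination): ``s >= 0``, ``sum(s) == 1``.
* **RAC** (restricted affine combination): ``-1 <= s <= 1``,
  ``sum(|s|) == 1``.  Negative weights *de-select* features that other
  selected groups would otherwise switch on.

The mask applied to an instance is the clamped combination
``m = clamp01(s @ G + eps)`` where ``eps`` is zero-mean Gaussian noise used
only during training (it pushes mask entries toward {0, 1} and lets the
optimizer explore alternative group combinations); at evaluation time
``eps = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureGroupMatrix",
    "SelectionWeights",
    "FeatureMask",
    "convex_combine",
    "restricted_affine_combine",
    "clamp_unit",
    "noisy_mask",
    "CC",
    "RAC",
]

CC = "CC"
RAC = "RAC"

_ATOL = 1e-6


@dataclass(frozen=True)
class FeatureGroupMatrix:
    """k x d matrix of soft feature groups, entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("group matrix must be k x d with k, d >= 1")
        if values.min() < -_ATOL or values.max() > 1.0 + _ATOL:
            raise ValueError("group entries must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SelectionWeights:
    """Length-k weights under the CC or RAC constraint."""

    values: np.ndarray
    scheme: str = CC

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("selection weights must be a 1-d vector")
        if self.scheme == CC:
            if values.min() < -_ATOL or values.max() > 1.0 + _ATOL:
                raise ValueError("CC weights must lie in [0, 1]")
            if abs(values.sum() - 1.0) > _ATOL:
                raise ValueError("CC weights must sum to 1")
        elif self.scheme == RAC:
            if np.abs(values).max() > 1.0 + _ATOL:
                raise ValueError("RAC weights must lie in [-1, 1]")
            if abs(np.abs(values).sum() - 1.0) > _ATOL:
                raise ValueError("RAC weights' absolute values must sum to 1")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureMask:
    """Length-d mask in [0, 1], applied element-wise to an instance."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("mask entries must lie in [0, 1]")


def _check_dims(s: np.ndarray, G: FeatureGroupMatrix):
    if s.shape[-1] != G.k:
        raise ValueError(
            f"weight length {s.shape[-1]} does not match group count {G.k}"
        )


def convex_combine(s: SelectionWeights, G: FeatureGroupMatrix) -> np.ndarray:
    """Convex combination ``s @ G`` of the group rows; output in [0, 1]."""
    if s.scheme != CC:
        raise ValueError("convex_combine requires CC weights")
    _check_dims(s.values, G)
    return s.values @ G.values


def restricted_affine_combine(s: SelectionWeights, G: FeatureGroupMatrix) -> np.ndarray:
    """Restricted affine combination ``s @ G``; output entries in [-1, 1].

    Coincides with :func:`convex_combine` whenever all weights are
    non-negative (the CC simplex is the non-negative face of the RAC
    domain).
    """
    if s.scheme != RAC:
        raise ValueError("restricted_affine_combine requires RAC weights")
    _check_dims(s.values, G)
    return s.values @ G.values


def clamp_unit(w: np.ndarray) -> FeatureMask:
    """Element-wise ``max(0, min(1, w))``, the mask clamping map U."""
    return FeatureMask(np.clip(np.asarray(w, dtype=np.float64), 0.0, 1.0))


def combine(weights: np.ndarray, G: FeatureGroupMatrix) -> np.ndarray:
    """Batched raw combination: rows of `weights` (n x k) against G (k x d)."""
    weights = np.asarray(weights, dtype=np.float64)
    _check_dims(weights, G)
    return weights @ G.values


def noisy_mask(
    s: SelectionWeights | np.ndarray,
    G: FeatureGroupMatrix,
    sigma: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    per_element: bool = True,
) -> FeatureMask:
    """Mask ``clamp01(s @ G + eps)`` with training-time Gaussian noise.

    `sigma` is the standard deviation of the zero-mean noise.  Noise is
    drawn per mask element by default (`per_element=False` shares a single
    draw across the mask, the alternative reading of a scalar eps).  With
    `training=False` or `sigma=0` the mask is the deterministic clamped
    combination.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    raw = s.values if isinstance(s, SelectionWeights) else np.asarray(s, float)
    if isinstance(s, SelectionWeights):
        _check_dims(raw, G)
        w = raw @ G.values
    else:
        w = combine(raw, G)
    if training and sigma > 0:
        if rng is None:
            raise ValueError("training-time noise requires a seeded rng")
        if per_element:
            eps = rng.normal(0.0, sigma, size=w.shape)
        else:
            shared = rng.normal(0.0, sigma, size=w.shape[:-1] + (1,))
            eps = np.broadcast_to(shared, w.shape)
        w = w + eps
    return clamp_unit(w)
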