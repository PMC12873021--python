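"""Selection networks mapping an instance to group-combination weights.

Both schemes share the same two-layer architecture without bias terms:
``z = W2 @ relu(W1 @ x)`` with ``W1`` of shape ``l x d`` and ``W2`` of shape
``k x l``.  The constraint is enforced by the output map:

* CC:  ``s = softmax(z)`` — simplex weights.
* RAC: ``s = z / ||z||_1`` — weights in [-1, 1] whose absolute values sum
  to 1, so a group can carry a negative (de-selecting) weight.

When the RAC denominator vanishes (e.g. an all-zero input gives an all-zero
ReLU layer) the formula is 0/0; we fall back to uniform weights ``1/k`` so
the downstream mask degrades gracefully to the group average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from .grouping import CC, RAC, SelectionWeights

__all__ = ["SelectorParameters", "cc_select", "rac_select", "init_selector"]

_L1_FLOOR = 1e-12


@dataclass
class SelectorParameters:
    """Weights of a two-layer selection network."""

    W1: np.ndarray  # l x d
    W2: np.ndarray  # k x l
    scheme: str = CC

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise ValueError("W1 and W2 must be matrices")
        if self.W2.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"hidden widths disagree: W1 is {self.W1.shape}, W2 is {self.W2.shape}"
            )
        if self.scheme not in (CC, RAC):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def d(self) -> int:
        return self.W1.shape[1]

    @property
    def l(self) -> int:
        return self.W1.shape[0]

    @property
    def k(self) -> int:
        return self.W2.shape[0]


def init_selector(
    d: int, k: int, l: int = 400, scheme: str = CC,
    rng: np.random.Generator | None = None,
) -> SelectorParameters:
    """Symmetric uniform fan-in initialization (U(-1/sqrt(fan_in), +))."""
    if rng is None:
        rng = np.random.default_rng()
    b1 = 1.0 / np.sqrt(d)
    b2 = 1.0 / np.sqrt(l)
    return SelectorParameters(
        W1=rng.uniform(-b1, b1, size=(l, d)),
        W2=rng.uniform(-b2, b2, size=(k, l)),
        scheme=scheme,
    )


def _logits(x: np.ndarray, params: SelectorParameters) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.d:
        raise ValueError(f"input length {x.shape[-1]} != configured d {params.d}")
    h = np.maximum(x @ params.W1.T, 0.0)
    return h @ params.W2.T


def cc_select(x: np.ndarray, params: SelectorParameters) -> SelectionWeights:
    """softmax(W2 relu(W1 x)) — convex-combination weights."""
    if params.scheme != CC:
        raise ValueError("cc_select requires CC parameters")
    z = _logits(x, params)
    return SelectionWeights(_softmax(z, axis=-1), scheme=CC)


def rac_select(x: np.ndarray, params: SelectorParameters) -> SelectionWeights:
    """L1-normalized W2 relu(W1 x) — restricted-affine weights."""
    if params.scheme != RAC:
        raise ValueError("rac_select requires RAC parameters")
    z = _logits(x, params)
    denom = np.abs(z).sum(axis=-1, keepdims=True)
    if np.any(denom <= _L1_FLOOR):
        warnings.warn(
            "zero-magnitude selection logits; falling back to uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
    k = params.k
    s = np.where(denom > _L1_FLOOR, z / np.where(denom > 0, denom, 1.0), 1.0 / k)
    return SelectionWeights(s, scheme=RAC)


def select_batch(X: np.ndarray, params: SelectorParameters) -> np.ndarray:
    """Row-wise selection weights for a batch (n x d) -> (n x k)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    z = _logits(X, params)
    if params.scheme == CC:
        return _softmax(z, axis=-1)
    denom = np.abs(z).sum(axis=-1, keepdims=True)
    return np.where(denom > _L1_FLOOR, z / np.where(denom > 0, denom, 1.0),
                    1.0 / params.k)
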