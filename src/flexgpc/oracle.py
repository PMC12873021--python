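"""Brute-force verification of the combination schemes' claimed properties.

The expressiveness ordering CC ⊆ RAC ⊆ clamped-RAC, the minimal-group
worked construction (a target family needing 4 groups under convex
combination but only 3 under restricted affine combination), the
1-Lipschitz continuity of the combination in the group stack, and the
uniform-stability inequality are all checked *empirically*: weight vectors
are enumerated on a grid over each scheme's domain and targets count as
reachable when some grid combination comes within an L∞ tolerance.  Grid
enumeration rather than symbolic algebra is used because the clamp makes
the reachable sets non-linear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .grouping import FeatureGroupMatrix, clamp_unit

__all__ = [
    "ReachabilityGrid",
    "reachable",
    "min_group_count",
    "lipschitz_estimate",
    "uniform_stability_probe",
    "fig_construction",
]

_GUARD = 10_000_000


@dataclass(frozen=True)
class ReachabilityGrid:
    scheme: str = "CC"               # CC, RAC or CRAC
    resolution: float = 0.05         # grid step on the weight domain
    tolerance: float = 0.05          # max L-infinity distance counted reachable

    def __post_init__(self):
        if self.scheme not in ("CC", "RAC", "CRAC"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def _simplex_grid(k: int, resolution: float) -> np.ndarray:
    """All non-negative weight vectors summing to 1 on the grid."""
    units = int(round(1.0 / resolution))
    points = []
    for cuts in itertools.combinations(range(units + k - 1), k - 1):
        prev = -1
        comp = []
        for c in cuts:
            comp.append(c - prev - 1)
            prev = c
        comp.append(units + k - 2 - prev)
        points.append(comp)
    return np.asarray(points, dtype=np.float64) * resolution


def _weight_grid(k: int, grid: ReachabilityGrid) -> np.ndarray:
    """Grid over the scheme's weight domain (simplex or signed L1 sphere)."""
    simplex = _simplex_grid(k, grid.resolution)
    if grid.scheme == "CC":
        if simplex.shape[0] > _GUARD:
            raise ResourceWarning("grid guard exceeded")
        return simplex
    # signed L1 sphere: every sign pattern applied to the simplex grid
    signs = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
    if simplex.shape[0] * signs.shape[0] > _GUARD:
        raise ResourceWarning("grid guard exceeded")
    points = (simplex[:, None, :] * signs[None, :, :]).reshape(-1, k)
    return points


def reachable(target: np.ndarray, G: FeatureGroupMatrix,
              grid: ReachabilityGrid) -> tuple[bool, float]:
    """Whether some on-grid combination lies within tolerance of `target`.

    Returns (is_reachable, best achieved L∞ distance).  CRAC clamps the
    combination to [0, 1] before measuring the distance.
    """
    if G.k > 5:
        raise ResourceWarning("reachable() is an exhaustive oracle; k must be <= 5")
    target = np.asarray(target, dtype=np.float64)
    W = _weight_grid(G.k, grid)
    combos = W @ G.values
    if grid.scheme == "CRAC":
        combos = np.clip(combos, 0.0, 1.0)
    dists = np.abs(combos - target).max(axis=1)
    best = float(dists.min())
    return best <= grid.tolerance, best


def min_group_count(target_masks, candidate_groups: FeatureGroupMatrix,
                    scheme: str = "RAC",
                    grid: ReachabilityGrid | None = None) -> int | None:
    """Smallest candidate subset whose combinations cover all targets.

    Subsets of the candidate pool are searched exhaustively in ascending
    size.  Reachability is tested on the *mask map* of the scheme, which is
    always clamped (``m = U(s @ G)``): for CC the clamp is a no-op on
    groups in [0, 1], for RAC it yields the clamped restricted affine
    composition.  Returns None when no subset covers the targets.
    """
    if candidate_groups.k > 6:
        raise ResourceWarning("candidate pool limited to 6 for exhaustive search")
    if grid is None:
        grid = ReachabilityGrid(scheme="CC")
    raw_scheme = "CC" if scheme == "CC" else "CRAC"
    targets = [np.asarray(t, dtype=np.float64) for t in target_masks]
    pool = candidate_groups.values
    for size in range(1, candidate_groups.k + 1):
        sub_grid = ReachabilityGrid(scheme=raw_scheme,
                                    resolution=grid.resolution,
                                    tolerance=grid.tolerance)
        for subset in itertools.combinations(range(candidate_groups.k), size):
            sub = FeatureGroupMatrix(pool[list(subset)])
            if all(reachable(t, sub, sub_grid)[0] for t in targets):
                return size
    return None


def fig_construction() -> tuple[list[np.ndarray], FeatureGroupMatrix]:
    """Worked target family: 4 groups under CC, 3 under (clamped) RAC.

    Three binary base groups over d = 6 — the first two overlapping on two
    features (overlap is what makes the clamp add expressiveness) — plus a
    fourth group equal to the clamped half-difference of the overlapping
    pair.  Targets are the four groups and the midpoints of the base pairs.
    Convex combinations need all four candidates (the half-difference has
    support where no convex mixture of the bases can vanish); the clamped
    restricted affine composition builds it from the three bases with
    weights (1/2, -1/2, 0).
    """
    g1 = np.array([1, 1, 1, 1, 0, 0], dtype=np.float64)
    g2 = np.array([0, 0, 1, 1, 1, 1], dtype=np.float64)
    g3 = np.array([0, 0, 0, 0, 1, 1], dtype=np.float64)
    g4 = np.clip(0.5 * (g1 - g2), 0.0, 1.0)  # [0.5, 0.5, 0, 0, 0, 0]
    targets = [g1, g2, g3, g4,
               0.5 * (g1 + g2), 0.5 * (g1 + g3), 0.5 * (g2 + g3)]
    return targets, FeatureGroupMatrix(np.stack([g1, g2, g3, g4]))


def lipschitz_estimate(num_trials: int, k=(2, 3, 4), d=(3, 5),
                       rng: np.random.Generator | None = None) -> float:
    """Max observed ||s @ (G - G')||2 / ||G - G'||F over random trials.

    Weights are uniform on the L1 unit sphere (Dirichlet magnitudes with
    random signs); group matrices have i.i.d. uniform [0, 1] entries.
    Zero-distance pairs are skipped.  The combination is 1-Lipschitz in the
    group stack, so the estimate must never exceed 1.
    """
    if num_trials < 1:
        raise ValueError("num_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    ks = (k,) if np.isscalar(k) else tuple(k)
    ds = (d,) if np.isscalar(d) else tuple(d)
    worst = 0.0
    combos = list(itertools.product(ks, ds))
    # spread trials evenly over the (k, d) shapes, vectorized per shape
    per = [num_trials // len(combos)] * len(combos)
    per[-1] += num_trials - sum(per)
    for (kk, dd), m in zip(combos, per):
        if m == 0:
            continue
        mags = rng.dirichlet(np.ones(kk), size=m)
        signs = rng.integers(0, 2, size=(m, kk)) * 2.0 - 1.0
        S = mags * signs
        dG = rng.uniform(0, 1, size=(m, kk, dd)) - rng.uniform(0, 1, size=(m, kk, dd))
        num = np.linalg.norm(np.einsum("mk,mkd->md", S, dG), axis=1)
        den = np.linalg.norm(dG.reshape(m, -1), axis=1)
        ok = den > 0
        if ok.any():
            worst = max(worst, float((num[ok] / den[ok]).max()))
    return worst


@dataclass
class StabilityProbeResult:
    """Leave-one-out probe of the uniform-stability inequality."""

    gamma_hat: float                 # max matched group-row shift (L2)
    beta_hat: float                  # max mask shift at fixed selection weights
    beta_end_to_end: float           # mask shift with each run's own selector
    matching_cost: float             # mean (1 - cosine) of the row matching
    holds: bool                      # beta_hat <= gamma_hat * (1 + 1e-6)
    per_replicate: list[dict] = field(default_factory=list)


def _match_rows(G_ref: np.ndarray, G_alt: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy maximum-cosine assignment of alt rows to reference rows."""
    k = G_ref.shape[0]
    norms_r = np.linalg.norm(G_ref, axis=1)
    norms_a = np.linalg.norm(G_alt, axis=1)
    cos = (G_ref @ G_alt.T) / np.outer(np.maximum(norms_r, 1e-12),
                                       np.maximum(norms_a, 1e-12))
    perm = np.full(k, -1)
    used = set()
    # take assignments in descending cosine order
    order = np.dstack(np.unravel_index(np.argsort(-cos, axis=None), cos.shape))[0]
    for i, j in order:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    cost = float(np.mean([1.0 - cos[i, perm[i]] for i in range(k)]))
    return perm, cost


def uniform_stability_probe(trainer, cohort, num_leave_one_out: int = 5,
                            rng: np.random.Generator | None = None,
                            probe_inputs: np.ndarray | None = None
                            ) -> StabilityProbeResult:
    """Empirically probe mask stability under single-instance removal.

    `trainer(X, Y)` must deterministically return a fitted model exposing a
    group matrix and selection weights.  For each replicate one training
    instance is removed, the model retrained, group rows matched to the
    reference model's by greedy maximum cosine, and two quantities
    measured: gamma-hat (largest matched row shift) and beta-hat (largest
    mask shift over the probe inputs, computed with the *reference* model's
    selection weights applied to both group matrices — the stability
    theorem bounds the mask shift induced by the group shift at fixed
    combination weights).  The end-to-end shift with each model's own
    selector is reported alongside, as is the matching cost, so any
    violation is attributable.
    """
    X, Y = cohort
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if rng is None:
        rng = np.random.default_rng()
    if probe_inputs is None:
        probe_inputs = X
    ref = trainer(X, Y)
    G_ref = ref.grouping.group_matrix().data
    from .autodiff import Tensor

    s_ref = ref.grouping.weights(Tensor(probe_inputs))
    if s_ref is None:
        raise ValueError("the probed model must have a selection network")
    s_ref = s_ref.data
    gamma_hat = beta_hat = beta_full = 0.0
    costs, records = [], []
    removable = rng.choice(X.shape[0], size=num_leave_one_out, replace=False)
    for r, drop in enumerate(removable):
        keep = np.setdiff1d(np.arange(X.shape[0]), [drop])
        alt = trainer(X[keep], np.asarray(Y)[keep])
        G_alt = alt.grouping.group_matrix().data
        perm, cost = _match_rows(G_ref, G_alt)
        G_alt_m = G_alt[perm]
        gamma_r = float(np.linalg.norm(G_ref - G_alt_m, axis=1).max())
        m_ref = np.clip(s_ref @ G_ref, 0.0, 1.0)
        m_alt = np.clip(s_ref @ G_alt_m, 0.0, 1.0)
        beta_r = float(np.linalg.norm(m_ref - m_alt, axis=1).max())
        m_own = alt.masks(probe_inputs)
        beta_f = float(np.linalg.norm(ref.masks(probe_inputs) - m_own, axis=1).max())
        gamma_hat = max(gamma_hat, gamma_r)
        beta_hat = max(beta_hat, beta_r)
        beta_full = max(beta_full, beta_f)
        costs.append(cost)
        records.append({"replicate": r, "dropped": int(drop), "gamma": gamma_r,
                        "beta": beta_r, "beta_end_to_end": beta_f,
                        "matching_cost": cost})
    return StabilityProbeResult(
        gamma_hat=gamma_hat,
        beta_hat=beta_hat,
        beta_end_to_end=beta_full,
        matching_cost=float(np.mean(costs)) if costs else 0.0,
        holds=beta_hat <= gamma_hat * (1.0 + 1e-6) + 1e-12,
        per_replicate=records,
    )
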