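"""Synthetic multi-visit EHR-like cohorts with planted grouping structure.

Emulates, at desk scale, the statistical structure the method assumes in
real claims data: a small set of sparse soft feature groups (phenotypes),
per-patient selection weights over them — including occasional *negative*
weights so the planted masks contain de-selection structure — binary
per-visit feature vectors drawn from the planted mask, multi-hot next-visit
diagnosis-group labels, a terminal mortality flag, and controllable
missingness and additive Gaussian input noise.

The generator is deliberately simple where realism is irrelevant to the
method (no comorbidity correlations beyond the planted groups, no coding
drift over visits); the planted truth (``G*``, ``s*``, ``m*``) is stored so
mask recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .grouping import clamp_unit

__all__ = [
    "SyntheticCohort",
    "generate_cohort",
    "inject_missingness",
    "inject_noise",
    "icd9_to_group",
    "save_cohort",
    "load_cohort",
]


@dataclass
class SyntheticCohort:
    """Cohort with planted ground truth.

    `visits[i]` is the (L_i x d) binary visit matrix of patient i;
    `next_labels[i]` is (L_i - 1 x c): the target of visit t is the label
    group multi-hot of admission t+1.  `mortality[i]` is the terminal
    binary outcome.  Truth: planted groups `G_star` (k x d), per-patient
    weights `s_star` (n x k) on the RAC domain, and masks
    `m_star = clamp01(s_star @ G_star)` (n x d).
    """

    visits: list[np.ndarray]
    next_labels: list[np.ndarray]
    mortality: np.ndarray
    G_star: np.ndarray
    s_star: np.ndarray
    m_star: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.visits)

    @property
    def d(self) -> int:
        return self.visits[0].shape[1]

    @property
    def n_label_groups(self) -> int:
        return self.next_labels[0].shape[1] if self.next_labels else 0

    def average_visits(self) -> float:
        return float(np.mean([v.shape[0] for v in self.visits]))

    def flatten(self):
        """Per-visit instances with next-visit labels.

        Returns (X, Y, patient_of_row): one row per visit that *has* a
        following admission; the last visit of each patient (and patients
        with a single visit) carries no next-admission target and is
        excluded.
        """
        rows, labels, owners = [], [], []
        for i, (v, y) in enumerate(zip(self.visits, self.next_labels)):
            for t in range(v.shape[0] - 1):
                rows.append(v[t])
                labels.append(y[t])
                owners.append(i)
        return (np.asarray(rows, dtype=np.float64),
                np.asarray(labels, dtype=np.float64),
                np.asarray(owners))

    def flatten_all(self):
        """All visits stacked, with the owning patient index per row."""
        owners = np.concatenate([
            np.full(v.shape[0], i) for i, v in enumerate(self.visits)
        ])
        return np.vstack(self.visits).astype(np.float64), owners


def _standardized_logistic(Z: np.ndarray, gain: float, offset: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Bernoulli draws from a logistic map of column-standardized scores."""
    mu = Z.mean(axis=0, keepdims=True)
    sd = Z.std(axis=0, keepdims=True)
    zs = (Z - mu) / np.where(sd > 1e-12, sd, 1.0)
    p = 1.0 / (1.0 + np.exp(-(gain * zs + offset)))
    return (rng.uniform(size=p.shape) < p).astype(np.float64)


def generate_cohort(
    n: int = 500,
    d: int = 100,
    k_true: int = 8,
    avg_visits: float = 2.7,
    n_label_groups: int = 20,
    frac_negative_weight: float = 0.3,
    seed: int = 0,
    group_zero_prob: float = 0.88,
    background_rate: float = 0.02,
) -> SyntheticCohort:
    """Draw a cohort with planted soft groups and RAC-structured weights.

    Each group row is 0 with probability `group_zero_prob`, otherwise
    Uniform(0.5, 1).  Each patient activates a primary group with weight
    ~U(0.55, 0.75) and a secondary group carrying the remaining weight;
    with probability `frac_negative_weight` the secondary weight is
    negative (a de-selecting group), so |weights| always sum to 1.  Visit
    counts follow 1 + Poisson(avg_visits - 1); each visit's features are
    Bernoulli(m*) plus independent background activations.  Next-visit
    labels come from a fixed random linear-logistic map of the next visit's
    planted-mask-filtered features; mortality from a logistic map of the
    last visit's.
    """
    if min(n, d, k_true, n_label_groups) < 1 or avg_visits < 1:
        raise ValueError("all counts must be positive and avg_visits >= 1")
    if not 0.0 <= frac_negative_weight <= 1.0:
        raise ValueError("frac_negative_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # planted soft groups; every group must contain at least one feature
    G = np.where(rng.uniform(size=(k_true, d)) < group_zero_prob, 0.0,
                 rng.uniform(0.5, 1.0, size=(k_true, d)))
    for j in range(k_true):
        if not G[j].any():
            G[j, rng.integers(d)] = rng.uniform(0.5, 1.0)
    expected_active = (1 - group_zero_prob) * d
    if expected_active < 0.5:
        raise ValueError(
            f"infeasible sparsity: expected {expected_active:.2f} active "
            f"features per group at group_zero_prob={group_zero_prob}"
        )

    # per-patient RAC weights: primary positive, secondary +/-
    s = np.zeros((n, k_true))
    primary = rng.integers(0, k_true, size=n)
    secondary = (primary + 1 + rng.integers(0, k_true - 1, size=n)) % k_true
    a = rng.uniform(0.55, 0.75, size=n)
    negative = rng.uniform(size=n) < frac_negative_weight
    s[np.arange(n), primary] = a
    s[np.arange(n), secondary] = np.where(negative, -(1 - a), 1 - a)
    m_star = np.clip(s @ G, 0.0, 1.0)

    # visits
    lengths = 1 + rng.poisson(max(avg_visits - 1.0, 0.0), size=n)
    visits = []
    for i in range(n):
        probs = np.broadcast_to(m_star[i], (lengths[i], d))
        x = (rng.uniform(size=(lengths[i], d)) < probs).astype(np.float64)
        noise = (rng.uniform(size=x.shape) < background_rate)
        visits.append(np.maximum(x, noise.astype(np.float64)))

    # fixed random label maps
    W_lab = rng.normal(size=(d, n_label_groups))
    w_mort = rng.normal(size=d)
    all_masked = np.vstack([m_star[i] * visits[i] for i in range(n)])
    Z_all = all_masked @ W_lab
    mu, sd = Z_all.mean(axis=0), Z_all.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)

    next_labels = []
    for i in range(n):
        masked = m_star[i] * visits[i]
        z = ((masked @ W_lab) - mu) / sd
        p = 1.0 / (1.0 + np.exp(-(1.5 * z - 1.75)))
        draws = (rng.uniform(size=p.shape) < p).astype(np.float64)
        next_labels.append(draws[1:])  # label of visit t = groups of visit t+1

    last_masked = np.vstack([m_star[i] * visits[i][-1] for i in range(n)])
    zm = last_masked @ w_mort
    zm = (zm - zm.mean()) / max(zm.std(), 1e-12)
    p_mort = 1.0 / (1.0 + np.exp(-(1.5 * zm - 0.8)))
    mortality = (rng.uniform(size=n) < p_mort).astype(np.float64)

    params = dict(n=n, d=d, k_true=k_true, avg_visits=avg_visits,
                  n_label_groups=n_label_groups,
                  frac_negative_weight=frac_negative_weight, seed=seed,
                  group_zero_prob=group_zero_prob,
                  background_rate=background_rate)
    return SyntheticCohort(visits=visits, next_labels=next_labels,
                           mortality=mortality, G_star=G, s_star=s,
                           m_star=m_star, params=params)


def inject_missingness(X: np.ndarray, rate: float, seed: int = 0) -> np.ndarray:
    """Zero each nonzero entry independently with probability `rate`."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    X = np.array(X, dtype=np.float64, copy=True)
    if rate == 0.0:
        return X
    rng = np.random.default_rng(seed)
    nz = X != 0
    drop = nz & (rng.uniform(size=X.shape) < rate)
    X[drop] = 0.0
    return X


def inject_noise(X: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. Normal(0, level) noise to every entry (level = std)."""
    if level < 0:
        raise ValueError("noise level must be non-negative")
    X = np.array(X, dtype=np.float64, copy=True)
    if level == 0.0:
        return X
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, level, size=X.shape)


def icd9_to_group(code: str) -> str:
    """First-three-character ICD-9 grouping key (V/E prefixes kept)."""
    if not code:
        raise ValueError("empty ICD-9 code")
    return str(code)[:3]


# ----------------------------------------------------------------------
# text-format round trip (matrix market + delimited tables + manifest)
# ----------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, directory: str | Path):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X, owners = cohort.flatten_all()
    mmwrite(directory / "visits.mtx", sparse.csr_matrix(X))
    pd.DataFrame({"patient": owners}).to_csv(directory / "visit_owner.csv",
                                             index=False)
    lab_rows = []
    for i, y in enumerate(cohort.next_labels):
        for t in range(y.shape[0]):
            for g in np.flatnonzero(y[t]):
                lab_rows.append((i, t, int(g)))
    pd.DataFrame(lab_rows, columns=["patient", "visit", "label_group"]).to_csv(
        directory / "next_labels.csv", index=False)
    pd.DataFrame({"mortality": cohort.mortality.astype(int)}).to_csv(
        directory / "mortality.csv", index=False)
    np.savetxt(directory / "G_star.csv", cohort.G_star, delimiter=",")
    np.savetxt(directory / "s_star.csv", cohort.s_star, delimiter=",")
    np.savetxt(directory / "m_star.csv", cohort.m_star, delimiter=",")
    (directory / "manifest.json").write_text(
        json.dumps(cohort.params, indent=2, sort_keys=True))


def load_cohort(directory: str | Path) -> SyntheticCohort:
    directory = Path(directory)
    params = json.loads((directory / "manifest.json").read_text())
    X = np.asarray(mmread(directory / "visits.mtx").todense(), dtype=np.float64)
    owners = pd.read_csv(directory / "visit_owner.csv")["patient"].to_numpy()
    G = np.loadtxt(directory / "G_star.csv", delimiter=",", ndmin=2)
    s = np.loadtxt(directory / "s_star.csv", delimiter=",", ndmin=2)
    m = np.loadtxt(directory / "m_star.csv", delimiter=",", ndmin=2)
    mortality = pd.read_csv(directory / "mortality.csv")["mortality"].to_numpy(
        dtype=np.float64)
    labels = pd.read_csv(directory / "next_labels.csv")
    n = int(owners.max()) + 1
    c = params["n_label_groups"]
    visits, next_labels = [], []
    for i in range(n):
        v = X[owners == i]
        visits.append(v)
        y = np.zeros((max(v.shape[0] - 1, 0), c))
        sub = labels[labels["patient"] == i]
        for _, row in sub.iterrows():
            y[int(row["visit"]), int(row["label_group"])] = 1.0
        next_labels.append(y)
    return SyntheticCohort(visits=visits, next_labels=next_labels,
                           mortality=mortality, G_star=G, s_star=s, m_star=m,
                           params=params)
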