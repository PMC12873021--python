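"""End-to-end prediction models built around the feature-grouping module.

Two model families are provided:

* :class:`FlexGPCMLP` — standard classification: the instance is masked by
  the grouping module and fed to a one-hidden-layer predictor.
* :class:`FlexGPCTransMLP` — sequence-to-sequence classification for
  multi-visit records: each visit is masked independently by the *shared*
  grouping module, the masked sequence is encoded by a single-block,
  single-head Transformer with causal (past-only) attention, and a
  per-position head predicts the next admission's label group vector.

Scheme variants: ``CC`` and ``RAC`` are the two selection networks;
``AVG`` replaces selection by the plain group average (input-independent
mask); ``MLPMASK`` drops grouping entirely and gates features with the
sigmoid of one linear layer.

Training runs in two phases: mask pre-training (squared distance between
masks and inputs, updating the selector and the group matrix) followed by
end-to-end minimization of the composite objective with Adam.  The group
matrix is stored as unconstrained parameters passed through a sigmoid so
its entries stay in [0, 1] by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, clamp01, relu, sigmoid, softmax
from .config import TrainingConfig
from .grouping import FeatureGroupMatrix, FeatureMask, SelectionWeights
from .objectives import prediction_loss

__all__ = [
    "FlexGPCMLP",
    "FlexGPCTransMLP",
    "train",
    "train_sequences",
    "flexgpc_mlp_forward",
    "flexgpc_trans_forward",
    "variant_mask",
    "extract_groups",
    "save_checkpoint",
    "load_checkpoint",
    "checkpoint_hash",
]

_L1_FLOOR = 1e-12


def _uniform(rng, fan_in, shape):
    b = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-b, b, size=shape), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def _softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) = relu(x) + log(1 + e^-|x|), stable for large |x|
    return relu(x) + (1.0 + (-x.abs()).exp()).log()


def _bce_with_logits(logits: Tensor, Y: np.ndarray) -> Tensor:
    """Mean-over-instances summed binary cross-entropy, on logits."""
    Yt = Tensor(Y)
    n = logits.shape[0]
    per = _softplus(logits) - logits * Yt
    return per.sum() * (1.0 / n)


def _recons_loss(X: np.ndarray, R: Tensor) -> Tensor:
    diff = R - Tensor(X)
    sq = (diff * diff).sum(axis=1)
    return ((sq + 1e-12) ** 0.5).sum()


def _group_entropy_t(G: Tensor) -> Tensor:
    k, d = G.shape
    return (-(G * G.log())).sum() * (1.0 / d + 1.0 / k)


# ----------------------------------------------------------------------
# grouping module shared by both model families
# ----------------------------------------------------------------------

class _GroupingModule:
    """Selector + group matrix producing masks for a batch of instances."""

    def __init__(self, d: int, config: TrainingConfig, rng: np.random.Generator):
        self.d = d
        self.config = config
        self.scheme = config.scheme
        k, l = config.k, config.l
        self.params: dict[str, Tensor] = {}
        if self.scheme in ("CC", "RAC"):
            self.params["sel_W1"] = _uniform(rng, d, (l, d))
            self.params["sel_W2"] = _uniform(rng, l, (k, l))
            if self.scheme == "RAC":
                # start on the convex face of the RAC domain: a sign-mixed
                # init lets the fastest pre-training descent direction flip
                # all weights negative, zeroing every mask for sparse inputs
                # (a degenerate saddle the optimizer cannot leave)
                self.params["sel_W2"].data = np.abs(self.params["sel_W2"].data)
        if self.scheme in ("CC", "RAC", "AVG"):
            # raw parameters; sigmoid keeps G in (0, 1); groups start sparse
            # (entries ~0.05) so inactive features are fitted from the outset
            # and gradients come from active features growing their groups
            self.params["G_raw"] = Tensor(
                rng.uniform(-0.5, 0.5, size=(k, d)) - 3.0, requires_grad=True
            )
        if self.scheme == "MLPMASK":
            self.params["mask_W"] = _uniform(rng, d, (d, d))
            self.params["mask_b"] = _zeros((d,))

    def group_matrix(self) -> Tensor:
        return sigmoid(self.params["G_raw"])

    def weights(self, X: Tensor) -> Tensor | None:
        """Selection weights for a batch, or None for AVG/MLPMASK."""
        if self.scheme == "CC":
            z = relu(X @ self.params["sel_W1"].T) @ self.params["sel_W2"].T
            return softmax(z, axis=-1)
        if self.scheme == "RAC":
            z = relu(X @ self.params["sel_W1"].T) @ self.params["sel_W2"].T
            denom = z.abs().sum(axis=-1, keepdims=True) + _L1_FLOOR
            return z / denom
        return None

    def mask(self, X: Tensor, training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        if self.scheme == "MLPMASK":
            return sigmoid(X @ self.params["mask_W"].T + self.params["mask_b"])
        G = self.group_matrix()
        if self.scheme == "AVG":
            w = G.sum(axis=0) * (1.0 / cfg.k)
            n = X.shape[0]
            w = Tensor(np.ones((n, 1))) @ w.reshape(1, self.d)
        else:
            s = self.weights(X)
            w = s @ G
        if training and cfg.sigma > 0:
            if rng is None:
                raise ValueError("training-time noise requires an rng")
            if cfg.per_element_noise:
                eps = rng.normal(0.0, cfg.sigma, size=(X.shape[0], self.d))
            else:
                eps = np.broadcast_to(
                    rng.normal(0.0, cfg.sigma, size=(X.shape[0], 1)),
                    (X.shape[0], self.d),
                )
            w = w + Tensor(eps)
        return clamp01(w)


class _MLP2:
    """Two-layer perceptron with biases (hidden ReLU, linear output)."""

    def __init__(self, d_in, d_hidden, d_out, rng, prefix):
        self.prefix = prefix
        self.params = {
            f"{prefix}_W1": _uniform(rng, d_in, (d_hidden, d_in)),
            f"{prefix}_b1": _zeros((d_hidden,)),
            f"{prefix}_W2": _uniform(rng, d_hidden, (d_out, d_hidden)),
            f"{prefix}_b2": _zeros((d_out,)),
        }

    def __call__(self, X: Tensor) -> Tensor:
        p = self.params
        h = relu(X @ p[f"{self.prefix}_W1"].T + p[f"{self.prefix}_b1"])
        return h @ p[f"{self.prefix}_W2"].T + p[f"{self.prefix}_b2"]


# ----------------------------------------------------------------------
# standard classification model
# ----------------------------------------------------------------------

class FlexGPCMLP:
    """Masked-input classifier: grouping module -> one-hidden-layer MLP."""

    kind = "mlp"

    def __init__(self, d: int, c: int, config: TrainingConfig,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.d, self.c = d, c
        self.config = config
        self.grouping = _GroupingModule(d, config, rng)
        self.predictor = _MLP2(d, config.predictor_hidden, c, rng, "pred")
        self.reconstructor = _MLP2(d, config.l, d, rng, "rec")
        self.params: dict[str, Tensor] = {}
        self.params.update(self.grouping.params)
        self.params.update(self.predictor.params)
        self.params.update(self.reconstructor.params)

    # -- forward -------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (probability Tensor, mask Tensor, weight Tensor or None)."""
        Xt = Tensor(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        m = self.grouping.mask(Xt, training=training, rng=rng)
        s = self.grouping.weights(Xt)
        Xm = Xt * m
        logits = self.predictor(Xm)
        return sigmoid(logits), m, s, logits, Xm

    # -- numpy conveniences (evaluation mode, eps = 0) ------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0].data

    def masks(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1].data

    def selection_weights(self, X: np.ndarray) -> np.ndarray | None:
        s = self.forward(X)[2]
        return None if s is None else s.data

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def mask_parameters(self) -> list[Tensor]:
        return list(self.grouping.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]):
        for name, arr in state.items():
            self.params[name].data = np.array(arr, dtype=np.float64)


def flexgpc_mlp_forward(x: np.ndarray, model: FlexGPCMLP):
    """Single-instance forward pass returning typed artifacts.

    Returns (probabilities, FeatureMask, SelectionWeights or None) for
    interpretability alongside prediction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("x must be a single length-d instance")
    probs, m, s, _, _ = model.forward(x)
    mask = FeatureMask(m.data[0])
    weights = None
    if s is not None:
        weights = SelectionWeights(s.data[0], scheme=model.config.scheme)
    return probs.data[0], mask, weights


def variant_mask(x: np.ndarray, model) -> FeatureMask:
    """Evaluation-mode mask of an ablation variant (AVG or MLPMASK)."""
    if model.config.scheme not in ("AVG", "MLPMASK"):
        raise ValueError("variant_mask is defined for AVG and MLPMASK models")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    m = model.grouping.mask(Tensor(x))
    return FeatureMask(m.data[0])


# ----------------------------------------------------------------------
# sequence model
# ----------------------------------------------------------------------

class FlexGPCTransMLP:
    """Per-visit masking + causal single-head Transformer + per-visit head."""

    kind = "trans"

    def __init__(self, d: int, c: int, config: TrainingConfig,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.d, self.c = d, c
        self.config = config
        dim = config.transformer_dim
        self.grouping = _GroupingModule(d, config, rng)
        self.reconstructor = _MLP2(d, config.l, d, rng, "rec")
        self.params: dict[str, Tensor] = {}
        self.params.update(self.grouping.params)
        self.params.update(self.reconstructor.params)
        tp = {
            "emb_W": _uniform(rng, d, (dim, d)),
            "pos": Tensor(rng.normal(0.0, 0.02, size=(config.max_seq_len, dim)),
                          requires_grad=True),
            "att_Wq": _uniform(rng, dim, (dim, dim)),
            "att_Wk": _uniform(rng, dim, (dim, dim)),
            "att_Wv": _uniform(rng, dim, (dim, dim)),
            "att_Wo": _uniform(rng, dim, (dim, dim)),
            "ln1_g": Tensor(np.ones(dim), requires_grad=True),
            "ln1_b": _zeros((dim,)),
            "ffn_W1": _uniform(rng, dim, (dim, dim)),
            "ffn_b1": _zeros((dim,)),
            "ffn_W2": _uniform(rng, dim, (dim, dim)),
            "ffn_b2": _zeros((dim,)),
            "ln2_g": Tensor(np.ones(dim), requires_grad=True),
            "ln2_b": _zeros((dim,)),
        }
        self.params.update(tp)
        self.predictor = _MLP2(dim, config.predictor_hidden, c, rng, "pred")
        self.params.update(self.predictor.params)

    @staticmethod
    def _layernorm(h: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = h.mean(axis=-1, keepdims=True)
        xc = h - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + 1e-5) ** 0.5) * g + b

    def _encode(self, Xm: Tensor) -> Tensor:
        """Causal single-head self-attention block over masked visits (L x d)."""
        p = self.params
        L = Xm.shape[0]
        if L > self.config.max_seq_len:
            raise ValueError(f"sequence length {L} exceeds max {self.config.max_seq_len}")
        dim = self.config.transformer_dim
        H = Xm @ p["emb_W"].T + p["pos"][:L]
        Q, K, V = H @ p["att_Wq"].T, H @ p["att_Wk"].T, H @ p["att_Wv"].T
        scores = (Q @ K.T) * (1.0 / np.sqrt(dim))
        causal = np.triu(np.full((L, L), -1e9), k=1)  # position t attends to <= t
        A = softmax(scores + Tensor(causal), axis=-1)
        H = self._layernorm(H + (A @ V) @ p["att_Wo"].T, p["ln1_g"], p["ln1_b"])
        F = relu(H @ p["ffn_W1"].T + p["ffn_b1"]) @ p["ffn_W2"].T + p["ffn_b2"]
        return self._layernorm(H + F, p["ln2_g"], p["ln2_b"])

    def forward(self, visits: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Forward one sequence (L x d); returns (probs, masks, weights)."""
        visits = np.atleast_2d(np.asarray(visits, dtype=np.float64))
        if visits.shape[0] < 1:
            raise ValueError("sequence must contain at least one visit")
        Xt = Tensor(visits)
        m = self.grouping.mask(Xt, training=training, rng=rng)
        s = self.grouping.weights(Xt)
        Xm = Xt * m
        H = self._encode(Xm)
        logits = self.predictor(H)
        return sigmoid(logits), m, s, logits, Xm

    def predict(self, visits: np.ndarray) -> np.ndarray:
        return self.forward(visits)[0].data

    def masks(self, visits: np.ndarray) -> np.ndarray:
        return self.forward(visits)[1].data

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def mask_parameters(self) -> list[Tensor]:
        return list(self.grouping.params.values())

    state_dict = FlexGPCMLP.state_dict
    load_state = FlexGPCMLP.load_state


def flexgpc_trans_forward(seq, model: FlexGPCTransMLP):
    """Per-visit predictions and masks for one visit sequence."""
    probs, m, s, _, _ = model.forward(np.asarray(seq, dtype=np.float64))
    return probs.data, m.data, (None if s is None else s.data)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class TrainResult:
    model: object
    history: list[dict]
    best_epoch: int
    split_indices: dict[str, np.ndarray] = field(default_factory=dict)


def _split_indices(n: int, split, rng) -> dict[str, np.ndarray]:
    idx = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    if n_train == 0 or n - n_train - n_val == 0:
        raise ValueError("empty split; dataset too small for the fractions")
    return {
        "train": idx[:n_train],
        "val": idx[n_train:n_train + n_val],
        "test": idx[n_train + n_val:],
    }


def _batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def train(model: FlexGPCMLP, X: np.ndarray, Y: np.ndarray,
          config: TrainingConfig | None = None,
          rng: np.random.Generator | None = None) -> TrainResult:
    """Two-phase training of a standard-classification model.

    Phase 1 pre-trains the mask (selector + group matrix) toward the
    inputs; phase 2 minimizes the composite objective end-to-end with Adam
    and keeps the parameters of the epoch with the best validation
    prediction loss (early stopping with the configured patience).
    """
    if config is None:
        config = model.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y disagree on the number of instances")
    splits = _split_indices(X.shape[0], config.split, rng)
    Xtr, Ytr = X[splits["train"]], Y[splits["train"]]
    Xva, Yva = X[splits["val"]], Y[splits["val"]]
    history: list[dict] = []

    # -- phase 1: mask pre-training ------------------------------------
    opt = Adam(model.mask_parameters(), lr=config.learning_rate)
    for epoch in range(config.pretrain_epochs):
        total = 0.0
        for batch in _batches(Xtr.shape[0], config.batch_size, rng):
            xb = Xtr[batch]
            opt.zero_grad()
            # noise-free: the pre-training anchor (masks ~ inputs) is a
            # fit, not an exploration phase; injected noise biases the
            # squared loss toward all-zero masks on sparse records
            m = model.grouping.mask(Tensor(xb))
            loss = ((m - Tensor(xb)) ** 2).sum()
            loss.backward()
            opt.step()
            total += float(loss.data)
        eval_mask = model.masks(Xtr) if model.kind == "mlp" else None
        record = {
            "phase": "pretrain",
            "epoch": epoch,
            "pretrain_loss": total,
        }
        if eval_mask is not None:
            record["pretrain_mae"] = float(np.abs(eval_mask - Xtr).mean())
        history.append(record)

    # -- phase 2: end-to-end -------------------------------------------
    weights = config.loss_weights
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    stale = 0
    for epoch in range(config.main_epochs):
        terms = {"pred": 0.0, "recons": 0.0, "mask": 0.0, "group": 0.0}
        for batch in _batches(Xtr.shape[0], config.batch_size, rng):
            xb, yb = Xtr[batch], Ytr[batch]
            opt.zero_grad()
            probs, m, s, logits, Xm = model.forward(xb, training=True, rng=rng)
            l_pred = _bce_with_logits(logits, yb)
            l_rec = _recons_loss(xb, model.reconstructor(Xm))
            l_mask = m.sum()
            loss = (l_pred + weights.lambda_recons * l_rec
                    + weights.lambda_mask * l_mask)
            if "G_raw" in model.grouping.params:
                l_grp = _group_entropy_t(model.grouping.group_matrix())
                loss = loss + weights.lambda_group * l_grp
                terms["group"] += float(l_grp.data)
            loss.backward()
            opt.step()
            terms["pred"] += float(l_pred.data)
            terms["recons"] += float(l_rec.data)
            terms["mask"] += float(l_mask.data)
        val_pred = prediction_loss(Yva, model.predict(Xva))
        history.append({
            "phase": "main", "epoch": epoch, "val_pred": val_pred, **terms,
        })
        if val_pred < best_val - 1e-12:
            best_val = val_pred
            best_state = model.state_dict()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       split_indices=splits)


def train_sequences(model: FlexGPCTransMLP, sequences: list,
                    config: TrainingConfig | None = None,
                    rng: np.random.Generator | None = None) -> TrainResult:
    """Two-phase training of the sequence model.

    `sequences` is a list of (visits, next_labels) pairs where `visits` is
    (L x d) and `next_labels` is (L-1 x c): the target of visit t is the
    label-group vector of admission t+1, so the final visit has no
    prediction target and is excluded from the prediction loss (it still
    contributes to the reconstruction and mask terms).
    """
    if config is None:
        config = model.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seqs = [(np.atleast_2d(np.asarray(v, dtype=np.float64)),
             np.atleast_2d(np.asarray(y, dtype=np.float64)))
            for v, y in sequences]
    splits = _split_indices(len(seqs), config.split, rng)
    train_ids, val_ids = splits["train"], splits["val"]
    history: list[dict] = []

    opt = Adam(model.mask_parameters(), lr=config.learning_rate)
    for epoch in range(config.pretrain_epochs):
        total = 0.0
        for batch in _batches(len(train_ids), config.batch_size, rng):
            opt.zero_grad()
            loss = None
            for sid in train_ids[batch]:
                v, _ = seqs[sid]
                m = model.grouping.mask(Tensor(v))  # noise-free, as in train()
                term = ((m - Tensor(v)) ** 2).sum()
                loss = term if loss is None else loss + term
            loss.backward()
            opt.step()
            total += float(loss.data)
        history.append({"phase": "pretrain", "epoch": epoch,
                        "pretrain_loss": total})

    weights = config.loss_weights
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    stale = 0

    def _val_loss() -> float:
        tot, cnt = 0.0, 0
        for sid in val_ids:
            v, y = seqs[sid]
            if y.shape[0] == 0:
                continue
            probs = model.predict(v)[:-1]
            tot += prediction_loss(y, probs) * y.shape[0]
            cnt += y.shape[0]
        return tot / max(cnt, 1)

    for epoch in range(config.main_epochs):
        for batch in _batches(len(train_ids), config.batch_size, rng):
            opt.zero_grad()
            loss = None
            for sid in train_ids[batch]:
                v, y = seqs[sid]
                probs, m, s, logits, Xm = model.forward(v, training=True, rng=rng)
                term = (weights.lambda_recons
                        * _recons_loss(v, model.reconstructor(Xm))
                        + weights.lambda_mask * m.sum())
                if y.shape[0] > 0:
                    term = term + _bce_with_logits(logits[:-1], y)
                loss = term if loss is None else loss + term
            if "G_raw" in model.grouping.params:
                loss = loss + (weights.lambda_group
                               * _group_entropy_t(model.grouping.group_matrix()))
            loss.backward()
            opt.step()
        val_pred = _val_loss()
        history.append({"phase": "main", "epoch": epoch, "val_pred": val_pred})
        if val_pred < best_val - 1e-12:
            best_val, best_state, best_epoch, stale = (
                val_pred, model.state_dict(), epoch, 0)
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       split_indices=splits)


# ----------------------------------------------------------------------
# interpretability and checkpoints
# ----------------------------------------------------------------------

def extract_groups(model, X: np.ndarray | None = None):
    """Learned group matrix and, per instance, selected/de-selected groups.

    Returns (FeatureGroupMatrix, weights array or None, report).  The
    report lists, for each supplied instance, the groups with positive
    weight (selected) and — under RAC only — negative weight (de-selected);
    CC weights are simplex-constrained so de-selection cannot occur.
    """
    if model.config.scheme == "MLPMASK":
        raise ValueError("MLPMASK has no feature groups")
    G = FeatureGroupMatrix(model.grouping.group_matrix().data)
    if X is None:
        return G, None, []
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if model.config.scheme == "AVG":
        return G, None, [{"instance": i, "selected": list(range(G.k)),
                          "deselected": []} for i in range(X.shape[0])]
    S = model.grouping.weights(Tensor(X)).data
    report = []
    for i, s in enumerate(S):
        report.append({
            "instance": i,
            "selected": [int(j) for j in np.flatnonzero(s > 0)],
            "deselected": [int(j) for j in np.flatnonzero(s < 0)],
        })
    return G, S, report


def save_checkpoint(model, path: str | Path):
    """Archive model parameters + config into a single .npz file."""
    meta = json.dumps({
        "kind": model.kind, "d": model.d, "c": model.c,
        "config": model.config.to_dict(),
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path):
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = TrainingConfig.from_dict(meta["config"])
    cls = FlexGPCMLP if meta["kind"] == "mlp" else FlexGPCTransMLP
    model = cls(meta["d"], meta["c"], config)
    model.load_state(state)
    return model


def checkpoint_hash(model) -> str:
    """Deterministic digest of the parameters (name order + raw bytes)."""
    h = hashlib.sha256()
    for name in sorted(model.params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(model.params[name].data).tobytes())
    return h.hexdigest()
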