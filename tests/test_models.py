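"""End-to-end models: forward composition, variants, training contracts."""

import numpy as np
import pytest

from flexgpc.autodiff import Tensor
from flexgpc.config import TrainingConfig
from flexgpc.grouping import clamp_unit
from flexgpc.models import (
    FlexGPCMLP,
    FlexGPCTransMLP,
    checkpoint_hash,
    extract_groups,
    flexgpc_mlp_forward,
    flexgpc_trans_forward,
    load_checkpoint,
    save_checkpoint,
    train,
    train_sequences,
    variant_mask,
)
from flexgpc.selection import SelectorParameters, select_batch

from conftest import tiny_config


def _model(scheme="RAC", d=6, c=2, seed=0, **over):
    cfg = tiny_config(scheme, seed=seed, **over)
    return FlexGPCMLP(d, c, cfg, np.random.default_rng(seed)), cfg


class TestForwardComposition:
    def test_forward_matches_hand_composed_chain(self, rng):
        """The model forward equals mask -> multiply -> predictor by parts."""
        model, cfg = _model("RAC")
        x = rng.uniform(size=(4, 6))
        probs, m, s, logits, Xm = model.forward(x)
        # selection weights via the numpy-level selector on model parameters
        params = SelectorParameters(
            W1=model.params["sel_W1"].data,
            W2=model.params["sel_W2"].data, scheme="RAC")
        s_np = select_batch(x, params)
        assert np.allclose(s.data, s_np, atol=1e-8)
        G = 1 / (1 + np.exp(-model.params["G_raw"].data))
        m_np = clamp_unit(s_np @ G).values
        assert np.allclose(m.data, m_np, atol=1e-8)
        xm = x * m_np
        h = np.maximum(xm @ model.params["pred_W1"].data.T
                       + model.params["pred_b1"].data, 0)
        z = h @ model.params["pred_W2"].data.T + model.params["pred_b2"].data
        assert np.allclose(probs.data, 1 / (1 + np.exp(-z)), atol=1e-8)

    def test_all_ones_mask_reduces_to_plain_predictor(self, rng):
        model, _ = _model("AVG")
        model.params["G_raw"].data[:] = 50.0  # sigmoid -> 1, average -> 1
        x = rng.uniform(size=(3, 6))
        probs = model.predict(x)
        h = np.maximum(x @ model.params["pred_W1"].data.T
                       + model.params["pred_b1"].data, 0)
        z = h @ model.params["pred_W2"].data.T + model.params["pred_b2"].data
        assert np.allclose(probs, 1 / (1 + np.exp(-z)), atol=1e-10)

    def test_all_zeros_mask_makes_prediction_input_independent(self, rng):
        model, _ = _model("AVG")
        model.params["G_raw"].data[:] = -50.0  # sigmoid -> 0
        p1 = model.predict(rng.uniform(size=(1, 6)))
        p2 = model.predict(rng.uniform(size=(1, 6)))
        assert np.allclose(p1, p2)

    def test_single_instance_wrapper_returns_typed_artifacts(self, rng):
        model, _ = _model("RAC")
        probs, mask, weights = flexgpc_mlp_forward(rng.uniform(size=6), model)
        assert probs.shape == (2,)
        assert mask.values.shape == (6,)
        assert weights.scheme == "RAC"
        assert abs(np.abs(weights.values).sum() - 1) < 1e-6

    def test_evaluation_forward_is_deterministic(self, rng):
        model, _ = _model("RAC")
        x = rng.uniform(size=(2, 6))
        assert np.array_equal(model.predict(x), model.predict(x))
        assert np.array_equal(model.masks(x), model.masks(x))


class TestVariants:
    def test_avg_mask_is_input_independent(self, rng):
        model, _ = _model("AVG")
        m1 = variant_mask(rng.uniform(size=6), model)
        m2 = variant_mask(rng.uniform(size=6), model)
        assert np.allclose(m1.values, m2.values)

    def test_avg_with_single_group_is_the_clamped_group(self, rng):
        cfg = tiny_config("AVG", k=1)
        model = FlexGPCMLP(6, 2, cfg, np.random.default_rng(0))
        G = 1 / (1 + np.exp(-model.params["G_raw"].data))
        m = variant_mask(np.zeros(6), model)
        assert np.allclose(m.values, np.clip(G[0], 0, 1))

    def test_mlpmask_outputs_open_unit_interval(self, rng):
        model, _ = _model("MLPMASK")
        m = variant_mask(rng.normal(size=6), model)
        assert np.all((m.values > 0) & (m.values < 1))

    def test_unknown_variant_rejected(self, rng):
        model, _ = _model("RAC")
        with pytest.raises(ValueError):
            variant_mask(np.zeros(6), model)

    def test_cc_masks_are_reachable_by_rac_on_same_groups(self, rng):
        """Scheme nesting: any CC mask is an RAC mask with the same weights."""
        from flexgpc.grouping import (CC, RAC, FeatureGroupMatrix,
                                      SelectionWeights, noisy_mask)
        G = FeatureGroupMatrix(rng.uniform(size=(3, 5)))
        w = rng.dirichlet(np.ones(3))
        m_cc = noisy_mask(SelectionWeights(w, scheme=CC), G)
        m_rac = noisy_mask(SelectionWeights(w, scheme=RAC), G)
        assert np.allclose(m_cc.values, m_rac.values)


class TestTransformer:
    def _tmodel(self, d=6, c=2, seed=0):
        cfg = tiny_config("RAC", seed=seed)
        return FlexGPCTransMLP(d, c, cfg, np.random.default_rng(seed))

    def test_single_visit_sequence_works(self, rng):
        model = self._tmodel()
        probs, masks, s = flexgpc_trans_forward(rng.uniform(size=(1, 6)), model)
        assert probs.shape == (1, 2) and masks.shape == (1, 6)

    def test_identical_patients_get_identical_outputs(self, rng):
        model = self._tmodel()
        seq = rng.uniform(size=(3, 6))
        p1, m1, _ = flexgpc_trans_forward(seq, model)
        p2, m2, _ = flexgpc_trans_forward(seq.copy(), model)
        assert np.array_equal(p1, p2) and np.array_equal(m1, m2)

    def test_causal_attention_ignores_future_visits(self, rng):
        model = self._tmodel()
        seq = rng.uniform(size=(4, 6))
        base, _, _ = flexgpc_trans_forward(seq, model)
        perturbed = seq.copy()
        perturbed[2] = rng.uniform(size=6)  # change visit t = 2
        after, _, _ = flexgpc_trans_forward(perturbed, model)
        assert np.allclose(base[:2], after[:2], atol=1e-12)
        assert not np.allclose(base[2:], after[2:])

    def test_empty_sequence_rejected(self):
        model = self._tmodel()
        with pytest.raises(ValueError):
            model.forward(np.zeros((0, 6)))

    def test_sequence_training_runs_and_is_deterministic(self, rng):
        cfg = tiny_config("RAC", pretrain_epochs=1, main_epochs=2, batch_size=8)
        seqs = []
        for _ in range(20):
            L = int(rng.integers(2, 4))
            seqs.append((rng.uniform(size=(L, 6)),
                         (rng.uniform(size=(L - 1, 2)) < 0.5).astype(float)))
        m1 = FlexGPCTransMLP(6, 2, cfg, np.random.default_rng(1))
        h1 = train_sequences(m1, seqs, cfg, np.random.default_rng(1)).history
        m2 = FlexGPCTransMLP(6, 2, cfg, np.random.default_rng(1))
        h2 = train_sequences(m2, seqs, cfg, np.random.default_rng(1)).history
        assert h1 == h2
        assert checkpoint_hash(m1) == checkpoint_hash(m2)


class TestTraining:
    def test_pretraining_reduces_mask_input_distance(self, blocky_data):
        """Mean |m - X| falls (non-strictly) across 5-epoch windows."""
        X, Y, _ = blocky_data
        cfg = tiny_config("RAC", pretrain_epochs=20, main_epochs=1, batch_size=16)
        model = FlexGPCMLP(X.shape[1], 1, cfg, np.random.default_rng(0))
        res = train(model, X, Y, cfg, np.random.default_rng(0))
        mae = [h["pretrain_mae"] for h in res.history if h["phase"] == "pretrain"]
        windows = [np.mean(mae[i:i + 5]) for i in range(0, 20, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(windows, windows[1:]))

    def test_separable_toy_reaches_perfect_validation_accuracy(self, blocky_data):
        X, Y, _ = blocky_data
        cfg = tiny_config("RAC", pretrain_epochs=5, main_epochs=40, patience=40,
                          lambda_recons=0.0, lambda_mask=0.0, lambda_group=0.0,
                          learning_rate=1e-2)
        model = FlexGPCMLP(X.shape[1], 1, cfg, np.random.default_rng(0))
        res = train(model, X, Y, cfg, np.random.default_rng(0))
        val = res.split_indices["val"]
        acc = ((model.predict(X[val]) > 0.5) == Y[val]).mean()
        assert acc == 1.0

    def test_same_seed_reproduces_history_and_checkpoint(self, blocky_data):
        X, Y, _ = blocky_data
        cfg = tiny_config("RAC", pretrain_epochs=2, main_epochs=3)
        m1 = FlexGPCMLP(X.shape[1], 1, cfg, np.random.default_rng(3))
        h1 = train(m1, X, Y, cfg, np.random.default_rng(3)).history
        m2 = FlexGPCMLP(X.shape[1], 1, cfg, np.random.default_rng(3))
        h2 = train(m2, X, Y, cfg, np.random.default_rng(3)).history
        assert h1 == h2
        assert checkpoint_hash(m1) == checkpoint_hash(m2)

    def test_empty_split_rejected(self):
        cfg = tiny_config("RAC")
        model = FlexGPCMLP(4, 1, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            train(model, np.ones((2, 4)), np.ones((2, 1)), cfg,
                  np.random.default_rng(0))


class TestExtractionAndCheckpoints:
    def test_cc_report_never_contains_deselected_groups(self, rng):
        model, _ = _model("CC")
        X = rng.uniform(size=(10, 6))
        G, S, report = extract_groups(model, X)
        assert all(len(r["deselected"]) == 0 for r in report)
        assert np.all(S >= 0)

    def test_rac_report_splits_by_weight_sign(self, rng):
        model, _ = _model("RAC")
        X = rng.uniform(size=(8, 6))
        G, S, report = extract_groups(model, X)
        for r, s in zip(report, S):
            assert r["selected"] == [int(j) for j in np.flatnonzero(s > 0)]
            assert r["deselected"] == [int(j) for j in np.flatnonzero(s < 0)]

    def test_group_matrix_entries_always_in_unit_interval(self, rng):
        model, _ = _model("RAC")
        G, _, _ = extract_groups(model)
        assert G.values.min() >= 0 and G.values.max() <= 1

    def test_mlpmask_has_no_groups(self, rng):
        model, _ = _model("MLPMASK")
        with pytest.raises(ValueError):
            extract_groups(model)

    def test_checkpoint_round_trip_preserves_predictions(self, rng, tmp_path):
        model, _ = _model("RAC")
        x = rng.uniform(size=(3, 6))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert np.array_equal(loaded.predict(x), model.predict(x))
        assert checkpoint_hash(loaded) == checkpoint_hash(model)
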