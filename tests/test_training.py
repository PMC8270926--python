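"""Training-engine tests: gradients, metrics, and learning behavior."""

import numpy as np
import pytest

from dexat.neurons import DEXATParams, LIFParams
from dexat.network import LSNNConfig, init_weights
from dexat.tasks import (
    SMNISTSpec,
    StoreRecallSpec,
    TaskBatch,
    encode_smnist,
    make_synthetic_digits,
    store_recall_factory,
)
from dexat.training import (
    TrainConfig,
    _loss_and_grads,
    bptt_train,
    decision_error,
    design_space_sweep,
    evaluate,
    surrogate_spike_grad,
)


class TestSurrogate:
    def test_peak_at_threshold(self):
        assert surrogate_spike_grad(1.0, 1.0, 0.3) == pytest.approx(0.3)

    def test_zero_outside_support(self):
        assert surrogate_spike_grad(2.0, 1.0, 0.3) == 0.0
        assert surrogate_spike_grad(0.0, 1.0, 0.3) == 0.0

    def test_midpoint_value(self):
        # gamma=0.3, v=0.5, B=1 -> 0.3 * (1 - 0.5) = 0.15
        assert surrogate_spike_grad(0.5, 1.0, 0.3) == pytest.approx(0.15)

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            surrogate_spike_grad(0.5, 0.0, 0.3)


class TestDecisionError:
    def test_all_correct_and_all_wrong(self):
        T, B = 10, 8
        readout = np.zeros((B, T, 2))
        targets = np.array([0, 1] * 4)
        mask = np.zeros(T, dtype=bool)
        mask[-3:] = True
        readout[np.arange(B), :, targets] = 1.0
        assert decision_error(readout, targets, mask) == 0.0
        assert decision_error(readout, 1 - targets, mask) == 1.0

    def test_counting_oracle(self):
        # 6 wrong out of 128 -> 0.046875
        B, T = 128, 5
        readout = np.zeros((B, T, 2))
        targets = np.zeros(B, dtype=int)
        readout[:, :, 0] = 1.0
        readout[:6, :, 1] = 2.0  # six false detections
        err = decision_error(readout, targets, np.ones(T, dtype=bool))
        assert err == pytest.approx(6 / 128)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty decision window"):
            decision_error(np.zeros((2, 4, 2)), np.zeros(2),
                           np.zeros(4, dtype=bool))


def _tiny_batch(rng, config, T=12):
    x = (rng.random((3, T, config.n_input)) < 0.4).astype(float)
    mask = np.zeros((3, T), dtype=bool)
    mask[:, -4:] = True
    return TaskBatch(input_spikes=x, target=rng.integers(0, 2, 3),
                     decision_mask=mask)


def test_gradients_match_finite_differences(rng):
    """With the hard spike replaced by a smooth sigmoid, the hand-written
    reverse pass must agree with central differences."""
    lif = LIFParams(delta_t=1.0, tau_m=20.0, t_refractory=0.0)
    config = LSNNConfig(
        n_input=3, n_lif=1, n_adaptive=1, n_output=2, lif=lif,
        adaptive=DEXATParams(lif=lif, tau_a1=5.0, tau_a2=20.0,
                             beta1=2.0, beta2=4.0),
        tau_out=10.0,
    )
    weights = init_weights(config, seed=1)
    batch = _tiny_batch(rng, config, T=10)
    cell = config.cell()
    eps = 0.25
    _, _, grads = _loss_and_grads(batch, weights, cell, config.kappa, 0.3,
                                  smooth_eps=eps, rate_reg_coeff=0.01)

    def loss_of():
        l, _, _ = _loss_and_grads(batch, weights, cell, config.kappa, 0.3,
                                  smooth_eps=eps, rate_reg_coeff=0.01)
        return l

    h = 1e-6
    for name in ("w_in", "w_rec", "w_out"):
        W = getattr(weights, name)
        G = getattr(grads, name)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            if name == "w_rec" and idx[0] == idx[1]:
                continue
            orig = W[idx]
            W[idx] = orig + h
            lp = loss_of()
            W[idx] = orig - h
            lm = loss_of()
            W[idx] = orig
            num = (lp - lm) / (2 * h)
            assert G[idx] == pytest.approx(num, rel=1e-5, abs=1e-9), (name, idx)


@pytest.fixture
def toy_spec():
    # shortest admissible trial: one 200 ms character slot plus recall
    return StoreRecallSpec(working_memory=200.0, delta_t=2.0)


@pytest.fixture
def toy_config():
    return LSNNConfig(
        n_input=40, n_lif=5, n_adaptive=5, n_output=2,
        lif=LIFParams(delta_t=2.0),
        adaptive=DEXATParams(lif=LIFParams(delta_t=2.0), tau_a1=30.0,
                             tau_a2=300.0, beta1=3.0, beta2=120.0),
    )


class TestBPTT:
    def test_zero_learning_rate_leaves_weights_unchanged(self, toy_spec, toy_config):
        tc = TrainConfig(learning_rate=0.0, max_iterations=3, seed=0,
                         batch_size_train=8, batch_size_eval=8)
        w, _ = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        w0 = init_weights(
            toy_config,
            seed=int(np.random.SeedSequence(0).spawn(3)[0].generate_state(1)[0] % 2**31),
        )
        assert np.array_equal(w.w_in, w0.w_in)
        assert np.array_equal(w.w_rec, w0.w_rec)
        assert np.array_equal(w.w_out, w0.w_out)

    def test_seeded_training_is_reproducible(self, toy_spec, toy_config):
        tc = TrainConfig(max_iterations=4, seed=9, batch_size_train=8,
                         batch_size_eval=8)
        _, rec_a = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        _, rec_b = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        assert np.array_equal(rec_a.loss, rec_b.loss)
        assert np.array_equal(rec_a.decision_error, rec_b.decision_error)
        assert rec_a.iteration_converged == rec_b.iteration_converged

    def test_loss_decreases_on_learnable_toy_task(self, toy_spec, toy_config):
        # mean loss over late iterations below the first iteration, 5 seeds
        import dataclasses

        deltas = []
        for seed in range(5):
            tc = TrainConfig(max_iterations=20, seed=seed, batch_size_train=32,
                             batch_size_eval=32, target_decision_error=0.001)
            cfg = dataclasses.replace(toy_config, seed=seed)
            _, rec = bptt_train(cfg, tc, store_recall_factory(toy_spec))
            deltas.append(rec.loss[:3].mean() - rec.loss[-3:].mean())
        assert np.mean(deltas) > 0

    def test_record_shape_and_convergence_flag(self, toy_spec, toy_config):
        tc = TrainConfig(max_iterations=5, seed=0, batch_size_train=8,
                         batch_size_eval=8, target_decision_error=0.001)
        _, rec = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        assert rec.n_iterations <= 5
        assert np.all((rec.decision_error >= 0) & (rec.decision_error <= 1))
        assert np.allclose(rec.accuracy, 1 - rec.decision_error)

    def test_gradient_clipping_bounds_update_size(self, toy_spec, toy_config):
        # with an absurdly tight clip the first Adam step still moves the
        # weights, but training runs and stays finite
        tc = TrainConfig(max_iterations=3, seed=0, batch_size_train=8,
                         batch_size_eval=8, grad_clip_norm=1e-6)
        w, rec = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        assert np.all(np.isfinite(rec.loss))
        assert np.all(np.isfinite(w.w_in))

    def test_record_serialization(self, tmp_path, toy_spec, toy_config):
        tc = TrainConfig(max_iterations=3, seed=0, batch_size_train=8,
                         batch_size_eval=8)
        _, rec = bptt_train(toy_config, tc, store_recall_factory(toy_spec))
        rec.to_csv(tmp_path / "rec.csv")
        rec.to_hdf5(tmp_path / "rec.h5")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "rec.csv")
        assert list(frame.columns) == ["iteration", "loss", "decision_error",
                                       "accuracy"]
        assert len(frame) == rec.n_iterations


def test_train_config_yaml_roundtrip(tmp_path):
    tc = TrainConfig(learning_rate=0.02, max_iterations=7, seed=3)
    tc.to_yaml(tmp_path / "train.yaml")
    assert TrainConfig.from_yaml(tmp_path / "train.yaml") == tc


def test_design_space_sweep_table_shape(toy_spec):
    grid = [
        {"tau_a1": 30.0, "tau_a2": 300.0, "working_memory": 200.0},
        {"tau_a": 300.0, "working_memory": 200.0},
    ]
    tc = TrainConfig(max_iterations=2, batch_size_train=8, batch_size_eval=8)
    df = design_space_sweep(grid, delta_t=2.0, n_seeds=2, seed=0, tconfig=tc)
    assert len(df) == 4
    assert set(df["neuron"]) == {"dexat", "alif"}
    assert {"iterations_to_converge", "final_decision_error",
            "converged"} <= set(df.columns)


def test_smnist_pipeline_separates_two_synthetic_classes():
    """An LSNN briefly trained on two synthetic digit classes classifies
    them above chance through the sequential-pixel encoding."""
    spec = SMNISTSpec(n_threshold_neurons=16, cue_steps=56)
    images, labels = make_synthetic_digits(400, seed=0)
    keep = np.flatnonzero(labels < 2)[:200]
    images, labels = images[keep], labels[keep]
    rasters = np.stack([encode_smnist(im, spec) for im in images])
    T = rasters.shape[1]
    mask = np.zeros(T, dtype=bool)
    mask[784:] = True

    def factory(rng, n):
        idx = rng.integers(0, len(labels), size=n)
        return TaskBatch(
            input_spikes=rasters[idx],
            target=labels[idx],
            decision_mask=np.broadcast_to(mask, (n, T)),
        )

    lif = LIFParams(delta_t=1.0)
    config = LSNNConfig(
        n_input=spec.n_input, n_lif=8, n_adaptive=8, n_output=2,
        lif=lif, adaptive=DEXATParams(lif=lif), seed=0,
    )
    tc = TrainConfig(max_iterations=30, seed=0, batch_size_train=32,
                     batch_size_eval=64, target_decision_error=0.01)
    weights, rec = bptt_train(config, tc, factory)
    eval_batch = factory(np.random.default_rng(99), 128)
    err = evaluate(config, weights, eval_batch)
    assert 1.0 - err > 0.5
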