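"""Surrogate-gradient BPTT for LSNNs, metrics, and design-space sweeps.

The spike nonlinearity is non-differentiable, so the backward pass replaces
its derivative with the pseudo-derivative
``psi = dampening * max(0, 1 - |v - B| / B)`` while keeping the exact
analytic gradients of the membrane, threshold-adaptation, and readout
recursions.  The reverse pass is written out by hand (reverse-mode through
the unrolled dynamics) and is checked against central finite differences in
the test suite using a smooth-sigmoid spike.

Convergence is operationalized as the evaluation decision error dropping
below ``target_decision_error`` on one held-out batch, checked every
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .neurons import LIFParams, alif_from_spike_jump, dexat_from_spike_jump
from .network import LSNNConfig, LSNNWeights, init_weights, run_network
from .tasks import StoreRecallSpec, TaskBatch, store_recall_factory

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "surrogate_spike_grad",
    "decision_error",
    "bptt_train",
    "train_store_recall",
    "evaluate",
    "design_space_sweep",
    "default_store_recall_network",
]


@dataclass(frozen=True)
class TrainConfig:
    """BPTT hyperparameters (Adam optimizer).

    The learning rate decays multiplicatively by ``lr_decay`` every
    ``lr_decay_every`` iterations.  ``dampening`` is the pseudo-derivative
    amplitude gamma.  ``rate_reg_coeff`` weights a quadratic penalty
    pulling each hidden neuron's mean firing rate toward
    ``rate_reg_target`` Hz (set to 0 to disable); it keeps units
    responsive during the long search phase of working-memory training.
    """

    learning_rate: float = 0.01
    lr_decay: float = 0.8
    lr_decay_every: int = 50
    dampening: float = 0.3
    batch_size_train: int = 256
    batch_size_eval: int = 128
    max_iterations: int = 200
    target_decision_error: float = 0.05
    rate_reg_coeff: float = 0.0
    rate_reg_target: float = 10.0
    grad_clip_norm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.learning_rate >= 0):
            raise ValueError("learning_rate must be >= 0")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.dampening < 0:
            raise ValueError("dampening must be >= 0")
        if not (0 < self.target_decision_error < 1):
            raise ValueError("target_decision_error must be in (0, 1)")
        if self.max_iterations < 1 or self.lr_decay_every < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.rate_reg_coeff < 0 or self.rate_reg_target < 0:
            raise ValueError("rate regularization terms must be >= 0")
        if self.grad_clip_norm < 0:
            raise ValueError("grad_clip_norm must be >= 0 (0 disables)")

    def to_yaml(self, path) -> None:
        import dataclasses
        from pathlib import Path

        import yaml

        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        from pathlib import Path

        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainRecord:
    """Per-iteration training trace.

    ``iteration_converged`` is the first (1-based) iteration whose
    evaluation decision error met the target, or None.
    """

    loss: np.ndarray
    decision_error: np.ndarray
    accuracy: np.ndarray
    iteration_converged: Optional[int]

    @property
    def n_iterations(self) -> int:
        return len(self.loss)

    @property
    def converged(self) -> bool:
        return self.iteration_converged is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations + 1),
                "loss": self.loss,
                "decision_error": self.decision_error,
                "accuracy": self.accuracy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("loss", data=self.loss)
            f.create_dataset("decision_error", data=self.decision_error)
            f.create_dataset("accuracy", data=self.accuracy)
            f.attrs["iteration_converged"] = (
                -1 if self.iteration_converged is None else self.iteration_converged
            )


def surrogate_spike_grad(
    v_mem: np.ndarray, B: np.ndarray, dampening: float
) -> np.ndarray:
    """Pseudo-derivative of the spike nonlinearity.

    ``dampening * max(0, 1 - |v_mem - B| / B)``: peaks at the threshold,
    vanishes once the membrane is a full threshold away.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise ValueError("threshold must be > 0")
    return dampening * np.maximum(0.0, 1.0 - np.abs(np.asarray(v_mem) - B) / B)


def decision_error(
    readout: np.ndarray, targets: np.ndarray, decision_mask: np.ndarray
) -> float:
    """Fraction of falsely detected cases in a batch.

    A case is false when the argmax of its window-averaged readout differs
    from the target label.  ``readout`` is (batch, T, n_out) (or time-major
    (T, batch, n_out) transposed by the caller); ``decision_mask`` is
    (batch, T) or (T,) boolean.
    """
    readout = np.asarray(readout)
    targets = np.asarray(targets)
    mask = np.asarray(decision_mask, dtype=bool)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, readout.shape[:2])
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("empty decision window")
    m = (readout * mask[:, :, None]).sum(axis=1) / counts[:, None]
    pred = m.argmax(axis=1)
    return float(np.mean(pred != targets))


def _window_logits(Y: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged readout; Y time-major (T,B,o), mask (B,T)."""
    counts = mask.sum(axis=1).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty decision window")
    m = np.einsum("tbo,bt->bo", Y, mask.astype(float)) / counts[:, None]
    return m, counts


def _softmax(m: np.ndarray) -> np.ndarray:
    e = np.exp(m - m.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(
    batch: TaskBatch,
    weights: LSNNWeights,
    cell,
    kappa: float,
    dampening: float,
    smooth_eps: Optional[float] = None,
    rate_reg_coeff: float = 0.0,
    rate_reg_target: float = 10.0,
    delta_t: float = 1.0,
    engine: str = "auto",
) -> tuple[float, float, LSNNWeights]:
    """Cross-entropy on softmax of window-averaged readout, plus gradients.

    Reverse-mode pass through the unrolled simulation: gradients flow
    through the membrane leak, the reset-by-subtraction, the recurrent
    synapses (one-step delay), both threshold-adaptation filters, and the
    readout leak; the spike uses ``surrogate_spike_grad`` (or the exact
    sigmoid derivative in smooth mode).  An optional quadratic firing-rate
    penalty (per-neuron mean rate vs ``rate_reg_target`` Hz) is added to
    the loss and differentiated along the same paths.
    """
    x = np.asarray(batch.input_spikes, dtype=np.float64)
    targets = np.asarray(batch.target)
    mask = np.asarray(batch.decision_mask, dtype=bool)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, x.shape[:2])
    n_batch, T, _ = x.shape
    h = cell.n_hidden

    out = run_network(
        x, weights, cell, kappa, record=True, smooth_eps=smooth_eps,
        engine=engine,
    )
    Z, Bth, Y, Vhat, Can = out["z"], out["B"], out["y"], out["vhat"], out["can"]

    m, counts = _window_logits(Y, mask)
    p = _softmax(m)
    onehot = np.zeros_like(p)
    onehot[np.arange(n_batch), targets] = 1.0
    loss = float(-np.mean(np.log(p[np.arange(n_batch), targets] + 1e-300)))
    err = float(np.mean(p.argmax(axis=1) != targets))

    dLdm = (p - onehot) / n_batch                       # (B, o)
    gm = (mask / counts[:, None]).T[:, :, None] * dLdm  # (T, B, o)

    gz_rate = 0.0
    if rate_reg_coeff > 0:
        hz_per_z = 1000.0 / delta_t
        rates = Z.mean(axis=(0, 1)) * hz_per_z          # per-neuron mean Hz
        loss_reg = rate_reg_coeff * float(
            np.mean((rates - rate_reg_target) ** 2)
        )
        loss += loss_reg
        gz_rate = (
            rate_reg_coeff * 2.0 * (rates - rate_reg_target)
            * hz_per_z / (h * T * n_batch)
        )                                               # (h,), same for all t,b

    c1 = (1.0 - cell.rho1) * cell.inv_dt
    c2 = (1.0 - cell.rho2) * cell.inv_dt

    from ._kernels import HAVE_NUMBA, backward_kernel

    GY = np.empty_like(Y)
    GVhat = np.empty_like(Vhat)

    w_out_T = np.ascontiguousarray(weights.w_out.T)
    w_rec_T = np.ascontiguousarray(weights.w_rec.T)

    if engine == "auto" and HAVE_NUMBA and smooth_eps is None:
        gz_rate_vec = np.zeros(h) + gz_rate
        backward_kernel(
            Z, Bth, Vhat, Can, np.ascontiguousarray(gm), w_rec_T, w_out_T,
            cell.alpha, cell.rho1, cell.rho2, cell.beta1, cell.beta2,
            c1, c2, kappa, dampening, gz_rate_vec, GY, GVhat,
        )
        return _weight_grads(x, Z, GY, GVhat, n_batch, h, loss, err)

    gy = np.zeros((n_batch, Y.shape[2]))
    gvhat_next = np.zeros((n_batch, h))
    gb1 = np.zeros((n_batch, h))
    gb2 = np.zeros((n_batch, h))

    for t in range(T - 1, -1, -1):
        gy = gm[t] + kappa * gy
        gv = cell.alpha * gvhat_next                        # dL/dv_t
        gz = (
            gy @ w_out_T
            + gvhat_next @ w_rec_T
            + c1 * gb1
            + c2 * gb2
            - Bth[t] * gv
            + gz_rate
        )
        if smooth_eps is None:
            psi = dampening * np.maximum(
                0.0, 1.0 - np.abs(Vhat[t] - Bth[t]) / Bth[t]
            )
            psi *= Can[t]
        else:
            psi = Z[t] * (1.0 - Z[t]) / smooth_eps          # exact sigmoid'
        gvhat = gv + psi * gz
        gB = -psi * gz - Z[t] * gv
        gb1 = cell.beta1 * gB + cell.rho1 * gb1
        gb2 = cell.beta2 * gB + cell.rho2 * gb2
        GY[t] = gy
        GVhat[t] = gvhat
        gvhat_next = gvhat

    return _weight_grads(x, Z, GY, GVhat, n_batch, h, loss, err)


def _weight_grads(x, Z, GY, GVhat, n_batch, h, loss, err):
    """Contract the per-step adjoints into weight gradients."""
    x_tm = x.transpose(1, 0, 2)                             # (T, B, n_in)
    z_prev = np.concatenate([np.zeros((1, n_batch, h)), Z[:-1]], axis=0)
    g_w_in = np.tensordot(x_tm, GVhat, axes=([0, 1], [0, 1]))
    g_w_rec = np.tensordot(z_prev, GVhat, axes=([0, 1], [0, 1]))
    np.fill_diagonal(g_w_rec, 0.0)
    g_w_out = np.tensordot(Z, GY, axes=([0, 1], [0, 1]))

    grads = LSNNWeights(w_in=g_w_in, w_rec=g_w_rec, w_out=g_w_out)
    return loss, err, grads


def evaluate(
    config: LSNNConfig,
    weights: LSNNWeights,
    batch: TaskBatch,
    *,
    eta_r: float = 0.0,
    noise_seed: int = 0,
) -> float:
    """Decision error of the network on one batch (optionally with
    multiplicative threshold noise of coefficient of variation ``eta_r``
    injected into the adaptive neurons)."""
    noise_rng = np.random.default_rng(noise_seed) if eta_r else None
    out = run_network(
        np.asarray(batch.input_spikes, dtype=np.float64),
        weights, config.cell(), config.kappa,
        eta_r=eta_r, noise_rng=noise_rng,
    )
    return decision_error(
        out["y"].transpose(1, 0, 2), batch.target, batch.decision_mask
    )


class _Adam:
    """Minimal Adam optimizer over a list of arrays."""

    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def bptt_train(
    config: LSNNConfig,
    tconfig: TrainConfig,
    task_factory: Callable[[np.random.Generator, int], TaskBatch],
    eval_task_factory: Optional[
        Callable[[np.random.Generator, int], TaskBatch]
    ] = None,
) -> tuple[LSNNWeights, TrainRecord]:
    """Train an LSNN with surrogate-gradient BPTT.

    ``task_factory(rng, n)`` must yield a :class:`TaskBatch` of n cases.  A
    fixed held-out batch is drawn once for evaluation — from
    ``eval_task_factory`` when given (e.g. the full-delay task while
    training batches follow a randomized-delay curriculum), otherwise from
    ``task_factory``.  Training stops early at the first iteration whose
    evaluation decision error is below the target.  Fully reproducible
    from ``tconfig.seed``.
    """
    ss = np.random.SeedSequence(tconfig.seed)
    w_ss, train_ss, eval_ss = ss.spawn(3)
    weights = init_weights(config, seed=int(w_ss.generate_state(1)[0] % 2**31))
    train_rng = np.random.default_rng(train_ss)
    eval_batch = (eval_task_factory or task_factory)(
        np.random.default_rng(eval_ss), tconfig.batch_size_eval
    )

    cell = config.cell()
    kappa = config.kappa
    params = [weights.w_in, weights.w_rec, weights.w_out]
    adam = _Adam([p.shape for p in params])

    losses, errors, accs = [], [], []
    converged_at: Optional[int] = None
    for it in range(1, tconfig.max_iterations + 1):
        batch = task_factory(train_rng, tconfig.batch_size_train)
        loss, _, grads = _loss_and_grads(
            batch, weights, cell, kappa, tconfig.dampening,
            rate_reg_coeff=tconfig.rate_reg_coeff,
            rate_reg_target=tconfig.rate_reg_target,
            delta_t=config.delta_t,
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at iteration {it}"
            )
        lr = tconfig.learning_rate * tconfig.lr_decay ** (
            (it - 1) // tconfig.lr_decay_every
        )
        glist = [grads.w_in, grads.w_rec, grads.w_out]
        if tconfig.grad_clip_norm > 0:
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in glist))
            if gnorm > tconfig.grad_clip_norm:
                scale = tconfig.grad_clip_norm / gnorm
                glist = [g * scale for g in glist]
        adam.step(params, glist, lr)
        np.fill_diagonal(weights.w_rec, 0.0)

        eval_err = evaluate(config, weights, eval_batch)
        losses.append(loss)
        errors.append(eval_err)
        accs.append(1.0 - eval_err)
        if eval_err < tconfig.target_decision_error:
            converged_at = it
            break

    record = TrainRecord(
        loss=np.asarray(losses),
        decision_error=np.asarray(errors),
        accuracy=np.asarray(accs),
        iteration_converged=converged_at,
    )
    return weights, record


def train_store_recall(
    config: LSNNConfig,
    tconfig: TrainConfig,
    spec: StoreRecallSpec,
    *,
    curriculum: bool = True,
) -> tuple[LSNNWeights, TrainRecord]:
    """Train on STORE-RECALL and evaluate at the full working memory.

    With ``curriculum`` (default) training batches randomize the STORE
    position, so delays range up to the working-memory requirement; the
    held-out evaluation batch always uses the full delay, which is what
    the convergence criterion is scored on.
    """
    return bptt_train(
        config,
        tconfig,
        store_recall_factory(spec, randomize_store=curriculum),
        store_recall_factory(spec),
    )


def default_store_recall_network(
    neuron: str = "dexat",
    *,
    delta_t: float = 1.0,
    tau_a: float = 1200.0,
    tau_a1: float = 30.0,
    tau_a2: float = 300.0,
    beta_ratio: Optional[float] = None,
    n_lif: int = 10,
    n_adaptive: int = 10,
    n_input: int = 40,
    seed: int = 0,
) -> LSNNConfig:
    """The 10 LIF + 10 adaptive STORE-RECALL network.

    Default adaptation strengths are set through the per-spike threshold
    jump: one spike raises a DEXAT threshold by 0.1*b_j0 (fast component)
    plus 0.4*b_j0 (slow component); an ALIF threshold by the matching
    total of 0.5*b_j0.  ``beta_ratio`` overrides beta2/beta1 while keeping
    the total per-spike jump at 0.5*b_j0.
    """
    total_jump = 0.5
    lif = LIFParams(delta_t=delta_t)
    if neuron == "dexat":
        if beta_ratio is None:
            adaptive = dexat_from_spike_jump(lif, tau_a1=tau_a1, tau_a2=tau_a2)
        else:
            # split the total jump so that beta2/beta1 == beta_ratio
            base = dexat_from_spike_jump(
                lif, tau_a1=tau_a1, tau_a2=tau_a2, jump1=1.0, jump2=1.0
            )
            u = base.beta2 / base.beta1  # beta ratio at equal jumps
            j1 = total_jump / (1.0 + beta_ratio / u)
            adaptive = dexat_from_spike_jump(
                lif, tau_a1=tau_a1, tau_a2=tau_a2,
                jump1=j1, jump2=total_jump - j1,
            )
    elif neuron == "alif":
        adaptive = alif_from_spike_jump(lif, tau_a=tau_a, jump=total_jump)
    else:
        raise ValueError(f"unknown neuron kind {neuron!r}")
    return LSNNConfig(
        n_input=n_input,
        n_lif=n_lif,
        n_adaptive=n_adaptive,
        n_output=2,
        lif=lif,
        adaptive=adaptive,
        seed=seed,
    )


def design_space_sweep(
    grid,
    *,
    delta_t: float = 1.0,
    n_seeds: int = 1,
    seed: int = 0,
    tconfig: Optional[TrainConfig] = None,
) -> pd.DataFrame:
    """Run one STORE-RECALL training per grid cell (times ``n_seeds``).

    ``grid`` is an iterable of dicts with keys ``working_memory`` and
    either ``tau_a`` (ALIF) or ``tau_a1``/``tau_a2`` and optionally
    ``beta_ratio`` (DEXAT).  Returns a tidy DataFrame with one row per
    (cell, seed): iterations to converge (NaN if none) and final decision
    error.
    """
    base = tconfig or TrainConfig()
    rows = []
    for cell_spec in grid:
        cell_spec = dict(cell_spec)
        wm = cell_spec.pop("working_memory")
        neuron = "alif" if "tau_a" in cell_spec else "dexat"
        for k in range(n_seeds):
            run_seed = seed + 1000 * k
            config = default_store_recall_network(
                neuron, delta_t=delta_t, seed=run_seed, **cell_spec
            )
            spec = StoreRecallSpec(working_memory=wm, delta_t=delta_t)
            tc = TrainConfig(
                learning_rate=base.learning_rate,
                lr_decay=base.lr_decay,
                lr_decay_every=base.lr_decay_every,
                dampening=base.dampening,
                batch_size_train=base.batch_size_train,
                batch_size_eval=base.batch_size_eval,
                max_iterations=base.max_iterations,
                target_decision_error=base.target_decision_error,
                seed=run_seed,
            )
            _, rec = train_store_recall(config, tc, spec)
            rows.append(
                {
                    "neuron": neuron,
                    "working_memory": wm,
                    **cell_spec,
                    "seed": run_seed,
                    "iterations_to_converge": (
                        np.nan if rec.iteration_converged is None
                        else rec.iteration_converged
                    ),
                    "final_decision_error": rec.decision_error[-1],
                    "converged": rec.converged,
                }
            )
    return pd.DataFrame(rows)
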