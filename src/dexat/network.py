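"""Recurrent LSNN of LIF plus adaptive (ALIF/DEXAT) hidden neurons.

The hidden layer mixes non-adaptive LIF neurons (first block) with adaptive
neurons (second block); all neurons are recurrently connected with delta
synapses and a one-step synaptic delay, and a linear readout low-pass
filters the hidden spike train with time constant ``tau_out``.

The vectorized time-stepping engine (:func:`run_network`) serves both plain
simulation and the BPTT training path in :mod:`dexat.training`, which needs
the per-step pre-reset membrane potentials and refractory masks recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .neurons import ALIFParams, DEXATParams, LIFParams

__all__ = [
    "LSNNConfig",
    "LSNNWeights",
    "SimTrace",
    "init_weights",
    "simulate",
    "run_network",
]


@dataclass(frozen=True)
class _Cell:
    """Per-neuron parameter vectors for the fused hidden layer."""

    alpha: np.ndarray      # membrane leak, shape (h,)
    rho1: np.ndarray       # fast threshold decay
    rho2: np.ndarray       # slow threshold decay
    beta1: np.ndarray
    beta2: np.ndarray
    b0: np.ndarray         # baseline threshold
    n_ref: np.ndarray      # refractory steps, int
    inv_dt: float
    n_lif: int

    @property
    def n_hidden(self) -> int:
        return self.b0.size

    @property
    def adaptive_mask(self) -> np.ndarray:
        return np.arange(self.n_hidden) >= self.n_lif


@dataclass(frozen=True)
class LSNNConfig:
    """Architecture and neuron parameters of an LSNN.

    ``lif`` holds the membrane constants shared by the whole hidden layer
    and the fixed threshold of the LIF block; ``adaptive`` the ALIF or
    DEXAT parameters of the adaptive block (its embedded ``lif`` governs
    the adaptive neurons' membranes and must use the same ``delta_t``).
    """

    n_input: int
    n_lif: int
    n_adaptive: int
    n_output: int
    lif: LIFParams = LIFParams()
    adaptive: Optional[Union[ALIFParams, DEXATParams]] = None
    tau_out: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_input", "n_lif", "n_adaptive", "n_output"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_lif + self.n_adaptive < 1:
            raise ValueError("need at least one hidden neuron")
        if self.n_adaptive > 0 and self.adaptive is None:
            raise ValueError("adaptive params required when n_adaptive > 0")
        if self.adaptive is not None and (
            self.adaptive.lif.delta_t != self.lif.delta_t
        ):
            raise ValueError("adaptive and LIF populations must share delta_t")
        if not (self.tau_out > 0):
            raise ValueError("tau_out must be > 0")

    @property
    def n_hidden(self) -> int:
        return self.n_lif + self.n_adaptive

    @property
    def delta_t(self) -> float:
        return self.lif.delta_t

    @property
    def adaptive_kind(self) -> Optional[str]:
        if self.adaptive is None:
            return None
        return "dexat" if isinstance(self.adaptive, DEXATParams) else "alif"

    @property
    def kappa(self) -> float:
        """Readout leak factor ``exp(-delta_t/tau_out)``."""
        return float(np.exp(-self.delta_t / self.tau_out))

    def cell(self) -> _Cell:
        h = self.n_hidden
        alpha = np.empty(h)
        rho1 = np.zeros(h)
        rho2 = np.zeros(h)
        beta1 = np.zeros(h)
        beta2 = np.zeros(h)
        b0 = np.empty(h)
        n_ref = np.empty(h, dtype=np.int64)

        nl = self.n_lif
        alpha[:nl] = self.lif.alpha
        b0[:nl] = self.lif.v_th_base
        n_ref[:nl] = self.lif.refrac_steps
        if self.n_adaptive > 0:
            p = self.adaptive
            alpha[nl:] = p.lif.alpha
            b0[nl:] = p.b_j0
            n_ref[nl:] = p.lif.refrac_steps
            if isinstance(p, DEXATParams):
                rho1[nl:] = p.rho1
                rho2[nl:] = p.rho2
                beta1[nl:] = p.beta1
                beta2[nl:] = p.beta2
            else:
                rho1[nl:] = p.rho
                beta1[nl:] = p.beta
        return _Cell(
            alpha=alpha, rho1=rho1, rho2=rho2, beta1=beta1, beta2=beta2,
            b0=b0, n_ref=n_ref, inv_dt=1.0 / self.delta_t, n_lif=nl,
        )


@dataclass
class LSNNWeights:
    """Trainable weights; ``w_rec`` has an exactly zero diagonal."""

    w_in: np.ndarray   # (n_input, n_hidden)
    w_rec: np.ndarray  # (n_hidden, n_hidden), zero diagonal
    w_out: np.ndarray  # (n_hidden, n_output)

    def validate(self, config: LSNNConfig) -> None:
        h = config.n_hidden
        if self.w_in.shape != (config.n_input, h):
            raise ValueError(f"w_in shape {self.w_in.shape} mismatches config")
        if self.w_rec.shape != (h, h):
            raise ValueError(f"w_rec shape {self.w_rec.shape} mismatches config")
        if self.w_out.shape != (h, config.n_output):
            raise ValueError(f"w_out shape {self.w_out.shape} mismatches config")
        if np.any(np.diagonal(self.w_rec) != 0.0):
            raise ValueError("w_rec diagonal must be exactly zero (no self-loops)")

    def copy(self) -> "LSNNWeights":
        return LSNNWeights(self.w_in.copy(), self.w_rec.copy(), self.w_out.copy())


def init_weights(config: LSNNConfig, seed: Optional[int] = None) -> LSNNWeights:
    """Zero-mean Gaussian weights scaled by 1/sqrt(fan-in); zero recurrent
    diagonal.  Reproducible from ``seed`` (defaults to ``config.seed``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h = config.n_hidden
    w_in = rng.standard_normal((config.n_input, h)) / np.sqrt(max(config.n_input, 1))
    w_rec = rng.standard_normal((h, h)) / np.sqrt(h)
    np.fill_diagonal(w_rec, 0.0)
    w_out = rng.standard_normal((h, config.n_output)) / np.sqrt(h)
    return LSNNWeights(w_in=w_in, w_rec=w_rec, w_out=w_out)


@dataclass
class SimTrace:
    """Recorded network activity: hidden spike raster ({0,1}), adaptive
    thresholds B(t), and readout activations, all time-major."""

    spikes: np.ndarray      # (T, n_hidden) in {0, 1}
    thresholds: np.ndarray  # (T, n_adaptive)
    readout: np.ndarray     # (T, n_output)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=self.spikes.astype(np.uint8))
            f.create_dataset("thresholds", data=self.thresholds)
            f.create_dataset("readout", data=self.readout)

    @classmethod
    def from_hdf5(cls, path) -> "SimTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                spikes=f["spikes"][()].astype(np.float64),
                thresholds=f["thresholds"][()],
                readout=f["readout"][()],
            )

    def spikes_to_csv(self, path) -> None:
        """Write the raster as a (time_step, neuron_index) event list."""
        t_idx, n_idx = np.nonzero(self.spikes)
        with open(path, "w") as f:
            f.write("time_step,neuron_index\n")
            for t, n in zip(t_idx, n_idx):
                f.write(f"{t},{n}\n")


def run_network(
    x: np.ndarray,
    weights: LSNNWeights,
    cell: _Cell,
    kappa: float,
    *,
    record: bool = False,
    eta_r: float = 0.0,
    noise_rng: Optional[np.random.Generator] = None,
    smooth_eps: Optional[float] = None,
    engine: str = "auto",
) -> dict:
    """Run the batched LSNN forward pass.

    Parameters
    ----------
    x : (batch, T, n_input) array
        Input spike raster (values in {0,1}; continuous allowed in smooth
        mode).
    record : bool
        Additionally store pre-reset membrane potentials and the
        spike-eligibility mask needed by the backward pass.
    eta_r : float
        Coefficient of variation of multiplicative Gaussian noise applied
        each step to the adaptive neurons' effective threshold, floored at
        0.01*b0 (device-variability injection).  Incompatible with
        ``record``.
    smooth_eps : float, optional
        Replace the hard spike with a sigmoid of temperature ``smooth_eps``
        (continuous z, refractoriness disabled) — used for gradient checks.
    engine : {"auto", "python"}
        "auto" uses the compiled kernel for the plain hard-spike case;
        "python" forces the reference NumPy loop (always used for smooth
        mode and threshold-noise injection).

    Returns a dict of time-major arrays: ``z`` (T,B,h), ``B`` (T,B,h),
    ``y`` (T,B,n_out) and, if ``record``, ``vhat`` and ``can``.
    """
    if engine not in ("auto", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    if eta_r and record:
        raise ValueError("gradient recording assumes a noiseless threshold")
    if eta_r and noise_rng is None:
        raise ValueError("eta_r > 0 requires a noise_rng")
    n_batch, T, n_in = x.shape
    h = cell.n_hidden
    n_out = weights.w_out.shape[1]
    smooth = smooth_eps is not None

    # all input projections in one matmul, then time-major for the loop
    xin = np.ascontiguousarray(
        (x.reshape(n_batch * T, n_in) @ weights.w_in).reshape(n_batch, T, h)
        .transpose(1, 0, 2)
    )

    c1 = (1.0 - cell.rho1) * cell.inv_dt
    c2 = (1.0 - cell.rho2) * cell.inv_dt
    ada = cell.adaptive_mask
    floor = 0.01 * cell.b0

    from ._kernels import HAVE_NUMBA, forward_kernel

    if engine == "auto" and HAVE_NUMBA and not smooth and not eta_r:
        Z = np.empty((T, n_batch, h))
        Bth = np.empty((T, n_batch, h))
        Y = np.empty((T, n_batch, n_out))
        Vhat = np.empty((T, n_batch, h))
        Can = np.empty((T, n_batch, h), dtype=np.bool_)
        forward_kernel(
            xin, weights.w_rec, weights.w_out, cell.alpha, cell.rho1,
            cell.rho2, cell.beta1, cell.beta2, cell.b0, c1, c2,
            cell.n_ref, kappa, Z, Bth, Y, Vhat, Can,
        )
        out = {"z": Z, "B": Bth, "y": Y}
        if record:
            out["vhat"] = Vhat
            out["can"] = Can
        return out

    Z = np.empty((T, n_batch, h))
    Bth = np.empty((T, n_batch, h))
    Y = np.empty((T, n_batch, n_out))
    if record:
        Vhat = np.empty((T, n_batch, h))
        Can = np.empty((T, n_batch, h), dtype=bool)

    v = np.zeros((n_batch, h))
    b1 = np.zeros((n_batch, h))
    b2 = np.zeros((n_batch, h))
    z = np.zeros((n_batch, h))
    r = np.zeros((n_batch, h), dtype=np.int64)
    y = np.zeros((n_batch, n_out))

    for t in range(T):
        b1 = cell.rho1 * b1 + c1 * z
        b2 = cell.rho2 * b2 + c2 * z
        B = cell.b0 + cell.beta1 * b1 + cell.beta2 * b2
        if eta_r:
            noise = noise_rng.standard_normal((n_batch, ada.sum()))
            B = B.copy()
            B[:, ada] = np.maximum(
                B[:, ada] * (1.0 + eta_r * noise), floor[ada]
            )
        vhat = cell.alpha * v + xin[t] + z @ weights.w_rec
        if smooth:
            can = np.ones((n_batch, h), dtype=bool)
            z = 1.0 / (1.0 + np.exp(-(vhat - B) / smooth_eps))
        else:
            can = r == 0
            z = ((vhat >= B) & can).astype(np.float64)
            r = np.where(z > 0, cell.n_ref, np.maximum(r - 1, 0))
        v = vhat - B * z
        y = kappa * y + z @ weights.w_out

        Z[t] = z
        Bth[t] = B
        Y[t] = y
        if record:
            Vhat[t] = vhat
            Can[t] = can

    out = {"z": Z, "B": Bth, "y": Y}
    if record:
        out["vhat"] = Vhat
        out["can"] = Can
    return out


def simulate(
    config: LSNNConfig,
    weights: LSNNWeights,
    input_spikes: np.ndarray,
    *,
    eta_r: float = 0.0,
    noise_seed: int = 0,
) -> SimTrace:
    """Simulate one input raster through the network.

    ``input_spikes`` is a binary (T, n_input) raster; recurrent spikes from
    step t feed step t+1.  Returns the hidden raster, adaptive-neuron
    thresholds, and readout trace.
    """
    weights.validate(config)
    input_spikes = np.asarray(input_spikes, dtype=np.float64)
    if input_spikes.ndim != 2 or input_spikes.shape[1] != config.n_input:
        raise ValueError(
            f"input raster must be (T, {config.n_input}), got {input_spikes.shape}"
        )
    if input_spikes.shape[0] < 1:
        raise ValueError("need at least one time step")
    if not np.isin(input_spikes, (0.0, 1.0)).all():
        raise ValueError("input raster must be binary")

    noise_rng = np.random.default_rng(noise_seed) if eta_r else None
    out = run_network(
        input_spikes[None], weights, config.cell(), config.kappa,
        eta_r=eta_r, noise_rng=noise_rng,
    )
    return SimTrace(
        spikes=out["z"][:, 0, :],
        thresholds=out["B"][:, 0, config.n_lif:],
        readout=out["y"][:, 0, :],
    )
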