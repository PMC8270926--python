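"""Memristive-device tooling: DEXAT parameter extraction and variability.

An OxRAM depression (LTD) curve — conductance versus RESET pulse number —
shows a fast initial drop followed by a slow tail.  After upsampling onto a
uniform time grid and min-max normalization, that decay is fitted with the
single-spike free-decay solution of the DEXAT threshold equations,

    b(t) = baseline + beta1 * exp(-t/tau_a1) + beta2 * exp(-t/tau_a2),

yielding hardware-derived adaptation time constants that feed the network
simulator directly.  The module also implements the resultant-variability
model (per-timestep coefficient of variation of repeated threshold traces,
summarized by its median eta_r), Monte-Carlo trace synthesis from it, and
injection of that noise into network simulations, plus a reduced behavioral
simulator of the 6T-1R threshold-modulator circuit and an endurance
(resistance-window shrinkage) knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import least_squares

from .neurons import DEXATParams, LIFParams
from .network import LSNNConfig, LSNNWeights, SimTrace, simulate

__all__ = [
    "ConductanceTrace",
    "DEXATFit",
    "VariabilityProfile",
    "preprocess_ltd",
    "fit_dexat",
    "asymmetric_nonlinearity",
    "extract_variability",
    "simulate_variability",
    "inject_neuron_variability",
    "ModulatorParams",
    "modulator_behavioral_sim",
    "endurance_window",
    "degrade_adaptive_params",
    "double_exponential",
    "synthetic_ltd_trace",
    "synthetic_ltp_trace",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass(frozen=True)
class ConductanceTrace:
    """Pulse- or time-indexed conductance values from a device.

    ``x`` must be strictly increasing; ``g`` finite and positive.
    ``direction`` is "LTP" (potentiation, rising) or "LTD" (depression,
    falling).
    """

    x: np.ndarray
    g: np.ndarray
    direction: str = "LTD"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.g.shape:
            raise ValueError("x and g must be equal-length 1-D arrays")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.g)) or np.any(self.g <= 0):
            raise ValueError("g must be finite and positive")
        if self.direction not in ("LTP", "LTD"):
            raise ValueError("direction must be 'LTP' or 'LTD'")


def double_exponential(
    t: np.ndarray,
    tau_a1: float,
    tau_a2: float,
    beta1: float,
    beta2: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """``baseline + beta1*exp(-t/tau_a1) + beta2*exp(-t/tau_a2)``."""
    t = np.asarray(t, dtype=float)
    return baseline + beta1 * np.exp(-t / tau_a1) + beta2 * np.exp(-t / tau_a2)


def preprocess_ltd(
    trace: ConductanceTrace, delta_t: float, pulse_duration: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample an LTD curve onto a uniform time grid and normalize.

    Pulse indices are mapped to time via ``pulse_duration`` (ms per unit of
    ``trace.x``; leave at 1.0 when ``x`` is already in ms), samples are
    linearly interpolated onto a ``delta_t`` grid, and the values min-max
    normalized so the output spans exactly [0, 1].  Idempotent.
    """
    if trace.x.size < 2:
        raise ValueError("need at least 2 points to interpolate")
    if delta_t <= 0 or pulse_duration <= 0:
        raise ValueError("delta_t and pulse_duration must be > 0")
    t_knots = (trace.x - trace.x[0]) * pulse_duration
    g = trace.g
    if g.max() == g.min():
        raise ValueError("constant trace cannot be min-max normalized")
    n = int(math.floor(t_knots[-1] / delta_t + 1e-9)) + 1
    t = np.arange(n) * delta_t
    y = np.interp(t, t_knots, g)
    y = (y - y.min()) / (y.max() - y.min())
    return t, y


@dataclass(frozen=True)
class DEXATFit:
    """Least-squares fit of a normalized decay to the DEXAT free-decay form.

    ``beta1``/``beta2`` are the amplitudes of the fast/slow exponentials
    (``tau_a1 <= tau_a2``); ``goodness`` is the residual 2-norm.
    """

    tau_a1: float
    tau_a2: float
    beta1: float
    beta2: float
    baseline: float
    goodness: float
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.tau_a1 > self.tau_a2:
            raise ValueError("tau_a1 must be <= tau_a2")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("betas must be >= 0")

    def curve(self, t: np.ndarray) -> np.ndarray:
        return double_exponential(
            t, self.tau_a1, self.tau_a2, self.beta1, self.beta2, self.baseline
        )

    def to_neuron_params(
        self, lif: Optional[LIFParams] = None, b_j0: float = 1.0
    ) -> DEXATParams:
        """Hand the fit to the network simulator.

        Converts the curve amplitudes into DEXAT scaling factors so that a
        single spike reproduces the fitted threshold transient:
        ``beta_i = amplitude_i * delta_t / (1 - rho_i)``.
        """
        lif = lif or LIFParams()
        rho1 = math.exp(-lif.delta_t / self.tau_a1)
        rho2 = math.exp(-lif.delta_t / self.tau_a2)
        return DEXATParams(
            lif=lif,
            tau_a1=self.tau_a1,
            tau_a2=self.tau_a2,
            beta1=self.beta1 * lif.delta_t / (1.0 - rho1),
            beta2=self.beta2 * lif.delta_t / (1.0 - rho2),
            b_j0=b_j0,
        )

    def to_yaml(self, path) -> None:
        d = {
            "kind": "dexat_fit",
            "tau_a1": float(self.tau_a1),
            "tau_a2": float(self.tau_a2),
            "beta1": float(self.beta1),
            "beta2": float(self.beta2),
            "baseline": float(self.baseline),
            "goodness": float(self.goodness),
            "converged": bool(self.converged),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DEXATFit":
        d = yaml.safe_load(Path(path).read_text())
        if d.pop("kind", None) != "dexat_fit":
            raise ValueError("not a DEXAT fit file")
        return cls(**d)


def fit_dexat(t: np.ndarray, y: np.ndarray, n_starts: int = 8) -> DEXATFit:
    """Fit a normalized decreasing curve with the DEXAT free-decay model.

    Trust-region nonlinear least squares with ``n_starts`` multi-starts
    over log-spaced (tau_a1, tau_a2) initializations spanning the sampling
    step to 10x the trace length; the tau ordering is enforced by sorting.
    A fit that fails everywhere is returned flagged (``converged=False``).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 5:
        raise ValueError("t and y must be equal-length 1-D arrays (>= 5 points)")
    if y[-1] > y[0]:
        raise ValueError("curve must be decreasing overall (LTD-like)")
    span = t[-1] - t[0]
    dt = np.median(np.diff(t))
    amp = y.max() - y.min()

    def resid(theta):
        tau1, tau2, a1, a2, c = theta
        return double_exponential(t - t[0], tau1, tau2, a1, a2, c) - y

    lo = [dt / 10.0, dt / 10.0, 0.0, 0.0, -0.5]
    hi = [100.0 * span, 100.0 * span, 5.0, 5.0, 1.0]
    taus = np.geomspace(max(dt, 1e-12), 10.0 * span, num=max(n_starts, 2))
    best = None
    for i in range(len(taus)):
        tau1_0 = taus[i]
        tau2_0 = taus[min(i + len(taus) // 2, len(taus) - 1)]
        if tau2_0 <= tau1_0:
            tau2_0 = tau1_0 * 10.0
        theta0 = [tau1_0, tau2_0, amp / 2.0, amp / 2.0, max(y.min(), 0.0)]
        try:
            sol = least_squares(
                resid, theta0, bounds=(lo, hi), method="trf", max_nfev=2000
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DEXATFit(
            tau_a1=float(dt), tau_a2=float(span), beta1=0.0, beta2=0.0,
            baseline=float(y.min()), goodness=float("inf"),
            converged=False, message="all multi-starts failed",
        )
    tau1, tau2, a1, a2, c = best.x
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    return DEXATFit(
        tau_a1=float(tau1), tau_a2=float(tau2),
        beta1=float(a1), beta2=float(a2), baseline=float(c),
        goodness=float(np.linalg.norm(resid([tau1, tau2, a1, a2, c]))),
        converged=bool(best.success),
        message=str(best.message),
    )


def asymmetric_nonlinearity(
    ltp: tuple[np.ndarray, np.ndarray],
    ltd: tuple[np.ndarray, np.ndarray],
    n_points: int = 256,
) -> float:
    """Asymmetric nonlinearity (ANL) of an LTP/LTD curve pair in [0, 1].

    Both curves must be preprocessed to [0, 1] (see :func:`preprocess_ltd`).
    Implemented as the mean absolute difference between the LTD curve and
    the mirrored LTP curve on a common normalized abscissa: 0 for a fully
    symmetric pair, bounded by 1.  One realization of the asymmetric-
    nonlinearity measure; the exact literature formula is replaceable.
    """
    out = []
    for name, (x, y) in (("ltp", ltp), ("ltd", ltd)):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError(f"{name}: need matching 1-D arrays")
        if y.min() < -1e-9 or y.max() > 1 + 1e-9:
            raise ValueError(f"{name}: curve must be normalized to [0, 1]")
        s = (x - x[0]) / (x[-1] - x[0])
        grid = np.linspace(0.0, 1.0, n_points)
        out.append(np.interp(grid, s, y))
    ltp_r, ltd_r = out
    return float(np.mean(np.abs(ltd_r - ltp_r[::-1])))


# --- variability ------------------------------------------------------------


@dataclass(frozen=True)
class VariabilityProfile:
    """Per-timestep statistics of repeated threshold traces.

    ``eta`` is the coefficient of variation sigma_i/mu_i at each timestep;
    ``eta_r`` (the resultant variability) is the median of the eta_i.
    """

    mu: np.ndarray
    sigma: np.ndarray
    eta: np.ndarray
    eta_r: float

    def to_yaml(self, path) -> None:
        d = {
            "eta_r": float(self.eta_r),
            "mu": [float(v) for v in self.mu],
            "sigma": [float(v) for v in self.sigma],
            "eta": [float(v) for v in self.eta],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def extract_variability(traces: np.ndarray) -> VariabilityProfile:
    """Resultant variability of >= 2 equal-length threshold traces.

    Rows are repeats (cycles and/or devices), columns timesteps; requires
    every per-timestep mean to be nonzero.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 traces of equal length")
    mu = traces.mean(axis=0)
    if np.any(mu == 0):
        raise ValueError("per-timestep mean must be nonzero")
    sigma = traces.std(axis=0, ddof=1)
    eta = sigma / mu
    return VariabilityProfile(
        mu=mu, sigma=sigma, eta=eta, eta_r=float(np.median(np.abs(eta)))
    )


def simulate_variability(
    mu_trace: np.ndarray, eta_r: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` simulated threshold traces around ``mu_trace``.

    Each point is independently Gaussian with mean mu_i and standard
    deviation eta_r * mu_i.  Reproducible from ``seed``.
    """
    if eta_r < 0:
        raise ValueError("eta_r must be >= 0")
    mu = np.asarray(mu_trace, dtype=float)
    rng = np.random.default_rng(seed)
    if eta_r == 0:
        return np.tile(mu, (n, 1))
    return mu + eta_r * mu * rng.standard_normal((n, mu.size))


def inject_neuron_variability(
    config: LSNNConfig,
    weights: LSNNWeights,
    input_spikes: np.ndarray,
    eta_r: float,
    seed: int = 0,
) -> SimTrace:
    """Simulate with device variability injected into the adaptive neurons.

    At each step every adaptive neuron's effective threshold is perturbed
    multiplicatively by Gaussian noise of coefficient of variation
    ``eta_r`` and floored at 0.01 * b_j0.
    """
    return simulate(
        config, weights, input_spikes, eta_r=eta_r, noise_seed=seed
    )


# --- endurance and the behavioral threshold modulator -----------------------


def endurance_window(
    cycles: float, mode: str = "exponential", rate: float = 1e-6,
    floor: float = 0.1,
) -> float:
    """Resistance-window scale in (0, 1] after ``cycles`` program cycles.

    ``linear``: 1 - rate*cycles (clipped at ``floor``); ``exponential``:
    floor + (1-floor)*exp(-rate*cycles).  The exact degradation law of a
    given stack is a calibration input, hence both forms are exposed.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not (0 < floor <= 1):
        raise ValueError("floor must be in (0, 1]")
    if mode == "linear":
        return float(max(1.0 - rate * cycles, floor))
    if mode == "exponential":
        return float(floor + (1.0 - floor) * math.exp(-rate * cycles))
    raise ValueError(f"unknown endurance mode {mode!r}")


def degrade_adaptive_params(p, window_scale: float):
    """Shrink an adaptive neuron's threshold dynamic range.

    Scales the beta factors by ``window_scale`` in (0, 1], emulating a
    shrunken device resistance window; the per-spike threshold jump and
    the whole adaptation transient scale with it.
    """
    if not (0 < window_scale <= 1):
        raise ValueError("window_scale must be in (0, 1]")
    if isinstance(p, DEXATParams):
        return replace(
            p, beta1=p.beta1 * window_scale, beta2=p.beta2 * window_scale
        )
    return replace(p, beta=p.beta * window_scale)


@dataclass(frozen=True)
class ModulatorParams:
    """Behavioral parameters of the 6T-1R threshold-modulator circuit.

    Conductance decays double-exponentially between spikes (the long RESET
    pulse); each spike applies a fixed SET whose resulting conductance is
    an increasing (logistic) function of the pre-SET conductance, coupling
    consecutive firing events.  The threshold is read through a resistive
    divider ``V_th = V_read * R_load / (R_load + 1/g)``.  Defaults give a
    peak-to-floor threshold ratio of 5.
    """

    g_min: float = 1.0 / 4.5e4   # S
    g_max: float = 1.0e-3        # S
    tau1: float = 30.0           # ms, fast decay
    tau2: float = 300.0          # ms, slow decay
    frac_fast: float = 0.5
    v_read: float = 1.0          # V
    r_load: float = 1.0e4        # Ohm
    set_floor_frac: float = 0.6  # weakest SET level as fraction of g_max
    coupling_sharpness: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.g_min < self.g_max):
            raise ValueError("need 0 < g_min < g_max")
        if not (0 < self.tau1 <= self.tau2):
            raise ValueError("need 0 < tau1 <= tau2")
        if not (0 <= self.frac_fast <= 1):
            raise ValueError("frac_fast must be in [0, 1]")

    def v_th(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return self.v_read * self.r_load / (self.r_load + 1.0 / g)

    def set_level(self, g_pre: float) -> float:
        """Post-SET conductance, increasing in the pre-SET conductance
        (a weaker HRS yields a stronger SET state)."""
        g_lo = self.set_floor_frac * self.g_max
        mid = 0.5 * (self.g_min + self.g_max)
        k = (self.g_max - self.g_min) / self.coupling_sharpness
        s = 1.0 / (1.0 + math.exp(-(g_pre - mid) / k))
        return g_lo + (self.g_max - g_lo) * s


def modulator_behavioral_sim(
    spike_times: np.ndarray,
    params: ModulatorParams = ModulatorParams(),
    t_end: Optional[float] = None,
    delta_t: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-driven behavioral simulation of the threshold modulator.

    ``spike_times`` (ms, sorted ascending) trigger SET events; between
    spikes the conductance relaxes double-exponentially toward ``g_min``
    and the threshold saturates at the floor in prolonged absence of
    spikes.  Returns ``(t, v_th)`` sampled every ``delta_t`` ms.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and np.any(np.diff(spike_times) < 0):
        raise ValueError("spike times must be sorted ascending")
    if t_end is None:
        t_end = (spike_times[-1] + 5.0 * params.tau2) if spike_times.size else 100.0
    t = np.arange(0.0, t_end + 1e-9, delta_t)
    g = np.full_like(t, params.g_min)

    g_peak = params.g_min
    t_last = -np.inf
    idx = 0
    for i, ti in enumerate(t):
        while idx < spike_times.size and spike_times[idx] <= ti:
            ts = spike_times[idx]
            dt_ = ts - t_last
            if np.isfinite(dt_):
                decay = params.frac_fast * math.exp(-dt_ / params.tau1) + (
                    1 - params.frac_fast
                ) * math.exp(-dt_ / params.tau2)
                g_pre = params.g_min + (g_peak - params.g_min) * decay
            else:
                g_pre = params.g_min
            g_peak = params.set_level(g_pre)
            t_last = ts
            idx += 1
        if np.isfinite(t_last):
            dt_ = ti - t_last
            decay = params.frac_fast * math.exp(-dt_ / params.tau1) + (
                1 - params.frac_fast
            ) * math.exp(-dt_ / params.tau2)
            g[i] = params.g_min + (g_peak - params.g_min) * decay
    return t, params.v_th(g)


# --- synthetic traces and plain-text IO -------------------------------------


def synthetic_ltd_trace(
    tau_a1: float = 30.0,
    tau_a2: float = 300.0,
    beta1: float = 0.5,
    beta2: float = 0.5,
    n_pulses: int = 60,
    pulse_duration: float = 20.0,
    g_min: float = 1e-5,
    g_max: float = 1e-3,
    noise: float = 0.0,
    seed: int = 0,
) -> ConductanceTrace:
    """Synthetic depression curve with a known double-exponential shape.

    Stands in for lab pulse-characterization data: conductance falls from
    ``g_max`` toward ``g_min`` following the two time constants (ms), with
    optional multiplicative Gaussian noise.
    """
    t = np.arange(n_pulses) * pulse_duration
    shape = double_exponential(t, tau_a1, tau_a2, beta1, beta2)
    shape = shape / shape[0]
    g = g_min + (g_max - g_min) * shape
    if noise > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise * rng.standard_normal(g.size))
        g = np.clip(g, g_min * 1e-3, None)
    return ConductanceTrace(x=np.arange(n_pulses), g=g, direction="LTD")


def synthetic_ltp_trace(
    mirror_of: Optional[ConductanceTrace] = None,
    perturbation: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> ConductanceTrace:
    """Synthetic potentiation curve.

    With ``mirror_of`` given, returns the exact mirror of that LTD trace
    (so the pair is fully symmetric, ANL = 0) optionally perturbed
    multiplicatively; otherwise builds a rising double exponential from
    the same keyword arguments as :func:`synthetic_ltd_trace`.
    """
    if mirror_of is not None:
        g = mirror_of.g[::-1].copy()
        if perturbation > 0:
            rng = np.random.default_rng(seed)
            g = g * (1.0 + perturbation * rng.standard_normal(g.size))
            g = np.clip(g, g.min() * 1e-3, None)
        return ConductanceTrace(x=mirror_of.x.copy(), g=g, direction="LTP")
    ltd = synthetic_ltd_trace(seed=seed, **kwargs)
    return ConductanceTrace(x=ltd.x.copy(), g=ltd.g[::-1].copy(), direction="LTP")


def write_trace_csv(trace: ConductanceTrace, path) -> None:
    """Two-column CSV with a one-line header."""
    with open(path, "w") as f:
        f.write("x,g\n")
        for xi, gi in zip(trace.x, trace.g):
            f.write(f"{xi},{gi}\n")


def read_trace_csv(path, direction: str = "LTD") -> ConductanceTrace:
    arr = np.genfromtxt(path, delimiter=",", skip_header=1)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a two-column CSV (x, g)")
    return ConductanceTrace(x=arr[:, 0], g=arr[:, 1], direction=direction)
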