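"""Discrete-time spiking-neuron primitives: LIF, ALIF, and DEXAT.

All three models share a leaky-integrator membrane simulated with a time
step ``delta_t`` (ms).  The adaptive variants raise the firing threshold on
every output spike and let it relax back to a baseline ``b_j0``:

* ALIF — a single low-pass filter of the spike train,
  ``b(t+dt) = rho * b(t) + (1 - rho) * z(t)`` with ``rho = exp(-dt/tau_a)``
  and threshold ``B(t) = b_j0 + beta * b(t)``.
* DEXAT — two such filters with a fast (``tau_a1``) and a slow (``tau_a2``)
  time constant updated independently from the same spike train, summed as
  ``B(t) = b_j0 + beta1 * b1(t) + beta2 * b2(t)``.

The spike variable ``z`` carries the value ``1/delta_t`` at a spike event
and 0 otherwise, so for ``delta_t << tau_a`` one spike raises the threshold
by approximately ``beta / tau_a`` (units of ``b_j0``).  Thresholds and
membrane potentials are dimensionless here; the :mod:`dexat.device` module
maps device volts onto this scale via min-max normalization.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "LIFParams",
    "ALIFParams",
    "DEXATParams",
    "NeuronState",
    "alif_threshold_step",
    "dexat_threshold_step",
    "membrane_step",
    "alif_from_spike_jump",
    "dexat_from_spike_jump",
    "params_to_yaml",
    "params_from_yaml",
]


@dataclass(frozen=True)
class LIFParams:
    """Membrane constants of a leaky integrate-and-fire neuron.

    Parameters
    ----------
    delta_t : float
        Simulation step (ms).
    tau_m : float
        Membrane time constant (ms); leak factor ``alpha = exp(-dt/tau_m)``.
    v_th_base : float
        Fixed firing threshold (dimensionless).
    t_refractory : float
        Absolute refractory period (ms), >= 0; rounded to whole steps.
    """

    delta_t: float = 1.0
    tau_m: float = 20.0
    v_th_base: float = 1.0
    t_refractory: float = 2.0

    def __post_init__(self) -> None:
        if not (self.delta_t > 0):
            raise ValueError(f"delta_t must be > 0, got {self.delta_t}")
        if not (self.tau_m > 0):
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if not (self.v_th_base > 0):
            raise ValueError(f"v_th_base must be > 0, got {self.v_th_base}")
        if self.t_refractory < 0:
            raise ValueError("t_refractory must be >= 0")

    @property
    def alpha(self) -> float:
        """Per-step membrane leak factor ``exp(-delta_t/tau_m)``."""
        return math.exp(-self.delta_t / self.tau_m)

    @property
    def refrac_steps(self) -> int:
        return int(round(self.t_refractory / self.delta_t))


@dataclass(frozen=True)
class ALIFParams:
    """Adaptive-threshold neuron with a single decay time constant."""

    lif: LIFParams
    tau_a: float
    beta: float
    b_j0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_a > 0):
            raise ValueError(f"tau_a must be > 0, got {self.tau_a}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (self.b_j0 > 0):
            raise ValueError("b_j0 must be > 0")

    @property
    def rho(self) -> float:
        """Threshold decay factor ``exp(-delta_t/tau_a)``, in (0, 1)."""
        return math.exp(-self.lif.delta_t / self.tau_a)


@dataclass(frozen=True)
class DEXATParams:
    """Double-exponential adaptive-threshold neuron.

    ``tau_a1 <= tau_a2`` are the fast and slow adaptation time constants;
    ``beta1``/``beta2`` scale the two threshold components.
    """

    lif: LIFParams
    tau_a1: float = 30.0
    tau_a2: float = 300.0
    beta1: float = 3.0
    beta2: float = 120.0
    b_j0: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_a1 <= self.tau_a2):
            raise ValueError(
                f"need 0 < tau_a1 <= tau_a2, got ({self.tau_a1}, {self.tau_a2})"
            )
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("beta1, beta2 must be >= 0")
        if not (self.b_j0 > 0):
            raise ValueError("b_j0 must be > 0")

    @property
    def rho1(self) -> float:
        return math.exp(-self.lif.delta_t / self.tau_a1)

    @property
    def rho2(self) -> float:
        return math.exp(-self.lif.delta_t / self.tau_a2)


AdaptiveParams = Union[ALIFParams, DEXATParams]


def alif_from_spike_jump(
    lif: LIFParams, tau_a: float, jump: float = 1.0, b_j0: float = 1.0
) -> ALIFParams:
    """Build ALIF params with an exact per-spike threshold jump.

    ``jump`` is the threshold increment caused by one spike, in units of
    ``b_j0``.  Solves ``beta * (1 - rho) / delta_t = jump * b_j0``.
    """
    rho = math.exp(-lif.delta_t / tau_a)
    beta = jump * b_j0 * lif.delta_t / (1.0 - rho)
    return ALIFParams(lif=lif, tau_a=tau_a, beta=beta, b_j0=b_j0)


def dexat_from_spike_jump(
    lif: LIFParams,
    tau_a1: float = 30.0,
    tau_a2: float = 300.0,
    jump1: float = 0.1,
    jump2: float = 0.4,
    b_j0: float = 1.0,
) -> DEXATParams:
    """DEXAT params from the per-spike jump of each threshold component."""
    rho1 = math.exp(-lif.delta_t / tau_a1)
    rho2 = math.exp(-lif.delta_t / tau_a2)
    return DEXATParams(
        lif=lif,
        tau_a1=tau_a1,
        tau_a2=tau_a2,
        beta1=jump1 * b_j0 * lif.delta_t / (1.0 - rho1),
        beta2=jump2 * b_j0 * lif.delta_t / (1.0 - rho2),
        b_j0=b_j0,
    )


@dataclass(frozen=True)
class NeuronState:
    """Evolving per-neuron state.

    ``z`` is the last output spike indicator in units of ``1/delta_t``
    (i.e. ``z = 1/delta_t`` at a spike, 0 otherwise).  ``b1``/``b2`` are the
    threshold deviation components (``b2`` unused for ALIF, both for LIF).
    """

    v_mem: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    refrac_count: int = 0
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("threshold components b1, b2 must be >= 0")
        if self.refrac_count < 0:
            raise ValueError("refrac_count must be >= 0")


def _require_finite(state: NeuronState) -> None:
    for name in ("v_mem", "b1", "b2", "z"):
        val = getattr(state, name)
        if not math.isfinite(val):
            raise ValueError(f"non-finite neuron state: {name} = {val}")


def alif_threshold_step(
    state: NeuronState, p: ALIFParams
) -> tuple[float, NeuronState]:
    """One threshold update for an ALIF neuron.

    Returns the adaptive threshold ``B`` for the current step and the state
    with ``b1`` advanced using the last spike ``state.z``.
    """
    _require_finite(state)
    b1 = p.rho * state.b1 + (1.0 - p.rho) * state.z
    B = p.b_j0 + p.beta * b1
    return B, replace(state, b1=b1)


def dexat_threshold_step(
    state: NeuronState, p: DEXATParams
) -> tuple[float, NeuronState]:
    """One threshold update for a DEXAT neuron (both components, same z)."""
    _require_finite(state)
    b1 = p.rho1 * state.b1 + (1.0 - p.rho1) * state.z
    b2 = p.rho2 * state.b2 + (1.0 - p.rho2) * state.z
    B = p.b_j0 + p.beta1 * b1 + p.beta2 * b2
    return B, replace(state, b1=b1, b2=b2)


def membrane_step(
    state: NeuronState, current_in: float, p: LIFParams, B: float
) -> NeuronState:
    """Leaky-integrator membrane update with reset-by-subtraction.

    ``v' = alpha * v + current_in``; the neuron fires (``z = 1/delta_t``)
    when ``v' >= B`` outside the refractory period, upon which ``B`` is
    subtracted from the membrane and the refractory counter is armed.
    """
    _require_finite(state)
    if not math.isfinite(current_in):
        raise ValueError(f"non-finite input current: {current_in}")
    if not (B > 0):
        raise ValueError(f"threshold must be > 0, got {B}")
    v = p.alpha * state.v_mem + current_in
    if v >= B and state.refrac_count == 0:
        return replace(
            state,
            v_mem=v - B,
            z=1.0 / p.delta_t,
            refrac_count=p.refrac_steps,
        )
    return replace(
        state, v_mem=v, z=0.0, refrac_count=max(state.refrac_count - 1, 0)
    )


# --- plain-text (YAML) round-trip of parameter sets -------------------------

_KINDS = {"lif": LIFParams, "alif": ALIFParams, "dexat": DEXATParams}


def _params_to_dict(p) -> dict:
    if isinstance(p, LIFParams):
        return {"kind": "lif", **asdict(p)}
    if isinstance(p, ALIFParams):
        d = asdict(p)
        d.pop("lif")
        return {"kind": "alif", "lif": asdict(p.lif), **d}
    if isinstance(p, DEXATParams):
        d = asdict(p)
        d.pop("lif")
        return {"kind": "dexat", "lif": asdict(p.lif), **d}
    raise TypeError(f"unsupported parameter type: {type(p)!r}")


def params_to_yaml(p, path) -> None:
    """Serialize a parameter set to a key-value YAML file."""
    Path(path).write_text(yaml.safe_dump(_params_to_dict(p), sort_keys=False))


def params_from_yaml(path):
    """Load a parameter set written by :func:`params_to_yaml`."""
    d = yaml.safe_load(Path(path).read_text())
    kind = d.pop("kind")
    if kind not in _KINDS:
        raise ValueError(f"unknown parameter kind {kind!r}")
    if kind == "lif":
        return LIFParams(**d)
    lif = LIFParams(**d.pop("lif"))
    return _KINDS[kind](lif=lif, **d)
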