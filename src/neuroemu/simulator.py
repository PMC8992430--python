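"""Deterministic single-compartment spiking-neuron stand-in.

Adaptive-exponential integrate-and-fire dynamics integrated by fixed-step
explicit Euler:

    C dV/dt = -g_L (V - E_L) + g_L * dT * exp((V - V_T)/dT) - w + gain * I(t)
    tau_w dw/dt = a (V - E_L) - w

A spike is registered when V reaches the cutoff V_peak; the voltage is
recorded at V_peak for one sample, then reset to V_reset, w is incremented
by b, and the membrane is clamped at V_reset for the refractory period
(adaptation keeps evolving). The model is cheap (milliseconds per trace),
fully deterministic, and produces genuine spike-shape / inter-spike features
with natural structural missingness, which is exactly what an emulation
study needs from its target.

Only the named mechanistic parameters are ever read; dimensions tagged
``inert`` in the :class:`~neuroemu.space.ParameterSpace` cannot influence
the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import ParameterSpace, default_parameter_space

__all__ = [
    "StimulusProtocol",
    "VoltageTrace",
    "IVF_3",
    "IDREST_7",
    "DEFAULT_PROTOCOLS",
    "simulate",
    "simulate_batch",
]

_EXP_CAP = 30.0  # cap on the exponential argument; avoids overflow mid-spike


@dataclass(frozen=True)
class StimulusProtocol:
    """A square current-injection protocol (times in ms, current in nA)."""

    name: str
    amplitude: float
    onset: float
    duration: float
    total_time: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset + self.duration > self.total_time:
            raise ValueError("onset + duration must not exceed total_time")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


#: Subthreshold protocol: 0.04 nA for 1000 ms.
IVF_3 = StimulusProtocol("IVf_3", amplitude=0.04, onset=250.0, duration=1000.0, total_time=1500.0)
#: Suprathreshold protocol: 0.27 nA for 2000 ms.
IDREST_7 = StimulusProtocol("IDRest_7", amplitude=0.27, onset=250.0, duration=2000.0, total_time=2500.0)

DEFAULT_PROTOCOLS: tuple[StimulusProtocol, ...] = (IVF_3, IDREST_7)


@dataclass
class VoltageTrace:
    """A sampled membrane-potential trace plus detected spike times."""

    dt: float
    voltage: np.ndarray  # mV, samples at t = 0, dt, 2*dt, ...
    spike_times: np.ndarray  # ms, strictly increasing

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage trace contains non-finite samples")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    @property
    def total_time(self) -> float:
        return (self.voltage.size - 1) * self.dt


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


def _unpack(space: ParameterSpace, P: np.ndarray) -> dict[str, np.ndarray]:
    return {name: P[:, space.index(name)] for name in (
        "cm", "g_leak", "e_leak", "v_thresh", "delta_t", "a_adapt",
        "b_adapt", "tau_w", "v_reset", "v_peak", "t_ref", "gain")}


def simulate_batch(
    P: np.ndarray,
    protocol: StimulusProtocol,
    dt: float = 0.1,
    space: ParameterSpace | None = None,
) -> list[VoltageTrace]:
    """Integrate a whole population at once (vectorized Euler).

    Rows of ``P`` are individuals in the coordinate frame of ``space``.
    Returns one :class:`VoltageTrace` per row, in row order.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    space = space or default_parameter_space(np.atleast_2d(P).shape[1])
    P = space.validate(P)
    n = P.shape[0]
    p = _unpack(space, P)

    n_steps = int(round(protocol.total_time / dt))
    out = np.empty((n, n_steps + 1))
    spikes: list[list[float]] = [[] for _ in range(n)]

    V = p["e_leak"].copy()
    w = np.zeros(n)
    refrac_until = np.full(n, -np.inf)
    just_spiked = np.zeros(n, dtype=bool)
    out[:, 0] = V

    cm, g_leak, e_leak = p["cm"], p["g_leak"], p["e_leak"]
    v_thresh, delta_t = p["v_thresh"], p["delta_t"]
    a_adapt, b_adapt, tau_w = p["a_adapt"], p["b_adapt"], p["tau_w"]
    v_reset, v_peak, t_ref, gain = p["v_reset"], p["v_peak"], p["t_ref"], p["gain"]

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt
        # reset after the sample recorded at V_peak
        if just_spiked.any():
            V = np.where(just_spiked, v_reset, V)
            w = np.where(just_spiked, w + b_adapt, w)
            refrac_until = np.where(just_spiked, t_prev + t_ref, refrac_until)
            just_spiked = np.zeros(n, dtype=bool)

        I_ext = gain * protocol.amplitude if protocol.onset <= t_prev < protocol.offset else 0.0
        exp_term = delta_t * np.exp(np.minimum((V - v_thresh) / delta_t, _EXP_CAP))
        dV = (-g_leak * (V - e_leak) + g_leak * exp_term - w + I_ext) / cm
        dw = (a_adapt * (V - e_leak) - w) / tau_w

        in_refrac = t_prev < refrac_until
        V = np.where(in_refrac, v_reset, V + dt * dV)
        w = w + dt * dw

        spiking = (~in_refrac) & (V >= v_peak)
        if spiking.any():
            t_spk = step * dt
            for i in np.flatnonzero(spiking):
                spikes[i].append(t_spk)
            V = np.where(spiking, v_peak, V)
            just_spiked = spiking

        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise IntegrationError(
                f"non-finite membrane potential for row {bad} at t={step * dt:.1f} ms"
            )
        out[:, step] = V

    return [
        VoltageTrace(dt=dt, voltage=out[i], spike_times=np.array(spikes[i]))
        for i in range(n)
    ]


def simulate(
    params: np.ndarray,
    protocol: StimulusProtocol,
    dt: float = 0.1,
    space: ParameterSpace | None = None,
) -> VoltageTrace:
    """Simulate a single individual; deterministic (same inputs, same trace)."""
    return simulate_batch(np.atleast_2d(params), protocol, dt=dt, space=space)[0]
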