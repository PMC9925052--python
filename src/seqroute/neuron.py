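"""Single-neuron AdEx dynamics and calibration protocols.

The membrane potential follows

    C dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T)
              - g_e (V - E_e) - g_i (V - E_i) - w + I_e
    tau_w dw/dt = a (V - E_L) - w

with exponential-decay conductance synapses. When V crosses the detection
threshold a spike is recorded, V is reset, w is incremented by b, and V is
clamped at the reset potential for the refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _kernels
from .params import DEFAULT_PARAMS, NeuronParameters

__all__ = [
    "SynapticEvent",
    "VoltageTrace",
    "IntegrationError",
    "integrate_neuron",
    "rheobase",
    "holding_current",
    "psp_amplitude",
    "adaptation_index",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class SynapticEvent:
    """A single conductance jump: ``peak_conductance`` nS at ``time`` ms."""

    time: float
    peak_conductance: float
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if self.peak_conductance <= 0:
            raise ValueError("peak_conductance must be positive")
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")


@dataclass
class VoltageTrace:
    """Sampled membrane potential with detected spike times."""

    times: np.ndarray
    V: np.ndarray
    spike_times: list = field(default_factory=list)
    w: np.ndarray | None = None  # adaptation current trace (pA)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def integrate_neuron(
    params: NeuronParameters = DEFAULT_PARAMS,
    drive: float | np.ndarray = 0.0,
    events: list[SynapticEvent] | None = None,
    duration: float = 1000.0,
    dt: float = 0.1,
    V0: float | None = None,
    w0: float = 0.0,
) -> VoltageTrace:
    """Integrate one neuron for ``duration`` ms at fixed step ``dt``.

    ``drive`` is either a constant current (pA) or a per-step
    piecewise-constant current series of length ``ceil(duration/dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / dt))
    drive_arr = np.broadcast_to(np.asarray(drive, dtype=float), (n_steps,)) \
        if np.ndim(drive) == 0 else np.asarray(drive, dtype=float)
    if drive_arr.shape != (n_steps,):
        raise ValueError("drive series length must equal the number of steps")
    events = sorted(events or [], key=lambda e: e.time)
    for e in events:
        if e.time > duration:
            raise ValueError("event time outside [0, duration]")
    ev_step = np.array([int(round(e.time / dt)) for e in events], dtype=np.int64)
    ev_g = np.array([e.peak_conductance for e in events], dtype=float)
    ev_inh = np.array([e.sign == "inhibitory" for e in events], dtype=np.uint8)
    vs, ws, spikes, fail = _kernels.integrate_single(
        *params.as_tuple(),
        np.ascontiguousarray(drive_arr), ev_step, ev_g, ev_inh,
        n_steps, dt,
        params.E_L if V0 is None else float(V0), float(w0), True,
    )
    if fail >= 0:
        raise IntegrationError(f"non-finite state at step {fail} (t={fail * dt:.3f} ms)")
    times = np.arange(n_steps + 1) * dt
    return VoltageTrace(times=times, V=vs, spike_times=list(spikes), w=ws)


def rheobase(
    params: NeuronParameters = DEFAULT_PARAMS,
    trial_duration: float = 1000.0,
    resolution: float = 1.0,
    upper: float = 300.0,
    dt: float = 0.1,
) -> float:
    """Minimal constant current (pA) eliciting >=1 spike within a trial.

    Bisection bracketed by a coarse scan in steps of ``upper / 30``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")

    def spikes(current: float) -> int:
        return len(integrate_neuron(params, current, None, trial_duration, dt).spike_times)

    lo, hi = 0.0, None
    step = upper / 30.0
    current = step
    while current <= upper + 1e-9:
        if spikes(current) > 0:
            hi = current
            break
        lo = current
        current += step
    if hi is None:
        raise ValueError(f"no spike up to the search bound {upper} pA")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def holding_current(params: NeuronParameters, holding_potential: float) -> float:
    """Constant current holding the coupled (V, w) system at a potential.

    Solves the steady state w = a (V - E_L) and the voltage equation for I.
    """
    V = holding_potential
    arg = min((V - params.V_T) / params.Delta_T,
              (params.V_detect - params.V_T) / params.Delta_T)
    w_ss = params.a * (V - params.E_L)
    return (params.g_L * (V - params.E_L)
            - params.g_L * params.Delta_T * np.exp(arg) + w_ss)


def psp_amplitude(
    params: NeuronParameters = DEFAULT_PARAMS,
    peak_conductance: float = 0.0,
    sign: str = "excitatory",
    holding_potential: float | None = None,
    settle: float = 300.0,
    window: float = 200.0,
    dt: float = 0.1,
    return_flag: bool = False,
):
    """Signed peak deflection (mV) from holding after one synaptic event.

    The neuron is held at ``holding_potential`` (default: rest) by a constant
    current solved from the (V, w) steady state, allowed to equilibrate for
    ``settle`` ms, then receives a single event; the extremum of
    V - holding within ``window`` ms is returned.  If a spike occurs the
    pre-spike extremum is returned and flagged.
    """
    if peak_conductance < 0:
        raise ValueError("peak_conductance must be >= 0")
    Vh = params.E_L if holding_potential is None else float(holding_potential)
    if Vh >= params.V_detect:
        raise ValueError("holding potential must lie below the detection threshold")
    if peak_conductance == 0.0:
        return (0.0, False) if return_flag else 0.0
    I_hold = holding_current(params, Vh)
    trace = integrate_neuron(
        params, I_hold,
        [SynapticEvent(settle, peak_conductance, sign)],
        duration=settle + window, dt=dt,
        V0=Vh, w0=params.a * (Vh - params.E_L),
    )
    i_on = int(round(settle / dt))
    spiked = any(t > settle for t in trace.spike_times)
    if spiked:
        first = min(t for t in trace.spike_times if t > settle)
        seg = trace.V[i_on:int(round(first / dt))]
    else:
        seg = trace.V[i_on:]
    defl = seg - Vh
    # extremum in the direction of the event: depolarizing peak for
    # excitatory events, hyperpolarizing trough for inhibitory ones
    peak = defl.max() if sign == "excitatory" else defl.min()
    return (float(peak), spiked) if return_flag else float(peak)


def adaptation_index(spike_times, orientation: str = "last_over_first") -> float:
    """Ratio of the last to the first inter-spike interval of a train.

    ``orientation='first_over_last'`` returns the reciprocal, for
    comparability with conventions where adapting cells score < 1.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise ValueError("need at least 3 spikes to compute an adaptation index")
    isi_first = spike_times[1] - spike_times[0]
    isi_last = spike_times[-1] - spike_times[-2]
    if orientation == "last_over_first":
        return float(isi_last / isi_first)
    if orientation == "first_over_last":
        return float(isi_first / isi_last)
    raise ValueError("orientation must be 'last_over_first' or 'first_over_last'")
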