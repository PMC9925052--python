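"""Synthetic-data generators emulating the experimental inputs.

Generates (i) current-clamp voltage traces from a known passive membrane
for capacitance/leak recovery, (ii) EPSP-amplitude sets implied by the
truncated-lognormal conductance distribution, (iii) density-preserving
scaled network fixtures, and (iv) trial-structured Poisson rasters with
optional planted followers for null calibration.  Every generator is
seed-deterministic and records its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (DEFAULT_OUT_DEGREE_TARGETS, DEFAULT_SIGMAS, NetworkModel,
                      WeightDistribution, build_network, calibrate_profile)
from .neuron import VoltageTrace, psp_amplitude
from .params import DEFAULT_PARAMS, NeuronParameters
from .simulation import SpikeRecord, TriggerProtocol

__all__ = [
    "FixtureSpec",
    "make_patch_traces",
    "make_amplitude_set",
    "make_fixture_network",
    "make_poisson_record",
    "PlantedFollower",
]


def make_patch_traces(
    g_L: float = 4.2,
    C: float = 239.8,
    currents=(-50.0, 50.0, 100.0),
    noise_sd: float = 0.5,
    E_L: float = -70.6,
    t_on: float = 200.0,
    duration: float = 1200.0,
    dt: float = 0.1,
    seed: int = 0,
):
    """Passive current-step traces plus ground truth.

    Returns (traces, truth) where each trace is the closed-form passive
    response V(t) = E_L + (I/g_L)(1 - exp(-(t - t_on) g_L / C)) with
    additive Gaussian noise.  Raises if a current would drive the passive
    steady state above the spike-detection threshold.
    """
    currents = list(currents)
    if not currents:
        raise ValueError("currents must be non-empty")
    rng = np.random.default_rng(seed)
    tau = C / g_L
    times = np.arange(0.0, duration + dt, dt)
    traces = []
    for current in currents:
        if E_L + current / g_L >= DEFAULT_PARAMS.V_detect:
            raise ValueError(
                f"current {current} pA drives the passive membrane above "
                "the spike-detection threshold; passive trace undefined")
        V = np.full_like(times, E_L)
        on = times >= t_on
        V[on] = E_L + (current / g_L) * (1.0 - np.exp(-(times[on] - t_on) / tau))
        V = V + rng.normal(0.0, noise_sd, V.shape)
        traces.append(VoltageTrace(times=times.copy(), V=V, spike_times=[]))
    truth = {"g_L": g_L, "C": C, "E_L": E_L, "t_on": t_on,
             "currents": currents, "noise_sd": noise_sd}
    return traces, truth


def make_amplitude_set(
    n: int = 122,
    dist: WeightDistribution | None = None,
    params: NeuronParameters = DEFAULT_PARAMS,
    seed: int = 0,
    grid_points: int = 60,
):
    """EPSP amplitudes (mV) implied by truncated-lognormal conductances.

    Conductances are drawn from ``dist`` and mapped through the model's
    EPSP amplitude at rest via a monotone interpolation grid.  Returns
    (amplitudes, conductances).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    dist = dist or WeightDistribution()
    rng = np.random.default_rng(seed)
    conductances = dist.sample(n, "E", rng)
    grid_g = np.linspace(0.0, dist.truncation_max, grid_points)
    grid_amp = np.array([psp_amplitude(params, g) if g > 0 else 0.0
                         for g in grid_g])
    amplitudes = np.interp(conductances, grid_g, grid_amp)
    return amplitudes, conductances


@dataclass(frozen=True)
class FixtureSpec:
    """Density-preserving scaled-down network specification.

    The side shrinks with sqrt(n / n_full) so neuron density matches the
    full-size model, and out-degree targets are kept at their full-size
    values, which preserves per-neuron in-degrees and the expected count
    of about two strong outgoing E->E connections per neuron.
    """

    n_neurons: int = 10_000
    n_full: int = 100_000
    side_full: float = 2000.0
    fraction_excitatory: float = 0.93
    targets: dict = field(default_factory=lambda: dict(DEFAULT_OUT_DEGREE_TARGETS))
    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    seed: int = 0

    @property
    def side(self) -> float:
        return self.side_full * np.sqrt(self.n_neurons / self.n_full)


def make_fixture_network(spec: FixtureSpec | None = None, **kwargs) -> NetworkModel:
    """Build a scaled network fixture from a :class:`FixtureSpec`."""
    spec = spec or FixtureSpec(**kwargs)
    profile = calibrate_profile(spec.n_neurons, spec.side,
                                spec.fraction_excitatory,
                                sigmas=spec.sigmas, targets=spec.targets)
    return build_network(n_neurons=spec.n_neurons, side=spec.side,
                         fraction_excitatory=spec.fraction_excitatory,
                         profile=profile, seed=spec.seed)


@dataclass(frozen=True)
class PlantedFollower:
    """Deterministic responder injected into a Poisson raster."""

    neuron: int
    response_probability: float = 1.0
    latency: float = 20.0       # ms after the trigger
    jitter: float = 2.0         # ms (sd of Gaussian latency jitter)


def make_poisson_record(
    n_neurons: int,
    rate: float,
    protocol: TriggerProtocol | None = None,
    planted: list[PlantedFollower] | None = None,
    fraction_excitatory: float = 0.93,
    seed: int = 0,
) -> SpikeRecord:
    """Trial-structured homogeneous Poisson raster at ``rate`` spk/s.

    Optionally adds planted followers that respond once per trial with a
    given probability at a jittered latency.  Used as the ground-truth
    input for null-calibration and power experiments.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    protocol = protocol or TriggerProtocol()
    rng = np.random.default_rng(seed)
    span = protocol.before_window + protocol.after_window  # ms per trial
    lam = rate * span / 1000.0  # expected spikes per neuron per trial
    trials, neurons, times = [], [], []
    if rate > 0:
        counts = rng.poisson(lam, size=(protocol.n_trials, n_neurons))
        tr_idx, n_idx = np.nonzero(counts)
        reps = counts[tr_idx, n_idx]
        tr_rep = np.repeat(tr_idx, reps)
        n_rep = np.repeat(n_idx, reps)
        t_rep = rng.uniform(-protocol.before_window, protocol.after_window,
                            tr_rep.size)
        trials.append(tr_rep)
        neurons.append(n_rep)
        times.append(t_rep)
    for pf in planted or []:
        hit = rng.random(protocol.n_trials) < pf.response_probability
        tr = np.nonzero(hit)[0]
        t = pf.latency + rng.normal(0.0, pf.jitter, tr.size)
        t = np.clip(t, 0.1, protocol.after_window - 0.1)
        trials.append(tr)
        neurons.append(np.full(tr.size, pf.neuron))
        times.append(t)
    if trials:
        trial = np.concatenate(trials).astype(np.int32)
        neuron = np.concatenate(neurons).astype(np.int32)
        time = np.concatenate(times)
    else:
        trial = np.empty(0, dtype=np.int32)
        neuron = np.empty(0, dtype=np.int32)
        time = np.empty(0)
    order = np.lexsort((time, trial))
    n_exc = int(round(n_neurons * fraction_excitatory))
    is_inh = np.zeros(n_neurons, dtype=np.uint8)
    is_inh[n_exc:] = 1
    return SpikeRecord(trial=trial[order], neuron=neuron[order],
                       time=time[order], n_neurons=n_neurons, is_inh=is_inh,
                       protocol=protocol, seed=seed)
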