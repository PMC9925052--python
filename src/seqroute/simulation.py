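"""Clock-driven network simulation with the single-spike trigger protocol.

Every neuron receives an independent background current re-sampled every
millisecond from N(mu_in, sigma_in) and held constant in between.  A
simulation starts with a kick-start volley (forced spikes in 500 random
excitatory neurons during the first 100 ms); the first second is
discarded.  Afterwards the trigger neuron(s) are forced to spike every
400 ms for ``n_trials`` trials; each trial owns a 100 ms window before
and a 300 ms window after its trigger spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .network import NetworkModel
from .params import DEFAULT_PARAMS, NeuronParameters

__all__ = [
    "BackgroundNoise",
    "TriggerProtocol",
    "ExternalInput",
    "SpikeRecord",
    "SimulationError",
    "run_protocol",
    "mean_firing_rate",
    "instantaneous_rate",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackgroundNoise:
    """Piecewise-constant Gaussian background current, per neuron."""

    mu_in: float = 80.0       # pA
    sigma_in: float = 50.0    # pA
    refresh_interval: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.sigma_in < 0:
            raise ValueError("sigma_in must be >= 0")
        if self.refresh_interval <= 0:
            raise ValueError("refresh_interval must be positive")


@dataclass(frozen=True)
class TriggerProtocol:
    """Single-spike trigger protocol and its trial structure."""

    trigger_ids: tuple = ()
    n_trials: int = 100
    inter_trial: float = 400.0      # ms
    kickstart_count: int = 500
    kickstart_window: float = 100.0  # ms
    discard: float = 1000.0          # ms
    before_window: float = 100.0     # ms
    after_window: float = 300.0      # ms

    def __post_init__(self) -> None:
        if self.before_window + self.after_window > self.inter_trial:
            raise ValueError("before_window + after_window must fit in inter_trial")
        object.__setattr__(self, "trigger_ids", tuple(int(i) for i in self.trigger_ids))

    @property
    def duration(self) -> float:
        """Total simulated time (ms)."""
        return (self.discard + self.before_window
                + (self.n_trials - 1) * self.inter_trial + self.after_window)

    def trigger_times(self) -> np.ndarray:
        """Absolute trigger (trial-onset) times (ms)."""
        first = self.discard + self.before_window
        return first + self.inter_trial * np.arange(self.n_trials)

    def with_triggers(self, ids) -> "TriggerProtocol":
        return replace(self, trigger_ids=tuple(int(i) for i in ids))


@dataclass(frozen=True)
class ExternalInput:
    """One extra conductance event per trial, delivered to a single neuron
    at ``delta_t`` ms relative to the trigger spike."""

    target_id: int
    peak_conductance: float   # nS
    sign: str = "excitatory"  # or "inhibitory"
    delta_t: float = 0.0      # ms

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be >= 0")


@dataclass
class SpikeRecord:
    """Trial-structured raster: (trial, neuron, time-from-trigger)."""

    trial: np.ndarray      # int32
    neuron: np.ndarray     # int32
    time: np.ndarray       # float64, ms relative to the trial's trigger spike
    n_neurons: int
    is_inh: np.ndarray
    protocol: TriggerProtocol
    noise: BackgroundNoise | None = None
    network_hash: str | None = None
    seed: int | None = None
    runaway_steps: int = 0

    @property
    def n_spikes(self) -> int:
        return int(self.trial.size)

    def spikes_in_trial(self, trial: int):
        m = self.trial == trial
        return self.neuron[m], self.time[m]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("trial", data=self.trial)
            f.create_dataset("neuron", data=self.neuron)
            f.create_dataset("time", data=self.time)
            f.create_dataset("is_inh", data=self.is_inh)
            f.attrs["n_neurons"] = self.n_neurons
            f.attrs["runaway_steps"] = self.runaway_steps
            if self.network_hash:
                f.attrs["network_hash"] = self.network_hash
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            for key, obj in (("protocol", self.protocol), ("noise", self.noise)):
                if obj is not None:
                    for name, val in vars(obj).items():
                        f.attrs[f"{key}.{name}"] = val

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRecord":
        import h5py

        with h5py.File(path, "r") as f:
            proto_kw = {}
            noise_kw = {}
            for key, val in f.attrs.items():
                if key.startswith("protocol."):
                    name = key.split(".", 1)[1]
                    proto_kw[name] = tuple(val) if name == "trigger_ids" else val.item()
                elif key.startswith("noise."):
                    noise_kw[key.split(".", 1)[1]] = val.item()
            return cls(
                trial=f["trial"][:], neuron=f["neuron"][:], time=f["time"][:],
                n_neurons=int(f.attrs["n_neurons"]), is_inh=f["is_inh"][:],
                protocol=TriggerProtocol(**proto_kw),
                noise=BackgroundNoise(**noise_kw) if noise_kw else None,
                network_hash=f.attrs.get("network_hash"),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                runaway_steps=int(f.attrs.get("runaway_steps", 0)),
            )

    def export_text(self, path: str | Path) -> None:
        """One spike per line: trial<TAB>neuron<TAB>ms."""
        with open(path, "w") as f:
            for tr, nid, t in zip(self.trial, self.neuron, self.time):
                f.write(f"{tr}\t{nid}\t{t:.4f}\n")


def run_protocol(
    net: NetworkModel,
    noise: BackgroundNoise,
    protocol: TriggerProtocol,
    externals: list[ExternalInput] | None = None,
    seed: int = 0,
    params: NeuronParameters = DEFAULT_PARAMS,
    dt: float = 0.1,
    runaway_frac: float = 0.10,
) -> SpikeRecord:
    """Simulate the trigger protocol on a network and return the raster.

    Trigger spikes are forced (full spike lifecycle) at each trial onset;
    with several trigger ids, all are forced in the same time step
    (simultaneous coactivation).  External inputs deliver one conductance
    jump per trial at ``trigger + delta_t``.
    """
    n = net.n_neurons
    for i in protocol.trigger_ids:
        if not 0 <= i < n:
            raise ValueError(f"trigger id {i} outside the network")
        if net.is_inh[i]:
            raise ValueError(f"trigger neuron {i} must be excitatory")
    externals = list(externals or [])
    for ext in externals:
        if not 0 <= ext.target_id < n:
            raise ValueError(f"external-input target {ext.target_id} outside the network")
    ss = np.random.SeedSequence(seed)
    kick_rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seed = int(ss.generate_state(1)[0] % (2**31 - 1))

    n_steps = int(round(protocol.duration / dt))
    trigger_steps = np.round(protocol.trigger_times() / dt).astype(np.int64)

    # forced spikes: kick-start volley + trigger coactivations
    forced = []
    if protocol.kickstart_count > 0:
        exc = net.excitatory_ids
        k = min(protocol.kickstart_count, exc.size)
        kick_ids = kick_rng.choice(exc, size=k, replace=False)
        kick_steps = np.floor(kick_rng.uniform(0, protocol.kickstart_window, k) / dt)
        forced.append(np.column_stack([kick_steps.astype(np.int64), kick_ids]))
    for step in trigger_steps:
        for tid in protocol.trigger_ids:
            forced.append(np.array([[step, tid]], dtype=np.int64))
    if forced:
        forced = np.concatenate(forced)
        order = np.argsort(forced[:, 0], kind="stable")
        forced_step = forced[order, 0]
        forced_id = forced[order, 1].astype(np.int32)
    else:
        forced_step = np.empty(0, dtype=np.int64)
        forced_id = np.empty(0, dtype=np.int32)

    # external conductance events, one per trial per input
    ext_rows = []
    for ext in externals:
        steps = trigger_steps + int(round(ext.delta_t / dt))
        for s in steps:
            if 0 <= s < n_steps:
                ext_rows.append((s, ext.target_id, ext.peak_conductance,
                                 1 if ext.sign == "inhibitory" else 0))
    if ext_rows:
        ext_rows.sort()
        ext_step = np.array([r[0] for r in ext_rows], dtype=np.int64)
        ext_id = np.array([r[1] for r in ext_rows], dtype=np.int32)
        ext_g = np.array([r[2] for r in ext_rows], dtype=np.float64)
        ext_inh = np.array([r[3] for r in ext_rows], dtype=np.uint8)
    else:
        ext_step = np.empty(0, dtype=np.int64)
        ext_id = np.empty(0, dtype=np.int32)
        ext_g = np.empty(0, dtype=np.float64)
        ext_inh = np.empty(0, dtype=np.uint8)

    indptr, targets, weights, delays = net.to_csr()
    delay_steps = np.maximum(np.round(delays / dt), 1).astype(np.int16)
    record_from = int(round(protocol.discard / dt))
    spike_cap = max(int(n * protocol.duration / 1000.0 * 5.0), 100_000)
    refresh_steps = max(int(round(noise.refresh_interval / dt)), 1)

    while True:
        spk_step, spk_id, n_spk, fail, runaway = _kernels.run_network(
            *params.as_tuple(),
            indptr, targets.astype(np.int32),
            weights.astype(np.float64), delay_steps,
            net.is_inh.astype(np.uint8),
            noise.mu_in, noise.sigma_in, refresh_steps,
            forced_step, forced_id,
            ext_step, ext_id, ext_g, ext_inh,
            n_steps, dt, record_from, sim_seed,
            runaway_frac, spike_cap,
        )
        if fail >= 0:
            raise SimulationError(
                f"non-finite state at step {fail} (t={fail * dt:.1f} ms)")
        if n_spk >= 0:
            break
        spike_cap *= 4

    times = spk_step[:n_spk] * dt
    ids = spk_id[:n_spk]
    # assign each spike to the trial whose [-before, +after) window holds it
    first = protocol.trigger_times()[0]
    rel = times - first
    trial = np.floor(rel / protocol.inter_trial + 0.5).astype(np.int32)
    # the +0.5 shift maps [-inter/2, inter/2) around each trigger; restrict
    # to the analysis windows and valid trial indices
    t_in_trial = rel - trial * protocol.inter_trial
    valid = ((trial >= 0) & (trial < protocol.n_trials)
             & (t_in_trial >= -protocol.before_window)
             & (t_in_trial < protocol.after_window))
    return SpikeRecord(
        trial=trial[valid], neuron=ids[valid], time=t_in_trial[valid],
        n_neurons=n, is_inh=net.is_inh, protocol=protocol, noise=noise,
        network_hash=net.content_hash() if n <= 20_000 else None,
        seed=seed, runaway_steps=int(runaway),
    )


def mean_firing_rate(rec: SpikeRecord, protocol: TriggerProtocol | None = None,
                     population: str | None = None) -> float:
    """Mean baseline rate (spk/s): spikes in before-windows over total
    before-window time, averaged over neurons."""
    protocol = protocol or rec.protocol
    if protocol.n_trials < 1:
        raise ValueError("record contains no trials")
    if population is None:
        n = rec.n_neurons
        mask = rec.time < 0
    else:
        want = 1 if population == "I" else 0
        n = int((rec.is_inh == want).sum())
        mask = (rec.time < 0) & (rec.is_inh[rec.neuron] == want)
    total_time_s = n * protocol.n_trials * protocol.before_window / 1000.0
    if total_time_s == 0:
        return 0.0
    return float(mask.sum() / total_time_s)


def instantaneous_rate(rec: SpikeRecord, window_sd: float = 250.0,
                       dt: float = 1.0, neurons=None):
    """Gaussian-kernel rate estimate (spk/s) per neuron over the trial span.

    Returns (times, rates) with rates of shape (n_neurons, n_times); the
    time integral of each row equals that neuron's spike count.
    """
    if window_sd <= 0:
        raise ValueError("window_sd must be positive")
    proto = rec.protocol
    t0, t1 = -proto.before_window, proto.after_window
    pad = 4.0 * window_sd
    times = np.arange(t0 - pad, t1 + pad + dt, dt)
    neurons = np.asarray(neurons if neurons is not None else np.arange(rec.n_neurons))
    rates = np.zeros((neurons.size, times.size))
    idx_of = {int(n): i for i, n in enumerate(neurons)}
    norm = 1.0 / (np.sqrt(2 * np.pi) * window_sd)  # kernel integrates to 1
    for nid, t in zip(rec.neuron, rec.time):
        row = idx_of.get(int(nid))
        if row is None:
            continue
        rates[row] += norm * np.exp(-0.5 * ((times - t) / window_sd) ** 2)
    return times, rates * 1000.0  # per ms -> per s
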