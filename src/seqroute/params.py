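"""Neuron and synapse parameter sets.

The default parameters describe a single-compartment adaptive exponential
integrate-and-fire (AdEx) neuron calibrated to turtle dorsal-cortex
whole-cell recordings: membrane capacitance and leak fitted from
current-clamp traces, adaptation constants chosen to match the measured
adaptation-index distribution, and conductance-based exponential-decay
synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class NeuronParameters:
    """AdEx membrane, adaptation and synapse constants.

    Units follow the conventions of the field: capacitance in pF,
    conductances in nS, voltages in mV, currents in pA, times in ms.
    """

    C: float = 239.8          # membrane capacitance (pF)
    g_L: float = 4.2          # leak conductance (nS)
    E_L: float = -70.6        # leak reversal / resting potential (mV)
    V_T: float = -50.4        # spike-initiation threshold (mV)
    Delta_T: float = 2.0      # slope factor of the exponential term (mV)
    a: float = 4.0            # subthreshold adaptation conductance (nS)
    b: float = 80.5           # spike-triggered adaptation increment (pA)
    tau_w: float = 144.0      # adaptation time constant (ms)
    E_e: float = 10.0         # excitatory reversal potential (mV)
    E_i: float = -75.0        # inhibitory reversal potential (mV)
    tau_syn: float = 1.103681  # synaptic conductance decay constant (ms)
    V_detect: float = 0.0     # spike detection threshold (mV)
    V_reset: float = -60.0    # post-spike reset potential (mV)
    t_ref: float = 2.0        # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if not (self.E_i < self.E_L < self.V_T < self.V_detect):
            raise ValueError("require E_i < E_L < V_T < V_detect")

    def replace(self, **kwargs) -> "NeuronParameters":
        return replace(self, **kwargs)

    def as_tuple(self) -> tuple:
        """Flat tuple in field order, for the numba kernels."""
        return tuple(getattr(self, f.name) for f in fields(self))

    def to_config(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` text file."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "NeuronParameters":
        kwargs = {}
        names = {f.name for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in names:
                raise KeyError(f"unknown parameter {key!r}")
            kwargs[key] = float(value.strip())
        return cls(**kwargs)


DEFAULT_PARAMS = NeuronParameters()
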