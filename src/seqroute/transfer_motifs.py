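"""Spike-transfer graphs and motif analysis.

A spike transfer is a presynaptic spike followed, within the same trial
and within 100 ms, by a spike of a synaptically connected postsynaptic
neuron.  Combining a raster with the connectivity yields a directed
acyclic graph of spike transfers; this module builds that graph and
summarizes transfer delays, low-order motifs (single, convergence, fan,
depth-2 chains) and the conductances of traversed connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkModel
from .simulation import SpikeRecord

__all__ = [
    "TransferGraph",
    "MotifCensus",
    "build_transfer_graph",
    "transfer_delay_distribution",
    "motif_census",
    "transfer_strength_histogram",
    "STRONG_THRESHOLD_NS",
]

#: lower bound of the strong-connection range (99.7th pct of the fitted
#: truncated lognormal)
STRONG_THRESHOLD_NS = 50.6


@dataclass
class TransferGraph:
    """Spike nodes and transfer edges of one record.

    ``nodes``: one row per spike (spike, trial, neuron, time, is_inh).
    ``edges``: one row per transfer (pre_spike, post_spike, trial,
    pre, post, delay, conductance, pair).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    window: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def export_edge_list(self, path: str | Path) -> None:
        cols = ["trial", "pre", "pre_time", "post", "post_time", "conductance"]
        df = self.edges.merge(
            self.nodes[["spike", "time"]].rename(
                columns={"spike": "pre_spike", "time": "pre_time"}), on="pre_spike")
        df = df.merge(
            self.nodes[["spike", "time"]].rename(
                columns={"spike": "post_spike", "time": "post_time"}), on="post_spike")
        df[cols].to_csv(path, sep="\t", index=False)


def build_transfer_graph(rec: SpikeRecord, net: NetworkModel,
                         window: float = 100.0) -> TransferGraph:
    """One edge per (pre-spike, post-spike) pair with an existing synapse
    and 0 < dt <= window, within trials only."""
    if rec.n_neurons != net.n_neurons:
        raise ValueError("record and network refer to different neuron sets")
    if (rec.network_hash is not None and net.n_neurons <= 20_000
            and rec.network_hash != net.content_hash()):
        raise ValueError("record was produced by a different network")
    nodes = pd.DataFrame({
        "spike": np.arange(rec.n_spikes),
        "trial": rec.trial.astype(int),
        "neuron": rec.neuron.astype(int),
        "time": rec.time,
        "is_inh": rec.is_inh[rec.neuron].astype(int),
    })
    indptr, targets, conductances, _ = net.to_csr()
    e_pre, e_post, e_g = [], [], []
    for _, tr_nodes in nodes.groupby("trial", sort=False):
        ids = tr_nodes["neuron"].to_numpy()
        ts = tr_nodes["time"].to_numpy()
        spikes = tr_nodes["spike"].to_numpy()
        order = np.argsort(ts, kind="stable")
        ids, ts, spikes = ids[order], ts[order], spikes[order]
        # spike lists per neuron for this trial
        by_neuron: dict = {}
        for k, nid in enumerate(ids):
            by_neuron.setdefault(nid, []).append(k)
        for k, nid in enumerate(ids):
            t = ts[k]
            for syn in range(indptr[nid], indptr[nid + 1]):
                tgt = targets[syn]
                rows = by_neuron.get(tgt)
                if not rows:
                    continue
                for r in rows:
                    dt_ = ts[r] - t
                    if 0.0 < dt_ <= window:
                        e_pre.append(spikes[k])
                        e_post.append(spikes[r])
                        e_g.append(conductances[syn])
    edges = pd.DataFrame({
        "pre_spike": np.array(e_pre, dtype=int),
        "post_spike": np.array(e_post, dtype=int),
    })
    if len(edges):
        spike_trial = nodes.set_index("spike")
        edges["trial"] = spike_trial.loc[edges["pre_spike"], "trial"].to_numpy()
        edges["pre"] = spike_trial.loc[edges["pre_spike"], "neuron"].to_numpy()
        edges["post"] = spike_trial.loc[edges["post_spike"], "neuron"].to_numpy()
        edges["delay"] = (spike_trial.loc[edges["post_spike"], "time"].to_numpy()
                          - spike_trial.loc[edges["pre_spike"], "time"].to_numpy())
        edges["conductance"] = np.array(e_g)
        pre_i = net.is_inh[edges["pre"]].astype(int)
        post_i = net.is_inh[edges["post"]].astype(int)
        edges["pair"] = np.char.add(np.where(pre_i == 1, "I", "E"),
                                    np.where(post_i == 1, "I", "E"))
    else:
        for col in ("trial", "pre", "post", "delay", "conductance", "pair"):
            edges[col] = []
    return TransferGraph(nodes=nodes, edges=edges, window=window)


def transfer_delay_distribution(g: TransferGraph, pair: str = "EE",
                                bin_width: float = 1.0):
    """Histogram of pre-to-post spike delays for one population pair.

    Returns (bin_edges, counts, mode) with the mode reported as the left
    edge of the most populated bin.
    """
    sel = g.edges[g.edges["pair"] == pair]["delay"].to_numpy()
    if sel.size == 0:
        raise ValueError(f"no transfer edges of pair {pair}")
    edges = np.arange(0.0, g.window + bin_width, bin_width)
    counts, _ = np.histogram(sel, bins=edges)
    mode = float(edges[np.argmax(counts)])
    return edges, counts, mode


@dataclass
class MotifCensus:
    """Counts of low-order motif classes per postsynaptic spike, split by
    population of the focal spike's neuron (depth <= 2, <= 4 spikes)."""

    per_population: pd.DataFrame  # rows E/I, columns motif classes
    fan_source_counts: pd.DataFrame  # diverging-source tally (both readings)

    def counts(self, population: str, motif: str) -> int:
        return int(self.per_population.loc[population, motif])


def motif_census(g: TransferGraph) -> MotifCensus:
    """Tally motif classes for each spike in the transfer graph.

    Classes per focal spike: ``single`` (exactly one in-edge),
    ``conv2`` / ``conv3plus`` (2 / >=3 in-edges), ``fan`` (some
    presynaptic spike of the focal spike has >=2 out-edges), and
    ``chain2`` (an in-edge whose source spike itself has an in-edge).
    ``fan_source_counts`` reports the alternative reading in which the
    diverging source spike, not its targets, is tallied.
    """
    n_nodes = len(g.nodes)
    indeg = np.zeros(n_nodes, dtype=int)
    outdeg = np.zeros(n_nodes, dtype=int)
    if g.n_edges:
        np.add.at(indeg, g.edges["post_spike"].to_numpy(), 1)
        np.add.at(outdeg, g.edges["pre_spike"].to_numpy(), 1)
    pops = np.where(g.nodes["is_inh"].to_numpy() == 1, "I", "E")
    motifs = ["single", "conv2", "conv3plus", "fan", "chain2"]
    table = pd.DataFrame(0, index=["E", "I"], columns=motifs)
    fan_tbl = pd.DataFrame(0, index=["E", "I"],
                           columns=["fan_targets", "fan_sources"])
    if g.n_edges:
        pre_arr = g.edges["pre_spike"].to_numpy()
        post_arr = g.edges["post_spike"].to_numpy()
        has_fan_parent = np.zeros(n_nodes, dtype=bool)
        has_chain = np.zeros(n_nodes, dtype=bool)
        has_fan_parent[post_arr[outdeg[pre_arr] >= 2]] = True
        has_chain[post_arr[indeg[pre_arr] >= 1]] = True
        for pop in ("E", "I"):
            mask = pops == pop
            d = indeg[mask]
            table.loc[pop, "single"] = int((d == 1).sum())
            table.loc[pop, "conv2"] = int((d == 2).sum())
            table.loc[pop, "conv3plus"] = int((d >= 3).sum())
            table.loc[pop, "fan"] = int(has_fan_parent[mask].sum())
            table.loc[pop, "chain2"] = int(has_chain[mask].sum())
            fan_tbl.loc[pop, "fan_targets"] = int(has_fan_parent[mask].sum())
            fan_tbl.loc[pop, "fan_sources"] = int(((outdeg >= 2) & mask).sum())
    return MotifCensus(per_population=table, fan_source_counts=fan_tbl)


def transfer_strength_histogram(g: TransferGraph, pair: str = "EE",
                                bins: int = 68,
                                strong_threshold: float = STRONG_THRESHOLD_NS):
    """Histogram of traversed-synapse conductances plus the fraction of
    edge mass above the strong-connection threshold."""
    sel = g.edges[g.edges["pair"] == pair]["conductance"].to_numpy()
    if sel.size == 0:
        raise ValueError(f"no transfer edges of pair {pair}")
    counts, edges = np.histogram(sel, bins=bins, range=(0.0, max(sel.max(), 67.8)))
    strong_fraction = float((sel > strong_threshold).mean())
    return edges, counts, strong_fraction
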