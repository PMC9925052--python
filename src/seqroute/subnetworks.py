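"""Sub-network decomposition, gates, gating maps and multi-trigger classes.

Followers are clustered by their trial-wise coactivation (k-modes on the
binary follower x trial matrix, K = max(1, round(n/6))).  Each cluster
("sub-network") has a gate: the member with the shortest median
first-spike delay from the trigger.  Sub-network activation is the
fraction of trials in which at least 40% of members fire; gating maps
measure the fold change of that activation under a single external input
to the gate across a grid of strengths and timings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .followers import FollowerReport
from .network import NetworkModel
from .simulation import (BackgroundNoise, ExternalInput, SpikeRecord,
                         TriggerProtocol, run_protocol)

__all__ = [
    "SubnetworkPartition",
    "ActivationSummary",
    "OutcomeDistribution",
    "kmodes",
    "kmodes_partition",
    "subnetwork_activation",
    "identify_gates",
    "outcome_entropy",
    "gating_map",
    "classify_multi_trigger",
]


# --- k-modes clustering --------------------------------------------------

def _hamming_to_modes(X, modes):
    # (n_samples, K) matrix of Hamming distances
    return (X[:, None, :] != modes[None, :, :]).sum(axis=2)


def kmodes(X: np.ndarray, K: int, seed: int = 0, n_init: int = 10,
           max_iter: int = 100):
    """K-modes clustering of binary row vectors with Hamming dissimilarity.

    Huang-style initialization: candidate modes are sampled per-attribute
    with probability proportional to category frequency, then snapped to
    the nearest distinct data rows.  The best of ``n_init`` restarts by
    total Hamming cost is returned as (labels, modes, cost).
    """
    X = np.asarray(X, dtype=np.uint8)
    n, d = X.shape
    if not 1 <= K <= n:
        raise ValueError("K must be in [1, n_samples]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        freq1 = X.mean(axis=0)
        cand = (rng.random((K, d)) < freq1).astype(np.uint8)
        # snap each candidate to the nearest data row, preferring distinct rows
        modes = np.empty((K, d), dtype=np.uint8)
        taken: set = set()
        for k in range(K):
            dist = (X != cand[k]).sum(axis=1).astype(float)
            for idx in np.argsort(dist, kind="stable"):
                key = X[idx].tobytes()
                if key not in taken:
                    taken.add(key)
                    modes[k] = X[idx]
                    break
            else:
                modes[k] = X[rng.integers(n)]
        labels = np.argmin(_hamming_to_modes(X, modes), axis=1)
        for _ in range(max_iter):
            new_modes = modes.copy()
            for k in range(K):
                members = X[labels == k]
                if members.size == 0:
                    # reseed an empty cluster with the worst-fit sample
                    dist = np.min(_hamming_to_modes(X, modes), axis=1)
                    new_modes[k] = X[np.argmax(dist)]
                    continue
                ones = members.mean(axis=0)
                nm = np.where(ones > 0.5, 1,
                              np.where(ones < 0.5, 0, modes[k])).astype(np.uint8)
                new_modes[k] = nm
            new_labels = np.argmin(_hamming_to_modes(X, new_modes), axis=1)
            if np.array_equal(new_labels, labels) and np.array_equal(new_modes, modes):
                break
            labels, modes = new_labels, new_modes
        cost = int(_hamming_to_modes(X, modes)[np.arange(n), labels].sum())
        if best is None or cost < best[2]:
            best = (labels.copy(), modes.copy(), cost)
    return best


@dataclass
class SubnetworkPartition:
    """Cluster label per follower plus bookkeeping."""

    labels: np.ndarray          # int per follower (rows of the matrix)
    K: int
    seed: int
    cost: int
    follower_ids: np.ndarray

    def members(self, cluster: int) -> np.ndarray:
        """Follower row indices of one cluster."""
        return np.nonzero(self.labels == cluster)[0]

    def member_ids(self, cluster: int) -> np.ndarray:
        """Neuron ids of one cluster."""
        return self.follower_ids[self.labels == cluster]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def two_largest(self) -> tuple:
        """The two largest clusters (ties broken by lower label)."""
        sizes = self.sizes()
        order = np.lexsort((np.arange(self.K), -sizes))
        return int(order[0]), int(order[1])


def kmodes_partition(matrix: np.ndarray, follower_ids=None, seed: int = 0,
                     n_init: int = 10, K: int | None = None) -> SubnetworkPartition:
    """Cluster the follower x trial activation matrix with K = round(n/6)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n = matrix.shape[0]
    if n < 1:
        raise ValueError("need at least one follower")
    if K is None:
        K = max(1, round(n / 6))
    labels, modes, cost = kmodes(matrix, K, seed=seed, n_init=n_init)
    if follower_ids is None:
        follower_ids = np.arange(n)
    return SubnetworkPartition(labels=labels, K=K, seed=seed, cost=cost,
                               follower_ids=np.asarray(follower_ids))


@dataclass
class ActivationSummary:
    """Sub-network activation fraction and fold change over baseline."""

    a: float
    a0: float | None = None
    activation_threshold: float = 0.40

    @property
    def fold_change(self) -> float:
        """100 * (a - a0) / a0, defined for a0 > 0."""
        if self.a0 is None or self.a0 == 0:
            raise ValueError("fold change undefined without a positive baseline")
        return 100.0 * (self.a - self.a0) / self.a0


def subnetwork_activation(matrix: np.ndarray, partition: SubnetworkPartition,
                          cluster: int, threshold: float = 0.40,
                          a0: float | None = None) -> ActivationSummary:
    """Fraction of trials in which >= ``threshold`` of the cluster's
    followers fire at least once."""
    rows = partition.members(cluster)
    if rows.size == 0:
        raise ValueError(f"cluster {cluster} is empty")
    frac = np.asarray(matrix, dtype=float)[rows].mean(axis=0)
    a = float((frac >= threshold - 1e-12).mean())
    return ActivationSummary(a=a, a0=a0, activation_threshold=threshold)


def identify_gates(rec: SpikeRecord,
                   partition: SubnetworkPartition) -> dict:
    """Gate per cluster: member with the minimal median first-spike delay
    across trials where it fired; ties broken by neuron id.  Clusters
    without spikes map to None."""
    first_by_neuron: dict = {}
    after = rec.time > 0
    for nid, tr, t in zip(rec.neuron[after], rec.trial[after], rec.time[after]):
        key = int(nid)
        cur = first_by_neuron.setdefault(key, {})
        if tr not in cur or t < cur[tr]:
            cur[tr] = t
    gates = {}
    for k in range(partition.K):
        ids = partition.member_ids(k)
        best = None
        for nid in sorted(int(i) for i in ids):
            firsts = first_by_neuron.get(nid)
            if not firsts:
                continue
            med = float(np.median(list(firsts.values())))
            if best is None or med < best[1]:
                best = (nid, med)
        gates[k] = None if best is None else best[0]
    return gates


@dataclass
class OutcomeDistribution:
    """Four-outcome distribution over trials for the two largest
    sub-networks (a, b) and its Shannon entropy."""

    frequencies: dict           # {'failure','ab','a','b'} -> fraction
    entropy: float              # bits
    clusters: tuple             # (label_a, label_b)


def outcome_entropy(matrix: np.ndarray, partition: SubnetworkPartition,
                    threshold: float = 0.40) -> OutcomeDistribution:
    """Entropy (bits) of {full failure, a&b, a alone, b alone} over trials."""
    if partition.K < 2:
        raise ValueError("need at least 2 clusters")
    ka, kb = partition.two_largest()
    m = np.asarray(matrix, dtype=float)
    act_a = m[partition.members(ka)].mean(axis=0) >= threshold - 1e-12
    act_b = m[partition.members(kb)].mean(axis=0) >= threshold - 1e-12
    n_trials = m.shape[1]
    freq = {
        "failure": float((~act_a & ~act_b).mean()),
        "ab": float((act_a & act_b).mean()),
        "a": float((act_a & ~act_b).mean()),
        "b": float((~act_a & act_b).mean()),
    }
    p = np.array([v for v in freq.values() if v > 0])
    H = float(-(p * np.log2(p)).sum())
    return OutcomeDistribution(frequencies=freq, entropy=H, clusters=(ka, kb))


def gating_map(
    net: NetworkModel,
    noise: BackgroundNoise,
    protocol: TriggerProtocol,
    gate: int,
    cluster: int,
    partition: SubnetworkPartition,
    conductances=None,
    delta_ts=None,
    signs=("excitatory", "inhibitory"),
    threshold: float = 0.40,
    seed: int = 0,
    params=None,
) -> pd.DataFrame:
    """Fold change of sub-network activation under a single external input
    to the gate, across a (sign, conductance, delta_t) grid.

    The baseline a0 is measured by re-running the protocol without any
    external input under the same seed.  Returns a tidy DataFrame with
    columns sign, conductance, delta_t, a, fold_change, halting,
    facilitation (masks at -/+50%).
    """
    from .params import DEFAULT_PARAMS

    params = params or DEFAULT_PARAMS
    if conductances is None:
        conductances = {"excitatory": np.geomspace(67.8 / 16, 67.8, 5),
                        "inhibitory": np.geomspace(542.4 / 16, 542.4, 5)}
    if delta_ts is None:
        delta_ts = np.arange(-50.0, 151.0, 10.0)
    member_ids = set(int(i) for i in partition.member_ids(cluster))

    def activation_of(rec: SpikeRecord) -> float:
        act = np.zeros((len(member_ids), protocol.n_trials))
        idx = {nid: i for i, nid in enumerate(sorted(member_ids))}
        after = rec.time > 0
        for nid, tr in zip(rec.neuron[after], rec.trial[after]):
            i = idx.get(int(nid))
            if i is not None:
                act[i, tr] = 1
        return float((act.mean(axis=0) >= threshold - 1e-12).mean())

    base = run_protocol(net, noise, protocol, externals=None, seed=seed,
                        params=params)
    a0 = activation_of(base)
    if a0 == 0:
        raise ValueError("baseline sub-network activation is zero; "
                         "fold change undefined")
    out = []
    for sign in signs:
        for g in np.atleast_1d(conductances[sign] if isinstance(conductances, dict)
                               else conductances):
            for dt_ in np.atleast_1d(delta_ts):
                ext = ExternalInput(target_id=gate, peak_conductance=float(g),
                                    sign=sign, delta_t=float(dt_))
                rec = run_protocol(net, noise, protocol, externals=[ext],
                                   seed=seed, params=params)
                a = activation_of(rec)
                fc = 100.0 * (a - a0) / a0
                out.append((sign, float(g), float(dt_), a, fc))
    df = pd.DataFrame(out, columns=["sign", "conductance", "delta_t", "a",
                                    "fold_change"])
    df["a0"] = a0
    df["halting"] = df["fold_change"] <= -50.0
    df["facilitation"] = df["fold_change"] >= 50.0
    return df


_CLASS_NAMES = ("a_only", "b_only", "ab_only", "a_and_ab", "b_and_ab",
                "a_b_ab")
CORE_CLASSES = ("a_and_ab", "b_and_ab", "a_b_ab")
COMBINATION_SPECIFIC_CLASSES = ("a_only", "b_only", "ab_only")


def classify_multi_trigger(report_a: FollowerReport, report_b: FollowerReport,
                           report_ab: FollowerReport) -> pd.DataFrame:
    """Set algebra over follower sets from triggers a, b and coactivation ab.

    Returns one row per follower in the union with its class (one of
    a_only, b_only, ab_only, a_and_ab, b_and_ab, a_b_ab) and the derived
    core / combination-specific split.  Core followers persist under
    coactivation; combination-specific followers depend on the exact
    trigger combination.
    """
    hashes = {r.network_hash for r in (report_a, report_b, report_ab)
              if r.network_hash is not None}
    if len(hashes) > 1:
        raise ValueError("reports come from different networks")
    A = set(int(i) for i in report_a.follower_ids)
    B = set(int(i) for i in report_b.follower_ids)
    AB = set(int(i) for i in report_ab.follower_ids)
    rows = []
    for nid in sorted(A | B | AB):
        in_a, in_b, in_ab = nid in A, nid in B, nid in AB
        if in_a and in_b and in_ab:
            cls = "a_b_ab"
        elif in_a and in_ab:
            cls = "a_and_ab"
        elif in_b and in_ab:
            cls = "b_and_ab"
        elif in_a and in_b:
            cls = "a_b_only"  # responds to both singles but lost under coactivation
        elif in_a:
            cls = "a_only"
        elif in_b:
            cls = "b_only"
        else:
            cls = "ab_only"
        rows.append((nid, cls, cls in CORE_CLASSES))
    return pd.DataFrame(rows, columns=["neuron", "trigger_class", "core"])
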