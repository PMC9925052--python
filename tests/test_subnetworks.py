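"""Sub-network decomposition, gates, outcome entropy, multi-trigger classes."""

import itertools

import numpy as np
import pytest

from seqroute.followers import FollowerReport, detect_followers
from seqroute.simulation import BackgroundNoise, SpikeRecord, TriggerProtocol
from seqroute.subnetworks import (classify_multi_trigger, gating_map,
                                  identify_gates, kmodes, kmodes_partition,
                                  outcome_entropy, subnetwork_activation)

from conftest import make_chain_network


def test_kmodes_recovers_anticorrelated_blocks():
    X = np.zeros((10, 30), np.uint8)
    X[:5, :15] = 1
    X[5:, 15:] = 1
    part = kmodes_partition(X, K=2, seed=0)
    assert part.cost == 0
    assert len(set(part.labels[:5])) == 1
    assert len(set(part.labels[5:])) == 1
    assert part.labels[0] != part.labels[5]


def test_k_rule_rounding():
    X = np.random.default_rng(0).integers(0, 2, (25, 12)).astype(np.uint8)
    part = kmodes_partition(X, seed=0)
    assert part.K == 4  # max(1, round(25/6))
    single = kmodes_partition(X[:3], seed=0)
    assert single.K == 1


def test_kmodes_matches_exhaustive_minimum():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, (8, 6)).astype(np.uint8)
    _, _, cost = kmodes(X, K=2, seed=1, n_init=20)

    def partition_cost(labels):
        total = 0
        for k in (0, 1):
            rows = X[np.array(labels) == k]
            if rows.size == 0:
                continue
            ones = rows.sum(axis=0)
            # optimal mode per attribute: majority value
            total += np.minimum(ones, rows.shape[0] - ones).sum()
        return total

    best = min(partition_cost(lab)
               for lab in itertools.product((0, 1), repeat=8))
    assert cost == best


def test_kmodes_deterministic_under_seed():
    X = np.random.default_rng(2).integers(0, 2, (20, 15)).astype(np.uint8)
    a = kmodes_partition(X, seed=7)
    b = kmodes_partition(X, seed=7)
    assert np.array_equal(a.labels, b.labels)
    assert a.cost == b.cost


def test_subnetwork_activation_threshold_semantics():
    part = kmodes_partition(np.ones((5, 4), np.uint8), K=1, seed=0)
    m = np.ones((5, 4), np.uint8)
    assert subnetwork_activation(m, part, 0).a == 1.0
    # exactly 2 of 5 followers (40%) active counts as activated
    m2 = np.zeros((5, 4), np.uint8)
    m2[:2, 0] = 1
    m2[:1, 1] = 1
    summ = subnetwork_activation(m2, part, 0)
    assert summ.a == pytest.approx(0.25)  # only trial 0 reaches 40%


def test_activation_hand_count_and_fold_change():
    m = np.array([[1, 1, 0, 0],
                  [1, 0, 0, 0],
                  [1, 1, 1, 0]], np.uint8)
    part = kmodes_partition(m, K=1, seed=0)
    s = subnetwork_activation(m, part, 0, threshold=0.4, a0=0.5)
    # fractions per trial: 1, 2/3, 1/3, 0 -> >=0.4 in trials 0, 1
    assert s.a == pytest.approx(0.5)
    assert s.fold_change == pytest.approx(0.0)
    s2 = subnetwork_activation(m, part, 0, threshold=0.4, a0=0.25)
    assert s2.fold_change == pytest.approx(100.0)


def _record_from_matrix(first_spike_times, n_trials):
    """first_spike_times: dict neuron -> list of (trial, time)."""
    spikes = []
    for nid, pairs in first_spike_times.items():
        for tr, t in pairs:
            spikes.append((tr, nid, t))
    arr = np.array(spikes, dtype=float)
    order = np.lexsort((arr[:, 2], arr[:, 0]))
    arr = arr[order]
    n = int(arr[:, 1].max()) + 1
    return SpikeRecord(trial=arr[:, 0].astype(np.int32),
                       neuron=arr[:, 1].astype(np.int32), time=arr[:, 2],
                       n_neurons=n, is_inh=np.zeros(n, np.uint8),
                       protocol=TriggerProtocol(n_trials=n_trials))


def test_identify_gates_earliest_median_and_trial_permutation():
    rec = _record_from_matrix({
        0: [(0, 5.0), (1, 6.0), (2, 4.0)],
        1: [(0, 15.0), (1, 16.0), (2, 14.0)],
        2: [(0, 9.0), (1, 30.0)],
    }, n_trials=3)
    part = kmodes_partition(np.ones((3, 3), np.uint8), K=1, seed=0,
                            follower_ids=np.array([0, 1, 2]))
    gates = identify_gates(rec, part)
    assert gates[0] == 0  # median 5 < median 15 and < median 19.5

    rec_perm = _record_from_matrix({
        0: [(2, 5.0), (0, 6.0), (1, 4.0)],
        1: [(2, 15.0), (0, 16.0), (1, 14.0)],
        2: [(2, 9.0), (0, 30.0)],
    }, n_trials=3)
    assert identify_gates(rec_perm, part)[0] == 0


def test_identify_gates_brute_force_oracle():
    rng = np.random.default_rng(4)
    data = {nid: [(tr, float(rng.uniform(1, 100)))
                  for tr in range(6) if rng.random() < 0.8]
            for nid in range(6)}
    data = {k: v for k, v in data.items() if v}
    rec = _record_from_matrix(data, n_trials=6)
    ids = np.array(sorted(data))
    part = kmodes_partition(np.ones((ids.size, 6), np.uint8), K=1, seed=0,
                            follower_ids=ids)
    gates = identify_gates(rec, part)
    medians = {nid: np.median([t for _, t in v]) for nid, v in data.items()}
    expected = min(sorted(medians), key=lambda nid: (medians[nid], nid))
    assert gates[0] == expected


def test_empty_cluster_has_no_gate():
    rec = _record_from_matrix({0: [(0, 5.0)]}, n_trials=2)
    part = kmodes_partition(np.array([[1, 0], [0, 1]], np.uint8), K=2, seed=0,
                            follower_ids=np.array([0, 5]))
    gates = identify_gates(rec, part)
    silent_cluster = part.labels[1]
    assert gates[silent_cluster] is None


def test_outcome_entropy_extremes_and_hand_value():
    m = np.ones((12, 8), np.uint8)
    part = kmodes_partition(np.vstack([np.ones((6, 8)), np.zeros((6, 8))]
                                      ).astype(np.uint8), K=2, seed=0)
    both_on = outcome_entropy(np.ones((12, 8), np.uint8), part)
    assert both_on.entropy == 0.0
    assert both_on.frequencies["ab"] == 1.0

    # uniform over the four outcomes -> 2 bits
    m = np.zeros((12, 8), np.uint8)
    a_rows = part.members(part.two_largest()[0])
    b_rows = part.members(part.two_largest()[1])
    m[np.ix_(a_rows, [0, 1])] = 1
    m[np.ix_(b_rows, [0, 2])] = 1
    m[np.ix_(a_rows, [4, 5])] = 1
    m[np.ix_(b_rows, [4, 6])] = 1
    u = outcome_entropy(m, part)
    assert u.entropy == pytest.approx(2.0)

    # counts (10, 10, 5, 0) over 25 trials
    m = np.zeros((12, 25), np.uint8)
    m[np.ix_(a_rows, range(10))] = 1       # a&b below adds b to first 10
    m[np.ix_(b_rows, range(10))] = 1
    m[np.ix_(a_rows, range(10, 20))] = 1   # a alone
    m[np.ix_(b_rows, range(20, 25))] = 1   # b alone
    res = outcome_entropy(m, part)
    p = np.array([10, 10, 5]) / 25
    assert res.entropy == pytest.approx(float(-(p * np.log2(p)).sum()))
    assert res.frequencies["failure"] == 0.0

    single = kmodes_partition(np.ones((3, 4), np.uint8), K=1, seed=0)
    with pytest.raises(ValueError):
        outcome_entropy(np.ones((3, 4), np.uint8), single)


def test_gating_map_on_deterministic_chain():
    # chain trigger -> gate -> members; the gate is the sole entry point
    net = make_chain_network((140.0, 140.0, 140.0), (1.0, 1.0, 1.0))
    proto = TriggerProtocol(trigger_ids=(0,), n_trials=5, kickstart_count=0)
    noise = BackgroundNoise(0.0, 0.0)
    part = kmodes_partition(np.ones((3, 5), np.uint8), K=1, seed=0,
                            follower_ids=np.array([1, 2, 3]))
    df = gating_map(net, noise, proto, gate=1, cluster=0, partition=part,
                    conductances={"excitatory": [0.0], "inhibitory": [542.4]},
                    delta_ts=[0.0], seed=0)
    null_row = df[(df.sign == "excitatory")].iloc[0]
    inh_row = df[(df.sign == "inhibitory")].iloc[0]
    assert null_row["a0"] == 1.0
    assert null_row["fold_change"] == pytest.approx(0.0)
    assert inh_row["fold_change"] <= -50.0     # halting
    assert bool(inh_row["halting"])


def test_gating_map_requires_positive_baseline():
    net = make_chain_network((1.0,), (1.0,))
    proto = TriggerProtocol(trigger_ids=(0,), n_trials=3, kickstart_count=0)
    part = kmodes_partition(np.ones((1, 3), np.uint8), K=1, seed=0,
                            follower_ids=np.array([1]))
    with pytest.raises(ValueError, match="baseline"):
        gating_map(net, BackgroundNoise(0.0, 0.0), proto, gate=1, cluster=0,
                   partition=part,
                   conductances={"excitatory": [1.0], "inhibitory": [1.0]},
                   delta_ts=[0.0])


def _report(ids, network_hash="h"):
    ids = np.asarray(sorted(ids))
    n = 50
    return FollowerReport(
        delta_fr=np.zeros(n), p_value=np.ones(n),
        is_follower=np.isin(np.arange(n), ids), is_inh=np.zeros(n, np.uint8),
        threshold=1e-7, nulls={}, protocol=TriggerProtocol(n_trials=4),
        activation=np.ones((ids.size, 4), np.uint8), follower_ids=ids,
        network_hash=network_hash)


def test_classify_multi_trigger_cases_and_partition():
    df = classify_multi_trigger(_report([1, 2, 3]), _report([4, 5]),
                                _report([2, 4, 6]))
    cls = dict(zip(df.neuron, df.trigger_class))
    assert cls[1] == "a_only" and not df[df.neuron == 1].core.item()
    assert cls[2] == "a_and_ab" and df[df.neuron == 2].core.item()
    assert cls[4] == "b_and_ab"
    assert cls[6] == "ab_only"
    assert set(df.neuron) == {1, 2, 3, 4, 5, 6}


def test_classify_multi_trigger_brute_force_random_sets():
    rng = np.random.default_rng(8)
    A = set(map(int, rng.choice(30, 10, replace=False)))
    B = set(map(int, rng.choice(30, 10, replace=False)))
    AB = set(map(int, rng.choice(30, 10, replace=False)))
    df = classify_multi_trigger(_report(A), _report(B), _report(AB))
    assert set(df.neuron) == A | B | AB
    for _, row in df.iterrows():
        nid = row.neuron
        expected_core = (nid in AB) and (nid in A or nid in B)
        assert row.core == expected_core


def test_classify_multi_trigger_network_mismatch():
    with pytest.raises(ValueError, match="different networks"):
        classify_multi_trigger(_report([1]), _report([2], "other"),
                               _report([3]))
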