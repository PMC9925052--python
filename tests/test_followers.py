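"""Follower detection: dFR, exact Poisson null, calibration, sequences."""

import numpy as np
import pytest
from scipy import stats

from seqroute.followers import (build_null, center_of_mass, compute_delta_fr,
                                detect_followers, rank_entropy)
from seqroute.simulation import SpikeRecord, TriggerProtocol
from seqroute.synthetic import PlantedFollower, make_poisson_record


PROTO = TriggerProtocol(n_trials=100)


def _manual_record(spikes, n_neurons=10, proto=PROTO, trigger_ids=()):
    """Build a record from a list of (trial, neuron, time)."""
    proto = TriggerProtocol(trigger_ids=trigger_ids, n_trials=proto.n_trials)
    arr = np.array(spikes, dtype=float).reshape(-1, 3)
    order = np.lexsort((arr[:, 2], arr[:, 0]))
    arr = arr[order]
    return SpikeRecord(trial=arr[:, 0].astype(np.int32),
                       neuron=arr[:, 1].astype(np.int32),
                       time=arr[:, 2], n_neurons=n_neurons,
                       is_inh=np.zeros(n_neurons, np.uint8), protocol=proto)


def test_delta_fr_perfect_and_silent_neurons():
    rec = make_poisson_record(
        100, 0.0, PROTO, planted=[PlantedFollower(neuron=3)], seed=0)
    d = compute_delta_fr(rec)
    assert d[3] == pytest.approx(1.0)
    assert d[5] == 0.0


def test_delta_fr_of_stationary_poisson_is_centred_on_zero():
    rec = make_poisson_record(20_000, 1.0, PROTO, seed=1)
    d = compute_delta_fr(rec)
    se = d.std() / np.sqrt(d.size)
    assert abs(d.mean()) < 3 * se + 1e-12


def test_null_zero_rate_is_degenerate_point_mass():
    null = build_null(0.0, PROTO)
    assert null.degenerate
    assert null.values.tolist() == [0.0]
    assert null.p_value(0.5) == 0.0 and null.p_value(0.0) == 1.0


def test_null_mean_zero_and_pmf_normalized():
    null = build_null(0.05, PROTO)
    assert abs((null.values * null.pmf).sum()) < 1e-9
    assert abs(null.pmf.sum() - 1.0) < 1e-12


def test_null_tail_matches_monte_carlo():
    rate = 0.05
    null = build_null(rate, PROTO)
    rng = np.random.default_rng(7)
    n_mc = 10**6
    A = rng.poisson(rate * 100 * 0.3, n_mc)
    B = rng.poisson(rate * 100 * 0.1, n_mc)
    d = (A - 3 * B) / 100.0
    x = null.quantile(0.95)
    p_exact = float(null.p_value(x))
    p_mc = (d >= x - 1e-12).mean()
    se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
    assert abs(p_mc - p_exact) < 3 * se


def test_separate_population_nulls():
    rec = make_poisson_record(1000, 0.5, PROTO, seed=3)
    # make the inhibitory population much faster by adding spikes
    report = detect_followers(rec)
    assert set(report.nulls) == {"E", "I"}
    assert report.nulls["E"].population == "E"


def test_planted_follower_detected_and_trigger_excluded():
    planted = [PlantedFollower(neuron=7), PlantedFollower(neuron=11)]
    rec = make_poisson_record(2000, 0.05, PROTO, planted=planted, seed=2)
    rec.protocol = TriggerProtocol(trigger_ids=(11,), n_trials=100)
    report = detect_followers(rec)
    assert 7 in report.follower_ids
    assert 11 not in report.follower_ids          # trigger always excluded
    assert np.isnan(report.delta_fr[11])
    assert report.activation.shape == (report.n_followers, 100)
    assert report.activation[list(report.follower_ids).index(7)].mean() > 0.9


def test_false_positive_rate_consistent_with_exact_null():
    # pure-Poisson records: observed false positives must match the exact
    # tail mass just above the critical value (binomial check)
    rate, n_neurons, reps = 0.05, 20_000, 50
    proto = TriggerProtocol(n_trials=100)
    null = build_null(rate, proto)
    crit = null.critical_value
    p_eff = float(null.p_value(crit))
    assert p_eff < 1e-7
    fp = 0
    for rep in range(reps):
        rec = make_poisson_record(n_neurons, rate, proto, seed=100 + rep)
        d = compute_delta_fr(rec)
        fp += int((d >= crit - 1e-12).sum())
    n_tests = reps * n_neurons
    lo, hi = stats.binom.interval(0.999, n_tests, max(p_eff, 1e-12))
    assert lo <= fp <= hi


def test_power_for_planted_responders_on_low_background():
    # responders active in >=30% of trials on a 0.02 spk/s background are
    # essentially always caught (the null critical value is far below 0.3)
    rate = 0.02
    proto = TriggerProtocol(n_trials=100)
    null = build_null(rate, proto)
    assert null.critical_value < 0.15
    planted = [PlantedFollower(neuron=i, response_probability=0.3)
               for i in range(500)]
    rec = make_poisson_record(2000, rate, proto, planted=planted, seed=9)
    report = detect_followers(rec)
    detected = np.isin(np.arange(500), report.follower_ids).mean()
    assert detected > 0.99


def test_follower_report_exports(tmp_path):
    rec = make_poisson_record(
        200, 0.05, PROTO, planted=[PlantedFollower(neuron=3)], seed=6)
    report = detect_followers(rec)
    csv = tmp_path / "followers.csv"
    report.export(csv)
    assert csv.read_text().splitlines()[0] == \
        "neuron,population,delta_fr,p_value,is_follower"
    h5 = tmp_path / "followers.h5"
    report.save(h5)
    import h5py

    with h5py.File(h5) as f:
        assert f["activation"].shape == report.activation.shape
        assert list(f["follower_ids"][:]) == list(report.follower_ids)


def test_rank_entropy_identical_order_is_zero():
    spikes = []
    for tr in range(20):
        for i, nid in enumerate(range(4)):
            spikes.append((tr, nid, 10.0 + 5 * i))
    proto = TriggerProtocol(n_trials=20)
    rec = _manual_record(spikes, proto=proto)
    report = detect_followers(rec)
    assert report.n_followers == 4
    curve = rank_entropy(rec, report)
    assert np.allclose(curve.H_k, 0.0)
    assert np.allclose(curve.normalized, 0.0)


def test_rank_entropy_uniform_first_rank_is_one():
    # rotate which of 4 followers fires first; the rest keep fixed order
    spikes = []
    n_trials = 20
    for tr in range(n_trials):
        lead = tr % 4
        spikes.append((tr, lead, 5.0))
        rest = [nid for nid in range(4) if nid != lead]
        for i, nid in enumerate(rest):
            spikes.append((tr, nid, 20.0 + 5 * i))
    proto = TriggerProtocol(n_trials=n_trials)
    rec = _manual_record(spikes, proto=proto)
    report = detect_followers(rec)
    curve = rank_entropy(rec, report)
    assert curve.normalized[0] == pytest.approx(1.0)


def test_rank_entropy_matches_hand_computation():
    # 4 followers, 6 trials; follower 0 and 1 swap ranks half the time
    orders = [[0, 1, 2, 3], [1, 0, 2, 3], [0, 1, 2, 3],
              [1, 0, 2, 3], [0, 1, 2, 3], [1, 0, 2, 3]]
    spikes = []
    for tr, order in enumerate(orders):
        for rank, nid in enumerate(order):
            spikes.append((tr, nid, 10.0 + 5 * rank))
    proto = TriggerProtocol(n_trials=6)
    rec = _manual_record(spikes, proto=proto)
    report = detect_followers(rec)
    curve = rank_entropy(rec, report)
    # ranks 1-2: 50/50 between two followers -> 1 bit; ranks 3-4: fixed
    assert curve.H_k == pytest.approx([1.0, 1.0, 0.0, 0.0], abs=1e-12)
    assert curve.H_u == pytest.approx(2.0)
    assert np.all((curve.normalized >= 0) & (curve.normalized <= 1 + 1e-12))


def test_rank_entropy_inclusion_rules():
    spikes = [(tr, nid, 10.0 + nid) for tr in range(3) for nid in range(4)]
    proto = TriggerProtocol(n_trials=3)
    rec = _manual_record(spikes, proto=proto)
    report = detect_followers(rec)
    with pytest.raises(ValueError, match="as many trials"):
        rank_entropy(rec, report)


def test_center_of_mass_single_and_two_followers():
    positions = np.array([[100.0, 200.0], [300.0, 400.0], [0.0, 0.0]])
    proto = TriggerProtocol(n_trials=4)
    spikes = [(0, 0, 10.0), (0, 0, 12.0)] + \
             [(tr, 0, 10.0) for tr in range(1, 4)]
    rec = _manual_record(spikes, n_neurons=3, proto=proto)
    report = detect_followers(rec)
    traj = center_of_mass(rec, report, positions, trial=0)
    valid = ~np.isnan(traj.x)
    assert np.allclose(traj.x[valid], 100.0)
    assert np.allclose(traj.y[valid], 200.0)

    spikes = [(tr, nid, 10.0 + 60.0 * nid) for tr in range(4) for nid in (0, 1)]
    rec2 = _manual_record(spikes, n_neurons=3, proto=proto)
    report2 = detect_followers(rec2)
    traj2 = center_of_mass(rec2, report2, positions, trial=0)
    i_early = np.argmin(np.abs(traj2.times - 10.0))
    i_late = np.argmin(np.abs(traj2.times - 70.0))
    assert traj2.x[i_early] == pytest.approx(100.0, abs=1.0)
    assert traj2.x[i_late] == pytest.approx(300.0, abs=1.0)


def test_center_of_mass_matches_windowed_average():
    rng = np.random.default_rng(0)
    positions = rng.uniform(0, 100, (5, 2))
    proto = TriggerProtocol(n_trials=5)
    spikes = [(0, nid, float(t)) for nid in range(5)
              for t in rng.uniform(1, 100, 3)]
    spikes += [(tr, nid, 10.0) for tr in range(1, 5) for nid in range(5)]
    rec = _manual_record(spikes, n_neurons=5, proto=proto)
    report = detect_followers(rec)
    assert report.n_followers == 5
    traj = center_of_mass(rec, report, positions, trial=0,
                          window=5.0, smoothing=1e-6)
    arr = np.array([s for s in spikes if s[0] == 0])
    for i, t in enumerate(traj.times):
        m = np.abs(arr[:, 2] - t) <= 2.5
        if m.any():
            expected = positions[arr[m, 1].astype(int)].mean(axis=0)
            assert traj.x[i] == pytest.approx(expected[0], abs=1e-6)
        else:
            assert np.isnan(traj.x[i])
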