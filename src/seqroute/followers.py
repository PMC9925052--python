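"""Follower detection and sequence statistics.

A follower is a neuron whose firing-rate modulation after the trigger
spike (dFR, normalized so that one extra spike per trial scores 1)
exceeds the upper 1e-7 quantile of a Poisson null: the difference of two
Poisson counts with the same underlying rate, durations matched to the
before/after analysis windows.  The null is evaluated exactly by
discrete convolution, separately for the excitatory and inhibitory
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .simulation import SpikeRecord, TriggerProtocol, mean_firing_rate

__all__ = [
    "NullModel",
    "FollowerReport",
    "RankEntropyCurve",
    "CoMTrajectory",
    "compute_delta_fr",
    "build_null",
    "detect_followers",
    "expected_sims_per_false_positive",
    "rank_entropy",
    "center_of_mass",
]


def compute_delta_fr(rec: SpikeRecord, protocol: TriggerProtocol | None = None):
    """Normalized firing-rate modulation per neuron.

    Raw modulation is the after-window rate minus the before-window rate;
    it is normalized by the modulation of a perfect follower (a neuron
    silent before and spiking exactly once per trial after), so the
    result is in units of extra spikes per trial.  Trigger neurons are
    excluded (NaN).
    """
    protocol = protocol or rec.protocol
    n = rec.n_neurons
    t_before = protocol.n_trials * protocol.before_window / 1000.0  # s
    t_after = protocol.n_trials * protocol.after_window / 1000.0
    after = rec.time > 0
    before = rec.time < 0
    cnt_after = np.bincount(rec.neuron[after], minlength=n)
    cnt_before = np.bincount(rec.neuron[before], minlength=n)
    raw = cnt_after / t_after - cnt_before / t_before
    perfect = protocol.n_trials / t_after  # one spike per trial, silent before
    delta = raw / perfect
    delta[list(protocol.trigger_ids)] = np.nan
    return delta


@dataclass
class NullModel:
    """Exact pmf of normalized dFR under a constant-rate Poisson process."""

    rate: float                # spk/s
    population: str            # 'E' or 'I'
    protocol: TriggerProtocol
    threshold: float
    values: np.ndarray         # support (normalized dFR)
    pmf: np.ndarray
    degenerate: bool = False

    def p_value(self, delta_fr):
        """Upper-tail probability P(null >= x)."""
        x = np.asarray(delta_fr, dtype=float)
        sf = np.concatenate([np.cumsum(self.pmf[::-1])[::-1], [0.0]])
        idx = np.searchsorted(self.values, x - 1e-12, side="left")
        out = sf[np.minimum(idx, self.values.size)]
        return np.where(np.isnan(x), np.nan, out)

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.pmf)
        return float(self.values[np.searchsorted(cdf, q, side="left")])

    @property
    def critical_value(self) -> float:
        """Smallest support value whose upper-tail mass is < threshold."""
        sf = np.cumsum(self.pmf[::-1])[::-1]
        above = np.nonzero(sf < self.threshold)[0]
        return float(self.values[above[0]]) if above.size else np.inf


def build_null(
    rate: float,
    protocol: TriggerProtocol,
    population: str = "E",
    threshold: float = 1e-7,
    tail_mass: float = 1e-12,
) -> NullModel:
    """Exact null distribution of normalized dFR at a baseline rate.

    The after and before spike counts over the pooled windows are
    independent Poissons with rates adjusted for the window durations;
    the pmf of their (scaled) difference is computed by discrete
    convolution up to a tail cutoff with mass below ``tail_mass``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    n = protocol.n_trials
    t_before = n * protocol.before_window / 1000.0
    t_after = n * protocol.after_window / 1000.0
    if rate == 0:
        return NullModel(rate, population, protocol, threshold,
                         np.array([0.0]), np.array([1.0]), degenerate=True)
    lam_a = rate * t_after
    lam_b = rate * t_before
    ka = int(stats.poisson.isf(tail_mass / 2, lam_a)) + 1
    kb = int(stats.poisson.isf(tail_mass / 2, lam_b)) + 1
    pa = stats.poisson.pmf(np.arange(ka + 1), lam_a)
    pb = stats.poisson.pmf(np.arange(kb + 1), lam_b)
    # normalized dFR = (A - B * t_after/t_before) / n_trials; with integer
    # window ratio r the support lives on the lattice (A - r B) / n
    ratio = protocol.after_window / protocol.before_window
    r_int = int(round(ratio))
    if abs(ratio - r_int) < 1e-9:
        lo = -r_int * kb
        pmf = np.zeros(ka + r_int * kb + 1)
        for bcount in range(kb + 1):
            pmf[bcount * -r_int - lo:bcount * -r_int - lo + ka + 1] += pb[bcount] * pa
        values = (np.arange(lo, ka + 1) / n).astype(float)
    else:  # non-integer ratio: enumerate the outer product lattice
        vals = (np.arange(ka + 1)[:, None] - ratio * np.arange(kb + 1)[None, :]) / n
        prob = pa[:, None] * pb[None, :]
        order = np.argsort(vals.ravel())
        values = vals.ravel()[order]
        pmf = prob.ravel()[order]
        uniq, inv = np.unique(np.round(values, 12), return_inverse=True)
        pmf = np.bincount(inv, weights=pmf)
        values = uniq
    pmf = pmf / pmf.sum()
    return NullModel(rate, population, protocol, threshold, values, pmf)


@dataclass
class FollowerReport:
    """Per-neuron dFR, p-value, follower flag, plus the follower x trial
    binary activation matrix."""

    delta_fr: np.ndarray
    p_value: np.ndarray
    is_follower: np.ndarray     # bool per neuron
    is_inh: np.ndarray
    threshold: float
    nulls: dict                 # population -> NullModel
    protocol: TriggerProtocol
    activation: np.ndarray      # (n_followers, n_trials) uint8
    follower_ids: np.ndarray
    network_hash: str | None = None

    @property
    def n_followers(self) -> int:
        return int(self.is_follower.sum())

    def follower_population(self, pop: str) -> np.ndarray:
        want = 1 if pop == "I" else 0
        return self.follower_ids[self.is_inh[self.follower_ids] == want]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "neuron": np.arange(self.delta_fr.size),
            "population": np.where(self.is_inh == 1, "I", "E"),
            "delta_fr": self.delta_fr,
            "p_value": self.p_value,
            "is_follower": self.is_follower,
        })

    def export(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save(self, path: str | Path) -> None:
        """Columnar container: per-neuron statistics plus the follower x
        trial binary activation matrix."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("delta_fr", data=self.delta_fr)
            f.create_dataset("p_value", data=self.p_value)
            f.create_dataset("is_follower", data=self.is_follower)
            f.create_dataset("is_inh", data=self.is_inh)
            f.create_dataset("activation", data=self.activation)
            f.create_dataset("follower_ids", data=self.follower_ids)
            f.attrs["threshold"] = self.threshold
            if self.network_hash:
                f.attrs["network_hash"] = self.network_hash


def detect_followers(
    rec: SpikeRecord,
    protocol: TriggerProtocol | None = None,
    threshold: float = 1e-7,
) -> FollowerReport:
    """Flag neurons whose dFR exceeds the population null's upper
    ``threshold`` quantile; build the follower x trial activation matrix."""
    protocol = protocol or rec.protocol
    if protocol.n_trials < 2:
        raise ValueError("need at least 2 trials to detect followers")
    delta = compute_delta_fr(rec, protocol)
    p = np.full(delta.size, np.nan)
    is_follower = np.zeros(delta.size, dtype=bool)
    nulls = {}
    for pop, want in (("E", 0), ("I", 1)):
        members = np.nonzero(rec.is_inh == want)[0]
        if members.size == 0:
            continue
        rate = mean_firing_rate(rec, protocol, population=pop)
        null = build_null(rate, protocol, pop, threshold)
        nulls[pop] = null
        pv = null.p_value(delta[members])
        p[members] = pv
        with np.errstate(invalid="ignore"):
            is_follower[members] = pv < threshold
    is_follower[list(protocol.trigger_ids)] = False
    follower_ids = np.nonzero(is_follower)[0]
    activation = np.zeros((follower_ids.size, protocol.n_trials), dtype=np.uint8)
    id_to_row = {int(f): i for i, f in enumerate(follower_ids)}
    after = rec.time > 0
    for nid, tr in zip(rec.neuron[after], rec.trial[after]):
        row = id_to_row.get(int(nid))
        if row is not None:
            activation[row, tr] = 1
    return FollowerReport(
        delta_fr=delta, p_value=p, is_follower=is_follower, is_inh=rec.is_inh,
        threshold=threshold, nulls=nulls, protocol=protocol,
        activation=activation, follower_ids=follower_ids,
        network_hash=rec.network_hash,
    )


def expected_sims_per_false_positive(threshold: float = 1e-7,
                                     n_tests: int = 100_000) -> float:
    """Expected number of simulations per false positive at a nominal
    test threshold with ``n_tests`` tested neurons per simulation."""
    return 1.0 / (threshold * n_tests)


@dataclass
class RankEntropyCurve:
    """Entropy of follower identity per sequence rank."""

    ranks: np.ndarray
    H_k: np.ndarray            # bits
    H_u: float                 # bits, uniform reference
    frequencies: np.ndarray    # (n_followers, n_ranks) p_ik
    n_followers: int
    n_trials_used: int

    @property
    def normalized(self) -> np.ndarray:
        return self.H_k / self.H_u if self.H_u > 0 else np.zeros_like(self.H_k)


def rank_entropy(
    rec: SpikeRecord,
    report: FollowerReport,
    min_present_fraction: float = 0.25,
) -> RankEntropyCurve:
    """Entropy of follower identity per rank of first-spike order.

    Follows the inclusion rules of the protocol: requires at least as
    many trials as followers, and uses only trials where at least
    ``min_present_fraction`` of followers are present.  Ties in first
    spike times are broken by neuron id.
    """
    proto = report.protocol
    fids = report.follower_ids
    n = fids.size
    if n == 0:
        raise ValueError("no followers")
    if proto.n_trials < n:
        raise ValueError("need at least as many trials as followers")
    id_to_row = {int(f): i for i, f in enumerate(fids)}
    counts = np.zeros((n, n))  # follower x rank
    used = 0
    for tr in range(proto.n_trials):
        ids, ts = rec.spikes_in_trial(tr)
        first = {}
        for nid, t in zip(ids, ts):
            if t <= 0:
                continue
            row = id_to_row.get(int(nid))
            if row is not None and (row not in first or t < first[row]):
                first[row] = t
        if len(first) < min_present_fraction * n:
            continue
        used += 1
        order = sorted(first.items(), key=lambda kv: (kv[1], fids[kv[0]]))
        for rank, (row, _) in enumerate(order):
            counts[row, rank] += 1
    if used == 0:
        raise ValueError("no qualifying trials")
    totals = counts.sum(axis=0)
    ranks = np.nonzero(totals > 0)[0]
    freq = np.zeros((n, ranks.size))
    H = np.zeros(ranks.size)
    for j, k in enumerate(ranks):
        p = counts[:, k] / totals[k]
        freq[:, j] = p
        nz = p[p > 0]
        H[j] = float(-(nz * np.log2(nz)).sum())
    H_u = float(np.log2(n)) if n > 1 else 0.0
    return RankEntropyCurve(ranks=ranks + 1, H_k=H, H_u=H_u, frequencies=freq,
                            n_followers=n, n_trials_used=used)


@dataclass
class CoMTrajectory:
    """Smoothed center-of-mass of follower activations over time."""

    times: np.ndarray
    x: np.ndarray   # NaN where no follower is active in the window
    y: np.ndarray


def center_of_mass(
    rec: SpikeRecord,
    report: FollowerReport,
    positions: np.ndarray,
    trial: int = 0,
    window: float = 5.0,
    smoothing: float = 15.0,
    dt: float = 1.0,
) -> CoMTrajectory:
    """Mean follower XY position in a sliding window, Gaussian-smoothed.

    Windows without active followers yield NaN gaps that are preserved
    through smoothing (normalized convolution over valid samples).
    """
    fids = set(int(f) for f in report.follower_ids)
    ids, ts = rec.spikes_in_trial(trial)
    pts = [(t, positions[int(nid)]) for nid, t in zip(ids, ts)
           if int(nid) in fids and t > 0]
    if not pts:
        raise ValueError("no follower spikes in the requested trial")
    proto = report.protocol
    times = np.arange(0.0, proto.after_window + dt, dt)
    x = np.full(times.size, np.nan)
    y = np.full(times.size, np.nan)
    arr_t = np.array([p[0] for p in pts])
    arr_xy = np.array([p[1] for p in pts])
    half = window / 2.0
    for i, t in enumerate(times):
        m = (arr_t >= t - half) & (arr_t <= t + half)
        if m.any():
            x[i] = arr_xy[m, 0].mean()
            y[i] = arr_xy[m, 1].mean()
    # Gaussian smoothing over valid samples only
    sd = smoothing / dt
    k = np.exp(-0.5 * (np.arange(-int(4 * sd), int(4 * sd) + 1) / sd) ** 2)
    valid = ~np.isnan(x)
    for arr in (x, y):
        vals = np.where(valid, arr, 0.0)
        num = np.convolve(vals, k, mode="same")
        den = np.convolve(valid.astype(float), k, mode="same")
        with np.errstate(invalid="ignore"):
            sm = num / den
        arr[valid] = sm[valid]
    return CoMTrajectory(times=times, x=x, y=y)
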