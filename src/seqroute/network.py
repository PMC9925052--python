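"""Spatially embedded random network generation.

Neurons are placed uniformly on a square with periodic boundaries.
Ordered pairs connect independently with a Gaussian distance-dependent
probability p(d) = A exp(-d^2 / 2 sigma^2); the zero-distance amplitude A
is calibrated analytically so the expected out-degree of each connection
type matches a target.  Excitatory conductances follow a lognormal
distribution right-truncated at 67.8 nS (moment-matched to mean 3.73 nS
and std 6.51 nS); inhibitory conductances are the same draws scaled by 8.
Conduction delays are uniform on [0.5, 2] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special, stats

from . import _kernels
from .fitting import match_truncated_moments, truncated_lognormal_ppf

__all__ = [
    "PAIR_TYPES",
    "WeightDistribution",
    "ConnectivityProfile",
    "NetworkModel",
    "place_neurons",
    "torus_distance",
    "calibrate_profile",
    "sample_weights",
    "build_network",
    "truncate_network",
]

PAIR_TYPES = ("EE", "EI", "IE", "II")  # source population first

#: mean outgoing connections per source cell (E->E, E->I, I->E, I->I)
DEFAULT_OUT_DEGREE_TARGETS = {"EE": 750.0, "EI": 190.0, "IE": 2690.0, "II": 110.0}

#: Gaussian decay length of the connection-probability profile (um).
#: A single value is feasible for all four connection types on the default
#: geometry; the printed out-degree targets, not sigma, pin the statistics
#: the analyses depend on.
DEFAULT_SIGMAS = {"EE": 150.0, "EI": 150.0, "IE": 150.0, "II": 150.0}

DELAY_RANGE = (0.5, 2.0)  # ms


@dataclass(frozen=True)
class WeightDistribution:
    """Truncated-lognormal synaptic conductance distribution (nS)."""

    mean: float = 3.73
    std: float = 6.51
    truncation_max: float = 67.8
    inhibitory_scale: float = 8.0
    underlying_mu: float = field(init=False)
    underlying_sigma: float = field(init=False)

    def __post_init__(self) -> None:
        mu, sigma = match_truncated_moments(self.mean, self.std, self.truncation_max)
        object.__setattr__(self, "underlying_mu", mu)
        object.__setattr__(self, "underlying_sigma", sigma)

    def ppf(self, q):
        """Quantile of the truncated excitatory conductance distribution."""
        return truncated_lognormal_ppf(q, self.underlying_mu,
                                       self.underlying_sigma, self.truncation_max)

    def sample(self, n: int, source_population: str = "E",
               rng: np.random.Generator | int | None = None) -> np.ndarray:
        return sample_weights(n, self, source_population, rng)


def sample_weights(n: int, dist: WeightDistribution,
                   source_population: str = "E",
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Rejection-sample ``n`` conductances (nS) from the truncated lognormal.

    Draws above the truncation point are discarded and re-sampled;
    inhibitory draws are scaled by ``dist.inhibitory_scale`` afterwards.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if source_population not in ("E", "I"):
        raise ValueError("source_population must be 'E' or 'I'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(dist.underlying_mu, dist.underlying_sigma, n - filled)
        keep = draw[draw <= dist.truncation_max]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    if source_population == "I":
        out *= dist.inhibitory_scale
    return out


def place_neurons(n: int, side: float = 2000.0, fraction_excitatory: float = 0.93,
                  seed: int | np.random.Generator | None = None):
    """Uniform positions on a [0, side)^2 torus plus E/I labels.

    Returns (positions (n, 2), is_inh uint8 array).  Exactly
    round(n * fraction_excitatory) neurons are excitatory; excitatory
    neurons occupy the lower indices.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < fraction_excitatory < 1:
        raise ValueError("fraction_excitatory must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.uniform(0.0, side, size=(n, 2))
    n_exc = int(round(n * fraction_excitatory))
    is_inh = np.zeros(n, dtype=np.uint8)
    is_inh[n_exc:] = 1
    return positions, is_inh


def torus_distance(p1, p2, side: float):
    """Euclidean distance with per-axis wrap-around (periodic boundaries)."""
    d = np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))
    d = np.minimum(d, side - d)
    return np.sqrt((d ** 2).sum(axis=-1))


def _pair_kernel_mean(sigma: float, side: float) -> float:
    """E[exp(-d^2/2 sigma^2)] for two independent uniform points on the torus.

    The wrapped per-axis distance is uniform on [0, side/2], so the
    expectation factorizes into the square of a one-dimensional erf term.
    """
    z = side / (2.0 * np.sqrt(2.0) * sigma)
    axis = (sigma / side) * np.sqrt(2.0 * np.pi) * special.erf(z)
    return float(axis ** 2)


@dataclass(frozen=True)
class ConnectivityProfile:
    """Calibrated Gaussian connection-probability profile per pair type."""

    sigma: dict
    amplitude: dict
    calibration_target: dict
    disc_radius: float = 200.0

    def probability(self, pair: str, distance) -> np.ndarray:
        """Connection probability at a given torus distance (um)."""
        d = np.asarray(distance, dtype=float)
        return self.amplitude[pair] * np.exp(-d**2 / (2.0 * self.sigma[pair] ** 2))

    def disc_probability(self, pair: str) -> float:
        """Implied mean connection probability within the disc radius."""
        s = self.sigma[pair]
        R = self.disc_radius
        return float(self.amplitude[pair] * (2.0 * s**2 / R**2)
                     * (1.0 - np.exp(-R**2 / (2.0 * s**2))))

    def expected_out_degree(self, pair: str, n_targets: int, side: float) -> float:
        return self.amplitude[pair] * n_targets * _pair_kernel_mean(self.sigma[pair], side)


def calibrate_profile(
    n_neurons: int,
    side: float,
    fraction_excitatory: float = 0.93,
    sigmas: dict | None = None,
    targets: dict | None = None,
    disc_radius: float = 200.0,
) -> ConnectivityProfile:
    """Set per-pair amplitudes so expected out-degrees match the targets.

    The expected out-degree under the profile is computed analytically
    (target count x amplitude x mean Gaussian kernel over the torus) and
    inverted for the amplitude.  Raises if a target needs amplitude > 1.
    """
    sigmas = dict(DEFAULT_SIGMAS if sigmas is None else sigmas)
    targets = dict(DEFAULT_OUT_DEGREE_TARGETS if targets is None else targets)
    n_exc = int(round(n_neurons * fraction_excitatory))
    n_inh = n_neurons - n_exc
    n_targets = {"EE": n_exc - 1, "EI": n_inh, "IE": n_exc, "II": n_inh - 1}
    amplitude = {}
    for pair in PAIR_TYPES:
        target = targets[pair]
        if target < 0:
            raise ValueError("out-degree targets must be >= 0")
        if target == 0:
            amplitude[pair] = 0.0
            continue
        denom = n_targets[pair] * _pair_kernel_mean(sigmas[pair], side)
        amp = target / denom
        if amp > 1.0:
            raise ValueError(
                f"infeasible profile: {pair} target {target} needs amplitude "
                f"{amp:.3f} > 1 at sigma={sigmas[pair]} um on side {side} um")
        amplitude[pair] = float(amp)
    return ConnectivityProfile(sigma=sigmas, amplitude=amplitude,
                               calibration_target=targets, disc_radius=disc_radius)


@dataclass
class NetworkModel:
    """Positions, populations and the synapse table of one network."""

    side: float
    positions: np.ndarray     # (n, 2) float64, um
    is_inh: np.ndarray        # (n,) uint8, 1 for inhibitory
    pre: np.ndarray           # (m,) int32
    post: np.ndarray          # (m,) int32
    conductance: np.ndarray   # (m,) float32, nS
    delay: np.ndarray         # (m,) float32, ms
    profile: ConnectivityProfile | None = None
    weight_dist: WeightDistribution | None = None
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_synapses(self) -> int:
        return int(self.pre.size)

    @property
    def excitatory_ids(self) -> np.ndarray:
        return np.nonzero(self.is_inh == 0)[0]

    @property
    def inhibitory_ids(self) -> np.ndarray:
        return np.nonzero(self.is_inh == 1)[0]

    def pair_mask(self, pair: str) -> np.ndarray:
        """Boolean mask over synapses for a source/target population pair."""
        src_inh = self.is_inh[self.pre] == 1
        tgt_inh = self.is_inh[self.post] == 1
        want_src = pair[0] == "I"
        want_tgt = pair[1] == "I"
        return (src_inh == want_src) & (tgt_inh == want_tgt)

    def out_degrees(self, pair: str = "EE") -> np.ndarray:
        """Per-source-neuron outgoing connection count for a pair type."""
        mask = self.pair_mask(pair)
        counts = np.bincount(self.pre[mask], minlength=self.n_neurons)
        src = self.excitatory_ids if pair[0] == "E" else self.inhibitory_ids
        return counts[src]

    def in_degrees(self, pair: str = "EE") -> np.ndarray:
        """Per-target-neuron incoming connection count for a pair type."""
        mask = self.pair_mask(pair)
        counts = np.bincount(self.post[mask], minlength=self.n_neurons)
        tgt = self.excitatory_ids if pair[1] == "E" else self.inhibitory_ids
        return counts[tgt]

    def to_csr(self):
        """(indptr, targets, conductance, delay) sorted by presynaptic id."""
        order = np.argsort(self.pre, kind="stable")
        indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.add.at(indptr, self.pre + 1, 1)
        np.cumsum(indptr, out=indptr)
        return (indptr, self.post[order], self.conductance[order], self.delay[order])

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Columnar HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["side"] = self.side
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("is_inh", data=self.is_inh)
            g = f.create_group("synapses")
            g.create_dataset("pre", data=self.pre)
            g.create_dataset("post", data=self.post)
            g.create_dataset("conductance", data=self.conductance)
            g.create_dataset("delay", data=self.delay)

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                side=float(f.attrs["side"]),
                positions=f["positions"][:],
                is_inh=f["is_inh"][:],
                pre=f["synapses/pre"][:],
                post=f["synapses/post"][:],
                conductance=f["synapses/conductance"][:],
                delay=f["synapses/delay"][:],
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )

    def export_edge_list(self, path: str | Path) -> None:
        """Plain-text edge list: pre<TAB>post<TAB>nS<TAB>ms, one per line."""
        with open(path, "w") as f:
            for p, q, g, d in zip(self.pre, self.post, self.conductance, self.delay):
                f.write(f"{p}\t{q}\t{g:.6g}\t{d:.6g}\n")

    def content_hash(self) -> str:
        """Hash of the synapse table and geometry, for consistency checks."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.positions, self.is_inh, self.pre, self.post,
                    self.conductance, self.delay):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def _grid_index(pos: np.ndarray, side: float, cell: float, n_axis: int):
    ix = np.minimum((pos[:, 0] / cell).astype(np.int64), n_axis - 1)
    iy = np.minimum((pos[:, 1] / cell).astype(np.int64), n_axis - 1)
    return ix * n_axis + iy


def _sample_pair_edges(positions, src_ids, tgt_ids, side, amplitude, sigma,
                       expected, seed):
    """Run the numba Bernoulli sampler for one pair type."""
    if amplitude == 0.0 or src_ids.size == 0 or tgt_ids.size == 0:
        return (np.empty(0, dtype=np.int32),) * 2
    cutoff = min(4.25 * sigma, side * 0.7072)
    cell = max(cutoff / 4.0, 1e-6)
    n_axis = max(int(np.ceil(side / cell)), 1)
    cell = side / n_axis
    tgt_pos = positions[tgt_ids]
    cells = _grid_index(tgt_pos, side, cell, n_axis)
    order = np.argsort(cells, kind="stable")
    cell_start = np.zeros(n_axis * n_axis + 1, dtype=np.int64)
    np.add.at(cell_start, cells + 1, 1)
    np.cumsum(cell_start, out=cell_start)
    cap = int(expected * 1.1) + 10_000
    src_pos = positions[src_ids]
    while True:
        out_pre = np.empty(cap, dtype=np.int32)
        out_post = np.empty(cap, dtype=np.int32)
        m = _kernels.sample_edges(
            np.ascontiguousarray(src_pos[:, 0]), np.ascontiguousarray(src_pos[:, 1]),
            src_ids.astype(np.int32),
            np.ascontiguousarray(tgt_pos[:, 0]), np.ascontiguousarray(tgt_pos[:, 1]),
            tgt_ids.astype(np.int32),
            cell_start, order.astype(np.int64),
            n_axis, cell, side,
            float(amplitude), 1.0 / (2.0 * sigma**2), cutoff**2,
            int(seed), out_pre, out_post,
        )
        if m >= 0:
            return out_pre[:m].copy(), out_post[:m].copy()
        cap = int(cap * 1.5)


def build_network(
    n_neurons: int = 100_000,
    side: float = 2000.0,
    fraction_excitatory: float = 0.93,
    profile: ConnectivityProfile | None = None,
    weight_dist: WeightDistribution | None = None,
    delay_range: tuple = DELAY_RANGE,
    seed: int = 0,
    max_neurons: int = 150_000,
    allow_large: bool = False,
) -> NetworkModel:
    """Generate a full network: positions, edges, conductances, delays."""
    if n_neurons > max_neurons and not allow_large:
        raise MemoryError(
            f"n_neurons={n_neurons} above the safety cap {max_neurons}; "
            "pass allow_large=True to override")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(6)
    rng_pos = np.random.default_rng(child[0])
    positions, is_inh = place_neurons(n_neurons, side, fraction_excitatory, rng_pos)
    if profile is None:
        profile = calibrate_profile(n_neurons, side, fraction_excitatory)
    if weight_dist is None:
        weight_dist = WeightDistribution()
    exc_ids = np.nonzero(is_inh == 0)[0].astype(np.int32)
    inh_ids = np.nonzero(is_inh == 1)[0].astype(np.int32)
    src_of = {"E": exc_ids, "I": inh_ids}
    pres, posts = [], []
    kernel_seeds = child[1].generate_state(4) % (2**31 - 1)
    for k, pair in enumerate(PAIR_TYPES):
        src = src_of[pair[0]]
        tgt = src_of[pair[1]]
        expected = profile.calibration_target[pair] * src.size
        p, q = _sample_pair_edges(positions, src, tgt, side,
                                  profile.amplitude[pair], profile.sigma[pair],
                                  expected, int(kernel_seeds[k]))
        pres.append(p)
        posts.append(q)
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    m = pre.size
    rng_w = np.random.default_rng(child[2])
    conductance = np.empty(m, dtype=np.float32)
    src_is_inh = is_inh[pre] == 1
    conductance[~src_is_inh] = sample_weights(int((~src_is_inh).sum()),
                                              weight_dist, "E", rng_w)
    conductance[src_is_inh] = sample_weights(int(src_is_inh.sum()),
                                             weight_dist, "I", rng_w)
    rng_d = np.random.default_rng(child[3])
    delay = rng_d.uniform(delay_range[0], delay_range[1], m).astype(np.float32)
    return NetworkModel(side=side, positions=positions, is_inh=is_inh,
                        pre=pre, post=post, conductance=conductance, delay=delay,
                        profile=profile, weight_dist=weight_dist, seed=seed)


def truncate_network(net: NetworkModel, mode: str,
                     strong_quantile: float = 0.997,
                     weak_quantile: float = 0.90) -> NetworkModel:
    """Keep only strong or weak E->E synapses; I-involving edges untouched.

    ``strong_only`` retains E->E synapses above the ``strong_quantile`` of
    the E->E conductance distribution, ``weak_only`` those below the
    ``weak_quantile``; ``full`` returns an identical copy.
    """
    if mode not in ("strong_only", "weak_only", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    ee = net.pair_mask("EE")
    if not ee.any():
        raise ValueError("network has no E->E synapses")
    keep = np.ones(net.n_synapses, dtype=bool)
    if mode == "strong_only":
        thr = np.quantile(net.conductance[ee], strong_quantile)
        keep[ee] = net.conductance[ee] > thr
    elif mode == "weak_only":
        thr = np.quantile(net.conductance[ee], weak_quantile)
        keep[ee] = net.conductance[ee] < thr
    return NetworkModel(side=net.side, positions=net.positions, is_inh=net.is_inh,
                        pre=net.pre[keep], post=net.post[keep],
                        conductance=net.conductance[keep], delay=net.delay[keep],
                        profile=net.profile, weight_dist=net.weight_dist,
                        seed=net.seed)
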