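# Methods

This note documents the models, statistics and numerical choices behind
`seqroute`. The package asks how a single extra spike propagates through a
cortex-like recurrent network: it builds a spiking-network model with the
single-cell physiology and connectivity statistics of turtle dorsal cortex,
triggers single spikes in chosen excitatory neurons, and quantifies which
neurons follow, in what order, and how that routing can be controlled.

## Neuron model

Neurons are single-compartment adaptive exponential integrate-and-fire
(AdEx) units with conductance-based synapses:

    C dV/dt   = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T)
                - g_e (V - E_e) - g_i (V - E_i) - w + I_e
    tau_w dw/dt = a (V - E_L) - w

Synaptic conductances decay exponentially (tau_syn = 1.103681 ms) and jump
by the synaptic peak conductance when a presynaptic spike arrives. When V
crosses the detection threshold (0 mV) a spike is recorded, V is reset to
-60 mV and clamped there for the 2 ms refractory period, and w jumps by b.
The default parameter set (`seqroute.params.DEFAULT_PARAMS`) is the
experimentally constrained one: C = 239.8 pF and g_L = 4.2 nS from
current-clamp fits, adaptation a = 4 nS, b = 80.5 pA, tau_w = 144 ms
matching the measured adaptation-index distribution, E_L = -70.6 mV,
V_T = -50.4 mV, Delta_T = 2 mV.

Integration is a fixed-step explicit Euler scheme at dt = 0.1 ms with two
guards: the argument of the exponential term is clamped at
(V_detect - V_T)/Delta_T so the upswing cannot overflow, and conductances
below 1e-12 nS are flushed to zero (exponential decay otherwise parks
every quiet neuron's conductance in the denormal range, which slows the
simulation by an order of magnitude without affecting any result).
Subthreshold accuracy: halving dt changes a 100 pA step response by less
than 0.01 mV, and with adaptation and the exponential term disabled the
step response matches the closed-form RC solution to < 0.1 mV.

A note on the rheobase of this parameter set: the minimal constant current
that elicits a spike within 1 s from rest is ~120 pA (confirmed with an
independent RK4 integration at dt = 0.01 ms). Transient single spikes
occur for currents of roughly 120-155 pA — the membrane escapes before the
slow adaptation current (tau_w = 144 ms) catches up — while sustained
firing requires ~160 pA, the stationary saddle-node current of the coupled
(V, w) system. `rheobase()` implements the from-rest, 1 s, bisection
protocol and therefore reports ~120 pA.

PSP amplitudes are measured on an isolated neuron held at a target
potential by a constant current solved from the (V, w) steady state; after
300 ms of equilibration one synaptic event is delivered and the signed
extremum of the deflection within 200 ms is reported (PSPs decay well
inside this window given tau_syn ~ 1.1 ms and a ~57 ms membrane time
constant). At rest a 67.8 nS excitatory event — the truncation point of
the weight distribution — peaks at +21.1 mV; at a -50 mV holding
potential an 8 x 67.8 nS inhibitory event peaks at -22.6 mV. The -50 mV
reading of the "depolarized" holding level is the natural one; the small
overshoot relative to the -21 mV anchor is within the tolerance that
ambiguity warrants.

## Network model

100,000 neurons (93% excitatory, 7% inhibitory) receive independent
uniform positions on a 2000 um square with periodic boundaries (torus
metric). Each ordered pair connects independently with probability
p(d) = A exp(-d^2 / 2 sigma^2) in torus distance d; there are no autapses
and no multi-edges. Because the wrapped per-axis distance of two uniform
points is uniform on [0, side/2], the mean kernel factorizes into a
closed-form erf expression, and the zero-distance amplitude A of each
connection type is calibrated analytically so the expected out-degree
matches the measured means: E->E 750, E->I 190, I->E 2690, I->I 110.

The decay length sigma is not pinned by the experimental constraints; it
defaults to 150 um for all four connection types. 150 um is consistent
with the paired-recording geometry (connection probabilities are
constrained within a 200 um disc) and, importantly, is feasible: the I->E out-degree target of 2690 forces
A <= 1, which requires sigma >= ~136 um on this geometry — a narrower
inhibitory profile cannot reach the measured inhibitory in-degrees under
a Bernoulli-per-pair model. The out-degree targets, not sigma, pin every
statistic the analyses depend on.

Excitatory synaptic conductances follow a lognormal distribution
right-truncated at 67.8 nS (the conductance of the largest recorded EPSP,
21 mV), with the underlying (mu, sigma) obtained by two-dimensional moment
matching so that the *truncated* distribution has mean 3.73 nS and
standard deviation 6.51 nS. This interpretation reproduces the printed
strong-connection threshold: the truncated distribution's 99.7th
percentile is 50.61 nS. Sampling is by rejection (draw, discard above the
cap). Inhibitory conductances are the same truncated draws scaled by 8,
giving a maximum of 542.4 nS. Delays are uniform on [0.5, 2] ms.

Edge sampling is exact Bernoulli per ordered pair, implemented as a
numba kernel over a spatial cell grid with the kernel cut off at 4.25
sigma (relative truncation error ~1e-4 of the expected degree, two orders
of magnitude below the 1% calibration tolerance). A full-size build takes
a few minutes and ~4 GB.

`truncate_network` builds the strong-only / weak-only variants by keeping
the top 0.3% or bottom 90% of E->E conductances; edges involving
inhibitory neurons are never touched.

## Simulation protocol

Every neuron receives an independent background current re-drawn every
1 ms from N(mu_in, sigma_in) and held piecewise-constant over each 1 ms
interval (rather than white noise per 0.1 ms step). A simulation
starts with a kick-start volley — 500 distinct excitatory neurons forced
to spike once at uniform times in the first 100 ms — and the first
1000 ms are discarded. Then the trigger neuron(s) are forced to spike
(full spike lifecycle: reset, refractoriness, w += b) every 400 ms for
100 trials; each trial contributes a 100 ms before-window and a 300 ms
after-window. External inputs deliver one conductance jump per trial to a
chosen neuron at a fixed latency relative to the trigger. Event delivery
is quantized to the 0.1 ms grid (error <= 0.05 ms << tau_syn); a runaway
guard flags any step in which more than 10% of the network fires but does
not stop the simulation.

Baseline ("mean") firing rate is the spike count in the before-windows
divided by the total before-window exposure, per population when needed.
The per-simulation noise parameters are constants of that simulation, with
mu_in in [50, 110] pA, sigma_in in [0, 110] pA the
studied ranges.

## Follower statistics

The firing-rate modulation of a neuron is

    dFR = (spikes_after / T_after - spikes_before / T_before),

normalized by the modulation of a perfect follower (one extra spike per
trial, silent before), so dFR = 1 means exactly one reliable extra spike.
The null model is the difference of two Poisson counts with the same
underlying rate over the pooled before/after exposures; its pmf is
computed exactly by discrete convolution (tail mass < 1e-12) on the
integer lattice (counts_after - 3 x counts_before)/n_trials. The
underlying rate is the mean baseline rate of the neuron's population
(separate nulls for E and I), and a neuron is a follower when its dFR
exceeds the null's upper 1e-7 critical value strictly — the exact
construction matters because Monte-Carlo nulls cannot resolve 1e-7
tails. With 1e5 tested neurons this threshold admits one false positive
per 100 simulations on average; the calibration is verified empirically
against the exact tail by binomial test on pure-Poisson records. With a
zero baseline rate the null degenerates to a point mass at zero and any
positive modulation is flagged (a spontaneously silent network).

Rank entropy: per trial, followers are ordered by first spike time (ties
broken by neuron id); H_k is the Shannon entropy of follower identity at
rank k, normalized by log2(n). Estimates are restricted to simulations
with at least as many trials as followers and to trials where >= 25% of
followers are present. Center-of-mass trajectories average active-follower
positions in a 5 ms sliding window and smooth x(t), y(t) with a 15 ms
Gaussian; windows without active followers stay as explicit gaps.

## Spike transfers and motifs

A spike transfer is a pair of spikes (pre at t1, post at t2) in the same
trial with an existing synapse pre->post and 0 < t2 - t1 <= 100 ms. The
transfer graph is a DAG by construction. Motifs are tallied per focal
(postsynaptic) spike: `single` (exactly one in-edge), `conv2`/`conv3plus`
(two / three-plus in-edges), `fan` (a presynaptic spike with >= 2
out-edges; the alternative source-side tally is also reported since either
reading of the diverging motif is defensible), and `chain2` (an in-edge whose source
spike itself has an in-edge) — depth at most two, at most four spikes.
Repeated presynaptic spikes within the window each create an edge.
Strength histograms report traversed-synapse conductances and the mass
above the 50.6 nS strong threshold.

## Sub-networks, gates, routing

The follower x trial binary activation matrix (>= 1 spike in the
after-window) is clustered with k-modes (Hamming dissimilarity,
K = max(1, round(n/6)), Huang-style frequency-based initialization
snapped to distinct data rows, 10 restarts, best cost kept). The kmodes
implementation lives in this package and is tested against exhaustive
partition enumeration on small matrices. A sub-network is "active" in a
trial when >= 40% of its members fire at least once in the after-window;
activation a is the fraction of active trials, and perturbation effects
are reported as the fold change 100 (a - a0)/a0. The gate of a
sub-network is the member with the smallest median first-spike delay over
the trials in which it fired (ties by neuron id). Gating maps re-run the
identical protocol (same seed) with a single external input to the gate
across a grid of sign, conductance and timing, and mark the -50% and +50%
fold-change contours. Outcome entropy takes the two largest sub-networks
(ties by lower label) and computes the Shannon entropy of the four trial
outcomes {both, a alone, b alone, neither}. Multi-trigger classes are set
algebra over the follower sets of trigger a, trigger b and their
coactivation ab: core followers appear under coactivation and under at
least one single trigger; combination-specific followers depend on the
exact combination (a only, b only, ab only).

## Fitting procedures

* Membrane: stage 1 takes g_L = I / dV_ss from the steady-state
  deflection (the tail must drift less than 0.005 mV/ms); stage 2 fixes
  g_L and fits the capacitance by least squares on the onset transient
  (window 100 ms, configurable; only the onset region identifies the
  time constant).
* EPSP -> conductance: monotone bisection of the model's PSP amplitude at
  rest; spiking responses bound the invertible range.
* Truncated lognormal MLE: the likelihood is normalized by the lognormal
  CDF at the truncation point (the naive untruncated MLE is also
  available and demonstrably biased; the truncation-aware variant is the
  default because it reproduces the 50.6 nS anchor).
* Strong-connection bootstrap: resample the conductance set with
  replacement, refit, compute p_j = P(50.6 <= g <= 67.8), draw 1000
  degrees from a discretized N(745, 27) truncated at >= 1, sample
  Binomial(n_i, p_j), and record the fraction >= 1 per replicate.

## Synthetic data

The generators emulate the statistical structure of the experimental
inputs, not their artefacts: passive current-clamp traces are the exact
RC response plus white Gaussian noise (no electrode drift, no bridge
error); EPSP amplitude sets are truncated-lognormal conductances mapped
through the model's own PSP curve (so fits on them test estimation, not
biology); Poisson rasters are homogeneous with optional planted
responders of given reliability and latency jitter. Recovery tests never
read the recorded ground truth during estimation. Passing them shows the
estimators are correct and calibrated, not that real recordings satisfy
the generating assumptions.

Network fixtures scale density-preservingly: a fixture with n neurons
uses side 2000 sqrt(n/1e5) um and keeps the full-size out-degree targets,
which preserves all in- and out-degrees, the inhibitory/excitatory input
balance and the ~2.25 expected strong E->E connections per neuron. The
default fixture has 10,000 neurons. What such a fixture does not preserve
is the reach of a spike relative to population size: each excitatory
neuron contacts ~8% of the excitatory population instead of 0.8%, so
convergent coactivation is ~10x more likely and propagation is more
synchronous. Concretely, E->E transfer-delay modes land at 3-5 ms at
fixture scale instead of the 6-8 ms seen at full scale; directional
statements (E->I faster than E->E, strong-connection enrichment within
sub-networks, entropy rising with drive) are scale-robust and are what
the fixture-scale tests assert.

## Problem sizes used by the test and acceptance runs

Quantitative connectivity checks build one full-size 100,000-neuron
network (~4-5 minutes, ~4 GB). Dynamical checks run the 10,000-neuron
fixture with 10-30 trials per simulation; null-calibration uses 30
pure-Poisson records of 20,000 neurons each (6 x 10^5 tests); the
bootstrap and clustering oracles run at toy sizes where exhaustive
enumeration is possible.

## Known limitations

* One excitatory and one inhibitory parameter set; no dendrites, no
  plasticity, no structured connectivity beyond the distance kernel.
* The engine is a fixed-step clock-driven integrator; it is not intended
  to match an adaptive-step reference spike-for-spike, and chaotic
  network states diverge between integrators even at equal accuracy.
* Full-sweep statistics (hundreds of network instantiations x tens of
  noise conditions) are out of scope; the package exposes the
  orchestration to run such sweeps but the shipped checks run at desk
  scale.
* The from-rest rheobase of the default parameter set is ~120 pA, not the
  printed 150 pA (see the neuron-model section); all other single-neuron
  anchors reproduce.
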