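# Methods

## Model

The network is a feed-forward relay chain with a recurrent cortical sheet.

**Input layer, 128×128.** Pure event sources with no dynamics: every ON
address-event is a spike of the matching pixel neuron at its timestamp.
OFF events are not modelled anywhere in the pipeline.

**LGN layer, 32×32.** Each relay cell pools a non-overlapping 4×4 input
tile with weight 1.0 and follows a plain leaky integrator,
`tau_L dV/dt = -V` with `tau_L = 10 ms`, spike threshold 0 mV, reset 0 mV
and a 10 ms refractory period during which the membrane is clamped and
deliveries are discarded. Because any single input spike lifts V above
threshold, the layer implements "first spike of a tile burst is relayed,
the rest are absorbed": an LGN cell fires at most 100 Hz no matter how
busy its tile is.

**Cortical layer, 60×60.** Current-based leaky integrate-and-fire
(Vogels–Abbott CUBA form):

    tau_m dV/dt = -V + g_e + g_i + N        tau_m = 5 ms

`g_e >= 0` and `g_i <= 0` decay exponentially with `tau_syn = 5 ms`; a
presynaptic spike adds its weight to the matching term after the synaptic
delay. `N` is a positive background-noise drive shared by no one —
each neuron integrates its own mean-reverting process

    N' = N + (dt/tau_n)(mu - N) + sd*sqrt(2 dt/tau_n)*xi,   xi ~ N(0,1)

with `mu = 0.7`, `sd = 0.5`, `tau_n = 5 ms`, clipped at zero so the drive
stays positive. The clip is the one concession to positivity: it biases
the stationary mean upward, to about 0.77 (the unclipped process would sit
at 0.70 with the same spread). A truly exponentially distributed
stationary law cannot be realised by a Gaussian-driven mean-reverting
process; the clipped process reproduces the mean, scale and correlation
time, which is what the dynamics are sensitive to.

Thresholds are per-neuron: 1.0 mV plus truncated-Gaussian noise on
[0, 0.3] mV (mean 0.15, sd 0.075) — "normally distributed between 0 and
0.3" admits several readings; the truncated normal honours both the range
and the shape. Reset is 0 mV, refractory period 5 ms.

## Wiring

20% of cortical neurons (exactly 720 of 3600) are drawn uniformly and
labelled inhibitory. Probability profiles attach to the **source**
neuron's type: excitatory sources connect to a target at distance d with
probability `exp(-d/3.5)`, forced to zero beyond 5 grid units (inclusive);
inhibitory sources with probability `exp(-8/d)` inside the annulus
5 < d ≤ 21 — note the probability *rises* with distance inside the
annulus, giving the long-range inhibitory surround its weight at the rim.
One Bernoulli draw per ordered pair, no self-connections, at most one
synapse per pair. Weights are U[0.3, 0.4] (excitatory) or U[-0.4, -0.3]
(inhibitory). Delays are `d + N(0, 0.5)` ms — one grid unit of distance
costs one millisecond — clipped below at the integration step. Distance
is plain Euclidean on the open sheet; there is no wraparound.

Afferent connection fields centre each cortical neuron (r, c) on the LGN
position `(r*31/59, c*31/59)` rounded to the nearest cell, so corners map
to corners and coverage of the 32×32 sheet is uniform; fields are clipped
at the borders (edge neurons receive fewer afferents). The `random`
regime connects each (LGN, cortex) pair with p = 0.2; `full` connects all
pairs. Afferent weights are U[0.4, 0.5] with minimal delay. Inhibitory
cortical neurons receive afferents like any other neuron.

The reduced-inhibition manipulation multiplies the inhibitory probability
by an indicator `d <= 8`, removing roughly 95% of inhibitory synapses
while leaving excitation untouched.

## Integration

Clock-driven, dt = 0.1 ms by default, exponential-Euler updates (exact
for the linear decays between deliveries; drive is held constant within a
step). Delayed deliveries are routed through a ring buffer keyed by
arrival step; delays are quantised to the nearest step with a one-step
floor. Per step the order is: deliver, decay, integrate, threshold.
Membrane voltage is frozen at reset during the refractory period, but
synaptic terms keep decaying and accumulating.

Two engines share this update order: a numba kernel for production and a
pure-Python stepper used as the readable reference. Gaussian noise
increments are drawn up front from the run seed and consumed identically
by both, so the engines agree spike for spike and every run is bit-exact
replayable from `(network seed, stimulus seed, run seed)`.

A toy-circuit convergence check (3-neuron chain) verifies spike times move
by less than 0.05 ms when dt is halved.

## Stimuli

The synthetic generator emulates logged recordings of a bright bar
sweeping a dark field in one of eight compass directions, as an event
camera reports them: ON events only, emitted from the bar's leading edge.
For every pixel the edge passes over, events are Poisson with rate
200 events/s per pixel during the ~1-pixel crossing window (about 1.6
expected events per pixel at the default speed). Defaults: bar 8 px along
motion, 128 px across (spanning the field), speed 128 px/s so a cardinal
traversal takes 1.0 s (diagonals take sqrt(2) times longer); the stimulus
geometry is deliberately generous so that every afferent field is swept
once per presentation. Instances differ by Poisson seed and a lateral
offset of the bar. Timestamps are integer microseconds; simultaneous
events order by (y, x). A deterministic mode (exactly one event per pixel
crossing) supports exact unit tests.

What the generator does **not** emulate: background/noise events, hot
pixels, OFF transients, contrast- and illumination-dependent event rates,
motion jitter, and partial-field bar trajectories. Synthetic streams are
therefore considerably cleaner and more spatially uniform than camera
logs. Passing tests show the architecture produces selectivity and
structured maps under idealised motion; they do not certify the exact SI
or gradient magnitudes a particular camera recording would yield — two
regimes are visibly sensitive to this (see Limitations).

The AER container is this package's own fixed layout (4-byte big-endian
address: bit 0 polarity, bits 1–8 x, bits 9–16 y; then 4-byte big-endian
microsecond timestamp); no compatibility with .aedat dialects is
attempted.

## Analysis conventions

Compass directions map to mathematical angles on the image plane: E = 0°,
N = 90°, W = 180°, S = 270°. Rates are spike counts divided by the
presentation duration (which differs between cardinal and diagonal
sweeps), averaged over instances. Orientation preference averages rates
over opposite direction pairs, doubles angles, and halves the resultant
angle back into [0, 180); negative angles are wrapped by +360° (direction)
or +180° (orientation). Neurons with all-zero rates get SI 0, an
undefined angle, and are excluded from gradients and preference
statistics. Gradient differences are folded circularly into [-180, 180]:
raw differences would make the statistic depend on the arbitrary 0° cut,
which contradicts its use as a fracture measure. Pooled SI means average
over all neurons of all networks (not over per-network means); the mean
gradient averages each map's interior mean across networks.

## Protocol and problem sizes

The full protocol is 5 networks × 10 instances × 8 directions per
variant. The packaged acceptance script uses a reduced protocol —
2 networks × 5 instances × 8 directions at the full 60×60 geometry and
dt = 0.1 ms — for the quantitative variants (cf3, cf5, cf7,
cf5 + reduced inhibition); the test suite additionally runs the wider
manipulation sweep (random, full, full + reduced inhibition) at
2 networks × 2 instances, which is sufficient for the ordering claims it
checks. A smaller smoke geometry (64×64 → 16×16 → 12×12, sigmas scaled
accordingly) backs the fast unit tests.

Seeds: one master seed expands through named SeedSequence keys into
wiring, threshold, stimulus and noise sub-seeds, so any single
presentation can be replayed in isolation. Stimulus seeds depend only on
(direction, instance): the same stimulus library is shown to every
network and variant, like a fixed set of recordings.

Rank statistics (Kruskal–Wallis omnibus, pairwise Mann–Whitney,
two-sided, alpha = 0.05, uncorrected) are delegated to SciPy.

## Limitations

* **Saturation under strong afferents.** With the default full-field bar
  and event rate, LGN drive is strong; a 7×7 connection field sums ~49
  afferents and pushes neurons to refractory-limited rates in every sweep
  direction, so selectivity *decreases* monotonically with field size
  here. Weaker or sparser input (as real camera logs provide) moves the
  optimum toward larger fields; the peak location is not an invariant of
  the architecture but of the architecture–stimulus pairing.
* **Ignition under reduced inhibition.** Cutting inhibition beyond 8 grid
  units removes ~95% of inhibitory synapses; with the background noise
  sitting within a standard deviation of threshold, recurrent excitation
  is then supercritical and the sheet self-sustains near the refractory
  limit, collapsing selectivity to ~0 rather than merely degrading it.
  The directional claims (reduced < intact, with full afferents lowest)
  are robust; the absolute SI level in this regime is not.
* Synthetic stimuli are cleaner than camera logs, so maps average smoother
  and gradient magnitudes land a few degrees below values measured from
  real recordings.
* The noise process approximates an exponential stationary law by a
  clipped Gaussian OU process (see above).
* No plasticity of any kind: the package deliberately stops at the innate
  map.
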