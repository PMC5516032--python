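# Methods

## Model

**Neurons.** Output units are leaky integrate-and-fire neurons,

    C dV/dt = g_L (E_L − V) + g (E_syn − V) + I_noise
    dg/dt   = −g/τ_syn + c_syn Σ_i w_ij S_i(t)

with C = 1, g_L = 0.4, E_L = −65, E_syn = −5, spike threshold −55,
τ_syn = 3 ms, c_syn = 0.12 per input spike, and fresh Gaussian current
noise (σ = 1.2) per neuron per step.  All constants are treated as
dimensionless numbers in a consistent system with dt = 1 ms; the
effective membrane time constant is C/g_L = 2.5 ms.  Integration is
explicit forward Euler with both derivatives evaluated at the previous
state, so an input spike at step t is felt by the voltage at step t+1.
A neuron whose updated voltage reaches threshold spikes and resets to
E_L within the same step; there is no refractory period and no
conductance reset.  Input units are spike sources (no dynamics).

The membrane noise is deliberately strong: an untrained network fires
only when noise and coincident EPSPs cooperate, and this
stochastic-resonance firing is what lets STDP engage at the start of
learning.

**Network.** 50 input and 50 output neurons; each of the 2500 pairs is
connected independently with probability 0.2; initial weights are
Normal(0.5, 0.05) clipped to [0, 1].  The connectivity mask is fixed;
only weights are plastic.

**Plasticity.** Pair-based STDP with weight-dependent learning rate
(see README for the kernel and the AR / SR / hybrid rate profiles).
Implementation notes:

* The LTD branch uses a decaying magnitude `exp(−|Δt|/τ₋)`; a literal
  reading of the kernel with a positive exponent for negative lags
  diverges and is treated as a typographical artifact.
* Exact pre/post coincidence (Δt = 0) takes the LTD branch.
* Pairing is all-to-all, implemented with exponentially decaying pre-
  and postsynaptic traces (one per neuron), which is O(1) per spike and
  mathematically identical to summing over all spike pairs.  The
  nominal `pairing_window` (7·max(τ) = 105 ms) documents the horizon
  beyond which a pair contributes less than e⁻⁷ of its peak.
* Within a step: LTP is applied at postsynaptic spikes against the pre
  trace (which excludes same-step presynaptic spikes, so coincident
  pairs are not double-counted as LTP), then LTD at presynaptic spikes
  against the post trace (which includes same-step postsynaptic
  spikes).  Weights are clipped to [0, 1] after every update.

**Kernel asymmetry and its consequences.** The printed kernel constants
make the LTD area |k₋|τ₋ = 1.35 about 7.5 times the LTP area
k₊τ₊ = 0.18.  Under *uncorrelated* pre/post firing the weight drift is
therefore depression-dominated: the stationary weight of the
multiplicative (AR) rule under Poisson pairing sits near
k₊τ₊/(k₊τ₊+|k₋|τ₋) ≈ 0.12 rather than at the instability minimum 0.5
that the Boltzmann argument predicts for amplitude-balanced random
walks.  Potentiation in this model is driven by *causal* correlation
(an input spike firing its target within a few ms), which training
provides and background noise does not.  Two observable consequences,
verified by the test suite: the single-synapse AR histogram under
independent Poisson firing peaks near 0.1, not mid-range; and
background-driven erasure is fast (tens of seconds) for every rule
whose learning rate stays positive at the bounds, so the hybrid decay
sweep transitions abruptly near α = 1 instead of linearly.

## Stationary-density predictor

`boltzmann_density` returns p(w) ∝ exp(−β·[ε₊(w)² + ε₋(w)²]), the
stationary density of an amplitude-balanced random walk in the
instability landscape.  β (default 8) is a free inverse-temperature
parameter; only the mode structure of the density is meaningful, and
only modality is asserted anywhere.

## Protocols and conventions

All experiments run over a cohort of networks (default 100; the
shipped tests use 20, sweeps 10 — chosen so a full suite completes in
minutes on one CPU while keeping rank-sum comparisons well-powered).
A master seed spawns one stream per network, split into a *weight
stream* (everything that can alter weights) and a *probe stream*
(membrane noise of frozen-weight tests), so probes can never perturb
an experiment and profiles share identical networks, patterns and
noise for paired comparisons.

* **Training**: one pattern presented back-to-back (1000 × 100 ms =
  100 s) with plasticity on; membrane state starts from rest at each
  session.
* **Testing**: 20 frozen-weight presentations, membrane noise on;
  responses binarized per trial (spiked at least once → 1); memory
  index per the README formula; a fully silent response set scores 0 by
  convention.  The engram ("output pattern") is the set of neurons
  responding in strictly more than 80 % of trials.
* **Decay**: after training, every neuron — input and output alike —
  fires an independent 5-Hz Poisson train for the decay period with
  plasticity on.  Output background spikes are imposed directly (they
  reset the voltage and engage STDP like threshold spikes); this keeps
  erasure going even once weights are too weak for input spikes to
  fire the outputs.  MI(0) is measured by a clean test session before
  the decay starts; later probes sample the network *inside* its noisy
  operating environment (pattern riding on the ongoing background), so
  an erased network shows a sparse random-response floor rather than
  silence.  The maintained ratio is evaluated at 800 s.
* **Appending**: patterns trained sequentially (default P1 for 100 s,
  then P2…P7 for 200 s each); at every 100 s of training, MI is probed
  for each pattern trained so far plus one held-out untrained pattern.
  Probes here are plain clean tests (no background — appending sessions
  have none).
* **Hybrid sweeps**: decay or append repeated over an α grid with
  matched seeds; the append variant uses P1 (100 s) + one appended
  pattern and tracks MI(P1) through the appending session.
* **Statistics**: two-sided Mann-Whitney rank-sum at the cohort level,
  no multiple-testing correction.

## Synthetic inputs

Patterns give each input neuron exactly one uniform-random integer
millisecond in a 100-ms window (10 Hz per neuron); times are drawn with
replacement and discretized to the 1-ms integration grid.  Background
activity is Bernoulli-per-step Poisson.  These generators emulate the
study's idealized stimulus statistics only: real spike trains have
refractoriness, rate fluctuations and correlations that are absent
here, so passing tests certify the model's behaviour under these
idealized conditions, not under physiological input.

## Numerical choices and degenerate inputs

* Weight updates are clipped after every event; masked-out entries are
  pinned at exactly 0.
* The single-synapse Monte-Carlo uses continuous event times
  (exponential gaps) and per-trial seeds derived from one SeedSequence;
  rate 0 returns the initial uniform draws unchanged.
* A NaN membrane state aborts the run (numerical blow-up is never
  silently absorbed).
* Maintained ratios are undefined when MI(0) = 0; cohort summaries drop
  such seeds (none occur at the default noise level).
* Seeds handed to the compiled kernels are reduced below 2³¹.

## Known limitations

* No inhibition, recurrence, refractoriness or homeostasis; excitatory
  feedforward only.
* Spike times are resolved at 1 ms; no event-driven sub-step timing.
* SR assembly weights saturate to within ~1e−15 of the bounds after
  100 s of training, where the symmetric rate vanishes; saturated
  synapses are then numerically frozen, so the SR maintained ratio
  stays in the 0.97-1.0 range rather than decaying by the ~12 % a partly
  unsaturated assembly would show.
* With the depression-dominated kernel (see above), intermediate-α
  hybrid rules erase fully within the 800-s decay horizon; the decay
  sweep is therefore a step function of α rather than a linear ramp,
  while the appending sweep's abrupt transition near α = 1 is
  reproduced.
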