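"""Leaky integrate-and-fire layer with sparse plastic feedforward input.

Membrane dynamics of output neuron j:

    C dV_j/dt = g_L (E_L - V_j) + g_j (E_syn - V_j) + I_noise
    dg_j/dt   = -g_j / tau_syn + c_syn * sum_i w_ij S_i(t)

integrated by explicit forward Euler at ``dt`` (both derivatives
evaluated at the previous state); when V_j crosses threshold a spike is
emitted and V_j resets to E_L within the same step.  I_noise is fresh
Gaussian current noise per neuron per step; it is what lets a naive
network begin firing (stochastic resonance) so STDP can engage.

All parameters are treated as dimensionless numbers in a consistent
system with dt = 1 ms; the effective membrane time constant is
C/g_L = 2.5 ms and the synaptic decay tau_syn = 3 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from stdpmem.plasticity import STDPConfig
from stdpmem.stimuli import SpikeTrains

__all__ = ["LIFParams", "LIFState", "FeedforwardNetwork", "build_network", "step", "run"]


@dataclass(frozen=True)
class LIFParams:
    """Membrane and synapse constants (dimensionless consistent units)."""

    C: float = 1.0
    g_L: float = 0.4
    E_L: float = -65.0
    E_syn: float = -5.0
    E_threshold: float = -55.0
    tau_syn: float = 3.0
    c_syn: float = 0.12
    noise_sigma: float = 1.2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_syn <= 0:
            raise ValueError("dt and tau_syn must be > 0")
        if not (self.E_L < self.E_threshold < self.E_syn):
            raise ValueError("need E_L < E_threshold < E_syn")
        if self.C <= 0 or self.g_L <= 0 or self.c_syn <= 0:
            raise ValueError("C, g_L and c_syn must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LIFState:
    """Per-neuron dynamic variables."""

    V: np.ndarray  # membrane voltage
    g: np.ndarray  # synaptic conductance

    @classmethod
    def resting(cls, n: int, params: LIFParams) -> "LIFState":
        return cls(V=np.full(n, params.E_L), g=np.zeros(n))

    def validate(self) -> None:
        if not (np.isfinite(self.V).all() and np.isfinite(self.g).all()):
            raise FloatingPointError("non-finite membrane state: numerical blow-up")
        if np.any(self.g < 0):
            raise ValueError("conductance must be >= 0")


@dataclass
class FeedforwardNetwork:
    """Sparse random feedforward coupling between input and output layers.

    ``mask`` fixes the connectivity at construction; ``W`` holds the
    plastic weights, exactly 0 wherever ``mask`` is False.
    """

    n_in: int
    n_out: int
    mask: np.ndarray  # (n_in, n_out) bool
    W: np.ndarray  # (n_in, n_out) float64
    params: LIFParams = field(default_factory=LIFParams)
    stdp: STDPConfig = field(default_factory=STDPConfig)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.W = np.ascontiguousarray(self.W, dtype=np.float64)
        if self.mask.shape != (self.n_in, self.n_out) or self.W.shape != self.mask.shape:
            raise ValueError("mask and W must both be (n_in, n_out)")
        self.validate_weights()

    def validate_weights(self) -> None:
        on = self.W[self.mask]
        if on.size and (on.min() < self.stdp.w_min or on.max() > self.stdp.w_max):
            raise ValueError("masked weights must lie within [w_min, w_max]")
        if np.any(self.W[~self.mask] != 0.0):
            raise ValueError("weights must be exactly 0 where mask is False")

    @property
    def n_connections(self) -> int:
        return int(self.mask.sum())

    def _csr(self):
        """Row- and column-compressed index form of the mask."""
        rows = [np.flatnonzero(self.mask[i]) for i in range(self.n_in)]
        cols = [np.flatnonzero(self.mask[:, j]) for j in range(self.n_out)]
        row_ptr = np.zeros(self.n_in + 1, dtype=np.int64)
        row_ptr[1:] = np.cumsum([r.size for r in rows])
        col_ptr = np.zeros(self.n_out + 1, dtype=np.int64)
        col_ptr[1:] = np.cumsum([c.size for c in cols])
        row_idx = (
            np.concatenate(rows).astype(np.int64)
            if row_ptr[-1]
            else np.empty(0, np.int64)
        )
        col_idx = (
            np.concatenate(cols).astype(np.int64)
            if col_ptr[-1]
            else np.empty(0, np.int64)
        )
        return row_ptr, row_idx, col_ptr, col_idx


def build_network(
    n_in: int = 50,
    n_out: int = 50,
    p_connect: float = 0.2,
    w_mean: float = 0.5,
    w_sd: float = 0.05,
    seed: int | None = None,
    params: LIFParams | None = None,
    stdp: STDPConfig | None = None,
) -> FeedforwardNetwork:
    """Sample a sparse random network with Gaussian initial weights.

    Each input-output pair is connected independently with probability
    ``p_connect``; existing weights are drawn from
    ``Normal(w_mean, w_sd)`` and clipped to the STDP weight bounds.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be >= 1")
    if not 0.0 < p_connect <= 1.0:
        raise ValueError("p_connect must lie in (0, 1]")
    if w_sd < 0:
        raise ValueError("w_sd must be >= 0")
    stdp = stdp or STDPConfig()
    rng = np.random.default_rng(seed)
    mask = rng.random((n_in, n_out)) < p_connect
    W = np.zeros((n_in, n_out))
    W[mask] = np.clip(
        rng.normal(w_mean, w_sd, size=int(mask.sum())), stdp.w_min, stdp.w_max
    )
    return FeedforwardNetwork(
        n_in=n_in,
        n_out=n_out,
        mask=mask,
        W=W,
        params=params or LIFParams(),
        stdp=stdp,
    )


def step(
    state: LIFState,
    params: LIFParams,
    presyn_spikes: np.ndarray,
    network: FeedforwardNetwork,
    rng: np.random.Generator | None = None,
) -> tuple[LIFState, np.ndarray]:
    """One forward-Euler step of the output layer (weights frozen).

    Both the conductance and voltage derivatives are evaluated at the
    incoming state; a neuron whose updated voltage reaches threshold
    spikes and resets to ``E_L`` in the same step.  Returns the new
    state and the binary output spike vector.
    """
    presyn_spikes = np.asarray(presyn_spikes)
    if presyn_spikes.shape != (network.n_in,):
        raise ValueError("presyn_spikes must have length n_in")
    if state.V.shape != (network.n_out,):
        raise ValueError("state size must match n_out")
    state.validate()

    dt = params.dt
    drive = params.c_syn * (presyn_spikes.astype(float) @ network.W)
    g_new = state.g + dt * (-state.g / params.tau_syn + drive)
    if params.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        noise = params.noise_sigma * rng.standard_normal(network.n_out)
    else:
        noise = 0.0
    dV = (
        params.g_L * (params.E_L - state.V)
        + state.g * (params.E_syn - state.V)
        + noise
    )
    V_new = state.V + (dt / params.C) * dV
    spikes = (V_new >= params.E_threshold).astype(np.uint8)
    V_new = np.where(spikes == 1, params.E_L, V_new)
    new_state = LIFState(V=V_new, g=g_new)
    new_state.validate()
    return new_state, spikes


def run(
    network: FeedforwardNetwork,
    inputs: SpikeTrains,
    plastic: bool = False,
    seed: int | None = None,
    snapshot_every_ms: float | None = None,
    forced_output: SpikeTrains | None = None,
) -> tuple[SpikeTrains, FeedforwardNetwork, dict[float, np.ndarray] | None]:
    """Simulate the network over a full input raster.

    Starts from the resting state.  When ``plastic``, trace-based STDP
    updates (with clipping) are applied at every pre- and postsynaptic
    spike on connected pairs; otherwise the weights are untouched.
    ``forced_output`` optionally imposes background spikes directly on
    the output neurons (spontaneous network activity during a decay
    session); forced spikes reset the voltage and engage STDP exactly
    like threshold-driven spikes.  The input network object is never
    mutated -- the returned network carries the final weights.

    Returns ``(output spikes, final network, snapshots)`` where
    snapshots maps time in ms to a weight-matrix copy (or None if not
    requested).
    """
    if inputs.n_neurons != network.n_in:
        raise ValueError("input raster row count must equal n_in")
    if inputs.dt != network.params.dt:
        raise ValueError("input raster dt must match the integrator dt")
    if forced_output is not None and (
        forced_output.n_neurons != network.n_out
        or forced_output.n_steps != inputs.n_steps
    ):
        raise ValueError("forced_output raster must be n_out x n_steps")
    from stdpmem._kernels import run_network

    p, s = network.params, network.stdp
    row_ptr, row_idx, col_ptr, col_idx = network._csr()
    W = network.W.copy()

    T = inputs.n_steps
    if snapshot_every_ms is None:
        bounds = [T]
    else:
        every = int(round(snapshot_every_ms / p.dt))
        if every < 1:
            raise ValueError("snapshot_every_ms must be >= dt")
        bounds = list(range(every, T, every)) + [T]

    forced = (
        np.zeros((0, 0), dtype=np.uint8)
        if forced_output is None
        else forced_output.raster
    )
    kseed = int(np.random.SeedSequence(seed).generate_state(1, dtype=np.uint32)[0] >> 1)
    V = np.full(network.n_out, p.E_L)
    g = np.zeros(network.n_out)
    x_pre = np.zeros(network.n_in)
    y_post = np.zeros(network.n_out)
    out = np.zeros((network.n_out, T), dtype=np.uint8)
    snapshots: dict[float, np.ndarray] | None = (
        {} if snapshot_every_ms is not None else None
    )
    start = 0
    for b in bounds:
        out[:, start:b] = run_network(
            W, V, g, x_pre, y_post,
            row_ptr, row_idx, col_ptr, col_idx,
            np.ascontiguousarray(inputs.raster[:, start:b]),
            np.ascontiguousarray(forced[:, start:b]) if forced.size else forced,
            p.C, p.g_L, p.E_L, p.E_syn, p.E_threshold, p.tau_syn, p.c_syn,
            p.noise_sigma, p.dt,
            s.k_plus, s.k_minus, s.tau_plus, s.tau_minus,
            s.profile_code, s.alpha, s.w_min, s.w_max,
            plastic, (kseed + start) % 2147483647,
        )
        if snapshots is not None:
            snapshots[b * p.dt] = W.copy()
        start = b
    final = replace(network, W=W if plastic else network.W.copy())
    return SpikeTrains(raster=out, dt=p.dt), final, snapshots
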