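"""Weight-dependent STDP: kernel, learning-rate profiles, stability analysis.

The plasticity rule is pair-based STDP.  A spike pair with timing
difference ``dt = t_post - t_pre`` changes the synaptic weight by

    dw = eps_+(w) * k_+ * exp(-dt/tau_+)      dt > 0   (LTP)
    dw = eps_-(w) * k_- * exp(-|dt|/tau_-)    dt <= 0  (LTD)

where ``eps_+/-`` is a weight-dependent learning rate.  Two profiles are
implemented, plus their convex combination:

* **AR** (asymmetric rate, the classic multiplicative rule):
  ``eps_+ = w_max - w``, ``eps_- = w - w_min``.  Weak synapses
  potentiate easily and strong ones depress easily, so every synapse is
  attracted to mid-range weight.
* **SR** (symmetric rate): ``eps_+ = eps_- = 2*min(w_max - w, w - w_min)``.
  Plasticity is maximal at mid-range and vanishes at both bounds, so
  saturated synapses are frozen -- the rule is bistable.
* **HYBRID**: ``alpha*SR + (1-alpha)*AR``.

The expected squared weight change ``eps_+(w)^2 + eps_-(w)^2`` defines a
synaptic *instability* landscape; treating weight drift under random
spike pairing as a random walk in that landscape gives a Boltzmann-like
stationary density ``p(w) ~ exp(-beta * instability(w))`` whose modes
predict where a synapse driven by uncorrelated Poisson firing settles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Profile",
    "STDPConfig",
    "DensityEstimate",
    "learning_rate",
    "kernel_delta_w",
    "instability",
    "boltzmann_density",
    "simulate_single_synapse",
]


class Profile(enum.Enum):
    """Learning-rate profile selector."""

    AR = "AR"
    SR = "SR"
    HYBRID = "HYBRID"


# integer codes shared with the compiled kernels
_PROFILE_CODE = {Profile.AR: 0, Profile.SR: 1, Profile.HYBRID: 2}


@dataclass(frozen=True)
class STDPConfig:
    """Constants of the STDP kernel and the learning-rate profile.

    Parameters
    ----------
    k_plus, k_minus
        LTP / LTD kernel amplitudes (dimensionless).  ``k_plus`` must be
        positive and ``k_minus`` negative.
    tau_plus, tau_minus
        Exponential decay constants of the LTP / LTD kernel branches, in ms.
    profile
        One of :class:`Profile` (``AR``, ``SR`` or ``HYBRID``).
    alpha
        SR proportion in the hybrid rule; ignored for pure AR / SR.
    w_min, w_max
        Hard weight bounds; weights are clipped to this interval after
        every update.
    pairing_window
        Nominal spike-pairing horizon in ms.  Pairing is implemented with
        exponentially decaying synaptic traces, which is equivalent to
        all-to-all pairing; beyond this horizon (7 * max(tau)) a pair's
        contribution is below ``exp(-7)`` of its peak and is negligible.
    """

    k_plus: float = 0.06
    k_minus: float = -0.09
    tau_plus: float = 3.0
    tau_minus: float = 15.0
    profile: Profile = Profile.AR
    alpha: float = 0.0
    w_min: float = 0.0
    w_max: float = 1.0
    pairing_window: float = field(default=105.0)

    def __post_init__(self) -> None:
        if self.k_plus <= 0:
            raise ValueError(f"k_plus must be > 0, got {self.k_plus}")
        if self.k_minus >= 0:
            raise ValueError(f"k_minus must be < 0, got {self.k_minus}")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")
        if isinstance(self.profile, str):  # tolerate plain strings from config files
            object.__setattr__(self, "profile", Profile(self.profile.upper()))

    @property
    def profile_code(self) -> int:
        return _PROFILE_CODE[self.profile]

    @property
    def effective_alpha(self) -> float:
        """SR share actually applied: 0 for AR, 1 for SR, alpha for HYBRID."""
        if self.profile is Profile.AR:
            return 0.0
        if self.profile is Profile.SR:
            return 1.0
        return self.alpha

    # -- config-file round trip -------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile"] = self.profile.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "STDPConfig":
        d = dict(d)
        if "profile" in d:
            d["profile"] = Profile(str(d["profile"]).upper())
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "STDPConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DensityEstimate:
    """Stationary weight density on a grid over ``[w_min, w_max]``."""

    grid: np.ndarray
    density: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        area = np.trapezoid(self.density, self.grid)
        if abs(area - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1, got {area}")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


def _check_weight(w: float, config: STDPConfig) -> None:
    if not (config.w_min <= w <= config.w_max):
        raise ValueError(
            f"weight {w} outside bounds [{config.w_min}, {config.w_max}]"
        )


def learning_rate(w: float, direction: str, config: STDPConfig) -> float:
    """Weight-dependent learning rate ``eps(w)`` for one update direction.

    Parameters
    ----------
    w
        Current synaptic weight, within ``[w_min, w_max]``.
    direction
        ``"LTP"`` or ``"LTD"``.
    """
    _check_weight(w, config)
    if direction not in ("LTP", "LTD"):
        raise ValueError(f"direction must be 'LTP' or 'LTD', got {direction!r}")
    ar = (config.w_max - w) if direction == "LTP" else (w - config.w_min)
    sr = 2.0 * min(config.w_max - w, w - config.w_min)
    a = config.effective_alpha
    return a * sr + (1.0 - a) * ar


def kernel_delta_w(delta_t: float, w: float, config: STDPConfig) -> float:
    """Weight change for a single spike pair with timing ``delta_t`` (ms).

    ``delta_t = t_post - t_pre``.  Positive timing takes the LTP branch,
    non-positive timing (including exact coincidence) the LTD branch.
    Both branches decay exponentially in ``|delta_t|``.
    """
    if not np.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    _check_weight(w, config)
    if delta_t > 0:
        eps = learning_rate(w, "LTP", config)
        return eps * config.k_plus * np.exp(-delta_t / config.tau_plus)
    eps = learning_rate(w, "LTD", config)
    return eps * config.k_minus * np.exp(-abs(delta_t) / config.tau_minus)


def instability(w: float, config: STDPConfig) -> float:
    """Synaptic instability ``eps_+(w)^2 + eps_-(w)^2``.

    The expected squared weight change at weight ``w``; minima of this
    landscape are the stable weights of the rule.
    """
    ep = learning_rate(w, "LTP", config)
    em = learning_rate(w, "LTD", config)
    return ep * ep + em * em


def boltzmann_density(
    config: STDPConfig, beta: float = 8.0, n_grid: int = 201
) -> DensityEstimate:
    """Boltzmann stationary density ``p(w) ~ exp(-beta * instability(w))``.

    ``beta`` plays the role of an inverse temperature for the random walk
    of the weight under uncorrelated spike pairing; it is a free
    parameter of the approximation, so only the mode structure of the
    density (not its detailed shape) is meaningful.
    """
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if n_grid < 3:
        raise ValueError(f"n_grid must be >= 3, got {n_grid}")
    grid = np.linspace(config.w_min, config.w_max, n_grid)
    inst = np.array([instability(w, config) for w in grid])
    p = np.exp(-beta * inst)
    p /= np.trapezoid(p, grid)
    return DensityEstimate(grid=grid, density=p, beta=beta)


def simulate_single_synapse(
    config: STDPConfig,
    duration: float = 1000.0,
    rate: float = 10.0,
    n_trials: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo stationary weights of one synapse under Poisson pairing.

    A presynaptic and a postsynaptic neuron fire independent Poisson
    trains at ``rate`` Hz for ``duration`` seconds.  Each trial starts
    from a uniform-random weight in ``[w_min, w_max]`` and applies the
    pair-based STDP rule (via exponentially decaying pre/post traces,
    equivalent to all-to-all pairing) with clipping after every update.

    Returns the final weight of each trial, shape ``(n_trials,)``.
    """
    if duration <= 0 or n_trials <= 0:
        raise ValueError("duration and n_trials must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    from stdpmem._kernels import single_synapse_trials

    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(n_trials, dtype=np.uint32) >> np.uint32(1)
    return single_synapse_trials(
        float(duration) * 1000.0,  # ms
        float(rate) / 1000.0,  # spikes per ms
        trial_seeds.astype(np.int64),
        config.k_plus,
        config.k_minus,
        config.tau_plus,
        config.tau_minus,
        config.profile_code,
        config.alpha,
        config.w_min,
        config.w_max,
    )
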