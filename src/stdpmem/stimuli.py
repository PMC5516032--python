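"""Input generators: temporal spike patterns and Poisson background trains.

A memory item is a *temporal input pattern*: every input neuron fires
exactly once at a random integer millisecond inside a fixed window
(default 50 neurons, 100 ms, i.e. 10 Hz per neuron).  Training presents
the same pattern back-to-back many times; spontaneous background
activity is modelled as independent per-neuron Poisson trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InputPattern",
    "SpikeTrains",
    "make_pattern",
    "tile_pattern",
    "poisson_train",
    "save_pattern_library",
    "load_pattern_library",
]


@dataclass(frozen=True)
class SpikeTrains:
    """Binary spike raster, ``raster[i, t] = 1`` if neuron i spikes at step t."""

    raster: np.ndarray  # (n_neurons, n_steps) uint8
    dt: float = 1.0  # ms per step

    def __post_init__(self) -> None:
        r = np.ascontiguousarray(np.asarray(self.raster, dtype=np.uint8))
        if r.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x time steps)")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        object.__setattr__(self, "raster", r)

    @property
    def n_neurons(self) -> int:
        return self.raster.shape[0]

    @property
    def n_steps(self) -> int:
        return self.raster.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def spike_count(self) -> int:
        return int(self.raster.sum())

    # -- sparse event-list round trip -------------------------------------
    def to_events(self) -> pd.DataFrame:
        """Sparse event list with columns ``neuron_id, time_ms``."""
        i, t = np.nonzero(self.raster)
        order = np.lexsort((i, t))
        return pd.DataFrame(
            {"neuron_id": i[order], "time_ms": t[order] * self.dt}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_events().to_csv(path, index=False)

    @classmethod
    def from_events(
        cls, events: pd.DataFrame, n_neurons: int, n_steps: int, dt: float = 1.0
    ) -> "SpikeTrains":
        raster = np.zeros((n_neurons, n_steps), dtype=np.uint8)
        idx = (np.asarray(events["time_ms"]) / dt).round().astype(int)
        raster[np.asarray(events["neuron_id"], dtype=int), idx] = 1
        return cls(raster=raster, dt=dt)

    @classmethod
    def from_csv(
        cls, path: str | Path, n_neurons: int, n_steps: int, dt: float = 1.0
    ) -> "SpikeTrains":
        return cls.from_events(pd.read_csv(path), n_neurons, n_steps, dt)


@dataclass(frozen=True)
class InputPattern:
    """One-spike-per-neuron temporal pattern inside a fixed window.

    ``spike_times[i]`` is the integer millisecond at which neuron ``i``
    fires; every neuron fires exactly once per window, so the implied
    per-neuron rate is ``1000 / window`` Hz.
    """

    n_neurons: int
    window: int  # ms
    spike_times: np.ndarray  # (n_neurons,) int

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=np.int64)
        if st.shape != (self.n_neurons,):
            raise ValueError("need exactly one spike time per neuron")
        if st.min() < 0 or st.max() >= self.window:
            raise ValueError("spike times must lie in [0, window)")
        object.__setattr__(self, "spike_times", st)

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.window

    def to_raster(self, dt: float = 1.0) -> SpikeTrains:
        n_steps = int(round(self.window / dt))
        raster = np.zeros((self.n_neurons, n_steps), dtype=np.uint8)
        raster[np.arange(self.n_neurons), (self.spike_times / dt).astype(int)] = 1
        return SpikeTrains(raster=raster, dt=dt)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"neuron_id": np.arange(self.n_neurons), "time_ms": self.spike_times}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window: int) -> "InputPattern":
        df = pd.read_csv(path).sort_values("neuron_id")
        return cls(
            n_neurons=len(df),
            window=window,
            spike_times=df["time_ms"].to_numpy(dtype=np.int64),
        )


def make_pattern(
    n_neurons: int = 50, window: int = 100, seed: int | None = None
) -> InputPattern:
    """Draw a pattern: each neuron fires once at a uniform time in ``[0, window)``.

    Times are independent across neurons and drawn with replacement
    (two neurons may share a time).  Identical seed, identical pattern.
    """
    if n_neurons < 1 or window < 1:
        raise ValueError("n_neurons and window must be >= 1")
    rng = np.random.default_rng(seed)
    times = rng.integers(0, window, size=n_neurons)
    return InputPattern(n_neurons=n_neurons, window=window, spike_times=times)


def tile_pattern(pattern: InputPattern, n_reps: int) -> SpikeTrains:
    """Concatenate ``n_reps`` back-to-back copies of the pattern."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    one = pattern.to_raster().raster
    return SpikeTrains(raster=np.tile(one, (1, n_reps)), dt=1.0)


def save_pattern_library(
    out_dir: str | Path,
    patterns: dict[str, InputPattern],
    seeds: dict[str, int] | None = None,
) -> None:
    """Write a set of labelled patterns (e.g. P1...P7) as CSV files.

    One ``<label>.csv`` per pattern plus a ``library.json`` sidecar
    recording window sizes and, when given, the seeds that generated
    each pattern, so the library is reproducible from the sidecar alone.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: dict[str, dict] = {}
    for label, pat in patterns.items():
        pat.to_csv(out_dir / f"{label}.csv")
        meta[label] = {
            "n_neurons": pat.n_neurons,
            "window": pat.window,
            "seed": None if seeds is None else seeds.get(label),
        }
    (out_dir / "library.json").write_text(json.dumps(meta, indent=2))


def load_pattern_library(out_dir: str | Path) -> dict[str, InputPattern]:
    """Read back a pattern library written by :func:`save_pattern_library`."""
    import json

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "library.json").read_text())
    return {
        label: InputPattern.from_csv(out_dir / f"{label}.csv", window=m["window"])
        for label, m in meta.items()
    }


def poisson_train(
    n_neurons: int,
    rate: float,
    duration: float,
    dt: float = 1.0,
    seed: int | None = None,
) -> SpikeTrains:
    """Independent Bernoulli-per-step Poisson trains.

    Parameters
    ----------
    rate
        Per-neuron firing rate in Hz.
    duration
        Train length in seconds.
    dt
        Step size in ms; each neuron spikes per step with probability
        ``rate * dt / 1000``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = rate * dt / 1000.0
    if p > 1.0:
        raise ValueError(f"rate*dt/1000 = {p} exceeds 1; reduce dt or rate")
    n_steps = int(round(duration * 1000.0 / dt))
    rng = np.random.default_rng(seed)
    raster = (rng.random((n_neurons, n_steps)) < p).astype(np.uint8)
    return SpikeTrains(raster=raster, dt=dt)
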