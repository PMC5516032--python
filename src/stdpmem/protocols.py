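"""Experiment designs: training, testing, decay, appending, hybrid sweeps.

Every experiment runs over a cohort of independently seeded network
instances.  A master seed spawns one stream per network, which is split
into a *weight stream* (connectivity, patterns, training noise, decay
noise -- everything that can change the weights) and a *probe stream*
(membrane noise during frozen-weight tests).  Probes draw only from the
probe stream, so inserting or removing probes never alters the weight
trajectory; and neither stream depends on the plasticity profile, so
AR / SR / hybrid runs on the same master seed are exactly paired.

The standard protocol mirrors the memory phenomenology studies:

* **train**: feed one temporal pattern back-to-back (1000 reps = 100 s)
  with plasticity on.
* **test**: 20 frozen-weight presentations of a pattern, membrane noise
  on; the memory index (MI) of the binarized responses measures recall
  consistency.
* **decay**: after training, drive the plastic network with 5-Hz
  Poisson background for hundreds of seconds, probing MI every 100 s;
  the maintained ratio MI(800)/MI(0) is the headline stability measure.
* **append**: train additional patterns sequentially and track the MI
  of earlier patterns (interference / catastrophic forgetting).
* **hybrid sweep**: repeat decay or append over a grid of the SR
  proportion alpha with matched seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from stdpmem.metrics import (
    MemoryIndexResult,
    binarize_responses,
    maintained_ratio,
    memory_index,
    output_pattern,
    pattern_correlation,
)
from stdpmem.network import FeedforwardNetwork, LIFParams, build_network, run
from stdpmem.plasticity import Profile, STDPConfig
from stdpmem.stimuli import (
    InputPattern,
    SpikeTrains,
    make_pattern,
    poisson_train,
    tile_pattern,
)

__all__ = [
    "SessionResult",
    "resolve_stdp",
    "train",
    "test",
    "decay_experiment",
    "append_experiment",
    "hybrid_sweep",
    "output_pattern_study",
]


def resolve_stdp(model, alpha: float | None = None) -> STDPConfig:
    """Turn ``'AR' | 'SR' | 'HYBRID' | Profile | STDPConfig`` into a config."""
    if isinstance(model, STDPConfig):
        return model
    if isinstance(model, str):
        model = Profile(model.upper())
    if model is Profile.HYBRID:
        if alpha is None:
            raise ValueError("HYBRID model needs alpha")
        return STDPConfig(profile=Profile.HYBRID, alpha=alpha)
    return STDPConfig(profile=model)


class _Stream:
    """Sequential deterministic integer-seed source from a SeedSequence."""

    def __init__(self, ss: np.random.SeedSequence):
        self._ss = ss

    def seed(self) -> int:
        child = self._ss.spawn(1)[0]
        return int(child.generate_state(1, dtype=np.uint32)[0] >> 1)


def _network_streams(master_seed: int, n_networks: int):
    """Per-network (weight stream, probe stream) pairs."""
    out = []
    for ss in np.random.SeedSequence(master_seed).spawn(n_networks):
        w, p = ss.spawn(2)
        out.append((_Stream(w), _Stream(p)))
    return out


@dataclass
class SessionResult:
    """Memory-index series of a cohort protocol run.

    ``mi_series`` has one row per (seed, probe time, pattern):
    columns ``seed, time_s, pattern_id, mi, n_firing``.
    """

    mi_series: pd.DataFrame
    weight_checkpoints: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.mi_series
        if len(df):
            if (df["mi"] < 0).any() or (df["mi"] > 1).any():
                raise ValueError("memory index out of [0, 1]")
            by_seed = df.groupby(["seed", "pattern_id"])["time_s"]
            if not by_seed.apply(lambda s: s.is_monotonic_increasing).all():
                raise ValueError("probe times must be non-decreasing")

    def mi_at(self, pattern_id: str, time_s: float) -> pd.Series:
        """Per-seed MI of one pattern at one probe time."""
        df = self.mi_series
        sel = df[(df["pattern_id"] == pattern_id) & (df["time_s"] == time_s)]
        return sel.set_index("seed")["mi"]

    def ratios(
        self, pattern_id: str = "P1", t0: float | None = None, t1: float | None = None
    ) -> pd.Series:
        """Per-seed maintained ratio MI(t1)/MI(t0) for one pattern.

        Defaults to the first and the ratio probe time recorded in
        ``meta`` (falling back to first/last probe).  Seeds whose
        starting MI is zero are dropped.
        """
        df = self.mi_series[self.mi_series["pattern_id"] == pattern_id]
        times = np.sort(df["time_s"].unique())
        t0 = times[0] if t0 is None else t0
        t1 = self.meta.get("ratio_time", times[-1]) if t1 is None else t1
        start = self.mi_at(pattern_id, t0)
        end = self.mi_at(pattern_id, t1)
        keep = start > 0
        return pd.Series(
            {s: maintained_ratio(start[s], end[s]) for s in start.index[keep]},
            name="ratio",
        )

    def summary(self) -> dict:
        g = self.mi_series.groupby(["pattern_id", "time_s"])["mi"]
        out = {
            "mi_mean": {
                f"{pid}@{t}": float(v) for (pid, t), v in g.mean().items()
            },
            "mi_sd": {f"{pid}@{t}": float(v) for (pid, t), v in g.std().items()},
            "n_seeds": int(self.mi_series["seed"].nunique()),
            **{k: v for k, v in self.meta.items() if _jsonable(v)},
        }
        try:
            r = self.ratios()
            out["maintained_ratio_mean"] = float(r.mean())
            out["maintained_ratio_sd"] = float(r.std())
        except (KeyError, IndexError, ZeroDivisionError):
            pass
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.mi_series.to_csv(out_dir / "mi_series.csv", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(self.summary(), indent=2, default=float)
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def train(
    network: FeedforwardNetwork,
    pattern: InputPattern,
    duration: float,
    seed: int | None = None,
) -> FeedforwardNetwork:
    """Plastic run over ``duration`` s of back-to-back pattern repetitions."""
    if duration == 0:
        return network
    reps_exact = duration * 1000.0 / pattern.window
    reps = int(round(reps_exact))
    if abs(reps - reps_exact) > 1e-9 or reps < 1:
        raise ValueError("duration must be a positive multiple of the pattern window")
    _, trained, _ = run(network, tile_pattern(pattern, reps), plastic=True, seed=seed)
    return trained


def test(
    network: FeedforwardNetwork,
    pattern: InputPattern,
    n_trials: int = 20,
    seed: int | None = None,
) -> MemoryIndexResult:
    """Frozen-weight memory test: ``n_trials`` pattern presentations.

    Membrane noise stays on (it is part of the network's operating
    regime); plasticity is off, so testing never alters the weights.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    out, _, _ = run(network, tile_pattern(pattern, n_trials), plastic=False, seed=seed)
    return memory_index(binarize_responses(out, pattern.window, n_trials))


def _probe(network, patterns: dict, probe_stream: _Stream, n_trials: int = 20):
    """MI of each labelled pattern at the current weights."""
    return {
        pid: test(network, pat, n_trials=n_trials, seed=probe_stream.seed())
        for pid, pat in patterns.items()
    }


def test_in_background(
    network: FeedforwardNetwork,
    pattern: InputPattern,
    noise_rate: float,
    n_trials: int = 20,
    seed: int | None = None,
) -> MemoryIndexResult:
    """Frozen-weight memory test with background activity still running.

    Decay-session probes sample the network in its operating
    environment: the test pattern rides on top of the ongoing
    ``noise_rate``-Hz spontaneous activity (Poisson spikes on the input
    neurons plus imposed Poisson firing of the output neurons).  An
    erased network therefore still shows sparse random background
    responses, which sets a noise floor for the memory index rather
    than exact silence.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    root = np.random.SeedSequence(seed)
    s_in, s_out, s_run = (
        int(ss.generate_state(1, dtype=np.uint32)[0] >> 1) for ss in root.spawn(3)
    )
    tiled = tile_pattern(pattern, n_trials)
    duration_s = tiled.n_steps * network.params.dt / 1000.0
    bg_in = poisson_train(
        network.n_in, noise_rate, duration_s, network.params.dt, seed=s_in
    )
    bg_out = poisson_train(
        network.n_out, noise_rate, duration_s, network.params.dt, seed=s_out
    )
    merged = SpikeTrains(
        raster=np.maximum(tiled.raster, bg_in.raster), dt=tiled.dt
    )
    out, _, _ = run(
        network, merged, plastic=False, seed=s_run, forced_output=bg_out
    )
    return memory_index(binarize_responses(out, pattern.window, n_trials))


def decay_experiment(
    model,
    alpha: float | None = None,
    train_s: float = 100.0,
    decay_s: float = 1000.0,
    noise_rate: float = 5.0,
    probe_every: float = 100.0,
    n_networks: int = 100,
    seed: int = 0,
    ratio_time: float = 800.0,
    n_in: int = 50,
    n_out: int = 50,
    p_connect: float = 0.2,
    params: LIFParams | None = None,
    keep_checkpoints: bool = False,
) -> SessionResult:
    """Train one pattern, then erase it with Poisson background noise.

    Per network: build, train ``train_s`` s on a fresh pattern P1, then
    run ``decay_s`` s of spontaneous background activity with plasticity
    on, probing MI(P1) every ``probe_every`` s (time 0 = end of
    training).  Background activity makes every neuron -- input and
    output alike -- fire an independent ``noise_rate``-Hz Poisson train
    (output spikes are imposed directly), so STDP keeps operating on
    uncorrelated pre/post activity throughout the decay session.  The
    maintained ratio is evaluated at ``ratio_time``.
    """
    if probe_every <= 0 or decay_s % probe_every:
        raise ValueError("probe_every must divide decay_s")
    stdp = resolve_stdp(model, alpha)
    params = params or LIFParams()
    rows = []
    checkpoints: dict = {}
    for k, (wstream, pstream) in enumerate(_network_streams(seed, n_networks)):
        net = build_network(
            n_in, n_out, p_connect, seed=wstream.seed(), params=params, stdp=stdp
        )
        pat = make_pattern(n_in, seed=wstream.seed())
        net = train(net, pat, train_s, seed=wstream.seed())
        # MI_0: test session before the decay session starts (no background)
        mi = test(net, pat, seed=pstream.seed())
        rows.append((k, 0.0, "P1", mi.mi, mi.n_firing))
        n_seg = int(round(decay_s / probe_every))
        for seg in range(1, n_seg + 1):
            raster = poisson_train(
                n_in, noise_rate, probe_every, params.dt, seed=wstream.seed()
            )
            background = poisson_train(
                n_out, noise_rate, probe_every, params.dt, seed=wstream.seed()
            )
            _, net, _ = run(
                net,
                raster,
                plastic=True,
                seed=wstream.seed(),
                forced_output=background,
            )
            mi = test_in_background(net, pat, noise_rate, seed=pstream.seed())
            rows.append((k, seg * probe_every, "P1", mi.mi, mi.n_firing))
        if keep_checkpoints:
            checkpoints[k] = net.W.copy()
    df = pd.DataFrame(
        rows, columns=["seed", "time_s", "pattern_id", "mi", "n_firing"]
    )
    meta = {
        "experiment": "decay",
        "model": stdp.profile.value,
        "alpha": stdp.effective_alpha,
        "ratio_time": ratio_time,
        "noise_rate": noise_rate,
        "train_s": train_s,
        "decay_s": decay_s,
        "master_seed": seed,
    }
    return SessionResult(mi_series=df, weight_checkpoints=checkpoints, meta=meta)


def append_experiment(
    model,
    durations: list[float] | None = None,
    alpha: float | None = None,
    probe_every: float = 100.0,
    n_networks: int = 100,
    seed: int = 0,
    n_in: int = 50,
    n_out: int = 50,
    p_connect: float = 0.2,
    params: LIFParams | None = None,
    keep_checkpoints: bool = False,
) -> SessionResult:
    """Sequentially train several patterns and track interference.

    ``durations[k]`` is the training time of pattern ``P{k+1}``; each
    network draws its own patterns.  At every ``probe_every`` s of
    training, MI is measured for every pattern trained so far plus one
    held-out untrained pattern.  Probe time is cumulative training time.
    When ``keep_checkpoints``, the weight matrix is stored per network
    after each pattern's session (for convergence statistics).
    """
    durations = durations if durations is not None else [100.0] + [200.0] * 6
    for d in durations:
        if d <= 0 or d % probe_every:
            raise ValueError("every duration must be a positive multiple of probe_every")
    stdp = resolve_stdp(model, alpha)
    params = params or LIFParams()
    rows = []
    checkpoints: dict = {}
    for k, (wstream, pstream) in enumerate(_network_streams(seed, n_networks)):
        net = build_network(
            n_in, n_out, p_connect, seed=wstream.seed(), params=params, stdp=stdp
        )
        pats = {
            f"P{i + 1}": make_pattern(n_in, seed=wstream.seed())
            for i in range(len(durations))
        }
        untrained = make_pattern(n_in, seed=wstream.seed())
        t = 0.0
        net_ckpts = []
        for i, dur in enumerate(durations):
            trained_so_far = {f"P{j + 1}": pats[f"P{j + 1}"] for j in range(i + 1)}
            for _ in range(int(round(dur / probe_every))):
                net = train(
                    net, pats[f"P{i + 1}"], probe_every, seed=wstream.seed()
                )
                t += probe_every
                probes = _probe(
                    net, {**trained_so_far, "untrained": untrained}, pstream
                )
                for pid, mi in probes.items():
                    rows.append((k, t, pid, mi.mi, mi.n_firing))
            net_ckpts.append(net.W.copy())
        if keep_checkpoints:
            checkpoints[k] = net_ckpts
    df = pd.DataFrame(
        rows, columns=["seed", "time_s", "pattern_id", "mi", "n_firing"]
    )
    meta = {
        "experiment": "append",
        "model": stdp.profile.value,
        "alpha": stdp.effective_alpha,
        "durations": list(durations),
        "ratio_time": float(sum(durations)),
        "master_seed": seed,
    }
    return SessionResult(mi_series=df, weight_checkpoints=checkpoints, meta=meta)


def final_comparison(
    result: SessionResult, pattern_id: str = "P1", against: str = "untrained"
) -> dict:
    """Two-sided Mann-Whitney rank-sum of final MI(pattern) vs MI(against)."""
    t_final = result.mi_series["time_s"].max()
    a = result.mi_at(pattern_id, t_final)
    b = result.mi_at(against, t_final)
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "pattern": pattern_id,
        "against": against,
        "time_s": float(t_final),
        "mi_mean": float(a.mean()),
        "against_mean": float(b.mean()),
        "U": float(stat),
        "p_value": float(p),
    }


def hybrid_sweep(
    alphas: list[float],
    experiment: str = "decay",
    settings: dict | None = None,
    n_networks: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Run decay or append over a grid of the SR proportion alpha.

    Seeds are matched across alpha values (identical networks, patterns
    and noise realizations), so per-seed ratios are paired.  For the
    append variant the schedule is P1 (100 s) followed by one appended
    pattern, and the ratio tracks MI(P1) through the appending session.

    Returns one row per alpha: ``alpha, mean_ratio, sd_ratio, n`` plus
    the per-seed ratios as a list column.
    """
    settings = dict(settings or {})
    rows = []
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha values must lie in [0, 1]")
        model = resolve_stdp(Profile.HYBRID, a) if 0.0 < a < 1.0 else (
            resolve_stdp(Profile.SR) if a == 1.0 else resolve_stdp(Profile.AR)
        )
        if experiment == "decay":
            res = decay_experiment(
                model, n_networks=n_networks, seed=seed, **settings
            )
            r = res.ratios("P1")
        elif experiment == "append":
            append_s = settings.pop("append_s", 1000.0)
            ratio_time = settings.pop("ratio_time", 800.0)
            res = append_experiment(
                model,
                durations=[100.0, append_s],
                n_networks=n_networks,
                seed=seed,
                **settings,
            )
            settings["append_s"] = append_s
            settings["ratio_time"] = ratio_time
            # P1's baseline is its first probe (end of P1 training, t=100)
            r = res.ratios("P1", t0=100.0, t1=100.0 + ratio_time)
        else:
            raise ValueError("experiment must be 'decay' or 'append'")
        rows.append(
            {
                "alpha": a,
                "mean_ratio": float(r.mean()),
                "sd_ratio": float(r.std()),
                "n": int(r.size),
                "ratios": r.to_list(),
            }
        )
    return pd.DataFrame(rows)


def output_pattern_study(
    n_inputs: int = 100,
    model="AR",
    alpha: float | None = None,
    seed: int = 0,
    train_s: float = 100.0,
    threshold: float = 0.8,
    n_in: int = 50,
    n_out: int = 50,
    p_connect: float = 0.2,
    params: LIFParams | None = None,
) -> dict[str, np.ndarray]:
    """Engram specificity: same initial network, different vs. same input.

    Clones of one fixed network (identical mask and initial weights) are
    trained (a) on ``n_inputs`` different patterns and (b) ``n_inputs``
    times on one pattern, each clone with its own noise stream.  The
    trained output pattern (neurons responding in > ``threshold`` of 20
    test trials) is extracted per clone and all pairwise Pearson
    correlations within each condition are returned.
    """
    if n_inputs < 2:
        raise ValueError("n_inputs must be >= 2")
    stdp = resolve_stdp(model, alpha)
    params = params or LIFParams()
    root = np.random.SeedSequence(seed)
    net_ss, pat_ss, noise_ss, shared_ss = root.spawn(4)
    base = build_network(
        n_in, n_out, p_connect, seed=_Stream(net_ss).seed(), params=params, stdp=stdp
    )
    pat_stream, noise_stream = _Stream(pat_ss), _Stream(noise_ss)
    shared_pattern = make_pattern(n_in, seed=_Stream(shared_ss).seed())

    def trained_output(pattern):
        net = train(base, pattern, train_s, seed=noise_stream.seed())
        out, _, _ = run(
            net, tile_pattern(pattern, 20), plastic=False, seed=noise_stream.seed()
        )
        return output_pattern(
            binarize_responses(out, pattern.window, 20), threshold
        )

    different = [
        trained_output(make_pattern(n_in, seed=pat_stream.seed()))
        for _ in range(n_inputs)
    ]
    same = [trained_output(shared_pattern) for _ in range(n_inputs)]

    def pairwise(vectors):
        vals = []
        for m in range(len(vectors)):
            for n in range(m + 1, len(vectors)):
                try:
                    vals.append(pattern_correlation(vectors[m], vectors[n]))
                except ValueError:  # constant engram vector: no correlation
                    continue
        return np.asarray(vals)

    return {"different": pairwise(different), "same": pairwise(same)}
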