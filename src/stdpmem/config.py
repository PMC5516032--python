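"""Flat key:value run configuration (YAML-compatible).

A run is fully specified by a config file plus a master seed: model
constants (LIF and STDP), the experiment name and its schedule knobs,
cohort size and output directory.  Unknown keys are rejected so a typo
cannot silently fall back to a default, and every run writes its
resolved config next to its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from stdpmem.network import LIFParams
from stdpmem.plasticity import STDPConfig

__all__ = ["RunConfig"]

_LIF_KEYS = {f.name for f in fields(LIFParams)}
_STDP_KEYS = {f.name for f in fields(STDPConfig)}
_RUN_KEYS = {
    "experiment",
    "model",
    "alpha",
    "cohort",
    "seed",
    "out_dir",
    "probe_every",
    "train_s",
    "decay_s",
    "noise_rate",
    "durations",
    "alphas",
    "append_s",
    "ratio_time",
    "trials",
    "duration",
    "rate",
    "beta",
    "n_inputs",
    "n_in",
    "n_out",
    "p_connect",
    "w_mean",
    "w_sd",
}


@dataclass
class RunConfig:
    """Resolved configuration for one CLI run."""

    experiment: str = "decay"
    model: str = "AR"
    alpha: float | None = None
    cohort: int = 100
    seed: int = 0
    out_dir: str = "results"
    lif: dict = field(default_factory=dict)
    stdp: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None = None, overrides: dict | None = None
             ) -> "RunConfig":
        """Read a flat YAML mapping and apply CLI overrides on top."""
        raw: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError("config file must be a flat key: value mapping")
            raw.update(loaded)
        for k, v in (overrides or {}).items():
            if v is not None:
                raw[k] = v

        known = _RUN_KEYS | _LIF_KEYS | _STDP_KEYS
        unknown = set(raw) - known
        if unknown:
            raise KeyError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        cfg = cls()
        cfg.lif = {k: raw.pop(k) for k in list(raw) if k in _LIF_KEYS}
        cfg.stdp = {
            k: raw.pop(k) for k in list(raw) if k in _STDP_KEYS and k != "alpha"
        }
        for name in ("experiment", "model", "cohort", "seed", "out_dir", "alpha"):
            if name in raw:
                setattr(cfg, name, raw.pop(name))
        cfg.cohort = int(cfg.cohort)
        cfg.seed = int(cfg.seed)
        cfg.extra = raw
        return cfg

    def lif_params(self) -> LIFParams:
        return LIFParams(**self.lif)

    def stdp_config(self) -> STDPConfig:
        d = dict(self.stdp)
        d["profile"] = self.model
        if self.alpha is not None:
            d["alpha"] = self.alpha
        return STDPConfig.from_dict(d)

    def resolved(self) -> dict:
        out = {
            "experiment": self.experiment,
            "model": self.model,
            "alpha": self.alpha,
            "cohort": self.cohort,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
        }
        out.update(self.lif)
        out.update(self.stdp)
        out.update(self.extra)
        return out

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=False))
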