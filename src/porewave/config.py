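"""Run configuration: validated, losslessly serializable, preset-aware."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .kmc import RingKineticRates
from .runlength import RunLengthParams
from .synthetic import HeightConventions


class ConfigError(ValueError):
    pass


@dataclass
class KymoConfig:
    n_traces: int = 200
    tau_II_ms: float = 75.0
    line_interval_s: float = 0.002
    jitter: bool = True


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end seeded run."""

    preset: str = "measured"
    seed: int = 0
    n_rings: int = 100
    duration_s: float = 30.0
    frame_interval_s: float = 0.2
    pixel_size_nm: float = 1.0
    ring_radius_nm: float = 10.0
    render_batch: int = 25
    rates: RingKineticRates = field(default_factory=RingKineticRates)
    conventions: HeightConventions = field(default_factory=HeightConventions)
    kymo: KymoConfig = field(default_factory=KymoConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        rl = d["rates"].pop("run_length_params")
        d["rates"]["run_length"] = rl
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def build(klass, sub: dict):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        if "rates" in d:
            sub = dict(d["rates"])
            if "run_length" in sub:
                rl = sub.pop("run_length")
                sub["run_length_params"] = build(RunLengthParams, rl)
            try:
                d["rates"] = build(RingKineticRates, sub)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        if "conventions" in d:
            d["conventions"] = build(HeightConventions, d["conventions"])
        if "kymo" in d:
            d["kymo"] = build(KymoConfig, d["kymo"])
        return build(cls, d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def measured_preset(seed: int = 0, **overrides) -> RunConfig:
    """The measured study conditions: 16-mer rings, k_open 1.8 s^-1,
    initiation 0.2 s^-1, k12 13 s^-1, k23 15 s^-1, heights 8.1/1.6/2.2 nm,
    200 ms frames, 2 ms lines, noise 0.3 nm."""
    cfg = RunConfig(preset="measured", seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigError(f"unknown RunConfig key: {k}")
        setattr(cfg, k, v)
    return cfg
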