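"""Run configuration: a YAML-serializable tree of priors, design and settings.

A run is reproducible from its configuration plus a seed alone; command-line
flags override configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .inference import NetSpec
from .parameters import PriorSpec
from .simulate import DEFAULT_DT, DEFAULT_T_MAX, DesignSpec

__all__ = ["SimSettings", "RunConfig"]


@dataclass
class SimSettings:
    dt: float = DEFAULT_DT
    t_max: float = DEFAULT_T_MAX
    frame_rate: float = 60.0  # stimulus updates per second, for trace output


@dataclass
class RunConfig:
    seed: int = 0
    design: str = "application"  # "application" | "single"
    trials: int = 10  # per condition ("application") or total ("single")
    n_participants: int = 34
    model: str = "mixed"  # fixture generation: mixed | diffusion | accumulator | gsr
    priors: PriorSpec = field(default_factory=PriorSpec)
    sim: SimSettings = field(default_factory=SimSettings)
    net: NetSpec = field(default_factory=NetSpec)
    out_dir: str = "."

    def design_spec(self) -> DesignSpec:
        if self.design == "application":
            return DesignSpec.application(self.trials)
        if self.design == "single":
            return DesignSpec.single(self.trials)
        raise ValueError(f"unknown design {self.design!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = self.priors.to_dict()
        d["net"]["hidden_layers"] = list(self.net.hidden_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "priors" in d:
            d["priors"] = PriorSpec.from_dict(d["priors"])
        if "sim" in d:
            d["sim"] = SimSettings(**d["sim"])
        if "net" in d:
            net = dict(d["net"])
            if "hidden_layers" in net:
                net["hidden_layers"] = tuple(net["hidden_layers"])
            d["net"] = NetSpec(**net)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
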