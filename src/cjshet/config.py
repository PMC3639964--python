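"""Study configuration: scenarios, models, inference protocol, seeds."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .inference import MODEL_TAGS
from .scenarios import ScenarioSpec, default_scenarios

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """Configuration of a replicate study.

    ``scenarios`` entries may be labels of the built-in generating regimes
    (``symmetric``, ``right_skewed``, ``left_skewed``, ``two_group``) or
    mappings giving :class:`ScenarioSpec` fields explicitly.
    """

    scenarios: list[ScenarioSpec]
    models: list[str] = field(default_factory=lambda: ["constant_p", "re_p"])
    engine: str = "mle"
    n_replicates: int = 100
    seed: int = 0
    protocol: dict = field(
        default_factory=lambda: dict(chains=1, iterations=30_000, burn_in=20_000, thin=10, n_nodes=20)
    )
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("config must name at least one scenario")
        if self.engine not in ("mle", "mcmc"):
            raise ValueError(f"unknown engine {self.engine!r}")
        for m in self.models:
            if m not in MODEL_TAGS:
                raise ValueError(f"unknown model {m!r}; expected one of {MODEL_TAGS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seed is None:
            raise ValueError("config must carry a seed")
        for key in ("chains", "iterations", "burn_in", "thin", "n_nodes"):
            if key in self.protocol and int(self.protocol[key]) < 0:
                raise ValueError(f"protocol value {key} must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = default_scenarios(
            n_occasions=int(raw.get("n_occasions", 15)),
            n_new_per_occasion=int(raw.get("n_new_per_occasion", 50)),
            phi_true=float(raw.get("phi_true", 0.7)),
        )
        specs = []
        for entry in raw.get("scenarios", []):
            if isinstance(entry, str):
                if entry not in known:
                    raise ValueError(f"unknown scenario label {entry!r}")
                specs.append(known[entry])
            else:
                entry = dict(entry)
                if "p_mean" in entry and isinstance(entry["p_mean"], list):
                    entry["p_mean"] = tuple(entry["p_mean"])
                specs.append(ScenarioSpec(**entry))
        kwargs = {
            k: raw[k]
            for k in ("models", "engine", "n_replicates", "seed", "protocol", "out_dir")
            if k in raw
        }
        return cls(scenarios=specs, **kwargs)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "scenarios": [
                dict(label=s.label, n_occasions=s.n_occasions,
                     n_new_per_occasion=s.n_new_per_occasion, phi_true=s.phi_true,
                     p_mean=list(s.p_mean) if isinstance(s.p_mean, tuple) else s.p_mean,
                     p_sd=s.p_sd, mixture_weight=s.mixture_weight)
                for s in self.scenarios
            ],
            "models": list(self.models),
            "engine": self.engine,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "protocol": dict(self.protocol),
            "out_dir": self.out_dir,
        }
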