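"""Pipeline configuration: one validated, file-round-trippable object.

Every stage parameter lives here with its default; unknown keys are
rejected so a typo in a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NeurometricsConfig(_Section):
    filter_low_hz: float = 2.0
    filter_high_hz: float = 30.0
    filter_order: int = 5
    iaf_search_low_hz: float = 7.0
    iaf_search_high_hz: float = 13.0
    alpha_parietal_band: str = "alpha"  # or "alpha_high" (upper-alpha reading)
    impute_k: int = 5


class VarConfig(_Section):
    p_max: int = 20
    order: int | None = None  # None = select by AIC/BIC (BIC preferred)
    n_folds: int = 10
    grid_min: float = 1e-5
    grid_max: float = 1e3
    grid_size: int = 50
    lambda_value: float | None = None  # None = blocked CV per row


class CteConfig(_Section):
    units: str = "nats"
    binarize_rule: str = "exact-zero"


class GraphConfig(_Section):
    damping: float = 0.85
    entropy_mode: str = "node"  # node | global


class HpeConfig(_Section):
    window: int = 120
    step: int = 60
    lambda_policy: str = "session"  # session | window


class SynthConfig(_Section):
    n_subjects: int = 1
    density: float = 0.4
    coupling: float = 0.35
    order: int = 2
    missing_rate: float = 0.2
    behavioural_coupling: float = 0.5
    phase_density_multipliers: tuple[float, float, float] = (1.5, 0.5, 1.0)


class PipelineConfig(_Section):
    """Top-level configuration; round-trips losslessly through YAML."""

    seed: int = 0
    neurometrics: NeurometricsConfig = Field(default_factory=NeurometricsConfig)
    var: VarConfig = Field(default_factory=VarConfig)
    cte: CteConfig = Field(default_factory=CteConfig)
    graph: GraphConfig = Field(default_factory=GraphConfig)
    hpe: HpeConfig = Field(default_factory=HpeConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
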