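"""Scenario configuration: schema, presets, loading, fixture generation."""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costs import CostModel
from .model import FourStageModel, FourStageSpec, ModelSpec
from .params import PRESETS, LifeCycleParams
from .cases import build_case_model

CaseId = Union[Literal[0, 1, 2, 3, 4], Literal["four-stage"]]


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mu_m1: float
    mu_f1: float
    mu_m2: float
    mu_f2: float
    alpha_m: float
    alpha_f: float
    d: float
    R: float

    def to_params(self) -> LifeCycleParams:
        return LifeCycleParams(**self.model_dump())


class CostConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    Cm: float = 1.0
    Cf: float = 1.0
    I: float = 1.0
    Dm: float = 0.0
    Df: float = 0.0
    c: float = 0.0


class ScenarioConfig(BaseModel):
    """A fully specified scenario: case, demography, costs, solver settings."""

    model_config = ConfigDict(extra="forbid")

    case: CaseId = 1
    preset: Literal["productive", "poor"] | None = "productive"
    params: ParamsConfig | None = None
    overrides: dict[str, float] = Field(default_factory=dict)
    cost: CostConfig = Field(default_factory=CostConfig)
    tol: float = 1e-10
    bracket: tuple[float, float] = (0.01, 0.99)
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.params is None and self.preset is None:
            raise ValueError("either 'preset' or explicit 'params' is required")
        allowed = set(ParamsConfig.model_fields)
        unknown = set(self.overrides) - allowed
        if unknown:
            raise ValueError(f"unknown override keys {sorted(unknown)}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        return self

    def life_cycle_params(self) -> LifeCycleParams:
        if self.params is not None:
            base = self.params.to_params()
        else:
            base = PRESETS[self.preset]  # type: ignore[index]
        return base.replace(**self.overrides) if self.overrides else base

    def cost_model(self) -> CostModel:
        if self.case == "four-stage":
            return CostModel(case_id=3)
        kwargs = self.cost.model_dump()
        if self.case == 0:
            kwargs["Cm"] = kwargs["Cf"] = 1.0
        return CostModel(case_id=int(self.case), **kwargs)

    def build_model(self) -> ModelSpec:
        params = self.life_cycle_params()
        if self.case == "four-stage":
            return FourStageModel(FourStageSpec(params))
        return build_case_model(int(self.case), params, self.cost_model())

    def dump(self) -> dict:
        # exclude defaults only: an explicit ``preset: null`` must round-trip
        data = self.model_dump(exclude_defaults=True)
        data.setdefault("case", self.case)
        if "bracket" in data:
            data["bracket"] = list(data["bracket"])
        return data


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return ScenarioConfig.model_validate(raw)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.dump(), sort_keys=True))


def generate_fixture(seed: int) -> ScenarioConfig:
    """A random valid scenario within biologically sensible parameter ranges.

    Deterministic in ``seed``; used for property tests and the ``fixtures``
    CLI command. The core pipeline itself is deterministic and never draws
    random numbers.
    """
    rng = np.random.default_rng(seed)
    case = int(rng.integers(0, 5))
    params = ParamsConfig(
        mu_m1=rng.uniform(0.02, 1.0), mu_f1=rng.uniform(0.02, 1.0),
        mu_m2=rng.uniform(0.02, 1.0), mu_f2=rng.uniform(0.02, 1.0),
        alpha_m=rng.uniform(0.1, 2.0), alpha_f=rng.uniform(0.1, 2.0),
        d=rng.uniform(0.0, 2.0), R=rng.uniform(1.0, 50.0),
    )
    cost = CostConfig()
    if case == 1:
        cm = rng.uniform(0.1, 0.9)
        cost = CostConfig(Cm=cm, Cf=1.0 - cm)
    elif case == 2:
        cost = CostConfig(I=rng.uniform(0.2, 2.0))
    elif case == 4:
        dm = rng.uniform(0.1, 0.9)
        cost = CostConfig(Dm=dm, Df=1.0 - dm, c=rng.uniform(0.0, 0.2))
    return ScenarioConfig(case=case, preset=None, params=params, cost=cost, seed=seed)
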