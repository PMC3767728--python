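"""Model configuration: base-case parameters, validation, scenario grid.

The base case describes elective hip/knee arthroplasty in a German hospital:
a restrictive transfusion trigger of 8.5 g/dl Hb, blood-loss means of 3.3
(hip) and 3.5 (knee) g/dl, and 2013-era euro unit costs (RBC unit 320 €,
autologous predonation 500 € flat, epoetin alfa 200 €/40,000 IU dose,
hospital day 300 €, pneumonia episode 5,000 €).  Every sensitivity scenario
is a named set of overrides on this base configuration.

Percent changes quoted in the sensitivity grid ("LOS +20%") are stored as
multiplicative factors (1.20); conversion happens once, at load time.
"""

from __future__ import annotations

import copy
import re
from pathlib import Path
from typing import Any, ClassVar, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEMA_VERSION = 1

__all__ = [
    "ConfigError",
    "CostInputs",
    "RegimenConfig",
    "ClinicalInputs",
    "ModelConfig",
    "ScenarioSpec",
    "load_config",
    "serialize",
    "build_scenarios",
    "apply_scenario",
    "as_factor",
]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


_PCT = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)\s*%\s*$")


def as_factor(value: Union[int, float, str]) -> float:
    """Convert a percent-increase string like ``"+20%"`` to a factor (1.20).

    Plain numbers pass through unchanged and are interpreted as factors.
    """
    if isinstance(value, str):
        m = _PCT.match(value)
        if m is None:
            raise ConfigError(f"cannot interpret {value!r} as a percent change")
        return 1.0 + float(m.group(1)) / 100.0
    return float(value)


class CostInputs(BaseModel):
    """Unit costs in euros, hospital perspective (single admission)."""

    model_config = ConfigDict(extra="forbid")

    allogeneic_unit_cost: float = Field(320.0, ge=0, description="€ per allogeneic RBC unit")
    autologous_collection_cost: float = Field(
        500.0, ge=0, description="€ flat per PAD patient; covers collection/storage of two units"
    )
    epo_dose_cost: float = Field(200.0, ge=0, description="€ per 40,000 IU epoetin alfa dose")
    hospital_day_cost: float = Field(300.0, ge=0, description="€ per inpatient day")
    pneumonia_cost: float = Field(5000.0, ge=0, description="€ per pneumonia episode")

    FIELDS: ClassVar[tuple[str, ...]] = (
        "allogeneic_unit_cost",
        "autologous_collection_cost",
        "epo_dose_cost",
        "hospital_day_cost",
        "pneumonia_cost",
    )


class RegimenConfig(BaseModel):
    """Epoetin alfa dosing protocol.

    Base case: up to 3 preoperative 40,000 IU injections until the running Hb
    reaches 13.3 g/dl (40% hematocrit); no injection on the day of surgery.
    The Weber protocol variant (termination 15 g/dl, up to 4 injections)
    gives its last injection on the day of surgery, where it can no longer
    affect Hb at incision — it is charged but has no Hb effect
    (``day_of_surgery_dose_counts_cost_only``).
    """

    model_config = ConfigDict(extra="forbid")

    termination_hb: float = Field(13.3, gt=0)
    max_injections: int = Field(3, ge=1)
    per_injection_increment_mean: float = Field(1.0, ge=0)
    per_injection_increment_sd: float = Field(0.6, ge=0)
    day_of_surgery_dose_counts_cost_only: bool = False


class ClinicalInputs(BaseModel):
    """Clinical constants and distribution parameters."""

    model_config = ConfigDict(extra="forbid")

    transfusion_trigger: float = Field(8.5, ge=7.0, le=10.0, description="Hb g/dl")
    cardiac_trigger_shift: float = Field(1.0, ge=0, description="trigger raise for cardiac history, Hb g/dl")
    hb_per_unit: float = Field(1.0, gt=0, description="Hb g/dl gained per RBC unit")
    transfuse_at_equality: bool = Field(
        False, description="whether a patient exactly at the trigger receives one unit"
    )

    blood_loss_mean_hip: float = Field(3.3, ge=0, description="Hb g/dl lost, hip arthroplasty")
    blood_loss_mean_knee: float = Field(3.5, ge=0, description="Hb g/dl lost, knee arthroplasty")
    blood_loss_sd: float = Field(1.0, ge=0)
    asa_loss_factor: float = Field(1.05, ge=1.0, description="blood-loss multiplier, ASA >= III")
    age_loss_factor: float = Field(1.05, ge=1.0, description="blood-loss multiplier, old age")
    revision_loss_factor: float = Field(1.25, ge=1.0, description="blood-loss multiplier, revision surgery")
    old_age_threshold: int = Field(75, ge=0, description="years")
    ebv_per_kg: float = Field(65.0, gt=0, description="estimated blood volume, ml per kg body weight")

    pad_hb_decrement_mean: float = Field(1.2, ge=0, description="mean preoperative Hb drop after donation, g/dl")
    pad_hb_decrement_sd: float = Field(0.83, ge=0)
    pad_units: int = Field(2, ge=0, description="autologous units banked per PAD patient")
    pad_min_hb: float = Field(11.0, gt=0, description="PAD not indicated below this baseline Hb")

    epo_regimen: RegimenConfig = Field(default_factory=RegimenConfig)
    ra_epo_attenuation: float = Field(
        0.8, gt=0, le=1.0, description="per-dose Hb increment multiplier for rheumatoid arthritis"
    )

    los_transfusion_factor: float = Field(1.2, ge=1.0, description="LOS multiplier, transfusion only")
    los_infection_factor: float = Field(1.6, ge=1.0, description="LOS multiplier, infection only")
    los_both_factor: float = Field(1.9, ge=1.0, description="LOS multiplier, transfusion and infection")
    los_age_factor: float = Field(1.0, ge=1.0, description="LOS multiplier for old age (no-op by default)")

    p_pneumonia_base: float = Field(0.008, ge=0, le=1)
    p_pneumonia_transfused: float = Field(0.016, ge=0, le=1)
    p_infection_base: float = Field(0.02, ge=0, le=1)
    p_infection_transfused: float = Field(0.04, ge=0, le=1)

    @field_validator(
        "los_transfusion_factor", "los_infection_factor", "los_both_factor", "los_age_factor",
        "asa_loss_factor", "age_loss_factor", "revision_loss_factor",
        mode="before",
    )
    @classmethod
    def _coerce_factor(cls, v: Any) -> float:
        return as_factor(v)


class ModelConfig(BaseModel):
    """One complete, runnable model parameterisation (one scenario = one config)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    name: str = "base"
    costs: CostInputs = Field(default_factory=CostInputs)
    clinical: ClinicalInputs = Field(default_factory=ClinicalInputs)

    #: path to a population-mix CSV; ``None`` means the built-in synthetic fixture
    population: Optional[str] = None

    #: baseline-Hb Weibull (shape, scale, location) per sex; calibrated so that
    #: about 23.2% of the synthetic population falls in the 10-13 g/dl band,
    #: with roughly 80% of those patients female.
    hb_weibull_female: tuple[float, float, float] = (9.5, 14.3, 0.0)
    hb_weibull_male: tuple[float, float, float] = (10.5, 15.67, 0.0)

    rheumatoid_risk_hip: float = Field(0.03, ge=0, le=1)
    rheumatoid_risk_knee: float = Field(0.05, ge=0, le=1)
    cardiac_history_probability: float = Field(0.145, ge=0, le=1)

    n_patients: int = Field(50_000, ge=1)
    seed: int = 1234

    #: reporting bands: half-open [lo, lo+width), ..., up to hi
    band_lo: float = 10.0
    band_hi: float = 13.0
    band_width: float = Field(0.5, gt=0)

    #: restrict summaries to a subgroup ("revision") or None for everyone
    subgroup: Optional[str] = None
    #: also emit an all-patients summary row alongside the Hb bands
    full_population: bool = False

    @field_validator("hb_weibull_female", "hb_weibull_male")
    @classmethod
    def _check_weibull(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        shape, scale, loc = v
        if shape <= 0 or scale <= 0:
            raise ValueError(f"Weibull shape and scale must be positive, got {v}")
        return (float(shape), float(scale), float(loc))

    @field_validator("subgroup")
    @classmethod
    def _check_subgroup(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v != "revision":
            raise ValueError(f"unknown subgroup {v!r}; supported: 'revision'")
        return v

    @model_validator(mode="after")
    def _check_bands(self) -> "ModelConfig":
        if self.band_hi <= self.band_lo:
            raise ValueError("band_hi must exceed band_lo")
        return self


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration.

    Omitted fields take base-case defaults; an empty file yields the full
    base-case configuration.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping, got {type(data).__name__}")
    try:
        return ModelConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries field name and bound
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def serialize(config: ModelConfig) -> str:
    """YAML serialisation that :func:`load_config` reparses to an equal config."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


class ScenarioSpec(BaseModel):
    """A named set of parameter overrides on the base configuration."""

    model_config = ConfigDict(extra="forbid")

    name: str
    overrides: dict[str, Any] = Field(default_factory=dict)


def build_scenarios(base: ModelConfig) -> list[ScenarioSpec]:
    """Expand the sensitivity grid into executable scenarios.

    Covers: base case; strict/liberal triggers; the revision-surgery
    subgroup; the Weber epoetin protocol; four alternative PAD Hb effects;
    three alternative blood-loss pairs; four alternative LOS increases for
    transfused patients; each cost input (and all costs jointly) varied
    +/-25%; and the zero-correlation bound that removes the blood-loss risk
    modifiers.
    """
    c = base.costs
    scenarios: list[ScenarioSpec] = [ScenarioSpec(name="base")]

    for trig in (8.0, 9.0):
        scenarios.append(ScenarioSpec(name=f"trigger_{trig}", overrides={"clinical.transfusion_trigger": trig}))

    scenarios.append(ScenarioSpec(name="revision_only", overrides={"subgroup": "revision"}))

    scenarios.append(
        ScenarioSpec(
            name="epo_weber",
            overrides={
                "clinical.epo_regimen.termination_hb": 15.0,
                "clinical.epo_regimen.max_injections": 4,
                "clinical.epo_regimen.day_of_surgery_dose_counts_cost_only": True,
            },
        )
    )

    for eff in (1.16, 1.05, 0.8, 0.67):
        scenarios.append(
            ScenarioSpec(name=f"pad_effect_-{eff}", overrides={"clinical.pad_hb_decrement_mean": eff})
        )

    for hip, knee in ((3.1, 2.9), (2.8, 2.5), (2.1, 1.9)):
        scenarios.append(
            ScenarioSpec(
                name=f"blood_loss_{hip}",
                overrides={
                    "clinical.blood_loss_mean_hip": hip,
                    "clinical.blood_loss_mean_knee": knee,
                },
            )
        )

    for pct in (5, 11, 29, 35):
        scenarios.append(
            ScenarioSpec(
                name=f"los_increase_{pct}pct",
                overrides={"clinical.los_transfusion_factor": 1.0 + pct / 100.0},
            )
        )

    single_costs = {
        "cost_epo": "epo_dose_cost",
        "cost_rbc": "allogeneic_unit_cost",
        "cost_pad": "autologous_collection_cost",
    }
    for label, field in single_costs.items():
        for tag, factor in (("up25", 1.25), ("down25", 0.75)):
            scenarios.append(
                ScenarioSpec(
                    name=f"{label}_{tag}",
                    overrides={f"costs.{field}": getattr(c, field) * factor},
                )
            )
    for tag, factor in (("up25", 1.25), ("down25", 0.75)):
        scenarios.append(
            ScenarioSpec(
                name=f"cost_total_{tag}",
                overrides={f"costs.{f}": getattr(c, f) * factor for f in CostInputs.FIELDS},
            )
        )

    scenarios.append(
        ScenarioSpec(
            name="zero_correlation",
            overrides={
                "clinical.asa_loss_factor": 1.0,
                "clinical.age_loss_factor": 1.0,
                "clinical.revision_loss_factor": 1.0,
            },
        )
    )
    return scenarios


def _set_path(data: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node = data
    for p in parts[:-1]:
        if not isinstance(node, dict) or p not in node:
            raise ConfigError(f"override path {path!r} does not resolve to an existing parameter")
        node = node[p]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise ConfigError(f"override path {path!r} does not resolve to an existing parameter")
    node[parts[-1]] = value


def apply_scenario(base: ModelConfig, scenario: ScenarioSpec) -> ModelConfig:
    """Return a deep-copied config with the scenario's overrides applied.

    The base config is never modified; repeated application is idempotent.
    """
    data = copy.deepcopy(base.model_dump())
    for path, value in scenario.overrides.items():
        _set_path(data, path, value)
    data["name"] = scenario.name
    try:
        return ModelConfig.model_validate(data)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"scenario {scenario.name!r} produced an invalid configuration: {exc}") from exc
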