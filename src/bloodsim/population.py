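"""Synthetic patient creation.

A patient is built by indexing a population-mix table (procedure stratum x
age band x sex cells with sampling frequencies, mirroring the structure of a
national DRG case-mix), then drawing physiology and comorbidity:

1. cell draw -> procedure stratum, age band, sex
2. uniform integer age within the band
3. body weight ~ Normal(cell mean, cell sd), floored
4. estimated blood volume = weight x 65 ml/kg
5. baseline Hb ~ sex-specific three-parameter Weibull
6. comorbidity flags: revision surgery, ASA >= III, rheumatoid arthritis,
   cardiac history (independent Bernoulli draws)
7. surgical blood loss ~ Normal(procedure mean, sd) truncated at 0, then
   multiplied by 1.05 (ASA >= III), 1.05 (age >= 75) and 1.25 (revision)

The fixture generator produces a schema-valid table with a plausible German
arthroplasty structure (57% hip, 62% female, mean age ~71, base LOS ~13 d)
so the package builds and tests without any external data file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ._rng import characteristics_stream
from .config import ClinicalInputs, ModelConfig

__all__ = [
    "PopulationTable",
    "PatientProfile",
    "FixtureParams",
    "sample_procedure_cell",
    "sample_age_within_band",
    "sample_weight",
    "estimated_blood_volume",
    "sample_baseline_hb",
    "assign_comorbidities",
    "sample_blood_loss",
    "create_patient",
    "generate_fixture_population",
]

#: column schema for population-mix CSV files
TABLE_COLUMNS = [
    "row_id",
    "procedure",
    "sex",
    "age_lo",
    "age_hi",
    "frequency",
    "revision_probability",
    "asa_ge3_probability",
    "base_los",
    "weight_mean",
    "weight_sd",
]

HB_CLAMP = (6.0, 18.0)
WEIGHT_FLOOR_KG = 35.0


class PopulationTable:
    """Procedure/demographic mix with per-cell sampling frequencies.

    Each row is one (procedure stratum, age band, sex) cell; frequencies form
    a probability mass over rows.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self.validate()
        self._cumfreq = np.cumsum(self.df["frequency"].to_numpy(float))

    def validate(self) -> None:
        df = self.df
        if df.empty:
            raise ValueError("population table is empty")
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"population table is missing columns: {missing}")
        freq = df["frequency"].to_numpy(float)
        if (freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        if not math.isclose(freq.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"frequencies must sum to 1, got {freq.sum():.6f}")
        for col in ("revision_probability", "asa_ge3_probability"):
            p = df[col].to_numpy(float)
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if (df["base_los"].to_numpy(float) <= 0).any():
            raise ValueError("base_los must be positive")
        if (df["age_lo"] > df["age_hi"]).any():
            raise ValueError("age bands must satisfy age_lo <= age_hi")
        bad = set(df["procedure"]) - {"hip", "knee"}
        if bad:
            raise ValueError(f"unknown procedures: {bad}")
        bad = set(df["sex"]) - {"female", "male"}
        if bad:
            raise ValueError(f"unknown sexes: {bad}")

    def sample_index(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self._cumfreq, rng.random(), side="right").clip(0, len(self.df) - 1))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PopulationTable) and self.df.equals(other.df)


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient's fixed characteristics, shared by all arms."""

    patient_id: int
    procedure: str  # "hip" | "knee"
    revision: bool
    age: int
    age_band: tuple[int, int]
    sex: str  # "female" | "male"
    weight: float  # kg
    ebv: float  # ml
    baseline_hb: float  # g/dl
    asa_ge3: bool
    rheumatoid: bool
    cardiac_history: bool
    blood_loss_hb: float  # g/dl, positive magnitude after modifiers
    base_los: float  # days


def sample_procedure_cell(
    table: PopulationTable, rng: np.random.Generator
) -> tuple[pd.Series, tuple[int, int], str]:
    """Draw one (row, age band, sex) cell with probability equal to its frequency."""
    row = table.df.iloc[table.sample_index(rng)]
    return row, (int(row["age_lo"]), int(row["age_hi"])), str(row["sex"])


def sample_age_within_band(band: tuple[int, int], rng: np.random.Generator) -> int:
    """Integer age drawn uniformly over the inclusive band."""
    lo, hi = band
    if lo > hi:
        raise ValueError(f"inverted age band {band}")
    return int(rng.integers(lo, hi + 1))


def sample_weight(
    row: pd.Series, rng: np.random.Generator, floor: float = WEIGHT_FLOOR_KG
) -> float:
    """Normal body-weight draw, clamped below at a physiological floor."""
    mean, sd = float(row["weight_mean"]), float(row["weight_sd"])
    if sd == 0:
        return max(mean, floor)
    return max(float(rng.normal(mean, sd)), floor)


def estimated_blood_volume(weight: float, ebv_per_kg: float = 65.0) -> float:
    """Estimated blood volume in ml: body weight times ml/kg (default 65)."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return weight * ebv_per_kg


def sample_baseline_hb(
    sex: str,
    params: tuple[float, float, float],
    rng: np.random.Generator,
    size: Optional[int] = None,
):
    """Baseline Hb from a three-parameter Weibull, clamped to [6, 18] g/dl.

    ``params`` is (shape, scale, location).  ``sex`` is accepted for interface
    symmetry with the config's per-sex parameter pairs.
    """
    shape, scale, loc = params
    if shape <= 0 or scale <= 0:
        raise ValueError(f"invalid Weibull parameters {params}")
    draw = loc + scale * rng.weibull(shape, size=size)
    return np.clip(draw, *HB_CLAMP) if size is not None else float(min(max(draw, HB_CLAMP[0]), HB_CLAMP[1]))


def assign_comorbidities(
    row: pd.Series, config: ModelConfig, rng: np.random.Generator
) -> tuple[bool, bool, bool, bool]:
    """Independent Bernoulli draws: (asa_ge3, rheumatoid, cardiac_history, revision).

    ASA and revision risks come from the population cell; rheumatoid risk is
    procedure-specific and cardiac-history risk population-wide, both from the
    model config.
    """
    revision = bool(rng.random() < float(row["revision_probability"]))
    asa = bool(rng.random() < float(row["asa_ge3_probability"]))
    p_ra = config.rheumatoid_risk_hip if row["procedure"] == "hip" else config.rheumatoid_risk_knee
    rheumatoid = bool(rng.random() < p_ra)
    cardiac = bool(rng.random() < config.cardiac_history_probability)
    return asa, rheumatoid, cardiac, revision


def sample_blood_loss(
    procedure: str,
    asa_ge3: bool,
    old_age: bool,
    revision: bool,
    clinical: ClinicalInputs,
    rng: np.random.Generator,
) -> float:
    """Surgical blood loss in Hb g/dl: truncated-normal base draw times risk modifiers."""
    mean = clinical.blood_loss_mean_hip if procedure == "hip" else clinical.blood_loss_mean_knee
    base = max(0.0, float(rng.normal(mean, clinical.blood_loss_sd))) if clinical.blood_loss_sd > 0 else mean
    loss = base
    if asa_ge3:
        loss *= clinical.asa_loss_factor
    if old_age:
        loss *= clinical.age_loss_factor
    if revision:
        loss *= clinical.revision_loss_factor
    return loss


def create_patient(
    patient_id: int,
    table: PopulationTable,
    config: ModelConfig,
    rng: Optional[np.random.Generator] = None,
) -> PatientProfile:
    """Create one patient; deterministic given ``(config.seed, patient_id)``."""
    if rng is None:
        rng = characteristics_stream(config.seed, patient_id)
    clin = config.clinical

    row, band, sex = sample_procedure_cell(table, rng)
    age = sample_age_within_band(band, rng)
    weight = sample_weight(row, rng)
    ebv = estimated_blood_volume(weight, clin.ebv_per_kg)
    weibull = config.hb_weibull_female if sex == "female" else config.hb_weibull_male
    baseline_hb = sample_baseline_hb(sex, weibull, rng)
    asa, rheumatoid, cardiac, revision = assign_comorbidities(row, config, rng)
    old_age = age >= clin.old_age_threshold
    loss = sample_blood_loss(str(row["procedure"]), asa, old_age, revision, clin, rng)

    return PatientProfile(
        patient_id=patient_id,
        procedure=str(row["procedure"]),
        revision=revision,
        age=age,
        age_band=band,
        sex=sex,
        weight=weight,
        ebv=ebv,
        baseline_hb=baseline_hb,
        asa_ge3=asa,
        rheumatoid=rheumatoid,
        cardiac_history=cardiac,
        blood_loss_hb=loss,
        base_los=float(row["base_los"]),
    )


class FixtureParams(BaseModel):
    """Knobs for the synthetic population-mix fixture.

    Defaults approximate the German elective hip/knee arthroplasty case mix:
    hip share ~57%, female share ~62%, age centred near 71 years, ~10.4%
    revision risk and ~40% ASA >= III, base length of stay ~13 days.
    """

    model_config = ConfigDict(extra="forbid")

    hip_share: float = Field(0.57, ge=0, le=1)
    female_share: float = Field(0.62, ge=0, le=1)
    revision_probability: float = Field(0.104, ge=0, le=1)
    #: (age_lo, age_hi, mass) cells; masses normalised internally
    age_bands: list[tuple[int, int, float]] = Field(
        default_factory=lambda: [
            (18, 44, 0.02),
            (45, 54, 0.05),
            (55, 64, 0.17),
            (65, 74, 0.38),
            (75, 84, 0.31),
            (85, 94, 0.07),
        ]
    )
    #: per-procedure strata: (suffix, within-procedure share, base_los, asa_probability)
    strata: dict[str, list[tuple[str, float, float, float]]] = Field(
        default_factory=lambda: {
            "hip": [("standard", 0.8, 12.5, 0.36), ("complex", 0.2, 15.0, 0.55)],
            "knee": [("standard", 0.8, 12.8, 0.37), ("complex", 0.2, 14.8, 0.53)],
        }
    )
    weight_mean_female: float = 74.0
    weight_mean_male: float = 85.0
    weight_sd: float = 13.0
    #: kg per year of age above/below 70 (weight declines with age)
    weight_age_slope: float = -0.2


def generate_fixture_population(
    params: Optional[FixtureParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> PopulationTable:
    """Build the synthetic population-mix table (deterministic for fixed params).

    ``rng`` is accepted for interface uniformity; the default fixture is a
    deterministic function of its parameters, so identical inputs always
    yield an identical table.
    """
    p = params or FixtureParams()
    age_mass = np.array([m for _, _, m in p.age_bands], float)
    age_mass = age_mass / age_mass.sum()

    rows = []
    for procedure, proc_share in (("hip", p.hip_share), ("knee", 1.0 - p.hip_share)):
        for suffix, stratum_share, base_los, asa_p in p.strata[procedure]:
            for (lo, hi, _), mass in zip(p.age_bands, age_mass):
                mid = (lo + hi) / 2.0
                for sex, sex_share in (("female", p.female_share), ("male", 1.0 - p.female_share)):
                    base_w = p.weight_mean_female if sex == "female" else p.weight_mean_male
                    rows.append(
                        {
                            "row_id": f"{procedure}_{suffix}_{lo}-{hi}_{sex}",
                            "procedure": procedure,
                            "sex": sex,
                            "age_lo": lo,
                            "age_hi": hi,
                            "frequency": proc_share * stratum_share * mass * sex_share,
                            "revision_probability": p.revision_probability,
                            "asa_ge3_probability": asa_p,
                            "base_los": base_los,
                            "weight_mean": base_w + p.weight_age_slope * (mid - 70.0),
                            "weight_sd": p.weight_sd,
                        }
                    )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df[df["frequency"] > 0].reset_index(drop=True)
    df["frequency"] = df["frequency"] / df["frequency"].sum()
    return PopulationTable(df)
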