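"""Monte-Carlo driver: clone patients across arms, aggregate, report.

Each created patient is cloned into the three blood-management arms (ABT,
PAD, EPO) with identical characteristics; arm-level event draws use
independent sub-streams so that paired cost contrasts benefit from common
random numbers without sharing event noise.  Results are stratified by
baseline Hb in half-open 0.5 g/dl bands from 10.0 to 13.0 g/dl; every cell
is reported as (mean, SE, SD) with SE = SD/sqrt(n).  PAD columns are
suppressed for bands below the PAD eligibility threshold (11.0 g/dl).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from ._rng import make_rng_factory
from .config import ModelConfig, ScenarioSpec, apply_scenario, build_scenarios
from .costing import CostBreakdown, cost_episode
from .population import PatientProfile, PopulationTable, create_patient, generate_fixture_population
from .strategies import ARMS, ArmState, apply_abt, apply_epo, apply_pad
from .surgery import (
    EpisodeEvents,
    effective_trigger,
    length_of_stay,
    postoperative_hb,
    sample_infection,
    sample_pneumonia,
    transfuse,
    units_required,
)

__all__ = [
    "ArmOutcome",
    "PatientRecord",
    "CellStat",
    "BandSummary",
    "run_patient",
    "run_simulation",
    "records_to_frame",
    "stratify_and_summarize",
    "run_scenario_grid",
    "write_report",
    "load_report",
]


@dataclass(frozen=True)
class ArmOutcome:
    state: ArmState
    events: EpisodeEvents
    los: float
    costs: CostBreakdown


@dataclass(frozen=True)
class PatientRecord:
    """One patient's profile plus the outcome of each arm's cloned episode."""

    profile: PatientProfile
    outcomes: dict[str, ArmOutcome]


def run_patient(
    profile: PatientProfile,
    config: ModelConfig,
    rng_factory: Callable[[str, str], np.random.Generator],
) -> PatientRecord:
    """Run one patient's surgery episode through all three arms."""
    clin = config.clinical
    trigger = effective_trigger(clin.transfusion_trigger, profile.cardiac_history, clin.cardiac_trigger_shift)
    outcomes: dict[str, ArmOutcome] = {}
    for arm in ARMS:
        if arm == "ABT":
            state = apply_abt(profile)
        elif arm == "PAD":
            state = apply_pad(profile, clin, rng_factory(arm, "strategy"))
        else:
            state = apply_epo(profile, clin, rng_factory(arm, "strategy"))
        postop = postoperative_hb(state, profile.blood_loss_hb)
        needed = units_required(postop, trigger, clin.hb_per_unit, clin.transfuse_at_equality)
        autologous, allogeneic = transfuse(state, needed)
        transfused = autologous + allogeneic > 0
        infection = bool(sample_infection(transfused, clin, rng_factory(arm, "infection")))
        pneumonia = bool(sample_pneumonia(transfused, clin, rng_factory(arm, "pneumonia")))
        los = length_of_stay(profile.base_los, transfused, infection, clin, age=profile.age)
        events = EpisodeEvents(
            postop_hb=postop,
            effective_trigger=trigger,
            autologous_units=autologous,
            allogeneic_units=allogeneic,
            transfused=transfused,
            infection=infection,
            pneumonia=pneumonia,
            final_hb=postop + (autologous + allogeneic) * clin.hb_per_unit,
        )
        costs = cost_episode(events, state, los, config.costs)
        outcomes[arm] = ArmOutcome(state=state, events=events, los=los, costs=costs)
    return PatientRecord(profile=profile, outcomes=outcomes)


def run_simulation(
    config: ModelConfig,
    table: Optional[PopulationTable] = None,
    n_patients: Optional[int] = None,
) -> list[PatientRecord]:
    """Create and run ``n_patients`` patients (default from the config)."""
    if table is None:
        table = PopulationTable.from_csv(config.population) if config.population else generate_fixture_population()
    n = n_patients if n_patients is not None else config.n_patients
    records = []
    for pid in range(n):
        profile = create_patient(pid, table, config)
        records.append(run_patient(profile, config, make_rng_factory(config.seed, pid)))
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records into one row per patient for aggregation."""
    rows = []
    for r in records:
        p = r.profile
        row = {
            "patient_id": p.patient_id,
            "baseline_hb": p.baseline_hb,
            "female": p.sex == "female",
            "age": p.age,
            "revision": p.revision,
            "hip": p.procedure == "hip",
            "asa_ge3": p.asa_ge3,
            "cardiac": p.cardiac_history,
            "rheumatoid": p.rheumatoid,
            "blood_loss_hb": p.blood_loss_hb,
        }
        for arm in ARMS:
            o = r.outcomes[arm]
            a = arm.lower()
            row.update(
                {
                    f"{a}_hb_adjusted": o.state.preop_hb_adjusted,
                    f"{a}_pad_applicable": o.state.pad_applicable,
                    f"{a}_epo_doses": o.state.epo_doses_given,
                    f"{a}_auto_units": o.events.autologous_units,
                    f"{a}_allo_units": o.events.allogeneic_units,
                    f"{a}_transfused": o.events.transfused,
                    f"{a}_infection": o.events.infection,
                    f"{a}_pneumonia": o.events.pneumonia,
                    f"{a}_los": o.los,
                    f"{a}_epo_cost": o.costs.epo_cost,
                    f"{a}_transfusion_cost": o.costs.transfusion_allogeneic_cost,
                    f"{a}_pad_cost": o.costs.pad_collection_cost,
                    f"{a}_los_cost": o.costs.los_cost,
                    f"{a}_pneumonia_cost": o.costs.pneumonia_cost,
                    f"{a}_total_cost": o.costs.total_cost,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CellStat:
    """One reporting cell: mean with its standard error and deviation."""

    mean: float
    se: Optional[float]
    sd: Optional[float]
    n: int

    def to_list(self) -> list:
        return [self.mean, self.se, self.sd, self.n]

    @classmethod
    def from_list(cls, v: list) -> "CellStat":
        return cls(mean=v[0], se=v[1], sd=v[2], n=int(v[3]))


def _cell(values: np.ndarray, n_se: Optional[int] = None) -> Optional[CellStat]:
    """Sample mean/SE/SD of ``values``; None for an empty cell."""
    v = np.asarray(values, float)
    if v.size == 0:
        return None
    mean = float(v.mean())
    if v.size < 2:
        return CellStat(mean=mean, se=None, sd=None, n=int(v.size))
    sd = float(v.std(ddof=1))
    n = n_se if n_se is not None else v.size
    return CellStat(mean=mean, se=sd / math.sqrt(n), sd=sd, n=int(v.size))


@dataclass
class BandSummary:
    """Per-Hb-band stratified statistics for all arms plus cost contrasts."""

    band: tuple[float, float]
    n: int
    baseline: dict[str, Optional[CellStat]] = field(default_factory=dict)
    arms: dict[str, dict[str, Optional[CellStat]]] = field(default_factory=dict)
    incremental: dict[str, Optional[CellStat]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(d):
            return {k: (None if v is None else v.to_list()) for k, v in d.items()}

        return {
            "band": list(self.band),
            "n": self.n,
            "baseline": enc(self.baseline),
            "arms": {arm: enc(stats) for arm, stats in self.arms.items()},
            "incremental": enc(self.incremental),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandSummary":
        def dec(e):
            return {k: (None if v is None else CellStat.from_list(v)) for k, v in e.items()}

        return cls(
            band=tuple(d["band"]),
            n=int(d["n"]),
            baseline=dec(d["baseline"]),
            arms={arm: dec(stats) for arm, stats in d["arms"].items()},
            incremental=dec(d["incremental"]),
        )


def _bands(config: ModelConfig) -> list[tuple[float, float]]:
    edges = np.arange(config.band_lo, config.band_hi + 1e-9, config.band_width)
    return [(float(lo), float(lo + config.band_width)) for lo in edges[:-1]]


def _arm_stats(sub: pd.DataFrame, arm: str) -> dict[str, Optional[CellStat]]:
    a = arm.lower()
    pct = lambda col: _cell(sub[col].to_numpy(float) * 100.0)
    stats: dict[str, Optional[CellStat]] = {}
    if arm == "PAD":
        applicable = sub[sub[f"{a}_pad_applicable"]]
        stats["hb_decrease"] = _cell(
            (applicable[f"{a}_hb_adjusted"] - applicable["baseline_hb"]).to_numpy(float)
        )
        auto = sub[sub[f"{a}_auto_units"] > 0]
        allo = sub[sub[f"{a}_allo_units"] > 0]
        stats["transfused_autologous_pct"] = _cell((sub[f"{a}_auto_units"] > 0).to_numpy(float) * 100.0)
        stats["units_autologous_per_transfusion"] = _cell(auto[f"{a}_auto_units"].to_numpy(float))
        stats["transfused_allogeneic_pct"] = _cell((sub[f"{a}_allo_units"] > 0).to_numpy(float) * 100.0)
        stats["units_allogeneic_per_transfusion"] = _cell(allo[f"{a}_allo_units"].to_numpy(float))
        stats["pad_collection_cost"] = _cell(sub[f"{a}_pad_cost"].to_numpy(float))
    else:
        transfused = sub[sub[f"{a}_transfused"]]
        stats["transfused_pct"] = pct(f"{a}_transfused")
        stats["units_per_transfusion"] = _cell(
            (transfused[f"{a}_auto_units"] + transfused[f"{a}_allo_units"]).to_numpy(float)
        )
    if arm == "EPO":
        stats["hb_increase"] = _cell((sub[f"{a}_hb_adjusted"] - sub["baseline_hb"]).to_numpy(float))
        stats["epo_doses"] = _cell(sub[f"{a}_epo_doses"].to_numpy(float))
        stats["epo_cost"] = _cell(sub[f"{a}_epo_cost"].to_numpy(float))
    stats["infection_pct"] = pct(f"{a}_infection")
    stats["los_days"] = _cell(sub[f"{a}_los"].to_numpy(float))
    stats["transfusion_cost"] = _cell(sub[f"{a}_transfusion_cost"].to_numpy(float))
    stats["los_cost"] = _cell(sub[f"{a}_los_cost"].to_numpy(float))
    stats["pneumonia_cost"] = _cell(sub[f"{a}_pneumonia_cost"].to_numpy(float))
    stats["total_cost"] = _cell(sub[f"{a}_total_cost"].to_numpy(float))
    return stats


def stratify_and_summarize(
    records: list[PatientRecord], config: ModelConfig
) -> list[BandSummary]:
    """Aggregate records into half-open baseline-Hb band summaries.

    Patients outside [band_lo, band_hi) are excluded from the band rows
    (they remain in the optional all-patients row when ``full_population``
    is set).  The revision subgroup filter applies first when configured.
    """
    if not records:
        raise ValueError("no records to summarize")
    frame = records_to_frame(records)
    if config.subgroup == "revision":
        frame = frame[frame["revision"]]
    total = len(frame)

    summaries = []
    bands = _bands(config)
    if config.full_population:
        bands = bands + [(-math.inf, math.inf)]
    for lo, hi in bands:
        sub = frame[(frame["baseline_hb"] >= lo) & (frame["baseline_hb"] < hi)]
        n = len(sub)
        summary = BandSummary(band=(lo, hi), n=n)
        if n == 0:
            summaries.append(summary)
            continue
        in_band = ((frame["baseline_hb"] >= lo) & (frame["baseline_hb"] < hi)).to_numpy(float)
        summary.baseline = {
            "percent_of_total": _cell(in_band * 100.0),
            "female_pct": _cell(sub["female"].to_numpy(float) * 100.0),
            "age_years": _cell(sub["age"].to_numpy(float)),
            "revision_pct": _cell(sub["revision"].to_numpy(float) * 100.0),
            "hip_pct": _cell(sub["hip"].to_numpy(float) * 100.0),
            "asa_ge3_pct": _cell(sub["asa_ge3"].to_numpy(float) * 100.0),
            "cardiac_pct": _cell(sub["cardiac"].to_numpy(float) * 100.0),
            "hb_base": _cell(sub["baseline_hb"].to_numpy(float)),
        }
        pad_band = lo >= config.clinical.pad_min_hb
        for arm in ARMS:
            if arm == "PAD" and not pad_band:
                continue  # PAD is not an option below the eligibility threshold
            summary.arms[arm] = _arm_stats(sub, arm)
        abt_total = sub["abt_total_cost"].to_numpy(float)
        epo_total = sub["epo_total_cost"].to_numpy(float)
        summary.incremental["abt_minus_epo_total"] = _cell(abt_total - epo_total)
        if pad_band:
            pad_total = sub["pad_total_cost"].to_numpy(float)
            summary.incremental["pad_minus_epo_total"] = _cell(pad_total - epo_total)
        summaries.append(summary)
    return summaries


def run_scenario_grid(
    base_config: ModelConfig,
    scenarios: Optional[list[ScenarioSpec]] = None,
    n_patients: Optional[int] = None,
) -> dict[str, list[BandSummary]]:
    """Run every scenario with a shared population table and shared seed.

    All scenarios reuse the base seed, so patient-characteristic draws are
    common random numbers across scenarios and deltas between scenarios are
    not dominated by sampling noise.
    """
    if scenarios is None:
        scenarios = build_scenarios(base_config)
    table = (
        PopulationTable.from_csv(base_config.population)
        if base_config.population
        else generate_fixture_population()
    )
    results = {}
    for spec in scenarios:
        cfg = apply_scenario(base_config, spec)
        records = run_simulation(cfg, table=table, n_patients=n_patients)
        results[spec.name] = stratify_and_summarize(records, cfg)
    return results


def _band_label(band: tuple[float, float]) -> str:
    if band[0] == -math.inf:
        return "all"
    return f"{band[0]:g}-{band[1]:g}"


def _fmt(cell: Optional[CellStat]) -> str:
    if cell is None:
        return ""
    se = "" if cell.se is None else f"{cell.se:.6g}"
    sd = "" if cell.sd is None else f"{cell.sd:.6g}"
    return f"{cell.mean:.6g} ({se}; {sd})"


def write_report(
    summaries: list[BandSummary], out_dir: Union[str, Path], name: str = "base"
) -> tuple[Path, Path]:
    """Write one scenario's summaries as a wide CSV and a JSON document.

    The CSV mirrors the stratified-results layout: one column per Hb band,
    one row per statistic, cells formatted ``mean (SE; SD)``; empty bands are
    emitted as missing markers.  The JSON holds every cell numerically and
    round-trips through :func:`load_report`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{name}.json"
    csv_path = out / f"{name}.csv"

    json_path.write_text(json.dumps([s.to_dict() for s in summaries], indent=1))

    labels = [_band_label(s.band) for s in summaries]
    rows: dict[str, dict[str, str]] = {}
    rows["n"] = {lab: str(s.n) for lab, s in zip(labels, summaries)}
    for lab, s in zip(labels, summaries):
        for key, cell in s.baseline.items():
            rows.setdefault(f"baseline.{key}", {})[lab] = _fmt(cell)
        for arm, stats in s.arms.items():
            for key, cell in stats.items():
                rows.setdefault(f"{arm}.{key}", {})[lab] = _fmt(cell)
        for key, cell in s.incremental.items():
            rows.setdefault(f"incremental.{key}", {})[lab] = _fmt(cell)
    table = pd.DataFrame(
        [[rows[r].get(lab, "") for lab in labels] for r in rows],
        index=list(rows),
        columns=labels,
    )
    table.index.name = "statistic"
    table.to_csv(csv_path)
    return csv_path, json_path


def load_report(json_path: Union[str, Path]) -> list[BandSummary]:
    """Reload a JSON report written by :func:`write_report`."""
    data = json.loads(Path(json_path).read_text())
    return [BandSummary.from_dict(d) for d in data]
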