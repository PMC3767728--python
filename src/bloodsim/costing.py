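"""Per-episode cost accounting, hospital perspective, euros.

Components follow the stratified results layout: epoetin doses, allogeneic
units, the flat autologous-collection charge (incurred by every
PAD-applicable patient whether or not the banked units are reinfused),
length of stay, and pneumonia treatment.  Autologous units carry no per-unit
transfusion charge beyond the collection fee.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import CostInputs
from .strategies import ArmState
from .surgery import EpisodeEvents

__all__ = ["CostBreakdown", "cost_episode", "incremental_cost"]


@dataclass(frozen=True)
class CostBreakdown:
    """Euro cost components for one arm's episode; total is their sum."""

    epo_cost: float
    transfusion_allogeneic_cost: float
    pad_collection_cost: float
    los_cost: float
    pneumonia_cost: float
    total_cost: float


def cost_episode(
    events: EpisodeEvents, state: ArmState, los_days: float, costs: CostInputs
) -> CostBreakdown:
    """Cost one arm's surgery episode.

    LOS is costed fractionally (days x per-day rate); the PAD collection
    charge is flat per applicable patient.
    """
    if los_days < 0:
        raise ValueError("los_days must be non-negative")
    epo = state.epo_doses_given * costs.epo_dose_cost
    allogeneic = events.allogeneic_units * costs.allogeneic_unit_cost
    pad = costs.autologous_collection_cost if state.pad_applicable else 0.0
    los = los_days * costs.hospital_day_cost
    pneumonia = costs.pneumonia_cost if events.pneumonia else 0.0
    return CostBreakdown(
        epo_cost=epo,
        transfusion_allogeneic_cost=allogeneic,
        pad_collection_cost=pad,
        los_cost=los,
        pneumonia_cost=pneumonia,
        total_cost=epo + allogeneic + pad + los + pneumonia,
    )


def incremental_cost(
    reference_costs: Sequence[float], comparator_costs: Sequence[float]
) -> tuple[float, float]:
    """Paired incremental cost: mean and SE of per-patient differences.

    The arms are clones of the same patients, so the contrast is paired:
    SE = SD(reference - comparator) / sqrt(n).
    """
    ref = np.asarray(reference_costs, float)
    comp = np.asarray(comparator_costs, float)
    if ref.shape != comp.shape:
        raise ValueError(f"unpaired cost lists: {ref.shape} vs {comp.shape}")
    if ref.size < 2:
        raise ValueError("need at least two paired observations")
    diff = ref - comp
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(diff.size))
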