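"""Surgery episode: post-operative Hb, transfusion ladder, events, stay.

The post-surgery Hb is the arm-adjusted preoperative Hb minus the patient's
drawn blood loss.  Patients at or below the (possibly cardiac-shifted)
transfusion trigger receive as many RBC units as needed to meet or exceed
it — autologous units first, then allogeneic.  Transfusion doubles the
pneumonia risk (1.6% vs 0.8%) and raises the infection risk; both events and
the transfusion itself inflate the length of stay (x1.2 transfusion only,
x1.6 infection only, x1.9 both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .config import ClinicalInputs
from .strategies import ArmState

__all__ = [
    "EpisodeEvents",
    "effective_trigger",
    "postoperative_hb",
    "units_required",
    "transfuse",
    "sample_infection",
    "sample_pneumonia",
    "length_of_stay",
]

_CEIL_EPS = 1e-9  # guards ceil() against float noise at exact unit multiples


@dataclass(frozen=True)
class EpisodeEvents:
    """Outcome of one arm's surgery episode for one patient clone."""

    postop_hb: float
    effective_trigger: float
    autologous_units: int
    allogeneic_units: int
    transfused: bool
    infection: bool
    pneumonia: bool
    final_hb: float


def effective_trigger(base_trigger: float, cardiac_history: bool, shift: float) -> float:
    """Transfusion trigger, raised by ``shift`` g/dl for cardiac history.

    The cardiac shift applies regardless of which base trigger is in use.
    """
    if base_trigger <= 0:
        raise ValueError(f"trigger must be positive, got {base_trigger}")
    return base_trigger + shift if cardiac_history else base_trigger


def postoperative_hb(state: ArmState, blood_loss_hb: float) -> float:
    """Adjusted preoperative Hb minus surgical loss, floored at zero."""
    return max(0.0, state.preop_hb_adjusted - blood_loss_hb)


def units_required(
    postop_hb: float,
    trigger: float,
    hb_per_unit: float,
    transfuse_at_equality: bool = False,
) -> int:
    """RBC units needed to bring ``postop_hb`` to (at least) the trigger.

    A patient already at the trigger exactly is considered to meet it and
    receives nothing, unless the equality boundary switch is set.
    """
    if hb_per_unit <= 0:
        raise ValueError(f"hb_per_unit must be positive, got {hb_per_unit}")
    if postop_hb > trigger:
        return 0
    if postop_hb == trigger:
        return 1 if transfuse_at_equality else 0
    return math.ceil((trigger - postop_hb) / hb_per_unit - _CEIL_EPS)


def transfuse(state: ArmState, units_needed: int) -> tuple[int, int]:
    """Split required units into (autologous, allogeneic) — banked units first."""
    if units_needed < 0:
        raise ValueError("units_needed must be non-negative")
    autologous = min(units_needed, state.autologous_units_available)
    return autologous, units_needed - autologous


def _bernoulli(
    p: float, rng: np.random.Generator, size: Optional[int]
) -> Union[bool, np.ndarray]:
    if size is None:
        return bool(rng.random() < p)
    return rng.random(size) < p


def sample_infection(
    transfused: bool,
    clinical: ClinicalInputs,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> Union[bool, np.ndarray]:
    """Nosocomial infection draw; transfusion (any source) raises the risk."""
    p = clinical.p_infection_transfused if transfused else clinical.p_infection_base
    return _bernoulli(p, rng, size)


def sample_pneumonia(
    transfused: bool,
    clinical: ClinicalInputs,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> Union[bool, np.ndarray]:
    """Pneumonia draw; risk doubles with transfusion (1.6% vs 0.8% at defaults)."""
    p = clinical.p_pneumonia_transfused if transfused else clinical.p_pneumonia_base
    return _bernoulli(p, rng, size)


def length_of_stay(
    base_los: float,
    transfused: bool,
    infection: bool,
    clinical: ClinicalInputs,
    age: Optional[int] = None,
) -> float:
    """Length of stay in days, kept fractional for costing.

    Base stay is inflated by the transfusion/infection multipliers and, when a
    non-default ``los_age_factor`` is configured, by the old-age multiplier.
    """
    if base_los <= 0:
        raise ValueError(f"base_los must be positive, got {base_los}")
    if transfused and infection:
        los = base_los * clinical.los_both_factor
    elif transfused:
        los = base_los * clinical.los_transfusion_factor
    elif infection:
        los = base_los * clinical.los_infection_factor
    else:
        los = base_los
    if age is not None and age >= clinical.old_age_threshold:
        los *= clinical.los_age_factor
    return los
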