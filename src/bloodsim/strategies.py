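"""Preoperative blood-management arms.

Each simulated patient is cloned into three arms that differ only in how the
preoperative hemoglobin is prepared:

* **ABT** — no blood conservation; surgery at baseline Hb.
* **PAD** — preoperative autologous donation: two units banked (if baseline
  Hb >= 11 g/dl), at the price of a stochastic Hb drop at surgery.
* **EPO** — epoetin alfa 40,000 IU injections given while the running Hb is
  below the termination threshold (13.3 g/dl base case), up to the regimen
  maximum; each injection raises Hb by a truncated-normal increment,
  attenuated for rheumatoid arthritis.

The PAD decrement is drawn once (cumulative over both donations) from a
normal truncated at zero whose location is solved so that the *realized*
mean drop equals the configured mean effect (the headline "PAD effect on
preoperative Hb" is a mean effect size, and donation never raises Hb).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .config import ClinicalInputs
from .population import PatientProfile

__all__ = ["ArmState", "apply_abt", "apply_pad", "apply_epo", "ARMS"]

ARMS = ("ABT", "PAD", "EPO")


@dataclass(frozen=True)
class ArmState:
    """Preoperative state of one patient clone after arm-specific preparation."""

    arm: str
    preop_hb_adjusted: float  # g/dl
    autologous_units_available: int = 0
    epo_doses_given: int = 0
    epo_doses_effective: int = 0
    pad_applicable: bool = False


def apply_abt(profile: PatientProfile) -> ArmState:
    """No blood conservation: surgery at the unmodified baseline Hb."""
    return ArmState(arm="ABT", preop_hb_adjusted=profile.baseline_hb)


@lru_cache(maxsize=64)
def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location mu such that E[max(0, N(mu, sd))] equals ``target_mean``."""
    if sd == 0 or target_mean == 0:
        return target_mean

    def clamped_mean(mu: float) -> float:
        z = mu / sd
        return mu * norm.cdf(z) + sd * norm.pdf(z)

    lo = target_mean - 6 * sd
    hi = target_mean + sd
    return float(brentq(lambda m: clamped_mean(m) - target_mean, lo, hi))


def apply_pad(profile: PatientProfile, clinical: ClinicalInputs, rng: np.random.Generator) -> ArmState:
    """Autologous predonation; not applicable below the minimum baseline Hb.

    Ineligible patients (baseline Hb < ``pad_min_hb``) proceed exactly as in
    the ABT arm, with no units banked and no collection charge.
    """
    if profile.baseline_hb < clinical.pad_min_hb:
        return ArmState(arm="PAD", preop_hb_adjusted=profile.baseline_hb, pad_applicable=False)
    mu = _truncnorm_location(clinical.pad_hb_decrement_mean, clinical.pad_hb_decrement_sd)
    if clinical.pad_hb_decrement_sd == 0:
        decrement = clinical.pad_hb_decrement_mean
    else:
        decrement = max(0.0, float(rng.normal(mu, clinical.pad_hb_decrement_sd)))
    return ArmState(
        arm="PAD",
        preop_hb_adjusted=max(0.0, profile.baseline_hb - decrement),
        autologous_units_available=clinical.pad_units,
        pad_applicable=True,
    )


def apply_epo(profile: PatientProfile, clinical: ClinicalInputs, rng: np.random.Generator) -> ArmState:
    """Epoetin alfa injection loop: check-then-dose on the running Hb.

    A dose is given only while the running (post-previous-increment) Hb is
    below the termination threshold and the injection count is below the
    regimen maximum.  Under the day-of-surgery protocol variant, the final
    scheduled injection is administered (and charged) but cannot act on the
    Hb at incision, so it counts in ``epo_doses_given`` only.
    """
    reg = clinical.epo_regimen
    max_effective = reg.max_injections - 1 if reg.day_of_surgery_dose_counts_cost_only else reg.max_injections
    hb = profile.baseline_hb
    given = effective = 0
    while hb < reg.termination_hb and effective < max_effective:
        given += 1
        effective += 1
        if reg.per_injection_increment_sd > 0:
            increment = max(0.0, float(rng.normal(reg.per_injection_increment_mean, reg.per_injection_increment_sd)))
        else:
            increment = reg.per_injection_increment_mean
        if profile.rheumatoid:
            increment *= clinical.ra_epo_attenuation
        hb += increment
    if reg.day_of_surgery_dose_counts_cost_only and hb < reg.termination_hb and given < reg.max_injections:
        given += 1  # day-of-surgery dose: charged, no Hb effect before incision
    return ArmState(
        arm="EPO",
        preop_hb_adjusted=hb,
        epo_doses_given=given,
        epo_doses_effective=effective,
    )
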