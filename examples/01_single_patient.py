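"""Trace one anemic patient through the three blood-management arms.

Builds a deterministic 70 kg woman with baseline Hb 11.5 g/dl facing a hip
arthroplasty losing 3.3 g/dl, with all stochastic noise switched off, and
prints each arm's preoperative adjustment, transfusion, stay and cost.
"""

from bloodsim import ModelConfig, run_patient
from bloodsim._rng import make_rng_factory
from bloodsim.population import PatientProfile

config = ModelConfig()
clin = config.clinical
clin.pad_hb_decrement_sd = 0.0
clin.epo_regimen.per_injection_increment_sd = 0.0
clin.p_infection_base = clin.p_infection_transfused = 0.0
clin.p_pneumonia_base = clin.p_pneumonia_transfused = 0.0

patient = PatientProfile(
    patient_id=0, procedure="hip", revision=False, age=70, age_band=(65, 74),
    sex="female", weight=70.0, ebv=70 * 65, baseline_hb=11.5, asa_ge3=False,
    rheumatoid=False, cardiac_history=False, blood_loss_hb=3.3, base_los=10.0,
)

record = run_patient(patient, config, make_rng_factory(config.seed, 0))
print(f"patient: {patient.sex}, {patient.age} y, baseline Hb {patient.baseline_hb} g/dl, "
      f"loss {patient.blood_loss_hb} g/dl, trigger {clin.transfusion_trigger} g/dl")
for arm, out in record.outcomes.items():
    e, c = out.events, out.costs
    print(f"{arm:>3}: preop Hb {out.state.preop_hb_adjusted:5.2f}  postop {e.postop_hb:5.2f}  "
          f"units auto/allo {e.autologous_units}/{e.allogeneic_units}  "
          f"LOS {out.los:4.1f} d  total {c.total_cost:7.0f} EUR")

# ABT transfuses one allogeneic unit (postop 8.2 < 8.5); PAD's lowered preop Hb
# costs two units but both come from the bank; EPO's two injections lift the
# preop Hb enough that no transfusion is needed at all.
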