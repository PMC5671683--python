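# Default severity-grading criteria (registry proxies).
#
# One block per severity level.  `rules` fire individually (OR); every rule
# inside one `combined` group must hold jointly (AND).  A missing flag state
# never satisfies a rule.  MD is not configured here: it is fixed to
# death_status in {died_at_facility, died_in_transport_or_referral}.
#
# Note the deliberate reading of the transfusion/haemorrhage overlap: near
# miss requires blood transfusion AND haemorrhage jointly; a transfusion
# without recorded haemorrhage counts as a potentially life-threatening
# condition ("any blood transfusion").  Registries that prefer the
# single-criterion reading can move blood_transfusion into MNM `rules`.
MNM:
  rules:
    - {field: eclampsia_or_mgso4, comparator: is_present}
    - {field: cardiac_disease, comparator: is_present}
    - {field: renal_disease, comparator: is_present}
    - {field: hospital_stay_days, comparator: greater_than, value: 7}
  combined:
    - - {field: blood_transfusion, comparator: is_present}
      - {field: haemorrhage_any, comparator: is_present}
PLTC:
  rules:
    - {field: abruptio_placentae, comparator: is_present}
    - {field: ectopic_pregnancy, comparator: is_present}
    - {field: uterine_rupture, comparator: is_present}
    - {field: postpartum_haemorrhage, comparator: is_present}
    - {field: puerperal_sepsis, comparator: is_present}
    - {field: puerperal_infection, comparator: is_present}
    - {field: severe_preeclampsia_no_mgso4, comparator: is_present}
    - {field: severe_hypertension, comparator: is_present}
    - {field: blood_transfusion, comparator: is_present}
    - {field: placenta_previa_with_haemorrhage, comparator: is_present}
    - {field: other_severe_condition, comparator: is_present}
LSMM:
  rules:
    - {field: anaemia, comparator: is_present}
    - {field: hiv_positive, comparator: is_present}
    - {field: diabetes, comparator: is_present}
    - {field: antenatal_admission, comparator: is_present}
    - {field: ovular_infection, comparator: is_present}
    - {field: urinary_tract_infection, comparator: is_present}
    - {field: other_maternal_condition, comparator: is_present}
    - {field: retained_placenta, comparator: is_present}
    - {field: referred, comparator: is_present}
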