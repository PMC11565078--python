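# Myocardial infarction: secondary-prevention medication coverage after
# STEMI or coronary intervention.  Code lists are editorial defaults and
# fully configurable; system URIs follow German hospital conventions.
name: mi
cohort:
  icd_prefixes: [I21]
  period:
    start: "2022-01-01T00:00:00+00:00"
    end: "2023-01-01T00:00:00+00:00"
stemi_icd_prefixes: ["I21.0", "I21.1", "I21.2", "I21.3"]
procedure_system: "http://fhir.de/CodeSystem/bfarm/ops"
intervention_procedure_codes: ["8-837"]
atc_system: "http://www.whocc.no/atc"
atc_prefixes:
  antiplatelet: [B01AC]
  statin: [C10AA]
  ezetimibe: [C10AX]
  anticoagulant: [B01AA, B01AB, B01AE, B01AF]
# adherence: antiplatelet_or_statin | antiplatelet_or_anticoag_and_statin
adherence_rule: antiplatelet_or_statin
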