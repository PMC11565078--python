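# Prostate cancer: treatment landscape and post-prostatectomy PSA
# surveillance.  The cohort window is deliberately asymmetric: diagnoses in
# 2021, treatments in 2021-2022 (PSA follow-up needs the longer horizon).
# Persistence/recurrence thresholds are editorial defaults in ng/mL.
name: pc
cohort:
  icd_prefixes: [C61]
  period:
    start: "2021-01-01T00:00:00+00:00"
    end: "2022-01-01T00:00:00+00:00"
treatment_period:
  start: "2021-01-01T00:00:00+00:00"
  end: "2023-01-01T00:00:00+00:00"
procedure_system: "http://fhir.de/CodeSystem/bfarm/ops"
prostatectomy_codes: ["5-604"]
radiation_codes: ["8-52"]
atc_system: "http://www.whocc.no/atc"
adt_atc_prefixes: [L02]
loinc_system: "http://loinc.org"
psa_codes: ["2857-1"]
local_system: "http://medintel.example/codes"
tnm_code: "tnm-stage"
isup_code: "isup-grade"
margin_code: "resection-margin"
rules:
  persistence_threshold: 0.1      # first post-op PSA at/above => persistence
  persistence_window_days: 180
  recurrence_threshold: 0.2       # confirmed post-nadir rise crossing this
  undetectable_threshold: 0.1     # nadir below this counts as undetectable
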