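# Stroke: door-to-needle / door-to-groin quality indicators and early
# neurological improvement (NIHSS baseline -> 24 h).
name: stroke
cohort:
  icd_prefixes: [I63, I61]
  period:
    start: "2022-01-01T00:00:00+00:00"
    end: "2023-01-01T00:00:00+00:00"
ischemic_prefixes: [I63]
hemorrhagic_prefixes: [I61]
procedure_system: "http://fhir.de/CodeSystem/bfarm/ops"
lysis_codes: ["8-020.8"]
thrombectomy_codes: ["8-836.80"]
loinc_system: "http://loinc.org"
nihss_code: "70182-1"
local_system: "http://medintel.example/codes"
onset_code: "symptom-onset"          # Observation.effective is the onset instant
eni_exclusion_code: "eni-exclusion"  # marker excluding a patient from ENI classification
baseline_tolerance_hours: 12
followup_offset_hours: 24
followup_tolerance_hours: 12
thresholds:
  needle_minutes: 60
  groin_minutes: 90
  boundary: leq   # leq counts treatment exactly at the threshold as in-window
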