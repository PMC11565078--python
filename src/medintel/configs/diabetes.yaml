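# Dysglycemia screening over all measured inpatients: biochemical flags
# from serum glucose and HbA1c, and the ICD-10 coding gap.
# Cutoffs are ADA-style editorial defaults (the clinically conventional
# choice); every threshold is configurable.
name: diabetes
period:
  start: "2022-01-01T00:00:00+00:00"
  end: "2023-01-01T00:00:00+00:00"
loinc_system: "http://loinc.org"
glucose_codes: ["2345-7", "2339-0"]
hba1c_codes: ["4548-4"]
icd_prefixes: [E10, E11, E12, E13, E14, R73]
thresholds:
  glucose_hyper_mgdl: 140.0
  glucose_diabetes_mgdl: 200.0
  hba1c_prediabetes_pct: 5.7
  hba1c_diabetes_pct: 6.5
  # when true, a maximum glucose inside [hyper, diabetes) also raises the
  # prediabetes flag; default off (prediabetes is an HbA1c finding)
  glucose_prediabetes_band: false
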