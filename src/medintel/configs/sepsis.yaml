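# Sepsis: antibiogram-style pathogen and antibiotic-use summaries plus
# per-patient inflammation timelines.  Organism identification uses an
# exact-match lexicon over culture-report conclusions (no NLP).
name: sepsis
cohort:
  icd_prefixes: [A40, A41]
  period:
    start: "2022-01-01T00:00:00+00:00"
    end: "2023-01-01T00:00:00+00:00"
loinc_system: "http://loinc.org"
culture_report_codes: ["600-7"]   # blood culture; empty list = all reports
crp_code: "1988-5"
procalcitonin_code: "33959-8"
atc_system: "http://www.whocc.no/atc"
antibiotic_atc_prefix: J01
top_k: 10
organism_lexicon:
  - Staphylococcus epidermidis
  - Escherichia coli
  - Enterococcus faecium
  - Staphylococcus aureus
  - Klebsiella pneumoniae
  - Pseudomonas aeruginosa
  - Enterococcus faecalis
  - Candida albicans
  - Streptococcus pneumoniae
  - Proteus mirabilis
  - Enterobacter cloacae
  - Serratia marcescens
  - Staphylococcus haemolyticus
  - Streptococcus agalactiae
  - Morganella morganii
antibiotic_names:
  J01CR05: piperacillin/tazobactam
  J01DH02: meropenem
  J01XA01: vancomycin
  J01DD04: ceftriaxone
  J01CR02: amoxicillin/clavulanate
  J01MA02: ciprofloxacin
  J01DC02: cefuroxime
  J01XX08: linezolid
  J01FA10: azithromycin
  J01EE01: sulfamethoxazole/trimethoprim
  J01GB03: gentamicin
  J01DH51: imipenem/cilastatin
  J01FF01: clindamycin
  J01XD01: metronidazole
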