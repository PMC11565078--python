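{
  "description": "Required top-level members (and their JSON types) of each use-case report document.",
  "mi": {
    "n_mi_diagnosed": "number",
    "n_cohort": "number",
    "cells": "object",
    "cell_pcts": "object",
    "n_antiplatelet_any": "number",
    "n_statin_any": "number",
    "n_adherent": "number",
    "patients": "array"
  },
  "stroke": {
    "n_cohort": "number",
    "n_ischemic": "number",
    "n_hemorrhagic": "number",
    "thresholds": "object",
    "lysis": "object",
    "thrombectomy": "object",
    "patients": "array"
  },
  "diabetes": {
    "n_patients": "number",
    "n_glucose_readings": "number",
    "n_hba1c_readings": "number",
    "n_hyperglycemic": "number",
    "n_prediabetes": "number",
    "n_diabetes": "number",
    "n_dysglycemic": "number",
    "n_coded": "number",
    "group_mean_glucose": "object",
    "group_mean_hba1c": "object",
    "thresholds": "object",
    "patients": "array"
  },
  "sepsis": {
    "n_cohort": "number",
    "pathogens": "object",
    "antibiotics": "object",
    "n_distinct_pathogens": "number",
    "timelines": "array"
  },
  "pc": {
    "n_cohort": "number",
    "n_prostatectomy": "number",
    "n_evaluable": "number",
    "n_flagged": "number",
    "flagged_patients": "array",
    "treatment_crosstab": "object",
    "therapy_counts": "object",
    "rules": "object",
    "patients": "array"
  }
}
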