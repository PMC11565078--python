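"""Dysglycemia screening and coding-gap detection.

The denominator is every patient with at least one serum-glucose or HbA1c
observation in the period (this is a laboratory screen, not an ICD-anchored
cohort).  Per patient, the worst (maximum) glucose and HbA1c drive three
non-exclusive biochemical flags:

* ``hyperglycemic`` — max glucose at/above the hyperglycemia cutoff
  (default 140 mg/dL);
* ``diabetes`` — max glucose at/above the diabetes cutoff (default
  200 mg/dL) or HbA1c at/above 6.5 %, with the detection source recorded
  (glucose / hba1c / both);
* ``prediabetes`` — HbA1c in the prediabetic band (default 5.7-6.4 %);
  optionally also a glucose maximum inside [hyper, diabetes).

The flags deliberately overlap (a patient can be both hyperglycemic and
diabetic); a separate exclusive ``severity`` category takes the worst flag.
Dysglycemia is the union of the three; the coding gap compares that union
against the presence of any dysglycemia ICD-10 condition (E10-E14, R73) in
the period.  Values reported in mmol/L are converted to mg/dL (x 18.016)
before comparison; non-numeric observations are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from ..fhir_core import Observation, Quantity
from ..store_query import DateFilter, ResourceStore, SearchQuery, TokenFilter
from ..timeutil import parse_instant
from .common import load_usecase_config, pct, require, round1

SEVERITIES = ("normal", "hyperglycemia", "prediabetes", "diabetes")


@dataclass(frozen=True)
class GlycemicThresholds:
    glucose_hyper_mgdl: float = 140.0
    glucose_diabetes_mgdl: float = 200.0
    hba1c_prediabetes_pct: float = 5.7
    hba1c_diabetes_pct: float = 6.5
    glucose_prediabetes_band: bool = False

    def __post_init__(self):
        if not self.glucose_hyper_mgdl < self.glucose_diabetes_mgdl:
            raise ValueError("hyperglycemia cutoff must lie below the diabetes cutoff")
        if not self.hba1c_prediabetes_pct < self.hba1c_diabetes_pct:
            raise ValueError("prediabetes band must lie below the HbA1c diabetes cutoff")

    @classmethod
    def from_config(cls, cfg: dict) -> "GlycemicThresholds":
        t = cfg.get("thresholds", {})
        return cls(
            glucose_hyper_mgdl=t.get("glucose_hyper_mgdl", 140.0),
            glucose_diabetes_mgdl=t.get("glucose_diabetes_mgdl", 200.0),
            hba1c_prediabetes_pct=t.get("hba1c_prediabetes_pct", 5.7),
            hba1c_diabetes_pct=t.get("hba1c_diabetes_pct", 6.5),
            glucose_prediabetes_band=t.get("glucose_prediabetes_band", False),
        )


@dataclass
class GlycemicPatient:
    patient_id: str
    max_glucose_mgdl: Optional[float]
    max_hba1c_pct: Optional[float]
    hyperglycemic: bool
    prediabetes: bool
    diabetes: bool
    diabetes_source: Optional[str]  # glucose | hba1c | both
    severity: str
    dysglycemic: bool
    icd_coded: bool


@dataclass
class GlycemicReport:
    n_patients: int
    n_glucose_readings: int
    n_hba1c_readings: int
    n_skipped_nonnumeric: int
    n_hyperglycemic: int
    pct_hyperglycemic: Optional[float]
    n_prediabetes: int
    pct_prediabetes: Optional[float]
    n_diabetes: int
    pct_diabetes: Optional[float]
    diabetes_by_source: dict
    n_dysglycemic: int
    pct_dysglycemic: Optional[float]
    n_coded: int
    pct_coded: Optional[float]
    n_uncoded: int
    pct_uncoded: Optional[float]
    group_mean_glucose: dict
    group_mean_hba1c: dict
    thresholds: dict
    patients: list = field(default_factory=list, repr=False)


def classify_patient(
    max_glucose: Optional[float],
    max_hba1c: Optional[float],
    t: GlycemicThresholds,
) -> tuple[bool, bool, bool, Optional[str], str]:
    """(hyperglycemic, prediabetes, diabetes, diabetes_source, severity)."""
    hyper = max_glucose is not None and max_glucose >= t.glucose_hyper_mgdl
    dm_glu = max_glucose is not None and max_glucose >= t.glucose_diabetes_mgdl
    dm_a1c = max_hba1c is not None and max_hba1c >= t.hba1c_diabetes_pct
    diabetes = dm_glu or dm_a1c
    source = None
    if diabetes:
        source = "both" if (dm_glu and dm_a1c) else ("glucose" if dm_glu else "hba1c")
    pre = max_hba1c is not None and t.hba1c_prediabetes_pct <= max_hba1c < t.hba1c_diabetes_pct
    if t.glucose_prediabetes_band and max_glucose is not None:
        pre = pre or (t.glucose_hyper_mgdl <= max_glucose < t.glucose_diabetes_mgdl)
    severity = (
        "diabetes" if diabetes else "prediabetes" if pre else "hyperglycemia" if hyper else "normal"
    )
    return hyper, pre, diabetes, source, severity


def diabetes_pipeline(
    store: ResourceStore,
    cohort_config: Union[str, dict] = "diabetes",
    thresholds: Optional[GlycemicThresholds] = None,
) -> GlycemicReport:
    cfg = load_usecase_config(cohort_config)
    t = thresholds or GlycemicThresholds.from_config(cfg)
    p = require(cfg, "period", "diabetes")
    start, end = parse_instant(p["start"]), parse_instant(p["end"])
    loinc = cfg.get("loinc_system", "http://loinc.org")
    glucose_codes = list(cfg["glucose_codes"])
    hba1c_codes = list(cfg["hba1c_codes"])
    icd_prefixes = list(require(cfg, "icd_prefixes", "diabetes"))

    date_filters = (DateFilter("date", "ge", start), DateFilter("date", "lt", end))
    per_patient: dict[str, dict] = {}
    counters = {"glucose": 0, "hba1c": 0, "skipped": 0}

    def collect(codes: list[str], kind: str) -> None:
        for code in codes:
            q = SearchQuery(
                "Observation",
                token_filters=(TokenFilter("code", code, system=loinc),),
                date_filters=date_filters,
            )
            for env in store.search(q):
                pid = env.subject_id()
                if pid is None:
                    continue
                value = env.typed.value if isinstance(env.typed, Observation) else None
                slot = per_patient.setdefault(pid, {"glucose": [], "hba1c": []})
                if not isinstance(value, Quantity):
                    counters["skipped"] += 1
                    continue
                counters[kind] += 1
                v = value.as_mgdl_glucose() if kind == "glucose" else value.value
                slot[kind].append(v)

    collect(glucose_codes, "glucose")
    collect(hba1c_codes, "hba1c")

    patients: list[GlycemicPatient] = []
    readings_by_severity: dict[str, dict[str, list[float]]] = {
        s: {"glucose": [], "hba1c": []} for s in SEVERITIES
    }
    for pid in sorted(per_patient):
        vals = per_patient[pid]
        max_glu = max(vals["glucose"]) if vals["glucose"] else None
        max_a1c = max(vals["hba1c"]) if vals["hba1c"] else None
        hyper, pre, dm, source, severity = classify_patient(max_glu, max_a1c, t)
        dys = hyper or pre or dm
        coded = False
        if dys:
            conds = store.search(
                SearchQuery(
                    "Condition",
                    date_filters=(
                        DateFilter("recorded-date", "ge", start),
                        DateFilter("recorded-date", "lt", end),
                    ),
                    subject=pid,
                )
            )
            coded = any(
                env.code_concept().matches(None, pref, prefix=True)
                for env in conds
                for pref in icd_prefixes
            )
        patients.append(
            GlycemicPatient(
                patient_id=pid,
                max_glucose_mgdl=max_glu,
                max_hba1c_pct=max_a1c,
                hyperglycemic=hyper,
                prediabetes=pre,
                diabetes=dm,
                diabetes_source=source,
                severity=severity,
                dysglycemic=dys,
                icd_coded=coded,
            )
        )
        readings_by_severity[severity]["glucose"].extend(vals["glucose"])
        readings_by_severity[severity]["hba1c"].extend(vals["hba1c"])

    n = len(patients)
    n_hyper = sum(1 for x in patients if x.hyperglycemic)
    n_pre = sum(1 for x in patients if x.prediabetes)
    n_dm = sum(1 for x in patients if x.diabetes)
    n_dys = sum(1 for x in patients if x.dysglycemic)
    n_coded = sum(1 for x in patients if x.dysglycemic and x.icd_coded)
    by_source = {
        s: sum(1 for x in patients if x.diabetes_source == s) for s in ("glucose", "hba1c", "both")
    }
    mean = lambda xs: round1(sum(xs) / len(xs)) if xs else None
    return GlycemicReport(
        n_patients=n,
        n_glucose_readings=counters["glucose"],
        n_hba1c_readings=counters["hba1c"],
        n_skipped_nonnumeric=counters["skipped"],
        n_hyperglycemic=n_hyper,
        pct_hyperglycemic=pct(n_hyper, n),
        n_prediabetes=n_pre,
        pct_prediabetes=pct(n_pre, n),
        n_diabetes=n_dm,
        pct_diabetes=pct(n_dm, n),
        diabetes_by_source=by_source,
        n_dysglycemic=n_dys,
        pct_dysglycemic=pct(n_dys, n),
        n_coded=n_coded,
        pct_coded=pct(n_coded, n_dys),
        n_uncoded=n_dys - n_coded,
        pct_uncoded=pct(n_dys - n_coded, n_dys),
        group_mean_glucose={s: mean(readings_by_severity[s]["glucose"]) for s in SEVERITIES},
        group_mean_hba1c={s: mean(readings_by_severity[s]["hba1c"]) for s in SEVERITIES},
        thresholds={
            "glucose_hyper_mgdl": t.glucose_hyper_mgdl,
            "glucose_diabetes_mgdl": t.glucose_diabetes_mgdl,
            "hba1c_prediabetes_pct": t.hba1c_prediabetes_pct,
            "hba1c_diabetes_pct": t.hba1c_diabetes_pct,
            "glucose_prediabetes_band": t.glucose_prediabetes_band,
        },
        patients=patients,
    )
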