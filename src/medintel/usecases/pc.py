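"""Prostate cancer: treatment landscape and post-prostatectomy PSA
surveillance.

The cohort anchors on ICD-10 C61 diagnoses in the diagnosis period; staging
(TNM, ISUP grade), therapy and PSA follow-up are read from a longer
treatment period.  PSA series are timestamp-ordered and rank-indexed (the
ordinal of each measurement in time order), which normalizes heterogeneous
sampling schedules across patients.

Flag definitions (configurable, stated in ng/mL):

* *PSA persistence* — the first PSA measured after prostatectomy, within
  ``persistence_window_days``, is at or above ``persistence_threshold``
  (default 0.1): the marker never became undetectable.
* *Biochemical recurrence* — after a post-operative value below
  ``undetectable_threshold`` (the nadir), a consecutive rising pair occurs
  whose second value reaches ``recurrence_threshold`` (default 0.2): a
  confirmed rise, not a solitary blip.

Both flags are only defined for patients with a prostatectomy and at least
one post-operative PSA; anyone else is counted as non-evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Optional, Sequence, Union

from ..cohort import CohortSpec, build_cohort
from ..fhir_core import Observation, Quantity
from ..store_query import DateFilter, ResourceStore, SearchQuery
from ..timeutil import Instant, parse_instant
from .common import load_usecase_config, pct, require


@dataclass(frozen=True)
class PCRules:
    persistence_threshold: float = 0.1
    persistence_window_days: int = 180
    recurrence_threshold: float = 0.2
    undetectable_threshold: float = 0.1

    def __post_init__(self):
        if min(
            self.persistence_threshold, self.recurrence_threshold, self.undetectable_threshold
        ) <= 0:
            raise ValueError("PSA thresholds must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "PCRules":
        r = cfg.get("rules", {})
        return cls(
            persistence_threshold=r.get("persistence_threshold", 0.1),
            persistence_window_days=r.get("persistence_window_days", 180),
            recurrence_threshold=r.get("recurrence_threshold", 0.2),
            undetectable_threshold=r.get("undetectable_threshold", 0.1),
        )


def psa_flags(
    post_op_values: Sequence[float],
    first_within_window: Optional[float],
    rules: PCRules,
) -> tuple[bool, bool]:
    """(persistence, recurrence) from a time-ordered post-operative series.

    ``first_within_window`` is the first post-op value inside the
    persistence window, or None if no measurement fell in it.
    """
    persistence = (
        first_within_window is not None and first_within_window >= rules.persistence_threshold
    )
    recurrence = False
    nadir_seen = False
    for i, v in enumerate(post_op_values):
        if v < rules.undetectable_threshold:
            nadir_seen = True
            continue
        if (
            nadir_seen
            and i > 0
            and v > post_op_values[i - 1]
            and v >= rules.recurrence_threshold
        ):
            recurrence = True
            break
    return persistence, recurrence


@dataclass
class PCPatient:
    patient_id: str
    tnm_stage: Optional[str]
    isup_grade: Optional[int]
    therapy: str  # surgery | radiation | systemic | active_surveillance
    prostatectomy_date: Optional[str]
    margin_status: Optional[str]
    psa_series: list  # [(rank, iso time, value)]
    evaluable: Optional[bool]
    psa_persistence: Optional[bool]
    biochemical_recurrence: Optional[bool]


@dataclass
class PCReport:
    n_cohort: int
    n_prostatectomy: int
    n_evaluable: int
    n_flagged: int
    flagged_patients: list
    treatment_crosstab: dict  # "stage|isup|therapy" -> count
    therapy_counts: dict
    therapy_pcts: dict
    rules: dict
    patients: list = field(default_factory=list, repr=False)


def pc_pipeline(
    store: ResourceStore,
    cohort_config: Union[str, dict] = "pc",
    rules: Optional[PCRules] = None,
) -> PCReport:
    cfg = load_usecase_config(cohort_config)
    rules = rules or PCRules.from_config(cfg)
    c = require(cfg, "cohort", "pc")
    spec = CohortSpec(
        name="pc",
        icd_prefixes=tuple(c["icd_prefixes"]),
        start=parse_instant(c["period"]["start"]),
        end=parse_instant(c["period"]["end"]),
    )
    cohort = build_cohort(store, spec)
    tp = cfg.get("treatment_period", c["period"])
    t_start, t_end = parse_instant(tp["start"]), parse_instant(tp["end"])
    proc_system = cfg.get("procedure_system")
    loinc = cfg.get("loinc_system", "http://loinc.org")
    local = cfg.get("local_system")
    atc_system = cfg.get("atc_system")

    proc_filters = (DateFilter("date", "ge", t_start), DateFilter("date", "lt", t_end))
    patients: list[PCPatient] = []
    for pid in cohort.patient_ids:
        procs = store.search(SearchQuery("Procedure", date_filters=proc_filters, subject=pid))

        def proc_date(codes: list) -> Optional[Instant]:
            dates = [
                env.period()[0]
                for env in procs
                if env.period() is not None
                and any(env.code_concept().matches(proc_system, cd, prefix=True) for cd in codes)
            ]
            return min(dates) if dates else None

        surgery_at = proc_date(cfg["prostatectomy_codes"])
        radiation_at = proc_date(cfg.get("radiation_codes", []))
        meds = store.search(
            SearchQuery(
                "MedicationAdministration",
                date_filters=(
                    DateFilter("effective-time", "ge", t_start),
                    DateFilter("effective-time", "lt", t_end),
                ),
                subject=pid,
            )
        )
        adt = any(
            cd.code.startswith(p)
            for env in meds
            for cd in env.code_concept().codings
            if atc_system is None or cd.system == atc_system
            for p in cfg.get("adt_atc_prefixes", [])
        )
        therapy = (
            "surgery"
            if surgery_at is not None
            else "radiation"
            if radiation_at is not None
            else "systemic"
            if adt
            else "active_surveillance"
        )

        obs = store.search(SearchQuery("Observation", subject=pid))

        def string_obs(code: Optional[str]) -> Optional[str]:
            if code is None:
                return None
            for env in obs:
                if env.code_concept().matches(local, code) and isinstance(env.typed.value, str):
                    return env.typed.value
            return None

        def numeric_obs(code: Optional[str]) -> Optional[float]:
            if code is None:
                return None
            for env in obs:
                if env.code_concept().matches(local, code) and isinstance(env.typed.value, Quantity):
                    return env.typed.value.value
            return None

        tnm = string_obs(cfg.get("tnm_code"))
        isup_val = numeric_obs(cfg.get("isup_code"))
        isup = int(isup_val) if isup_val is not None else None
        margin = string_obs(cfg.get("margin_code"))

        psa_points: list[tuple[Instant, float]] = []
        for env in obs:
            if not any(env.code_concept().matches(loinc, cd) for cd in cfg["psa_codes"]):
                continue
            period = env.period()
            value = env.typed.value if isinstance(env.typed, Observation) else None
            if period is None or not isinstance(value, Quantity):
                continue
            when = period[0]
            if t_start <= when < t_end:
                psa_points.append((when, value.value))
        psa_points.sort(key=lambda p: (p[0].at, p[1]))
        series = [(rank, when.isoformat(), v) for rank, (when, v) in enumerate(psa_points, start=1)]

        evaluable = persistence = recurrence = None
        if surgery_at is not None:
            post = [(when, v) for when, v in psa_points if when > surgery_at]
            if post:
                evaluable = True
                window_end = surgery_at + timedelta(days=rules.persistence_window_days)
                first_in_window = next((v for when, v in post if when <= window_end), None)
                persistence, recurrence = psa_flags(
                    [v for _, v in post], first_in_window, rules
                )
            else:
                evaluable = False

        patients.append(
            PCPatient(
                patient_id=pid,
                tnm_stage=tnm,
                isup_grade=isup,
                therapy=therapy,
                prostatectomy_date=surgery_at.isoformat() if surgery_at else None,
                margin_status=margin,
                psa_series=series,
                evaluable=evaluable,
                psa_persistence=persistence,
                biochemical_recurrence=recurrence,
            )
        )

    crosstab: dict[str, int] = {}
    for p in patients:
        key = f"{p.tnm_stage or '?'}|{p.isup_grade if p.isup_grade is not None else '?'}|{p.therapy}"
        crosstab[key] = crosstab.get(key, 0) + 1
    therapy_counts: dict[str, int] = {}
    for p in patients:
        therapy_counts[p.therapy] = therapy_counts.get(p.therapy, 0) + 1
    flagged = [
        p.patient_id for p in patients if p.psa_persistence or p.biochemical_recurrence
    ]
    return PCReport(
        n_cohort=len(cohort),
        n_prostatectomy=sum(1 for p in patients if p.prostatectomy_date is not None),
        n_evaluable=sum(1 for p in patients if p.evaluable),
        n_flagged=len(flagged),
        flagged_patients=sorted(flagged),
        treatment_crosstab=dict(sorted(crosstab.items())),
        therapy_counts=dict(sorted(therapy_counts.items())),
        therapy_pcts={k: pct(v, len(patients)) for k, v in sorted(therapy_counts.items())},
        rules={
            "persistence_threshold": rules.persistence_threshold,
            "persistence_window_days": rules.persistence_window_days,
            "recurrence_threshold": rules.recurrence_threshold,
            "undetectable_threshold": rules.undetectable_threshold,
        },
        patients=patients,
    )
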