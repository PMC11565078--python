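"""Sepsis: antibiogram-style summaries and per-patient inflammation timelines.

Isolates are microbiology culture reports (DiagnosticReport) of the cohort
patients whose conclusion names an organism from a configurable exact-match
lexicon; conclusions outside the lexicon are bucketed as ``other`` and
counted, never dropped.  Antibiotic use is every systemic antibacterial
administration (ATC prefix J01) in the period, named through a configurable
ATC-to-substance catalog.  Frequencies are percentages of the respective
totals (all isolates; all prescriptions) and the top-k view is stable:
count descending, organism/substance name ascending on ties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

from ..cohort import CohortSpec, build_cohort
from ..fhir_core import DiagnosticReport, Observation, Quantity
from ..store_query import DateFilter, ResourceStore, SearchQuery, TokenFilter
from ..timeutil import parse_instant
from .common import load_usecase_config, pct, require


@dataclass
class FrequencyTable:
    total: int
    counts: dict  # name -> count, insertion order = count desc, name asc
    pcts: dict
    top: list  # [(name, count, pct)] first k


@dataclass
class PatientTimeline:
    patient_id: str
    crp: list            # [(iso time, value)]
    procalcitonin: list
    isolates: list       # [(iso time, organism)]
    antibiotics: list    # [(start iso, end iso, substance)]


@dataclass
class SepsisReport:
    n_cohort: int
    pathogens: FrequencyTable
    antibiotics: FrequencyTable
    n_distinct_pathogens: int
    timelines: list = field(default_factory=list, repr=False)


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().casefold())


def build_frequency_table(counts: dict[str, int], top_k: int) -> FrequencyTable:
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return FrequencyTable(
        total=total,
        counts=dict(ordered),
        pcts={name: pct(n, total) for name, n in ordered},
        top=[(name, n, pct(n, total)) for name, n in ordered[:top_k]],
    )


def sepsis_pipeline(
    store: ResourceStore,
    cohort_config: Union[str, dict] = "sepsis",
) -> SepsisReport:
    cfg = load_usecase_config(cohort_config)
    c = require(cfg, "cohort", "sepsis")
    spec = CohortSpec(
        name="sepsis",
        icd_prefixes=tuple(c["icd_prefixes"]),
        start=parse_instant(c["period"]["start"]),
        end=parse_instant(c["period"]["end"]),
    )
    cohort = build_cohort(store, spec)
    loinc = cfg.get("loinc_system", "http://loinc.org")
    culture_codes = list(cfg.get("culture_report_codes", []))
    atc_system = cfg.get("atc_system")
    ab_prefix = cfg.get("antibiotic_atc_prefix", "J01")
    top_k = int(cfg.get("top_k", 10))
    lexicon = {_normalize(name): name for name in cfg.get("organism_lexicon", [])}
    ab_names = dict(cfg.get("antibiotic_names", {}))

    organism_counts: dict[str, int] = {}
    antibiotic_counts: dict[str, int] = {}
    timelines: list[PatientTimeline] = []
    date_filters = (DateFilter("issued", "ge", spec.start), DateFilter("issued", "lt", spec.end))
    med_filters = (
        DateFilter("effective-time", "ge", spec.start),
        DateFilter("effective-time", "lt", spec.end),
    )
    obs_filters = (DateFilter("date", "ge", spec.start), DateFilter("date", "lt", spec.end))

    for pid in cohort.patient_ids:
        reports = store.search(SearchQuery("DiagnosticReport", date_filters=date_filters, subject=pid))
        if culture_codes:
            reports = [
                r
                for r in reports
                if any(r.code_concept().matches(loinc, cd) for cd in culture_codes)
            ]
        isolates = []
        for env in reports:
            dr = env.typed
            assert isinstance(dr, DiagnosticReport)
            if not dr.conclusion:
                continue
            organism = lexicon.get(_normalize(dr.conclusion), "other")
            organism_counts[organism] = organism_counts.get(organism, 0) + 1
            when = dr.issued.isoformat() if dr.issued else None
            isolates.append((when, organism))

        meds = store.search(
            SearchQuery("MedicationAdministration", date_filters=med_filters, subject=pid)
        )
        administrations = []
        for env in meds:
            concept = env.code_concept()
            code = next(
                (
                    cd.code
                    for cd in concept.codings
                    if (atc_system is None or cd.system == atc_system)
                    and cd.code.startswith(ab_prefix)
                ),
                None,
            )
            if code is None:
                continue
            name = ab_names.get(code, code)
            antibiotic_counts[name] = antibiotic_counts.get(name, 0) + 1
            period = env.period()
            if period is not None:
                start, end = period
                administrations.append(
                    (start.isoformat(), (end or start).isoformat(), name)
                )

        def series(code: str) -> list:
            q = SearchQuery(
                "Observation",
                token_filters=(TokenFilter("code", code, system=loinc),),
                date_filters=obs_filters,
                subject=pid,
            )
            out = []
            for env in store.search(q):
                period = env.period()
                value = env.typed.value if isinstance(env.typed, Observation) else None
                if period is not None and isinstance(value, Quantity):
                    out.append((period[0].isoformat(), value.value))
            out.sort()
            return out

        timelines.append(
            PatientTimeline(
                patient_id=pid,
                crp=series(cfg["crp_code"]),
                procalcitonin=series(cfg["procalcitonin_code"]),
                isolates=sorted(isolates),
                antibiotics=sorted(administrations),
            )
        )

    return SepsisReport(
        n_cohort=len(cohort),
        pathogens=build_frequency_table(organism_counts, top_k),
        antibiotics=build_frequency_table(antibiotic_counts, top_k),
        n_distinct_pathogens=len(organism_counts),
        timelines=timelines,
    )
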