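"""ICD-anchored cohort building and resource linkage.

A cohort is the set of patients whose first matching Condition (by ICD-10
code prefix) was recorded inside a half-open calendar period ``[start, end)``
— the operational reading of "newly diagnosed in <year>".  The earliest
matching condition per patient is the *index condition*; ties on the
timestamp break by condition id, ascending, so cohorts are deterministic.

ICD system URIs vary across installations (ICD-10 vs ICD-10-GM), so code
matching is permissive: any coding whose code matches a configured prefix
counts, whatever its system URI.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Optional

import pandas as pd

from .errors import ConfigError, QueryError
from .fhir_core import Condition, Quantity
from .flatten import Frame
from .store_query import ResourceStore, SearchQuery, TokenFilter
from .timeutil import Instant, parse_instant


@dataclass(frozen=True)
class CohortSpec:
    """Anchor definition: ICD-10 prefixes + half-open period."""

    name: str
    icd_prefixes: tuple[str, ...]
    start: Instant
    end: Instant

    def __post_init__(self):
        if not self.icd_prefixes:
            raise ConfigError(f"cohort {self.name!r}: icd_prefixes must be non-empty")
        if not self.start < self.end:
            raise ConfigError(f"cohort {self.name!r}: start must precede end")

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortSpec":
        try:
            return cls(
                name=doc["name"],
                icd_prefixes=tuple(doc["icd_prefixes"]),
                start=parse_instant(doc["period"]["start"], "period.start"),
                end=parse_instant(doc["period"]["end"], "period.end"),
            )
        except KeyError as exc:
            raise ConfigError(f"cohort spec missing {exc}") from None


@dataclass(frozen=True)
class IndexCondition:
    code: str
    recorded: Instant
    condition_id: str


@dataclass
class Cohort:
    """Ordered patient set plus each patient's earliest matching condition."""

    name: str
    patient_ids: list[str]
    index_conditions: dict[str, IndexCondition]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.patient_ids)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.index_conditions


@dataclass(frozen=True)
class LinkSpec:
    """What to link to a cohort: a resource type, optional code filters and a
    time window (absolute, or relative to each patient's index date)."""

    resource_type: str
    code_filters: tuple[TokenFilter, ...] = ()
    window_start: Optional[Instant] = None       # absolute window
    window_end: Optional[Instant] = None
    rel_start: Optional[timedelta] = None        # relative-to-index window
    rel_end: Optional[timedelta] = None

    def __post_init__(self):
        absolute = self.window_start is not None or self.window_end is not None
        relative = self.rel_start is not None or self.rel_end is not None
        if absolute and relative:
            raise ConfigError("LinkSpec window is either absolute or relative, not both")


def build_cohort(store: ResourceStore, spec: CohortSpec, lookback: Optional[timedelta] = None) -> Cohort:
    """Patients with >=1 matching Condition recorded in ``[start, end)``.

    ``lookback``: optional incident-case exclusion — a patient is dropped if
    any matching condition was recorded within ``lookback`` *before* the
    period (default: no exclusion).
    """
    best: dict[str, IndexCondition] = {}
    excluded: set[str] = set()
    for prefix in spec.icd_prefixes:
        q = SearchQuery(
            resource_type="Condition",
            token_filters=(TokenFilter(param="code", code=prefix, prefix=True),),
        )
        for env in store.search(q):
            cond = env.typed
            assert isinstance(cond, Condition)
            if cond.recordedDate is None or cond.subject is None:
                continue
            pid = env.subject_id()
            if pid is None:
                continue
            when = cond.recordedDate
            if not (spec.start <= when < spec.end):
                if (
                    lookback is not None
                    and when < spec.start
                    and when >= Instant(spec.start.at - lookback)
                ):
                    excluded.add(pid)
                continue
            code = cond.code.first_code() or ""
            cand = IndexCondition(code=code, recorded=when, condition_id=env.id)
            cur = best.get(pid)
            if cur is None or (cand.recorded, cand.condition_id) < (cur.recorded, cur.condition_id):
                best[pid] = cand
    for pid in excluded:
        best.pop(pid, None)
    patient_ids = sorted(best)
    return Cohort(name=spec.name, patient_ids=patient_ids, index_conditions=best, spec=spec)


_LINK_DATE_PARAM = {
    "Observation": "date",
    "Procedure": "date",
    "MedicationAdministration": "effective-time",
    "DiagnosticReport": "issued",
    "Condition": "recorded-date",
    "Encounter": "date",
}


def link_resources(store: ResourceStore, cohort: Cohort, link: LinkSpec) -> Frame:
    """Resources of one type, restricted to cohort patients, code filters and
    the window; one row per resource.

    Columns: patient_id, code, value, unit, start, end (ISO strings) plus
    provenance.
    """
    if link.resource_type not in _LINK_DATE_PARAM:
        raise QueryError(f"cannot link resource type {link.resource_type!r}")
    rows: list[dict] = []
    for pid in cohort.patient_ids:
        idx = cohort.index_conditions[pid]
        if link.rel_start is not None or link.rel_end is not None:
            lo = idx.recorded + (link.rel_start or timedelta(0))
            hi = idx.recorded + (link.rel_end or timedelta(0))
        else:
            lo, hi = link.window_start, link.window_end
        q = SearchQuery(
            resource_type=link.resource_type,
            token_filters=link.code_filters,
            subject=pid,
        )
        for env in store.search(q):
            period = env.period()
            if period is None:
                continue
            start, end = period
            if end is None:
                end = start
            if lo is not None and end < lo:
                continue
            if hi is not None and start > hi:
                continue
            concept = env.code_concept()
            value = unit = None
            typed_value = getattr(env.typed, "value", None)
            if isinstance(typed_value, Quantity):
                value, unit = typed_value.value, typed_value.unit_key()
            elif isinstance(typed_value, str):
                value = typed_value
            rows.append(
                {
                    "resource_type": env.resource_type,
                    "resource_id": env.id,
                    "patient_id": pid,
                    "code": concept.first_code() if concept else None,
                    "value": value,
                    "unit": unit,
                    "start": start.isoformat(),
                    "end": end.isoformat(),
                }
            )
    columns = ["resource_type", "resource_id", "patient_id", "code", "value", "unit", "start", "end"]
    df = pd.DataFrame(rows, columns=columns)
    return Frame(df)


def count_encounters(store: ResourceStore, start: Instant, end: Instant) -> int:
    """Number of Encounter resources whose period overlaps ``[start, end)``."""
    n = 0
    for env in store.all_of_type("Encounter"):
        period = env.period()
        if period is None:
            continue
        p_start, p_end = period
        if p_end is None:
            p_end = p_start
        if p_end >= start and p_start < end:
            n += 1
    return n
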