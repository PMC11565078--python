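"""In-memory resource store with a subset of FHIR search semantics.

The store stands in, at desk scale, for a hospital FHIR server: pipelines
issue the same conjunctive token/date/subject queries whether they run
against an offline NDJSON corpus or (optionally) a live REST endpoint.

Search semantics
----------------
* Token filters match ``(system, code)``; ``system=None`` matches any
  system.  Prefix mode matches code prefixes, which is how ICD-10
  chapter/category filters work (filter ``"E11"`` matches ``"E11.9"``).
* Date filters compare against the resource's normalized ``(start, end)``
  with interval-overlap semantics: ``ge T`` keeps resources whose end is on
  or after T, ``le T`` those whose start is on or before T — so a
  period-valued administration never vanishes from a range query that
  overlaps it.
* Results are deterministic (ordered by resource id); pagination partitions
  that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

from .errors import QueryError
from .fhir_core import (
    Reference,
    ResourceEnvelope,
    read_source,
)
from .timeutil import Instant

log = logging.getLogger(__name__)

# search-param name -> how to read it off an envelope, per resource type
_SUPPORTED_PARAMS: dict[str, dict[str, str]] = {
    "Condition": {"code": "code", "recorded-date": "period", "subject": "subject"},
    "Observation": {"code": "code", "date": "period", "subject": "subject"},
    "Procedure": {"code": "code", "date": "period", "subject": "subject"},
    "MedicationAdministration": {
        "medication-code": "code",
        "effective-time": "period",
        "subject": "subject",
    },
    "DiagnosticReport": {"code": "code", "issued": "period", "subject": "subject"},
    "Encounter": {"date": "period", "subject": "subject"},
    "Patient": {},
}


@dataclass(frozen=True)
class TokenFilter:
    param: str
    code: str
    system: Optional[str] = None
    prefix: bool = False


@dataclass(frozen=True)
class DateFilter:
    param: str
    op: str  # ge | le | gt | lt
    when: Instant

    def __post_init__(self):
        if self.op not in ("ge", "le", "gt", "lt"):
            raise QueryError(f"unsupported date op {self.op!r}")


@dataclass(frozen=True)
class SearchQuery:
    """Conjunctive query over one resource type."""

    resource_type: str
    token_filters: tuple[TokenFilter, ...] = ()
    date_filters: tuple[DateFilter, ...] = ()
    subject: Optional[str] = None  # patient id
    page_size: int = 1000

    def __post_init__(self):
        if self.page_size <= 0:
            raise QueryError("page_size must be positive")


@dataclass
class NotFound:
    """Typed miss for reference resolution."""

    reference: str


class ResourceStore:
    """Indexed collection of envelopes supporting search and resolution.

    Indices are rebuilt deterministically from the corpus:

    * ``(resourceType, id)`` -> envelope
    * patient id -> resource ids per resourceType (subject index)
    * ``(resourceType, system, code)`` -> resource ids (token index)
    """

    def __init__(self) -> None:
        self._by_key: dict[tuple[str, str], ResourceEnvelope] = {}
        self._subject_index: dict[str, dict[str, list[str]]] = {}
        self._code_index: dict[tuple[str, str, str], list[str]] = {}

    # -- construction -------------------------------------------------------

    def add(self, env: ResourceEnvelope) -> None:
        key = env.key
        if key in self._by_key:
            log.warning("duplicate resource %s/%s replaces earlier copy", *key)
            self._remove_from_indices(self._by_key[key])
        self._by_key[key] = env
        subj = env.subject_id()
        if subj is not None:
            self._subject_index.setdefault(subj, {}).setdefault(env.resource_type, []).append(env.id)
        concept = env.code_concept()
        if concept is not None:
            for coding in concept.codings:
                self._code_index.setdefault(
                    (env.resource_type, coding.system, coding.code), []
                ).append(env.id)

    def _remove_from_indices(self, env: ResourceEnvelope) -> None:
        subj = env.subject_id()
        if subj is not None:
            ids = self._subject_index.get(subj, {}).get(env.resource_type, [])
            if env.id in ids:
                ids.remove(env.id)
        concept = env.code_concept()
        if concept is not None:
            for coding in concept.codings:
                ids = self._code_index.get((env.resource_type, coding.system, coding.code), [])
                if env.id in ids:
                    ids.remove(env.id)

    @classmethod
    def from_envelopes(cls, envelopes: Iterable[ResourceEnvelope]) -> "ResourceStore":
        store = cls()
        for env in envelopes:
            store.add(env)
        return store

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[ResourceEnvelope]:
        return iter(self._by_key.values())

    def get(self, resource_type: str, rid: str) -> Optional[ResourceEnvelope]:
        return self._by_key.get((resource_type, rid))

    def all_of_type(self, resource_type: str) -> list[ResourceEnvelope]:
        return sorted(
            (e for e in self._by_key.values() if e.resource_type == resource_type),
            key=lambda e: e.id,
        )

    def resources_for_patient(self, patient_id: str, resource_type: str) -> list[ResourceEnvelope]:
        ids = self._subject_index.get(patient_id, {}).get(resource_type, [])
        out = [self._by_key[(resource_type, rid)] for rid in set(ids)]
        out.sort(key=lambda e: e.id)
        return out

    # -- search -------------------------------------------------------------

    def search(self, q: SearchQuery) -> list[ResourceEnvelope]:
        """All resources satisfying every filter, ordered by id."""
        self._check_params(q)
        candidates = self._candidates(q)
        out = [env for env in candidates if _matches(env, q)]
        out.sort(key=lambda e: e.id)
        return out

    def search_pages(self, q: SearchQuery) -> Iterator[list[ResourceEnvelope]]:
        """The same result set, cut into pages of ``q.page_size``."""
        results = self.search(q)
        for i in range(0, len(results), q.page_size):
            yield results[i : i + q.page_size]

    def _check_params(self, q: SearchQuery) -> None:
        supported = _SUPPORTED_PARAMS.get(q.resource_type)
        if supported is None:
            raise QueryError(
                f"unsupported resource type {q.resource_type!r}; "
                f"supported: {sorted(_SUPPORTED_PARAMS)}"
            )
        token_params = {p for p, kind in supported.items() if kind == "code"}
        date_params = {p for p, kind in supported.items() if kind == "period"}
        for tf in q.token_filters:
            if tf.param not in token_params:
                raise QueryError(
                    f"{q.resource_type} does not support token param {tf.param!r}; "
                    f"supported: {sorted(token_params)}"
                )
        for df in q.date_filters:
            if df.param not in date_params:
                raise QueryError(
                    f"{q.resource_type} does not support date param {df.param!r}; "
                    f"supported: {sorted(date_params)}"
                )

    def _candidates(self, q: SearchQuery) -> Iterable[ResourceEnvelope]:
        """Narrow the scan with the cheapest applicable index."""
        if q.subject is not None:
            return self.resources_for_patient(q.subject, q.resource_type)
        exact = [tf for tf in q.token_filters if not tf.prefix and tf.system is not None]
        if exact:
            tf = exact[0]
            ids = self._code_index.get((q.resource_type, tf.system, tf.code), [])
            return [self._by_key[(q.resource_type, rid)] for rid in set(ids)]
        prefixed = [tf for tf in q.token_filters if tf.prefix]
        if prefixed:
            tf = prefixed[0]
            ids: set[str] = set()
            for (rtype, system, code), rids in self._code_index.items():
                if rtype != q.resource_type:
                    continue
                if tf.system is not None and system != tf.system:
                    continue
                if code.startswith(tf.code):
                    ids.update(rids)
            return [self._by_key[(q.resource_type, rid)] for rid in ids]
        return (e for e in self._by_key.values() if e.resource_type == q.resource_type)

    # -- resolution ---------------------------------------------------------

    def resolve(self, ref: Reference) -> Union[ResourceEnvelope, NotFound]:
        rtype, rid = ref.parts()  # raises FieldValidationError if malformed
        env = self._by_key.get((rtype, rid))
        return env if env is not None else NotFound(ref.reference)


def _matches(env: ResourceEnvelope, q: SearchQuery) -> bool:
    if env.resource_type != q.resource_type:
        return False
    if q.subject is not None and env.subject_id() != q.subject:
        return False
    for tf in q.token_filters:
        concept = env.code_concept()
        if concept is None or not concept.matches(tf.system, tf.code, prefix=tf.prefix):
            return False
    for df in q.date_filters:
        period = env.period()
        if period is None:
            return False
        start, end = period
        if end is None:
            end = start
        if df.op == "ge" and not (end >= df.when):
            return False
        if df.op == "gt" and not (end > df.when):
            return False
        if df.op == "le" and not (start <= df.when):
            return False
        if df.op == "lt" and not (start < df.when):
            return False
    return True


def naive_search(resources: Iterable[ResourceEnvelope], q: SearchQuery) -> list[ResourceEnvelope]:
    """Reference implementation: filter every resource, no indices.

    Kept deliberately simple — the indexed search is tested for set equality
    against this full scan.
    """
    out = [env for env in resources if _matches(env, q)]
    out.sort(key=lambda e: e.id)
    return out


def load_store(sources: Sequence[Union[str, "Path"]], on_error: str = "raise") -> ResourceStore:
    """Build a store from NDJSON/Bundle files; later duplicate (type, id)
    replaces earlier with a logged warning."""
    from pathlib import Path

    store = ResourceStore()
    for src in sources:
        p = Path(src)
        if not p.exists():
            raise FileNotFoundError(f"source not readable: {p}")
        for env in read_source(p):
            store.add(env)
    return store


def patients_referenced_by(
    resources: Iterable[ResourceEnvelope],
) -> tuple[set[str], int]:
    """Distinct patient ids referenced as subject; also counts skipped
    resources (those without a parseable Patient subject)."""
    ids: set[str] = set()
    skipped = 0
    for env in resources:
        pid = env.subject_id()
        if pid is None:
            skipped += 1
        else:
            ids.add(pid)
    return ids, skipped


# ---------------------------------------------------------------------------
# optional live REST adapter
# ---------------------------------------------------------------------------

class RestBackend:
    """Minimal adapter honoring the :class:`SearchQuery` contract against a
    FHIR REST endpoint (GET search with token/date params, ``_count`` paging,
    Bundle.link "next" continuation).

    ``fetch`` is injectable for testing; the default uses :mod:`urllib`.
    All bundled pipelines and tests run offline against :class:`ResourceStore`.
    """

    def __init__(self, base_url: str, fetch: Optional[Callable[[str], dict]] = None):
        self.base_url = base_url.rstrip("/")
        self._fetch = fetch or self._urllib_fetch

    @staticmethod
    def _urllib_fetch(url: str) -> dict:  # pragma: no cover - network
        import json as _json
        import urllib.request

        with urllib.request.urlopen(url) as resp:
            return _json.loads(resp.read().decode("utf-8"))

    def build_url(self, q: SearchQuery) -> str:
        from urllib.parse import quote

        parts = []
        for tf in q.token_filters:
            token = f"{tf.system}|{tf.code}" if tf.system else tf.code
            parts.append(f"{tf.param}={quote(token, safe='|')}")
        for df in q.date_filters:
            parts.append(f"{df.param}={df.op}{quote(df.when.isoformat())}")
        if q.subject is not None:
            parts.append(f"subject=Patient/{quote(q.subject)}")
        parts.append(f"_count={q.page_size}")
        return f"{self.base_url}/{q.resource_type}?" + "&".join(parts)

    def search(self, q: SearchQuery) -> list[ResourceEnvelope]:
        from .fhir_core import parse_resource

        url = self.build_url(q)
        out: list[ResourceEnvelope] = []
        while url:
            bundle = self._fetch(url)
            for entry in bundle.get("entry", []) or []:
                res = entry.get("resource")
                if res is not None:
                    out.append(parse_resource(res))
            url = next(
                (l.get("url") for l in bundle.get("link", []) if l.get("relation") == "next"),
                None,
            )
        out.sort(key=lambda e: e.id)
        return out
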