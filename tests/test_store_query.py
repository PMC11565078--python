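"""Indexed store: search semantics, resolution, pagination, oracle equality."""

import numpy as np
import pytest

from medintel.errors import QueryError
from medintel.fhir_core import Reference, parse_resource, serialize_resource
from medintel.store_query import (
    DateFilter,
    NotFound,
    ResourceStore,
    SearchQuery,
    TokenFilter,
    load_store,
    patients_referenced_by,
)
from medintel.synth import builders as b
from medintel.timeutil import parse_instant

from oracles import naive_query

ICD = b.ICD_SYSTEM


def _small_store():
    trees = [
        b.patient("p1"),
        b.patient("p2"),
        b.condition("c1", "p1", "I21.0", "2022-02-01T10:00:00+00:00"),
        b.condition("c2", "p1", "I21.4", "2022-03-01T10:00:00+00:00"),
        b.condition("c3", "p2", "I63.5", "2022-04-01T10:00:00+00:00"),
        b.observation_quantity("o1", "p1", "2345-7", 100.0, "mg/dL", "2021-12-31T23:00:00+00:00"),
        b.observation_quantity("o2", "p1", "2345-7", 120.0, "mg/dL", "2022-06-01T10:00:00+00:00"),
        b.medication_administration(
            "m1", "p2", "J01CR05", "2021-12-20T08:00:00+00:00", "2022-01-05T08:00:00+00:00"
        ),
    ]
    return ResourceStore.from_envelopes(parse_resource(t) for t in trees)


class TestSearch:
    def test_code_prefix_matches_icd_family(self):
        store = _small_store()
        hits = store.search(
            SearchQuery("Condition", token_filters=(TokenFilter("code", "I21", prefix=True),))
        )
        assert [e.id for e in hits] == ["c1", "c2"]

    def test_exact_token_with_system(self):
        store = _small_store()
        hits = store.search(
            SearchQuery("Condition", token_filters=(TokenFilter("code", "I63.5", system=ICD),))
        )
        assert [e.id for e in hits] == ["c3"]
        miss = store.search(
            SearchQuery(
                "Condition", token_filters=(TokenFilter("code", "I63.5", system="urn:other"),)
            )
        )
        assert miss == []

    def test_date_range_restricts_to_study_year(self):
        store = _small_store()
        hits = store.search(
            SearchQuery(
                "Observation",
                date_filters=(
                    DateFilter("date", "ge", parse_instant("2022-01-01T00:00:00+00:00")),
                    DateFilter("date", "lt", parse_instant("2023-01-01T00:00:00+00:00")),
                ),
            )
        )
        assert [e.id for e in hits] == ["o2"]

    def test_period_overlap_keeps_spanning_administration(self):
        """A medication running into the window must not vanish from it."""
        store = _small_store()
        hits = store.search(
            SearchQuery(
                "MedicationAdministration",
                date_filters=(
                    DateFilter("effective-time", "ge", parse_instant("2022-01-01T00:00:00+00:00")),
                ),
            )
        )
        assert [e.id for e in hits] == ["m1"]

    def test_unknown_param_lists_supported(self):
        store = _small_store()
        with pytest.raises(QueryError) as exc:
            store.search(
                SearchQuery("Encounter", token_filters=(TokenFilter("code", "x"),))
            )
        assert "subject" in str(exc.value) or "supported" in str(exc.value)

    def test_prefix_monotonicity(self):
        store = _small_store()

        def ids(prefixes):
            out = set()
            for p in prefixes:
                out |= {
                    e.id
                    for e in store.search(
                        SearchQuery(
                            "Condition", token_filters=(TokenFilter("code", p, prefix=True),)
                        )
                    )
                }
            return out

        assert ids(["I21"]) <= ids(["I21", "I63"])


class TestOracleEquivalence:
    def test_randomized_queries_match_full_scan(self, demo_store, demo_corpus):
        envelopes, _ = demo_corpus
        raw = [e.raw for e in envelopes]
        rng = np.random.default_rng(42)
        systems = [None, ICD, b.LOINC_SYSTEM, b.ATC_SYSTEM]
        codes = ["I", "I21", "I63.5", "E11.9", "2345-7", "A41", "J01", "C61", "8-83", "Z99"]
        types = [
            "Condition",
            "Observation",
            "Procedure",
            "MedicationAdministration",
            "DiagnosticReport",
            "Encounter",
        ]
        pids = [e.id for e in envelopes if e.resource_type == "Patient"]
        for _ in range(60):
            rtype = types[rng.integers(0, len(types))]
            tf = ()
            if rtype != "Encounter" and rng.random() < 0.7:
                tf = (
                    TokenFilter(
                        "code" if rtype != "MedicationAdministration" else "medication-code",
                        codes[rng.integers(0, len(codes))],
                        system=systems[rng.integers(0, len(systems))],
                        prefix=bool(rng.random() < 0.6),
                    ),
                )
            df = ()
            if rng.random() < 0.5:
                day = int(rng.integers(0, 364))
                param = {
                    "Condition": "recorded-date",
                    "MedicationAdministration": "effective-time",
                    "DiagnosticReport": "issued",
                }.get(rtype, "date")
                op = ["ge", "le", "gt", "lt"][rng.integers(0, 4)]
                df = (
                    DateFilter(
                        param, op, parse_instant(f"2022-01-01T00:00:00+00:00") + __import__("datetime").timedelta(days=day)
                    ),
                )
            subject = pids[rng.integers(0, len(pids))] if rng.random() < 0.3 else None
            q = SearchQuery(rtype, token_filters=tf, date_filters=df, subject=subject)
            got = [e.id for e in demo_store.search(q)]
            assert got == naive_query(raw, q)

    def test_pagination_partitions_result(self, demo_store):
        q = SearchQuery(
            "Observation",
            token_filters=(TokenFilter("code", "2345-7", system=b.LOINC_SYSTEM),),
            page_size=37,
        )
        unpaged = [e.id for e in demo_store.search(q)]
        paged = [e.id for page in demo_store.search_pages(q) for e in page]
        assert paged == unpaged
        assert len(set(paged)) == len(paged)


class TestStoreBasics:
    def test_duplicate_replaces_with_warning(self, caplog):
        store = ResourceStore()
        store.add(parse_resource(b.patient("p1", gender="male")))
        with caplog.at_level("WARNING"):
            store.add(parse_resource(b.patient("p1", gender="female")))
        assert len(store) == 1
        assert store.get("Patient", "p1").typed.gender == "female"
        assert any("duplicate" in r.message for r in caplog.records)

    def test_load_store_counts(self, tmp_path):
        import json

        lines = [b.patient(f"p{i}") for i in range(10)] + [
            b.observation_quantity(f"o{i}", f"p{i % 10}", "2345-7", 100.0, "mg/dL",
                                   "2022-01-01T00:00:00+00:00")
            for i in range(30)
        ]
        p = tmp_path / "c.ndjson"
        p.write_text("\n".join(json.dumps(t) for t in lines) + "\n")
        store = load_store([p])
        assert len(store) == 40

    def test_load_store_missing_source(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_store([tmp_path / "nope.ndjson"])

    def test_resolve_hit_dangling_and_malformed(self):
        store = _small_store()
        assert store.resolve(Reference("Patient/p1")).id == "p1"
        assert isinstance(store.resolve(Reference("Patient/ghost")), NotFound)
        from medintel.errors import FieldValidationError

        with pytest.raises(FieldValidationError):
            store.resolve(Reference("garbage"))

    def test_patients_referenced_by(self):
        store = _small_store()
        conds = store.all_of_type("Condition")
        ids, skipped = patients_referenced_by(conds)
        assert ids == {"p1", "p2"} and skipped == 0
        assert patients_referenced_by([]) == (set(), 0)

    def test_generated_corpus_has_no_dangling_subjects(self, demo_store):
        dangling = 0
        for env in demo_store:
            pid = env.subject_id()
            if pid is not None and demo_store.get("Patient", pid) is None:
                dangling += 1
        assert dangling == 0


class TestRestAdapter:
    def test_same_query_contract_with_paged_fake_server(self):
        from medintel.store_query import RestBackend

        page1 = {
            "resourceType": "Bundle",
            "entry": [{"resource": b.condition("c1", "p1", "I21.0", "2022-02-01T10:00:00+00:00")}],
            "link": [{"relation": "next", "url": "http://fake/page2"}],
        }
        page2 = {
            "resourceType": "Bundle",
            "entry": [{"resource": b.condition("c2", "p1", "I21.4", "2022-03-01T10:00:00+00:00")}],
        }
        fetched = []

        def fake_fetch(url):
            fetched.append(url)
            return page2 if url.endswith("page2") else page1

        backend = RestBackend("http://fake/fhir", fetch=fake_fetch)
        q = SearchQuery(
            "Condition",
            token_filters=(TokenFilter("code", "I21", system=ICD, prefix=True),),
            page_size=1,
        )
        results = backend.search(q)
        assert [e.id for e in results] == ["c1", "c2"]
        assert fetched[0].startswith("http://fake/fhir/Condition?")
        assert "_count=1" in fetched[0] and "code=" in fetched[0]
        # offline store answers the same query with the same resources
        offline = _small_store().search(q)
        assert [e.id for e in offline] == [e.id for e in results]
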