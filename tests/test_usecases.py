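"""Clinical pipelines: category logic, boundaries, exclusions, oracles."""

import numpy as np
import pytest

from medintel.fhir_core import parse_resource
from medintel.store_query import ResourceStore
from medintel.synth import builders as b, fixture_from_counts, fixture_store
from medintel.usecases import (
    GlycemicThresholds,
    MIRules,
    PCRules,
    StrokeThresholds,
    diabetes_pipeline,
    mi_pipeline,
    pc_pipeline,
    sepsis_pipeline,
    stroke_pipeline,
)
from medintel.usecases.common import report_to_dict
from medintel.usecases.diabetes import classify_patient
from medintel.usecases.pc import psa_flags

from oracles import brute_force_psa_flags


def _store(trees):
    return ResourceStore.from_envelopes(parse_resource(t) for t in trees)


# ---------------------------------------------------------------------------
# myocardial infarction
# ---------------------------------------------------------------------------

class TestMI:
    def test_untreated_cohort_lands_in_none_none(self):
        store = fixture_store("mi", {"n": 5, "antiplatelet_any": 0, "statin_any": 0, "adherent": 0})
        r = mi_pipeline(store)
        assert r.n_cohort == 5
        assert r.cells["none|none"] == 5 and r.n_adherent == 0

    def test_denominator_requires_stemi_or_intervention(self):
        t = "2022-03-01T10:00:00+00:00"
        store = _store(
            [
                b.patient("stemi"), b.patient("nstemi"), b.patient("pci"),
                b.condition("c1", "stemi", "I21.0", t),
                b.condition("c2", "nstemi", "I21.4", t),
                b.condition("c3", "pci", "I21.4", t),
                b.procedure("p1", "pci", "8-837", t),
            ]
        )
        r = mi_pipeline(store)
        assert r.n_mi_diagnosed == 3
        assert r.n_cohort == 2  # NSTEMI without intervention is out

    def test_crosstab_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        t = "2022-03-01T10:00:00+00:00"
        trees, expected = [], {}
        for i in range(120):
            pid = f"p{i:03d}"
            trees += [b.patient(pid), b.condition(f"c{i}", pid, "I21.0", t)]
            n_ap = int(rng.integers(0, 3))
            statin = bool(rng.integers(0, 2))
            ez = statin and bool(rng.integers(0, 2))
            for k in range(n_ap):
                trees.append(
                    b.medication_administration(f"m{i}-ap{k}", pid, ["B01AC06", "B01AC04"][k], t)
                )
            if statin:
                trees.append(b.medication_administration(f"m{i}-st", pid, "C10AA01", t))
            if ez:
                trees.append(b.medication_administration(f"m{i}-ez", pid, "C10AX09", t))
            ap_cat = ["none", "single", "dual"][n_ap]
            lip_cat = "statin_ezetimibe" if ez else ("statin" if statin else "none")
            key = f"{ap_cat}|{lip_cat}"
            expected[key] = expected.get(key, 0) + 1
        r = mi_pipeline(_store(trees))
        assert {k: v for k, v in r.cells.items() if v} == expected
        assert sum(r.cells.values()) == r.n_cohort == 120

    def test_percentages_are_half_up_one_decimal(self):
        store = fixture_store("mi", {"n": 3, "antiplatelet_any": 1, "statin_any": 0, "adherent": 1})
        r = mi_pipeline(store)
        assert r.pct_antiplatelet_any == 33.3 and r.pct_adherent == 33.3

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            MIRules(antiplatelet_atc_prefixes=("B01AC",), anticoagulant_atc_prefixes=("B01AC",))


# ---------------------------------------------------------------------------
# stroke
# ---------------------------------------------------------------------------

def _stroke_patient(pid, treat_minutes, proc_code="8-020.8", admit="2022-04-01T08:00:00+00:00"):
    from datetime import datetime, timedelta

    t0 = datetime.fromisoformat(admit)
    return [
        b.patient(pid),
        b.condition(f"{pid}-c", pid, "I63.5", admit),
        b.encounter(f"{pid}-e", pid, admit),
        b.procedure(f"{pid}-t", pid, proc_code, (t0 + timedelta(minutes=treat_minutes)).isoformat()),
    ]


class TestStroke:
    def test_boundary_minute_follows_configured_rule(self):
        store = _store(_stroke_patient("x", 60))
        leq = stroke_pipeline(store, thresholds=StrokeThresholds(boundary="leq"))
        strict = stroke_pipeline(store, thresholds=StrokeThresholds(boundary="strict_less"))
        assert leq.lysis.n_within == 1
        assert strict.lysis.n_within == 0

    def test_minutes_are_floored(self):
        store = _store(_stroke_patient("x", 59.99))
        r = stroke_pipeline(store)
        assert r.patients[0].lysis_minutes == 59

    def test_treatment_before_admission_is_data_error(self):
        store = _store(_stroke_patient("x", -10))
        r = stroke_pipeline(store)
        p = r.patients[0]
        assert p.data_error and p.lysis_minutes is None
        assert r.lysis.n_data_error == 1 and r.lysis.n_timed == 0

    def test_exclusion_accounting(self):
        counts = {
            "lysis": {"n": 12, "within": 10, "eni_decrease": 5, "eni_no_change": 2,
                      "eni_increase": 1},
        }
        r = stroke_pipeline(fixture_store("stroke", counts))
        s = r.lysis
        assert s.n_eni_evaluable + s.n_excluded == s.n_treated == 12
        assert s.eni_counts == {"decrease": 5, "no_change": 2, "increase": 1}

    def test_marker_excludes_from_classes_but_not_correlation(self):
        counts = {
            "lysis": {"n": 0, "within": 0},
            "thrombectomy": {"n": 10, "within": 8, "eni_decrease": 4, "eni_no_change": 1,
                             "eni_increase": 2, "excluded": 3},
        }
        r = stroke_pipeline(fixture_store("stroke", counts))
        s = r.thrombectomy
        assert s.n_eni_evaluable == 7
        assert s.correlation_n == 10  # marker patients still have NIHSS pairs
        assert s.n_excluded == 3

    def test_window_monotone_in_threshold(self, demo_store):
        tight = stroke_pipeline(demo_store, thresholds=StrokeThresholds(needle_minutes=30))
        default = stroke_pipeline(demo_store, thresholds=StrokeThresholds(needle_minutes=60))
        loose = stroke_pipeline(demo_store, thresholds=StrokeThresholds(needle_minutes=240))
        assert tight.lysis.n_within <= default.lysis.n_within <= loose.lysis.n_within


# ---------------------------------------------------------------------------
# diabetes
# ---------------------------------------------------------------------------

class TestDiabetes:
    def test_normoglycemic_patient_has_no_flags(self):
        t = "2022-05-01T08:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.observation_quantity("g", "a", "2345-7", 100.0, "mg/dL", t),
                b.observation_quantity("h", "a", "4548-4", 5.5, "%", t),
            ]
        )
        r = diabetes_pipeline(store)
        p = r.patients[0]
        assert not (p.hyperglycemic or p.prediabetes or p.diabetes)
        assert p.severity == "normal" and r.n_dysglycemic == 0

    def test_mmol_per_l_converted_before_comparison(self):
        t = "2022-05-01T08:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.observation_quantity("g", "a", "2345-7", 11.5, "mmol/L", t, ucum="mmol/L"),
            ]
        )
        r = diabetes_pipeline(store)
        p = r.patients[0]
        assert p.max_glucose_mgdl == pytest.approx(11.5 * 18.016)
        assert p.diabetes and p.diabetes_source == "glucose"

    def test_non_numeric_observation_skipped_and_counted(self):
        t = "2022-05-01T08:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.observation_string("s", "a", "2345-7", "hemolyzed", t, system=b.LOINC_SYSTEM),
                b.observation_quantity("g", "a", "2345-7", 100.0, "mg/dL", t),
            ]
        )
        r = diabetes_pipeline(store)
        assert r.n_skipped_nonnumeric == 1 and r.n_glucose_readings == 1

    @pytest.mark.parametrize(
        "glu, a1c, expect",
        [
            (139.9, None, "normal"),
            (141.0, None, "hyperglycemia"),
            (201.0, None, "diabetes"),
            (100.0, 5.8, "prediabetes"),
            (100.0, 6.6, "diabetes"),
            (150.0, 6.0, "prediabetes"),  # worst flag wins
        ],
    )
    def test_severity_ladder(self, glu, a1c, expect):
        *_, severity = classify_patient(glu, a1c, GlycemicThresholds())
        assert severity == expect

    def test_diabetes_count_antitone_in_cutoff(self, demo_store):
        low = diabetes_pipeline(demo_store, thresholds=GlycemicThresholds(glucose_diabetes_mgdl=180))
        mid = diabetes_pipeline(demo_store)
        high = diabetes_pipeline(demo_store, thresholds=GlycemicThresholds(glucose_diabetes_mgdl=300))
        assert low.n_diabetes >= mid.n_diabetes >= high.n_diabetes

    def test_coded_plus_uncoded_partition_dysglycemic(self, demo_store):
        r = diabetes_pipeline(demo_store)
        assert r.n_coded + r.n_uncoded == r.n_dysglycemic

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GlycemicThresholds(glucose_hyper_mgdl=250, glucose_diabetes_mgdl=200)


# ---------------------------------------------------------------------------
# sepsis
# ---------------------------------------------------------------------------

class TestSepsis:
    def test_unknown_organism_bucketed_as_other(self):
        t = "2022-05-01T08:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.condition("c", "a", "A41.9", t),
                b.diagnostic_report("d1", "a", "600-7", t, conclusion="Escherichia coli"),
                b.diagnostic_report("d2", "a", "600-7", t, conclusion="Klingon bloodworm"),
            ]
        )
        r = sepsis_pipeline(store)
        assert r.pathogens.counts == {"Escherichia coli": 1, "other": 1}

    def test_top_k_stable_ordering(self):
        counts = {
            "n_patients": 4,
            "isolates": {
                "Escherichia coli": 3,
                "Candida albicans": 3,
                "Staphylococcus aureus": 5,
            },
        }
        r = sepsis_pipeline(fixture_store("sepsis", counts))
        # count desc, then name asc on the tie
        assert [name for name, _, _ in r.pathogens.top] == [
            "Staphylococcus aureus",
            "Candida albicans",
            "Escherichia coli",
        ]

    def test_pcts_sum_to_100_over_denominators(self, demo_store):
        r = sepsis_pipeline(demo_store)
        for table in (r.pathogens, r.antibiotics):
            if table.total:
                assert sum(table.pcts.values()) == pytest.approx(100.0, abs=0.5)

    def test_single_patient_timeline_sorted(self):
        t0 = "2022-05-01T08:00:00+00:00"
        t1 = "2022-05-02T08:00:00+00:00"
        t2 = "2022-05-03T08:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.condition("c", "a", "A41.9", t0),
                b.observation_quantity("r3", "a", "1988-5", 90.0, "mg/L", t2),
                b.observation_quantity("r1", "a", "1988-5", 220.0, "mg/L", t0),
                b.observation_quantity("r2", "a", "1988-5", 150.0, "mg/L", t1),
                b.diagnostic_report("d", "a", "600-7", t1, conclusion="Escherichia coli"),
                b.medication_administration("m", "a", "J01CR05", t0, t2),
            ]
        )
        tl = sepsis_pipeline(store).timelines[0]
        assert [v for _, v in tl.crp] == [220.0, 150.0, 90.0]
        assert len(tl.isolates) == 1 and len(tl.antibiotics) == 1


# ---------------------------------------------------------------------------
# prostate cancer
# ---------------------------------------------------------------------------

class TestPC:
    def test_all_undetectable_series_unflagged(self):
        store = fixture_store("pc", {"n": 1, "prostatectomy": 1, "persistence": 0, "recurrence": 0})
        r = pc_pipeline(store)
        p = r.patients[0]
        assert p.evaluable and not p.psa_persistence and not p.biochemical_recurrence

    def test_no_postop_psa_is_nonevaluable(self):
        diag = "2021-03-01T09:00:00+00:00"
        store = _store(
            [
                b.patient("a"),
                b.condition("c", "a", "C61", diag),
                b.procedure("s", "a", "5-604", "2021-06-01T09:00:00+00:00"),
                b.observation_quantity("psa", "a", "2857-1", 8.0, "ng/mL", diag),  # pre-op only
            ]
        )
        r = pc_pipeline(store)
        p = r.patients[0]
        assert p.evaluable is False and p.psa_persistence is None

    def test_rank_index_follows_time_order(self):
        store = fixture_store("pc", {"n": 1, "prostatectomy": 1, "recurrence": 1})
        p = pc_pipeline(store).patients[0]
        ranks = [r for r, _, _ in p.psa_series]
        times = [t for _, t, _ in p.psa_series]
        assert ranks == list(range(1, len(ranks) + 1))
        assert times == sorted(times)

    def test_flags_match_direct_definition_on_simulated_series(self):
        rules = PCRules()
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(1, 8))
            values = []
            level = float(rng.uniform(0.01, 0.4))
            for _ in range(n):
                level = max(0.005, level + float(rng.normal(0, 0.12)))
                values.append(round(level, 3))
            first_in_window = values[0] if rng.random() < 0.9 else None
            assert psa_flags(values, first_in_window, rules) == brute_force_psa_flags(
                values,
                first_in_window,
                rules.persistence_threshold,
                rules.recurrence_threshold,
                rules.undetectable_threshold,
            )

    def test_treatment_crosstab_counts_cohort(self, demo_store):
        r = pc_pipeline(demo_store)
        assert sum(r.treatment_crosstab.values()) == r.n_cohort
        assert sum(r.therapy_counts.values()) == r.n_cohort


def test_reports_serialize_to_plain_json(demo_store):
    import json

    for pipeline in (mi_pipeline, stroke_pipeline, diabetes_pipeline, sepsis_pipeline, pc_pipeline):
        doc = report_to_dict(pipeline(demo_store))
        json.dumps(doc)  # must not raise
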