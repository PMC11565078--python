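"""Count-exact fixture builder.

Given a table of category counts, build a corpus that the corresponding
pipeline *deterministically* maps back to exactly those counts: every
planted value sits well away from any decision boundary, and category
membership is encoded in the resources themselves (codes, timings, series
shapes), never in side channels.  This is how printed marginal summaries
from an inaccessible source system are reproduced at desk scale.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

from ..errors import ConfigError
from ..fhir_core import parse_resource
from ..store_query import ResourceStore
from . import builders as b

UTC = timezone.utc


def _iso(dt: datetime) -> str:
    return dt.isoformat()


def fixture_from_counts(template: str, counts: dict) -> list[dict]:
    """Build a raw-resource corpus realizing ``counts`` for one use case.

    Templates: ``mi``, ``stroke``, ``diabetes``, ``sepsis``, ``pc``.
    Raises :class:`ConfigError` on an unknown template or an infeasible
    count table.
    """
    builders = {
        "mi": _mi_fixture,
        "stroke": _stroke_fixture,
        "diabetes": _diabetes_fixture,
        "sepsis": _sepsis_fixture,
        "pc": _pc_fixture,
    }
    if template not in builders:
        raise ConfigError(f"unknown fixture template {template!r}; known: {sorted(builders)}")
    return builders[template](dict(counts))


def fixture_store(template: str, counts: dict) -> ResourceStore:
    return ResourceStore.from_envelopes(
        parse_resource(tree) for tree in fixture_from_counts(template, counts)
    )


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(f"infeasible count table: {msg}")


# ---------------------------------------------------------------------------

def _mi_fixture(c: dict) -> list[dict]:
    """Patients coded STEMI, with planted medication-category margins.

    Required: n, antiplatelet_any, statin_any, adherent (under the default
    antiplatelet-or-statin rule).  Optional: ezetimibe, dual_antiplatelet.
    """
    n = c["n"]
    ap = c["antiplatelet_any"]
    st = c["statin_any"]
    adherent = c["adherent"]
    ez = c.get("ezetimibe", 0)
    dual = c.get("dual_antiplatelet", ap)
    overlap = ap + st - adherent
    _check(0 <= overlap <= min(ap, st), "antiplatelet/statin overlap out of range")
    _check(adherent <= n, "adherent exceeds n")
    _check(ap + st - overlap <= n, "union exceeds n")
    _check(ez <= st, "ezetimibe must accompany a statin here")
    _check(dual <= ap, "dual antiplatelet exceeds antiplatelet_any")

    when = datetime(2022, 3, 15, 9, 0, tzinfo=UTC)
    out: list[dict] = []
    ap_flags = [True] * ap + [False] * (n - ap)
    # statin: overlap with the first `overlap` antiplatelet patients, the
    # rest among the non-antiplatelet block
    st_flags = [False] * n
    for i in range(overlap):
        st_flags[i] = True
    for i in range(st - overlap):
        st_flags[ap + i] = True
    statin_seen = 0
    for i in range(n):
        pid = f"mi-p{i:04d}"
        out.append(b.patient(pid))
        out.append(b.condition(f"mi-c{i:04d}", pid, "I21.0", _iso(when)))
        t = _iso(when + timedelta(hours=2))
        if ap_flags[i]:
            out.append(b.medication_administration(f"mi-m{i:04d}-ap1", pid, "B01AC06", t))
            if i < dual:
                out.append(b.medication_administration(f"mi-m{i:04d}-ap2", pid, "B01AC04", t))
        if st_flags[i]:
            out.append(b.medication_administration(f"mi-m{i:04d}-st", pid, "C10AA01", t))
            if statin_seen < ez:
                out.append(b.medication_administration(f"mi-m{i:04d}-ez", pid, "C10AX09", t))
            statin_seen += 1
    return out


# ---------------------------------------------------------------------------

def _therapy_block(
    prefix: str,
    n: int,
    within: int,
    eni: tuple[int, int, int],
    excluded_marker: int,
    proc_code: str,
    minutes_in: int,
    minutes_out: int,
    day0: datetime,
) -> list[dict]:
    eni_total = sum(eni)
    _check(within <= n, f"{prefix}: within exceeds treated")
    _check(eni_total + excluded_marker <= n, f"{prefix}: ENI categories exceed treated")
    out: list[dict] = []
    labels = (
        ["decrease"] * eni[0]
        + ["no_change"] * eni[1]
        + ["increase"] * eni[2]
        + ["marker"] * excluded_marker
    )
    labels += ["missing"] * (n - len(labels))
    followup = {"decrease": 6.0, "no_change": 10.0, "increase": 14.0, "marker": 8.0}
    for i in range(n):
        pid = f"{prefix}-p{i:04d}"
        admit = day0 + timedelta(days=i % 300, hours=8)
        out.append(b.patient(pid))
        out.append(b.condition(f"{prefix}-c{i:04d}", pid, "I63.5", _iso(admit)))
        out.append(b.encounter(f"{prefix}-e{i:04d}", pid, _iso(admit)))
        minutes = minutes_in if i < within else minutes_out
        treat = admit + timedelta(minutes=minutes)
        out.append(b.procedure(f"{prefix}-t{i:04d}", pid, proc_code, _iso(treat)))
        onset = admit - timedelta(minutes=90)
        out.append(b.observation_marker(f"{prefix}-o{i:04d}", pid, "symptom-onset", _iso(onset)))
        label = labels[i]
        out.append(
            b.observation_quantity(
                f"{prefix}-nb{i:04d}", pid, "70182-1", 10.0, "{score}", _iso(admit + timedelta(hours=1))
            )
        )
        if label != "missing":
            out.append(
                b.observation_quantity(
                    f"{prefix}-nf{i:04d}",
                    pid,
                    "70182-1",
                    followup[label],
                    "{score}",
                    _iso(admit + timedelta(hours=25)),
                )
            )
        if label == "marker":
            out.append(
                b.observation_marker(
                    f"{prefix}-x{i:04d}", pid, "eni-exclusion", _iso(admit + timedelta(hours=26))
                )
            )
    return out


def _stroke_fixture(c: dict) -> list[dict]:
    """Disjoint thrombolysis and thrombectomy blocks plus untreated padding.

    Required: lysis {n, within, eni_decrease, eni_no_change, eni_increase};
    thrombectomy adds ``excluded`` (classification-excluded marker patients).
    Optional: ischemic_extra / hemorrhagic_extra untreated cohort padding.
    """
    ly = c["lysis"]
    th = c.get("thrombectomy", {"n": 0, "within": 0})
    day0 = datetime(2022, 1, 3, tzinfo=UTC)
    out = _therapy_block(
        "sk-ly",
        ly["n"],
        ly["within"],
        (ly.get("eni_decrease", 0), ly.get("eni_no_change", 0), ly.get("eni_increase", 0)),
        ly.get("excluded", 0),
        "8-020.8",
        40,
        75,
        day0,
    )
    out += _therapy_block(
        "sk-th",
        th["n"],
        th["within"],
        (th.get("eni_decrease", 0), th.get("eni_no_change", 0), th.get("eni_increase", 0)),
        th.get("excluded", 0),
        "8-836.80",
        60,
        120,
        day0,
    )
    for kind, code in (("ischemic_extra", "I63.9"), ("hemorrhagic_extra", "I61.9")):
        for i in range(c.get(kind, 0)):
            pid = f"sk-{kind[:3]}-p{i:04d}"
            out.append(b.patient(pid))
            out.append(
                b.condition(
                    f"sk-{kind[:3]}-c{i:04d}", pid, code, _iso(day0 + timedelta(days=i % 300))
                )
            )
    return out


# ---------------------------------------------------------------------------

def _diabetes_fixture(c: dict) -> list[dict]:
    """Patient classes realizing the biochemical-flag margins.

    Required: n, hyperglycemic, prediabetes, diabetes_glucose,
    diabetes_hba1c, diabetes_both, dysglycemic, coded.
    """
    n = c["n"]
    dg, dh, db = c["diabetes_glucose"], c["diabetes_hba1c"], c["diabetes_both"]
    diabetes = dg + dh + db
    pre = c["prediabetes"]
    hyper = c["hyperglycemic"]
    dys = c["dysglycemic"]
    coded = c["coded"]
    hyper_only = dys - diabetes - pre
    _check(hyper_only >= 0, "union smaller than diabetes + prediabetes")
    prediab_hyper = hyper - (dg + db) - hyper_only
    _check(0 <= prediab_hyper <= pre, "hyperglycemic margin incompatible with classes")
    normal = n - dys
    _check(normal >= 0, "dysglycemic exceeds n")
    _check(coded <= dys, "coded exceeds dysglycemic")

    # (class size, max glucose mg/dL, HbA1c %) — values sit off every cutoff
    classes = [
        ("diab_glu", dg, 250.0, 5.5),
        ("diab_a1c", dh, 100.0, 7.5),
        ("diab_both", db, 250.0, 7.5),
        ("prediab_hyper", prediab_hyper, 160.0, 6.0),
        ("prediab", pre - prediab_hyper, 100.0, 6.0),
        ("hyper_only", hyper_only, 160.0, 5.5),
        ("normal", normal, 100.0, 5.5),
    ]
    when = datetime(2022, 6, 1, 8, 0, tzinfo=UTC)
    out: list[dict] = []
    i = 0
    coded_left = coded
    for name, size, glu, a1c in classes:
        for _ in range(size):
            pid = f"dm-p{i:05d}"
            out.append(b.patient(pid))
            out.append(
                b.observation_quantity(f"dm-g{i:05d}", pid, "2345-7", glu, "mg/dL", _iso(when))
            )
            out.append(
                b.observation_quantity(f"dm-h{i:05d}", pid, "4548-4", a1c, "%", _iso(when))
            )
            if name != "normal" and coded_left > 0:
                out.append(b.condition(f"dm-c{i:05d}", pid, "E11.9", _iso(when)))
                coded_left -= 1
            i += 1
    return out


# ---------------------------------------------------------------------------

def _sepsis_fixture(c: dict) -> list[dict]:
    """Cohort with exact isolate and prescription frequency tables.

    Required: n_patients, isolates {organism: count},
    prescriptions {ATC code: count}.
    """
    n = c["n_patients"]
    _check(n > 0, "need at least one patient")
    when0 = datetime(2022, 2, 1, 8, 0, tzinfo=UTC)
    out: list[dict] = []
    for i in range(n):
        pid = f"sep-p{i:04d}"
        out.append(b.patient(pid))
        out.append(
            b.condition(f"sep-c{i:04d}", pid, "A41.9", _iso(when0 + timedelta(days=i % 300)))
        )
    k = 0
    for organism, count in sorted(c.get("isolates", {}).items()):
        for _ in range(count):
            pid = f"sep-p{k % n:04d}"
            out.append(
                b.diagnostic_report(
                    f"sep-d{k:05d}",
                    pid,
                    "600-7",
                    _iso(when0 + timedelta(days=k % 300, hours=6)),
                    conclusion=organism,
                )
            )
            k += 1
    k = 0
    for atc, count in sorted(c.get("prescriptions", {}).items()):
        for _ in range(count):
            pid = f"sep-p{k % n:04d}"
            start = when0 + timedelta(days=k % 300, hours=8)
            out.append(
                b.medication_administration(
                    f"sep-m{k:05d}", pid, atc, _iso(start), _iso(start + timedelta(days=5))
                )
            )
            k += 1
    return out


# ---------------------------------------------------------------------------

def _pc_fixture(c: dict) -> list[dict]:
    """Prostate-cancer cohort with planted PSA-course outcomes.

    Required: n, prostatectomy, persistence, recurrence.  Surgery patients
    beyond the flagged ones get an unremarkable undetectable course.
    """
    n = c["n"]
    surg = c["prostatectomy"]
    pers = c.get("persistence", 0)
    rec = c.get("recurrence", 0)
    _check(pers + rec <= surg <= n, "flagged exceeds prostatectomies or surgeries exceed n")
    diag = datetime(2021, 3, 1, 9, 0, tzinfo=UTC)
    surgery = datetime(2021, 6, 1, 9, 0, tzinfo=UTC)
    courses = (
        [("persistence", (0.15, 0.18))] * pers
        + [("recurrence", (0.05, 0.25, 0.4))] * rec
        + [("clean", (0.03, 0.04))] * (surg - pers - rec)
    )
    out: list[dict] = []
    for i in range(n):
        pid = f"pc-p{i:03d}"
        out.append(b.patient(pid, gender="male"))
        out.append(b.condition(f"pc-c{i:03d}", pid, "C61", _iso(diag + timedelta(days=i % 280))))
        out.append(b.observation_string(f"pc-tnm{i:03d}", pid, "tnm-stage", "T2N0M0", _iso(diag)))
        out.append(
            b.observation_quantity(
                f"pc-isup{i:03d}", pid, "isup-grade", 2.0, "{grade}", _iso(diag), system=b.LOCAL_SYSTEM
            )
        )
        out.append(
            b.observation_quantity(f"pc-psa0-{i:03d}", pid, "2857-1", 8.0, "ng/mL", _iso(diag))
        )
        if i < surg:
            out.append(b.procedure(f"pc-s{i:03d}", pid, "5-604", _iso(surgery)))
            out.append(
                b.observation_string(f"pc-m{i:03d}", pid, "resection-margin", "R0", _iso(surgery))
            )
            _, values = courses[i]
            for j, v in enumerate(values):
                out.append(
                    b.observation_quantity(
                        f"pc-psa{j + 1}-{i:03d}",
                        pid,
                        "2857-1",
                        v,
                        "ng/mL",
                        _iso(surgery + timedelta(days=60 + 110 * j)),
                    )
                )
    return out
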