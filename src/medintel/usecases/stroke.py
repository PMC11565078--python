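"""Stroke: door-to-needle / door-to-groin times and early neurological
improvement (ENI).

For every cohort patient with a thrombolysis or thrombectomy procedure the
pipeline computes

* minutes from emergency-room admission (``Encounter.period.start`` of the
  most recent encounter starting at or before treatment) to treatment start,
  floored to whole minutes, and whether that falls inside the
  guideline window (default: <=60 min needle, <=90 min groin);
* minutes from symptom onset (a designated Observation whose effective time
  *is* the onset, covering witnessed onset or last-known-well) to treatment;
* the NIHSS score at baseline and ~24 h (nearest Observations within
  configurable tolerances) and the resulting ENI class
  (decrease / no_change / increase of the score);
* the rank (Spearman) correlation between onset-to-treatment minutes and
  the NIHSS percent change, over the pairs where both exist.

Patients lacking a 24 h NIHSS are excluded from classification with a
reason; a designated marker Observation (e.g. ongoing weaning from
ventilation) likewise excludes from classification but not from the
correlation, whose denominator is therefore allowed to differ.
Treatment before admission is a data error: the patient is counted but kept
out of the within-window statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Optional, Union

from scipy import stats as sps

from ..cohort import CohortSpec, build_cohort
from ..fhir_core import Observation, Quantity
from ..store_query import DateFilter, ResourceStore, SearchQuery
from ..timeutil import Instant, parse_instant, whole_minutes
from .common import load_usecase_config, pct, require

ENI_CLASSES = ("decrease", "no_change", "increase")


@dataclass(frozen=True)
class StrokeThresholds:
    needle_minutes: int = 60
    groin_minutes: int = 90
    boundary: str = "leq"  # leq | strict_less

    def __post_init__(self):
        if self.needle_minutes <= 0 or self.groin_minutes <= 0:
            raise ValueError("window thresholds must be positive")
        if self.boundary not in ("leq", "strict_less"):
            raise ValueError("boundary must be 'leq' or 'strict_less'")

    def within(self, minutes: int, therapy: str) -> bool:
        limit = self.needle_minutes if therapy == "lysis" else self.groin_minutes
        return minutes <= limit if self.boundary == "leq" else minutes < limit


@dataclass
class StrokePatient:
    patient_id: str
    therapy: str  # lysis | thrombectomy | both
    stroke_type: Optional[str]  # ischemic | hemorrhagic
    lysis_minutes: Optional[int] = None
    lysis_within: Optional[bool] = None
    groin_minutes: Optional[int] = None
    groin_within: Optional[bool] = None
    onset_to_needle_minutes: Optional[int] = None
    onset_to_groin_minutes: Optional[int] = None
    nihss_baseline: Optional[float] = None
    nihss_24h: Optional[float] = None
    eni_delta: Optional[float] = None
    eni_pct_change: Optional[float] = None
    eni_class: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    data_error: bool = False


@dataclass
class TherapyStats:
    n_treated: int
    n_timed: int          # admission found, non-negative interval
    n_within: int
    pct_within: Optional[float]
    n_data_error: int
    n_eni_evaluable: int
    n_excluded: int
    eni_counts: dict
    eni_pcts: dict
    correlation_n: int
    correlation_rho: Optional[float]


@dataclass
class StrokeReport:
    n_cohort: int
    n_ischemic: int
    n_hemorrhagic: int
    thresholds: dict
    lysis: TherapyStats
    thrombectomy: TherapyStats
    patients: list = field(default_factory=list, repr=False)


def _nearest_obs(
    observations: list, target: Instant, tolerance: timedelta
) -> Optional[float]:
    """Value of the numeric observation closest to ``target`` within
    tolerance; ties break toward the earlier observation."""
    best: tuple[float, str, float] | None = None
    for env in observations:
        period = env.period()
        if period is None:
            continue
        value = env.typed.value if isinstance(env.typed, Observation) else None
        if not isinstance(value, Quantity):
            continue
        dist = abs((period[0].at - target.at).total_seconds())
        if dist <= tolerance.total_seconds():
            key = (dist, period[0].isoformat(), value.value)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def stroke_pipeline(
    store: ResourceStore,
    cohort_config: Union[str, dict] = "stroke",
    thresholds: Optional[StrokeThresholds] = None,
) -> StrokeReport:
    cfg = load_usecase_config(cohort_config)
    if thresholds is None:
        t = cfg.get("thresholds", {})
        thresholds = StrokeThresholds(
            needle_minutes=t.get("needle_minutes", 60),
            groin_minutes=t.get("groin_minutes", 90),
            boundary=t.get("boundary", "leq"),
        )
    c = require(cfg, "cohort", "stroke")
    spec = CohortSpec(
        name="stroke",
        icd_prefixes=tuple(c["icd_prefixes"]),
        start=parse_instant(c["period"]["start"]),
        end=parse_instant(c["period"]["end"]),
    )
    cohort = build_cohort(store, spec)
    proc_system = cfg.get("procedure_system")
    loinc = cfg.get("loinc_system", "http://loinc.org")
    local = cfg.get("local_system")
    nihss_code = cfg["nihss_code"]
    onset_code = cfg["onset_code"]
    excl_code = cfg.get("eni_exclusion_code")
    base_tol = timedelta(hours=cfg.get("baseline_tolerance_hours", 12))
    fup_offset = timedelta(hours=cfg.get("followup_offset_hours", 24))
    fup_tol = timedelta(hours=cfg.get("followup_tolerance_hours", 12))
    ischemic = tuple(cfg.get("ischemic_prefixes", ("I63",)))
    hemorrhagic = tuple(cfg.get("hemorrhagic_prefixes", ("I61",)))

    n_isch = n_hem = 0
    for pid in cohort.patient_ids:
        code = cohort.index_conditions[pid].code
        if any(code.startswith(p) for p in ischemic):
            n_isch += 1
        elif any(code.startswith(p) for p in hemorrhagic):
            n_hem += 1

    period_filters = (DateFilter("date", "ge", spec.start), DateFilter("date", "lt", spec.end))
    patients: list[StrokePatient] = []
    for pid in cohort.patient_ids:
        procs = store.search(SearchQuery("Procedure", date_filters=period_filters, subject=pid))

        def first_proc_start(codes: list) -> Optional[Instant]:
            starts = [
                env.period()[0]
                for env in procs
                if env.period() is not None
                and any(env.code_concept().matches(proc_system, cd) for cd in codes)
            ]
            return min(starts) if starts else None

        lysis_at = first_proc_start(cfg["lysis_codes"])
        groin_at = first_proc_start(cfg["thrombectomy_codes"])
        if lysis_at is None and groin_at is None:
            continue
        therapy = "both" if (lysis_at and groin_at) else ("lysis" if lysis_at else "thrombectomy")

        code = cohort.index_conditions[pid].code
        stroke_type = (
            "ischemic"
            if any(code.startswith(p) for p in ischemic)
            else "hemorrhagic"
            if any(code.startswith(p) for p in hemorrhagic)
            else None
        )
        rec = StrokePatient(patient_id=pid, therapy=therapy, stroke_type=stroke_type)

        encounters = store.search(SearchQuery("Encounter", subject=pid))
        first_treat = min(t for t in (lysis_at, groin_at) if t is not None)
        starts = [env.period()[0] for env in encounters if env.period() is not None]
        at_or_before = [s for s in starts if s <= first_treat]
        # most recent admission before treatment; an admission-only-after
        # treatment surfaces as a negative interval (data error) below
        admission = max(at_or_before) if at_or_before else (min(starts) if starts else None)

        for label, treat_at in (("lysis", lysis_at), ("thrombectomy", groin_at)):
            if treat_at is None:
                continue
            if admission is None:
                continue
            minutes = whole_minutes(admission, treat_at)
            if minutes < 0:
                rec.data_error = True
                continue
            within = thresholds.within(minutes, label)
            if label == "lysis":
                rec.lysis_minutes, rec.lysis_within = minutes, within
            else:
                rec.groin_minutes, rec.groin_within = minutes, within

        obs = store.search(SearchQuery("Observation", subject=pid))
        onset_envs = [e for e in obs if e.code_concept().matches(local, onset_code)]
        onset = min((e.period()[0] for e in onset_envs if e.period()), default=None)
        if onset is not None:
            if lysis_at is not None and lysis_at >= onset:
                rec.onset_to_needle_minutes = whole_minutes(onset, lysis_at)
            if groin_at is not None and groin_at >= onset:
                rec.onset_to_groin_minutes = whole_minutes(onset, groin_at)

        nihss = [e for e in obs if e.code_concept().matches(loinc, nihss_code)]
        anchor = admission if admission is not None else first_treat
        rec.nihss_baseline = _nearest_obs(nihss, anchor, base_tol)
        rec.nihss_24h = _nearest_obs(nihss, anchor + fup_offset, fup_tol)
        marker = excl_code is not None and any(
            e.code_concept().matches(local, excl_code) for e in obs
        )
        if rec.nihss_baseline is not None and rec.nihss_24h is not None:
            rec.eni_delta = rec.nihss_24h - rec.nihss_baseline
            if rec.nihss_baseline > 0:
                rec.eni_pct_change = 100.0 * rec.eni_delta / rec.nihss_baseline
            if marker:
                rec.excluded, rec.exclusion_reason = True, "exclusion_marker"
            else:
                rec.eni_class = (
                    "decrease" if rec.eni_delta < 0 else "increase" if rec.eni_delta > 0 else "no_change"
                )
        else:
            rec.excluded = True
            rec.exclusion_reason = "no_followup_nihss" if rec.nihss_baseline is not None else "no_nihss"
        patients.append(rec)

    def therapy_stats(label: str) -> TherapyStats:
        if label == "lysis":
            group = [p for p in patients if p.therapy in ("lysis", "both")]
            minutes = [(p.lysis_minutes, p.lysis_within) for p in group]
            onset_minutes = {p.patient_id: p.onset_to_needle_minutes for p in group}
        else:
            group = [p for p in patients if p.therapy in ("thrombectomy", "both")]
            minutes = [(p.groin_minutes, p.groin_within) for p in group]
            onset_minutes = {p.patient_id: p.onset_to_groin_minutes for p in group}
        timed = [(m, w) for m, w in minutes if m is not None]
        n_within = sum(1 for _, w in timed if w)
        eni_group = [p for p in group if p.eni_class is not None]
        counts = {cls: sum(1 for p in eni_group if p.eni_class == cls) for cls in ENI_CLASSES}
        pairs = [
            (onset_minutes[p.patient_id], p.eni_pct_change)
            for p in group
            if onset_minutes[p.patient_id] is not None and p.eni_pct_change is not None
        ]
        rho = None
        if len(pairs) >= 3:
            xs, ys = zip(*pairs)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sps.ConstantInputWarning)
                result = sps.spearmanr(xs, ys)
            rho = None if result.statistic != result.statistic else float(result.statistic)
        return TherapyStats(
            n_treated=len(group),
            n_timed=len(timed),
            n_within=n_within,
            pct_within=pct(n_within, len(timed)),
            n_data_error=sum(1 for p in group if p.data_error),
            n_eni_evaluable=len(eni_group),
            n_excluded=sum(1 for p in group if p.excluded),
            eni_counts=counts,
            eni_pcts={cls: pct(n, len(eni_group)) for cls, n in counts.items()},
            correlation_n=len(pairs),
            correlation_rho=rho,
        )

    return StrokeReport(
        n_cohort=len(cohort),
        n_ischemic=n_isch,
        n_hemorrhagic=n_hem,
        thresholds={
            "needle_minutes": thresholds.needle_minutes,
            "groin_minutes": thresholds.groin_minutes,
            "boundary": thresholds.boundary,
        },
        lysis=therapy_stats("lysis"),
        thrombectomy=therapy_stats("thrombectomy"),
        patients=patients,
    )
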