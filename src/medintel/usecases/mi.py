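"""Myocardial infarction: secondary-prevention medication coverage.

Denominator: patients newly diagnosed with acute MI (ICD-10 I21.*) in the
period who were either coded as STEMI or received a coronary intervention.
For each such patient, medication administrations in the period are bucketed
by ATC prefix into antiplatelet / statin / ezetimibe / anticoagulant, and a
3x3 cross-tab (antiplatelet none/single/dual x lipid none/statin/
statin+ezetimibe) summarizes the treatment pattern.

The "guideline therapy" flag is a pluggable predicate over the per-patient
category flags.  The default — any antiplatelet OR any statin — is the rule
under which the cross-tab margins decompose consistently (the complement is
exactly the patients in the none/none cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from ..cohort import CohortSpec, build_cohort
from ..store_query import DateFilter, ResourceStore, SearchQuery, TokenFilter
from ..timeutil import parse_instant
from .common import load_usecase_config, pct, require

AP_CATEGORIES = ("none", "single", "dual")
LIPID_CATEGORIES = ("none", "statin", "statin_ezetimibe")

AdherencePredicate = Callable[[dict], bool]


def adherence_antiplatelet_or_statin(flags: dict) -> bool:
    return flags["antiplatelet"] or flags["statin"]


def adherence_ap_or_anticoag_and_statin(flags: dict) -> bool:
    return (flags["antiplatelet"] or flags["anticoagulant"]) and flags["statin"]


_ADHERENCE_RULES: dict[str, AdherencePredicate] = {
    "antiplatelet_or_statin": adherence_antiplatelet_or_statin,
    "antiplatelet_or_anticoag_and_statin": adherence_ap_or_anticoag_and_statin,
}


@dataclass(frozen=True)
class MIRules:
    """Category definitions; prefix sets must be pairwise disjoint."""

    antiplatelet_atc_prefixes: tuple[str, ...] = ("B01AC",)
    statin_atc_prefixes: tuple[str, ...] = ("C10AA",)
    ezetimibe_atc_prefixes: tuple[str, ...] = ("C10AX",)
    anticoagulant_atc_prefixes: tuple[str, ...] = ("B01AA", "B01AB", "B01AE", "B01AF")
    stemi_icd_prefixes: tuple[str, ...] = ("I21.0", "I21.1", "I21.2", "I21.3")
    intervention_procedure_codes: tuple[str, ...] = ("8-837",)
    adherence_rule: AdherencePredicate = adherence_antiplatelet_or_statin

    def __post_init__(self):
        sets = [
            set(self.antiplatelet_atc_prefixes),
            set(self.statin_atc_prefixes),
            set(self.ezetimibe_atc_prefixes),
            set(self.anticoagulant_atc_prefixes),
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("ATC category prefix sets must be pairwise disjoint")

    @classmethod
    def from_config(cls, cfg: dict) -> "MIRules":
        atc = require(cfg, "atc_prefixes", "mi")
        rule_name = cfg.get("adherence_rule", "antiplatelet_or_statin")
        if rule_name not in _ADHERENCE_RULES:
            raise ValueError(f"unknown adherence_rule {rule_name!r}")
        return cls(
            antiplatelet_atc_prefixes=tuple(atc["antiplatelet"]),
            statin_atc_prefixes=tuple(atc["statin"]),
            ezetimibe_atc_prefixes=tuple(atc["ezetimibe"]),
            anticoagulant_atc_prefixes=tuple(atc["anticoagulant"]),
            stemi_icd_prefixes=tuple(cfg.get("stemi_icd_prefixes", cls.stemi_icd_prefixes)),
            intervention_procedure_codes=tuple(
                cfg.get("intervention_procedure_codes", cls.intervention_procedure_codes)
            ),
            adherence_rule=_ADHERENCE_RULES[rule_name],
        )


@dataclass
class MIPatient:
    patient_id: str
    stemi: bool
    intervention: bool
    n_antiplatelet_agents: int
    antiplatelet: bool
    statin: bool
    ezetimibe: bool
    anticoagulant: bool
    ap_category: str
    lipid_category: str
    adherent: bool


@dataclass
class MICrossTab:
    """Counts and printed-style percentages over the MI denominator."""

    n_mi_diagnosed: int
    n_cohort: int
    cells: dict  # "(ap,lipid)" -> count
    cell_pcts: dict
    n_antiplatelet_any: int
    pct_antiplatelet_any: Optional[float]
    n_single_antiplatelet: int
    n_dual_antiplatelet: int
    n_statin_any: int
    pct_statin_any: Optional[float]
    n_ezetimibe: int
    pct_ezetimibe: Optional[float]
    n_adherent: int
    pct_adherent: Optional[float]
    patients: list = field(default_factory=list, repr=False)


def mi_pipeline(
    store: ResourceStore,
    cohort_config: Union[str, dict] = "mi",
    rules: Optional[MIRules] = None,
) -> MICrossTab:
    cfg = load_usecase_config(cohort_config)
    rules = rules or MIRules.from_config(cfg)
    c = require(cfg, "cohort", "mi")
    spec = CohortSpec(
        name="mi",
        icd_prefixes=tuple(c["icd_prefixes"]),
        start=parse_instant(c["period"]["start"]),
        end=parse_instant(c["period"]["end"]),
    )
    cohort = build_cohort(store, spec)
    atc_system = cfg.get("atc_system")
    proc_system = cfg.get("procedure_system")

    date_filters = (
        DateFilter("date", "ge", spec.start),
        DateFilter("date", "lt", spec.end),
    )
    patients: list[MIPatient] = []
    for pid in cohort.patient_ids:
        stemi = any(
            env.code_concept().matches(None, p, prefix=True)
            for env in store.search(
                SearchQuery(
                    "Condition",
                    date_filters=(
                        DateFilter("recorded-date", "ge", spec.start),
                        DateFilter("recorded-date", "lt", spec.end),
                    ),
                    subject=pid,
                )
            )
            for p in rules.stemi_icd_prefixes
        )
        procs = store.search(SearchQuery("Procedure", date_filters=date_filters, subject=pid))
        intervention = any(
            env.code_concept().matches(proc_system, code)
            for env in procs
            for code in rules.intervention_procedure_codes
        )
        if not (stemi or intervention):
            continue

        meds = store.search(
            SearchQuery(
                "MedicationAdministration",
                date_filters=(
                    DateFilter("effective-time", "ge", spec.start),
                    DateFilter("effective-time", "lt", spec.end),
                ),
                subject=pid,
            )
        )
        substances: dict[str, set[str]] = {
            "antiplatelet": set(),
            "statin": set(),
            "ezetimibe": set(),
            "anticoagulant": set(),
        }
        categories = (
            ("antiplatelet", rules.antiplatelet_atc_prefixes),
            ("statin", rules.statin_atc_prefixes),
            ("ezetimibe", rules.ezetimibe_atc_prefixes),
            ("anticoagulant", rules.anticoagulant_atc_prefixes),
        )
        for env in meds:
            concept = env.code_concept()
            for coding in concept.codings:
                if atc_system is not None and coding.system != atc_system:
                    continue
                for cat, prefixes in categories:
                    if any(coding.code.startswith(p) for p in prefixes):
                        substances[cat].add(coding.code)
        flags = {cat: bool(codes) for cat, codes in substances.items()}
        n_ap = len(substances["antiplatelet"])
        ap_cat = "none" if n_ap == 0 else ("single" if n_ap == 1 else "dual")
        if flags["statin"] and flags["ezetimibe"]:
            lipid_cat = "statin_ezetimibe"
        elif flags["statin"]:
            lipid_cat = "statin"
        else:
            lipid_cat = "none"  # ezetimibe without a statin stays outside the statin arms
        patients.append(
            MIPatient(
                patient_id=pid,
                stemi=stemi,
                intervention=intervention,
                n_antiplatelet_agents=n_ap,
                antiplatelet=flags["antiplatelet"],
                statin=flags["statin"],
                ezetimibe=flags["ezetimibe"],
                anticoagulant=flags["anticoagulant"],
                ap_category=ap_cat,
                lipid_category=lipid_cat,
                adherent=bool(rules.adherence_rule(flags)),
            )
        )

    n = len(patients)
    cells = {f"{ap}|{lip}": 0 for ap in AP_CATEGORIES for lip in LIPID_CATEGORIES}
    for p in patients:
        cells[f"{p.ap_category}|{p.lipid_category}"] += 1
    return MICrossTab(
        n_mi_diagnosed=len(cohort),
        n_cohort=n,
        cells=cells,
        cell_pcts={k: pct(v, n) for k, v in cells.items()},
        n_antiplatelet_any=sum(1 for p in patients if p.antiplatelet),
        pct_antiplatelet_any=pct(sum(1 for p in patients if p.antiplatelet), n),
        n_single_antiplatelet=sum(1 for p in patients if p.ap_category == "single"),
        n_dual_antiplatelet=sum(1 for p in patients if p.ap_category == "dual"),
        n_statin_any=sum(1 for p in patients if p.statin),
        pct_statin_any=pct(sum(1 for p in patients if p.statin), n),
        n_ezetimibe=sum(1 for p in patients if p.ezetimibe),
        pct_ezetimibe=pct(sum(1 for p in patients if p.ezetimibe), n),
        n_adherent=sum(1 for p in patients if p.adherent),
        pct_adherent=pct(sum(1 for p in patients if p.adherent), n),
        patients=patients,
    )
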