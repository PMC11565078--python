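"""Synthetic-hospital generator.

Emulates the statistical structure the pipelines consume: a screened
inpatient population with glucose/HbA1c laboratory panels, plus disease
blocks (myocardial infarction, stroke, sepsis, prostate cancer) whose
prevalences, category mixes and timing distributions default to the
fractions of the study population they model.  Each block draws from its
own pseudo-random stream split off the master seed, so adding or resizing a
block never perturbs another block's draws.

Every generated patient gets a ground-truth label row, serialized beside
the corpus, enabling parameter-recovery tests: the pipelines must read the
planted labels back out of the resources alone.  Generated values keep a
guard band around every decision boundary (glycemic cutoffs, door-to-needle
windows, PSA thresholds), so label recovery is exact by construction, and
label *frequencies* are binomial in the configured prevalences.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from ..fhir_core import ResourceEnvelope, parse_resource, write_ndjson
from . import builders as b

UTC = timezone.utc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class DiabetesBlock(BaseModel):
    """Glycemic mix of the screened population.  Group fractions follow the
    hospital-population structure this generator emulates; reading counts
    follow its laboratory intensity (about 12.5 glucose and 0.46 HbA1c
    measurements per screened patient)."""

    group_probs: dict[str, float] = Field(
        default={"normal": 0.610, "hyperglycemia": 0.114, "prediabetes": 0.118, "diabetes": 0.158}
    )
    diabetes_source_probs: dict[str, float] = Field(
        default={"glucose": 0.584, "hba1c": 0.168, "both": 0.248}
    )
    glucose_readings_mean: float = 12.5
    hba1c_prob: float = 0.456
    coded_prob: float = 0.442

    @model_validator(mode="after")
    def _probs_valid(self):
        for name, probs in (("group_probs", self.group_probs), ("diabetes_source_probs", self.diabetes_source_probs)):
            total = sum(probs.values())
            if any(p < 0 for p in probs.values()) or abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1 (got {total})")
        return self


class MIBlock(BaseModel):
    prevalence: float = 0.021
    p_stemi: float = 0.30
    p_intervention: float = 0.35
    # joint antiplatelet x statin mix among the STEMI/intervention group
    combo_probs: dict[str, float] = Field(
        default={"both": 0.6212, "ap_only": 0.0947, "statin_only": 0.0111, "neither": 0.2730}
    )
    p_dual_given_ap: float = 0.8
    p_ezetimibe_given_statin: float = 0.427
    p_anticoagulant: float = 0.10


class StrokeBlock(BaseModel):
    prevalence: float = 0.036
    ischemic_frac: float = 0.852
    p_lysis: float = 0.1292
    p_thrombectomy: float = 0.0846
    needle_within_prob: float = 0.867
    groin_within_prob: float = 0.759
    guard_band_minutes: int = 2
    eni_probs_lysis: dict[str, float] = Field(
        default={"decrease": 0.643, "no_change": 0.159, "increase": 0.198}
    )
    eni_probs_thrombectomy: dict[str, float] = Field(
        default={"decrease": 0.632, "no_change": 0.066, "increase": 0.302}
    )
    p_no_followup: float = 0.05
    p_weaning_marker: float = 0.2315  # thrombectomy only


class SepsisBlock(BaseModel):
    prevalence: float = 0.051
    isolates_per_patient: float = 1.48
    prescriptions_per_patient: float = 0.88
    organism_weights: dict[str, float] = Field(
        default={
            "Staphylococcus epidermidis": 0.289,
            "Escherichia coli": 0.179,
            "Enterococcus faecium": 0.130,
            "Staphylococcus aureus": 0.090,
            "Klebsiella pneumoniae": 0.070,
            "Pseudomonas aeruginosa": 0.060,
            "Enterococcus faecalis": 0.050,
            "Candida albicans": 0.045,
            "Streptococcus pneumoniae": 0.035,
            "Proteus mirabilis": 0.022,
            "Enterobacter cloacae": 0.015,
            "Serratia marcescens": 0.015,
        }
    )
    antibiotic_weights: dict[str, float] = Field(
        default={
            "J01CR05": 0.372,
            "J01DH02": 0.137,
            "J01XA01": 0.117,
            "J01DD04": 0.090,
            "J01CR02": 0.070,
            "J01MA02": 0.060,
            "J01DC02": 0.050,
            "J01XX08": 0.040,
            "J01FA10": 0.030,
            "J01EE01": 0.020,
            "J01GB03": 0.014,
        }
    )


class PCBlock(BaseModel):
    prevalence: float = 0.0076
    p_prostatectomy: float = 0.2007
    p_relapse_given_surgery: float = 0.0556
    p_persistence_given_relapse: float = 1 / 3
    p_radiation: float = 0.10
    p_adt: float = 0.05


class SynthConfig(BaseModel):
    """Full generator configuration; ``seed`` is mandatory."""

    n_patients: int = Field(gt=0)
    seed: int
    year: int = 2022
    diabetes: DiabetesBlock = Field(default_factory=DiabetesBlock)
    mi: MIBlock = Field(default_factory=MIBlock)
    stroke: StrokeBlock = Field(default_factory=StrokeBlock)
    sepsis: SepsisBlock = Field(default_factory=SepsisBlock)
    pc: PCBlock = Field(default_factory=PCBlock)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


class GroundTruth:
    """Planted per-patient labels, keyed by patient id."""

    def __init__(self):
        self.rows: dict[str, dict] = {}

    def set(self, pid: str, **labels) -> None:
        self.rows.setdefault(pid, {"patient_id": pid}).update(labels)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.rows.values(), key=lambda r: r["patient_id"]))

    def count(self, column: str, value=True) -> int:
        return sum(1 for r in self.rows.values() if r.get(column) == value)

    def write_csv(self, path: Union[str, Path]) -> None:
        self.frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _iso(dt: datetime) -> str:
    return dt.isoformat()


def _categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    weights = np.asarray([probs[k] for k in names], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def generate_corpus(config: SynthConfig) -> tuple[list[ResourceEnvelope], GroundTruth]:
    """Generate a reference-closed corpus plus its ground truth.

    Identical configs (seed included) produce identical corpora.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(6)
    rng_base, rng_dm, rng_mi, rng_sk, rng_sep, rng_pc = (
        np.random.default_rng(s) for s in streams
    )
    year0 = datetime(config.year, 1, 1, tzinfo=UTC)
    truth = GroundTruth()
    out: list[dict] = []
    n = config.n_patients
    pids = [f"g-p{i:05d}" for i in range(n)]

    # base population: demographics + one inpatient encounter in the year
    admit_days = rng_base.integers(0, 360, size=n)
    genders = rng_base.choice(["female", "male"], size=n)
    birth_years = rng_base.integers(1930, 2000, size=n)
    admissions: list[datetime] = []
    for i, pid in enumerate(pids):
        out.append(b.patient(pid, gender=str(genders[i]), birth_date=f"{birth_years[i]}-06-15"))
        admit = year0 + timedelta(days=int(admit_days[i]), hours=8)
        admissions.append(admit)
        out.append(b.encounter(f"g-e{i:05d}", pid, _iso(admit), _iso(admit + timedelta(days=7))))
        truth.set(pid, admit=_iso(admit))

    _gen_diabetes(config.diabetes, rng_dm, pids, admissions, out, truth)
    _gen_mi(config.mi, rng_mi, pids, admissions, out, truth)
    _gen_stroke(config.stroke, rng_sk, pids, admissions, out, truth)
    _gen_sepsis(config.sepsis, rng_sep, pids, admissions, out, truth)
    _gen_pc(config.pc, rng_pc, pids, out, truth)

    envelopes = [parse_resource(tree) for tree in out]
    return envelopes, truth


def write_corpus(
    config: SynthConfig, outdir: Union[str, Path]
) -> tuple[Path, Path, Path]:
    """Generate and write corpus NDJSON + ground-truth CSV + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    envelopes, truth = generate_corpus(config)
    corpus_path = outdir / "corpus.ndjson"
    truth_path = outdir / "ground_truth.csv"
    config_path = outdir / "synth_config.yaml"
    write_ndjson(envelopes, corpus_path)
    truth.write_csv(truth_path)
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
    return corpus_path, truth_path, config_path


# -- block generators --------------------------------------------------------

def _clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _gen_diabetes(
    blk: DiabetesBlock,
    rng: np.random.Generator,
    pids: list[str],
    admissions: list[datetime],
    out: list[dict],
    truth: GroundTruth,
) -> None:
    oid = 0
    for i, pid in enumerate(pids):
        group = _categorical(rng, blk.group_probs)
        admit = admissions[i]
        n_glu = max(1, int(rng.poisson(blk.glucose_readings_mean)))
        source = None
        # baseline glucose course per group; peaks planted where the group
        # demands a threshold crossing (guard band >= 5 mg/dL everywhere)
        if group == "normal":
            glu = _clipped_normal(rng, 103.0, 12.0, 60.0, 134.0, n_glu)
            a1c = rng.uniform(4.8, 5.6) if rng.random() < blk.hba1c_prob else None
        elif group == "hyperglycemia":
            glu = _clipped_normal(rng, 106.0, 12.0, 60.0, 134.0, n_glu)
            glu[int(rng.integers(0, n_glu))] = rng.uniform(146.0, 194.0)
            a1c = rng.uniform(4.8, 5.6) if rng.random() < blk.hba1c_prob else None
        elif group == "prediabetes":
            glu = _clipped_normal(rng, 128.0, 6.0, 60.0, 134.0, n_glu)
            a1c = rng.uniform(5.75, 6.45)
        else:  # diabetes
            source = _categorical(rng, blk.diabetes_source_probs)
            if source in ("glucose", "both"):
                glu = _clipped_normal(rng, 160.0, 25.0, 60.0, 194.0, n_glu)
                glu[int(rng.integers(0, n_glu))] = rng.uniform(206.0, 350.0)
            else:
                glu = _clipped_normal(rng, 110.0, 10.0, 60.0, 134.0, n_glu)
            if source in ("hba1c", "both"):
                a1c = rng.uniform(6.6, 9.5)
            else:
                a1c = rng.uniform(4.8, 5.6) if rng.random() < blk.hba1c_prob else None
        for v in glu:
            when = admit + timedelta(hours=float(rng.uniform(0, 144)))
            out.append(
                b.observation_quantity(
                    f"g-dmg{oid:06d}", pid, "2345-7", round(float(v), 1), "mg/dL", _iso(when)
                )
            )
            oid += 1
        if a1c is not None:
            out.append(
                b.observation_quantity(
                    f"g-dmh{oid:06d}", pid, "4548-4", round(float(a1c), 2), "%",
                    _iso(admit + timedelta(hours=4)),
                )
            )
            oid += 1
        dys = group != "normal"
        coded = bool(dys and rng.random() < blk.coded_prob)
        if coded:
            out.append(
                b.condition(f"g-dmc{oid:06d}", pid, "E11.9", _iso(admit + timedelta(days=1)))
            )
            oid += 1
        truth.set(
            pid,
            glycemic_group=group,
            diabetes_source=source,
            dysglycemic=dys,
            diabetes=group == "diabetes",
            dm_coded=coded,
        )


def _gen_mi(
    blk: MIBlock,
    rng: np.random.Generator,
    pids: list[str],
    admissions: list[datetime],
    out: list[dict],
    truth: GroundTruth,
) -> None:
    k = 0
    for i, pid in enumerate(pids):
        has_mi = rng.random() < blk.prevalence
        truth.set(pid, mi=has_mi)
        if not has_mi:
            continue
        admit = admissions[i]
        stemi = rng.random() < blk.p_stemi
        intervention = rng.random() < blk.p_intervention
        icd = "I21.0" if stemi else "I21.4"
        out.append(b.condition(f"g-mic{k:05d}", pid, icd, _iso(admit)))
        if intervention:
            out.append(
                b.procedure(f"g-mip{k:05d}", pid, "8-837", _iso(admit + timedelta(hours=3)))
            )
        in_denom = stemi or intervention
        combo = _categorical(rng, blk.combo_probs)
        ap = combo in ("both", "ap_only")
        statin = combo in ("both", "statin_only")
        t = _iso(admit + timedelta(hours=6))
        m = 0
        if ap:
            out.append(b.medication_administration(f"g-mim{k:05d}-{m}", pid, "B01AC06", t)); m += 1
            if rng.random() < blk.p_dual_given_ap:
                out.append(b.medication_administration(f"g-mim{k:05d}-{m}", pid, "B01AC04", t)); m += 1
        if statin:
            out.append(b.medication_administration(f"g-mim{k:05d}-{m}", pid, "C10AA01", t)); m += 1
            if rng.random() < blk.p_ezetimibe_given_statin:
                out.append(b.medication_administration(f"g-mim{k:05d}-{m}", pid, "C10AX09", t)); m += 1
        if rng.random() < blk.p_anticoagulant:
            out.append(b.medication_administration(f"g-mim{k:05d}-{m}", pid, "B01AA03", t)); m += 1
        truth.set(
            pid,
            mi_denominator=in_denom,
            mi_stemi=stemi,
            mi_intervention=intervention,
            mi_antiplatelet=ap,
            mi_statin=statin,
            mi_adherent=ap or statin,
        )
        k += 1


def _gen_stroke(
    blk: StrokeBlock,
    rng: np.random.Generator,
    pids: list[str],
    admissions: list[datetime],
    out: list[dict],
    truth: GroundTruth,
) -> None:
    guard = blk.guard_band_minutes
    k = 0
    for i, pid in enumerate(pids):
        has = rng.random() < blk.prevalence
        truth.set(pid, stroke=has)
        if not has:
            continue
        admit = admissions[i]
        ischemic = rng.random() < blk.ischemic_frac
        out.append(
            b.condition(f"g-skc{k:05d}", pid, "I63.5" if ischemic else "I61.9", _iso(admit))
        )
        lysis = ischemic and rng.random() < blk.p_lysis
        thrombectomy = ischemic and rng.random() < blk.p_thrombectomy
        onset = admit - timedelta(minutes=float(rng.uniform(30, 240)))
        therapy_times = {}
        if lysis:
            within = rng.random() < blk.needle_within_prob
            minutes = rng.uniform(15, 60 - guard) if within else rng.uniform(60 + guard, 200)
            therapy_times["lysis"] = admit + timedelta(minutes=float(minutes))
            out.append(
                b.procedure(f"g-skl{k:05d}", pid, "8-020.8", _iso(therapy_times["lysis"]))
            )
            truth.set(pid, lysis_within=bool(within))
        if thrombectomy:
            within = rng.random() < blk.groin_within_prob
            minutes = rng.uniform(30, 90 - guard) if within else rng.uniform(90 + guard, 260)
            therapy_times["thrombectomy"] = admit + timedelta(minutes=float(minutes))
            out.append(
                b.procedure(f"g-skt{k:05d}", pid, "8-836.80", _iso(therapy_times["thrombectomy"]))
            )
            truth.set(pid, groin_within=bool(within))
        if lysis or thrombectomy:
            out.append(b.observation_marker(f"g-sko{k:05d}", pid, "symptom-onset", _iso(onset)))
            baseline = float(rng.integers(4, 21))
            out.append(
                b.observation_quantity(
                    f"g-sknb{k:05d}", pid, "70182-1", baseline, "{score}",
                    _iso(admit + timedelta(hours=1)),
                )
            )
            eni_probs = blk.eni_probs_thrombectomy if thrombectomy else blk.eni_probs_lysis
            if rng.random() < blk.p_no_followup:
                truth.set(pid, eni_class="missing")
            else:
                cls = _categorical(rng, eni_probs)
                delta = {"decrease": -1, "no_change": 0, "increase": 1}[cls] * float(
                    rng.integers(1, 4)
                )
                out.append(
                    b.observation_quantity(
                        f"g-sknf{k:05d}", pid, "70182-1", max(0.0, baseline + delta), "{score}",
                        _iso(admit + timedelta(hours=25)),
                    )
                )
                marker = thrombectomy and rng.random() < blk.p_weaning_marker
                if marker:
                    out.append(
                        b.observation_marker(
                            f"g-skx{k:05d}", pid, "eni-exclusion", _iso(admit + timedelta(hours=26))
                        )
                    )
                truth.set(pid, eni_class="excluded" if marker else cls)
        truth.set(pid, stroke_lysis=lysis, stroke_thrombectomy=thrombectomy)
        k += 1


def _gen_sepsis(
    blk: SepsisBlock,
    rng: np.random.Generator,
    pids: list[str],
    admissions: list[datetime],
    out: list[dict],
    truth: GroundTruth,
) -> None:
    k = 0
    for i, pid in enumerate(pids):
        has = rng.random() < blk.prevalence
        truth.set(pid, sepsis=has)
        if not has:
            continue
        admit = admissions[i]
        out.append(b.condition(f"g-sepc{k:05d}", pid, "A41.9", _iso(admit)))
        n_iso = int(rng.poisson(blk.isolates_per_patient))
        for j in range(n_iso):
            organism = _categorical(rng, blk.organism_weights)
            out.append(
                b.diagnostic_report(
                    f"g-sepd{k:05d}-{j}", pid, "600-7",
                    _iso(admit + timedelta(hours=6 + 24 * j)), conclusion=organism,
                )
            )
        n_rx = int(rng.poisson(blk.prescriptions_per_patient))
        for j in range(n_rx):
            atc = _categorical(rng, blk.antibiotic_weights)
            start = admit + timedelta(hours=8 + 24 * j)
            out.append(
                b.medication_administration(
                    f"g-sepm{k:05d}-{j}", pid, atc, _iso(start), _iso(start + timedelta(days=5))
                )
            )
        for j in range(3):
            out.append(
                b.observation_quantity(
                    f"g-sepcrp{k:05d}-{j}", pid, "1988-5",
                    round(float(rng.uniform(5, 300)), 1), "mg/L",
                    _iso(admit + timedelta(days=j)),
                )
            )
            out.append(
                b.observation_quantity(
                    f"g-seppct{k:05d}-{j}", pid, "33959-8",
                    round(float(rng.uniform(0.1, 50)), 2), "ng/mL",
                    _iso(admit + timedelta(days=j)),
                )
            )
        truth.set(pid, sepsis_isolates=n_iso, sepsis_prescriptions=n_rx)
        k += 1


def _gen_pc(
    blk: PCBlock,
    rng: np.random.Generator,
    pids: list[str],
    out: list[dict],
    truth: GroundTruth,
) -> None:
    # PC uses its own diagnosis year (the year before the study period) with
    # treatments spilling into the study year.
    k = 0
    for pid in pids:
        has = rng.random() < blk.prevalence
        truth.set(pid, pc=has)
        if not has:
            continue
        diag = datetime(2021, 1, 1, tzinfo=UTC) + timedelta(days=int(rng.integers(0, 330)))
        out.append(b.condition(f"g-pcc{k:04d}", pid, "C61", _iso(diag)))
        out.append(
            b.observation_string(
                f"g-pctnm{k:04d}", pid, "tnm-stage",
                str(rng.choice(["T1N0M0", "T2N0M0", "T3N0M0", "T3N1M0"])), _iso(diag),
            )
        )
        out.append(
            b.observation_quantity(
                f"g-pcisup{k:04d}", pid, "isup-grade", float(rng.integers(1, 6)), "{grade}",
                _iso(diag), system=b.LOCAL_SYSTEM,
            )
        )
        out.append(
            b.observation_quantity(
                f"g-pcpsa0-{k:04d}", pid, "2857-1", round(float(rng.uniform(4, 30)), 1),
                "ng/mL", _iso(diag),
            )
        )
        surgery = rng.random() < blk.p_prostatectomy
        flag = None
        if surgery:
            surg_at = diag + timedelta(days=int(rng.integers(30, 120)))
            out.append(b.procedure(f"g-pcs{k:04d}", pid, "5-604", _iso(surg_at)))
            out.append(
                b.observation_string(
                    f"g-pcm{k:04d}", pid, "resection-margin",
                    str(rng.choice(["R0", "R1"], p=[0.8, 0.2])), _iso(surg_at),
                )
            )
            relapse = rng.random() < blk.p_relapse_given_surgery
            if relapse:
                if rng.random() < blk.p_persistence_given_relapse:
                    flag = "persistence"
                    series = [rng.uniform(0.12, 0.5), rng.uniform(0.12, 0.6)]
                else:
                    flag = "recurrence"
                    low = rng.uniform(0.01, 0.08)
                    series = [low, rng.uniform(0.22, 0.5), rng.uniform(0.5, 1.5)]
            else:
                flag = "none"
                series = [rng.uniform(0.01, 0.08) for _ in range(2)]
            for j, v in enumerate(series):
                out.append(
                    b.observation_quantity(
                        f"g-pcpsa{j + 1}-{k:04d}", pid, "2857-1", round(float(v), 3), "ng/mL",
                        _iso(surg_at + timedelta(days=60 + 110 * j)),
                    )
                )
            therapy = "surgery"
        elif rng.random() < blk.p_radiation:
            out.append(
                b.procedure(f"g-pcr{k:04d}", pid, "8-52", _iso(diag + timedelta(days=60)))
            )
            therapy = "radiation"
        elif rng.random() < blk.p_adt:
            out.append(
                b.medication_administration(
                    f"g-pca{k:04d}", pid, "L02AE02", _iso(diag + timedelta(days=30))
                )
            )
            therapy = "systemic"
        else:
            therapy = "active_surveillance"
        truth.set(pid, pc_therapy=therapy, pc_flag=flag)
        k += 1
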