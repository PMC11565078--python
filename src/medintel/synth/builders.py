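"""Raw-JSON builders for synthetic FHIR resources.

All corpora produced by this package go through these helpers, so every
generated resource is reference-closed by construction (ids are handed in
explicitly) and timestamps always carry an explicit UTC offset.
"""

from __future__ import annotations

from typing import Optional, Sequence

ICD_SYSTEM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
LOINC_SYSTEM = "http://loinc.org"
ATC_SYSTEM = "http://www.whocc.no/atc"
OPS_SYSTEM = "http://fhir.de/CodeSystem/bfarm/ops"
LOCAL_SYSTEM = "http://medintel.example/codes"


def codeable(system: str, code: str, display: Optional[str] = None) -> dict:
    coding: dict = {"system": system, "code": code}
    if display is not None:
        coding["display"] = display
    return {"coding": [coding]}


def patient(pid: str, gender: str = "unknown", birth_date: str = "1960-01-01") -> dict:
    return {"resourceType": "Patient", "id": pid, "gender": gender, "birthDate": birth_date}


def encounter(eid: str, pid: str, start: str, end: Optional[str] = None) -> dict:
    period: dict = {"start": start}
    if end is not None:
        period["end"] = end
    return {
        "resourceType": "Encounter",
        "id": eid,
        "subject": {"reference": f"Patient/{pid}"},
        "period": period,
    }


def condition(
    cid: str, pid: str, icd_code: str, recorded: str, system: str = ICD_SYSTEM
) -> dict:
    return {
        "resourceType": "Condition",
        "id": cid,
        "code": codeable(system, icd_code),
        "subject": {"reference": f"Patient/{pid}"},
        "recordedDate": recorded,
    }


def observation_quantity(
    oid: str,
    pid: str,
    code: str,
    value: float,
    unit: str,
    effective: str,
    system: str = LOINC_SYSTEM,
    ucum: Optional[str] = None,
) -> dict:
    vq: dict = {"value": value, "unit": unit}
    vq["code"] = ucum if ucum is not None else unit
    return {
        "resourceType": "Observation",
        "id": oid,
        "code": codeable(system, code),
        "subject": {"reference": f"Patient/{pid}"},
        "effectiveDateTime": effective,
        "valueQuantity": vq,
    }


def observation_string(
    oid: str, pid: str, code: str, value: str, effective: str, system: str = LOCAL_SYSTEM
) -> dict:
    return {
        "resourceType": "Observation",
        "id": oid,
        "code": codeable(system, code),
        "subject": {"reference": f"Patient/{pid}"},
        "effectiveDateTime": effective,
        "valueString": value,
    }


def observation_marker(
    oid: str, pid: str, code: str, effective: str, system: str = LOCAL_SYSTEM
) -> dict:
    """Code-only observation whose *effective time* is the payload (e.g. a
    symptom-onset instant) or that acts as a boolean marker."""
    return {
        "resourceType": "Observation",
        "id": oid,
        "code": codeable(system, code),
        "subject": {"reference": f"Patient/{pid}"},
        "effectiveDateTime": effective,
    }


def procedure(
    prid: str, pid: str, code: str, performed: str, system: str = OPS_SYSTEM
) -> dict:
    return {
        "resourceType": "Procedure",
        "id": prid,
        "code": codeable(system, code),
        "subject": {"reference": f"Patient/{pid}"},
        "performedDateTime": performed,
    }


def medication_administration(
    mid: str,
    pid: str,
    atc_code: str,
    start: str,
    end: Optional[str] = None,
    system: str = ATC_SYSTEM,
) -> dict:
    out: dict = {
        "resourceType": "MedicationAdministration",
        "id": mid,
        "medicationCodeableConcept": codeable(system, atc_code),
        "subject": {"reference": f"Patient/{pid}"},
    }
    if end is None:
        out["effectiveDateTime"] = start
    else:
        out["effectivePeriod"] = {"start": start, "end": end}
    return out


def diagnostic_report(
    did: str,
    pid: str,
    code: str,
    issued: str,
    conclusion: Optional[str] = None,
    results: Sequence[str] = (),
    system: str = LOINC_SYSTEM,
) -> dict:
    out: dict = {
        "resourceType": "DiagnosticReport",
        "id": did,
        "code": codeable(system, code),
        "subject": {"reference": f"Patient/{pid}"},
        "issued": issued,
    }
    if conclusion is not None:
        out["conclusion"] = conclusion
    if results:
        out["result"] = [{"reference": r} for r in results]
    return out
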