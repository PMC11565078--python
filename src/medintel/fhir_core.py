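"""Typed data model for the FHIR R4 resource subset used by the pipelines.

Seven clinical resource types (Patient, Encounter, Condition, Observation,
Procedure, MedicationAdministration, DiagnosticReport) get typed variants;
any other ``resourceType`` is kept as a generic envelope.  Parsing is total:
for an arbitrary JSON object the result is either a validated
:class:`ResourceEnvelope` or a structured error — never an uncontrolled
exception.  The original JSON tree rides along in the envelope, so
serialization is lossless even for members the typed layer ignores
(extensions, profiles, narrative).

Choice fields (``effectiveDateTime`` vs ``effectivePeriod``,
``performedDateTime`` vs ``performedPeriod``) normalize to a
``(start, end)`` pair; a point instant has ``start == end``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Iterable, Iterator, Optional, Union

from .errors import FieldValidationError, MedIntelError, NdjsonLineError, StructuralError
from .timeutil import Instant, parse_date, parse_instant

log = logging.getLogger(__name__)

TYPED_RESOURCE_TYPES = (
    "Patient",
    "Encounter",
    "Condition",
    "Observation",
    "Procedure",
    "MedicationAdministration",
    "DiagnosticReport",
)


# ---------------------------------------------------------------------------
# element types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coding:
    """One entry of a terminology binding; matching identity is (system, code)."""

    system: str = ""
    code: str = ""
    display: Optional[str] = None

    def matches(self, system: Optional[str], code_or_prefix: str, prefix: bool = False) -> bool:
        """Token match against a filter; ``system=None`` matches any system."""
        if not self.code:
            return False
        if system is not None and self.system != system:
            return False
        if prefix:
            return self.code.startswith(code_or_prefix)
        return self.code == code_or_prefix

    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


@dataclass(frozen=True)
class CodeableConcept:
    """An ordered list of codings plus optional free text.

    An empty concept (no codings) is legal and matches no code filter.
    """

    codings: tuple[Coding, ...] = ()
    text: Optional[str] = None

    def matches(self, system: Optional[str], code_or_prefix: str, prefix: bool = False) -> bool:
        return any(c.matches(system, code_or_prefix, prefix) for c in self.codings)

    def first_code(self, system: Optional[str] = None) -> Optional[str]:
        for c in self.codings:
            if system is None or c.system == system:
                return c.code
        return None


# glucose molar mass convention: 1 mmol/L = 18.016 mg/dL
MGDL_PER_MMOLL_GLUCOSE = 18.016

_UCUM_MGDL = "mg/dL"
_UCUM_MMOLL = "mmol/L"


@dataclass(frozen=True)
class Quantity:
    """A measured amount.  ``ucum_code``, when present, is the comparison key
    for units; otherwise the display ``unit`` string is matched verbatim."""

    value: float
    unit: str = ""
    ucum_code: Optional[str] = None

    def unit_key(self) -> str:
        return self.ucum_code if self.ucum_code else self.unit

    def as_mgdl_glucose(self) -> float:
        """Value in mg/dL, converting from mmol/L when so labelled."""
        if self.unit_key() == _UCUM_MMOLL:
            return self.value * MGDL_PER_MMOLL_GLUCOSE
        return self.value


@dataclass(frozen=True)
class Reference:
    """A ``ResourceType/id`` pointer.  Parsing never resolves: dangling
    references are representable and resolution belongs to the store."""

    reference: str

    def parts(self) -> tuple[str, str]:
        if "/" not in self.reference:
            raise FieldValidationError("reference", f"not of form Type/id: {self.reference!r}")
        rtype, _, rid = self.reference.partition("/")
        if not rtype or not rid:
            raise FieldValidationError("reference", f"not of form Type/id: {self.reference!r}")
        return rtype, rid

    @property
    def target_type(self) -> str:
        return self.parts()[0]

    @property
    def target_id(self) -> str:
        return self.parts()[1]


Period = tuple[Instant, Optional[Instant]]  # normalized (start, end); point => start == end


# ---------------------------------------------------------------------------
# resource variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FhirResource:
    resourceType: str
    id: str


@dataclass(frozen=True)
class Patient(FhirResource):
    birthDate: Optional[date] = None
    gender: Optional[str] = None


@dataclass(frozen=True)
class Encounter(FhirResource):
    subject: Optional[Reference] = None
    period: Optional[Period] = None


@dataclass(frozen=True)
class Condition(FhirResource):
    code: CodeableConcept = field(default_factory=CodeableConcept)
    subject: Optional[Reference] = None
    recordedDate: Optional[Instant] = None
    encounter: Optional[Reference] = None


@dataclass(frozen=True)
class Observation(FhirResource):
    code: CodeableConcept = field(default_factory=CodeableConcept)
    subject: Optional[Reference] = None
    effective: Optional[Period] = None
    value: Union[Quantity, str, None] = None
    encounter: Optional[Reference] = None


@dataclass(frozen=True)
class Procedure(FhirResource):
    code: CodeableConcept = field(default_factory=CodeableConcept)
    subject: Optional[Reference] = None
    performed: Optional[Period] = None


@dataclass(frozen=True)
class MedicationAdministration(FhirResource):
    medication: CodeableConcept = field(default_factory=CodeableConcept)
    subject: Optional[Reference] = None
    effective: Optional[Period] = None


@dataclass(frozen=True)
class DiagnosticReport(FhirResource):
    code: CodeableConcept = field(default_factory=CodeableConcept)
    subject: Optional[Reference] = None
    issued: Optional[Instant] = None
    results: tuple[Reference, ...] = ()
    conclusion: Optional[str] = None


@dataclass(frozen=True)
class GenericResource(FhirResource):
    """Envelope-only variant for resource types outside the supported set."""


@dataclass(frozen=True)
class ResourceEnvelope:
    """The typed view of a resource plus the original JSON tree.

    ``raw`` is the authority for serialization (lossless round-trip);
    ``typed`` is the authority for analytics.
    """

    typed: FhirResource
    raw: dict

    @property
    def resource_type(self) -> str:
        return self.typed.resourceType

    @property
    def id(self) -> str:
        return self.typed.id

    @property
    def key(self) -> tuple[str, str]:
        return (self.typed.resourceType, self.typed.id)

    def subject_id(self) -> Optional[str]:
        """Patient id of the subject reference, if this resource has one."""
        subj = getattr(self.typed, "subject", None)
        if subj is None:
            return None
        try:
            rtype, rid = subj.parts()
        except FieldValidationError:
            return None
        return rid if rtype == "Patient" else None

    def period(self) -> Optional[Period]:
        """Normalized temporal extent used by date search and cohort windows."""
        t = self.typed
        if isinstance(t, (Observation, MedicationAdministration)):
            return t.effective
        if isinstance(t, Procedure):
            return t.performed
        if isinstance(t, Encounter):
            return t.period
        if isinstance(t, Condition):
            return (t.recordedDate, t.recordedDate) if t.recordedDate else None
        if isinstance(t, DiagnosticReport):
            return (t.issued, t.issued) if t.issued else None
        return None

    def code_concept(self) -> Optional[CodeableConcept]:
        t = self.typed
        if isinstance(t, MedicationAdministration):
            return t.medication
        return getattr(t, "code", None)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _req_str(tree: dict, member: str, path: str) -> str:
    v = tree.get(member)
    if not isinstance(v, str) or not v:
        raise FieldValidationError(f"{path}{member}", f"missing or non-string: {v!r}")
    return v


def _opt_str(tree: dict, member: str, path: str) -> Optional[str]:
    v = tree.get(member)
    if v is None:
        return None
    if not isinstance(v, str):
        raise FieldValidationError(f"{path}{member}", f"expected string, got {type(v).__name__}")
    return v


def _parse_coding(tree: Any, path: str) -> Coding:
    if not isinstance(tree, dict):
        raise FieldValidationError(path, f"expected object, got {type(tree).__name__}")
    return Coding(
        system=_opt_str(tree, "system", path + ".") or "",
        code=_opt_str(tree, "code", path + ".") or "",
        display=_opt_str(tree, "display", path + "."),
    )


def _parse_concept(tree: Any, path: str) -> CodeableConcept:
    if tree is None:
        return CodeableConcept()
    if not isinstance(tree, dict):
        raise FieldValidationError(path, f"expected object, got {type(tree).__name__}")
    codings_tree = tree.get("coding", [])
    if not isinstance(codings_tree, list):
        raise FieldValidationError(path + ".coding", "expected array")
    codings = tuple(
        _parse_coding(c, f"{path}.coding[{i}]") for i, c in enumerate(codings_tree)
    )
    return CodeableConcept(codings=codings, text=_opt_str(tree, "text", path + "."))


def _parse_quantity(tree: Any, path: str) -> Quantity:
    if not isinstance(tree, dict):
        raise FieldValidationError(path, f"expected object, got {type(tree).__name__}")
    v = tree.get("value")
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise FieldValidationError(path + ".value", f"expected number, got {v!r}")
    if not math.isfinite(v):
        raise FieldValidationError(path + ".value", f"non-finite value {v!r}")
    return Quantity(
        value=float(v),
        unit=_opt_str(tree, "unit", path + ".") or "",
        ucum_code=_opt_str(tree, "code", path + "."),
    )


def _parse_reference(tree: Any, path: str) -> Optional[Reference]:
    if tree is None:
        return None
    if not isinstance(tree, dict):
        raise FieldValidationError(path, f"expected object, got {type(tree).__name__}")
    ref = tree.get("reference")
    if ref is None:
        return None
    if not isinstance(ref, str):
        raise FieldValidationError(path + ".reference", "expected string")
    return Reference(ref)


def _parse_choice_period(tree: dict, stem: str, path: str) -> Optional[Period]:
    """Normalize ``<stem>DateTime`` / ``<stem>Period`` to (start, end)."""
    dt = tree.get(stem + "DateTime")
    if dt is not None:
        at = parse_instant(dt, f"{path}{stem}DateTime")
        return (at, at)
    per = tree.get(stem + "Period")
    if per is not None:
        return _parse_period(per, f"{path}{stem}Period")
    return None


def _parse_period(tree: Any, path: str) -> Optional[Period]:
    if tree is None:
        return None
    if not isinstance(tree, dict):
        raise FieldValidationError(path, f"expected object, got {type(tree).__name__}")
    start_s, end_s = tree.get("start"), tree.get("end")
    if start_s is None and end_s is None:
        return None
    start = parse_instant(start_s, path + ".start") if start_s is not None else None
    end = parse_instant(end_s, path + ".end") if end_s is not None else None
    if start is None:
        start = end  # open-start period: collapse to the known endpoint
    return (start, end)


def _parse_patient(tree: dict, rid: str) -> Patient:
    bd = tree.get("birthDate")
    return Patient(
        resourceType="Patient",
        id=rid,
        birthDate=parse_date(bd, "birthDate") if bd is not None else None,
        gender=_opt_str(tree, "gender", ""),
    )


def _parse_encounter(tree: dict, rid: str) -> Encounter:
    return Encounter(
        resourceType="Encounter",
        id=rid,
        subject=_parse_reference(tree.get("subject"), "subject"),
        period=_parse_period(tree.get("period"), "period"),
    )


def _parse_condition(tree: dict, rid: str) -> Condition:
    rd = tree.get("recordedDate")
    return Condition(
        resourceType="Condition",
        id=rid,
        code=_parse_concept(tree.get("code"), "code"),
        subject=_parse_reference(tree.get("subject"), "subject"),
        recordedDate=parse_instant(rd, "recordedDate") if rd is not None else None,
        encounter=_parse_reference(tree.get("encounter"), "encounter"),
    )


def _parse_observation(tree: dict, rid: str) -> Observation:
    value: Union[Quantity, str, None] = None
    if "valueQuantity" in tree:
        value = _parse_quantity(tree["valueQuantity"], "valueQuantity")
    elif "valueString" in tree:
        vs = tree["valueString"]
        if not isinstance(vs, str):
            raise FieldValidationError("valueString", "expected string")
        value = vs
    return Observation(
        resourceType="Observation",
        id=rid,
        code=_parse_concept(tree.get("code"), "code"),
        subject=_parse_reference(tree.get("subject"), "subject"),
        effective=_parse_choice_period(tree, "effective", ""),
        value=value,
        encounter=_parse_reference(tree.get("encounter"), "encounter"),
    )


def _parse_procedure(tree: dict, rid: str) -> Procedure:
    return Procedure(
        resourceType="Procedure",
        id=rid,
        code=_parse_concept(tree.get("code"), "code"),
        subject=_parse_reference(tree.get("subject"), "subject"),
        performed=_parse_choice_period(tree, "performed", ""),
    )


def _parse_medadmin(tree: dict, rid: str) -> MedicationAdministration:
    return MedicationAdministration(
        resourceType="MedicationAdministration",
        id=rid,
        medication=_parse_concept(tree.get("medicationCodeableConcept"), "medicationCodeableConcept"),
        subject=_parse_reference(tree.get("subject"), "subject"),
        effective=_parse_choice_period(tree, "effective", ""),
    )


def _parse_diagreport(tree: dict, rid: str) -> DiagnosticReport:
    issued = tree.get("issued")
    results_tree = tree.get("result", [])
    if not isinstance(results_tree, list):
        raise FieldValidationError("result", "expected array")
    results = []
    for i, r in enumerate(results_tree):
        ref = _parse_reference(r, f"result[{i}]")
        if ref is not None:
            results.append(ref)
    return DiagnosticReport(
        resourceType="DiagnosticReport",
        id=rid,
        code=_parse_concept(tree.get("code"), "code"),
        subject=_parse_reference(tree.get("subject"), "subject"),
        issued=parse_instant(issued, "issued") if issued is not None else None,
        results=tuple(results),
        conclusion=_opt_str(tree, "conclusion", ""),
    )


_VARIANT_PARSERS = {
    "Patient": _parse_patient,
    "Encounter": _parse_encounter,
    "Condition": _parse_condition,
    "Observation": _parse_observation,
    "Procedure": _parse_procedure,
    "MedicationAdministration": _parse_medadmin,
    "DiagnosticReport": _parse_diagreport,
}


def parse_resource(json_tree: Any) -> ResourceEnvelope:
    """Parse one JSON object into a validated :class:`ResourceEnvelope`.

    Raises :class:`StructuralError` if the tree is not an object or lacks
    ``resourceType``, and :class:`FieldValidationError` (with the offending
    path) for malformed fields.  Any other outcome is a valid envelope;
    unsupported resource types get a :class:`GenericResource` typed view.
    """
    if not isinstance(json_tree, dict):
        raise StructuralError(f"resource must be a JSON object, got {type(json_tree).__name__}")
    rtype = json_tree.get("resourceType")
    if not isinstance(rtype, str) or not rtype:
        raise StructuralError("missing resourceType")
    rid = json_tree.get("id")
    if rid is None:
        rid = ""
    elif not isinstance(rid, str):
        raise FieldValidationError("id", f"expected string, got {type(rid).__name__}")
    parser = _VARIANT_PARSERS.get(rtype)
    if parser is None:
        return ResourceEnvelope(GenericResource(resourceType=rtype, id=rid), json_tree)
    try:
        typed = parser(json_tree, rid)
    except MedIntelError:
        raise
    except Exception as exc:  # defensive: totality over arbitrary JSON
        raise FieldValidationError(rtype, f"unexpected structure: {exc}") from exc
    return ResourceEnvelope(typed, json_tree)


def serialize_resource(env: ResourceEnvelope) -> dict:
    """Return the JSON tree of the resource (value-identical to the input)."""
    return env.raw


# ---------------------------------------------------------------------------
# NDJSON / Bundle I/O
# ---------------------------------------------------------------------------

def read_ndjson(
    path: Union[str, Path],
    on_error: str = "raise",
) -> Iterator[ResourceEnvelope]:
    """Stream envelopes from a bulk-export NDJSON file (one resource per line).

    Blank lines are skipped.  ``on_error="raise"`` (default) aborts with an
    :class:`NdjsonLineError` carrying the line number; ``on_error="skip"``
    logs a warning and continues.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                tree = json.loads(line)
                yield parse_resource(tree)
            except (json.JSONDecodeError, MedIntelError) as exc:
                if on_error == "skip":
                    log.warning("skipping %s line %d: %s", path, line_no, exc)
                    continue
                raise NdjsonLineError(line_no, exc) from exc


def write_ndjson(envelopes: Iterable[ResourceEnvelope], path: Union[str, Path]) -> int:
    """Write envelopes as compact NDJSON; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for env in envelopes:
            fh.write(json.dumps(serialize_resource(env), separators=(",", ":"), sort_keys=False))
            fh.write("\n")
            n += 1
    return n


def read_bundle(path: Union[str, Path]) -> Iterator[ResourceEnvelope]:
    """Unwrap ``entry[].resource`` of a JSON Bundle (collection/searchset)."""
    with open(path, "r", encoding="utf-8") as fh:
        tree = json.load(fh)
    if not isinstance(tree, dict) or tree.get("resourceType") != "Bundle":
        raise StructuralError(f"{path}: not a FHIR Bundle")
    for entry in tree.get("entry", []) or []:
        res = entry.get("resource") if isinstance(entry, dict) else None
        if res is not None:
            yield parse_resource(res)


def read_source(path: Union[str, Path]) -> Iterator[ResourceEnvelope]:
    """Read either an NDJSON corpus or a JSON Bundle, sniffing the format."""
    p = Path(path)
    with open(p, "r", encoding="utf-8") as fh:
        head = fh.read(4096).lstrip()
    if head.startswith("{") and '"Bundle"' in head[:200]:
        return read_bundle(p)
    return read_ndjson(p)
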