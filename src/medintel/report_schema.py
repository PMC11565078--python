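"""Structural validation of report documents against the shipped schema.

The schema is intentionally small: required top-level members and their JSON
types per use case, enough to catch a pipeline emitting a malformed report.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ConfigError

SCHEMA_PATH = Path(__file__).resolve().parent / "schemas" / "report_schema.json"

_JSON_TYPES = {
    "object": dict,
    "array": list,
    "number": (int, float),
    "string": str,
    "boolean": bool,
}


def load_schema() -> dict:
    with open(SCHEMA_PATH, "r", encoding="utf-8") as fh:
        return json.load(fh)


def validate_report(usecase: str, doc: dict) -> list[str]:
    """Return a list of violations (empty = valid)."""
    schema = load_schema()
    if usecase not in schema:
        raise ConfigError(f"no schema for use case {usecase!r}")
    problems = []
    for member, jtype in schema[usecase].items():
        if member not in doc:
            problems.append(f"missing member {member!r}")
        elif doc[member] is not None and not isinstance(doc[member], _JSON_TYPES[jtype]):
            problems.append(
                f"member {member!r} has type {type(doc[member]).__name__}, expected {jtype}"
            )
    return problems
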