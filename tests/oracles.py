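"""Independent reference implementations used as oracles.

Everything here works on raw JSON trees (or plain Python lists) and shares
no matching/evaluation code with the package, so an agreement test is a
genuine dual-route check.
"""

from __future__ import annotations

from datetime import datetime, timezone
from typing import Any, Optional


# -- naive FHIR search over raw JSON ----------------------------------------

def _raw_timestamp(tree: dict, member: str) -> Optional[str]:
    v = tree.get(member)
    return v if isinstance(v, str) else None


def _raw_period(tree: dict) -> Optional[tuple[str, str]]:
    """Normalized (start, end) ISO strings straight off the raw JSON."""
    rt = tree["resourceType"]
    if rt == "Observation" or rt == "MedicationAdministration":
        dt = _raw_timestamp(tree, "effectiveDateTime")
        if dt:
            return (dt, dt)
        per = tree.get("effectivePeriod") or {}
        s, e = per.get("start"), per.get("end")
        if s or e:
            return (s or e, e or s)
        return None
    if rt == "Procedure":
        dt = _raw_timestamp(tree, "performedDateTime")
        if dt:
            return (dt, dt)
        per = tree.get("performedPeriod") or {}
        s, e = per.get("start"), per.get("end")
        if s or e:
            return (s or e, e or s)
        return None
    if rt == "Encounter":
        per = tree.get("period") or {}
        s, e = per.get("start"), per.get("end")
        if s or e:
            return (s or e, e or s)
        return None
    if rt == "Condition":
        dt = _raw_timestamp(tree, "recordedDate")
        return (dt, dt) if dt else None
    if rt == "DiagnosticReport":
        dt = _raw_timestamp(tree, "issued")
        return (dt, dt) if dt else None
    return None


def _to_utc(iso: str) -> datetime:
    dt = datetime.fromisoformat(iso.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _raw_codings(tree: dict) -> list[dict]:
    concept = (
        tree.get("medicationCodeableConcept")
        if tree["resourceType"] == "MedicationAdministration"
        else tree.get("code")
    )
    if not isinstance(concept, dict):
        return []
    return [c for c in concept.get("coding", []) if isinstance(c, dict)]


def raw_matches_query(tree: dict, q) -> bool:
    """Re-implementation of the search predicate over the raw JSON tree."""
    if tree.get("resourceType") != q.resource_type:
        return False
    if q.subject is not None:
        ref = (tree.get("subject") or {}).get("reference")
        if ref != f"Patient/{q.subject}":
            return False
    for tf in q.token_filters:
        ok = False
        for coding in _raw_codings(tree):
            code = coding.get("code") or ""
            if not code:
                continue
            if tf.system is not None and coding.get("system") != tf.system:
                continue
            if tf.prefix:
                ok = code.startswith(tf.code)
            else:
                ok = code == tf.code
            if ok:
                break
        if not ok:
            return False
    for df in q.date_filters:
        period = _raw_period(tree)
        if period is None:
            return False
        start, end = _to_utc(period[0]), _to_utc(period[1])
        when = df.when.at.astimezone(timezone.utc)
        if df.op == "ge" and not end >= when:
            return False
        if df.op == "gt" and not end > when:
            return False
        if df.op == "le" and not start <= when:
            return False
        if df.op == "lt" and not start < when:
            return False
    return True


def naive_query(raw_trees: list[dict], q) -> list[str]:
    """Sorted ids of raw resources matching the query."""
    return sorted(t.get("id", "") for t in raw_trees if raw_matches_query(t, q))


# -- naive path evaluation ---------------------------------------------------

def naive_walk(tree: Any, steps) -> list[Any]:
    """Recursive re-implementation of path navigation (collection
    semantics), structured differently from the iterative production code."""
    if not steps:
        return [tree] if not isinstance(tree, list) else list(tree)
    step, rest = steps[0], steps[1:]
    nodes = tree if isinstance(tree, list) else [tree]
    if step.kind == "member":
        collected: list[Any] = []
        for node in nodes:
            if isinstance(node, dict) and step.name in node:
                v = node[step.name]
                collected.extend(v if isinstance(v, list) else [v])
        return naive_walk_collection(collected, rest)
    if step.kind == "index":
        if -len(nodes) <= step.index < len(nodes):
            return naive_walk_collection([nodes[step.index]], rest)
        return []
    if step.kind == "where":
        kept = [n for n in nodes if isinstance(n, dict) and n.get("system") == step.system]
        return naive_walk_collection(kept, rest)
    raise AssertionError(step.kind)


def naive_walk_collection(nodes: list[Any], steps) -> list[Any]:
    if not steps:
        return nodes
    return naive_walk(list(nodes), steps)


# -- nested-loop join ---------------------------------------------------------

def naive_join(left_rows: list[dict], right_rows: list[dict], on: str, how: str) -> list[dict]:
    out = []
    for lr in left_rows:
        key = lr.get(on)
        matched = False
        if key is not None and key == key:  # not null/NaN
            for rr in right_rows:
                if rr.get(on) == key:
                    row = dict(lr)
                    for k, v in rr.items():
                        if k != on:
                            row[k if k not in lr else f"{k}_right"] = v
                    out.append(row)
                    matched = True
        if not matched and how == "left":
            out.append(dict(lr))
    return out


# -- PSA flag direct definitions ----------------------------------------------

def brute_force_psa_flags(
    post_op: list[float],
    first_within_window: Optional[float],
    persistence_threshold: float,
    recurrence_threshold: float,
    undetectable_threshold: float,
) -> tuple[bool, bool]:
    """Direct restatement of the flag definitions, scanning all pairs."""
    persistence = (
        first_within_window is not None and first_within_window >= persistence_threshold
    )
    recurrence = False
    for j in range(1, len(post_op)):
        had_nadir = any(post_op[i] < undetectable_threshold for i in range(j))
        rising = post_op[j] > post_op[j - 1]
        crossed = post_op[j] >= recurrence_threshold
        # the nadir itself may be the first of the rising pair
        if had_nadir and rising and crossed:
            recurrence = True
    return persistence, recurrence
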