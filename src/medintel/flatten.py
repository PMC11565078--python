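"""Nested-resource-to-table transformation.

A small path-expression grammar selects values out of FHIR JSON trees and a
set of compiled :class:`PathSpec` columns turns a list of resources into a
rectangular :class:`Frame` (a provenance-tagged pandas DataFrame).  This is
a deliberately minimal tabulation language, not an implementation of the
full FHIRPath specification.

Grammar
-------
::

    path  := member ('.' step)* ('|' mode)?
    step  := member | 'where(system=' URI ')'
    member:= identifier ('[' integer ']')?
    mode  := 'first' | 'join(' separator ')' | 'explode'

Navigation follows collection semantics: a member access over a list maps
over its elements and flattens one level; ``[i]`` indexes the current
collection; ``where(system=URI)`` keeps the codings (or any objects) whose
``system`` member equals the URI.  The list mode decides multiplicity:
``first`` (default) takes the first match in document order, ``join(sep)``
concatenates stringified matches, ``explode`` emits one row per match.

Compilation errors are raised at definition time with a caret-annotated
position; extraction itself never raises on missing paths — a missing value
is an explicit null, never a dropped row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Any, Sequence, Union

import pandas as pd

from .errors import ContractError, PathSyntaxError
from .fhir_core import ResourceEnvelope

log = logging.getLogger(__name__)

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TS_PATTERN = re.compile(
    r"^\d{4}-\d{2}-\d{2}([T ]\d{2}:\d{2}(:\d{2}(\.\d+)?)?([+-]\d{2}:\d{2}|Z)?)?$"
)


@dataclass(frozen=True)
class _Step:
    kind: str  # "member" | "index" | "where"
    name: str = ""
    index: int = 0
    system: str = ""


@dataclass(frozen=True)
class PathSpec:
    """A compiled column definition: name + navigation steps + list mode."""

    column_name: str
    steps: tuple[_Step, ...]
    mode: str = "first"  # first | join | explode
    join_sep: str = ";"
    expr: str = ""


def compile_pathspec(column_name: str, expr: str) -> PathSpec:
    """Compile ``expr`` into a :class:`PathSpec`, failing loudly with a
    caret-annotated :class:`PathSyntaxError` on any malformed input."""
    body, mode, sep = _split_mode(expr)
    steps: list[_Step] = []
    pos = 0
    n = len(body)
    expect_segment = True
    while pos < n:
        if not expect_segment:
            if body[pos] != ".":
                raise PathSyntaxError(expr, pos, f"expected '.' but found {body[pos]!r}")
            pos += 1
            expect_segment = True
            continue
        if pos >= n or body[pos] == ".":
            raise PathSyntaxError(expr, pos, "empty path segment")
        if body.startswith("where(", pos):
            close = body.find(")", pos)
            if close == -1:
                raise PathSyntaxError(expr, pos, "unterminated where(...)")
            inner = body[pos + len("where(") : close]
            if not inner.startswith("system="):
                raise PathSyntaxError(expr, pos + len("where("), "where supports only system=URI")
            uri = inner[len("system=") :]
            if not uri:
                raise PathSyntaxError(expr, pos + len("where(system="), "empty system URI")
            steps.append(_Step("where", system=uri))
            pos = close + 1
        else:
            m = _IDENT.match(body, pos)
            if m is None:
                raise PathSyntaxError(expr, pos, f"expected identifier, found {body[pos]!r}")
            steps.append(_Step("member", name=m.group()))
            pos = m.end()
            if pos < n and body[pos] == "[":
                close = body.find("]", pos)
                if close == -1:
                    raise PathSyntaxError(expr, pos, "unterminated index")
                idx_text = body[pos + 1 : close]
                try:
                    idx = int(idx_text)
                except ValueError:
                    raise PathSyntaxError(expr, pos + 1, f"index must be an integer, got {idx_text!r}") from None
                steps.append(_Step("index", index=idx))
                pos = close + 1
        expect_segment = False
    if expect_segment:
        raise PathSyntaxError(expr, n, "empty path segment")
    if not steps:
        raise PathSyntaxError(expr, 0, "empty path")
    return PathSpec(column_name=column_name, steps=tuple(steps), mode=mode, join_sep=sep, expr=expr)


def _split_mode(expr: str) -> tuple[str, str, str]:
    if "|" not in expr:
        return expr.strip(), "first", ";"
    body, _, mode_text = expr.rpartition("|")
    mode_text = mode_text.strip()
    if mode_text == "first":
        return body.strip(), "first", ";"
    if mode_text == "explode":
        return body.strip(), "explode", ";"
    m = re.fullmatch(r"join\((.*)\)", mode_text)
    if m:
        return body.strip(), "join", m.group(1)
    raise PathSyntaxError(expr, expr.rfind("|") + 1, f"unknown list mode {mode_text!r}")


def evaluate_path(tree: Any, spec: PathSpec) -> list[Any]:
    """Evaluate the navigation steps, returning the matched collection in
    document order (before list-mode reduction)."""
    nodes: list[Any] = [tree]
    for step in spec.steps:
        if step.kind == "member":
            nxt: list[Any] = []
            for node in nodes:
                if isinstance(node, dict) and step.name in node:
                    v = node[step.name]
                    if isinstance(v, list):
                        nxt.extend(v)
                    else:
                        nxt.append(v)
            nodes = nxt
        elif step.kind == "index":
            nodes = [nodes[step.index]] if -len(nodes) <= step.index < len(nodes) else []
        elif step.kind == "where":
            nodes = [
                n for n in nodes if isinstance(n, dict) and n.get("system") == step.system
            ]
    return nodes


# ---------------------------------------------------------------------------
# Frame
# ---------------------------------------------------------------------------

PROVENANCE_COLUMNS = ("resource_type", "resource_id")


class Frame:
    """A rectangular table with per-row resource provenance.

    Thin wrapper over :class:`pandas.DataFrame`; the first two columns are
    always ``resource_type`` and ``resource_id``.
    """

    def __init__(self, df: pd.DataFrame):
        for col in PROVENANCE_COLUMNS:
            if col not in df.columns:
                raise ContractError(f"Frame requires provenance column {col!r}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False, lineterminator="\n")

    def to_csv_text(self) -> str:
        return self.df.to_csv(index=False, lineterminator="\n")

    def write_jsonl(self, path) -> None:
        self.df.to_json(path, orient="records", lines=True, date_format="iso")


def _coerce_column(name: str, values: list[Any]) -> list[Any]:
    """Type a column from its first non-null value; clash falls back to
    string with a logged warning."""
    first = next((v for v in values if v is not None), None)
    if first is None:
        return values

    def classify(v: Any) -> str:
        if isinstance(v, bool):
            return "boolean"
        if isinstance(v, (int, float)):
            return "decimal"
        if isinstance(v, str) and _TS_PATTERN.match(v):
            return "timestamp"
        return "string"

    target = classify(first)
    kinds = {classify(v) for v in values if v is not None}
    if kinds - {target}:
        log.warning("column %r mixes types %s; falling back to string", name, sorted(kinds))
        return [None if v is None else _stringify(v) for v in values]
    if target == "decimal":
        return [None if v is None else float(v) for v in values]
    if target == "string" and not all(isinstance(v, (str, type(None))) for v in values):
        return [None if v is None else _stringify(v) for v in values]
    return values


def _stringify(v: Any) -> str:
    if isinstance(v, str):
        return v
    import json

    return json.dumps(v, separators=(",", ":"), sort_keys=True)


def extract(resources: Sequence[ResourceEnvelope], specs: Sequence[PathSpec]) -> Frame:
    """Flatten resources into one row each (or one row per exploded element).

    At most one spec may use ``explode``; other columns repeat for each
    exploded element.  An exploded empty match still emits one row with a
    null cell, so patient-level denominators never silently shrink.
    """
    exploded = [s for s in specs if s.mode == "explode"]
    if len(exploded) > 1:
        raise ContractError("at most one explode column per extraction")

    rows: dict[str, list[Any]] = {c: [] for c in PROVENANCE_COLUMNS}
    for s in specs:
        rows[s.column_name] = []

    for env in resources:
        cells: dict[str, Any] = {}
        explode_values: list[Any] = [None]
        for s in specs:
            matched = evaluate_path(env.raw, s)
            if s.mode == "first":
                cells[s.column_name] = matched[0] if matched else None
            elif s.mode == "join":
                cells[s.column_name] = (
                    s.join_sep.join(_stringify(v) for v in matched) if matched else None
                )
            else:  # explode
                explode_values = matched if matched else [None]
        n_out = len(explode_values) if exploded else 1
        for _ in range(n_out):
            rows["resource_type"].append(env.resource_type)
            rows["resource_id"].append(env.id)
        for s in specs:
            if s.mode == "explode":
                rows[s.column_name].extend(explode_values)
            else:
                rows[s.column_name].extend([cells[s.column_name]] * n_out)

    for s in specs:
        rows[s.column_name] = _coerce_column(s.column_name, rows[s.column_name])
    df = pd.DataFrame({c: pd.Series(v, dtype=object) for c, v in rows.items()})
    # let numeric columns take a numeric dtype where possible
    for s in specs:
        col = df[s.column_name]
        if all(isinstance(v, (float, type(None))) for v in col):
            df[s.column_name] = pd.to_numeric(col)
    return Frame(df)


def join_frames(left: Frame, right: Frame, on: str, how: str = "inner") -> Frame:
    """Relational join on one column.  Null join keys never match (rows with
    a null key are dropped for inner joins and kept unmatched for left
    joins)."""
    if how not in ("inner", "left"):
        raise ContractError(f"how must be inner or left, not {how!r}")
    for side, fr in (("left", left), ("right", right)):
        if on not in fr.df.columns:
            raise ContractError(f"join column {on!r} missing on {side} side")
    lf, rf = left.df, right.df
    r_nonnull = rf[rf[on].notna()]
    l_nonnull = lf[lf[on].notna()]
    merged = l_nonnull.merge(r_nonnull, on=on, how="inner", suffixes=("", "_right"))
    if how == "left":
        matched_keys = set(r_nonnull[on])
        unmatched = lf[~lf[on].isin(matched_keys) | lf[on].isna()]
        merged = pd.concat([merged, unmatched], ignore_index=True)
    # provenance of the joined frame follows the left side
    if "resource_type" not in merged.columns and "resource_type_right" in merged.columns:
        merged = merged.rename(
            columns={"resource_type_right": "resource_type", "resource_id_right": "resource_id"}
        )
    return Frame(merged.reset_index(drop=True))


def load_pathspecs_yaml(source: Union[str, "Path", dict]) -> list[PathSpec]:
    """Load column definitions from a YAML block of the form::

        columns:
          - name: code
            path: code.coding.where(system=http://loinc.org).code | first
    """
    import yaml
    from pathlib import Path

    if isinstance(source, dict):
        doc = source
    else:
        with open(Path(source), "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    cols = doc.get("columns") if isinstance(doc, dict) else None
    if not cols:
        raise ContractError("pathspec YAML must contain a non-empty 'columns' list")
    return [compile_pathspec(c["name"], c["path"]) for c in cols]
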