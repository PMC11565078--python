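"""Shared helpers for the clinical pipelines: percentage formatting in the
printed style (half-up, one decimal), config loading, report serialization."""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from ..errors import ConfigError

CONFIG_DIR = Path(__file__).resolve().parent.parent / "configs"
USECASE_NAMES = ("mi", "stroke", "diabetes", "sepsis", "pc")


def pct(count: int, denom: int) -> Optional[float]:
    """``100 * count / denom`` rounded half-up to 1 decimal; None for an
    empty denominator (printed-style percentages)."""
    if denom == 0:
        return None
    q = (Decimal(count) * 100 / Decimal(denom)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def round1(x: Optional[float]) -> Optional[float]:
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def load_usecase_config(name_or_path: Union[str, Path, dict]) -> dict:
    """Resolve a use-case config: a dict passes through, a known name loads
    the shipped default YAML, anything else is treated as a file path."""
    if isinstance(name_or_path, dict):
        return name_or_path
    if isinstance(name_or_path, str) and name_or_path in USECASE_NAMES:
        path = CONFIG_DIR / f"{name_or_path}.yaml"
    else:
        path = Path(name_or_path)
    if not path.exists():
        raise ConfigError(f"config not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return doc


def require(cfg: dict, key: str, usecase: str) -> Any:
    if key not in cfg:
        raise ConfigError(f"use case {usecase!r}: missing config block {key!r}")
    return cfg[key]


def report_to_dict(report: Any) -> dict:
    """Dataclass report -> plain JSON-serializable dict (recursive)."""

    def conv(v: Any) -> Any:
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if hasattr(v, "isoformat"):
            return v.isoformat()
        return v

    return conv(report)


def write_report_json(report: Any, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
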