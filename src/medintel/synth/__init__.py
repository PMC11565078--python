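"""Synthetic-hospital generation: stochastic corpora with ground truth, and
count-exact fixtures that realize a requested category table."""

from __future__ import annotations

import shutil
from pathlib import Path
from typing import Union

from ..usecases.common import CONFIG_DIR, USECASE_NAMES
from .builders import (
    ATC_SYSTEM,
    ICD_SYSTEM,
    LOCAL_SYSTEM,
    LOINC_SYSTEM,
    OPS_SYSTEM,
)
from .fixtures import fixture_from_counts, fixture_store
from .generator import GroundTruth, SynthConfig, generate_corpus, write_corpus

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "write_corpus",
    "fixture_from_counts",
    "fixture_store",
    "emit_default_configs",
    "ICD_SYSTEM",
    "LOINC_SYSTEM",
    "ATC_SYSTEM",
    "OPS_SYSTEM",
    "LOCAL_SYSTEM",
]


def emit_default_configs(outdir: Union[str, Path]) -> list[Path]:
    """Write the five shipped use-case configs plus the demo generator
    config into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (*USECASE_NAMES, "synth_demo"):
        src = CONFIG_DIR / f"{name}.yaml"
        dst = outdir / f"{name}.yaml"
        shutil.copyfile(src, dst)
        written.append(dst)
    return written
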