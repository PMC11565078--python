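"""Optional static plots mirroring the dashboard views: medication flow
cross-tab, treatment-timing strips with the guideline band, category pies,
a patient inflammation timeline, and rank-indexed PSA courses.

All functions write a file and return its path; they are deliberately thin
matplotlib wrappers — the numbers come from the report objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_mi_crosstab(report, path: Union[str, Path]) -> Path:
    """Stacked-bar rendering of the antiplatelet x lipid cross-tab."""
    from .usecases.mi import AP_CATEGORIES, LIPID_CATEGORIES

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    bottoms = [0.0] * len(AP_CATEGORIES)
    for lip in LIPID_CATEGORIES:
        heights = [report.cells[f"{ap}|{lip}"] for ap in AP_CATEGORIES]
        ax.bar(AP_CATEGORIES, heights, bottom=bottoms, label=lip)
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_xlabel("antiplatelet therapy")
    ax.set_ylabel("patients")
    ax.set_title(f"medication pattern (n={report.n_cohort})")
    ax.legend(title="lipid-lowering")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_stroke_timing(report, path: Union[str, Path]) -> Path:
    """Per-patient strip of door-to-treatment minutes with the window band."""
    path = Path(path)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
    for ax, label, limit, attr in (
        (axes[0], "thrombolysis", report.thresholds["needle_minutes"], "lysis_minutes"),
        (axes[1], "thrombectomy", report.thresholds["groin_minutes"], "groin_minutes"),
    ):
        minutes = [getattr(p, attr) for p in report.patients if getattr(p, attr) is not None]
        ax.axhspan(0, limit, color="green", alpha=0.15)
        ax.plot(range(len(minutes)), minutes, ".", ms=4)
        ax.set_title(label)
        ax.set_xlabel("patient")
        ax.set_ylabel("minutes from admission")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_category_pies(report, path: Union[str, Path]) -> Path:
    """Top-k pathogen and antibiotic pies."""
    path = Path(path)
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for ax, table, title in (
        (axes[0], report.pathogens, "isolated organisms"),
        (axes[1], report.antibiotics, "antibiotic prescriptions"),
    ):
        names = [name for name, _, _ in table.top]
        counts = [n for _, n, _ in table.top]
        if counts:
            ax.pie(counts, labels=names, textprops={"fontsize": 7})
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_patient_timeline(timeline, path: Union[str, Path]) -> Path:
    """CRP / procalcitonin course with isolate events and antibiotic bars."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 4))
    if timeline.crp:
        ax.plot([t for t, _ in timeline.crp], [v for _, v in timeline.crp], "-o", label="CRP")
    if timeline.procalcitonin:
        ax.plot(
            [t for t, _ in timeline.procalcitonin],
            [v for _, v in timeline.procalcitonin],
            "-s",
            label="PCT",
        )
    for t, organism in timeline.isolates:
        ax.axvline(t, color="red", alpha=0.4)
    ax.set_title(f"patient {timeline.patient_id}")
    ax.legend()
    ax.tick_params(axis="x", labelrotation=45, labelsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_psa_courses(report, path: Union[str, Path]) -> Path:
    """Rank-indexed PSA lines for surgical patients; flagged in red."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    for p in report.patients:
        if p.prostatectomy_date is None or not p.psa_series:
            continue
        ranks = [r for r, _, _ in p.psa_series]
        values = [v for _, _, v in p.psa_series]
        flagged = bool(p.psa_persistence or p.biochemical_recurrence)
        ax.plot(ranks, values, "-", color="red" if flagged else "grey",
                alpha=0.9 if flagged else 0.4, lw=1.5 if flagged else 0.8)
    ax.set_xlabel("measurement rank")
    ax.set_ylabel("PSA (ng/mL)")
    ax.set_yscale("symlog", linthresh=1.0)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
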