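"""Figure-level artifacts as plain-data exports.

Every number in a run's summary bundle is recomputable from the exported
fold-change CSV alone; plotting is optional and purely cosmetic.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import FoldChangeRecord
from .qc import QCReport
from .shift_stats import ClassSummary, TissueComparison, reference_sem

__all__ = [
    "export_volcano",
    "octant_counts",
    "export_summary",
    "load_summary",
    "plot_volcano",
]


def octant_counts(records: list[FoldChangeRecord]) -> dict[str, int]:
    """Counts for the eight volcano cells (direction x significance x SEM)."""
    counts = {
        f"{d}_{s}_{b}": 0
        for d in ("up", "down")
        for s in ("sig", "nonsig")
        for b in ("beyond", "within")
    }
    for r in records:
        c = r.category
        if c is None:
            raise ValueError("record categories are unset; run classify first")
        key = (
            f"{c.direction}_"
            f"{'sig' if c.significant else 'nonsig'}_"
            f"{'beyond' if c.beyond_sem else 'within'}"
        )
        counts[key] += 1
    return counts


def export_volcano(
    records: list[FoldChangeRecord],
    path: str | os.PathLike | None = None,
    *,
    sem_scope: str = "global",
) -> tuple[pd.DataFrame, dict[str, int], dict]:
    """Volcano table (CSV) plus the 8-cell count annex and metadata.

    One row per record: label, fold change, log2 fold change, -log10 p,
    category color and flags.  Raises if records are empty or unclassified.
    """
    if not records:
        raise ValueError("no records to export")
    counts = octant_counts(records)  # validates categories
    ref = reference_sem(records, sem_scope)
    with np.errstate(divide="ignore"):
        rows = [
            {
                "species": r.species.label,
                "lipid_class": r.species.lipid_class.value,
                "fold_change": r.fold_change,
                "log2_fold_change": float(np.log2(r.fold_change)),
                "neg_log10_p": float(-np.log10(r.p_value)) if r.p_value > 0 else np.inf,
                "p_value": r.p_value,
                "sem": r.sem,
                "color": r.category.color,
                "direction": r.category.direction,
                "significant": r.category.significant,
                "beyond_sem": r.category.beyond_sem,
            }
            for r in records
        ]
    df = pd.DataFrame(rows)
    metadata = {
        "tissue": records[0].tissue,
        "mode": records[0].mode,
        "sem_scope": sem_scope,
        "reference_sem": {
            ("global" if k is None else k.value): v for k, v in ref.items()
        },
        "octant_counts": counts,
    }
    if path is not None:
        df.to_csv(path, index=False, encoding="utf-8")
    return df, counts, metadata


def _summary_to_jsonable(s: ClassSummary) -> dict:
    return {
        "lipid_class": s.lipid_class.value,
        "tissue": s.tissue,
        "n_up_beyond": s.n_up_beyond,
        "n_down_beyond": s.n_down_beyond,
        "n_up_total": s.n_up_total,
        "n_down_total": s.n_down_total,
        "binomial_p": s.binomial_p,
        "mean_effect_pct": s.mean_effect_pct,
        "mean_effect_sem_pct": s.mean_effect_sem_pct,
        "one_sample_p": s.one_sample_p,
    }


def _comparison_to_jsonable(c: TissueComparison) -> dict:
    return {
        "lipid_class": c.lipid_class.value if c.lipid_class is not None else "all",
        "table": np.asarray(c.table).tolist(),
        "fisher_p": c.fisher_p,
        "two_sample_p": c.two_sample_p,
        "venn": {
            "brain_only": c.venn.brain_only,
            "both": c.venn.both,
            "liver_only": c.venn.liver_only,
            "tier": c.venn.tier,
        },
    }


def export_summary(
    class_summaries: list[ClassSummary],
    tissue_comparisons: list[TissueComparison],
    qc: QCReport | None = None,
    config: dict | None = None,
    path: str | os.PathLike | None = None,
) -> dict:
    """Machine-readable bundle of every figure-level quantity of a run.

    Deterministic given the same inputs (keys sorted, no timestamps), so
    re-running an identical configuration yields a byte-identical file.
    """
    bundle = {
        "class_summaries": [_summary_to_jsonable(s) for s in class_summaries],
        "tissue_comparisons": [_comparison_to_jsonable(c) for c in tissue_comparisons],
        "qc": qc.to_dict() if qc is not None else None,
        "config": config or {},
    }
    if path is not None:
        Path(path).write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return bundle


def load_summary(path: str | os.PathLike) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def plot_volcano(df: pd.DataFrame, metadata: dict, path: str | os.PathLike) -> None:
    """Optional volcano scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"grey": "#9e9e9e", "green": "#2e7d32", "blue": "#1565c0", "red": "#c62828"}
    fig, ax = plt.subplots(figsize=(5, 4))
    finite = df[np.isfinite(df["neg_log10_p"])]
    for color, sub in finite.groupby("color"):
        ax.scatter(
            sub["log2_fold_change"],
            sub["neg_log10_p"],
            s=12,
            c=colors.get(color, "black"),
            label=f"{color} ({len(sub)})",
        )
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="black")
    ax.axvline(0.0, ls="-", lw=0.8, c="black")
    ax.set_xlabel("log2 fold change (treated / control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{metadata['tissue']} ({metadata['mode']})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
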