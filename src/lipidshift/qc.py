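"""Measurement-quality computations.

Covers the four QC quantities the pipeline tracks: spike-in extraction
recovery, intra-/inter-day replicate CV, matrix-effect changes in
deuterated-standard ratios between two sample matrices, and the allometric
(body-surface-area) dose conversion used to translate a human dose to a
mouse dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .panel import MeasurementSet

__all__ = [
    "QCReport",
    "DoseResult",
    "recovery",
    "replicate_cv",
    "matrix_effect",
    "human_to_mouse_dose",
    "dilution_linearity",
    "qc_report",
]


@dataclass
class QCReport:
    recovery_pct: Optional[float] = None
    intra_day_cv_pct: Optional[float] = None
    inter_day_cv_pct: Optional[float] = None
    combined_cv_pct: Optional[float] = None
    matrix_mean_pct: Optional[float] = None
    matrix_max_pct: Optional[float] = None
    recovery_per_analyte: dict[str, float] = field(default_factory=dict)
    matrix_per_pair: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recovery_pct": self.recovery_pct,
            "intra_day_cv_pct": self.intra_day_cv_pct,
            "inter_day_cv_pct": self.inter_day_cv_pct,
            "combined_cv_pct": self.combined_cv_pct,
            "matrix_mean_pct": self.matrix_mean_pct,
            "matrix_max_pct": self.matrix_max_pct,
            "recovery_per_analyte": dict(self.recovery_per_analyte),
            "matrix_per_pair": dict(self.matrix_per_pair),
        }


def recovery(
    spiked: dict[str, float], reference: dict[str, float]
) -> tuple[float, dict[str, float]]:
    """Mean extraction recovery (%) and the per-analyte breakdown.

    Per analyte: 100 * measured / expected.
    """
    if set(spiked) != set(reference):
        diff = sorted(set(spiked).symmetric_difference(reference))
        raise ValueError(f"analyte keys differ between spiked and reference: {diff}")
    if not spiked:
        raise ValueError("empty analyte table")
    per = {}
    for key in spiked:
        if reference[key] <= 0:
            raise ValueError(f"expected amount for {key!r} must be > 0")
        per[key] = 100.0 * spiked[key] / reference[key]
    return float(np.mean(list(per.values()))), per


def replicate_cv(
    data: MeasurementSet,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Intra-day, inter-day and combined replicate CV on raw counts (%).

    Intra-day: mean over (analyte, mouse, day) of sd/mean across same-day
    replicates.  Inter-day: mean over (analyte, mouse) of sd/mean across the
    day means.  Combined: mean of the two.  A component with no evaluable
    group (single replicate, single day) is reported as None.
    """
    counts = data.counts.to_numpy()
    meta = {s.injection_id: s for s in data.samples}

    by_mouse_day: dict[tuple[str, str, int], list[int]] = {}
    by_mouse: dict[tuple[str, str], dict[int, list[int]]] = {}
    for k, inj in enumerate(data.counts.columns):
        s = meta[inj]
        by_mouse_day.setdefault((s.mouse_id, s.tissue, s.day), []).append(k)
        by_mouse.setdefault((s.mouse_id, s.tissue), {}).setdefault(s.day, []).append(k)

    def cv_of(block: np.ndarray) -> np.ndarray:
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean > 0, sd / mean, np.nan)

    intra_cvs = []
    for cols in by_mouse_day.values():
        if len(cols) >= 2:
            intra_cvs.append(cv_of(counts[:, cols]))
    inter_cvs = []
    for days in by_mouse.values():
        if len(days) >= 2:
            day_means = np.column_stack(
                [counts[:, cols].mean(axis=1) for cols in days.values()]
            )
            inter_cvs.append(cv_of(day_means))

    intra = 100.0 * float(np.nanmean(np.concatenate(intra_cvs))) if intra_cvs else None
    inter = 100.0 * float(np.nanmean(np.concatenate(inter_cvs))) if inter_cvs else None
    if intra is not None and inter is not None:
        combined = (intra + inter) / 2.0
    else:
        combined = intra if inter is None else inter
    return intra, inter, combined


def matrix_effect(
    std_ratios_a: dict[str, float], std_ratios_b: dict[str, float]
) -> tuple[float, float, dict[str, float]]:
    """Mean and max % change of standard ratios between two matrices.

    Per standard pair: 100 * |ratio_A / ratio_B - 1|.
    """
    if set(std_ratios_a) != set(std_ratios_b):
        diff = sorted(set(std_ratios_a).symmetric_difference(std_ratios_b))
        raise ValueError(f"standard-pair keys differ between matrices: {diff}")
    if not std_ratios_a:
        raise ValueError("empty ratio table")
    per = {}
    for key in std_ratios_a:
        a, b = std_ratios_a[key], std_ratios_b[key]
        if a <= 0 or b <= 0:
            raise ValueError(f"ratios must be > 0 (pair {key!r})")
        per[key] = 100.0 * abs(a / b - 1.0)
    values = list(per.values())
    return float(np.mean(values)), float(np.max(values)), per


@dataclass(frozen=True)
class DoseResult:
    mg_per_kg: float
    rounded: int


def human_to_mouse_dose(
    human_dose_mg_per_day: float,
    human_weight_kg: float,
    *,
    km_human: float = 37.0,
    km_mouse: float = 3.0,
) -> DoseResult:
    """Body-surface-area dose conversion from human to mouse.

    mouse dose [mg/kg] = (human dose / human weight) * Km_human / Km_mouse,
    with the conventional Km factors 37 (adult human) and 3 (mouse).
    """
    if min(human_dose_mg_per_day, human_weight_kg, km_human, km_mouse) <= 0:
        raise ValueError("all dose inputs must be > 0")
    dose = (human_dose_mg_per_day / human_weight_kg) * (km_human / km_mouse)
    return DoseResult(mg_per_kg=dose, rounded=int(round(dose)))


def dilution_linearity(
    concentrations, signals
) -> tuple[float, float, float]:
    """Least-squares line through a dilution series; returns (slope, intercept, R^2)."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matching points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def qc_report(
    data: MeasurementSet | None = None,
    *,
    spiked: dict[str, float] | None = None,
    reference: dict[str, float] | None = None,
    std_ratios_a: dict[str, float] | None = None,
    std_ratios_b: dict[str, float] | None = None,
) -> QCReport:
    """Assemble a QCReport from whichever inputs are available."""
    report = QCReport()
    if data is not None:
        intra, inter, combined = replicate_cv(data)
        report.intra_day_cv_pct = intra
        report.inter_day_cv_pct = inter
        report.combined_cv_pct = combined
    if spiked is not None and reference is not None:
        mean_rec, per = recovery(spiked, reference)
        report.recovery_pct = mean_rec
        report.recovery_per_analyte = per
    if std_ratios_a is not None and std_ratios_b is not None:
        mean_pct, max_pct, per = matrix_effect(std_ratios_a, std_ratios_b)
        report.matrix_mean_pct = mean_pct
        report.matrix_max_pct = max_pct
        report.matrix_per_pair = per
    return report
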