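"""Distribution-shift statistics on fold-change records.

The centrepiece is the "eight-square" volcano classification: each species
is placed by direction (fold change above/below 1), significance (p < 0.05,
strict) and effect strength (|fold change - 1| greater than the *average*
per-species SEM of the reference set, strict).  The 2x2x2 cells carry the
conventional colors: grey (neither), green (beyond SEM only), blue
(significant only), red (both).

On top of the classification sit the class-level statistics: counts of
beyond-SEM species by direction with an exact two-sided binomial test
against a 50% chance of increase, the mean class effect (% of control) with
a one-sample t-test against 100%, and cross-tissue comparisons (Fisher's
exact test on the 2x2 up/down table, a two-sample t-test on per-species fold
changes, and a direction-annotated Venn partition of beyond-SEM species).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .nomenclature import LipidClass
from .normalize import FoldChangeRecord

__all__ = [
    "OctantCategory",
    "ClassSummary",
    "TissueComparison",
    "VennPartition",
    "classify",
    "reference_sem",
    "binomial_shift",
    "fisher_tissue",
    "class_mean_effect",
    "summarize_class",
    "compare_class_between_tissues",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

# acyl-carnitine aggregates cover CX with X > 3; free carnitine (C0) and
# acetyl-carnitine (C2) are reported individually instead
MIN_ACYL_CARNITINE_CARBONS = 4


@dataclass(frozen=True)
class OctantCategory:
    """One of the eight volcano cells: direction x significance x effect size."""

    direction: str  # "up" | "down"
    significant: bool
    beyond_sem: bool

    @property
    def color(self) -> str:
        if self.significant:
            return "red" if self.beyond_sem else "blue"
        return "green" if self.beyond_sem else "grey"


@dataclass
class ClassSummary:
    """Per (lipid class, tissue) shift summary."""

    lipid_class: LipidClass
    tissue: str
    n_up_beyond: int
    n_down_beyond: int
    n_up_total: int
    n_down_total: int
    binomial_p: float
    mean_effect_pct: float
    mean_effect_sem_pct: float
    one_sample_p: float


@dataclass
class VennPartition:
    """Direction-annotated partition of beyond-SEM species across tissues.

    Values are direction strings; for species beyond SEM in both tissues the
    value records both directions (they may disagree).  ``tier`` entries mark
    whether a species qualified by effect strength ("beyond") or, when
    within-SEM significant species are included, by significance ("within").
    """

    brain_only: dict[str, str] = field(default_factory=dict)
    both: dict[str, dict[str, str]] = field(default_factory=dict)
    liver_only: dict[str, str] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)


@dataclass
class TissueComparison:
    """Cross-tissue comparison for one lipid class (or the whole panel)."""

    lipid_class: LipidClass | None
    table: np.ndarray  # rows brain/liver, columns up_beyond/down_beyond
    fisher_p: float
    two_sample_p: float
    venn: VennPartition


def reference_sem(
    records: list[FoldChangeRecord], sem_scope: str = "global"
) -> dict[LipidClass | None, float]:
    """Average per-species SEM, globally or per lipid class."""
    if not records:
        raise ValueError("empty record list")
    if sem_scope == "global":
        return {None: float(np.mean([r.sem for r in records]))}
    if sem_scope == "per_class":
        by_class: dict[LipidClass, list[float]] = {}
        for r in records:
            by_class.setdefault(r.species.lipid_class, []).append(r.sem)
        return {cls: float(np.mean(v)) for cls, v in by_class.items()}
    raise ValueError(f"unknown sem_scope {sem_scope!r}")


def classify(
    records: list[FoldChangeRecord],
    sem_scope: str = "global",
    alpha: float = ALPHA,
) -> list[FoldChangeRecord]:
    """Assign the eight-square category to every record.

    The reference SEM is the mean per-species SEM over all records
    (``global``, panel-wide overview) or over the record's class
    (``per_class``, per-class panels).  All inequalities are strict: a fold
    change exactly at the reference SEM, or p exactly at alpha, does not
    qualify.  Records must share tissue and mode.
    """
    if not records:
        raise ValueError("cannot classify an empty record list")
    if len({(r.tissue, r.mode) for r in records}) != 1:
        raise ValueError("records must share a single tissue and mode")
    ref = reference_sem(records, sem_scope)
    out = []
    for r in records:
        ref_sem = ref[None] if sem_scope == "global" else ref[r.species.lipid_class]
        cat = OctantCategory(
            direction="up" if r.fold_change > 1.0 else "down",
            significant=r.p_value < alpha,
            beyond_sem=abs(r.fold_change - 1.0) > ref_sem,
        )
        out.append(replace(r, category=cat))
    return out


def binomial_shift(n_up: int, n_down: int) -> float:
    """Exact two-sided binomial p for an up/down split under p0 = 0.5.

    Two-sided by the minimum-likelihood convention (all outcomes no more
    likely than the observed one are summed).
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    n = n_up + n_down
    if n < 1:
        raise ValueError("need at least one species")
    return float(stats.binomtest(n_up, n, 0.5, alternative="two-sided").pvalue)


def fisher_tissue(table) -> float:
    """Exact two-sided Fisher p for a 2x2 up/down x tissue table.

    A table with a zero margin carries no information about association; by
    convention p = 1.0 is returned (and logged).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.info("2x2 table has a zero margin; returning p = 1.0 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _class_records(
    records: list[FoldChangeRecord],
    lipid_class: LipidClass,
    *,
    acyl_only: bool,
) -> list[FoldChangeRecord]:
    sel = [r for r in records if r.species.lipid_class is lipid_class]
    if lipid_class is LipidClass.CAR and acyl_only:
        sel = [r for r in sel if r.species.carbons >= MIN_ACYL_CARNITINE_CARBONS]
    return sel


def class_mean_effect(
    records: list[FoldChangeRecord],
    lipid_class: LipidClass,
    *,
    acyl_carnitines_only: bool = True,
) -> tuple[float, float, float]:
    """Mean class effect as % of control, its SEM, and a one-sample t p-value.

    The mean and SEM are taken across the species-level fold changes of the
    class; the two-tailed one-sample t-test is against 1.0 (no change).  For
    carnitines, the aggregate covers the acyl-carnitines (chain length > 3)
    only by default; free and acetyl-carnitine are reported individually.
    """
    sel = _class_records(records, lipid_class, acyl_only=acyl_carnitines_only)
    if len(sel) < 2:
        raise ValueError(
            f"need >= 2 species of class {lipid_class.value} (got {len(sel)})"
        )
    fcs = np.array([r.fold_change for r in sel])
    mean_pct = 100.0 * float(fcs.mean())
    sem_pct = 100.0 * float(fcs.std(ddof=1) / np.sqrt(len(fcs)))
    if fcs.std(ddof=1) == 0.0:
        if np.isclose(fcs.mean(), 1.0):
            p = 1.0
        else:
            warnings.warn(
                "zero variance across species with mean != 1; one-sample p = 0"
            )
            p = 0.0
    else:
        p = float(stats.ttest_1samp(fcs, 1.0).pvalue)
    return mean_pct, sem_pct, p


def summarize_class(
    records: list[FoldChangeRecord],
    lipid_class: LipidClass,
    *,
    count_beyond_only: bool = True,
) -> ClassSummary:
    """Build the per-class shift summary from classified records of one tissue.

    The binomial test uses the beyond-SEM species by default (the study's
    tallies); ``count_beyond_only=False`` counts every species.
    """
    sel = _class_records(records, lipid_class, acyl_only=False)
    if not sel:
        raise ValueError(f"no records of class {lipid_class.value}")
    if any(r.category is None for r in sel):
        raise ValueError("records must be classified first (category is unset)")
    tissue = sel[0].tissue
    up = [r for r in sel if r.category.direction == "up"]
    down = [r for r in sel if r.category.direction == "down"]
    up_b = [r for r in up if r.category.beyond_sem]
    down_b = [r for r in down if r.category.beyond_sem]
    if count_beyond_only:
        n_for_test = (len(up_b), len(down_b))
    else:
        n_for_test = (len(up), len(down))
    binom_p = binomial_shift(*n_for_test) if sum(n_for_test) >= 1 else 1.0
    mean_pct, sem_pct, one_p = class_mean_effect(sel, lipid_class)
    return ClassSummary(
        lipid_class=lipid_class,
        tissue=tissue,
        n_up_beyond=len(up_b),
        n_down_beyond=len(down_b),
        n_up_total=len(up),
        n_down_total=len(down),
        binomial_p=binom_p,
        mean_effect_pct=mean_pct,
        mean_effect_sem_pct=sem_pct,
        one_sample_p=one_p,
    )


def compare_class_between_tissues(
    brain_records: list[FoldChangeRecord],
    liver_records: list[FoldChangeRecord],
    lipid_class: LipidClass | None = None,
    *,
    include_within_sem: bool = False,
) -> TissueComparison:
    """Cross-tissue 2x2 Fisher test, class-effect t-test and Venn partition.

    Both record lists must be classified and cover the same species.  The
    Venn partition contains the beyond-SEM species of either tissue; with
    ``include_within_sem`` the significant-but-within-SEM species join with
    tier "within".
    """
    if lipid_class is not None:
        brain_records = _class_records(brain_records, lipid_class, acyl_only=False)
        liver_records = _class_records(liver_records, lipid_class, acyl_only=False)
    b_labels = {r.species.label for r in brain_records}
    l_labels = {r.species.label for r in liver_records}
    if b_labels != l_labels:
        diff = sorted(b_labels.symmetric_difference(l_labels))
        raise ValueError(f"species sets differ between tissues: {diff}")
    if any(r.category is None for r in brain_records + liver_records):
        raise ValueError("records must be classified first (category is unset)")

    def beyond(recs):
        return {
            r.species.label: r.category.direction
            for r in recs
            if r.category.beyond_sem
        }

    def within_sig(recs):
        return {
            r.species.label: r.category.direction
            for r in recs
            if r.category.significant and not r.category.beyond_sem
        }

    b_beyond, l_beyond = beyond(brain_records), beyond(liver_records)
    table = np.array(
        [
            [sum(d == "up" for d in b_beyond.values()),
             sum(d == "down" for d in b_beyond.values())],
            [sum(d == "up" for d in l_beyond.values()),
             sum(d == "down" for d in l_beyond.values())],
        ]
    )

    b_members = dict(b_beyond)
    l_members = dict(l_beyond)
    tier = {lab: "beyond" for lab in set(b_members) | set(l_members)}
    if include_within_sem:
        for lab, d in within_sig(brain_records).items():
            b_members.setdefault(lab, d)
            tier.setdefault(lab, "within")
        for lab, d in within_sig(liver_records).items():
            l_members.setdefault(lab, d)
            tier.setdefault(lab, "within")

    both = {
        lab: {"brain": b_members[lab], "liver": l_members[lab]}
        for lab in sorted(set(b_members) & set(l_members))
    }
    venn = VennPartition(
        brain_only={
            lab: b_members[lab] for lab in sorted(set(b_members) - set(l_members))
        },
        both=both,
        liver_only={
            lab: l_members[lab] for lab in sorted(set(l_members) - set(b_members))
        },
        tier=tier,
    )

    b_fc = np.array([r.fold_change for r in brain_records])
    order = {r.species.label: i for i, r in enumerate(brain_records)}
    l_fc = np.empty_like(b_fc)
    for r in liver_records:
        l_fc[order[r.species.label]] = r.fold_change
    res = stats.ttest_ind(b_fc, l_fc, equal_var=True)
    two_p = float(res.pvalue)
    if not np.isfinite(two_p):
        two_p = 1.0 if np.isclose(b_fc.mean(), l_fc.mean()) else 0.0

    return TissueComparison(
        lipid_class=lipid_class,
        table=table,
        fisher_p=fisher_tissue(table),
        two_sample_p=two_p,
        venn=venn,
    )
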