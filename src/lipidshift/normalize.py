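"""Normalization chain: raw counts -> per-mouse values -> fold changes.

Three stages, matching the study's data analysis:

1. ``normalize_to_standards`` — each lipid's counts are divided by the
   counts of its class' deuterated standard in the same injection (mean of
   the standards where a class has several), then technical replicates are
   averaged per mouse.  Because the standards are spiked before extraction,
   extraction recovery and any per-injection global scale cancel here.
2. ``class_relative`` — optionally, each species value is divided by the sum
   over its class in the same sample, isolating within-class redistribution
   from the class-level effect.
3. ``fold_changes`` — per species: treated mean / control mean of the
   per-mouse values, its SEM, and a two-tailed two-sample t-test p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import LipidSpecies, parse_species
from .panel import MeasurementSet

if TYPE_CHECKING:  # pragma: no cover
    from .shift_stats import OctantCategory

__all__ = [
    "NormalizedSample",
    "FoldChangeRecord",
    "NormalizationError",
    "normalize_to_standards",
    "class_relative",
    "fold_changes",
    "MODE_ABSOLUTE",
    "MODE_CLASS_RELATIVE",
]

logger = logging.getLogger(__name__)

MODE_ABSOLUTE = "absolute"
MODE_CLASS_RELATIVE = "class_relative"


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedSample:
    """Triplicate-averaged lipid/standard ratios for one (mouse, tissue)."""

    mouse_id: str
    tissue: str
    group: str
    values: pd.Series  # index: species label -> ratio

    def copy_with(self, values: pd.Series) -> "NormalizedSample":
        return NormalizedSample(self.mouse_id, self.tissue, self.group, values)


@dataclass
class FoldChangeRecord:
    """Per-species treated/control effect in one tissue and mode.

    ``fold_change`` is treated mean / control mean of per-mouse values (1.0 =
    no change); ``sem`` is the treated-group SEM expressed in fold-change
    units (divided by the control mean); ``category`` is filled by
    :func:`lipidshift.shift_stats.classify`.
    """

    species: LipidSpecies
    tissue: str
    mode: str
    fold_change: float
    sem: float
    p_value: float
    category: Optional["OctantCategory"] = field(default=None)


def normalize_to_standards(data: MeasurementSet) -> list[NormalizedSample]:
    """Divide each lipid by its class standard, then average triplicates.

    Raises :class:`NormalizationError` naming the injection and class if any
    standard count is zero or negative.
    """
    panel = data.panel
    counts = data.counts

    # per-class denominator per injection (mean over the class' standards)
    problems = []
    denom_rows = {}
    for cls, std_labels in panel.class_standard_map.items():
        block = counts.loc[std_labels]
        bad = block.columns[(block <= 0).any(axis=0)]
        for inj in bad:
            problems.append(
                f"non-positive standard count for class {cls.value} in injection {inj!r}"
            )
        denom_rows[cls] = block.mean(axis=0)
    if problems:
        raise NormalizationError("\n".join(problems))

    species = panel.measured_species
    sp_labels = [s.label for s in species]
    denom = np.vstack([denom_rows[s.lipid_class].to_numpy() for s in species])
    ratios = counts.loc[sp_labels].to_numpy() / denom

    meta = {s.injection_id: s for s in data.samples}
    order: list[tuple[str, str, str]] = []
    groups: dict[tuple[str, str, str], list[int]] = {}
    for k, inj in enumerate(counts.columns):
        s = meta[inj]
        key = (s.mouse_id, s.tissue, s.group)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(k)

    n_reps = {len(v) for v in groups.values()}
    if len(n_reps) > 1:
        logger.warning(
            "unequal replicate counts per mouse (%s); averaging available replicates",
            sorted(n_reps),
        )

    out = []
    for mouse_id, tissue, group in order:
        cols = groups[(mouse_id, tissue, group)]
        values = pd.Series(ratios[:, cols].mean(axis=1), index=sp_labels)
        out.append(NormalizedSample(mouse_id, tissue, group, values))
    return out


def class_relative(samples: list[NormalizedSample]) -> list[NormalizedSample]:
    """Divide each species by the sum over its class in the same sample.

    After this, values within each class sum to 1 per sample; a uniform
    class-level effect cancels exactly.
    """
    if not samples:
        return []
    species = [parse_species(lab) for lab in samples[0].values.index]
    class_members: dict = {}
    for s in species:
        class_members.setdefault(s.lipid_class, []).append(s.label)

    out = []
    for sample in samples:
        values = sample.values.copy()
        for cls, labels in class_members.items():
            total = float(values[labels].sum())
            if total <= 0:
                raise NormalizationError(
                    f"non-positive {cls.value} class total for mouse "
                    f"{sample.mouse_id!r} ({sample.tissue})"
                )
            values[labels] = values[labels] / total
        out.append(sample.copy_with(values))
    return out


def _two_sample_p(
    treated: np.ndarray, control: np.ndarray, *, welch: bool
) -> np.ndarray:
    """Vectorized two-tailed two-sample t-test along axis 0.

    Degenerate zero-variance cases follow the limit convention: p = 1 when
    the group means coincide, 0 otherwise.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated, control, axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if np.any(bad):
        same = np.isclose(treated.mean(axis=0), control.mean(axis=0))
        p = np.where(bad, np.where(same, 1.0, 0.0), p)
    return p


def fold_changes(
    samples: list[NormalizedSample],
    tissue: str,
    mode: str = MODE_ABSOLUTE,
    *,
    test: str = "student",
    sem_basis: str = "treated",
    log_transform: bool = False,
    multiple_testing: str | None = None,
) -> list[FoldChangeRecord]:
    """Per-species fold change, SEM and two-sample t-test for one tissue.

    ``test`` selects the pooled-variance Student's t-test (default, the
    study's choice) or ``"welch"``.  ``sem_basis`` is ``"treated"`` (treated
    SEM / control mean, default) or ``"delta"`` (delta-method, including the
    control-mean variance).  ``multiple_testing="bh"`` applies
    Benjamini-Hochberg to the p-values (default: none).
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test variant {test!r}")
    if sem_basis not in ("treated", "delta"):
        raise ValueError(f"unknown sem_basis {sem_basis!r}")
    sel = [s for s in samples if s.tissue == tissue]
    ctrl = [s for s in sel if s.group == "control"]
    trt = [s for s in sel if s.group == "treated"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise NormalizationError(
            f"need >= 2 mice per group in tissue {tissue!r} "
            f"(control: {len(ctrl)}, treated: {len(trt)})"
        )
    labels = list(ctrl[0].values.index)
    c = np.vstack([s.values.reindex(labels).to_numpy() for s in ctrl])
    t = np.vstack([s.values.reindex(labels).to_numpy() for s in trt])

    mean_c = c.mean(axis=0)
    mean_t = t.mean(axis=0)
    zero = mean_c <= 0
    if np.any(zero):
        bad = [labels[i] for i in np.nonzero(zero)[0][:5]]
        raise NormalizationError(f"non-positive control mean for species {bad}")

    fc = mean_t / mean_c
    n_t, n_c = t.shape[0], c.shape[0]
    sem_t = t.std(axis=0, ddof=1) / np.sqrt(n_t)
    if sem_basis == "treated":
        sem = sem_t / mean_c
    else:
        var_c = c.var(axis=0, ddof=1) / n_c
        sem = np.sqrt(sem_t**2 + fc**2 * var_c) / mean_c

    if log_transform:
        if np.any(t <= 0) or np.any(c <= 0):
            raise NormalizationError("log_transform requires strictly positive values")
        p = _two_sample_p(np.log(t), np.log(c), welch=(test == "welch"))
    else:
        p = _two_sample_p(t, c, welch=(test == "welch"))

    if multiple_testing == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif multiple_testing not in (None, "none"):
        raise ValueError(f"unknown multiple_testing {multiple_testing!r}")

    return [
        FoldChangeRecord(
            species=parse_species(lab),
            tissue=tissue,
            mode=mode,
            fold_change=float(fc[i]),
            sem=float(sem[i]),
            p_value=float(p[i]),
        )
        for i, lab in enumerate(labels)
    ]
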