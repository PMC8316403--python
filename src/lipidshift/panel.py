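"""Panel definition and the raw-measurement data model.

A *panel* is the fixed list of MRM transitions acquired per injection: the
lipid species of six classes plus the deuterated internal standards spiked
into every sample before extraction, together with the mapping from each
class to the standard(s) used as its normalization denominator.

A :class:`MeasurementSet` is the pipeline's sole data input: a table of
counts-per-second indexed by (analyte label x injection) plus per-injection
sample metadata (mouse, tissue, treatment group, technical replicate,
acquisition day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .nomenclature import LipidClass, LipidSpecies, parse_species

__all__ = [
    "PanelDefinition",
    "SampleMeta",
    "MeasurementSet",
    "ValidationError",
    "default_panel",
    "DEFAULT_CLASS_SPECIES",
    "DEFAULT_STANDARDS",
]

GROUPS = ("control", "treated")


class ValidationError(ValueError):
    """Input data violates the panel/measurement invariants.

    The message lists *all* detected violations, one per line.
    """


@dataclass
class PanelDefinition:
    """The analyte panel: species, per-class standards, tissues measured."""

    species: list[LipidSpecies]
    class_standard_map: dict[LipidClass, list[str]]
    tissue_list: list[str]

    def __post_init__(self) -> None:
        problems: list[str] = []
        labels = [s.label for s in self.species]
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                problems.append(f"duplicate species label in panel: {lab!r}")
            seen.add(lab)
        standard_labels = {s.label for s in self.species if s.is_standard}
        for cls, stds in self.class_standard_map.items():
            if not stds:
                problems.append(f"class {cls.value} has an empty standard list")
            for lab in stds:
                if lab not in standard_labels:
                    problems.append(
                        f"standard {lab!r} for class {cls.value} is not a flagged "
                        "standard in the panel species list"
                    )
        for s in self.species:
            if not s.is_standard and s.lipid_class not in self.class_standard_map:
                problems.append(
                    f"species {s.label!r}: class {s.lipid_class.value} has no standard"
                )
        if not self.tissue_list:
            problems.append("tissue_list is empty")
        if problems:
            raise ValidationError("\n".join(problems))

    @property
    def analyte_labels(self) -> list[str]:
        return [s.label for s in self.species]

    @property
    def measured_species(self) -> list[LipidSpecies]:
        """Panel species excluding internal standards."""
        return [s for s in self.species if not s.is_standard]

    @property
    def standards(self) -> list[LipidSpecies]:
        return [s for s in self.species if s.is_standard]

    def species_of_class(self, cls: LipidClass) -> list[LipidSpecies]:
        return [s for s in self.measured_species if s.lipid_class is cls]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one injection (one technical replicate of one mouse)."""

    injection_id: str
    mouse_id: str
    tissue: str
    group: str
    replicate: int
    day: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"injection {self.injection_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"injection {self.injection_id!r}: replicate must be >= 1"
            )


@dataclass
class MeasurementSet:
    """Raw counts-per-second per (analyte x injection) with sample metadata.

    ``counts`` is a DataFrame indexed by analyte label with one column per
    injection_id.  Construction validates every invariant and raises a single
    :class:`ValidationError` listing all violations.
    """

    panel: PanelDefinition
    samples: list[SampleMeta]
    counts: pd.DataFrame
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self._skip_validation:
            self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        panel_labels = set(self.panel.analyte_labels)
        index_labels = set(map(str, self.counts.index))
        for lab in sorted(panel_labels - index_labels):
            problems.append(f"panel analyte missing from counts table: {lab!r}")
        for lab in sorted(index_labels - panel_labels):
            problems.append(f"counts table row not in panel: {lab!r}")

        meta_ids = [s.injection_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            problems.append("duplicate injection_id in sample metadata")
        col_ids = set(map(str, self.counts.columns))
        for inj in sorted(set(meta_ids) - col_ids):
            problems.append(f"injection missing from counts table: {inj!r}")
        for inj in sorted(col_ids - set(meta_ids)):
            problems.append(f"counts column without sample metadata: {inj!r}")

        if self.counts.isna().any().any():
            na = self.counts.isna()
            cells = [
                f"({idx!r}, {col!r})"
                for idx in self.counts.index
                for col in self.counts.columns[na.loc[idx]]
            ]
            problems.append("missing counts at: " + ", ".join(cells[:10]))
        else:
            neg = self.counts < 0
            if neg.any().any():
                cells = [
                    f"({idx!r}, {col!r})"
                    for idx in self.counts.index
                    for col in self.counts.columns[neg.loc[idx]]
                ]
                problems.append("negative counts at: " + ", ".join(cells[:10]))

        keys = [(s.mouse_id, s.tissue, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            problems.append(f"duplicate (mouse, tissue, replicate): {dupes}")
        rep_counts: dict[tuple[str, str], int] = {}
        for s in self.samples:
            rep_counts[(s.mouse_id, s.tissue)] = (
                rep_counts.get((s.mouse_id, s.tissue), 0) + 1
            )
        if len(set(rep_counts.values())) > 1:
            problems.append(
                "unequal replicate counts per (mouse, tissue): "
                + str(sorted(set(rep_counts.values())))
            )

        if problems:
            raise ValidationError("\n".join(problems))

        # canonical ordering: panel order on rows, metadata order on columns
        self.counts = self.counts.loc[self.panel.analyte_labels, meta_ids].astype(float)

    @property
    def n_replicates(self) -> int:
        per = {}
        for s in self.samples:
            per[(s.mouse_id, s.tissue)] = per.get((s.mouse_id, s.tissue), 0) + 1
        return max(per.values()) if per else 0

    def sample_for(self, injection_id: str) -> SampleMeta:
        for s in self.samples:
            if s.injection_id == injection_id:
                return s
        raise KeyError(injection_id)


# --------------------------------------------------------------------------
# Default panel: the study's 199 named species (39 TAG, 43 PCaa, 39 PCae,
# 22 lyso-PC, 15 SM, 41 carnitines) plus one deuterated standard per class
# (two for carnitines: octanoyl- and palmitoyl-carnitine-d3).
# --------------------------------------------------------------------------

_TAG = {
    48: (0, 1, 2, 3),
    50: (1, 2, 3, 4),
    52: (2, 3, 4, 5, 6),
    54: (3, 4, 5, 6, 7, 9),
    56: (4, 5, 6, 7, 8, 9),
    58: (4, 5, 6, 7, 8, 9, 10),
    60: (5, 6, 7, 8, 9, 10, 11),
}
_PCAA = {
    30: (0, 1, 2),
    32: (0, 1, 2, 3),
    34: (1, 2, 3, 4),
    36: (1, 2, 3, 4, 5, 6),
    38: (2, 3, 4, 5, 6, 7),
    40: (2, 3, 4, 5, 6, 7, 8),
    42: (1, 2, 3, 4, 5, 6, 7),
    44: (3, 4, 5, 6, 7, 8),
}
_PCAE = {
    30: (0, 1, 2),
    32: (0, 1, 2, 3),
    34: (0, 1, 2, 3, 4),
    36: (1, 2, 3, 4, 5),
    38: (1, 2, 3, 4, 5, 6),
    40: (1, 2, 3, 4, 5, 6),
    42: (1, 2, 3, 4, 5),
    44: (3, 4, 5, 6, 7),
}
_LYSO_PC = [
    (6, 0), (10, 0), (14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1),
    (18, 2), (20, 0), (20, 3), (20, 4), (22, 0), (22, 1), (24, 0), (24, 1),
    (26, 0), (26, 1), (28, 0), (28, 1), (30, 0), (30, 1),
]
_SM = [
    (14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (20, 0), (20, 1), (22, 0),
    (22, 1), (22, 2), (22, 3), (24, 0), (24, 1), (24, 2), (26, 1),
]
_CAR = [
    (0, 0), (2, 0), (3, 0), (4, 0), (4, 1), (5, 0), (5, 1), (6, 0), (6, 1),
    (6, 2), (7, 0), (8, 0), (8, 1), (8, 2), (9, 0), (10, 0), (10, 1),
    (10, 2), (11, 0), (12, 0), (12, 1), (12, 2), (13, 0), (14, 0), (14, 1),
    (14, 2), (14, 3), (15, 0), (16, 0), (16, 1), (16, 2), (16, 3), (17, 0),
    (18, 0), (18, 1), (18, 2), (18, 3), (20, 0), (20, 1), (20, 2), (20, 3),
]

DEFAULT_CLASS_SPECIES: dict[LipidClass, list[tuple[int, int]]] = {
    LipidClass.TAG: [(c, d) for c, dbs in _TAG.items() for d in dbs],
    LipidClass.PCAA: [(c, d) for c, dbs in _PCAA.items() for d in dbs],
    LipidClass.PCAE: [(c, d) for c, dbs in _PCAE.items() for d in dbs],
    LipidClass.LYSO_PC: list(_LYSO_PC),
    LipidClass.SM: list(_SM),
    LipidClass.CAR: list(_CAR),
}

# (class, carbons, double_bonds) of the deuterated standards; modeled on the
# commercial spike-in mix (e.g. 06:0 PC, 19:0 lyso-PC, 06:0 SM, octanoyl- and
# palmitoyl-carnitine-d3).
DEFAULT_STANDARDS: dict[LipidClass, list[tuple[int, int]]] = {
    LipidClass.TAG: [(48, 1)],
    LipidClass.PCAA: [(12, 0)],
    LipidClass.PCAE: [(30, 1)],
    LipidClass.LYSO_PC: [(19, 0)],
    LipidClass.SM: [(6, 0)],
    LipidClass.CAR: [(8, 0), (16, 0)],
}


def default_panel(tissues: tuple[str, ...] = ("brain", "liver")) -> PanelDefinition:
    """Build the default 199-species panel with per-class deuterated standards."""
    species: list[LipidSpecies] = []
    for cls, pairs in DEFAULT_CLASS_SPECIES.items():
        for carbons, db in pairs:
            species.append(LipidSpecies(cls, carbons, db))
    standard_map: dict[LipidClass, list[str]] = {}
    for cls, pairs in DEFAULT_STANDARDS.items():
        labels = []
        for carbons, db in pairs:
            std = LipidSpecies(cls, carbons, db, is_standard=True)
            species.append(std)
            labels.append(std.label)
        standard_map[cls] = labels
    return PanelDefinition(species, standard_map, list(tissues))


def panel_from_labels(
    species_labels: list[str],
    standards: dict[str, list[str]],
    tissues: list[str],
) -> PanelDefinition:
    """Assemble a panel from text labels (the YAML dialect's content)."""
    from .nomenclature import lipid_class_from_code

    species = [parse_species(lab) for lab in species_labels]
    standard_map: dict[LipidClass, list[str]] = {}
    for cls_code, labs in standards.items():
        cls = lipid_class_from_code(cls_code)
        parsed = []
        for lab in labs:
            sp = parse_species(lab)
            if not sp.is_standard:
                sp = LipidSpecies(sp.lipid_class, sp.carbons, sp.double_bonds, True)
            parsed.append(sp)
            species.append(sp)
        standard_map[cls] = [sp.label for sp in parsed]
    return PanelDefinition(species, standard_map, list(tissues))
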