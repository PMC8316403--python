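"""Lipid nomenclature at sum-composition level.

Targeted shotgun MS panels report each analyte as a head-group class plus the
*total* acyl-carbon and double-bond count summed over all chains (e.g.
``PCaa C36:4`` — a diacyl-phosphatidylcholine with 36 acyl carbons and 4
double bonds in sn1+sn2 combined).  Structural isomers are not resolved, so
species identity here is exactly ``(class, carbons, double_bonds)``.

Conventions encoded:

* Carnitines are printed bare, ``C<chain>`` with an optional ``:<db>``
  (``C0`` = free carnitine, ``C2`` = acetyl-carnitine); there is no class
  prefix because that is how the field labels them.
* Lyso-PC carbon counts are zero-padded to two digits (``lyso-PC C06:0``).
* Sphingomyelins carry an implicit d18:1 backbone; only the variable N-acyl
  chain is encoded in the label.
* Deuterated internal standards are ordinary species flagged
  ``is_standard`` and printed with an ``IS `` prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "LipidClass",
    "LipidSpecies",
    "LipidParseError",
    "parse_species",
    "format_species",
]


class LipidParseError(ValueError):
    """Raised when a species label cannot be interpreted."""


class LipidClass(Enum):
    """The six analyte classes of the panel."""

    TAG = "TAG"
    PCAA = "PCaa"
    PCAE = "PCae"
    LYSO_PC = "lysoPC"
    SM = "SM"
    CAR = "CAR"

    @property
    def code(self) -> str:
        return self.value

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]


_DISPLAY = {
    LipidClass.TAG: "triacylglyceride",
    LipidClass.PCAA: "diacyl-phosphatidylcholine",
    LipidClass.PCAE: "phosphatidylcholine plasmalogen",
    LipidClass.LYSO_PC: "lyso-phosphatidylcholine",
    LipidClass.SM: "sphingomyelin",
    LipidClass.CAR: "carnitine",
}

# Accepted spellings, keyed by lower case with spaces/hyphens stripped.
_CLASS_ALIASES = {
    "tag": LipidClass.TAG,
    "pcaa": LipidClass.PCAA,
    "pcae": LipidClass.PCAE,
    "lysopc": LipidClass.LYSO_PC,
    "sm": LipidClass.SM,
    "car": LipidClass.CAR,
    "carnitine": LipidClass.CAR,
}


def lipid_class_from_code(code: str) -> LipidClass:
    """Resolve a class code (``TAG``, ``PCaa``, ``lyso-PC`` ...) to the enum."""
    key = code.lower().replace("-", "").replace(" ", "")
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise LipidParseError(f"unknown lipid class {code!r}") from None


@dataclass(frozen=True)
class LipidSpecies:
    """One analyte identity: class + summed carbons:double-bonds.

    ``carbons`` counts total acyl carbons (for carnitines, the acyl chain
    length; 0 for free carnitine).  ``is_standard`` marks a deuterated
    internal standard.
    """

    lipid_class: LipidClass
    carbons: int
    double_bonds: int = 0
    is_standard: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double_bonds must be non-negative")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double_bonds ({self.double_bonds}) exceeds carbons ({self.carbons})"
            )

    @property
    def label(self) -> str:
        return format_species(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_CARNITINE_RE = re.compile(r"C(\d+)(?::(\d+))?$")
_SPECIES_RE = re.compile(r"(.+?)\s+C(\d+)(?::(\d+))?$")


def parse_species(label: str) -> LipidSpecies:
    """Parse a species label such as ``"PCaa C36:4"``, ``"SM C24:1"`` or ``"C5"``.

    Bare ``C<n>[:<db>]`` labels are carnitines.  An ``IS `` prefix marks a
    deuterated internal standard.  Unknown classes and malformed labels raise
    :class:`LipidParseError` naming the offending token.
    """
    if label is None or not str(label).strip():
        raise LipidParseError("empty species label")
    text = str(label).strip()

    is_standard = False
    if text[:3].upper() == "IS ":
        is_standard = True
        text = text[3:].strip()

    m = _CARNITINE_RE.fullmatch(text)
    if m:
        carbons = int(m.group(1))
        db = int(m.group(2)) if m.group(2) is not None else 0
        return _build(LipidClass.CAR, carbons, db, is_standard, label)

    m = _SPECIES_RE.fullmatch(text)
    if not m:
        raise LipidParseError(f"cannot parse species label {label!r}")
    cls_token, carbons_s, db_s = m.group(1), m.group(2), m.group(3)
    lipid_class = lipid_class_from_code(cls_token)
    if db_s is None and lipid_class is not LipidClass.CAR:
        raise LipidParseError(
            f"label {label!r} lacks a double-bond count (expected '<class> C<carbons>:<db>')"
        )
    return _build(lipid_class, int(carbons_s), int(db_s or 0), is_standard, label)


def _build(
    cls: LipidClass, carbons: int, db: int, is_standard: bool, label: str
) -> LipidSpecies:
    try:
        return LipidSpecies(cls, carbons, db, is_standard)
    except ValueError as exc:
        raise LipidParseError(f"invalid species label {label!r}: {exc}") from None


def format_species(species: LipidSpecies) -> str:
    """Canonical text form of a species (inverse of :func:`parse_species`)."""
    cls = species.lipid_class
    if cls is LipidClass.CAR:
        body = f"C{species.carbons}"
        if species.double_bonds:
            body += f":{species.double_bonds}"
    elif cls is LipidClass.LYSO_PC:
        body = f"lyso-PC C{species.carbons:02d}:{species.double_bonds}"
    else:
        body = f"{cls.value} C{species.carbons}:{species.double_bonds}"
    return f"IS {body}" if species.is_standard else body
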