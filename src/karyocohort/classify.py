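"""Four-level hierarchical classification of a parsed karyotype.

Level 1 — mosaicism: ``mosaic`` / ``non_mosaic`` / ``polymorphism`` / ``normal``.
Level 2 — structural class: the set of abnormality categories present, plus a
single *primary* label chosen by a fixed precedence order.
Level 3 — chromosomal involvement: the chromosomes carrying any abnormality
(``mar`` is a valid label); hermaphroditism, triploidy and normal karyotypes
carry no chromosome annotation (``None``).
Level 4 — balance: ``balanced`` when no chromosomal material is gained or
lost (inversions, reciprocal translocations, carrier-form Robertsonian
fusions, all polymorphisms), ``unbalanced`` otherwise.

The cytogenetic polymorphism set comprises pericentric inversion of
chromosome 9, heterochromatin (qh) length variants, satellites (ps) and
satellite stalks (pstk); a polymorphism co-occurring with a true abnormality
does not soften the call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .iscn import (
    Abnormality,
    AbnormalityKind,
    Clone,
    Karyotype,
    NUMERICAL_KINDS,
    VARIANT_KINDS,
    parse_karyotype,
)

__all__ = [
    "Level1",
    "Level2",
    "Level4",
    "LEVEL2_PRECEDENCE",
    "ClassifiedResult",
    "classify",
    "classify_string",
    "classify_level1",
    "classify_level2",
    "classify_level3",
    "classify_level4",
    "is_polymorphism_abnormality",
]


class Level1(enum.StrEnum):
    MOSAIC = "mosaic"
    NON_MOSAIC = "non_mosaic"
    POLYMORPHISM = "polymorphism"
    NORMAL = "normal"


class Level2(enum.StrEnum):
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"
    DUPLICATION = "duplication"
    DELETION = "deletion"
    ISOCHROMOSOME = "isochromosome"
    PSU_DIC = "psu_dic"
    ROBERTSONIAN = "robertsonian"
    DERIVATIVE = "derivative"
    ADDITION = "addition"
    STRUCTURAL_ABERRATION = "structural_aberration"
    ANEUPLOIDY = "aneuploidy"
    TRIPLOID = "triploid"
    HERMAPHRODITISM = "hermaphroditism"
    LENGTH_POLYMORPHISM = "length_polymorphism"
    NORMAL = "normal"


class Level4(enum.StrEnum):
    BALANCED = "balanced"
    UNBALANCED = "unbalanced"


#: Primary-label precedence, highest first. A sample carrying several Level-2
#: labels is reported under the first of its labels in this order; the full
#: label set is retained alongside.
LEVEL2_PRECEDENCE: tuple[Level2, ...] = (
    Level2.HERMAPHRODITISM,
    Level2.TRIPLOID,
    Level2.ANEUPLOIDY,
    Level2.ROBERTSONIAN,
    Level2.TRANSLOCATION,
    Level2.DERIVATIVE,
    Level2.PSU_DIC,
    Level2.ISOCHROMOSOME,
    Level2.DELETION,
    Level2.DUPLICATION,
    Level2.ADDITION,
    Level2.INVERSION,
    Level2.STRUCTURAL_ABERRATION,
    Level2.LENGTH_POLYMORPHISM,
    Level2.NORMAL,
)

_PRECEDENCE_RANK = {label: i for i, label in enumerate(LEVEL2_PRECEDENCE)}

#: Level-3 carries no chromosome set for these primaries.
_NONE_SENTINEL_PRIMARIES = frozenset(
    {Level2.HERMAPHRODITISM, Level2.TRIPLOID, Level2.NORMAL}
)

_KIND_TO_LEVEL2 = {
    AbnormalityKind.NUMERICAL_GAIN: Level2.ANEUPLOIDY,
    AbnormalityKind.NUMERICAL_LOSS: Level2.ANEUPLOIDY,
    AbnormalityKind.MARKER_GAIN: Level2.ANEUPLOIDY,
    AbnormalityKind.INVERSION: Level2.INVERSION,
    AbnormalityKind.RECIPROCAL_TRANSLOCATION: Level2.TRANSLOCATION,
    AbnormalityKind.ROBERTSONIAN: Level2.ROBERTSONIAN,
    AbnormalityKind.DELETION: Level2.DELETION,
    AbnormalityKind.DUPLICATION: Level2.DUPLICATION,
    AbnormalityKind.ISOCHROMOSOME: Level2.ISOCHROMOSOME,
    AbnormalityKind.PSU_DIC: Level2.PSU_DIC,
    AbnormalityKind.DERIVATIVE: Level2.DERIVATIVE,
    AbnormalityKind.ADDITION: Level2.ADDITION,
    AbnormalityKind.HETEROCHROMATIN_VARIANT: Level2.LENGTH_POLYMORPHISM,
    AbnormalityKind.SATELLITE_VARIANT: Level2.LENGTH_POLYMORPHISM,
    AbnormalityKind.SATELLITE_STALK_VARIANT: Level2.LENGTH_POLYMORPHISM,
    AbnormalityKind.OTHER_STRUCTURAL: Level2.STRUCTURAL_ABERRATION,
}

#: Abnormality kinds that always gain or lose material.
_UNBALANCED_KINDS = NUMERICAL_KINDS | {
    AbnormalityKind.DELETION,
    AbnormalityKind.DUPLICATION,
    AbnormalityKind.ADDITION,
    AbnormalityKind.DERIVATIVE,
    AbnormalityKind.ISOCHROMOSOME,
    AbnormalityKind.PSU_DIC,
}


@dataclass(frozen=True, slots=True)
class ClassifiedResult:
    level1: Level1
    level2: frozenset[Level2]
    level2_primary: Level2
    level3: frozenset[str] | None
    level4: Level4

    def __post_init__(self) -> None:
        if (self.level1 is Level1.NORMAL) != (self.level2 == frozenset({Level2.NORMAL})):
            raise ValueError("level1=normal iff level2={normal}")
        if (self.level3 is None) != (self.level2_primary in _NONE_SENTINEL_PRIMARIES):
            raise ValueError("level3 is None exactly for hermaphroditism/triploid/normal")
        if self.level1 is Level1.POLYMORPHISM and self.level4 is not Level4.BALANCED:
            raise ValueError("polymorphisms are always balanced")


def is_polymorphism_abnormality(ab: Abnormality) -> bool:
    """True for the clinically neutral variants: inv(9) and qh/ps/pstk tokens."""
    if ab.kind in VARIANT_KINDS:
        return True
    return ab.kind is AbnormalityKind.INVERSION and ab.chromosomes == ("9",)


def _is_hermaphroditism(k: Karyotype) -> bool:
    """Exactly the coexistence of normal 46,XX and 46,XY cell lines."""
    if len(k.clones) != 2:
        return False
    if any(c.abnormalities or c.modal_number != 46 for c in k.clones):
        return False
    return {c.sex_designation for c in k.clones} == {"XX", "XY"}


def classify_level1(k: Karyotype) -> Level1:
    if _is_hermaphroditism(k):
        return Level1.NON_MOSAIC
    if len({c.genotype_key for c in k.clones}) >= 2:
        return Level1.MOSAIC
    clone = k.clones[0]
    if not clone.abnormalities:
        return Level1.NORMAL if clone.modal_number == 46 else Level1.NON_MOSAIC
    if all(is_polymorphism_abnormality(ab) for ab in clone.abnormalities):
        return Level1.POLYMORPHISM
    return Level1.NON_MOSAIC


def classify_level2(k: Karyotype) -> tuple[frozenset[Level2], Level2]:
    if _is_hermaphroditism(k):
        labels = frozenset({Level2.HERMAPHRODITISM})
        return labels, Level2.HERMAPHRODITISM
    found: set[Level2] = set()
    for clone in k.clones:
        if clone.modal_number == 69:
            found.add(Level2.TRIPLOID)
        for ab in clone.abnormalities:
            found.add(_KIND_TO_LEVEL2[ab.kind])
    if not found:
        found = {Level2.NORMAL}
    primary = min(found, key=_PRECEDENCE_RANK.__getitem__)
    return frozenset(found), primary


def classify_level3(k: Karyotype, level2_primary: Level2) -> frozenset[str] | None:
    if level2_primary in _NONE_SENTINEL_PRIMARIES:
        return None
    chroms: set[str] = set()
    for ab in k.all_abnormalities():
        chroms.update(ab.chromosomes)
    return frozenset(chroms)


def _rob_is_balanced(clone: Clone) -> bool:
    """A Robertsonian fusion is balanced only in carrier form.

    Both long arms must join at the centromere (q10;q10) and the modal number
    must drop by one per fusion after accounting for any numerical tokens —
    e.g. 45,XX,rob(13;14)(q10;q10) is balanced while
    46,XX,+13,rob(13;14)(q10;q10) is not.
    """
    fusions = [ab for ab in clone.abnormalities
               if ab.kind is AbnormalityKind.ROBERTSONIAN]
    for ab in fusions:
        if any(not b.is_centromeric for b in ab.breakpoints):
            return False
    gains = sum(1 for ab in clone.abnormalities if ab.kind in
                (AbnormalityKind.NUMERICAL_GAIN, AbnormalityKind.MARKER_GAIN))
    losses = sum(1 for ab in clone.abnormalities
                 if ab.kind is AbnormalityKind.NUMERICAL_LOSS)
    n_fused = len(fusions) + sum(
        1 for ab in clone.abnormalities if ab.kind is AbnormalityKind.PSU_DIC
    )
    expected = 44 + len(clone.sex_designation) + gains - losses - n_fused
    return clone.modal_number == expected


def classify_level4(k: Karyotype) -> Level4:
    if _is_hermaphroditism(k):
        return Level4.UNBALANCED
    for clone in k.clones:
        if clone.modal_number == 69:
            return Level4.UNBALANCED
        for ab in clone.abnormalities:
            if ab.kind in _UNBALANCED_KINDS:
                return Level4.UNBALANCED
            if ab.kind is AbnormalityKind.ROBERTSONIAN and not _rob_is_balanced(clone):
                return Level4.UNBALANCED
    return Level4.BALANCED


def classify(k: Karyotype) -> ClassifiedResult:
    """Run all four levels; pure and deterministic."""
    level1 = classify_level1(k)
    level2, primary = classify_level2(k)
    level3 = classify_level3(k, primary)
    level4 = classify_level4(k)
    return ClassifiedResult(level1, level2, primary, level3, level4)


def classify_string(text: str) -> ClassifiedResult:
    """Convenience wrapper: parse an ISCN string and classify it."""
    return classify(parse_karyotype(text))
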