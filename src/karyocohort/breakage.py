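"""Counting of chromosomal breakage events outside centromeric regions.

Every breakpoint written in a structural token counts as one event unless it
sits at the centromere (band designation "10" on either arm). Hence a
pericentric inversion contributes two events, a reciprocal translocation one
per involved chromosome, an interstitial deletion two and a terminal deletion
one, while carrier-form Robertsonian fusions (q10;q10) and whole-arm
isochromosomes (p10/q10) contribute none. Length-variant polymorphism tokens
(qh+/-, ps+, pstk+) carry no breakpoints. Identical abnormalities repeated
across clones of a mosaic are counted once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .classify import Level1
from .iscn import AbnormalityKind, Band, Karyotype, parse_karyotype

__all__ = ["BreakageSummary", "CohortBreakage", "extract_breakage", "cohort_breakage"]


@dataclass(frozen=True, slots=True)
class BreakageSummary:
    """Non-centromeric breakage events of one karyotype."""

    events: tuple[tuple[str, Band], ...]
    n_unresolved_derivatives: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def per_chromosome(self) -> dict[str, int]:
        return dict(Counter(chrom for chrom, _ in self.events))


def extract_breakage(k: Karyotype) -> BreakageSummary:
    """One event per non-centromeric breakpoint over all distinct abnormalities."""
    events: list[tuple[str, Band]] = []
    unresolved = 0
    for ab in k.distinct_abnormalities():
        if ab.kind is AbnormalityKind.DERIVATIVE and not ab.breakpoints:
            unresolved += 1  # der without breakpoint detail: 0 events, flagged
            continue
        for band in ab.breakpoints:
            if not band.is_centromeric:
                events.append((band.chromosome, band))
    return BreakageSummary(tuple(events), unresolved)


@dataclass(slots=True)
class CohortBreakage:
    """Cohort-level breakage tally stratified by Level-1 class."""

    n_fetuses: int = 0
    fetuses_by_level1: dict[str, int] = field(default_factory=dict)
    events_by_chromosome: dict[str, int] = field(default_factory=dict)
    total_events: int = 0


def cohort_breakage(
    items: Iterable[tuple[Karyotype | str, Level1 | str]],
) -> CohortBreakage:
    """Tally fetuses with >=1 breakage event and events per chromosome.

    ``items`` yields (karyotype, level1) pairs; karyotypes may be given as
    ISCN strings. Fetus counts are stratified by the Level-1 class, so the
    polymorphic inv(9) carriers form their own stratum; strata always sum to
    the total number of fetuses with events.
    """
    out = CohortBreakage()
    per_chrom: Counter[str] = Counter()
    strata: Counter[str] = Counter()
    for karyotype, level1 in items:
        k = parse_karyotype(karyotype) if isinstance(karyotype, str) else karyotype
        summary = extract_breakage(k)
        if summary.n_events == 0:
            continue
        out.n_fetuses += 1
        strata[str(level1)] += 1
        out.total_events += summary.n_events
        per_chrom.update(summary.per_chromosome)
    out.fetuses_by_level1 = dict(strata)
    out.events_by_chromosome = dict(per_chrom)
    return out
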