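"""Searchable karyotype store.

Distinct abnormal karyotype strings from a classified cohort, deduplicated
with occurrence counts, filterable by chromosome, mosaicism class (Level 1),
structural class (Level 2) and balance status (Level 4) — the query semantics
of an interactive karyotype-lookup service, as a flat table instead of a
hosted app. "None" is a queryable chromosome value and returns the records
(triploids, hermaphroditism) that carry no chromosome annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .classify import ClassifiedResult, Level1, Level2, Level4, classify_string
from .iscn import CHROMOSOMES

__all__ = ["KaryotypeRecord", "KaryotypeStore", "build_store", "query"]

_VALID_CHROMS = set(CHROMOSOMES) | {"mar", "None"}


@dataclass(frozen=True, slots=True)
class KaryotypeRecord:
    karyotype: str
    result: ClassifiedResult
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("occurrence count must be >= 1")


@dataclass(frozen=True)
class KaryotypeStore:
    records: tuple[KaryotypeRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "karyotype": r.karyotype,
                "count": r.count,
                "level1": str(r.result.level1),
                "level2_all": ";".join(sorted(map(str, r.result.level2))),
                "level2_primary": str(r.result.level2_primary),
                "level3": "None" if r.result.level3 is None
                else ";".join(sorted(r.result.level3)),
                "level4": str(r.result.level4),
            })
        return pd.DataFrame(
            rows, columns=["karyotype", "count", "level1", "level2_all",
                           "level2_primary", "level3", "level4"])


def build_store(
    cohort: Iterable[str | tuple[str, ClassifiedResult]],
) -> KaryotypeStore:
    """Deduplicate the abnormal karyotypes of a classified cohort.

    Accepts bare ISCN strings (classified on the fly) or (string, result)
    pairs. Normal karyotypes are excluded; records are ordered by descending
    count, then lexicographically.
    """
    counts: dict[str, int] = {}
    results: dict[str, ClassifiedResult] = {}
    for item in cohort:
        if isinstance(item, str):
            s, res = item, None
        else:
            s, res = item
        s = s.strip()
        counts[s] = counts.get(s, 0) + 1
        if res is not None and s not in results:
            results[s] = res
    records = []
    for s, n in counts.items():
        res = results.get(s) or classify_string(s)
        if res.level1 is Level1.NORMAL:
            continue
        records.append(KaryotypeRecord(s, res, n))
    records.sort(key=lambda r: (-r.count, r.karyotype))
    return KaryotypeStore(tuple(records))


def _check(value: str, valid: set[str], what: str) -> str:
    if value not in valid:
        raise ValueError(f"invalid {what} {value!r}; valid values: {sorted(valid)}")
    return value


def query(
    store: KaryotypeStore,
    chromosome: str | None = None,
    level1: str | None = None,
    level2: str | None = None,
    level4: str | None = None,
) -> list[KaryotypeRecord]:
    """Conjunctive filter over the store; omitted filters match everything.

    A chromosome matches when it is in the record's Level-3 set (or when
    the filter value is "None" and the record has no chromosome set).
    """
    if chromosome is not None:
        chromosome = _check(str(chromosome), _VALID_CHROMS, "chromosome")
    if level1 is not None:
        level1 = _check(str(level1), {str(v) for v in Level1}, "level1 class")
    if level2 is not None:
        level2 = _check(str(level2), {str(v) for v in Level2}, "level2 class")
    if level4 is not None:
        level4 = _check(str(level4), {str(v) for v in Level4}, "balance status")

    out = []
    for r in store.records:
        if chromosome is not None:
            if chromosome == "None":
                if r.result.level3 is not None:
                    continue
            elif r.result.level3 is None or chromosome not in r.result.level3:
                continue
        if level1 is not None and str(r.result.level1) != level1:
            continue
        if level2 is not None and level2 not in {str(x) for x in r.result.level2}:
            continue
        if level4 is not None and str(r.result.level4) != level4:
            continue
        out.append(r)
    return out
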