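"""Cohort-level rate tables.

All percentages in this package go through :func:`rate`, which rounds
half-up to two decimals (so 353/38,636 prints as 0.91 and 690/1,663 as
41.49). Tables are tidy pandas DataFrames with ``count``, ``denominator``
and ``percent`` columns next to their grouping keys, and every percent can
be recomputed from its own row.

The denominator convention everywhere is the number of successfully
karyotyped samples: rows whose ``karyotype`` is missing (failed cultures)
are dropped by :func:`classify_cohort` before any rate is formed.
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .classify import Level1, Level2, Level4, classify_string
from .indications import IndicationRecord, ScreeningThresholds, primary_indication
from .iscn import AbnormalityKind, Karyotype, parse_karyotype

__all__ = [
    "rate",
    "classify_cohort",
    "add_indications",
    "level1_table",
    "category_rates",
    "pair_counts",
    "unbalanced_by_indication",
]


def rate(count: int, denominator: int) -> float:
    """Percentage ``100*count/denominator`` rounded half-up to two decimals."""
    if denominator <= 0:
        raise ZeroDivisionError("rate denominator must be > 0")
    if not (0 <= count <= denominator):
        raise ValueError("count must lie in [0, denominator]")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


_LEVEL3_NONE = "None"


def classify_cohort(df: pd.DataFrame, karyotype_column: str = "karyotype") -> pd.DataFrame:
    """Parse and classify every successful sample of a cohort table.

    Returns a copy restricted to rows with a karyotype string, with appended
    columns ``level1``, ``level2_all`` (semicolon-joined), ``level2_primary``,
    ``level3`` (semicolon-joined or "None") and ``level4``.
    """
    mask = df[karyotype_column].notna() & (df[karyotype_column].astype(str).str.strip() != "")
    out = df.loc[mask].copy()
    results = [classify_string(s) for s in out[karyotype_column]]
    out["level1"] = [str(r.level1) for r in results]
    out["level2_all"] = [";".join(sorted(map(str, r.level2))) for r in results]
    out["level2_primary"] = [str(r.level2_primary) for r in results]
    out["level3"] = [
        _LEVEL3_NONE if r.level3 is None else ";".join(sorted(r.level3)) for r in results
    ]
    out["level4"] = [str(r.level4) for r in results]
    return out


def add_indications(
    df: pd.DataFrame, thresholds: ScreeningThresholds | None = None
) -> pd.DataFrame:
    """Append a ``primary_indication`` column computed from the record fields."""
    out = df.copy()

    def _opt(v):
        return None if pd.isna(v) else float(v)

    primaries = []
    for row in out.itertuples(index=False):
        record = IndicationRecord(
            maternal_age_at_edd=float(row.maternal_age_at_edd),
            year=int(row.year),
            serum_t21_risk=_opt(getattr(row, "serum_t21_risk", None)),
            serum_t18_risk=_opt(getattr(row, "serum_t18_risk", None)),
            afp_mom=_opt(getattr(row, "afp_mom", None)),
            nt_mm=_opt(getattr(row, "nt_mm", None)),
            nipt_z_21=_opt(getattr(row, "nipt_z_21", None)),
            nipt_z_18=_opt(getattr(row, "nipt_z_18", None)),
            nipt_z_13=_opt(getattr(row, "nipt_z_13", None)),
            ultrasound_structural=bool(getattr(row, "ultrasound_structural", False)),
            parent_chromosomal_abnormality=bool(getattr(row, "parent_chromosomal_abnormality", False)),
            prior_chromosomal_pregnancy=bool(getattr(row, "prior_chromosomal_pregnancy", False)),
            parent_intellectual_disability=bool(getattr(row, "parent_intellectual_disability", False)),
            monogenic_disease=bool(getattr(row, "monogenic_disease", False)),
            cord_blood_sample=bool(getattr(row, "cord_blood_sample", False)),
            adverse_history=bool(getattr(row, "adverse_history", False)),
        )
        primaries.append(str(primary_indication(record, thresholds)))
    out["primary_indication"] = primaries
    return out


def level1_table(classified: pd.DataFrame, by_year: bool = False) -> pd.DataFrame:
    """Counts and percents of the four Level-1 classes; they partition each denominator."""
    if classified.empty:
        raise ValueError("cannot tabulate an empty cohort")
    classes = [str(c) for c in Level1]

    def _one(sub: pd.DataFrame, keys: dict) -> list[dict]:
        denom = len(sub)
        counts = sub["level1"].value_counts()
        return [
            {**keys, "level1": c, "count": int(counts.get(c, 0)),
             "denominator": denom, "percent": rate(int(counts.get(c, 0)), denom)}
            for c in classes
        ]

    rows: list[dict] = []
    if by_year:
        for year, sub in classified.groupby("year"):
            rows.extend(_one(sub, {"year": int(year)}))
    else:
        rows.extend(_one(classified, {}))
    return pd.DataFrame(rows)


def _contains_label(series: pd.Series, label: str) -> pd.Series:
    return series.str.split(";").map(lambda labels: label in labels)


def category_rates(
    classified: pd.DataFrame, level2_label: str, stratify_by_level1: bool = False
) -> pd.DataFrame:
    """Per-chromosome rates for one Level-2 category.

    Unstratified: each chromosome's count over the whole-cohort denominator
    (an incidence). Stratified: a chromosome's share *within* the mosaic and
    within the non-mosaic carriers of the category, i.e. the denominator is
    the stratum's case count.
    """
    valid = {str(v) for v in Level2}
    if level2_label not in valid:
        raise ValueError(f"unknown level-2 label {level2_label!r}; valid: {sorted(valid)}")
    subset = classified.loc[_contains_label(classified["level2_all"], level2_label)]
    rows: list[dict] = []
    if subset.empty:
        return pd.DataFrame(
            columns=(["level1"] if stratify_by_level1 else [])
            + ["chromosome", "count", "denominator", "percent"]
        )

    def _chrom_counts(sub: pd.DataFrame) -> Counter:
        c: Counter = Counter()
        for val in sub["level3"]:
            if val != _LEVEL3_NONE:
                c.update(val.split(";"))
        return c

    if stratify_by_level1:
        for stratum, sub in subset.groupby("level1"):
            denom = len(sub)
            for chrom, n in sorted(_chrom_counts(sub).items()):
                rows.append({"level1": stratum, "chromosome": chrom, "count": n,
                             "denominator": denom, "percent": rate(n, denom)})
    else:
        denom = len(classified)
        for chrom, n in sorted(_chrom_counts(subset).items()):
            rows.append({"chromosome": chrom, "count": n,
                         "denominator": denom, "percent": rate(n, denom)})
    return pd.DataFrame(rows)


def pair_counts(
    karyotypes: Iterable[Karyotype | str],
    kind: str = "robertsonian",
) -> tuple[dict[tuple[str, str], int], int]:
    """Unordered chromosome-pair tallies for translocations.

    ``kind`` is "robertsonian" or "reciprocal_translocation". Three-way
    translocations contribute each unordered pair; the second return value
    counts how many multi-way tokens were seen, so they can be reported
    separately.
    """
    try:
        want = AbnormalityKind(kind)
    except ValueError as exc:
        raise ValueError(
            "kind must be 'robertsonian' or 'reciprocal_translocation'"
        ) from exc
    if want not in (AbnormalityKind.ROBERTSONIAN, AbnormalityKind.RECIPROCAL_TRANSLOCATION):
        raise ValueError("kind must be 'robertsonian' or 'reciprocal_translocation'")
    tally: Counter[tuple[str, str]] = Counter()
    n_multiway = 0
    for item in karyotypes:
        k = parse_karyotype(item) if isinstance(item, str) else item
        for ab in k.distinct_abnormalities():
            if ab.kind is not want:
                continue
            chroms = list(ab.chromosomes)
            if len(chroms) > 2:
                n_multiway += 1
            for i in range(len(chroms)):
                for j in range(i + 1, len(chroms)):
                    pair = tuple(sorted((chroms[i], chroms[j]), key=_chrom_sort_key))
                    tally[pair] += 1
    return dict(tally), n_multiway


def _chrom_sort_key(c: str) -> tuple[int, str]:
    return (int(c), "") if c.isdigit() else (100, c)


def unbalanced_by_indication(classified_with_indications: pd.DataFrame) -> pd.DataFrame:
    """Rate of unbalanced results within each primary-indication group."""
    rows = []
    for ind, sub in classified_with_indications.groupby("primary_indication"):
        denom = len(sub)
        n_unbal = int((sub["level4"] == str(Level4.UNBALANCED)).sum())
        rows.append({"primary_indication": ind, "count": n_unbal,
                     "denominator": denom, "percent": rate(n_unbal, denom)})
    return pd.DataFrame(rows).sort_values("percent", ascending=False, ignore_index=True)
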