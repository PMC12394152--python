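"""Prenatal-diagnosis indication rules.

Each sample's clinical record maps onto one of twelve referral categories
via the screening cutoffs used in routine practice: advanced maternal age
(>= 35 years at the estimated due date), high-risk serum screening (trisomy-21
risk > 1/270, trisomy-18 risk > 1/350, or AFP > 2.5 MoM), increased nuchal
translucency (> 3.0 mm), high-risk NIPT (trisomy 21/18/13 Z-score > 3),
ultrasound structural anomalies, parental chromosomal abnormality, a prior
chromosomally abnormal pregnancy, parental intellectual disability,
monogenic disease, cord-blood sampling, adverse pregnancy history, and a
residual "others" category that fires only when nothing else does.

Boundary behaviour is deliberate: the age cutoff is inclusive ("at or beyond
35"), every other threshold is a strict inequality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Indication",
    "ScreeningThresholds",
    "IndicationRecord",
    "DEFAULT_PRECEDENCE",
    "eligible_indications",
    "primary_indication",
]


class Indication(enum.StrEnum):
    ADVANCED_MATERNAL_AGE = "advanced_maternal_age"
    HIGH_RISK_SERUM = "high_risk_serum"
    INCREASED_NT = "increased_NT"
    HIGH_RISK_NIPT = "high_risk_NIPT"
    ULTRASOUND_STRUCTURAL = "ultrasound_structural"
    PARENT_CHROMOSOMAL_ABNORMALITY = "parent_chromosomal_abnormality"
    PRIOR_CHROMOSOMAL_PREGNANCY = "prior_chromosomal_pregnancy"
    PARENT_INTELLECTUAL_DISABILITY = "parent_intellectual_disability"
    MONOGENIC_DISEASE = "monogenic_disease"
    CORD_BLOOD = "cord_blood"
    ADVERSE_HISTORY = "adverse_history"
    OTHERS = "others"


@dataclass(frozen=True, slots=True)
class ScreeningThresholds:
    """Referral cutoffs; risks are fractions, NT in mm, ages in years."""

    t21_serum_risk: float = 1 / 270
    t18_serum_risk: float = 1 / 350
    afp_mom: float = 2.5
    nt_mm: float = 3.0
    nipt_z: float = 3.0
    advanced_age_years: float = 35.0

    def __post_init__(self) -> None:
        for name in ("t21_serum_risk", "t18_serum_risk"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be a risk fraction in (0,1)")
        for name in ("afp_mom", "nt_mm", "nipt_z", "advanced_age_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True, slots=True)
class IndicationRecord:
    """One sample's clinical screening fields; absent measurements are None."""

    maternal_age_at_edd: float
    year: int
    serum_t21_risk: float | None = None
    serum_t18_risk: float | None = None
    afp_mom: float | None = None
    nt_mm: float | None = None
    nipt_z_21: float | None = None
    nipt_z_18: float | None = None
    nipt_z_13: float | None = None
    ultrasound_structural: bool = False
    parent_chromosomal_abnormality: bool = False
    prior_chromosomal_pregnancy: bool = False
    parent_intellectual_disability: bool = False
    monogenic_disease: bool = False
    cord_blood_sample: bool = False
    adverse_history: bool = False

    def __post_init__(self) -> None:
        if not (10 <= self.maternal_age_at_edd <= 60):
            raise ValueError("maternal age must lie in [10, 60] years")
        if self.nt_mm is not None and self.nt_mm < 0:
            raise ValueError("NT cannot be negative")
        if not (2010 <= self.year <= 2024):
            raise ValueError("year must lie in [2010, 2024]")


#: Default single-assignment priority, strongest first; "others" is implicit
#: last because it never co-occurs with another eligible category.
DEFAULT_PRECEDENCE: tuple[Indication, ...] = (
    Indication.ULTRASOUND_STRUCTURAL,
    Indication.INCREASED_NT,
    Indication.HIGH_RISK_NIPT,
    Indication.HIGH_RISK_SERUM,
    Indication.PARENT_CHROMOSOMAL_ABNORMALITY,
    Indication.PRIOR_CHROMOSOMAL_PREGNANCY,
    Indication.MONOGENIC_DISEASE,
    Indication.PARENT_INTELLECTUAL_DISABILITY,
    Indication.CORD_BLOOD,
    Indication.ADVERSE_HISTORY,
    Indication.ADVANCED_MATERNAL_AGE,
    Indication.OTHERS,
)


def _gt(value: float | None, threshold: float) -> bool:
    return value is not None and value > threshold


def eligible_indications(
    r: IndicationRecord, th: ScreeningThresholds | None = None
) -> frozenset[Indication]:
    """All categories whose rule fires; {others} iff none does."""
    th = th or ScreeningThresholds()
    fired: set[Indication] = set()
    if r.maternal_age_at_edd >= th.advanced_age_years:
        fired.add(Indication.ADVANCED_MATERNAL_AGE)
    if (
        _gt(r.serum_t21_risk, th.t21_serum_risk)
        or _gt(r.serum_t18_risk, th.t18_serum_risk)
        or _gt(r.afp_mom, th.afp_mom)
    ):
        fired.add(Indication.HIGH_RISK_SERUM)
    if _gt(r.nt_mm, th.nt_mm):
        fired.add(Indication.INCREASED_NT)
    if _gt(r.nipt_z_21, th.nipt_z) or _gt(r.nipt_z_18, th.nipt_z) or _gt(r.nipt_z_13, th.nipt_z):
        fired.add(Indication.HIGH_RISK_NIPT)
    if r.ultrasound_structural:
        fired.add(Indication.ULTRASOUND_STRUCTURAL)
    if r.parent_chromosomal_abnormality:
        fired.add(Indication.PARENT_CHROMOSOMAL_ABNORMALITY)
    if r.prior_chromosomal_pregnancy:
        fired.add(Indication.PRIOR_CHROMOSOMAL_PREGNANCY)
    if r.parent_intellectual_disability:
        fired.add(Indication.PARENT_INTELLECTUAL_DISABILITY)
    if r.monogenic_disease:
        fired.add(Indication.MONOGENIC_DISEASE)
    if r.cord_blood_sample:
        fired.add(Indication.CORD_BLOOD)
    if r.adverse_history:
        fired.add(Indication.ADVERSE_HISTORY)
    if not fired:
        fired.add(Indication.OTHERS)
    return frozenset(fired)


def primary_indication(
    r: IndicationRecord,
    th: ScreeningThresholds | None = None,
    precedence: tuple[Indication, ...] = DEFAULT_PRECEDENCE,
) -> Indication:
    """Highest-priority eligible category under the configured precedence."""
    fired = eligible_indications(r, th)
    for cat in precedence:
        if cat in fired:
            return cat
    raise AssertionError("eligible_indications always yields at least one category")
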