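"""Seeded synthetic amniocentesis-cohort generator.

Emulates a large amniotic-fluid karyotyping service: each sample gets a
clinical screening record (maternal age, serum risks, NT, NIPT Z-scores,
referral flags), a calendar year, and an ISCN karyotype string drawn from
configurable frequency tables, alongside ground-truth four-level labels
constructed from the template that produced the string. A small fraction of
samples fail culture and carry no karyotype.

Default frequencies reproduce the category structure of a ~38,6k-sample
amniocentesis population: Level-1 mix 4.68% non-mosaic / 0.71% mosaic /
1.70% polymorphism / 92.91% normal; polymorphisms split 353:302 between
inv(9) and length variants (Y-chromosome heterochromatin most common);
aneuploidy dominated by trisomy 21 among non-mosaics and by X-chromosome
aneuploidy among mosaics; Robertsonian fusions led by rob(13;14); reciprocal
translocations led by t(11;22). Weights marked ``non-authoritative`` in the
comments fill gaps where only qualitative ordering is known; they are
configuration, not measurement.

Identical :class:`CohortConfig` values (including the seed) yield
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ClassifiedResult, Level1, Level2, Level4
from .indications import Indication, IndicationRecord

__all__ = [
    "CohortConfig",
    "SyntheticSample",
    "generate_cohort",
    "sample_abnormal_karyotype",
    "cohort_to_dataframe",
    "default_indication_mix",
]

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_LEVEL1_PROBS: dict[str, float] = {
    "non_mosaic": 0.0468,
    "mosaic": 0.0071,
    "polymorphism": 0.0170,
    "normal": 0.9291,
}

# Non-mosaic Level-2 case weights (counts per ~38.6k samples). Translocation/
# derivative split the printed 187 joint count; dup/add/psu dic/triploid/
# hermaphroditism are non-authoritative small remainders.
_DEFAULT_NONMOSAIC_MIX: dict[str, float] = {
    "aneuploidy": 1338,
    "inversion": 70,
    "robertsonian": 97,
    "translocation": 160,
    "derivative": 27,
    "deletion": 64,
    "isochromosome": 6,
    "duplication": 12,
    "addition": 10,
    "psu_dic": 4,
    "triploid": 10,
    "hermaphroditism": 4,
}

_DEFAULT_MOSAIC_MIX: dict[str, float] = {
    "aneuploidy": 219,
    "inversion": 2,
    "robertsonian": 2,
    "translocation": 31,
    "deletion": 8,
    "isochromosome": 13,
}

_DEFAULT_POLYMORPHISM_SPLIT: dict[str, float] = {"inv9": 353, "length": 302}

# Length-polymorphism chromosome shares (%): Y and 15 lead; rest spread over
# the heterochromatin (1, 9, 16) and satellite (13, 14, 21, 22) carriers
# (non-authoritative beyond the two leaders).
_DEFAULT_LENGTH_POLY_CHROMS: dict[str, float] = {
    "Y": 18.69, "15": 17.38, "14": 11.0, "21": 10.5, "22": 10.0,
    "13": 9.5, "1": 8.0, "16": 7.93, "9": 7.0,
}

_DEFAULT_ANEUPLOIDY_CHROMS_NONMOSAIC: dict[str, float] = {
    "21": 52.09, "X": 29.00, "18": 15.17, "13": 1.95, "mar": 1.64, "Y": 0.15,
}

# Mosaic aneuploidy remainder beyond the five printed shares is spread over
# two mid-size autosomes (non-authoritative).
_DEFAULT_ANEUPLOIDY_CHROMS_MOSAIC: dict[str, float] = {
    "X": 46.12, "21": 14.61, "mar": 13.24, "Y": 11.42, "18": 3.65,
    "13": 2.96, "8": 4.0, "20": 4.0,
}

# Robertsonian pair table: 11 types totalling 99 cases; tail weights beyond
# the three printed leaders are non-authoritative.
_DEFAULT_ROB_PAIRS: dict[tuple[str, str], float] = {
    ("13", "14"): 47, ("14", "21"): 15, ("21", "21"): 14, ("13", "21"): 5,
    ("14", "15"): 4, ("15", "21"): 4, ("13", "13"): 3, ("14", "22"): 3,
    ("15", "22"): 2, ("21", "22"): 1, ("22", "22"): 1,
}

# Reciprocal pairs: two printed leaders plus a diffuse tail drawn uniformly.
_DEFAULT_RECIPROCAL_PAIRS: dict[tuple[str, str], float] = {
    ("11", "22"): 8, ("2", "10"): 5,
}
_DEFAULT_RECIPROCAL_TAIL_WEIGHT = 30.0

# Inversion chromosomes other than 9 (Y, 10, 1 printed; tail non-authoritative).
_DEFAULT_INVERSION_CHROMS: dict[str, float] = {
    "Y": 23, "10": 8, "1": 7, "2": 5, "7": 5, "5": 4, "11": 4, "3": 3,
    "4": 3, "6": 3, "8": 2, "12": 2, "18": 2, "20": 1,
}

_DEFAULT_DELETION_CHROMS: dict[str, float] = {
    "5": 11, "X": 11, "18": 10, "4": 6, "7": 5, "11": 4, "13": 4,
    "1": 3, "2": 3, "3": 3, "6": 3, "9": 3, "10": 2, "15": 2, "22": 2,
}

_DEFAULT_ISO_CHROMS: dict[str, float] = {"X": 14, "Y": 4, "12": 1}

_YEARS = tuple(y for y in range(2010, 2025))


def default_indication_mix(year: int) -> dict[str, float]:
    """Per-year indication weights (%): advanced maternal age dominates
    throughout; serum screening declines over the years while NIPT, NT and
    ultrasound referrals rise."""
    t = year - 2010
    w = {
        str(Indication.ADVANCED_MATERNAL_AGE): 58.59,
        str(Indication.HIGH_RISK_SERUM): max(3.0, 24.0 - 1.5 * t),
        str(Indication.HIGH_RISK_NIPT): min(18.0, max(0.2, 1.4 * (t - 2))),
        str(Indication.INCREASED_NT): 2.0 + 0.25 * t,
        str(Indication.ULTRASOUND_STRUCTURAL): 3.0 + 0.45 * t,
        str(Indication.PARENT_CHROMOSOMAL_ABNORMALITY): 0.8,
        str(Indication.PRIOR_CHROMOSOMAL_PREGNANCY): 0.6,
        str(Indication.PARENT_INTELLECTUAL_DISABILITY): 0.1,
        str(Indication.MONOGENIC_DISEASE): 0.3,
        str(Indication.CORD_BLOOD): 0.05,
        str(Indication.ADVERSE_HISTORY): 1.5,
        str(Indication.OTHERS): 1.2,
    }
    return w


@dataclass(frozen=True)
class CohortConfig:
    """Frequency parameterisation of the generator; the seed fixes everything."""

    n_samples: int = 38_636
    seed: int = 0
    level1_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LEVEL1_PROBS))
    nonmosaic_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NONMOSAIC_MIX))
    mosaic_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MOSAIC_MIX))
    polymorphism_split: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_POLYMORPHISM_SPLIT))
    length_poly_chroms: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_POLY_CHROMS))
    failure_rate: float = 16 / 38_652

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not (0 <= self.failure_rate < 1):
            raise ValueError("failure_rate must lie in [0, 1)")
        missing = set(_DEFAULT_LEVEL1_PROBS) - set(self.level1_probs)
        if missing:
            raise ValueError(f"level1_probs missing classes: {sorted(missing)}")
        total = sum(self.level1_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"level1_probs must sum to 1, got {total}")
        for name in ("level1_probs", "nonmosaic_mix", "mosaic_mix",
                     "polymorphism_split", "length_poly_chroms"):
            table = getattr(self, name)
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} contains a negative weight")
            if name != "level1_probs" and sum(table.values()) <= 0:
                raise ValueError(f"{name} has no positive weight")


@dataclass(frozen=True)
class SyntheticSample:
    sample_id: str
    year: int
    record: IndicationRecord
    karyotype: str | None
    truth: ClassifiedResult | None


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _pick(rng: np.random.Generator, table: Mapping):
    keys = list(table.keys())
    weights = np.asarray([table[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


_BAND_POOL = ("11", "12", "13", "21", "22", "23", "31", "32", "33")


def _band(rng: np.random.Generator) -> str:
    return _BAND_POOL[int(rng.integers(len(_BAND_POOL)))]


def _sex(rng: np.random.Generator) -> str:
    return "XX" if rng.random() < 0.5 else "XY"


def _result(level1: Level1, labels: set[Level2], primary: Level2,
            chroms: set[str] | None, level4: Level4) -> ClassifiedResult:
    return ClassifiedResult(
        level1, frozenset(labels), primary,
        None if chroms is None else frozenset(chroms), level4,
    )


def _aneuploid_clone(rng: np.random.Generator, chrom: str) -> tuple[str, str, set[str]]:
    """Return (abnormal clone body, matching normal clone body, chromosomes)."""
    if chrom == "X":
        pick = rng.random()
        if pick < 0.5:
            return "45,X", "46,XX", {"X"}
        if pick < 0.8:
            return "47,XXX", "46,XX", {"X"}
        return "47,XXY", "46,XY", {"X"}
    if chrom == "Y":
        return "47,XYY", "46,XY", {"Y"}
    sex = _sex(rng)
    if chrom == "mar":
        return f"47,{sex},+mar", f"46,{sex}", {"mar"}
    return f"47,{sex},+{chrom}", f"46,{sex}", {chrom}


def _structural_clone(
    rng: np.random.Generator, category: str
) -> tuple[str, str, set[str], Level4]:
    """Return (abnormal clone body, normal clone body, chromosomes, balance)."""
    if category == "inversion":
        chrom = _pick(rng, _DEFAULT_INVERSION_CHROMS)
        sex = "XY" if chrom == "Y" else _sex(rng)
        body = f"46,{sex},inv({chrom})(p11q{_band(rng)[0]}1)" if chrom == "Y" else \
            f"46,{sex},inv({chrom})(p1{int(rng.integers(1, 4))}q2{int(rng.integers(1, 4))})"
        return body, f"46,{sex}", {chrom}, Level4.BALANCED
    if category == "robertsonian":
        pair = _pick(rng, _DEFAULT_ROB_PAIRS)
        sex = _sex(rng)
        word = "rob" if rng.random() < 0.8 else "der"
        body = f"45,{sex},{word}({pair[0]};{pair[1]})(q10;q10)"
        return body, f"46,{sex}", set(pair), Level4.BALANCED
    if category == "translocation":
        table = dict(_DEFAULT_RECIPROCAL_PAIRS)
        table[("__tail__", "__tail__")] = _DEFAULT_RECIPROCAL_TAIL_WEIGHT
        pair = _pick(rng, table)
        if pair[0] == "__tail__":
            labels = [str(i) for i in range(1, 23)]
            i, j = rng.choice(len(labels), size=2, replace=False)
            pair = (labels[int(i)], labels[int(j)])
        sex = _sex(rng)
        body = f"46,{sex},t({pair[0]};{pair[1]})(q{_band(rng)};p{_band(rng)})"
        return body, f"46,{sex}", set(pair), Level4.BALANCED
    if category == "derivative":
        labels = [str(i) for i in range(1, 23)]
        i, j = rng.choice(len(labels), size=2, replace=False)
        a, b = labels[int(i)], labels[int(j)]
        sex = _sex(rng)
        body = f"46,{sex},der({a})t({a};{b})(q{_band(rng)};q{_band(rng)})"
        return body, f"46,{sex}", {a, b}, Level4.UNBALANCED
    if category == "deletion":
        chrom = _pick(rng, _DEFAULT_DELETION_CHROMS)
        sex = "X" if chrom == "X" else _sex(rng)
        if rng.random() < 0.5:
            detail = f"del({chrom})(q{_band(rng)})"
        else:
            detail = f"del({chrom})(q1{int(rng.integers(1, 4))}q3{int(rng.integers(1, 4))})"
        normal = "46,XX" if chrom == "X" else f"46,{sex}"
        return f"46,{sex},{detail}", normal, {chrom}, Level4.UNBALANCED
    if category == "isochromosome":
        chrom = _pick(rng, _DEFAULT_ISO_CHROMS)
        if chrom in ("X", "Y"):
            return f"46,X,i({chrom})(q10)", "46,XX" if chrom == "X" else "46,XY", \
                {chrom}, Level4.UNBALANCED
        sex = _sex(rng)
        return f"46,{sex},i({chrom})(q10)", f"46,{sex}", {chrom}, Level4.UNBALANCED
    if category == "duplication":
        labels = [str(i) for i in range(1, 23)]
        chrom = labels[int(rng.integers(len(labels)))]
        sex = _sex(rng)
        body = f"46,{sex},dup({chrom})(q1{int(rng.integers(1, 4))}q3{int(rng.integers(1, 4))})"
        return body, f"46,{sex}", {chrom}, Level4.UNBALANCED
    if category == "addition":
        labels = [str(i) for i in range(1, 23)]
        chrom = labels[int(rng.integers(len(labels)))]
        sex = _sex(rng)
        return f"46,{sex},add({chrom})(p{_band(rng)})", f"46,{sex}", {chrom}, Level4.UNBALANCED
    if category == "psu_dic":
        pair = ("21", "14") if rng.random() < 0.5 else ("15", "15")
        sex = _sex(rng)
        body = f"45,{sex},psu dic({pair[0]};{pair[1]})(q22;q11)"
        return body, f"46,{sex}", set(pair), Level4.UNBALANCED
    raise ValueError(f"unknown structural category {category!r}")


_CATEGORY_TO_LEVEL2 = {
    "aneuploidy": Level2.ANEUPLOIDY,
    "inversion": Level2.INVERSION,
    "robertsonian": Level2.ROBERTSONIAN,
    "translocation": Level2.TRANSLOCATION,
    "derivative": Level2.DERIVATIVE,
    "deletion": Level2.DELETION,
    "isochromosome": Level2.ISOCHROMOSOME,
    "duplication": Level2.DUPLICATION,
    "addition": Level2.ADDITION,
    "psu_dic": Level2.PSU_DIC,
}


def sample_abnormal_karyotype(
    category: str,
    rng: np.random.Generator,
    mosaic: bool = False,
    cfg: CohortConfig | None = None,
) -> tuple[str, ClassifiedResult]:
    """Draw one abnormal ISCN string plus its intended four-level labels.

    ``category`` is a Level-2 abnormal label ("aneuploidy", "robertsonian",
    "triploid", ...); with ``mosaic=True`` the abnormal clone is paired with
    a matching normal clone and bracketed cell counts.
    """
    level1 = Level1.MOSAIC if mosaic else Level1.NON_MOSAIC
    if category == "triploid":
        if mosaic:
            raise ValueError("triploid mosaics are not generated")
        s = ("69,XXX", "69,XXY", "69,XYY")[int(rng.integers(3))]
        return s, _result(Level1.NON_MOSAIC, {Level2.TRIPLOID}, Level2.TRIPLOID,
                          None, Level4.UNBALANCED)
    if category == "hermaphroditism":
        if mosaic:
            raise ValueError("hermaphroditism is a non-mosaic pattern")
        n1, n2 = int(rng.integers(3, 31)), int(rng.integers(3, 31))
        s = f"chi 46,XX[{n1}]/46,XY[{n2}]" if rng.random() < 0.5 else "46,XX/46,XY"
        return s, _result(Level1.NON_MOSAIC, {Level2.HERMAPHRODITISM},
                          Level2.HERMAPHRODITISM, None, Level4.UNBALANCED)

    if category == "aneuploidy":
        table = _DEFAULT_ANEUPLOIDY_CHROMS_MOSAIC if mosaic else \
            _DEFAULT_ANEUPLOIDY_CHROMS_NONMOSAIC
        chrom = _pick(rng, table)
        abnormal, normal, chroms = _aneuploid_clone(rng, chrom)
        level4 = Level4.UNBALANCED
        label = Level2.ANEUPLOIDY
    else:
        abnormal, normal, chroms, level4 = _structural_clone(rng, category)
        label = _CATEGORY_TO_LEVEL2[category]

    if mosaic:
        n1, n2 = int(rng.integers(3, 31)), int(rng.integers(3, 31))
        s = f"mos {abnormal}[{n1}]/{normal}[{n2}]"
    else:
        s = abnormal
    return s, _result(level1, {label}, label, chroms, level4)


def _sample_polymorphism(
    rng: np.random.Generator, cfg: CohortConfig
) -> tuple[str, ClassifiedResult]:
    which = _pick(rng, cfg.polymorphism_split)
    if which == "inv9":
        bands = ("p11q12", "p11q13", "p12q13", "p13q21")[int(rng.integers(4))]
        s = f"46,XN,inv(9)({bands})"
        return s, _result(Level1.POLYMORPHISM, {Level2.INVERSION},
                          Level2.INVERSION, {"9"}, Level4.BALANCED)
    chrom = _pick(rng, cfg.length_poly_chroms)
    if chrom in ("1", "9", "16", "Y"):
        sex = "XY" if chrom == "Y" else _sex(rng)
        direction = "-" if (chrom == "Y" and rng.random() < 0.3) else "+"
        token = f"{chrom}qh{direction}"
    else:  # acrocentric: satellite or satellite-stalk variant
        sex = _sex(rng)
        token = f"{chrom}ps+" if rng.random() < 0.6 else f"{chrom}pstk+"
    return f"46,{sex},{token}", _result(
        Level1.POLYMORPHISM, {Level2.LENGTH_POLYMORPHISM},
        Level2.LENGTH_POLYMORPHISM, {chrom}, Level4.BALANCED)


# ---------------------------------------------------------------------------
# indication records
# ---------------------------------------------------------------------------

def _make_record(rng: np.random.Generator, target: str, year: int) -> IndicationRecord:
    """Fill the screening fields so that ``target`` is the primary indication.

    Ages straddle the 35-year cutoff: at/above it only when the target is
    advanced maternal age (or a stronger category that tolerates it),
    below it otherwise so that weaker targets are not pre-empted.
    """
    ama = str(Indication.ADVANCED_MATERNAL_AGE)
    if target == ama:
        age = float(np.round(rng.uniform(35.0, 44.0), 1))
    else:
        age = float(np.clip(np.round(rng.normal(29.5, 3.0), 1), 18.0, 34.9))
    kwargs: dict = {"maternal_age_at_edd": age, "year": year}
    if target == str(Indication.HIGH_RISK_SERUM):
        if rng.random() < 0.7:
            kwargs["serum_t21_risk"] = 1 / float(rng.uniform(30, 260))
        elif rng.random() < 0.5:
            kwargs["serum_t18_risk"] = 1 / float(rng.uniform(30, 340))
        else:
            kwargs["afp_mom"] = float(rng.uniform(2.6, 6.0))
    elif target == str(Indication.INCREASED_NT):
        kwargs["nt_mm"] = float(np.round(rng.uniform(3.1, 7.0), 1))
    elif target == str(Indication.HIGH_RISK_NIPT):
        key = ("nipt_z_21", "nipt_z_18", "nipt_z_13")[int(rng.integers(3))]
        kwargs[key] = float(np.round(rng.uniform(3.2, 15.0), 2))
    elif target == str(Indication.ULTRASOUND_STRUCTURAL):
        kwargs["ultrasound_structural"] = True
    elif target == str(Indication.PARENT_CHROMOSOMAL_ABNORMALITY):
        kwargs["parent_chromosomal_abnormality"] = True
    elif target == str(Indication.PRIOR_CHROMOSOMAL_PREGNANCY):
        kwargs["prior_chromosomal_pregnancy"] = True
    elif target == str(Indication.PARENT_INTELLECTUAL_DISABILITY):
        kwargs["parent_intellectual_disability"] = True
    elif target == str(Indication.MONOGENIC_DISEASE):
        kwargs["monogenic_disease"] = True
    elif target == str(Indication.CORD_BLOOD):
        kwargs["cord_blood_sample"] = True
    elif target == str(Indication.ADVERSE_HISTORY):
        kwargs["adverse_history"] = True
    # "others": nothing set, nothing fires
    return IndicationRecord(**kwargs)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_karyotype(
    rng: np.random.Generator, cfg: CohortConfig
) -> tuple[str, ClassifiedResult]:
    level1 = _pick(rng, cfg.level1_probs)
    if level1 == "normal":
        s = "46,XX" if rng.random() < 0.5 else "46,XY"
        return s, _result(Level1.NORMAL, {Level2.NORMAL}, Level2.NORMAL,
                          None, Level4.BALANCED)
    if level1 == "polymorphism":
        return _sample_polymorphism(rng, cfg)
    mosaic = level1 == "mosaic"
    mix = cfg.mosaic_mix if mosaic else cfg.nonmosaic_mix
    category = _pick(rng, mix)
    return sample_abnormal_karyotype(category, rng, mosaic=mosaic, cfg=cfg)


def generate_cohort(cfg: CohortConfig) -> list[SyntheticSample]:
    """Generate the full cohort; deterministic in ``cfg`` (including seed)."""
    rng = np.random.default_rng(cfg.seed)
    mix_cache = {y: default_indication_mix(y) for y in _YEARS}
    samples: list[SyntheticSample] = []
    for i in range(cfg.n_samples):
        year = _YEARS[int(rng.integers(len(_YEARS)))]
        target = _pick(rng, mix_cache[year])
        record = _make_record(rng, target, year)
        if rng.random() < cfg.failure_rate:
            karyotype, truth = None, None
        else:
            karyotype, truth = _sample_karyotype(rng, cfg)
        samples.append(SyntheticSample(f"S{i:06d}", year, record, karyotype, truth))
    return samples


_RECORD_FIELDS = (
    "maternal_age_at_edd", "serum_t21_risk", "serum_t18_risk", "afp_mom",
    "nt_mm", "nipt_z_21", "nipt_z_18", "nipt_z_13", "ultrasound_structural",
    "parent_chromosomal_abnormality", "prior_chromosomal_pregnancy",
    "parent_intellectual_disability", "monogenic_disease",
    "cord_blood_sample", "adverse_history",
)


def cohort_to_dataframe(samples: list[SyntheticSample]) -> pd.DataFrame:
    """Flatten a cohort into the tidy CSV layout the pipeline consumes."""
    rows = []
    for s in samples:
        row: dict = {"sample_id": s.sample_id, "year": s.year}
        for name in _RECORD_FIELDS:
            row[name] = getattr(s.record, name)
        row["karyotype"] = s.karyotype
        if s.truth is not None:
            row["truth_level1"] = str(s.truth.level1)
            row["truth_level2_primary"] = str(s.truth.level2_primary)
            row["truth_level4"] = str(s.truth.level4)
        else:
            row["truth_level1"] = None
            row["truth_level2_primary"] = None
            row["truth_level4"] = None
        rows.append(row)
    return pd.DataFrame(rows)
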