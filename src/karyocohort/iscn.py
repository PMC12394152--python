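"""ISCN 2016 karyotype model: domain types, parser and canonical formatter.

The supported notation subset covers every karyotype class that occurs in
routine amniotic-fluid G-banding reports: a ploidy + sex-designation header,
``/``-separated clones with optional ``[n]`` cell counts and an optional
``mos``/``chi`` prefix, numerical tokens (``+21``, ``-7``, ``+mar``),
structural tokens (``inv``, ``t`` incl. three-way, ``rob``, ``del``, ``dup``,
``i``, ``psu dic``, ``der`` with an optional embedded ``t``, ``add``) and the
cytogenetic polymorphism suffix tokens (``qh+/-``, ``ps+``, ``pstk+``).

Whitespace and keyword case are normalised on input (``inv (9)`` == ``inv(9)``),
so :func:`format_karyotype` emits a canonical string and
``parse_karyotype(format_karyotype(k)) == k`` for every parseable input.

Deliberately out of scope (raises :class:`UnsupportedNotationError`): ``fra``,
``ins``, ring chromosomes, plain ``dic``, FISH/array nomenclature and sub-band
arithmetic.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "AUTOSOMES",
    "CHROMOSOMES",
    "ACROCENTRICS",
    "CENTROMERIC_DESIGNATION",
    "AbnormalityKind",
    "Band",
    "Abnormality",
    "Clone",
    "Karyotype",
    "ISCNError",
    "ISCNSyntaxError",
    "UnsupportedNotationError",
    "parse_karyotype",
    "format_karyotype",
]

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")
ACROCENTRICS: tuple[str, ...] = ("13", "14", "15", "21", "22")

#: Band designation denoting the centromere on either arm (p10 / q10).
CENTROMERIC_DESIGNATION = "10"


class ISCNError(ValueError):
    """Base class for karyotype-string failures."""


class ISCNSyntaxError(ISCNError):
    """Malformed input: carries the offending token and its position."""

    def __init__(self, message: str, text: str = "", token: str = ""):
        self.token = token
        self.position = text.find(token) if token and token in text else -1
        detail = f" at position {self.position}: {token!r}" if self.position >= 0 else (
            f": {token!r}" if token else ""
        )
        super().__init__(f"{message}{detail}")


class UnsupportedNotationError(ISCNError):
    """Valid ISCN that lies outside the supported subset (fra, ins, r, ...)."""


class AbnormalityKind(enum.StrEnum):
    NUMERICAL_GAIN = "numerical_gain"
    NUMERICAL_LOSS = "numerical_loss"
    MARKER_GAIN = "marker_gain"
    INVERSION = "inversion"
    RECIPROCAL_TRANSLOCATION = "reciprocal_translocation"
    ROBERTSONIAN = "robertsonian"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    ISOCHROMOSOME = "isochromosome"
    PSU_DIC = "psu_dic"
    DERIVATIVE = "derivative"
    ADDITION = "addition"
    HETEROCHROMATIN_VARIANT = "heterochromatin_variant"
    SATELLITE_VARIANT = "satellite_variant"
    SATELLITE_STALK_VARIANT = "satellite_stalk_variant"
    OTHER_STRUCTURAL = "other_structural"


#: Numerical kinds: one chromosome, no breakpoints.
NUMERICAL_KINDS = frozenset(
    {AbnormalityKind.NUMERICAL_GAIN, AbnormalityKind.NUMERICAL_LOSS, AbnormalityKind.MARKER_GAIN}
)

#: Length-variant kinds: one chromosome, no breakpoints, +/- direction in the token.
VARIANT_KINDS = frozenset(
    {
        AbnormalityKind.HETEROCHROMATIN_VARIANT,
        AbnormalityKind.SATELLITE_VARIANT,
        AbnormalityKind.SATELLITE_STALK_VARIANT,
    }
)


@dataclass(frozen=True, slots=True)
class Band:
    """A cytogenetic band position, e.g. chromosome 9, arm p, band 12."""

    chromosome: str
    arm: str
    designation: str

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES and self.chromosome != "mar":
            raise ValueError(f"invalid chromosome label {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"band arm must be 'p' or 'q', got {self.arm!r}")
        if not re.fullmatch(r"\d+(?:\.\d+)?", self.designation):
            raise ValueError(f"invalid band designation {self.designation!r}")

    @property
    def is_centromeric(self) -> bool:
        return self.designation == CENTROMERIC_DESIGNATION

    def __str__(self) -> str:  # "p12", "q21.1"
        return f"{self.arm}{self.designation}"


@dataclass(frozen=True, slots=True)
class Abnormality:
    """One typed abnormality token of a clone.

    ``raw_token`` is the canonical (whitespace/case normalised) token text;
    ``implicit`` marks sex-chromosome aneuploidies inferred from the header
    (e.g. the loss of one X in ``45,X``), which carry no token of their own
    and are therefore skipped by the formatter.
    """

    kind: AbnormalityKind
    chromosomes: tuple[str, ...]
    breakpoints: tuple[Band, ...] = ()
    raw_token: str = ""
    implicit: bool = False

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            if c not in CHROMOSOMES and c != "mar":
                raise ValueError(f"invalid chromosome label {c!r} in {self.raw_token!r}")
        if self.kind in NUMERICAL_KINDS or self.kind in VARIANT_KINDS:
            if len(self.chromosomes) != 1 or self.breakpoints:
                raise ValueError(f"{self.kind} carries exactly 1 chromosome, 0 breakpoints")
        if self.kind is AbnormalityKind.INVERSION and len(self.chromosomes) != 1:
            raise ValueError("inversion involves exactly 1 chromosome")
        if self.kind in (AbnormalityKind.RECIPROCAL_TRANSLOCATION, AbnormalityKind.ROBERTSONIAN):
            if len(self.chromosomes) < 2:
                raise ValueError(f"{self.kind} involves at least 2 chromosomes")


@dataclass(frozen=True, slots=True)
class Clone:
    """A cell line: modal number, sex designation, abnormalities, cell count."""

    modal_number: int
    sex_designation: str
    abnormalities: tuple[Abnormality, ...] = ()
    cell_count: int | None = None

    def __post_init__(self) -> None:
        if self.modal_number < 0:
            raise ValueError("modal number must be >= 0")
        if not self.sex_designation or not re.fullmatch(r"[XYN]+", self.sex_designation):
            raise ValueError(f"invalid sex designation {self.sex_designation!r}")
        if self.cell_count is not None and self.cell_count <= 0:
            raise ValueError("cell count, when present, must be > 0")

    @property
    def genotype_key(self) -> tuple:
        """Identity of the cell line, ignoring how many cells were counted."""
        return (self.modal_number, self.sex_designation, self.abnormalities)


@dataclass(frozen=True, slots=True)
class Karyotype:
    clones: tuple[Clone, ...]
    prefix: str = ""  # "", "mos" or "chi"
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("karyotype needs at least one clone")
        if self.prefix not in ("", "mos", "chi"):
            raise ValueError(f"invalid prefix {self.prefix!r}")
        if self.prefix and len(self.clones) < 2:
            raise ValueError(f"{self.prefix!r} prefix requires at least two clones")

    @property
    def mos_prefix(self) -> bool:
        return self.prefix == "mos"

    def all_abnormalities(self) -> list[Abnormality]:
        return [ab for clone in self.clones for ab in clone.abnormalities]

    def distinct_abnormalities(self) -> list[Abnormality]:
        """Abnormalities deduplicated across clones, in order of appearance."""
        seen: dict[Abnormality, None] = {}
        for ab in self.all_abnormalities():
            seen.setdefault(ab)
        return list(seen)


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^(mos|chi)\b[\s,]*", re.IGNORECASE)
_CELLCOUNT_RE = re.compile(r"\[(\d+)\]$")
_BAND_RE = re.compile(r"([pq])(\d+(?:\.\d+)?)")
_CHROM_RE = r"(?:[1-9]|1\d|2[0-2]|X|Y)"

_UNSUPPORTED_RE = re.compile(
    r"^(?:fra|ins|r|dic|trp|hsr|ish|arr|fis)\(", re.IGNORECASE
)


def _parse_band_run(s: str, chromosome: str, token: str, text: str) -> tuple[Band, ...]:
    """Parse a concatenated band run like 'p12q13' into Band objects."""
    pos = 0
    bands: list[Band] = []
    for m in _BAND_RE.finditer(s):
        if m.start() != pos:
            raise ISCNSyntaxError("malformed band designation", text, token)
        bands.append(Band(chromosome, m.group(1), m.group(2)))
        pos = m.end()
    if pos != len(s) or not bands:
        raise ISCNSyntaxError("malformed band designation", text, token)
    return tuple(bands)


def _require_chrom(label: str, text: str, token: str, allow_mar: bool = False) -> str:
    label = label.upper() if label.upper() in ("X", "Y") else label
    if label in CHROMOSOMES or (allow_mar and label == "mar"):
        return label
    raise ISCNSyntaxError("invalid chromosome label", text, token)


def _parse_token(tok: str, text: str) -> Abnormality:
    """Parse one comma-delimited clone token into a typed Abnormality."""
    if _UNSUPPORTED_RE.match(tok):
        raise UnsupportedNotationError(
            f"notation {tok!r} is valid ISCN but outside the supported subset"
        )

    # numerical: +21, -7, +mar, +X ...
    m = re.fullmatch(r"([+-])(\w+)", tok)
    if m:
        sign, body = m.groups()
        if body.lower() == "mar":
            if sign == "-":
                raise ISCNSyntaxError("'-mar' is not supported", text, tok)
            return Abnormality(AbnormalityKind.MARKER_GAIN, ("mar",), raw_token="+mar")
        c = _require_chrom(body, text, tok)
        kind = AbnormalityKind.NUMERICAL_GAIN if sign == "+" else AbnormalityKind.NUMERICAL_LOSS
        return Abnormality(kind, (c,), raw_token=f"{sign}{c}")

    # length-variant suffix tokens: 9qh+, Yqh-, 21ps+, 14pstk+
    m = re.fullmatch(rf"({_CHROM_RE})(qh|pstk|ps)([+-])", tok, re.IGNORECASE)
    if m:
        c = _require_chrom(m.group(1).upper(), text, tok)
        suffix = m.group(2).lower()
        direction = m.group(3)
        if suffix == "qh":
            kind = AbnormalityKind.HETEROCHROMATIN_VARIANT
        elif suffix == "pstk":
            kind = AbnormalityKind.SATELLITE_STALK_VARIANT
            if direction == "-":
                raise ISCNSyntaxError("'pstk-' is not supported", text, tok)
        else:
            kind = AbnormalityKind.SATELLITE_VARIANT
        return Abnormality(kind, (c,), raw_token=f"{c}{suffix}{direction}")

    # inv(9)(p12q13) or bare inv(9)
    m = re.fullmatch(rf"inv\(({_CHROM_RE})\)(?:\(([pq][\d.pq]*)\))?", tok, re.IGNORECASE)
    if m:
        c = _require_chrom(m.group(1).upper(), text, tok)
        bands: tuple[Band, ...] = ()
        if m.group(2):
            bands = _parse_band_run(m.group(2).lower(), c, tok, text)
            if len(bands) != 2:
                raise ISCNSyntaxError("inversion requires two breakpoints", text, tok)
        raw = f"inv({c})" + (f"({bands[0]}{bands[1]})" if bands else "")
        return Abnormality(AbnormalityKind.INVERSION, (c,), bands, raw)

    # t(a;b)(q21;p13), three-way t(a;b;c)(...)
    m = re.fullmatch(r"t\(([^()]+)\)\(([^()]+)\)", tok, re.IGNORECASE)
    if m:
        chroms = tuple(_require_chrom(c.upper(), text, tok) for c in m.group(1).split(";"))
        segs = m.group(2).lower().split(";")
        if len(chroms) < 2 or len(chroms) > 3 or len(segs) != len(chroms):
            raise ISCNSyntaxError("translocation chromosome/breakpoint mismatch", text, tok)
        bands = []
        for c, seg in zip(chroms, segs):
            run = _parse_band_run(seg, c, tok, text)
            if len(run) != 1:
                raise ISCNSyntaxError("one breakpoint per translocation segment", text, tok)
            bands.append(run[0])
        raw = f"t({';'.join(chroms)})({';'.join(str(b) for b in bands)})"
        return Abnormality(AbnormalityKind.RECIPROCAL_TRANSLOCATION, chroms, tuple(bands), raw)

    # rob(13;14)(q10;q10)
    m = re.fullmatch(r"rob\(([^()]+)\)\(([^()]+)\)", tok, re.IGNORECASE)
    if m:
        chroms = tuple(_require_chrom(c.upper(), text, tok) for c in m.group(1).split(";"))
        segs = m.group(2).lower().split(";")
        if len(chroms) != 2 or len(segs) != 2:
            raise ISCNSyntaxError("robertsonian requires two chromosomes", text, tok)
        bands = []
        for c, seg in zip(chroms, segs):
            run = _parse_band_run(seg, c, tok, text)
            if len(run) != 1:
                raise ISCNSyntaxError("one breakpoint per robertsonian arm", text, tok)
            bands.append(run[0])
        raw = f"rob({';'.join(chroms)})({';'.join(str(b) for b in bands)})"
        return Abnormality(AbnormalityKind.ROBERTSONIAN, chroms, tuple(bands), raw)

    # del(5)(q13q33) / del(5)(p15);  dup(1)(q21q32);  add(5)(p15)
    m = re.fullmatch(rf"(del|dup|add)\(({_CHROM_RE})\)\(([pq][\d.pq]*)\)", tok, re.IGNORECASE)
    if m:
        word = m.group(1).lower()
        c = _require_chrom(m.group(2).upper(), text, tok)
        bands = _parse_band_run(m.group(3).lower(), c, tok, text)
        kind = {
            "del": AbnormalityKind.DELETION,
            "dup": AbnormalityKind.DUPLICATION,
            "add": AbnormalityKind.ADDITION,
        }[word]
        if word == "add" and len(bands) != 1:
            raise ISCNSyntaxError("add carries a single attachment band", text, tok)
        if len(bands) > 2:
            raise ISCNSyntaxError(f"{word} carries one or two breakpoints", text, tok)
        raw = f"{word}({c})({''.join(str(b) for b in bands)})"
        return Abnormality(kind, (c,), bands, raw)

    # i(X)(q10) — whole-arm isochromosome
    m = re.fullmatch(rf"i\(({_CHROM_RE})\)\(([pq]10)\)", tok, re.IGNORECASE)
    if m:
        c = _require_chrom(m.group(1).upper(), text, tok)
        band = Band(c, m.group(2)[0].lower(), "10")
        return Abnormality(
            AbnormalityKind.ISOCHROMOSOME, (c,), (band,), f"i({c})({band})"
        )

    # psu dic(21;14)(q22;q11) — whitespace already stripped to 'psudic'
    m = re.fullmatch(r"psudic\(([^()]+)\)\(([^()]+)\)", tok, re.IGNORECASE)
    if m:
        chroms = tuple(_require_chrom(c.upper(), text, tok) for c in m.group(1).split(";"))
        segs = m.group(2).lower().split(";")
        if len(chroms) != 2 or len(segs) != 2:
            raise ISCNSyntaxError("psu dic requires two chromosomes", text, tok)
        bands = []
        for c, seg in zip(chroms, segs):
            run = _parse_band_run(seg, c, tok, text)
            if len(run) != 1:
                raise ISCNSyntaxError("one breakpoint per psu dic arm", text, tok)
            bands.append(run[0])
        raw = f"psu dic({';'.join(chroms)})({';'.join(str(b) for b in bands)})"
        return Abnormality(AbnormalityKind.PSU_DIC, chroms, tuple(bands), raw)

    # derivative chromosomes
    #   der(13;14)(q10;q10)        whole-arm centric fusion -> robertsonian
    #   der(9)t(9;15)(q22;q24)     derivative with embedded translocation
    #   der(7)                     derivative without breakpoint detail
    m = re.fullmatch(r"der\(([^()]+)\)(.*)", tok, re.IGNORECASE)
    if m:
        head, rest = m.group(1), m.group(2)
        if ";" in head:
            chroms = tuple(_require_chrom(c.upper(), text, tok) for c in head.split(";"))
            mm = re.fullmatch(r"\(([^()]+)\)", rest)
            if len(chroms) != 2 or not mm:
                raise ISCNSyntaxError("malformed whole-arm derivative", text, tok)
            segs = mm.group(1).lower().split(";")
            if len(segs) != 2:
                raise ISCNSyntaxError("malformed whole-arm derivative", text, tok)
            bands = tuple(
                _parse_band_run(seg, c, tok, text)[0] for c, seg in zip(chroms, segs)
            )
            if any(not b.is_centromeric for b in bands):
                raise UnsupportedNotationError(
                    f"derivative {tok!r} with non-centromeric arms is outside the subset"
                )
            raw = f"der({';'.join(chroms)})({';'.join(str(b) for b in bands)})"
            # ISCN allows both rob(...) and der(...)(q10;q10) for centric fusions
            return Abnormality(AbnormalityKind.ROBERTSONIAN, chroms, bands, raw)
        c = _require_chrom(head.upper(), text, tok)
        if not rest:
            return Abnormality(AbnormalityKind.DERIVATIVE, (c,), (), f"der({c})")
        mm = re.fullmatch(r"t\(([^()]+)\)\(([^()]+)\)", rest, re.IGNORECASE)
        if mm:
            t_chroms = tuple(
                _require_chrom(x.upper(), text, tok) for x in mm.group(1).split(";")
            )
            segs = mm.group(2).lower().split(";")
            if len(t_chroms) < 2 or len(segs) != len(t_chroms):
                raise ISCNSyntaxError("malformed derivative translocation", text, tok)
            bands = []
            for tc, seg in zip(t_chroms, segs):
                run = _parse_band_run(seg, tc, tok, text)
                if len(run) != 1:
                    raise ISCNSyntaxError("one breakpoint per segment", text, tok)
                bands.append(run[0])
            chroms = (c,) + tuple(x for x in t_chroms if x != c)
            raw = f"der({c})t({';'.join(t_chroms)})({';'.join(str(b) for b in bands)})"
            return Abnormality(AbnormalityKind.DERIVATIVE, chroms, tuple(bands), raw)
        raise ISCNSyntaxError("malformed derivative token", text, tok)

    raise ISCNSyntaxError("unrecognised abnormality token", text, tok)


def _infer_sex_aneuploidy(modal: int, sex: str, text: str, clone_text: str) -> tuple[Abnormality, ...]:
    """Synthesise implicit sex-chromosome gains/losses from the header.

    ``45,X`` carries a monosomy-X even though no ``-X`` token is written;
    likewise ``47,XXY`` gains an X over the XY reference. Returns () for a
    normal-complement or masked (``XN``) header.
    """
    if "N" in sex:
        if len(sex) != 2 or modal != 46:
            raise ISCNSyntaxError("masked sex designation must be 46,XN-form", text, clone_text)
        return ()
    if modal == 69 and len(sex) == 3:  # triploid: classified from the modal number
        return ()
    if modal != 44 + len(sex):
        raise ISCNSyntaxError(
            "modal number inconsistent with sex designation", text, clone_text
        )
    counts = Counter(sex)
    ref = Counter({"X": 1, "Y": 1}) if counts["Y"] > 0 else Counter({"X": 2})
    abns: list[Abnormality] = []
    for c in ("X", "Y"):
        d = counts[c] - ref[c]
        kind = AbnormalityKind.NUMERICAL_GAIN if d > 0 else AbnormalityKind.NUMERICAL_LOSS
        for _ in range(abs(d)):
            abns.append(Abnormality(kind, (c,), raw_token="", implicit=True))
    return tuple(abns)


def _parse_clone(clone_text: str, text: str) -> Clone:
    ct = clone_text
    cell_count: int | None = None
    m = _CELLCOUNT_RE.search(ct)
    if m:
        cell_count = int(m.group(1))
        if cell_count <= 0:
            raise ISCNSyntaxError("cell count must be > 0", text, clone_text)
        ct = ct[: m.start()]
    fields = [f for f in ct.split(",")]
    if len(fields) < 2 or not fields[0] or not fields[1]:
        raise ISCNSyntaxError("clone needs 'modal,sex' header", text, clone_text)
    if not re.fullmatch(r"\d+", fields[0]):
        raise ISCNSyntaxError("modal number must be an integer", text, fields[0])
    modal = int(fields[0])
    sex = fields[1].upper()
    if not re.fullmatch(r"[XYN]{1,4}", sex):
        raise ISCNSyntaxError("invalid sex designation", text, fields[1])

    abns = tuple(_parse_token(t, text) for t in fields[2:] if t != "")
    if len([t for t in fields[2:] if t == ""]) > 0:
        raise ISCNSyntaxError("empty abnormality token", text, clone_text)

    if not abns:
        abns = _infer_sex_aneuploidy(modal, sex, text, clone_text)
    elif all(ab.kind in NUMERICAL_KINDS for ab in abns):
        gains = sum(1 for ab in abns if ab.kind in
                    (AbnormalityKind.NUMERICAL_GAIN, AbnormalityKind.MARKER_GAIN))
        losses = sum(1 for ab in abns if ab.kind is AbnormalityKind.NUMERICAL_LOSS)
        if modal != 44 + len(sex) + gains - losses:
            raise ISCNSyntaxError(
                "modal number contradicts numerical-token arithmetic", text, clone_text
            )
    return Clone(modal, sex, abns, cell_count)


def parse_karyotype(text: str) -> Karyotype:
    """Parse an ISCN karyotype string into a :class:`Karyotype`.

    Raises :class:`ISCNSyntaxError` for malformed input and
    :class:`UnsupportedNotationError` for valid ISCN outside the subset;
    never returns a partial value.
    """
    if text is None or not str(text).strip():
        raise ISCNSyntaxError("empty karyotype string")
    raw = str(text)
    s = raw.strip()
    m = _PREFIX_RE.match(s)
    prefix = m.group(1).lower() if m else ""
    body = s[m.end():] if m else s
    body = re.sub(r"\s+", "", body)
    body = re.sub(r"psu\.?dic", "psudic", body, flags=re.IGNORECASE)
    if not body:
        raise ISCNSyntaxError("empty karyotype body", raw)
    clones = tuple(_parse_clone(ct, raw) for ct in body.split("/"))
    if prefix and len(clones) < 2:
        raise ISCNSyntaxError(f"'{prefix}' prefix requires at least two clones", raw)
    return Karyotype(clones, prefix, raw)


# --------------------------------------------------------------------------
# formatting
# --------------------------------------------------------------------------

def format_clone(clone: Clone) -> str:
    parts = [f"{clone.modal_number},{clone.sex_designation}"]
    parts.extend(ab.raw_token for ab in clone.abnormalities if not ab.implicit)
    s = ",".join(parts)
    if clone.cell_count is not None:
        s += f"[{clone.cell_count}]"
    return s


def format_karyotype(k: Karyotype) -> str:
    """Render a karyotype canonically; inverse of :func:`parse_karyotype`."""
    body = "/".join(format_clone(c) for c in k.clones)
    return f"{k.prefix} {body}" if k.prefix else body
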