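# Methods

## Scope and data model

`karyocohort` operates on ISCN-notated G-banding results from amniotic-fluid
cell culture. A karyotype is modelled as an ordered list of clones
(cell lines), each with a modal chromosome number, a sex designation over
{X, Y, N}, an optional bracketed cell count, and a list of typed
abnormalities; abnormalities carry their chromosomes and breakpoint bands.
The supported grammar subset covers the classes that occur in routine
amniocentesis reporting: numerical tokens (`+c`, `-c`, `+mar`), `inv`, `t`
(two- and three-way), `rob`, `del`, `dup`, `i(p10/q10)`, `psu dic`, `der`
(bare, whole-arm `der(a;b)(q10;q10)`, or with an embedded `t`), `add`, and
the polymorphism suffix tokens `qh+/-`, `ps+`, `pstk+`. Ring chromosomes,
insertions, fragile sites, plain dicentrics and molecular (FISH/array)
nomenclature are deliberately rejected with a distinct
`UnsupportedNotationError` so callers can distinguish out-of-scope notation
from typos.

Parsing decisions worth noting:

* Whitespace and keyword case are normalised (`inv (9)` ≡ `inv(9)`), and the
  formatter emits the normalised canonical form, giving an exact
  parse∘format∘parse round-trip.
* A masked sex designation `46,XN` is accepted; `N` never participates in an
  abnormality.
* Sex-chromosome aneuploidies written only in the header (`45,X`,
  `47,XXY`) are materialised as *implicit* numerical abnormalities against
  the XX/XY reference, so classification and chromosome tallies see them;
  the formatter skips them. The reference for a lone sex chromosome is
  monosomy X.
* For clones whose abnormalities are purely numerical, the modal number must
  equal 44 + |sex designation| + gains − losses; `46,XX,+21` is rejected.
  Clones with structural tokens skip this arithmetic (structural tokens can
  legitimately change the count, e.g. centric fusions).
* Band designations are stored verbatim as arm + digit string; no ideogram
  coordinate resolution is attempted, since all downstream summaries work at
  chromosome (or centromeric/non-centromeric) granularity.

## Four-level classification

Level 1 tests, in order: the narrow hermaphroditism pattern (exactly
46,XX and 46,XY, nothing else → non-mosaic), genetic distinctness of ≥ 2
clones (→ mosaic; cell counts are ignored for distinctness and no minimum
cell-count threshold is applied), polymorphism-only single clones
(→ polymorphism), bare 46-chromosome clones (→ normal), else non-mosaic.
A neutral variant co-occurring with a true abnormality never downgrades the
call; inv(9) with any (or no) printed breakpoints is the polymorphism and is
never counted among other inversions.

Level 2 unions the category of every abnormality over all clones, adds
`triploid` for any 69-chromosome clone, and selects the primary label by the
fixed precedence hermaphroditism > triploid > aneuploidy > robertsonian >
translocation > derivative > psu dic > isochromosome > deletion >
duplication > addition > inversion > structural aberration > length
polymorphism > normal. The precedence is a package design choice (reported
combinations such as aneuploidy-with-structural-change are conventionally
counted under aneuploidy); the full label set is always retained, so no
information is lost to the tie-break. `+mar` is treated as aneuploidy with
chromosome label `mar`. `der(a;b)(q10;q10)` is classified as Robertsonian:
ISCN allows both spellings for centric fusions.

Level 3 is the union of involved chromosomes, with `None` exactly for
hermaphroditism/triploid/normal primaries (these involve the whole
complement or none specifically).

Level 4 marks unbalanced on any material gain/loss: numerical changes,
markers, del/dup/add, derivatives, isochromosomes, psu dic, triploidy,
hermaphroditism. Robertsonian fusions are balanced only in carrier form:
both arms joining at q10 *and* the clone's modal number lower by one per
fusion after numerical-token accounting, so `45,XX,rob(13;14)(q10;q10)` is
balanced while `46,XX,rob(13;14)(q10;q10)` (an effective trisomy) is not.
Three-way reciprocal translocations are treated as balanced when
material-neutral. All polymorphisms are balanced by definition.

## Breakage counting

One event per breakpoint band whose designation is not `10`; the
centromeric region is defined as exactly the `p10`/`q10` designation, so
pericentric bands such as `p11`/`q11` *do* count (this reproduces the
convention under which inv(Y)(p11q11)-type events dominate the Y-chromosome
tally). Consequences of the convention: inversions contribute 2, reciprocal
translocations 1 per involved chromosome, interstitial deletions 2,
terminal deletions 1, duplications 2 (when written with two bands; a
single-band dup counts 1 — the one-vs-two choice for dup/add is a documented
convention, not a measured fact), additions 1, `i(q10)` and `rob(q10;q10)` 0.
A `der` without breakpoint detail contributes 0 events and is flagged in
the summary. Identical abnormalities repeated across clones of one mosaic
are counted once. Cohort aggregation stratifies fetuses (≥ 1 event) by
Level-1 class; the strata sum to the total by construction, mirroring the
additivity identity of the polymorphic/non-mosaic/mosaic split.

## Indication rules

Thresholds, with units and defaults: serum trisomy-21 risk 1/270 and
trisomy-18 risk 1/350 (risk fractions, strict `>` on the fraction); AFP 2.5
MoM (strict); NT 3.0 mm (strict); NIPT Z 3.0 for trisomy 21/18/13 (strict);
maternal age 35 years at the estimated due date (*inclusive*, "at or
beyond"). Serum risks are stored as numeric fractions to avoid "1 in N"
string parsing. Exactly one primary indication is assigned per record via a
documented, overridable precedence (ultrasound anomalies > increased NT >
high-risk NIPT > high-risk serum > parental chromosomal abnormality > prior
chromosomal pregnancy > monogenic disease > parental intellectual
disability > cord blood > adverse history > advanced maternal age >
others); the residual `others` fires only when nothing else does. The
source conventions are silent on the tie-break, so the order encodes one
plausible clinical reading (specific findings outrank age) and is a
parameter, not a fact.

## Rate tables

All percentages use a single primitive: round-half-up of 100·count/denominator
to two decimals, computed in decimal arithmetic (so 0.125% → 0.13, never
banker's rounding). The denominator convention is the number of successfully
karyotyped samples — failed cultures are dropped before any rate. Each tidy
table row carries its own count and denominator, so every percentage is
recomputable from its row; Level-1 percentages sum to 100 ± 0.02 (rounding
slack) in every partition. One known notational mismatch: 1,557/38,636 is
4.0299…%, which rounds half-up to 4.03; a published figure that prints 4.02
for this fraction truncated rather than rounded, and the package does not
reproduce truncation.

## Synthetic cohort generator

The generator emulates the *marginal* statistical structure of a large
single-centre amniocentesis service over 2010–2024:

* Level-1 mix 4.68% non-mosaic, 0.71% mosaic, 1.70% polymorphism, 92.91%
  normal; culture failure probability 16/38,652.
* Polymorphisms split 353:302 between inv(9) and length variants; length
  variants weight the Y chromosome highest (18.69%), then chromosome 15
  (17.38%), with the remainder spread over the heterochromatin (1, 9, 16)
  and satellite (13, 14, 15, 21, 22) carriers — the tail weights are
  plausible fill-ins, not measurements.
* Non-mosaic abnormal cases follow the category counts 1,338 aneuploidy,
  70 inversion, 97 Robertsonian, 187 translocation + derivative, 64
  deletion, 6 isochromosome; mosaic cases follow 219 aneuploidy, 2
  inversion, 2 Robertsonian, 31 translocation, 8 deletion, 13
  isochromosome. The small budget left in the non-mosaic mix is spread
  over duplication/addition/psu dic/triploid/hermaphroditism, for which no
  counts are printed anywhere; these weights are likewise non-authoritative.
* Aneuploidy chromosome mixes differ by mosaicism (trisomy 21 dominates
  non-mosaics at 52.09%, X-aneuploidy dominates mosaics at 46.12%);
  Robertsonian pairs follow an 11-type table led by (13;14) 47, (14;21) 15,
  (21;21) 14; reciprocal pairs put 8 on (11;22) and 5 on (2;10) with a
  uniform tail.
* Mosaic strings are two clones (abnormal + matching normal) with cell
  counts drawn uniformly from 3–30 per clone. Indication records are drawn
  from per-year category weights in which advanced maternal age stays near
  58.6% while serum screening declines and NIPT/NT/ultrasound referrals
  rise; maternal ages straddle the 35-year cutoff via a two-component
  mixture. Yearly sample sizes are uniform across 2010–2024 by default.

Each generated sample carries intended ground-truth labels built from its
template, and the generator guarantees (and tests verify) that re-parsing
and re-classifying reproduces them exactly. What the generator does *not*
emulate: correlations between indication and karyotype outcome (a high-risk
NIPT referral is no more likely to be abnormal than any other), maternal-age
trisomy risk curves, per-year drift in detection rates, multi-abnormality
karyotypes, and the `structural_aberration` residual class (no grammar
token maps to it). Passing tests therefore demonstrate the pipeline's
correctness on realistic *marginals*, not epidemiological realism of joint
distributions — in particular, per-indication positive rates on synthetic
cohorts are flat by design.

## Problem sizes and numerical choices

The acceptance run and the full-scale tests use n = 38,636 (the study
scale); unit and property tests use a 4,000-sample fixture and 20 × 6,000
for the seed-coverage check. Binomial recovery tolerances are
3·sqrt(p(1−p)/n) on the configured proportion p. All randomness flows from
one `numpy` `default_rng` seed; identical configurations are byte-identical.
Store queries sort by descending count then lexicographically, making
output order deterministic. Degenerate inputs fail loudly: empty cohorts,
zero denominators, invalid probability vectors and unparseable strings all
raise before any partial result is produced.

## Known limitations

* The ISCN subset excludes ins/r/fra/dic and sub-band arithmetic; breakpoint
  positions are not validated against an ideogram.
* Balance of complex derivatives is conservative: any `der` outside the
  whole-arm fusion form counts as unbalanced even if a fully balanced
  interpretation exists.
* Low-level pseudomosaicism and confined placental mosaicism are not
  adjudicated; any two distinct clones make a mosaic.
* The query store deduplicates identical strings; per-case listing would
  need the cohort table itself.
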