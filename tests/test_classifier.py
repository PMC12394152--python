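"""Four-level classification: examples forced by the definitions, precedence,
and cohort-level invariants."""

import itertools

import pytest

from karyocohort import Level1, Level2, Level4, classify_string, parse_karyotype
from karyocohort.classify import LEVEL2_PRECEDENCE, classify


class TestLevel1:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("46,XY", Level1.NORMAL),
            ("46,XN,inv(9)(p12q13)", Level1.POLYMORPHISM),
            ("46,XX,9qh+", Level1.POLYMORPHISM),
            ("mos 45,X[12]/46,XX[18]", Level1.MOSAIC),
            ("47,XX,+21", Level1.NON_MOSAIC),
            ("69,XXX", Level1.NON_MOSAIC),
            ("46,XX/46,XY", Level1.NON_MOSAIC),  # hermaphroditism, not mosaicism
            ("45,X", Level1.NON_MOSAIC),
        ],
    )
    def test_examples(self, text, expected):
        assert classify_string(text).level1 is expected

    def test_polymorphism_with_true_abnormality_is_abnormal(self):
        # a neutral variant does not soften a real abnormality
        r = classify_string("47,XX,+21,9qh+")
        assert r.level1 is Level1.NON_MOSAIC

    def test_hermaphroditism_plus_abnormality_is_mosaic(self):
        r = classify_string("46,XX/46,XY/47,XY,+21")
        assert r.level1 is Level1.MOSAIC
        assert Level2.HERMAPHRODITISM not in r.level2


class TestLevel2:
    @pytest.mark.parametrize(
        "text, labels, primary",
        [
            ("45,XY,rob(13;14)(q10;q10)", {Level2.ROBERTSONIAN}, Level2.ROBERTSONIAN),
            ("46,XX/46,XY", {Level2.HERMAPHRODITISM}, Level2.HERMAPHRODITISM),
            ("mos 47,XX,+21[7]/46,XX,t(2;10)(q21;q22)[23]",
             {Level2.ANEUPLOIDY, Level2.TRANSLOCATION}, Level2.ANEUPLOIDY),
            ("47,XY,+mar", {Level2.ANEUPLOIDY}, Level2.ANEUPLOIDY),
            ("69,XXY", {Level2.TRIPLOID}, Level2.TRIPLOID),
            ("46,XX,14pstk+", {Level2.LENGTH_POLYMORPHISM}, Level2.LENGTH_POLYMORPHISM),
        ],
    )
    def test_examples(self, text, labels, primary):
        r = classify_string(text)
        assert r.level2 == frozenset(labels)
        assert r.level2_primary is primary

    # one representative karyotype per structural label, combinable as
    # extra clones of a mosaic
    _CLONES = {
        Level2.ANEUPLOIDY: "47,XX,+21",
        Level2.ROBERTSONIAN: "45,XX,rob(13;14)(q10;q10)",
        Level2.TRANSLOCATION: "46,XX,t(2;10)(q21;q22)",
        Level2.DERIVATIVE: "46,XX,der(9)t(9;15)(q22;q24)",
        Level2.PSU_DIC: "45,XX,psu dic(21;14)(q22;q11)",
        Level2.ISOCHROMOSOME: "46,X,i(X)(q10)",
        Level2.DELETION: "46,XX,del(5)(q13q33)",
        Level2.DUPLICATION: "46,XX,dup(1)(q21q32)",
        Level2.ADDITION: "46,XX,add(5)(p15)",
        Level2.INVERSION: "46,XX,inv(2)(p11q13)",
        Level2.LENGTH_POLYMORPHISM: "46,XX,9qh+",
    }

    def test_primary_precedence_all_pairs(self):
        """For every pair of labels, the primary is the earlier one in the
        precedence order (oracle: rank lookup in the documented list)."""
        rank = {lab: i for i, lab in enumerate(LEVEL2_PRECEDENCE)}
        for a, b in itertools.combinations(self._CLONES, 2):
            text = f"{self._CLONES[a]}/{self._CLONES[b]}"
            r = classify_string(text)
            assert {a, b} <= r.level2
            expected = min((a, b), key=rank.__getitem__)
            assert r.level2_primary is expected, text


class TestLevel3:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("46,XX,t(11;22)(q23;q11)", {"11", "22"}),
            ("69,XXX", None),
            ("46,XX/46,XY", None),
            ("46,XY", None),
            ("47,XY,+mar", {"mar"}),
            ("mos 45,X[5]/47,XX,+18[4]/46,XX[21]", {"X", "18"}),
        ],
    )
    def test_examples(self, text, expected):
        r = classify_string(text)
        assert r.level3 == (None if expected is None else frozenset(expected))

    def test_none_sentinel_iff_primary_requires_it(self, small_cohort):
        sentinel = {Level2.HERMAPHRODITISM, Level2.TRIPLOID, Level2.NORMAL}
        for s in small_cohort:
            if s.karyotype is None:
                continue
            r = classify_string(s.karyotype)
            assert (r.level3 is None) == (r.level2_primary in sentinel)


class TestLevel4:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("45,XX,rob(13;14)(q10;q10)", Level4.BALANCED),
            ("45,XX,der(13;14)(q10;q10)", Level4.BALANCED),
            ("46,XX,rob(13;14)(q10;q10)", Level4.UNBALANCED),  # trisomic fusion
            ("46,XX,der(13;14)(q10;q10),+13", Level4.UNBALANCED),
            ("46,X,i(X)(q10)", Level4.UNBALANCED),
            ("46,XX,inv(2)(p11q13)", Level4.BALANCED),
            ("46,XX,t(11;22)(q23;q11)", Level4.BALANCED),
            ("46,XY,t(1;3;5)(q21;p13;q22)", Level4.BALANCED),
            ("47,XX,+21", Level4.UNBALANCED),
            ("46,XX/46,XY", Level4.UNBALANCED),
            ("69,XXX", Level4.UNBALANCED),
            ("46,XX,9qh+", Level4.BALANCED),
            ("46,XY", Level4.BALANCED),
            ("46,XX,del(5)(p15)", Level4.UNBALANCED),
        ],
    )
    def test_examples(self, text, expected):
        assert classify_string(text).level4 is expected


class TestComposition:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("47,XX,+21",
             (Level1.NON_MOSAIC, {Level2.ANEUPLOIDY}, frozenset({"21"}), Level4.UNBALANCED)),
            ("46,XN,inv(9)(p12q13)",
             (Level1.POLYMORPHISM, {Level2.INVERSION}, frozenset({"9"}), Level4.BALANCED)),
            ("mos 45,X[5]/46,XX[25]",
             (Level1.MOSAIC, {Level2.ANEUPLOIDY}, frozenset({"X"}), Level4.UNBALANCED)),
        ],
    )
    def test_examples(self, text, expected):
        r = classify_string(text)
        assert (r.level1, set(r.level2), r.level3, r.level4) == expected

    def test_pure_function(self):
        text = "mos 47,XX,+21[7]/46,XX,t(2;10)(q21;q22)[23]"
        assert classify_string(text) == classify_string(text)

    def test_classify_equals_composition(self):
        k = parse_karyotype("mos 45,X[5]/46,XX[25]")
        r = classify(k)
        assert r == classify_string("mos 45,X[5]/46,XX[25]")

    def test_polymorphism_implies_balanced(self, small_cohort):
        for s in small_cohort:
            if s.truth is not None and s.truth.level1 is Level1.POLYMORPHISM:
                assert classify_string(s.karyotype).level4 is Level4.BALANCED

    def test_generator_truth_recovered(self, small_cohort):
        """The classifier reproduces the generator's intended labels exactly."""
        checked = 0
        for s in small_cohort:
            if s.karyotype is None:
                continue
            assert classify_string(s.karyotype) == s.truth
            checked += 1
        assert checked > 3000
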