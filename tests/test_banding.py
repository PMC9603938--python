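"""Banding-sequence algebra: parsing, inversions, scenarios, breakpoints, distance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytobarcode.banding import (
    BandingError,
    BandingSequence,
    ConstraintUnsatisfiable,
    InversionStep,
    apply_inversion,
    apply_scenario,
    breakpoint_count,
    constrained_scenario_search,
    min_inversion_distance,
    parse_banding,
    parse_scenario_notation,
    verify_scenario,
)
from conftest import DERIVATION_LINES, STANDARD_LABELS


def brute_breakpoints(seq, ref):
    """Enumeration oracle: list all neighbor pairs (with framing caps) and
    count those not adjacent in the reference in either orientation."""
    order = {f: i for i, f in enumerate(ref.fragments)}
    n = len(ref)
    pairs = list(zip(seq.fragments, seq.fragments[1:]))
    count = 0
    if order[seq.fragments[0]] not in (0, n - 1):
        count += 1
    for a, b in pairs:
        if abs(order[a] - order[b]) != 1:
            count += 1
    if order[seq.fragments[-1]] not in (0, n - 1):
        count += 1
    return count


class TestParseBanding:
    def test_identity_standard(self, standard_seq):
        assert len(standard_seq) == 18
        assert "".join(standard_seq.fragments) == STANDARD_LABELS

    def test_new_species_order(self, new_species_seq):
        assert new_species_seq.fragments == tuple("aedhionjkbcfglmqpr")

    def test_slashes_and_whitespace_ignored(self, standard_seq):
        seq = parse_banding("a ed/hi onjk bc/fglmqpr", standard_seq.labels)
        assert seq.fragments == tuple("aedhionjkbcfglmqpr")

    @pytest.mark.parametrize(
        "text, message",
        [
            ("abcx", "unknown label 'x' at position 4"),
            ("abca", "duplicate label 'a' at position 4"),
            ("abc", "missing"),
        ],
    )
    def test_validation_errors(self, text, message):
        with pytest.raises(BandingError, match=message):
            parse_banding(text, set("abcd"))

    def test_comma_separated_multichar_labels(self):
        seq = parse_banding("s2, s1, s3", {"s1", "s2", "s3"})
        assert seq.fragments == ("s2", "s1", "s3")


class TestApplyInversion:
    def test_paper_first_step_back_from_standard(self, standard_seq):
        # inverting j..o of the standard gives the last derivation line's state
        out = apply_inversion(standard_seq, InversionStep(10, 15))
        assert "".join(out.fragments) == "abcdefghionmlkjpqr"

    def test_single_fragment_is_identity(self, standard_seq):
        assert apply_inversion(standard_seq, InversionStep(7, 7)) == standard_seq

    def test_out_of_bounds(self, standard_seq):
        with pytest.raises(BandingError, match="out of bounds"):
            apply_inversion(standard_seq, InversionStep(10, 19))

    @given(
        start=st.integers(1, 18),
        length=st.integers(0, 17),
        perm=st.permutations(list(STANDARD_LABELS)),
    )
    @settings(max_examples=100, deadline=None)
    def test_involution_and_label_conservation(self, start, length, perm):
        end = min(start + length, 18)
        seq = BandingSequence("IIL", tuple(perm))
        step = InversionStep(start, end)
        once = apply_inversion(seq, step)
        assert sorted(once.fragments) == sorted(seq.fragments)
        assert apply_inversion(once, step) == seq


class TestScenarioNotation:
    def test_printed_derivation_parses_to_seven_steps(self):
        sc = parse_scenario_notation(DERIVATION_LINES)
        assert len(sc.steps) == 7
        assert "".join(sc.start_seq.fragments) == "aedhionjkbcfglmqpr"
        assert "".join(sc.end_seq.fragments) == STANDARD_LABELS
        assert [s.name for s in sc.steps] == [
            "IIL-complex a", "IIL-complex b", "IIL-complex c", "IIL-complex d",
            "IIL-2", "IIL-3", "IIL-1",
        ]

    def test_round_trip_preserves_line_content(self):
        # re-rendering reproduces the fragment content of every printed line
        sc = parse_scenario_notation(DERIVATION_LINES)
        rendered = sc.render()

        def content(line):
            body = line.rsplit(":", 1)[-1]
            return [c for c in body if c.isalpha()]

        assert len(rendered) == len(DERIVATION_LINES)
        for got, want in zip(rendered, DERIVATION_LINES):
            assert content(got) == content(want)

    def test_minimal_single_line(self):
        sc = parse_scenario_notation(["ab[dc]ef"])
        assert sc.steps == [InversionStep(3, 4)]
        assert sc.start_seq.fragments == tuple("abdcef")
        assert "".join(sc.end_seq.fragments) == "abcdef"

    @pytest.mark.parametrize("line", ["a[bc", "a]bc[d", "a[b]c[d]", "a[]bc"])
    def test_bracket_errors(self, line):
        with pytest.raises(BandingError):
            parse_scenario_notation([line])

    def test_inconsistent_consecutive_lines(self):
        with pytest.raises(BandingError, match="inconsistent"):
            parse_scenario_notation(["ab[dc]ef", "abcdfe"])


class TestVerifyScenario:
    def test_derivation_reaches_standard(self, new_species_seq, standard_seq):
        sc = parse_scenario_notation(DERIVATION_LINES)
        report = verify_scenario(new_species_seq, sc, standard_seq)
        assert report.ok
        assert report.first_mismatch is None
        assert len(report.intermediates) == 7

    def test_empty_scenario_identity(self, standard_seq):
        from cytobarcode.banding import Scenario

        sc = Scenario(steps=[], start_seq=standard_seq)
        assert verify_scenario(standard_seq, sc, standard_seq).ok

    def test_reversed_step_order_fails_with_first_mismatch(
        self, new_species_seq, standard_seq
    ):
        sc = parse_scenario_notation(DERIVATION_LINES)
        from cytobarcode.banding import Scenario

        rev = Scenario(steps=list(reversed(sc.steps)), start_seq=new_species_seq,
                       intermediates=sc.intermediates)
        report = verify_scenario(new_species_seq, rev, standard_seq)
        assert not report.ok
        assert report.first_mismatch == 1

    def test_label_set_mismatch(self, standard_seq):
        from cytobarcode.banding import Scenario

        other = BandingSequence("IIL", tuple("xyz"))
        with pytest.raises(BandingError, match="different label sets"):
            verify_scenario(standard_seq, Scenario(steps=[], start_seq=standard_seq), other)


class TestBreakpoints:
    def test_reference_has_zero(self, standard_seq):
        assert breakpoint_count(standard_seq, standard_seq) == 0

    def test_full_reversal_has_zero(self, standard_seq):
        rev = BandingSequence("IIL", standard_seq.fragments[::-1])
        assert breakpoint_count(rev, standard_seq) == 0

    def test_one_inversion_example(self, standard_seq):
        seq = parse_banding("abcdefghionmlkjpqr", standard_seq.labels)
        assert breakpoint_count(seq, standard_seq) == 2
        assert brute_breakpoints(seq, standard_seq) == 2

    def test_new_species_has_nine(self, new_species_seq, standard_seq):
        assert breakpoint_count(new_species_seq, standard_seq) == 9
        assert brute_breakpoints(new_species_seq, standard_seq) == 9

    @given(perm=st.permutations(list("abcdefgh")))
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, perm, standard_seq):
        ref = parse_banding("abcdefgh", set("abcdefgh"))
        seq = BandingSequence("IIL", tuple(perm))
        assert breakpoint_count(seq, ref) == brute_breakpoints(seq, ref)


class TestMinInversionDistance:
    def test_identity_distance_zero(self, standard_seq):
        res = min_inversion_distance(standard_seq, standard_seq)
        assert res.distance == 0
        assert len(res.scenarios) == 1
        assert res.scenarios[0].steps == []

    def test_single_reversal_distance_one(self, standard_seq):
        seq = apply_inversion(standard_seq, InversionStep(4, 9))
        res = min_inversion_distance(seq, standard_seq)
        assert res.distance == 1
        assert verify_scenario(seq, res.scenarios[0], standard_seq).ok

    def test_new_species_distance_is_seven(self, new_species_seq, standard_seq):
        # breakpoint bound gives >= 5; exhaustive iterative deepening proves
        # the printed 7-step scenario is in fact minimal
        res = min_inversion_distance(new_species_seq, standard_seq)
        assert res.exact
        assert 5 <= res.distance <= 7
        assert res.distance == 7
        assert verify_scenario(new_species_seq, res.scenarios[0], standard_seq).ok

    def test_scenarios_are_valid_and_lexicographically_enumerated(self, standard_seq):
        seq = apply_inversion(standard_seq, InversionStep(3, 8))
        res = min_inversion_distance(seq, standard_seq, max_scenarios=5)
        for sc in res.scenarios:
            assert len(sc.steps) == res.distance
            assert verify_scenario(seq, sc, standard_seq).ok

    def test_budget_exhaustion_returns_interval(self, new_species_seq, standard_seq):
        res = min_inversion_distance(new_species_seq, standard_seq, node_budget=100)
        assert not res.exact
        assert res.distance is None
        assert res.lower_bound == 5  # ceil(9 / 2)
        assert res.lower_bound <= 7 <= res.upper_bound + 2  # greedy certificate
        assert res.upper_bound >= res.lower_bound


class TestConstrainedSearch:
    def test_required_step_equals_only_optimal_move(self, standard_seq):
        seq = apply_inversion(standard_seq, InversionStep(10, 15))  # inverts j..o
        res = constrained_scenario_search(seq, standard_seq, [("IIL-1", "jklmno")])
        assert res.distance == 1
        assert res.scenarios[0].steps[0].name == "IIL-1"

    def test_unsatisfiable_constraint(self, standard_seq):
        seq = apply_inversion(standard_seq, InversionStep(10, 15))
        with pytest.raises(ConstraintUnsatisfiable):
            constrained_scenario_search(
                seq, standard_seq, [("impossible", "ar")], node_budget=20_000
            )

    def test_new_species_with_required_shared_inversions(
        self, new_species_seq, standard_seq
    ):
        res = constrained_scenario_search(
            new_species_seq, standard_seq,
            [("IIL-1", "jklmno"), ("IIL-3", "jklm")],
        )
        assert res.distance <= 7
        sc = res.scenarios[0]
        assert {s.name for s in sc.steps} >= {"IIL-1", "IIL-3"}
        assert verify_scenario(new_species_seq, sc, standard_seq).ok
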