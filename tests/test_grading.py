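"""Part-1/Part-2 grading rules and the overall verdict."""

import pytest
from hypothesis import given, strategies as st

from eshval import (
    CohortSpec,
    GROSS_BIAS_DEVICE,
    generate_cohort,
    grade_cohort_pairs,
    grade_part1,
    grade_part2,
    overall_verdict,
    tally_part2,
)
from eshval.differences import ComparisonPair, build_cohort_pairs
from eshval.grading import Part1Result, Part2Result, UnsupportedSampleSizeError


class TestPart1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((97, 99, 99), "pass"),   # study's achieved SBP counts
            ((98, 99, 99), "pass"),   # study's achieved DBP counts
            ((72, 87, 96), "pass"),   # two-of-three met at 10/15, all-of met
            ((64, 99, 99), "fail"),   # all-of violated at 5 mmHg
            ((73, 87, 96), "pass"),   # exactly on every two-of-three threshold
            ((65, 81, 93), "fail"),   # all-of met but only 0 of three upper
            ((73, 87, 92), "fail"),   # all-of violated at 15 mmHg
        ],
    )
    def test_threshold_logic(self, counts, expected):
        assert grade_part1(counts) == expected

    def test_non_cumulative_counts_rejected(self):
        with pytest.raises(ValueError, match="cumulative"):
            grade_part1((90, 85, 99))

    def test_other_sample_sizes_unsupported(self):
        with pytest.raises(UnsupportedSampleSizeError):
            grade_part1((50, 60, 70), n_total=85)

    @given(
        st.tuples(st.integers(0, 99), st.integers(0, 99), st.integers(0, 99)),
        st.integers(0, 2),
    )
    def test_improving_a_count_never_flips_pass_to_fail(self, counts, idx):
        n5, n10, n15 = sorted(counts)
        improved = [n5, n10, n15]
        improved[idx] = min(improved[idx] + 1, 99)
        improved = sorted(improved)
        if grade_part1((n5, n10, n15)) == "pass":
            assert grade_part1(tuple(improved)) == "pass"


def _subject_pairs(sid, diffs):
    return [
        ComparisonPair.build(sid, slot, "sbp", device=120 + d, reference=120)
        for slot, d in zip(("BP2", "BP4", "BP6"), diffs)
    ]


class TestPart2:
    def test_all_within_5_everywhere(self):
        pairs = [p for i in range(33) for p in _subject_pairs(f"S{i}", (1, 2, 3))]
        assert tally_part2(pairs) == (33, 0)

    def test_subject_with_no_difference_within_5(self):
        pairs = [p for i in range(32) for p in _subject_pairs(f"S{i}", (1, 2, 3))]
        pairs += _subject_pairs("S32", (6, 6, 6))
        assert tally_part2(pairs) == (32, 1)

    def test_wrong_pair_count_per_subject_rejected(self):
        with pytest.raises(ValueError, match="expected 3"):
            tally_part2(_subject_pairs("S0", (1, 2, 3))[:2])

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_tallies_match_brute_force_recount(self, seed):
        cohort = generate_cohort(CohortSpec(seed=seed))
        pairs = build_cohort_pairs(cohort.sessions)["dbp"]
        got = tally_part2(pairs)
        by_subject = {}
        for p in pairs:
            by_subject.setdefault(p.subject_id, []).append(abs(p.signed_difference))
        n2 = sum(1 for v in by_subject.values() if sum(d <= 5 for d in v) >= 2)
        n0 = sum(1 for v in by_subject.values() if sum(d <= 5 for d in v) == 0)
        assert got == (n2, n0)

    @pytest.mark.parametrize(
        "tallies, expected",
        [((33, 0), ("pass", "pass")), ((23, 0), ("fail", "pass")),
         ((24, 4), ("pass", "fail")), ((24, 3), ("pass", "pass"))],
    )
    def test_grade_thresholds(self, tallies, expected):
        assert grade_part2(tallies) == expected

    def test_other_subject_counts_unsupported(self):
        with pytest.raises(UnsupportedSampleSizeError):
            grade_part2((20, 0), n_subjects=30)


class TestOverallVerdict:
    @staticmethod
    def _components(**overrides):
        p1 = Part1Result(counts=(97, 99, 99), grade="pass")
        p2 = Part2Result(33, 0, "pass", "pass")
        parts = {"p1s": p1, "p1d": p1, "p2s": p2, "p2d": p2}
        parts.update(overrides)
        return parts

    def test_all_pass_gives_overall_pass(self):
        c = self._components()
        assert overall_verdict(c["p1s"], c["p1d"], c["p2s"], c["p2d"]) == "PASS"

    @pytest.mark.parametrize(
        "override",
        [
            {"p1d": Part1Result(counts=(60, 80, 90), grade="fail")},
            {"p2s": Part2Result(20, 0, "fail", "pass")},
            {"p2d": Part2Result(30, 5, "pass", "fail")},
        ],
    )
    def test_any_single_component_failure_fails_overall(self, override):
        c = self._components(**override)
        assert overall_verdict(c["p1s"], c["p1d"], c["p2s"], c["p2d"]) == "FAIL"

    def test_gross_bias_device_fails_end_to_end(self):
        cohort = generate_cohort(CohortSpec(seed=11), GROSS_BIAS_DEVICE)
        verdict = grade_cohort_pairs(build_cohort_pairs(cohort.sessions))
        assert verdict.overall == "FAIL"
        # +20 mmHg bias with 2 mmHg noise: essentially no difference within 15
        assert verdict.part1["sbp"].counts[2] <= 5
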