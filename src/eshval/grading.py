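"""Part-1, Part-2 and overall pass/fail grading of a device validation.

The 2010 protocol revision fixes the design at 33 subjects and 99
device-reference comparisons per pressure type and grades:

* Part 1 (pooled): of the 99 absolute differences, at least two of
  {n<=5 >= 73, n<=10 >= 87, n<=15 >= 96} must hold AND all of
  {n<=5 >= 65, n<=10 >= 81, n<=15 >= 93} must hold.
* Part 2 (per subject): at least 24 of the 33 subjects must have >= 2 of
  their 3 differences within 5 mmHg, and at most 3 subjects may have none
  of their 3 within 5 mmHg.

The device passes overall iff every component grade passes.  Thresholds
are protocol constants valid only at n = 33/99; other sample sizes raise
an explicit error rather than scaling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .differences import ComparisonPair

__all__ = [
    "N_PAIRS",
    "N_SUBJECTS",
    "PART1_TWO_OF_THREE",
    "PART1_ALL_OF",
    "PART2_MIN_SUBJECTS_2OF3",
    "PART2_MAX_SUBJECTS_0OF3",
    "Part1Result",
    "Part2Result",
    "ValidationVerdict",
    "UnsupportedSampleSizeError",
    "grade_part1",
    "tally_part2",
    "grade_part2",
    "overall_verdict",
    "grade_cohort_pairs",
]

N_PAIRS = 99
N_SUBJECTS = 33

# Part-1 thresholds at (<=5, <=10, <=15) mmHg, n = 99.
PART1_TWO_OF_THREE = (73, 87, 96)
PART1_ALL_OF = (65, 81, 93)

# Part-2 thresholds at n = 33 subjects.
PART2_MIN_SUBJECTS_2OF3 = 24
PART2_MAX_SUBJECTS_0OF3 = 3


class UnsupportedSampleSizeError(ValueError):
    """Grading thresholds only apply at the protocol's fixed sample size."""


def grade_part1(counts: tuple[int, int, int], n_total: int = N_PAIRS) -> str:
    """Grade pooled cumulative counts (n5, n10, n15) against Part 1.

    ``counts`` must be cumulative (n5 <= n10 <= n15 <= n_total) and
    ``n_total`` must be 99.
    """
    if n_total != N_PAIRS:
        raise UnsupportedSampleSizeError(
            f"Part-1 thresholds are defined only at {N_PAIRS} pairs, got {n_total}"
        )
    n5, n10, n15 = counts
    if not (0 <= n5 <= n10 <= n15 <= n_total):
        raise ValueError(f"counts must be cumulative and <= {n_total}, got {counts}")
    two_of_three = sum(c >= t for c, t in zip(counts, PART1_TWO_OF_THREE))
    all_of = all(c >= t for c, t in zip(counts, PART1_ALL_OF))
    return "pass" if (two_of_three >= 2 and all_of) else "fail"


@dataclass(frozen=True)
class Part1Result:
    counts: tuple[int, int, int]
    grade: str
    mean_sd: tuple[float, float] | None = None  # headline mean +/- SD, mmHg


@dataclass(frozen=True)
class Part2Result:
    n_subjects_with_2of3_within5: int
    n_subjects_with_0of3_within5: int
    grade2: str
    grade3: str


def tally_part2(pairs: Sequence[ComparisonPair]) -> tuple[int, int]:
    """Per-subject tallies for Part 2 from one pressure type's pairs.

    Returns (number of subjects with >= 2 of their 3 differences within
    5 mmHg, number with 0 of 3 within 5 mmHg).  Every subject must have
    exactly 3 pairs.
    """
    by_subject: dict[str, list[ComparisonPair]] = defaultdict(list)
    for p in pairs:
        by_subject[p.subject_id].append(p)
    n_2of3 = 0
    n_0of3 = 0
    for sid, subject_pairs in by_subject.items():
        if len(subject_pairs) != 3:
            raise ValueError(
                f"subject {sid} has {len(subject_pairs)} pairs, expected 3"
            )
        within5 = sum(1 for p in subject_pairs if p.abs_difference <= 5)
        if within5 >= 2:
            n_2of3 += 1
        if within5 == 0:
            n_0of3 += 1
    return n_2of3, n_0of3


def grade_part2(tallies: tuple[int, int], n_subjects: int = N_SUBJECTS) -> tuple[str, str]:
    """Grade Part-2 tallies: (>=24 with 2/3 within 5, <=3 with 0/3 within 5)."""
    if n_subjects != N_SUBJECTS:
        raise UnsupportedSampleSizeError(
            f"Part-2 thresholds are defined only at {N_SUBJECTS} subjects, got {n_subjects}"
        )
    n_2of3, n_0of3 = tallies
    grade2 = "pass" if n_2of3 >= PART2_MIN_SUBJECTS_2OF3 else "fail"
    grade3 = "pass" if n_0of3 <= PART2_MAX_SUBJECTS_0OF3 else "fail"
    return grade2, grade3


@dataclass(frozen=True)
class ValidationVerdict:
    part1: Mapping[str, Part1Result]  # keyed "sbp"/"dbp"
    part2: Mapping[str, Part2Result]
    overall: str  # "PASS" | "FAIL"


def overall_verdict(
    part1_sbp: Part1Result,
    part1_dbp: Part1Result,
    part2_sbp: Part2Result,
    part2_dbp: Part2Result,
) -> str:
    """PASS iff every component grade (2x Part 1, 4x Part 2) passes."""
    grades = [
        part1_sbp.grade,
        part1_dbp.grade,
        part2_sbp.grade2,
        part2_sbp.grade3,
        part2_dbp.grade2,
        part2_dbp.grade3,
    ]
    return "PASS" if all(g == "pass" for g in grades) else "FAIL"


def grade_cohort_pairs(pairs_by_type: Mapping[str, Sequence[ComparisonPair]]) -> ValidationVerdict:
    """End-to-end grading of a cohort's comparison pairs for both types."""
    from .differences import band_counts, summary_stats

    part1: dict[str, Part1Result] = {}
    part2: dict[str, Part2Result] = {}
    for ptype in ("sbp", "dbp"):
        pairs = pairs_by_type[ptype]
        if len(pairs) != N_PAIRS:
            raise UnsupportedSampleSizeError(
                f"{ptype}: {len(pairs)} pairs; grading is defined only at {N_PAIRS}"
            )
        counts = band_counts(pairs)
        stats = summary_stats(pairs)
        part1[ptype] = Part1Result(
            counts=counts,
            grade=grade_part1(counts),
            mean_sd=(stats.mean_abs, stats.sd_abs),
        )
        tallies = tally_part2(pairs)
        grade2, grade3 = grade_part2(tallies)
        part2[ptype] = Part2Result(
            n_subjects_with_2of3_within5=tallies[0],
            n_subjects_with_0of3_within5=tallies[1],
            grade2=grade2,
            grade3=grade3,
        )
    overall = overall_verdict(part1["sbp"], part1["dbp"], part2["sbp"], part2["dbp"])
    return ValidationVerdict(part1=part1, part2=part2, overall=overall)
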