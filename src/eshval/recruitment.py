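"""Recruitment-range classification, quota checks, and screening summaries.

The validation protocol stratifies entry pressures into low/medium/high
ranges (SBP 90-129 / 130-160 / 161-180; DBP 40-79 / 80-100 / 101-130) with
a minimum number of participants per stratum and per sex.  Readings outside
the printed ranges are still recruited and folded into the low or high
stratum.  Entry pressure is the two-observer mean at the first slot (BPA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_sessions import Cohort, ObserverPairReading

__all__ = [
    "SBP_SUBROWS",
    "DBP_SUBROWS",
    "RecruitmentTally",
    "QuotaReport",
    "classify_sbp",
    "classify_dbp",
    "tally_recruitment",
    "check_quotas",
    "AgreementResult",
    "check_observer_agreement",
]

BANDS = ("low", "medium", "high")

#: Screening-table sub-rows (label, lower, upper, band folded into).
SBP_SUBROWS = (
    ("<90", None, 89, "low"),
    ("90-129", 90, 129, "low"),
    ("130-160", 130, 160, "medium"),
    ("161-180", 161, 180, "high"),
    (">180", 181, None, "high"),
)
DBP_SUBROWS = (
    ("<40", None, 39, "low"),
    ("40-79", 40, 79, "low"),
    ("80-100", 80, 100, "medium"),
    ("101-130", 101, 130, "high"),
    (">130", 131, None, "high"),
)


def classify_sbp(value: float) -> str:
    """Band an entry SBP: <130 low, 130-160 medium, >160 high.

    Out-of-range pressures fold into the nearest extreme band.
    """
    if value <= 0:
        raise ValueError("pressure must be positive")
    if value < 130:
        return "low"
    if value <= 160:
        return "medium"
    return "high"


def classify_dbp(value: float) -> str:
    """Band an entry DBP: <80 low, 80-100 medium, >100 high."""
    if value <= 0:
        raise ValueError("pressure must be positive")
    if value < 80:
        return "low"
    if value <= 100:
        return "medium"
    return "high"


def _subrow_label(value: float, subrows) -> str:
    for label, lo, hi, _band in subrows:
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return label
    raise AssertionError("subrows do not partition the line")


def entry_pressures(pair: ObserverPairReading) -> tuple[float, float]:
    """Two-observer mean (SBP, DBP) used to range a subject at entry."""
    sbp = (pair.observer1.sbp + pair.observer2.sbp) / 2
    dbp = (pair.observer1.dbp + pair.observer2.dbp) / 2
    return sbp, dbp


@dataclass
class RecruitmentTally:
    """Per-band and per-subrow counts of entry pressures, plus sex counts."""

    n_subjects: int = 0
    sbp_bands: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BANDS, 0))
    dbp_bands: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BANDS, 0))
    sbp_subrows: dict[str, int] = field(
        default_factory=lambda: {r[0]: 0 for r in SBP_SUBROWS}
    )
    dbp_subrows: dict[str, int] = field(
        default_factory=lambda: {r[0]: 0 for r in DBP_SUBROWS}
    )
    sex_counts: dict[str, int] = field(
        default_factory=lambda: {"male": 0, "female": 0}
    )


def tally_recruitment(cohort: Cohort) -> RecruitmentTally:
    """Count entry pressures per recruitment band and sub-row.

    Band counts always sum to the cohort size for each pressure type
    (the bands partition the pressure line).
    """
    tally = RecruitmentTally(n_subjects=len(cohort.sessions))
    for session in cohort.sessions:
        sbp, dbp = entry_pressures(session.bpa)
        tally.sbp_bands[classify_sbp(sbp)] += 1
        tally.dbp_bands[classify_dbp(dbp)] += 1
        tally.sbp_subrows[_subrow_label(sbp, SBP_SUBROWS)] += 1
        tally.dbp_subrows[_subrow_label(dbp, DBP_SUBROWS)] += 1
        tally.sex_counts[session.sex] += 1
    return tally


@dataclass
class QuotaReport:
    minimum_per_band: int
    minimum_per_sex: int
    underfilled_sbp_bands: list[str]
    underfilled_dbp_bands: list[str]
    underfilled_sexes: list[str]

    @property
    def all_met(self) -> bool:
        return not (
            self.underfilled_sbp_bands
            or self.underfilled_dbp_bands
            or self.underfilled_sexes
        )


def check_quotas(
    tally: RecruitmentTally,
    minimum_per_band: int = 10,
    minimum_per_sex: int = 10,
) -> QuotaReport:
    """Flag recruitment bands or sexes below the protocol minimum.

    The protocol asks for 10-12 subjects per stratum; only the lower bound
    is enforced, the upper bound is informational.
    """
    return QuotaReport(
        minimum_per_band=minimum_per_band,
        minimum_per_sex=minimum_per_sex,
        underfilled_sbp_bands=[
            b for b in BANDS if tally.sbp_bands[b] < minimum_per_band
        ],
        underfilled_dbp_bands=[
            b for b in BANDS if tally.dbp_bands[b] < minimum_per_band
        ],
        underfilled_sexes=[
            s for s in ("male", "female") if tally.sex_counts[s] < minimum_per_sex
        ],
    )


@dataclass(frozen=True)
class AgreementResult:
    """Supervisor's check of the two blinded observers, per pressure type."""

    sbp: str  # "accept" | "repeat"
    dbp: str

    @property
    def overall(self) -> str:
        return "accept" if self.sbp == "accept" and self.dbp == "accept" else "repeat"


def check_observer_agreement(
    pair: ObserverPairReading, threshold: int = 4
) -> AgreementResult:
    """Flag a pair for repetition when observers differ by >= threshold mmHg.

    Applied independently per pressure type; the default 4 mmHg threshold
    is the protocol's repeat rule.
    """
    d_sbp = abs(pair.observer1.sbp - pair.observer2.sbp)
    d_dbp = abs(pair.observer1.dbp - pair.observer2.dbp)
    return AgreementResult(
        sbp="repeat" if d_sbp >= threshold else "accept",
        dbp="repeat" if d_dbp >= threshold else "accept",
    )
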