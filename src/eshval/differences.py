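"""Device-vs-reference comparison pairs and banded absolute differences.

Each complete session contributes three comparisons per pressure type: the
device readings at BP2, BP4 and BP6, each matched to a reference built from
the neighbouring two-observer auscultatory slots.  At the protocol's fixed
n = 33 this yields the 99 comparison pairs whose absolute differences are
banded at 5, 10 and 15 mmHg ("within X" meaning |difference| <= X).

The exact anchoring of each device reading to its flanking observer slots
is configurable (``PairingStrategy``): the default ``flanking_mean`` averages
the observer references immediately before and after the device reading,
which is the symmetric reading of "their average was taken"; ``preceding``,
``following`` and ``flanking_closest`` are provided so a protocol-exact rule
can be selected without code changes.  The chosen mode is recorded in the
report for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_sessions import ObserverPairReading, SubjectSession, ANALYSIS_DEVICE_SLOTS
from .recruitment import check_observer_agreement

__all__ = [
    "PAIRING_STRATEGIES",
    "BAND_EDGES",
    "ComparisonPair",
    "DiffSummary",
    "DisagreementError",
    "observer_reference",
    "build_pairs",
    "build_cohort_pairs",
    "band_difference",
    "band_counts",
    "summary_stats",
]

PAIRING_STRATEGIES = ("flanking_mean", "preceding", "following", "flanking_closest")

#: Flanking observer slots for each analysed device slot (preceding, following).
FLANKING = {"BP2": ("BP1", "BP3"), "BP4": ("BP3", "BP5"), "BP6": ("BP5", "BP7")}

BAND_EDGES = (5, 10, 15)
BAND_NAMES = ("within5", "within10", "within15", "beyond15")


class DisagreementError(ValueError):
    """An unresolved observer disagreement must not enter the analysis."""


def observer_reference(pair: ObserverPairReading, threshold: int = 4) -> tuple[float, float]:
    """Reference (SBP, DBP): the mean of the two blinded observers.

    Both observers read to the nearest 2 mmHg, so the mean is an exact
    integer.  A pair still flagged for repetition (difference >= 4 mmHg)
    raises :class:`DisagreementError`.
    """
    agreement = check_observer_agreement(pair, threshold=threshold)
    if agreement.overall != "accept":
        raise DisagreementError(
            f"observer disagreement (sbp={agreement.sbp}, dbp={agreement.dbp})"
        )
    return (
        (pair.observer1.sbp + pair.observer2.sbp) / 2,
        (pair.observer1.dbp + pair.observer2.dbp) / 2,
    )


@dataclass(frozen=True)
class ComparisonPair:
    """One device reading matched to its observer reference."""

    subject_id: str
    slot: str  # BP2 | BP4 | BP6
    pressure_type: str  # "sbp" | "dbp"
    device_value: float
    reference_value: float
    signed_difference: float  # device - reference
    abs_difference: float
    band: str

    @classmethod
    def build(
        cls, subject_id: str, slot: str, pressure_type: str, device: float, reference: float
    ) -> "ComparisonPair":
        signed = device - reference
        return cls(
            subject_id=subject_id,
            slot=slot,
            pressure_type=pressure_type,
            device_value=device,
            reference_value=reference,
            signed_difference=signed,
            abs_difference=abs(signed),
            band=band_difference(abs(signed)),
        )


def band_difference(abs_difference: float) -> str:
    """Band an absolute difference: within5 / within10 / within15 / beyond15.

    Boundaries are inclusive ("within 5" means |d| <= 5).
    """
    if abs_difference < 0:
        raise ValueError("absolute difference cannot be negative")
    if abs_difference <= 5:
        return "within5"
    if abs_difference <= 10:
        return "within10"
    if abs_difference <= 15:
        return "within15"
    return "beyond15"


def _reference_for_slot(
    session: SubjectSession, slot: str, pressure_type: str, strategy: str
) -> float:
    before, after = FLANKING[slot]
    idx = 0 if pressure_type == "sbp" else 1
    ref_before = observer_reference(session.slot(before))[idx]
    ref_after = observer_reference(session.slot(after))[idx]
    if strategy == "flanking_mean":
        return (ref_before + ref_after) / 2
    if strategy == "preceding":
        return ref_before
    if strategy == "following":
        return ref_after
    if strategy == "flanking_closest":
        device = getattr(session.slot(slot), pressure_type)
        # tie broken toward the preceding measurement
        if abs(device - ref_after) < abs(device - ref_before):
            return ref_after
        return ref_before
    raise ValueError(f"unknown pairing strategy {strategy!r}")


def build_pairs(
    session: SubjectSession, strategy: str = "flanking_mean"
) -> list[ComparisonPair]:
    """Build the six comparison pairs (3 SBP + 3 DBP) for one session.

    Device slots BP2/BP4/BP6 are each paired with a reference from the
    neighbouring observer slots per the strategy; BPA and BPB never enter
    the comparisons.
    """
    if strategy not in PAIRING_STRATEGIES:
        raise ValueError(f"unknown pairing strategy {strategy!r}")
    pairs: list[ComparisonPair] = []
    for slot in ANALYSIS_DEVICE_SLOTS:
        device = session.slot(slot)
        if device is None:
            raise ValueError(f"session {session.subject_id}: missing slot {slot}")
        for ptype in ("sbp", "dbp"):
            reference = _reference_for_slot(session, slot, ptype, strategy)
            pairs.append(
                ComparisonPair.build(
                    session.subject_id, slot, ptype, getattr(device, ptype), reference
                )
            )
    return pairs


def build_cohort_pairs(
    sessions: Iterable[SubjectSession], strategy: str = "flanking_mean"
) -> dict[str, list[ComparisonPair]]:
    """All comparison pairs for a cohort, keyed by pressure type."""
    out: dict[str, list[ComparisonPair]] = {"sbp": [], "dbp": []}
    for session in sessions:
        for pair in build_pairs(session, strategy=strategy):
            out[pair.pressure_type].append(pair)
    return out


def band_counts(pairs: Sequence[ComparisonPair]) -> tuple[int, int, int]:
    """Cumulative (n<=5, n<=10, n<=15) counts over a list of pairs."""
    n5 = sum(1 for p in pairs if p.abs_difference <= 5)
    n10 = sum(1 for p in pairs if p.abs_difference <= 10)
    n15 = sum(1 for p in pairs if p.abs_difference <= 15)
    return n5, n10, n15


@dataclass(frozen=True)
class DiffSummary:
    """Mean and sample SD of signed and absolute device-reference differences."""

    n: int
    mean_signed: float
    sd_signed: float
    mean_abs: float
    sd_abs: float


def summary_stats(pairs: Sequence[ComparisonPair]) -> DiffSummary:
    """Summarise differences with the sample (n-1) standard deviation.

    Both signed and absolute summaries are reported; the absolute one is
    the analogue of the protocol's headline mean +/- SD.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to compute a sample SD")
    signed = [p.signed_difference for p in pairs]
    absolute = [p.abs_difference for p in pairs]

    def _mean_sd(values: list[float]) -> tuple[float, float]:
        n = len(values)
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        return mean, math.sqrt(var)

    mean_s, sd_s = _mean_sd(signed)
    mean_a, sd_a = _mean_sd(absolute)
    return DiffSummary(
        n=len(pairs), mean_signed=mean_s, sd_signed=sd_s, mean_abs=mean_a, sd_abs=sd_a
    )
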