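"""Pipeline orchestration and the five-table validation report.

``run_validation`` takes a cohort (read from CSV or simulated) through
recruitment tallying, pair building, banded-difference grading and
Bland-Altman checks, and assembles a JSON-serialisable report shaped like
a validation write-up: screening/recruitment table, demographics summary,
Part-1/Part-2 validation results, observations per pressure range, and the
inter-observer difference summary, plus run provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .bland_altman import ba_table, inside_limits
from .differences import (
    build_cohort_pairs,
    band_counts,
    summary_stats,
    ComparisonPair,
)
from .grading import grade_cohort_pairs, ValidationVerdict
from .io_sessions import Cohort, EXCLUSION_REASONS, OBSERVER_SLOTS
from .recruitment import (
    check_quotas,
    entry_pressures,
    tally_recruitment,
)

__all__ = ["ReportConfig", "ValidationReport", "run_validation",
           "summarize_demographics", "observer_difference_summary"]

#: Observer slots whose readings enter the 99 comparisons (BPA is entry only).
ANALYSIS_OBSERVER_SLOTS = tuple(s for s in OBSERVER_SLOTS if s != "BPA")

# Per-measurement range bands for the observations table.
MEASUREMENT_BANDS = {
    "sbp": (("low (<130)", None, 129.99), ("medium (130-160)", 130, 160),
            ("high (>160)", 160.01, None)),
    "dbp": (("low (<80)", None, 79.99), ("medium (80-100)", 80, 100),
            ("high (>100)", 100.01, None)),
}


@dataclass(frozen=True)
class ReportConfig:
    strategy: str = "flanking_mean"
    limits: tuple[float, ...] = (5, 10, 15)
    seed: int | None = None


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return mean, sd


def summarize_demographics(cohort: Cohort) -> dict[str, Any]:
    """Demographics summary: per field min-max range and mean (sample SD)."""
    if not cohort.sessions:
        raise ValueError("cohort is empty")
    sessions = cohort.sessions
    out: dict[str, Any] = {
        "n": len(sessions),
        "sex": {
            "male": sum(1 for s in sessions if s.sex == "male"),
            "female": sum(1 for s in sessions if s.sex == "female"),
        },
    }
    numeric_fields = (
        "age", "arm_circumference", "wrist_circumference", "height", "weight", "bmi",
    )
    for name in numeric_fields:
        values = [getattr(s, name) for s in sessions]
        mean, sd = _mean_sd(values)
        out[name] = {"range": [min(values), max(values)], "mean": mean, "sd": sd}
    for ptype, idx in (("entry_sbp", 0), ("entry_dbp", 1)):
        values = [entry_pressures(s.bpa)[idx] for s in sessions]
        mean, sd = _mean_sd(values)
        out[ptype] = {"range": [min(values), max(values)], "mean": mean, "sd": sd}
    return out


def observer_difference_summary(cohort: Cohort) -> dict[str, Any]:
    """Observer-2 minus observer-1 differences pooled over analysis slots.

    Reports the signed range/mean/SD per pressure type (the shape of an
    observer-agreement table), the absolute-difference summary, and the
    total number of repeated measurements.
    """
    out: dict[str, Any] = {}
    total_repeats = 0
    for ptype in ("sbp", "dbp"):
        diffs: list[float] = []
        for session in cohort.sessions:
            for slot in ANALYSIS_OBSERVER_SLOTS:
                pair = session.slot(slot)
                diffs.append(
                    getattr(pair.observer2, ptype) - getattr(pair.observer1, ptype)
                )
        mean, sd = _mean_sd(diffs)
        abs_diffs = [abs(d) for d in diffs]
        mean_abs, sd_abs = _mean_sd(abs_diffs)
        out[ptype] = {
            "range": [min(diffs), max(diffs)],
            "mean": mean,
            "sd": sd,
            "mean_abs": mean_abs,
            "sd_abs": sd_abs,
            "n": len(diffs),
        }
    for session in cohort.sessions:
        for slot in OBSERVER_SLOTS:
            total_repeats += session.slot(slot).repeat_count
    out["repeated_measurements"] = total_repeats
    return out


def _observations_per_range(pairs_by_type: Mapping[str, Sequence[ComparisonPair]]) -> dict:
    """Count the 99 per-measurement reference values in each pressure band."""
    out: dict[str, Any] = {}
    for ptype, bands in MEASUREMENT_BANDS.items():
        refs = [p.reference_value for p in pairs_by_type[ptype]]
        counts = {}
        for label, lo, hi in bands:
            counts[label] = sum(
                1 for r in refs
                if (lo is None or r >= lo) and (hi is None or r <= hi)
            )
        out[ptype] = {
            "overall_range": [min(refs), max(refs)] if refs else None,
            "counts": counts,
            "n": len(refs),
            # headline row present in the source table but undefined there;
            # carried explicitly as not computed
            "maximum_difference": None,
            "note": "maximum_difference not computed: quantity undefined",
        }
    return out


@dataclass
class ValidationReport:
    """JSON-round-trippable container for the full validation output."""

    data: dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.data, indent=indent, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(data=json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "ValidationReport":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    @property
    def overall(self) -> str:
        return self.data["validation"]["overall"]


def _verdict_to_dict(verdict: ValidationVerdict) -> dict[str, Any]:
    out: dict[str, Any] = {
        "part1": {
            "pass_requirement": {
                "two_of_three": [73, 87, 96],
                "all_of": [65, 81, 93],
            },
            "achieved": {},
        },
        "part2": {
            "pass_requirement": {
                "min_subjects_2of3_within5": 24,
                "max_subjects_0of3_within5": 3,
            },
            "achieved": {},
        },
        "overall": verdict.overall,
    }
    for ptype in ("sbp", "dbp"):
        p1 = verdict.part1[ptype]
        out["part1"]["achieved"][ptype] = {
            "counts": list(p1.counts),
            "grade": p1.grade,
            "mean_abs_diff": p1.mean_sd[0] if p1.mean_sd else None,
            "sd_abs_diff": p1.mean_sd[1] if p1.mean_sd else None,
        }
        p2 = verdict.part2[ptype]
        out["part2"]["achieved"][ptype] = {
            "n_subjects_2of3_within5": p2.n_subjects_with_2of3_within5,
            "n_subjects_0of3_within5": p2.n_subjects_with_0of3_within5,
            "grade2": p2.grade2,
            "grade3": p2.grade3,
        }
    return out


def run_validation(cohort: Cohort, config: ReportConfig = ReportConfig()) -> ValidationReport:
    """Run the full validation pipeline on a cohort and assemble the report.

    Deterministic for a fixed cohort and config; every numeric cell is
    recomputed from the sessions.
    """
    if not cohort.sessions:
        raise ValueError("validation stage: cohort is empty")

    tally = tally_recruitment(cohort)
    quotas = check_quotas(tally)

    pairs_by_type = build_cohort_pairs(cohort.sessions, strategy=config.strategy)
    verdict = grade_cohort_pairs(pairs_by_type)

    diff_summaries = {}
    inside = {}
    for ptype in ("sbp", "dbp"):
        stats = summary_stats(pairs_by_type[ptype])
        diff_summaries[ptype] = {
            "n": stats.n,
            "mean_signed": stats.mean_signed,
            "sd_signed": stats.sd_signed,
            "mean_abs": stats.mean_abs,
            "sd_abs": stats.sd_abs,
        }
        points = ba_table(pairs_by_type[ptype])
        inside[ptype] = {}
        for limit in config.limits:
            fraction, all_inside = inside_limits(points, limit)
            inside[ptype][str(int(limit))] = {
                "fraction": fraction,
                "all_inside": all_inside,
            }

    data: dict[str, Any] = {
        "recruitment": {
            "screening": {
                "total_screened": cohort.screened_total,
                "exclusions": {
                    reason: cohort.exclusions.get(reason, 0)
                    for reason in EXCLUSION_REASONS
                },
                "total_excluded": cohort.total_excluded,
                "total_recruited": len(cohort.sessions),
            },
            "sbp_subrows": tally.sbp_subrows,
            "dbp_subrows": tally.dbp_subrows,
            "sbp_bands": tally.sbp_bands,
            "dbp_bands": tally.dbp_bands,
            "sex_counts": tally.sex_counts,
            "quotas_met": quotas.all_met,
            "underfilled": {
                "sbp": quotas.underfilled_sbp_bands,
                "dbp": quotas.underfilled_dbp_bands,
                "sex": quotas.underfilled_sexes,
            },
        },
        "demographics": summarize_demographics(cohort),
        "validation": _verdict_to_dict(verdict),
        "differences": diff_summaries,
        "bland_altman_inside_limits": inside,
        "observations_per_range": _observations_per_range(pairs_by_type),
        "observer_differences": observer_difference_summary(cohort),
        "provenance": {
            "strategy": config.strategy,
            "seed": config.seed,
            "version": __version__,
            "n_subjects": len(cohort.sessions),
            "n_pairs_per_type": {
                t: len(pairs_by_type[t]) for t in ("sbp", "dbp")
            },
        },
    }
    return ValidationReport(data=data)
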