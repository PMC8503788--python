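"""Synthetic validation cohorts with the statistical structure the analysis assumes.

The generator emulates a 33-subject wrist-device validation cohort of obese
hypertensive adults: entry pressures stratified low/medium/high with at
least 10 subjects per stratum, observer readings rounded to the nearest
2 mmHg with an inter-observer agreement rule (repeat when they differ by
4 mmHg or more), and a test device whose error is a constant bias plus
Gaussian noise with an optional pressure-proportional slope.

Within a session the true pressure follows a small Gaussian random walk
across the nine slots, so consecutive measurements are correlated but not
identical — the feature that makes the choice of device-to-reference
pairing rule observable.  SBP and DBP strata are assigned jointly (a
subject low in SBP is low in DBP), which keeps diastolic below systolic
structurally and mirrors the correlation of the two pressures.

Everything is deterministic given the spec's seed; the same spec writes a
byte-identical cohort file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_sessions import (
    Cohort,
    EXCLUSION_REASONS,
    ObserverPairReading,
    PressureReading,
    SubjectSession,
)

__all__ = [
    "DeviceErrorModel",
    "CohortSpec",
    "IDEAL_DEVICE",
    "PAPER_LIKE_DEVICE",
    "GROSS_BIAS_DEVICE",
    "TABLE1_EXCLUSION_RATES",
    "generate_cohort",
    "generate_screening_funnel",
]


@dataclass(frozen=True)
class DeviceErrorModel:
    """Error model of the simulated oscillometric device.

    device reading = true + bias + pressure_slope * (true - 120)
                     + Normal(0, noise_sd), rounded to 1 mmHg, clipped to
    the 0-299 mmHg detection range.
    """

    bias: float = 1.9  # mmHg; scale of the study device's mean deviation
    noise_sd: float = 1.5  # mmHg
    pressure_slope: float = 0.0  # extra bias per mmHg above 120

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


IDEAL_DEVICE = DeviceErrorModel(bias=0.0, noise_sd=0.0)
PAPER_LIKE_DEVICE = DeviceErrorModel(bias=1.9, noise_sd=1.5)
GROSS_BIAS_DEVICE = DeviceErrorModel(bias=20.0, noise_sd=2.0)

# Entry-pressure sampling ranges per stratum (inclusive, mmHg), chosen to
# respect both the protocol strata and the observed cohort span
# (SBP 107-180, DBP 67-128).
SBP_BAND_RANGES = {"low": (107, 129), "medium": (130, 160), "high": (161, 180)}
DBP_BAND_RANGES = {"low": (67, 79), "medium": (80, 100), "high": (101, 128)}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults reproduce the study conditions: 33 obese subjects (BMI >= 30),
    12 men / 21 women, >= 10 subjects per pressure stratum, observers
    reading to the nearest 2 mmHg.
    """

    n_subjects: int = 33
    min_per_band: int = 10
    n_male: int = 12
    n_female: int = 21
    age_range: tuple[float, float] = (36, 79)
    weight_range: tuple[float, float] = (88, 136)
    bmi_range: tuple[float, float] = (31.48, 81.75)
    wrist_range: tuple[float, float] = (13, 28)
    arm_range: tuple[float, float] = (33, 90)
    observer_noise_sd: float = 1.0  # mmHg, per observer, before 2-mmHg rounding
    within_session_drift_sd: float = 0.5  # mmHg random-walk step between slots
    max_repeats: int = 5  # simulated re-takes allowed per observer pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_subjects:
            raise ValueError("n_male + n_female must equal n_subjects")
        if 3 * self.min_per_band > self.n_subjects:
            raise ValueError(
                f"quotas unsatisfiable: 3 strata x {self.min_per_band} > "
                f"{self.n_subjects} subjects"
            )
        if self.observer_noise_sd < 0 or self.within_session_drift_sd < 0:
            raise ValueError("noise parameters must be non-negative")


#: Screening-funnel rates reproducing the study's Table-1 accounting
#: (90 screened, 36 + 18 + 3 excluded, 33 recruited).
TABLE1_EXCLUSION_RATES = {
    "range adjustment": 36 / 90,
    "observer disagreement": 18 / 90,
    "other": 3 / 90,
}


def _round_to_even(x: float) -> int:
    """Round to the nearest multiple of 2 mmHg (observer terminal digits)."""
    return int(2 * round(x / 2))


def _band_assignment(n: int, min_per_band: int, rng: np.random.Generator) -> list[str]:
    """Assign strata as evenly as possible, shuffled, quotas guaranteed."""
    base, extra = divmod(n, 3)
    counts = {"low": base, "medium": base, "high": base}
    for band in list(counts)[:extra]:
        counts[band] += 1
    if any(c < min_per_band for c in counts.values()):
        raise ValueError("quotas unsatisfiable under even stratum allocation")
    bands = [b for b, c in counts.items() for _ in range(c)]
    rng.shuffle(bands)
    return bands


def _simulate_observer_pair(
    true_sbp: float,
    true_dbp: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ObserverPairReading:
    """Two blinded observers with independent noise and the repeat rule.

    Pairs disagreeing by >= 4 mmHg in either pressure are re-drawn (a
    simulated repeat measurement) up to ``max_repeats`` times; beyond that
    the second observer is forced to agree, mimicking supervised
    re-measurement until consensus.
    """
    s = spec.observer_noise_sd
    repeats = 0
    for attempt in range(spec.max_repeats + 1):
        o1_sbp = _round_to_even(true_sbp + rng.normal(0, s))
        o1_dbp = _round_to_even(true_dbp + rng.normal(0, s))
        o2_sbp = _round_to_even(true_sbp + rng.normal(0, s))
        o2_dbp = _round_to_even(true_dbp + rng.normal(0, s))
        if abs(o1_sbp - o2_sbp) < 4 and abs(o1_dbp - o2_dbp) < 4:
            break
        repeats += 1
    else:
        o2_sbp, o2_dbp = o1_sbp, o1_dbp
    return ObserverPairReading(
        observer1=PressureReading(o1_sbp, o1_dbp),
        observer2=PressureReading(o2_sbp, o2_dbp),
        repeat_count=repeats,
    )


def _simulate_device(
    true_sbp: float,
    true_dbp: float,
    device: DeviceErrorModel,
    rng: np.random.Generator,
) -> PressureReading:
    def one(true: float) -> int:
        val = true + device.bias + device.pressure_slope * (true - 120.0)
        val += rng.normal(0, device.noise_sd)
        return int(np.clip(round(val), 0, 299))

    sbp = one(true_sbp)
    dbp = one(true_dbp)
    dbp = min(dbp, sbp - 1)  # detection-range invariant; never binds at defaults
    return PressureReading(sbp, dbp)


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    device: DeviceErrorModel = PAPER_LIKE_DEVICE,
) -> Cohort:
    """Generate a complete synthetic cohort, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    bands = _band_assignment(spec.n_subjects, spec.min_per_band, rng)
    sexes = ["male"] * spec.n_male + ["female"] * spec.n_female
    rng.shuffle(sexes)

    sessions: list[SubjectSession] = []
    for i in range(spec.n_subjects):
        band = bands[i]
        sbp_lo, sbp_hi = SBP_BAND_RANGES[band]
        dbp_lo, dbp_hi = DBP_BAND_RANGES[band]
        # entry pressures on the 2-mmHg grid: noiseless observers then read
        # the true value exactly, so an error-free device shows zero difference
        entry_sbp = 2.0 * rng.integers(math.ceil(sbp_lo / 2), sbp_hi // 2 + 1)
        entry_dbp = 2.0 * rng.integers(math.ceil(dbp_lo / 2), dbp_hi // 2 + 1)

        age = float(np.round(rng.uniform(*spec.age_range), 0))
        weight = float(np.round(rng.uniform(*spec.weight_range), 1))
        bmi_target = rng.uniform(*spec.bmi_range)
        height = float(np.round(math.sqrt(weight / bmi_target) * 100, 1))
        bmi = round(weight / (height / 100.0) ** 2, 2)
        wrist = float(np.round(rng.uniform(*spec.wrist_range), 1))
        arm = float(np.round(rng.uniform(*spec.arm_range), 1))

        # true pressure random walk over the 9 slots
        steps = rng.normal(0, spec.within_session_drift_sd, size=(9, 2))
        true = np.empty((9, 2))
        true[0] = (entry_sbp, entry_dbp)
        for k in range(1, 9):
            true[k] = true[k - 1] + steps[k]

        slot_values: dict[str, object] = {}
        slot_names = ("bpa", "bpb", "bp1", "bp2", "bp3", "bp4", "bp5", "bp6", "bp7")
        for k, name in enumerate(slot_names):
            t_sbp, t_dbp = true[k]
            if name in ("bpa", "bp1", "bp3", "bp5", "bp7"):
                slot_values[name] = _simulate_observer_pair(t_sbp, t_dbp, spec, rng)
            else:
                slot_values[name] = _simulate_device(t_sbp, t_dbp, device, rng)

        sessions.append(
            SubjectSession(
                subject_id=f"S{i + 1:03d}",
                sex=sexes[i],
                age=age,
                arm_circumference=arm,
                wrist_circumference=wrist,
                height=height,
                weight=weight,
                bmi=bmi,
                **slot_values,
            )
        )
    return Cohort(sessions=sessions, screened_total=spec.n_subjects, exclusions={})


def generate_screening_funnel(
    spec: CohortSpec = CohortSpec(),
    exclusion_rates: dict[str, float] = TABLE1_EXCLUSION_RATES,
    device: DeviceErrorModel = PAPER_LIKE_DEVICE,
) -> Cohort:
    """Generate a cohort carrying a screening funnel consistent by construction.

    Exclusion counts are derived from per-reason rates of the screened
    total; the screened total is then fixed as recruited + excluded so the
    accounting invariant holds exactly.  The default rates reproduce the
    study's funnel: 90 screened, 57 excluded (36 range adjustment, 18
    observer disagreement, 3 other), 33 recruited.
    """
    unknown = set(exclusion_rates) - set(EXCLUSION_REASONS)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    if any(not (0 <= r <= 1) for r in exclusion_rates.values()):
        raise ValueError("exclusion rates must lie in [0, 1]")
    total_rate = sum(exclusion_rates.values())
    if total_rate >= 1:
        raise ValueError("total exclusion rate must be < 1")

    cohort = generate_cohort(spec, device)
    n = len(cohort.sessions)
    screened_guess = n / (1.0 - total_rate)
    exclusions = {
        reason: int(round(rate * screened_guess))
        for reason, rate in exclusion_rates.items()
        if round(rate * screened_guess) > 0
    }
    screened_total = n + sum(exclusions.values())
    return Cohort(
        sessions=cohort.sessions,
        screened_total=screened_total,
        exclusions=exclusions,
    )
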