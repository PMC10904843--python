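"""Cohort analytics: system-interaction counts, exact Venn regions,
demographics, the LDL-C two-sample t-test, and prevalence arithmetic.

Interaction counts use superset containment (a patient with systems
{kidney, cardiac, neuro} contributes to the kidney–cardiac pair), while
Venn regions count patients whose affected-system set EQUALS the region
exactly. The two obey the identity

    order-k count of C  =  Σ venn_regions(S) over S ⊇ C.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .ehr_model import PatientRecord, Race, Sex, age_at
from .errors import ConfigurationError, DataError
from .fabry_screen import SYSTEMS

SystemSet = frozenset[str]


def _validate_systems(patient_systems: dict[str, SystemSet]) -> None:
    known = set(SYSTEMS)
    for pid, systems in patient_systems.items():
        extra = set(systems) - known
        if extra:
            raise DataError(f"patient {pid!r} has unknown system(s) {sorted(extra)}")


def interaction_counts(
    patient_systems: dict[str, SystemSet], k: int
) -> dict[tuple[str, ...], int]:
    """Counts of patients whose affected systems CONTAIN each size-k
    combination; every combination of size k is present (zeros included).
    Combination keys are tuples in canonical system order."""
    if not 1 <= k <= 5:
        raise ConfigurationError(f"interaction order k must be in 1..5, got {k}")
    _validate_systems(patient_systems)
    counts: dict[tuple[str, ...], int] = {}
    for combo in combinations(SYSTEMS, k):
        needed = set(combo)
        counts[combo] = sum(1 for s in patient_systems.values() if needed <= s)
    return counts


def venn_regions(patient_systems: dict[str, SystemSet]) -> dict[SystemSet, int]:
    """Exact-region counts: region S counts patients whose affected-system
    set equals S. All 31 non-empty subsets are present (zeros included);
    patients with no affected system fall in no region."""
    _validate_systems(patient_systems)
    regions: dict[SystemSet, int] = {
        frozenset(combo): 0
        for k in range(1, 6)
        for combo in combinations(SYSTEMS, k)
    }
    for systems in patient_systems.values():
        key = frozenset(systems)
        if key:
            regions[key] += 1
    return regions


@dataclass
class AgeStats:
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class DemographicsSummary:
    sex_counts: dict[Sex, int] = field(default_factory=dict)
    sex_proportions: dict[Sex, float] = field(default_factory=dict)
    race_counts: dict[Race, int] = field(default_factory=dict)
    race_proportions: dict[Race, float] = field(default_factory=dict)
    age_by_sex: dict[Sex, AgeStats] = field(default_factory=dict)


def _proportions(counts: dict) -> dict:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def demographics_summary(
    patients: list[PatientRecord],
    subset_ids: set[str],
    reference: dt.date,
) -> DemographicsSummary:
    """Sex/race counts and proportions plus per-sex age median and IQR
    (linear-interpolation quartiles) over the given patient subset.

    Ages are completed years at *reference*. An empty subset yields an
    empty summary, not an error.
    """
    known = {p.patient_id for p in patients}
    missing = subset_ids - known
    if missing:
        raise DataError(f"subset references unknown patient id(s): {sorted(missing)[:3]}")

    subset = [p for p in patients if p.patient_id in subset_ids]
    summary = DemographicsSummary()
    if not subset:
        return summary

    for p in subset:
        summary.sex_counts[p.sex] = summary.sex_counts.get(p.sex, 0) + 1
        summary.race_counts[p.race] = summary.race_counts.get(p.race, 0) + 1
    summary.sex_proportions = _proportions(summary.sex_counts)
    summary.race_proportions = _proportions(summary.race_counts)

    for sex in (Sex.MALE, Sex.FEMALE):
        ages = np.array([
            age_at(p.date_of_birth, reference) for p in subset if p.sex is sex
        ], dtype=float)
        if ages.size:
            q1, med, q3 = np.percentile(ages, [25, 50, 75])  # type-7 linear
            summary.age_by_sex[sex] = AgeStats(ages.size, float(med), float(q1), float(q3))
    return summary


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float


def two_sample_t_test(
    values_a, values_b, variant: str = "welch"
) -> TTestResult:
    """Two-sided two-sample t-test for a difference in means.

    ``variant="welch"`` (default) uses unequal variances with
    Welch–Satterthwaite degrees of freedom; ``"pooled"`` assumes equal
    variances. Each group needs n ≥ 2 and at least one group must have
    nonzero variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DataError("both groups have zero variance; t-test undefined")
    if variant not in {"welch", "pooled"}:
        raise ConfigurationError(f"unknown t-test variant {variant!r}")

    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(a.size + b.size - 2)
    else:
        df = (va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def prevalence_one_in_n(n_cases: int, cohort_size: int, round_to: int = 1) -> int:
    """Express a prevalence as "1 in N": N = cohort_size / n_cases rounded
    to the nearest multiple of *round_to* (ties away from zero)."""
    if n_cases < 1:
        raise DataError("prevalence undefined for zero cases")
    if cohort_size < n_cases:
        raise DataError("cohort_size must be at least n_cases")
    if round_to < 1:
        raise ConfigurationError("round_to must be a positive integer")
    return _round_half_away(cohort_size / n_cases / round_to) * round_to


def percent_increase(additional: float, baseline: float) -> float:
    """Percentage increase of *additional* cases over a *baseline* count."""
    if baseline <= 0:
        raise DataError("baseline must be positive")
    return 100.0 * additional / baseline


def expected_cases(cohort_size: int, rate_per_person: float, rounding: str = "nearest") -> int:
    """Expected case count at a per-person rate, rounded up (``"ceil"``) or
    to the nearest integer (``"nearest"``, ties away from zero)."""
    if not 0 < rate_per_person < 1:
        raise DataError("rate_per_person must be in (0, 1)")
    expectation = cohort_size * rate_per_person
    if rounding == "ceil":
        return math.ceil(expectation)
    if rounding == "nearest":
        return _round_half_away(expectation)
    raise ConfigurationError(f"unknown rounding mode {rounding!r}")
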