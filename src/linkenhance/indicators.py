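"""Stratified mortality indicators on a classified death dataset.

Provides the building blocks — percent increase, median age at death,
indirectly standardised mortality ratios (SMRs, scaled x100) with exact
gamma confidence intervals — and :func:`build_tables`, which assembles
them into the three report tables: counts with percent increases by
demographic stratum, median ages, and SMRs by cause/sex/method.

Rounding throughout is to 1 decimal, ties away from zero, matching how
such tables are conventionally printed.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .enhancement import METHODS, EnhancementResult
from .records import (
    BUILTIN_CAUSE_GROUPS,
    CauseGroup,
    DeathRecord,
    Remoteness,
    Sex,
    classify_cause,
)

__all__ = [
    "round1",
    "percent_increase",
    "percent_share",
    "median_age",
    "RateTable",
    "PopulationTable",
    "SmrResult",
    "expected_deaths",
    "smr_with_ci",
    "build_tables",
    "AGE_BANDS_COUNTS",
    "AGE_BANDS_5YR",
    "age_band",
    "default_standard_rates",
    "default_standard_population",
]


def round1(value: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_increase(baseline: int, enhanced: int) -> float:
    """Percent change from ``baseline`` to ``enhanced``, 1-decimal rounded."""
    if baseline <= 0:
        raise ValueError("percent increase undefined for baseline <= 0")
    return round1(100.0 * (enhanced - baseline) / baseline)


def percent_share(part: float, whole: float) -> float:
    """``part`` as a 1-decimal percentage of ``whole``."""
    if whole <= 0:
        raise ValueError("percent share undefined for whole <= 0")
    return round1(100.0 * part / whole)


def median_age(ages: Sequence[float]) -> float | None:
    """Median age at death (even counts average the middle pair).

    Returns ``None`` for an empty stratum — a missing value, not zero.
    """
    if len(ages) == 0:
        return None
    return round1(statistics.median(ages))


# --------------------------------------------------------------------------
# Age bands
# --------------------------------------------------------------------------

# counts/median tables: infancy split out, then 5-year bands to 85+
AGE_BANDS_COUNTS: tuple[str, ...] = ("0", "1-4") + tuple(
    f"{lo}-{lo + 4}" for lo in range(5, 85, 5)
) + ("85+",)

# standardisation: uniform 5-year bands with 0-4 merged
AGE_BANDS_5YR: tuple[str, ...] = tuple(f"{lo}-{lo + 4}" for lo in range(0, 85, 5)) + ("85+",)


def age_band(age: float, bands: Sequence[str] = AGE_BANDS_COUNTS) -> str:
    """Band label containing ``age``; final band is open-ended."""
    if age < 0:
        raise ValueError("age must be non-negative")
    for label in bands:
        if label.endswith("+"):
            if age >= int(label[:-1]):
                return label
        elif "-" in label:
            lo, hi = label.split("-")
            if int(lo) <= age <= int(hi):
                return label
        elif age == int(label):
            return label
    raise ValueError(f"age {age} not covered by bands {bands!r}")


# --------------------------------------------------------------------------
# Standardisation tables
# --------------------------------------------------------------------------


def _validate_strata(entries: Mapping[tuple[Sex, str], float], kind: str, minimum: float = 0.0) -> None:
    for (sex, band), value in entries.items():
        if not isinstance(sex, Sex):
            raise ValueError(f"{kind} key sex must be a Sex enum, got {sex!r}")
        if value < minimum:
            raise ValueError(f"{kind} for ({sex.value}, {band}) is negative: {value}")


@dataclass(frozen=True)
class RateTable:
    """Reference death rates per person-year by (sex, age band)."""

    entries: Mapping[tuple[Sex, str], float]

    def __post_init__(self) -> None:
        _validate_strata(self.entries, "rate")

    @property
    def strata(self) -> set[tuple[Sex, str]]:
        return set(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "RateTable":
        return cls(_read_stratum_csv(path, "rate", delimiter))

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        _write_stratum_csv(path, self.entries, "rate", delimiter)


@dataclass(frozen=True)
class PopulationTable:
    """Person counts by (sex, age band)."""

    entries: Mapping[tuple[Sex, str], float]

    def __post_init__(self) -> None:
        _validate_strata(self.entries, "population count")

    @property
    def strata(self) -> set[tuple[Sex, str]]:
        return set(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "PopulationTable":
        return cls(_read_stratum_csv(path, "count", delimiter))

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        _write_stratum_csv(path, self.entries, "count", delimiter)


def _read_stratum_csv(path: str | Path, value_col: str, delimiter: str) -> dict[tuple[Sex, str], float]:
    entries: dict[tuple[Sex, str], float] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter=delimiter):
            key = (Sex(row["sex"].strip()), row["age_band"].strip())
            if key in entries:
                raise ValueError(f"{path}: duplicate stratum {key}")
            entries[key] = float(row[value_col])
    return entries


def _write_stratum_csv(
    path: str | Path, entries: Mapping[tuple[Sex, str], float], value_col: str, delimiter: str
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(["sex", "age_band", value_col])
        for (sex, band), value in sorted(entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            writer.writerow([sex.value, band, repr(value)])


def expected_deaths(rates: RateTable, population: PopulationTable) -> float:
    """Sum of rate x population over strata (indirect standardisation).

    The two tables must cover identical (sex, band) strata.
    """
    missing = rates.strata ^ population.strata
    if missing:
        raise ValueError(f"rate/population strata mismatch: {sorted((s.value, b) for s, b in missing)}")
    return sum(rates.entries[key] * population.entries[key] for key in rates.entries)


# --------------------------------------------------------------------------
# SMR with exact gamma interval
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SmrResult:
    stratum: str
    observed: int
    expected: float
    smr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def smr_with_ci(
    observed: int, expected: float, alpha: float = 0.05, scale: float = 100.0
) -> SmrResult:
    """SMR with the exact gamma confidence interval.

    With ``d`` observed deaths the lower bound uses the gamma quantile at
    shape ``d`` (zero when ``d = 0``) and the upper bound shape ``d + 1``,
    both at unit scale and divided by the expected count.  Equivalent to
    halved chi-square quantiles at 2d and 2(d + 1) degrees of freedom.
    """
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    if observed < 0:
        raise ValueError("observed deaths must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    smr = scale * observed / expected
    low = 0.0 if observed == 0 else scale * stats.gamma.ppf(alpha / 2.0, a=observed) / expected
    high = scale * stats.gamma.ppf(1.0 - alpha / 2.0, a=observed + 1) / expected
    return SmrResult("", observed, expected, smr, low, high, alpha)


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

_SEX_GROUPS = ("male", "female", "total")


def _classified(results_by_id: Mapping[str, EnhancementResult], death: DeathRecord, method: str) -> bool:
    return bool(getattr(results_by_id[death.death_id], method))


def _counts_row(deaths: Iterable[DeathRecord], results_by_id, label: tuple[str, str]) -> dict:
    subset = list(deaths)
    row: dict = {"dimension": label[0], "category": label[1]}
    for method in METHODS:
        row[method] = sum(_classified(results_by_id, d, method) for d in subset)
    baseline = row["as_reported"]
    for method in ("algorithm", "at_least_one"):
        row[f"{method}_increase_pct"] = (
            percent_increase(baseline, row[method]) if baseline > 0 else float("nan")
        )
    return row


def _median_row(deaths: Sequence[DeathRecord], results_by_id, label: tuple[str, str]) -> dict:
    row: dict = {"dimension": label[0], "category": label[1]}
    for method in METHODS:
        for sex_group in _SEX_GROUPS:
            ages = [
                d.age_years
                for d in deaths
                if _classified(results_by_id, d, method)
                and (sex_group == "total" or d.sex.value == sex_group)
            ]
            value = median_age(ages)
            row[f"{method}_{sex_group}"] = float("nan") if value is None else value
    return row


def build_tables(
    deaths: Sequence[DeathRecord],
    results: Sequence[EnhancementResult],
    rates_by_cause: Mapping[str, RateTable] | None = None,
    population: PopulationTable | None = None,
    cause_groups: Sequence[CauseGroup] = BUILTIN_CAUSE_GROUPS,
    alpha: float = 0.05,
    smr_scale: float = 100.0,
) -> dict[str, pd.DataFrame]:
    """Assemble the three report tables from classified deaths.

    Returns a dict with ``"counts"`` (per-stratum counts and percent
    increases), ``"median_age"`` and — when ``rates_by_cause`` and
    ``population`` are supplied — ``"smr"``.  ``rates_by_cause`` maps a
    cause-group name (or ``"total"`` for all-cause) to its reference
    RateTable; causes without a rate table are omitted from the SMR table.
    Deaths with Unknown remoteness appear in totals but not in the
    remoteness-stratified rows.
    """
    results_by_id = {r.death_id: r for r in results}
    missing = [d.death_id for d in deaths if d.death_id not in results_by_id]
    if missing:
        raise ValueError(f"no enhancement result for death(s) {missing[:5]}")

    cause_of = {d.death_id: classify_cause(d.cause_icd10, cause_groups) for d in deaths}

    strata: list[tuple[tuple[str, str], list[DeathRecord]]] = []
    for band in AGE_BANDS_COUNTS:
        strata.append((("age", band), [d for d in deaths if age_band(d.age_years) == band]))
    for sex in (Sex.MALE, Sex.FEMALE):
        strata.append((("sex", sex.value), [d for d in deaths if d.sex is sex]))
    for rem in Remoteness:
        if rem is Remoteness.UNKNOWN:
            continue
        strata.append((("remoteness", rem.value), [d for d in deaths if d.remoteness is rem]))
    for group in cause_groups:
        strata.append((("cause", group.name), [d for d in deaths if cause_of[d.death_id] == group.name]))
    strata.append((("total", "total"), list(deaths)))

    counts = pd.DataFrame([_counts_row(subset, results_by_id, label) for label, subset in strata])

    median_strata = [s for s in strata if s[0][0] in ("cause", "remoteness", "total")]
    medians = pd.DataFrame([_median_row(subset, results_by_id, label) for label, subset in median_strata])

    tables = {"counts": counts, "median_age": medians}

    if rates_by_cause is not None and population is not None:
        tables["smr"] = _smr_table(
            deaths, results_by_id, cause_of, rates_by_cause, population, cause_groups, alpha, smr_scale
        )
    return tables


def _sex_expected(rates: RateTable, population: PopulationTable) -> dict[str, float]:
    expected: dict[str, float] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        sub_rates = RateTable({k: v for k, v in rates.entries.items() if k[0] is sex})
        sub_pop = PopulationTable({k: v for k, v in population.entries.items() if k[0] is sex})
        expected[sex.value] = expected_deaths(sub_rates, sub_pop)
    expected["total"] = expected["male"] + expected["female"]
    return expected


def _smr_table(
    deaths, results_by_id, cause_of, rates_by_cause, population, cause_groups, alpha, scale
) -> pd.DataFrame:
    rows = []
    cause_names = [g.name for g in cause_groups] + ["total"]
    for cause in cause_names:
        rates = rates_by_cause.get(cause)
        if rates is None:
            continue
        expected = _sex_expected(rates, population)
        in_cause = [d for d in deaths if cause == "total" or cause_of[d.death_id] == cause]
        for method in METHODS:
            row: dict = {"cause": cause, "method": method}
            for sex_group in _SEX_GROUPS:
                observed = sum(
                    1
                    for d in in_cause
                    if _classified(results_by_id, d, method)
                    and (sex_group == "total" or d.sex.value == sex_group)
                )
                res = smr_with_ci(observed, expected[sex_group], alpha=alpha, scale=scale)
                row[f"{sex_group}_observed"] = observed
                row[f"{sex_group}_expected"] = expected[sex_group]
                row[f"{sex_group}_smr"] = round1(res.smr)
                row[f"{sex_group}_ci_low"] = round1(res.ci_low)
                row[f"{sex_group}_ci_high"] = round1(res.ci_high)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Bundled synthetic standardisation defaults (for self-contained runs)
# --------------------------------------------------------------------------

# All-cause reference rates per person-year rising roughly log-linearly
# with age; cause tables are fixed shares of the all-cause rate.  These
# are synthetic stand-ins for an external national standard.
_CAUSE_SHARES = {"cancer": 0.28, "cardiovascular": 0.33, "external": 0.06}


def _base_rate(band_index: int) -> float:
    # ~5e-4 in childhood up to ~0.13 at 85+
    return 5e-4 * (1.38 ** band_index)


def default_standard_rates() -> dict[str, RateTable]:
    tables: dict[str, RateTable] = {}
    all_cause: dict[tuple[Sex, str], float] = {}
    for i, band in enumerate(AGE_BANDS_5YR):
        for sex, factor in ((Sex.MALE, 1.15), (Sex.FEMALE, 0.9)):
            all_cause[(sex, band)] = _base_rate(i) * factor
    tables["total"] = RateTable(all_cause)
    for cause, share in _CAUSE_SHARES.items():
        tables[cause] = RateTable({k: v * share for k, v in all_cause.items()})
    return tables


def default_standard_population() -> PopulationTable:
    # young-skewed pyramid, ~160k people total
    entries: dict[tuple[Sex, str], float] = {}
    for i, band in enumerate(AGE_BANDS_5YR):
        size = 12000.0 * (0.82 ** i)
        entries[(Sex.MALE, band)] = round(size * 0.5)
        entries[(Sex.FEMALE, band)] = round(size * 0.5)
    return PopulationTable(entries)
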