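"""Per-death classification under the three reporting methods.

Methods, from most to least conservative:

* ``as_reported`` — the death registration alone says yes.
* ``algorithm``  — weight of evidence: accepted as reported, or for other
  deaths at least 2 of 3+ countable linked units report yes, or at least
  1 of 1-2 units.
* ``at_least_one`` — any single report anywhere suffices.

A proportion-threshold variant (a fixed fraction of units must report
yes) is also provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import DeathRecord, LinkedRecord, TriState
from .units import UnitOfInformation, countable_units, derive_units, effective_flag

__all__ = [
    "EnhancementConfig",
    "EnhancementResult",
    "classify_as_reported",
    "classify_at_least_one",
    "classify_algorithm",
    "classify_proportion",
    "enhance_dataset",
    "method_counts",
]

METHODS = ("as_reported", "algorithm", "at_least_one")


@dataclass(frozen=True)
class EnhancementConfig:
    """Switches controlling how the classifiers see the evidence.

    count_missing_units:
        count units whose status is missing toward the algorithm's unit
        totals (default: a missing field carries no information).
    method1_on_raw_records:
        evaluate the at-least-one method on raw linked records instead of
        derived units; differs only when flags conflict within one stay.
    proportion_threshold:
        when set, additionally classify each death under the
        proportion-of-units variant at this threshold.
    gap_days:
        tolerated gap between discharge and readmission when collapsing
        hospital episodes into stays.
    """

    count_missing_units: bool = False
    method1_on_raw_records: bool = False
    proportion_threshold: float | None = None
    gap_days: int = 0


@dataclass(frozen=True)
class EnhancementResult:
    death_id: str
    as_reported: bool
    algorithm: bool
    at_least_one: bool
    n_units: int
    n_units_yes: int
    proportion: bool | None = None

    def __post_init__(self) -> None:
        if self.n_units_yes > self.n_units:
            raise ValueError("n_units_yes cannot exceed n_units")
        if self.as_reported and not (self.algorithm and self.at_least_one):
            raise ValueError("as_reported implies both enhanced methods")
        if self.algorithm and not self.at_least_one:
            raise ValueError("algorithm implies at_least_one")


def classify_as_reported(death: DeathRecord) -> bool:
    """True iff the death registration itself reports the person as Indigenous."""
    return death.reported_indigenous is TriState.YES


def classify_at_least_one(
    death: DeathRecord,
    units: Sequence[UnitOfInformation],
    count_missing: bool = False,
) -> bool:
    if classify_as_reported(death):
        return True
    _, k = countable_units(units, count_missing)
    return k >= 1


def classify_algorithm(
    death: DeathRecord,
    units: Sequence[UnitOfInformation],
    count_missing: bool = False,
) -> bool:
    if classify_as_reported(death):
        return True
    n, k = countable_units(units, count_missing)
    if n >= 3:
        return k >= 2
    if n >= 1:
        return k >= 1
    return False


def classify_proportion(
    death: DeathRecord,
    units: Sequence[UnitOfInformation],
    threshold: float,
    count_missing: bool = False,
) -> bool:
    """Variant requiring a fraction >= ``threshold`` of units to report yes."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if classify_as_reported(death):
        return True
    n, k = countable_units(units, count_missing)
    return n >= 1 and k / n >= threshold


def enhance_dataset(
    deaths: Sequence[DeathRecord],
    linked_records: Iterable[LinkedRecord],
    config: EnhancementConfig | None = None,
) -> list[EnhancementResult]:
    """Classify every death under all methods.

    Linked records referencing a death_id absent from ``deaths`` are
    ignored with a warning (unlinked residue).  Deaths with no linked
    records fall back to the as-reported classification alone.
    """
    config = config or EnhancementConfig()
    by_death: dict[str, list[LinkedRecord]] = {d.death_id: [] for d in deaths}
    orphans = 0
    for record in linked_records:
        bucket = by_death.get(record.death_id)
        if bucket is None:
            orphans += 1
            continue
        bucket.append(record)
    if orphans:
        warnings.warn(
            f"{orphans} linked record(s) reference unknown death_id values and were ignored",
            stacklevel=2,
        )

    results: list[EnhancementResult] = []
    for death in deaths:
        records = by_death[death.death_id]
        units = derive_units(death, records, gap_days=config.gap_days)
        n, k = countable_units(units, config.count_missing_units)
        if config.method1_on_raw_records:
            at_least_one = classify_as_reported(death) or any(
                effective_flag(r) is TriState.YES for r in records
            )
        else:
            at_least_one = classify_at_least_one(death, units, config.count_missing_units)
        proportion = None
        if config.proportion_threshold is not None:
            proportion = classify_proportion(
                death, units, config.proportion_threshold, config.count_missing_units
            )
        results.append(
            EnhancementResult(
                death_id=death.death_id,
                as_reported=classify_as_reported(death),
                algorithm=classify_algorithm(death, units, config.count_missing_units),
                at_least_one=at_least_one,
                n_units=n,
                n_units_yes=k,
                proportion=proportion,
            )
        )
    return results


def method_counts(results: Iterable[EnhancementResult]) -> Mapping[str, int]:
    """Aggregate classified-death counts per method."""
    counts = {m: 0 for m in METHODS}
    for r in results:
        for m in METHODS:
            counts[m] += bool(getattr(r, m))
    return counts


_RESULT_COLUMNS = ("death_id", "as_reported", "algorithm", "at_least_one", "n_units", "n_units_yes", "proportion")


def write_results(path, results: Iterable[EnhancementResult], delimiter: str = ",") -> None:
    import csv

    def flag(value: bool | None) -> str:
        return "" if value is None else str(int(value))

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(_RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [r.death_id, int(r.as_reported), int(r.algorithm), int(r.at_least_one),
                 r.n_units, r.n_units_yes, flag(r.proportion)]
            )


def read_results(path, delimiter: str = ",") -> list[EnhancementResult]:
    import csv

    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        results = []
        for row in reader:
            prop = row.get("proportion", "") or ""
            results.append(
                EnhancementResult(
                    death_id=row["death_id"],
                    as_reported=bool(int(row["as_reported"])),
                    algorithm=bool(int(row["algorithm"])),
                    at_least_one=bool(int(row["at_least_one"])),
                    n_units=int(row["n_units"]),
                    n_units_yes=int(row["n_units_yes"]),
                    proportion=bool(int(prop)) if prop else None,
                )
            )
    return results
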