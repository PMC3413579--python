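"""Derivation of evidence units from raw linked records.

Hospital (APD) episode records for a person are collapsed into stays;
every other linked record maps to one unit after parental-status
inheritance on infant birth rows.  The death registration record itself
is never emitted as a unit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .records import DeathRecord, LinkedRecord, Source, TriState

__all__ = [
    "UnitSource",
    "UnitOfInformation",
    "collapse_apd_stays",
    "apply_infant_inheritance",
    "derive_units",
    "countable_units",
]


class UnitSource(str, Enum):
    APD_STAY = "APD_stay"
    EDDC = "EDDC"
    PDC = "PDC"
    RBDM_BIRTH = "RBDM_birth"


_UNIT_SOURCE_ORDER = {s: i for i, s in enumerate(UnitSource)}

_RECORD_TO_UNIT_SOURCE = {
    Source.EDDC: UnitSource.EDDC,
    Source.PDC_MOTHER: UnitSource.PDC,
    Source.PDC_INFANT: UnitSource.PDC,
    Source.RBDM_MOTHER: UnitSource.RBDM_BIRTH,
    Source.RBDM_INFANT: UnitSource.RBDM_BIRTH,
}


@dataclass(frozen=True)
class UnitOfInformation:
    """One independent evidence item about a person's reported status."""

    death_id: str
    source: UnitSource
    reports_indigenous: TriState
    n_source_records: int = 1

    def __post_init__(self) -> None:
        if self.n_source_records < 1:
            raise ValueError("n_source_records must be >= 1")
        if self.source is not UnitSource.APD_STAY and self.n_source_records != 1:
            raise ValueError("only APD_stay units may collapse multiple records")


def _combine_flags(flags: Iterable[TriState]) -> TriState:
    # any yes wins; else no if any definite no; else missing
    result = TriState.MISSING
    for flag in flags:
        if flag is TriState.YES:
            return TriState.YES
        if flag is TriState.NO:
            result = TriState.NO
    return result


def _transfer_linked(earlier: LinkedRecord, later: LinkedRecord) -> bool:
    if earlier.transferred_to is not None and earlier.transferred_to == later.facility:
        return True
    if later.transferred_from is not None and later.transferred_from == earlier.facility:
        return True
    return False


def collapse_apd_stays(
    episodes: Sequence[LinkedRecord], gap_days: int = 0
) -> list[UnitOfInformation]:
    """Merge hospital episode records for one person into stay units.

    Episodes are sorted by admission date; an episode joins the current
    stay when its admission falls within ``gap_days`` of the stay's
    running discharge date, or when a transfer pointer connects it to the
    stay's last episode.  A stay reports yes if any constituent episode
    flags yes, no if all non-missing flags are no, missing otherwise.
    """
    if not episodes:
        return []
    ids = {e.death_id for e in episodes}
    if len(ids) > 1:
        raise ValueError(f"episodes span multiple persons: {sorted(ids)}")
    for e in episodes:
        if e.source is not Source.APD:
            raise ValueError(f"record {e.record_id!r} is not an APD episode")

    ordered = sorted(episodes, key=lambda e: (e.admit_date, e.discharge_date, e.record_id))
    gap = _dt.timedelta(days=gap_days)
    stays: list[list[LinkedRecord]] = [[ordered[0]]]
    stay_end = ordered[0].discharge_date
    for episode in ordered[1:]:
        previous = stays[-1][-1]
        assert stay_end is not None and episode.admit_date is not None
        if episode.admit_date <= stay_end + gap or _transfer_linked(previous, episode):
            stays[-1].append(episode)
            stay_end = max(stay_end, episode.discharge_date)
        else:
            stays.append([episode])
            stay_end = episode.discharge_date

    death_id = ordered[0].death_id
    return [
        UnitOfInformation(
            death_id=death_id,
            source=UnitSource.APD_STAY,
            reports_indigenous=_combine_flags(e.indigenous_flag for e in stay),
            n_source_records=len(stay),
        )
        for stay in stays
    ]


def apply_infant_inheritance(record: LinkedRecord) -> TriState:
    """Effective status for an infant birth row after parental inheritance.

    A perinatal infant row reports yes when the mother does; a birth
    registration infant row reports yes when either parent does.
    Otherwise the infant's own flag stands.
    """
    if record.source is Source.PDC_INFANT:
        if record.mother_indigenous_flag is TriState.YES:
            return TriState.YES
        return record.indigenous_flag
    if record.source is Source.RBDM_INFANT:
        if TriState.YES in (record.mother_indigenous_flag, record.father_indigenous_flag):
            return TriState.YES
        return record.indigenous_flag
    raise ValueError(f"inheritance applies to infant rows only, not {record.source.value}")


def effective_flag(record: LinkedRecord) -> TriState:
    """Record's status flag after inheritance where applicable."""
    if record.source in (Source.PDC_INFANT, Source.RBDM_INFANT):
        return apply_infant_inheritance(record)
    return record.indigenous_flag


def derive_units(
    death: DeathRecord,
    records: Sequence[LinkedRecord],
    gap_days: int = 0,
) -> list[UnitOfInformation]:
    """All units of information for one death, ordered by source then date."""
    for r in records:
        if r.death_id != death.death_id:
            raise ValueError(
                f"record {r.record_id!r} belongs to {r.death_id!r}, not {death.death_id!r}"
            )
    apd = [r for r in records if r.source is Source.APD]
    units = collapse_apd_stays(apd, gap_days=gap_days)
    others = [r for r in records if r.source is not Source.APD]
    others.sort(key=lambda r: (_UNIT_SOURCE_ORDER[_RECORD_TO_UNIT_SOURCE[r.source]], r.record_id))
    units.extend(
        UnitOfInformation(
            death_id=death.death_id,
            source=_RECORD_TO_UNIT_SOURCE[r.source],
            reports_indigenous=effective_flag(r),
        )
        for r in others
    )
    return units


def countable_units(
    units: Iterable[UnitOfInformation], count_missing: bool = False
) -> tuple[int, int]:
    """(n, k): countable units and those reporting yes.

    Units with a missing status carry no information and are excluded
    from ``n`` unless ``count_missing`` is set.
    """
    n = 0
    k = 0
    for unit in units:
        if unit.reports_indigenous is TriState.MISSING and not count_missing:
            continue
        n += 1
        if unit.reports_indigenous is TriState.YES:
            k += 1
    return n, k
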