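"""Synthetic linked death cohorts with configurable misreporting structure.

Generates a deaths table, a linked-records table and a per-death truth
table that together emulate the statistical structure the enhancement
analysis assumes: true status prevalence, per-source reporting
sensitivity and false-positive rates, age/cause-dependent hospital stay
counts (stays expand into transfer-chained episode rows), ED and
birth-related records, and record-linkage errors injected at given
missed/false-link rates.

One root seed drives independent per-stage streams (demographics,
record structure, status flags, linkage errors), so perturbing one stage
leaves draws in the others unchanged.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enhancement import EnhancementConfig, enhance_dataset, method_counts
from .indicators import AGE_BANDS_COUNTS
from .records import (
    DeathRecord,
    LinkedRecord,
    Remoteness,
    Sex,
    Source,
    TriState,
    write_deaths,
    write_linked_records,
)

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "generate_cohort",
    "inject_linkage_errors",
    "recovery_check",
    "paper_like_config",
]

_FLAG_SOURCES = ("death", "APD", "EDDC", "PDC", "RBDM")

_CAUSES = ("cancer", "cardiovascular", "external", "other")

_OTHER_CODES = ("J18", "E11", "K70", "G30", "N18", "F03", "A41", "J44")

# 3-character external-cause codes V01..Y98
_EXTERNAL_CODES = tuple(
    f"{letter}{num:02d}"
    for letter in "VWXY"
    for num in range(100)
    if ("V", 1) <= (letter, num) <= ("Y", 98)
)


def _default_stay_intensity() -> dict[str, dict[str, float]]:
    cause_mult = {"cancer": 1.6, "cardiovascular": 1.3, "external": 0.5, "other": 1.0}
    out: dict[str, dict[str, float]] = {}
    for i, band in enumerate(AGE_BANDS_COUNTS):
        base = 0.2 + 0.18 * i
        out[band] = {cause: base * mult for cause, mult in cause_mult.items()}
    return out


def _default_age_weights() -> dict[str, dict[str, float]]:
    indigenous = [
        0.060, 0.010, 0.004, 0.006, 0.008, 0.012, 0.015, 0.030, 0.035, 0.060,
        0.085, 0.080, 0.075, 0.110, 0.100, 0.095, 0.065, 0.050, 0.100,
    ]
    other = [0.008, 0.002, 0.001, 0.001, 0.003, 0.005, 0.006, 0.008, 0.010, 0.015,
             0.022, 0.030, 0.040, 0.055, 0.070, 0.095, 0.130, 0.180, 0.319]
    return {
        "indigenous": dict(zip(AGE_BANDS_COUNTS, indigenous)),
        "other": dict(zip(AGE_BANDS_COUNTS, other)),
    }


def _default_remoteness_weights() -> dict[str, dict[str, float]]:
    return {
        "indigenous": {
            "MajorCities": 0.295, "InnerRegional": 0.325, "OuterRegional": 0.235,
            "Remote": 0.080, "VeryRemote": 0.040, "Unknown": 0.025,
        },
        "other": {
            "MajorCities": 0.600, "InnerRegional": 0.250, "OuterRegional": 0.118,
            "Remote": 0.015, "VeryRemote": 0.005, "Unknown": 0.012,
        },
    }


def _default_cause_weights() -> dict[str, dict[str, float]]:
    return {
        "indigenous": {"cancer": 0.22, "cardiovascular": 0.31, "external": 0.10, "other": 0.37},
        "other": {"cancer": 0.28, "cardiovascular": 0.33, "external": 0.06, "other": 0.33},
    }


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort generator.

    Per-source maps use the keys ``death, APD, EDDC, PDC, RBDM``.
    Default sensitivities follow reported per-dataset levels of correct
    status recording (death data 0.76, hospital 0.88, perinatal 0.68);
    ED and birth-registration quality is unreported, so their defaults
    (0.80) are placeholders.  Default linkage-error rates are 4/1000
    false links and 5/1000 missed links.
    """

    n_deaths: int = 2000
    prevalence_true_indigenous: float = 0.02
    report_sensitivity: dict = field(
        default_factory=lambda: {"death": 0.76, "APD": 0.88, "EDDC": 0.80, "PDC": 0.68, "RBDM": 0.80}
    )
    report_fp_rate: dict = field(default_factory=lambda: {s: 0.0 for s in _FLAG_SOURCES})
    missing_rate: dict = field(default_factory=lambda: {s: 0.0 for s in _FLAG_SOURCES})
    stay_intensity: dict = field(default_factory=_default_stay_intensity)
    remoteness_intensity: dict = field(
        default_factory=lambda: {
            "MajorCities": 1.2, "InnerRegional": 1.0, "OuterRegional": 0.85,
            "Remote": 0.65, "VeryRemote": 0.5, "Unknown": 1.0,
        }
    )
    episodes_per_stay_mean: float = 1.25
    ed_intensity: float = 0.7
    birth_record_probability: float = 0.9
    mother_record_probability: float = 0.01
    false_link_rate: float = 0.004
    missed_link_rate: float = 0.005
    age_band_weights: dict = field(default_factory=_default_age_weights)
    remoteness_weights: dict = field(default_factory=_default_remoteness_weights)
    cause_weights: dict = field(default_factory=_default_cause_weights)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_deaths < 0:
            raise ValueError("n_deaths must be >= 0")
        for name in ("report_sensitivity", "report_fp_rate", "missing_rate"):
            table = getattr(self, name)
            for source in _FLAG_SOURCES:
                p = table.get(source)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{source!r}] must be a probability, got {p!r}")
        for rate_name in ("false_link_rate", "missed_link_rate", "prevalence_true_indigenous",
                          "birth_record_probability", "mother_record_probability"):
            p = getattr(self, rate_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{rate_name} must be a probability, got {p!r}")
        if self.episodes_per_stay_mean < 1.0:
            raise ValueError("episodes_per_stay_mean must be >= 1")
        if self.ed_intensity < 0:
            raise ValueError("ed_intensity must be >= 0")
        for band, by_cause in self.stay_intensity.items():
            for cause, mean in by_cause.items():
                if mean < 0:
                    raise ValueError(f"stay_intensity[{band}][{cause}] must be >= 0")
        for status in ("indigenous", "other"):
            for table_name in ("age_band_weights", "remoteness_weights", "cause_weights"):
                weights = getattr(self, table_name)[status]
                if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                    raise ValueError(f"{table_name}[{status!r}] must be non-negative, non-zero weights")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config


def paper_like_config(n_deaths: int = 2000, seed: int | None = None) -> GeneratorConfig:
    """The default scenario: reported sensitivities, linkage-error rates on."""
    return GeneratorConfig(n_deaths=n_deaths, seed=seed)


@dataclass
class Cohort:
    """A generated cohort plus its ground truth.

    ``truth`` has one row per death: the true status, the probability the
    death record reports yes, and the semicolon-joined per-unit report
    probabilities (used by analytic recovery checks).  ``linkage_log``
    records every injected linkage error.
    """

    deaths: list[DeathRecord]
    linked_records: list[LinkedRecord]
    truth: pd.DataFrame
    linkage_log: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_deaths(outdir / "deaths.csv", self.deaths)
        write_linked_records(outdir / "linked.csv", self.linked_records)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.linkage_log.to_csv(outdir / "linkage_log.csv", index=False)


def _band_ages(band: str) -> tuple[int, int]:
    if band == "85+":
        return 85, 99
    if "-" in band:
        lo, hi = band.split("-")
        return int(lo), int(hi)
    return int(band), int(band)


def _weighted_choice(rng: np.random.Generator, weights: dict, size: int) -> list:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def _draw_flag(rng: np.random.Generator, p_yes: float, p_missing: float) -> TriState:
    if p_missing > 0 and rng.random() < p_missing:
        return TriState.MISSING
    return TriState.YES if rng.random() < p_yes else TriState.NO


def _icd_code(rng: np.random.Generator, cause: str) -> str:
    if cause == "cancer":
        return f"C{rng.integers(0, 98):02d}"
    if cause == "cardiovascular":
        return f"I{rng.integers(0, 100):02d}"
    if cause == "external":
        return _EXTERNAL_CODES[rng.integers(0, len(_EXTERNAL_CODES))]
    return _OTHER_CODES[rng.integers(0, len(_OTHER_CODES))]


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate a reproducible cohort; ``seed`` overrides ``config.seed``."""
    config.validate()
    root = seed if seed is not None else (config.seed if config.seed is not None else 0)
    streams = np.random.SeedSequence(root).spawn(4)
    demo = np.random.default_rng(streams[0])
    struct = np.random.default_rng(streams[1])
    flags = np.random.default_rng(streams[2])
    link = np.random.default_rng(streams[3])

    n = config.n_deaths
    true_flags = demo.random(n) < config.prevalence_true_indigenous
    sexes = [Sex.MALE if male else Sex.FEMALE for male in demo.random(n) < 0.5]
    band_pool = {
        status: _weighted_choice(demo, config.age_band_weights[status], n)
        for status in ("indigenous", "other")
    }
    remote_pool = {
        status: _weighted_choice(demo, config.remoteness_weights[status], n)
        for status in ("indigenous", "other")
    }
    cause_pool = {
        status: _weighted_choice(demo, config.cause_weights[status], n)
        for status in ("indigenous", "other")
    }
    # uniform draw within band resolved per death below
    age_fracs = demo.random(n)

    sens = config.report_sensitivity
    fp = config.report_fp_rate
    miss = config.missing_rate

    deaths: list[DeathRecord] = []
    records: list[LinkedRecord] = []
    truth_rows: list[dict] = []
    record_counter = 0

    def next_record_id() -> str:
        nonlocal record_counter
        record_counter += 1
        return f"r{record_counter:07d}"

    for i in range(n):
        status = "indigenous" if true_flags[i] else "other"
        band = band_pool[status][i]
        lo, hi = _band_ages(band)
        age = lo + int(age_fracs[i] * (hi - lo + 1))
        remoteness = Remoteness(remote_pool[status][i])
        cause = cause_pool[status][i]
        death_id = f"d{i + 1:06d}"

        def report_p(source: str) -> float:
            return sens[source] if true_flags[i] else fp[source]

        death_flag = _draw_flag(flags, report_p("death"), miss["death"])
        p_death_report = (1.0 - miss["death"]) * report_p("death")

        deaths.append(
            DeathRecord(
                death_id=death_id,
                age_years=age,
                sex=sexes[i],
                remoteness=remoteness,
                cause_icd10=_icd_code(demo, cause),
                reported_indigenous=death_flag,
            )
        )

        unit_ps: list[float] = []

        # hospital stays -> transfer-chained episode rows
        intensity = config.stay_intensity[band][cause] * config.remoteness_intensity[remoteness.value]
        n_stays = struct.poisson(intensity)
        cursor = _dt.date(2005, 1, 1) + _dt.timedelta(days=int(struct.integers(0, 365)))
        for _ in range(n_stays):
            n_episodes = 1 + int(struct.poisson(config.episodes_per_stay_mean - 1.0))
            stay_flag = _draw_flag(flags, report_p("APD"), miss["APD"])
            unit_ps.append((1.0 - miss["APD"]) * report_p("APD"))
            facilities = [f"F{int(struct.integers(1, 60)):02d}" for _ in range(n_episodes)]
            admit = cursor
            for j in range(n_episodes):
                discharge = admit + _dt.timedelta(days=int(struct.integers(1, 8)))
                records.append(
                    LinkedRecord(
                        record_id=next_record_id(),
                        death_id=death_id,
                        source=Source.APD,
                        indigenous_flag=stay_flag,
                        admit_date=admit,
                        discharge_date=discharge,
                        facility=facilities[j],
                        transferred_from=facilities[j - 1] if j > 0 else None,
                        transferred_to=facilities[j + 1] if j < n_episodes - 1 else None,
                    )
                )
                admit = discharge
            cursor = admit + _dt.timedelta(days=int(struct.integers(2, 60)))

        # emergency department attendances
        for _ in range(struct.poisson(config.ed_intensity)):
            records.append(
                LinkedRecord(
                    record_id=next_record_id(),
                    death_id=death_id,
                    source=Source.EDDC,
                    indigenous_flag=_draw_flag(flags, report_p("EDDC"), miss["EDDC"]),
                )
            )
            unit_ps.append((1.0 - miss["EDDC"]) * report_p("EDDC"))

        # birth-related records: infants carry parental flags (assumed to
        # share the infant's true status), mothers carry their own only
        if age == 0 and struct.random() < config.birth_record_probability:
            p_pdc = (1.0 - miss["PDC"]) * report_p("PDC")
            records.append(
                LinkedRecord(
                    record_id=next_record_id(),
                    death_id=death_id,
                    source=Source.PDC_INFANT,
                    indigenous_flag=_draw_flag(flags, report_p("PDC"), miss["PDC"]),
                    mother_indigenous_flag=_draw_flag(flags, report_p("PDC"), miss["PDC"]),
                )
            )
            unit_ps.append(1.0 - (1.0 - p_pdc) ** 2)
            p_rbdm = (1.0 - miss["RBDM"]) * report_p("RBDM")
            records.append(
                LinkedRecord(
                    record_id=next_record_id(),
                    death_id=death_id,
                    source=Source.RBDM_INFANT,
                    indigenous_flag=_draw_flag(flags, report_p("RBDM"), miss["RBDM"]),
                    mother_indigenous_flag=_draw_flag(flags, report_p("RBDM"), miss["RBDM"]),
                    father_indigenous_flag=_draw_flag(flags, report_p("RBDM"), miss["RBDM"]),
                )
            )
            unit_ps.append(1.0 - (1.0 - p_rbdm) ** 3)
        elif (
            sexes[i] is Sex.FEMALE
            and 15 <= age <= 44
            and struct.random() < config.mother_record_probability
        ):
            records.append(
                LinkedRecord(
                    record_id=next_record_id(),
                    death_id=death_id,
                    source=Source.PDC_MOTHER,
                    indigenous_flag=_draw_flag(flags, report_p("PDC"), miss["PDC"]),
                )
            )
            unit_ps.append((1.0 - miss["PDC"]) * report_p("PDC"))
            records.append(
                LinkedRecord(
                    record_id=next_record_id(),
                    death_id=death_id,
                    source=Source.RBDM_MOTHER,
                    indigenous_flag=_draw_flag(flags, report_p("RBDM"), miss["RBDM"]),
                )
            )
            unit_ps.append((1.0 - miss["RBDM"]) * report_p("RBDM"))

        truth_rows.append(
            {
                "death_id": death_id,
                "true_indigenous": int(true_flags[i]),
                "p_death_report": p_death_report,
                "unit_p_reports": ";".join(f"{p:.10g}" for p in unit_ps),
                "n_units": len(unit_ps),
            }
        )

    records, log_rows = inject_linkage_errors(
        records,
        [d.death_id for d in deaths],
        missed_link_rate=config.missed_link_rate,
        false_link_rate=config.false_link_rate,
        rng=link,
    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["death_id", "true_indigenous", "p_death_report", "unit_p_reports", "n_units"],
    )
    linkage_log = pd.DataFrame(
        log_rows, columns=["record_id", "action", "old_death_id", "new_death_id"]
    )
    return Cohort(deaths=deaths, linked_records=records, truth=truth, linkage_log=linkage_log)


def inject_linkage_errors(
    records: Sequence[LinkedRecord],
    death_ids: Sequence[str],
    missed_link_rate: float,
    false_link_rate: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[LinkedRecord], list[dict]]:
    """Drop and reassign records to emulate missed and false links.

    Each record is independently dropped with ``missed_link_rate``;
    surviving records are reassigned to a uniformly chosen *other*
    death_id with ``false_link_rate``.  Returns the perturbed records and
    a log of every perturbation.
    """
    for name, rate in (("missed_link_rate", missed_link_rate), ("false_link_rate", false_link_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be a probability, got {rate!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[LinkedRecord] = []
    log: list[dict] = []
    ids = list(death_ids)
    for record in records:
        if missed_link_rate > 0 and rng.random() < missed_link_rate:
            log.append(
                {"record_id": record.record_id, "action": "dropped",
                 "old_death_id": record.death_id, "new_death_id": ""}
            )
            continue
        if false_link_rate > 0 and len(ids) > 1 and rng.random() < false_link_rate:
            new_id = record.death_id
            while new_id == record.death_id:
                new_id = ids[rng.integers(0, len(ids))]
            log.append(
                {"record_id": record.record_id, "action": "false_link",
                 "old_death_id": record.death_id, "new_death_id": new_id}
            )
            record = replace(record, death_id=new_id)
        out.append(record)
    return out, log


# --------------------------------------------------------------------------
# End-to-end recovery check
# --------------------------------------------------------------------------


def _poisson_binomial_tail(ps: Sequence[float]) -> tuple[float, float]:
    """(P(K=0), P(K=1)) for a sum of independent Bernoulli(p_j)."""
    p0, p1 = 1.0, 0.0
    for p in ps:
        p1 = p1 * (1.0 - p) + p0 * p
        p0 *= 1.0 - p
    return p0, p1


def _analytic_probs(p_death: float, unit_ps: Sequence[float]) -> dict[str, float]:
    p0, p1 = _poisson_binomial_tail(unit_ps)
    n = len(unit_ps)
    p_alo = 1.0 - (1.0 - p_death) * p0
    if n == 0:
        p_alg = p_death
    elif n <= 2:
        p_alg = p_death + (1.0 - p_death) * (1.0 - p0)
    else:
        p_alg = p_death + (1.0 - p_death) * (1.0 - p0 - p1)
    return {"as_reported": p_death, "algorithm": p_alg, "at_least_one": p_alo}


def recovery_check(
    config: GeneratorConfig, n_reps: int, seed: int | None = None
) -> pd.DataFrame:
    """Compare simulated per-method counts to closed-form expectations.

    Runs generate -> derive units -> enhance ``n_reps`` times and, per
    method, totals the simulated counts against the analytic expectation
    computed from each cohort's realised unit structure (per-death
    Poisson-binomial over the truth table's unit report probabilities).
    Requires a noise-free scenario: zero false-positive, missing and
    linkage-error rates, since the closed form conditions on an intact
    unit structure.

    Returns one row per method with simulated and expected totals, the
    binomial standard error, the z-score, and a 3-SE flag.
    """
    config.validate()
    noise = dict(config.report_fp_rate)
    noise.update({f"missing_{k}": v for k, v in config.missing_rate.items()})
    noise["false_link_rate"] = config.false_link_rate
    noise["missed_link_rate"] = config.missed_link_rate
    bad = {k: v for k, v in noise.items() if v != 0.0}
    if bad:
        raise ValueError(f"recovery_check requires a noise-free scenario; nonzero: {bad}")

    streams = np.random.SeedSequence(seed if seed is not None else 0).spawn(n_reps)
    methods = ("as_reported", "algorithm", "at_least_one")
    simulated = {m: 0 for m in methods}
    expected = {m: 0.0 for m in methods}
    variance = {m: 0.0 for m in methods}
    true_total = 0

    for stream in streams:
        # deterministic per-rep seed derived from the spawned stream
        cohort = generate_cohort(config, seed=int(stream.generate_state(1)[0]))
        counts = method_counts(enhance_dataset(cohort.deaths, cohort.linked_records, EnhancementConfig()))
        true_total += int(cohort.truth["true_indigenous"].sum())
        for m in methods:
            simulated[m] += counts[m]
        for row in cohort.truth.itertuples(index=False):
            if not row.true_indigenous:
                continue  # zero report probability everywhere in a noise-free run
            unit_ps = [float(p) for p in row.unit_p_reports.split(";") if p]
            probs = _analytic_probs(float(row.p_death_report), unit_ps)
            for m in methods:
                expected[m] += probs[m]
                variance[m] += probs[m] * (1.0 - probs[m])

    rows = []
    for m in methods:
        se = float(np.sqrt(variance[m]))
        diff = simulated[m] - expected[m]
        z = diff / se if se > 0 else 0.0
        rows.append(
            {
                "method": m,
                "simulated": simulated[m],
                "expected": expected[m],
                "se": se,
                "z": z,
                "within_3se": abs(z) <= 3.0,
                "true_indigenous_total": true_total,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
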