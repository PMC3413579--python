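import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from linkenhance.enhancement import enhance_dataset
from linkenhance.indicators import (
    AGE_BANDS_5YR,
    AGE_BANDS_COUNTS,
    PopulationTable,
    RateTable,
    age_band,
    build_tables,
    default_standard_population,
    default_standard_rates,
    expected_deaths,
    median_age,
    percent_increase,
    percent_share,
    round1,
    smr_with_ci,
)
from linkenhance.records import Remoteness, Sex, TriState

from conftest import make_death, make_record


# ---------------------------------------------------------------- arithmetic


@pytest.mark.parametrize(
    "baseline,enhanced,expected",
    [(580, 780, 34.5), (580, 908, 56.6), (57, 121, 112.3), (57, 92, 61.4), (100, 100, 0.0)],
)
def test_percent_increase(baseline, enhanced, expected):
    assert percent_increase(baseline, enhanced) == expected


def test_percent_increase_zero_baseline():
    with pytest.raises(ValueError):
        percent_increase(0, 10)


def test_rounding_half_away_from_zero():
    assert round1(0.25, 1) == 0.3
    assert round1(-0.25, 1) == -0.3
    assert round1(34.45) == 34.5


@settings(max_examples=50, deadline=None)
@given(b=st.integers(1, 10_000), e1=st.integers(0, 10_000), e2=st.integers(0, 10_000))
def test_percent_increase_monotone(b, e1, e2):
    lo, hi = sorted((e1, e2))
    assert percent_increase(b, lo) <= percent_increase(b, hi)


def test_percent_share():
    assert percent_share(580, 780) == 74.4
    assert percent_share(580, 908) == 63.9
    with pytest.raises(ValueError):
        percent_share(1, 0)


# ---------------------------------------------------------------- median age


def test_median_examples():
    assert median_age([63]) == 63.0
    assert median_age([60, 62, 64, 70]) == 63.0
    assert median_age([]) is None


def test_median_against_sort_oracle():
    rnd = random.Random(7)
    ages = [rnd.randint(0, 100) for _ in range(101)]
    assert median_age(ages) == float(sorted(ages)[50])


# ---------------------------------------------------------------- age bands


def test_age_band_assignment():
    assert age_band(0) == "0"
    assert age_band(3) == "1-4"
    assert age_band(84) == "80-84"
    assert age_band(97) == "85+"
    assert age_band(2, AGE_BANDS_5YR) == "0-4"
    with pytest.raises(ValueError):
        age_band(-1)


def test_count_bands_partition():
    for age in range(0, 131):
        hits = [b for b in AGE_BANDS_COUNTS if age_band(age) == b]
        assert len(hits) == 1


# ---------------------------------------------------------------- standardisation


def _random_tables(rnd, n_bands=18):
    bands = AGE_BANDS_5YR[:n_bands]
    rates = {}
    pop = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        for band in bands:
            rates[(sex, band)] = rnd.uniform(0.0, 0.1)
            pop[(sex, band)] = rnd.randint(0, 5000)
    return RateTable(rates), PopulationTable(pop)


def test_expected_deaths_trivial():
    rates = RateTable({(Sex.MALE, "0-4"): 0.01})
    pop = PopulationTable({(Sex.MALE, "0-4"): 1000})
    assert expected_deaths(rates, pop) == pytest.approx(10.0)


def test_expected_deaths_additivity():
    rates = RateTable({(Sex.MALE, "0-4"): 0.01, (Sex.FEMALE, "0-4"): 0.002})
    pop = PopulationTable({(Sex.MALE, "0-4"): 1000, (Sex.FEMALE, "0-4"): 5000})
    assert expected_deaths(rates, pop) == pytest.approx(20.0)


def test_expected_deaths_brute_force_oracle():
    rnd = random.Random(11)
    rates, pop = _random_tables(rnd)
    oracle = 0.0
    for key in rates.entries:
        oracle += rates.entries[key] * pop.entries[key]
    assert expected_deaths(rates, pop) == pytest.approx(oracle, rel=1e-12)


def test_expected_deaths_key_mismatch():
    rates = RateTable({(Sex.MALE, "0-4"): 0.01})
    pop = PopulationTable({(Sex.FEMALE, "0-4"): 1000})
    with pytest.raises(ValueError, match="mismatch"):
        expected_deaths(rates, pop)


def test_stratum_table_csv_round_trip(tmp_path):
    rnd = random.Random(3)
    rates, pop = _random_tables(rnd)
    rates.to_csv(tmp_path / "rates.csv")
    pop.to_csv(tmp_path / "population.csv")
    assert RateTable.from_csv(tmp_path / "rates.csv").entries == rates.entries
    assert PopulationTable.from_csv(tmp_path / "population.csv").entries == pop.entries


# ---------------------------------------------------------------- SMR + gamma CI


def test_smr_identity():
    res = smr_with_ci(50, 50.0)
    assert res.smr == pytest.approx(100.0)
    assert res.ci_low < 100.0 < res.ci_high


def test_smr_zero_observed_closed_form():
    res = smr_with_ci(0, 2.0)
    assert res.ci_low == 0.0
    assert res.ci_high == pytest.approx(100.0 * -math.log(0.025) / 2.0, rel=1e-12)


def test_smr_chi_square_oracle():
    res = smr_with_ci(10, 5.0)
    low = 100.0 * 0.5 * stats.chi2.ppf(0.025, 2 * 10) / 5.0
    high = 100.0 * 0.5 * stats.chi2.ppf(0.975, 2 * (10 + 1)) / 5.0
    assert res.ci_low == pytest.approx(low, abs=1e-9)
    assert res.ci_high == pytest.approx(high, abs=1e-9)


def test_smr_bounds_bracket_estimate():
    for observed in (1, 3, 17, 120):
        res = smr_with_ci(observed, 9.5)
        assert 0 < res.ci_low <= res.smr <= res.ci_high


def test_smr_input_validation():
    with pytest.raises(ValueError):
        smr_with_ci(5, 0.0)
    with pytest.raises(ValueError):
        smr_with_ci(-1, 2.0)
    with pytest.raises(ValueError):
        smr_with_ci(5, 2.0, alpha=1.5)


def test_smr_coverage_quick():
    # conservatively covering in a short Poisson simulation
    rng = np.random.default_rng(42)
    theta, expected = 1.4, 9.0
    hits = 0
    n = 400
    for obs in rng.poisson(theta * expected, size=n):
        res = smr_with_ci(int(obs), expected)
        hits += res.ci_low <= 100.0 * theta <= res.ci_high
    assert hits / n >= 0.93


# ---------------------------------------------------------------- tables


def _fixture_dataset():
    deaths = [
        make_death("d1", 70, Sex.MALE, Remoteness.MAJOR_CITIES, "C50", TriState.YES),
        make_death("d2", 45, Sex.FEMALE, Remoteness.REMOTE, "I21", TriState.NO),
        make_death("d3", 85, Sex.MALE, Remoteness.INNER_REGIONAL, "X42", TriState.NO),
        make_death("d4", 30, Sex.FEMALE, Remoteness.UNKNOWN, "J18", TriState.NO),
        make_death("d5", 62, Sex.MALE, Remoteness.MAJOR_CITIES, "C34", TriState.NO),
    ]
    linked = [
        make_record("r1", "d2", flag=TriState.YES),
        make_record("r2", "d3", flag=TriState.YES),
        make_record("r3", "d3", flag=TriState.NO),
        make_record("r4", "d3", flag=TriState.NO),
        make_record("r5", "d5", flag=TriState.YES),
        make_record("r6", "d5", flag=TriState.YES),
    ]
    results = enhance_dataset(deaths, linked)
    return deaths, results


def test_build_tables_counts_match_per_cell_oracle():
    deaths, results = _fixture_dataset()
    tables = build_tables(deaths, results)
    counts = tables["counts"].set_index(["dimension", "category"])
    by_id = {r.death_id: r for r in results}
    # independent group-by oracle per cell
    for sex in ("male", "female"):
        subset = [d for d in deaths if d.sex.value == sex]
        for method in ("as_reported", "algorithm", "at_least_one"):
            oracle = sum(getattr(by_id[d.death_id], method) for d in subset)
            assert counts.loc[("sex", sex), method] == oracle
    total = counts.loc[("total", "total")]
    assert total["as_reported"] == 1
    assert total["algorithm"] == 3  # d1 reported, d2 (n=1,k=1), d5 (n=2,k=2)
    assert total["at_least_one"] == 4


def test_counts_conservation_across_remoteness():
    deaths, results = _fixture_dataset()
    counts = build_tables(deaths, results)["counts"].set_index(["dimension", "category"])
    remoteness_rows = counts.loc["remoteness"]
    unknown = [d for d in deaths if d.remoteness is Remoteness.UNKNOWN]
    by_id = {r.death_id: r for r in results}
    for method in ("as_reported", "algorithm", "at_least_one"):
        unknown_count = sum(getattr(by_id[d.death_id], method) for d in unknown)
        assert remoteness_rows[method].sum() + unknown_count == counts.loc[("total", "total"), method]


def test_tables_invariant_to_row_order():
    deaths, results = _fixture_dataset()
    tables_fwd = build_tables(deaths, results)
    tables_rev = build_tables(list(reversed(deaths)), list(reversed(results)))
    for name in tables_fwd:
        assert tables_fwd[name].equals(tables_rev[name])


def test_all_methods_agree_gives_identical_columns():
    deaths = [make_death(f"d{i}", 50 + i, reported_indigenous=TriState.YES) for i in range(4)]
    results = enhance_dataset(deaths, [])
    counts = build_tables(deaths, results)["counts"]
    assert (counts["as_reported"] == counts["algorithm"]).all()
    assert (counts["as_reported"] == counts["at_least_one"]).all()


def test_smr_table_from_defaults():
    deaths, results = _fixture_dataset()
    tables = build_tables(deaths, results, default_standard_rates(), default_standard_population())
    smr = tables["smr"]
    assert set(smr["cause"]) == {"cancer", "cardiovascular", "external", "total"}
    # enhancement only adds deaths, so total-method SMRs are ordered
    total = smr[smr["cause"] == "total"].set_index("method")
    assert (
        total.loc["as_reported", "total_smr"]
        <= total.loc["algorithm", "total_smr"]
        <= total.loc["at_least_one", "total_smr"]
    )


def test_median_table_empty_stratum_is_nan():
    deaths, results = _fixture_dataset()
    medians = build_tables(deaths, results)["median_age"].set_index(["dimension", "category"])
    # nobody as-reported in very remote areas
    assert math.isnan(medians.loc[("remoteness", "VeryRemote"), "as_reported_total"])
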