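"""Concentration x consumption intake estimation and adequacy."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import omega3diet as od
from omega3diet.intake import (
    STATISTICS,
    ConsumptionStats,
    ConsumptionStratum,
    assess_adequacy,
    category_mean_content,
    category_median_content,
    estimate_intake,
    load_bundled_intake,
    load_consumption_table,
    reference_for_stratum,
    write_consumption_table,
)
from omega3diet.records import Category, ConfigError, ContractError
from omega3diet.requirements import Authority, Nutrient, Sex


def _stratum(consumption, sex=Sex.FEMALE, age=(19.0, 65.0), bw=57.0):
    return ConsumptionStratum(
        sex=sex, age_low=age[0], age_high=age[1], consumption=consumption, body_weight_mean=bw
    )


def _scored(values, cat):
    from omega3diet.content import classify_band, round_half_up, Omega3Content

    return [
        Omega3Content(
            food_id=f"{cat.value}-{i}",
            content_exact=v,
            content_display=round_half_up(v),
            band=classify_band(round_half_up(v)),
            category=cat,
        )
        for i, v in enumerate(values)
    ]


def test_category_mean_is_arithmetic_mean():
    scored = _scored([0.10, 0.30], Category.FISH)
    assert category_mean_content(scored, Category.FISH) == pytest.approx(0.20)


def test_singleton_category_mean_is_that_content():
    scored = _scored([0.042], Category.MOLLUSK)
    assert category_mean_content(scored, Category.MOLLUSK) == pytest.approx(0.042)


def test_mollusk_fixture_mean_content(scored_all):
    # frozen from summing the 15 printed share x fat products by hand
    assert category_mean_content(scored_all, Category.MOLLUSK) == pytest.approx(
        0.0035971, abs=1e-6
    )


def test_median_content_pathway(scored_all):
    med = category_median_content(scored_all, Category.MOLLUSK)
    assert med == pytest.approx(0.00257, abs=1e-6)
    assert med < category_mean_content(scored_all, Category.MOLLUSK)


def test_empty_category_mean_is_an_error(scored_all):
    with pytest.raises(ContractError):
        category_mean_content([], Category.FISH)


def test_contribution_is_consumption_times_content():
    stratum = _stratum({Category.FISH: ConsumptionStats(10.0, 5.0, 20.0)})
    est = estimate_intake(stratum, {Category.FISH: 0.08}, Nutrient.EPA_DHA)
    assert est.contributions[Category.FISH]["mean"] == pytest.approx(0.8)
    assert est.totals["p95"] == pytest.approx(1.6)


def test_zero_consumption_annihilates():
    stratum = _stratum(
        {c: ConsumptionStats(0.0, 0.0, 0.0) for c in (Category.FISH, Category.MOLLUSK)}
    )
    est = estimate_intake(stratum, {Category.FISH: 0.08, Category.MOLLUSK: 0.003}, Nutrient.EPA_DHA)
    assert all(v == 0.0 for v in est.totals.values())


def test_totals_are_category_sums_women_19_65_ala():
    stratum = _stratum(
        {
            Category.EDIBLE_OIL: ConsumptionStats(1.0, 1.0, 1.0),
            Category.NUT_SEED: ConsumptionStats(1.0, 1.0, 1.0),
        }
    )
    est = estimate_intake(
        stratum, {Category.EDIBLE_OIL: 0.711, Category.NUT_SEED: 2.738}, Nutrient.ALA
    )
    assert est.totals["mean"] == pytest.approx(3.449)


def test_missing_category_content_names_the_category():
    stratum = _stratum({Category.FISH: ConsumptionStats(1.0, 1.0, 1.0)})
    with pytest.raises(ConfigError, match="fish"):
        estimate_intake(stratum, {}, Nutrient.EPA_DHA)


def test_cross_category_contributions_are_excluded():
    """Oil consumption never leaks into the EPA+DHA estimate."""
    stratum = _stratum(
        {
            Category.EDIBLE_OIL: ConsumptionStats(100.0, 100.0, 100.0),
            Category.FISH: ConsumptionStats(1.0, 1.0, 1.0),
        }
    )
    est = estimate_intake(stratum, {Category.FISH: 0.08}, Nutrient.EPA_DHA)
    assert set(est.contributions) == {Category.FISH}


def test_adequacy_flags_women_19_65():
    stratum = _stratum(
        {
            Category.EDIBLE_OIL: ConsumptionStats(1.0, 1.0, 1.0),
            Category.NUT_SEED: ConsumptionStats(1.0, 1.0, 1.0),
        }
    )
    ref = reference_for_stratum(stratum, Nutrient.ALA, Authority.NIH)
    assert ref.amount_low == 1.1
    # mean 3.449 is adequate; the published median 0.549 is not
    high = estimate_intake(
        stratum, {Category.EDIBLE_OIL: 0.711, Category.NUT_SEED: 2.738}, Nutrient.ALA
    )
    assert assess_adequacy(high, ref)["mean"] is True
    low = estimate_intake(
        stratum, {Category.EDIBLE_OIL: 0.549, Category.NUT_SEED: 0.0}, Nutrient.ALA
    )
    assert assess_adequacy(low, ref)["mean"] is False


def test_adequacy_boundary_equality_is_adequate():
    stratum = _stratum({Category.FISH: ConsumptionStats(1.0, 1.0, 1.0)})
    est = estimate_intake(stratum, {Category.FISH: 0.25}, Nutrient.EPA_DHA)
    ref = reference_for_stratum(stratum, Nutrient.EPA_DHA, Authority.WHO)
    assert all(assess_adequacy(est, ref).values())


def test_adequacy_nutrient_mismatch_is_a_contract_error():
    stratum = _stratum({Category.FISH: ConsumptionStats(1.0, 1.0, 1.0)})
    est = estimate_intake(stratum, {Category.FISH: 0.08}, Nutrient.EPA_DHA)
    ref = reference_for_stratum(stratum, Nutrient.ALA, Authority.NIH)
    with pytest.raises(ContractError):
        assess_adequacy(est, ref)


@pytest.mark.parametrize(
    "age,sex,expected",
    [
        ((0.0, 3.0), Sex.FEMALE, 0.7),
        ((3.0, 6.0), Sex.MALE, 0.9),
        ((6.0, 12.0), Sex.MALE, 1.2),
        ((6.0, 12.0), Sex.FEMALE, 1.0),
        ((12.0, 16.0), Sex.FEMALE, 1.1),
        ((16.0, 18.0), Sex.MALE, 1.6),
        ((65.0, 120.0), Sex.FEMALE, 1.1),
    ],
)
def test_stratum_maps_to_oldest_contained_reference_group(age, sex, expected):
    stratum = _stratum({}, sex=sex, age=age)
    ref = reference_for_stratum(stratum, Nutrient.ALA, Authority.NIH)
    assert ref.amount_low == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(
    mean=st.floats(0, 100),
    p50=st.floats(0, 50),
    scale=st.floats(0.1, 10),
    content=st.floats(1e-4, 0.6),
)
def test_scale_equivariance_of_contributions(mean, p50, scale, content):
    stats = ConsumptionStats(mean=mean, p50=p50, p95=max(p50, 60.0))
    doubled = ConsumptionStats(
        mean=mean * scale, p50=p50 * scale, p95=max(p50, 60.0) * scale
    )
    base = estimate_intake(
        _stratum({Category.FISH: stats}), {Category.FISH: content}, Nutrient.EPA_DHA
    )
    scaled = estimate_intake(
        _stratum({Category.FISH: doubled}), {Category.FISH: content}, Nutrient.EPA_DHA
    )
    for s in STATISTICS:
        assert scaled.totals[s] == pytest.approx(scale * base.totals[s], rel=1e-9)


def test_increasing_a_contribution_never_flips_adequate_to_inadequate():
    stratum = _stratum({Category.FISH: ConsumptionStats(5.0, 3.0, 9.0)})
    ref = reference_for_stratum(stratum, Nutrient.EPA_DHA, Authority.WHO)
    flags = assess_adequacy(
        estimate_intake(stratum, {Category.FISH: 0.06}, Nutrient.EPA_DHA), ref
    )
    richer = assess_adequacy(
        estimate_intake(stratum, {Category.FISH: 0.08}, Nutrient.EPA_DHA), ref
    )
    for s in STATISTICS:
        assert richer[s] >= flags[s]


# --- published-table consistency -------------------------------------------


def _pivot(df):
    cats = df[df.category != "all"]
    alls = df[df.category == "all"]
    return cats, alls


@pytest.mark.parametrize("nutrient", [Nutrient.ALA, Nutrient.EPA_DHA])
def test_printed_all_foods_column_is_category_sum_within_rounding(nutrient):
    df = load_bundled_intake(nutrient)
    cats, alls = _pivot(df)
    grouped = cats.groupby(["sex", "age_low"])[list(STATISTICS)].sum()
    for row in alls.itertuples(index=False):
        sums = grouped.loc[(row.sex, row.age_low)]
        for s in STATISTICS:
            assert abs(getattr(row, s) - sums[s]) <= 0.001 + 1e-9


def test_female_ala_mean_column_sums_exactly():
    df = load_bundled_intake(Nutrient.ALA)
    cats, alls = _pivot(df)
    fem = alls[alls.sex == "female"]
    grouped = cats[cats.sex == "female"].groupby("age_low")["mean"].sum()
    for row in fem.itertuples(index=False):
        assert grouped.loc[row.age_low] == pytest.approx(row.mean, abs=1e-12)


def test_19_65_epa_dha_mean_cells_sum_exactly_for_both_sexes():
    df = load_bundled_intake(Nutrient.EPA_DHA)
    cats, alls = _pivot(df)
    for sex, expected in (("male", 0.386), ("female", 0.315)):
        total = cats[(cats.sex == sex) & (cats.age_low == 19)]["mean"].sum()
        printed = alls[(alls.sex == sex) & (alls.age_low == 19)]["mean"].iloc[0]
        assert printed == pytest.approx(expected)
        assert total == pytest.approx(printed, abs=1e-12)


@pytest.mark.parametrize("nutrient,authority", [
    (Nutrient.ALA, Authority.NIH),
    (Nutrient.EPA_DHA, Authority.WHO),
])
def test_printed_adequacy_markers_match_reference_comparison(nutrient, authority):
    """The published '#' markers on all-foods cells equal value >= reference."""
    df = load_bundled_intake(nutrient)
    _, alls = _pivot(df)
    for row in alls.itertuples(index=False):
        stratum = _stratum({}, sex=Sex(row.sex), age=(row.age_low, row.age_high))
        ref = reference_for_stratum(stratum, nutrient, authority)
        for s in STATISTICS:
            assert (getattr(row, s) >= ref.amount_low) == bool(getattr(row, f"{s}_flag"))


def test_consumption_table_round_trip(tmp_path):
    strata = [
        _stratum(
            {
                Category.FISH: ConsumptionStats(10.0, 4.0, 30.0),
                Category.EDIBLE_OIL: ConsumptionStats(8.0, 6.0, 20.0),
            },
            sex=Sex.MALE,
            age=(19.0, 65.0),
            bw=70.0,
        )
    ]
    path = tmp_path / "consumption.tsv"
    write_consumption_table(strata, path)
    assert load_consumption_table(path) == strata


def test_consumption_table_missing_column_errors():
    src = io.StringIO("sex,age_low,category,mean,p50,p95\n")
    with pytest.raises(od.DataError, match="age_high"):
        load_consumption_table(src)
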