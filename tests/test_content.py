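"""Content scoring, display rounding, bands and ranking."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import omega3diet as od
from omega3diet.content import (
    Band,
    Omega3Basis,
    UndefinedShareError,
    band_distribution,
    classify_band,
    omega3_share,
    rank_by_content,
    round_half_up,
    score_content,
)
from omega3diet.records import Category, ContractError, FattyAcidProfile, FoodCompositionRecord


def _record(share=None, fat=0.5, profile=None, food_id="x", name="food", cat=Category.FISH):
    return FoodCompositionRecord(
        food_id=food_id,
        name=name,
        category=cat,
        fat_fraction=fat,
        omega3_share_of_fat=share,
        fa_profile=profile,
    )


@pytest.mark.parametrize(
    "ala,epa,dha,sfa,mufa,pufa,expected",
    [
        (10, 0, 0, 40, 30, 30, 0.10),
        (0, 0, 0, 40, 30, 30, 0.0),
        (5.4, 1.2, 2.4, 20, 30, 10, 0.15),
    ],
)
def test_omega3_share_is_omega3_over_total_fatty_acids(ala, epa, dha, sfa, mufa, pufa, expected):
    prof = FattyAcidProfile(ala, epa, dha, sfa, mufa, pufa)
    assert omega3_share(prof) == pytest.approx(expected)


def test_zero_fatty_acid_sum_raises_undefined_share():
    prof = FattyAcidProfile(0, 0, 0, 0, 0, 0)
    with pytest.raises(UndefinedShareError):
        omega3_share(prof)


def test_flaxseed_oil_scores_high(by_id):
    c = by_id["oil-01"]
    assert c.content_exact == pytest.approx(0.535456)
    assert c.content_display == 0.54
    assert c.band is Band.HIGH


def test_mackerel_scores_high(by_id):
    c = by_id["fish-01"]
    assert c.content_display == 0.08
    assert c.band is Band.HIGH


def test_zero_fat_scores_zero_low():
    c = score_content(_record(share=0.5, fat=0.0))
    assert c.content_exact == 0.0
    assert c.content_display == 0.0
    assert c.band is Band.LOW


@pytest.mark.parametrize(
    "exact,display,band",
    [
        (0.0049, 0.00, Band.LOW),
        (0.005, 0.01, Band.MODERATE),  # half-up promotes to moderate
        (0.0054, 0.01, Band.MODERATE),
        (0.0149, 0.01, Band.MODERATE),
        (0.02, 0.02, Band.MODERATE),
        (0.0249, 0.02, Band.MODERATE),
        (0.025, 0.03, Band.HIGH),
        (0.535456, 0.54, Band.HIGH),
    ],
)
def test_display_rounding_and_banding(exact, display, band):
    d = round_half_up(exact)
    assert d == display
    assert classify_band(d) is band


def test_strict_epa_dha_basis_uses_long_chain_numerator():
    prof = FattyAcidProfile(ala=5, epa=2, dha=3, sfa_total=40, mufa_total=30, pufa_total=30)
    rec = _record(profile=prof, fat=0.5)
    total = score_content(rec, Omega3Basis.TOTAL)
    strict = score_content(rec, Omega3Basis.EPA_DHA)
    assert total.content_exact == pytest.approx(0.10 * 0.5)
    assert strict.content_exact == pytest.approx(0.05 * 0.5)


def test_oracle_equivalence_of_share_and_profile_paths():
    """A record with a share equal to its profile's derived share scores
    identically by either route."""
    prof = FattyAcidProfile(ala=4.2, epa=1.1, dha=0.7, sfa_total=10, mufa_total=20, pufa_total=12)
    share = prof.omega3_mass / prof.fa_sum
    via_share = score_content(_record(share=share, fat=0.31))
    via_profile = score_content(_record(profile=prof, fat=0.31))
    assert via_share.content_exact == via_profile.content_exact


def test_ranking_top_oil_is_flaxseed(bundled):
    scored = od.score_table(bundled["edible_oils"].records)
    assert rank_by_content(scored, 1)[0].name == "Flaxseed oil"


def test_ranking_top3_nuts_by_exact_content(bundled):
    scored = od.score_table(bundled["nuts_seeds"].records)
    top3 = rank_by_content(scored, 3)
    assert [c.name for c in top3] == ["Flaxseed", "Chia seed", "Awkeotsang"]
    assert [c.content_exact for c in top3] == pytest.approx([0.21762, 0.20034, 0.0785])


def test_ranking_shorter_than_n_and_tie_break_by_name():
    a = score_content(_record(share=0.2, fat=0.5, food_id="b", name="Beta"))
    b = score_content(_record(share=0.2, fat=0.5, food_id="a", name="Alpha"))
    assert [c.name for c in rank_by_content([a], 10)] == ["Beta"]
    assert [c.name for c in rank_by_content([a, b], 10)] == ["Alpha", "Beta"]


def test_ranking_empty_input_is_an_error():
    with pytest.raises(ContractError):
        rank_by_content([], 5)


def test_crustacean_band_distribution(scored_all):
    dist = band_distribution(scored_all, Category.CRUSTACEAN)
    assert dist.counts[Band.LOW] == 17
    assert dist.total == 21
    assert dist.fractions[Band.LOW] == pytest.approx(17 / 21)


def test_mollusk_band_distribution(scored_all):
    dist = band_distribution(scored_all, Category.MOLLUSK)
    assert dist.counts[Band.LOW] == 11
    assert dist.fractions[Band.LOW] == pytest.approx(11 / 15)


def test_singleton_band_distribution_is_all_one_band():
    c = score_content(_record(share=0.5, fat=0.1, cat=Category.FISH))
    dist = band_distribution([c], Category.FISH)
    assert dist.fractions[Band.HIGH] == 1.0
    assert dist.fractions[Band.LOW] == 0.0


def test_empty_category_distribution_is_an_error(scored_all):
    oils_only = [c for c in scored_all if c.category is Category.EDIBLE_OIL]
    with pytest.raises(ContractError):
        band_distribution(oils_only, Category.FISH)


@pytest.mark.parametrize(
    "table,n_match",
    [
        ("edible_oils", 23),
        ("nuts_seeds", 19),
        ("crustaceans", 21),
        ("mollusks", 15),
        ("fish", 45),  # three printed rows are internally inconsistent
    ],
)
def test_recomputed_displays_match_printed_contents(bundled, table, n_match):
    t = bundled[table]
    matches = 0
    for rec in t:
        c = score_content(rec)
        listed = t.listed_contents[rec.food_id]
        if listed.censored:
            matches += c.content_display < listed.value
        else:
            matches += math.isclose(c.content_display, listed.value)
    assert matches == n_match


# --- properties -------------------------------------------------------------

shares = st.floats(0.0, 1.0, allow_nan=False)
fats = st.floats(0.0, 1.0, allow_nan=False)


@settings(derandomize=True, max_examples=200)
@given(share=shares, fat=fats, bump=st.floats(1e-6, 0.5))
def test_content_strictly_monotone_in_share_and_fat(share, fat, bump):
    base = score_content(_record(share=share, fat=fat)).content_exact
    if share + bump <= 1.0 and fat > 0:
        more_share = score_content(_record(share=share + bump, fat=fat)).content_exact
        assert more_share > base
    if fat + bump <= 1.0 and share > 0:
        more_fat = score_content(_record(share=share, fat=fat + bump)).content_exact
        assert more_fat > base


@settings(derandomize=True, max_examples=300)
@given(display=st.floats(0.0, 1.0, allow_nan=False))
def test_band_partition_every_display_maps_to_one_band(display):
    assert sum(classify_band(display) is b for b in Band) == 1


def test_fractions_sum_to_one_and_counts_to_total(scored_all):
    for cat in Category:
        dist = band_distribution(scored_all, cat)
        assert sum(dist.fractions.values()) == pytest.approx(1.0)
        assert sum(dist.counts.values()) == dist.total


def test_content_never_exceeds_fat_fraction(all_records):
    for rec in all_records:
        c = score_content(rec)
        assert 0.0 <= c.content_exact <= rec.fat_fraction + 1e-12
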