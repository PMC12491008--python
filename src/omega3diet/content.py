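"""Omega-3 content scoring, display rounding, banding and ranking.

The content of a food is ``share_of_fat x fat_fraction`` in g omega-3 per g
food, where the share of fat is (ALA+EPA+DHA) / (SFA+MUFA+PUFA). Published
tables print this at two decimals with half-up rounding, and the low /
moderate / high bands are defined on that displayed value:

* low:       display < 0.01
* moderate:  0.01 <= display <= 0.02
* high:      display > 0.02

Banding on the displayed value (rather than the exact one) is deliberate:
a food at 0.0054 g/g prints as 0.01 and is treated as a moderate source.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .records import (
    Category,
    ContractError,
    DataError,
    FattyAcidProfile,
    FoodCompositionRecord,
)

__all__ = [
    "Band",
    "Omega3Basis",
    "Omega3Content",
    "BandDistribution",
    "UndefinedShareError",
    "round_half_up",
    "omega3_share",
    "score_content",
    "score_table",
    "classify_band",
    "rank_by_content",
    "band_distribution",
]


class UndefinedShareError(DataError):
    """The omega-3 share is undefined (zero total fatty acids)."""


class Band(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class Omega3Basis(str, enum.Enum):
    """Which omega-3 species enter the numerator of the share."""

    TOTAL = "total"  # ALA + EPA + DHA
    EPA_DHA = "epa_dha"  # long-chain only; needs a full fatty-acid profile


#: Band cut points, applied to the 2-decimal display value.
LOW_CUTOFF = 0.01
HIGH_CUTOFF = 0.02

DISPLAY_DECIMALS = 2


def round_half_up(x: float, decimals: int = DISPLAY_DECIMALS) -> float:
    """Round half away from zero at ``decimals`` places (0.005 -> 0.01)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Omega3Content:
    """Scored omega-3 content of one food."""

    food_id: str
    content_exact: float  # g omega-3 per g food, unrounded
    content_display: float  # half-up rounded to 2 decimals
    band: Band
    name: str | None = None
    category: Category | None = None


@dataclass(frozen=True)
class BandDistribution:
    """Counts and fractions of foods per band within one category."""

    category: Category
    counts: Mapping[Band, int]
    fractions: Mapping[Band, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def omega3_share(profile: FattyAcidProfile, basis: Omega3Basis = Omega3Basis.TOTAL) -> float:
    """Fraction of total fatty acids that is omega-3.

    Returns (ALA+EPA+DHA)/(SFA+MUFA+PUFA), or (EPA+DHA)/(SFA+MUFA+PUFA)
    under the strict long-chain basis.
    """
    denom = profile.fa_sum
    if denom <= 0.0:
        raise UndefinedShareError("total fatty acids is zero; share undefined")
    num = profile.omega3_mass if basis is Omega3Basis.TOTAL else profile.epa_dha_mass
    return num / denom


def classify_band(content_display: float) -> Band:
    if content_display < LOW_CUTOFF:
        return Band.LOW
    if content_display <= HIGH_CUTOFF:
        return Band.MODERATE
    return Band.HIGH


def score_content(
    record: FoodCompositionRecord, basis: Omega3Basis = Omega3Basis.TOTAL
) -> Omega3Content:
    """Score one record: content = share_of_fat x fat_fraction.

    Under the default (total omega-3) basis a directly listed share is used
    when present, otherwise the share is derived from the fatty-acid
    profile. The strict EPA+DHA basis always requires a profile.
    """
    if basis is Omega3Basis.TOTAL and record.omega3_share_of_fat is not None:
        share = record.omega3_share_of_fat
    elif record.fa_profile is not None:
        share = omega3_share(record.fa_profile, basis)
    else:
        raise DataError(
            f"{record.food_id}: basis {basis.value!r} needs a fatty-acid profile"
        )
    exact = share * record.fat_fraction
    display = round_half_up(exact)
    return Omega3Content(
        food_id=record.food_id,
        content_exact=exact,
        content_display=display,
        band=classify_band(display),
        name=record.name,
        category=record.category,
    )


def score_table(
    records: Iterable[FoodCompositionRecord], basis: Omega3Basis = Omega3Basis.TOTAL
) -> list[Omega3Content]:
    return [score_content(r, basis) for r in records]


def rank_by_content(scored: Sequence[Omega3Content], top_n: int) -> list[Omega3Content]:
    """Top ``top_n`` foods by exact content, descending; ties by name."""
    if not scored:
        raise ContractError("rank_by_content: empty input")
    if top_n < 1:
        raise ContractError(f"rank_by_content: top_n must be >= 1, got {top_n}")
    ordered = sorted(scored, key=lambda c: (-c.content_exact, c.name or c.food_id))
    return ordered[:top_n]


def band_distribution(
    scored: Iterable[Omega3Content], category: Category
) -> BandDistribution:
    """Band counts and fractions over the scored records of one category."""
    members = [c for c in scored if c.category == category]
    if not members:
        raise ContractError(f"band_distribution: no scored records in {category.value}")
    counts = {band: 0 for band in Band}
    for c in members:
        counts[c.band] += 1
    n = len(members)
    fractions = {band: counts[band] / n for band in Band}
    return BandDistribution(category=category, counts=counts, fractions=fractions)
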