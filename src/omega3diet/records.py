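"""Core domain types for food composition records.

Internal convention: every composition quantity is a fraction in [0, 1]
(g per g of food, or fraction of total fatty acids), never a percent.
External tables frequently print percents; loaders convert at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Omega3DietError(Exception):
    """Base class for all package errors."""


class DataError(Omega3DietError):
    """Malformed or inconsistent input data."""


class ConfigError(Omega3DietError):
    """Invalid configuration (unknown category, missing mapping, bad spec)."""


class ContractError(Omega3DietError):
    """An operation was called outside its contract (empty input, mismatch)."""


class Category(str, enum.Enum):
    """The five food categories of the assessment."""

    EDIBLE_OIL = "edible_oil"
    NUT_SEED = "nut_seed"
    FISH = "fish"
    CRUSTACEAN = "crustacean"
    MOLLUSK = "mollusk"


#: Categories whose omega-3 is essentially all plant ALA.
PLANT_CATEGORIES = (Category.EDIBLE_OIL, Category.NUT_SEED)
#: Categories whose omega-3 is dominated by long-chain EPA+DHA.
AQUATIC_CATEGORIES = (Category.FISH, Category.CRUSTACEAN, Category.MOLLUSK)


class Preparation(str, enum.Enum):
    RAW = "raw"
    ROASTED = "roasted"
    COOKED = "cooked"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class FattyAcidProfile:
    """Fatty-acid masses in g per 100 g of food.

    ``sfa_total + mufa_total + pufa_total`` is the total identified fatty
    acids; ALA, EPA and DHA are subsets of ``pufa_total``.
    """

    ala: float
    epa: float
    dha: float
    sfa_total: float
    mufa_total: float
    pufa_total: float

    # small slack for values that were rounded upstream
    _TOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("ala", "epa", "dha", "sfa_total", "mufa_total", "pufa_total"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise DataError(f"fatty-acid mass {name} must be non-negative, got {v!r}")
        if self.omega3_mass > self.pufa_total + self._TOL:
            raise DataError(
                "ala+epa+dha exceeds pufa_total "
                f"({self.omega3_mass:.6g} > {self.pufa_total:.6g})"
            )
        # fa_sum == 0 is representable; using it as a share denominator
        # raises UndefinedShareError, and records reject such profiles.

    @property
    def omega3_mass(self) -> float:
        """ALA + EPA + DHA, g per 100 g food."""
        return self.ala + self.epa + self.dha

    @property
    def epa_dha_mass(self) -> float:
        """EPA + DHA, g per 100 g food."""
        return self.epa + self.dha

    @property
    def fa_sum(self) -> float:
        """Total identified fatty acids, g per 100 g food."""
        return self.sfa_total + self.mufa_total + self.pufa_total


@dataclass(frozen=True)
class FoodCompositionRecord:
    """One food item of a composition table.

    Either ``omega3_share_of_fat`` (fraction of total fatty acids that is
    ALA+EPA+DHA) or a full ``fa_profile`` must be present; both may be.
    """

    food_id: str
    name: str
    category: Category
    fat_fraction: float
    species_binomial: str | None = None
    preparation: Preparation = Preparation.UNKNOWN
    omega3_share_of_fat: float | None = None
    fa_profile: FattyAcidProfile | None = None
    #: True when the source printed the share as an upper bound ("< x").
    share_censored: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fat_fraction <= 1.0):
            raise DataError(
                f"{self.food_id}: fat_fraction must lie in [0, 1], got {self.fat_fraction!r}"
            )
        if self.omega3_share_of_fat is not None and not (
            0.0 <= self.omega3_share_of_fat <= 1.0
        ):
            raise DataError(
                f"{self.food_id}: omega3_share_of_fat must lie in [0, 1], "
                f"got {self.omega3_share_of_fat!r}"
            )
        if self.omega3_share_of_fat is None and self.fa_profile is None:
            raise DataError(
                f"{self.food_id}: need omega3_share_of_fat or fa_profile, found neither"
            )
        if self.fa_profile is not None and self.fa_profile.fa_sum <= 0.0:
            raise DataError(
                f"{self.food_id}: fatty-acid profile must have sfa+mufa+pufa > 0"
            )


class Severity(str, enum.Enum):
    INFO = "info"
    MISMATCH = "mismatch"


@dataclass(frozen=True)
class ListedValue:
    """A printed value, possibly left-censored ("< value")."""

    value: float
    censored: bool = False

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.censored else f"{self.value:g}"


@dataclass(frozen=True)
class QCFinding:
    """One quality-control observation about a loaded record."""

    food_id: str
    field_name: str
    listed_value: str
    recomputed_value: str
    severity: Severity
    message: str = ""
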