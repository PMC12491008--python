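"""Recommended omega-3 intakes and minimal daily portions.

Two nutrients are tracked. ALA has age- and sex-specific dietary reference
intakes (NIH): 0.32 g/day (0-6 mo), 0.5 (7-12 mo), 0.7 (1-3 y), 0.9
(4-8 y), 1.2/1.0 for boys/girls 9-13 y, 1.6/1.1 for males/females 14 y and
older, 1.4 when pregnant and 1.3 when lactating. EPA+DHA has no formal DRI;
authorities converge on 250-500 mg/day (WHO, AHA; >= 1 g/day for
cardiovascular patients under care), 250 mg/day (EFSA), and about
250 mg/day implied by the US guideline of 8 oz of seafood per week (DGA).

The daily minimally required consumption (DMRC) of a food is
``target / content`` in g food per day; it is the exact inverse of the
supplied-amount check, so meeting the guideline at the DMRC holds with
equality. ALA can substitute for EPA+DHA only through endogenous
conversion, taken here at a default 15% mass yield.
"""

from __future__ import annotations

import enum
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .content import Omega3Content, round_half_up
from .records import ConfigError, ContractError, DataError

__all__ = [
    "Nutrient",
    "Authority",
    "Sex",
    "LifeStage",
    "ReferenceIntake",
    "RequiredAmount",
    "GuidelineCheck",
    "DEFAULT_REGISTRY",
    "EPA_DHA_TIERS",
    "OZ_AVOIRDUPOIS_G",
    "FISH_PORTION_G",
    "DEFAULT_CONVERSION_RATE",
    "lookup_reference",
    "minimal_required_consumption",
    "ala_equivalent_epa_dha",
    "meets_guideline",
    "UnreachableTargetError",
    "RegistryLookupError",
    "dump_registry",
    "load_registry",
]


class Nutrient(str, enum.Enum):
    ALA = "ALA"
    EPA_DHA = "EPA_DHA"


class Authority(str, enum.Enum):
    NIH = "NIH"
    WHO = "WHO"
    AHA = "AHA"
    EFSA = "EFSA"
    DGA = "DGA"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    ANY = "any"


class LifeStage(str, enum.Enum):
    NONE = "none"
    PREGNANT = "pregnant"
    LACTATING = "lactating"


#: The three EPA+DHA scenario targets, g/day (general, upper-general, clinical).
EPA_DHA_TIERS = (0.25, 0.5, 1.0)

#: Grams per avoirdupois ounce; 1.1 oz/day of fish is 31.2 g/day.
OZ_AVOIRDUPOIS_G = 28.35
FISH_PORTION_G = 31.2  # default daily fish portion (1.1 oz); 34.2 also circulates
DEFAULT_CONVERSION_RATE = 0.15

_OPEN_AGE = 200.0  # practical upper bound for open-ended age intervals


class RegistryLookupError(ConfigError):
    """No (or no unique) reference record matches the query."""


class UnreachableTargetError(ContractError):
    """A zero-content food cannot meet any positive target."""


@dataclass(frozen=True)
class ReferenceIntake:
    """One authority- and life-stage-specific recommendation.

    Age intervals are half-open, lower-inclusive, in years: a boundary age
    such as exactly 13 resolves to the younger stratum of the printed
    labels (9-13 is [9, 14), 14-18 is [14, 19)).
    """

    nutrient: Nutrient
    authority: Authority
    sex: Sex
    age_low: float  # years, inclusive
    age_high: float  # years, exclusive
    amount_low: float  # g/day
    amount_high: float | None = None  # g/day, upper end of a printed range
    life_stage: LifeStage = LifeStage.NONE
    condition: str = "general"  # e.g. "clinical" for the AHA >=1 g tier

    def __post_init__(self) -> None:
        if self.amount_low <= 0:
            raise DataError("amount_low must be positive")
        if self.amount_high is not None and self.amount_high < self.amount_low:
            raise DataError("amount_high must be >= amount_low")
        if self.age_high <= self.age_low:
            raise DataError("empty age interval")

    def covers(self, sex: Sex, age_years: float, life_stage: LifeStage) -> bool:
        if self.life_stage is not life_stage:
            return False
        if self.sex is not Sex.ANY and sex is not Sex.ANY and self.sex is not sex:
            return False
        return self.age_low <= age_years < self.age_high


def _nih_ala() -> list[ReferenceIntake]:
    A, N = Authority.NIH, Nutrient.ALA
    rows = [
        (Sex.ANY, 0.0, 7 / 12, 0.32),  # 0-6 months
        (Sex.ANY, 7 / 12, 1.0, 0.50),  # 7-12 months
        (Sex.ANY, 1.0, 4.0, 0.70),  # 1-3 years
        (Sex.ANY, 4.0, 9.0, 0.90),  # 4-8 years
        (Sex.MALE, 9.0, 14.0, 1.20),
        (Sex.FEMALE, 9.0, 14.0, 1.00),
        (Sex.MALE, 14.0, _OPEN_AGE, 1.60),  # adolescents, adults, elderly
        (Sex.FEMALE, 14.0, _OPEN_AGE, 1.10),
    ]
    refs = [
        ReferenceIntake(N, A, sex, lo, hi, amount) for sex, lo, hi, amount in rows
    ]
    refs.append(
        ReferenceIntake(N, A, Sex.FEMALE, 0.0, _OPEN_AGE, 1.40, life_stage=LifeStage.PREGNANT)
    )
    refs.append(
        ReferenceIntake(N, A, Sex.FEMALE, 0.0, _OPEN_AGE, 1.30, life_stage=LifeStage.LACTATING)
    )
    return refs


def _epa_dha() -> list[ReferenceIntake]:
    N = Nutrient.EPA_DHA
    return [
        ReferenceIntake(N, Authority.WHO, Sex.ANY, 0.0, _OPEN_AGE, 0.25, 0.50),
        ReferenceIntake(N, Authority.AHA, Sex.ANY, 0.0, _OPEN_AGE, 0.25, 0.50),
        ReferenceIntake(
            N, Authority.AHA, Sex.ANY, 0.0, _OPEN_AGE, 1.00, condition="clinical"
        ),
        ReferenceIntake(N, Authority.EFSA, Sex.ANY, 0.0, _OPEN_AGE, 0.25),
        ReferenceIntake(N, Authority.DGA, Sex.ANY, 0.0, _OPEN_AGE, 0.25),
    ]


DEFAULT_REGISTRY: tuple[ReferenceIntake, ...] = tuple(_nih_ala() + _epa_dha())


def lookup_reference(
    nutrient: Nutrient,
    authority: Authority,
    sex: Sex,
    age_years: float,
    life_stage: LifeStage = LifeStage.NONE,
    condition: str = "general",
    registry: tuple[ReferenceIntake, ...] = DEFAULT_REGISTRY,
) -> ReferenceIntake:
    """Resolve the unique recommendation for a person.

    Pregnancy/lactation overrides the sex-age lookup when flagged.
    """
    matches = [
        r
        for r in registry
        if r.nutrient is nutrient
        and r.authority is authority
        and r.condition == condition
        and r.covers(sex, age_years, life_stage)
    ]
    if not matches:
        raise RegistryLookupError(
            f"no {authority.value} {nutrient.value} recommendation for "
            f"sex={sex.value}, age={age_years} y, life_stage={life_stage.value}"
        )
    if len(matches) > 1:
        raise RegistryLookupError(
            f"ambiguous registry: {len(matches)} records match "
            f"{nutrient.value}/{authority.value}/{sex.value}/{age_years}"
        )
    return matches[0]


@dataclass(frozen=True)
class RequiredAmount:
    """Daily minimally required consumption of one food for one target."""

    food_id: str
    nutrient: Nutrient
    target: float  # g nutrient/day
    grams_exact: float  # g food/day = target / content
    grams_rounded: int  # half-up to the nearest gram


def minimal_required_consumption(
    content: Omega3Content, target: float, nutrient: Nutrient = Nutrient.ALA
) -> RequiredAmount:
    """g food/day needed so that content x grams equals the target."""
    if target <= 0:
        raise ContractError(f"target must be positive, got {target!r}")
    if content.content_exact <= 0:
        raise UnreachableTargetError(
            f"{content.food_id}: zero omega-3 content cannot meet a {target} g/day target"
        )
    grams = target / content.content_exact
    return RequiredAmount(
        food_id=content.food_id,
        nutrient=nutrient,
        target=target,
        grams_exact=grams,
        grams_rounded=int(round_half_up(grams, 0)),
    )


def ala_equivalent_epa_dha(
    ala_g: float, conversion_rate: float = DEFAULT_CONVERSION_RATE
) -> float:
    """EPA+DHA equivalent (g/day) of an ALA intake via endogenous conversion."""
    if ala_g < 0:
        raise ContractError(f"ala_g must be non-negative, got {ala_g!r}")
    if not (0.0 <= conversion_rate <= 1.0):
        raise ContractError(f"conversion_rate must lie in [0, 1], got {conversion_rate!r}")
    return ala_g * conversion_rate


@dataclass(frozen=True)
class GuidelineCheck:
    food_id: str
    supplied: float  # g nutrient/day actually provided
    target: float
    meets: bool


def meets_guideline(
    content: Omega3Content, daily_grams: float, target: float
) -> GuidelineCheck:
    """Does eating ``daily_grams`` of the food supply at least the target?"""
    if daily_grams < 0:
        raise ContractError(f"daily_grams must be non-negative, got {daily_grams!r}")
    supplied = content.content_exact * daily_grams
    # float-tolerant boundary so target/content grams meets its own target
    meets = supplied >= target or math.isclose(supplied, target, rel_tol=1e-9)
    return GuidelineCheck(
        food_id=content.food_id, supplied=supplied, target=target, meets=meets
    )


def dump_registry(path: str | Path, registry=DEFAULT_REGISTRY) -> None:
    """Serialize a registry to YAML so it can be edited without code changes."""
    rows = []
    for r in registry:
        d = asdict(r)
        for k in ("nutrient", "authority", "sex", "life_stage"):
            d[k] = d[k].value
        rows.append(d)
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False), encoding="utf-8")


def load_registry(path: str | Path) -> tuple[ReferenceIntake, ...]:
    rows = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    refs = []
    for d in rows:
        refs.append(
            ReferenceIntake(
                nutrient=Nutrient(d["nutrient"]),
                authority=Authority(d["authority"]),
                sex=Sex(d["sex"]),
                age_low=float(d["age_low"]),
                age_high=float(d["age_high"]),
                amount_low=float(d["amount_low"]),
                amount_high=None if d.get("amount_high") is None else float(d["amount_high"]),
                life_stage=LifeStage(d.get("life_stage", "none")),
                condition=d.get("condition", "general"),
            )
        )
    return tuple(refs)
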