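"""Synthetic consumption surveys and composition tables.

The national consumption statistics this pipeline consumes are strongly
right-skewed (P50 far below the mean, mean below P95), as is typical of
single-day dietary recalls. Per stratum x category, the generator draws
iid log-normal consumption values — the simplest family reproducing that
skew — parameterised by location ``mu`` and scale ``sigma`` on the log
scale, then summarises them with the mean and nearest-rank empirical
percentiles. A fixed seed fully determines the output.

``taiwan_like_spec`` back-derives (mu, sigma) for each of the seven age
strata, both sexes and five food categories from the bundled survey intake
tables divided by the bundled category-mean contents, so the synthetic
survey matches the published mean and median magnitudes cell by cell (the
log-normal P95 then overshoots the published one — a two-parameter family
cannot match all three statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import load_all_bundled
from .content import Band, score_table
from .intake import (
    NUTRIENT_CATEGORIES,
    ConsumptionStats,
    ConsumptionStratum,
    category_mean_content,
)
from .records import (
    Category,
    ConfigError,
    FattyAcidProfile,
    FoodCompositionRecord,
    Preparation,
)
from .requirements import Nutrient, Sex

__all__ = [
    "CellSpec",
    "ConsumptionSpec",
    "generate_consumption",
    "generate_composition",
    "taiwan_like_spec",
    "nearest_rank",
]


def nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: value at rank ceil(q*n), 1-based."""
    n = len(sorted_values)
    if n == 0:
        raise ConfigError("nearest_rank: empty sample")
    rank = max(1, math.ceil(q * n))
    return float(sorted_values[rank - 1])


@dataclass(frozen=True)
class CellSpec:
    """Log-normal consumption for one stratum x category cell."""

    sex: Sex
    age_low: float
    age_high: float
    category: Category
    mu: float  # log-scale location; median consumption = exp(mu) g/day
    sigma: float  # log-scale spread, >= 0 (0 = degenerate at exp(mu))
    n: int  # respondents in the cell
    body_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")
        if self.n < 1:
            raise ConfigError(f"sample size must be >= 1, got {self.n}")

    @property
    def key(self) -> tuple:
        return (self.sex.value, self.age_low, self.age_high, self.category.value)


@dataclass(frozen=True)
class ConsumptionSpec:
    cells: Sequence[CellSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cells:
            raise ConfigError("ConsumptionSpec needs at least one cell")


def generate_consumption(
    spec: ConsumptionSpec, seed: int | None = None
) -> tuple[pd.DataFrame, list[ConsumptionStratum]]:
    """Draw individual-level consumption and derive stratum statistics.

    Returns the individual records (one row per person x category) and the
    :class:`ConsumptionStratum` collection ready for intake estimation.
    Identical (spec, seed) pairs yield identical output.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cells = sorted(spec.cells, key=lambda c: c.key)
    frames = []
    stratum_stats: dict[tuple, dict] = {}
    for cell in cells:
        degenerate = cell.sigma == 0.0
        if degenerate:
            values = np.full(cell.n, math.exp(cell.mu))
        else:
            values = rng.lognormal(mean=cell.mu, sigma=cell.sigma, size=cell.n)
        frames.append(
            pd.DataFrame(
                {
                    "sex": cell.sex.value,
                    "age_low": cell.age_low,
                    "age_high": cell.age_high,
                    "category": cell.category.value,
                    "consumption_g_day": values,
                }
            )
        )
        ordered = np.sort(values)
        key = (cell.sex, cell.age_low, cell.age_high)
        entry = stratum_stats.setdefault(key, {"consumption": {}, "bw": None})
        entry["consumption"][cell.category] = ConsumptionStats(
            # exact collapse for degenerate cells (no summation round-off)
            mean=float(values[0]) if degenerate else float(values.mean()),
            p50=nearest_rank(ordered, 0.50),
            p95=nearest_rank(ordered, 0.95),
        )
        if cell.body_weight is not None:
            entry["bw"] = cell.body_weight
    individuals = pd.concat(frames, ignore_index=True)
    strata = [
        ConsumptionStratum(
            sex=sex,
            age_low=lo,
            age_high=hi,
            consumption=entry["consumption"],
            body_weight_mean=entry["bw"],
        )
        for (sex, lo, hi), entry in sorted(
            stratum_stats.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        )
    ]
    return individuals, strata


# ---------------------------------------------------------------------------
# Composition generator

#: Plausible fat-fraction ranges per category (g fat / g food).
_FAT_RANGES: dict[Category, tuple[float, float]] = {
    Category.EDIBLE_OIL: (0.80, 1.00),
    Category.NUT_SEED: (0.20, 0.75),
    Category.FISH: (0.01, 0.40),
    Category.CRUSTACEAN: (0.001, 0.07),
    Category.MOLLUSK: (0.001, 0.03),
}

# Exact-content ranges that land safely inside each display band after
# half-up rounding at two decimals.
_BAND_CONTENT: dict[Band, tuple[float, float]] = {
    Band.LOW: (0.0, 0.0049),
    Band.MODERATE: (0.0051, 0.0249),
    Band.HIGH: (0.0251, 0.60),
}

#: How the omega-3 mass splits across ALA / EPA / DHA per category.
_OMEGA3_SPLIT: dict[Category, tuple[float, float, float]] = {
    Category.EDIBLE_OIL: (1.0, 0.0, 0.0),
    Category.NUT_SEED: (1.0, 0.0, 0.0),
    Category.FISH: (0.05, 0.45, 0.50),
    Category.CRUSTACEAN: (0.05, 0.45, 0.50),
    Category.MOLLUSK: (0.05, 0.45, 0.50),
}

_IDENTIFIED_FA = 0.95  # fraction of fat mass recovered as identified fatty acids


def generate_composition(
    n_per_category: Mapping[Category, int],
    band_mix: Mapping[Band, float],
    seed: int = 0,
    fat_ranges: Mapping[Category, tuple[float, float]] | None = None,
) -> list[FoodCompositionRecord]:
    """Generate composition records whose bands follow ``band_mix``.

    Each record carries both a share-of-fat and a fully consistent
    fatty-acid profile (share recomputes exactly from the profile). A mix
    requesting a band whose minimum content exceeds the category's fat cap
    is rejected up front.
    """
    ranges = {**_FAT_RANGES, **(fat_ranges or {})}
    total = sum(band_mix.get(b, 0.0) for b in Band)
    if any(band_mix.get(b, 0.0) < 0 for b in Band):
        raise ConfigError("band_mix fractions must be non-negative")
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"band_mix must sum to 1, got {total}")
    for cat, n in n_per_category.items():
        if n < 0:
            raise ConfigError(f"negative count for {cat.value}")
        fat_max = ranges[cat][1]
        for band, frac in band_mix.items():
            if frac > 0 and _BAND_CONTENT[band][0] > fat_max:
                raise ConfigError(
                    f"band {band.value!r} is infeasible for {cat.value}: "
                    f"needs content >= {_BAND_CONTENT[band][0]}, fat cap is {fat_max}"
                )

    rng = np.random.default_rng(seed)
    bands = [b for b in Band]
    probs = np.array([band_mix.get(b, 0.0) for b in bands])
    records: list[FoodCompositionRecord] = []
    for cat in sorted(n_per_category, key=lambda c: c.value):
        fat_lo, fat_hi = ranges[cat]
        for i in range(n_per_category[cat]):
            band = bands[rng.choice(len(bands), p=probs)]
            c_lo, c_hi = _BAND_CONTENT[band]
            # fat must be able to carry the band's minimum content
            f_lo = max(fat_lo, c_lo)
            fat = float(rng.uniform(f_lo, fat_hi))
            content = float(rng.uniform(c_lo, min(c_hi, fat)))
            share = content / fat if fat > 0 else 0.0
            profile = _make_profile(cat, fat, share)
            records.append(
                FoodCompositionRecord(
                    food_id=f"{cat.value}-syn-{i:04d}",
                    name=f"synthetic {cat.value.replace('_', ' ')} {i}",
                    category=cat,
                    fat_fraction=fat,
                    preparation=Preparation.RAW,
                    omega3_share_of_fat=profile.omega3_mass / profile.fa_sum,
                    fa_profile=profile,
                )
            )
    return records


def _make_profile(cat: Category, fat: float, share: float) -> FattyAcidProfile:
    fa_sum = fat * 100.0 * _IDENTIFIED_FA  # g / 100 g food
    omega3 = share * fa_sum
    w_ala, w_epa, w_dha = _OMEGA3_SPLIT[cat]
    remainder = fa_sum - omega3
    return FattyAcidProfile(
        ala=omega3 * w_ala,
        epa=omega3 * w_epa,
        dha=omega3 * w_dha,
        sfa_total=remainder * 0.40,
        mufa_total=remainder * 0.30,
        pufa_total=omega3 + remainder * 0.30,
    )


# ---------------------------------------------------------------------------
# Survey-like default spec

_BODY_WEIGHTS = {  # kg, survey-plausible means per (age_low, sex)
    (0.0, Sex.MALE): 13.0, (0.0, Sex.FEMALE): 12.5,
    (3.0, Sex.MALE): 19.0, (3.0, Sex.FEMALE): 18.5,
    (6.0, Sex.MALE): 31.0, (6.0, Sex.FEMALE): 30.0,
    (12.0, Sex.MALE): 52.0, (12.0, Sex.FEMALE): 48.0,
    (16.0, Sex.MALE): 63.0, (16.0, Sex.FEMALE): 54.0,
    (19.0, Sex.MALE): 70.0, (19.0, Sex.FEMALE): 57.0,
    (65.0, Sex.MALE): 65.0, (65.0, Sex.FEMALE): 56.0,
}


def taiwan_like_spec(n_per_cell: int = 500, seed: int = 0) -> ConsumptionSpec:
    """A survey-shaped spec calibrated to the bundled intake tables.

    For each stratum x category, implied consumption mean M and median m
    are the published intake statistics divided by the bundled
    category-mean content; the log-normal then has mu = ln(m) and
    sigma = sqrt(2 ln(M/m)).
    """
    from .intake import load_bundled_intake

    tables = load_all_bundled()
    scored = [c for t in tables.values() for c in score_table(t.records)]
    contents = {
        cat: category_mean_content(scored, cat)
        for cats in NUTRIENT_CATEGORIES.values()
        for cat in cats
    }
    cells: list[CellSpec] = []
    for nutrient in (Nutrient.ALA, Nutrient.EPA_DHA):
        df = load_bundled_intake(nutrient)
        df = df[df["category"] != "all"]
        for row in df.itertuples(index=False):
            cat = Category(row.category)
            sex = Sex(row.sex)
            m = row.p50 / contents[cat]
            big_m = row.mean / contents[cat]
            if m <= 0 or big_m <= m:
                sigma = 0.0
            else:
                sigma = math.sqrt(2.0 * math.log(big_m / m))
            cells.append(
                CellSpec(
                    sex=sex,
                    age_low=float(row.age_low),
                    age_high=float(row.age_high),
                    category=cat,
                    mu=math.log(m),
                    sigma=sigma,
                    n=n_per_cell,
                    body_weight=_BODY_WEIGHTS.get((float(row.age_low), sex)),
                )
            )
    return ConsumptionSpec(cells=cells, seed=seed)
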