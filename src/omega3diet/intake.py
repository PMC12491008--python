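"""Population intake estimation: concentration x consumption.

Daily nutrient intake per stratum (sex x age interval) and food category is
the product of the category's mean omega-3 content (g/g) and the stratum's
consumption statistic (g food/day), assuming 100% bioavailability as in
screening-level exposure assessment. Plant categories (edible oils,
nuts/seeds) contribute ALA; aquatic categories (fish, crustaceans,
mollusks) contribute EPA+DHA; cross-contributions are excluded.

Percentile convention: the P95 total is the sum of per-category P95
contributions. Summed percentiles overstate the true total's P95 (a person
is rarely a P95 consumer of every category at once), so totals at P50/P95
are upper-bound conveniences, not distributional percentiles. Totals are
summed at full precision, never re-rounded first.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from importlib import resources

from .content import Omega3Content
from .records import (
    AQUATIC_CATEGORIES,
    Category,
    ConfigError,
    ContractError,
    DataError,
    PLANT_CATEGORIES,
)
from .requirements import (
    Authority,
    LifeStage,
    Nutrient,
    ReferenceIntake,
    Sex,
    lookup_reference,
)

__all__ = [
    "STATISTICS",
    "NUTRIENT_CATEGORIES",
    "ConsumptionStats",
    "ConsumptionStratum",
    "IntakeEstimate",
    "category_mean_content",
    "category_median_content",
    "estimate_intake",
    "assess_adequacy",
    "reference_for_stratum",
    "load_consumption_table",
    "write_consumption_table",
    "load_bundled_intake",
]

#: The three consumption / intake statistics carried everywhere.
STATISTICS = ("mean", "p50", "p95")

#: Which food categories feed which nutrient estimate.
NUTRIENT_CATEGORIES: dict[Nutrient, tuple[Category, ...]] = {
    Nutrient.ALA: PLANT_CATEGORIES,
    Nutrient.EPA_DHA: AQUATIC_CATEGORIES,
}


@dataclass(frozen=True)
class ConsumptionStats:
    """mean / median / 95th-percentile consumption, g/day."""

    mean: float
    p50: float
    p95: float

    def __post_init__(self) -> None:
        for s in STATISTICS:
            if getattr(self, s) < 0:
                raise DataError(f"consumption statistic {s} must be non-negative")
        if self.p50 > self.p95 + 1e-12:
            raise DataError(f"p50 ({self.p50}) exceeds p95 ({self.p95})")

    def get(self, stat: str) -> float:
        return getattr(self, stat)


@dataclass(frozen=True)
class ConsumptionStratum:
    """Sex x age-interval consumption per food category.

    Age intervals are half-open [age_low, age_high) in years. Mean body
    weight is survey metadata; the intake arithmetic never uses it.
    """

    sex: Sex
    age_low: float
    age_high: float
    consumption: Mapping[Category, ConsumptionStats]
    body_weight_mean: float | None = None

    @property
    def label(self) -> str:
        return f"{self.sex.value} {self.age_low:g}-{self.age_high:g} y"


@dataclass(frozen=True)
class IntakeEstimate:
    """Per-stratum nutrient intake: category contributions plus totals."""

    stratum: ConsumptionStratum
    nutrient: Nutrient
    contributions: Mapping[Category, Mapping[str, float]]
    totals: Mapping[str, float]


def category_mean_content(
    scored: Iterable[Omega3Content], category: Category
) -> float:
    """Arithmetic mean of exact contents over one category's foods."""
    values = [c.content_exact for c in scored if c.category == category]
    if not values:
        raise ContractError(f"category_mean_content: no scored foods in {category.value}")
    return sum(values) / len(values)


def category_median_content(
    scored: Iterable[Omega3Content], category: Category
) -> float:
    """Median exact content of one category (alternate central scenario)."""
    values = [c.content_exact for c in scored if c.category == category]
    if not values:
        raise ContractError(f"category_median_content: no scored foods in {category.value}")
    return statistics.median(values)


def estimate_intake(
    stratum: ConsumptionStratum,
    contents: Mapping[Category, float],
    nutrient: Nutrient,
) -> IntakeEstimate:
    """contribution[cat][stat] = consumption[cat][stat] x content[cat]."""
    contributions: dict[Category, dict[str, float]] = {}
    for cat in NUTRIENT_CATEGORIES[nutrient]:
        stats = stratum.consumption.get(cat)
        if stats is None:
            continue
        if cat not in contents:
            raise ConfigError(
                f"no {nutrient.value} content supplied for consumed category {cat.value}"
            )
        contributions[cat] = {s: stats.get(s) * contents[cat] for s in STATISTICS}
    totals = {
        s: sum(contrib[s] for contrib in contributions.values()) for s in STATISTICS
    }
    return IntakeEstimate(
        stratum=stratum, nutrient=nutrient, contributions=contributions, totals=totals
    )


def assess_adequacy(
    estimate: IntakeEstimate, reference: ReferenceIntake
) -> dict[str, bool]:
    """Adequate (True) iff the statistic meets the reference's lower amount."""
    if estimate.nutrient is not reference.nutrient:
        raise ContractError(
            f"nutrient mismatch: estimate is {estimate.nutrient.value}, "
            f"reference is {reference.nutrient.value}"
        )
    return {s: estimate.totals[s] >= reference.amount_low for s in STATISTICS}


def reference_for_stratum(
    stratum: ConsumptionStratum,
    nutrient: Nutrient,
    authority: Authority,
    registry=None,
) -> ReferenceIntake:
    """Reference for a survey stratum that may span several DRI age groups.

    The oldest age group contained in the stratum is used (evaluated just
    inside the stratum's upper bound), a deterministic and
    growth-conservative choice when the survey's own mapping is unknown.
    """
    age = min(stratum.age_high, 100.0) - 1e-9
    kwargs = {} if registry is None else {"registry": registry}
    return lookup_reference(
        nutrient, authority, stratum.sex, age, LifeStage.NONE, **kwargs
    )


# ---------------------------------------------------------------------------
# Delimited-text IO

_CONSUMPTION_COLUMNS = (
    "sex", "age_low", "age_high", "body_weight", "category", "mean", "p50", "p95",
)


def load_consumption_table(source: str | Path | IO[str]) -> list[ConsumptionStratum]:
    """Read long-format consumption rows into strata.

    Expected columns: sex, age_low, age_high, body_weight, category, mean,
    p50, p95 — one row per stratum x category; tab- or comma-delimited.
    """
    stream = (
        open(source, "r", encoding="utf-8", newline="")
        if isinstance(source, (str, Path))
        else source
    )
    close = stream is not source
    try:
        first = stream.readline()
        if first == "":
            raise DataError("empty consumption input: no header row")
        delim = "\t" if "\t" in first else ","
        header = [h.strip() for h in first.rstrip("\r\n").split(delim)]
        missing = [c for c in _CONSUMPTION_COLUMNS if c not in header and c != "body_weight"]
        if missing:
            raise DataError(f"missing mandatory consumption column(s) {missing}")
        reader = csv.DictReader(stream, fieldnames=header, delimiter=delim)
        cells: dict[tuple, dict] = {}
        for row in reader:
            key = (Sex(row["sex"]), float(row["age_low"]), float(row["age_high"]))
            cell = cells.setdefault(key, {"consumption": {}, "body_weight": None})
            bw = row.get("body_weight")
            if bw not in (None, ""):
                cell["body_weight"] = float(bw)
            cat = Category(row["category"])
            cell["consumption"][cat] = ConsumptionStats(
                mean=float(row["mean"]), p50=float(row["p50"]), p95=float(row["p95"])
            )
        return [
            ConsumptionStratum(
                sex=sex,
                age_low=lo,
                age_high=hi,
                consumption=cell["consumption"],
                body_weight_mean=cell["body_weight"],
            )
            for (sex, lo, hi), cell in cells.items()
        ]
    finally:
        if close:
            stream.close()


def write_consumption_table(
    strata: Sequence[ConsumptionStratum], dest: str | Path | IO[str], delimiter: str = "\t"
) -> None:
    stream = (
        open(dest, "w", encoding="utf-8", newline="")
        if isinstance(dest, (str, Path))
        else dest
    )
    close = stream is not dest
    try:
        w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
        w.writerow(_CONSUMPTION_COLUMNS)
        for st in strata:
            for cat in sorted(st.consumption, key=lambda c: c.value):
                s = st.consumption[cat]
                w.writerow(
                    [
                        st.sex.value,
                        repr(st.age_low),
                        repr(st.age_high),
                        "" if st.body_weight_mean is None else repr(st.body_weight_mean),
                        cat.value,
                        repr(s.mean),
                        repr(s.p50),
                        repr(s.p95),
                    ]
                )
    finally:
        if close:
            stream.close()


_BUNDLED_INTAKE = {
    Nutrient.ALA: "ala_intake_taiwan.tsv",
    Nutrient.EPA_DHA: "epa_dha_intake_taiwan.tsv",
}


def load_bundled_intake(nutrient: Nutrient) -> pd.DataFrame:
    """The national-survey intake table for one nutrient, long format.

    Columns: sex, age_low, age_high, category ('all' = all foods), mean,
    p50, p95 in g/day, and 0/1 adequacy-marker flags as printed.
    """
    ref = resources.files("omega3diet.data").joinpath(_BUNDLED_INTAKE[nutrient])
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")
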