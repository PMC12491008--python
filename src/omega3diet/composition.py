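"""Loading, validation and quality control of food composition tables.

Tables are delimited text (comma or tab) with a header row. A
:class:`TableDialect` maps source column names onto record fields, declares
which columns are printed as percents, and maps source category labels onto
the closed five-category vocabulary. Percent columns are converted to
fractions on load (57.7 -> 0.577); the in-memory representation is always
fractional.

The composition tables of the underlying nutrient-database survey (edible
oils, nuts and seeds, fish, crustaceans, mollusks) are bundled verbatim as
package data and exposed through :func:`load_bundled`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .content import Omega3Content, score_content
from .records import (
    Category,
    ConfigError,
    DataError,
    FattyAcidProfile,
    FoodCompositionRecord,
    ListedValue,
    Preparation,
    QCFinding,
    Severity,
)

__all__ = [
    "TableDialect",
    "CANONICAL_DIALECT",
    "BUNDLED_DIALECT",
    "RowDiagnostic",
    "CompositionTable",
    "load_composition_table",
    "write_composition_table",
    "load_bundled",
    "load_all_bundled",
    "BUNDLED_TABLES",
    "validate_and_qc",
]

_PROFILE_FIELDS = ("ala", "epa", "dha", "sfa_total", "mufa_total", "pufa_total")


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for one family of composition tables.

    ``columns`` maps record fields to source column names. Recognised
    fields: food_id, name, species, category, preparation, fat_fraction,
    omega3_share, the six profile masses, and listed_content (a printed
    g/g content used only for QC). ``percent_fields`` lists the fields
    whose source values are percents to be divided by 100.
    """

    columns: Mapping[str, str]
    percent_fields: frozenset = frozenset()
    category_map: Mapping[str, Category] = field(default_factory=dict)
    default_category: Category | None = None
    default_preparation: Preparation = Preparation.UNKNOWN
    delimiter: str | None = None  # sniffed from the header when None

    def source_column(self, field_name: str) -> str | None:
        return self.columns.get(field_name)


#: Dialect of files written by :func:`write_composition_table` (fractions).
CANONICAL_DIALECT = TableDialect(
    columns={
        "food_id": "food_id",
        "name": "name",
        "species": "species",
        "category": "category",
        "preparation": "preparation",
        "fat_fraction": "fat_fraction",
        "omega3_share": "omega3_share_of_fat",
        **{f: f for f in _PROFILE_FIELDS},
    },
    category_map={c.value: c for c in Category},
)

#: Dialect of the bundled survey tables (share and fat printed as percents).
BUNDLED_DIALECT = TableDialect(
    columns={
        "food_id": "food_id",
        "name": "name",
        "species": "species",
        "fat_fraction": "fat_pct",
        "omega3_share": "share_pct",
        "listed_content": "listed_content",
    },
    percent_fields=frozenset({"fat_fraction", "omega3_share"}),
)


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a source row was rejected (1-based data row number)."""

    row_number: int
    food_id: str | None
    reason: str


class CompositionTable(Sequence[FoodCompositionRecord]):
    """A loaded table: records plus per-row QC side information."""

    def __init__(
        self,
        records: list[FoodCompositionRecord],
        listed_contents: dict[str, ListedValue] | None = None,
        rejected: list[RowDiagnostic] | None = None,
        name: str | None = None,
        stated_count: int | None = None,
    ) -> None:
        self.records = records
        self.listed_contents = listed_contents or {}
        self.rejected = rejected or []
        self.name = name
        #: Item count stated by the source documentation, when it differs
        #: from the printed table it is surfaced as an info finding.
        self.stated_count = stated_count

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):  # type: ignore[override]
        return self.records[i]

    def __iter__(self) -> Iterator[FoodCompositionRecord]:
        return iter(self.records)


def _parse_maybe_censored(text: str) -> ListedValue:
    text = text.strip()
    if text.startswith("<"):
        return ListedValue(value=float(text[1:].strip()), censored=True)
    return ListedValue(value=float(text))


def _open_source(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_composition_table(
    source, dialect: TableDialect = CANONICAL_DIALECT, **table_kwargs
) -> CompositionTable:
    """Load a delimited composition table.

    Rows that cannot be coerced are rejected with row-level diagnostics,
    never silently dropped; a missing mandatory column fails the whole
    load. When duplicate ``food_id`` values occur, the raw-preparation
    record wins (the survey prefers raw over cooked measurements).
    """
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        first = stream.readline()
        if first == "":
            raise DataError("empty input: no header row")
        delim = dialect.delimiter or _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\r\n").split(delim)]
        for fld in ("food_id", "name", "fat_fraction"):
            col = dialect.source_column(fld)
            if col is None or col not in header:
                raise DataError(f"missing mandatory column {col or fld!r}")
        reader = csv.DictReader(stream, fieldnames=header, delimiter=delim)
        records: list[FoodCompositionRecord] = []
        listed: dict[str, ListedValue] = {}
        rejected: list[RowDiagnostic] = []
        for row_number, row in enumerate(reader, start=1):
            try:
                rec, lv = _parse_row(row, dialect)
            except (DataError, ValueError, KeyError) as exc:
                rejected.append(
                    RowDiagnostic(
                        row_number=row_number,
                        food_id=(row.get(dialect.source_column("food_id") or "") or None),
                        reason=str(exc),
                    )
                )
                continue
            records.append(rec)
            if lv is not None:
                listed[rec.food_id] = lv
        records = _dedupe_raw_wins(records)
        return CompositionTable(records, listed, rejected, **table_kwargs)
    finally:
        if close:
            stream.close()


def _get(row: Mapping[str, str], dialect: TableDialect, field_name: str) -> str | None:
    col = dialect.source_column(field_name)
    if col is None:
        return None
    v = row.get(col)
    if v is None:
        return None
    v = v.strip()
    return v or None


def _parse_row(
    row: Mapping[str, str], dialect: TableDialect
) -> tuple[FoodCompositionRecord, ListedValue | None]:
    food_id = _get(row, dialect, "food_id")
    name = _get(row, dialect, "name")
    if not food_id or not name:
        raise DataError("missing food_id or name")

    cat_text = _get(row, dialect, "category")
    if cat_text is not None:
        if dialect.category_map and cat_text in dialect.category_map:
            category = dialect.category_map[cat_text]
        else:
            raise DataError(f"unknown category label {cat_text!r}")
    elif dialect.default_category is not None:
        category = dialect.default_category
    else:
        raise DataError("no category column and no default category")

    prep_text = _get(row, dialect, "preparation")
    preparation = Preparation(prep_text) if prep_text else dialect.default_preparation

    scale = lambda fld, v: v / 100.0 if fld in dialect.percent_fields else v

    fat_text = _get(row, dialect, "fat_fraction")
    if fat_text is None:
        raise DataError("missing fat content")
    fat_fraction = scale("fat_fraction", float(fat_text))

    share_text = _get(row, dialect, "omega3_share")
    share = None
    share_censored = False
    if share_text is not None:
        lv = _parse_maybe_censored(share_text)
        share = scale("omega3_share", lv.value)
        share_censored = lv.censored

    profile = None
    profile_vals = {f: _get(row, dialect, f) for f in _PROFILE_FIELDS}
    if all(v is not None for v in profile_vals.values()):
        profile = FattyAcidProfile(**{f: float(v) for f, v in profile_vals.items()})
    elif any(v is not None for v in profile_vals.values()):
        missing = [f for f, v in profile_vals.items() if v is None]
        raise DataError(f"incomplete fatty-acid profile, missing {missing}")

    listed_text = _get(row, dialect, "listed_content")
    listed = _parse_maybe_censored(listed_text) if listed_text is not None else None

    rec = FoodCompositionRecord(
        food_id=food_id,
        name=name,
        category=category,
        fat_fraction=fat_fraction,
        species_binomial=_get(row, dialect, "species"),
        preparation=preparation,
        omega3_share_of_fat=share,
        fa_profile=profile,
        share_censored=share_censored,
    )
    return rec, listed


def _dedupe_raw_wins(records: list[FoodCompositionRecord]) -> list[FoodCompositionRecord]:
    by_id: dict[str, FoodCompositionRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.food_id not in by_id:
            by_id[rec.food_id] = rec
            order.append(rec.food_id)
        else:
            kept = by_id[rec.food_id]
            if kept.preparation is not Preparation.RAW and rec.preparation is Preparation.RAW:
                by_id[rec.food_id] = rec
    return [by_id[i] for i in order]


def write_composition_table(
    records: Iterable[FoodCompositionRecord], dest, delimiter: str = "\t"
) -> None:
    """Write records in the canonical fractional dialect (round-trip safe)."""
    stream = dest if isinstance(dest, io.TextIOBase) else open(dest, "w", encoding="utf-8", newline="")
    close = stream is not dest
    header = [
        "food_id", "name", "species", "category", "preparation",
        "fat_fraction", "omega3_share_of_fat", *_PROFILE_FIELDS,
    ]
    try:
        w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
        w.writerow(header)
        for r in records:
            prof = r.fa_profile
            w.writerow(
                [
                    r.food_id,
                    r.name,
                    r.species_binomial or "",
                    r.category.value,
                    r.preparation.value,
                    repr(r.fat_fraction),
                    ""
                    if r.omega3_share_of_fat is None
                    else ("<" if r.share_censored else "") + repr(r.omega3_share_of_fat),
                    *(
                        [repr(getattr(prof, f)) for f in _PROFILE_FIELDS]
                        if prof is not None
                        else [""] * len(_PROFILE_FIELDS)
                    ),
                ]
            )
    finally:
        if close:
            stream.close()


#: table name -> (resource file, category, count stated by the source text).
BUNDLED_TABLES: dict[str, tuple[str, Category, int | None]] = {
    "edible_oils": ("edible_oils.tsv", Category.EDIBLE_OIL, 22),
    "nuts_seeds": ("nuts_seeds.tsv", Category.NUT_SEED, 18),
    "fish": ("fish.tsv", Category.FISH, None),  # table lists high-content species only
    "crustaceans": ("crustaceans.tsv", Category.CRUSTACEAN, 21),
    "mollusks": ("mollusks.tsv", Category.MOLLUSK, 15),
}


def load_bundled(table: str) -> CompositionTable:
    """Load one bundled composition table by name (see ``BUNDLED_TABLES``)."""
    try:
        filename, category, stated = BUNDLED_TABLES[table]
    except KeyError:
        raise ConfigError(
            f"unknown bundled table {table!r}; expected one of {sorted(BUNDLED_TABLES)}"
        ) from None
    dialect = replace(BUNDLED_DIALECT, default_category=category)
    ref = resources.files("omega3diet.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return load_composition_table(fh, dialect, name=table, stated_count=stated)


def load_all_bundled() -> dict[str, CompositionTable]:
    return {name: load_bundled(name) for name in BUNDLED_TABLES}


def _band_of_exact(exact: float) -> str:
    # band the *unrounded* value with the same cut points, for boundary QC
    if exact < 0.01:
        return "low"
    if exact <= 0.02:
        return "moderate"
    return "high"


def validate_and_qc(
    table: CompositionTable | Iterable[FoodCompositionRecord],
    listed_contents: Mapping[str, ListedValue] | None = None,
) -> list[QCFinding]:
    """Recompute contents and compare against the listed values.

    Emits a ``mismatch`` finding whenever the recomputed display value
    disagrees with the printed one (a censored "<x" entry matches any
    display below x). Emits ``info`` findings when half-up display rounding
    moved a food across a band boundary (e.g. exact 0.0054 displaying as
    0.01), when a share was censored in the source, and when the table's
    stated item count differs from the number of rows. QC never aborts;
    findings come back in input order and are fully deterministic.
    """
    if listed_contents is None and isinstance(table, CompositionTable):
        listed_contents = table.listed_contents
    listed_contents = listed_contents or {}
    findings: list[QCFinding] = []

    if isinstance(table, CompositionTable) and table.stated_count is not None:
        n = len(table.records)
        if n != table.stated_count:
            findings.append(
                QCFinding(
                    food_id=table.name or "<table>",
                    field_name="record_count",
                    listed_value=str(table.stated_count),
                    recomputed_value=str(n),
                    severity=Severity.INFO,
                    message="stated item count differs from printed rows",
                )
            )

    for rec in table:
        scored: Omega3Content = score_content(rec)
        listed = listed_contents.get(rec.food_id)
        if listed is not None:
            if listed.censored:
                ok = scored.content_display < listed.value - 1e-12
            else:
                ok = abs(scored.content_display - listed.value) < 1e-9
            if not ok:
                findings.append(
                    QCFinding(
                        food_id=rec.food_id,
                        field_name="content",
                        listed_value=str(listed),
                        recomputed_value=f"{scored.content_display:.2f}",
                        severity=Severity.MISMATCH,
                        message=(
                            f"{rec.name}: listed content {listed} is not reproduced "
                            f"by share x fat = {scored.content_exact:.6f}"
                        ),
                    )
                )
        if _band_of_exact(scored.content_exact) != scored.band.value:
            findings.append(
                QCFinding(
                    food_id=rec.food_id,
                    field_name="band",
                    listed_value=f"exact {scored.content_exact:.6f}",
                    recomputed_value=f"display {scored.content_display:.2f}",
                    severity=Severity.INFO,
                    message=f"{rec.name}: display rounding crosses a band boundary",
                )
            )
        if rec.share_censored:
            findings.append(
                QCFinding(
                    food_id=rec.food_id,
                    field_name="omega3_share_of_fat",
                    listed_value=f"<{rec.omega3_share_of_fat:g}",
                    recomputed_value=f"{rec.omega3_share_of_fat:g}",
                    severity=Severity.INFO,
                    message=f"{rec.name}: share printed as an upper bound; bound used",
                )
            )
    return findings
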