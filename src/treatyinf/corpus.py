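"""Treaty-corpus data model, validation, I/O and slicing.

The unit of analysis is a bilateral investment treaty (BIT): an agreement
between exactly two parties carrying a signature date, one or more health
safeguard categories (``defensive`` / ``neutral`` / ``offensive``) and the
clause text that is compared across treaties.  Party names are opaque
strings — composite entities such as the Belgium-Luxembourg Economic Union
("BLEU") count as a single party and are never split or normalised.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "CorpusError",
    "SchemaError",
    "ValidationError",
    "TreatyRecord",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "filter_corpus",
    "write_report",
]

#: Valid health-safeguard category labels (stored lower-case).
CATEGORIES = frozenset({"defensive", "neutral", "offensive"})

#: Delimiter separating multiple category labels in one CSV cell.
CATEGORY_DELIMITER = ";"

CSV_COLUMNS = (
    "treaty_id",
    "country_a",
    "country_b",
    "date_signed",
    "categories",
    "clause_text",
)


class CorpusError(ValueError):
    """Base class for corpus construction problems."""


class SchemaError(CorpusError):
    """The input file does not match the documented schema."""


class ValidationError(CorpusError):
    """A record violates a treaty-record invariant."""


def _parse_date(value: str, treaty_id: str) -> _dt.date:
    """Parse an ISO-8601 date (YYYY-MM-DD) or a bare year."""
    value = str(value).strip()
    if value.isdigit() and len(value) == 4:
        return _dt.date(int(value), 1, 1)
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ValidationError(
            f"record {treaty_id!r}: cannot parse date_signed {value!r} "
            "(expected YYYY-MM-DD or a bare year)"
        ) from exc


def _parse_categories(value: str, treaty_id: str) -> frozenset[str]:
    labels = frozenset(
        part.strip().lower()
        for part in str(value).split(CATEGORY_DELIMITER)
        if part.strip()
    )
    if not labels:
        raise ValidationError(f"record {treaty_id!r}: no category label (uncategorised records are rejected)")
    unknown = labels - CATEGORIES
    if unknown:
        raise ValidationError(
            f"record {treaty_id!r}: unknown categories {sorted(unknown)}; "
            f"valid labels are {sorted(CATEGORIES)}"
        )
    return labels


@dataclass(frozen=True)
class TreatyRecord:
    """One dyadic treaty: id, the two parties, signature date, categories, clause text.

    Invariants (enforced at construction):

    * the two parties are distinct — multi-party agreements are rejected;
    * ``categories`` is a non-empty subset of :data:`CATEGORIES`
      (multiclass treaties carry several labels);
    * ``clause_text`` is non-empty (the metric is text-based).
    """

    treaty_id: str
    country_a: str
    country_b: str
    date_signed: _dt.date
    categories: frozenset[str]
    clause_text: str

    def __post_init__(self) -> None:
        if not str(self.treaty_id):
            raise ValidationError("treaty_id must be non-empty")
        for slot, name in (("country_a", self.country_a), ("country_b", self.country_b)):
            if not str(name).strip():
                raise ValidationError(f"record {self.treaty_id!r}: empty {slot}")
            if CATEGORY_DELIMITER in str(name):
                raise ValidationError(
                    f"record {self.treaty_id!r}: {slot} {name!r} lists more than one party; "
                    "treaties must be bilateral"
                )
        if self.country_a == self.country_b:
            raise ValidationError(
                f"record {self.treaty_id!r}: the two parties must be distinct "
                f"(got {self.country_a!r} twice)"
            )
        object.__setattr__(self, "categories", frozenset(self.categories))
        if not self.categories:
            raise ValidationError(f"record {self.treaty_id!r}: categories must be non-empty")
        unknown = self.categories - CATEGORIES
        if unknown:
            raise ValidationError(
                f"record {self.treaty_id!r}: unknown categories {sorted(unknown)}; "
                f"valid labels are {sorted(CATEGORIES)}"
            )
        if not str(self.clause_text).strip():
            raise ValidationError(f"record {self.treaty_id!r}: empty clause_text")

    @property
    def parties(self) -> frozenset[str]:
        return frozenset((self.country_a, self.country_b))

    @property
    def year(self) -> int:
        return self.date_signed.year


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of :class:`TreatyRecord` with a provenance label."""

    records: tuple[TreatyRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.treaty_id in seen:
                raise ValidationError(f"duplicate treaty_id {rec.treaty_id!r}")
            seen.add(rec.treaty_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TreatyRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> TreatyRecord:
        return self.records[idx]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def treaty_ids(self) -> tuple[str, ...]:
        return tuple(rec.treaty_id for rec in self.records)

    @property
    def countries(self) -> frozenset[str]:
        """All parties appearing anywhere in the corpus."""
        out: set[str] = set()
        for rec in self.records:
            out |= rec.parties
        return frozenset(out)

    def get(self, treaty_id: str) -> TreatyRecord:
        for rec in self.records:
            if rec.treaty_id == treaty_id:
                return rec
        raise KeyError(treaty_id)

    def relabel(self, label: str) -> "Corpus":
        return replace(self, label=label)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_corpus(path: str | Path, fmt: str | None = None, label: str | None = None) -> Corpus:
    """Read a validated corpus from CSV or JSON.

    CSV schema (header required):
    ``treaty_id,country_a,country_b,date_signed,categories,clause_text``;
    JSON is an array of objects with the same keys.  Category cells may hold
    several semicolon-separated labels; labels are case-insensitive on input
    and stored lower-case.  Dates are ISO-8601 or a bare year.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ValidationError` (naming the offending treaty id) for malformed
    records: duplicate ids, identical or multiple parties per slot, unknown
    or absent categories, empty clause text.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = frame.to_dict(orient="records")
        columns = set(frame.columns)
    elif fmt == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        columns = set(rows[0]) if rows else set(CSV_COLUMNS)
    else:
        raise ValueError(f"unknown corpus format {fmt!r} (use 'csv' or 'json')")

    missing = [col for col in CSV_COLUMNS if col not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records = []
    for row in rows:
        treaty_id = str(row["treaty_id"])
        records.append(
            TreatyRecord(
                treaty_id=treaty_id,
                country_a=str(row["country_a"]),
                country_b=str(row["country_b"]),
                date_signed=_parse_date(row["date_signed"], treaty_id),
                categories=_parse_categories(row["categories"], treaty_id),
                clause_text=str(row["clause_text"]),
            )
        )
    return Corpus(records=tuple(records), label=label if label is not None else path.stem)


def write_corpus(corpus: Corpus, path: str | Path, fmt: str | None = None) -> Path:
    """Write a corpus to CSV or JSON using the documented schema.

    Round-trips: ``read_corpus(write_corpus(c, p), fmt)`` reproduces ``c``
    record for record.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows = [
        {
            "treaty_id": rec.treaty_id,
            "country_a": rec.country_a,
            "country_b": rec.country_b,
            "date_signed": rec.date_signed.isoformat(),
            "categories": CATEGORY_DELIMITER.join(sorted(rec.categories)),
            "clause_text": rec.clause_text,
        }
        for rec in corpus
    ]
    if fmt == "csv":
        pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown corpus format {fmt!r} (use 'csv' or 'json')")
    return path


def filter_corpus(
    corpus: Corpus,
    category: str | None = None,
    period: tuple[int, int] | None = None,
) -> Corpus:
    """Slice a corpus by safeguard category and/or signature period.

    A multiclass treaty qualifies for each of its classes, so per-category
    counts over the three classes sum to at least N.  ``period`` is an
    inclusive ``(start_year, end_year)`` range on the calendar year of
    signature.  Record order is preserved; category and period filters
    commute.
    """
    if category is not None:
        category = category.lower()
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; valid labels are {sorted(CATEGORIES)}"
            )
    if period is not None:
        start, end = int(period[0]), int(period[1])
        if start > end:
            raise ValueError(f"period start {start} exceeds end {end}")

    kept = []
    for rec in corpus:
        if category is not None and category not in rec.categories:
            continue
        if period is not None and not (start <= rec.year <= end):
            continue
        kept.append(rec)

    parts = [corpus.label] if corpus.label else []
    if category is not None:
        parts.append(category)
    if period is not None:
        parts.append(f"{start}-{end}")
    return Corpus(records=tuple(kept), label=" ".join(parts))


def write_report(table, path: str | Path, fmt: str | None = None) -> Path:
    """Write an influence or similarity-pair table deterministically.

    Influence tables are sorted by descending INF with lexical tie-break on
    the country name; pair tables keep their canonical pair order with scores
    printed at 6 decimal places.  Output is byte-identical for identical
    inputs.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)

    # Duck-typed on the two table shapes to avoid a circular import.
    if hasattr(table, "scores") and isinstance(getattr(table, "scores"), dict):
        rows = sorted(table.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if fmt == "csv":
            frame = pd.DataFrame(rows, columns=["country", "inf"])
            frame["threshold"] = table.threshold
            frame["M"] = table.m
            frame["D"] = table.d
            frame["label"] = table.label
            frame.to_csv(path, index=False, float_format="%.6f")
        elif fmt == "json":
            path.write_text(
                json.dumps({country: round(score, 6) for country, score in rows}, indent=1),
                encoding="utf-8",
            )
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    elif hasattr(table, "pairs"):
        rows = [(a, b, f"{score:.6f}") for a, b, score in table.pairs]
        if fmt == "csv":
            pd.DataFrame(rows, columns=["id_a", "id_b", "score"]).to_csv(path, index=False)
        elif fmt == "json":
            path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    else:
        raise TypeError(f"cannot write a report for {type(table).__name__}")
    return path
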