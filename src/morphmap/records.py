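"""Specimen records: data model, CSV I/O, validation and tabulation.

A digitised museum voucher carries an identity, a sex, female wing-pattern
labels (morph / morph group), a subspecies designation, verbatim locality
text and manually geocoded coordinates with a positional error in km.  Only
records geocoded to better than a configurable error (default 40 km) enter
the spatial analyses.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "SpecimenRecord",
    "RecordSet",
    "RecordError",
    "read_records",
    "write_records",
    "filter_geocoded",
    "tabulate",
    "write_tabulation",
]

CSV_COLUMNS = [
    "voucher_id",
    "sex",
    "morph",
    "morph_group",
    "subspecies",
    "country",
    "locality",
    "latitude",
    "longitude",
    "geocode_error_km",
]

VALID_SEXES = {"male", "female", "unknown"}


class RecordError(ValueError):
    """Raised for unrecoverable problems in a record set (e.g. duplicate vouchers)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One digitised voucher specimen.

    Coordinates are WGS84 decimal degrees; ``None`` means not geocoded.
    ``geocode_error_km`` is the linear positional uncertainty of the manual
    geocode.  Morph labels apply to females only in this system (males are
    monomorphic); a morph on a non-female record is flagged by
    :meth:`validation_warnings` but is not an error — historical labels are
    messy.
    """

    voucher_id: str
    sex: str = "unknown"
    morph: str = ""
    morph_group: str = ""
    subspecies: str = ""
    country: str = ""
    locality: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    geocode_error_km: Optional[float] = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.voucher_id:
            raise RecordError("voucher_id must be non-empty")
        if (self.latitude is None) != (self.longitude is None):
            raise RecordError(
                f"record {self.voucher_id}: latitude and longitude must be "
                "both present or both missing"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise RecordError(f"record {self.voucher_id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise RecordError(f"record {self.voucher_id}: longitude out of range")
        if self.geocode_error_km is not None and self.geocode_error_km < 0:
            raise RecordError(f"record {self.voucher_id}: negative geocode error")
        if self.sex not in VALID_SEXES:
            raise RecordError(
                f"record {self.voucher_id}: sex must be one of {sorted(VALID_SEXES)}"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None

    def validation_warnings(self) -> list[str]:
        out = []
        if self.morph and self.sex != "female":
            out.append(
                f"record {self.voucher_id}: morph {self.morph!r} on a "
                f"{self.sex} specimen (morphs are female wing patterns)"
            )
        return out


class RecordSet:
    """Ordered collection of :class:`SpecimenRecord` with unique voucher ids."""

    def __init__(self, records: Iterable[SpecimenRecord], provenance: str = ""):
        self.records: list[SpecimenRecord] = list(records)
        self.provenance = provenance
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.voucher_id in seen:
                raise RecordError(
                    f"duplicate voucher_id {rec.voucher_id!r} at rows "
                    f"{seen[rec.voucher_id]} and {i}"
                )
            seen[rec.voucher_id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def validation_warnings(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            out.extend(rec.validation_warnings())
        return out


def _parse_float(cell: str, what: str, voucher: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN", "NULL"}:
        return None
    try:
        value = float(cell)
    except ValueError:
        raise RecordError(f"record {voucher}: unparseable {what} {cell!r}") from None
    if not math.isfinite(value):
        raise RecordError(f"record {voucher}: non-finite {what}")
    return value


def read_records(path: str | Path, *, strict: bool = True) -> RecordSet:
    """Read specimen records from a UTF-8 CSV with a header row.

    Unknown columns are preserved per record in ``extra``.  Blank coordinate
    or error cells become missing values (never zero).  A duplicate voucher
    id is always a hard error; with ``strict=False`` records with unparseable
    cells are dropped and reported as warnings instead of raising.
    """
    path = Path(path)
    records: list[SpecimenRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RecordError(f"{path}: empty file, no header row")
        known = set(CSV_COLUMNS)
        for rownum, row in enumerate(reader, start=2):
            voucher = (row.get("voucher_id") or "").strip()
            try:
                lat = _parse_float(row.get("latitude") or "", "latitude", voucher)
                lon = _parse_float(row.get("longitude") or "", "longitude", voucher)
                if (lat is None) != (lon is None):
                    # a half-geocoded pair is unusable: treat as not geocoded
                    warnings.warn(
                        f"record {voucher}: only one coordinate present; "
                        "treating the pair as missing",
                        stacklevel=2,
                    )
                    lat = lon = None
                rec = SpecimenRecord(
                    voucher_id=voucher,
                    sex=(row.get("sex") or "unknown").strip().lower() or "unknown",
                    morph=(row.get("morph") or "").strip(),
                    morph_group=(row.get("morph_group") or "").strip(),
                    subspecies=(row.get("subspecies") or "").strip(),
                    country=(row.get("country") or "").strip(),
                    locality=(row.get("locality") or "").strip(),
                    latitude=lat,
                    longitude=lon,
                    geocode_error_km=_parse_float(
                        row.get("geocode_error_km") or "", "geocode error", voucher
                    ),
                    extra={k: v for k, v in row.items() if k not in known},
                )
            except RecordError as err:
                problems.append(f"row {rownum}: {err}")
                continue
            records.append(rec)
    if problems:
        msg = f"{path}: {len(problems)} invalid record(s): " + "; ".join(problems)
        if strict:
            raise RecordError(msg)
        warnings.warn(msg, stacklevel=2)
    return RecordSet(records, provenance=str(path))


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a record set back to CSV in the canonical column order."""
    extra_cols: list[str] = []
    for rec in rs:
        for k in rec.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS + extra_cols)
        for rec in rs:
            writer.writerow(
                [
                    rec.voucher_id,
                    rec.sex,
                    rec.morph,
                    rec.morph_group,
                    rec.subspecies,
                    rec.country,
                    rec.locality,
                    "" if rec.latitude is None else repr(rec.latitude),
                    "" if rec.longitude is None else repr(rec.longitude),
                    "" if rec.geocode_error_km is None else repr(rec.geocode_error_km),
                ]
                + [rec.extra.get(k, "") for k in extra_cols]
            )


def filter_geocoded(rs: RecordSet, max_error_km: float = 40.0) -> RecordSet:
    """Keep records with coordinates and geocode error strictly below the cut.

    The default 40 km reproduces the usual curation rule for manually
    geocoded historical labels; the inequality is strict, so a record at
    exactly ``max_error_km`` is dropped.  Records with missing coordinates or
    missing error are dropped.  Order is preserved; the filter is idempotent
    and monotone in ``max_error_km``.
    """
    if not max_error_km > 0:
        raise ValueError("max_error_km must be positive")
    kept = [
        rec
        for rec in rs
        if rec.has_coordinates
        and rec.geocode_error_km is not None
        and rec.geocode_error_km < max_error_km
    ]
    return RecordSet(kept, provenance=rs.provenance)


def tabulate(rs: RecordSet, by: str) -> list[tuple[str, int]]:
    """Count records by a categorical field.

    ``by`` is one of ``country``, ``sex``, ``morph_group``, ``subspecies``.
    Returns ``(key, count)`` pairs sorted by descending count, ties broken
    alphabetically; blank labels are tallied under ``"(unassigned)"``.
    """
    if by not in {"country", "sex", "morph_group", "subspecies"}:
        raise ValueError(f"cannot tabulate by {by!r}")
    counts = Counter(getattr(rec, by) or "(unassigned)" for rec in rs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def write_tabulation(table: list[tuple[str, int]], path: str | Path, by: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([by, "count"])
        writer.writerows(table)


def relabel_groups(rs: RecordSet, registry) -> RecordSet:
    """Fill each record's ``morph_group`` from the registry where blank."""
    out = []
    for rec in rs:
        if rec.morph and not rec.morph_group:
            group = registry.group_of(rec.morph)
            if group:
                rec = replace(rec, morph_group=group)
        out.append(rec)
    return RecordSet(out, provenance=rs.provenance)
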