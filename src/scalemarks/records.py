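"""Data model, validation and CSV I/O for per-scale growth-mark observations.

One record describes a single scale taken from one of nine body areas of a
specimen (horizontal position Anterior/Central/Posterior x vertical position
Dorsal/Middle/Ventral). Mark counts exist only for scales in good condition:
damaged and regenerated scales carry no count because their growth record is
unreliable, so ``marks`` is structurally absent (``None``) for them — a zero
would be a legal count for a readable scale and must not be conflated.

Scale length is stored as a bare positive real; its unit is a dataset-level
convention (the per-unit length slope in the model simply rescales with it).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

SPECIES = ("cephalus", "curema")
LOCALITIES = ("SL", "SAB", "LM", "TA", "CA", "ME")
SEXES = ("F", "M")
HORIZONTAL = ("A", "C", "P")
VERTICAL = ("D", "M", "V")
AREAS = tuple(h + v for h in HORIZONTAL for v in VERTICAL)
STATUSES = ("good", "damaged", "regenerated")

CSV_HEADER = (
    "specimen_id",
    "species",
    "locality",
    "sex",
    "standard_length_cm",
    "area",
    "scale_length",
    "scale_width",
    "scale_radius",
    "status",
    "marks",
)


class SchemaError(ValueError):
    """The CSV header does not match the canonical schema."""


class RecordValidationError(ValueError):
    """A record (or row) violates the data-model invariants."""


class NoReadableScalesError(ValueError):
    """Filtering removed every scale: no good-status records remain."""


@dataclass(frozen=True)
class ScaleRecord:
    """A single scale: specimen covariates, measurements, status, mark count."""

    specimen_id: str
    species: str
    locality: str
    sex: str
    standard_length: float
    area: str
    scale_length: float
    scale_width: Optional[float] = None
    scale_radius: Optional[float] = None
    status: str = "good"
    marks: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise RecordValidationError("specimen_id must be non-empty")
        if self.species not in SPECIES:
            raise RecordValidationError(f"unknown species {self.species!r}")
        if self.locality not in LOCALITIES:
            raise RecordValidationError(f"unknown locality {self.locality!r}")
        if self.sex not in SEXES:
            raise RecordValidationError(f"unknown sex {self.sex!r}")
        if self.area not in AREAS:
            raise RecordValidationError(f"invalid area code {self.area!r}")
        if self.status not in STATUSES:
            raise RecordValidationError(f"unknown status {self.status!r}")
        if not (self.standard_length > 0):
            raise RecordValidationError("standard_length must be > 0")
        if not (self.scale_length > 0):
            raise RecordValidationError("scale_length must be > 0")
        for name in ("scale_width", "scale_radius"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise RecordValidationError(f"{name} must be > 0 when present")
        if self.status == "good":
            if self.marks is None:
                raise RecordValidationError(
                    f"good scale of {self.specimen_id} lacks a mark count"
                )
            if int(self.marks) != self.marks or self.marks < 0:
                raise RecordValidationError("marks must be a non-negative integer")
        elif self.marks is not None:
            raise RecordValidationError(
                f"{self.status} scale of {self.specimen_id} must not carry marks"
            )


# specimen-level fields that must agree across every scale of a specimen
_SPECIMEN_FIELDS = ("species", "locality", "sex", "standard_length")


@dataclass
class ScaleDataset:
    """An ordered collection of validated scale records plus provenance."""

    records: list[ScaleRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise RecordValidationError("a dataset must contain at least one record")
        seen: dict[str, tuple] = {}
        for rec in self.records:
            key = tuple(getattr(rec, f) for f in _SPECIMEN_FIELDS)
            prev = seen.setdefault(rec.specimen_id, key)
            if prev != key:
                raise RecordValidationError(
                    f"specimen {rec.specimen_id!r} has inconsistent covariates: "
                    f"{dict(zip(_SPECIMEN_FIELDS, prev))} vs "
                    f"{dict(zip(_SPECIMEN_FIELDS, key))}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        """Distinct specimen ids in order of first appearance."""
        out: list[str] = []
        seen = set()
        for rec in self.records:
            if rec.specimen_id not in seen:
                seen.add(rec.specimen_id)
                out.append(rec.specimen_id)
        return out

    def subset(self, predicate) -> "ScaleDataset":
        kept = [r for r in self.records if predicate(r)]
        if not kept:
            raise NoReadableScalesError("subset is empty")
        return ScaleDataset(kept, dict(self.metadata))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(text: str, column: str, row: int, optional: bool = False):
    if text == "":
        if optional:
            return None
        raise RecordValidationError(f"row {row}: column {column!r} is empty")
    try:
        return float(text)
    except ValueError:
        raise RecordValidationError(
            f"row {row}: column {column!r} is not numeric: {text!r}"
        ) from None


def load_scale_table(path) -> ScaleDataset:
    """Read a canonical scale-record CSV into a validated :class:`ScaleDataset`.

    Raises :class:`SchemaError` when the header deviates from ``CSV_HEADER``
    and :class:`RecordValidationError` (citing the 1-based data row) when a
    row violates the record invariants.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: file is empty") from None
        if tuple(header) != CSV_HEADER:
            missing = set(CSV_HEADER) - set(header)
            unknown = set(header) - set(CSV_HEADER)
            parts = []
            if missing:
                parts.append(f"missing columns {sorted(missing)}")
            if unknown:
                parts.append(f"unknown columns {sorted(unknown)}")
            if not parts:
                parts.append("columns out of order")
            raise SchemaError(f"{path}: " + "; ".join(parts))
        records = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(CSV_HEADER):
                raise RecordValidationError(
                    f"row {i}: expected {len(CSV_HEADER)} fields, got {len(row)}"
                )
            vals = dict(zip(CSV_HEADER, row))
            marks_text = vals["marks"]
            try:
                rec = ScaleRecord(
                    specimen_id=vals["specimen_id"],
                    species=vals["species"],
                    locality=vals["locality"],
                    sex=vals["sex"],
                    standard_length=_parse_float(
                        vals["standard_length_cm"], "standard_length_cm", i
                    ),
                    area=vals["area"],
                    scale_length=_parse_float(vals["scale_length"], "scale_length", i),
                    scale_width=_parse_float(
                        vals["scale_width"], "scale_width", i, optional=True
                    ),
                    scale_radius=_parse_float(
                        vals["scale_radius"], "scale_radius", i, optional=True
                    ),
                    status=vals["status"],
                    marks=int(marks_text) if marks_text != "" else None,
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"row {i}: {exc}") from None
            except ValueError:
                raise RecordValidationError(
                    f"row {i}: marks is not an integer: {marks_text!r}"
                ) from None
            records.append(rec)
    return ScaleDataset(records, metadata={"source": str(path)})


def write_scale_table(dataset: ScaleDataset, path) -> str:
    """Write a dataset as the canonical CSV; absent fields become empty cells."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in dataset.records:
            writer.writerow(
                [
                    rec.specimen_id,
                    rec.species,
                    rec.locality,
                    rec.sex,
                    _fmt(rec.standard_length),
                    rec.area,
                    _fmt(rec.scale_length),
                    _fmt(rec.scale_width),
                    _fmt(rec.scale_radius),
                    rec.status,
                    _fmt(rec.marks),
                ]
            )
    return str(path)


def filter_readable(dataset: ScaleDataset) -> ScaleDataset:
    """Keep only good-status scales (the ones with a usable mark count)."""
    kept = [r for r in dataset.records if r.status == "good"]
    if not kept:
        raise NoReadableScalesError("no readable scales: all damaged or regenerated")
    return ScaleDataset(kept, dict(dataset.metadata))


def split_by_species(dataset: ScaleDataset) -> dict[str, ScaleDataset]:
    """Partition a (possibly mixed) dataset into one dataset per species."""
    groups: dict[str, list[ScaleRecord]] = {}
    for rec in dataset.records:
        groups.setdefault(rec.species, []).append(rec)
    return {
        sp: ScaleDataset(recs, dict(dataset.metadata)) for sp, recs in groups.items()
    }
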