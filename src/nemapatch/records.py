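"""Record types and CSV I/O for patch-occupancy field data.

The sampling unit throughout is the *patch*: a discrete piece of ephemeral
habitat (a rotting fruit, flower, fungus, piece of litter, or an
experimentally placed agar bait) that a nematode population may colonize.
Three record kinds are supported:

* :class:`CollectionRecord` — one opportunistically or systematically sampled
  substrate patch, with its position in the sampling hierarchy
  (locality → site/tree → quadrat → patch) and the set of species observed.
* :class:`BaitRecord` — one agar bait from the 7-site × 5-array × 6-bait-type
  colonization experiment, including whether the bait was recovered.
* :class:`ExclosureRecord` — one bait from the 6-site size-selective
  exclosure experiment in which mesh pore size restricts which phoretic
  carriers can reach the bait.

All files are plain UTF-8 CSV with a mandatory header; the multi-valued
``species_present`` cell uses ``;`` as an internal delimiter. Species names
are normalized on construction: surrounding whitespace is trimmed, internal
runs of whitespace collapse to one space, and a single-letter genus
abbreviation is upper-cased (``"c. briggsae"`` ≡ ``"C. briggsae"``). There is
no fuzzy matching — misspellings are distinct names — so counts remain
auditable against the raw file.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

__all__ = [
    "SchemaError",
    "RecordValidationError",
    "SubstrateCategory",
    "BaitType",
    "ExclosureTreatment",
    "CollectionRecord",
    "BaitRecord",
    "ExclosureRecord",
    "normalize_species_name",
    "parse_collections",
    "parse_baits",
    "parse_exclosures",
    "write_collections",
    "write_baits",
    "write_exclosures",
    "filter_records",
]

SPECIES_DELIMITER = ";"


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RecordValidationError(ValueError):
    """A row violates a record invariant (bad enum, duplicate id, ...)."""


class SubstrateCategory(str, Enum):
    FRUIT = "fruit"
    FLOWER = "flower"
    FUNGUS = "fungus"
    LEAF_LITTER = "leaf_litter"
    STEM = "stem"
    OTHER = "other"


class BaitType(str, Enum):
    """The six bait designs of the colonization experiment.

    ``peptone_*`` baits are 1% agar + 5% peptone + 1% glucose;
    ``gustavia_*`` baits are 1% agar + 25% defaunated G. superba flower
    slurry; ``gustavia_raw_ground`` is additionally seeded with fresh
    unsterilized slurry; ``gustavia_mesh`` is covered by 1-mm nylon mesh and
    placed mesh-down. ``*_dish`` baits sit in their plastic petri dish,
    ``*_ground`` baits are in direct contact with the forest floor.
    """

    PEPTONE_DISH = "peptone_dish"
    PEPTONE_GROUND = "peptone_ground"
    GUSTAVIA_DISH = "gustavia_dish"
    GUSTAVIA_GROUND = "gustavia_ground"
    GUSTAVIA_RAW_GROUND = "gustavia_raw_ground"
    GUSTAVIA_MESH = "gustavia_mesh"


#: Bait types whose agar touches the forest floor directly. The mesh bait
#: sits mesh-down on the floor but its agar is only reachable through the
#: mesh, so it is not counted as ground contact.
GROUND_CONTACT_TYPES = frozenset(
    {BaitType.PEPTONE_GROUND, BaitType.GUSTAVIA_GROUND, BaitType.GUSTAVIA_RAW_GROUND}
)


class ExclosureTreatment(str, Enum):
    """Accessibility treatments, most to least accessible."""

    DIRECT_GROUND = "direct_ground"
    OPEN_CUP = "open_cup"
    MESH_4MM = "mesh_4mm"
    MESH_1MM = "mesh_1mm"
    MESH_0P064MM = "mesh_0p064mm"
    MESH_0P01MM = "mesh_0p01mm"


#: Treatment order from most to least accessible (used for report ordering).
TREATMENT_ORDER = tuple(ExclosureTreatment)

_GENUS_ABBREV = re.compile(r"^([A-Za-z])\.?\s+(.+)$")


def normalize_species_name(name: str) -> str:
    """Canonicalize a species-name string.

    Trims/collapses whitespace and upper-cases a one-letter genus
    abbreviation. Full binomials ("Oscheius tipulae") pass through unchanged.
    """
    s = " ".join(str(name).split())
    m = _GENUS_ABBREV.match(s)
    if m:
        return f"{m.group(1).upper()}. {m.group(2)}"
    return s


def _normalized_species_set(values: Iterable[str]) -> frozenset[str]:
    out = frozenset(normalize_species_name(v) for v in values if str(v).strip())
    return out


def is_caenorhabditis(name: str) -> bool:
    """Whether a (normalized) species name belongs to *Caenorhabditis*."""
    s = normalize_species_name(name)
    return s.startswith("C. ") or s.startswith("Caenorhabditis ")


@dataclass(frozen=True)
class CollectionRecord:
    """One sampled substrate patch.

    ``species_present`` holds presence only; within-patch abundance is
    outside the data model. A nonempty species set forces
    ``nematodes_present``.
    """

    sample_id: str
    locality: str
    year: int
    substrate_category: SubstrateCategory
    nematodes_present: bool
    species_present: frozenset[str] = frozenset()
    site: str | None = None
    quadrat: str | None = None
    substrate_taxon: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species_present", _normalized_species_set(self.species_present)
        )
        object.__setattr__(
            self, "substrate_category", SubstrateCategory(self.substrate_category)
        )
        if not str(self.sample_id):
            raise RecordValidationError("sample_id must be nonempty")
        if self.species_present and not self.nematodes_present:
            raise RecordValidationError(
                f"sample {self.sample_id!r}: species recorded but "
                "nematodes_present is false"
            )
        if self.temperature is not None:
            t = float(self.temperature)
            if not math.isfinite(t) or not (-10.0 <= t <= 60.0):
                raise RecordValidationError(
                    f"sample {self.sample_id!r}: temperature {t!r} outside -10..60"
                )


@dataclass(frozen=True)
class BaitRecord:
    """One agar bait of the bait-type experiment.

    Recovery gating: a bait that was not recovered (eaten/removed before
    collection) carries no observations, so all presence fields must be
    false and the species set empty. Unrecovered baits are excluded from
    analysis denominators.
    """

    site: str
    array: str
    bait_type: BaitType
    recovered: bool
    nematodes_present: bool
    caenorhabditis_present: bool
    species_present: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species_present", _normalized_species_set(self.species_present)
        )
        object.__setattr__(self, "bait_type", BaitType(self.bait_type))
        if not self.recovered and (
            self.nematodes_present or self.caenorhabditis_present or self.species_present
        ):
            raise RecordValidationError(
                f"bait {self.site}/{self.array}/{self.bait_type.value}: "
                "observations recorded on an unrecovered bait"
            )
        if self.caenorhabditis_present and not self.nematodes_present:
            raise RecordValidationError(
                f"bait {self.site}/{self.array}/{self.bait_type.value}: "
                "caenorhabditis_present implies nematodes_present"
            )
        if self.species_present and not self.nematodes_present:
            raise RecordValidationError(
                f"bait {self.site}/{self.array}/{self.bait_type.value}: "
                "species recorded but nematodes_present is false"
            )

    @property
    def ground_contact(self) -> bool:
        return self.bait_type in GROUND_CONTACT_TYPES


@dataclass(frozen=True)
class ExclosureRecord:
    """One bait of the size-selective exclosure experiment."""

    site: str
    position: str
    treatment: ExclosureTreatment
    recovered: bool
    nematodes_present: bool
    species_present: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species_present", _normalized_species_set(self.species_present)
        )
        object.__setattr__(self, "treatment", ExclosureTreatment(self.treatment))
        if not self.recovered and (self.nematodes_present or self.species_present):
            raise RecordValidationError(
                f"exclosure bait {self.site}/{self.position}: "
                "observations recorded on an unrecovered bait"
            )
        if self.species_present and not self.nematodes_present:
            raise RecordValidationError(
                f"exclosure bait {self.site}/{self.position}: "
                "species recorded but nematodes_present is false"
            )

    @property
    def caenorhabditis_present(self) -> bool:
        return any(is_caenorhabditis(s) for s in self.species_present)


# ---------------------------------------------------------------------------
# CSV parsing / writing
# ---------------------------------------------------------------------------

_COLLECTION_REQUIRED = (
    "sample_id",
    "locality",
    "year",
    "substrate_category",
    "nematodes_present",
    "species_present",
)
_COLLECTION_OPTIONAL = (
    "site",
    "quadrat",
    "substrate_taxon",
    "latitude",
    "longitude",
    "temperature",
)
_BAIT_REQUIRED = (
    "site",
    "array",
    "bait_type",
    "recovered",
    "nematodes_present",
    "caenorhabditis_present",
    "species_present",
)
_EXCLOSURE_REQUIRED = (
    "site",
    "position",
    "treatment",
    "recovered",
    "nematodes_present",
    "species_present",
)

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RecordValidationError(f"row {row}: column {column!r}: bad boolean {value!r}")


def _parse_optional_float(value: str | None) -> float | None:
    if value is None or not str(value).strip():
        return None
    return float(value)


def _parse_species_cell(value: str | None) -> frozenset[str]:
    if value is None or not str(value).strip():
        return frozenset()
    return _normalized_species_set(str(value).split(SPECIES_DELIMITER))


def _open_source(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(Path(source), newline="", encoding="utf-8"), True


def _reader(source, required: Sequence[str]):
    stream, owned = _open_source(source)
    reader = csv.DictReader(stream)
    header = reader.fieldnames
    if header is None:
        if owned:
            stream.close()
        raise SchemaError("empty input: header row required")
    missing = [c for c in required if c not in header]
    if missing:
        if owned:
            stream.close()
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return stream, owned, reader


def _enum_value(enum_cls, raw: str, column: str, row: int):
    try:
        return enum_cls(str(raw).strip())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise RecordValidationError(
            f"row {row}: column {column!r}: unknown value {raw!r} "
            f"(allowed: {allowed})"
        ) from None


def parse_collections(source) -> list[CollectionRecord]:
    """Parse a collections CSV into validated records.

    ``source`` is a path or an open text stream. Row order is preserved;
    an empty ``species_present`` cell becomes an empty set. Duplicate
    ``sample_id`` values raise :class:`RecordValidationError`.
    """
    stream, owned, reader = _reader(source, _COLLECTION_REQUIRED)
    records: list[CollectionRecord] = []
    seen: set[str] = set()
    try:
        for i, row in enumerate(reader, start=2):
            sid = str(row["sample_id"]).strip()
            if sid in seen:
                raise RecordValidationError(
                    f"row {i}: duplicate sample_id {sid!r}"
                )
            seen.add(sid)
            try:
                rec = CollectionRecord(
                    sample_id=sid,
                    locality=str(row["locality"]).strip(),
                    year=int(row["year"]),
                    substrate_category=_enum_value(
                        SubstrateCategory, row["substrate_category"],
                        "substrate_category", i,
                    ),
                    nematodes_present=_parse_bool(
                        row["nematodes_present"], "nematodes_present", i
                    ),
                    species_present=_parse_species_cell(row.get("species_present")),
                    site=(str(row["site"]).strip() or None) if row.get("site") else None,
                    quadrat=(str(row["quadrat"]).strip() or None)
                    if row.get("quadrat")
                    else None,
                    substrate_taxon=(str(row["substrate_taxon"]).strip() or None)
                    if row.get("substrate_taxon")
                    else None,
                    latitude=_parse_optional_float(row.get("latitude")),
                    longitude=_parse_optional_float(row.get("longitude")),
                    temperature=_parse_optional_float(row.get("temperature")),
                )
            except RecordValidationError:
                raise
            except ValueError as exc:
                raise RecordValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    finally:
        if owned:
            stream.close()
    return records


def parse_baits(source) -> list[BaitRecord]:
    """Parse a bait-experiment CSV into validated records."""
    stream, owned, reader = _reader(source, _BAIT_REQUIRED)
    records: list[BaitRecord] = []
    try:
        for i, row in enumerate(reader, start=2):
            records.append(
                BaitRecord(
                    site=str(row["site"]).strip(),
                    array=str(row["array"]).strip(),
                    bait_type=_enum_value(BaitType, row["bait_type"], "bait_type", i),
                    recovered=_parse_bool(row["recovered"], "recovered", i),
                    nematodes_present=_parse_bool(
                        row["nematodes_present"], "nematodes_present", i
                    ),
                    caenorhabditis_present=_parse_bool(
                        row["caenorhabditis_present"], "caenorhabditis_present", i
                    ),
                    species_present=_parse_species_cell(row.get("species_present")),
                )
            )
    finally:
        if owned:
            stream.close()
    return records


def parse_exclosures(source) -> list[ExclosureRecord]:
    """Parse an exclosure-experiment CSV into validated records."""
    stream, owned, reader = _reader(source, _EXCLOSURE_REQUIRED)
    records: list[ExclosureRecord] = []
    try:
        for i, row in enumerate(reader, start=2):
            records.append(
                ExclosureRecord(
                    site=str(row["site"]).strip(),
                    position=str(row["position"]).strip(),
                    treatment=_enum_value(
                        ExclosureTreatment, row["treatment"], "treatment", i
                    ),
                    recovered=_parse_bool(row["recovered"], "recovered", i),
                    nematodes_present=_parse_bool(
                        row["nematodes_present"], "nematodes_present", i
                    ),
                    species_present=_parse_species_cell(row.get("species_present")),
                )
            )
    finally:
        if owned:
            stream.close()
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, frozenset):
        return SPECIES_DELIMITER.join(sorted(value))
    return str(value)


def _open_dest(dest) -> tuple[IO[str], bool]:
    if hasattr(dest, "write"):
        return dest, False
    return open(Path(dest), "w", newline="", encoding="utf-8"), True


def _write(records, dest, columns: Sequence[str]) -> None:
    stream, owned = _open_dest(dest)
    try:
        writer = csv.writer(stream)
        writer.writerow(columns)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, c)) for c in columns])
    finally:
        if owned:
            stream.close()


def write_collections(records: Iterable[CollectionRecord], dest) -> None:
    """Write collection records as CSV (lossless round-trip with the parser)."""
    _write(records, dest, _COLLECTION_REQUIRED + _COLLECTION_OPTIONAL)


def write_baits(records: Iterable[BaitRecord], dest) -> None:
    _write(records, dest, _BAIT_REQUIRED)


def write_exclosures(records: Iterable[ExclosureRecord], dest) -> None:
    _write(records, dest, _EXCLOSURE_REQUIRED)


def filter_records(
    records: Iterable[CollectionRecord],
    *,
    locality: str | None = None,
    year: int | None = None,
    site: str | None = None,
    substrate_category: SubstrateCategory | str | None = None,
):
    """Subset collection records on hierarchy labels. Idempotent."""
    out = list(records)
    if locality is not None:
        out = [r for r in out if r.locality == locality]
    if year is not None:
        out = [r for r in out if r.year == int(year)]
    if site is not None:
        out = [r for r in out if r.site == site]
    if substrate_category is not None:
        cat = SubstrateCategory(substrate_category)
        out = [r for r in out if r.substrate_category == cat]
    return out
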