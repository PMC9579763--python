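"""Occurrence-table data model, readers/writers and cleaning filters.

A fossil *occurrence* is one record of a taxon at one geographical locality
in one stratigraphic context.  Occurrence tables compiled from the
literature carry known artefacts — taxonomically indeterminate records,
occurrences based on isolated scales or teeth that cannot be attributed
reliably, and inconsistent locality identifiers — which this module removes
or canonicalizes before any diversity estimation.  Every filter appends to
a cleaning log so that raw and cleaned record counts always reconcile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Determinacy",
    "Material",
    "Environment",
    "OccurrenceRecord",
    "CleaningLogEntry",
    "OccurrenceDataset",
    "DatasetSummary",
    "read_occurrences",
    "write_occurrences",
    "filter_indeterminate",
    "filter_material",
    "dedupe_localities",
    "summarize",
]


class Determinacy(str, Enum):
    """How precisely the taxon of a record is identified."""

    SPECIES = "species-determinate"
    GENUS = "genus-determinate"
    INDETERMINATE = "indeterminate"


class Material(str, Enum):
    BODY = "body"
    SCALE = "scale"
    TOOTH = "tooth"
    UNKNOWN = "unknown"


class Environment(str, Enum):
    MARINE = "marine"
    BRACKISH = "brackish"
    FRESHWATER = "freshwater"
    UNKNOWN = "unknown"


# column roles understood by read_occurrences; the first three are required
REQUIRED_ROLES = ("genus", "locality_id", "stratigraphy")
OPTIONAL_ROLES = (
    "occurrence_id",
    "species",
    "determinacy",
    "material",
    "locality_name",
    "modern_lat",
    "modern_lon",
    "palaeo_lat",
    "palaeo_lon",
    "environment",
    "earliest_stage",
    "latest_stage",
    "age_max",
    "age_min",
)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence.

    ``age_max``/``age_min`` are numeric ages in Ma with ``age_max`` the
    older bound; ``earliest_stage``/``latest_stage`` are ICS stage names
    with ``earliest_stage`` the older stage.  Either representation (or
    both) may be present.
    """

    occurrence_id: str
    genus: str | None
    species: str | None
    determinacy: Determinacy
    material: Material
    locality_id: str
    locality_name: str = ""
    modern_lat: float | None = None
    modern_lon: float | None = None
    palaeo_lat: float | None = None
    palaeo_lon: float | None = None
    environment: Environment = Environment.UNKNOWN
    earliest_stage: str | None = None
    latest_stage: str | None = None
    age_max: float | None = None
    age_min: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.age_max is not None and self.age_min is not None:
            if self.age_max < self.age_min:
                problems.append(
                    f"age_max ({self.age_max}) < age_min ({self.age_min})"
                )
        for name, value, lim in (
            ("modern_lat", self.modern_lat, 90.0),
            ("palaeo_lat", self.palaeo_lat, 90.0),
            ("modern_lon", self.modern_lon, 180.0),
            ("palaeo_lon", self.palaeo_lon, 180.0),
        ):
            if value is not None and abs(value) > lim:
                problems.append(f"{name} out of range: {value}")
        if self.determinacy is Determinacy.SPECIES and not (
            self.genus and self.species
        ):
            problems.append(
                "species-determinate record lacks genus or species name"
            )
        return problems

    @property
    def species_binomial(self) -> str | None:
        """'Genus species' for species-determinate records, else None."""
        if self.determinacy is Determinacy.SPECIES:
            return f"{self.genus} {self.species}"
        return None


@dataclass(frozen=True)
class CleaningLogEntry:
    rule: str
    removed: int
    note: str = ""


@dataclass
class OccurrenceDataset:
    """An ordered collection of occurrence records plus its cleaning history."""

    records: list[OccurrenceRecord]
    provenance: str = ""
    cleaning_log: list[CleaningLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.occurrence_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("occurrence_id values must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def with_records(
        self, records: Sequence[OccurrenceRecord], rule: str, removed: int, note: str = ""
    ) -> "OccurrenceDataset":
        """A new dataset with ``records`` and one more cleaning-log entry."""
        return OccurrenceDataset(
            records=list(records),
            provenance=self.provenance,
            cleaning_log=[*self.cleaning_log, CleaningLogEntry(rule, removed, note)],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "occurrence_id": r.occurrence_id,
                    "genus": r.genus,
                    "species": r.species,
                    "determinacy": r.determinacy.value,
                    "material": r.material.value,
                    "locality_id": r.locality_id,
                    "locality_name": r.locality_name,
                    "modern_lat": r.modern_lat,
                    "modern_lon": r.modern_lon,
                    "palaeo_lat": r.palaeo_lat,
                    "palaeo_lon": r.palaeo_lon,
                    "environment": r.environment.value,
                    "earliest_stage": r.earliest_stage,
                    "latest_stage": r.latest_stage,
                    "age_max": r.age_max,
                    "age_min": r.age_min,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "occurrence_id", "genus", "species", "determinacy", "material",
                "locality_id", "locality_name", "modern_lat", "modern_lon",
                "palaeo_lat", "palaeo_lon", "environment", "earliest_stage",
                "latest_stage", "age_max", "age_min",
            ],
        )


@dataclass(frozen=True)
class DatasetSummary:
    n_occurrences: int
    n_species: int
    n_genera: int
    n_localities: int
    per_environment: Mapping[str, int]


def _parse_enum(value: object, enum_cls, default):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    text = str(value).strip().lower()
    if not text:
        return default
    aliases = {
        "species": Determinacy.SPECIES,
        "species-determinate": Determinacy.SPECIES,
        "genus": Determinacy.GENUS,
        "genus-determinate": Determinacy.GENUS,
        "indeterminate": Determinacy.INDETERMINATE,
        "indet": Determinacy.INDETERMINATE,
    }
    if enum_cls is Determinacy and text in aliases:
        return aliases[text]
    try:
        return enum_cls(text)
    except ValueError:
        return default


def _infer_determinacy(genus: str | None, species: str | None) -> Determinacy:
    open_nomenclature = {"sp", "sp.", "spp", "spp.", "indet", "indet."}
    if genus:
        if species and species.strip().lower() not in open_nomenclature:
            return Determinacy.SPECIES
        return Determinacy.GENUS
    return Determinacy.INDETERMINATE


def _clean_text(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _parse_float(value: object, role: str, problems: list[str]) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        problems.append(f"unparseable {role}: {text!r}")
        return None


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str],
    *,
    strict: bool = True,
    provenance: str | None = None,
) -> OccurrenceDataset:
    """Read an occurrence CSV/TSV into an :class:`OccurrenceDataset`.

    Parameters
    ----------
    path:
        CSV or TSV file (delimiter chosen by extension, ``.tsv``/``.tab``
        meaning tab).
    column_map:
        Mapping of column *roles* to column names in the file.  Required
        roles: ``genus``, ``locality_id`` and stratigraphy (either
        ``earliest_stage``/``latest_stage`` or ``age_max``/``age_min``).
    strict:
        When True (default) any malformed row raises; when False malformed
        rows are dropped and logged in the cleaning log.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)

    for role in ("genus", "locality_id"):
        col = column_map.get(role)
        if col is None or col not in frame.columns:
            raise ValueError(f"required column role {role!r} is missing or unmapped")
    has_stages = all(
        column_map.get(r) in frame.columns for r in ("earliest_stage", "latest_stage")
    )
    has_ages = all(column_map.get(r) in frame.columns for r in ("age_max", "age_min"))
    if not (has_stages or has_ages):
        raise ValueError(
            "required column role 'stratigraphy' is missing: map either "
            "earliest_stage/latest_stage or age_max/age_min"
        )

    def cell(row: pd.Series, role: str) -> object:
        col = column_map.get(role)
        if col is None or col not in frame.columns:
            return None
        return row[col]

    records: list[OccurrenceRecord] = []
    dropped: list[str] = []
    for idx, row in frame.iterrows():
        problems: list[str] = []
        genus = _clean_text(cell(row, "genus"))
        species = _clean_text(cell(row, "species"))
        det = cell(row, "determinacy")
        determinacy = (
            _parse_enum(det, Determinacy, None)
            if column_map.get("determinacy")
            else None
        )
        if determinacy is None:
            determinacy = _infer_determinacy(genus, species)
        rec = OccurrenceRecord(
            occurrence_id=_clean_text(cell(row, "occurrence_id")) or f"row{idx}",
            genus=genus,
            species=species,
            determinacy=determinacy,
            material=_parse_enum(cell(row, "material"), Material, Material.UNKNOWN),
            locality_id=_clean_text(cell(row, "locality_id")) or "",
            locality_name=_clean_text(cell(row, "locality_name")) or "",
            modern_lat=_parse_float(cell(row, "modern_lat"), "modern_lat", problems),
            modern_lon=_parse_float(cell(row, "modern_lon"), "modern_lon", problems),
            palaeo_lat=_parse_float(cell(row, "palaeo_lat"), "palaeo_lat", problems),
            palaeo_lon=_parse_float(cell(row, "palaeo_lon"), "palaeo_lon", problems),
            environment=_parse_enum(
                cell(row, "environment"), Environment, Environment.UNKNOWN
            ),
            earliest_stage=_clean_text(cell(row, "earliest_stage")),
            latest_stage=_clean_text(cell(row, "latest_stage")),
            age_max=_parse_float(cell(row, "age_max"), "age_max", problems),
            age_min=_parse_float(cell(row, "age_min"), "age_min", problems),
        )
        problems.extend(rec.validate())
        if not rec.locality_id:
            problems.append("empty locality_id")
        if problems:
            message = f"row {idx}: " + "; ".join(problems)
            if strict:
                raise ValueError(message)
            dropped.append(message)
            continue
        records.append(rec)

    ds = OccurrenceDataset(records=records, provenance=provenance or str(path))
    if dropped:
        ds.cleaning_log.append(
            CleaningLogEntry("drop-malformed-rows", len(dropped), " | ".join(dropped))
        )
    return ds


def write_occurrences(ds: OccurrenceDataset, path: str | Path) -> None:
    """Write the dataset as CSV plus a ``<name>.cleaning_log.csv`` sidecar."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(".cleaning_log.csv")
    with open(sidecar, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["rule", "removed", "note"])
        for entry in ds.cleaning_log:
            writer.writerow([entry.rule, entry.removed, entry.note])


def filter_indeterminate(
    ds: OccurrenceDataset, rank: str = "genus"
) -> OccurrenceDataset:
    """Drop taxonomically indeterminate records.

    For both ``rank='genus'`` and ``rank='species'`` only fully
    indeterminate records are removed: genus-determinate records ("Genus
    sp.") are retained even for species-level analyses, because they are
    resolved at counting time by the taxonomic-hierarchy rule (a "Genus
    sp." only counts where no determinate species of that genus is present
    at the same locality).
    """
    if rank not in {"genus", "species"}:
        raise ValueError(f"rank must be 'genus' or 'species', got {rank!r}")
    kept = [r for r in ds.records if r.determinacy is not Determinacy.INDETERMINATE]
    return ds.with_records(
        kept, f"filter-indeterminate[{rank}]", len(ds.records) - len(kept)
    )


def filter_material(ds: OccurrenceDataset) -> OccurrenceDataset:
    """Drop scale- and tooth-based occurrences.

    Isolated scales and teeth are hard to attribute to a taxon and may be
    morphotypes of one body taxon, so they are excluded.  Records with
    unknown material are retained (only positively identified scale/tooth
    records are removed); their count is noted in the log.
    """
    kept = [
        r for r in ds.records if r.material not in (Material.SCALE, Material.TOOTH)
    ]
    n_unknown = sum(1 for r in kept if r.material is Material.UNKNOWN)
    note = f"{n_unknown} record(s) with unknown material retained" if n_unknown else ""
    return ds.with_records(
        kept, "filter-scale-tooth", len(ds.records) - len(kept), note
    )


def dedupe_localities(
    ds: OccurrenceDataset,
    policy: str = "by-id",
    *,
    coord_tolerance: float = 0.01,
) -> tuple[OccurrenceDataset, int, list[str]]:
    """Canonicalize locality identifiers and count distinct localities.

    ``policy='by-id'`` trusts the supplied ``locality_id`` (identity
    follows the id, not stratigraphy, so a single geographical locality
    with several horizons stays one locality while one horizon cropping
    out at several sites stays several).  ``policy='by-name-and-coords'``
    merges records sharing a locality name whose coordinates agree within
    ``coord_tolerance`` degrees.

    Returns ``(dataset, n_distinct_localities, warnings)``.
    """
    warnings: list[str] = []
    if policy == "by-id":
        groups: dict[str, list[OccurrenceRecord]] = {}
        for r in ds.records:
            groups.setdefault(r.locality_id, []).append(r)
        for loc_id, recs in groups.items():
            coords = {
                (r.modern_lat, r.modern_lon)
                for r in recs
                if r.modern_lat is not None and r.modern_lon is not None
            }
            if len(coords) > 1:
                lats = [c[0] for c in coords]
                lons = [c[1] for c in coords]
                if (max(lats) - min(lats) > coord_tolerance
                        or max(lons) - min(lons) > coord_tolerance):
                    warnings.append(
                        f"locality {loc_id!r}: conflicting coordinates "
                        f"beyond {coord_tolerance} degrees"
                    )
        out = ds.with_records(list(ds.records), "dedupe-localities[by-id]", 0)
        return out, len(groups), warnings

    if policy != "by-name-and-coords":
        raise ValueError(f"unknown dedupe policy {policy!r}")

    # greedy clustering per name: a record joins the first cluster whose
    # anchor coordinates are within tolerance
    clusters: list[tuple[str, float | None, float | None, str]] = []
    canonical: dict[str, str] = {}
    for r in ds.records:
        name = r.locality_name or r.locality_id
        assigned = None
        for cname, clat, clon, cid in clusters:
            if cname != name:
                continue
            if r.modern_lat is None or clat is None:
                assigned = cid
                break
            if (abs(r.modern_lat - clat) <= coord_tolerance
                    and abs((r.modern_lon or 0.0) - (clon or 0.0)) <= coord_tolerance):
                assigned = cid
                break
        if assigned is None:
            assigned = f"{name}#{sum(1 for c in clusters if c[0] == name) + 1}"
            clusters.append((name, r.modern_lat, r.modern_lon, assigned))
        canonical[r.occurrence_id] = assigned

    new_records = [
        replace(r, locality_id=canonical[r.occurrence_id]) for r in ds.records
    ]
    out = ds.with_records(new_records, "dedupe-localities[by-name-and-coords]", 0)
    return out, len(clusters), warnings


def summarize(ds: OccurrenceDataset) -> DatasetSummary:
    """Headline counts of a (cleaned) dataset.

    Species and genus tallies use determinate names only: species are
    distinct binomials among species-determinate records, genera are
    distinct genus names among genus- or species-determinate records.
    """
    species = {
        r.species_binomial for r in ds.records if r.species_binomial is not None
    }
    genera = {
        r.genus
        for r in ds.records
        if r.genus and r.determinacy is not Determinacy.INDETERMINATE
    }
    localities = {r.locality_id for r in ds.records}
    per_env: dict[str, int] = {}
    for r in ds.records:
        per_env[r.environment.value] = per_env.get(r.environment.value, 0) + 1
    return DatasetSummary(
        n_occurrences=len(ds.records),
        n_species=len(species),
        n_genera=len(genera),
        n_localities=len(localities),
        per_environment=per_env,
    )
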