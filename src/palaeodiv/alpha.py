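"""Local (alpha) richness per locality, environment splits and map tables.

Species per locality is the local-richness measure.  Occurrences
indeterminate at species level are retained following the taxonomic
hierarchy of the Paleobiology Database: a genus-determinate record
("Genus sp.") contributes one species to a locality only when no
determinate species of the same genus occurs there.  Local richness uses
midpoint-assigned bins so that age-uncertain occurrences still
contribute; diversity estimation (see :mod:`palaeodiv.estimators`)
restricts to single-bin records instead — two views over one dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binning import AssignmentFlag, BinAssignment, BinScheme
from .occurrences import Determinacy, Environment, OccurrenceDataset

__all__ = [
    "LocalityRichness",
    "count_local_richness",
    "environment_split",
    "palaeolat_profile",
    "map_tables",
    "southern_hemisphere_share",
    "hierarchy_species_count",
]

_MARINE_LIKE = {Environment.MARINE, Environment.BRACKISH}


@dataclass(frozen=True)
class LocalityRichness:
    locality_id: str
    bin_name: str
    n_species: int
    n_genera: int
    environment_class: str  # marine | freshwater | mixed | unknown
    palaeo_lat: float | None = None
    palaeo_lon: float | None = None
    n_records: int = 0


def hierarchy_species_count(records: Sequence) -> tuple[int, int]:
    """(n_species, n_genera) for one locality under the hierarchy rule.

    Species = distinct determinate binomials plus one per genus that is
    only represented by genus-determinate records; genera = distinct
    determinate genus names.
    """
    det_species = {r.species_binomial for r in records if r.species_binomial}
    det_genera = {r.genus for r in records if r.determinacy is Determinacy.SPECIES}
    genus_only = {
        r.genus for r in records
        if r.determinacy is Determinacy.GENUS and r.genus
    }
    n_species = len(det_species) + len(genus_only - det_genera)
    n_genera = len(det_genera | genus_only)
    return n_species, n_genera


def _class_of(records: Sequence) -> str:
    envs = {r.environment for r in records if r.environment is not Environment.UNKNOWN}
    if not envs:
        return "unknown"
    if envs <= _MARINE_LIKE:
        return "marine"
    if envs == {Environment.FRESHWATER}:
        return "freshwater"
    return "mixed"


def _first_palaeo(records: Sequence) -> tuple[float | None, float | None]:
    for r in records:
        if r.palaeo_lat is not None and r.palaeo_lon is not None:
            return r.palaeo_lat, r.palaeo_lon
    for r in records:
        if r.palaeo_lat is not None:
            return r.palaeo_lat, None
    return None, None


def count_local_richness(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
) -> list[LocalityRichness]:
    """Per (locality, bin) richness under the hierarchy rule.

    ``assignment`` is normally a midpoint assignment so that age-uncertain
    records contribute; both single-bin and midpoint-assigned records are
    counted.
    """
    per_bin = assignment.records_in_bins(
        ds, (AssignmentFlag.SINGLE_BIN, AssignmentFlag.MIDPOINT)
    )
    out: list[LocalityRichness] = []
    for bin_name in sorted(per_bin):
        by_loc: dict[str, list] = {}
        for rec in per_bin[bin_name]:
            by_loc.setdefault(rec.locality_id, []).append(rec)
        for loc in sorted(by_loc):
            recs = by_loc[loc]
            n_sp, n_gen = hierarchy_species_count(recs)
            if n_sp == 0:
                continue  # only indeterminate records at this locality
            lat, lon = _first_palaeo(recs)
            out.append(
                LocalityRichness(
                    locality_id=loc,
                    bin_name=bin_name,
                    n_species=n_sp,
                    n_genera=n_gen,
                    environment_class=_class_of(recs),
                    palaeo_lat=lat,
                    palaeo_lon=lon,
                    n_records=len(recs),
                )
            )
    return out


def environment_split(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
) -> tuple[list[LocalityRichness], list[LocalityRichness], int]:
    """Marine and freshwater local-richness views.

    Brackish records pool with marine.  Localities with records of both
    classes appear in both subsets with class-specific recounts; records
    of unknown environment are excluded and their count returned as the
    third element.
    """
    marine_records, fresh_records, n_unknown = [], [], 0
    for rec in ds.records:
        if rec.environment in _MARINE_LIKE:
            marine_records.append(rec)
        elif rec.environment is Environment.FRESHWATER:
            fresh_records.append(rec)
        else:
            n_unknown += 1
    marine = count_local_richness(
        OccurrenceDataset(records=marine_records, provenance=ds.provenance),
        assignment,
    )
    fresh = count_local_richness(
        OccurrenceDataset(records=fresh_records, provenance=ds.provenance),
        assignment,
    )
    return marine, fresh, n_unknown


def palaeolat_profile(
    rich: Iterable[LocalityRichness],
) -> tuple[pd.DataFrame, int]:
    """(table, n_dropped): one row per locality per bin with palaeolatitude
    and richness, for latitude-through-time plotting."""
    rows, dropped = [], 0
    for lr in rich:
        if lr.palaeo_lat is None:
            dropped += 1
            continue
        rows.append(
            {
                "bin": lr.bin_name,
                "locality_id": lr.locality_id,
                "palaeo_lat": lr.palaeo_lat,
                "n_species": lr.n_species,
                "n_genera": lr.n_genera,
                "environment_class": lr.environment_class,
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=["bin", "locality_id", "palaeo_lat", "n_species",
                     "n_genera", "environment_class"],
        ),
        dropped,
    )


def map_tables(
    rich: Iterable[LocalityRichness],
    scheme: BinScheme,
    ambiguous: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-bin map-ready tables of (palaeo_lat, palaeo_lon, n_genera).

    ``ambiguous`` maps locality ids whose age is uncertain between two
    adjacent bins to that bin pair; those localities are duplicated into
    both bins' tables so either palaeogeographic map shows them.
    """
    ambiguous = ambiguous or {}
    rows_by_bin: dict[str, list[dict]] = {name: [] for name in scheme.names()}
    for lr in rich:
        row = {
            "locality_id": lr.locality_id,
            "palaeo_lat": lr.palaeo_lat,
            "palaeo_lon": lr.palaeo_lon,
            "n_genera": lr.n_genera,
            "n_species": lr.n_species,
            "duplicated": lr.locality_id in ambiguous,
        }
        targets = ambiguous.get(lr.locality_id, (lr.bin_name,))
        for bin_name in targets:
            if bin_name in rows_by_bin:
                rows_by_bin[bin_name].append(dict(row))
    return {
        name: pd.DataFrame(
            rows,
            columns=["locality_id", "palaeo_lat", "palaeo_lon",
                     "n_genera", "n_species", "duplicated"],
        )
        for name, rows in rows_by_bin.items()
    }


def southern_hemisphere_share(ds: OccurrenceDataset) -> float | None:
    """Share of distinct localities at negative *modern* latitude."""
    lat_by_loc: dict[str, float] = {}
    for r in ds.records:
        if r.modern_lat is not None:
            lat_by_loc.setdefault(r.locality_id, r.modern_lat)
    if not lat_by_loc:
        return None
    south = sum(1 for lat in lat_by_loc.values() if lat < 0)
    return south / len(lat_by_loc)
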