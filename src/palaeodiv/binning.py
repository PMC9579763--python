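"""ICS stage table and roughly equal-length (~9 Ma) analysis bins.

Raw stratigraphic stages vary widely in duration (3.3 Ma for the
Kasimovian against 15.8 Ma for the Visean), which confounds per-interval
comparisons.  Short neighbouring stages are therefore merged (e.g.
Kasimovian + Gzhelian -> one 8.1 Ma bin) and long stages split (the Visean
into an early Chadian-Holkerian and a late Asbian-Brigantian part, the
split age defaulting to the Dunsapie-basalt-calibrated 338.0 Ma so the two
halves last 8.7 and 7.1 Ma).

Occurrences whose stratigraphic range sits inside exactly one bin are
"single-bin" and enter diversity estimation; records spanning bins are
either excluded ("multi-bin") or, for local-richness and map purposes,
placed in the bin containing the midpoint of their age range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .occurrences import OccurrenceDataset, OccurrenceRecord

__all__ = [
    "Stage",
    "StageTable",
    "Bin",
    "BinScheme",
    "AssignmentFlag",
    "Assignment",
    "BinAssignment",
    "load_default_stages",
    "build_equal_length_scheme",
    "assign_single_bin",
    "assign_midpoint",
    "DEFAULT_VISEAN_SPLIT_MA",
]

# age of the early/late Visean boundary, giving 8.7 + 7.1 Ma halves
DEFAULT_VISEAN_SPLIT_MA = 338.0

_AGE_EPS = 1e-9


@dataclass(frozen=True)
class Stage:
    name: str
    base_ma: float  # older boundary
    top_ma: float   # younger boundary

    @property
    def duration(self) -> float:
        return self.base_ma - self.top_ma


class StageTable:
    """Ordered, contiguous ICS stages from oldest to youngest."""

    def __init__(self, stages: Iterable[Stage]):
        self.stages = list(stages)
        if not self.stages:
            raise ValueError("stage table is empty")
        for s in self.stages:
            if s.duration <= 0:
                raise ValueError(f"stage {s.name!r} has non-positive duration")
        for older, younger in zip(self.stages, self.stages[1:]):
            if abs(older.top_ma - younger.base_ma) > 1e-6:
                raise ValueError(
                    f"stages {older.name!r} and {younger.name!r} are not contiguous"
                )
        self._by_name = {s.name.lower(): s for s in self.stages}

    @classmethod
    def from_csv(cls, path: str | Path) -> "StageTable":
        frame = pd.read_csv(path)
        return cls(
            Stage(str(r.stage), float(r.base_ma), float(r.top_ma))
            for r in frame.itertuples()
        )

    def __iter__(self) -> Iterator[Stage]:
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def get(self, name: str) -> Stage:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise KeyError(f"stage {name!r} not in stage table") from None

    def index(self, name: str) -> int:
        stage = self.get(name)
        return self.stages.index(stage)

    def age_range(self, earliest: str, latest: str) -> tuple[float, float]:
        """(base_ma, top_ma) spanned by an earliest-to-latest stage range."""
        e, l = self.get(earliest), self.get(latest)
        if self.stages.index(e) > self.stages.index(l):
            raise ValueError(
                f"earliest_stage {earliest!r} is younger than latest_stage {latest!r}"
            )
        return e.base_ma, l.top_ma

    @property
    def span(self) -> float:
        return self.stages[0].base_ma - self.stages[-1].top_ma


def load_default_stages() -> StageTable:
    """The packaged ICS stage boundary table (2018 chart vintage)."""
    with resources.as_file(
        resources.files("palaeodiv.data").joinpath("ics_stages.csv")
    ) as path:
        return StageTable.from_csv(path)


@dataclass(frozen=True)
class Bin:
    name: str
    members: tuple[str, ...]  # stage names or sub-stage span descriptions
    base_ma: float
    top_ma: float

    @property
    def duration(self) -> float:
        return self.base_ma - self.top_ma

    def contains_range(self, base: float, top: float) -> bool:
        return top >= self.top_ma - _AGE_EPS and base <= self.base_ma + _AGE_EPS

    def overlaps_range(self, base: float, top: float) -> bool:
        return base > self.top_ma + _AGE_EPS and top < self.base_ma - _AGE_EPS


class BinScheme:
    """Ordered, contiguous analysis bins from oldest to youngest."""

    def __init__(self, bins: Iterable[Bin]):
        self.bins = list(bins)
        if not self.bins:
            raise ValueError("bin scheme is empty")
        for older, younger in zip(self.bins, self.bins[1:]):
            if abs(older.top_ma - younger.base_ma) > 1e-6:
                raise ValueError(
                    f"bins {older.name!r} and {younger.name!r} are not contiguous"
                )
        self._by_name = {b.name: b for b in self.bins}

    def __iter__(self) -> Iterator[Bin]:
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def __getitem__(self, name: str) -> Bin:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    def index(self, name: str) -> int:
        return self.bins.index(self._by_name[name])

    def bin_for_age(self, age_ma: float) -> Bin | None:
        """Bin containing a point age; a boundary age goes to the older bin."""
        oldest = self.bins[0]
        if abs(age_ma - oldest.base_ma) <= _AGE_EPS:
            return oldest
        for b in self.bins:
            if b.top_ma <= age_ma < b.base_ma:
                return b
        return None

    def bins_for_range(self, base: float, top: float) -> list[Bin]:
        hits = [b for b in self.bins if b.overlaps_range(base, top)]
        if hits:
            return hits
        # zero-duration range (point age): fall back to the point rule
        b = self.bin_for_age((base + top) / 2.0)
        return [b] if b is not None else []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [b.name for b in self.bins],
                "members": ["; ".join(b.members) for b in self.bins],
                "base_ma": [b.base_ma for b in self.bins],
                "top_ma": [b.top_ma for b in self.bins],
                "duration_ma": [b.duration for b in self.bins],
            }
        )


# the standard grouping from Eifelian & Givetian to Wuchiapingian &
# Changhsingian; "VISEAN_SPLIT" is replaced by the two Visean halves
_STANDARD_GROUPS: list[tuple[str, tuple[str, ...]]] = [
    ("Eifelian & Givetian", ("Eifelian", "Givetian")),
    ("Frasnian", ("Frasnian",)),
    ("Famennian", ("Famennian",)),
    ("Tournaisian", ("Tournaisian",)),
    ("VISEAN_SPLIT", ("Visean",)),
    ("Serpukhovian", ("Serpukhovian",)),
    ("Bashkirian", ("Bashkirian",)),
    ("Moscovian", ("Moscovian",)),
    ("Kasimovian & Gzhelian", ("Kasimovian", "Gzhelian")),
    ("Asselian & Sakmarian", ("Asselian", "Sakmarian")),
    ("Artinskian", ("Artinskian",)),
    ("Kungurian", ("Kungurian",)),
    ("Roadian & Wordian", ("Roadian", "Wordian")),
    ("Capitanian", ("Capitanian",)),
    ("Wuchiapingian & Changhsingian", ("Wuchiapingian", "Changhsingian")),
]


def build_equal_length_scheme(
    stages: StageTable | None = None,
    *,
    visean_split_ma: float = DEFAULT_VISEAN_SPLIT_MA,
) -> BinScheme:
    """The 16-bin roughly equal-length scheme, Eifelian & Givetian through
    Wuchiapingian & Changhsingian.

    Short stages are merged and the Visean is split at ``visean_split_ma``
    into an early (Chadian-Holkerian) and a late (Asbian-Brigantian) bin.
    Raises KeyError naming any stage missing from ``stages``.
    """
    if stages is None:
        stages = load_default_stages()
    bins: list[Bin] = []
    for name, members in _STANDARD_GROUPS:
        if name == "VISEAN_SPLIT":
            visean = stages.get("Visean")
            if not (visean.top_ma < visean_split_ma < visean.base_ma):
                raise ValueError(
                    f"visean_split_ma={visean_split_ma} outside the Visean "
                    f"({visean.base_ma}-{visean.top_ma} Ma)"
                )
            bins.append(
                Bin("early Visean", ("Visean (Chadian-Holkerian)",),
                    visean.base_ma, visean_split_ma)
            )
            bins.append(
                Bin("late Visean", ("Visean (Asbian-Brigantian)",),
                    visean_split_ma, visean.top_ma)
            )
            continue
        member_stages = [stages.get(m) for m in members]  # KeyError if absent
        bins.append(
            Bin(
                name,
                members,
                max(s.base_ma for s in member_stages),
                min(s.top_ma for s in member_stages),
            )
        )
    return BinScheme(bins)


class AssignmentFlag(str, Enum):
    SINGLE_BIN = "single-bin"
    MULTI_BIN = "multi-bin"
    MIDPOINT = "midpoint-assigned"
    UNASSIGNABLE = "unassignable"


@dataclass(frozen=True)
class Assignment:
    occurrence_id: str
    bin_name: str | None
    flag: AssignmentFlag
    reason: str = ""
    candidate_bins: tuple[str, ...] = ()


class BinAssignment(Mapping[str, Assignment]):
    """occurrence_id -> Assignment, with convenience views."""

    def __init__(self, assignments: Iterable[Assignment]):
        self._by_id = {a.occurrence_id: a for a in assignments}

    def __getitem__(self, occurrence_id: str) -> Assignment:
        return self._by_id[occurrence_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def records_in_bins(
        self, ds: OccurrenceDataset, flags: tuple[AssignmentFlag, ...]
    ) -> dict[str, list[OccurrenceRecord]]:
        """bin name -> records whose assignment flag is in ``flags``."""
        out: dict[str, list[OccurrenceRecord]] = {}
        for rec in ds.records:
            a = self._by_id.get(rec.occurrence_id)
            if a is None or a.bin_name is None or a.flag not in flags:
                continue
            out.setdefault(a.bin_name, []).append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "occurrence_id": list(self._by_id),
                "bin": [a.bin_name for a in self._by_id.values()],
                "flag": [a.flag.value for a in self._by_id.values()],
                "reason": [a.reason for a in self._by_id.values()],
                "candidate_bins": [
                    "; ".join(a.candidate_bins) for a in self._by_id.values()
                ],
            }
        )


def _record_age_range(
    rec: OccurrenceRecord, stages: StageTable
) -> tuple[float, float] | str:
    """(base_ma, top_ma) of a record, or a reason string when undeterminable."""
    if rec.age_max is not None and rec.age_min is not None:
        return rec.age_max, rec.age_min
    if rec.earliest_stage and rec.latest_stage:
        try:
            return stages.age_range(rec.earliest_stage, rec.latest_stage)
        except KeyError as err:
            return str(err)
        except ValueError as err:
            return str(err)
    if rec.earliest_stage:
        try:
            s = stages.get(rec.earliest_stage)
            return s.base_ma, s.top_ma
        except KeyError as err:
            return str(err)
    return "no stratigraphic range (stages or numeric ages) available"


def assign_single_bin(
    ds: OccurrenceDataset,
    scheme: BinScheme,
    stages: StageTable | None = None,
) -> BinAssignment:
    """Assign records whose whole stratigraphic range fits one bin.

    Records spanning more than one bin are flagged multi-bin (their
    candidate bins recorded, so a range that is ambiguous between exactly
    two adjacent bins can be plotted in both); records with unknown stages
    are unassignable.  Only single-bin records enter diversity estimation.
    """
    if stages is None:
        stages = load_default_stages()
    assignments = []
    for rec in ds.records:
        rng = _record_age_range(rec, stages)
        if isinstance(rng, str):
            assignments.append(
                Assignment(rec.occurrence_id, None, AssignmentFlag.UNASSIGNABLE, rng)
            )
            continue
        base, top = rng
        hits = scheme.bins_for_range(base, top)
        if len(hits) == 1 and hits[0].contains_range(base, top):
            assignments.append(
                Assignment(
                    rec.occurrence_id, hits[0].name, AssignmentFlag.SINGLE_BIN,
                    candidate_bins=(hits[0].name,),
                )
            )
        elif not hits:
            assignments.append(
                Assignment(
                    rec.occurrence_id, None, AssignmentFlag.UNASSIGNABLE,
                    f"range {base}-{top} Ma outside the bin scheme",
                )
            )
        else:
            assignments.append(
                Assignment(
                    rec.occurrence_id, None, AssignmentFlag.MULTI_BIN,
                    candidate_bins=tuple(b.name for b in hits),
                )
            )
    return BinAssignment(assignments)


def assign_midpoint(
    ds: OccurrenceDataset,
    scheme: BinScheme,
    stages: StageTable | None = None,
) -> BinAssignment:
    """Assign every datable record to the bin containing its age-range
    midpoint.

    Records already attributable to a single bin keep the single-bin flag;
    range-spanning records are flagged midpoint-assigned.  A midpoint
    falling exactly on a bin boundary goes to the older bin.  This view is
    used for local richness and maps; it never yields multi-bin.
    """
    if stages is None:
        stages = load_default_stages()
    single = assign_single_bin(ds, scheme, stages)
    assignments = []
    for rec in ds.records:
        prior = single[rec.occurrence_id]
        if prior.flag is AssignmentFlag.SINGLE_BIN:
            assignments.append(prior)
            continue
        rng = _record_age_range(rec, stages)
        if isinstance(rng, str):
            assignments.append(
                Assignment(rec.occurrence_id, None, AssignmentFlag.UNASSIGNABLE, rng)
            )
            continue
        base, top = rng
        mid = (base + top) / 2.0
        b = scheme.bin_for_age(mid)
        if b is None:
            assignments.append(
                Assignment(
                    rec.occurrence_id, None, AssignmentFlag.UNASSIGNABLE,
                    f"midpoint {mid} Ma outside the bin scheme",
                )
            )
        else:
            assignments.append(
                Assignment(
                    rec.occurrence_id, b.name, AssignmentFlag.MIDPOINT,
                    candidate_bins=prior.candidate_bins,
                )
            )
    return BinAssignment(assignments)
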