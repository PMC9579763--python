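"""Evenness, rank-occurrence, waste-basket and sampling diagnostics.

Coverage-standardized richness estimates carry a strong evenness signal:
intervals dominated by a few very frequent taxa plus a long tail of
singletons receive depressed low-quorum estimates, while singleton-rich
intervals inflate the squares extrapolator.  The diagnostics here
quantify that structure per time bin — rank-occurrence distributions,
singleton/doubleton proportions, the occurrence share of historically
over-inclusive "waste-basket" genera, and a range-through sampling
probability — so estimate tables can be read against the biases that
shape them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binning import AssignmentFlag, BinAssignment, BinScheme
from .estimators import AbundanceCounts, goods_u
from .occurrences import Determinacy, Environment, OccurrenceDataset

__all__ = [
    "RankOccurrenceDistribution",
    "rank_distribution",
    "wastebasket_share",
    "mean_rank",
    "sampling_probability",
    "load_default_wastebasket",
    "diagnostics_table",
]


def load_default_wastebasket() -> list[str]:
    """The shipped default list of waste-basket genera (overridable)."""
    text = (
        resources.files("palaeodiv.data")
        .joinpath("wastebasket_genera.txt")
        .read_text()
    )
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class RankOccurrenceDistribution:
    """Occurrence counts per taxon sorted descending (rank 1 = most frequent).

    Ties are broken alphabetically by taxon name, so the ordering is
    stable across runs and platforms.
    """

    bin_name: str
    rank: str
    taxa: tuple[str, ...]
    counts: tuple[int, ...]

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def singleton_proportion(self) -> float | None:
        if self.is_empty:
            return None
        return sum(1 for c in self.counts if c == 1) / len(self.counts)

    @property
    def doubleton_proportion(self) -> float | None:
        if self.is_empty:
            return None
        return sum(1 for c in self.counts if c == 2) / len(self.counts)

    def dominance(self, k: int = 1) -> float | None:
        """Share of occurrences held by the top-k taxa."""
        if self.is_empty:
            return None
        return sum(self.counts[:k]) / self.n

    def rank_of(self, taxon: str) -> int | None:
        try:
            return self.taxa.index(taxon) + 1
        except ValueError:
            return None


def rank_distribution(ab: AbundanceCounts) -> RankOccurrenceDistribution:
    """Sort a bin's taxon occurrence counts into a rank distribution."""
    items = sorted(ab.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankOccurrenceDistribution(
        bin_name=ab.bin_name,
        rank=ab.rank,
        taxa=tuple(k for k, _ in items),
        counts=tuple(v for _, v in items),
    )


def wastebasket_share(
    ab: AbundanceCounts, genus_list: Sequence[str] | None = None
) -> float:
    """Share of a bin's occurrences belonging to the listed genera.

    For species-rank counts a taxon belongs to a listed genus when its
    name starts with that genus.  Additive over disjoint genus lists.
    """
    if genus_list is None:
        genus_list = load_default_wastebasket()
    if ab.n == 0:
        return 0.0
    listed = set(genus_list)
    total = 0
    for taxon, count in ab.counts.items():
        genus = taxon.split(" ")[0]
        if genus in listed:
            total += count
    return total / ab.n


def mean_wastebasket_share(
    abundance_by_bin: Mapping[str, AbundanceCounts],
    genus_list: Sequence[str] | None = None,
    bins: Sequence[str] | None = None,
) -> float | None:
    """Mean waste-basket share across bins (optionally a named subset)."""
    names = list(bins) if bins is not None else list(abundance_by_bin)
    shares = [
        wastebasket_share(abundance_by_bin[b], genus_list)
        for b in names
        if b in abundance_by_bin and abundance_by_bin[b].n > 0
    ]
    if not shares:
        return None
    return sum(shares) / len(shares)


def mean_rank(
    abundance_by_bin: Mapping[str, AbundanceCounts],
    genus_list: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Mean rank position of each listed genus across the bins where it
    occurs (rank 1 = most frequent); None where a genus is absent from
    every bin."""
    if genus_list is None:
        genus_list = load_default_wastebasket()
    out: dict[str, float | None] = {}
    dists = {b: rank_distribution(ab) for b, ab in abundance_by_bin.items()}
    for genus in genus_list:
        ranks = []
        for dist in dists.values():
            r = dist.rank_of(genus)
            if r is not None:
                ranks.append(r)
        out[genus] = sum(ranks) / len(ranks) if ranks else None
    return out


def sampling_probability(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
    scheme: BinScheme,
    environments: set[Environment] | None = None,
) -> tuple[dict[str, float | None], float | None]:
    """Range-through sampling probability per bin and its average.

    A genus is range-through in a bin when the bin lies between its first
    and last sampled bins (endpoints included).  The per-bin probability
    is the fraction of range-through genera actually sampled there; bins
    with no range-through genera are undefined and excluded from the
    average.  This occupancy definition is one defensible reading of
    per-interval sampling probability; see the package methods note.
    """
    records = ds.records
    if environments is not None:
        records = [r for r in records if r.environment in environments]
    sub = OccurrenceDataset(records=list(records), provenance=ds.provenance)
    per_bin = assignment.records_in_bins(sub, (AssignmentFlag.SINGLE_BIN,))
    order = scheme.names()
    presence: dict[str, set[int]] = {}
    for bin_name, recs in per_bin.items():
        idx = order.index(bin_name)
        for rec in recs:
            if rec.genus and rec.determinacy is not Determinacy.INDETERMINATE:
                presence.setdefault(rec.genus, set()).add(idx)
    per_bin_prob: dict[str, float | None] = {}
    for i, bin_name in enumerate(order):
        through = [g for g, bins in presence.items()
                   if min(bins) <= i <= max(bins)]
        if not through:
            per_bin_prob[bin_name] = None
            continue
        sampled = sum(1 for g in through if i in presence[g])
        per_bin_prob[bin_name] = sampled / len(through)
    defined = [p for p in per_bin_prob.values() if p is not None]
    average = sum(defined) / len(defined) if defined else None
    return per_bin_prob, average


def diagnostics_table(
    abundance_by_bin: Mapping[str, AbundanceCounts],
    scheme: BinScheme,
    genus_list: Sequence[str] | None = None,
    sampling: Mapping[str, float | None] | None = None,
) -> pd.DataFrame:
    """Per-bin diagnostics: singleton/doubleton proportions, top-2
    dominance, Good's u, waste-basket share and (optionally) sampling
    probability."""
    rows = []
    for bin_name in scheme.names():
        ab = abundance_by_bin.get(bin_name)
        if ab is None or ab.is_empty:
            continue
        dist = rank_distribution(ab)
        rows.append(
            {
                "bin": bin_name,
                "n_occurrences": ab.n,
                "s_obs": ab.s_obs,
                "singleton_proportion": dist.singleton_proportion,
                "doubleton_proportion": dist.doubleton_proportion,
                "top2_dominance": dist.dominance(2),
                "goods_u": goods_u(ab),
                "wastebasket_share": wastebasket_share(ab, genus_list),
                "sampling_probability": (
                    sampling.get(bin_name) if sampling else None
                ),
            }
        )
    return pd.DataFrame(rows)


def rank_distribution_long(
    abundance_by_bin: Mapping[str, AbundanceCounts],
) -> pd.DataFrame:
    """Long-format (bin, rank, taxon, count) table for plotting."""
    rows = []
    for bin_name, ab in abundance_by_bin.items():
        dist = rank_distribution(ab)
        for i, (taxon, count) in enumerate(zip(dist.taxa, dist.counts), start=1):
            rows.append({"bin": bin_name, "rank": i, "taxon": taxon, "count": count})
    return pd.DataFrame(rows, columns=["bin", "rank", "taxon", "count"])
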