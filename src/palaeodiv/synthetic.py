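"""Synthetic occurrence datasets with known ground truth.

The generator emulates the sampling structure that the analysis assumes:
per-bin locality counts, a geometric-series relative-abundance vector of
tunable evenness (parameter k: occurrence probability of the i-th taxon
proportional to k*(1-k)**(i-1), spanning near-uniform small k to heavily
dominated large k), marine/freshwater locality labels, multi-bin age
uncertainty, injectable indeterminate and scale/tooth records, and a
"waste-basket" lumping map that reassigns true genera to one over-
inclusive reported genus.  Every injected artefact is recorded in the
ground truth so cleaning can be audited record by record.  One master
seed drives everything; per-bin substreams are spawned deterministically
so any single bin is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import binning, estimators
from .binning import BinScheme, build_equal_length_scheme
from .occurrences import (
    Determinacy,
    Environment,
    Material,
    OccurrenceDataset,
    OccurrenceRecord,
)

__all__ = [
    "BinConfig",
    "SimulationConfig",
    "GroundTruth",
    "BinTruth",
    "generate",
    "evenness_experiment",
    "EvennessReport",
    "geometric_probabilities",
]


def geometric_probabilities(s_true: int, k: float) -> np.ndarray:
    """Normalized geometric-series relative abundances p_i ~ k*(1-k)**(i-1)."""
    if not 0.0 < k < 1.0:
        raise ValueError(f"evenness parameter k must be in (0, 1), got {k}")
    if s_true < 1:
        raise ValueError(f"S_true must be >= 1, got {s_true}")
    raw = k * (1.0 - k) ** np.arange(s_true)
    return raw / raw.sum()


@dataclass(frozen=True)
class BinConfig:
    """Per-bin simulation settings."""

    name: str
    s_true: int = 50
    n_localities: int = 20
    occurrences_per_locality: float = 6.0  # Poisson mean, floor 1
    evenness_k: float = 0.1
    marine_fraction: float = 0.6
    indeterminate_rate: float = 0.0
    scale_tooth_rate: float = 0.0
    age_uncertain_rate: float = 0.0
    lumping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, rate in (
            ("marine_fraction", self.marine_fraction),
            ("indeterminate_rate", self.indeterminate_rate),
            ("scale_tooth_rate", self.scale_tooth_rate),
            ("age_uncertain_rate", self.age_uncertain_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")
        if self.s_true < 1:
            raise ValueError("s_true must be >= 1")
        if self.n_localities < 1:
            raise ValueError("n_localities must be >= 1")


@dataclass
class SimulationConfig:
    seed: int
    bins: list[BinConfig]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=int(data["seed"]),
            bins=[BinConfig(**b) for b in data["bins"]],
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "bins": [
                {
                    "name": b.name,
                    "s_true": b.s_true,
                    "n_localities": b.n_localities,
                    "occurrences_per_locality": b.occurrences_per_locality,
                    "evenness_k": b.evenness_k,
                    "marine_fraction": b.marine_fraction,
                    "indeterminate_rate": b.indeterminate_rate,
                    "scale_tooth_rate": b.scale_tooth_rate,
                    "age_uncertain_rate": b.age_uncertain_rate,
                    "lumping": dict(b.lumping),
                }
                for b in self.bins
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class BinTruth:
    s_true: int
    probabilities: Mapping[str, float]  # true species binomial -> p_i
    injected_indeterminate: tuple[str, ...]
    injected_scale_tooth: tuple[str, ...]
    age_widened: tuple[str, ...]
    lumping: Mapping[str, str]


@dataclass
class GroundTruth:
    seed: int
    bins: dict[str, BinTruth]

    @property
    def injected_removable(self) -> set[str]:
        """Occurrence ids that the cleaning filters should remove."""
        ids: set[str] = set()
        for t in self.bins.values():
            ids.update(t.injected_indeterminate)
            ids.update(t.injected_scale_tooth)
        return ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bin_name, t in self.bins.items():
            for taxon, p in t.probabilities.items():
                rows.append(
                    {"bin": bin_name, "taxon": taxon, "probability": p,
                     "s_true": t.s_true}
                )
        return pd.DataFrame(rows, columns=["bin", "taxon", "probability", "s_true"])


def _taxon_names(s_true: int) -> list[tuple[str, str]]:
    return [(f"Genus{i:04d}", f"sp{i:04d}") for i in range(1, s_true + 1)]


def generate(
    cfg: SimulationConfig,
    scheme: BinScheme | None = None,
) -> tuple[OccurrenceDataset, GroundTruth]:
    """Draw a synthetic occurrence dataset and its ground truth.

    Per bin, each locality's occurrence list is a multinomial draw from
    the geometric relative-abundance vector; the lumping map is applied
    to reported genus names, then indeterminate and scale/tooth records
    are injected (as extra records, binomial in the bin's base record
    count) and a fraction of base records have their age range widened
    into the adjacent bin.  Byte-identical output for a given config.
    """
    if scheme is None:
        scheme = build_equal_length_scheme()
    master = np.random.SeedSequence(cfg.seed)
    records: list[OccurrenceRecord] = []
    truths: dict[str, BinTruth] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"occ{counter:06d}"

    for i, bcfg in enumerate(cfg.bins):
        if bcfg.name not in scheme:
            raise ValueError(f"bin {bcfg.name!r} is not in the bin scheme")
        b = scheme[bcfg.name]
        bin_idx = scheme.index(bcfg.name)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
        probs = geometric_probabilities(bcfg.s_true, bcfg.evenness_k)
        names = _taxon_names(bcfg.s_true)
        true_probs = {f"{g} {s}": float(p) for (g, s), p in zip(names, probs)}

        loc_envs = rng.random(bcfg.n_localities) < bcfg.marine_fraction
        base_ids: list[str] = []
        bin_records: list[OccurrenceRecord] = []
        for j in range(bcfg.n_localities):
            loc_id = f"{bcfg.name}|loc{j:03d}"
            env = Environment.MARINE if loc_envs[j] else Environment.FRESHWATER
            lat = float(rng.uniform(-60, 60))
            lon = float(rng.uniform(-180, 180))
            plat = float(rng.uniform(-70, 40))
            plon = float(rng.uniform(-180, 180))
            n_occ = max(1, int(rng.poisson(bcfg.occurrences_per_locality)))
            draws = rng.choice(bcfg.s_true, size=n_occ, p=probs)
            for d in draws:
                genus, species = names[int(d)]
                genus = bcfg.lumping.get(genus, genus)
                age = float(rng.uniform(b.top_ma, b.base_ma))
                rec = OccurrenceRecord(
                    occurrence_id=next_id(),
                    genus=genus,
                    species=species,
                    determinacy=Determinacy.SPECIES,
                    material=Material.BODY,
                    locality_id=loc_id,
                    locality_name=loc_id,
                    modern_lat=lat,
                    modern_lon=lon,
                    palaeo_lat=plat,
                    palaeo_lon=plon,
                    environment=env,
                    age_max=age,
                    age_min=age,
                )
                base_ids.append(rec.occurrence_id)
                bin_records.append(rec)

        # widen age ranges of a fraction of base records into a neighbour bin
        widened: list[str] = []
        if bcfg.age_uncertain_rate > 0:
            neighbour = (scheme.bins[bin_idx + 1]
                         if bin_idx + 1 < len(scheme)
                         else scheme.bins[bin_idx - 1])
            mask = rng.random(len(bin_records)) < bcfg.age_uncertain_rate
            for idx_r in np.flatnonzero(mask):
                rec = bin_records[idx_r]
                lo = min(b.top_ma, neighbour.top_ma)
                hi = max(b.base_ma, neighbour.base_ma)
                bin_records[idx_r] = OccurrenceRecord(
                    **{**rec.__dict__, "age_max": hi, "age_min": lo}
                )
                widened.append(rec.occurrence_id)

        # inject removable artefacts as extra records
        injected_indet: list[str] = []
        injected_scale: list[str] = []
        n_base = len(bin_records)
        for rate, bucket, kind in (
            (bcfg.indeterminate_rate, injected_indet, "indet"),
            (bcfg.scale_tooth_rate, injected_scale, "scale"),
        ):
            if rate <= 0:
                continue
            n_extra = int(rng.binomial(n_base, rate))
            for _ in range(n_extra):
                template = bin_records[int(rng.integers(n_base))]
                if kind == "indet":
                    rec = OccurrenceRecord(
                        **{
                            **template.__dict__,
                            "occurrence_id": next_id(),
                            "genus": None,
                            "species": None,
                            "determinacy": Determinacy.INDETERMINATE,
                        }
                    )
                else:
                    material = (Material.SCALE
                                if rng.random() < 0.5 else Material.TOOTH)
                    rec = OccurrenceRecord(
                        **{
                            **template.__dict__,
                            "occurrence_id": next_id(),
                            "material": material,
                        }
                    )
                bucket.append(rec.occurrence_id)
                bin_records.append(rec)

        records.extend(bin_records)
        truths[bcfg.name] = BinTruth(
            s_true=bcfg.s_true,
            probabilities=true_probs,
            injected_indeterminate=tuple(injected_indet),
            injected_scale_tooth=tuple(injected_scale),
            age_widened=tuple(widened),
            lumping=dict(bcfg.lumping),
        )

    ds = OccurrenceDataset(
        records=records, provenance=f"synthetic(seed={cfg.seed})"
    )
    return ds, GroundTruth(seed=cfg.seed, bins=truths)


@dataclass(frozen=True)
class EvennessReport:
    """Paired even/uneven simulation outcome at equal true richness."""

    s_true: int
    total_occurrences: int
    quorum_estimates_even: Mapping[float, float | None]
    quorum_estimates_uneven: Mapping[float, float | None]
    squares_even: float | None
    squares_uneven: float | None

    def quorum_gap(self, q: float) -> float | None:
        a = self.quorum_estimates_even.get(q)
        b = self.quorum_estimates_uneven.get(q)
        if a is None or b is None:
            return None
        return a - b

    def relative_quorum_gap(self, q: float) -> float | None:
        gap = self.quorum_gap(q)
        a = self.quorum_estimates_even.get(q)
        if gap is None or not a:
            return None
        return gap / a

    @property
    def relative_squares_gap(self) -> float | None:
        if self.squares_even is None or self.squares_uneven is None:
            return None
        if not self.squares_even:
            return None
        return (self.squares_even - self.squares_uneven) / self.squares_even


def evenness_experiment(
    seed: int,
    s_true: int = 100,
    n_localities: int = 40,
    occurrences_per_locality: float = 10.0,
    k_even: float = 0.02,
    k_uneven: float = 0.2,
    quorums: Sequence[float] = estimators.DEFAULT_QUORUMS,
    bin_name: str = "Serpukhovian",
) -> EvennessReport:
    """Paired even vs. uneven assemblages with equal richness and equal
    occurrence totals; returns the coverage-rarefied and squares estimates
    for both arms.

    Per-locality occurrence totals are drawn once and shared by both
    arms, so the arms differ only in the evenness of the underlying
    relative-abundance vector.
    """
    if not 0.0 < k_even < k_uneven < 1.0:
        raise ValueError("expected 0 < k_even < k_uneven < 1")
    scheme = build_equal_length_scheme()
    b = scheme[bin_name]
    sizes_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    sizes = np.maximum(
        1, sizes_rng.poisson(occurrences_per_locality, size=n_localities)
    )

    arms: dict[str, tuple[dict, float | None]] = {}
    total = int(sizes.sum())
    for arm_idx, (label, k) in enumerate((("even", k_even), ("uneven", k_uneven))):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(arm_idx,))
        )
        probs = geometric_probabilities(s_true, k)
        names = _taxon_names(s_true)
        records = []
        counter = 0
        for j in range(n_localities):
            loc_id = f"{label}|loc{j:03d}"
            draws = rng.choice(s_true, size=int(sizes[j]), p=probs)
            for d in draws:
                genus, species = names[int(d)]
                counter += 1
                age = float(rng.uniform(b.top_ma, b.base_ma))
                records.append(
                    OccurrenceRecord(
                        occurrence_id=f"{label}{counter:06d}",
                        genus=genus,
                        species=species,
                        determinacy=Determinacy.SPECIES,
                        material=Material.BODY,
                        locality_id=loc_id,
                        environment=Environment.MARINE,
                        age_max=age,
                        age_min=age,
                    )
                )
        ds = OccurrenceDataset(records=records, provenance=f"evenness[{label}]")
        assignment = binning.assign_single_bin(ds, scheme)
        inc = estimators.build_incidence(ds, assignment, rank="species")[bin_name]
        ab = estimators.build_abundance(ds, assignment, rank="species")[bin_name]
        quorum_est = {
            q: (e.estimate if e.attainable else None)
            for q, e in zip(quorums, estimators.quorum_sweep(inc, quorums))
        }
        sq = estimators.squares_estimate(ab)
        arms[label] = (quorum_est, sq.estimate)

    return EvennessReport(
        s_true=s_true,
        total_occurrences=total,
        quorum_estimates_even=arms["even"][0],
        quorum_estimates_uneven=arms["uneven"][0],
        squares_even=arms["even"][1],
        squares_uneven=arms["uneven"][1],
    )
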