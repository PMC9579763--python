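"""Sampling-standardized richness estimation.

The statistical core: per-bin incidence-frequency matrices (sampling unit
= geographical locality), Good's coverage, size-based rarefaction and
extrapolation of species/genus richness following the Chao-Jost incidence
framework, coverage-standardized ("quorum") estimates with a 2x
extrapolation cap, bootstrap confidence intervals, the squares
extrapolator of Alroy, and split-and-sum consistency tests.

Notation (incidence data, one time bin)
---------------------------------------
T      number of sampling units (localities)
Y_i    incidence frequency of taxon i: number of units occupied
S_obs  observed richness, Q1/Q2 number of unique/duplicate taxa
U      total incidences, sum of Y_i

Interpolated richness for t <= T units::

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t)

Extrapolated richness for t* extra units::

    S(T + t*) = S_obs + Q0_hat * [1 - (1 - Q1 / (T*Q0_hat + Q1))**t*]

with the (bias-corrected Chao2) undetected-richness term::

    Q0_hat = ((T-1)/T) * Q1**2 / (2*Q2)          if Q2 > 0
    Q0_hat = ((T-1)/T) * Q1*(Q1-1) / 2           if Q2 == 0

Estimated coverage of the reference sample::

    C_hat = 1 - (Q1/U) * [(T-1)*Q1 / ((T-1)*Q1 + 2*Q2)]

Coverage-standardized estimation finds the (fractional) sample size whose
expected coverage equals a target quorum q and reports richness there,
interpolating linearly between adjacent integer sizes; quorums not
reachable by t = 2T are reported as unattainable rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .binning import AssignmentFlag, BinAssignment
from .occurrences import Determinacy, Environment, OccurrenceDataset

__all__ = [
    "IncidenceFrequencies",
    "AbundanceCounts",
    "DiversityEstimate",
    "build_incidence",
    "build_abundance",
    "goods_u",
    "coverage_reference",
    "expected_coverage",
    "rarefy_size",
    "extrapolate_size",
    "chao2_undetected",
    "estimate_at_quorum",
    "quorum_sweep",
    "bootstrap_ci",
    "squares_estimate",
    "split_and_sum",
    "rarefaction_curve",
    "DEFAULT_QUORUMS",
]

DEFAULT_QUORUMS = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Per-bin incidence-frequency matrix collapsed to taxon frequencies.

    ``counts`` maps taxon name -> number of localities occupied (1..T).
    Duplicate occurrences of a taxon within one locality collapse to a
    single incidence.
    """

    bin_name: str
    rank: str
    T: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for taxon, y in self.counts.items():
            if not 0 < y <= self.T:
                raise ValueError(
                    f"incidence of {taxon!r} is {y}, outside 1..T={self.T}"
                )

    @property
    def y(self) -> np.ndarray:
        return np.asarray(sorted(self.counts.values(), reverse=True), dtype=float)

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def q1(self) -> int:
        return sum(1 for y in self.counts.values() if y == 1)

    @property
    def q2(self) -> int:
        return sum(1 for y in self.counts.values() if y == 2)

    @property
    def u(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return self.s_obs == 0

    @property
    def is_degenerate(self) -> bool:
        return self.T < 2 or self.u == 0


@dataclass(frozen=True)
class AbundanceCounts:
    """Per-bin raw occurrence counts per taxon (input to squares, Good's u)."""

    bin_name: str
    rank: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for taxon, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count of {taxon!r} is {n}, must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def s1(self) -> int:
        return sum(1 for n in self.counts.values() if n == 1)

    @property
    def sum_sq(self) -> int:
        return sum(n * n for n in self.counts.values())

    @property
    def is_empty(self) -> bool:
        return self.s_obs == 0


@dataclass(frozen=True)
class DiversityEstimate:
    """A richness estimate with its method, level and attainability."""

    bin_name: str
    method: str  # coverage-rarefied | size-rarefied | squares | observed
    level: float | None  # quorum q or sample size t
    estimate: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    mode: str | None = None  # interpolated | extrapolated
    attainable: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.estimate is not None and self.ci_low is not None
                and self.ci_high is not None):
            if not (self.ci_low <= self.estimate + 1e-9
                    and self.estimate <= self.ci_high + 1e-9):
                raise ValueError("estimate must lie inside its interval")


def _locality_taxa(
    records: Sequence, rank: str
) -> dict[str, set[str]]:
    """locality_id -> set of taxon names at the requested rank.

    At genus rank a taxon is the genus name of any determinate record.  At
    species rank, determinate binomials count directly and a
    genus-determinate record ("Genus sp.") counts as the pseudo-taxon
    "Genus sp." only at localities where that genus has no determinate
    species (the Paleobiology-Database hierarchy rule).
    """
    by_loc: dict[str, list] = {}
    for rec in records:
        by_loc.setdefault(rec.locality_id, []).append(rec)
    out: dict[str, set[str]] = {}
    for loc, recs in by_loc.items():
        taxa: set[str] = set()
        if rank == "genus":
            taxa = {
                r.genus for r in recs
                if r.genus and r.determinacy is not Determinacy.INDETERMINATE
            }
        elif rank == "species":
            det = {r.species_binomial for r in recs if r.species_binomial}
            det_genera = {r.genus for r in recs
                          if r.determinacy is Determinacy.SPECIES}
            taxa |= det
            for r in recs:
                if r.determinacy is Determinacy.GENUS and r.genus not in det_genera:
                    taxa.add(f"{r.genus} sp.")
        else:
            raise ValueError(f"rank must be 'genus' or 'species', got {rank!r}")
        if taxa:
            out[loc] = taxa
    return out


def build_incidence(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
    rank: str = "genus",
) -> dict[str, IncidenceFrequencies]:
    """Per-bin incidence frequencies over single-bin records.

    The sampling unit is the distinct locality within the bin; a taxon's
    frequency Y_i is the number of localities it occupies there.
    """
    per_bin = assignment.records_in_bins(ds, (AssignmentFlag.SINGLE_BIN,))
    out: dict[str, IncidenceFrequencies] = {}
    for bin_name, records in per_bin.items():
        loc_taxa = _locality_taxa(records, rank)
        counts: dict[str, int] = {}
        for taxa in loc_taxa.values():
            for t in taxa:
                counts[t] = counts.get(t, 0) + 1
        out[bin_name] = IncidenceFrequencies(
            bin_name=bin_name, rank=rank, T=len(loc_taxa), counts=counts
        )
    return out


def build_abundance(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
    rank: str = "genus",
) -> dict[str, AbundanceCounts]:
    """Per-bin raw occurrence counts per taxon over single-bin records.

    At species rank, genus-determinate records subsumed by a determinate
    congeneric species at the same locality are dropped (they do not
    represent a distinct species); unsubsumed ones count to the "Genus
    sp." pseudo-taxon.
    """
    per_bin = assignment.records_in_bins(ds, (AssignmentFlag.SINGLE_BIN,))
    out: dict[str, AbundanceCounts] = {}
    for bin_name, records in per_bin.items():
        counts: dict[str, int] = {}
        if rank == "genus":
            for r in records:
                if r.genus and r.determinacy is not Determinacy.INDETERMINATE:
                    counts[r.genus] = counts.get(r.genus, 0) + 1
        else:
            det_by_loc: dict[str, set[str]] = {}
            for r in records:
                if r.determinacy is Determinacy.SPECIES:
                    det_by_loc.setdefault(r.locality_id, set()).add(r.genus)
            for r in records:
                if r.determinacy is Determinacy.SPECIES:
                    name = r.species_binomial
                elif (r.determinacy is Determinacy.GENUS
                        and r.genus not in det_by_loc.get(r.locality_id, set())):
                    name = f"{r.genus} sp."
                else:
                    continue
                counts[name] = counts.get(name, 0) + 1
        out[bin_name] = AbundanceCounts(bin_name=bin_name, rank=rank, counts=counts)
    return out


def goods_u(ab: AbundanceCounts) -> float | None:
    """Good's coverage u = 1 - singletons/occurrences; None when N = 0."""
    if ab.n == 0:
        return None
    return 1.0 - ab.s1 / ab.n


def coverage_reference(inc: IncidenceFrequencies) -> float | None:
    """Estimated coverage of the full reference sample of T localities.

    Returns None when U = 0; for the degenerate T = 1 case the (T-1)
    factor drives the estimate to max(0, 1 - Q1/U) which is 0 when all
    taxa are unique to the single unit.
    """
    if inc.u == 0:
        return None
    q1, q2, t, u = inc.q1, inc.q2, inc.T, inc.u
    if q1 == 0:
        return 1.0
    denom = (t - 1) * q1 + 2 * q2
    if denom == 0:
        return max(0.0, 1.0 - q1 / u)
    return 1.0 - (q1 / u) * ((t - 1) * q1 / denom)


def _comb_ratio(top: np.ndarray, t: int, T: int, lower: int) -> np.ndarray:
    """C(top, t) / C(lower, t) computed stably in log space (0 if top < t)."""
    top = np.asarray(top, dtype=float)
    with np.errstate(invalid="ignore"):
        logs = (
            gammaln(top + 1) - gammaln(top - t + 1)
            - (gammaln(lower + 1) - gammaln(lower - t + 1))
        )
    out = np.where(top >= t, np.exp(logs), 0.0)
    return out


def rarefy_size(inc: IncidenceFrequencies, t: int) -> float:
    """Expected richness in a random subsample of t of the T localities."""
    if not 1 <= t <= inc.T:
        raise ValueError(f"t={t} outside 1..T={inc.T}")
    y = inc.y
    return float(inc.s_obs - _comb_ratio(inc.T - y, t, inc.T, inc.T).sum())


def chao2_undetected(inc: IncidenceFrequencies) -> float:
    """Bias-corrected Chao2 estimate of undetected richness Q0_hat."""
    t, q1, q2 = inc.T, inc.q1, inc.q2
    if t < 2:
        return 0.0
    if q2 > 0:
        return (t - 1) / t * q1 * q1 / (2.0 * q2)
    return (t - 1) / t * q1 * (q1 - 1) / 2.0


def extrapolate_size(
    inc: IncidenceFrequencies, t_star: int, *, enforce_cap: bool = True
) -> float:
    """Expected richness after t_star additional localities (t = T + t_star).

    With ``enforce_cap`` the extrapolation is limited to double the
    reference sample size (t_star <= T); beyond-cap requests raise.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    if enforce_cap and t_star > inc.T:
        raise ValueError(
            f"extrapolation to T+{t_star} exceeds the 2T cap (T={inc.T})"
        )
    q0 = chao2_undetected(inc)
    q1 = inc.q1
    if q1 == 0 or q0 == 0:
        return float(inc.s_obs)
    return float(
        inc.s_obs + q0 * (1.0 - (1.0 - q1 / (inc.T * q0 + q1)) ** t_star)
    )


def expected_coverage(inc: IncidenceFrequencies, t: int) -> float | None:
    """Expected sample coverage of t localities (interpolated, reference,
    or extrapolated)."""
    if inc.u == 0:
        return None
    T, u = inc.T, inc.u
    if t < 1:
        return 0.0
    if t < T:
        y = inc.y
        terms = (y / u) * _comb_ratio(T - y, t, T, T - 1)
        return float(1.0 - terms.sum())
    c_ref = coverage_reference(inc)
    if t == T or c_ref is None:
        return c_ref
    q1, q2 = inc.q1, inc.q2
    if q1 == 0:
        return 1.0
    denom = (T - 1) * q1 + 2 * q2
    if denom == 0:
        return c_ref
    ratio = (T - 1) * q1 / denom
    return float(1.0 - (q1 / u) * ratio ** (t - T + 1))


def rarefaction_curve(
    inc: IncidenceFrequencies, *, t_max: int | None = None
) -> pd.DataFrame:
    """Table of (t, expected richness, expected coverage) for t = 1..t_max.

    ``t_max`` defaults to 2T (the extrapolation cap)."""
    if inc.is_empty:
        return pd.DataFrame(columns=["t", "richness", "coverage", "mode"])
    if t_max is None:
        t_max = 2 * inc.T
    rows = []
    for t in range(1, t_max + 1):
        if t <= inc.T:
            rich = rarefy_size(inc, t)
            mode = "interpolated"
        else:
            rich = extrapolate_size(inc, t - inc.T, enforce_cap=False)
            mode = "extrapolated"
        rows.append((t, rich, expected_coverage(inc, t), mode))
    return pd.DataFrame(rows, columns=["t", "richness", "coverage", "mode"])


def estimate_at_quorum(
    inc: IncidenceFrequencies, q: float
) -> DiversityEstimate:
    """Richness standardized to target coverage (quorum) q.

    Scans integer sample sizes t = 1..2T for the first whose expected
    coverage reaches q and interpolates richness linearly between the
    bracketing coverages (t = 0 contributes the point (coverage 0,
    richness 0)).  Quorums beyond the coverage reachable at twice the
    reference sample size are unattainable.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quorum must be in (0, 1), got {q}")
    if inc.is_empty or inc.u == 0:
        return DiversityEstimate(
            inc.bin_name, "coverage-rarefied", q, None,
            attainable=False, reason="empty bin",
        )
    if inc.T < 2:
        return DiversityEstimate(
            inc.bin_name, "coverage-rarefied", q, None,
            attainable=False, reason="single sampling unit (degenerate)",
        )
    prev_cov, prev_rich = 0.0, 0.0
    for t in range(1, 2 * inc.T + 1):
        if t <= inc.T:
            rich = rarefy_size(inc, t)
            mode = "interpolated"
        else:
            rich = extrapolate_size(inc, t - inc.T)
            mode = "extrapolated"
        cov = expected_coverage(inc, t)
        if cov is None:
            break
        if cov >= q:
            if cov > prev_cov:
                frac = (q - prev_cov) / (cov - prev_cov)
            else:
                frac = 1.0
            est = prev_rich + frac * (rich - prev_rich)
            return DiversityEstimate(
                inc.bin_name, "coverage-rarefied", q, float(est), mode=mode
            )
        prev_cov, prev_rich = cov, rich
    return DiversityEstimate(
        inc.bin_name, "coverage-rarefied", q, None, attainable=False,
        reason=f"coverage {q} not reached by t = 2T = {2 * inc.T}",
    )


def quorum_sweep(
    inc: IncidenceFrequencies,
    quorums: Sequence[float] = DEFAULT_QUORUMS,
) -> list[DiversityEstimate]:
    """Map :func:`estimate_at_quorum` over a list of quorums."""
    return [estimate_at_quorum(inc, q) for q in quorums]


def bootstrap_ci(
    inc: IncidenceFrequencies,
    q: float,
    B: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float] | None:
    """Percentile 95% bootstrap interval for the quorum-q estimate.

    The bootstrap assemblage comprises the observed taxa with
    coverage-adjusted detection probabilities plus ceil(Q0_hat)
    pseudo-taxa sharing the estimated undetected probability mass; each
    replicate redraws per-taxon incidences Binomial(T, p_i) and re-runs
    the estimator.  Deterministic given the seed.  Returns None for
    degenerate inputs or when fewer than two replicates yield an
    attainable estimate.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if inc.is_empty or inc.is_degenerate:
        return None
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    T = inc.T
    y = inc.y
    c_ref = coverage_reference(inc)
    if c_ref is None:
        return None
    # coverage-adjusted detection probabilities (Chao-style bootstrap)
    phi = (y / T) * (1.0 - y / T) ** T
    denom = phi.sum()
    lam = 0.0 if denom <= 0 else (1.0 - c_ref) / denom
    p_obs = (y / T) * (1.0 - lam * (1.0 - y / T) ** T)
    q0 = chao2_undetected(inc)
    n_pseudo = int(math.ceil(q0))
    probs = list(np.clip(p_obs, 1.0 / (T * T * 10.0), 1.0))
    if n_pseudo > 0:
        p0 = (inc.u / T) * (1.0 - c_ref) / q0
        probs.extend([min(1.0, max(p0, 1e-12))] * n_pseudo)
    probs_arr = np.asarray(probs)
    estimates = []
    for _ in range(B):
        y_star = rng.binomial(T, probs_arr)
        counts = {f"tax{i}": int(v) for i, v in enumerate(y_star) if v > 0}
        if not counts:
            continue
        boot = IncidenceFrequencies(inc.bin_name, inc.rank, T, counts)
        est = estimate_at_quorum(boot, q)
        if est.attainable and est.estimate is not None:
            estimates.append(est.estimate)
    if len(estimates) < 2:
        return None
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def squares_estimate(ab: AbundanceCounts) -> DiversityEstimate:
    """The squares richness extrapolator.

    S_squares = S_obs + s1^2 * sum(n_i^2) / (N^2 - s1 * S_obs), designed
    for uneven occurrence-frequency distributions (many singletons plus
    very frequent taxa).  With no singletons it returns the observed
    richness; all-singleton samples and non-positive denominators are
    typed undefined results, never numbers.
    """
    if ab.is_empty:
        return DiversityEstimate(
            ab.bin_name, "squares", None, None, attainable=False,
            reason="empty bin",
        )
    s_obs, s1, n = ab.s_obs, ab.s1, ab.n
    if s1 == 0:
        return DiversityEstimate(ab.bin_name, "squares", None, float(s_obs))
    if s1 == s_obs:
        return DiversityEstimate(
            ab.bin_name, "squares", None, None, attainable=False,
            reason="all taxa are singletons",
        )
    denom = n * n - s1 * s_obs
    if denom <= 0:
        return DiversityEstimate(
            ab.bin_name, "squares", None, None, attainable=False,
            reason="non-positive denominator",
        )
    return DiversityEstimate(
        ab.bin_name, "squares", None,
        float(s_obs + s1 * s1 * ab.sum_sq / denom),
    )


def _subset(ds: OccurrenceDataset, environments: set[Environment]) -> OccurrenceDataset:
    recs = [r for r in ds.records if r.environment in environments]
    return OccurrenceDataset(records=recs, provenance=ds.provenance)


def split_and_sum(
    ds: OccurrenceDataset,
    assignment: BinAssignment,
    rank: str = "genus",
) -> pd.DataFrame:
    """Split-and-sum consistency test by palaeoenvironment.

    Runs the squares estimator on the marine (including brackish) subset,
    the freshwater subset and the pooled dataset per bin, and reports the
    deviation (marine + freshwater - pooled).  Large positive deviations
    flag bins where subsetting inflates the singleton-driven
    extrapolation, typically when one environment dominates sampling.
    """
    marine = _subset(ds, {Environment.MARINE, Environment.BRACKISH})
    fresh = _subset(ds, {Environment.FRESHWATER})
    pooled_ab = build_abundance(ds, assignment, rank)
    marine_ab = build_abundance(marine, assignment, rank)
    fresh_ab = build_abundance(fresh, assignment, rank)
    rows = []
    for bin_name, pooled in pooled_ab.items():
        pooled_est = squares_estimate(pooled)
        parts = {}
        flags = []
        for label, table in (("marine", marine_ab), ("freshwater", fresh_ab)):
            ab = table.get(bin_name)
            if ab is None or ab.is_empty:
                parts[label] = 0.0
                flags.append(f"{label} subset empty")
                continue
            est = squares_estimate(ab)
            if est.estimate is None:
                parts[label] = float(ab.s_obs)
                flags.append(f"{label} squares undefined ({est.reason})")
            else:
                parts[label] = est.estimate
        total = parts["marine"] + parts["freshwater"]
        pooled_val = (pooled_est.estimate if pooled_est.estimate is not None
                      else float(pooled.s_obs))
        if pooled_est.estimate is None:
            flags.append(f"pooled squares undefined ({pooled_est.reason})")
        rows.append(
            {
                "bin": bin_name,
                "marine_estimate": parts["marine"],
                "freshwater_estimate": parts["freshwater"],
                "sum": total,
                "pooled_estimate": pooled_val,
                "deviation": total - pooled_val,
                "flags": "; ".join(flags),
            }
        )
    return pd.DataFrame(rows)
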