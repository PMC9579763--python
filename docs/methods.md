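# Methods

This note documents the statistical procedures implemented in
`palaeodiv`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model and cleaning

An occurrence is one record of a taxon at one geographical locality in
one stratigraphic context. Records carry a determinacy level
(species-determinate, genus-determinate, indeterminate), a material type
(body, scale, tooth, unknown), a locality identifier, modern and
(optionally) palaeorotated coordinates, an environment label (marine,
brackish, freshwater, unknown) and a stratigraphic range given as ICS
stages and/or numeric ages in Ma.

Cleaning removes fully indeterminate records and records positively
identified as isolated scales or teeth — material that usually cannot be
attributed to a taxon reliably, and whose morphotypes may belong to one
body taxon. Records of *unknown* material are retained (only identified
scale/tooth records are removed), with the retained count noted in the
log. Material typing is read from an explicit column; free-text lithology
or preservation descriptions are not parsed, so upstream compilation must
supply structured input. Genus-determinate records ("Genus sp.") survive
cleaning even for species-level analyses because they are resolved at
counting time (below).

Every filter appends a `(rule, removed)` entry to a cleaning log, and
the log always reconciles raw versus cleaned sizes; filters are
idempotent and commute.

Locality identity follows the supplied `locality_id`, not stratigraphy.
This deliberately supports both conventions seen in practice: one
geographical locality with several fossiliferous horizons can be one
locality (give the horizons one id), and one horizon cropping out at
several sites can be several (give them distinct ids). An alternative
`by-name-and-coords` policy merges records sharing a locality name whose
coordinates agree within a tolerance (default 0.01°, configurable);
conflicting coordinates under one id beyond the tolerance raise a
warning, never an error.

Parsing is strict by default (malformed rows abort with the row cited);
a lenient mode drops and logs them instead.

## Equal-length time bins

Raw ICS stages range from ~3 to ~16 Ma, which confounds per-interval
comparisons, so analyses run on a 16-bin scheme of roughly equal
(~9 Ma) intervals from the Eifelian & Givetian to the Wuchiapingian &
Changhsingian: short neighbouring stages are merged (Eifelian &
Givetian; Kasimovian & Gzhelian; Asselian & Sakmarian; Roadian &
Wordian; Wuchiapingian & Changhsingian) and the long Visean is split
into an early (Chadian–Holkerian) and a late (Asbian–Brigantian) bin.
The split age defaults to 338.0 Ma — the radiometrically calibrated
(Dunsapie basalt) boundary, giving 8.7 and 7.1 Ma halves — and is
configurable. Stage boundary ages ship as a versioned CSV fixture (2018
ICS chart vintage) and can be overridden; with the shipped table the
merged Kasimovian & Gzhelian bin lasts 8.1 Ma.

Earlier Devonian stages (Lochkovian–Emsian) are present in the stage
table and the scheme builder is extensible, but no standard grouping is
defined for them; occurrences older than the Eifelian are unassignable
under the default scheme.

Two assignment views serve different purposes:

- **single-bin** (used for diversity estimation): a record qualifies
  only if its entire stratigraphic range — numeric ages when present,
  else the span of its stage range — lies within one bin; otherwise it
  is multi-bin (candidate bins recorded) or unassignable.
- **midpoint** (used for local richness and maps): range-spanning
  records are placed in the bin containing the midpoint of their age
  range, so age-uncertain material still contributes to per-locality
  counts. A midpoint exactly on a bin boundary goes to the **older**
  bin — a deterministic tie-break consistent with closed-at-base
  intervals.

Localities whose age is ambiguous between exactly two adjacent bins are
flagged from the single-bin candidate set and duplicated into both bins'
map tables (only the map tables; estimation never double-counts them).

## Local (alpha) richness

Species per locality is the local-richness measure. Counting follows
the taxonomic hierarchy of the Paleobiology Database: a "Genus sp."
record adds one species at a locality only when no determinate species
of that genus occurs there; otherwise it is subsumed. Genus counts use
distinct determinate genus names. The hierarchy rule is applied
symmetrically at both ranks, never undercounts distinct determinate
species, and never exceeds plain name-counting plus genus-only records.

Environment splits pool brackish with marine. Mixed-environment
localities are recounted per class (not assigned wholesale), so a
locality with two marine and one freshwater species contributes n = 2 to
the marine subset and n = 1 to the freshwater one; unknown-environment
records are excluded with a logged count. Southern-hemisphere tallies
use modern latitude, since "known localities" is a claim about modern
geography.

## Coverage-based rarefaction and extrapolation

Diversity estimation treats the distinct locality within a bin as the
sampling unit and works on incidence frequencies `Y_i` (localities
occupied per taxon; within-locality duplicates collapse). The estimator
formulas are the incidence-data interpolation/extrapolation framework of
Chao and Jost (see the README for the formulas): hypergeometric
interpolated richness `S(t)`, extrapolation through the bias-corrected
Chao2 undetected-richness term `Q̂0`, and the singleton/doubleton
coverage estimator `Ĉ`. The expected coverage of `t < T` units is
`1 − Σᵢ (Y_i/U)·C(T−Y_i, t)/C(T−1, t)`; extrapolated coverage decays the
residual unique mass geometrically. Binomial-coefficient ratios are
computed in log-gamma space, so large `T` is numerically safe.

A quorum-`q` estimate finds the first integer sample size whose expected
coverage reaches `q` and interpolates richness linearly between the
bracketing coverages, with `t = 0` contributing the anchor (coverage 0,
richness 0); this is deterministic and finer-grained than
nearest-integer rounding. Extrapolation is capped at twice the observed
sample size, and quorums not reachable by `t = 2T` are reported as
typed *unattainable* results, never clamped numbers. Bins with fewer
than 3 localities (configurable) or reference coverage below a floor
(default 0.1, configurable) are excluded from quorum sweeps — very small,
low-coverage bins produce meaningless standardized estimates. The
default quorum list is 0.3–0.7 in steps of 0.1; higher quorums are
typically unattainable for long-tailed fossil data because singletons
keep coverage low.

An important interpretive point, which the synthetic experiments below
make quantitative: coverage-standardized richness is a *relative*
measure. For an even assemblage of `S` taxa the quorum-`q` estimate sits
near `q·S` regardless of sampling depth (for uniform incidence, expected
coverage equals the expected detected fraction of taxa). It orders bins
sampled to equal completeness; it does not estimate true richness.

**Confidence intervals** are nonparametric bootstrap (default B = 200,
percentile 95%, one integer seed governs all replicates): the bootstrap
assemblage comprises the observed taxa at coverage-adjusted detection
probabilities plus `⌈Q̂0⌉` pseudo-taxa sharing the estimated undetected
probability mass; each replicate redraws incidences `Binomial(T, p_i)`
and re-runs the estimator. A bootstrap was chosen over analytic
variances because it propagates the full estimator (including the
quorum search and cap) rather than a linearization; degenerate inputs
return an absent interval with a flag.

**Degenerate cases.** `T = 1` makes the `(T−1)` coverage factor vanish;
such bins are flagged degenerate rather than estimated. `Q1 = 0` gives
reference coverage 1 and a flat extrapolation at `S_obs`.

## Squares estimator and split-and-sum tests

The squares estimator extrapolates from raw occurrence counts:
`S_sq = S_obs + s1²·Σn_i²/(N² − s1·S_obs)`. With no singletons it
returns observed richness exactly; all-singleton bins and non-positive
denominators return typed undefined values (silent numeric fallbacks
would corrupt trend tables). Squares reacts to the same unevenness that
depresses low-quorum coverage estimates, but in the opposite direction —
many singletons alongside very frequent taxa *raise* it — which is why
the two methods disagree most in the most biased intervals.

Split-and-sum tests run squares on the marine (including brackish) and
freshwater subsets and on the pooled bin, reporting
`(marine + freshwater) − pooled`. Disjoint subsets without singletons
deviate by zero; subsetting an uneven assemblage strands taxa as
singletons inside each subset and inflates the sum, so large deviations
diagnose environment-dominated sampling. Empty subsets contribute an
observed 0 with a flag.

## Bias diagnostics

Rank-occurrence distributions sort per-taxon counts descending with
ties broken alphabetically (stable across runs and platforms), and
report singleton/doubleton proportions and top-k dominance. Waste-basket
analysis ships a default six-genus list (*Acrolepis*, *Amblypterus*,
*Elonichthys*, *Palaeoniscum*, *Platysomus*, *Rhadinichthys*) as an
overridable data file and reports each bin's occurrence share of listed
genera and their mean rank across bins.

Sampling probability is implemented as **range-through occupancy**: a
genus is range-through in every bin between its first and last sampled
bins (endpoints included), and the per-bin probability is the fraction
of range-through genera actually sampled there. This is one defensible
definition among several (per-locality and three-timer-style variants
exist); because the definition is a package choice, the resulting
numbers should be compared only within analyses using this package.
Including endpoints biases the probability upward for short-ranging
taxa; the simulation test therefore measures interior bins only.

## Synthetic data: what it emulates and what it does not

The generator draws, per bin, each locality's occurrence list from a
geometric-series relative-abundance vector `p_i ∝ k(1−k)^(i−1)`. The
single evenness parameter `k` spans near-uniform (k → 0) to heavily
dominated assemblages; k = 0.2 puts ~20% of occurrences in the top
taxon, matching the dominance scale that waste-basket genera reach in
real intervals. On top of the base draws it can lump true genera into a
reported waste-basket genus, inject indeterminate and scale/tooth
records at given rates (as extra records, so cleaning can be audited
exactly), widen age ranges into a neighbouring bin for a fraction of
records, and label localities marine/freshwater by a mixing fraction.
Locality occurrence totals are Poisson with floor 1. One master seed
drives everything; per-bin substreams are spawned deterministically, so
output tables are byte-identical across runs.

The generator models *sampling structure only*. It does not model plate
motion, lithology, preservation physics, taxonomic error beyond the
lumping map, or spatial autocorrelation among localities; taxa are
exchangeable within the geometric series and independent across bins.
Passing tests therefore show that the estimators behave correctly under
the stated sampling model — not that real occurrence data satisfy that
model.

Two standing experiments use the generator:

- **Parameter recovery** (one bin, S_true = 100, 40 localities, mean 15
  occurrences each, k = 0.01 — near-uniform, with ~560 occurrences deep
  enough to observe all 100 taxa): the squares estimate lands within a
  fraction of a percent of true richness. The quorum-0.7 estimate sits
  near 70, the intrinsic value of coverage-standardized richness for an
  even assemblage (see above), and is reported alongside for exactly
  that reason.
- **Evenness sensitivity** (paired arms, equal S_true = 100 and equal
  per-locality totals shared between arms — 40 localities, mean 10
  occurrences — differing only in k: 0.02 vs 0.2): the uneven arm
  receives a much lower quorum-0.3 estimate, and the squares gap is
  smaller in relative terms, quantifying both that evenness drives
  coverage-standardized estimates and that squares is comparatively more
  robust to it. Problem sizes were chosen so each experiment completes
  in well under a minute while leaving the effects far above simulation
  noise; directions are asserted, magnitudes logged.

## Known limitations

- Palaeocoordinates are consumed as input columns; plate rotation is out
  of scope, as is map rendering (the package emits map-ready tables).
- Hill numbers of order q ≠ 0, residual modelling and beta-diversity
  partitioning are not implemented.
- No taxonomic name resolution or synonymy: the waste-basket machinery
  diagnoses lumping, it does not fix it.
- The genus-only pseudo-taxon ("Genus sp.") used at species rank is
  treated as one taxon across localities within a bin; if the underlying
  specimens represent several species, species-level incidence is
  conservatively undercounted.
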