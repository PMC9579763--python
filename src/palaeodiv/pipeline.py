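"""End-to-end run assembly: clean -> bin -> alpha -> estimate -> diagnose.

Everything here is plumbing over the analysis modules: a RunConfig read
from YAML, a deterministic pipeline that writes CSV tables plus a plain-
text log, and stage-count bookkeeping (records in = records out +
removals logged).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import alpha, binning, diagnostics, estimators, occurrences
from .binning import AssignmentFlag

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline"]


class ConfigError(Exception):
    """Invalid or inconsistent run configuration."""


class DataError(Exception):
    """Input data failed validation during a pipeline stage."""


DEFAULT_COLUMN_MAP = {
    "occurrence_id": "occurrence_id",
    "genus": "genus",
    "species": "species",
    "determinacy": "determinacy",
    "material": "material",
    "locality_id": "locality_id",
    "locality_name": "locality_name",
    "modern_lat": "modern_lat",
    "modern_lon": "modern_lon",
    "palaeo_lat": "palaeo_lat",
    "palaeo_lon": "palaeo_lon",
    "environment": "environment",
    "earliest_stage": "earliest_stage",
    "latest_stage": "latest_stage",
    "age_max": "age_max",
    "age_min": "age_min",
}


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    stage_table_path: str | None = None
    rank: str = "genus"
    quorums: Sequence[float] = estimators.DEFAULT_QUORUMS
    bootstrap_replicates: int = 200
    seed: int = 0
    min_localities: int = 3
    min_coverage: float = 0.1
    visean_split_ma: float = binning.DEFAULT_VISEAN_SPLIT_MA
    wastebasket_path: str | None = None
    strict: bool = True
    compute_bootstrap: bool = False

    def __post_init__(self) -> None:
        qs = list(self.quorums)
        if qs != sorted(qs) or len(set(qs)) != len(qs):
            raise ConfigError("quorums must be strictly increasing")
        if any(not 0.0 < q < 1.0 for q in qs):
            raise ConfigError("quorums must lie in (0, 1)")
        if self.rank not in {"genus", "species"}:
            raise ConfigError(f"rank must be genus or species, got {self.rank!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _wastebasket_list(cfg: RunConfig) -> list[str]:
    if cfg.wastebasket_path is None:
        return diagnostics.load_default_wastebasket()
    text = Path(cfg.wastebasket_path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis and write tables to ``cfg.output_dir``.

    Returns the output directory.  Raises ConfigError / DataError with
    the failing stage named.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"config_hash: {cfg.config_hash()}",
        f"seed: {cfg.seed}",
    ]

    # -- clean ---------------------------------------------------------
    try:
        ds = occurrences.read_occurrences(
            cfg.input_path, cfg.column_map, strict=cfg.strict
        )
    except (OSError, ValueError) as err:
        raise DataError(f"stage clean (read): {err}") from err
    n_raw = len(ds)
    ds = occurrences.filter_indeterminate(ds, rank=cfg.rank)
    ds = occurrences.filter_material(ds)
    ds, n_localities, warnings = occurrences.dedupe_localities(ds, "by-id")
    for w in warnings:
        log_lines.append(f"clean: warning: {w}")
    log_lines.append(
        f"clean: {n_raw} raw -> {len(ds)} records, {n_localities} localities"
    )
    occurrences.write_occurrences(ds, out / "cleaned.csv")

    # -- bin -----------------------------------------------------------
    stages = (binning.StageTable.from_csv(cfg.stage_table_path)
              if cfg.stage_table_path else binning.load_default_stages())
    try:
        scheme = binning.build_equal_length_scheme(
            stages, visean_split_ma=cfg.visean_split_ma
        )
    except (KeyError, ValueError) as err:
        raise ConfigError(f"stage bin (scheme): {err}") from err
    scheme.to_frame().to_csv(out / "bin_scheme.csv", index=False)
    single = binning.assign_single_bin(ds, scheme, stages)
    midpoint = binning.assign_midpoint(ds, scheme, stages)
    single.to_frame().to_csv(out / "assignments_single.csv", index=False)
    midpoint.to_frame().to_csv(out / "assignments_midpoint.csv", index=False)
    n_single = sum(
        1 for a in single.values() if a.flag is AssignmentFlag.SINGLE_BIN
    )
    log_lines.append(
        f"bin: {n_single}/{len(ds)} records attributable to a single bin"
    )

    # -- alpha ---------------------------------------------------------
    rich = alpha.count_local_richness(ds, midpoint)
    pd.DataFrame([r.__dict__ for r in rich]).to_csv(
        out / "local_richness.csv", index=False
    )
    profile, n_dropped = alpha.palaeolat_profile(rich)
    profile.to_csv(out / "palaeolat_profile.csv", index=False)
    log_lines.append(
        f"alpha: {len(rich)} locality-bin entries; "
        f"{n_dropped} without palaeocoordinates dropped from the profile"
    )
    ambiguous = {}
    for rec in ds.records:
        a = single[rec.occurrence_id]
        if (a.flag is AssignmentFlag.MULTI_BIN
                and len(a.candidate_bins) == 2):
            ambiguous[rec.locality_id] = tuple(a.candidate_bins)
    maps = alpha.map_tables(rich, scheme, ambiguous)
    map_dir = out / "map_tables"
    map_dir.mkdir(exist_ok=True)
    for bin_name, table in maps.items():
        safe = bin_name.replace(" ", "_").replace("&", "and")
        table.to_csv(map_dir / f"{safe}.csv", index=False)

    # -- estimate ------------------------------------------------------
    inc = estimators.build_incidence(ds, single, cfg.rank)
    ab = estimators.build_abundance(ds, single, cfg.rank)
    est_rows = []
    curve_frames = []
    if cfg.quorums:
        for bin_name in scheme.names():
            if bin_name not in inc:
                continue
            freq = inc[bin_name]
            cov = estimators.coverage_reference(freq)
            excluded = (freq.T < cfg.min_localities
                        or cov is None or cov < cfg.min_coverage)
            if excluded:
                log_lines.append(
                    f"estimate: bin {bin_name!r} excluded "
                    f"(T={freq.T}, coverage={cov})"
                )
            for q in cfg.quorums:
                if excluded:
                    est_rows.append(
                        {"bin": bin_name, "method": "coverage-rarefied",
                         "level": q, "estimate": None, "ci_low": None,
                         "ci_high": None, "mode": None, "attainable": False,
                         "reason": "bin excluded (too few localities or "
                                   "coverage below floor)"}
                    )
                    continue
                e = estimators.estimate_at_quorum(freq, q)
                lo = hi = None
                if cfg.compute_bootstrap and e.attainable:
                    ci = estimators.bootstrap_ci(
                        freq, q, B=cfg.bootstrap_replicates, seed=cfg.seed
                    )
                    if ci:
                        lo, hi = ci
                est_rows.append(
                    {"bin": bin_name, "method": e.method, "level": q,
                     "estimate": e.estimate, "ci_low": lo, "ci_high": hi,
                     "mode": e.mode, "attainable": e.attainable,
                     "reason": e.reason}
                )
            curve = estimators.rarefaction_curve(freq)
            curve.insert(0, "bin", bin_name)
            curve_frames.append(curve)
    else:
        log_lines.append("estimate: empty quorum list, estimation stage skipped")
    for bin_name in scheme.names():
        if bin_name not in ab:
            continue
        e = estimators.squares_estimate(ab[bin_name])
        est_rows.append(
            {"bin": bin_name, "method": "squares", "level": None,
             "estimate": e.estimate, "ci_low": None, "ci_high": None,
             "mode": "extrapolated", "attainable": e.attainable,
             "reason": e.reason}
        )
    pd.DataFrame(est_rows).to_csv(out / "estimates.csv", index=False)
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "rarefaction_curves.csv", index=False
        )
    split = estimators.split_and_sum(ds, single, cfg.rank)
    split.to_csv(out / "split_and_sum.csv", index=False)

    # -- diagnose ------------------------------------------------------
    genus_ab = ab if cfg.rank == "genus" else estimators.build_abundance(
        ds, single, "genus"
    )
    wastebasket = _wastebasket_list(cfg)
    sampling, sampling_avg = diagnostics.sampling_probability(
        ds, single, scheme
    )
    diag = diagnostics.diagnostics_table(
        genus_ab, scheme, wastebasket, sampling
    )
    diag.to_csv(out / "diagnostics.csv", index=False)
    diagnostics.rank_distribution_long(genus_ab).to_csv(
        out / "rank_distributions.csv", index=False
    )
    log_lines.append(f"diagnose: mean sampling probability {sampling_avg}")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
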