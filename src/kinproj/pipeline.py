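"""Projection pipeline: kin summaries, ensembles, and regional aggregation.

Orchestrates the full analysis: per-location kinship projections across a
trajectory ensemble, the reported summary metrics (total family size, kin
counts per category, mean kin ages), median and 80% projection intervals
across trajectories, and population-weighted regional aggregates. Results are
tidy pandas tables ready for plotting or export.

Reporting conventions: a Focal age label means its age class ([65, 70) for
"65"), a year label means its 5-year period, and the 80% projection interval
is the 10th–90th percentile band across trajectories, computed with linear
interpolation of order statistics (quantile type 7).
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernel import (
    KIN_CATEGORIES,
    KinArray,
    KinNetwork,
    time_invariant_kinship,
    time_variant_kinship,
)
from .rates import AgeGrid, RateSeries, read_rate_series
from .synthetic import TrendParams, sample_trajectories

__all__ = [
    "ZeroKinError",
    "EnsembleSummary",
    "RunConfig",
    "total_family_size",
    "mean_kin_age",
    "summarize_ensemble",
    "aggregate_regions",
    "run_analysis",
]

logger = logging.getLogger("kinproj")


class ZeroKinError(ValueError):
    """A mean kin age was requested for an empty kin population."""


@dataclass(frozen=True)
class EnsembleSummary:
    """Median and 80% projection interval of one metric across trajectories."""

    median: float
    lo80: float
    hi80: float
    n_trajectories: int

    def __post_init__(self):
        if not (self.lo80 <= self.median <= self.hi80):
            raise ValueError("projection interval must bracket the median")


def total_family_size(net: KinNetwork, focal_age: int, time=None) -> float:
    """Total living kin across the ten reported categories, Focal excluded.

    Sums expected counts over all kin ages and sexes of great-grandparents,
    grandparents, parents, children, grandchildren, great-grandchildren,
    aunts/uncles, niblings, siblings, and cousins.
    """
    return float(sum(
        net.category_total(cat, focal_age, time) for cat in KIN_CATEGORIES
    ))


def mean_kin_age(arr: KinArray | np.ndarray, grid: AgeGrid | None = None,
                 sex: str = "both") -> float:
    """Count-weighted mean age of one kin population, in years.

    Ages are age-class midpoints (lower bound + step/2). ``sex`` restricts to
    the female or male block of a two-sex array. Raises :class:`ZeroKinError`
    when the kin population is empty rather than returning a number.
    """
    if isinstance(arr, KinArray):
        grid = arr.grid
        counts = {"both": arr.by_age, "female": arr.female, "male": arr.male}[sex]
    else:
        if grid is None:
            raise ValueError("grid is required for a bare count vector")
        counts = np.asarray(arr, dtype=float)
        n = grid.n_classes
        if counts.size == 2 * n:  # stacked two-sex vector
            counts = {"both": counts[:n] + counts[n:],
                      "female": counts[:n], "male": counts[n:]}[sex]
    total = counts.sum()
    if total <= 0:
        raise ZeroKinError("mean kin age undefined: no living kin of this type")
    return float(np.average(grid.midpoints, weights=counts))


def summarize_ensemble(values) -> EnsembleSummary:
    """Median and 10th/90th percentiles of per-trajectory metric values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty trajectory collection")
    lo, med, hi = np.percentile(v, [10.0, 50.0, 90.0], method="linear")
    return EnsembleSummary(median=float(med), lo80=float(lo), hi80=float(hi),
                           n_trajectories=int(v.size))


def aggregate_regions(
    per_location: dict[str, np.ndarray],
    region_map: dict[str, str],
    weights: dict[str, float],
) -> dict[str, EnsembleSummary]:
    """Population-weighted regional aggregation of per-trajectory metrics.

    ``per_location`` maps location → per-trajectory metric vector. For each
    region, the per-trajectory regional metric is the weights-weighted mean
    over member locations; the ensemble summary is then taken across
    trajectories. Weights are typically the population at Focal's age.
    """
    unmapped = sorted(set(per_location) - set(region_map))
    if unmapped:
        raise ValueError(f"locations not mapped to a region: {unmapped}")
    by_region: dict[str, list[str]] = {}
    for loc in per_location:
        by_region.setdefault(region_map[loc], []).append(loc)
    out = {}
    for region, locs in by_region.items():
        w = np.array([float(weights[loc]) for loc in locs])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError(f"region {region!r} has non-positive total weight")
        stack = np.vstack([np.asarray(per_location[loc], dtype=float) for loc in locs])
        regional = (w[:, None] * stack).sum(axis=0) / w.sum()
        out[region] = summarize_ensemble(regional)
    return out


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end projection run.

    ``mode`` selects the input source: ``"synthetic"`` builds rates from
    ``trends`` ({location → TrendParams}); ``"file"`` reads the canonical
    long-format CSV at ``rates_path`` (no trajectory ensemble: one
    deterministic trajectory per location).
    """

    mode: str = "synthetic"
    trends: dict = field(default_factory=dict)
    rates_path: str | None = None
    format_config: dict | None = None
    locations: list = field(default_factory=list)
    #: calendar years; None means 1950–2100 for synthetic input, or every
    #: year present in the file for file input
    years: list | None = None
    focal_ages: list = field(default_factory=lambda: [0, 35, 65])
    variant: str = "two_sex_androgynous"
    n_trajectories: int = 100
    seed: int = 0
    out_dir: str | None = None
    region_map: dict | None = None
    grid: AgeGrid = field(default_factory=AgeGrid.default)
    keep_full_results: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trends = {}
        for loc, tp in (raw.pop("trends", None) or {}).items():
            from .synthetic import ScheduleParams

            trends[loc] = TrendParams(
                start=ScheduleParams(**tp["start"]),
                end=ScheduleParams(**tp["end"]),
                **{k: v for k, v in tp.items() if k not in ("start", "end")},
            )
        grid = raw.pop("grid", None)
        cfg = cls(trends=trends, **raw)
        if grid:
            cfg.grid = AgeGrid(**grid)
        return cfg

    def metadata(self) -> dict:
        meta = dataclasses.asdict(self)
        meta["grid"] = {"n_classes": self.grid.n_classes,
                        "step_years": self.grid.step_years}
        meta["trends"] = {loc: dataclasses.asdict(tp) for loc, tp in self.trends.items()}
        meta["quantile_rule"] = "linear interpolation of order statistics (type 7)"
        return meta


def _location_ensembles(config: RunConfig):
    """Yield (location, median RateSeries, list of trajectory RateSeries)."""
    if config.mode == "synthetic":
        years = config.years or list(range(1950, 2105, 5))
        locations = config.locations or list(config.trends)
        for i, loc in enumerate(locations):
            tp = dataclasses.replace(
                config.trends[loc],
                n_trajectories=config.n_trajectories,
                location=loc,
            )
            loc_seed = (config.seed + 7919 * (i + 1)) % (2**31)
            ens = sample_trajectories(tp, config.grid, years, seed=loc_seed)
            yield loc, ens.median, list(ens.trajectories)
    elif config.mode == "file":
        series_map = read_rate_series(config.rates_path, config.format_config)
        locations = config.locations or sorted(series_map)
        for loc in locations:
            if loc not in series_map:
                raise KeyError(f"location {loc!r} not present in {config.rates_path}")
            s = series_map[loc]
            yield loc, s, [s]
    else:
        raise ValueError(f"unknown input mode {config.mode!r}")


def _summarize_network(net: KinNetwork, config: RunConfig, years):
    """Per-(year, focal age) category totals, mean ages and family size."""
    rows = []
    for year in years:
        for age_years in config.focal_ages:
            x = config.grid.class_index(age_years)
            for cat in KIN_CATEGORIES:
                counts = net.category_counts(cat, x, year)
                total = float(counts.sum())
                try:
                    mka = mean_kin_age(counts, config.grid)
                except ZeroKinError:
                    mka = np.nan
                rows.append((year, age_years, cat, total, mka))
            rows.append((year, age_years, "total_family_size",
                         total_family_size(net, x, year), np.nan))
    return rows


def run_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full projection analysis described by ``config``.

    For every location and trajectory: fit the time-invariant boundary model
    at the first year, project forward with the time-variant kernel, and
    summarise. Returns (and optionally writes under ``config.out_dir``):

    - ``trajectories``: per (location, trajectory, year, focal_age, metric)
      values, where metric is a kin category count, a mean kin age
      (``mean_age:<category>``), or ``total_family_size``;
    - ``summary``: ensemble median/lo80/hi80 per location and metric;
    - ``regional``: population-weighted regional summaries (if a region map
      is configured);
    - ``kin_full``: median-trajectory expected counts by kin age class and sex.

    A failure in one location aborts that location with a logged diagnostic;
    other locations continue.
    """
    t0 = _time.perf_counter()
    traj_rows, full_rows = [], []
    per_loc_metrics: dict[str, dict] = {}
    weights: dict[str, dict] = {}
    for loc, median_series, trajectories in _location_ensembles(config):
        t_loc = _time.perf_counter()
        years = [float(y) for y in (config.years or median_series.times)]
        try:
            nets = []
            for k, series in enumerate(trajectories):
                initial = time_invariant_kinship(series.period_at(0), config.variant)
                net = time_variant_kinship(series, initial, config.variant)
                nets.append(net)
                for (year, age_years, metric, value, mka) in _summarize_network(
                    net, config, years
                ):
                    traj_rows.append((loc, k, year, age_years, metric, value))
                    if np.isfinite(mka):
                        traj_rows.append(
                            (loc, k, year, age_years, f"mean_age:{metric}", mka)
                        )
            # median-trajectory full age-sex detail
            median_initial = time_invariant_kinship(
                median_series.period_at(0), config.variant
            )
            median_net = time_variant_kinship(
                median_series, median_initial, config.variant
            )
            if config.keep_full_results:
                for year in years:
                    for age_years in config.focal_ages:
                        x = config.grid.class_index(age_years)
                        for cat in KIN_CATEGORIES:
                            arr = median_net.category_counts(cat, x, year)
                            omega = config.grid.n_classes
                            female = arr[:omega]
                            male = (arr[omega:] if len(arr) > omega
                                    else np.zeros(omega))
                            for kx in range(omega):
                                lb = config.grid.lower_bounds[kx]
                                if female[kx] > 0:
                                    full_rows.append((loc, year, age_years, cat,
                                                      lb, "female", female[kx]))
                                if male[kx] > 0:
                                    full_rows.append((loc, year, age_years, cat,
                                                      lb, "male", male[kx]))
            # weights for regional aggregation: female population at Focal's age
            weights[loc] = {}
            for year in years:
                for age_years in config.focal_ages:
                    x = config.grid.class_index(age_years)
                    per = median_series.period(year)
                    weights[loc][(year, age_years)] = float(per.population.female[x])
            per_loc_metrics[loc] = {"n_traj": len(trajectories)}
            logger.info("location %s: %d trajectories in %.1fs",
                        loc, len(trajectories), _time.perf_counter() - t_loc)
        except Exception:
            logger.exception("location %s failed; continuing", loc)
            continue

    traj_df = pd.DataFrame(
        traj_rows,
        columns=["location", "trajectory", "year", "focal_age", "metric", "value"],
    )
    summaries = []
    for (loc, year, age, metric), sub in traj_df.groupby(
        ["location", "year", "focal_age", "metric"]
    ):
        es = summarize_ensemble(sub["value"].to_numpy())
        summaries.append((loc, year, age, metric, es.median, es.lo80, es.hi80))
    summary_df = pd.DataFrame(
        summaries,
        columns=["location", "year", "focal_age", "metric", "median", "lo80", "hi80"],
    )

    regional_df = pd.DataFrame(
        columns=["region", "year", "focal_age", "metric", "median", "lo80", "hi80"]
    )
    if config.region_map:
        reg_rows = []
        for (year, age, metric), sub in traj_df.groupby(["year", "focal_age", "metric"]):
            per_location = {}
            for loc, lsub in sub.groupby("location"):
                per_location[loc] = (
                    lsub.sort_values("trajectory")["value"].to_numpy()
                )
            w = {loc: weights[loc][(year, age)] for loc in per_location}
            for region, es in aggregate_regions(
                per_location, config.region_map, w
            ).items():
                reg_rows.append((region, year, age, metric,
                                 es.median, es.lo80, es.hi80))
        regional_df = pd.DataFrame(reg_rows, columns=list(regional_df.columns))

    full_df = pd.DataFrame(
        full_rows,
        columns=["location", "year", "focal_age", "kin_category",
                 "kin_age_class", "sex", "expected_count"],
    )
    results = {
        "trajectories": traj_df,
        "summary": summary_df,
        "regional": regional_df,
        "kin_full": full_df,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        with open(out / "metadata.yaml", "w") as fh:
            yaml.safe_dump(config.metadata(), fh, sort_keys=True)
    logger.info("analysis finished in %.1fs (seed=%d)",
                _time.perf_counter() - t0, config.seed)
    return results
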