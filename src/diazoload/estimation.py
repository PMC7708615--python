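"""Core estimation chain: volumetric fixation → areal rates → basin loads.

The chain implements a deliberately simple upscaling model:

1. **Volumetric rate.** For each genus in each tube sample, estimated
   fixation = per-biovolume rate (µmol N mm⁻³ d⁻¹) × biovolume (mm³ L⁻¹).
   Numerically the product is already in mmol N m⁻³ d⁻¹ because
   1 µmol L⁻¹ = 1 mmol m⁻³.
2. **Areal rate.** The volumetric rate is taken as representative of the top
   10 m and depth-integrated by multiplying with the integration depth,
   giving mmol N m⁻² d⁻¹.
3. **Monthly basin mean.** Genus rates are summed within each sampling
   event; events are averaged within each station-month; station-month means
   are averaged (unweighted) across the basin's stations. The monthly total
   is the mean daily rate × 30 days, regardless of calendar month length.
4. **Annual load.** Monthly totals are summed to mmol N m⁻² yr⁻¹ and scaled
   by basin surface area and the molar mass of nitrogen (14.0067 g mol⁻¹)
   to kilotonnes N per year.

Months without any sampling event contribute zero to the annual sum (with a
logged gap warning); winter biovolumes of the filamentous diazotrophs are
near zero, so this is a small, conservative bias. Where sampling is too
sparse for stable annual means, years can be pooled into multi-year blocks
(:func:`pooled_year_blocks`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .monitoring_io import GROUP_CYANO, MonitoringSample
from .rates import GenusRate

logger = logging.getLogger(__name__)

#: Standard atomic weight of nitrogen, g mol⁻¹.
N_MOLAR_MASS = 14.0067

#: Fixed month length used for monthly totals, days.
DAYS_PER_MONTH = 30.0

#: Depth over which the volumetric rate is integrated, m.
DEFAULT_INTEGRATION_DEPTH = 10.0


@dataclasses.dataclass(frozen=True)
class BasinConfig:
    """A basin: surface area, member stations and the year-pooling width."""

    name: str
    area_km2: float
    stations: tuple[str, ...]
    pooling_years: int = 1

    def __post_init__(self):
        if not self.area_km2 > 0:
            raise ConfigurationError(f"basin area must be > 0, got {self.area_km2}")
        if not self.stations:
            raise ConfigurationError(f"basin {self.name!r} has no stations")
        if self.pooling_years < 1:
            raise ConfigurationError("pooling_years must be >= 1")
        object.__setattr__(self, "stations", tuple(self.stations))


@dataclasses.dataclass(frozen=True)
class ArealRate:
    """Depth-integrated fixation for one genus in one sampling event."""

    station: str
    date: object
    taxon: str
    volumetric: float  # mmol N m⁻³ day⁻¹
    areal: float  # mmol N m⁻² day⁻¹
    integration_depth: float  # m

    def __post_init__(self):
        expected = self.volumetric * self.integration_depth
        if self.areal != expected:
            raise ValidationError(
                f"areal ({self.areal}) != volumetric × depth ({expected})"
            )


@dataclasses.dataclass(frozen=True)
class MonthlyBasinEstimate:
    """Mean daily and 30-day total areal fixation for one basin-month."""

    basin: str
    year_block: tuple[int, ...]
    month: int
    mean_daily: float  # mmol N m⁻² day⁻¹
    monthly_total: float  # mmol N m⁻² month⁻¹
    n_samples: int


@dataclasses.dataclass(frozen=True)
class AnnualLoad:
    """Annual areal fixation and the basin-wide mass load it implies."""

    basin: str
    year_block: tuple[int, ...]
    areal_annual: float  # mmol N m⁻² year⁻¹
    load: float  # kt N year⁻¹
    sd: float | None = None  # kt N year⁻¹, across years where applicable


@dataclasses.dataclass(frozen=True)
class LoadSummary:
    """Across-year mean ± sample standard deviation of annual loads."""

    basin: str
    mean: float  # kt N year⁻¹
    sd: float | None  # kt N year⁻¹ (None when < 2 values)
    n: int
    years: tuple[int, ...]


def load_kt_per_year(areal_annual: float, area_km2: float) -> float:
    """Convert mmol N m⁻² yr⁻¹ over ``area_km2`` to kt N yr⁻¹.

    kt = mmol m⁻² yr⁻¹ × area[m²] × 14.0067×10⁻³ g mmol⁻¹ / 10⁹ g kt⁻¹.
    """
    return areal_annual * area_km2 * 1e6 * N_MOLAR_MASS * 1e-12


def volumetric_fixation(sample: MonitoringSample, rate: GenusRate) -> float:
    """Per-sample volumetric fixation, mmol N m⁻³ day⁻¹ (rate × biovolume)."""
    if sample.taxon != rate.taxon:
        raise ValidationError(
            f"taxon mismatch: sample {sample.taxon!r} vs rate {rate.taxon!r}"
        )
    return rate.rate * sample.biovolume


def integrate_areal(volumetric: float, depth: float = DEFAULT_INTEGRATION_DEPTH) -> float:
    """Depth-integrate a volumetric rate (mmol m⁻³ d⁻¹ × m → mmol m⁻² d⁻¹)."""
    if not depth > 0:
        raise ValidationError(f"integration depth must be > 0, got {depth!r}")
    return volumetric * depth


def areal_rate_table(
    samples: pd.DataFrame,
    rates: Mapping[str, GenusRate],
    depth: float = DEFAULT_INTEGRATION_DEPTH,
) -> pd.DataFrame:
    """Per-(station, event, genus) volumetric and areal rates.

    Only taxa present in ``rates`` contribute (the ``other`` pool is not
    diazotrophic). Returns columns station, date, taxon, biovolume,
    volumetric, areal, integration_depth.
    """
    if not depth > 0:
        raise ValidationError(f"integration depth must be > 0, got {depth!r}")
    cols = ["station", "date", "taxon", "biovolume", "volumetric", "areal",
            "integration_depth"]
    if samples.empty:
        return pd.DataFrame(columns=cols)
    diazo = samples[samples["taxon"].isin(rates)].copy()
    rate_map = {k: v.rate for k, v in rates.items()}
    diazo["volumetric"] = diazo["taxon"].map(rate_map) * diazo["biovolume"]
    diazo["areal"] = diazo["volumetric"] * depth
    diazo["integration_depth"] = depth
    return diazo[cols].reset_index(drop=True)


def event_areal_table(
    samples: pd.DataFrame,
    rates: Mapping[str, GenusRate],
    depth: float = DEFAULT_INTEGRATION_DEPTH,
) -> pd.DataFrame:
    """Total areal fixation per sampling event (station, date).

    Every distinct (station, date) in the *full* input is an event, including
    casts in which no diazotroph was recorded — those are genuine zeros, not
    missing observations, and enter the monthly means as 0.
    """
    cols = ["station", "date", "year", "month", "areal"]
    if samples.empty:
        return pd.DataFrame(columns=cols)
    events = samples[["station", "date"]].drop_duplicates().set_index(["station", "date"])
    per_taxon = areal_rate_table(samples, rates, depth)
    if per_taxon.empty:
        totals = pd.Series(0.0, index=events.index)
    else:
        totals = per_taxon.groupby(["station", "date"])["areal"].sum()
    out = events.join(totals.rename("areal")).fillna({"areal": 0.0}).reset_index()
    dates = pd.to_datetime(out["date"])
    out["year"] = dates.dt.year
    out["month"] = dates.dt.month
    return out[cols]


def monthly_basin_mean(
    events: pd.DataFrame,
    basin: BasinConfig,
    month: int,
    year_block: Sequence[int],
) -> MonthlyBasinEstimate:
    """Basin-mean daily areal fixation for one month of one year block.

    Events are averaged within each station-month (pooling all years of the
    block), then station means are averaged without weighting across the
    basin's stations. A basin-month with no events at any station yields
    mean_daily 0 and a logged gap warning.
    """
    year_block = tuple(sorted(year_block))
    sel = events[
        events["station"].isin(basin.stations)
        & (events["month"] == month)
        & events["year"].isin(year_block)
    ]
    n = len(sel)
    if n == 0:
        logger.warning(
            "no samples for basin %s, month %d, years %s; monthly mean set to 0",
            basin.name, month, year_block,
        )
        mean_daily = 0.0
    else:
        mean_daily = float(sel.groupby("station")["areal"].mean().mean())
    return MonthlyBasinEstimate(
        basin=basin.name,
        year_block=year_block,
        month=month,
        mean_daily=mean_daily,
        monthly_total=mean_daily * DAYS_PER_MONTH,
        n_samples=n,
    )


def monthly_basin_table(
    events: pd.DataFrame,
    basin: BasinConfig,
    year_block: Sequence[int],
    gap_policy: str = "zero",
) -> list[MonthlyBasinEstimate]:
    """All twelve monthly estimates for a basin and year block.

    gap_policy "zero" keeps unsampled months as explicit zero entries;
    "skip" drops them (the annual *sum* is identical either way — the switch
    only changes whether the gaps appear in the output tables).
    """
    if gap_policy not in ("zero", "skip"):
        raise ConfigurationError(f"gap_policy must be 'zero' or 'skip', got {gap_policy!r}")
    monthlies = [monthly_basin_mean(events, basin, m, year_block) for m in range(1, 13)]
    if gap_policy == "skip":
        monthlies = [m for m in monthlies if m.n_samples > 0]
    return monthlies


def annual_load(
    monthlies: Sequence[MonthlyBasinEstimate], basin: BasinConfig
) -> AnnualLoad:
    """Sum monthly totals into an annual areal estimate and basin mass load."""
    months = [m.month for m in monthlies]
    if len(months) != len(set(months)):
        raise ValidationError(f"duplicate month in year block: {sorted(months)}")
    wrong = {m.basin for m in monthlies} - {basin.name}
    if wrong:
        raise ValidationError(f"monthly estimates from foreign basin(s): {sorted(wrong)}")
    blocks = {m.year_block for m in monthlies}
    if len(blocks) > 1:
        raise ValidationError(f"monthly estimates mix year blocks: {sorted(blocks)}")
    areal_annual = float(sum(m.monthly_total for m in monthlies))
    year_block = blocks.pop() if blocks else ()
    return AnnualLoad(
        basin=basin.name,
        year_block=year_block,
        areal_annual=areal_annual,
        load=load_kt_per_year(areal_annual, basin.area_km2),
    )


def pooled_year_blocks(years: Iterable[int], pooling: int = 1) -> list[tuple[int, ...]]:
    """Partition a contiguous span of years into near-equal blocks.

    ``pooling`` is the target block size in years: 1 gives annual singleton
    blocks; otherwise the span is split into round(n / pooling) contiguous
    blocks whose sizes differ by at most one, with the remainder assigned
    middle-out (a 19-year span at pooling 6 gives blocks of 6, 7 and 6
    years).
    """
    ys = sorted(set(int(y) for y in years))
    if not ys:
        return []
    if ys != list(range(ys[0], ys[-1] + 1)):
        missing = sorted(set(range(ys[0], ys[-1] + 1)) - set(ys))
        raise ValidationError(f"years must be contiguous; missing {missing}")
    if pooling < 1:
        raise ConfigurationError(f"pooling must be >= 1, got {pooling}")
    if pooling == 1:
        return [(y,) for y in ys]
    n = len(ys)
    n_blocks = max(1, round(n / pooling))
    base, rem = divmod(n, n_blocks)
    sizes = [base] * n_blocks
    centre = (n_blocks - 1) / 2
    for i in sorted(range(n_blocks), key=lambda i: (abs(i - centre), i))[:rem]:
        sizes[i] += 1
    blocks, start = [], 0
    for s in sizes:
        blocks.append(tuple(ys[start:start + s]))
        start += s
    return blocks


def estimate_basin_loads(
    samples: pd.DataFrame,
    rates: Mapping[str, GenusRate],
    basins: Mapping[str, BasinConfig],
    depth: float = DEFAULT_INTEGRATION_DEPTH,
    gap_policy: str = "zero",
    pooling: Mapping[str, int] | None = None,
) -> tuple[list[MonthlyBasinEstimate], list[AnnualLoad]]:
    """End-to-end: depth-corrected samples → monthly estimates and loads.

    ``pooling`` overrides each basin's configured ``pooling_years``. Years
    are taken from the data footprint of each basin's stations; basins with
    no data are skipped with a warning.
    """
    events = event_areal_table(samples, rates, depth)
    all_monthlies: list[MonthlyBasinEstimate] = []
    loads: list[AnnualLoad] = []
    for name, basin in basins.items():
        sel = events[events["station"].isin(basin.stations)]
        if sel.empty:
            logger.warning("basin %s has no sampling events; skipped", name)
            continue
        years = range(int(sel["year"].min()), int(sel["year"].max()) + 1)
        width = (pooling or {}).get(name, basin.pooling_years)
        for block in pooled_year_blocks(years, width):
            monthlies = monthly_basin_table(events, basin, block, gap_policy)
            all_monthlies.extend(monthlies)
            loads.append(annual_load(monthlies, basin))
    return all_monthlies, loads


def multi_year_summary(
    loads: Sequence[AnnualLoad], years_subset: Iterable[int] | None = None
) -> LoadSummary:
    """Mean ± sample standard deviation (n−1) of annual/block loads.

    With ``years_subset`` only loads whose year block lies entirely inside
    the subset are used. sd is None when a single load remains; an empty
    selection is an error.
    """
    sel = list(loads)
    if years_subset is not None:
        subset = set(int(y) for y in years_subset)
        sel = [l for l in sel if set(l.year_block) <= subset]
    if not sel:
        raise ValidationError("no annual loads in the requested year subset")
    basins = {l.basin for l in sel}
    if len(basins) > 1:
        raise ValidationError(f"loads mix basins: {sorted(basins)}")
    vals = np.array([l.load for l in sel], dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else None
    years = tuple(sorted(y for l in sel for y in l.year_block))
    return LoadSummary(basin=basins.pop(), mean=float(vals.mean()), sd=sd,
                       n=len(vals), years=years)


def carbon_fraction_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Filamentous-cyanobacteria share of total autotroph carbon per
    station-month (pooled across years).

    Returns columns station, month, cyano_carbon, total_carbon, fraction.
    fraction is NaN (and flagged in the log) where the total carbon is zero.
    Requires the optional carbon and group columns.
    """
    for col in ("carbon", "group"):
        if col not in samples.columns or samples[col].isna().all():
            raise ConfigurationError(f"carbon fraction requires the {col!r} column")
    df = samples.dropna(subset=["carbon", "group"]).copy()
    df["month"] = pd.to_datetime(df["date"]).dt.month
    total = df.groupby(["station", "month"])["carbon"].sum().rename("total_carbon")
    cyano = (
        df[df["group"] == GROUP_CYANO]
        .groupby(["station", "month"])["carbon"].sum()
        .rename("cyano_carbon")
    )
    out = pd.concat([cyano, total], axis=1).fillna({"cyano_carbon": 0.0}).reset_index()
    zero = out["total_carbon"] == 0
    if zero.any():
        logger.warning(
            "zero total carbon for %d station-month(s); fraction undefined", zero.sum()
        )
    out["fraction"] = np.where(zero, np.nan, out["cyano_carbon"] / out["total_carbon"])
    return out[["station", "month", "cyano_carbon", "total_carbon", "fraction"]]


def carbon_fraction(samples: pd.DataFrame, station: str, month: int) -> float:
    """Scalar convenience wrapper around :func:`carbon_fraction_table`."""
    tbl = carbon_fraction_table(samples)
    sel = tbl[(tbl["station"] == station) & (tbl["month"] == month)]
    if sel.empty:
        return math.nan
    return float(sel["fraction"].iloc[0])
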