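"""Synthetic plankton monitoring tables with known ground truth.

The generator emulates the features of Baltic monitoring series that matter
to the load-estimation chain: three diazotroph genera with distinct
unimodal summer blooms (a Gaussian bump in day-of-year on top of a winter
baseline that is non-zero only for *Aphanizomenon*), strong lognormal
patchiness with occasional zero catches, slow interannual trends, per-month
sampling frequencies that peak in summer, and the tube-depth convention (a
0–20 m station reports about half the 0–10 m concentration, which the
pipeline corrects by 2×).

Each sampled biovolume is drawn as

    seasonal_mean(day, year) × LN(0, σ) × Bernoulli(1 − p) / E[LN × Bern]

so the *expectation* of every draw equals the configured seasonal mean.
Because the whole estimation chain is linear in biovolume, the expected
pipeline output has a closed form, which :func:`expected_loads` evaluates
exactly — that is the generator's ground truth, and noise-free scenarios
(σ = 0, p = 0) must reproduce it to machine precision.

Sampling days within a month are deterministic (evenly spaced), so the
ground-truth expectation is exact rather than an average over random
schedules. There is no spatial correlation between stations and no
mechanistic bloom dynamics.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import load_config
from .estimation import (
    AnnualLoad,
    BasinConfig,
    DAYS_PER_MONTH,
    DEFAULT_INTEGRATION_DEPTH,
    load_kt_per_year,
    pooled_year_blocks,
)
from .exceptions import ValidationError
from .monitoring_io import (
    CANONICAL_COLUMNS,
    GROUP_CYANO,
    GROUP_DIATOMS,
    GROUP_FLAGELLATES,
    StationConfig,
)
from .rates import GenusRate, default_rates


@dataclasses.dataclass(frozen=True)
class BloomParams:
    """Seasonal bloom of one taxon (or autotroph group) at one station.

    Biovolumes in mm³ L⁻¹ refer to the *true* 0–10 m mean; the generator
    divides by the station's depth correction when emitting tube values.
    """

    peak_day: float  # day of year of the bloom maximum
    peak_biovolume: float  # mm³ L⁻¹ at the maximum (reference year)
    seasonal_width: float  # Gaussian width, days
    winter_baseline: float = 0.0  # mm³ L⁻¹ far from the bloom
    interannual_trend: float = 0.0  # fractional change per year
    noise_sigma: float = 1.0  # lognormal sigma of sampling patchiness
    zero_inflation: float = 0.0  # probability of a zero catch

    def __post_init__(self):
        if not (self.peak_biovolume >= self.winter_baseline >= 0):
            raise ValidationError(
                f"need peak_biovolume >= winter_baseline >= 0, got "
                f"{self.peak_biovolume} / {self.winter_baseline}"
            )
        if not self.seasonal_width > 0:
            raise ValidationError(f"seasonal_width must be > 0, got {self.seasonal_width}")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError(f"zero_inflation must be in [0, 1), got {self.zero_inflation}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclasses.dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of a synthetic monitoring campaign."""

    seed: int
    years: tuple[int, ...]
    stations: dict[str, StationConfig]
    blooms: dict[str, dict[str, BloomParams]]  # station -> genus -> params
    schedule: dict[str, dict[int, int]]  # station -> month -> events
    others: dict[str, dict[str, BloomParams]] = dataclasses.field(default_factory=dict)
    reference_year: int = 2008
    carbon_density: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            GROUP_CYANO: 200.0,  # µg C per mm³ biovolume
            GROUP_DIATOMS: 110.0,
            GROUP_FLAGELLATES: 180.0,
        }
    )

    def __post_init__(self):
        ys = sorted(self.years)
        if not ys:
            raise ValidationError("scenario needs at least one year")
        if ys != list(range(ys[0], ys[-1] + 1)):
            raise ValidationError("scenario years must be contiguous")
        object.__setattr__(self, "years", tuple(ys))
        for mapping, what in ((self.blooms, "blooms"), (self.schedule, "schedule"),
                              (self.others, "others")):
            unknown = set(mapping) - set(self.stations)
            if unknown:
                raise ValidationError(f"{what} reference unknown station(s): {sorted(unknown)}")


def seasonal_mean(params: BloomParams, day_of_year, year, reference_year: int):
    """Expected true biovolume on a given day (vectorised over day/year).

    Gaussian bump plus baseline; contributions beyond six widths from the
    peak are clamped to exactly zero so that taxa absent in winter really
    are absent. The interannual trend scales the whole curve by
    (1 + trend)^(year − reference_year).
    """
    doy = np.asarray(day_of_year, dtype=float)
    yr = np.asarray(year, dtype=float)
    z = (doy - params.peak_day) / params.seasonal_width
    bump = np.where(np.abs(z) <= 6.0, np.exp(-0.5 * z * z), 0.0)
    base = params.winter_baseline + (params.peak_biovolume - params.winter_baseline) * bump
    return base * (1.0 + params.interannual_trend) ** (yr - reference_year)


def scheduled_days(year: int, month: int, n_events: int) -> list[int]:
    """Deterministic, evenly spaced sampling days of month."""
    if n_events <= 0:
        return []
    length = calendar.monthrange(year, month)[1]
    return [min(length, int((j + 0.5) * length / n_events) + 1) for j in range(n_events)]


def _station_events(scenario: SyntheticScenario, station: str):
    """(dates, day-of-year, year) arrays for one station's full campaign."""
    sched = scenario.schedule.get(station, {})
    dates: list[datetime.date] = []
    for year in scenario.years:
        for month in range(1, 13):
            for day in scheduled_days(year, month, sched.get(month, 0)):
                dates.append(datetime.date(year, month, day))
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    yr = np.array([d.year for d in dates], dtype=float)
    return dates, doy, yr


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Analytic expectation of the pipeline output for a scenario."""

    loads: tuple[AnnualLoad, ...]  # at each basin's configured pooling
    loads_annual: tuple[AnnualLoad, ...]  # pooling 1

    def to_dict(self) -> dict:
        def row(l: AnnualLoad) -> dict:
            return {
                "basin": l.basin,
                "years": list(l.year_block),
                "areal_annual_mmol_m2_yr": l.areal_annual,
                "load_kt_yr": l.load,
            }

        return {
            "pooled_loads": [row(l) for l in self.loads],
            "annual_loads": [row(l) for l in self.loads_annual],
        }


def _noise_factors(rng: np.random.Generator, params: BloomParams, n: int) -> np.ndarray:
    """Mean-one multiplicative noise: lognormal patchiness × zero catches."""
    if params.noise_sigma > 0:
        factors = rng.lognormal(mean=-0.5 * params.noise_sigma ** 2,
                                sigma=params.noise_sigma, size=n)
    else:
        factors = np.ones(n)
    if params.zero_inflation > 0:
        keep = rng.random(n) >= params.zero_inflation
        factors = factors * keep / (1.0 - params.zero_inflation)
    return factors


def generate(
    scenario: SyntheticScenario,
    seed: int | None = None,
    rates: Mapping[str, GenusRate] | None = None,
    basins: Mapping[str, BasinConfig] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic monitoring table and its analytic ground truth.

    Returns a tidy table in the same schema :mod:`diazoload.monitoring_io`
    reads (biovolumes as the tube would report them, i.e. *before* depth
    correction) together with the exact expected pipeline loads. Output is
    deterministic for a fixed ``seed`` (default: ``scenario.seed``).

    A taxon row is emitted whenever its seasonal mean is positive, so a zero
    catch appears as an explicit zero-biovolume row rather than a missing
    one — the sampling event itself took place and must enter the monthly
    means.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    rates = default_rates() if rates is None else rates
    basins = load_config().basins if basins is None else basins

    cols: dict[str, list] = {c: [] for c in CANONICAL_COLUMNS}
    for sid, st in scenario.stations.items():
        dates, doy, yr = _station_events(scenario, sid)
        n = len(dates)
        if n == 0:
            continue
        corr = st.depth_correction
        emit_groups = [
            (taxon, params, GROUP_CYANO)
            for taxon, params in sorted(scenario.blooms.get(sid, {}).items())
        ] + [
            ("other", params, group)
            for group, params in sorted(scenario.others.get(sid, {}).items())
        ]
        for taxon, params, group in emit_groups:
            mean = seasonal_mean(params, doy, yr, scenario.reference_year)
            factors = _noise_factors(rng, params, n)
            emitted = mean / corr * factors
            mask = mean > 0
            if not mask.any():
                continue
            density = scenario.carbon_density.get(group, 0.0)
            k = int(mask.sum())
            cols["station"].extend([sid] * k)
            cols["date"].extend(d for d, m in zip(dates, mask) if m)
            cols["depth_top"].extend([st.tube_top] * k)
            cols["depth_bottom"].extend([st.tube_bottom] * k)
            cols["taxon"].extend([taxon] * k)
            cols["biovolume"].extend(emitted[mask])
            cols["carbon"].extend(emitted[mask] * density)
            cols["group"].extend([group] * k)

    df = pd.DataFrame(cols)
    if not df.empty:
        df["date"] = pd.to_datetime(df["date"])
        df = df.sort_values(["station", "date", "taxon", "group"]).reset_index(drop=True)
    truth = GroundTruth(
        loads=tuple(expected_loads(scenario, rates, basins)),
        loads_annual=tuple(expected_loads(scenario, rates, basins, pooling=1)),
    )
    return df, truth


def expected_station_month_daily(
    scenario: SyntheticScenario,
    station: str,
    month: int,
    years: Sequence[int],
    rates: Mapping[str, GenusRate],
    depth: float = DEFAULT_INTEGRATION_DEPTH,
) -> float | None:
    """Expected station-month mean daily areal rate, mmol N m⁻² day⁻¹.

    Averages the analytic expectation over the deterministic sampling days
    of ``month`` across ``years``. None when the station is never sampled in
    that month (it then drops out of the basin mean, as in the pipeline).
    """
    sched = scenario.schedule.get(station, {})
    n = sched.get(month, 0)
    if n == 0:
        return None
    total, count = 0.0, 0
    for year in years:
        for day in scheduled_days(year, month, n):
            doy = datetime.date(year, month, day).timetuple().tm_yday
            areal = 0.0
            for taxon, params in scenario.blooms.get(station, {}).items():
                if taxon in rates:
                    mean = float(seasonal_mean(params, doy, year, scenario.reference_year))
                    areal += rates[taxon].rate * mean * depth
            total += areal
            count += 1
    return total / count


def expected_loads(
    scenario: SyntheticScenario,
    rates: Mapping[str, GenusRate] | None = None,
    basins: Mapping[str, BasinConfig] | None = None,
    pooling: int | Mapping[str, int] | None = None,
    depth: float = DEFAULT_INTEGRATION_DEPTH,
) -> list[AnnualLoad]:
    """Exact expected annual/block loads, mirroring the pipeline's
    aggregation (event → station-month → basin-month → annual → load)."""
    rates = default_rates() if rates is None else rates
    basins = load_config().basins if basins is None else basins
    out: list[AnnualLoad] = []
    for name, basin in basins.items():
        members = [s for s in basin.stations if s in scenario.stations]
        if not members:
            continue
        if pooling is None:
            width = basin.pooling_years
        elif isinstance(pooling, int):
            width = pooling
        else:
            width = pooling.get(name, basin.pooling_years)
        for block in pooled_year_blocks(scenario.years, width):
            areal_annual = 0.0
            for month in range(1, 13):
                station_means = [
                    m
                    for s in members
                    if (m := expected_station_month_daily(
                        scenario, s, month, block, rates, depth)) is not None
                ]
                mean_daily = sum(station_means) / len(station_means) if station_means else 0.0
                areal_annual += mean_daily * DAYS_PER_MONTH
            out.append(
                AnnualLoad(
                    basin=name,
                    year_block=tuple(block),
                    areal_annual=areal_annual,
                    load=load_kt_per_year(areal_annual, basin.area_km2),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Default Baltic-like scenario
# ---------------------------------------------------------------------------

_BP_SCHEDULE = {1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 2, 7: 3, 8: 2, 9: 2, 10: 1, 11: 1, 12: 1}
_BS_SCHEDULE = {1: 1, 2: 1, 3: 2, 4: 2, 5: 1, 6: 1, 7: 1, 8: 1, 9: 1, 10: 1, 11: 1, 12: 1}
_BB_SCHEDULE = {m: 1 for m in range(1, 13)}


def _cyano(peak_day, peak, width, baseline=0.0, trend=0.0):
    return BloomParams(
        peak_day=peak_day, peak_biovolume=peak, seasonal_width=width,
        winter_baseline=baseline, interannual_trend=trend,
        noise_sigma=1.0, zero_inflation=0.05,
    )


def _smooth(peak_day, peak, width, baseline=0.0):
    # background autotroph groups: milder patchiness, never fully absent
    return BloomParams(
        peak_day=peak_day, peak_biovolume=peak, seasonal_width=width,
        winter_baseline=baseline, noise_sigma=0.6, zero_inflation=0.0,
    )


def default_scenario(seed: int = 0, years: Sequence[int] = range(1999, 2018)) -> SyntheticScenario:
    """A Baltic-like eight-station campaign, 1999–2017 by default.

    Bloom parameters are calibrated to the region's observed phenology and
    magnitudes: an *Aphanizomenon*-dominated north with a winter-only
    baseline presence, *Nodularia* strongest in the southern Baltic Proper,
    *Dolichospermum* minor everywhere, near-absent cyanobacteria in the
    Bothnian Bay (July mean < 0.001 mm³ L⁻¹), Bothnian Sea July areal
    fixation of order 1 mmol N m⁻² day⁻¹, and a strong upward Bothnian Sea
    trend against a nearly flat Baltic Proper. Spring diatom and summer
    flagellate carbon provide the autotroph background for the
    carbon-fraction summaries.
    """
    stations = load_config().stations
    northern_bp = {
        "Aphanizomenon": _cyano(195, 0.25, 25, baseline=0.004, trend=0.005),
        "Nodularia": _cyano(215, 0.07, 20, trend=0.005),
        "Dolichospermum": _cyano(200, 0.025, 20, trend=0.005),
    }
    southern_bp = {
        "Aphanizomenon": _cyano(190, 0.10, 25, baseline=0.003, trend=0.005),
        "Nodularia": _cyano(215, 0.15, 20, trend=0.005),
        "Dolichospermum": _cyano(205, 0.025, 20, trend=0.005),
    }
    bothnian_sea = {
        "Aphanizomenon": _cyano(200, 0.10, 25, baseline=0.002, trend=0.07),
        "Nodularia": _cyano(215, 0.004, 15, trend=0.07),
        "Dolichospermum": _cyano(200, 0.01, 20, trend=0.07),
    }
    bothnian_bay = {
        "Aphanizomenon": _cyano(205, 0.0008, 20, baseline=0.00003),
        "Dolichospermum": _cyano(205, 0.0001, 15),
    }
    blooms = {
        "B1": northern_bp, "BY31": northern_bp,
        "BY15": southern_bp, "BY5": southern_bp, "BY2": southern_bp,
        "C3": bothnian_sea, "B3+B7": bothnian_sea,
        "F9/A13": bothnian_bay,
    }
    others = {}
    for sid in stations:
        if sid == "F9/A13":
            others[sid] = {
                GROUP_DIATOMS: _smooth(110, 0.15, 25, baseline=0.01),
                GROUP_FLAGELLATES: _smooth(180, 0.30, 60, baseline=0.05),
            }
        elif sid in ("C3", "B3+B7"):
            others[sid] = {
                GROUP_DIATOMS: _smooth(110, 0.8, 20, baseline=0.02),
                GROUP_FLAGELLATES: _smooth(180, 0.45, 60, baseline=0.05),
            }
        else:
            others[sid] = {
                GROUP_DIATOMS: _smooth(80, 1.2, 20, baseline=0.02),
                GROUP_FLAGELLATES: _smooth(180, 0.50, 60, baseline=0.05),
            }
    schedule = {}
    for sid, st in stations.items():
        if st.basin == "baltic_proper":
            schedule[sid] = dict(_BP_SCHEDULE)
        elif st.basin == "bothnian_sea":
            schedule[sid] = dict(_BS_SCHEDULE)
        else:
            schedule[sid] = dict(_BB_SCHEDULE)
    return SyntheticScenario(
        seed=seed,
        years=tuple(years),
        stations=dict(stations),
        blooms=blooms,
        others=others,
        schedule=schedule,
    )
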