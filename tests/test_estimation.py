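"""Volumetric→areal→monthly→annual aggregation and load conversion."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from diazoload import estimation as est
from diazoload.exceptions import ConfigurationError, ValidationError
from diazoload.monitoring_io import MonitoringSample
from diazoload.rates import default_rates

from conftest import make_samples


def sample(taxon="Aphanizomenon", biovolume=1.0, station="C3"):
    return MonitoringSample(
        station=station, date=pd.Timestamp("2005-07-10").date(),
        depth_top=0.0, depth_bottom=10.0, taxon=taxon, biovolume=biovolume,
    )


BOTHNIAN_SEA = est.BasinConfig("bothnian_sea", area_km2=79000,
                               stations=("C3", "B3+B7"), pooling_years=6)


class TestVolumetricFixation:
    def test_unit_biovolume_gives_rate(self, genus_rates):
        v = est.volumetric_fixation(sample(biovolume=1.0), genus_rates["Aphanizomenon"])
        assert v == pytest.approx(0.66)

    def test_zero_biovolume(self, genus_rates):
        assert est.volumetric_fixation(sample(biovolume=0.0),
                                       genus_rates["Aphanizomenon"]) == 0.0

    def test_dolichospermum_half_unit(self, genus_rates):
        v = est.volumetric_fixation(sample("Dolichospermum", 0.5),
                                    genus_rates["Dolichospermum"])
        assert v == pytest.approx(0.60)

    def test_taxon_mismatch_is_error(self, genus_rates):
        with pytest.raises(ValidationError):
            est.volumetric_fixation(sample("Nodularia"), genus_rates["Aphanizomenon"])


class TestIntegrateAreal:
    def test_ten_metre_chain_from_default_rate(self):
        assert est.integrate_areal(0.66, 10.0) == pytest.approx(6.6)

    def test_zero_rate_any_depth(self):
        assert est.integrate_areal(0.0, 3.7) == 0.0

    def test_identity_depth(self):
        assert est.integrate_areal(1.0, 1.0) == 1.0

    def test_nonpositive_depth_is_error(self):
        with pytest.raises(ValidationError):
            est.integrate_areal(1.0, 0.0)


class TestMonthlyBasinMean:
    def test_single_july_event(self, genus_rates):
        df = make_samples([("C3", "2005-07-10", "Aphanizomenon", 1.0)])
        events = est.event_areal_table(df, genus_rates)
        m = est.monthly_basin_mean(events, BOTHNIAN_SEA, 7, [2005])
        assert m.mean_daily == pytest.approx(6.6)
        assert m.monthly_total == pytest.approx(198.0)
        assert m.n_samples == 1

    def test_station_means_weighted_equally(self, genus_rates):
        # C3: two events (areal 6.6, 13.2) -> station mean 9.9
        # B3+B7: one event 6.6; basin mean = (9.9 + 6.6)/2
        df = make_samples([
            ("C3", "2005-07-05", "Aphanizomenon", 1.0),
            ("C3", "2005-07-20", "Aphanizomenon", 2.0),
            ("B3+B7", "2005-07-12", "Aphanizomenon", 1.0),
        ])
        events = est.event_areal_table(df, genus_rates)
        m = est.monthly_basin_mean(events, BOTHNIAN_SEA, 7, [2005])
        assert m.mean_daily == pytest.approx((9.9 + 6.6) / 2)
        assert m.n_samples == 3

    def test_empty_month_is_zero_with_warning(self, genus_rates, caplog):
        df = make_samples([("C3", "2005-07-10", "Aphanizomenon", 1.0)])
        events = est.event_areal_table(df, genus_rates)
        with caplog.at_level(logging.WARNING, logger="diazoload.estimation"):
            m = est.monthly_basin_mean(events, BOTHNIAN_SEA, 2, [2005])
        assert m.mean_daily == 0.0
        assert m.n_samples == 0
        assert any("no samples" in r.message for r in caplog.records)

    def test_cast_without_diazotrophs_counts_as_zero_event(self, genus_rates):
        df = make_samples([
            ("C3", "2005-07-05", "Aphanizomenon", 1.0),
            ("C3", "2005-07-20", "other", 0.5),  # cast with no cyanobacteria
        ])
        events = est.event_areal_table(df, genus_rates)
        m = est.monthly_basin_mean(events, BOTHNIAN_SEA, 7, [2005])
        assert m.mean_daily == pytest.approx(3.3)
        assert m.n_samples == 2


class TestAnnualLoad:
    @staticmethod
    def _monthlies(mean_daily_by_month, year=(2005,)):
        return [
            est.MonthlyBasinEstimate(
                basin="bothnian_sea", year_block=year, month=m,
                mean_daily=v, monthly_total=v * 30.0,
                n_samples=1 if v else 0,
            )
            for m, v in mean_daily_by_month.items()
        ]

    def test_summer_only_constant_rate(self):
        months = {m: (0.66 if m in (6, 7, 8) else 0.0) for m in range(1, 13)}
        load = est.annual_load(self._monthlies(months), BOTHNIAN_SEA)
        assert load.areal_annual == pytest.approx(59.4)
        assert load.load == pytest.approx(65.7, abs=0.05)

    def test_all_zero(self):
        months = {m: 0.0 for m in range(1, 13)}
        load = est.annual_load(self._monthlies(months), BOTHNIAN_SEA)
        assert load.load == 0.0

    def test_hand_converted_magnitude(self):
        assert est.load_kt_per_year(72.0, 79000) == pytest.approx(79.67, abs=0.05)

    def test_duplicate_month_is_error(self):
        months = self._monthlies({m: 0.1 for m in range(1, 13)})
        with pytest.raises(ValidationError):
            est.annual_load(months + [months[0]], BOTHNIAN_SEA)


class TestPooledYearBlocks:
    def test_nineteen_years_pool_into_6_7_6(self):
        blocks = est.pooled_year_blocks(range(1999, 2018), pooling=6)
        assert blocks == [
            tuple(range(1999, 2005)),
            tuple(range(2005, 2012)),
            tuple(range(2012, 2018)),
        ]

    def test_pooling_one_gives_singletons(self):
        blocks = est.pooled_year_blocks(range(1999, 2018), pooling=1)
        assert len(blocks) == 19
        assert all(len(b) == 1 for b in blocks)

    def test_noncontiguous_years_error(self):
        with pytest.raises(ValidationError, match="contiguous"):
            est.pooled_year_blocks([1999, 2000, 2002], pooling=1)


class TestMultiYearSummary:
    @staticmethod
    def _loads(values, basin="bothnian_sea", start=2000):
        return [
            est.AnnualLoad(basin=basin, year_block=(start + i,),
                           areal_annual=0.0, load=v)
            for i, v in enumerate(values)
        ]

    def test_two_point_sd(self):
        s = est.multi_year_summary(self._loads([1.0, 3.0]))
        assert s.mean == 2.0
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_identical_loads_have_zero_sd(self):
        s = est.multi_year_summary(self._loads([5.0, 5.0, 5.0]))
        assert s.sd == 0.0

    def test_hand_arithmetic_five_years(self):
        s = est.multi_year_summary(self._loads([350, 400, 420, 380, 370]))
        assert s.mean == pytest.approx(384.0)
        assert s.sd == pytest.approx(27.0185, abs=1e-3)

    def test_single_load_has_no_sd(self):
        s = est.multi_year_summary(self._loads([10.0]))
        assert s.mean == 10.0
        assert s.sd is None

    def test_empty_subset_is_error(self):
        with pytest.raises(ValidationError):
            est.multi_year_summary(self._loads([1.0, 2.0]), years_subset=[1950])

    def test_year_subset_selection(self):
        s = est.multi_year_summary(self._loads([10, 20, 30, 40]),
                                   years_subset=[2000, 2001])
        assert s.mean == 15.0
        assert s.n == 2


class TestCarbonFraction:
    def test_thirty_percent(self):
        df = make_samples([
            ("B1", "2005-07-10", "Aphanizomenon", 0.15, 30.0, "cyanobacteria_filamentous"),
            ("B1", "2005-07-10", "other", 0.5, 50.0, "diatoms"),
            ("B1", "2005-07-10", "other", 0.2, 20.0, "flagellates_other"),
        ])
        assert est.carbon_fraction(df, "B1", 7) == pytest.approx(0.30)

    def test_no_cyanobacteria_rows_gives_zero(self):
        df = make_samples([("B1", "2005-07-10", "other", 0.5, 50.0, "diatoms")])
        assert est.carbon_fraction(df, "B1", 7) == 0.0

    def test_zero_total_carbon_is_nan_and_flagged(self, caplog):
        df = make_samples([("B1", "2005-07-10", "other", 0.5, 0.0, "diatoms")])
        with caplog.at_level(logging.WARNING, logger="diazoload.estimation"):
            out = est.carbon_fraction(df, "B1", 7)
        assert math.isnan(out)
        assert any("undefined" in r.message for r in caplog.records)

    def test_missing_carbon_column_is_error(self):
        df = make_samples([("B1", "2005-07-10", "Aphanizomenon", 0.15)])
        with pytest.raises(ConfigurationError, match="carbon"):
            est.carbon_fraction_table(df)


def test_monthly_total_is_exactly_thirty_times_mean_daily(genus_rates):
    df = make_samples([("C3", "2005-07-10", "Aphanizomenon", 0.123)])
    events = est.event_areal_table(df, genus_rates)
    m = est.monthly_basin_mean(events, BOTHNIAN_SEA, 7, [2005])
    assert m.monthly_total == 30.0 * m.mean_daily


def test_areal_rate_invariant_enforced():
    with pytest.raises(ValidationError):
        est.ArealRate(station="C3", date=None, taxon="Nodularia",
                      volumetric=1.0, areal=5.0, integration_depth=10.0)


def test_estimate_basin_loads_shapes(genus_rates, cfg):
    rows = []
    for year in (2005, 2006):
        for st in ("C3", "B3+B7"):
            rows.append((st, f"{year}-07-10", "Aphanizomenon", 0.1))
    df = make_samples(rows)
    monthlies, loads = est.estimate_basin_loads(
        df, genus_rates, {"bothnian_sea": BOTHNIAN_SEA}, pooling={"bothnian_sea": 2}
    )
    assert len(loads) == 1
    assert loads[0].year_block == (2005, 2006)
    assert len(monthlies) == 12
    assert loads[0].load == pytest.approx(
        est.load_kt_per_year(0.1 * 0.66 * 10 * 30, 79000))
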