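import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cherisk import data_model as dm
from cherisk.errors import (DegenerateGradientError, ImputationError,
                            RangeError, SchemaError, SeriesLookupError)

COUNTRY_HEADER = ",".join(dm.COUNTRY_COLUMNS)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------

class TestPackagedTables:
    def test_country_table_shape(self, study_countries):
        assert len(study_countries) == 34
        groups = [c.income_group for c in study_countries.values()]
        assert groups.count(dm.IncomeGroup.LI) == 17
        assert groups.count(dm.IncomeGroup.LMI) == 17
        for c in study_countries.values():
            assert 0 < c.gini < 1
            assert c.gni_per_capita > 0

    def test_service_catalog_shape(self, service_catalog):
        assert len(service_catalog) == 29
        diseases = {s.disease_id for s in service_catalog.values()}
        assert len(diseases) == 13
        # every disease maps to exactly one broad group
        groups = {}
        for s in service_catalog.values():
            groups.setdefault(s.disease_id, set()).add(s.disease_group)
        assert all(len(g) == 1 for g in groups.values())

    def test_missing_gini_filled_with_regional_average(self, study_countries):
        afg, khm = study_countries["AFG"], study_countries["KHM"]
        assert afg.gini_imputed and khm.gini_imputed
        # South Asia donor pool is Nepal only
        assert afg.gini == pytest.approx(0.328)
        # East Asia & Pacific pool: Lao, Myanmar, Samoa, Viet Nam
        assert khm.gini == pytest.approx(np.mean([0.360, 0.307, 0.387,
                                                  0.357]))

    @pytest.mark.parametrize("code,country,expected", [
        ("HC27", "ETH", 135.09),   # TB care, low-income cost column
        ("HC27", "GHA", 175.65),   # same service, lower-middle-income
        ("HC38", "BDI", 0.03),     # aspirin, LI
        ("HC38", "VNM", 0.05),     # aspirin, LMI
    ])
    def test_unit_cost_selects_income_group_column(
            self, study_countries, service_catalog, code, country, expected):
        assert dm.unit_cost_for(service_catalog[code],
                                study_countries[country]) == expected


# ---------------------------------------------------------------------------
# Loader validation
# ---------------------------------------------------------------------------

class TestLoaderValidation:
    def test_empty_file_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "countries.csv", "")
        with pytest.raises(SchemaError):
            dm.load_countries(p)

    def test_header_only_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "countries.csv", COUNTRY_HEADER + "\n")
        with pytest.raises(SchemaError):
            dm.load_countries(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "countries.csv",
                   "country_id,name\nXXA,Testland\n")
        with pytest.raises(SchemaError, match="gini"):
            dm.load_countries(p)

    def test_out_of_range_gini_cites_row_and_column(self, tmp_path):
        p = _write(tmp_path, "countries.csv", COUNTRY_HEADER + "\n"
                   "XXA,Testland,LI,West,2015,500,1.2,\n")
        with pytest.raises(RangeError) as err:
            dm.load_countries(p)
        assert err.value.row == 2
        assert err.value.column == "gini"

    def test_percent_scale_gini_rescaled(self, tmp_path):
        p = _write(tmp_path, "countries.csv", COUNTRY_HEADER + "\n"
                   "XXA,Testland,LI,West,2015,500,47.3,\n")
        assert dm.load_countries(p)["XXA"].gini == pytest.approx(0.473)

    def test_negative_unit_cost_is_range_error(self, tmp_path):
        p = _write(tmp_path, "services.csv",
                   ",".join(dm.SERVICE_COLUMNS) + "\n"
                   "S1,thing,disease_a,ncd,-1.0,2.0\n")
        with pytest.raises(RangeError):
            dm.load_services(p)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _oop_table(values):
    return dm.OopShareTable({k: dm.OopShare(v) for k, v in values.items()})


class TestRegionalImputation:
    region_map = {"A": "West", "B": "West", "C": "West", "D": "East"}

    def test_mean_of_region_donors(self):
        table = _oop_table({("A", "d"): 0.2, ("B", "d"): 0.4,
                            ("C", "d"): None, ("D", "d"): 0.9})
        filled = dm.impute_regional_average(table, self.region_map)
        entry = filled.entries[("C", "d")]
        assert entry.share == pytest.approx(0.3)
        assert entry.imputed and entry.region_used == "West"
        # donor entries untouched
        assert not filled.entries[("A", "d")].imputed

    def test_three_donor_mean(self):
        table = _oop_table({("A", "d"): 0.1, ("B", "d"): 0.2,
                            ("D", "d"): None})
        region_map = {"A": "West", "B": "West", "C": "West", "D": "West"}
        table.entries[("C", "d")] = dm.OopShare(0.6)
        filled = dm.impute_regional_average(table, region_map)
        assert filled.entries[("D", "d")].share == pytest.approx(0.3)

    def test_no_missing_is_identity(self):
        table = _oop_table({("A", "d"): 0.2, ("B", "d"): 0.4})
        assert dm.impute_regional_average(table, self.region_map) == table

    def test_idempotent(self):
        table = _oop_table({("A", "d"): 0.2, ("B", "d"): 0.4,
                            ("C", "d"): None})
        once = dm.impute_regional_average(table, self.region_map)
        twice = dm.impute_regional_average(once, self.region_map)
        assert once == twice

    def test_whole_region_missing_raises(self):
        table = _oop_table({("A", "d"): 0.2, ("D", "d"): None})
        with pytest.raises(ImputationError, match="East"):
            dm.impute_regional_average(table, self.region_map)

    def test_utilization_imputed_per_quintile(self):
        u1, u2 = (0.1, 0.2, 0.3, 0.4, 0.5), (0.3, 0.4, 0.5, 0.6, 0.7)
        table = dm.UtilizationTable({
            ("A", "s"): dm.UtilizationEntry(u=u1),
            ("B", "s"): dm.UtilizationEntry(u=u2),
            ("C", "s"): dm.UtilizationEntry(u=None),
        })
        filled = dm.impute_regional_average(table, self.region_map)
        assert filled.entries[("C", "s")].u == pytest.approx(
            tuple((a + b) / 2 for a, b in zip(u1, u2)))


# ---------------------------------------------------------------------------
# Wealth-gradient fallback
# ---------------------------------------------------------------------------

class TestAverageGradient:
    @pytest.mark.parametrize("flat,gradient,expected", [
        (0.5, (1, 1, 1, 1, 1), (0.5, 0.5, 0.5, 0.5, 0.5)),
        (0.4, (0.5, 0.75, 1.0, 1.25, 1.5), (0.2, 0.3, 0.4, 0.5, 0.6)),
    ])
    def test_examples(self, flat, gradient, expected):
        out = dm.apply_average_gradient(flat, gradient)
        assert out == pytest.approx(expected)
        assert out.mean() == pytest.approx(flat)

    def test_clipping_at_one(self):
        out = dm.apply_average_gradient(0.9, (0.5, 0.75, 1.0, 1.25, 1.5))
        assert out[3] == 1.0 and out[4] == 1.0  # 1.125 and 1.35 clipped
        assert out[:3] == pytest.approx((0.45, 0.675, 0.9))

    def test_zero_gradient_raises(self):
        with pytest.raises(DegenerateGradientError):
            dm.apply_average_gradient(0.5, (0, 0, 0, 0, 0))

    @given(flat=st.floats(0.0, 0.2),
           gradient=st.lists(st.floats(0.01, 2.0), min_size=5, max_size=5))
    def test_small_rates_preserve_mean_and_order(self, flat, gradient):
        # flat <= 0.2 with gradient <= 2x mean cannot clip
        out = dm.apply_average_gradient(flat, sorted(gradient))
        assert out.mean() == pytest.approx(flat, abs=1e-12)
        assert (np.diff(out) >= -1e-15).all()

    def test_flat_rows_expanded_from_country_gradient(self):
        # country A's two empirical services share gradient shape 1..1.5
        emp = (0.2, 0.25, 0.3, 0.35, 0.4)  # mean 0.3, mean-one grad 2/3..4/3
        table = dm.UtilizationTable({
            ("A", "s1"): dm.UtilizationEntry(u=emp),
            ("A", "s2"): dm.UtilizationEntry(u=None, flat_value=0.3),
        })
        out = dm.expand_flat_utilization(table, {"A": "West"})
        entry = out.entries[("A", "s2")]
        assert entry.gradient_source is dm.GradientSource.country_average_gradient
        assert entry.u == pytest.approx(emp)


# ---------------------------------------------------------------------------
# Currency conversion
# ---------------------------------------------------------------------------

class TestCurrencyConversion:
    series = dm.CurrencySeries(cpi={2010: 100.0, 2016: 105.0},
                               fx={("XOF", 2010): 500.0})

    def test_usd_2016_unchanged(self):
        assert dm.convert_to_2016_usd(42.0, "USD", 2016, self.series) == 42.0

    def test_cpi_deflation(self):
        assert dm.convert_to_2016_usd(100.0, "USD", 2010, self.series) \
            == pytest.approx(105.0)

    def test_fx_then_cpi(self):
        # 500 XOF in 2010 -> 1 USD nominal -> 1.05 USD of 2016
        assert dm.convert_to_2016_usd(500.0, "XOF", 2010, self.series) \
            == pytest.approx(1.05)

    def test_zero_amount(self):
        assert dm.convert_to_2016_usd(0.0, "XOF", 2010, self.series) == 0.0

    def test_missing_year_raises(self):
        with pytest.raises(SeriesLookupError):
            dm.convert_to_2016_usd(1.0, "USD", 1999, self.series)

    def test_cpi_requires_base_year(self):
        with pytest.raises(SchemaError):
            dm.CurrencySeries(cpi={2010: 100.0}, fx={})


# ---------------------------------------------------------------------------
# Bundle round trip and completeness
# ---------------------------------------------------------------------------

class TestBundle:
    def test_round_trip(self, tmp_path, fixture_bundle):
        paths = fixture_bundle.write_csvs(tmp_path)
        reloaded = dm.load_inputs(paths["countries"], paths["services"],
                                  paths["oop_shares"], paths["utilization"])
        assert reloaded.countries == fixture_bundle.countries
        assert reloaded.services == fixture_bundle.services
        assert reloaded.oop_shares == fixture_bundle.oop_shares
        assert reloaded.utilization == fixture_bundle.utilization

    def test_every_pair_resolves(self, fixture_bundle):
        for cid in fixture_bundle.countries:
            for code in fixture_bundle.services:
                r = fixture_bundle.resolve(cid, code)
                assert r.unit_cost >= 0
                assert 0 <= r.oop_share <= 1
                assert r.utilization.shape == (5,)
                assert ((r.utilization >= 0) & (r.utilization <= 1)).all()

    def test_load_inputs_imputes_absent_pairs(self, tmp_path,
                                              study_countries,
                                              service_catalog):
        # OOP table covering one disease for a single SSA country only:
        # every other country must be filled by regional imputation, and
        # countries outside SSA (no donor) must raise.
        _write(tmp_path, "oop.csv", "country_id,disease_id,share\n"
               "ETH,tuberculosis,0.4\n")
        util_rows = ["country_id,service_code,u_q1,u_q2,u_q3,u_q4,u_q5"]
        util_rows.append("ETH,HC27,0.5,0.5,0.5,0.5,0.5")
        _write(tmp_path, "util.csv", "\n".join(util_rows) + "\n")
        with pytest.raises(ImputationError):
            dm.load_inputs(dm.packaged_fixture_path("table1_countries"),
                           dm.packaged_fixture_path("table3_services"),
                           tmp_path / "oop.csv", tmp_path / "util.csv")
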