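"""Demographic rates: counting, formulas, interval correction, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forestdyn as fd

from conftest import make_table, row


class TestCountInterval:
    def test_direct_enumeration(self):
        # 10 alive at start, 2 deaths, 3 recruits -> (10, 2, 3, 11)
        rows = []
        for i in range(10):
            rows.append(row("P1", f"t{i}", 2000, 10.0))
        for i in range(8):  # survivors
            rows.append(row("P1", f"t{i}", 2003, 11.0))
        for i in range(8, 10):  # deaths
            rows.append(row("P1", f"t{i}", 2003, None, None, "dead"))
        for i in range(3):  # recruits
            rows.append(row("P1", f"r{i}", 2003, 5.5))
        c = fd.count_interval(make_table(rows), "P1", "I1")
        assert (c.n0, c.nm, c.nr, c.nt) == (10, 2, 3, 11)

    def test_no_changes(self, two_census_table):
        rows = [row("P1", "t1", 2000, 10.0), row("P1", "t1", 2002, 10.5)]
        c = fd.count_interval(make_table(rows), "P1", "I1")
        assert (c.n0, c.nm, c.nr, c.nt) == (1, 0, 0, 1)

    def test_empty_plot_gives_zero_counts(self):
        rows = [row("P1", "t1", 2000, 10.0), row("P1", "t1", 2002, 10.5)]
        plots = [{"plot_id": p, "area_m2": 600, "site": "NF", "sector": ""}
                 for p in ("P1", "P2")]
        c = fd.count_interval(make_table(rows, plots), "P2", "I1")
        assert (c.n0, c.nm, c.nr, c.nt) == (0, 0, 0, 0)

    def test_unknown_plot_or_interval_raises(self, two_census_table):
        with pytest.raises(KeyError):
            fd.count_interval(two_census_table, "nope", "I1")
        with pytest.raises(KeyError):
            fd.count_interval(two_census_table, "P1", "I9")

    def test_stem_conservation_on_simulation(self, paper_like):
        table, _, _ = paper_like
        for c in fd.count_all_intervals(table):
            assert c.nt == c.n0 - c.nm + c.nr  # exact integer identity


class TestRateFormulas:
    def test_zero_events_give_zero_rates(self):
        assert fd.mortality_rate(100, 0, 3) == 0.0
        assert fd.recruitment_rate(0, 100, 3) == 0.0

    def test_one_year_interval_reduces_to_proportion(self):
        assert fd.mortality_rate(100, 10, 1) == pytest.approx(10.0)
        assert fd.recruitment_rate(10, 100, 1) == pytest.approx(10.0)

    def test_two_year_interval_annualizes(self):
        expect = 100 * (1 - 0.9**0.5)  # = 5.1317 frozen from direct evaluation
        assert fd.mortality_rate(100, 10, 2) == pytest.approx(expect, rel=1e-12)
        assert fd.recruitment_rate(10, 100, 2) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(5.131670194948623)

    def test_empty_cohort_is_flagged_missing_not_zero(self):
        assert math.isnan(fd.mortality_rate(0, 0, 3))
        assert math.isnan(fd.recruitment_rate(0, 0, 3))

    def test_interval_correction_values(self):
        assert fd.interval_correction(5.0, 1.0) == 5.0  # identity at t=1
        assert fd.interval_correction(5.0, 4.0) == pytest.approx(
            5.5864356903611, rel=1e-12)
        assert fd.interval_correction(3.0, 6.0) == pytest.approx(
            3.462369032351118, rel=1e-12)
        with pytest.raises(ValueError):
            fd.interval_correction(5.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n0=st.integers(1, 10_000), frac=st.floats(0.0, 1.0),
           t=st.integers(1, 10))
    def test_compounding_inverse_consistency(self, n0, frac, t):
        """Applying the estimated annual loss for t years recovers nm."""
        nm = int(round(n0 * frac))
        m = fd.mortality_rate(n0, nm, t)
        survivors = n0 * (1 - m / 100) ** t
        assert survivors == pytest.approx(n0 - nm, abs=1e-6 * max(n0, 1))

    def test_rates_in_percent_range(self):
        for nm in range(0, 101, 10):
            m = fd.mortality_rate(100, nm, 4)
            assert 0 <= m <= 100


class TestRelabelingInvariance:
    def test_rates_invariant_to_tree_ids_and_row_order(self, two_census_table):
        base = fd.rates_table(two_census_table)
        obs = two_census_table.obs.copy()
        mapping = {t: f"zz_{t}" for t in obs["tree_id"].unique()}
        obs["tree_id"] = obs["tree_id"].map(mapping)
        shuffled = fd.CensusTable(
            obs=obs.sample(frac=1.0, random_state=7).reset_index(drop=True),
            plots=two_census_table.plots.copy())
        out = fd.rates_table(shuffled)
        pd.testing.assert_frame_equal(base, out)


class TestSiteRates:
    def _rates(self, values, site="NF"):
        return pd.DataFrame({
            "plot_id": [f"P{i}" for i in range(len(values))],
            "site": site, "interval": "I1", "t": 3.0,
            "n0": 10, "nm": 1, "nr": 1, "nt": 10,
            "M": values, "R": values, "M_corr": values, "R_corr": values})

    def test_mean_and_sample_sd(self):
        out = fd.site_rates(self._rates([4.0, 6.0]))
        assert out.loc[0, "M_corr_mean"] == pytest.approx(5.0)
        assert out.loc[0, "M_corr_sd"] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_single_plot_sd_is_undefined(self):
        out = fd.site_rates(self._rates([4.0]))
        assert out.loc[0, "M_corr_mean"] == 4.0
        assert math.isnan(out.loc[0, "M_corr_sd"])

    def test_identical_plots_sd_zero(self):
        out = fd.site_rates(self._rates([5.0, 5.0, 5.0]))
        assert out.loc[0, "M_corr_sd"] == 0.0

    def test_pooled_mode_sums_counts_first(self):
        df = pd.concat([self._rates([4.0, 6.0])], ignore_index=True)
        out = fd.site_rates(df, pooled=True)
        assert out.loc[0, "n0"] == 20
        expect = fd.interval_correction(fd.mortality_rate(20, 2, 3.0), 3.0)
        assert out.loc[0, "M_corr"] == pytest.approx(expect)


class TestParameterRecovery:
    def test_annual_censuses_recover_constant_hazard(self):
        """With t=1 censuses, mean M converges to 100*(1 - exp(-h))."""
        h = 0.04
        cfg = fd.SimulationConfig(
            n_plots_ff=0, n_plots_nf=30,
            census_years=tuple(float(y) for y in range(2000, 2006)),
            base_hazard=h, size_hazard=(1, 1, 1), drought_effect=0.0,
            fire_year=None, growth_sd=0.05, seed=42)
        table, _ = fd.simulate_census(cfg)
        rates = fd.rates_table(table)
        est = rates["M"].mean()
        truth = 100 * (1 - math.exp(-h))
        assert est == pytest.approx(truth, abs=0.5)
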