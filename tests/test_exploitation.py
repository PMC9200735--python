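import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baymix.exploitation import (
    LOState,
    apply_exogenous_removals,
    baranov_catch,
    catch_based_fleet_removals,
    extrapolate_ratios,
    fishing_mortality,
    interannual_factor,
    split_landings_discards,
)


class TestFishingMortality:
    def test_product_formula(self):
        F = fishing_mortality(10.0, 0.02, 0.5, np.array([0.8]))
        assert F[0] == pytest.approx(0.08)

    def test_zero_selectivity_kills_f(self):
        F = fishing_mortality(10.0, 0.5, 1.0, np.array([0.0, 0.3]))
        assert F[0] == 0.0 and F[1] > 0

    def test_linearity_in_effort(self):
        sel = np.array([0.2, 0.9])
        assert np.allclose(
            fishing_mortality(20.0, 0.1, 0.5, sel),
            2 * fishing_mortality(10.0, 0.1, 0.5, sel),
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fishing_mortality(-1.0, 0.1, 1.0, np.array([0.5]))


class TestBaranov:
    def test_no_fishing_leaves_only_natural_deaths(self):
        catch, surv, nat = baranov_catch(np.array([1000.0]), np.zeros((1, 1)), 0.6, 1.0)
        assert catch.sum() == 0.0
        assert surv[0] == pytest.approx(1000.0 * np.exp(-0.05))
        assert nat[0] == pytest.approx(1000.0 * (1 - np.exp(-0.05)))

    def test_closed_form_against_euler_substep_oracle(self):
        """10^4-substep Euler integration of the competing-risks ODE."""
        N, F, m = 1000.0, 0.1, 0.05
        catch, surv, nat = baranov_catch(np.array([N]), np.array([[F]]), m * 12.0, 1.0)
        n_sub, dt = 10_000, 1.0 / 10_000
        n, c = N, 0.0
        for _ in range(n_sub):
            c += F * n * dt
            n *= 1.0 - (F + m) * dt
        assert catch[0, 0] == pytest.approx(92.86, abs=0.05)
        assert catch[0, 0] == pytest.approx(c, rel=1e-3)
        assert surv[0] == pytest.approx(n, rel=1e-3)

    def test_equal_f_splits_catch_equally(self):
        catch, _, _ = baranov_catch(np.array([500.0]), np.array([[0.2], [0.2]]), 0.3)
        assert catch[0, 0] == pytest.approx(catch[1, 0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0, 1e6),
        st.lists(st.floats(0, 2), min_size=1, max_size=4),
        st.floats(0, 2),
    )
    def test_accounting_closes_exactly(self, n, fs, M):
        F = np.array(fs)[:, None]
        catch, surv, nat = baranov_catch(np.array([n]), F, M, 1.0)
        assert surv[0] + catch.sum() + nat[0] == pytest.approx(n, rel=1e-12, abs=1e-9)

    def test_catch_monotone_in_effort_factors(self):
        base, _, _ = baranov_catch(np.array([1000.0]), np.array([[0.1]]), 0.5)
        more, _, _ = baranov_catch(np.array([1000.0]), np.array([[0.2]]), 0.5)
        assert more.sum() > base.sum()


class TestLandingsDiscardsSplit:
    def test_below_mcrs_never_landed(self):
        catch = np.array([100.0])
        landings, discards = split_landings_discards(
            catch, np.zeros(1), np.array([True])
        )
        assert landings[0] == 0.0 and discards[0] == 100.0

    def test_no_ogive_above_mcrs_all_landed(self):
        landings, discards = split_landings_discards(
            np.array([50.0, 60.0]), np.zeros(2), np.array([False, False])
        )
        assert np.array_equal(landings, [50.0, 60.0]) and discards.sum() == 0.0

    def test_lo_with_zero_de_minimis_forbids_discarding(self):
        catch = np.array([100.0, 40.0])
        landings, discards = split_landings_discards(
            catch, np.array([0.5, 0.2]), np.array([True, False]), LOState(True, 0.0)
        )
        assert discards.sum() == 0.0
        assert landings.sum() == pytest.approx(catch.sum())  # all counted

    def test_lo_caps_discards_at_de_minimis(self):
        catch = np.array([100.0])
        _, discards = split_landings_discards(
            catch, np.array([1.0]), np.array([False]), LOState(True, 0.06)
        )
        assert discards.sum() == pytest.approx(6.0)


class TestInterannualFactors:
    obs_hake = {("gn", 1, 2010): 150.0, ("gn", 1, 2012): 300.0}
    obs_neph = {(2010,): 40.0, (2013,): 60.0}

    def test_base_year_ratio_is_one_at_every_granularity(self):
        assert interannual_factor(self.obs_hake, "hake", "gn", 1, 2010) == 1.0
        assert interannual_factor({("gn", 2010): 5.0}, "sole", "gn", year=2010) == 1.0
        assert interannual_factor(self.obs_neph, "nephrops", year=2010) == 1.0

    def test_hake_ratio(self):
        assert interannual_factor(self.obs_hake, "hake", "gn", 1, 2012) == 2.0

    def test_nephrops_ratio_shared_across_metiers(self):
        r1 = interannual_factor(self.obs_neph, "nephrops", "gn", year=2013)
        r2 = interannual_factor(self.obs_neph, "nephrops", "tr", year=2013)
        assert r1 == r2 == 1.5

    def test_zero_base_year_identifies_key(self):
        with pytest.raises(ValueError, match="2010"):
            interannual_factor({("gn", 1, 2010): 0.0}, "hake", "gn", 1, 2012)


class TestExtrapolation:
    def test_halved_slope_worked_example(self):
        out = extrapolate_ratios(
            np.array([1.0, 1.2, 1.4]), halve_slope=True, force_significant=True
        )
        assert out == pytest.approx({2017: 1.5, 2018: 1.6, 2019: 1.7, 2020: 1.8})

    def test_flat_series_extends_flat(self):
        out = extrapolate_ratios(np.array([1.0, 1.0, 1.0]), force_significant=True)
        assert all(v == 1.0 for v in out.values())

    def test_non_significant_carries_2016_value(self):
        # a noisy 3-point series (1 dof) is far from significant at 5%
        out = extrapolate_ratios(np.array([1.0, 1.5, 1.1]), alpha=0.05)
        assert all(v == pytest.approx(1.1) for v in out.values())

    def test_results_floored_at_zero(self):
        out = extrapolate_ratios(
            np.array([1.0, 0.5, 0.05]), force_significant=True
        )
        assert min(out.values()) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_ratios(np.array([1.0, 1.1]))


class TestCatchBasedRemovals:
    @pytest.mark.parametrize("ratio, expected", [(0.0, 0.0), (1.0, 200.0), (0.5, 100.0)])
    def test_elementwise_product(self, ratio, expected):
        out = catch_based_fleet_removals(np.array([200.0]), np.array([ratio]))
        assert out[0] == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            catch_based_fleet_removals(np.ones(3), np.ones(4))


class TestExogenousRemovals:
    def test_plain_subtraction(self):
        new, short = apply_exogenous_removals(np.array([100.0]), np.array([10.0]))
        assert new[0] == 90.0 and short[0] == 0.0

    def test_clipping_reports_shortfall(self):
        new, short = apply_exogenous_removals(np.array([100.0]), np.array([150.0]))
        assert new[0] == 0.0 and short[0] == 50.0

    def test_zero_series_is_identity(self):
        n = np.array([5.0, 7.0])
        new, short = apply_exogenous_removals(n, np.zeros(2))
        assert np.array_equal(new, n) and short.sum() == 0.0
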