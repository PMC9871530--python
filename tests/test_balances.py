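"""Electron/carbon pool aggregation, CO₂ attribution, yields, comparisons."""

import math

import pytest

from mixochain.balances import (
    BalanceError,
    CO2Attribution,
    carbon_fixation_rate,
    co2_attribution,
    compare_communities,
    period_balance,
    yield_elongated,
)
from mixochain.reactor_rates import RateRecord
from mixochain.stoichiometry import default_registry

REG = default_registry()


def _steady(compound, rate, t0=0.0, t1=10.0, n=10):
    dt = (t1 - t0) / n
    return [
        RateRecord(t0 + i * dt, t0 + (i + 1) * dt, compound, rate) for i in range(n)
    ]


class TestPeriodBalance:
    def test_single_compound_pool_is_rate_times_gamma(self):
        bal = period_balance(_steady("n-caproate", 2.0), REG, (0.0, 10.0))
        assert bal.pools_e["C6"] == pytest.approx(2.0 * 32)
        assert bal.pools_c["C6"] == pytest.approx(2.0 * 6)

    def test_closed_system_has_zero_unknown(self):
        # heterotrophic lactate fermentation, exactly balanced:
        # lactate → ½ n-butyrate + CO2 + H2
        rates = (
            _steady("lactate", -4.0)
            + _steady("n-butyrate", 2.0)
            + _steady("CO2", 4.0)
            + _steady("H2", 4.0)
        )
        bal = period_balance(rates, REG, (0.0, 10.0))
        assert bal.pools_e["unknown"] == pytest.approx(0.0, abs=1e-6)
        assert bal.pools_c["unknown"] == pytest.approx(0.0, abs=1e-6)

    def test_mixotrophic_donor_pools_match_printed_values(self):
        # lactate at 112 e-mmol and H2+CO at 119 e-mmol consumed
        rates = (
            _steady("lactate", -112.0 / 12)
            + _steady("H2", -59.5 / 2)
            + _steady("CO", -59.5 / 2)
        )
        bal = period_balance(rates, REG, (0.0, 10.0))
        assert bal.pools_e["lactate_in"] == pytest.approx(-112.0)
        assert bal.pools_e["H2"] + bal.pools_e["CO"] == pytest.approx(-119.0)
        assert bal.donors_e() == pytest.approx(231.0)

    def test_acetate_pools_by_net_sign(self):
        consumed = period_balance(_steady("acetate", -3.0), REG, (0.0, 10.0))
        produced = period_balance(_steady("acetate", 3.0), REG, (0.0, 10.0))
        assert consumed.pools_e["acetate_in"] == pytest.approx(-24.0)
        assert produced.pools_e["C2"] == pytest.approx(24.0)

    def test_time_weighted_mean_over_uneven_intervals(self):
        rates = [
            RateRecord(0.0, 1.0, "acetate", 2.0),
            RateRecord(1.0, 4.5, "acetate", 6.0),  # 3.5-day interval dominates
        ]
        bal = period_balance(rates, REG, (0.0, 4.5))
        expected = (2.0 * 1.0 + 6.0 * 3.5) / 4.5
        assert bal.pools_e["C2"] == pytest.approx(expected * 8)

    def test_empty_window_rejected(self):
        with pytest.raises(BalanceError):
            period_balance(_steady("acetate", 1.0), REG, (50.0, 60.0))


class TestCarbonFixation:
    def test_net_uptake_sign_bookkeeping(self):
        rates = _steady("CO", -10.0) + _steady("CO2", 4.0)
        fix = carbon_fixation_rate(rates, (0.0, 10.0))
        assert fix.c_mmol_per_L_d == pytest.approx(6.0)

    def test_no_gas_activity_fixes_nothing(self):
        assert carbon_fixation_rate([], (0.0, 1.0)).c_mmol_per_L_d == 0.0

    def test_co2_equivalent_view_matches_printed_factor(self):
        rates = _steady("CO", -2.0)
        fix = carbon_fixation_rate(rates, (0.0, 10.0))
        assert fix.g_co2_eq_per_L_d == pytest.approx(0.088, abs=5e-4)

    def test_antisymmetric_under_sign_swap(self):
        fwd = carbon_fixation_rate(_steady("CO", -7.0) + _steady("CO2", 3.0), (0.0, 10.0))
        rev = carbon_fixation_rate(_steady("CO", 7.0) + _steady("CO2", -3.0), (0.0, 10.0))
        assert fwd.c_mmol_per_L_d == pytest.approx(-rev.c_mmol_per_L_d)


class TestCO2Attribution:
    def test_study_period_numbers(self):
        # expected 9.17 and emitted 5.41 imply 3.76–3.77 abated
        att = co2_attribution(-9.17, {}, 5.41)
        assert att.abated == pytest.approx(3.76, abs=0.01)
        assert att.co_oxidation == 0.0

    def test_excess_emission_booked_as_co_oxidation(self):
        att = co2_attribution(-5.0, {}, 6.0)
        assert att.abated == 0.0
        assert att.co_oxidation == pytest.approx(1.0)

    def test_all_zero_when_inactive(self):
        att = co2_attribution(0.0, {}, 0.0)
        assert (att.expected_decarboxylation, att.abated, att.emitted, att.co_oxidation) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_odd_chain_products_do_not_decarboxylate(self):
        att = co2_attribution(-10.0, {"propionate": 4.0, "n-valerate": 1.0}, 2.0)
        assert att.expected_decarboxylation == pytest.approx(5.0)
        assert att.abated == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "lactate, odd, emitted",
        [(-9.17, {}, 5.41), (-5.0, {}, 6.0), (-10.0, {"propionate": 4.0}, 2.0)],
    )
    def test_identity_always_holds(self, lactate, odd, emitted):
        att = co2_attribution(lactate, odd, emitted)
        assert att.emitted == pytest.approx(
            att.expected_decarboxylation - att.abated + att.co_oxidation
        )

    def test_inconsistent_odd_chain_rates_flagged(self):
        with pytest.raises(BalanceError, match="exceed"):
            co2_attribution(-2.0, {"propionate": 5.0}, 1.0)

    def test_attribution_identity_enforced_at_construction(self):
        with pytest.raises(BalanceError):
            CO2Attribution(9.0, 1.0, 5.0, 0.0)


class TestYield:
    def _balance_with(self, elongated_e, lactate_e):
        rates = _steady("lactate", -lactate_e / 12) + _steady("n-caproate", elongated_e / 32)
        return period_balance(rates, REG, (0.0, 10.0))

    def test_mixotrophic_and_heterotrophic_reference_yields(self):
        assert yield_elongated(self._balance_with(156.8, 112.0)) == pytest.approx(1.40, abs=0.005)
        assert yield_elongated(self._balance_with(78.06, 112.0)) == pytest.approx(0.697, abs=0.005)

    def test_no_elongated_products_yields_zero(self):
        assert yield_elongated(self._balance_with(0.0, 112.0)) == 0.0

    def test_invariant_to_rescaling_all_rates(self):
        a = yield_elongated(self._balance_with(156.8, 112.0))
        b = yield_elongated(self._balance_with(156.8 * 3.7, 112.0 * 3.7))
        assert a == pytest.approx(b)

    def test_zero_lactate_consumption_rejected(self):
        bal = period_balance(_steady("n-caproate", 1.0), REG, (0.0, 10.0))
        with pytest.raises(BalanceError):
            yield_elongated(bal)


class TestCompareCommunities:
    def _mixo(self):
        rates = (
            _steady("lactate", -112.0 / 12)
            + _steady("H2", -59.5 / 2)
            + _steady("CO", -59.5 / 2)
            + _steady("n-caproate", 66.6 / 32)
        )
        return period_balance(rates, REG, (0.0, 10.0))

    def _hetero(self):
        rates = _steady("lactate", -112.0 / 12) + _steady("n-caproate", 5.7 / 32)
        return period_balance(rates, REG, (0.0, 10.0))

    def test_identical_balances_give_unit_ratios(self):
        bal = self._mixo()
        cmp = compare_communities(bal, bal)
        for key in ("lactate_in", "C6", "total_donors", "C6_C8"):
            assert cmp[key].ratio == pytest.approx(1.0)

    def test_medium_chain_fold_difference(self):
        cmp = compare_communities(self._mixo(), self._hetero())
        assert cmp["C6_C8"].ratio == pytest.approx(66.6 / 5.7, rel=1e-6)
        assert cmp["C6_C8"].ratio >= 11

    def test_donor_consumption_doubles_with_gas(self):
        cmp = compare_communities(self._mixo(), self._hetero())
        assert cmp["total_donors"].ratio == pytest.approx((112 + 119) / 112, rel=1e-6)

    def test_zero_denominator_flagged_as_infinite(self):
        mixo = self._mixo()
        hetero = period_balance(_steady("lactate", -112.0 / 12), REG, (0.0, 10.0))
        cmp = compare_communities(mixo, hetero)
        assert math.isinf(cmp["C6_C8"].ratio)
        assert cmp["C6_C8"].undefined
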