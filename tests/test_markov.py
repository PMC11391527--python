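import dataclasses

import numpy as np
import pytest

from hipcea.markov import (
    CONVERTED_HA,
    DEAD,
    PRIMARY_IF,
    StateError,
    compute_icer,
    cycle_transition,
    discount_weight,
    run_cohort,
)
from hipcea.synthetic import generate_random_params


def _annuity(rate: float, n: int) -> float:
    return sum((1.0 + rate) ** (-t) for t in range(1, n + 1))


class TestCycleTransition:
    def test_dead_cohort_is_absorbing(self, base_params, lifetable):
        occ = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        nxt, ev = cycle_transition(occ, "IF", 1, base_params, lifetable)
        np.testing.assert_allclose(nxt, occ, atol=1e-15)
        assert ev.conv_if_to_ha == ev.conv_ha_to_tha == 0.0

    def test_mass_conservation_random_occupancies(self, base_params, lifetable, rng):
        for _ in range(200):
            occ = rng.dirichlet(np.ones(5))
            nxt, _ = cycle_transition(occ, "HA", 3, base_params, lifetable)
            assert abs(nxt.sum() - 1.0) < 1e-12
            assert (nxt >= -1e-15).all()

    def test_if_failure_split_composition(self, base_params, zero_mortality_table):
        """With no background deaths, the inflow to the salvage-HA state is
        fail_if x split x (1 - perioperative HA mortality)."""
        occ = np.zeros(5)
        occ[PRIMARY_IF] = 1.0
        nxt, ev = cycle_transition(occ, "IF", 1, base_params, zero_mortality_table)
        expected = 0.033 * 0.5 * (1 - 0.053)
        assert nxt[CONVERTED_HA] == pytest.approx(expected, abs=1e-15)
        assert ev.conv_if_to_ha == pytest.approx(0.033 * 0.5, abs=1e-15)

    def test_invalid_occupancy_rejected(self, base_params, lifetable):
        with pytest.raises(StateError):
            cycle_transition(np.array([0.7, 0, 0, 0, 0.1]), "IF", 1, base_params, lifetable)
        with pytest.raises(ValueError, match="cycle_index"):
            cycle_transition(np.array([1.0, 0, 0, 0, 0.0]), "IF", 9, base_params, lifetable)


class TestRunCohort:
    @pytest.mark.parametrize("arm", ["IF", "HA"])
    def test_trace_invariants(self, arm, base_params, lifetable):
        res = run_cohort(arm, base_params, lifetable)
        occ = res.trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert (occ >= -1e-15).all()
        assert (np.diff(occ[:, DEAD]) >= -1e-15).all()  # death is absorbing

    def test_trace_invariants_random_params(self, rng):
        from hipcea.parameters import LifeTable

        for k in range(20):
            p = generate_random_params(rng=rng)
            table = LifeTable.from_mapping(
                {a: float(rng.uniform(0, 0.2)) for a in range(p.start_age, p.start_age + 5)}
            )
            for arm in ("IF", "HA"):
                res = run_cohort(arm, p, table)
                occ = res.trace.occupancy
                np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
                assert (np.diff(occ[:, DEAD]) >= -1e-15).all()
                assert 0.0 <= res.discounted_qaly <= p.horizon_cycles * max(p.u_if, p.u_ha, p.u_tha)
                init_cost = p.c_if if arm == "IF" else p.c_ha
                assert res.discounted_cost >= init_cost  # costs only accrue

    def test_degenerate_closed_form_undiscounted(self, base_params, zero_mortality_table):
        p = base_params.replace(
            periop_mort_if=0.0, periop_mort_ha=0.0, periop_mort_tha=0.0,
            fail_if=0.0, fail_ha=0.0, discount_rate=0.0,
        )
        res = run_cohort("IF", p, zero_mortality_table)
        assert res.discounted_qaly == pytest.approx(5 * 0.63, abs=1e-12)
        assert res.discounted_cost == pytest.approx(8_632.0, abs=1e-9)

    def test_degenerate_closed_form_discounted_annuity(self, base_params, zero_mortality_table):
        p = base_params.replace(
            periop_mort_if=0.0, periop_mort_ha=0.0, periop_mort_tha=0.0,
            fail_if=0.0, fail_ha=0.0,
        )
        res = run_cohort("IF", p, zero_mortality_table)
        assert res.discounted_qaly == pytest.approx(0.63 * _annuity(0.03, 5), abs=1e-12)
        assert res.discounted_qaly == pytest.approx(2.88522, abs=5e-6)

    def test_qaly_strictly_decreasing_in_discount_rate(self, base_params, lifetable):
        qalys = [
            run_cohort("HA", base_params.replace(discount_rate=r), lifetable).discounted_qaly
            for r in (0.0, 0.01, 0.03, 0.06, 0.10)
        ]
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    @pytest.mark.parametrize("accrual, hcc", [("begin", False), ("end", True)])
    def test_alternative_accrual_raises_discounted_totals(
        self, accrual, hcc, base_params, lifetable
    ):
        default = run_cohort("HA", base_params, lifetable)
        other = run_cohort("HA", base_params, lifetable,
                           accrual=accrual, half_cycle_correction=hcc)
        # earlier crediting discounts less, so totals can only grow
        assert other.discounted_qaly > default.discounted_qaly
        assert other.discounted_cost > default.discounted_cost

    def test_life_table_must_cover_horizon(self, base_params):
        from hipcea.parameters import LifeTable

        short = LifeTable.from_mapping({80: 0.05, 81: 0.05})
        with pytest.raises(LookupError, match="cover"):
            run_cohort("IF", base_params, short)

    def test_discount_weight_conventions(self):
        assert discount_weight(1, 0.03) == pytest.approx(1 / 1.03)
        assert discount_weight(1, 0.03, accrual="begin") == 1.0
        assert discount_weight(2, 0.03, half_cycle_correction=True) == pytest.approx(
            1.03 ** -1.5
        )
        with pytest.raises(ValueError, match="accrual"):
            discount_weight(1, 0.03, accrual="middle")


class TestIcer:
    def _arm(self, res, cost, qaly):
        return dataclasses.replace(res, discounted_cost=cost, discounted_qaly=qaly)

    def test_icer_arithmetic_on_rounded_totals(self, base_params, lifetable):
        base = run_cohort("IF", base_params, lifetable)
        ref = self._arm(base, 12_167.0, 2.75)
        comp = self._arm(base, 13_324.0, 2.94)
        inc = compute_icer(ref, comp, wtp=11_083.0)
        assert inc.icer == pytest.approx(1_157 / 0.19, rel=1e-12)
        assert inc.icer == pytest.approx(6_089.47, abs=0.01)
        assert inc.classification == "cost_effective"

    def test_dominance_when_cheaper_and_more_effective(self, base_params, lifetable):
        base = run_cohort("IF", base_params, lifetable)
        inc = compute_icer(self._arm(base, 10_000.0, 2.0), self._arm(base, 9_000.0, 2.5), 11_083)
        assert inc.classification == "dominant"
        assert inc.icer < 0  # negative ratio flags dominance

    def test_dominated_and_not_cost_effective(self, base_params, lifetable):
        base = run_cohort("IF", base_params, lifetable)
        worse = compute_icer(self._arm(base, 9_000.0, 2.5), self._arm(base, 10_000.0, 2.0), 11_083)
        assert worse.classification == "dominated"
        dear = compute_icer(self._arm(base, 9_000.0, 2.0), self._arm(base, 12_000.0, 2.1), 11_083)
        assert dear.classification == "not_cost_effective"
        assert dear.icer == pytest.approx(30_000.0)

    def test_identical_arms_indeterminate(self, base_params, lifetable):
        res = run_cohort("IF", base_params, lifetable)
        inc = compute_icer(res, res, 11_083)
        assert inc.delta_cost == inc.delta_qaly == 0.0
        assert inc.icer is None
        assert inc.classification == "indeterminate"

    def test_icer_scales_linearly_with_global_cost_multiplier(self, base_params, lifetable):
        k = 3.7
        scaled = base_params.replace(
            **{f: getattr(base_params, f) * k
               for f in ("c_if", "c_ha", "c_if_to_ha", "c_if_to_tha", "c_ha_to_tha")}
        )
        inc = compute_icer(run_cohort("IF", base_params, lifetable),
                           run_cohort("HA", base_params, lifetable), 11_083)
        inc_k = compute_icer(run_cohort("IF", scaled, lifetable),
                             run_cohort("HA", scaled, lifetable), 11_083)
        assert inc_k.icer == pytest.approx(k * inc.icer, rel=1e-12)
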