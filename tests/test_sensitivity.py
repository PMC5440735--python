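"""Deterministic scenario engine: one-way and multiway cost modifications."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sui_cua.costs import CostBreakdown, breakdown_from_costs
from sui_cua.errors import ConfigError, ValidationError
from sui_cua.sensitivity import (
    Modification,
    Scenario,
    apply_scenario,
    default_scenarios,
    run_sensitivity,
)
from sui_cua.study_inputs import COMPONENT_COSTS, QALY_GAINS


@pytest.fixture
def app_breakdown():
    return breakdown_from_costs(COMPONENT_COSTS["app"])


@pytest.fixture
def control_breakdown():
    return breakdown_from_costs(COMPONENT_COSTS["control"])


class TestApplyScenario:
    def test_pfmt_halved_total(self, app_breakdown):
        scen = Scenario("halve", (Modification("pfmt_time", "scale", 0.5),))
        assert apply_scenario(app_breakdown, scen).total == pytest.approx(315.1, abs=0.2)

    def test_laundry_time_excluded_total(self, app_breakdown):
        scen = Scenario("excl", (Modification("laundry_time", "exclude"),))
        out = apply_scenario(app_breakdown, scen)
        assert out.laundry_time == 0.0
        assert out.total == pytest.approx(508.5, abs=0.2)

    def test_empty_scenario_is_identity(self, app_breakdown):
        assert apply_scenario(app_breakdown, Scenario("noop")) == app_breakdown

    def test_untouched_components_bit_identical(self, app_breakdown):
        scen = Scenario("halve", (Modification("pfmt_time", "scale", 0.5),))
        out = apply_scenario(app_breakdown, scen)
        assert out.laundry_time == app_breakdown.laundry_time
        assert out.aids == app_breakdown.aids

    def test_unknown_component_rejected(self):
        with pytest.raises(ConfigError):
            Modification("app_development", "scale", 0.5)

    def test_scale_requires_positive_factor(self):
        with pytest.raises(ConfigError):
            Modification("pfmt_time", "scale", 0.0)

    components = st.sampled_from(
        ["assessment", "pfmt_time", "laundry_time", "aids", "laundry_loads"]
    )
    factors = st.floats(0.1, 3.0)

    @given(components, factors, factors)
    def test_scale_composition(self, component, a, b):
        bd = CostBreakdown(6.4, 0.0, 463.7, 38.5, 15.4, 23.0)
        two_step = apply_scenario(
            apply_scenario(bd, Scenario("a", (Modification(component, "scale", a),))),
            Scenario("b", (Modification(component, "scale", b),)),
        )
        one_step = apply_scenario(
            bd, Scenario("ab", (Modification(component, "scale", a * b),))
        )
        assert two_step.total == pytest.approx(one_step.total, rel=1e-12)

    @given(components)
    def test_exclude_idempotent(self, component):
        bd = CostBreakdown(6.4, 0.0, 463.7, 38.5, 15.4, 23.0)
        once = apply_scenario(bd, Scenario("x", (Modification(component, "exclude"),)))
        twice = apply_scenario(once, Scenario("x", (Modification(component, "exclude"),)))
        assert once == twice
        assert once.total == pytest.approx(bd.total - getattr(bd, component), abs=1e-9)

    @given(components, factors)
    def test_one_way_delta_algebra(self, component, f):
        # scaling component c by f changes the total by (f-1)*c
        bd = CostBreakdown(6.4, 0.0, 463.7, 38.5, 15.4, 23.0)
        out = apply_scenario(bd, Scenario("s", (Modification(component, "scale", f),)))
        assert out.total - bd.total == pytest.approx(
            (f - 1.0) * getattr(bd, component), rel=1e-9, abs=1e-9
        )


class TestRunSensitivity:
    def test_published_scenarios(self, app_breakdown, control_breakdown):
        table = run_sensitivity(
            app_breakdown,
            control_breakdown,
            QALY_GAINS["app"],
            QALY_GAINS["control"],
            default_scenarios(),
        )
        expected = {
            "base": 7615.5,
            "pfmt_time_halved": -2425.7,
            "laundry_cost_halved": 9785.5,
            "laundry_time_excluded": 14870.6,
            "multiway": 6999.5,
        }
        icers = table.icers()
        for name, value in expected.items():
            assert icers[name] == pytest.approx(value, rel=0.002), name
        # ICER range spans a sign change iff some scenario turns delta-cost negative
        assert min(icers.values()) < 0
        assert table.row("pfmt_time_halved").result.delta_cost < 0

    def test_per_arm_totals(self, app_breakdown, control_breakdown):
        table = run_sensitivity(
            app_breakdown, control_breakdown,
            QALY_GAINS["app"], QALY_GAINS["control"], default_scenarios(),
        )
        expected = {
            "pfmt_time_halved": (315.1, 335.7),
            "laundry_cost_halved": (535.4, 452.4),
            "laundry_time_excluded": (508.5, 382.3),
            "multiway": (265.1, 205.7),
        }
        for name, (app_total, control_total) in expected.items():
            row = table.row(name)
            assert row.cost_intervention == pytest.approx(app_total, abs=0.2), name
            assert row.cost_comparator == pytest.approx(control_total, abs=0.2), name

    def test_scenarios_leave_qaly_untouched(self, app_breakdown, control_breakdown):
        table = run_sensitivity(
            app_breakdown, control_breakdown, 0.01, 0.002, default_scenarios()
        )
        for row in table.rows:
            assert row.qaly_gain_intervention == 0.01
            assert row.qaly_gain_comparator == 0.002

    def test_scaling_zero_component_is_identity_row(self, control_breakdown):
        scen = [Scenario("s", (Modification("treatment_delivery", "scale", 0.5),))]
        table = run_sensitivity(
            control_breakdown, control_breakdown, 0.01, 0.002, scen
        )
        assert table.row("s").cost_intervention == table.row("base").cost_intervention

    def test_empty_scenarios_rejected(self, control_breakdown):
        with pytest.raises(ValidationError):
            run_sensitivity(control_breakdown, control_breakdown, 0.01, 0.002, [])
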