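"""Medium setup, allowance bounds, qualitative screening, and rollback."""

import cobra
import pytest
from hypothesis import given, settings, strategies as st

from exoflux import fixtures as fx
from exoflux.constraints import (
    MediumConfig,
    allowance_bounds,
    integrate_quantitative,
    screen_qualitative_exchanges,
    set_medium_constraints,
)
from exoflux.flux_engine import is_feasible
from exoflux.model_core import ExchangeProfile


def _config():
    return MediumConfig(
        classes={"EX_na_e": "ion", "EX_vitb_e": "vitamin",
                 "EX_his_e": "essential_aa", "EX_h2o_e": "bulk"},
        oxygen_exchange="EX_o2_e",
        closed_uptake=["EX_h2o2_e"],
        biomass_reaction="BIOMASS",
    )


class TestMediumConstraints:
    def test_class_and_oxygen_bounds(self, medium_model):
        out = set_medium_constraints(medium_model, _config())
        assert out.reactions.EX_na_e.lower_bound == -100.0
        assert out.reactions.EX_vitb_e.lower_bound == -1.0
        assert out.reactions.EX_his_e.lower_bound == -10.0
        assert out.reactions.EX_h2o_e.lower_bound == -100.0
        assert out.reactions.EX_o2_e.bounds == (-1000.0, 0.0)
        # ROS uptake closed so oxygen demand cannot be dodged
        assert out.reactions.EX_h2o2_e.lower_bound == 0.0
        # unclassed exchange keeps the generous defaults
        assert out.reactions.EX_glc_e.bounds == (-2000.0, 2000.0)
        assert out.reactions.BIOMASS.lower_bound == 0.008
        assert is_feasible(out)

    def test_rejects_class_on_non_exchange(self, medium_model):
        cfg = _config()
        cfg.classes["BIOMASS"] = "ion"
        with pytest.raises(ValueError, match="BIOMASS"):
            set_medium_constraints(medium_model, cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = _config()
        cfg.to_yaml(tmp_path / "medium.yaml")
        back = MediumConfig.from_yaml(tmp_path / "medium.yaml")
        assert back.classes == cfg.classes
        assert back.oxygen_bounds == cfg.oxygen_bounds
        assert back.min_growth == cfg.min_growth


class TestAllowanceBounds:
    @pytest.mark.parametrize("x,expected", [
        (-860.0, (-1032.0, -688.0)),
        (32.35, (25.880, 38.82)),
        (-304.27, (-365.124, -243.416)),
        (0.0, (0.0, 0.0)),
    ])
    def test_printed_extremes(self, x, expected):
        lo, hi = allowance_bounds(x)
        assert lo == pytest.approx(expected[0], abs=1e-9)
        assert hi == pytest.approx(expected[1], abs=1e-9)

    @given(st.floats(min_value=-1e6, max_value=1e6),
           st.floats(min_value=0.0, max_value=0.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_odd_symmetry_and_ordering(self, x, a):
        lo, hi = allowance_bounds(x, a)
        assert lo <= x <= hi or a == 0  # interval always brackets x
        mlo, mhi = allowance_bounds(-x, a)
        assert mlo == pytest.approx(-hi) and mhi == pytest.approx(-lo)


def _transport_sink_model():
    """Metabolite with reversible transport, a producer, and a consumer."""
    m = cobra.Model("screen_toy")
    mets = {mid: cobra.Metabolite(mid, compartment=mid[-1])
            for mid in ("x_e", "x_c", "y_c", "iso_e")}
    m.add_metabolites(list(mets.values()))
    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid)
        m.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        r.bounds = (lb, ub)
    rxn("EX_x_e", {"x_e": -1}, -100, 100)
    rxn("Xt", {"x_e": -1, "x_c": 1}, -100, 100)
    rxn("CONSUME", {"x_c": -1, "y_c": 1}, 0, 100)
    rxn("PRODUCE", {"y_c": -1, "x_c": 1}, 0, 100)
    rxn("DM_y", {"y_c": -1}, -100, 100)
    # isolated metabolite: exchange exists, no transport at all
    rxn("EX_iso_e", {"iso_e": -1}, -100, 100)
    m.objective = "CONSUME"
    return m


class TestQualitativeScreening:
    def test_directions_follow_network_capability(self):
        model = _transport_sink_model()
        profile = ExchangeProfile("s", "s", {"x": -1.0, "iso": 2.0})
        mapping = {"x": "EX_x_e", "iso": "EX_iso_e"}
        res = screen_qualitative_exchanges(model, profile, mapping)
        # reversible transport + source + sink: both directions usable
        assert "x" in res.usable_uptake and "x" in res.usable_secretion
        # fully disconnected metabolite: discarded in both directions
        assert ("iso", "uptake") in res.discarded
        assert ("iso", "secretion") in res.discarded

    def test_uptake_only_when_no_producer(self):
        model, profile, _ = fx.make_exchange_completion_fixture(2, 0, seed=1)
        mapping = {"a": "EX_a_e", "w": "EX_w_e"}
        res = screen_qualitative_exchanges(model, profile, mapping)
        # nutrients are consumed by biomass but nothing produces them
        assert res.usable_uptake == ["a", "w"]
        assert res.usable_secretion == []
        assert set(res.discarded) == {("a", "secretion"), ("w", "secretion")}

    def test_infeasible_model_rejected(self, medium_model):
        medium_model.reactions.EX_glc_e.bounds = (0.0, 0.0)
        medium_model.reactions.BIOMASS.lower_bound = 1.0
        with pytest.raises(ValueError, match="infeasible"):
            screen_qualitative_exchanges(
                medium_model, ExchangeProfile("s", "s", {"glc": -1.0}),
                {"glc": "EX_glc_e"})


class TestQuantitativeIntegration:
    def test_compatible_pairs_all_applied(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        toy_aerobic.reactions.BIOMASS.lower_bound = 0.008
        profile = ExchangeProfile("s", "s", {"glc": -5.0, "o2": -30.0})
        mapping = {"glc": "EX_glc_e", "o2": "EX_o2_e"}
        out, ledger = integrate_quantitative(toy_aerobic, profile, mapping)
        assert len(ledger.applied) == 2 and not ledger.restored
        assert out.reactions.EX_glc_e.bounds == (-6.0, -4.0)
        assert is_feasible(out)

    def test_conflicting_pair_restored_in_order(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        toy_aerobic.reactions.BIOMASS.lower_bound = 0.008
        # a glucose uptake of at most 1.2 U cannot support 8-9.6 U of
        # lactate secretion (max 2 lactate per glucose): pair 2 must roll back
        profile = ExchangeProfile("s", "s", {"glc": -1.0, "lac": 8.0})
        mapping = {"glc": "EX_glc_e", "lac": "EX_lac_e"}
        out, ledger = integrate_quantitative(toy_aerobic, profile, mapping)
        assert [e[0] for e in ledger.applied] == ["EX_glc_e"]
        assert [e[0] for e in ledger.restored] == ["EX_lac_e"]
        # rolled-back exchange keeps its original bounds
        assert out.reactions.EX_lac_e.bounds == (0.0, 1000.0)
        assert is_feasible(out)

    def test_rollback_is_order_dependent_and_deterministic(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        toy_aerobic.reactions.BIOMASS.lower_bound = 0.008
        mapping = {"glc": "EX_glc_e", "lac": "EX_lac_e"}
        fwd = ExchangeProfile("s", "s", {"glc": -1.0, "lac": 8.0})
        rev = ExchangeProfile("s", "s", {"lac": 8.0, "glc": -1.0})
        _, ledger_fwd = integrate_quantitative(toy_aerobic, fwd, mapping)
        _, ledger_rev = integrate_quantitative(toy_aerobic, rev, mapping)
        assert [e[0] for e in ledger_fwd.restored] == ["EX_lac_e"]
        assert [e[0] for e in ledger_rev.restored] == ["EX_glc_e"]

    def test_ledger_partitions_profile_entries(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        toy_aerobic.reactions.BIOMASS.lower_bound = 0.008
        profile = ExchangeProfile(
            "s", "s", {"glc": -5.0, "lac": 200.0, "unknown_met": -1.0})
        mapping = {"glc": "EX_glc_e", "lac": "EX_lac_e"}
        screen = screen_qualitative_exchanges(toy_aerobic, profile, mapping)
        _, ledger = integrate_quantitative(toy_aerobic, profile, mapping,
                                           screen=screen)
        total = (len(ledger.applied) + len(ledger.restored)
                 + len(ledger.discarded_qualitative) + len(ledger.unmapped))
        assert total == len(profile.entries)
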