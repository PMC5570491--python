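"""FBA, parsimonious FBA, FVA, growth checks, and flux sampling."""

import cobra
import numpy as np
import pytest

from exoflux import fixtures as fx
from exoflux.flux_engine import (
    check_growth_feasibility,
    fba,
    fva,
    parsimonious_fba,
    sample_fluxes,
)


class TestFba:
    def test_glycolysis_atp_optimum(self, toy_glycolysis):
        toy_glycolysis.reactions.EX_glc_e.bounds = (-1.0, -1.0)
        solution = fba(toy_glycolysis, objective="ATPM")
        assert solution.objective_value == pytest.approx(2.0, abs=1e-9)
        assert solution["EX_lac_e"] == pytest.approx(2.0, abs=1e-9)

    def test_all_exchanges_closed_yields_zero(self, toy_glycolysis):
        for rxn in toy_glycolysis.reactions:
            if len(rxn.metabolites) == 1:
                rxn.bounds = (0.0, 0.0)
        solution = fba(toy_glycolysis, objective="ATPM")
        assert solution.status != "optimal" or \
            solution.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_tightened_bound_never_raises_maximum(self, toy_aerobic):
        loose = fba(toy_aerobic, objective="ATPM").objective_value
        toy_aerobic.reactions.EX_glc_e.lower_bound = -2.0
        tight = fba(toy_aerobic, objective="ATPM").objective_value
        assert tight <= loose + 1e-9


class TestParsimoniousFba:
    def test_identical_parallel_pathways_split_half_half(self, toy_parallel):
        solution = parsimonious_fba(toy_parallel, objective="EX_pyr_e")
        assert solution["P1"] == pytest.approx(solution["P2"], abs=1e-6)
        assert solution["P1"] == pytest.approx(5.0, abs=1e-4)

    def test_objective_preserved_within_relative_tolerance(self, toy_parallel):
        lp = fba(toy_parallel, objective="EX_pyr_e").objective_value
        qp = parsimonious_fba(toy_parallel, objective="EX_pyr_e").objective_value
        assert abs(qp - lp) <= 1e-6 * max(1.0, abs(lp)) + 1e-9

    def test_single_pathway_matches_fba(self, toy_glycolysis):
        toy_glycolysis.reactions.EX_glc_e.bounds = (-1.0, -1.0)
        lp = fba(toy_glycolysis, objective="ATPM")
        qp = parsimonious_fba(toy_glycolysis, objective="ATPM")
        assert qp.objective_value == pytest.approx(lp.objective_value,
                                                   rel=1e-6)
        assert qp["GLYC"] == pytest.approx(lp["GLYC"], abs=1e-4)

    def test_repeated_runs_identical(self, toy_parallel):
        a = parsimonious_fba(toy_parallel, objective="EX_pyr_e")
        b = parsimonious_fba(toy_parallel, objective="EX_pyr_e")
        assert np.allclose(a.fluxes.to_numpy(), b.fluxes.to_numpy(),
                           atol=1e-9)

    def test_norm_not_exceeding_alternate_optimum(self, toy_parallel):
        # the lopsided alternate optimum (all flux on P1) has a strictly
        # larger internal norm than the parsimonious split
        solution = parsimonious_fba(toy_parallel, objective="EX_pyr_e")
        internal = [r.id for r in toy_parallel.reactions
                    if len(r.metabolites) > 1]
        norm = float(sum(solution[r] ** 2 for r in internal))
        lopsided = {"GLCt": 10.0, "P1": 10.0, "P2": 0.0, "PYRt": 20.0}
        alt_norm = float(sum(v ** 2 for v in lopsided.values()))
        assert norm < alt_norm


class TestFva:
    def test_clamped_exchange_has_degenerate_range(self, toy_glycolysis):
        toy_glycolysis.reactions.EX_glc_e.bounds = (-1.0, -1.0)
        ranges = fva(toy_glycolysis, reactions=["EX_glc_e"],
                     objective_fraction=0.0)
        lo, hi = ranges["EX_glc_e"]
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_antiparallel_internal_loop_spans_wide_range(self):
        model = cobra.Model("loop")
        a = cobra.Metabolite("a_c", compartment="c")
        b = cobra.Metabolite("b_c", compartment="c")
        model.add_metabolites([a, b])
        for rid, stoich in [("F", {a: -1, b: 1}), ("R", {b: -1, a: 1})]:
            rxn = cobra.Reaction(rid)
            model.add_reactions([rxn])
            rxn.add_metabolites(stoich)
            rxn.bounds = (0, 100)
        ex = cobra.Reaction("EX_a_c")
        model.add_reactions([ex])
        ex.add_metabolites({a: -1})
        ex.bounds = (0, 0)
        model.objective = "F"
        ranges = fva(model, objective_fraction=0.0)
        assert ranges["F"] == (pytest.approx(0.0), pytest.approx(100.0))
        assert ranges["R"] == (pytest.approx(0.0), pytest.approx(100.0))

    def test_parsimonious_flux_within_every_range(self, toy_aerobic):
        toy_aerobic.reactions.EX_glc_e.bounds = (-1.0, -1.0)
        solution = parsimonious_fba(toy_aerobic, objective="ATPM")
        ranges = fva(toy_aerobic, objective_fraction=1.0)
        assert ranges.contains(solution.fluxes, tol=1e-4)


class TestGrowthFeasibility:
    def test_rate_inside_achievable_range(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        feasible, (lo, hi) = check_growth_feasibility(toy_aerobic, 0.03,
                                                      error=0.2)
        assert feasible
        assert lo <= 0.03 * 0.8 and hi >= 0.03 * 1.2

    def test_rate_above_achievable_range(self, toy_aerobic):
        toy_aerobic.objective = "BIOMASS"
        _, (_, hi) = check_growth_feasibility(toy_aerobic, 0.03)
        feasible, _ = check_growth_feasibility(toy_aerobic, hi * 2.0,
                                               error=0.2)
        assert not feasible

    def test_rejects_nonpositive_rate(self, toy_aerobic):
        with pytest.raises(ValueError):
            check_growth_feasibility(toy_aerobic, 0.0)


class TestSampling:
    @pytest.fixture
    def bounded_model(self, toy_glycolysis):
        toy_glycolysis.reactions.EX_glc_e.bounds = (-1.0, -0.5)
        return toy_glycolysis

    def test_same_seed_reproduces_stream(self, bounded_model):
        a = sample_fluxes(bounded_model, n_points=40, seed=7)
        b = sample_fluxes(bounded_model, n_points=40, seed=7)
        assert (a.samples.values == b.samples.values).all()

    def test_samples_within_fva_bounds(self, bounded_model):
        samples = sample_fluxes(bounded_model, n_points=40, seed=3)
        ranges = fva(bounded_model, objective_fraction=0.0)
        for i in range(len(samples.samples)):
            assert ranges.contains(samples.samples.iloc[i], tol=1e-6)

    def test_marginal_matches_uniform_on_segment(self):
        # 1-D polytope: v_in = v_out in [0, 1]; the marginal of either flux
        # should be uniform with mean 1/2 and sd 1/sqrt(12)
        model = cobra.Model("segment")
        x = cobra.Metabolite("x_c", compartment="c")
        model.add_metabolites([x])
        for rid, coef in [("IN", 1), ("OUT", -1)]:
            rxn = cobra.Reaction(rid)
            model.add_reactions([rxn])
            rxn.add_metabolites({x: coef})
            rxn.bounds = (0, 1)
        model.objective = "OUT"
        samples = sample_fluxes(model, n_points=400, seed=17, thinning=10)
        mean = float(samples.samples["OUT"].mean())
        # 3 standard errors with a conservative effective sample size
        assert abs(mean - 0.5) < 3 * (1 / np.sqrt(12)) / np.sqrt(40)

    def test_unbounded_direction_rejected(self, toy_glycolysis):
        toy_glycolysis.reactions.ATPM.upper_bound = float("inf")
        with pytest.raises(ValueError, match="bound"):
            sample_fluxes(toy_glycolysis, n_points=10, seed=1)
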