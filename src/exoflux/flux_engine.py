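"""Optimization kernel: FBA, two-stage parsimonious FBA, FVA, growth-rate
feasibility checks, and hit-and-run flux sampling.

FBA solves ``opt c^T v  s.t.  S v = 0, lb <= v <= ub`` through the model's
LP solver (GLPK by default).  Parsimonious FBA first solves that LP, then
fixes the linear optimum (to relative tolerance) and minimizes the squared
Euclidean norm of the *internal* (non-exchange) fluxes, which selects a
unique flux vector among the alternate LP optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import cobra
import numpy as np
import pandas as pd
import scipy.optimize as sopt
import scipy.sparse as sp
from cobra.flux_analysis import flux_variability_analysis
from cobra.util.array import create_stoichiometric_matrix

from .model_core import FluxSolution

__all__ = [
    "fba",
    "parsimonious_fba",
    "fva",
    "FvaRange",
    "check_growth_feasibility",
    "sample_fluxes",
    "SampleSet",
    "is_feasible",
]

#: LP feasibility / optimality tolerances surfaced for reproducibility.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9


@dataclass
class FvaRange:
    """Per-reaction flux ranges subject to objective optimality."""

    ranges: pd.DataFrame  # columns: minimum, maximum

    def __getitem__(self, reaction_id: str) -> Tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])

    def contains(self, fluxes: pd.Series, tol: float = 1e-6) -> bool:
        sub = fluxes.reindex(self.ranges.index)
        return bool(
            ((sub >= self.ranges["minimum"] - tol)
             & (sub <= self.ranges["maximum"] + tol)).all()
        )


@dataclass
class SampleSet:
    """Matrix of sampled steady-state flux vectors plus sampler parameters."""

    samples: pd.DataFrame  # rows = samples, columns = reaction ids
    n_points: int
    thinning: int
    seed: int

    @property
    def medians(self) -> pd.Series:
        return self.samples.median(axis=0)


def _configure(model: cobra.Model) -> None:
    model.tolerance = FEASIBILITY_TOL


def fba(model: cobra.Model, objective: Optional[str] = None,
        sense: str = "max") -> FluxSolution:
    """Flux balance analysis: optimize a single linear flux objective."""
    with model as m:
        _configure(m)
        if objective is not None:
            m.objective = objective
        m.objective_direction = "max" if sense.startswith("max") else "min"
        solution = m.optimize()
        if solution.status != "optimal":
            return FluxSolution(fluxes=pd.Series(dtype=float),
                                objective_value=float("nan"),
                                status=solution.status)
        return FluxSolution(fluxes=solution.fluxes.copy(),
                            objective_value=float(solution.objective_value),
                            status="optimal")


def is_feasible(model: cobra.Model) -> bool:
    """Whether the model admits any flux satisfying S v = 0 and the bounds."""
    with model as m:
        _configure(m)
        value = m.slim_optimize(error_value=float("nan"))
    return not math.isnan(value)


def parsimonious_fba(model: cobra.Model, objective: Optional[str] = None,
                     sense: str = "max", objective_tol: float = 1e-6) -> FluxSolution:
    """Two-stage parsimonious FBA with a Euclidean-norm secondary objective.

    Stage 1 optimizes the linear objective by FBA.  Stage 2 constrains the
    objective to its optimum (within relative tolerance ``objective_tol``)
    and minimizes ``1/2 * sum(v_j^2)`` over internal (non-exchange)
    reactions, a strictly convex QP whose solution is unique on the
    internal fluxes.
    """
    stage1 = fba(model, objective=objective, sense=sense)
    if stage1.status != "optimal":
        raise ValueError(f"stage-1 LP not optimal: {stage1.status}")

    with model as m:
        if objective is not None:
            m.objective = objective
        n = len(m.reactions)
        S = sp.csr_matrix(create_stoichiometric_matrix(m, array_type="lil"))
        lb = np.array([r.lower_bound for r in m.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in m.reactions], dtype=float)
        c = np.zeros(n)
        coeffs = cobra.util.solver.linear_reaction_coefficients(m)
        for rxn, coef in coeffs.items():
            c[m.reactions.index(rxn)] = coef
        internal = np.array(
            [len(r.metabolites) > 1 for r in m.reactions], dtype=bool
        )
        rxn_ids = [r.id for r in m.reactions]

    opt = stage1.objective_value
    slack = objective_tol * max(1.0, abs(opt))
    x0 = stage1.fluxes.reindex(rxn_ids).to_numpy(dtype=float)

    H = sp.diags(internal.astype(float)).tocsc()

    def fun(x: np.ndarray) -> float:
        return 0.5 * float(x[internal] @ x[internal])

    def grad(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[internal] = x[internal]
        return g

    constraints = [
        sopt.LinearConstraint(S, 0.0, 0.0),
        sopt.LinearConstraint(sp.csr_matrix(c.reshape(1, -1)),
                              opt - slack, opt + slack),
    ]
    import warnings

    with warnings.catch_warnings():
        # the stoichiometric Jacobian is rank-deficient by construction
        # (conserved moieties); trust-constr handles it via dense SVD
        warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
        res = sopt.minimize(
            fun, x0, jac=grad, hess=lambda x: H, method="trust-constr",
            constraints=constraints, bounds=sopt.Bounds(lb, ub),
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
        )
    if not res.success and res.constr_violation > 1e-6:
        raise RuntimeError(f"stage-2 QP failed: {res.message}")
    fluxes = pd.Series(res.x, index=rxn_ids)
    return FluxSolution(fluxes=fluxes, objective_value=float(c @ res.x),
                        status="optimal")


def fva(model: cobra.Model, reactions: Optional[Sequence[str]] = None,
        objective_fraction: float = 1.0) -> FvaRange:
    """Flux variability analysis: per-reaction min/max flux.

    With ``objective_fraction=1.0`` the linear objective is held at its
    optimum; ``0.0`` drops the optimality requirement and explores the
    whole feasible polytope (the model's own bound constraints, e.g. a
    minimal-growth lower bound, always remain in force).
    """
    with model as m:
        _configure(m)
        frame = flux_variability_analysis(
            m, reaction_list=reactions,
            fraction_of_optimum=objective_fraction,
            processes=1,
        )
    return FvaRange(ranges=frame)


def check_growth_feasibility(
    model: cobra.Model, experimental_rate: float, error: float = 0.2,
    biomass_reaction: Optional[str] = None,
) -> Tuple[bool, Tuple[float, float]]:
    """Test whether the model can grow at an experimental rate +/- error.

    Sets the biomass bounds to ``[mu(1-e), mu(1+e)]`` and solves one FBA.
    Returns the verdict together with the model's unconstrained achievable
    biomass range for diagnosis.
    """
    if experimental_rate <= 0:
        raise ValueError("experimental growth rate must be positive")
    if biomass_reaction is None:
        biomass_reaction = _objective_reaction_id(model)
    rng = fva(model, reactions=[biomass_reaction], objective_fraction=0.0)
    lo, hi = rng[biomass_reaction]
    with model as m:
        _configure(m)
        rxn = m.reactions.get_by_id(biomass_reaction)
        rxn.bounds = (experimental_rate * (1 - error),
                      experimental_rate * (1 + error))
        feasible = not math.isnan(m.slim_optimize(error_value=float("nan")))
    return feasible, (lo, hi)


def _objective_reaction_id(model: cobra.Model) -> str:
    coeffs = cobra.util.solver.linear_reaction_coefficients(model)
    if not coeffs:
        raise ValueError("model has no linear objective reaction")
    return next(iter(coeffs)).id


def sample_fluxes(model: cobra.Model, n_points: int, seed: int,
                  thinning: int = 100) -> SampleSet:
    """Artificial-centering hit-and-run sampling of the flux polytope.

    ``thinning`` is the number of chain steps between retained points
    (the warmup set is generated internally by the sampler).  Fails fast
    if any flux direction is unbounded, since hit-and-run requires a
    bounded polytope.
    """
    from cobra.sampling import ACHRSampler

    for rxn in model.reactions:
        if math.isinf(rxn.lower_bound) or math.isinf(rxn.upper_bound):
            raise ValueError(
                f"reaction {rxn.id} has an infinite bound; the flux polytope "
                "must be bounded before sampling"
            )
    if not is_feasible(model):
        raise ValueError("model infeasible; cannot sample")
    with model as m:
        _configure(m)
        sampler = ACHRSampler(m, thinning=thinning, seed=seed)
        frame = sampler.sample(n_points)
    return SampleSet(samples=frame, n_points=n_points, thinning=thinning,
                     seed=seed)
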