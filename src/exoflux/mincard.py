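"""Minimum-cardinality completion of a measured exchange profile.

Targeted exometabolomic platforms quantify only a subset of the metabolites
a cell actually exchanges with its medium, and closing every unmeasured
exchange of a genome-scale model typically leaves no feasible steady state.
This module finds a minimal set of additional ("missing") exchange
reactions whose activation restores feasibility:

* :func:`min_exchange_cardinality` — the L1 relaxation.  Every candidate
  exchange is split into nonnegative uptake and secretion components
  ``v_e`` and the LP ``min 1^T v_e  s.t.  [S S_e][v; v_e] = 0,
  lb <= v <= ub, 0 <= v_e`` is solved.  Minimizing the one-norm of ``v_e``
  recovers, with high probability, the minimum-cardinality support when
  the number of independent constraints greatly exceeds that cardinality.
* :func:`verify_minimality_fva` — closes non-active candidates, then tests
  each active exchange for necessity (close it, check feasibility); any
  removable exchange is excluded and the LP re-run, so the final set is
  irreducible.
* :func:`brute_force_min_card` — exact oracle by subset enumeration,
  usable only on small candidate sets; it exists so that the L1 answer can
  be checked against ground truth on test instances.
* :func:`prune_model` — removes unused exchanges and blocked internal
  reactions, yielding the condition-specific model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Tuple

import cobra
from cobra.flux_analysis import find_blocked_reactions

from .flux_engine import fba, is_feasible
from .model_core import FluxSolution

__all__ = [
    "CandidateExchangeSet",
    "ActiveExchange",
    "ConditionModel",
    "candidate_exchanges",
    "min_exchange_cardinality",
    "verify_minimality_fva",
    "brute_force_min_card",
    "prune_model",
    "build_condition_model",
]

#: Flux above which a candidate component counts as active (U).
ACTIVE_TOL = 1e-6
#: Cap on candidate uptake/secretion components so the LP stays bounded (U).
CANDIDATE_CAP = 2000.0
#: Epsilon for blocked-reaction identification during pruning (U).
BLOCKED_EPS = 1e-4


@dataclass(frozen=True)
class ActiveExchange:
    exchange_id: str
    direction: str  # "uptake" or "secretion"
    flux: float  # net magnitude in U


@dataclass
class CandidateExchangeSet:
    """Unmeasured exchange reactions, each split into nonnegative components."""

    exchange_ids: List[str]

    def __post_init__(self) -> None:
        self.exchange_ids = sorted(self.exchange_ids)

    def __len__(self) -> int:
        return len(self.exchange_ids)


@dataclass
class ConditionModel:
    """A pruned, sample-specific model plus provenance."""

    model: cobra.Model
    sample_id: str
    measured_exchanges: List[str]
    added_exchanges: List[ActiveExchange]
    removed_exchanges: List[str]
    removed_blocked: List[str]

    def provenance(self) -> Dict[str, object]:
        return {
            "sample_id": self.sample_id,
            "measured_exchanges": list(self.measured_exchanges),
            "added_exchanges": [
                {"exchange_id": a.exchange_id, "direction": a.direction,
                 "flux": a.flux}
                for a in self.added_exchanges
            ],
            "removed_exchanges": list(self.removed_exchanges),
            "removed_blocked": list(self.removed_blocked),
        }


def candidate_exchanges(model: cobra.Model,
                        measured: Iterable[str]) -> CandidateExchangeSet:
    """All model exchanges not covered by the measured profile."""
    measured = set(measured)
    ids = [r.id for r in model.reactions
           if len(r.metabolites) == 1 and r.id not in measured]
    return CandidateExchangeSet(exchange_ids=ids)


def _augment(model: cobra.Model, candidates: CandidateExchangeSet,
             cap: float) -> Tuple[cobra.Model, Dict[str, Tuple[str, str]]]:
    """Close candidate exchanges and add unidirectional components for each.

    Returns the augmented model and a map ``exchange id -> (uptake
    component id, secretion component id)``.  Candidates are processed in
    lexicographic order so the LP column order — and hence the solver's
    tie-breaking — is deterministic.
    """
    aug = model.copy()
    comp_map: Dict[str, Tuple[str, str]] = {}
    new_rxns = []
    for ex_id in candidates.exchange_ids:
        rxn = aug.reactions.get_by_id(ex_id)
        (met, coef), = rxn.metabolites.items()
        rxn.bounds = (0.0, 0.0)
        up = cobra.Reaction(f"{ex_id}__up")
        up.add_metabolites({met: -coef})  # reverse of secretion direction
        up.bounds = (0.0, cap)
        sec = cobra.Reaction(f"{ex_id}__sec")
        sec.add_metabolites({met: coef})
        sec.bounds = (0.0, cap)
        new_rxns.extend([up, sec])
        comp_map[ex_id] = (up.id, sec.id)
    aug.add_reactions(new_rxns)
    return aug, comp_map


def min_exchange_cardinality(
    model: cobra.Model,
    candidates: CandidateExchangeSet,
    active_tol: float = ACTIVE_TOL,
    cap: float = CANDIDATE_CAP,
) -> Tuple[List[ActiveExchange], FluxSolution]:
    """Solve the L1-relaxed exchange-cardinality minimization.

    The model must already carry the measured constraints (and a
    minimal-growth bound if growth is required).  Returns the active set —
    candidates whose *net* component flux exceeds ``active_tol``, with
    uptake/secretion components of one metabolite netted against each
    other so both are never reported active — and the full flux solution
    of the augmented LP.
    """
    aug, comp_map = _augment(model, candidates, cap)
    component_ids = [cid for pair in comp_map.values() for cid in pair]
    aug.objective = {aug.reactions.get_by_id(cid): 1.0 for cid in component_ids}
    aug.objective_direction = "min"
    solution = aug.optimize()
    if solution.status != "optimal":
        raise ValueError(
            "profile unsatisfiable even with completed metabolome "
            f"(LP status: {solution.status})"
        )
    active: List[ActiveExchange] = []
    for ex_id in candidates.exchange_ids:
        up_id, sec_id = comp_map[ex_id]
        net = float(solution.fluxes[up_id]) - float(solution.fluxes[sec_id])
        if net > active_tol:
            active.append(ActiveExchange(ex_id, "uptake", net))
        elif net < -active_tol:
            active.append(ActiveExchange(ex_id, "secretion", -net))
    flux_solution = FluxSolution(fluxes=solution.fluxes.copy(),
                                 objective_value=float(solution.objective_value),
                                 status="optimal")
    return active, flux_solution


def _open_active(model: cobra.Model, candidates: CandidateExchangeSet,
                 active: Sequence[ActiveExchange], cap: float) -> cobra.Model:
    """Copy with non-active candidates closed and active ones opened
    one-directionally (uptake: [-cap, 0]; secretion: [0, cap])."""
    out = model.copy()
    active_by_id = {a.exchange_id: a for a in active}
    for ex_id in candidates.exchange_ids:
        rxn = out.reactions.get_by_id(ex_id)
        a = active_by_id.get(ex_id)
        if a is None:
            rxn.bounds = (0.0, 0.0)
        elif a.direction == "uptake":
            rxn.bounds = (-cap, 0.0)
        else:
            rxn.bounds = (0.0, cap)
    return out


def verify_minimality_fva(
    model: cobra.Model,
    candidates: CandidateExchangeSet,
    active: Sequence[ActiveExchange],
    active_tol: float = ACTIVE_TOL,
    cap: float = CANDIDATE_CAP,
    max_iterations: int = 10,
) -> Tuple[List[ActiveExchange], int]:
    """Ensure every active exchange is necessary; re-run the LP otherwise.

    With all non-active candidates closed, each active exchange is closed
    in turn and feasibility tested.  A removable exchange (system still
    feasible without it) is excluded from the candidate set and the
    cardinality LP re-run.  The loop terminates because each iteration
    strictly shrinks the candidate pool; the returned cardinality is never
    larger than the input's.
    """
    active = list(active)
    remaining = list(candidates.exchange_ids)
    for iteration in range(1, max_iterations + 1):
        opened = _open_active(model, candidates, active, cap)
        removable = None
        for a in active:
            with opened:
                opened.reactions.get_by_id(a.exchange_id).bounds = (0.0, 0.0)
                if is_feasible(opened):
                    removable = a
                    break
        if removable is None:
            return active, iteration
        remaining = [e for e in remaining if e != removable.exchange_id]
        active, _ = min_exchange_cardinality(
            model, CandidateExchangeSet(exchange_ids=remaining),
            active_tol=active_tol, cap=cap,
        )
    raise RuntimeError(
        f"minimality verification did not converge in {max_iterations} "
        f"iterations; last active set: {[a.exchange_id for a in active]}"
    )


def brute_force_min_card(
    model: cobra.Model,
    candidates: CandidateExchangeSet,
    cap: float = CANDIDATE_CAP,
    max_candidates: int = 15,
) -> int:
    """Exact minimum cardinality by exhaustive subset enumeration.

    Opens every subset of candidate exchanges (both directions) in order
    of increasing size and returns the size of the first feasible one.
    Exponential — refuses more than ``max_candidates`` candidates.  This
    is the independent oracle against which the L1 relaxation is checked.
    """
    ids = candidates.exchange_ids
    if len(ids) > max_candidates:
        raise ValueError(
            f"{len(ids)} candidates exceed the enumeration limit "
            f"({max_candidates})"
        )
    base = model.copy()
    for ex_id in ids:
        base.reactions.get_by_id(ex_id).bounds = (0.0, 0.0)
    for k in range(len(ids) + 1):
        for subset in combinations(ids, k):
            with base:
                for ex_id in subset:
                    base.reactions.get_by_id(ex_id).bounds = (-cap, cap)
                if is_feasible(base):
                    return k
    raise ValueError("infeasible even with all candidate exchanges open")


def prune_model(
    model: cobra.Model,
    measured: Iterable[str],
    active: Sequence[ActiveExchange],
    sample_id: str = "",
    eps: float = BLOCKED_EPS,
    cap: float = CANDIDATE_CAP,
    optimum_rel_tol: float = 1e-6,
) -> ConditionModel:
    """Prune to a condition-specific model.

    Non-active unmeasured exchanges are removed outright; active ones are
    opened in their verified direction.  Internal reactions that cannot
    carry |v| >= ``eps`` in any feasible flux (blocked reactions) are then
    removed.  Pruning must preserve feasibility and the maximal value of
    the model objective to relative tolerance, else an error is raised
    (an overlarge ``eps`` is the usual culprit).
    """
    measured = set(measured)
    cands = candidate_exchanges(model, measured)
    out = _open_active(model, cands, active, cap)

    active_ids = {a.exchange_id for a in active}
    removed_exchanges = [e for e in cands.exchange_ids if e not in active_ids]
    out.remove_reactions(removed_exchanges, remove_orphans=True)

    before = fba(out)
    if before.status != "optimal":
        raise RuntimeError("model infeasible after exchange removal")

    blocked = find_blocked_reactions(out, zero_cutoff=eps, processes=1)
    blocked = [b if isinstance(b, str) else b.id for b in blocked]
    out.remove_reactions(blocked, remove_orphans=True)

    after = fba(out)
    if after.status != "optimal":
        raise RuntimeError(
            "pruning broke feasibility; blocked-reaction eps may be too large"
        )
    denom = max(1.0, abs(before.objective_value))
    if abs(after.objective_value - before.objective_value) > optimum_rel_tol * denom:
        raise RuntimeError(
            "pruning changed the objective optimum: "
            f"{before.objective_value} -> {after.objective_value}"
        )
    return ConditionModel(
        model=out,
        sample_id=sample_id,
        measured_exchanges=sorted(measured),
        added_exchanges=list(active),
        removed_exchanges=removed_exchanges,
        removed_blocked=blocked,
    )


def build_condition_model(
    model: cobra.Model,
    measured: Iterable[str],
    sample_id: str = "",
    active_tol: float = ACTIVE_TOL,
    cap: float = CANDIDATE_CAP,
    eps: float = BLOCKED_EPS,
) -> ConditionModel:
    """Full pipeline: cardinality LP, minimality verification, pruning.

    ``model`` must already carry the medium and measured-profile bounds
    (see :mod:`exoflux.constraints`).
    """
    measured = list(measured)
    cands = candidate_exchanges(model, measured)
    active, _ = min_exchange_cardinality(model, cands, active_tol=active_tol,
                                         cap=cap)
    active, _ = verify_minimality_fva(model, cands, active,
                                      active_tol=active_tol, cap=cap)
    return prune_model(model, measured, active, sample_id=sample_id, eps=eps,
                       cap=cap)
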