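"""Medium setup and quantitative integration of measured exchange fluxes.

The workflow mirrors how targeted exometabolomic profiles are attached to a
genome-scale model grown in serum-containing medium of unknown composition:

1. :func:`set_medium_constraints` opens every exchange to generous default
   bounds and then tightens classes of nutrients (ions, vitamins, essential
   amino acids, bulk compounds), oxygen, and reactive-oxygen uptakes, and
   installs a minimal-growth lower bound on biomass.
2. :func:`screen_qualitative_exchanges` asks, metabolite by metabolite,
   whether the network can actually consume and/or secrete it (forcing a
   tiny flux in each direction and testing feasibility); directions the
   network cannot realize are discarded from the profile.
3. :func:`integrate_quantitative` applies each measured flux ``x`` as a
   bound pair with a fractional allowance (default 20%: the bounds are
   min/max of ``0.8 x`` and ``1.2 x``), one exchange at a time, rolling
   back any pair that makes growth infeasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import cobra
import yaml

from .flux_engine import is_feasible
from .model_core import ExchangeProfile

__all__ = [
    "MediumConfig",
    "ConstraintLedger",
    "set_medium_constraints",
    "allowance_bounds",
    "screen_qualitative_exchanges",
    "integrate_quantitative",
    "ScreenResult",
]

#: Forced-flux magnitude used during qualitative screening (U).
SCREEN_EPS = 1e-4


@dataclass
class MediumConfig:
    """Medium bounds for the global model.

    ``class_bounds`` gives the uptake lower bound per nutrient class;
    ``classes`` assigns exchange reactions to those classes.  Exchanges in
    ``closed_uptake`` (reactive oxygen species) get uptake bound 0 so that
    models cannot dodge oxygen uptake by importing ROS directly.
    """

    default_lb: float = -2000.0
    default_ub: float = 2000.0
    class_bounds: Dict[str, float] = field(default_factory=lambda: {
        "ion": -100.0,
        "vitamin": -1.0,
        "essential_aa": -10.0,
        "bulk": -100.0,  # water, protons
    })
    classes: Dict[str, str] = field(default_factory=dict)
    oxygen_exchange: Optional[str] = None
    oxygen_bounds: Tuple[float, float] = (-1000.0, 0.0)
    closed_uptake: List[str] = field(default_factory=list)
    biomass_reaction: Optional[str] = None
    min_growth: float = 0.008

    @classmethod
    def from_yaml(cls, path) -> "MediumConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key, value in (data or {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown medium config key {key!r}")
            setattr(cfg, key, value)
        if isinstance(cfg.oxygen_bounds, list):
            cfg.oxygen_bounds = tuple(cfg.oxygen_bounds)
        return cfg

    def to_yaml(self, path) -> None:
        data = {
            "default_lb": self.default_lb,
            "default_ub": self.default_ub,
            "class_bounds": dict(self.class_bounds),
            "classes": dict(self.classes),
            "oxygen_exchange": self.oxygen_exchange,
            "oxygen_bounds": list(self.oxygen_bounds),
            "closed_uptake": list(self.closed_uptake),
            "biomass_reaction": self.biomass_reaction,
            "min_growth": self.min_growth,
        }
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class ConstraintLedger:
    """Provenance of quantitative constraint integration for one sample.

    Every profile entry lands in exactly one of ``applied`` (bound pair in
    force), ``restored`` (applied then rolled back on infeasibility),
    ``discarded_qualitative`` (direction the network cannot realize), or
    ``unmapped`` (no exchange reaction for the metabolite).
    """

    sample_id: str
    applied: List[Tuple[str, float, float]] = field(default_factory=list)
    restored: List[Tuple[str, str]] = field(default_factory=list)
    discarded_qualitative: List[Tuple[str, str]] = field(default_factory=list)
    unmapped: List[str] = field(default_factory=list)

    def summary(self) -> Dict[str, int]:
        return {
            "applied": len(self.applied),
            "restored": len(self.restored),
            "discarded_qualitative": len(self.discarded_qualitative),
            "unmapped": len(self.unmapped),
        }


def set_medium_constraints(model: cobra.Model, config: MediumConfig) -> cobra.Model:
    """Return a copy of the model with medium bounds applied.

    Defaults first, class overrides second, then oxygen, ROS closures, and
    the minimal-growth bound on the biomass (objective) reaction.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.reactions if len(r.metabolites) == 1}
    for name in list(config.classes) + list(config.closed_uptake):
        if name not in exchange_ids:
            raise ValueError(f"{name!r} is not an exchange reaction of the model")
    if config.oxygen_exchange is not None and config.oxygen_exchange not in exchange_ids:
        raise ValueError(f"oxygen exchange {config.oxygen_exchange!r} not in model")

    for ex_id in exchange_ids:
        out.reactions.get_by_id(ex_id).bounds = (config.default_lb, config.default_ub)
    for ex_id, label in config.classes.items():
        if label not in config.class_bounds:
            raise ValueError(f"class {label!r} has no bound in class_bounds")
        out.reactions.get_by_id(ex_id).lower_bound = config.class_bounds[label]
    if config.oxygen_exchange is not None:
        out.reactions.get_by_id(config.oxygen_exchange).bounds = config.oxygen_bounds
    for ex_id in config.closed_uptake:
        out.reactions.get_by_id(ex_id).lower_bound = 0.0

    biomass_id = config.biomass_reaction
    if biomass_id is None:
        coeffs = cobra.util.solver.linear_reaction_coefficients(out)
        if not coeffs:
            raise ValueError("no biomass reaction given and no model objective set")
        biomass_id = next(iter(coeffs)).id
    out.reactions.get_by_id(biomass_id).lower_bound = config.min_growth
    return out


def allowance_bounds(x: float, allowance: float = 0.2) -> Tuple[float, float]:
    """Bound pair around a measured flux ``x`` with a fractional allowance.

    The literal prescription lb = (1-a)x, ub = (1+a)x inverts for negative
    (uptake) fluxes, so the pair is ordered by min/max; e.g. x = -860 with
    a 20% allowance gives (-1032, -688).
    """
    if not math.isfinite(x):
        raise ValueError("measured flux must be finite")
    a, b = (1.0 - allowance) * x, (1.0 + allowance) * x
    return (min(a, b), max(a, b))


@dataclass
class ScreenResult:
    usable_uptake: List[str]
    usable_secretion: List[str]
    discarded: List[Tuple[str, str]]  # (metabolite id, direction)


def screen_qualitative_exchanges(
    model: cobra.Model,
    profile: ExchangeProfile,
    mapping: Mapping[str, str],
    eps: float = SCREEN_EPS,
) -> ScreenResult:
    """Identify which profiled metabolites the network can take up / secrete.

    For each mapped metabolite both directions are probed by forcing a tiny
    flux (uptake: ub = -eps; secretion: lb = +eps) on the exchange and
    testing feasibility.  A metabolite whose exchange cannot carry a
    direction (no catabolic or anabolic route) has that direction
    discarded; a fully disconnected metabolite is discarded in both.
    """
    if not is_feasible(model):
        raise ValueError("model infeasible before screening; check medium config")
    usable_up: List[str] = []
    usable_sec: List[str] = []
    discarded: List[Tuple[str, str]] = []
    for met in profile.entries:
        ex_id = mapping.get(met)
        if ex_id is None:
            continue
        rxn = model.reactions.get_by_id(ex_id)
        lb0, ub0 = rxn.bounds
        with model:
            rxn.bounds = (min(lb0, -eps), -eps)  # force uptake of >= eps
            up_ok = is_feasible(model)
        with model:
            rxn.bounds = (eps, max(ub0, eps))  # force secretion of >= eps
            sec_ok = is_feasible(model)
        if up_ok:
            usable_up.append(met)
        else:
            discarded.append((met, "uptake"))
        if sec_ok:
            usable_sec.append(met)
        else:
            discarded.append((met, "secretion"))
    return ScreenResult(usable_uptake=usable_up, usable_secretion=usable_sec,
                        discarded=discarded)


def integrate_quantitative(
    model: cobra.Model,
    profile: ExchangeProfile,
    mapping: Mapping[str, str],
    allowance: float = 0.2,
    screen: Optional[ScreenResult] = None,
) -> Tuple[cobra.Model, ConstraintLedger]:
    """Apply one sample's measured fluxes as bound pairs with rollback.

    Constraint pairs are applied in profile row order (the outcome of the
    rollback is order-dependent, so the order is deterministic and logged).
    After each application one FBA checks that growth at the model's
    minimal-growth bound is still possible; on infeasibility the pair's
    previous bounds are restored and the event logged.  The returned model
    is always feasible.
    """
    out = model.copy()
    ledger = ConstraintLedger(sample_id=profile.sample_id)
    if not is_feasible(out):
        raise ValueError("model infeasible before constraint integration")

    for met, x in profile.entries.items():
        ex_id = mapping.get(met)
        if ex_id is None:
            ledger.unmapped.append(met)
            continue
        direction = "uptake" if x < 0 else "secretion" if x > 0 else "zero"
        if screen is not None and direction != "zero":
            usable = (met in screen.usable_uptake if direction == "uptake"
                      else met in screen.usable_secretion)
            if not usable:
                ledger.discarded_qualitative.append((met, direction))
                continue
        lo, hi = allowance_bounds(x, allowance)
        rxn = out.reactions.get_by_id(ex_id)
        old = rxn.bounds
        rxn.bounds = (lo, hi)
        if is_feasible(out):
            ledger.applied.append((ex_id, lo, hi))
        else:
            rxn.bounds = old
            ledger.restored.append((ex_id, "infeasible with pair applied"))
    if not is_feasible(out):
        raise RuntimeError("model infeasible after integration despite rollback")
    return out, ledger
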