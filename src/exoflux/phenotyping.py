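"""Metabolite-centric flux splits, ATP yield, and energy-phenotype calls.

A flux split takes one flux distribution (from parsimonious FBA maximizing
ATP hydrolysis) and asks which reactions *produce* a target metabolite
pooled across compartments: for each reaction j with pooled production
``P_j = sum_i S_ij * v_j > 0`` the share ``P_j / Phi`` is reported, where
``Phi = sum_j P_j``.  Transport reactions — where the pooled metabolite
appears on both sides — and boundary reactions are excluded before
summation, since shuttling a metabolite between compartments produces
nothing.

The ATP yield is ``Phi_ATP / |glucose uptake|``.  Because other carbon
sources stay open, the yield of a real condition-specific model may exceed
the glucose-only theoretical ceilings (2 for glycolysis to lactate, 32 for
full oxidation at P/O 2.5 / 1.5); :func:`max_atp_from_glucose` performs
that glucose-only sanity check by closing every other carbon uptake.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import cobra

from .flux_engine import fba
from .model_core import FluxSolution

__all__ = [
    "FluxSplitReport",
    "PhenotypeCall",
    "flux_splits",
    "atp_yield",
    "classify_energy_phenotype",
    "max_atp_from_glucose",
    "DEFAULT_SUBTYPE_TABLE",
]

_SHARE_TOL = 1e-9


@dataclass
class FluxSplitReport:
    """Per-reaction production of a pooled target metabolite."""

    metabolite_ids: List[str]
    production: Dict[str, float]  # reaction id -> P_j > 0, in U
    excluded: List[str]  # transport/boundary reactions removed pre-summation
    zero_production: bool = False

    @property
    def total(self) -> float:
        return sum(self.production.values())

    @property
    def shares(self) -> Dict[str, float]:
        phi = self.total
        if phi == 0:
            return {}
        return {r: p / phi for r, p in self.production.items()}

    @property
    def major_producer(self) -> Optional[str]:
        if not self.production:
            return None
        return max(self.production, key=lambda r: (self.production[r], r))


@dataclass
class PhenotypeCall:
    """Energy classification of one condition-specific model."""

    atp_yield: float
    major_producers: Dict[str, str]  # cofactor name -> reaction id
    energy_class: str  # "glycolytic" | "OxPhos" | "unclassified"
    subtype: str  # "I".."VIII" or "unclassified"


def _pooled_coefficient(rxn: cobra.Reaction, targets: set) -> Tuple[float, float]:
    """(total positive, total negative) stoichiometry of target species."""
    pos = neg = 0.0
    for met, coef in rxn.metabolites.items():
        if met.id in targets:
            if coef > 0:
                pos += coef
            else:
                neg += coef
    return pos, neg


def flux_splits(
    model: cobra.Model,
    solution: FluxSolution,
    metabolite_ids: Sequence[str],
    exclusions: Iterable[str] = (),
    tol: float = 1e-9,
) -> FluxSplitReport:
    """Production shares of a metabolite pooled across compartments.

    ``exclusions`` adds explicit reaction ids to the automatic exclusion
    of boundary reactions and transport-like reactions (target species on
    both sides of the equation, e.g. an ATP/ADP antiporter).
    """
    targets = set(metabolite_ids)
    missing = targets - {m.id for m in model.metabolites}
    if missing:
        raise ValueError(f"metabolites not in model: {sorted(missing)}")
    exclusions = set(exclusions)
    production: Dict[str, float] = {}
    excluded: List[str] = []
    for rxn in model.reactions:
        pos, neg = _pooled_coefficient(rxn, targets)
        if pos == 0 and neg == 0:
            continue
        if rxn.id in exclusions or len(rxn.metabolites) == 1 or (pos > 0 and neg < 0):
            excluded.append(rxn.id)
            continue
        v = float(solution.fluxes.get(rxn.id, 0.0))
        p = (pos + neg) * v  # net pooled stoichiometry times rate
        if p > tol:
            production[rxn.id] = p
    report = FluxSplitReport(
        metabolite_ids=list(metabolite_ids),
        production=production,
        excluded=sorted(excluded),
        zero_production=not production,
    )
    return report


def atp_yield(
    model: cobra.Model,
    solution: FluxSolution,
    atp_metabolites: Sequence[str],
    glucose_exchange: str,
    exclusions: Iterable[str] = (),
) -> float:
    """Total ATP production flux divided by the glucose uptake magnitude.

    Raises if glucose uptake is zero in the solution — the yield is then
    undefined, not zero.
    """
    glc = float(solution.fluxes[glucose_exchange])
    if glc >= 0:
        raise ValueError(
            f"glucose uptake is {glc} in this solution; ATP yield undefined"
        )
    report = flux_splits(model, solution, atp_metabolites, exclusions)
    return report.total / abs(glc)


#: Major-producer tuples (ATP, NADH, NADPH, FADH2) for the eight energy
#: subtypes.  The reaction names follow the producers reported for the
#: glycolytic (I-II) and OxPhos (III-VIII) groups: phosphoglycerate kinase
#: vs ATP synthase for ATP; glyceraldehyde-3-phosphate dehydrogenase vs
#: 2-oxoglutarate dehydrogenase for NADH; malic enzyme, isocitrate
#: dehydrogenase or dihydroceramide desaturase for NADPH.  The table is a
#: configuration value: reaction ids are reconstruction-specific, so
#: callers analyzing their own models supply their own tuples.
DEFAULT_SUBTYPE_TABLE: Dict[Tuple[str, str, str, str], str] = {
    ("PGK", "GAPD", "G6PDH2r", "SUCD1m"): "I",
    ("PGK", "GAPD", "G6PDH2r", "DHCR72r"): "II",
    ("ATPS4m", "GAPD", "DESAT18_3", "SUCD1m"): "III",
    ("ATPS4m", "GAPD", "ME2", "SUCD1m"): "IV",
    ("ATPS4m", "GAPD", "ICDHyr", "SUCD1m"): "V",
    ("ATPS4m", "AKGDm", "DESAT18_3", "SUCD1m"): "VI",
    ("ATPS4m", "AKGDm", "ME2", "SUCD1m"): "VII",
    ("ATPS4m", "AKGDm", "ICDHyr", "SUCD1m"): "VIII",
}

#: Observed ATP-yield boundaries between the glycolytic and OxPhos groups,
#: reported as descriptive statistics alongside a call.  Classification
#: itself is by major-producer identity, from which these boundaries derive.
GLYCOLYTIC_YIELD_BOUNDARY = 4.21
OXPHOS_YIELD_BOUNDARY = 7.26


def classify_energy_phenotype(
    yield_value: float,
    major_producers: Mapping[str, str],
    glycolytic_atp_producers: Iterable[str] = ("PGK",),
    oxphos_atp_producers: Iterable[str] = ("ATPS4m",),
    subtype_table: Optional[Mapping[Tuple[str, str, str, str], str]] = None,
) -> PhenotypeCall:
    """Call the energy class and subtype from major-producer identities.

    ``major_producers`` must contain entries for "ATP", "NADH", "NADPH"
    and "FADH2".  The energy class is glycolytic when the top ATP producer
    is a phosphoglycerate-kinase-type reaction and OxPhos when it is ATP
    synthase; the subtype is looked up from the full producer tuple, or
    reported as "unclassified" with the tuple preserved in the call.
    """
    for key in ("ATP", "NADH", "NADPH", "FADH2"):
        if key not in major_producers:
            raise ValueError(f"major producer for {key} missing")
    if subtype_table is None:
        subtype_table = DEFAULT_SUBTYPE_TABLE
    atp_rxn = major_producers["ATP"]
    if atp_rxn in set(glycolytic_atp_producers):
        energy_class = "glycolytic"
    elif atp_rxn in set(oxphos_atp_producers):
        energy_class = "OxPhos"
    else:
        energy_class = "unclassified"
    tup = (major_producers["ATP"], major_producers["NADH"],
           major_producers["NADPH"], major_producers["FADH2"])
    subtype = subtype_table.get(tup, "unclassified")
    return PhenotypeCall(atp_yield=yield_value,
                         major_producers=dict(major_producers),
                         energy_class=energy_class, subtype=subtype)


def _carbon_count(met: cobra.Metabolite) -> int:
    formula = met.formula or ""
    match = re.search(r"C(\d*)(?![a-z])", formula)
    if not match:
        return 0
    return int(match.group(1) or 1)


def max_atp_from_glucose(
    model: cobra.Model,
    glucose_exchange: str,
    atp_hydrolysis: str,
    open_bound: float = 2000.0,
) -> float:
    """Maximum ATP hydrolysis flux per unit glucose, glucose-only carbon.

    Closes the uptake of every carbon-containing exchange metabolite other
    than glucose, opens all exchange upper bounds (secretions
    unrestricted), fixes glucose uptake to 1 U and maximizes the ATP
    hydrolysis reaction.  Oxygen and other inorganic uptakes keep their
    bounds.
    """
    if atp_hydrolysis not in model.reactions:
        raise ValueError(f"no ATP hydrolysis reaction {atp_hydrolysis!r}")
    with model as m:
        for rxn in m.reactions:
            if len(rxn.metabolites) != 1:
                continue
            met = next(iter(rxn.metabolites))
            rxn.upper_bound = open_bound
            if rxn.id != glucose_exchange and _carbon_count(met) > 0:
                rxn.lower_bound = 0.0
        m.reactions.get_by_id(glucose_exchange).bounds = (-1.0, -1.0)
        # biomass demand would compete for ATP; drop any positive lower
        # bounds on internal reactions for the sanity check
        for rxn in m.reactions:
            if len(rxn.metabolites) > 1 and rxn.lower_bound > 0:
                rxn.lower_bound = 0.0
        solution = fba(m, objective=atp_hydrolysis, sense="max")
        if solution.status != "optimal":
            raise ValueError(f"glucose-only FBA {solution.status}")
        return solution.objective_value / 1.0
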