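"""Environmental and genetic perturbation scans.

* :func:`phpp_scan` — phenotypic phase plane: two exchange fluxes are fixed
  on a grid (lb = ub at each point) and biomass is maximized; infeasible
  points are flagged, never reported as zero growth.
* :func:`classify_oxotype` — sweeps the oxygen axis and classifies a model
  by the window of clamped oxygen-uptake magnitudes at which it can still
  meet its minimal-growth bound: ``low`` (only the low end of the scan),
  ``high`` (only the high end), or ``indifferent`` (the whole range).
* :func:`single_gene_deletion` / :func:`reaction_essentiality` — GPR-aware
  knockouts with growth classes *terminated* (< 5% of wild type),
  *reduced* (5-95%) and *unchanged* (>= 95%).
* :func:`detect_reductive_carboxylation` — FVA on isocitrate dehydrogenase
  and aconitase (forward = oxidative) at the minimal-growth bound, with an
  optional oxygen clamp; a flux range entirely below zero means the model
  is obliged to run the reductive direction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import cobra
import numpy as np

from .flux_engine import fva, is_feasible

__all__ = [
    "PhPPGrid",
    "EssentialityReport",
    "OxotypeCall",
    "phpp_scan",
    "classify_oxotype",
    "single_gene_deletion",
    "reaction_essentiality",
    "detect_reductive_carboxylation",
    "DEFAULT_AXIS_RANGES",
]

#: Default axis ranges in U, spanning the variability of the measured
#: uptake/secretion bounds across the study's models (start, stop, step 20).
DEFAULT_AXIS_RANGES: Dict[str, Tuple[float, float]] = {
    "oxygen": (0.0, -1000.0),
    "glucose": (0.0, -1080.0),
    "glutamine": (0.0, -400.0),
    "lactate": (1620.0, 0.0),
}
DEFAULT_STEP = 20.0

TERMINATED_FRACTION = 0.05
UNCHANGED_FRACTION = 0.95

_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


@dataclass
class PhPPGrid:
    """Optimal growth over a rectangular grid of two fixed exchange fluxes."""

    axis1: str
    axis2: str
    values1: np.ndarray
    values2: np.ndarray
    growth: np.ndarray  # shape (len(values1), len(values2)); NaN = infeasible
    feasible: np.ndarray  # boolean mask, same shape

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.growth, index=self.values1,
                            columns=self.values2)


@dataclass
class EssentialityReport:
    """Knockout outcomes per gene or reaction."""

    wild_type_growth: float
    classes: Dict[str, str]  # target -> terminated | reduced | unchanged
    knockout_growth: Dict[str, float]

    def essential(self) -> List[str]:
        return sorted(t for t, c in self.classes.items() if c == "terminated")


@dataclass
class OxotypeCall:
    """Feasible oxygen-uptake window and its low/high/indifferent class."""

    feasible_interval: Tuple[float, float]  # magnitudes, U
    scanned_interval: Tuple[float, float]
    oxotype: str


def _axis_values(start: float, stop: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round(abs(stop - start) / step)) + 1
    direction = 1.0 if stop >= start else -1.0
    return start + direction * step * np.arange(n)


def phpp_scan(
    model: cobra.Model,
    axis1: str,
    axis2: str,
    range1: Tuple[float, float],
    range2: Tuple[float, float],
    step: float = DEFAULT_STEP,
) -> PhPPGrid:
    """Phenotypic phase plane over two fixed exchange fluxes.

    At each grid point both exchanges are clamped (lb = ub = value) and
    biomass maximized.  A point that conflicts with the model's other
    constraints is flagged infeasible (NaN growth).
    """
    for ax in (axis1, axis2):
        rxn = model.reactions.get_by_id(ax)
        if len(rxn.metabolites) != 1:
            raise ValueError(f"{ax} is not an exchange reaction")
    v1 = _axis_values(*range1, step)
    v2 = _axis_values(*range2, step)
    growth = np.full((len(v1), len(v2)), np.nan)
    feasible = np.zeros((len(v1), len(v2)), dtype=bool)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            with model as m:
                m.reactions.get_by_id(axis1).bounds = (a, a)
                m.reactions.get_by_id(axis2).bounds = (b, b)
                value = m.slim_optimize(error_value=float("nan"))
            if not math.isnan(value):
                growth[i, j] = value
                feasible[i, j] = True
    return PhPPGrid(axis1=axis1, axis2=axis2, values1=v1, values2=v2,
                    growth=growth, feasible=feasible)


def classify_oxotype(
    model: cobra.Model,
    oxygen_exchange: str,
    scan_range: Tuple[float, float] = DEFAULT_AXIS_RANGES["oxygen"],
    step: float = DEFAULT_STEP,
    split: Optional[float] = None,
) -> OxotypeCall:
    """Classify a model by its window of feasible clamped oxygen uptakes.

    The oxygen exchange is fixed (lb = ub) at each scan value and
    feasibility of the model — which must carry its minimal-growth bound —
    is tested.  Feasible across the whole scan: ``indifferent``; feasible
    at the zero-uptake end only: ``low``; feasible at the high-uptake end
    only: ``high``.  A window touching neither end is resolved by
    comparing its midpoint with ``split`` (default: midpoint of the
    scanned range); the underlying published distinction is visual, so the
    split is an explicit, configurable interpretation.
    """
    values = _axis_values(*scan_range, step)
    magnitudes = np.abs(values)
    ok = np.zeros(len(values), dtype=bool)
    for i, v in enumerate(values):
        with model as m:
            m.reactions.get_by_id(oxygen_exchange).bounds = (v, v)
            ok[i] = not math.isnan(m.slim_optimize(error_value=float("nan")))
    if not ok.any():
        raise ValueError("no feasible oxygen uptake value in the scanned range")
    lo = float(magnitudes[ok].min())
    hi = float(magnitudes[ok].max())
    scan_lo, scan_hi = float(magnitudes.min()), float(magnitudes.max())
    if split is None:
        split = 0.5 * (scan_lo + scan_hi)
    if ok.all():
        oxotype = "indifferent"
    elif lo <= scan_lo < hi < scan_hi:
        oxotype = "low"
    elif scan_lo < lo and hi >= scan_hi:
        oxotype = "high"
    else:
        oxotype = "low" if 0.5 * (lo + hi) <= split else "high"
    return OxotypeCall(feasible_interval=(lo, hi),
                       scanned_interval=(scan_lo, scan_hi), oxotype=oxotype)


def _growth_class(knockout: float, wild_type: float) -> str:
    if wild_type <= 0:
        raise ValueError("wild-type growth must be positive to classify")
    fraction = knockout / wild_type
    if fraction < TERMINATED_FRACTION:
        return "terminated"
    if fraction < UNCHANGED_FRACTION:
        return "reduced"
    return "unchanged"


def collapse_transcripts(gene_ids: Iterable[str]) -> Dict[str, List[str]]:
    """Group transcript-level gene ids by base id (trailing ``.N`` stripped)."""
    groups: Dict[str, List[str]] = {}
    for gid in gene_ids:
        groups.setdefault(_TRANSCRIPT_SUFFIX.sub("", gid), []).append(gid)
    return groups


def single_gene_deletion(
    model: cobra.Model,
    genes: Optional[Sequence[str]] = None,
) -> EssentialityReport:
    """Knock out each (transcript-collapsed) gene and classify growth.

    All transcripts of one base gene are disabled at once; reactions whose
    GPR then evaluates false are bounded to zero and biomass re-maximized.
    Classes are relative to the model's own wild-type maximum: terminated
    < 5%, reduced 5-95%, unchanged >= 95%.  An infeasible knockout model
    counts as zero growth.
    """
    wt = model.slim_optimize(error_value=float("nan"))
    if math.isnan(wt) or wt <= 0:
        raise ValueError("wild-type model must grow to screen deletions")
    groups = collapse_transcripts(g.id for g in model.genes)
    if genes is not None:
        genes = [_TRANSCRIPT_SUFFIX.sub("", g) for g in genes]
        missing = [g for g in genes if g not in groups]
        if missing:
            raise ValueError(f"genes not in model: {missing}")
        groups = {g: groups[g] for g in genes}
    classes: Dict[str, str] = {}
    growth: Dict[str, float] = {}
    for base, members in sorted(groups.items()):
        with model as m:
            for gid in members:
                m.genes.get_by_id(gid).knock_out()
            value = m.slim_optimize(error_value=float("nan"))
        ko = 0.0 if math.isnan(value) else max(value, 0.0)
        growth[base] = ko
        classes[base] = _growth_class(ko, wt)
    return EssentialityReport(wild_type_growth=float(wt), classes=classes,
                              knockout_growth=growth)


def reaction_essentiality(
    model: cobra.Model,
    reactions: Sequence[str],
) -> EssentialityReport:
    """Close reactions one at a time and classify growth as for genes."""
    wt = model.slim_optimize(error_value=float("nan"))
    if math.isnan(wt) or wt <= 0:
        raise ValueError("wild-type model must grow to screen reactions")
    classes: Dict[str, str] = {}
    growth: Dict[str, float] = {}
    for rid in reactions:
        with model as m:
            m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
            value = m.slim_optimize(error_value=float("nan"))
        ko = 0.0 if math.isnan(value) else max(value, 0.0)
        growth[rid] = ko
        classes[rid] = _growth_class(ko, wt)
    return EssentialityReport(wild_type_growth=float(wt), classes=classes,
                              knockout_growth=growth)


def detect_reductive_carboxylation(
    model: cobra.Model,
    reaction_ids: Sequence[str],
    oxygen_exchange: Optional[str] = None,
    oxygen_override: Optional[Tuple[float, float]] = None,
    tol: float = 1e-6,
) -> Dict[str, str]:
    """Classify TCA reactions as obligate_reverse / optional / forward_only.

    ``reaction_ids`` name isocitrate dehydrogenase and aconitase with the
    forward (positive) direction defined as oxidative.  FVA runs over the
    whole feasible space at the model's minimal-growth bound; if
    ``oxygen_override`` is given, the oxygen exchange is clamped to it
    first (e.g. ``(-100, -100)`` to emulate hypoxia).  A range with
    max < 0 is obligate reverse flux (net reductive carboxylation); a
    range spanning zero leaves the direction optional; min > 0 is forward
    only.
    """
    for rid in reaction_ids:
        model.reactions.get_by_id(rid)  # raises KeyError if absent
    with model as m:
        if oxygen_override is not None:
            if oxygen_exchange is None:
                raise ValueError("oxygen_override requires oxygen_exchange")
            m.reactions.get_by_id(oxygen_exchange).bounds = oxygen_override
        if not is_feasible(m):
            raise ValueError("model infeasible under the oxygen override")
        ranges = fva(m, reactions=list(reaction_ids), objective_fraction=0.0)
    calls: Dict[str, str] = {}
    for rid in reaction_ids:
        lo, hi = ranges[rid]
        if hi < -tol:
            calls[rid] = "obligate_reverse"
        elif lo > tol:
            calls[rid] = "forward_only"
        else:
            calls[rid] = "optional"
    return calls
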