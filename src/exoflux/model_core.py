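"""Model and profile data structures, standard-format I/O, and unit utilities.

Metabolic models are represented as :class:`cobra.Model` objects throughout
the package.  The flux unit everywhere is U = fmol/cell/hr; with a unitary
cell weight of 1e-12 g this coincides numerically with mmol/gDW/hr, so models
parameterized in the conventional unit need no rescaling.

Sign convention for exchange (boundary) reactions: negative flux = uptake
from the medium, positive flux = secretion into the medium.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import cobra
import pandas as pd
from cobra.io import (
    load_json_model,
    read_sbml_model,
    save_json_model,
    write_sbml_model,
)

__all__ = [
    "ExchangeProfile",
    "FluxSolution",
    "load_model",
    "save_model",
    "validate_model",
    "load_profiles",
    "load_mapping",
    "split_reversible",
    "merge_split_fluxes",
    "growth_rate_from_doubling_time",
    "doubling_time_from_growth_rate",
    "infer_dry_weight",
]


class ModelFormatError(ValueError):
    """Raised when a model file violates the declared standard."""


@dataclass
class ExchangeProfile:
    """One sample's measured extracellular fluxes.

    ``entries`` maps metabolite ids to measured exchange fluxes in U;
    negative values are uptakes, positive values secretions.  Zero entries
    are kept but flagged in :attr:`zero_entries`.
    """

    sample_id: str
    cell_line: str
    entries: Dict[str, float] = field(default_factory=dict)

    @property
    def zero_entries(self) -> List[str]:
        return [m for m, x in self.entries.items() if x == 0.0]

    @property
    def uptakes(self) -> Dict[str, float]:
        return {m: x for m, x in self.entries.items() if x < 0}

    @property
    def secretions(self) -> Dict[str, float]:
        return {m: x for m, x in self.entries.items() if x > 0}

    def __post_init__(self) -> None:
        for m, x in self.entries.items():
            if not math.isfinite(x):
                raise ValueError(f"non-finite flux for metabolite {m!r}")


@dataclass
class FluxSolution:
    """A solved flux distribution.

    ``fluxes`` maps reaction ids to rates in U; ``status`` is one of
    ``optimal``, ``infeasible`` or ``unbounded``.
    """

    fluxes: pd.Series
    objective_value: float
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelFormatError(f"cannot infer model format from {path.name!r}")


def load_model(path, format: Optional[str] = None) -> cobra.Model:
    """Read a metabolic model from SBML (Level 3 + FBC) or COBRA JSON.

    The loaded model is validated: every reaction must carry finite-or-open
    bounds with lb <= ub, every stoichiometric coefficient must be finite
    and nonzero, and an objective reaction must be set.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "sbml":
            model = read_sbml_model(str(path))
        elif fmt == "json":
            model = load_json_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {fmt!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # libsbml / json decoding errors
        raise ModelFormatError(f"failed to parse {path.name}: {exc}") from exc
    validate_model(model)
    return model


def save_model(model: cobra.Model, path, format: Optional[str] = None) -> None:
    """Write a model as SBML L3-FBC or COBRA JSON, inferred from the suffix."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        write_sbml_model(model, str(path))
    elif fmt == "json":
        save_json_model(model, str(path))
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants; raise :class:`ModelFormatError` on failure."""
    for rxn in model.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise ModelFormatError(f"reaction {rxn.id}: missing bound")
        if math.isnan(rxn.lower_bound) or math.isnan(rxn.upper_bound):
            raise ModelFormatError(f"reaction {rxn.id}: NaN bound")
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelFormatError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        for met, coef in rxn.metabolites.items():
            if coef == 0 or not math.isfinite(coef):
                raise ModelFormatError(
                    f"reaction {rxn.id}: invalid coefficient {coef} for {met.id}"
                )
    if not model.objective.variables:
        raise ModelFormatError("model has no objective reaction")


def exchange_reactions(model: cobra.Model) -> List[cobra.Reaction]:
    """All boundary pseudo-reactions (reactions touching a single metabolite)."""
    return [r for r in model.reactions if len(r.metabolites) == 1]


# ---------------------------------------------------------------------------
# profile / mapping I/O
# ---------------------------------------------------------------------------

_REPLICATE_SUFFIX = re.compile(r"-\d+$")


def load_profiles(path) -> List[ExchangeProfile]:
    """Read a TSV/CSV exchange-flux table into one profile per sample column.

    Column 1 holds metabolite ids; each further column is one sample.  A
    sample id with a trailing ``-<n>`` replicate suffix is assigned the
    cell-line name with the suffix stripped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("profile table needs a metabolite column plus >=1 sample")
    met_col = table.columns[0]
    mets = table[met_col].tolist()
    dupes = sorted({m for m in mets if mets.count(m) > 1})
    if dupes:
        raise ValueError(f"duplicate metabolite rows: {', '.join(dupes)}")
    profiles = []
    for col in table.columns[1:]:
        entries: Dict[str, float] = {}
        for row_idx, (met, raw) in enumerate(zip(mets, table[col])):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                raise ValueError(
                    f"empty cell at row {row_idx + 2}, column {col!r}"
                )
            try:
                entries[met] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {raw!r} at row {row_idx + 2}, column {col!r}"
                ) from exc
        cell_line = _REPLICATE_SUFFIX.sub("", col)
        profiles.append(ExchangeProfile(sample_id=col, cell_line=cell_line, entries=entries))
    return profiles


def load_mapping(path) -> Dict[str, str]:
    """Read a two-column metabolite-id -> exchange-reaction-id TSV."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("mapping table needs two columns")
    mapping: Dict[str, str] = {}
    for met, ex in zip(table.iloc[:, 0], table.iloc[:, 1]):
        if met in mapping:
            raise ValueError(f"duplicate mapping for metabolite {met!r}")
        mapping[str(met)] = str(ex)
    return mapping


def unmapped_metabolites(profile: ExchangeProfile, mapping: Mapping[str, str]) -> List[str]:
    """Profile metabolites with no exchange reaction in the mapping.

    These are reported, never dropped silently: the caller decides whether
    to extend the model or exclude the metabolite.
    """
    return [m for m in profile.entries if m not in mapping]


# ---------------------------------------------------------------------------
# reversible-reaction splitting
# ---------------------------------------------------------------------------

def split_reversible(model: cobra.Model) -> Tuple[cobra.Model, Dict[str, Tuple[str, Optional[str]]]]:
    """Convert every net reaction into a pair of unidirectional reactions.

    Returns a copy in which each reversible reaction ``R`` (lb < 0) is
    replaced by ``R__fwd`` with bounds ``[max(lb0, 0), ub0]`` mapped to
    ``[0, ub]`` and ``R__rev`` (the mirrored stoichiometry) with bounds
    ``[0, -lb0]``, plus a back-mapping ``original id -> (forward id,
    reverse id or None)``.  Net flux of the original reaction equals
    forward minus reverse.  Irreversible reactions pass through unchanged.
    """
    split = model.copy()
    backmap: Dict[str, Tuple[str, Optional[str]]] = {}
    new_reactions = []
    for rxn in list(split.reactions):
        if rxn.lower_bound >= 0:
            backmap[rxn.id] = (rxn.id, None)
            continue
        rev = cobra.Reaction(f"{rxn.id}__rev")
        rev.name = f"{rxn.name} (reverse)"
        rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        rev.bounds = (0.0, -rxn.lower_bound)
        new_reactions.append(rev)
        backmap[rxn.id] = (rxn.id, rev.id)
        rxn.bounds = (0.0, max(rxn.upper_bound, 0.0))
    split.add_reactions(new_reactions)
    return split, backmap


def merge_split_fluxes(
    backmap: Mapping[str, Tuple[str, Optional[str]]], fluxes: Mapping[str, float]
) -> Dict[str, float]:
    """Reconstruct net fluxes of the original model from a split-model solution."""
    merged = {}
    for orig, (fwd, rev) in backmap.items():
        v = float(fluxes[fwd])
        if rev is not None:
            v -= float(fluxes[rev])
        merged[orig] = v
    return merged


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def growth_rate_from_doubling_time(doubling_time_hr: float) -> float:
    """Exponential growth rate (per hour) from a doubling time, mu = ln2 / T."""
    if doubling_time_hr <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / doubling_time_hr


def doubling_time_from_growth_rate(mu_per_hr: float) -> float:
    """Doubling time in hours from an exponential growth rate, T = ln2 / mu."""
    if mu_per_hr <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / mu_per_hr


def infer_dry_weight(dry_mass_pg: float, reference_volume_um3: float,
                     target_volume_um3: float) -> float:
    """Scale a reference cell's dry mass to another cell by volume ratio.

    Returns ``dry_mass_pg * target_volume / reference_volume`` in pg, the
    standard proportional-density estimate (e.g. 60 pg at 4000 um^3 scaled
    to a 243 um^3 lymphocyte gives 3.645 pg).
    """
    if dry_mass_pg <= 0 or reference_volume_um3 <= 0 or target_volume_um3 <= 0:
        raise ValueError("all arguments must be positive")
    return dry_mass_pg * target_volume_um3 / reference_volume_um3
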