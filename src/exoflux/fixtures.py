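"""Deterministic toy metabolic networks with analytically known answers.

These generators stand in for a genome-scale human reconstruction and a
panel of measured exometabolomic profiles in every test: each network is
small enough that its optima follow from stoichiometric bookkeeping, and
each generator is seed-deterministic.

The energy fixtures use lumped textbook stoichiometry: glycolysis invests
2 ATP and returns 4 (net 2) plus 2 NADH per glucose; one acetyl-CoA turn
of the TCA cycle yields 1 GTP-equivalent ATP, 3 NADH and 1 FADH2; and the
respiratory chain is parameterized at P/O 2.5 per NADH and 1.5 per FADH2.
Full oxidation of glucose therefore yields 2 + 2 + 10*2.5 + 2*1.5 = 32 ATP,
and anaerobic glycolysis to lactate yields 2 — the two reference points
used throughout the phenotyping checks.  The 36/38-ATP conventions are
deliberately not used.

Metabolite ``formula`` attributes carry carbon counts only, so internal
reactions can be audited for elemental-carbon balance; hydrogen/oxygen
bookkeeping in the lumped reactions is closed through explicit water and
proton species where it matters and ignored otherwise.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import cobra
import numpy as np

from .model_core import ExchangeProfile

__all__ = [
    "make_toy_glycolysis",
    "make_toy_aerobic",
    "make_parallel_pathways",
    "make_rc_loop",
    "make_exchange_completion_fixture",
    "make_l1_redundancy_fixture",
    "make_oxotype_fixture",
    "make_synthetic_profile",
    "carbon_balance_errors",
]

#: carbon counts for the shared metabolite vocabulary
_CARBON = {
    "glc": 6, "pyr": 3, "lac": 3, "cit": 6, "icit": 6, "akg": 5,
    "accoa": 23, "coa": 21, "co2": 1, "gln": 5,
    "atp": 10, "adp": 10, "pi": 0, "nad": 21, "nadh": 21,
    "fad": 27, "fadh2": 27, "o2": 0, "h2o": 0, "h": 0, "biomass": 0,
}


def _met(model: cobra.Model, base: str, compartment: str) -> cobra.Metabolite:
    mid = f"{base}_{compartment}"
    if mid in model.metabolites:
        return model.metabolites.get_by_id(mid)
    met = cobra.Metabolite(mid, compartment=compartment,
                           formula=f"C{_CARBON.get(base, 0)}")
    model.add_metabolites([met])
    return met


def _rxn(model: cobra.Model, rid: str, stoich: Dict[str, float],
         lb: float, ub: float, gpr: str = "") -> cobra.Reaction:
    rxn = cobra.Reaction(rid)
    model.add_reactions([rxn])
    mets = {}
    for mid, coef in stoich.items():
        base, compartment = mid.rsplit("_", 1)
        mets[_met(model, base, compartment)] = coef
    rxn.add_metabolites(mets)
    rxn.bounds = (lb, ub)
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def _add_exchange(model: cobra.Model, base: str, lb: float, ub: float) -> cobra.Reaction:
    met = _met(model, base, "e")
    return _rxn(model, f"EX_{base}_e", {met.id: -1.0}, lb, ub)


def _glycolysis_block(model: cobra.Model, with_ldh: bool = True) -> None:
    """Glucose uptake through lactate overflow with full cofactor cycling."""
    for base in ("glc", "pyr", "lac", "atp", "adp", "pi", "nad", "nadh",
                 "h2o", "h"):
        _met(model, base, "c")
    _add_exchange(model, "glc", -10.0, 0.0)
    _rxn(model, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gpr="gGLUT1")
    # lumped Embden-Meyerhof: 2 ATP invested, 4 recovered
    _rxn(model, "GLYC", {
        "glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
        "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2, "h_c": 2,
    }, 0, 1000, gpr="gPGK")
    if with_ldh:
        _rxn(model, "LDH", {"pyr_c": -1, "nadh_c": -1, "h_c": -1,
                            "lac_c": 1, "nad_c": 1}, 0, 1000, gpr="gLDHA")
        _rxn(model, "LACt", {"lac_c": -1, "lac_e": 1}, 0, 1000, gpr="gMCT4")
        _add_exchange(model, "lac", 0.0, 1000.0)
    _rxn(model, "ATPM", {"atp_c": -1, "h2o_c": -1,
                         "adp_c": 1, "pi_c": 1, "h_c": 1}, 0, 1000)
    _rxn(model, "H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000)
    _add_exchange(model, "h2o", -1000.0, 1000.0)
    _rxn(model, "Ht", {"h_e": -1, "h_c": 1}, -1000, 1000)
    _add_exchange(model, "h", -1000.0, 1000.0)


def make_toy_glycolysis() -> cobra.Model:
    """Anaerobic glycolysis: glucose -> 2 lactate, net 2 ATP per glucose.

    NADH generated by glycolysis is reoxidized by lactate dehydrogenase, so
    the network is redox-closed without oxygen.  Maximizing ATP hydrolysis
    at glucose uptake 1 gives exactly 2.
    """
    model = cobra.Model("toy_glycolysis")
    _glycolysis_block(model, with_ldh=True)
    model.objective = "ATPM"
    return model


def make_toy_aerobic(with_biomass: bool = True) -> cobra.Model:
    """Full glucose oxidation: 32 ATP per glucose with oxygen open.

    Adds pyruvate dehydrogenase, a lumped TCA turn, and a respiratory
    chain at P/O 2.5 (NADH) / 1.5 (FADH2) on top of the glycolysis block.
    With oxygen closed, the lactate overflow route still yields 2 ATP per
    glucose.  ``with_biomass`` adds a biomass reaction (30 ATP plus one
    pyruvate-derived precursor per unit biomass) and its sink, so the same
    network serves growth-based analyses.
    """
    model = cobra.Model("toy_aerobic")
    _glycolysis_block(model, with_ldh=True)
    for base in ("accoa", "coa", "co2", "fad", "fadh2", "o2"):
        _met(model, base, "c")
    _rxn(model, "PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                        "accoa_c": 1, "nadh_c": 1, "co2_c": 1},
         0, 1000, gpr="gPDHA1 and gPDHB")
    _rxn(model, "TCA", {
        "accoa_c": -1, "nad_c": -3, "fad_c": -1, "adp_c": -1, "pi_c": -1,
        "h2o_c": -2,
        "coa_c": 1, "nadh_c": 3, "fadh2_c": 1, "atp_c": 1, "co2_c": 2,
    }, 0, 1000, gpr="gCS and gSUCLG1")
    _rxn(model, "ETC_NADH", {
        "nadh_c": -1, "o2_c": -0.5, "adp_c": -2.5, "pi_c": -2.5, "h_c": -1,
        "nad_c": 1, "atp_c": 2.5, "h2o_c": 3.5,
    }, 0, 1000, gpr="gNDUFA1 and gATP5F1")
    _rxn(model, "ETC_FADH2", {
        "fadh2_c": -1, "o2_c": -0.5, "adp_c": -1.5, "pi_c": -1.5,
        "fad_c": 1, "atp_c": 1.5, "h2o_c": 2.5,
    }, 0, 1000, gpr="gSDHA and gATP5F1")
    _rxn(model, "O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000)
    _add_exchange(model, "o2", -1000.0, 0.0)
    _rxn(model, "CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000)
    _add_exchange(model, "co2", -1000.0, 1000.0)
    if with_biomass:
        _met(model, "biomass", "c")
        _rxn(model, "BIOMASS", {
            "pyr_c": -1, "atp_c": -30, "h2o_c": -30,
            "adp_c": 30, "pi_c": 30, "h_c": 30, "biomass_c": 1,
        }, 0, 1000, gpr="gBIO1")
        _rxn(model, "DM_biomass_c", {"biomass_c": -1}, 0, 1000)
    model.objective = "ATPM"
    return model


def make_parallel_pathways() -> cobra.Model:
    """Two identical routes from substrate to product.

    Any split between P1 and P2 is alternate-optimal for the linear
    objective; the Euclidean-norm stage of parsimonious FBA must place
    exactly half the flux on each.
    """
    model = cobra.Model("toy_parallel")
    for base in ("glc", "pyr"):
        _met(model, base, "c")
    _add_exchange(model, "glc", -10.0, 0.0)
    _rxn(model, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000)
    _rxn(model, "P1", {"glc_c": -1, "pyr_c": 2}, 0, 1000)
    _rxn(model, "P2", {"glc_c": -1, "pyr_c": 2}, 0, 1000)
    _rxn(model, "PYRt", {"pyr_c": -1, "pyr_e": 1}, 0, 1000)
    _met(model, "pyr", "e")
    _add_exchange(model, "pyr", 0.0, 1000.0)
    model.objective = "EX_pyr_e"
    return model


def make_rc_loop() -> cobra.Model:
    """TCA-segment fixture for reductive-carboxylation detection.

    Citrate demand can be met two ways: an oxygen-dependent oxidative
    route (lumped glucose -> citrate, with respiratory NADH reoxidation)
    or glutamine-derived 2-oxoglutarate carboxylated backwards through
    isocitrate dehydrogenase (IDH, forward = oxidative decarboxylation)
    and aconitase (ACONT, forward = citrate -> isocitrate).  Clamping the
    oxygen exchange to zero kills the oxidative route and forces net
    reverse flux through both reactions.
    """
    model = cobra.Model("toy_rc")
    for base in ("gln", "akg", "icit", "cit", "co2", "nad", "nadh", "glc",
                 "o2"):
        _met(model, base, "c")
    _add_exchange(model, "gln", -10.0, 0.0)
    _rxn(model, "GLNt", {"gln_e": -1, "gln_c": 1}, 0, 1000)
    # lumped glutaminase + glutamate dehydrogenase (nitrogen not tracked)
    _rxn(model, "GLS_GDH", {"gln_c": -1, "nad_c": -1,
                            "akg_c": 1, "nadh_c": 1}, 0, 1000)
    _rxn(model, "IDH", {"icit_c": -1, "nad_c": -1,
                        "akg_c": 1, "co2_c": 1, "nadh_c": 1},
         -1000, 1000, gpr="gIDH2")
    _rxn(model, "ACONT", {"cit_c": -1, "icit_c": 1}, -1000, 1000, gpr="gACO2")
    _add_exchange(model, "glc", -10.0, 0.0)
    _rxn(model, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000)
    # lumped oxidative citrate synthesis from glucose
    _rxn(model, "OXPATH", {"glc_c": -1, "nad_c": -2,
                           "cit_c": 1, "nadh_c": 2}, 0, 1000)
    _rxn(model, "ETC", {"nadh_c": -1, "o2_c": -0.5, "nad_c": 1}, 0, 1000)
    _rxn(model, "O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000)
    _add_exchange(model, "o2", -1000.0, 0.0)
    _rxn(model, "CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000)
    _add_exchange(model, "co2", -1000.0, 1000.0)
    _rxn(model, "AKGt", {"akg_c": -1, "akg_e": 1}, 0, 1000)
    _met(model, "akg", "e")
    _add_exchange(model, "akg", 0.0, 1000.0)
    _rxn(model, "DM_cit_c", {"cit_c": -1}, 1.0, 1000.0)
    model.objective = "DM_cit_c"
    return model


def make_exchange_completion_fixture(
    n_candidates: int, n_required: int, seed: int,
) -> Tuple[cobra.Model, ExchangeProfile, List[str]]:
    """Network whose measured profile alone is infeasible.

    Biomass consumes one measured carbon source plus ``n_required``
    precursors, each importable *only* through its own unmeasured
    exchange; the remaining ``n_candidates - n_required`` candidate
    exchanges feed decoy metabolites with no route to biomass.  The
    ground-truth minimal completion is therefore exactly the required
    exchange set, unique by construction.  The seed shuffles which
    candidate indices are required, so id order carries no information.
    """
    if not 0 <= n_required <= n_candidates <= 15:
        raise ValueError("need 0 <= n_required <= n_candidates <= 15")
    rng = np.random.default_rng(seed)
    required_idx = sorted(rng.choice(n_candidates, size=n_required,
                                     replace=False).tolist())
    model = cobra.Model(f"toy_completion_{n_candidates}_{n_required}_{seed}")
    for base in ("a", "w"):
        _met(model, base, "c")
        _add_exchange(model, base, -10.0, 0.0)
        _rxn(model, f"{base.upper()}t", {f"{base}_e": -1, f"{base}_c": 1},
             0, 1000)
    # biomass drain consumes both measured nutrients plus the required
    # precursors; it is multi-metabolite, hence never a boundary reaction
    biomass_stoich: Dict[str, float] = {"a_c": -1.0, "w_c": -1.0}
    truth: List[str] = []
    for i in range(n_candidates):
        base = f"m{i:02d}"
        _met(model, base, "c")
        # open in the global-model state; the cardinality LP closes
        # candidates itself before introducing unidirectional components
        ex = _add_exchange(model, base, -1000.0, 1000.0)
        _rxn(model, f"{base.upper()}t", {f"{base}_e": -1, f"{base}_c": 1},
             -1000, 1000)
        if i in required_idx:
            biomass_stoich[f"{base}_c"] = -1.0
            truth.append(ex.id)
    _rxn(model, "BIOMASS", biomass_stoich, 0.008, 1000.0)
    model.objective = "BIOMASS"
    profile = ExchangeProfile(
        sample_id=f"synthetic-{seed}", cell_line="synthetic",
        entries={"a": -10.0, "w": -10.0},
    )
    return model, profile, sorted(truth)


def make_l1_redundancy_fixture() -> Tuple[cobra.Model, List[str], str]:
    """Instance where the one-norm optimum is not minimum-cardinality.

    Biomass needs 10 units of B per unit of the measured nutrient W.
    Candidate ``EX_p_e`` imports a rich precursor converted 1 -> 9 B but
    its transporter is capacity-limited to 1 U, so the L1 optimum tops up
    with candidate ``EX_b_e`` (total one-norm 2, cardinality 2) even
    though ``EX_b_e`` alone is feasible at flux 10 (cardinality 1).  The
    FVA minimality check must detect ``EX_p_e`` as removable and the
    re-run must return ``{EX_b_e}``.

    Returns (model, measured exchange ids, sole member of the true
    minimal set).
    """
    model = cobra.Model("toy_l1_redundancy")
    for base in ("b", "p", "w"):
        _met(model, base, "c")
    _add_exchange(model, "w", -1000.0, 0.0)
    _rxn(model, "Wt", {"w_e": -1, "w_c": 1}, 0, 1000)
    _add_exchange(model, "b", 0.0, 0.0)
    _rxn(model, "Bt", {"b_e": -1, "b_c": 1}, -1000, 1000)
    _add_exchange(model, "p", 0.0, 0.0)
    _rxn(model, "Pt", {"p_e": -1, "p_c": 1}, 0, 1.0)  # capacity cap
    _rxn(model, "PCONV", {"p_c": -1, "b_c": 9}, 0, 1000)
    _rxn(model, "BIOMASS", {"b_c": -10, "w_c": -1}, 1.0, 1000.0)
    model.objective = "BIOMASS"
    return model, ["EX_w_e"], "EX_b_e"


def make_oxotype_fixture(kind: str) -> cobra.Model:
    """Tiny growth models whose feasible oxygen-uptake windows are known.

    All three share a glycolysis core (2 ATP + 2 NADH per glucose), a
    respiratory chain (the only NADH sink unless noted), a free ATP
    dissipation reaction, and a biomass drain with lower bound 1.

    ``low``: no fermentative NADH sink and glucose capped at 100 U, so a
    clamped oxygen uptake above ~99 U has no electron donor — feasible
    only at the low end of the scan.  ``high``: biomass costs 300 ATP,
    achievable only with substantial respiration (|vO2| >= ~43 U), so the
    low end of the scan is infeasible.  ``indifferent``: a lactate
    overflow route plus generous glucose make every scanned oxygen value
    feasible.
    """
    model = cobra.Model(f"toy_oxotype_{kind}")
    for base in ("glc", "nad", "nadh", "atp", "adp", "biomass", "o2",
                 "pyr"):
        _met(model, base, "c")
    glc_lb = -100.0 if kind == "low" else -2000.0
    _add_exchange(model, "glc", glc_lb, 0.0)
    _rxn(model, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 2000)
    _rxn(model, "GLYC", {"glc_c": -1, "adp_c": -2, "nad_c": -2,
                         "pyr_c": 2, "atp_c": 2, "nadh_c": 2}, 0, 2000)
    _rxn(model, "O2t", {"o2_e": -1, "o2_c": 1}, 0, 2000)
    _add_exchange(model, "o2", -1000.0, 0.0)
    _rxn(model, "ETC", {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2.5,
                        "nad_c": 1, "atp_c": 2.5}, 0, 4000)
    _rxn(model, "PYRt", {"pyr_c": -1, "pyr_e": 1}, 0, 4000)
    _met(model, "pyr", "e")
    _add_exchange(model, "pyr", 0.0, 4000.0)
    _rxn(model, "ATPM", {"atp_c": -1, "adp_c": 1}, 0, 20000)
    if kind == "low":
        _rxn(model, "BIOMASS", {"glc_c": -1, "biomass_c": 1}, 0, 1000)
    elif kind == "high":
        _rxn(model, "BIOMASS", {"glc_c": -1, "atp_c": -300, "adp_c": 300,
                                "biomass_c": 1}, 0, 1000)
    elif kind == "indifferent":
        _met(model, "lac", "c")
        _rxn(model, "LDH", {"pyr_c": -1, "nadh_c": -1,
                            "lac_c": 1, "nad_c": 1}, 0, 4000)
        _rxn(model, "LACt", {"lac_c": -1, "lac_e": 1}, 0, 4000)
        _met(model, "lac", "e")
        _add_exchange(model, "lac", 0.0, 4000.0)
        _rxn(model, "BIOMASS", {"glc_c": -1, "biomass_c": 1}, 0, 1000)
    else:
        raise ValueError(f"unknown oxotype fixture kind {kind!r}")
    _rxn(model, "DM_biomass_c", {"biomass_c": -1}, 0, 1000)
    model.objective = "BIOMASS"
    model.reactions.BIOMASS.lower_bound = 1.0
    return model


def make_synthetic_profile(
    model: cobra.Model,
    exchanges: Sequence[str],
    seed: int,
    noise: float = 0.1,
    corrupt: Optional[str] = None,
) -> ExchangeProfile:
    """Measured profile drawn from a feasible reference flux of the model.

    The reference flux is the FBA optimum of the model's own objective;
    each listed exchange flux is perturbed multiplicatively by
    ``1 + U(-noise, +noise)``.  Because the unperturbed vector is jointly
    feasible, integration with allowance ``a`` applies every pair whenever
    ``noise <= a / (1 + a)`` (the perturbed interval then still contains
    the reference value).  ``corrupt`` names one exchange whose entry is
    scaled far outside any feasible range, to exercise rollback.
    """
    from .flux_engine import fba as _fba

    rng = np.random.default_rng(seed)
    # solve on a fresh copy: a previously used solver instance can return
    # an alternate basis with last-digit differences, breaking determinism
    ref = _fba(model.copy())
    if ref.status != "optimal":
        raise ValueError("model must be solvable to draw a reference profile")
    entries: Dict[str, float] = {}
    for ex_id in exchanges:
        rxn = model.reactions.get_by_id(ex_id)
        if len(rxn.metabolites) != 1:
            raise ValueError(f"{ex_id} is not an exchange reaction")
        met = next(iter(rxn.metabolites))
        base = met.id.rsplit("_", 1)[0]
        v = float(ref.fluxes[ex_id])
        factor = 1.0 + rng.uniform(-noise, noise)
        x = v * factor
        if corrupt == ex_id:
            x = v * 50.0 if v != 0 else 1000.0
        entries[base] = x
    return ExchangeProfile(sample_id=f"synthetic-{seed}",
                           cell_line="synthetic", entries=entries)


def carbon_balance_errors(model: cobra.Model) -> List[str]:
    """Internal reactions whose elemental-carbon bookkeeping does not close.

    Boundary reactions and reactions touching a lumped biomass species
    (whose elemental composition is deliberately unspecified) are skipped.
    """
    bad = []
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1:
            continue  # boundary
        if any(m.id.startswith("biomass") for m in rxn.metabolites):
            continue
        total = 0.0
        for met, coef in rxn.metabolites.items():
            formula = met.formula or "C0"
            carbons = int(formula[1:]) if formula.startswith("C") else 0
            total += coef * carbons
        if abs(total) > 1e-9:
            bad.append(f"{rxn.id}: net carbon {total}")
    return bad
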