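import cobra
import pytest

from exoflux import fixtures as fx


def _build_medium_test_model() -> cobra.Model:
    """Global-model stand-in with one exchange per medium class.

    Growth consumes the default-class carbon source; every other exchange
    exists only to receive its class bound.
    """
    model = cobra.Model("medium_toy")
    mets = {}
    for base in ("glc", "na", "vitb", "his", "h2o", "o2", "h2o2", "biomass"):
        for comp in ("e", "c"):
            m = cobra.Metabolite(f"{base}_{comp}", compartment=comp)
            mets[m.id] = m
    model.add_metabolites(list(mets.values()))
    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid)
        model.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        r.bounds = (lb, ub)
        return r

    for base in ("glc", "na", "vitb", "his", "h2o", "o2", "h2o2"):
        rxn(f"EX_{base}_e", {f"{base}_e": -1}, -2000, 2000)
        rxn(f"{base.upper()}t", {f"{base}_e": -1, f"{base}_c": 1}, -2000, 2000)
    rxn("BIOMASS", {"glc_c": -1, "biomass_c": 1}, 0, 1000)
    rxn("DM_biomass_c", {"biomass_c": -1}, 0, 1000)
    model.objective = "BIOMASS"
    return model


@pytest.fixture
def toy_glycolysis():
    return fx.make_toy_glycolysis()


@pytest.fixture
def toy_aerobic():
    return fx.make_toy_aerobic()


@pytest.fixture
def toy_parallel():
    return fx.make_parallel_pathways()


@pytest.fixture
def toy_rc():
    return fx.make_rc_loop()


@pytest.fixture
def medium_model():
    return _build_medium_test_model()
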