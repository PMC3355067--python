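import pytest

from initnet.gpr import parse_gpr
from initnet.model_core import MetabolicModel, Metabolite, Reaction


def make_model(reactions, compartments=None, formulas=None, id="fixture"):
    """Build a model from {rid: (stoich, reversible[, gpr])} shorthand."""
    compartments = compartments or {}
    formulas = formulas or {}
    rxns = []
    mets = set()
    for rid, entry in reactions.items():
        stoich, reversible = entry[0], entry[1]
        gpr = parse_gpr(entry[2]) if len(entry) > 2 else None
        rxns.append(
            Reaction(id=rid, stoichiometry=dict(stoich), reversible=reversible, gpr=gpr)
        )
        mets |= set(stoich)
    metabolites = [
        Metabolite(
            id=m,
            name=m,
            compartment=compartments.get(m, "cytosol"),
            formula=formulas.get(m),
        )
        for m in sorted(mets)
    ]
    genes = sorted(set().union(*(r.genes for r in rxns)) if rxns else set())
    return MetabolicModel(metabolites=metabolites, reactions=rxns, genes=genes, id=id)


@pytest.fixture
def chain_model():
    """Ex_A => A -r1-> B -r2-> C (all irreversible, uptake on A)."""
    return make_model(
        {
            "Ex_A": ({"A": 1.0}, False),
            "r1": ({"A": -1.0, "B": 1.0}, False, "gA"),
            "r2": ({"B": -1.0, "C": 1.0}, False, "gB"),
        }
    )


@pytest.fixture
def toy_model():
    return make_model(
        {
            "Ex_glc": ({"glc": 1.0}, True),
            "Ex_pyr": ({"pyr": -1.0}, False),
            "glyc": ({"glc": -1.0, "pyr": 2.0}, False, "(g1 and g2) or g3"),
        },
        formulas={"glc": {"C": 6, "H": 12, "O": 6}, "pyr": {"C": 3, "H": 6, "O": 3}},
    )
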