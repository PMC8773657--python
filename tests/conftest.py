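"""Shared fixtures: the overflow toy model and an independent LP oracle.

The oracle builds the enzyme-constrained LP a second time, from scratch,
in COBRApy/optlang (GLPK) — a different modelling layer and a different
solver from the package's scipy/HiGHS path — so agreement between the
two is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import pytest

from ecgem import assign_enzyme_entries, build_ec_model, preprocess
from ecgem.ec_core import ECModel
from ecgem.fixtures import ToyCoreParams, toy_core_model


@pytest.fixture(scope="session")
def toy_params() -> ToyCoreParams:
    return ToyCoreParams()


@pytest.fixture(scope="session")
def toy_bundle(toy_params):
    """(unsplit model, kcat table, subunit table) of the overflow toy."""
    return toy_core_model(toy_params)


@pytest.fixture(scope="session")
def toy_split(toy_bundle):
    """(preprocessed model, enzyme entries, provenance) of the overflow toy."""
    model, kcat_table, subunit_table = toy_bundle
    split, provenance = preprocess(model)
    entries = assign_enzyme_entries(split, kcat_table, subunit_table)
    return split, entries, provenance


@pytest.fixture(scope="session")
def toy_ec_factory(toy_split):
    """ECModel of the overflow toy at a chosen enzyme pool bound (g/gDW)."""
    split, entries, _ = toy_split

    def factory(pool_bound: float) -> ECModel:
        return build_ec_model(split, entries, ptot=pool_bound, f=1.0)

    return factory


def cobra_ec_optimum(model, entries, pool_bound: float, objective: str | None = None):
    """Independent enzyme-constrained FBA optimum via COBRApy + GLPK.

    Returns (status, objective value).  Dense re-formulation: the pool
    constraint is added as an optlang expression over flux variables.
    """
    from cobra.core import Metabolite as CMetabolite
    from cobra.core import Model as CModel
    from cobra.core import Reaction as CReaction

    cm = CModel(model.id)
    mets = {m.id: CMetabolite(m.id, compartment=m.compartment or "c") for m in model.metabolites}
    cm.add_reactions(
        [CReaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
         for r in model.reactions]
    )
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    cm.objective = objective or model.objective_reaction
    if entries:
        expr = sum(
            e.cost_coefficient * cm.reactions.get_by_id(e.reaction_id).flux_expression
            for e in entries
        )
        cm.add_cons_vars(cm.problem.Constraint(expr, ub=pool_bound))
    sol = cm.optimize()
    return sol.status, sol.objective_value


@pytest.fixture(scope="session")
def lp_oracle():
    return cobra_ec_optimum
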