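"""The enzyme-constrained linear program.

An enzyme-constrained model is an ordinary flux balance problem

    max  c'v   s.t.  S·v = 0,  vlb ≤ v ≤ vub

plus exactly one extra linear row, the total enzyme pool constraint

    Σ_i  v_i · MW_i / (σ_i · kcat_i)  ≤  ptot · f

summed over the reactions that carry an enzyme entry.  The
stoichiometric matrix is untouched: no pseudo-metabolites or enzyme
exchange reactions are introduced, so any constraint-based analysis that
works on the plain model works on the enzyme-constrained one.

Besides plain optimisation this module implements the parsimonious
two-stage program: maximise growth, then fix the growth rate and
minimise total enzyme usage E_min = Σ v·MW/(σ·kcat).  The minimum-enzyme
solution is the canonical flux distribution reported everywhere else in
the package, because flux vectors at the growth optimum are otherwise
non-unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .enzyme_data import EnzymeEntry
from .gem_io import EnzymeConstraintRecord, MetabolicModel, ModelValidationError

#: relative slack used when a flux is pinned to a previously solved optimum
FIX_RTOL = 1e-9
#: tolerance used in feasibility assertions
FEAS_TOL = 1e-6

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    """Solved flux state plus its enzyme-cost decomposition."""

    status: str
    objective_value: float
    fluxes: dict[str, float]
    enzyme_costs: dict[str, float]
    total_enzyme_usage: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": list(self.fluxes),
                "flux": list(self.fluxes.values()),
                "enzyme_cost": [self.enzyme_costs.get(r, 0.0) for r in self.fluxes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ECModel:
    """A preprocessed metabolic model together with its enzyme constraint."""

    model: MetabolicModel
    constraint: EnzymeConstraintRecord

    def __post_init__(self) -> None:
        rxn_ids = set(self.model.reaction_ids)
        unknown = [e.reaction_id for e in self.constraint.entries if e.reaction_id not in rxn_ids]
        if unknown:
            raise ModelValidationError(
                f"enzyme entries reference reaction(s) not in the model: {sorted(unknown)}"
            )

    @property
    def pool_bound(self) -> float:
        return self.constraint.pool_upper_bound

    def entry_for(self, reaction_id: str) -> EnzymeEntry | None:
        return self.constraint.entry_for(reaction_id)

    def cost_coefficients(self) -> dict[str, float]:
        """g enzyme per unit flux for every entry reaction."""
        return {e.reaction_id: e.cost_coefficient for e in self.constraint.entries}

    def with_entries(self, entries: list[EnzymeEntry]) -> "ECModel":
        record = EnzymeConstraintRecord.from_parameters(
            ptot=self.constraint.ptot,
            f=self.constraint.f,
            sigma_default=self.constraint.sigma_default,
            entries=entries,
        )
        return ECModel(model=self.model, constraint=record)

    def copy(self) -> "ECModel":
        return ECModel(
            model=self.model.copy(),
            constraint=EnzymeConstraintRecord.from_parameters(
                ptot=self.constraint.ptot,
                f=self.constraint.f,
                sigma_default=self.constraint.sigma_default,
                entries=list(self.constraint.entries),
            ),
        )


def build_ec_model(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    ptot: float,
    f: float,
    sigma_default: float = 1.0,
) -> ECModel:
    """Attach the pooled enzyme constraint (bound ptot·f) to a preprocessed model."""
    record = EnzymeConstraintRecord.from_parameters(
        ptot=ptot, f=f, sigma_default=sigma_default, entries=entries
    )
    return ECModel(model=model, constraint=record)


def reaction_enzyme_cost(flux: float, entry: EnzymeEntry) -> float:
    """Enzyme mass tied up by one reaction: v · MW / (σ · kcat), g/gDW."""
    if flux < 0:
        raise ValueError(
            f"negative flux {flux} for {entry.reaction_id}: split the model first"
        )
    return flux * entry.cost_coefficient


def solve_lp(
    ec: ECModel,
    objective: Mapping[str, float],
    direction: str = "max",
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    pool_bound: float | None = None,
) -> FluxSolution:
    """Solve the enzyme-constrained LP with an arbitrary linear objective.

    ``objective`` maps reaction ids to objective coefficients.
    ``bound_overrides`` temporarily replaces (lb, ub) of named reactions.
    ``pool_bound`` overrides the enzyme pool bound (None = the model's).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    model = ec.model
    n = len(model.reactions)
    index = {r.id: j for j, r in enumerate(model.reactions)}
    for rid in objective:
        if rid not in index:
            raise KeyError(f"objective reaction {rid!r} not in model")

    c = np.zeros(n)
    for rid, coeff in objective.items():
        c[index[rid]] = coeff
    sign = -1.0 if direction == "max" else 1.0

    bounds = []
    overrides = bound_overrides or {}
    for r in model.reactions:
        lb, ub = overrides.get(r.id, (r.lower_bound, r.upper_bound))
        bounds.append((lb, ub))

    A_eq = model.stoichiometric_matrix()
    b_eq = np.zeros(len(model.metabolites))

    cost = ec.cost_coefficients()
    pool = ec.pool_bound if pool_bound is None else pool_bound
    A_ub = None
    b_ub = None
    if cost:
        row = np.zeros(n)
        for rid, coeff in cost.items():
            row[index[rid]] = coeff
        A_ub = row.reshape(1, -1)
        b_ub = np.array([pool])

    res = linprog(
        sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=bounds, method="highs", options=_HIGHS_OPTIONS,
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {}, {}, float("nan"))

    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    enzyme_costs = {rid: fluxes[rid] * coeff for rid, coeff in cost.items()}
    return FluxSolution(
        status="optimal",
        objective_value=float(-res.fun if direction == "max" else res.fun),
        fluxes=fluxes,
        enzyme_costs=enzyme_costs,
        total_enzyme_usage=float(sum(enzyme_costs.values())),
    )


def optimize(
    ec: ECModel,
    objective: str | None = None,
    direction: str = "max",
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """FBA on the enzyme-constrained model for a single-reaction objective."""
    rid = objective if objective is not None else ec.model.objective_reaction
    if not ec.model.has_reaction(rid):
        raise KeyError(f"objective reaction {rid!r} not in model")
    return solve_lp(ec, {rid: 1.0}, direction=direction, bound_overrides=bound_overrides)


def minimize_enzyme_usage(
    ec: ECModel,
    biomass_reaction: str | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Two-stage parsimonious solve: max growth, then min total enzyme mass.

    Stage 1 maximises the biomass reaction; stage 2 pins the biomass flux
    to the stage-1 optimum (relative slack 1e-9, to absorb round-off) and
    minimises Σ v·MW/(σ·kcat).  The returned solution is stage 2's; its
    ``objective_value`` is E_min (g enzyme/gDW).
    """
    rid = biomass_reaction if biomass_reaction is not None else ec.model.objective_reaction
    stage1 = optimize(ec, rid, "max", bound_overrides=bound_overrides)
    if not stage1.optimal:
        return stage1
    mu = stage1.objective_value
    slack = abs(mu) * FIX_RTOL
    overrides = dict(bound_overrides or {})
    overrides[rid] = (mu - slack, mu + slack)
    cost = ec.cost_coefficients()
    if not cost:
        # nothing to minimise: stage-1 solution is already canonical
        return stage1
    stage2 = solve_lp(ec, cost, direction="min", bound_overrides=overrides)
    return stage2
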