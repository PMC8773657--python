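"""Simulation protocols: carbon-source growth, overflow scans, trade-off scans.

All protocols report the parsimonious (minimum-enzyme) flux state, so
per-reaction numbers are reproducible despite the LP's alternate optima.

* Growth on a carbon source: open one exchange at a stated uptake bound,
  close the competing carbon exchanges, maximise growth.
* Overflow scan: fix the growth rate on a grid with unlimited substrate,
  minimise substrate uptake (enzyme-minimal tie-break), and record
  byproduct secretion, O₂ uptake and the oxidative-phosphorylation ratio
  v_O2 / v_substrate.  The switch point is the first grid growth rate at
  which any byproduct is secreted.
* Trade-off scan: sweep the substrate uptake bound, maximise growth and
  compute the minimum enzyme amount E_min at that growth; biomass yield
  (gDW per g substrate) and enzyme usage efficiency (gDW·h⁻¹ per g
  enzyme, v_biomass / E_min) move in opposite directions once the enzyme
  pool binds.

Prediction quality metrics: estimation error |sim−exp|/exp per
condition, and the normalized flux error sqrt(Σ(sim−exp)²/Σexp²) over a
panel of conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ec_core import (
    ECModel,
    FIX_RTOL,
    FluxSolution,
    minimize_enzyme_usage,
    optimize,
    solve_lp,
)
from .preprocess import REVERSE_SUFFIX

#: molecular weight of glucose, g/mmol
MW_GLUCOSE = 0.18016

#: secretion below this (mmol/gDW/h) counts as zero when locating the switch point
SECRETION_TOL = 1e-6

#: stand-in for an unlimited exchange bound
UNBOUNDED = 1e6


# --------------------------------------------------------------------------
# metrics

def estimation_error(sim: float, exp: float) -> float:
    """Relative growth-rate error |sim − exp| / exp."""
    if exp <= 0:
        raise ValueError(f"experimental value must be > 0, got {exp}")
    return abs(sim - exp) / exp


def normalized_flux_error(sim: Sequence[float], exp: Sequence[float]) -> float:
    """sqrt( Σ(sim−exp)² / Σexp² ) over paired conditions."""
    if len(sim) != len(exp):
        raise ValueError(f"length mismatch: {len(sim)} simulated vs {len(exp)} measured")
    sim_a = np.asarray(sim, dtype=float)
    exp_a = np.asarray(exp, dtype=float)
    denom = float(np.sum(exp_a**2))
    if denom <= 0:
        raise ValueError("sum of squared experimental values must be > 0")
    return math.sqrt(float(np.sum((sim_a - exp_a) ** 2)) / denom)


# --------------------------------------------------------------------------
# medium handling on split models

def _reverse_id(ec: ECModel, exchange_id: str) -> str | None:
    rid = exchange_id + REVERSE_SUFFIX
    return rid if ec.model.has_reaction(rid) else None


def uptake_overrides(ec: ECModel, exchange_id: str, uptake_ub: float) -> dict[str, tuple[float, float]]:
    """Bound overrides setting the uptake capacity of one exchange.

    On a split model the uptake direction is the ``_reverse`` copy of the
    exchange; on an unsplit model it is the negative range of the
    exchange itself.
    """
    if not ec.model.has_reaction(exchange_id):
        available = sorted(r.id for r in ec.model.exchanges())
        raise KeyError(f"no exchange {exchange_id!r}; available exchanges: {available}")
    rev = _reverse_id(ec, exchange_id)
    if rev is not None:
        return {rev: (0.0, uptake_ub)}
    rxn = ec.model.reaction(exchange_id)
    return {exchange_id: (-uptake_ub, rxn.upper_bound)}


def uptake_flux(ec: ECModel, sol: FluxSolution, exchange_id: str) -> float:
    """Net uptake through an exchange (≥ 0), on split or unsplit models."""
    fwd = sol.fluxes.get(exchange_id, 0.0)
    rev_id = _reverse_id(ec, exchange_id)
    rev = sol.fluxes.get(rev_id, 0.0) if rev_id else 0.0
    return max(rev - fwd, 0.0) if rev_id else max(-fwd, 0.0)


def secretion_flux(ec: ECModel, sol: FluxSolution, exchange_id: str) -> float:
    """Net secretion through an exchange (≥ 0)."""
    fwd = sol.fluxes.get(exchange_id, 0.0)
    rev_id = _reverse_id(ec, exchange_id)
    rev = sol.fluxes.get(rev_id, 0.0) if rev_id else 0.0
    return max(fwd - rev, 0.0)


# --------------------------------------------------------------------------
# growth on carbon sources

@dataclass(frozen=True)
class GrowthComparison:
    carbon_source: str
    v_growth_sim: float
    v_growth_exp: float

    @property
    def estimation_error(self) -> float:
        return estimation_error(self.v_growth_sim, self.v_growth_exp)


def max_growth_on_carbon_source(
    ec: ECModel,
    exchange_id: str,
    uptake_ub: float = 10.0,
    closed_exchanges: Iterable[str] = (),
) -> FluxSolution:
    """Parsimonious max-growth state with a single carbon source open.

    ``closed_exchanges`` are competing carbon exchanges whose uptake is
    set to zero (their secretion direction stays open).
    """
    overrides = uptake_overrides(ec, exchange_id, uptake_ub)
    for other in closed_exchanges:
        if other == exchange_id:
            continue
        overrides.update(uptake_overrides(ec, other, 0.0))
    return minimize_enzyme_usage(ec, bound_overrides=overrides)


def growth_comparison_table(
    ec: ECModel,
    experimental: dict[str, float],
    uptake_ub: float = 10.0,
) -> list[GrowthComparison]:
    """Simulate each carbon source in ``experimental`` (exchange id -> measured growth)."""
    sources = list(experimental)
    out = []
    for ex in sources:
        sol = max_growth_on_carbon_source(
            ec, ex, uptake_ub, closed_exchanges=[s for s in sources if s != ex]
        )
        sim = sol.fluxes.get(ec.model.objective_reaction, float("nan")) if sol.optimal else float("nan")
        out.append(GrowthComparison(ex, sim, experimental[ex]))
    return out


# --------------------------------------------------------------------------
# overflow scan

@dataclass
class OverflowScanResult:
    """One row per grid growth rate; infeasible points have status != optimal."""

    rows: list[dict] = field(default_factory=list)
    secretion_tol: float = SECRETION_TOL

    @property
    def switch_point(self) -> float | None:
        """Smallest grid growth with any byproduct secretion above tolerance."""
        for row in self.rows:
            if row["status"] == "optimal" and row["total_byproduct"] > self.secretion_tol:
                return row["growth"]
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def overflow_scan(
    ec: ECModel,
    growth_grid: Sequence[float],
    substrate_exchange_id: str,
    byproduct_exchange_ids: Sequence[str],
    oxygen_exchange_id: str | None = None,
    objective: str = "min_uptake",
    secretion_tol: float = SECRETION_TOL,
    extra_bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> OverflowScanResult:
    """Fixed-growth scan with unlimited substrate.

    At each grid point the biomass flux is pinned, the substrate uptake
    bound is lifted, and substrate uptake is minimised (``objective =
    "min_uptake"``, ties broken by minimum enzyme usage) or total enzyme
    usage is minimised directly (``"min_enzyme"``).
    """
    grid = list(growth_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("growth grid must be strictly increasing")
    if objective not in ("min_uptake", "min_enzyme"):
        raise ValueError(f"unknown scan objective {objective!r}")
    biomass = ec.model.objective_reaction
    uptake_rid = _reverse_id(ec, substrate_exchange_id) or substrate_exchange_id
    split = _reverse_id(ec, substrate_exchange_id) is not None

    result = OverflowScanResult(secretion_tol=secretion_tol)
    for growth in grid:
        overrides = dict(extra_bound_overrides or {})
        overrides.update(uptake_overrides(ec, substrate_exchange_id, UNBOUNDED))
        overrides[biomass] = (growth, growth)
        if objective == "min_uptake":
            # split model: uptake = reverse flux (minimise it);
            # unsplit: uptake = -flux, so minimising uptake = maximising flux
            sol = solve_lp(ec, {uptake_rid: 1.0},
                           direction="min" if split else "max",
                           bound_overrides=overrides)
            if sol.optimal and ec.cost_coefficients():
                v_up = sol.fluxes[uptake_rid]
                slack = max(abs(v_up) * FIX_RTOL, 1e-12)
                overrides2 = dict(overrides)
                overrides2[uptake_rid] = (v_up - slack, v_up + slack)
                tie = solve_lp(ec, ec.cost_coefficients(), "min", bound_overrides=overrides2)
                if tie.optimal:
                    sol = tie
        else:
            sol = solve_lp(ec, ec.cost_coefficients() or {biomass: 0.0}, "min",
                           bound_overrides=overrides)

        row: dict = {"growth": growth, "status": sol.status}
        if sol.optimal:
            v_sub = uptake_flux(ec, sol, substrate_exchange_id)
            secretions = {
                f"secretion_{ex}": secretion_flux(ec, sol, ex) for ex in byproduct_exchange_ids
            }
            v_o2 = uptake_flux(ec, sol, oxygen_exchange_id) if oxygen_exchange_id else 0.0
            row.update(
                substrate_uptake=v_sub,
                o2_uptake=v_o2,
                oxphos_ratio=(v_o2 / v_sub if v_sub > 0 else 0.0),
                total_enzyme_usage=sol.total_enzyme_usage,
                total_byproduct=sum(secretions.values()),
                **secretions,
            )
        else:
            row.update(
                substrate_uptake=float("nan"), o2_uptake=float("nan"),
                oxphos_ratio=float("nan"), total_enzyme_usage=float("nan"),
                total_byproduct=float("nan"),
                **{f"secretion_{ex}": float("nan") for ex in byproduct_exchange_ids},
            )
        result.rows.append(row)
    return result


# --------------------------------------------------------------------------
# energy pathway enzyme cost

@dataclass
class EnergyCostBreakdown:
    """Enzyme cost of an ATP-producing pathway, per unit ATP flux."""

    label: str
    reaction_ids: list[str]
    total_enzyme_cost: float
    net_atp_flux: float
    cost_per_atp: float | None  # None when the pathway generates no ATP

    @property
    def defined(self) -> bool:
        return self.cost_per_atp is not None


def energy_enzyme_cost(
    ec: ECModel,
    sol: FluxSolution,
    pathway_reaction_ids: Sequence[str],
    atp_metabolite_id: str = "atp_c",
    label: str = "",
    per_mol: bool = False,
) -> EnergyCostBreakdown:
    """Enzyme cost per unit net ATP produced by a reaction set.

    Numerator: summed enzyme costs of the member reactions in ``sol``.
    Denominator: Σ (ATP stoichiometric coefficient) · flux over members.
    ``per_mol=True`` reports g enzyme per (mol ATP/h) instead of per
    (mmol ATP/h) — a factor 1000.
    """
    missing = [r for r in pathway_reaction_ids if not ec.model.has_reaction(r)]
    if missing:
        raise KeyError(f"pathway reaction(s) not in model: {missing}")
    total_cost = sum(sol.enzyme_costs.get(r, 0.0) for r in pathway_reaction_ids)
    net_atp = 0.0
    for rid in pathway_reaction_ids:
        coeff = ec.model.reaction(rid).stoichiometry.get(atp_metabolite_id, 0.0)
        net_atp += coeff * sol.fluxes.get(rid, 0.0)
    if net_atp > 0:
        cost_per_atp = total_cost / net_atp * (1000.0 if per_mol else 1.0)
    else:
        cost_per_atp = None
    return EnergyCostBreakdown(
        label=label, reaction_ids=list(pathway_reaction_ids),
        total_enzyme_cost=total_cost, net_atp_flux=net_atp, cost_per_atp=cost_per_atp,
    )


# --------------------------------------------------------------------------
# yield / enzyme-efficiency trade-off

@dataclass
class TradeoffResult:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tradeoff_scan(
    ec: ECModel,
    uptake_grid: Sequence[float],
    substrate_exchange_id: str,
    substrate_mw: float = MW_GLUCOSE,
    extra_bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> TradeoffResult:
    """Sweep the substrate uptake bound; report growth, E_min, yield, efficiency.

    yield = v_biomass / (v_substrate · MW_substrate)   [gDW / g substrate]
    enzyme_efficiency = v_biomass / E_min              [gDW·h⁻¹ / g enzyme]
    """
    grid = list(uptake_grid)
    if any(g <= 0 for g in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("uptake grid must be positive and strictly increasing")
    biomass = ec.model.objective_reaction
    result = TradeoffResult()
    for bound in grid:
        overrides = dict(extra_bound_overrides or {})
        overrides.update(uptake_overrides(ec, substrate_exchange_id, bound))
        sol = minimize_enzyme_usage(ec, bound_overrides=overrides)
        row: dict = {"uptake_bound": bound, "status": sol.status}
        if sol.optimal:
            mu = sol.fluxes[biomass]
            v_sub = uptake_flux(ec, sol, substrate_exchange_id)
            e_min = sol.total_enzyme_usage
            row.update(
                growth=mu,
                substrate_uptake=v_sub,
                e_min=e_min,
                biomass_yield=(mu / (v_sub * substrate_mw) if v_sub > 0 else float("nan")),
                enzyme_efficiency=(mu / e_min if e_min > 0 else float("nan")),
            )
        else:
            row.update(growth=float("nan"), substrate_uptake=float("nan"),
                       e_min=float("nan"), biomass_yield=float("nan"),
                       enzyme_efficiency=float("nan"))
        result.rows.append(row)
    return result
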