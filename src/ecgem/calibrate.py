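"""Automated turnover-number calibration.

Underestimated kcat values inflate a reaction's enzyme cost and throttle
the whole model.  Two flagging rules identify them:

1. **Enzyme usage** — at the parsimonious growth optimum, any reaction
   whose enzyme cost exceeds 1% of the enzyme pool bound is suspect: a
   single enzyme rarely commands that share of the proteome.
2. **¹³C flux consistency** — a reaction whose maximal catalytic
   capacity when granted 10% of the total enzyme pool,
   v_max = 0.10 · ptot·f · σ · kcat / MW,
   still falls short of its experimentally measured (¹³C-MFA) flux
   cannot carry the observed flux and must be under-parameterised.

Flagged kcats are replaced by the maximum value reported in reference
databases (BRENDA / SABIO-RK style tables); replacements only ever raise
kcat, so calibration monotonically relaxes the constraint and the
maximal growth rate never decreases.  Usage rounds iterate to a fixed
point, then the ¹³C rule is applied once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .ec_core import ECModel, FluxSolution, minimize_enzyme_usage, optimize
from .enzyme_data import EnzymeEntry
from .preprocess import ISOZYME_SUFFIX, REVERSE_SUFFIX, source_id


@dataclass(frozen=True)
class C13FluxSet:
    """Measured fluxes (mmol/gDW/h) keyed by reaction id, one condition."""

    fluxes: dict[str, float]
    condition: str = ""

    def __post_init__(self) -> None:
        negative = {r: v for r, v in self.fluxes.items() if v < 0}
        if negative:
            raise ValueError(
                f"measured fluxes must be non-negative on split reaction ids: {negative}; "
                "resolve direction before loading"
            )


@dataclass(frozen=True)
class KcatReference:
    """Database maxima: reaction id -> (kcat_max in h⁻¹)."""

    by_reaction: dict[str, float]
    source: str = "BRENDA"

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.by_reaction.items() if v <= 0}
        if bad:
            raise ValueError(f"reference kcat values must be > 0: {bad}")

    def lookup(self, reaction_id: str) -> float | None:
        """Reference kcat for a (possibly split) reaction id."""
        if reaction_id in self.by_reaction:
            return self.by_reaction[reaction_id]
        src = source_id(reaction_id)
        return self.by_reaction.get(src)


@dataclass(frozen=True)
class CalibrationChange:
    rule: str  # {enzyme_usage, c13_consistency}
    reaction_id: str
    old_kcat: float
    new_kcat: float
    trigger_value: float  # usage share, or measured-flux deficit

    def __post_init__(self) -> None:
        if self.new_kcat <= self.old_kcat:
            raise ValueError(
                f"calibration must raise kcat: {self.reaction_id} "
                f"{self.old_kcat} -> {self.new_kcat}"
            )


@dataclass
class CalibrationReport:
    """Per-round record of every kcat change plus the final growth rate."""

    rounds: list[list[CalibrationChange]] = field(default_factory=list)
    uncorrectable: list[str] = field(default_factory=list)
    growth_trajectory: list[float] = field(default_factory=list)
    final_growth: float = float("nan")
    aborted: bool = False

    @property
    def n_changes(self) -> int:
        return sum(len(r) for r in self.rounds)

    def all_changes(self) -> list[CalibrationChange]:
        return [c for r in self.rounds for c in r]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"round": i + 1, "rule": c.rule, "reaction_id": c.reaction_id,
             "old_kcat": c.old_kcat, "new_kcat": c.new_kcat,
             "trigger_value": c.trigger_value}
            for i, rnd in enumerate(self.rounds) for c in rnd
        ]
        return pd.DataFrame(
            rows, columns=["round", "rule", "reaction_id", "old_kcat", "new_kcat", "trigger_value"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def flag_enzyme_usage(
    sol: FluxSolution, pool_bound: float, threshold: float = 0.01
) -> list[tuple[str, float]]:
    """Reactions whose enzyme cost exceeds ``threshold`` of the pool bound.

    Shares are computed against the solution-independent pool bound
    ptot·f (not the used total), so the flagged set does not depend on
    which alternate optimum the solver returned.  Sorted by share,
    largest first.
    """
    if pool_bound <= 0:
        raise ValueError(f"pool_bound must be > 0, got {pool_bound}")
    if not sol.optimal:
        raise ValueError(f"cannot flag from a non-optimal solution (status {sol.status})")
    flagged = [
        (rid, cost / pool_bound)
        for rid, cost in sol.enzyme_costs.items()
        if cost / pool_bound > threshold
    ]
    flagged.sort(key=lambda t: (-t[1], t[0]))
    return flagged


def _split_ids_for(ec: ECModel, measured_id: str) -> list[str]:
    """Model entry ids that descend from a measured (source) reaction id."""
    candidates = []
    for e in ec.constraint.entries:
        rid = e.reaction_id
        if rid == measured_id or source_id(rid) == measured_id:
            candidates.append(rid)
        elif rid.startswith(measured_id + ISOZYME_SUFFIX) or rid.startswith(
            measured_id + REVERSE_SUFFIX
        ):
            candidates.append(rid)
    return candidates


def flag_c13(
    ec: ECModel, c13: C13FluxSet, pool_fraction: float = 0.10
) -> list[tuple[str, float, float]]:
    """Reactions whose 10%-of-pool catalytic capacity is below the ¹³C flux.

    Capacity of reaction i granted ``pool_fraction`` of the total enzyme
    amount: v_i = pool_fraction · ptot·f · σ_i · kcat_i / MW_i.  Returns
    (reaction id, capacity, measured flux) for every shortfall.  Measured
    ids with no enzyme entry are skipped with a warning.
    """
    if not (0 < pool_fraction <= 1):
        raise ValueError(f"pool_fraction must be in (0, 1], got {pool_fraction}")
    import warnings

    flagged: list[tuple[str, float, float]] = []
    for measured_id, measured_flux in c13.fluxes.items():
        ids = _split_ids_for(ec, measured_id)
        if not ids:
            warnings.warn(
                f"measured reaction {measured_id!r} has no enzyme entry in the model; skipped",
                stacklevel=2,
            )
            continue
        for rid in ids:
            entry = ec.entry_for(rid)
            capacity = pool_fraction * ec.pool_bound * entry.sigma * entry.kcat / entry.mw
            if capacity < measured_flux:
                flagged.append((rid, capacity, measured_flux))
    return flagged


def apply_corrections(
    entries: Sequence[EnzymeEntry],
    flagged: Sequence[str],
    ref: KcatReference,
    rule: str = "enzyme_usage",
    trigger_values: Mapping[str, float] | None = None,
) -> tuple[list[EnzymeEntry], list[CalibrationChange], list[str]]:
    """Raise flagged kcats to their reference maxima.

    A flagged reaction is changed only when the reference value is
    strictly greater than its current kcat (never downgrade); otherwise
    it is listed as uncorrectable.  Returns (new entries, changes,
    uncorrectable ids).
    """
    triggers = trigger_values or {}
    flagged_set = list(dict.fromkeys(flagged))  # preserve order, dedupe
    changes: list[CalibrationChange] = []
    uncorrectable: list[str] = []
    by_id = {e.reaction_id: e for e in entries}
    for rid in flagged_set:
        entry = by_id.get(rid)
        if entry is None:
            uncorrectable.append(rid)
            continue
        ref_kcat = ref.lookup(rid)
        if ref_kcat is None or ref_kcat <= entry.kcat:
            uncorrectable.append(rid)
            continue
        by_id[rid] = entry.with_kcat(ref_kcat, source="brenda_sabio_max")
        changes.append(
            CalibrationChange(rule, rid, entry.kcat, ref_kcat, triggers.get(rid, float("nan")))
        )
    new_entries = [by_id[e.reaction_id] for e in entries]
    return new_entries, changes, uncorrectable


def calibrate(
    ec: ECModel,
    ref: KcatReference,
    c13: C13FluxSet | None = None,
    max_rounds: int = 10,
    usage_threshold: float = 0.01,
    c13_pool_fraction: float = 0.10,
) -> tuple[ECModel, CalibrationReport]:
    """Run the two-principle calibration to convergence.

    Enzyme-usage rounds (flag at the parsimonious growth optimum, raise
    flagged kcats to reference maxima, re-solve) repeat until no
    applicable change remains or ``max_rounds`` is hit; then the ¹³C
    consistency rule is applied once, if measured fluxes are given.
    """
    if max_rounds < 1:
        raise ValueError(f"max_rounds must be >= 1, got {max_rounds}")
    report = CalibrationReport()
    current = ec

    for _ in range(max_rounds):
        sol = minimize_enzyme_usage(current)
        if not sol.optimal:
            report.aborted = True
            report.final_growth = float("nan")
            return current, report
        growth = sol.fluxes[current.model.objective_reaction]
        report.growth_trajectory.append(growth)
        flagged = flag_enzyme_usage(sol, current.pool_bound, usage_threshold)
        if not flagged:
            break
        new_entries, changes, uncorrectable = apply_corrections(
            current.constraint.entries,
            [rid for rid, _ in flagged],
            ref,
            rule="enzyme_usage",
            trigger_values=dict(flagged),
        )
        report.uncorrectable.extend(u for u in uncorrectable if u not in report.uncorrectable)
        if not changes:
            break
        report.rounds.append(changes)
        current = current.with_entries(new_entries)

    if c13 is not None:
        flagged_c13 = flag_c13(current, c13, c13_pool_fraction)
        if flagged_c13:
            new_entries, changes, uncorrectable = apply_corrections(
                current.constraint.entries,
                [rid for rid, _, _ in flagged_c13],
                ref,
                rule="c13_consistency",
                trigger_values={rid: measured for rid, _, measured in flagged_c13},
            )
            report.uncorrectable.extend(
                u for u in uncorrectable if u not in report.uncorrectable
            )
            if changes:
                report.rounds.append(changes)
                current = current.with_entries(new_entries)

    final = optimize(current)
    report.final_growth = final.objective_value if final.optimal else float("nan")
    if final.optimal:
        report.growth_trajectory.append(report.final_growth)
    return current, report


# --- tabular I/O -----------------------------------------------------------

def read_c13_table(path, condition: str = "") -> C13FluxSet:
    """Read a ¹³C flux TSV (reaction_id, flux)."""
    df = pd.read_csv(path, sep="\t")
    if not {"reaction_id", "flux"} <= set(df.columns):
        raise ValueError("c13 table must have columns reaction_id, flux")
    return C13FluxSet(
        {str(r.reaction_id): float(r.flux) for r in df.itertuples(index=False)}, condition
    )


def read_reference_table(path) -> KcatReference:
    """Read a reference kcat TSV (reaction_id, kcat_max, unit[, source])."""
    from .enzyme_data import SECONDS_PER_HOUR

    df = pd.read_csv(path, sep="\t")
    if not {"reaction_id", "kcat_max", "unit"} <= set(df.columns):
        raise ValueError("reference table must have columns reaction_id, kcat_max, unit")
    table: dict[str, float] = {}
    for r in df.itertuples(index=False):
        k = float(r.kcat_max)
        if r.unit == "per_s":
            k *= SECONDS_PER_HOUR
        elif r.unit != "per_h":
            raise ValueError(f"unknown kcat unit {r.unit!r} for {r.reaction_id}")
        table[str(r.reaction_id)] = k
    return KcatReference(table)
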