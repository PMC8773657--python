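"""Metabolic network containers and model I/O.

Reads SBML Level 3 (through COBRApy/libsbml) and COBRA-style JSON, and
reads/writes an enzyme-constrained JSON dialect: the standard COBRA JSON
layout for the network plus one top-level ``"enzyme_constraint"`` block

    {"ptot": ..., "f": ..., "sigma_default": ..., "pool_upper_bound": ...,
     "entries": [{"reaction_id", "kcat_per_hour", "mw_kda", "sigma", "source"}]}

SBML has no slot for a proteome pool constraint, so the dialect is the
on-disk form of an enzyme-constrained model.  The schema is this
package's own and round-trips exactly through :func:`save_ec_model` /
:func:`load_ec_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .enzyme_data import EnzymeEntry

_POOL_RTOL = 1e-9


class ModelValidationError(ValueError):
    """A model or constraint record violates a structural invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """One (possibly reversible) reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``gpr`` is the gene-protein-reaction rule, a
    boolean expression over gene ids with ``and``/``or``.  After isozyme
    splitting, ``enzyme_genes`` holds the single gene set (complex) that
    catalyses this reaction; it is None before splitting or for
    spontaneous reactions.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: str = ""
    ec_number: str | None = None
    enzyme_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions: all-negative or all-positive stoichiometry.

        Covers exchange, demand and sink reactions; such reactions never
        carry an enzyme entry.
        """
        coeffs = [c for c in self.stoichiometry.values() if c != 0]
        if not coeffs:
            return True
        return all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPRs and one objective reaction."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    objective_reaction: str
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite id(s): {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction id(s): {dupes}")
        met_set = set(met_ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolite(s): {sorted(unknown)}"
                )
            if not r.stoichiometry and not r.is_exchange:
                raise ModelValidationError(f"reaction {r.id} has empty stoichiometry")
        if self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # -- convenience accessors ------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
            id=self.id,
        )

    def stoichiometric_matrix(self):
        """Sparse S (metabolites x reactions), column order = self.reactions."""
        from scipy.sparse import lil_matrix

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = lil_matrix((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[met_index[met], j] = coeff
        return S.tocsr()


@dataclass
class EnzymeConstraintRecord:
    """The single pooled enzyme constraint: Σ v·MW/(σ·kcat) ≤ ptot·f.

    ptot: total protein content (g protein / gDW); f: mass fraction of
    the proteome that is model enzymes; pool_upper_bound must equal
    ptot·f.
    """

    ptot: float
    f: float
    sigma_default: float
    pool_upper_bound: float
    entries: list[EnzymeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ptot <= 0:
            raise ModelValidationError(f"ptot must be > 0, got {self.ptot}")
        if not (0 < self.f <= 1):
            raise ModelValidationError(f"f must be in (0, 1], got {self.f}")
        if not (0 < self.sigma_default <= 1):
            raise ModelValidationError(f"sigma_default must be in (0, 1], got {self.sigma_default}")
        expected = self.ptot * self.f
        if not math.isclose(self.pool_upper_bound, expected, rel_tol=_POOL_RTOL):
            raise ModelValidationError(
                f"pool_upper_bound {self.pool_upper_bound} != ptot*f = {expected}"
            )
        ids = [e.reaction_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate enzyme entries for reaction(s): {dupes}")

    @classmethod
    def from_parameters(
        cls, ptot: float, f: float, sigma_default: float = 1.0,
        entries: Iterable[EnzymeEntry] = (),
    ) -> "EnzymeConstraintRecord":
        return cls(ptot=ptot, f=f, sigma_default=sigma_default,
                   pool_upper_bound=ptot * f, entries=list(entries))

    def entry_for(self, reaction_id: str) -> EnzymeEntry | None:
        for e in self.entries:
            if e.reaction_id == reaction_id:
                return e
        return None


# --------------------------------------------------------------------------
# loading

def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load an SBML L3 (FBC) or COBRA-JSON model.

    ``format`` is "sbml" or "json"; inferred from the suffix when omitted.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"model file not found: {p}")
    if format is None:
        format = "sbml" if p.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "sbml":
        import cobra.io

        return from_cobra(cobra.io.read_sbml_model(str(p)))
    if format == "json":
        with open(p) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{p} is not valid JSON: {exc}") from exc
        return _model_from_cobra_json(doc, model_id=doc.get("id", p.stem))
    raise ValueError(f"unknown model format {format!r} (expected 'sbml' or 'json')")


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model to the package's container."""
    from cobra.util.solver import linear_reaction_coefficients

    objective = None
    coeffs = linear_reaction_coefficients(cm)
    if coeffs:
        objective = max(coeffs, key=lambda r: abs(coeffs[r])).id
    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                ec_number=(r.annotation.get("ec-code") if isinstance(
                    r.annotation.get("ec-code"), str) else None),
            )
        )
    if objective is None:
        objective = reactions[0].id
    return MetabolicModel(
        metabolites=[Metabolite(m.id, m.name or "", m.compartment or "") for m in cm.metabolites],
        reactions=reactions,
        genes=[g.id for g in cm.genes],
        objective_reaction=objective,
        id=cm.id or "model",
    )


def _model_from_cobra_json(doc: Mapping, model_id: str) -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise FormatError(f"COBRA JSON missing required key {key!r}")
    metabolites = [
        Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
        for m in doc["metabolites"]
    ]
    reactions = []
    objective = None
    seen: set[str] = set()
    for r in doc["reactions"]:
        rid = r["id"]
        if rid in seen:
            raise ModelValidationError(f"duplicate reaction id in file: {rid!r}")
        seen.add(rid)
        ec = r.get("annotation", {}).get("ec-code")
        if isinstance(ec, list):
            ec = ec[0] if ec else None
        genes = r.get("enzyme_genes")
        reactions.append(
            Reaction(
                id=rid,
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=r.get("gene_reaction_rule", ""),
                ec_number=ec,
                enzyme_genes=frozenset(genes) if genes is not None else None,
            )
        )
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            objective = rid
    if objective is None:
        objective = reactions[0].id if reactions else ""
    gene_ids = [g["id"] if isinstance(g, Mapping) else str(g) for g in doc.get("genes", [])]
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=gene_ids,
        objective_reaction=objective, id=model_id,
    )


# --------------------------------------------------------------------------
# the enzyme-constrained JSON dialect

def _model_to_cobra_json(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": 1.0 if r.id == model.objective_reaction else 0.0,
                **({"annotation": {"ec-code": r.ec_number}} if r.ec_number else {}),
                **({"enzyme_genes": sorted(r.enzyme_genes)} if r.enzyme_genes is not None else {}),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
    }


def save_ec_model(model: MetabolicModel, constraint: EnzymeConstraintRecord, path) -> None:
    """Write network + enzyme constraint as one JSON document."""
    rxn_ids = set(model.reaction_ids)
    unknown = [e.reaction_id for e in constraint.entries if e.reaction_id not in rxn_ids]
    if unknown:
        raise ModelValidationError(
            f"enzyme entries reference reaction(s) absent from the model: {sorted(unknown)}"
        )
    doc = _model_to_cobra_json(model)
    doc["enzyme_constraint"] = {
        "ptot": constraint.ptot,
        "f": constraint.f,
        "sigma_default": constraint.sigma_default,
        "pool_upper_bound": constraint.pool_upper_bound,
        "entries": [
            {
                "reaction_id": e.reaction_id,
                "kcat_per_hour": e.kcat,
                "mw_kda": e.mw,
                "sigma": e.sigma,
                "source": e.source,
            }
            for e in constraint.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_ec_model(path) -> tuple[MetabolicModel, EnzymeConstraintRecord]:
    """Read an enzyme-constrained JSON file back into (model, constraint)."""
    p = Path(path)
    if not p.exists():
        raise IOError(f"ec-model file not found: {p}")
    with open(p) as fh:
        doc = json.load(fh)
    if "enzyme_constraint" not in doc:
        raise FormatError(
            f"{p} has no 'enzyme_constraint' block: this looks like plain COBRA JSON; "
            "use load_model() for unconstrained models"
        )
    model = _model_from_cobra_json(doc, model_id=doc.get("id", p.stem))
    block = doc["enzyme_constraint"]
    constraint = EnzymeConstraintRecord(
        ptot=float(block["ptot"]),
        f=float(block["f"]),
        sigma_default=float(block["sigma_default"]),
        pool_upper_bound=float(block["pool_upper_bound"]),
        entries=[
            EnzymeEntry(
                reaction_id=e["reaction_id"],
                kcat=float(e["kcat_per_hour"]),
                mw=float(e["mw_kda"]),
                sigma=float(e["sigma"]),
                source=e["source"],
            )
            for e in block["entries"]
        ],
    )
    rxn_ids = set(model.reaction_ids)
    unknown = [e.reaction_id for e in constraint.entries if e.reaction_id not in rxn_ids]
    if unknown:
        raise ModelValidationError(
            f"enzyme entries reference reaction(s) absent from the model: {sorted(unknown)}"
        )
    return model, constraint
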