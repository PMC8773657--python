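"""Per-reaction enzyme parameters: molecular weights, turnover numbers, saturation.

An enzyme-constrained model needs, for every catalysed reaction *i*, a
molecular weight ``MW_i`` (kDa = g/mmol), a turnover number ``kcat_i``
(h⁻¹) and a saturation coefficient ``sigma_i`` in (0, 1].  The flux
through the reaction then carries an enzyme mass cost

    cost_i = v_i * MW_i / (sigma_i * kcat_i)      [g enzyme / gDW]

Molecular weights of multimeric enzymes are the stoichiometric sum of
their subunit masses: a complex with subunit copy numbers 24:24:12 weighs
an order of magnitude more than the same subunits counted once each, and
that difference propagates directly into the enzyme cost of the reaction.

The proteome-derived mass fraction ``f`` (g enzyme / g total protein) is
the mass share of the quantified proteome covered by the model's genes:

    f = sum_{i in model} A_i * MW_i / sum_{j in proteome} A_j * MW_j

with ``A`` mole-ratio abundances (e.g. ppm).  Together with the total
protein content ``ptot`` (g protein / gDW) it sets the enzyme pool bound
``ptot * f``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .gem_io import MetabolicModel

logger = logging.getLogger(__name__)

#: recognised provenance labels for a kcat value
KCAT_SOURCES = ("ml_prediction", "brenda_sabio_max", "manual", "default")

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class SubunitComposition:
    """Subunit make-up of one enzyme (or enzyme complex).

    ``components`` lists ``(gene_id, copy_number, subunit_mw_kda)`` with
    copy numbers ≥ 1 and distinct gene ids.
    """

    components: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _, _ in self.components]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene ids in subunit composition: {genes}")
        for gene, copies, mw in self.components:
            if copies < 1 or int(copies) != copies:
                raise ValueError(f"copy number for {gene} must be a positive integer, got {copies}")
            if mw <= 0:
                raise ValueError(f"subunit molecular weight for {gene} must be > 0, got {mw}")


@dataclass(frozen=True)
class EnzymeEntry:
    """Kinetic record attached to one (split) reaction.

    kcat is stored in h⁻¹; mw in kDa (= g/mmol); sigma dimensionless.
    """

    reaction_id: str
    kcat: float
    mw: float
    sigma: float = 1.0
    source: str = "default"

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValueError(f"kcat must be > 0 for {self.reaction_id}, got {self.kcat}")
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0 for {self.reaction_id}, got {self.mw}")
        if not (0 < self.sigma <= 1):
            raise ValueError(f"sigma must be in (0, 1] for {self.reaction_id}, got {self.sigma}")
        if self.source not in KCAT_SOURCES:
            raise ValueError(f"unknown kcat source {self.source!r}; expected one of {KCAT_SOURCES}")

    @property
    def cost_coefficient(self) -> float:
        """g enzyme per unit flux: MW / (sigma * kcat)."""
        return self.mw / (self.sigma * self.kcat)

    def with_kcat(self, kcat: float, source: str) -> "EnzymeEntry":
        return replace(self, kcat=kcat, source=source)


@dataclass(frozen=True)
class ProteomeRecord:
    """One quantified protein: mole-ratio abundance (e.g. ppm) and mass (kDa)."""

    protein_id: str
    abundance: float
    mw: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"abundance must be >= 0 for {self.protein_id}")
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0 for {self.protein_id}")


def complex_molecular_weight(comp: SubunitComposition) -> float:
    """Molecular weight of a (possibly multimeric) enzyme in kDa.

    Sum over subunits of copy_number * subunit_mw.  E.g. the E. coli
    pyruvate dehydrogenase complex (AceE/AceF/Lpd) weighs ~216 kDa when
    each subunit is counted once but ~4586 kDa at its true 24:24:12
    stoichiometry.
    """
    if not comp.components:
        raise ValueError("empty subunit composition")
    return sum(copies * mw for _, copies, mw in comp.components)


def effective_efficiency(
    entries_for_complex: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Bottleneck (kcat, mw) pair of a complex with per-subunit kinetics.

    Returns the input pair with the minimal kcat/mw ratio (the least
    catalytically efficient subunit limits the complex); ties go to the
    first occurrence.  The output is always an element of the input.
    """
    if not entries_for_complex:
        raise ValueError("no (kcat, mw) candidates supplied")
    return min(entries_for_complex, key=lambda km: km[0] / km[1])


def assign_enzyme_entries(
    model: "MetabolicModel",
    kcat_table: Mapping[str, float],
    subunit_table: Mapping[str, tuple[int, float]],
    sigma_default: float = 1.0,
) -> list[EnzymeEntry]:
    """Build the per-reaction enzyme entries for a preprocessed model.

    Parameters
    ----------
    model
        Preprocessed model (irreversible, one enzyme alternative per
        reaction).
    kcat_table
        reaction id -> kcat (h⁻¹).  Keys may be the split (derived) ids
        or the original source ids; a derived-id entry takes precedence
        over its source's, so direction- or isozyme-specific values can
        override the shared one.
    subunit_table
        gene id -> (copy_number, subunit_mw_kda).  Genes missing a copy
        number entry default to a single copy (with a logged warning),
        which reproduces the one-copy-per-subunit baseline of methods
        that ignore complex stoichiometry.
    sigma_default
        Saturation applied to every entry (overridable downstream).

    Exchange, biomass/sink and spontaneous (empty-GPR) reactions receive
    no entry; a reaction without a kcat receives no entry, i.e. zero
    enzyme cost.
    """
    if not (0 < sigma_default <= 1):
        raise ValueError(f"sigma_default must be in (0, 1], got {sigma_default}")
    for rid, kcat in kcat_table.items():
        if kcat <= 0:
            raise ValueError(f"non-positive kcat for reaction {rid!r}: {kcat}")

    entries: list[EnzymeEntry] = []
    missing_copy: set[str] = set()
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        genes = rxn.enzyme_genes
        if genes is None and rxn.gpr.strip():
            # model not run through preprocess.split_isozymes; resolve here
            from .preprocess import parse_gpr

            alts = parse_gpr(rxn.gpr)
            if len(alts) != 1:
                raise ValueError(
                    f"reaction {rxn.id} still has {len(alts)} enzyme alternatives; "
                    "run preprocess() first"
                )
            genes = alts[0]
        if not genes:
            continue  # spontaneous
        kcat = _lookup_split_aware(kcat_table, rxn.id)
        if kcat is None:
            continue  # no kcat -> enzyme cost 0
        components = []
        for gene in sorted(genes):
            if gene in subunit_table:
                copies, mw = subunit_table[gene]
            else:
                continue
            components.append((gene, int(copies), float(mw)))
        known = {g for g, _, _ in components}
        absent = set(genes) - known
        if absent:
            missing_copy |= absent
        if not components:
            continue  # no mass information at all -> cannot cost this enzyme
        mw = complex_molecular_weight(SubunitComposition(tuple(components)))
        entries.append(
            EnzymeEntry(
                reaction_id=rxn.id,
                kcat=float(kcat),
                mw=mw,
                sigma=sigma_default,
                source="ml_prediction",
            )
        )
    if missing_copy:
        logger.warning(
            "no subunit record for %d gene(s) (e.g. %s); their mass contribution is omitted",
            len(missing_copy),
            sorted(missing_copy)[:5],
        )
    return entries


def _lookup_split_aware(table: Mapping[str, float], derived_id: str) -> float | None:
    """kcat lookup that falls back from a split id to its source id.

    ``R_reverse_num2`` is tried verbatim, then with the isozyme suffix
    stripped (``R_reverse``), then with the direction suffix stripped
    (``R``).
    """
    if derived_id in table:
        return table[derived_id]
    rid = derived_id
    for _ in range(2):
        if "_num" in rid:
            base, _, tail = rid.rpartition("_num")
            if tail.isdigit():
                rid = base
        elif rid.endswith("_reverse"):
            rid = rid[: -len("_reverse")]
        else:
            break
        if rid in table:
            return table[rid]
    return None


def compute_enzyme_mass_fraction(
    proteome: Iterable[ProteomeRecord],
    model_protein_ids: set[str],
    id_prefix_strip: str | None = None,
) -> float:
    """Mass fraction f of the proteome covered by the model's proteins.

    f = Σ_{i ∈ model} A_i·MW_i / Σ_{j ∈ proteome} A_j·MW_j, in (0, 1].
    ``id_prefix_strip`` removes a fixed prefix from proteome ids before
    matching (abundance databases often prepend a taxon or locus prefix).
    """
    num = 0.0
    den = 0.0
    matched = False
    for rec in proteome:
        pid = rec.protein_id
        if id_prefix_strip and pid.startswith(id_prefix_strip):
            pid = pid[len(id_prefix_strip):]
        mass = rec.abundance * rec.mw
        den += mass
        if pid in model_protein_ids:
            num += mass
            matched = True
    if den <= 0:
        raise ValueError("proteome has zero total mass; cannot compute enzyme mass fraction")
    if not matched:
        warnings.warn(
            "no proteome protein matched the model's gene ids; enzyme mass fraction is 0",
            stacklevel=2,
        )
        return 0.0
    return num / den


# --- tabular I/O -----------------------------------------------------------

def read_kcat_table(path) -> dict[str, float]:
    """Read a kcat TSV (reaction_id, kcat, unit ∈ {per_s, per_h}[, source]) to h⁻¹."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "kcat", "unit"}
    if not required <= set(df.columns):
        raise ValueError(f"kcat table must have columns {sorted(required)}, got {list(df.columns)}")
    out: dict[str, float] = {}
    for row in df.itertuples(index=False):
        kcat = float(row.kcat)
        if row.unit == "per_s":
            kcat *= SECONDS_PER_HOUR
        elif row.unit != "per_h":
            raise ValueError(f"unknown kcat unit {row.unit!r} for {row.reaction_id}")
        out[str(row.reaction_id)] = kcat
    return out


def write_kcat_table(table: Mapping[str, float], path, source: str = "manual") -> None:
    pd.DataFrame(
        {"reaction_id": list(table), "kcat": list(table.values()),
         "unit": "per_h", "source": source}
    ).to_csv(path, sep="\t", index=False)


def read_subunit_table(path) -> dict[str, tuple[int, float]]:
    """Read a subunit TSV (gene_id, subunit_mw_kda, copy_number)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "subunit_mw_kda", "copy_number"}
    if not required <= set(df.columns):
        raise ValueError(f"subunit table must have columns {sorted(required)}")
    return {
        str(r.gene_id): (int(r.copy_number), float(r.subunit_mw_kda))
        for r in df.itertuples(index=False)
    }


def write_subunit_table(table: Mapping[str, tuple[int, float]], path) -> None:
    pd.DataFrame(
        {"gene_id": list(table),
         "subunit_mw_kda": [mw for _, mw in table.values()],
         "copy_number": [c for c, _ in table.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_proteome_table(path) -> list[ProteomeRecord]:
    """Read a proteome TSV (protein_id, abundance_ppm, mw_kda)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "abundance_ppm", "mw_kda"}
    if not required <= set(df.columns):
        raise ValueError(f"proteome table must have columns {sorted(required)}")
    return [
        ProteomeRecord(str(r.protein_id), float(r.abundance_ppm), float(r.mw_kda))
        for r in df.itertuples(index=False)
    ]


def write_proteome_table(records: Iterable[ProteomeRecord], path) -> None:
    recs = list(records)
    pd.DataFrame(
        {"protein_id": [r.protein_id for r in recs],
         "abundance_ppm": [r.abundance for r in recs],
         "mw_kda": [r.mw for r in recs]}
    ).to_csv(path, sep="\t", index=False)
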