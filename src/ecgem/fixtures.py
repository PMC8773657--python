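"""Self-contained synthetic inputs with analytically known optima.

Everything the rest of the package consumes — models, kcat tables,
subunit tables, proteomes, measured-flux tables — can be generated here,
so the full pipeline builds and tests without any external download.

The centrepiece, :func:`toy_core_model`, mirrors the respiration-versus-
fermentation structure of overflow metabolism: one substrate can be
burned through a high-yield, enzyme-expensive respiratory branch or a
low-yield, enzyme-cheap fermentative branch whose excess redox must be
re-oxidised with O₂.  Its parameters are chosen so every quantity of
interest (plain-FBA optimum, enzyme-constrained optimum, the overflow
switch growth rate, the minimum uptake at fixed growth) has a closed
form, recorded as methods on :class:`ToyCoreParams` and re-derived in
tests rather than hard-coded twice.

Closed forms (σ = 1 throughout; y = ATP per glucose, a = ATP per unit
biomass, c = enzyme cost coefficient MW/kcat per unit flux):

* respiration:  cost per glucose  c_r,  cost per ATP  c_r / y_r
* fermentation chain (ferm + redox re-oxidation):
  c_f_tot = c_f + nadh_per_glc · c_nox,  cost per ATP  c_f_tot / y_f
* plain FBA max growth at uptake bound G:   μ = y_r · G / a
  (respiration dominates: higher ATP yield, no enzyme limit)
* overflow switch at pool bound P: respiration alone supports growth μ
  iff  c_r · a · μ / y_r ≤ P, so  μ_switch = P · y_r / (c_r · a)
* above the switch the minimum-uptake mixture makes both the ATP balance
  and the pool constraint tight (two equations, two pathway fluxes).

Defaults satisfy c_f_tot / y_f < c_r / y_r < ∞: fermentation is cheaper
per ATP but wastes substrate, which is exactly the overflow trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzyme_data import ProteomeRecord, SubunitComposition
from .gem_io import MetabolicModel, Metabolite, Reaction


# --------------------------------------------------------------------------
# the overflow toy model

@dataclass(frozen=True)
class ToyCoreParams:
    """Parameters of the respiration/fermentation toy network + closed forms."""

    atp_per_glc_resp: float = 20.0   # y_r
    atp_per_glc_ferm: float = 2.0    # y_f
    o2_per_glc_resp: float = 6.0
    nadh_per_glc_ferm: float = 2.0
    o2_per_nadh: float = 0.5
    acetate_per_glc_ferm: float = 2.0
    atp_per_biomass: float = 10.0    # a
    kcat_resp: float = 10_000.0      # h⁻¹
    kcat_ferm: float = 10_000.0
    kcat_nadhox: float = 10_000.0
    mw_resp: float = 1000.0          # kDa: complex respA(x2, 300) + respB(x2, 200)
    mw_ferm: float = 60.0            # one 60 kDa subunit per isozyme
    mw_nadhox: float = 10.0
    glc_uptake_bound: float = 10.0   # mmol/gDW/h

    # -- enzyme cost coefficients (g enzyme per unit flux, σ = 1) -------
    @property
    def cost_resp(self) -> float:
        return self.mw_resp / self.kcat_resp

    @property
    def cost_ferm(self) -> float:
        return self.mw_ferm / self.kcat_ferm

    @property
    def cost_nadhox(self) -> float:
        return self.mw_nadhox / self.kcat_nadhox

    @property
    def cost_ferm_chain(self) -> float:
        """Enzyme cost per unit glucose fermented, redox re-oxidation included."""
        return self.cost_ferm + self.nadh_per_glc_ferm * self.cost_nadhox

    # -- closed forms ----------------------------------------------------
    def fba_max_growth(self, uptake_bound: float | None = None) -> float:
        """Plain FBA optimum: all substrate respired."""
        g = self.glc_uptake_bound if uptake_bound is None else uptake_bound
        return self.atp_per_glc_resp * g / self.atp_per_biomass

    def ec_max_growth(self, pool_bound: float, uptake_bound: float | None = None) -> float:
        """Enzyme-constrained optimum by vertex enumeration of the 2-variable LP.

        max (y_r·x + y_f·z)/a  s.t.  x + z ≤ G,  c_r·x + c_fz·z ≤ P.
        """
        g = self.glc_uptake_bound if uptake_bound is None else uptake_bound
        p = pool_bound
        y_r, y_f, a = self.atp_per_glc_resp, self.atp_per_glc_ferm, self.atp_per_biomass
        c_r, c_fz = self.cost_resp, self.cost_ferm_chain
        candidates = [(0.0, 0.0), (min(g, p / c_r), 0.0), (0.0, min(g, p / c_fz))]
        if abs(c_r - c_fz) > 0:
            x = (p - c_fz * g) / (c_r - c_fz)
            z = g - x
            if 0 <= x <= g and 0 <= z:
                candidates.append((x, z))
        best = 0.0
        for x, z in candidates:
            if x + z <= g + 1e-12 and c_r * x + c_fz * z <= p + 1e-12:
                best = max(best, (y_r * x + y_f * z) / a)
        return best

    def overflow_switch_growth(self, pool_bound: float) -> float:
        """Largest growth rate supportable by respiration alone."""
        return pool_bound * self.atp_per_glc_resp / (self.cost_resp * self.atp_per_biomass)

    def max_growth_unlimited_substrate(self, pool_bound: float) -> float:
        """Pool-limited ceiling: all enzyme spent on the cheapest-per-ATP route."""
        per_atp_resp = self.cost_resp / self.atp_per_glc_resp
        per_atp_ferm = self.cost_ferm_chain / self.atp_per_glc_ferm
        return pool_bound / (min(per_atp_resp, per_atp_ferm) * self.atp_per_biomass)

    def min_uptake_at_growth(self, growth: float, pool_bound: float) -> tuple[float, float, float]:
        """(glucose uptake, respiration flux, fermentation flux) minimising uptake.

        Below the switch growth rate, respiration alone; above, the
        unique mixture with both the ATP balance and the enzyme pool
        tight.
        """
        y_r, y_f, a = self.atp_per_glc_resp, self.atp_per_glc_ferm, self.atp_per_biomass
        c_r, c_fz = self.cost_resp, self.cost_ferm_chain
        if growth <= self.overflow_switch_growth(pool_bound):
            x = a * growth / y_r
            return x, x, 0.0
        det = y_r * c_fz - y_f * c_r
        x = (a * growth * c_fz - pool_bound * y_f) / det
        z = (pool_bound * y_r - a * growth * c_r) / det
        return x + z, x, z


def toy_core_model(
    params: ToyCoreParams = ToyCoreParams(),
) -> tuple[MetabolicModel, dict[str, float], dict[str, tuple[int, float]]]:
    """The ~10-reaction overflow toy network with its kcat and subunit tables.

    BiGG-style ids (EX_glc__D_e, atp_c, …).  The glucose transporter is
    reversible (exercises the reversibility split) and the fermentation
    step has two isozymes with identical kinetics (exercises the isozyme
    split without moving the optimum).  Exchanges, transporters and the
    biomass sink are spontaneous and carry no enzyme.
    """
    p = params
    mets = [
        Metabolite("glc__D_e", "D-glucose", "e"),
        Metabolite("glc__D_c", "D-glucose", "c"),
        Metabolite("atp_c", "ATP", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("o2_e", "O2", "e"),
        Metabolite("o2_c", "O2", "c"),
        Metabolite("ac_c", "acetate", "c"),
        Metabolite("ac_e", "acetate", "e"),
        Metabolite("h2o_e", "H2O", "e"),
    ]
    reactions = [
        Reaction("EX_glc__D_e", {"glc__D_e": -1.0},
                 lower_bound=-p.glc_uptake_bound, upper_bound=1000.0,
                 name="glucose exchange"),
        Reaction("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0},
                 lower_bound=-1000.0, upper_bound=1000.0, name="glucose transport"),
        Reaction("RESP", {"glc__D_c": -1.0, "o2_c": -p.o2_per_glc_resp,
                          "atp_c": p.atp_per_glc_resp},
                 upper_bound=1000.0, gpr="respA and respB", name="respiration (lumped)"),
        Reaction("FERM", {"glc__D_c": -1.0, "ac_c": p.acetate_per_glc_ferm,
                          "atp_c": p.atp_per_glc_ferm, "nadh_c": p.nadh_per_glc_ferm},
                 upper_bound=1000.0, gpr="fermA or fermB", name="fermentation (lumped)"),
        Reaction("NADHOX", {"nadh_c": -1.0, "o2_c": -p.o2_per_nadh, "h2o_e": 1.0},
                 upper_bound=1000.0, gpr="noxA", name="NADH oxidase"),
        Reaction("EX_h2o_e", {"h2o_e": -1.0}, upper_bound=1000.0, name="water exchange"),
        Reaction("ACt", {"ac_c": -1.0, "ac_e": 1.0}, upper_bound=1000.0,
                 name="acetate transport"),
        Reaction("EX_ac_e", {"ac_e": -1.0}, upper_bound=1000.0, name="acetate exchange"),
        Reaction("O2t", {"o2_e": -1.0, "o2_c": 1.0}, upper_bound=1000.0,
                 name="O2 transport"),
        Reaction("EX_o2_e", {"o2_e": -1.0}, lower_bound=-1000.0, upper_bound=1000.0,
                 name="O2 exchange"),
        Reaction("BIOMASS", {"atp_c": -p.atp_per_biomass}, upper_bound=1000.0,
                 name="biomass (ATP drain)"),
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=["respA", "respB", "fermA", "fermB", "noxA"],
        objective_reaction="BIOMASS",
        id="toy_overflow",
    )
    kcat_table = {"RESP": p.kcat_resp, "FERM": p.kcat_ferm, "NADHOX": p.kcat_nadhox}
    # respA/respB at two copies each: 2*300 + 2*200 = mw_resp = 1000 kDa
    subunit_table = {
        "respA": (2, 300.0),
        "respB": (2, 200.0),
        "fermA": (1, p.mw_ferm),
        "fermB": (1, p.mw_ferm),
        "noxA": (1, p.mw_nadhox),
    }
    assert 2 * 300.0 + 2 * 200.0 == p.mw_resp
    return model, kcat_table, subunit_table


# --------------------------------------------------------------------------
# synthetic proteomes

def toy_proteome(
    seed: int, n_total: int, n_in_model: int
) -> tuple[list[ProteomeRecord], set[str], float]:
    """Random proteome plus the exactly computed expected mass fraction.

    Abundances uniform on [1, 100], masses uniform on [10, 100] kDa; the
    first ``n_in_model`` proteins are 'in the model'.  Returns (records,
    model protein ids, expected f) with f recomputed by direct arithmetic
    so tests can assert against an independent pass.
    """
    if n_in_model > n_total:
        raise ValueError(f"n_in_model ({n_in_model}) > n_total ({n_total})")
    rng = np.random.default_rng(seed)
    abundances = rng.uniform(1.0, 100.0, size=n_total)
    mws = rng.uniform(10.0, 100.0, size=n_total)
    records = [
        ProteomeRecord(f"p{i}", float(abundances[i]), float(mws[i])) for i in range(n_total)
    ]
    model_ids = {f"p{i}" for i in range(n_in_model)}
    masses = abundances * mws
    expected_f = float(masses[:n_in_model].sum() / masses.sum()) if n_in_model else 0.0
    return records, model_ids, expected_f


# --------------------------------------------------------------------------
# random small networks for oracle-equivalence harnesses

@dataclass(frozen=True)
class ToySpec:
    """Recipe for a random ≤ 8-reaction feasible, bounded network."""

    seed: int = 42
    n_chain: int = 3            # conversion steps in the backbone
    n_extra_reactions: int = 2  # parallel alternatives with different kinetics
    pool_bound: float = 0.05    # suggested g enzyme/gDW for callers
    uptake_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.n_chain < 1 or self.n_extra_reactions < 0:
            raise ValueError("n_chain >= 1 and n_extra_reactions >= 0 required")
        if self.n_chain + self.n_extra_reactions + 2 > 8:
            raise ValueError("random toy models are capped at 8 reactions")


def random_toy_model(
    spec: ToySpec,
) -> tuple[MetabolicModel, dict[str, float], dict[str, tuple[int, float]]]:
    """Random irreversible chain network: source → conversions → sink.

    Deterministic in the seed.  Always feasible (zero flux) and bounded
    (the source bound caps everything); the plain-FBA optimum is strictly
    positive.  Extra reactions duplicate random backbone steps with
    independent kinetics, creating alternate routes whose optima the
    enzyme constraint must arbitrate.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chain
    mets = [Metabolite(f"m{i}_c", f"metabolite {i}", "c") for i in range(n + 1)]
    reactions = [
        Reaction("SRC_m0", {"m0_c": 1.0}, upper_bound=spec.uptake_bound, name="source"),
    ]
    kcat_table: dict[str, float] = {}
    subunit_table: dict[str, tuple[int, float]] = {}
    genes: list[str] = []
    for i in range(n):
        out_coeff = float(rng.uniform(0.5, 2.0))
        rid = f"CONV{i}"
        gene = f"g{i}"
        reactions.append(
            Reaction(rid, {f"m{i}_c": -1.0, f"m{i+1}_c": out_coeff},
                     upper_bound=float(rng.uniform(20.0, 100.0)), gpr=gene,
                     name=f"conversion {i}")
        )
        kcat_table[rid] = float(rng.uniform(1e3, 1e5))
        subunit_table[gene] = (int(rng.integers(1, 5)), float(rng.uniform(10.0, 500.0)))
        genes.append(gene)
    for j in range(spec.n_extra_reactions):
        i = int(rng.integers(0, n))
        src = next(r for r in reactions if r.id == f"CONV{i}")
        rid = f"ALT{j}"
        gene = f"ga{j}"
        reactions.append(
            Reaction(rid, dict(src.stoichiometry),
                     upper_bound=float(rng.uniform(20.0, 100.0)), gpr=gene,
                     name=f"alternative to CONV{i}")
        )
        kcat_table[rid] = float(rng.uniform(1e3, 1e5))
        subunit_table[gene] = (int(rng.integers(1, 5)), float(rng.uniform(10.0, 500.0)))
        genes.append(gene)
    reactions.append(
        Reaction(f"DM_m{n}", {f"m{n}_c": -1.0}, upper_bound=1000.0, name="demand")
    )
    model = MetabolicModel(
        metabolites=mets, reactions=reactions, genes=genes,
        objective_reaction=f"DM_m{n}", id=f"random_toy_{spec.seed}",
    )
    return model, kcat_table, subunit_table


# --------------------------------------------------------------------------
# worked example: a large multimeric complex

#: Subunit masses (kDa) of the E. coli pyruvate dehydrogenase complex
#: components (AceE, AceF, Lpd), consistent with curated E. coli
#: complex-composition data to printed precision.
PDH_SUBUNIT_MW = {"aceE": 99.67, "aceF": 66.08, "lpd": 50.68}

#: Curated subunit stoichiometry of the assembled complex.
PDH_TRUE_STOICHIOMETRY = {"aceE": 24, "aceF": 24, "lpd": 12}


def pdh_composition(stoichiometric: bool = True) -> SubunitComposition:
    """Pyruvate dehydrogenase subunit composition.

    ``stoichiometric=True`` uses the curated 24:24:12 copy numbers of the
    assembled megacomplex (~4586 kDa); ``False`` counts one copy of each
    subunit (~216 kDa), the baseline of workflows that ignore complex
    stoichiometry.  The ~21-fold mass difference propagates directly into
    the reaction's enzyme cost.
    """
    copies = PDH_TRUE_STOICHIOMETRY if stoichiometric else {g: 1 for g in PDH_SUBUNIT_MW}
    return SubunitComposition(
        tuple((gene, copies[gene], PDH_SUBUNIT_MW[gene]) for gene in ("aceE", "aceF", "lpd"))
    )
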