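# Methods

## The model

An enzyme-constrained metabolic model extends flux balance analysis with
a single proteome-allocation row. For every catalysed, irreversible
reaction *i* with flux `v_i` (mmol·gDW⁻¹·h⁻¹), the enzyme mass tied up
is `v_i · MW_i / (σ_i · kcat_i)` in g·gDW⁻¹ (with `MW` in kDa = g/mmol
and `kcat` in h⁻¹, the units cancel to grams of enzyme per gram dry
weight). The sum over all catalysed reactions is capped by the enzyme
pool `ptot · f`:

* `ptot` — total protein per dry weight. Default 0.56 g/gDW, the
  standard macromolecular-composition value for exponentially growing
  *E. coli*.
* `f` — the fraction of that protein which is enzymes the model
  accounts for. Computed from a quantitative proteome as the
  abundance-weighted mass share of the model's gene products:
  `f = Σ_{i∈model} A_i·MW_i / Σ_{j∈proteome} A_j·MW_j`. All model genes
  are counted in the numerator, whether or not they carry flux in any
  particular simulation: the pool is a budget, not a usage report.
* `σ_i` — saturation, the usable fraction of an enzyme's nominal
  capacity in vivo. Default 1 for every reaction (overridable per
  entry), which makes the constraint deliberately optimistic: kcat
  values are in-vitro or predicted maxima, and an average saturation
  would only rescale the pool, a role `f` already plays.

The constraint is one extra LP row. The stoichiometric matrix, bounds
and objective are untouched, so every standard constraint-based analysis
applies to the enzyme-constrained model unchanged.

### Assumptions

* Steady state and a linear objective, as in FBA.
* One enzyme per (split) reaction. Isozymes are alternatives (OR in the
  gene-protein-reaction rule) and become separate reaction copies;
  complexes (AND) are single enzymes whose mass is the stoichiometric
  sum of subunit masses. Copy numbers default to 1 when the subunit
  table has no entry, reproducing the one-copy baseline of workflows
  that ignore complex stoichiometry — the difference is itself of
  interest (see the PDH example below).
* A reaction without a kcat contributes zero enzyme cost. This biases
  the model toward optimism for poorly annotated pathways; the
  alternative (median imputation) invents kinetics we do not have.
* Exchange, demand/sink and spontaneous (empty-GPR) reactions are never
  costed. Boundary reactions are detected structurally: all
  stoichiometric coefficients of one sign.

### Preprocessing

Reversible reactions are split into a forward copy and a `_reverse`
copy with negated stoichiometry (the two directions may have different
turnover numbers); purely backward reactions are flipped. Reactions
with *n* > 1 enzyme alternatives become `_num1 … _numN` copies.
Direction is split before isozymes, so a reversible two-isozyme
reaction yields ids like `R_reverse_num2`. Both transforms are
flux-equivalent; the tests assert that the plain-FBA optimum never
moves. kcat tables may be keyed by source or derived ids; a derived-id
entry (e.g. `R_reverse`) overrides the shared source value, so
direction-specific kinetics can be supplied where known.

### Parsimonious reporting

Flux vectors at the growth optimum are not unique. Every reported flux
state is therefore the **minimum-enzyme solution**: maximise growth,
pin the biomass flux (relative slack 1e-9 to absorb round-off), then
minimise total enzyme usage `E_min = Σ v·MW/(σ·kcat)`. This makes all
downstream numbers — flagged calibration sets, secretion profiles,
pathway cost decompositions — reproducible. For the fixed-growth
overflow scan the primary objective is minimum substrate uptake (ties
broken by minimum enzyme), which reduces gracefully to plain FBA when
the pool is slack; a pure minimum-enzyme mode is available as an
alternative.

### Calibration

Underestimated kcats inflate enzyme costs and throttle growth. Two
rules flag them:

1. **Usage rule** — at the parsimonious optimum, a reaction whose
   enzyme cost exceeds 1% of the pool bound. The share is taken of the
   solution-independent bound `ptot·f` rather than of the used total,
   so the flagged set does not depend on which alternate optimum the
   solver returned.
2. **Measured-flux rule** — a reaction whose catalytic capacity when
   granted 10% of the pool, `0.10 · ptot·f · σ·kcat/MW`, is below its
   experimentally measured flux. This catches enzymes the LP simply
   routes around (they carry no flux, so the usage rule never sees
   them).

Flagged kcats are raised to the reference-database maximum — never
lowered — so the constraint only relaxes and growth is monotone over
rounds. Usage rounds iterate to a fixed point (default cap 10 rounds);
the measured-flux rule then runs once. Calibration on an
already-calibrated model is a no-op.

### Analysis metrics

* estimation error `|sim − exp| / exp` per condition;
* normalized flux error `sqrt(Σ(sim−exp)² / Σexp²)` over a panel;
* biomass yield `v_biomass / (v_substrate · MW_substrate)` in gDW per g
  substrate (glucose MW constant 0.18016 g/mmol);
* enzyme usage efficiency `v_biomass / E_min` in gDW·h⁻¹ per g enzyme;
* pathway enzyme cost per ATP: summed member costs divided by the net
  ATP production `Σ (ATP coefficient)·flux` over the member reactions,
  reported per mmol·h⁻¹ by default and ×1000 when per-mol reporting is
  requested. Pathway membership is user-supplied: no universal
  fermentation/respiration partition exists across models.

## Synthetic data

`fixtures.toy_core_model` is a ~12-reaction network with a respiratory
branch (20 ATP/glucose, cost 0.005 g enzyme per unit ATP flux) and a
fermentative branch (2 ATP/glucose, cost 0.004 including the O₂-linked
re-oxidation of its NADH). Because fermentation is cheaper per ATP but
respiration is cheaper per glucose, the model reproduces the overflow
phenomenology: below the switch growth rate `P·y_r/(c_r·a)` the
minimum-uptake solution is purely respiratory; above it the unique
tight mixture secretes acetate. All such quantities have closed forms
implemented as methods on `ToyCoreParams` (by two-variable vertex
enumeration, independent of the LP solver) and the tests assert the
solver against them. The glucose transporter is reversible and the
fermentation step has two identical isozymes, so both splits are
exercised without moving any optimum.

`fixtures.random_toy_model` generates seeded, feasible, bounded chain
networks of at most 8 reactions with random stoichiometry, bounds and
kinetics, used to cross-check the scipy/HiGHS implementation against an
independently coded COBRApy/GLPK formulation of the same LP.

What the fixtures do **not** emulate: genome-scale redundancy, realistic
GPR depth, cofactor balancing beyond one NADH species, maintenance ATP,
and biomass equations with real composition. Passing tests establish
the correctness of the construction and the LP, not the biological
accuracy of any particular parameterisation; that depends on the kcat,
subunit and proteome tables supplied.

## Numerical choices

* LP solver: scipy `linprog` (HiGHS), requested feasibility/optimality
  tolerances 1e-9; test assertions use 1e-6.
* Biomass (and scan-stage) pinning uses relative slack 1e-9 rather than
  exact equality, avoiding spurious infeasibility from round-off.
* Secretion counts as overflow above 1e-6 mmol·gDW⁻¹·h⁻¹.
* "Unlimited" substrate in scans is a bound of 1e6; the min-uptake
  objective keeps the LP bounded.
* Pool-bound consistency (`pool = ptot·f`) is enforced to 1e-9 relative
  on construction and on file load.
* Infeasible scan grid points are recorded with their status, not
  raised; infeasible/unbounded optimisations return a status, never
  silent zeros.
* GPR DNF de-duplicates identical alternatives but keeps supersets: a
  complex may legitimately contain every gene of a smaller alternative.
* Ties in the complex bottleneck rule (minimal kcat/MW) go to the first
  listed candidate.

## Open design decisions

* The enzyme-constrained JSON dialect (COBRA-JSON plus one
  `"enzyme_constraint"` block) is this package's own schema; SBML has
  no standard slot for the pool constraint. Files round-trip exactly.
* When a complex has per-subunit kcat candidates,
  `effective_efficiency` picks the bottleneck (kcat, MW) pair; when the
  kcat table is keyed per reaction — the primary mode — that value is
  used with the full-complex molecular weight. Both paths are exposed.
* The usage-rule share is computed against the pool bound, not against
  used enzyme (see above); a caller can rescale the threshold if the
  other reading is wanted.
* The worked subunit example ships masses AceE 99.67, AceF 66.08,
  Lpd 50.68 kDa for pyruvate dehydrogenase: counted once each the
  complex is 216.43 kDa, at the curated 24:24:12 stoichiometry it is
  4586.16 kDa — a 21-fold difference in enzyme cost for the same
  reaction.

## Limitations

* No thermodynamic, regulatory or membrane-occupancy constraints; the
  single pool is the only proteome limit.
* kcat prediction, subunit-composition retrieval and model curation are
  out of scope: the package consumes tables.
* SBML export of the enzyme constraint is not supported (by design; the
  JSON dialect is the on-disk form).
* Alternate optima are handled by a deterministic tie-break, not
  enumerated; flux variability analysis on the enzyme-constrained model
  is left to the standard tools, which the unchanged model format
  permits.
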