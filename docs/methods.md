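# Methods

## Model and assumptions

`fluxcost` works on constraint-based metabolic models: a stoichiometric
matrix S (metabolites × reactions), per-reaction flux bounds
α_i ≤ v_i ≤ β_i in mmol·gDW⁻¹·h⁻¹, a biomass pseudo-reaction whose flux w
is the fitness proxy, and a boolean GPR rule per enzyme-catalysed reaction
(AND = complex, all subunits required; OR = isoenzymes, any one suffices).
FBA assumes steady state (S v = 0) and growth-rate maximisation; it cannot
predict fitness *gains* from deletions, so all costs are clipped below at
zero and experimental comparisons filter out mutants growing faster than
the wild type by more than two standard deviations.

Three constraint classes are layered on the model's intrinsic bounds:
irreversibility (α_i ≥ 0 where declared), the environment, and knockouts.
An environment (`Medium`) caps the import flux of selected exchange
reactions; every other exchange is export-only (v_i ≥ 0).  Exchange flux is
negative for import.  A knockout forces v_r = 0 for each disabled reaction.

### Gene deletion semantics

A deleted gene set G disables reaction r iff GPR(r) evaluates false with the
genes of G absent and all other genes present.  Two semantics are supported:

* **redundant** (standard FBA): the GPR is used as written, so an isoenzyme
  deletion with a surviving partner is free;
* **nonredundant**: every OR node is first rewritten to AND, uniformly and
  recursively, so deleting any member of an isoenzyme set disables the
  reaction.

Pair deletions evaluate the GPR *jointly* (both genes absent) rather than
taking the union of single-gene knockout sets; the joint evaluation subsumes
the union and captures isoenzyme pairs that disable a rule neither gene
disables alone.

### Cost metrics

With w_wt the wild-type optimum in a medium and w_ΔX the optimum with
reaction set X blocked (an infeasible knockout LP is reported as w = 0 —
biologically, the mutant cannot grow):

* gene-loss cost  c^GLC = (w_wt − w_ΔR)/w_wt over the necessary-reaction
  set R of the gene, clipped to [0, 1];
* function-loss cost  c^FLC = Σ_r (w_wt − w_Δr)/w_wt over every reaction r
  the gene is *associated* with (appears anywhere in the GPR), each blocked
  one at a time; c^FLC may exceed 1 for multifunctional genes.  An optional
  `max` aggregation replaces the sum with the worst single-reaction cost;
  the default is the sum;
* hybrid 1 = FLC for multifunctional genes, GLC otherwise; hybrid 2 = FLC
  for isoenzyme-associated genes, GLC otherwise.  For genes that are
  neither, all four metrics coincide exactly (asserted in tests).

A gene is *isoenzyme-associated* if it is individually sufficient to
satisfy the GPR of at least one unblocked reaction and at least one other
gene of that GPR is too.  This sufficiency definition generalises the plain
OR pair to nested rules; a lone sufficient gene (e.g. the c in
`(a and b) or c`) does not form an isoenzyme set.  A gene is
*multifunctional* if associated with ≥ 2 unblocked reactions.  Genes whose
associated reactions are all blocked are purged from every analysis.

### Blocked reactions

A reaction is blocked iff its feasible flux range is {0} (flux-variability
test, no growth requirement) under every tested medium.  The default test
set is the enumerated minimal media plus an "all-open" medium in which every
exchange imports at a large finite cap (1000); a truly unbounded all-open
medium would make the growth LP unbounded, which the solver surfaces as an
error rather than conflating it with infeasibility.

### Minimal media

Starting from a reference medium (one carbon source, one nitrogen source,
fixed secondary nutrients), alternative sources for a role are found by
substituting every other exchange reaction at the same uptake cap (default
10 mmol·gDW⁻¹·h⁻¹) and keeping those that restore wild-type growth.  The
media set is every (carbon, nitrogen) pairing passing the growth test.
Dual-role metabolites may pair with themselves (configurable); sources are
operationalised as exchange reactions, the model's only environmental
interface.

### Evolutionary rates

Per-species d_N/d_S ratios are converted to within-species ascending ranks
(average ranks on ties) over the genes with data in that species; a gene's
representative rate k̂ is the mean of its ranks across the species where it
has an ortholog.  Genes with no ortholog anywhere are excluded.  All
downstream statistics are rank-based, so any strictly monotone transform of
the raw ratios leaves results unchanged.  Correlation distributions collect
one Spearman ρ per growth-supporting medium for a metric × gene-subset
pair; media with fewer than three paired genes or zero variance are skipped
with a warning.  Within each isoenzyme set with ≥ 2 rated members, the
highest-k̂ member is labelled fast-evolving and the lowest slow-evolving
(ties and multi-set membership resolved deterministically by identifier
order / majority and logged); the `fast_iso`/`slow_iso` subsets include all
non-isoenzymes plus the labelled members, the `*_only` variants just the
labelled members.

### Epistasis

ε_ij = w_ij − w_i·w_j with w = 1 − c from the loss cost.  Predictions are
classified by magnitude alone (|ε| > 10⁻⁴ by default; FBA is
deterministic, so no p-value applies), experimental records by
|ε| > 0.08 and p < 0.05.  Comparison produces a 3 × 3 confusion matrix
(synergistic / antagonistic / none), per-class precision and recall, a
one-sided Fisher exact enrichment p per class on the collapsed 2 × 2
table, and precision/recall curves over an ε-cutoff grid
(10⁻⁴ … 10⁻², 25 logarithmic points by default).

## Numerical choices

* LP backend: GLPK (swiglpk) with bound swapping and warm-started simplex
  re-solves; scipy HiGHS as fallback.  The two agree to 10⁻⁶ on fixtures
  (tested); only the objective value is contractual — flux vectors at
  degenerate optima are not unique.
* Tolerances: |v| < 10⁻⁹ is zero flux; growth ≤ 10⁻⁶ is "no growth".
* Shortcut: blocking a reaction set whose members all carry zero flux in
  the wild-type optimum leaves that optimum feasible, so the cost is 0
  without a solve.  Loss costs are additionally memoised by blocked set, so
  a single-function gene and its reaction share one LP.
* Tiny negative costs from solver noise are clipped to 0; per-reaction
  costs are clipped to [0, 1].

## Synthetic fixtures: what they emulate and what they do not

The generator builds a linear biomass backbone fed by `n_carbon` alternative
carbon sources (each behind its own uptake reaction with a random yield in
[0.6, 1]) and `n_nitrogen` nitrogen sources, so media enumeration produces a
carbon × nitrogen grid and costs vary across media (a gene on an unused
uptake path costs nothing in that medium).  Enzymatic slots draw isoenzyme
(OR, arity 2–3), complex (AND) or single-gene rules at configured
fractions; single-gene slots occasionally reuse an existing gene
(multifunctionality), and OR slots occasionally recruit an existing
singly-mapped gene so some isoenzymes are also multifunctional — without
this, every toy isoenzyme's GLC would be identically zero and the
isoenzyme-panel correlation undefined.  Partial-capacity bypass reactions
give fractional removal costs; dead-end reactions carry genes that the
blocked-reaction purge must remove.  Defaults (200 genes, 10 × 5 sources →
50 media, 30% isoenzyme slots) are the reference simulation conditions used
by the test suite and `scripts/acceptance.py`.

Synthetic rates are k = exp(−3·burden + η), η ~ N(0, 0.5), per gene and
species (5 species, 10% missing orthologs), with burden = the gene's mean
FLC across media.  This *builds in* the cost/rate anticorrelation; passing
tests therefore show that the pipeline recovers a planted signal and that
the metrics order as expected when isoenzymes carry real functional burden
— they do not show that real genomes behave this way, nor calibrate
effect sizes.  Toy networks are chains with bypasses, not realistic
yeast-scale topologies: no cofactor coupling, no compartments, no
alternative objective functions.

## Known limitations

* Isoenzyme backup is modelled as all-or-nothing in both semantics; no
  partial, expression- or condition-dependent backup weighting.
* The GLC/FLC dichotomy ignores protein abundance and kinetics.
* MOMA-style quadratic objectives, flux sampling and thermodynamic
  constraints are out of scope.
* Essentiality calls are a simple threshold (default 0.99) on a normalized
  cost; odds-ratio comparisons against experimental essentiality require an
  external truth table that the package consumes but does not provide.
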