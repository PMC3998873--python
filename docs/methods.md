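# Methods

## Model

The package treats every metabolic reaction as an irreversible
single-substrate Michaelis–Menten (MM) system, V = Vmax·S/(K_M + S), and
works entirely in the fold-change space between a condition and a
reference. Writing the exact steady-state inversion S = K_M·V/(Vmax − V)
for both conditions and taking logs,

    ln(S/S*) = ln(V/V*) − ln(Vmax/Vmax*) + ln((1 − s*)/(1 − s)),

with saturations s = V/Vmax and s* = V*/Vmax*. Two assumptions make this
usable without kinetic parameters:

1. **Non-saturation** (V ≪ Vmax): the last term is dropped. The cost of
   this is quantified exactly below.
2. **Transcript–capacity proportionality**: the fold change of Vmax is
   replaced by the fold change of the transcript(s) encoding the enzyme,
   ln(T/T*). The robustness of downstream conclusions to gene-to-gene
   deviations from this proportionality is probed by the slope-resampling
   procedure in `stats`.

K_M cancels entirely in fold-change space as long as it is unchanged
between conditions; the optional `KineticAdjustment` re-introduces
per-reaction ln(K_M/K_M*) corrections for enzymes known to be regulated
post-translationally.

### Coupling degrees

Mass balance at steady state (total production = total consumption at
every internal metabolite) links each reaction's flux term to its
neighbors, yielding a family of scores for the natural-log fold change of
a metabolite S:

- degree 0 assumes flux homeostasis (ln V/V* = 0): score = −Δcons(S);
- degree 1 eliminates the flux term through the producer instead:
  score = Δprod(S) − Δcons(S) + ln(R/R*), the precursor term being
  omitted (assumed zero) or taken from measurements;
- higher degrees replace the unresolved ln(R/R*) recursively with the
  degree-1 relation of R (upstream expansion) and resolve the consuming
  flux through the consumers' products (downstream expansion). On an
  unbranched path the downstream expansion telescopes exactly to
  −Δcons(S) + Δcons(P_d) + ln(P_d/P_d*).

Δprod/Δcons are arithmetic means of the per-reaction Δ values in log
space (geometric means of the ratios) over the side's reactions that have
data. The side aggregates always include **all** reactions of the side,
including the one the recursion arrived through: this is what the
mass-balance substitution of the degree-1 relation produces, and the
kinetic oracle confirms it (excluding the traversed reaction leaves a
spurious producer term on chain topologies and breaks the telescoping
identity).

### Per-reaction transcript changes

Gene–protein–reaction rules are parsed into AND/OR trees and evaluated
bottom-up over the significance-filtered ln ratios: OR (isoenzymes) takes
the mean of the measured children in log space; AND (complexes) takes the
minimum of T/T* — read as the most limiting subunit. "Lowest fold
change" is ambiguous for mixtures of up- and down-regulated subunits; the
min-of-ratio reading is the default and min-|ln ratio| is available as
`complex_rule="min_abs"`. Similarly `isoenzyme_rule="arithmetic"` gives
the arithmetic-mean-of-ratios variant for sensitivity analysis.
Insignificant transcripts are treated as absent, not as ratio 1; a node
with no surviving children propagates "no data", and a metabolite is
scored only if at least one contributing reaction has data — so the
number of scoreable metabolites varies with the degree.

### Path semantics and weighting

The recursion enumerates simple paths on metabolite nodes (a metabolite
is never revisited within one path; reactions may recur across paths).
At each branch point every (reaction, neighbor-metabolite) pair is one
branch and carries weight 1/(number of branches), multiplied along the
path. This equal flux-split heuristic is the declared substitute for
unknown flux split ratios: mass balance distributes flux across branches
and no split ratios are assumed known. It is validated against the
kinetic oracle, not against any published per-metabolite value.
Measured metabolites truncate the recursion (their ln ratio is used and
the path stops). Currency metabolites (ATP/ADP/AMP, NAD(P)(H), CO2, H2O,
phosphate, H+, … — a configurable list, matched on the id stem with
compartment suffixes stripped) are never used as path-through nodes but
remain reaction participants for GPR purposes. Metabolites and reactions
are processed in lexicographic order so all outputs are byte-stable.

## Reaction directions

Scores need one functional direction per reaction. Flux variability
analysis under the measured exchange-flux bounds (and, when provided, the
measured growth rate applied as an equality bound on the biomass
reaction — chemostat growth is a measurement, not an objective) labels
each reaction per condition; blocked (|flux| ≤ 1e-6 throughout),
ambiguous (range straddles zero), and inconsistent-across-conditions
reactions are pruned, and backward reactions are flipped so flux is
positive as written. `optimality_fraction` (default 0.0, i.e. pure
feasibility) optionally enforces the classical FVA protocol of requiring
a fraction of the FBA optimum. LPs are solved with HiGHS via
`scipy.optimize.linprog`; the test suite cross-checks against GLPK
(through cobrapy) and against brute-force vertex enumeration, and results
agree within 1e-6.

## Synthetic kinetic networks (the oracle)

`kinetics_oracle` generates chain, branched, and random-DAG MM networks
with log-uniform K_M in [0.1, 10] and Vmax chosen so that baseline
saturation lies within a factor two of a target. Boundary input fluxes
are fixed and equal in both conditions. Steady states are solved by the
per-reaction closed form on single-consumer topologies and otherwise by
Newton-type root finding on log concentrations (`scipy.optimize.root`,
hybr), with mass-balance residuals verified to 1e-10. Perturbations
assign every enzyme gene a ln fold change of random sign and magnitude
uniform in [ln 2, ln 4] — the 2–4× range typical of significant
differential expression.

What the generator emulates: two-condition steady states, exact
transcript–capacity proportionality, single-substrate kinetics, known
directions, complete and noise-free measurements. What it does not:
measurement noise, multi-substrate and reversible kinetics, allosteric
and post-translational regulation, compartmentation, or changed flux
directions. Passing the oracle tests therefore demonstrates that the
scoring machinery implements the intended algebra and converges to the
truth where the model's assumptions hold exactly — not that real
transcriptome–metabolome pairs will reach such correlations.

Problem sizes used in the validation suite: 20 chain networks of 5–10
metabolites at saturation target 0.002 for score–oracle equivalence
(deeply unsaturated, so that the kinetic approximation error is
negligible relative to the 2% agreement bound being tested), and 200
repeats × 199 permutations on an 8-metabolite chain for permutation-test
calibration — small enough to run in well under a minute each while
leaving the statistical assertions meaningful.

## Approximation error surface

With the exact inversion above, the approximate prediction of the
concentration ratio is off by exactly the factor (1 − s)/(1 − s*), so the
error surface is defined as the relative error of the predicted fold
change, E(s, s*) = |s − s*| / (1 − s*). It is zero on the diagonal
(unchanged saturation, whatever the expression change), grows
monotonically with |ln((1 − s)/(1 − s*))|, and in the half-saturation
regime (s* ≈ 0.5 with a ±0.1 saturation shift) has a characteristic
(median) value of 20%. This fold-change-space normalization is the
package's definition; normalizing by the exact *ln* fold change instead
(|approx − exact|/|exact|) would make the number depend on the size of
the expression change and roughly double it in the same regime.

## Statistics

Pearson correlation (metabolite changes dependent, scores independent)
with the usual two-sided t-test on the slope; fewer than three pairs or a
zero-variance vector yield explicit "insufficient data" / "undefined"
results rather than errors. The permutation test shuffles gene labels
without replacement *before* score recomputation and reports the raw
fraction of permuted r² exceeding the observed one (a (k+1)/(n+1)
smoothed estimator is available). The robustness procedure draws a
mRNA→protein slope correction per gene from N(slope_mean, slope_sd)
(defaults 1.0 and 0.3 — literature-derived configuration defaults, not
computed in-package), rescales the ln ratios, recomputes degree-1 scores
and counts the simulations whose correlation stays significant; per-gene
(rather than per-simulation) draws are used because a single global
factor would leave the Pearson correlation unchanged. FDR control is
Benjamini–Hochberg; the positive-fraction test is the two-sided exact
binomial test against 0.5; score variants (with/without measured
neighbors) are compared by the paired Wilcoxon signed-rank test, paired
because the same metabolites are scored under both modes.

## Design choices made where the design was open

- Fold changes enter as log2 (the source-study convention) and are
  converted to natural log exactly once at ingestion.
- Measured metabolite names map to model species through an explicit
  two-column mapping file; no fuzzy matching. Compartment pooling (one
  node per species name, union of its reactions) is available behind a
  configuration flag; by default measured metabolites are taken as
  cytosolic.
- FVA direction calls default to pure feasibility rather than an
  optimality requirement, because the constraints are measurements.
- The downstream expansion resolves fluxes only through consumers'
  products (never turning back upstream through a product's other
  producers); this keeps upstream and downstream expansions acting on
  disjoint terms of the degree-1 relation and preserves the telescoping
  identity.
- SBML is written in the legacy COBRA dialect (notes-field gene
  associations, kinetic-law bounds) for maximal toolbox compatibility,
  and read in both that dialect and the modern fbc form (fbc wins when
  both are present).

## Known limitations

- Saturated enzymes (s not ≪ 1) violate the core approximation; the
  error surface quantifies the cost but the scores do not correct it.
- Post-translational and allosteric regulation are unmodelled unless
  explicit K_M adjustments are supplied; strongly affected metabolites
  can show sign-reversed scores.
- The equal flux-split weighting is a heuristic; where true splits are
  very uneven, distant contributions are mis-weighted.
- Direction assignment assumes directions are condition-invariant after
  pruning; genuinely direction-switching pathways are excluded from
  scoring rather than modelled.
- The permutation and robustness procedures recompute scores per
  iteration and are intended for the small-to-medium metabolite panels
  typical of targeted metabolomics, not for exhaustive genome-scale
  sweeps.
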