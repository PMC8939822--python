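# Methods

This note records the modelling assumptions, parameter choices and known
limitations of fluxmark, in the package's own terms.  Nothing stated here
goes beyond what the test suite and `scripts/acceptance.py` actually
compute.

## Constraint-based core

All analyses operate on a stoichiometric model with flux bounds and
boolean gene–protein–reaction (GPR) rules, held in a cobrapy `Model` and
solved with optlang/GLPK.  Conventions follow BiGG/COBRA practice:

* fluxes in mmol·gDCW⁻¹·h⁻¹; ±1000 encodes an unbounded reaction, [0, 1000]
  an irreversible one;
* exchange fluxes negative for uptake, positive for secretion; applying a
  medium sets the listed exchange lower bounds, closes uptake on all other
  exchanges and sets every exchange upper bound to 1000;
* the biomass pseudo-reaction is the objective in every simulation, and
  pseudo-reactions (exchange, demand, sink, biomass, ATP maintenance) are
  recognised from an explicit tag or from BiGG id conventions
  (`EX_`/`DM_`/`SK_` prefix, objective flag, `ATPM`).

Numerical choices: feasibility/zero-flux tolerance 10⁻⁶ throughout;
"growth fixed at g" is implemented as the band [g − 10⁻⁶, g + 10⁻⁶];
steady-state residuals ‖S·v‖∞ of reported distributions are asserted
≤ 10⁻⁶.  Remaining LP degeneracy after Manhattan-norm minimisation is
broken by the solver's deterministic pivoting over a fixed variable
order, so identical inputs reproduce identical outputs run-to-run.

The Manhattan-norm step (min ∑|v_i| with growth fixed) is posed directly
on each reaction's forward/reverse solver variables; it spans *all*
reactions, including pseudo-reactions — restricting it to internal
reactions only rescales exchange fluxes that are already pinned by the
stoichiometry at fixed growth.

## Deletion screens

A knockout set makes a reaction inactive when its GPR evaluates false
with those genes set false; orphan reactions (empty GPR) are never
disabled, and genes outside every GPR have GR ratio 1 by construction.
Thresholds: lethal GR < 10⁻⁵ (a conventional numerical-zero cutoff);
"sick" is operationalised as GR < 1 − 10⁻³, separating real growth loss
from LP noise — the qualitative notion "just below 1" needs a numeric
slack and 10⁻³ is well above solver tolerance.  Double deletions are
enumerated over unordered pairs only; pairs containing a single-lethal
gene inherit GR 0 without re-solving (GR is monotone under additional
deletions).

Summary ratios: growth-related singles (lethal + sick, with the
lethal-only variant reported alongside, since published comparison tables
rarely say which is meant) over n; growth-related pairs over n², counting
pairs with GR < 1 − 10⁻³ whose effect is not already implied by a
single-lethal member (configurable); "interacting" genes are members of
at least one pair with GR(pair) < min(GR_i, GR_j) − 10⁻³ — an explicit
epistasis rule chosen here because the notion has no standard numeric
definition.

## Expression integration

**GIMME.** Reaction-level expression from the GPR: min over AND, max over
OR (the standard mapping for enzyme complexes vs isozymes).  The
low-expression threshold is the 25th percentile (linear interpolation) of
the profile's gene levels; the inconsistency LP minimises
∑(threshold − expr_i)·|v_i| over below-threshold reactions subject to
growth ≥ 0.9 × maximal growth, and below-threshold reactions with zero
flux in that solution are removed.  Genes present in the model but absent
from a profile count as above threshold (absence of evidence does not
delete reactions); both the percentile and the growth fraction are
configurable.

**TRFBA.** On a model made irreversible (reversible reactions split into
forward/backward halves) and OR-free (each top-level OR branch becomes a
parallel reaction copy; nested rules are first normalised to disjunctive
form, with a configurable 32-conjunct cap against pathological blow-up),
one constraint per measured gene j bounds the summed flux of its
supported reactions: ∑_{i∈K_j} v_i ≤ E_j·C.  C converts expression units
to flux units (mmol·gDCW⁻¹·h⁻¹ per expression unit).

**C_brk and the sweep.** C_brk is the smallest C at which constrained
growth reaches the C-unconstrained maximum (within 10⁻⁶), located by
doubling then bisection to a relative tolerance of 10⁻³, with a search
error beyond C = 10⁹.  The sweep evaluates the nine interior points
0.1·C_brk … 0.9·C_brk: the printed step rule ("0 to C_brk in steps of
0.1·C_brk") would produce eleven grid points, but nine distributions per
line is the harder structural constraint and C = 0 (no flux through any
measured gene's reactions) and C = C_brk (the unconstrained optimum) are
the two degenerate endpoints, so the interior grid is used.  Each point
maximises growth, then minimises the Manhattan norm at that growth;
fluxes are folded back to the source reaction ids (OR copies summed,
directions differenced), where they again satisfy S·v = 0 to 10⁻⁶.
GIMME → TRFBA are chained per cell line in that order, each line using
its own threshold.

## Biomarker selection and PCA

Per line, Pearson r between each reaction's flux series and the growth
series across the (≥ 3) feasible sweep points; p-values from the t
statistic with n − 2 degrees of freedom; constant series are excluded
(r undefined).  Selection uses the *signed* threshold r > 0.9 with
p ≤ 0.05 — the literal reading of "coefficient more than 0.9" — and an
absolute-value mode is available as a flag.  The candidate set is the
intersection across lines (empty intersection warns and yields an empty
report).

PCA rows are the feasible sweep points of all lines over the common
reactions.  Rows are divided by their growth rate by default ("flux per
unit growth"): the sweep's shared growth axis otherwise dominates the
variance and carries no between-line information; raw-flux mode is kept
as an option.  Columns are mean-centred but not variance-scaled (all
share flux units; scaling is configurable).  All min(n_obs, n_react)
components are kept so variance fractions sum to 1; component signs are
fixed by making the largest-magnitude loading positive; "top reactions"
per component are those with |loading| above a configurable quantile
(default 0.75) — a quantile because any fixed absolute cutoff would be
scale-dependent.

## Synthetic study conditions

The generator builds, deterministically from a seed, the desk-scale
analogue of a compartmentalised GEM: by default 4 linear pathways × 5
internal steps (≈ 30 reactions, 2 compartments), each pathway importing a
dedicated nutrient (uptake bound −10) and feeding one of 2 shared biomass
precursors; pathway p feeds precursor min(p, K−1), so the first precursor
has a sole producing route and the last pools the remaining (redundant)
routes.  Feature placement (2 isozyme OR-steps, 1 orphan step, one
AND-complex step per pathway) is drawn from a single seeded NumPy
generator.  Ground truth — essential genes (blockers of sole routes),
synthetic-lethal pairs (isozyme pairs on sole routes; cross-route blocker
pairs when a precursor has exactly two routes), per-pathway gene and
reaction sets — is derived from the construction, never from an LP.

Two deliberate design features make the pipeline's outputs informative on
this toy:

* **Distinct route yields.** Pathway p's final step has precursor yield
  1 − 0.05·p.  With identical yields the Manhattan-norm LP is exactly
  degenerate in how it splits flux across redundant routes and the
  "context-specific flux program" would be a solver artifact; distinct
  yields make the optimum unique.
* **Rate-limiting redundant precursor.** Default expression programs give
  sole-route pathways a high multiplier (×6) in every line and vary only
  the redundant routes (×1.5 up-weight cycling across lines, +0.5 per
  cycle).  The redundant precursor is then the growth bottleneck
  throughout the sweep, every redundant route runs exactly at its TRFBA
  cap E_r·C, and the flux vectors inherit the expression program — which
  is what gives the deletion screens, sweeps and PCA a known answer.
  Gene levels are base 100 × pathway multiplier, plus optional Gaussian
  noise truncated at zero (default noise_sd = 0: the reference conditions
  are noise-free).

What the toy does **not** emulate: realistic expression distributions,
mass/charge balance, maintenance ATP costs, medium composition of any
real culture, or the scale of a genome-scale model (thousands of
reactions, extensive reversibility, deep GPR nesting).  Passing tests
demonstrate the algorithms' correctness and determinism, not predictive
validity on real transcriptomes.

## Problem sizes

Default analyses are sized for interactive use: the toy screen solves
≤ n + n² /2 small LPs (n ≈ 30 genes), each sweep ≈ 40 LPs including the
C_brk bisection, and the full 4-line panel completes in about a second;
the brute-force LP oracle in the tests enumerates basic solutions only
for models of ≤ 8 reactions.  The same code paths run unchanged on a
genome-scale SBML model, where a single-gene screen is minutes and a
full double-gene screen (≈ n²/2 LPs) is hours.

## Known limitations

* The double-deletion "growth-related pair" numerator and the epistasis
  rule are declared conventions (see above); comparisons against tables
  computed with other conventions can differ.
* GIMME keeps orphan reactions regardless of neighbourhood expression —
  there is no evidence to remove them — so an expression-silenced pathway
  retains its orphan steps.
* `find_c_brk` assumes growth is non-decreasing in C (true by LP
  relaxation) and saturates below C = 10⁹; profiles that never saturate
  (e.g. all-zero expression on an essential gene) raise a search error.
* The PCA growth-normalisation drops zero-growth sweep points (no flux
  program to normalise).
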