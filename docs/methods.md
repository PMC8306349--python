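# Methods

This note documents the statistical machinery in `mealnet`, its assumptions,
the defaults that matter, and the places where a design choice was genuinely
open.

## Unit of analysis

The unit of observation is the *eating occasion* (meal): one participant-labeled
intake event on one recall day. Occasion labels are normalized to the four
analysis meal types — breakfast, lunch, dinner (absorbing "supper"), snack —
under a configurable policy. The defaults for labels outside those four are
brunch → lunch, just-a-drink → snack, just-a-supplement → dropped; these are
explicit package conventions (recall instruments differ in how such occasions
are used downstream), kept overridable in the occasion policy so users can
match their own protocol. Multiple snack occasions on one recall day stay
separate meals, and all meals are treated as independent observations when
networks are fitted; the ICC module (below) quantifies how much that
independence assumption is strained by participant-level clustering.

Recall days totalling under 600 kcal are excluded as implausible; days over
4500 kcal are retained but flagged for review (pregnancy raises energy
requirements, so a high upper screen with retention is used). Both bounds are
strict and configurable.

## Diet-quality scoring and stratification

Diet quality is a 13-component, energy-adjusted index (9 adequacy + 4
moderation components, maximum 100). Component scores are linear between a
zero-point density and a full-point density, clipped at both ends; moderation
components run downward (lower density is better). Scoring standards are
**not** hard-coded: they are a required configuration table, and the shipped
`hei2015_standards_example.yaml` is labeled an example to be verified against
official documentation before substantive use. Densities are computed on
*pooled* intake — component amounts and energy summed over all of a
participant's plausible recalls, then divided — rather than averaging
per-recall scores; the two orders of operations genuinely differ and the
pooled (per-person) convention is the one implemented and tested.

Participants are ranked by total score and split into tertiles as evenly as
possible; when n is not divisible by 3 the extra members go to the low, then
the mid tertile, with ties broken by participant ID. Both conventions are
arbitrary but fixed, for determinism. Networks and ICCs are computed for the
low and high tertiles.

## Network estimation

Meal-level gram intake is zero-inflated and heavily skewed, so networks are
fitted with a semiparametric Gaussian copula graphical model: pairwise
Spearman rank correlation (midranks for the massive ties at zero; Kendall
tau-b available as an option) is mapped to a latent Gaussian correlation by
the sine transforms r = 2·sin(π·ρs/6) and r = sin(π·τ/2), which are exact
under a Gaussian copula and invariant to strictly increasing marginal
transforms. The transformed matrix need not be positive semidefinite;
eigenvalues are clipped at 1e−6 and the matrix rescaled to unit diagonal
(iterated until the floor holds). The graphical lasso then maximizes
logdet Θ − tr(RΘ) − λ·Σ_{i≠j}|Θ_ij|, penalizing off-diagonals only; the
solver is scikit-learn's coordinate descent with a tightened inner tolerance
(the default inner tolerance leaves ~1e−3 elementwise error on small
problems; tests verify ≤1e−4 agreement with a direct convex solve of the
box-constrained dual). Edges are nonzero off-diagonal partial correlations
p̂_ij = −Θ̂_ij/√(Θ̂_ii Θ̂_jj), with a 1e−8 floor guarding float noise.

Before fitting, food groups consumed in fewer than 5% of the network's meals
are excluded (strictly fewer: exactly 5% is retained), which prevents
episodically co-consumed rare foods from dominating the rank correlations.

The penalty λ is chosen by 5-fold cross-validation at the meal level
(participant-level folding is available for sensitivity analysis): for each
candidate λ the model is fitted on the training folds' sine-transformed rank
correlation and scored by held-out Gaussian log-likelihood
logdet Θ̂ − tr(S_test Θ̂) against the held-out fold's correlation, with exact
ties resolved toward the larger (sparser) λ. The default grid is 9 log-spaced
points on [0.01, 1]; penalties below 0.01 are both slow to solve and never
competitive for matrices of 25–40 food groups at a few hundred meals, but the
grid is fully configurable. Inside the CV loop the solver runs at a looser
tolerance (1e−4, 100 iterations) than the final fit — only the likelihood
*ranking* matters there — and a candidate λ whose subproblem is numerically
infeasible on a near-singular fold simply loses the comparison.

**Known limitation.** Held-out-likelihood CV is prediction-optimal, not
selection-consistent: on synthetic data with planted sparse structure the CV
curve is nearly flat across weak penalties and the argmax lands well below
the support-recovery-optimal λ, so the fitted network carries many weak
spurious edges (recall of true edges is essentially perfect; precision is
not). This is a property of the selection rule, not the solver — at a fixed
penalty above the noise level the same machinery recovers planted supports
exactly, and the package's recovery tests are structured accordingly. A
glmnet-style one-standard-error rule is exposed for users who prefer sparser
networks (`cv_select_lambda(..., rule="1se")` ... see below), but the default
follows the maximum-likelihood convention. Edge lists should therefore be
read with edge weight in mind: weak edges near the penalty boundary are the
first suspects.

Trimester-specific networks reuse the pooled meal's λ (no new CV), re-apply
the 5% filter to that trimester's meals, and skip trimesters with fewer than
20 meals.

## Communities and node roles

Community detection runs Louvain (resolution 1, seeded) on the graph whose
edge weights are |p̂_ij|, with the partial-correlation sign retained as an
edge attribute. Only communities of at least two food groups are reported;
singleton nodes are listed separately as conditionally independent.
Modularity is weighted Newman–Girvan, computed by an in-package routine that
doubles as the self-consistency check on the Louvain output.

Node roles use the within-community degree z-score (WC) and participation
coefficient (PC). Both use binary link counts by default — the classical
cartography convention — with a weighted-strength variant exposed as an
option. WC standardizes a node's internal link count over its community with
the population standard deviation, and is 0 by convention when the
community's internal degrees are constant. PC = 1 − Σ_s (κ_is/k_i)², 0 for
isolated nodes. The role bands: hubs are WC ≥ 1.0, split by PC ≤ 0.30
(provincial), ≤ 0.75 (connector), > 0.75 (kinless); non-hubs by PC ≤ 0.05
(ultra-peripheral), ≤ 0.62 (peripheral), < 0.80 (connector), ≥ 0.80
(kinless). The published non-hub bands overlap at exactly PC = 0.80; the
package resolves that point as kinless, a documented tie rule exercised by a
boundary-grid test.

Communities of similar composition in the two strata share a number via
greedy maximum-Jaccard matching (threshold 0.25, deterministic tie-breaks,
symmetric in argument order); unmatched communities get fresh numbers.

## Variance decomposition (ICC)

Per food group, intake variance is decomposed with random-intercept models
estimated by REML: a three-level model with participant and meal-type
components (ICC_mealtype = σ²_m/(σ²_p+σ²_m+σ²_e), the share of intake
variation explained by which meal the food is eaten at), and a two-level
model per meal type (ICC = σ²_u/(σ²_u+σ²_e), between-participant share).
Meal type enters as a crossed random classification by default; with only
four levels this component is weakly identified and should be read
descriptively (a participant-nested variant is available). Intake is modeled
on the observed gram scale including zeros; `log1p` is exposed for
sensitivity. Groups below the 5% prevalence threshold in a stratum (or in a
meal type, for the two-level cells) are omitted from that table. ICC > 0.30
(strict) is flagged: at that level a node in the corresponding network is
driven by a subset of habitual consumers rather than the stratum as a whole.

The REML objective is profiled over the residual variance and maximized over
the variance ratios γ_r = σ²_r/σ²_e ≥ 0; the Woodbury identity reduces each
evaluation to a q×q Cholesky (q = number of random-effect levels), making
hundreds of fits cheap. The one-ratio problem uses a high-precision bounded
scalar search; the two-ratio problem uses bound-constrained quasi-Newton from
three starts followed by cyclic scalar polish, with explicit checks of the
γ = 0 boundaries. On balanced designs the estimates coincide with closed-form
ANOVA variance components to ~1e−8, which is the test oracle; an independent
mixed-model implementation is cross-checked on unbalanced data.

## Prevalence comparison

Node prevalence (share of meals at which a group is consumed, the node-size
quantity) is compared between strata per food group and meal type with a
Pearson chi-square test on the 2×2 consumed-by-stratum table, no continuity
correction by default (Yates is a flag), meal counts as denominators
(participant-level denominators are an option). Tests with an empty margin
are reported as NA. No multiple-testing adjustment is applied by default,
matching single-test α = 0.05 usage; Benjamini–Hochberg is exposed as an
option.

## Synthetic cohort generator

The generator exists so the full pipeline is testable end-to-end with known
truth. Per (meal type × stratum) it plants a sparse precision matrix with
unit diagonal — so the planted partial correlation is simply −Θ*_ij — with
~6% of pairs active at magnitudes 0.25–0.45 and diagonal inflation (followed
by rescaling) only if the draw is not positive definite. Consumption is a
latent-Gaussian single hurdle: a meal's latent vector is
Z = √ρ_b·U_participant + √(1−ρ_b)·ε with ε ~ N(0, Σ*), group g is consumed
iff Z_g > τ_g (τ matched to a target prevalence decaying geometrically from
0.6 to 0.03 across the 40 groups, so a realistic share of groups sits near
the 5% filter), and the amount is exp(μ_g + σ_g Z_g) grams. One latent
correlation therefore governs both occurrence and amount — exactly the
structure the copula estimator can partially observe — and the
equicorrelated participant term makes the latent two-level ICC equal ρ_b by
construction (default 0.2, consistent with the mostly-low between-participant
ICCs such cohorts show).

Cohort-scale defaults: 120 participants per stratum (low/mid/high, each with
its own planted model; networks are analyzed for low and high), up to three
recall days each (P(1,2,3 recalls) = 0.1/0.2/0.7, one per trimester), three
main meals plus 0–2 snacks per day, dinners labeled "supper" 30% of the time
and snacks "just a drink" 5% of the time to exercise label normalization, 2%
of recall days rescaled to 300–500 kcal to exercise the energy screen, and
amount/energy scales (μ = 3.9 log-grams, σ = 0.6, 0.85 kcal/g) calibrated so
daily totals centre near 2600 kcal. The generator also emits a per-recall
component-amounts table constructed to reproduce each participant's planted
diet-quality total exactly under pooled scoring, with stratum score ranges
disjoint, so tertile assignment recovers the planted strata and the whole
scoring path is exercised rather than bypassed. Everything is driven by one
seeded generator in fixed order: identical seed and config give
byte-identical output tables.

What the generator does **not** emulate: real food-code systems, seasonal or
day-of-week structure, energy-density heterogeneity across foods, reporting
error, or any missingness beyond varying recall counts. Passing recovery
tests therefore show the estimators work under the model's own assumptions
(copula + hurdle + equicorrelated clustering), not that real recall data
satisfy them.

## Numerical conventions

- PSD repair floor 1e−6; glasso outer tolerance 1e−5 (inner 1e−9), 500
  iterations, non-convergence warns; edge floor |p̂| < 1e−8.
- CV: 5 folds, seeded meal-level assignment, looser in-loop solver settings,
  exact ties toward larger λ.
- Louvain seed fixed (0) by default; community numbering by decreasing size
  with lexicographic tie-break.
- REML: variance ratios bounded in [0, 1e6]; scalar searches at xatol 1e−12;
  residual invariance of ICCs across shifts/scales holds to ~1e−5
  (optimizer termination noise).
- Test problem sizes (e.g., 25–40 synthetic participants per stratum for
  end-to-end checks, n = 4000 meals for recovery experiments) were chosen to
  make the relevant Monte-Carlo error small relative to the tolerance being
  asserted while keeping the default suite quick to run.
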