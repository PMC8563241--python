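# Methods

## Model and assumptions

The package fits the univariate additive + dominance animal model per age,

    y = Xβ + Za + Wd + ε,
    a ~ N(0, A σa²),  d ~ N(0, D σd²),  ε ~ N(0, I σε²),

to body weight of a two-line terminal cross. Each age is fitted as an
independent univariate model; no repeatability or multivariate structure
across ages is used, and no maternal genetic or maternal-environment
effects are modelled. Fixed effects are categorical sex and hatch date
with first-level reference coding (level order = order of first
appearance). When the response is crossbred body weight, the recommended
usage (and the CLI default) fits the model to the cross's records only;
parental lines still contribute through the pedigree and receive BLUPs.
Fitting records from several lines at once is supported but assumes the
lines share a common mean apart from the modelled fixed effects — a
genetic-group mean difference (e.g. heterosis) that is not in `X` will
otherwise distort the variance components.

## Relationship matrices

`A` is built by the tabular (recursive) method on a parents-first ordering:
`a_ii = 1 + ½ a(s_i, d_i)` and `a_ij = ½(a(j, s_i) + a(j, d_i))`, with
unknown parents contributing zero. Founders are therefore assumed
unrelated and non-inbred (standard base-population assumption). Parents
referenced but not listed are rejected rather than silently created;
`read_pedigree(..., add_missing_founders=True)` (CLI
`--add-missing-founders`) opts into auto-creation. Identifiers are
compared as whitespace-trimmed strings without case folding.

`D` uses the classical non-inbred dominance relationship
`d_ij = ¼(a(s_i,s_j)a(d_i,d_j) + a(s_i,d_j)a(d_i,s_j))` with the diagonal
fixed at 1 and zero off-diagonals for animals with an unknown parent.
Inbreeding is deliberately ignored in `D`, matching standard
animal-breeding software. This formula equals the true double-IBD
probability only in the absence of related matings: for the offspring of a
full-sib mating, gene-dropping shows the true probability differs
substantially. The gene-dropping Monte-Carlo estimator
(`gene_drop_relationships`) is provided as an independent oracle and the
equivalence tests use random non-inbred two-lineage cross pedigrees, where
the formula is exact — which is also the structure of the study design
itself. Matrices are dense; at the desk scales used here (≤ ~5000
animals) direct Cholesky factorisation and inversion are adequate, so no
sparse inverse construction (Henderson/Quaas rules) is implemented.
Lower-triangle triplet CSV export is available at any size.

## REML estimation

Variance components are estimated by maximising the restricted
log-likelihood

    ℓ_R = −½ [ (n−p) log 2π + log|V| + log|X'V⁻¹X| + y'Py ],

with `V = σa² ZAZ' + σd² WDW' + σε² I`. The first three iterations are
EM updates (`σk²* = σk² + σk⁴/q_k (y'P V_k P y − tr(P V_k))`), which
guarantee ascent; thereafter an average-information (AI) Newton step is
attempted with up to five step-halvings and is accepted only if it does
not decrease ℓ_R, falling back to EM otherwise. By construction the
recorded likelihood trace is non-decreasing (slack 1e−10); if no
admissible ascent step remains the iteration stops. Components are kept
non-negative by projection; a component at zero for three consecutive
iterations is fixed there and removed from the update set, which is how
exact-zero dominance variances at early ages arise. Convergence requires
relative component change < `tol` (default 1e−8) **and** |Δℓ_R| < 1e−6;
hitting `max_iter` (default 200) returns `converged=False` rather than
raising. Standard errors come from the inverse AI matrix over the free
components at the optimum; the SE of h² uses the delta method on that
inverse (the components pinned at zero contribute zero SE). Initial
values default to an equal three-way split of the OLS residual variance.

Cholesky factorisations add a diagonal jitter of 1e−10 × mean diagonal,
escalating by factors of 10 on failure; all numerics are deterministic
given the inputs.

`h² = σa²/σp²`, `σd²/σp²` and `σp² = σa²+σd²+σε²` are derived exactly;
two-decimal rounding happens only in the report layer
(`GeneticParameters.round`, `fit_report`). With σp² = 0 the ratios are
reported as missing.

## BLUP

Henderson's mixed-model equations are solved densely with the variance
ratios σε²/σa² and σε²/σd² added to the A⁻¹ and D⁻¹ blocks; a random
effect with zero variance is dropped from the equations and its BLUP
vector returned as exact zeros. The normal-equation residual norm is
reported and is < 1e−8 in all tested configurations. `solve_mme` requires
σε² > 0; the `AdditiveDominanceResults.mme` accessor additionally handles
the σε² = 0 boundary (which genuinely occurs when genetic variance
dominates) by solving with a vanishing residual ridge of 1e−8 σp². As
the genetic variances shrink to zero the BLUPs vanish and the fixed-effect
solution reduces to OLS — the limit used as an oracle in the tests.

## Heterosis

`H% = 100 (LSM_cross − MP)/MP` with `MP` the average of the two parental
line LSMs. An LSM is computed by fitting an additive fixed-effects linear
model (sex + hatch) within the line and averaging the cell predictions
with equal weight over the *observed* fixed-factor level combinations
(classical LSMEANS over observed margins). Whether pooled-sex or
sex-averaged means are "the" convention is genuinely open; the unweighted
observed-margin average is the documented choice here. A missing line LSM
(no records at that age) propagates to a missing H% — no imputation —
reproducing the unidentified-parents gap in the motivating study's week-2
row. An LSM from a single record equals that record with a missing SE.

## Association and correlation

`genotype_effect` fits `value ~ genotype + sex` by OLS (hatch can be added
as an extra factor; the motivating analysis states only that sex was
fixed), reports the genotype F-test against the sex-only reduction, and
adjusted genotype means (predictions averaged equally over observed
covariate levels). Pairwise comparisons use the Tukey–Kramer studentized
range with the unequal-n standard error √(MSE/2 (1/nᵢ + 1/nⱼ)) — group
sizes in such designs are unbalanced — at α = 0.05 (`p ≤ α` significant),
with no multiple-testing correction across ages or traits. For two
balanced groups this reduces exactly to the pooled t-test (q = t√2).
Letters are built by the insert-and-absorb sweep: start from one column
holding all groups, split columns on each significant pair, absorb subset
columns, and label columns in order of their best member's mean; the
display is invariant to genotype relabelling. With all values identical
the comparison degenerates to p = 1 and a single shared letter.
Normalised-expression comparisons reuse the same routine on externally
supplied expression values; computing normalisation from raw qPCR signal
is out of scope. `pearson_correlation` is the standard product-moment r
with a two-sided t-based p, requiring ≥ 3 complete pairs; zero variance
leaves r missing.

## Synthetic data

The generator emulates the study design: founders of the sire line (LK)
and dam line (SUT), optional within-line generations, and a terminal
LK-male × SUT-female cross producing KR offspring. Defaults are the study
conditions: 150 LK and 300 SUT founders yielding 600 cross offspring
(study: 613), week-6 variance components (σa², σd², σε²) =
(14250.04, 3314.70, 712.57) g², baseline μ = 572.36 g with a +143.09 g
cross offset (true midparent heterosis 25%, the study's week-6 value),
sex effects ±40 g and four hatch groups within ±15 g (mean-zero within
factor so line means are not shifted), and founder marker-genotype
frequencies from the study's mating groups (*GH*: LK 13:48
A1A1:A3A3, SUT 57:34; *IGF-I*: LK 18:63 AC:CC, SUT 143:25 AA:CC).
Founders alternate sex within line so parental-line records carry both
sexes (otherwise sex would be confounded with line in the heterosis LSMs);
each dam is mated once and sires are reused round-robin, giving the
full-sib/half-sib structure that makes σa² and σd² jointly identifiable.
Sex alternates deterministically and hatch cycles in pairs, keeping sex
and hatch unconfounded. Marker transmission is Mendelian; marker loci
have zero phenotypic effect by default (null calibration), with optional
per-genotype effects.

Additive effects are drawn from N(0, A σa²) and dominance deviations
directly from N(0, D σd²) via jittered Cholesky — exactly the covariance
the analysis model assumes, making parameter recovery a clean end-to-end
test. The generator therefore does **not** emulate: multi-locus genotypic
dominance (directional dominance, inbreeding depression), genetic
correlations across ages (each age is drawn independently), maternal
effects, genotype-correlated environments, or selection; passing tests
show the estimation machinery is correct under the model's own
assumptions, not that real chicken data satisfy them. Sex and hatch are
simulated independent of genotype. The study's reported record counts are
mutually inconsistent and are not matched; the dam line's internal
composite history is not modelled. All outputs are bit-reproducible from
`SimulationConfig.seed` through a single random stream.

## Problem sizes in the test suite

The oracle-equivalence tests use 25 random pedigrees of 15–60 animals with
100 000 gene-dropping replicates each; agreement is asserted entrywise on
the 3-Monte-Carlo-SE scale with a family-wise bound across the ~10⁴
stochastic entries (at 3 SE exactly, ~0.27% chance exceedances are
expected, so the literal per-entry bound would fail spuriously).
Parameter recovery runs 40 replicates of a 1500-record design (22 sires,
104 dams, 12 offspring per mating, truth (100, 40, 60) g²) — 40 rather
than the minimum 20 because the Monte-Carlo SD of the replicate mean for
σd² (~19 g² per replicate) must sit well inside the 10% bias band.
Heterosis recovery uses one 5000-animal simulation compared against an
analytic Monte-Carlo SE computed from the exact covariance of the three
line means; F-test calibration uses 1000 null replicates of n = 60.

## Known limitations

- The motivating study's text ("heritability varied from 0.53 to 1.00")
  disagrees with its own parameter table (0.32–1.00); the table is taken
  as authoritative throughout.
- Week-0-style boundary fits (σε² = 0, h² = 1) are genuine REML boundary
  solutions and are reported as such, not special-cased away; printed
  dominance values of order 10⁻⁶ at early ages are the corresponding
  near-zero BLUPs under σd² ≈ 0.
- Two of the published per-age totals differ from their component sums by
  one unit in the last decimal (printed rounding); derived-parameter
  checks allow ±0.02 there.
- The dominance relationship ignores inbreeding; with related matings the
  D matrix is an approximation to the true double-IBD probabilities.
- Epistatic components, genomic relationship matrices, Bayesian variance
  estimation and SEs of individual BLUPs are out of scope.
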