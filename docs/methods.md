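# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want to
know.

## Data model

The canonical in-memory container is a long pandas DataFrame with one row
per (plot, trait) observation: `genotype, release_year, year, location,
management, replicate, row, col, trait, value`. A *growing condition* is
one year × location × management combination, keyed `"2015/GGE/HN_WF_RF"`;
it is the environmental unit of every analysis. Management codes join
three treatment levels — nitrogen `HN`/`LN` (220/110 kg N/ha), fungicide
`WF`/`NF`, water `RF`/`IR`/`RO` — and only the nine combinations realised
in the trial network parse as valid. Trait names are controlled by a
registry (`data/trait_registry.yaml`: name, source, unit, nonnegativity,
disease flag) that users can extend at run time. Wide per-plot CSVs are
pivoted to this long form on input; arbitrary source headers are absorbed
by a column map, since deposited files rarely share header conventions.

## Quality control

Two rules, applied at plot level (the only level where a negative raw
value can exist):

1. **Range recoding.** Values outside a trait's valid interval, and any
   negative value of a nonnegative trait, are recoded to missing — never
   deleted, so the plot record and its other traits survive. Shipped
   defaults: grain yield ≤ 3000 dt/ha, thousand-grain weight ≤ 80 g.
   Observed trait ranges are deliberately *not* used as rules; they
   describe data, not physics.
2. **±k sd screen.** Within each (growing condition, trait) group, an
   observation beyond mean ± k·sd is excluded (dropped). Defaults: k = 4,
   applied only to harvest index and spike number — the two ratio/count
   traits whose measurement process produces sporadic gross errors.
   The sd is the sample standard deviation (n−1); groups with fewer than
   3 values are skipped. Note an arithmetic consequence: with n values
   the largest attainable standardized deviation is (n−1)/√n, so a single
   outlier cannot be flagged at k = 4 in groups smaller than ~19 — the
   screen is meant for condition-level groups with hundreds of plots.

**TFI** is the plain sum of the six fungal infection scores, assuming
infected areas are additive. Default policy: missing if any component is
missing; a sum-of-available mode exists for sparse disease scoring.

## BLUEs (per trait × growing condition)

Model: `y_irc = μ + g_i + R_r + C_c + e`, cultivar fixed, row and column
random intercepts (two independent, crossed variance components — there is
no block term because replicate blocks occupy row bands and are absorbed
by the row effects). The reported BLUE is the estimated marginal mean
μ̂ + ĝ_i on the observation scale.

Estimation is REML, profiled over the fixed effects and the residual
variance, leaving a 2-dimensional optimisation over the variance ratios
(σ²_row/σ²_e, σ²_col/σ²_e) on the log scale (Nelder–Mead, fatol 1e-8).
Because the random structure has only `n_rows + n_cols` levels, each
likelihood evaluation reduces via the Woodbury identity to dense solves of
size q ≈ 40 and p = number of cultivars, making a 220-cultivar condition a
few tens of milliseconds — the whole 45-condition × 8-trait table fits in
about a minute. After optimisation the three boundary candidates (either
or both components zero) are also evaluated and the best kept, so a zero
variance component is returned exactly and the fit then coincides with
ordinary genotype means. The implementation is cross-checked in the test
suite against `statsmodels` MixedLM (variance components and BLUEs agree
on random instances).

Fallbacks, flagged `fallback="means"` rather than raised: row/column
missing for more than half the plots, a degenerate grid (fewer than two
rows or columns, or no residual degrees of freedom), or a failed REML fit.
The pipeline must survive the unbalanced network; a condition without
usable layout still yields per-cultivar arithmetic means.

## Trait consistency (R²_sma)

For a trait and two growing conditions, the cultivar BLUEs shared by both
are fitted with a standardized major axis line — slope sign(r)·s_y/s_x —
appropriate because neither condition is "the cause" of the other and both
carry error. Its coefficient of determination equals the squared Pearson
correlation; the SMA slope/intercept are reported for completeness. Pairs
are unordered: k eligible conditions give C(k,2) pairs (45 conditions →
990), each with at least 3 shared cultivars.

Grouping assigns a pair to a level only when *both* its conditions share
that level on every fixed factor (e.g. grouping by management keeps pairs
of equal management and any year/location; management–location grouping
keeps pairs differing in year alone). Level means are compared by one-way
ANOVA; when p < α = 0.05, unprotected Fisher LSD pairwise t-tests use the
pooled within-group mean square, rendered as a compact letter display
(duplicate-and-absorb over significant pairs, levels ordered by
descending mean, ties broken by name). The LSD is deliberately not
multiplicity-adjusted beyond the ANOVA gate — that is the stated
procedure being implemented, not an oversight.

## Breeding progress

BP of a trait in one condition is the OLS slope of cultivar BLUE on year
of release (units: trait units per year), with its two-sided p-value;
estimable when release years vary and n ≥ 3. The second stage treats
growing conditions as observations and regresses BP of yield on BP of
five component traits (thousand-grain weight, harvest index, straw mass,
grains per spike, spike number), unweighted — weighting by the first-stage
standard errors is a documented option, off by default, since the plain
procedure uses the slopes as data. Grouping by a single factor fits one
model per level plus the pooled "all" model; levels with fewer than p + 2
conditions are skipped, constant regressor columns are dropped with a
warning. Stars follow the 0.05/0.01/0.001 convention.

## Stability indices

Given the complete-case genotype × environment BLUE matrix `x_ij` (row
means x̄_i., column means x̄_.j, grand mean x̄_.., environmental index
e_j = x̄_.j − x̄_..):

* `S²_xi = Σ_j (x_ij − x̄_i.)² / (E−1)` — environmental variance (Römer);
* `b_i = Σ_j (x_ij − x̄_i.) e_j / Σ_j e_j²` — Finlay–Wilkinson regression;
* `s²_di = Σ_j (x_ij − x̄_i. − b_i e_j)² / (E−2)` — Eberhart–Russell
  deviation mean squares, *without* the plot-error correction term
  (−σ²_e/r): the inputs are BLUEs, not raw replicates;
* `r²_i = b_i² Σ_j e_j² / Σ_j (x_ij − x̄_i.)²` — Pinthus;
* `W_i = Σ_j (x_ij − x̄_i. − x̄_.j + x̄_..)²` — Wricke ecovalence;
* `σ²_i = [G(G−1)W_i − Σ_k W_k] / [(G−1)(G−2)(E−1)]` — Shukla;
* `D²_i = Σ_j (x_ij − x̄_i. − b_min e_j)²`, b_min = min_k b_k — Hanson;
* `P_i = Σ_j (x_ij − M_j)² / (2E)`, M_j the environment maximum —
  Lin–Binns superiority;
* `S⁴_i = Σ_j (rank_ij − rank̄_i.)² / (E−1)` on corrected values
  x_ij − x̄_i. + x̄_.. ranked within environments (mean ranks for ties) —
  Nassar–Hühn corrected-rank variance. Superscript conventions for the
  Hühn family vary in the literature; the corrected-rank *variance* is
  what is implemented, and documented as such.

Exact identities asserted in the tests: Σ_i W_i equals the interaction sum
of squares, mean_i b_i = 1, mean_i σ²_i equals the interaction mean
square. Orientation metadata (`INDEX_DIRECTION`) records that small
values mean stable for all indices except b_i (near 1 = average
responsiveness) and r²_i (near 1 = dynamic stability). Degenerate edges:
E = 2 leaves s²_di undefined, G = 2 leaves σ²_i undefined (reported
missing, not raised).

The stability regression treats genotypes as observations, one OLS per
index, with the infection regressor in two modes: the genotype-mean TFI
BLUE over the condition subset (default) or the chosen stability index of
the TFI matrix itself — the choice is genuinely ambiguous in the source
procedure, so both are provided rather than guessing. Environments are
treated as exchangeable; no weighting.

## LMG relative importance

`share_k = Σ_{S ⊆ P∖{k}} |S|!(p−|S|−1)!/p! · (R²(S∪{k}) − R²(S))`, all R²
from OLS with intercept (computed on centered data), enumerated
exhaustively — 2^p fits, trivial at the p ≤ 7 used here, so no sampling
approximation is implemented. Shares are nonnegative, sum exactly to the
full-model R², and are reported both on the R² scale and normalized to 1;
stacked-bar reporting emits both so either rendering can be drawn.
Collinear inputs are rejected with the offending column names. The test
suite checks the subset-weighted form against an independently coded
average over all p! orderings.

## Field-vs-model correlation comparison

Both inputs are genotype × trait tables; Pearson correlations are computed
pairwise-complete (n ≥ 3, non-constant). A pair is concordant when the
point (r_field, r_model) lies within 0.09 *perpendicular* distance of the
identity line (|Δr|/√2 — "distance to the line" is read geometrically;
users preferring a vertical threshold can pass d_max = Δ/√2) and both
|r| exceed 0.5. No crop model is run; its outputs are just a table, and
the examples build a synthetic stand-in from the generator's truth.
Field correlations pool cultivar BLUE means across the selected
conditions; per-year correlation averaging is a documented alternative the
caller can implement by subsetting.

## Synthetic MET generator

Observation model per agronomic trait:

    y = grand_mean + g_i + slope·(release_year_i − midpoint) + e_cond
        + management_shift + gxe_{i,cond} + row_r + col_c + ε,

all components Gaussian; `gxe_{i,j} ~ N(0, sd_i)` with sd_i drawn once per
genotype from a uniform range, so genotypes differ in *true* stability and
stability estimators can be validated against ground truth. Genotype main
effects load on a shared latent factor ("vigor", loadings per trait), which
induces the cross-trait genotype correlations real panels show — positive
yield–biomass–harvest-index, negative yield–protein (dilution) — and gives
the correlation-comparison stage something real to measure. Disease
scores use the same latent additive scale (baseline, resistance trend in
score units per release year, fungicide suppression, a heavy-tailed
residual via half-normal inflation controlled by `overdispersion`) and are
clamped to [0, 100]. Release years are spread evenly over the span; plots
are laid out on a near-square grid with replicate blocks as row bands and
genotypes re-randomised within blocks (a randomized complete block
design); everything is reproducible from a single seed.

Shipped designs: `make_paper_like_design()` — the full unbalanced network
(29 year × location environments over six years and six sites, nine
managements with irrigation only at GGE, the rain-out shelter only at KIE,
a 220-cultivar early-phase panel and a 52-cultivar subset in later
seasons, three replicates for KIE rain-fed); the exact composition of the
29 environments beyond these constraints is a modelling choice, since only
the counts and placement rules are documented for the real network.
`make_phase1_subset_design()` — the balanced analysis subset (3 years × 5
locations × 3 rain-fed managements = 45 conditions, 220 cultivars).
`make_demo_design()` — 12 conditions for examples and smoke tests.

Default parameter magnitudes (yield mean 65 dt/ha, genotype sd 5, progress
0.37 dt/ha/year, management shifts of −8 dt/ha for low nitrogen and −4 for
no fungicide, etc.) are set so simulated values fall inside the observed
trait ranges of German winter wheat; within-plot error variances are free
parameters of the generator, documented in `default_trait_specs`, not
claims about any real dataset.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: spatial autocorrelation beyond additive
row/column effects, weather-driven G×E structure (interactions are
exchangeable noise, not systematic genotype × environment-covariate
responses), non-Gaussian trait distributions, missing-data mechanisms
correlated with trait values, and measurement-error differences between
the two sampling sources.

## Problem sizes and numerics

The default test-suite and acceptance runs use the 220-cultivar,
45-condition subset (one REML fit per trait × condition, ~360 fits), 100
seeded replicates for the BLUE-recovery comparison and 200 for
breeding-progress recovery — sizes chosen so Monte-Carlo standard errors
are small relative to the tested effects while a full run stays in the
minutes range on one core. Numerical tolerances: REML fatol 1e-8 with
λ ∈ [e−34, e+10] (e−34 reported as an exact zero component); stability
identities hold to 1e-9 on random matrices; LMG equals the permutation
average to 1e-10. Ties in environment ranks use mean ranks; ties in
letter-display means are broken by level name for determinism.

## Known limitations

* Per-condition BLUE fitting ignores information sharing across
  conditions; a factor-analytic multi-environment model would be more
  efficient but estimates a different quantity than the stated per
  condition procedure.
* The LSD letters are unprotected; with many levels the per-family error
  exceeds α by construction.
* `s²_di` and `σ²_i` omit plot-error corrections, as the inputs are
  BLUEs; comparisons with replicate-level implementations will differ by
  that term.
* The second-stage BP and stability regressions ignore the sampling error
  of their left- and right-hand sides (errors-in-variables attenuation is
  inherited from the stated procedure).
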