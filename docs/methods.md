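# Methods

`reefscape` implements a comparative seascape-connectivity analysis for
multi-site marine surveys: it asks whether compositional dissimilarity —
of alleles within species (genetic β-diversity) and of species within
families (species β-diversity) — increases with in-water distance, and
whether the two levels covary, in basins with contrasting habitat
configurations. This note documents the models, estimators, numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## Genetic β-diversity

Genetic differentiation between sampling sites is measured with the
standardized statistic G″ST. Per biallelic locus with k populations, alt
allele frequency p_i and n_i genotyped diploids in population i, the
sample-size-corrected gene diversities follow Nei & Chesser (1983):

    ñ   = harmonic mean of n_i
    Ĥ_S = [mean_i 2 p_i (1 − p_i)] · 2ñ / (2ñ − 1)
    Ĥ_T = 2 p̄ (1 − p̄) + Ĥ_S / (2 ñ k),     p̄ = mean_i p_i

Multi-locus statistics are ratios of across-locus averaged Ĥ_S and Ĥ_T
(ratio of averages, not average of ratios):

    G_ST  = (Ĥ_T − Ĥ_S) / Ĥ_T                         (Nei 1973)
    G′_ST = G_ST (k − 1 + Ĥ_S) / ((k − 1)(1 − Ĥ_S))     (Hedrick 2005)
    G″_ST = k (Ĥ_T − Ĥ_S) / ((k Ĥ_T − Ĥ_S)(1 − Ĥ_S))    (Meirmans & Hedrick 2011)

Unbiased estimators can be negative in panmictic samples; values are never
clamped, because a small negative estimate is information (absence of
structure), not an error. Loci at which any population of the comparison
has no genotyped individual are dropped — pair-locally for pairwise
matrices, so different site pairs may rest on slightly different locus
subsets within one resampling iteration. Monomorphic loci contribute to the
averaged diversities but have no per-locus ratio; a dataset monomorphic at
every locus yields a flagged undefined statistic rather than a silent zero.

A loop-based transcription of the same formulas lives in
`reefscape.reference` and was written first, directly from the published
estimator definitions, with no code shared with the vectorized path; the
test suite requires agreement below 1e-12 on randomized datasets.

## Filtering and resampling

Quality filtering applies four rules in a fixed, documented order:
individuals with more than 50% missing calls; SNPs missing in more than 20%
of individuals within any one sampling site; SNPs missing in more than 5% of
all individuals; then one SNP per RAD locus tag (the smallest position, with
record order breaking ties). Denominators are recomputed after each step, so
the per-site missingness rule is evaluated on the individuals that survived
step one. The source workflows this mirrors do not state an order; the
individual-first convention was chosen and fixed. A consequence worth
knowing: filtering is idempotent for realistic missingness levels, but a
pathological dataset reduced to very few loci can see an individual's
missing fraction re-evaluated upward on the second pass.

A species enters the analysis only if every site retains at least 3
individuals after filtering. To equalize information across species,
each analysis iteration draws a fixed number of loci (by default the minimum
across the basin's species; the motivating survey design uses 2852) without
replacement and caps every site at 10 individuals, and all derived
statistics are averaged over iterations (default 999). Iteration i uses a
random stream spawned from the master seed with spawn key (i,), so any
iteration is reproducible in isolation. The synthetic experiments shipped
with the package use 5–25 iterations: their genotypes are generated at
roughly the target loci count and the individual cap, so between-iteration
variance is negligible and the extra iterations would only re-average noise
that is already tiny. The tests verify this directly (cell-wise sd across
iterations is recorded in every aggregated matrix).

## Species β-diversity

Jaccard dissimilarity and its Baselga partition into turnover and
nestedness-resultant components. Pairwise, with a shared species, b and c
site-exclusive:

    β_jac = (b + c) / (a + b + c)
    β_jtu = 2 min(b, c) / (a + 2 min(b, c))
    β_jne = β_jac − β_jtu

Multiple-site (Baselga 2012), with S_i site richness, S_T pooled richness,
and Σmin/Σmax the summed min/max of site-exclusive counts over pairs:

    β_JTU = 2Σmin / (ΣS_i − S_T + 2Σmin)
    β_JAC = (Σmin + Σmax) / (ΣS_i − S_T + Σmin + Σmax)

Additivity β_jac = β_jtu + β_jne is exact in these formulas and asserted to
1e-12 throughout. Per-family metrics subset the incidence table to the
family's species but keep all sites: a site with no family members
contributes its partner's full richness as exclusives. A pair in which
*both* sites lack the family is undefined (flagged, excluded from model
tables) rather than set to zero — setting it to zero would fabricate perfect
similarity from double absence. The multiple-site partition is additionally
cross-checked in the tests against vegan's `nestedbetajac` through Rscript.

Pelagic larval duration (PLD, days) summaries use the recorded species value
when available, otherwise the median over congeners with data, otherwise
missing (and excluded from trait contrasts).

## Least-cost in-water distance

Sites are snapped to the nearest sea cell (within 2 cells by default) of a
regular lon/lat grid; sea cells form a graph whose edges connect neighboring
cells with haversine weights (Earth radius 6371 km), and Dijkstra gives the
shortest all-water path. The default 16-cell neighborhood (rook, bishop and
knight moves) has a worst-direction lattice overshoot of about 2.4% against
the true great circle, and typically under 1%; the 8-cell neighborhood
(~8% worst case) is available for comparison. Diagonal and knight moves are
blocked when the two cells flanking the move are both land, so paths cannot
slip between diagonally adjacent land cells. Bathymetry is used only to
delineate land (elevation ≥ 0 by default); depth does not weight edges.
Sites in different connected components get an infinite, flagged distance.

## MLPE mixed models

Stacked pairwise observations are not independent: two pairs sharing a site
are correlated. The maximum-likelihood population-effects model (Clarke et
al. 2002) fits

    y = α + β x + u_group + ε,
    corr(ε_r, ε_s) = ρ  iff pairs r and s share exactly one site,

with an optional group (species or family) random intercept u. ρ is
restricted to [0, 0.5), where the sharing-structure correlation matrix is
positive definite for these designs. Fitting profiles the residual variance
out of the (restricted) likelihood and optimizes numerically over ρ and the
variance ratio λ = σ²_u/σ²_ε with L-BFGS-B from multiple starts; covariance
matrices are assembled densely per group block, which is exact and cheap at
these sizes (tens of rows per group). REML is the default; ML is available,
and the ML log-likelihood at the estimates is checked in the tests against a
direct multivariate-normal density evaluated on the explicitly assembled
covariance.

Wald inference on the slope uses a t reference with n_pairs − n_groups − 1
degrees of freedom. This convention is one of several defensible choices for
pairwise designs and is recorded in every fit; with 4 sites (6 pairs per
group) variance components are weakly identified, so fits flag when σ̂²_u
hits the zero boundary. Calibration experiments shipped with the package
(8 sites × 6 groups, 200 replicates) show mean slope recovery within the
Monte-Carlo 99% band and a Wald type-I error near nominal (0.04–0.06 at
α = 0.05). Marginal and conditional R² follow Nakagawa & Schielzeth:
R²m = σ²_f/(σ²_f+σ²_u+σ²_ε) and R²c = (σ²_f+σ²_u)/(σ²_f+σ²_u+σ²_ε), with
σ²_f the variance of the fixed-effect predictor over the data.

With a single group the model degrades, with a warning, to MLPE without a
random intercept. Model rosters report p-values only and never label fits
significant; the α = 0.05 convention appears solely in the synthetic
contrast experiments, mirroring its use in the motivating study design.

## Synthetic two-basin generator

The generator emulates the data structure of a two-ocean reef fish survey:
four sites per basin on a low-latitude transect (inter-site in-water
distances ~556–2113 km in the compact basin, ~806–3974 km in the spread
basin), 7 vs 12 genotyped species, five families with study-scale richness
(5–93 species), ~3200 SNP loci per species with 2% missing calls and 10% of
RAD tags carrying a second SNP, and 12 individuals per site so the
10-per-site cap binds.

Seascapes are rectangular grids with procedurally placed island blocks; a
block that would wall any site off from the shared sea (checked with rook
connectivity, a sufficient condition for the 16-neighbor sea graph) is
reverted, so inter-site distances are always finite by construction.

Allele frequencies follow a logit-scale Gaussian field: per locus, an
ancestral frequency p₀ ~ U(0.1, 0.9) receives site deviations with
covariance σ²_f·exp(−d/κ) + σ²_n·I, and genotypes are Binomial(2, p_site).
κ is the isolation-by-distance range: the spread basin uses κ = 1500 km
(within the span of its site distances), the compact basin the fully
connected limit κ = ∞, in which the shared field cancels between sites and
differentiation comes only from the independent site noise — flat in
distance by construction. The ∞ limit, rather than merely "large", is the
honest representation of that regime here: with thousands of loci the
per-pair mean differentiation is nearly deterministic, so even a vanishing
residual decay slope would register as statistically significant, which is
not the biology the compact basin stands for. Noise scales were calibrated
once so basin-level mean G″ST magnitudes land at the study-condition levels
(≈0.02 compact, ≈0.04 spread, species ranging ~0.01–0.08 via a lognormal
per-species dispersal factor, sd 0.4) and then frozen. A Gaussian field was
chosen over a coalescent simulator deliberately: it gives direct, tunable
control of the IBD signal at trivial cost; coalescent realism is an explicit
non-goal.

Communities are per-species independent Bernoulli occupancies: each species
has a range-center site (always occupied), occupancy probability
p_max·exp(−d/λ) elsewhere, and a site richness gradient inducing nestedness;
a configurable share of species is centered on the basin's hub site
(70% compact, 30% spread), making the compact basin's dissimilarity more
nestedness-driven. A threshold mode (deterministic range edges with
per-species range-size jitter) exists to construct exactly nested
assemblages for testing the turnover/nestedness partition. Independent
Bernoulli occupancy keeps β-diversity expectations tractable but carries an
irreducible binomial noise floor: realized family-level β values run higher
than typical real survey tables, and co-occurrence structure is absent. The
generator is therefore evidence about the *pipeline* — that each stage
recovers the structure it is designed to measure — not about reef fish.

What passing the end-to-end experiment shows: over seeded replicates, the
spread basin yields a significant positive genetic-IBD slope (detection
≈100%), while the compact basin yields non-significant genetic IBD together
with significant species IBD (≈80% of replicates), and the spread basin's
species–genetic covariation (β-SGDC) slope is positive on average. What it
does not show: correctness of magnitudes for any real basin, behavior under
real ascertainment bias, linked selection, or current-driven asymmetric
dispersal — all out of scope.

## Degenerate inputs and numerical conventions

- Genotype calls outside {0, 1, 2, missing} are rejected at construction.
- An empty VCF body is a warning and a 0-locus dataset, not an error; a
  sample absent from the site table is an error naming the sample.
- Aggregation over iterations ignores flagged cells per cell; a cell flagged
  in every iteration stays flagged.
- The exact panmixia limit of the genetic generator (κ = ∞, σ_n = 0) has a
  rank-one covariance; a 1e-10 ridge keeps its Cholesky factor defined.
- MLPE optimizer non-convergence is flagged in the fit object, never silent;
  the profiled objective is evaluated from multiple starts and the best
  optimum kept.
- ANOVA contrasts require at least one within-group degree of freedom and
  error otherwise.

## Problem sizes used by the shipped experiments

The acceptance script and the heavier tests run: 100 randomized datasets for
estimator-oracle equivalence; 50 random incidence tables for partition
additivity; 200 + 200 MLPE replicates for slope recovery and type-I error;
20 end-to-end two-basin replicates at 5 resampling iterations per species;
and a 30×50-cell all-sea lattice for distance accuracy. These sizes hold the
full run to a few minutes while leaving the Monte-Carlo bands comfortably
narrower than the margins they certify.
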