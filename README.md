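# reefscape

Comparative seascape-connectivity analysis for multi-site marine surveys.

`reefscape` is aimed at marine population geneticists and community
ecologists who sample the same set of sites at two levels of biological
organization — SNP genotypes for a panel of species, and site-by-species
occurrence lists for their families — and want to know whether habitat
configuration leaves the same footprint on both. It computes genetic
β-diversity as Hedrick's G″ST between sampling sites (with the iterative
loci/individual subsampling needed to compare species genotyped at different
depths), species β-diversity as Jaccard dissimilarity partitioned into
turnover and nestedness (Baselga), shortest in-water distances over a
gridded land/sea mask, and fits maximum-likelihood population-effects (MLPE)
mixed models for isolation by distance (IBD) and β species–genetic diversity
correlations (β-SGDC), with marginal/conditional R². A synthetic two-basin
generator makes the whole pipeline runnable and testable without any
download.

## The statistics in brief

Genetic differentiation per site pair, from unbiased gene diversities
Ĥ_S, Ĥ_T (Nei & Chesser) averaged over loci:

    G″ST = k(Ĥ_T − Ĥ_S) / ((kĤ_T − Ĥ_S)(1 − Ĥ_S))

Species dissimilarity per site pair, with a shared and b, c exclusive
species:

    β_jac = (b+c)/(a+b+c),  β_jtu = 2min(b,c)/(a+2min(b,c)),  β_jne = β_jac − β_jtu

IBD and β-SGDC as mixed models over stacked pairwise tables,

    y_pair = α + β·x_pair + u_group + ε,   corr(ε, ε′) = ρ iff the pairs share a site,

fitted by REML with ρ profiled on [0, 0.5), Wald slope tests, and Nakagawa–
Schielzeth R²m/R²c. See `docs/methods.md` for the full formulary and the
design choices.

## Worked example

Summary stage on the bundled two-ocean diversity table (19 genotyped reef
fish species in five families, four sites per basin):

```python
from reefscape.pipeline import load_two_ocean_summary, summarize_two_ocean

s = summarize_two_ocean(load_two_ocean_summary())
gd = s["beta_gd"]
print(gd.group_means, gd.f, gd.p)
```

prints (abridged)

```
beta-GD means: Caribbean 0.0178 +/- 0.016, WIO 0.0379 +/- 0.021
ANOVA: F = 4.76, p = 0.043
```

i.e. genetic β-diversity is about twice as high, on average, in the basin
with the more isolated habitat patches, and the one-way ANOVA puts the
between-basin contrast just under the 5% level.

Fitting an MLPE model to a simulated pair table with a known slope of 2.0
and residual pair-sharing correlation ρ = 0.3:

```python
from reefscape.mlpe import fit_mlpe
from reefscape.synth import simulate_pair_table

fit = fit_mlpe(simulate_pair_table(n_sites=8, n_groups=6, slope=2.0,
                                   rho=0.3, seed=1))
```

```
MLPE: slope = 2.126 (SE 0.175), rho = 0.20, p = 2.03e-24, R2m = 0.33, R2c = 0.44
```

The slope estimate covers the generating value and the fitted ρ picks up the
induced pair-sharing correlation.

The full synthetic experiment — two basins, genotypes through VCF-shaped
datasets, filtering, resampling, G″ST, β-diversity, least-cost distances and
the three MLPE hypotheses per basin — runs from the command line:

```bash
reefscape run --seed 1 --n-iter 25 --out results/
reefscape simulate --seed 1 --out data/synthetic/   # emit VCFs, CSVs, mask
reefscape dist --grid mask.asc --sites sites.csv --neighborhood 16 --out dist.csv
```

`results/table1.csv` holds per-family β_jac/β_jtu/β_jne and per-species
overall G″ST; `results/table2.csv` the model roster (hypothesis, response,
predictor, basin, estimate, p, R²m, R²c).

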