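"""Slow, loop-based reference implementations used for validation.

These transcribe the published estimator formulas symbol by symbol — the
Nei & Chesser (1983) unbiased gene diversities, Hedrick (2005) G'ST,
Meirmans & Hedrick (2011) G''ST, and the Baselga (2010, 2012) Jaccard
partitions — with plain Python loops and no shared code with the vectorized
analysis modules.  They exist so the fast paths can be checked against an
independent transcription of the same mathematics.
"""

from __future__ import annotations

import math
from typing import Sequence

MISSING = -1


def _harmonic_mean(values: Sequence[float]) -> float:
    return len(values) / sum(1.0 / v for v in values)


def ref_gst_hedrick(calls, pop_labels) -> dict:
    """Multi-locus G_ST, G'_ST, G''_ST from a genotype matrix.

    calls: (n_individuals, n_loci) alt dosages with -1 missing;
    pop_labels: population label per individual.

    Per locus with k populations, alt frequency p_i and n_i genotyped
    individuals in population i:

        n~     = harmonic mean of n_i
        H_S    = mean_i 2 p_i (1 - p_i)              (within-pop diversity)
        H^_S   = H_S * 2 n~ / (2 n~ - 1)             (unbiased)
        p.     = mean_i p_i
        H_T    = 2 p. (1 - p.)                       (total diversity)
        H^_T   = H_T + H^_S / (2 n~ k)               (unbiased)

    Loci where any population has zero genotyped individuals are dropped.
    Multi-locus statistics form ratios of across-locus averaged H^_S, H^_T:

        G_ST   = (H_T - H_S) / H_T
        G'_ST  = G_ST (k - 1 + H_S) / ((k - 1)(1 - H_S))
        G''_ST = k (H_T - H_S) / ((k H_T - H_S)(1 - H_S))
    """
    pops = sorted(set(pop_labels))
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    n_ind = len(calls)
    n_loci = len(calls[0]) if n_ind else 0

    hs_list, ht_list = [], []
    for l in range(n_loci):
        freqs, sizes = [], []
        ok = True
        for pop in pops:
            alt = 0
            n = 0
            for i in range(n_ind):
                if pop_labels[i] == pop and calls[i][l] != MISSING:
                    alt += calls[i][l]
                    n += 1
            if n == 0:
                ok = False
                break
            freqs.append(alt / (2 * n))
            sizes.append(n)
        if not ok:
            continue
        n_harm = _harmonic_mean(sizes)
        hs = sum(2 * p * (1 - p) for p in freqs) / k
        hs_hat = hs * (2 * n_harm) / (2 * n_harm - 1)
        p_bar = sum(freqs) / k
        ht = 2 * p_bar * (1 - p_bar)
        ht_hat = ht + hs_hat / (2 * n_harm * k)
        hs_list.append(hs_hat)
        ht_list.append(ht_hat)

    if not hs_list:
        return {"defined": False, "Gst": math.nan, "Gprime_st": math.nan,
                "Gdouble_st": math.nan, "n_loci": 0}
    hs_bar = sum(hs_list) / len(hs_list)
    ht_bar = sum(ht_list) / len(ht_list)
    if ht_bar == 0:
        return {"defined": False, "Gst": math.nan, "Gprime_st": math.nan,
                "Gdouble_st": math.nan, "n_loci": len(hs_list)}
    gst = (ht_bar - hs_bar) / ht_bar
    gprime = gst * (k - 1 + hs_bar) / ((k - 1) * (1 - hs_bar))
    gdouble = k * (ht_bar - hs_bar) / ((k * ht_bar - hs_bar) * (1 - hs_bar))
    return {"defined": True, "Gst": gst, "Gprime_st": gprime,
            "Gdouble_st": gdouble, "n_loci": len(hs_list)}


def ref_beta_pair(species_a: set, species_b: set) -> tuple[float, float, float]:
    """Pairwise Jaccard dissimilarity and its turnover/nestedness partition
    from two presence sets: returns (beta_jac, beta_jtu, beta_jne)."""
    a = len(species_a & species_b)
    b = len(species_a - species_b)
    c = len(species_b - species_a)
    if a + b + c == 0:
        return math.nan, math.nan, math.nan
    jac = (b + c) / (a + b + c)
    if a + 2 * min(b, c) == 0:
        jtu = 0.0
    else:
        jtu = 2 * min(b, c) / (a + 2 * min(b, c))
    return jac, jtu, jac - jtu


def ref_beta_multi(site_species: Sequence[set]) -> tuple[float, float, float]:
    """Multiple-site Jaccard partition (Baselga 2012) from presence sets.

    With S_i the richness of site i, S_T the pooled richness, and b_ij the
    number of species in i absent from j:

        beta_JTU = 2 Smin / (sum S_i - S_T + 2 Smin)
        beta_JAC = (Smin + Smax) / (sum S_i - S_T + Smin + Smax)
        beta_JNE = beta_JAC - beta_JTU

    where Smin/Smax sum min/max(b_ij, b_ji) over site pairs.
    """
    n = len(site_species)
    if n < 2:
        return math.nan, math.nan, math.nan
    pooled = set()
    for s in site_species:
        pooled |= s
    sum_si = sum(len(s) for s in site_species)
    st = len(pooled)
    smin = smax = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            b = len(site_species[i] - site_species[j])
            c = len(site_species[j] - site_species[i])
            smin += min(b, c)
            smax += max(b, c)
    if sum_si - st + smin + smax == 0:
        return math.nan, math.nan, math.nan
    if sum_si - st + 2 * smin == 0:
        jtu = 0.0
    else:
        jtu = 2 * smin / (sum_si - st + 2 * smin)
    jac = (smin + smax) / (sum_si - st + smin + smax)
    return jac, jtu, jac - jtu


def ref_mlpe_loglik(y, X, beta, groups, pair_sites, rho, sigma2_u, sigma2_e):
    """Exact multivariate-normal log-likelihood of the MLPE model, by direct
    assembly of the full covariance matrix and scipy's density.

    Residual correlation within a group is rho for two rows sharing exactly
    one site and 0 otherwise; a group random intercept adds sigma2_u to every
    within-group covariance cell.
    """
    import numpy as np
    from scipy.stats import multivariate_normal

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if groups[i] != groups[j]:
                continue
            V[i, j] += sigma2_u
            if i == j:
                V[i, j] += sigma2_e
            else:
                shared = len(set(pair_sites[i]) & set(pair_sites[j]))
                if shared == 1:
                    V[i, j] += rho * sigma2_e
    mean = X @ np.asarray(beta, float)
    return float(multivariate_normal.logpdf(y, mean=mean, cov=V))
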