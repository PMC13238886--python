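"""Genetic differentiation: Nei G_ST, Hedrick G'_ST and G''_ST.

Gene diversities use the Nei & Chesser (1983) sample-size-corrected
estimators with the harmonic mean of per-population sample sizes; the
standardized statistics follow Hedrick (2005) and the small-k correction of
Meirmans & Hedrick (2011),

    G''_ST = k (H_T - H_S) / ((k H_T - H_S)(1 - H_S)).

Multi-locus values are ratios of across-locus averaged diversities
(ratio of averages, not average of ratios).  Unbiased estimators can go
slightly negative in panmictic samples; values are never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset
from .pairwise import PairwiseMatrix, aggregate_matrices

logger = logging.getLogger(__name__)


@dataclass
class HetStats:
    """Per-locus unbiased gene diversities for k populations."""

    hs: np.ndarray          # unbiased within-population diversity per locus
    ht: np.ndarray          # unbiased total diversity per locus
    n_harmonic: np.ndarray  # harmonic mean sample size per locus
    k: int
    n_loci_dropped: int     # loci with a fully missing population


@dataclass
class DifferentiationStats:
    gst: float
    gprime_st: float
    gdouble_st: float
    per_locus: pd.DataFrame
    n_loci: int
    defined: bool = True


def _freq_tables(ds: GenotypeDataset, populations: np.ndarray):
    """Alt-allele frequency and genotyped-count tables, (k, n_loci) each."""
    pops = pd.unique(populations)
    k = len(pops)
    n_loci = ds.n_loci
    p = np.zeros((k, n_loci))
    n = np.zeros((k, n_loci))
    present = ds.calls != MISSING
    dose = np.where(present, ds.calls, 0).astype(float)
    for a, pop in enumerate(pops):
        rows = populations == pop
        n[a] = present[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[a] = dose[rows].sum(axis=0) / (2 * n[a])
    return pops, p, n


def het_stats(
    ds: GenotypeDataset, populations: np.ndarray | None = None
) -> HetStats:
    """Unbiased per-locus H_S and H_T across populations.

    ``populations`` defaults to the dataset's site assignments.  Loci at
    which any population has no genotyped individual are dropped (their
    count is reported and logged).
    """
    populations = ds.sites if populations is None else np.asarray(populations, object)
    pops, p, n = _freq_tables(ds, populations)
    k = len(pops)
    if k < 2:
        raise ValueError("differentiation requires at least two populations")
    ok = (n > 0).all(axis=0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d loci with a fully missing population",
            ds.species_id, n_dropped,
        )
    p, n = p[:, ok], n[:, ok]
    n_harm = k / (1.0 / n).sum(axis=0)
    hs_raw = (2 * p * (1 - p)).mean(axis=0)
    hs = hs_raw * (2 * n_harm) / (2 * n_harm - 1)
    p_bar = p.mean(axis=0)
    ht_raw = 2 * p_bar * (1 - p_bar)
    ht = ht_raw + hs / (2 * n_harm * k)
    return HetStats(hs=hs, ht=ht, n_harmonic=n_harm, k=k, n_loci_dropped=n_dropped)


def gst_statistics(hs: HetStats) -> DifferentiationStats:
    """G_ST, G'_ST and G''_ST from per-locus diversities.

    Monomorphic loci (H_T = 0) enter the across-locus averages but have no
    per-locus ratio; if every locus is monomorphic overall the global
    statistic is flagged undefined rather than silently zero.
    """
    k = hs.k
    hs_bar = float(hs.hs.mean()) if hs.hs.size else np.nan
    ht_bar = float(hs.ht.mean()) if hs.ht.size else np.nan

    poly = hs.ht > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        gst_loc = (hs.ht - hs.hs) / hs.ht
        gp_loc = gst_loc * (k - 1 + hs.hs) / ((k - 1) * (1 - hs.hs))
        gd_loc = k * (hs.ht - hs.hs) / ((k * hs.ht - hs.hs) * (1 - hs.hs))
    per_locus = pd.DataFrame(
        {
            "hs": hs.hs, "ht": hs.ht,
            "gst": np.where(poly, gst_loc, np.nan),
            "gprime_st": np.where(poly, gp_loc, np.nan),
            "gdouble_st": np.where(poly, gd_loc, np.nan),
        }
    )
    if not hs.hs.size or not np.isfinite(ht_bar) or ht_bar == 0:
        return DifferentiationStats(
            gst=np.nan, gprime_st=np.nan, gdouble_st=np.nan,
            per_locus=per_locus, n_loci=int(hs.hs.size), defined=False,
        )
    gst = (ht_bar - hs_bar) / ht_bar
    gprime = gst * (k - 1 + hs_bar) / ((k - 1) * (1 - hs_bar))
    gdouble = k * (ht_bar - hs_bar) / ((k * ht_bar - hs_bar) * (1 - hs_bar))
    return DifferentiationStats(
        gst=gst, gprime_st=gprime, gdouble_st=gdouble,
        per_locus=per_locus, n_loci=int(hs.hs.size), defined=True,
    )


def gst_global(ds: GenotypeDataset, populations=None) -> DifferentiationStats:
    """Overall multi-locus differentiation across all populations."""
    return gst_statistics(het_stats(ds, populations))


GST_METRIC = "G''ST"


def pairwise_gst(
    ds: GenotypeDataset, site_ids: Sequence[str] | None = None
) -> PairwiseMatrix:
    """Pairwise G''_ST between sampling sites (k = 2 per pair).

    Loci fully missing in either member of a pair are excluded pair-locally,
    so different pairs may use different locus subsets.  Sites without
    individuals get a flagged (nan) row/column.
    """
    if site_ids is None:
        site_ids = list(pd.unique(ds.sites))
    site_ids = [str(s) for s in site_ids]
    n = len(site_ids)
    vals = np.zeros((n, n))
    counts = ds.site_counts()
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = site_ids[i], site_ids[j]
            if counts.get(si, 0) == 0 or counts.get(sj, 0) == 0:
                vals[i, j] = vals[j, i] = np.nan
                continue
            rows = np.flatnonzero((ds.sites == si) | (ds.sites == sj))
            sub = ds.subset(ind_idx=rows)
            stats = gst_statistics(het_stats(sub))
            vals[i, j] = vals[j, i] = stats.gdouble_st if stats.defined else np.nan
    return PairwiseMatrix(site_ids=site_ids, values=vals, metric=GST_METRIC)


def aggregate_iterations(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Cell-wise mean (and sd) of pairwise matrices over resampling
    iterations; see :func:`reefscape.pairwise.aggregate_matrices`."""
    return aggregate_matrices(matrices)
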