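"""Synthetic two-basin seascapes, genotypes and communities.

The generator emulates the data structure of a comparative two-ocean reef
fish survey: two basins of four sampling sites each, multiple genotyped
species nested in families, ~3000 SNP loci per species with missing calls,
allele-frequency similarity that decays with in-water distance at a
basin-specific range, and site-by-species incidence tables whose
compositional similarity also decays with distance.

Genetics use a logit-scale Gaussian-field model rather than a coalescent:
per locus, an ancestral frequency p0 ~ U(0.1, 0.9) receives site deviations
drawn from a multivariate normal with covariance

    sigma_field^2 * exp(-d_ij / kappa) + sigma_noise^2 * I,

so ``kappa`` (km) sets the isolation-by-distance range and ``sigma_noise``
the distance-independent baseline differentiation.  ``kappa = inf`` is the
fully-connected limit: site deviations from the shared field are identical
and all differentiation comes from the independent noise, flat in distance.
Diploid genotypes are Binomial(2, p_site) with injected missingness.

Default parameter values reproduce the conditions of the motivating survey
design: a compact basin (inter-site distances ~550-2100 km, decay range far
beyond the basin span, baseline G''ST around 0.02) and a spread basin
(~800-3900 km, decay range 1500 km, mean G''ST around 0.04).

Communities are per-species independent Bernoulli occupancies decaying with
distance from a range-center site (scale ``lambda_km``), with a site
richness gradient that induces nestedness.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .betadiv import CommunityTable
from .genio import MISSING, GenotypeDataset, write_vcf
from .pairwise import PairwiseMatrix
from .seadist import DISTANCE_METRIC, SeascapeGrid, write_ascii_grid

logger = logging.getLogger(__name__)


@dataclass
class BasinConfig:
    """One basin of the synthetic experiment."""

    name: str
    # cumulative eastward site offsets in degrees (4 sites on a low-latitude
    # transect); compact ~ 556-2112 km, spread ~ 806-3934 km span
    site_lon_offsets: tuple = (0.0, 5.0, 11.0, 19.0)
    origin_lon: float = 0.0
    lat: float = 0.0
    # genetics
    n_species: int = 7
    n_loci: int = 3200
    ind_per_site: int = 12
    kappa_km: float = math.inf   # allele-frequency similarity decay range
    sigma_field: float = 0.35    # logit-scale sd of the distance-structured field
    sigma_noise: float = 0.25    # logit-scale sd of independent site noise
    species_scale_sd: float = 0.4  # lognormal sd of per-species dispersal scaling
    genotype_missing_rate: float = 0.02
    multi_snp_fraction: float = 0.10  # RAD tags carrying a second SNP
    # community
    species_per_family: tuple = (5, 32, 5, 21, 12)
    lambda_km: float = 3000.0    # occupancy decay range
    richness_gradient: float = 0.25
    occupancy_max: float = 0.95
    center_concentration: float = 0.5  # share of species centered on the hub site
    range_scale_sd: float = 0.0    # lognormal sd of per-species lambda jitter
    occupancy_mode: str = "bernoulli"  # or "threshold": deterministic range edges
    # seascape
    grid_resolution: float = 0.5
    grid_margin_deg: float = 3.0
    land_fraction: float = 0.03

    @property
    def n_sites(self) -> int:
        return len(self.site_lon_offsets)


@dataclass
class SynthConfig:
    """Two-basin experiment: a compact, well-connected basin and a spread
    basin with isolation by distance at both levels."""

    compact: BasinConfig = field(
        default_factory=lambda: BasinConfig(
            name="compact",
            site_lon_offsets=(0.0, 5.0, 11.0, 19.0),
            n_species=7,
            kappa_km=math.inf,
            species_per_family=(5, 32, 5, 21, 12),
            lambda_km=2000.0,
            center_concentration=0.7,
        )
    )
    spread: BasinConfig = field(
        default_factory=lambda: BasinConfig(
            name="spread",
            site_lon_offsets=(0.0, 7.25, 18.0, 35.4),
            n_species=12,
            kappa_km=1500.0,
            sigma_field=0.38,
            sigma_noise=0.09,
            species_per_family=(42, 93, 17, 71, 22),
            lambda_km=3500.0,
            occupancy_max=0.97,
            center_concentration=0.3,
        )
    )
    seed: int = 0

    @property
    def basins(self) -> list[BasinConfig]:
        return [self.compact, self.spread]


def _basin_rng(seed: int, basin: BasinConfig, stream: str, index: int = 0):
    # stable across processes (unlike hash()), so runs are seed-deterministic
    key = zlib.crc32(f"{basin.name}/{stream}".encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(key, index))
    )


def simulate_seascape(
    basin: BasinConfig, seed: int = 0
) -> tuple[SeascapeGrid, pd.DataFrame]:
    """Procedural grid (sea with scattered island blocks) plus site table.

    Islands never cover a site cell: any island cell falling on a site is
    reverted to sea (logged), which plays the role of repositioning.
    """
    rng = _basin_rng(seed, basin, "seascape")
    res = basin.grid_resolution
    lon_min = basin.origin_lon - basin.grid_margin_deg
    lon_max = basin.origin_lon + max(basin.site_lon_offsets) + basin.grid_margin_deg
    lat_min, lat_max = basin.lat - 4.0, basin.lat + 4.0
    lons = np.arange(lon_min + res / 2, lon_max, res)
    lats = np.arange(lat_max - res / 2, lat_min, -res)
    sea = np.ones((len(lats), len(lons)), dtype=bool)

    site_lons = basin.origin_lon + np.asarray(basin.site_lon_offsets)
    site_lats = np.full(basin.n_sites, basin.lat)
    site_cells = {
        (int(np.argmin(np.abs(lats - la))), int(np.argmin(np.abs(lons - lo))))
        for lo, la in zip(site_lons, site_lats)
    }

    def _sites_connected(mask: np.ndarray) -> bool:
        # rook (4-)connectivity: any rook path is a valid sea-graph path,
        # so this is a sufficient condition for the sites staying connected
        from scipy import ndimage

        labels, _ = ndimage.label(mask)
        site_labels = {labels[r, c] for r, c in site_cells}
        return 0 not in site_labels and len(site_labels) == 1

    target_land = int(basin.land_fraction * sea.size)
    placed = 0
    attempts = 0
    while placed < target_land and attempts < 200:
        attempts += 1
        h = int(rng.integers(1, 4))
        w = int(rng.integers(1, 5))
        r0 = int(rng.integers(0, max(1, len(lats) - h)))
        c0 = int(rng.integers(0, max(1, len(lons) - w)))
        block = [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]
        kept = [cell for cell in block if cell not in site_cells and sea[cell]]
        if len(kept) < len(block):
            logger.info("island block overlapped a site; site cells kept at sea")
        for r, c in kept:
            sea[r, c] = False
        # an island must not wall any site off from the shared sea
        if not _sites_connected(sea):
            for r, c in kept:
                sea[r, c] = True
            logger.info("island block would disconnect a site; reverted")
            continue
        placed += len(kept)

    grid = SeascapeGrid(lons=lons, lats=lats, sea=sea)
    sites = pd.DataFrame(
        {
            "site_id": [f"{basin.name[:3].upper()}{k + 1}" for k in range(basin.n_sites)],
            "name": [f"{basin.name} site {k + 1}" for k in range(basin.n_sites)],
            "lon": site_lons,
            "lat": site_lats,
            "basin": basin.name,
        }
    )
    return grid, sites


def _site_covariance(basin: BasinConfig, distances: np.ndarray) -> np.ndarray:
    if math.isinf(basin.kappa_km):
        decay = np.ones_like(distances)
    else:
        decay = np.exp(-distances / basin.kappa_km)
    cov = basin.sigma_field**2 * decay + basin.sigma_noise**2 * np.eye(
        len(distances)
    )
    # ridge keeps the Cholesky factor defined in the exact panmixia limit
    # (kappa = inf, sigma_noise = 0), where the field part is rank one
    cov += 1e-10 * np.eye(len(distances))
    return cov


def simulate_genotypes(
    basin: BasinConfig,
    distances: PairwiseMatrix,
    seed: int = 0,
) -> list[GenotypeDataset]:
    """Per-species genotype datasets with distance-structured allele
    frequencies; see module docstring for the model."""
    if not np.isfinite(distances.values).all():
        raise ValueError("distances must be finite to simulate genotypes")
    site_ids = distances.site_ids
    n_sites = len(site_ids)
    cov = _site_covariance(basin, distances.values)

    datasets = []
    for s in range(basin.n_species):
        rng = _basin_rng(seed, basin, "genotypes", s)
        # species differ in dispersal: scale the whole covariance
        scale = rng.lognormal(mean=0.0, sigma=basin.species_scale_sd)
        chol = np.linalg.cholesky(cov * scale**2)
        n_loci = basin.n_loci
        p0 = rng.uniform(0.1, 0.9, size=n_loci)
        z = logit(p0)[None, :] + chol @ rng.standard_normal((n_sites, n_loci))
        p_site = expit(z)

        calls = np.empty((n_sites * basin.ind_per_site, n_loci), dtype=np.int8)
        sites_arr = np.empty(n_sites * basin.ind_per_site, dtype=object)
        individuals = []
        for k, sid in enumerate(site_ids):
            rows = slice(k * basin.ind_per_site, (k + 1) * basin.ind_per_site)
            calls[rows] = rng.binomial(
                2, p_site[k], size=(basin.ind_per_site, n_loci)
            ).astype(np.int8)
            sites_arr[rows] = sid
            individuals += [
                f"{sid}_sp{s}i{j}" for j in range(basin.ind_per_site)
            ]
        miss = rng.random(calls.shape) < basin.genotype_missing_rate
        calls[miss] = MISSING

        # RAD tags: a fraction of tags carry a second, later SNP
        n_extra = int(round(basin.multi_snp_fraction * n_loci))
        tags = np.array([f"tag{t}" for t in range(n_loci)], dtype=object)
        positions = np.full(n_loci, 10, dtype=int)
        if n_extra:
            extra_tags = rng.choice(n_loci, size=n_extra, replace=False)
            extra_calls = np.empty((calls.shape[0], n_extra), dtype=np.int8)
            for e, t in enumerate(extra_tags):
                pe = expit(z[:, t] + 0.2 * rng.standard_normal(n_sites))
                for k in range(n_sites):
                    rows = slice(k * basin.ind_per_site, (k + 1) * basin.ind_per_site)
                    extra_calls[rows, e] = rng.binomial(
                        2, pe[k], size=basin.ind_per_site
                    ).astype(np.int8)
            miss_e = rng.random(extra_calls.shape) < basin.genotype_missing_rate
            extra_calls[miss_e] = MISSING
            calls = np.hstack([calls, extra_calls])
            tags = np.concatenate([tags, np.array(
                [f"tag{t}" for t in extra_tags], dtype=object)])
            positions = np.concatenate([positions, np.full(n_extra, 57, dtype=int)])
            order = np.lexsort((positions, tags.astype(str)))
            calls = calls[:, order]
            tags = tags[order]
            positions = positions[order]

        datasets.append(
            GenotypeDataset(
                species_id=f"{basin.name}_sp{s}",
                individuals=individuals,
                sites=sites_arr,
                locus_tags=tags,
                positions=positions,
                calls=calls,
            )
        )
    return datasets


def simulate_pair_table(
    n_sites: int = 8,
    n_groups: int = 6,
    slope: float = 2.0,
    intercept: float = 1.0,
    rho: float = 0.3,
    sigma2_u: float = 0.25,
    sigma2_e: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-form pair table from the MLPE generative model.

    Every unordered site pair appears once per group; residuals of pairs
    sharing exactly one site are correlated at ``rho``; each group carries a
    Gaussian random intercept with variance ``sigma2_u``.  Used for
    parameter-recovery and calibration experiments on the MLPE fitter.
    """
    from itertools import combinations

    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    pairs = list(combinations(sites, 2))
    m = len(pairs)
    S = np.zeros((m, m))
    for r in range(m):
        for s in range(r + 1, m):
            if len(set(pairs[r]) & set(pairs[s])) == 1:
                S[r, s] = S[s, r] = 1.0
    chol = np.linalg.cholesky(sigma2_e * (np.eye(m) + rho * S))
    rows = []
    for g in range(n_groups):
        u = rng.normal(0.0, np.sqrt(sigma2_u))
        eps = chol @ rng.standard_normal(m)
        x = rng.uniform(0.0, 1.0, m)
        for (si, sj), xi, e in zip(pairs, x, eps):
            rows.append(
                {"group": f"g{g}", "site_i": si, "site_j": sj,
                 "response": intercept + slope * xi + u + e, "predictor": xi}
            )
    return pd.DataFrame(rows)


FAMILY_NAMES = ("famA", "famB", "famC", "famD", "famE")


def simulate_communities(
    basin: BasinConfig,
    distances: PairwiseMatrix,
    seed: int = 0,
) -> CommunityTable:
    """Site x species incidence with distance-decaying composition.

    Each species has a range-center site (where it is always present) and
    occupancy probability exp(-d/lambda) elsewhere, damped by a site richness
    gradient so assemblages are partly nested.
    """
    if not np.isfinite(distances.values).all():
        raise ValueError("distances must be finite to simulate communities")
    rng = _basin_rng(seed, basin, "community")
    site_ids = distances.site_ids
    n_sites = len(site_ids)
    richness_factor = 1.0 - basin.richness_gradient * (
        np.arange(n_sites) / max(n_sites - 1, 1)
    )

    records = {}
    fam_map = {}
    trait_rows = []
    for f, n_sp in enumerate(basin.species_per_family):
        fam = FAMILY_NAMES[f % len(FAMILY_NAMES)]
        for j in range(n_sp):
            for attempt in range(2):
                if rng.random() < basin.center_concentration:
                    center = 0  # hub: the richest site, gives nested ranges
                else:
                    center = int(rng.integers(n_sites))
                lam = basin.lambda_km
                if basin.range_scale_sd > 0:
                    lam *= rng.lognormal(mean=0.0, sigma=basin.range_scale_sd)
                d = distances.values[center]
                prob = basin.occupancy_max * np.exp(-d / lam)
                prob = np.clip(prob * richness_factor, 0, 1)
                if basin.occupancy_mode == "threshold":
                    occ = (prob >= 0.5).astype(int)
                elif basin.occupancy_mode == "bernoulli":
                    occ = (rng.random(n_sites) < prob).astype(int)
                else:
                    raise ValueError(
                        f"unknown occupancy_mode {basin.occupancy_mode!r}"
                    )
                occ[center] = 1
                if occ.sum() > 0:
                    break
            else:
                warnings.warn(f"family {fam}: regenerated an empty species range")
            name = f"{basin.name}_{fam}_sp{j}"
            records[name] = occ
            fam_map[name] = fam
            genus = f"{fam}_gen{j // 3}"
            pld = float(np.round(rng.lognormal(mean=np.log(28.0), sigma=0.4), 1))
            if rng.random() < 0.15:
                pld = np.nan
            trait_rows.append({"species": name, "genus": genus, "pld_days": pld})

    incidence = pd.DataFrame(records, index=site_ids)
    return CommunityTable(
        incidence=incidence,
        family_map=pd.Series(fam_map),
        traits=pd.DataFrame(trait_rows),
    )


def write_synth_outputs(outdir, cfg: SynthConfig) -> dict:
    """Emit the full synthetic dataset as plain-text files: per-species VCFs,
    sites.csv, incidence.csv, family_map.csv, traits.csv, mask.asc and a
    manifest recording the seed and parameters."""
    import json
    from pathlib import Path

    from .seadist import build_sea_graph, least_cost_distance

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "basins": {}}
    all_sites = []
    for basin in cfg.basins:
        bdir = outdir / basin.name
        bdir.mkdir(exist_ok=True)
        grid, sites = simulate_seascape(basin, cfg.seed)
        all_sites.append(sites)
        write_ascii_grid(grid, bdir / "mask.asc")
        graph = build_sea_graph(grid)
        dist = least_cost_distance(graph, grid, sites)
        dist.to_csv(bdir / "distances.csv")
        for ds in simulate_genotypes(basin, dist, cfg.seed):
            write_vcf(ds, bdir / f"{ds.species_id}.vcf")
        community = simulate_communities(basin, dist, cfg.seed)
        community.incidence.to_csv(bdir / "incidence.csv")
        community.family_map.rename("family").rename_axis("species").to_csv(
            bdir / "family_map.csv"
        )
        community.traits.to_csv(bdir / "traits.csv", index=False)
        manifest["basins"][basin.name] = asdict(basin)
    pd.concat(all_sites).to_csv(outdir / "sites.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
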