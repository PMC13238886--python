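"""Per-basin analysis orchestration and between-basin comparisons.

``run_basin`` chains the stages for one ocean basin: genotype filtering and
eligibility, iterative loci/individual resampling with pairwise G''ST
averaged across iterations, per-family Jaccard partitions, and the three
MLPE hypotheses (genetic isolation by distance, species isolation by
distance, and the beta species-genetic diversity correlation).
``run_two_basin_experiment`` runs both synthetic basins end to end and adds
the between-basin one-way ANOVAs.

Outputs mirror the two standard summary tables of this kind of study: a
per-family/per-species diversity table and an MLPE model roster
(hypothesis, response, predictor, basin, estimate, p, R2m, R2c).  The
roster reports p-values only; it never labels fits significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import betadiv, gendiff, genio, mlpe, seadist, synth
from .betadiv import CommunityTable
from .genio import FilterConfig, GenotypeDataset, ResampleConfig
from .pairwise import PairwiseMatrix

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    f: float
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]


def ocean_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA of a per-unit metric between basins."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least one value")
    if len(values) - len(labels) < 1:
        raise ValueError("zero within-group degrees of freedom")
    f, p = stats.f_oneway(*samples)
    return AnovaResult(
        f=float(f),
        p=float(p),
        group_means={str(g): float(np.mean(s)) for g, s in zip(labels, samples)},
        group_sds={
            str(g): float(np.std(s, ddof=1)) if len(s) > 1 else np.nan
            for g, s in zip(labels, samples)
        },
        group_ns={str(g): int(len(s)) for g, s in zip(labels, samples)},
    )


def sgdc_pairing(
    genetic: dict[str, PairwiseMatrix],
    community_beta: dict[str, PairwiseMatrix],
    family_map: dict[str, str],
) -> pd.DataFrame:
    """Pair each genotyped species' pairwise genetic differentiation
    (predictor) with its family's pairwise species dissimilarity (response),
    grouped by species.  Flagged cells drop that row."""
    rows = []
    n_dropped = 0
    for species, gmat in genetic.items():
        if species not in family_map:
            raise ValueError(f"species {species!r} has no family assignment")
        fam = family_map[species]
        if fam not in community_beta:
            raise ValueError(
                f"family {fam!r} (species {species!r}) has no community matrix"
            )
        cmat = community_beta[fam]
        for si, sj, gd in gmat.pairs():
            sd = cmat.get(si, sj)
            if not (np.isfinite(gd) and np.isfinite(sd)):
                n_dropped += 1
                continue
            rows.append(
                {"group": species, "site_i": si, "site_j": sj,
                 "response": sd, "predictor": gd}
            )
    table = pd.DataFrame(rows, columns=mlpe.PAIR_COLUMNS)
    table.attrs["n_dropped"] = n_dropped
    return table


@dataclass
class BasinData:
    """Inputs for one basin."""

    name: str
    site_table: pd.DataFrame
    distances: PairwiseMatrix
    genotypes: list[GenotypeDataset]
    community: CommunityTable
    species_families: dict[str, str]


@dataclass
class AnalysisConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    target_loci: int | None = None  # None = min across eligible species
    responses: tuple = ("beta_jtu", "beta_jac")


@dataclass
class BasinResult:
    name: str
    overall_gd: pd.Series                    # per-species mean overall G''ST
    pairwise_gd: dict[str, PairwiseMatrix]   # per-species iteration means
    family_beta: dict[str, dict[str, PairwiseMatrix]]  # family -> metric -> matrix
    multisite: pd.DataFrame                  # per-family multiple-site triple
    fits: pd.DataFrame                       # MLPE roster rows for this basin
    fit_objects: dict[str, mlpe.MLPEFit]
    excluded_species: list[str]
    n_iter: int
    target_loci: int


def _resampled_gst(
    ds: GenotypeDataset, cfg: ResampleConfig
) -> tuple[float, PairwiseMatrix]:
    """Mean overall G''ST and mean pairwise matrix over iterations."""
    site_ids = sorted(pd.unique(ds.sites))
    overall = []
    mats = []
    for _, sub in genio.resample_iterations(ds, cfg):
        stats_ = gendiff.gst_global(sub)
        overall.append(stats_.gdouble_st if stats_.defined else np.nan)
        mats.append(gendiff.pairwise_gst(sub, site_ids=site_ids))
    return float(np.nanmean(overall)), gendiff.aggregate_iterations(mats)


def run_basin(data: BasinData, cfg: AnalysisConfig | None = None) -> BasinResult:
    cfg = cfg or AnalysisConfig()

    # --- genotype stage -------------------------------------------------
    filtered: dict[str, GenotypeDataset] = {}
    excluded = []
    for ds in data.genotypes:
        try:
            fds, report = genio.filter_genotypes(ds, cfg.filter)
        except ValueError as exc:
            raise RuntimeError(f"stage genio failed on {ds.species_id}: {exc}")
        elig = genio.check_species_eligibility(fds, data.site_table, cfg.filter)
        if not elig.eligible:
            logger.info(
                "%s excluded: sites below minimum individuals: %s",
                ds.species_id, elig.failing_sites,
            )
            excluded.append(ds.species_id)
            continue
        filtered[ds.species_id] = fds
    if not filtered:
        raise RuntimeError(f"stage genio: no eligible species in basin {data.name}")

    target = cfg.target_loci or min(ds.n_loci for ds in filtered.values())
    rcfg = ResampleConfig(
        n_iter=cfg.resample.n_iter,
        target_loci=target,
        max_ind_per_site=cfg.resample.max_ind_per_site,
        seed=cfg.resample.seed,
    )
    overall_gd = {}
    pairwise_gd = {}
    for sp, ds in filtered.items():
        overall_gd[sp], pairwise_gd[sp] = _resampled_gst(ds, rcfg)
    overall_gd = pd.Series(overall_gd, name="beta_gd")

    # --- community stage ------------------------------------------------
    family_beta: dict[str, dict[str, PairwiseMatrix]] = {}
    multisite_rows = []
    for fam in data.community.families:
        family_beta[fam] = betadiv.pairwise_beta(data.community, fam)
        triple = betadiv.multisite_beta(data.community, fam)
        multisite_rows.append({"family": fam, **triple.as_dict()})
    multisite = pd.DataFrame(multisite_rows)

    # --- MLPE stage -----------------------------------------------------
    fits = {}
    rows = []

    def _add(hypothesis, response, predictor, table):
        fit = mlpe.fit_mlpe(table)
        key = f"{hypothesis}:{response}"
        fits[key] = fit
        rows.append(
            {
                "hypothesis": hypothesis, "response": response,
                "predictor": predictor, "basin": data.name,
                "estimate": fit.slope, "p": fit.p_value,
                "r2m": fit.r2m, "r2c": fit.r2c,
                "n_obs": fit.n_obs, "n_groups": fit.n_groups,
                "converged": fit.converged,
            }
        )

    _add(
        "genetic_ibd", "beta_gd", "distance_km",
        mlpe.build_pair_table(pairwise_gd, data.distances),
    )
    for metric in cfg.responses:
        _add(
            "species_ibd", metric, "distance_km",
            mlpe.build_pair_table(
                {f: family_beta[f][metric] for f in family_beta}, data.distances
            ),
        )
    for metric in cfg.responses:
        _add(
            "beta_sgdc", metric, "beta_gd",
            sgdc_pairing(
                pairwise_gd,
                {f: family_beta[f][metric] for f in family_beta},
                data.species_families,
            ),
        )

    return BasinResult(
        name=data.name,
        overall_gd=overall_gd,
        pairwise_gd=pairwise_gd,
        family_beta=family_beta,
        multisite=multisite,
        fits=pd.DataFrame(rows),
        fit_objects=fits,
        excluded_species=excluded,
        n_iter=rcfg.n_iter,
        target_loci=target,
    )


@dataclass
class ExperimentResult:
    basins: dict[str, BasinResult]
    model_roster: pd.DataFrame       # table2-like
    diversity_table: pd.DataFrame    # table1-like
    anova_gd: AnovaResult
    anova_jtu: AnovaResult
    anova_pld: AnovaResult | None


def simulate_basin_data(
    basin: synth.BasinConfig, seed: int = 0
) -> BasinData:
    """Simulate seascape, distances, genotypes and communities for a basin,
    assigning genotyped species to families round-robin."""
    grid, sites = synth.simulate_seascape(basin, seed)
    graph = seadist.build_sea_graph(grid)
    distances = seadist.least_cost_distance(graph, grid, sites)
    genotypes = synth.simulate_genotypes(basin, distances, seed)
    community = synth.simulate_communities(basin, distances, seed)
    fams = sorted(community.family_map.unique())
    species_families = {
        ds.species_id: fams[i % len(fams)] for i, ds in enumerate(genotypes)
    }
    return BasinData(
        name=basin.name,
        site_table=sites,
        distances=distances,
        genotypes=genotypes,
        community=community,
        species_families=species_families,
    )


def run_two_basin_experiment(
    cfg: synth.SynthConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> ExperimentResult:
    """Full synthetic experiment: both basins end to end plus the
    between-basin ANOVA contrasts on β-GD, β_jtu and PLD."""
    cfg = cfg or synth.SynthConfig()
    analysis = analysis or AnalysisConfig()

    results: dict[str, BasinResult] = {}
    gd_vals, gd_groups = [], []
    jtu_vals, jtu_groups = [], []
    pld_vals, pld_groups = [], []
    table1_rows = []
    for basin in cfg.basins:
        data = simulate_basin_data(basin, cfg.seed)
        res = run_basin(data, analysis)
        results[basin.name] = res
        gd_vals += list(res.overall_gd.values)
        gd_groups += [basin.name] * len(res.overall_gd)
        jtu_vals += list(res.multisite["beta_jtu"])
        jtu_groups += [basin.name] * len(res.multisite)
        pld = betadiv.trait_summary(data.community)
        pld_vals += list(pld.dropna())
        pld_groups += [basin.name] * int(pld.notna().sum())
        for _, row in res.multisite.iterrows():
            table1_rows.append({"basin": basin.name, "unit": row["family"],
                                "level": "family", **row.drop("family").to_dict()})
        for sp, gd in res.overall_gd.items():
            table1_rows.append({"basin": basin.name, "unit": sp,
                                "level": "species", "beta_gd": gd})

    roster = pd.concat([r.fits for r in results.values()], ignore_index=True)
    anova_pld = None
    if len(set(pld_groups)) >= 2:
        anova_pld = ocean_anova(pld_vals, pld_groups)
    return ExperimentResult(
        basins=results,
        model_roster=roster,
        diversity_table=pd.DataFrame(table1_rows),
        anova_gd=ocean_anova(gd_vals, gd_groups),
        anova_jtu=ocean_anova(jtu_vals, jtu_groups),
        anova_pld=anova_pld,
    )


# --- summary-stage reproduction from a published-style diversity table ----

def load_two_ocean_summary() -> pd.DataFrame:
    """Bundled example diversity table: per-species genetic β-diversity
    (G''ST) and per-family Jaccard partitions for 19 reef fish species in
    five families across two ocean basins."""
    with resources.files("reefscape.data").joinpath(
        "two_ocean_beta_summary.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def summarize_two_ocean(table: pd.DataFrame) -> dict:
    """Group means/sds and between-basin ANOVA F for the per-species genetic
    β-diversity and the per-family species turnover of a diversity table."""
    gd = ocean_anova(table["beta_gd"], table["ocean"])
    fam = table.drop_duplicates(subset=["family", "ocean"])
    jtu = ocean_anova(fam["beta_jtu_sd"], fam["ocean"])
    return {
        "beta_gd": gd,
        "beta_jtu": jtu,
        "additivity_max_abs": float(
            (fam["beta_jac_sd"] - fam["beta_jtu_sd"] - fam["beta_jne_sd"])
            .abs().max()
        ),
    }
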