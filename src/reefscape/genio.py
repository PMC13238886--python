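"""Genotype and site-table I/O, quality filtering, and resampling.

The genotype container is an individuals x loci matrix of alt-allele dosages
(0/1/2, ``-1`` = missing call) for one species, with each individual assigned
to a sampling site.  Filtering follows a fixed order: (1) drop individuals
with too much missing data, (2) drop SNPs too often missing within any one
sampling site, (3) drop SNPs too often missing overall, (4) keep a single SNP
per RAD locus tag.  Denominators are recomputed after each step, so e.g. the
per-site SNP missingness is evaluated on the individuals that survived step 1.

Resampling equalizes datasets across species: each iteration draws a fixed
number of loci without replacement and caps every site at a maximum number of
individuals, with a per-iteration random stream derived from one master seed
so any iteration is reproducible in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["site_id", "name", "lon", "lat", "basin"]


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a site table (site_id, name, lon, lat, basin)."""
    missing_cols = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing_cols:
        raise ValueError(f"site table missing columns: {missing_cols}")
    if sites["site_id"].duplicated().any():
        dups = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicated site ids: {dups}")
    if not sites["lon"].between(-180, 180).all():
        raise ValueError("longitudes must lie in [-180, 180]")
    if not sites["lat"].between(-90, 90).all():
        raise ValueError("latitudes must lie in [-90, 90]")
    return sites.reset_index(drop=True)


def read_site_table(path) -> pd.DataFrame:
    return validate_site_table(pd.read_csv(path, dtype={"site_id": str}))


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for one species.

    calls[i, l] is the alt-allele dosage of individual i at locus l
    (0, 1, 2, or -1 for a missing call).
    """

    species_id: str
    individuals: list[str]
    sites: np.ndarray          # site_id per individual
    locus_tags: np.ndarray     # RAD locus tag (CHROM) per SNP
    positions: np.ndarray      # POS per SNP
    calls: np.ndarray          # (n_individuals, n_loci) int8

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=object)
        self.locus_tags = np.asarray(self.locus_tags, dtype=object)
        self.positions = np.asarray(self.positions, dtype=int)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.locus_tags)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.locus_tags)} loci"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def site_counts(self) -> pd.Series:
        return pd.Series(self.sites).value_counts()

    def subset(self, ind_idx=None, locus_idx=None) -> "GenotypeDataset":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        locus_idx = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeDataset(
            species_id=self.species_id,
            individuals=[self.individuals[i] for i in ind_idx],
            sites=self.sites[ind_idx],
            locus_tags=self.locus_tags[locus_idx],
            positions=self.positions[locus_idx],
            calls=self.calls[np.ix_(ind_idx, locus_idx)],
        )


def _site_for_sample(sample: str, site_ids: set[str],
                     sample_sites: Mapping[str, str] | None) -> str:
    if sample_sites is not None:
        if sample not in sample_sites:
            raise ValueError(f"sample {sample!r} not present in the sample-site map")
        site = sample_sites[sample]
    else:
        # convention: sample ids are "<site_id>_<individual>"
        site = sample.split("_", 1)[0]
    if site not in site_ids:
        raise ValueError(
            f"sample {sample!r} maps to site {site!r} which is not in the site table"
        )
    return site


def read_genotypes(
    vcf_path,
    site_table: pd.DataFrame,
    sample_sites: Mapping[str, str] | None = None,
    species_id: str | None = None,
) -> GenotypeDataset:
    """Read diploid GT calls from a VCF into a :class:`GenotypeDataset`.

    Only biallelic records are kept (multiallelic records are dropped and
    counted in the log).  Genotypes are decoded to alt-allele dosage; any
    call with a missing allele ("./.", ".") becomes -1.  Sample-to-site
    assignment uses ``sample_sites`` if given, otherwise the
    ``<site_id>_<individual>`` naming convention.
    """
    from cyvcf2 import VCF

    site_table = validate_site_table(site_table)
    site_ids = set(site_table["site_id"])
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sites = np.array(
        [_site_for_sample(s, site_ids, sample_sites) for s in samples], dtype=object
    )

    tags, positions, rows = [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = variant.gt_types
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        rows.append(row)
        tags.append(variant.CHROM)
        positions.append(variant.POS)
    vcf.close()
    if n_multi:
        logger.info("dropped %d multiallelic records from %s", n_multi, vcf_path)
    if not rows:
        warnings.warn(f"no biallelic variant records in {vcf_path}", stacklevel=2)
        calls = np.zeros((len(samples), 0), dtype=np.int8)
    else:
        calls = np.array(rows, dtype=np.int8).T
    if species_id is None:
        species_id = Path(str(vcf_path)).stem
    return GenotypeDataset(
        species_id=species_id,
        individuals=samples,
        sites=sites,
        locus_tags=np.array(tags, dtype=object),
        positions=np.array(positions, dtype=int),
        calls=calls,
    )


@dataclass
class FilterConfig:
    max_ind_missing: float = 0.50
    max_snp_missing_per_site: float = 0.20
    max_snp_missing_overall: float = 0.05
    first_snp_per_locus: bool = True
    min_ind_per_site: int = 3

    def __post_init__(self) -> None:
        for name in ("max_ind_missing", "max_snp_missing_per_site",
                     "max_snp_missing_overall"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not in [0, 1]")


@dataclass
class FilterReport:
    n_individuals_in: int
    n_loci_in: int
    removed_individuals: int = 0
    removed_snps_site_missing: int = 0
    removed_snps_overall_missing: int = 0
    removed_snps_locus_dedup: int = 0

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.removed_individuals

    @property
    def n_loci_out(self) -> int:
        return (self.n_loci_in - self.removed_snps_site_missing
                - self.removed_snps_overall_missing - self.removed_snps_locus_dedup)


def filter_genotypes(
    ds: GenotypeDataset, cfg: FilterConfig | None = None
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the quality filters in their fixed order; see module docstring."""
    cfg = cfg or FilterConfig()
    report = FilterReport(n_individuals_in=ds.n_individuals, n_loci_in=ds.n_loci)

    miss = ds.calls == MISSING

    # 1. individuals with too much missing data
    if ds.n_loci > 0:
        ind_frac = miss.mean(axis=1)
    else:
        ind_frac = np.zeros(ds.n_individuals)
    keep_ind = ind_frac <= cfg.max_ind_missing
    report.removed_individuals = int((~keep_ind).sum())
    if not keep_ind.any():
        raise ValueError(
            f"{ds.species_id}: dataset empty after the individual missingness filter"
        )
    ds = ds.subset(ind_idx=np.flatnonzero(keep_ind))
    miss = ds.calls == MISSING

    keep_loc = np.ones(ds.n_loci, dtype=bool)

    # 2. per-site SNP missingness, on the surviving individuals
    for site in pd.unique(ds.sites):
        rows = ds.sites == site
        frac = miss[rows].mean(axis=0)
        keep_loc &= frac <= cfg.max_snp_missing_per_site
    report.removed_snps_site_missing = int((~keep_loc).sum())
    ds = ds.subset(locus_idx=np.flatnonzero(keep_loc))
    miss = ds.calls == MISSING

    # 3. overall SNP missingness
    keep_loc = miss.mean(axis=0) <= cfg.max_snp_missing_overall if ds.n_loci else np.ones(0, bool)
    report.removed_snps_overall_missing = int((~keep_loc).sum())
    ds = ds.subset(locus_idx=np.flatnonzero(keep_loc))

    # 4. one SNP per RAD locus tag: smallest position, record order breaks ties
    if cfg.first_snp_per_locus and ds.n_loci:
        order = np.arange(ds.n_loci)
        df = pd.DataFrame({"tag": ds.locus_tags, "pos": ds.positions, "idx": order})
        first = (df.sort_values(["tag", "pos", "idx"], kind="stable")
                   .groupby("tag", sort=False).head(1)["idx"]
                   .sort_values().to_numpy())
        report.removed_snps_locus_dedup = ds.n_loci - len(first)
        ds = ds.subset(locus_idx=first)

    return ds, report


@dataclass
class EligibilityReport:
    eligible: bool
    site_counts: dict[str, int]
    failing_sites: list[str]


def check_species_eligibility(
    ds: GenotypeDataset,
    site_table: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> EligibilityReport:
    """A species is eligible when every site holds at least min_ind_per_site
    genotyped individuals."""
    cfg = cfg or FilterConfig()
    counts = ds.site_counts()
    site_counts = {
        str(s): int(counts.get(s, 0)) for s in site_table["site_id"]
    }
    failing = [s for s, n in site_counts.items() if n < cfg.min_ind_per_site]
    return EligibilityReport(
        eligible=not failing, site_counts=site_counts, failing_sites=failing
    )


@dataclass
class ResampleConfig:
    n_iter: int = 999
    target_loci: int = 2852
    max_ind_per_site: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.target_loci < 1:
            raise ValueError("target_loci must be >= 1")


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Random stream for one resampling iteration, derived from the master
    seed so iteration i is reproducible without replaying iterations < i."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def resample_once(
    ds: GenotypeDataset, cfg: ResampleConfig, iteration: int
) -> GenotypeDataset:
    if ds.n_loci < cfg.target_loci:
        raise ValueError(
            f"{ds.species_id}: {ds.n_loci} loci available but target_loci="
            f"{cfg.target_loci}; lower the target"
        )
    rng = iteration_rng(cfg.seed, iteration)
    locus_idx = np.sort(rng.choice(ds.n_loci, size=cfg.target_loci, replace=False))
    keep: list[int] = []
    for site in pd.unique(ds.sites):
        idx = np.flatnonzero(ds.sites == site)
        n_keep = min(cfg.max_ind_per_site, len(idx))
        keep.extend(rng.choice(idx, size=n_keep, replace=False))
    keep = np.sort(np.asarray(keep))
    return ds.subset(ind_idx=keep, locus_idx=locus_idx)


def resample_iterations(
    ds: GenotypeDataset, cfg: ResampleConfig
) -> Iterator[tuple[int, GenotypeDataset]]:
    """Yield (iteration, subsampled dataset) for each resampling iteration."""
    for i in range(cfg.n_iter):
        yield i, resample_once(ds, cfg, i)


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write the dataset as a minimal VCF 4.2 text file (GT only)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for tag in pd.unique(ds.locus_tags):
            fh.write(f"##contig=<ID={tag}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.individuals) + "\n")
        for l in range(ds.n_loci):
            gts = "\t".join(gt_map[int(v)] for v in ds.calls[:, l])
            fh.write(
                f"{ds.locus_tags[l]}\t{ds.positions[l]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
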