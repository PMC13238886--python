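"""Species beta-diversity: Jaccard dissimilarity partitioned into turnover
and nestedness (Baselga 2010, 2012), pairwise and multiple-site, per family.

For a site pair with a shared species, b and c site-exclusive species:

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 min(b, c) / (a + 2 min(b, c))
    beta_jne = beta_jac - beta_jtu

Per-family metrics subset the incidence table to the family's species but
keep every site: a site with no family members simply contributes its full
partner richness as exclusives.  A pair where *both* sites lack the family is
undefined (nan) and later dropped from pair tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairwise import PairwiseMatrix

BETA_METRICS = ("beta_jac", "beta_jtu", "beta_jne")


@dataclass
class CommunityTable:
    """Site x species incidence with a species-to-family map and optional
    per-species traits (genus, pelagic larval duration in days)."""

    incidence: pd.DataFrame            # sites x species, strictly 0/1
    family_map: pd.Series              # species -> family
    traits: pd.DataFrame | None = None  # columns: species, genus, pld_days

    def __post_init__(self) -> None:
        vals = self.incidence.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("incidence table must be strictly binary")
        unmapped = [s for s in self.incidence.columns if s not in self.family_map.index]
        if unmapped:
            raise ValueError(f"species without a family: {unmapped}")

    @property
    def sites(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def families(self) -> list[str]:
        fams = self.family_map.loc[list(self.incidence.columns)]
        return sorted(fams.unique())

    def family_incidence(self, family: str | None) -> pd.DataFrame:
        if family is None:
            return self.incidence
        members = [
            s for s in self.incidence.columns if self.family_map[s] == family
        ]
        if not members:
            raise ValueError(
                f"unknown family {family!r}; available: {self.families}"
            )
        return self.incidence[members]


@dataclass
class BetaTriple:
    beta_jac: float
    beta_jtu: float
    beta_jne: float

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_jac": self.beta_jac,
            "beta_jtu": self.beta_jtu,
            "beta_jne": self.beta_jne,
        }


def _pair_triple(a: int, b: int, c: int) -> tuple[float, float, float]:
    if a + b + c == 0:
        return np.nan, np.nan, np.nan
    jac = (b + c) / (a + b + c)
    denom = a + 2 * min(b, c)
    jtu = 2 * min(b, c) / denom if denom else 0.0
    return jac, jtu, jac - jtu


def pairwise_beta(
    community: CommunityTable, family: str | None = None
) -> dict[str, PairwiseMatrix]:
    """Pairwise Jaccard triple between sites, as three PairwiseMatrix."""
    inc = community.family_incidence(family).to_numpy(dtype=bool)
    sites = community.sites
    n = len(sites)
    out = {m: np.zeros((n, n)) for m in BETA_METRICS}
    for i in range(n):
        for j in range(i + 1, n):
            a = int((inc[i] & inc[j]).sum())
            b = int((inc[i] & ~inc[j]).sum())
            c = int((inc[j] & ~inc[i]).sum())
            jac, jtu, jne = _pair_triple(a, b, c)
            for m, v in zip(BETA_METRICS, (jac, jtu, jne)):
                out[m][i, j] = out[m][j, i] = v
    return {
        m: PairwiseMatrix(site_ids=list(sites), values=out[m], metric=m)
        for m in BETA_METRICS
    }


def multisite_beta(community: CommunityTable, family: str | None = None) -> BetaTriple:
    """Multiple-site Jaccard partition over all sites jointly."""
    inc = community.family_incidence(family).to_numpy(dtype=bool)
    n = inc.shape[0]
    if n < 2:
        return BetaTriple(np.nan, np.nan, np.nan)
    sum_si = int(inc.sum())
    st = int(inc.any(axis=0).sum())
    smin = smax = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            b = int((inc[i] & ~inc[j]).sum())
            c = int((inc[j] & ~inc[i]).sum())
            smin += min(b, c)
            smax += max(b, c)
    if sum_si - st + smin + smax == 0:
        return BetaTriple(np.nan, np.nan, np.nan)
    jtu_den = sum_si - st + 2 * smin
    jtu = 2 * smin / jtu_den if jtu_den else 0.0
    jac = (smin + smax) / (sum_si - st + smin + smax)
    return BetaTriple(beta_jac=jac, beta_jtu=jtu, beta_jne=jac - jtu)


def trait_summary(
    community: CommunityTable, family: str | None = None
) -> pd.Series:
    """Pelagic larval duration per species, with a genus-median fallback.

    A species keeps its recorded PLD; a species without one gets the median
    PLD of congeners that have data; otherwise it stays missing (and is
    simply absent from downstream trait comparisons).
    """
    if community.traits is None:
        raise ValueError("community table has no trait data")
    species = list(community.family_incidence(family).columns)
    traits = community.traits.set_index("species")
    genus_median = (
        community.traits.dropna(subset=["pld_days"])
        .groupby("genus")["pld_days"].median()
    )
    out = {}
    for sp in species:
        if sp in traits.index and pd.notna(traits.loc[sp, "pld_days"]):
            out[sp] = float(traits.loc[sp, "pld_days"])
        elif sp in traits.index and traits.loc[sp, "genus"] in genus_median.index:
            out[sp] = float(genus_median[traits.loc[sp, "genus"]])
        else:
            out[sp] = np.nan
    return pd.Series(out, name="pld_days")


def read_community(
    incidence_csv, family_csv, traits_csv=None
) -> CommunityTable:
    """Load a community table from CSVs: incidence (rows = sites, columns =
    species, 0/1 cells), family map (species,family), optional traits
    (species,genus,pld_days)."""
    incidence = pd.read_csv(incidence_csv, index_col=0)
    fam = pd.read_csv(family_csv).set_index("species")["family"]
    traits = pd.read_csv(traits_csv) if traits_csv is not None else None
    return CommunityTable(incidence=incidence, family_map=fam, traits=traits)
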