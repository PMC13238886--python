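import numpy as np
import pandas as pd
import pytest

from reefscape.genio import GenotypeDataset
from reefscape.pairwise import PairwiseMatrix


@pytest.fixture
def site_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": ["S1", "S2", "S3", "S4"],
            "name": ["one", "two", "three", "four"],
            "lon": [0.0, 5.0, 11.0, 19.0],
            "lat": [0.0, 0.0, 0.0, 0.0],
            "basin": ["b"] * 4,
        }
    )


def make_dataset(
    calls,
    sites,
    locus_tags=None,
    positions=None,
    species_id="sp",
) -> GenotypeDataset:
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    if locus_tags is None:
        locus_tags = [f"tag{i}" for i in range(n_loci)]
    if positions is None:
        positions = list(range(10, 10 + n_loci))
    return GenotypeDataset(
        species_id=species_id,
        individuals=[f"{s}_i{k}" for k, s in enumerate(sites)],
        sites=np.array(sites, dtype=object),
        locus_tags=np.array(locus_tags, dtype=object),
        positions=np.array(positions, dtype=int),
        calls=calls,
    )


def random_dataset(rng, n_sites=4, ind_per_site=6, n_loci=30,
                   missing_rate=0.05) -> GenotypeDataset:
    sites = [f"S{k+1}" for k in range(n_sites) for _ in range(ind_per_site)]
    p = rng.uniform(0.05, 0.95, size=(n_sites, n_loci))
    calls = np.concatenate(
        [
            rng.binomial(2, p[k], size=(ind_per_site, n_loci))
            for k in range(n_sites)
        ]
    ).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    return make_dataset(calls, sites)


def square(values, site_ids, metric="x") -> PairwiseMatrix:
    vals = np.asarray(values, float)
    return PairwiseMatrix(site_ids=list(site_ids), values=vals, metric=metric)


@pytest.fixture
def vcf_writer(tmp_path):
    """Write a hand-specified VCF body; returns path."""

    def _write(samples, records, name="test.vcf"):
        path = tmp_path / name
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples),
        ]
        for chrom, pos, ref, alt, gts in records:
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
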