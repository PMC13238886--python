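"""Genotype reading, quality filtering, eligibility and resampling."""

import numpy as np
import pandas as pd
import pytest

from reefscape.genio import (
    FilterConfig,
    ResampleConfig,
    check_species_eligibility,
    filter_genotypes,
    read_genotypes,
    resample_iterations,
    resample_once,
    validate_site_table,
    write_vcf,
)

from conftest import make_dataset, random_dataset


class TestReadGenotypes:
    def test_hand_written_gt_fields_decode_to_dosages(self, vcf_writer, site_table):
        path = vcf_writer(
            ["S1_a", "S1_b", "S2_a"],
            [
                ("tag1", 12, "A", "T", ["0/0", "0/1", "1/1"]),
                ("tag2", 7, "G", "C", ["./.", "1|1", "0/0"]),
            ],
        )
        ds = read_genotypes(path, site_table)
        assert ds.individuals == ["S1_a", "S1_b", "S2_a"]
        assert list(ds.sites) == ["S1", "S1", "S2"]
        np.testing.assert_array_equal(
            ds.calls, np.array([[0, -1], [1, 2], [2, 0]], dtype=np.int8)
        )
        assert list(ds.positions) == [12, 7]

    def test_empty_vcf_body_gives_zero_loci_with_warning(self, vcf_writer, site_table):
        path = vcf_writer(["S1_a", "S1_b", "S2_a"], [])
        with pytest.warns(UserWarning, match="no biallelic"):
            ds = read_genotypes(path, site_table)
        assert ds.n_individuals == 3
        assert ds.n_loci == 0

    def test_multiallelic_records_are_dropped(self, vcf_writer, site_table):
        path = vcf_writer(
            ["S1_a", "S2_a"],
            [
                ("tag1", 5, "A", "T", ["0/0", "0/1"]),
                ("tag2", 9, "A", "T,G", ["0/0", "0/2"]),
            ],
        )
        ds = read_genotypes(path, site_table)
        assert ds.n_loci == 1

    def test_unknown_sample_error_names_it(self, vcf_writer, site_table):
        path = vcf_writer(["S1_a", "X9"], [("tag1", 5, "A", "T", ["0/0", "0/1"])])
        with pytest.raises(ValueError, match="X9"):
            read_genotypes(path, site_table)

    def test_vcf_round_trip(self, tmp_path, site_table):
        ds = random_dataset(np.random.default_rng(1))
        write_vcf(ds, tmp_path / "rt.vcf")
        back = read_genotypes(tmp_path / "rt.vcf", site_table)
        np.testing.assert_array_equal(back.calls, ds.calls)
        assert back.individuals == ds.individuals


class TestSiteTable:
    def test_duplicate_ids_rejected(self, site_table):
        bad = pd.concat([site_table, site_table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            validate_site_table(bad)

    def test_coordinates_validated(self, site_table):
        bad = site_table.copy()
        bad.loc[0, "lon"] = 500.0
        with pytest.raises(ValueError, match="longitude"):
            validate_site_table(bad)


class TestFilterGenotypes:
    def test_individual_above_missing_cutoff_removed(self):
        # second individual has 60% missing (> 50%)
        calls = np.array(
            [[0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
             [-1, -1, -1, -1, -1, -1, 0, 1, 2, 0],
             [0, 0, 0, 0, 0, 0, 0, 0, 0, 0]],
            dtype=np.int8,
        )
        ds = make_dataset(calls, ["S1", "S1", "S2"])
        out, report = filter_genotypes(ds, FilterConfig(
            max_snp_missing_per_site=1.0, max_snp_missing_overall=1.0))
        assert report.removed_individuals == 1
        assert out.n_individuals == 2

    def test_first_snp_per_locus_keeps_smallest_position(self):
        calls = np.zeros((2, 3), dtype=np.int8)
        calls[0] = [0, 1, 2]
        ds = make_dataset(
            calls, ["S1", "S2"],
            locus_tags=["locA", "locA", "locB"],
            positions=[48, 12, 5],
        )
        out, report = filter_genotypes(ds, FilterConfig(
            max_snp_missing_per_site=1.0, max_snp_missing_overall=1.0))
        assert report.removed_snps_locus_dedup == 1
        kept = dict(zip(out.locus_tags, out.positions))
        assert kept == {"locA": 12, "locB": 5}

    def test_planted_pattern_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, n_sites=3, ind_per_site=5, n_loci=40,
                            missing_rate=0.25)
        cfg = FilterConfig(max_ind_missing=0.30, max_snp_missing_per_site=0.25,
                           max_snp_missing_overall=0.15)
        out, report = filter_genotypes(ds, cfg)

        # brute-force recount applying the three rules in order
        miss = ds.calls == -1
        keep_ind = [i for i in range(ds.n_individuals)
                    if miss[i].mean() <= cfg.max_ind_missing]
        surv = miss[keep_ind]
        surv_sites = ds.sites[keep_ind]
        keep_snp = []
        for l in range(ds.n_loci):
            ok = True
            for s in set(surv_sites):
                rows = surv_sites == s
                if surv[rows, l].mean() > cfg.max_snp_missing_per_site:
                    ok = False
            if surv[:, l].mean() > cfg.max_snp_missing_overall:
                ok = False
            if ok:
                keep_snp.append(l)
        assert out.n_individuals == len(keep_ind)
        # every tag unique in this fixture, so dedup removes nothing
        assert out.n_loci == len(keep_snp)

    def test_filtering_is_idempotent(self):
        ds = random_dataset(np.random.default_rng(3), n_loci=60,
                            missing_rate=0.05)
        once, _ = filter_genotypes(ds)
        twice, report = filter_genotypes(once)
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert report.removed_individuals == 0
        assert report.n_loci_out == once.n_loci

    def test_report_counts_are_conserved(self):
        ds = random_dataset(np.random.default_rng(5), missing_rate=0.3)
        out, r = filter_genotypes(ds)
        assert r.n_individuals_in - r.removed_individuals == out.n_individuals
        assert (r.n_loci_in - r.removed_snps_site_missing
                - r.removed_snps_overall_missing
                - r.removed_snps_locus_dedup) == out.n_loci

    def test_all_individuals_removed_raises(self):
        calls = np.full((2, 4), -1, dtype=np.int8)
        ds = make_dataset(calls, ["S1", "S2"])
        with pytest.raises(ValueError, match="empty after"):
            filter_genotypes(ds)


class TestEligibility:
    @pytest.mark.parametrize(
        "counts,expected,failing",
        [((10, 10, 10, 10), True, []), ((10, 10, 2, 10), False, ["S3"])],
    )
    def test_min_individuals_per_site(self, site_table, counts, expected, failing):
        sites = [f"S{k+1}" for k, n in enumerate(counts) for _ in range(n)]
        ds = make_dataset(np.zeros((len(sites), 2), dtype=np.int8), sites)
        rep = check_species_eligibility(ds, site_table)
        assert rep.eligible is expected
        assert rep.failing_sites == failing

    def test_five_species_fixture_with_two_failures(self, site_table):
        patterns = [(5, 5, 5, 5), (3, 3, 3, 3), (4, 0, 4, 4), (9, 9, 9, 2), (6, 7, 8, 9)]
        eligible = 0
        for counts in patterns:
            sites = [f"S{k+1}" for k, n in enumerate(counts) for _ in range(n)]
            ds = make_dataset(np.zeros((len(sites), 2), dtype=np.int8), sites)
            if check_species_eligibility(ds, site_table).eligible:
                eligible += 1
        assert eligible == 3


class TestResampling:
    def test_site_capped_at_maximum(self):
        sites = ["S1"] * 12 + ["S2"] * 8
        ds = make_dataset(np.zeros((20, 5), dtype=np.int8), sites)
        cfg = ResampleConfig(n_iter=3, target_loci=5, max_ind_per_site=10, seed=1)
        for _, sub in resample_iterations(ds, cfg):
            counts = sub.site_counts()
            assert counts["S1"] == 10
            assert counts["S2"] == 8

    def test_same_seed_gives_identical_sequences(self):
        ds = random_dataset(np.random.default_rng(0))
        cfg = ResampleConfig(n_iter=4, target_loci=20, max_ind_per_site=4, seed=42)
        a = [sub.calls for _, sub in resample_iterations(ds, cfg)]
        b = [sub.calls for _, sub in resample_iterations(ds, cfg)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_iteration_reproducible_in_isolation(self):
        ds = random_dataset(np.random.default_rng(0))
        cfg = ResampleConfig(n_iter=5, target_loci=20, max_ind_per_site=4, seed=9)
        all_iters = {i: sub for i, sub in resample_iterations(ds, cfg)}
        np.testing.assert_array_equal(
            all_iters[3].calls, resample_once(ds, cfg, 3).calls
        )

    def test_retention_fraction_matches_uniform_subsampling(self):
        # a site with 12 individuals capped at 10: each individual retained
        # in ~10/12 of iterations (99% binomial band over 999 iterations)
        sites = ["S1"] * 12
        ds = make_dataset(np.zeros((12, 3), dtype=np.int8), sites)
        cfg = ResampleConfig(n_iter=999, target_loci=3, max_ind_per_site=10, seed=5)
        kept = np.zeros(12)
        for _, sub in resample_iterations(ds, cfg):
            for ind in sub.individuals:
                kept[ds.individuals.index(ind)] += 1
        frac = kept / cfg.n_iter
        p = 10 / 12
        band = 2.58 * np.sqrt(p * (1 - p) / cfg.n_iter)
        assert np.all(np.abs(frac - p) < band + 1e-9)

    def test_resampling_never_fabricates_calls(self):
        ds = random_dataset(np.random.default_rng(2))
        cfg = ResampleConfig(n_iter=2, target_loci=10, max_ind_per_site=3, seed=3)
        for _, sub in resample_iterations(ds, cfg):
            for k, ind in enumerate(sub.individuals):
                parent_row = ds.calls[ds.individuals.index(ind)]
                parent_cols = {
                    (t, p): i for i, (t, p) in enumerate(
                        zip(ds.locus_tags, ds.positions))
                }
                for j, key in enumerate(zip(sub.locus_tags, sub.positions)):
                    assert sub.calls[k, j] == parent_row[parent_cols[key]]

    def test_too_few_loci_raises_with_advice(self):
        ds = random_dataset(np.random.default_rng(1), n_loci=5)
        cfg = ResampleConfig(n_iter=1, target_loci=10, seed=0)
        with pytest.raises(ValueError, match="lower the target"):
            resample_once(ds, cfg, 0)
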