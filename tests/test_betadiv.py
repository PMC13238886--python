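"""Jaccard dissimilarity partitioning, pairwise and multiple-site."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefscape.betadiv import (
    CommunityTable,
    multisite_beta,
    pairwise_beta,
    trait_summary,
)
from reefscape.reference import ref_beta_multi, ref_beta_pair


def community(incidence_rows, species=None, families=None, traits=None):
    n_sp = len(incidence_rows[0])
    species = species or [f"sp{i}" for i in range(n_sp)]
    inc = pd.DataFrame(
        incidence_rows, columns=species,
        index=[f"S{i+1}" for i in range(len(incidence_rows))],
    )
    fam = pd.Series(families or {s: "fam" for s in species})
    return CommunityTable(incidence=inc, family_map=fam, traits=traits)


def random_incidence(rng, n_sites=4, n_species=20):
    rows = rng.integers(0, 2, size=(n_sites, n_species))
    return community(rows.tolist())


class TestPairwiseBeta:
    def test_identical_sites_zero(self):
        com = community([[1, 1, 0, 1], [1, 1, 0, 1]])
        mats = pairwise_beta(com)
        for m in mats.values():
            assert m.get("S1", "S2") == 0.0

    def test_disjoint_compositions_complete_turnover(self):
        com = community([[1, 1, 0, 0], [0, 0, 1, 1]])
        mats = pairwise_beta(com)
        assert mats["beta_jac"].get("S1", "S2") == 1.0
        assert mats["beta_jtu"].get("S1", "S2") == 1.0
        assert mats["beta_jne"].get("S1", "S2") == 0.0

    def test_strict_nesting_pure_nestedness(self):
        # a=5 shared, b=0, c=5 exclusive to the richer site
        rows = [[1] * 5 + [0] * 5, [1] * 10]
        com = community(rows)
        mats = pairwise_beta(com)
        assert mats["beta_jac"].get("S1", "S2") == pytest.approx(0.5)
        assert mats["beta_jtu"].get("S1", "S2") == 0.0
        assert mats["beta_jne"].get("S1", "S2") == pytest.approx(0.5)

    def test_unknown_family_error_lists_available(self):
        com = community([[1, 0], [0, 1]],
                        families={"sp0": "famA", "sp1": "famB"})
        with pytest.raises(ValueError, match="famA"):
            pairwise_beta(com, "famZ")

    def test_both_sites_empty_for_family_flagged(self):
        com = community(
            [[1, 0], [1, 0], [0, 0]],
            families={"sp0": "famA", "sp1": "famB"},
        )
        mats = pairwise_beta(com, "famB")
        assert np.isnan(mats["beta_jac"].get("S1", "S2"))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_arithmetic_oracle(self, seed):
        com = random_incidence(np.random.default_rng(seed))
        mats = pairwise_beta(com)
        inc = com.incidence
        for si, sj, jac in mats["beta_jac"].pairs():
            sa = set(inc.columns[inc.loc[si] == 1])
            sb = set(inc.columns[inc.loc[sj] == 1])
            rjac, rjtu, rjne = ref_beta_pair(sa, sb)
            assert jac == pytest.approx(rjac, abs=1e-12)
            assert mats["beta_jtu"].get(si, sj) == pytest.approx(rjtu, abs=1e-12)
            assert mats["beta_jne"].get(si, sj) == pytest.approx(rjne, abs=1e-12)


class TestMultisiteBeta:
    def test_all_sites_identical_zero(self):
        com = community([[1, 0, 1]] * 4)
        t = multisite_beta(com)
        assert (t.beta_jac, t.beta_jtu, t.beta_jne) == (0.0, 0.0, 0.0)

    def test_two_sites_reduces_to_pairwise(self):
        com = random_incidence(np.random.default_rng(3), n_sites=2)
        t = multisite_beta(com)
        mats = pairwise_beta(com)
        assert t.beta_jac == pytest.approx(mats["beta_jac"].get("S1", "S2"))
        assert t.beta_jtu == pytest.approx(mats["beta_jtu"].get("S1", "S2"))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_arithmetic_oracle(self, seed):
        com = random_incidence(np.random.default_rng(100 + seed))
        t = multisite_beta(com)
        sets = [
            set(com.incidence.columns[com.incidence.loc[s] == 1])
            for s in com.sites
        ]
        rjac, rjtu, rjne = ref_beta_multi(sets)
        assert t.beta_jac == pytest.approx(rjac, abs=1e-12)
        assert t.beta_jtu == pytest.approx(rjtu, abs=1e-12)
        assert t.beta_jne == pytest.approx(rjne, abs=1e-12)

    def test_single_site_undefined(self):
        com = community([[1, 0, 1]])
        t = multisite_beta(com)
        assert np.isnan(t.beta_jac)

    def test_matches_vegan_external_oracle(self, tmp_path):
        rng = np.random.default_rng(42)
        com = random_incidence(rng, n_sites=4, n_species=25)
        t = multisite_beta(com)
        csv = tmp_path / "inc.csv"
        com.incidence.to_csv(csv)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}", row.names=1))
            v <- nestedbetajac(m)
            cat(sprintf("%.15f", c(v[["jaccard"]], v[["turnover"]],
                                   v[["nestedness"]])), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        jac, jtu, jne = map(float, out.stdout.strip().split("\n"))
        assert t.beta_jac == pytest.approx(jac, abs=1e-9)
        assert t.beta_jtu == pytest.approx(jtu, abs=1e-9)
        assert t.beta_jne == pytest.approx(jne, abs=1e-9)


@st.composite
def incidence_tables(draw):
    n_sites = draw(st.integers(2, 6))
    n_species = draw(st.integers(1, 15))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, 1), min_size=n_species, max_size=n_species),
            min_size=n_sites, max_size=n_sites,
        )
    )
    return community(rows)


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(incidence_tables())
    def test_additivity_and_bounds(self, com):
        mats = pairwise_beta(com)
        for si, sj, jac in mats["beta_jac"].pairs():
            jtu = mats["beta_jtu"].get(si, sj)
            jne = mats["beta_jne"].get(si, sj)
            if np.isnan(jac):
                continue
            assert abs(jac - jtu - jne) < 1e-12
            assert 0 <= jtu <= jac <= 1
        t = multisite_beta(com)
        if not np.isnan(t.beta_jac):
            assert abs(t.beta_jac - t.beta_jtu - t.beta_jne) < 1e-12
            assert 0 <= t.beta_jtu <= t.beta_jac <= 1

    def test_invariant_to_site_and_species_permutation(self):
        rng = np.random.default_rng(9)
        com = random_incidence(rng)
        t = multisite_beta(com)
        inc = com.incidence
        shuffled = CommunityTable(
            incidence=inc.sample(frac=1, axis=0, random_state=1)
                          .sample(frac=1, axis=1, random_state=2),
            family_map=com.family_map,
        )
        t2 = multisite_beta(shuffled)
        assert t2.beta_jac == pytest.approx(t.beta_jac, abs=1e-12)
        assert t2.beta_jtu == pytest.approx(t.beta_jtu, abs=1e-12)

    def test_globally_absent_species_changes_nothing(self):
        com = random_incidence(np.random.default_rng(10))
        t = multisite_beta(com)
        inc = com.incidence.copy()
        inc["ghost"] = 0
        fam = pd.concat([com.family_map, pd.Series({"ghost": "fam"})])
        t2 = multisite_beta(CommunityTable(incidence=inc, family_map=fam))
        assert t2.beta_jac == pytest.approx(t.beta_jac, abs=1e-12)

    def test_removing_shared_species_never_decreases_jaccard(self):
        rng = np.random.default_rng(12)
        com = random_incidence(rng, n_sites=2)
        inc = com.incidence
        shared = [c for c in inc.columns if inc[c].all()]
        if not shared:
            inc[inc.columns[0]] = 1
            shared = [inc.columns[0]]
        before = pairwise_beta(com)["beta_jac"].get("S1", "S2")
        inc2 = inc.drop(columns=shared[0])
        com2 = CommunityTable(incidence=inc2, family_map=com.family_map)
        after = pairwise_beta(com2)["beta_jac"].get("S1", "S2")
        assert after >= before - 1e-12


class TestTraitSummary:
    def make_community(self, traits):
        return community(
            [[1, 1, 1], [1, 1, 1]],
            species=["g1_a", "g1_b", "g2_a"],
            traits=pd.DataFrame(traits),
        )

    def test_recorded_pld_passes_through(self):
        com = self.make_community(
            {"species": ["g1_a", "g1_b", "g2_a"],
             "genus": ["g1", "g1", "g2"],
             "pld_days": [28.0, 20.0, 35.0]}
        )
        assert trait_summary(com)["g1_a"] == 28.0

    def test_missing_pld_uses_genus_median(self):
        com = community(
            [[1, 1, 1, 1]],
            species=["g1_a", "g1_b", "g1_c", "g1_d"],
            traits=pd.DataFrame(
                {"species": ["g1_a", "g1_b", "g1_c", "g1_d"],
                 "genus": ["g1"] * 4,
                 "pld_days": [np.nan, 20.0, 30.0, 40.0]}
            ),
        )
        assert trait_summary(com)["g1_a"] == 30.0

    def test_genus_without_data_stays_missing(self):
        com = self.make_community(
            {"species": ["g1_a", "g1_b", "g2_a"],
             "genus": ["g1", "g1", "g2"],
             "pld_days": [28.0, 20.0, np.nan]}
        )
        assert np.isnan(trait_summary(com)["g2_a"])
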