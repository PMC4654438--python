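import numpy as np
import pandas as pd
import pytest

from locuspop.differentiation import (amova, fst_spectrum_summary,
                                      multilocus_fst, pairwise_fst,
                                      wc_components, wc_fst_per_locus)
from locuspop.genotype_io import GenotypeMatrix
from locuspop.synthetic_data import SimulationConfig, simulate_balding_nichols

from conftest import manifest_from_labels


def wc_oracle(n, p, h):
    """Direct transcription of the Weir-Cockerham component formulas for one
    locus, r groups, from diploid counts n, frequencies p, het freqs h."""
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    r = len(n)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestPerLocusFst:
    def test_components_match_hand_evaluation(self, two_group_geno):
        """2 groups of 10 diploids at p=0.9/0.1 with 2 hets each: the
        vectorised components equal the scalar formula evaluation."""
        geno, labels = two_group_geno
        res = wc_fst_per_locus(geno, labels)
        a, b, c = wc_oracle([10, 10], [0.9, 0.1], [0.2, 0.2])
        assert res["a"].item() == pytest.approx(a, abs=1e-10)
        assert res["b"].item() == pytest.approx(b, abs=1e-10)
        assert res["c"].item() == pytest.approx(c, abs=1e-10)
        assert res["fst"].item() == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_identical_groups_near_zero(self):
        row = [0] * 5 + [1] * 3 + [2] * 2
        dos = np.array([row + row], dtype=np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(20)], dos)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        fst = wc_fst_per_locus(geno, labels)["fst"].item()
        assert fst <= 0  # identical samples: estimate is slightly negative
        assert abs(fst) < 0.1

    def test_fixed_difference_is_one(self):
        dos = np.array([[2] * 10 + [0] * 10], dtype=np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(20)], dos)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        assert wc_fst_per_locus(geno, labels)["fst"].item() == pytest.approx(1.0)

    def test_monomorphic_locus_flagged(self):
        dos = np.zeros((1, 20), dtype=np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(20)], dos)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        assert np.isnan(wc_fst_per_locus(geno, labels)["fst"].item())

    def test_allele_relabeling_invariance(self, two_group_geno):
        geno, labels = two_group_geno
        flipped = GenotypeMatrix(geno.samples, (2 - geno.dosages).astype(np.int8))
        f1 = wc_fst_per_locus(geno, labels)["fst"].item()
        f2 = wc_fst_per_locus(flipped, labels)["fst"].item()
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_group_label_permutation_invariance(self, two_group_geno):
        geno, labels = two_group_geno
        swapped = np.where(labels == "A", "B", "A")
        f1 = wc_fst_per_locus(geno, labels)["fst"].item()
        f2 = wc_fst_per_locus(geno, swapped)["fst"].item()
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_permutation_requires_seed(self, two_group_geno):
        geno, labels = two_group_geno
        with pytest.raises(ValueError, match="seed"):
            wc_fst_per_locus(geno, labels, n_permutations=10)


class TestMultilocusFst:
    def test_single_locus_identity(self, two_group_geno):
        geno, labels = two_group_geno
        res = wc_fst_per_locus(geno, labels)
        ml = multilocus_fst(res)
        assert ml.ratio_of_sums == pytest.approx(res["fst"].item())
        assert ml.mean_of_ratios == pytest.approx(res["fst"].item())

    def test_identical_loci_identity(self, two_group_geno):
        geno, labels = two_group_geno
        dos = np.repeat(geno.dosages, 5, axis=0)
        geno5 = GenotypeMatrix(geno.samples, dos)
        ml = multilocus_fst(wc_fst_per_locus(geno5, labels))
        single = wc_fst_per_locus(geno, labels)["fst"].item()
        assert ml.ratio_of_sums == pytest.approx(single, abs=1e-12)

    def test_matches_independent_resummation(self):
        """Ratio-of-sums over 50 loci equals an explicit per-row re-summation."""
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(40)], dos)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        res = wc_fst_per_locus(geno, labels)
        ml = multilocus_fst(res)
        num = den = 0.0
        for row in res.dropna(subset=["fst"]).itertuples():
            num += row.a
            den += row.a + row.b + row.c
        assert ml.ratio_of_sums == pytest.approx(num / den, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            multilocus_fst(pd.DataFrame({"a": [], "b": [], "c": [], "fst": []}))


class TestPairwiseFst:
    def test_matrix_symmetry_zero_diagonal(self, small_sim):
        geno, _, manifest, _ = small_sim
        m, p = pairwise_fst(geno, manifest, "group", n_permutations=0, seed=1)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 0.0)

    def test_random_split_of_one_unit_is_null(self):
        """Splitting a panmictic pool at random gives fst ~ 0, large p."""
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, size=(100, 1)),
                           size=(100, 60)).astype(np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(60)], dos)
        manifest = manifest_from_labels(
            geno.samples, ["P1"] * 30 + ["P2"] * 30, ["G1"] * 30 + ["G2"] * 30)
        m, p = pairwise_fst(geno, manifest, "group", n_permutations=200, seed=4)
        assert abs(m.iloc[0, 1]) < 0.02
        assert p.iloc[0, 1] > 0.05

    def test_recovers_generating_differentiation(self):
        """Two populations simulated at F=0.2 (n=100 each, 500 loci):
        the pairwise estimate lands within +-0.03 of the parameter."""
        cfg = SimulationConfig(
            seed=21, groups=[("G1", [("P1", 100)]), ("G2", [("P2", 100)])],
            n_variants=500, region_start=1, region_length=100_000,
            F_between_groups=0.2, F_between_pops_within_group=0.0,
            ancestral_maf={"low": 0.05, "high": 0.5, "rare_fraction": 0.0})
        geno, _, manifest, _ = simulate_balding_nichols(cfg)
        m, _ = pairwise_fst(geno, manifest, "group", n_permutations=0, seed=1)
        assert m.iloc[0, 1] == pytest.approx(0.2, abs=0.03)


class TestAmova:
    def test_components_match_sums_of_squares_oracle(self):
        """2 groups x 2 populations x 20 diploids, 20 loci: components match
        a naive per-copy sums-of-squares/mean-squares decomposition."""
        rng = np.random.default_rng(17)
        cfg = SimulationConfig(
            seed=33,
            groups=[("G1", [("P1", 20), ("P2", 20)]),
                    ("G2", [("P3", 20), ("P4", 20)])],
            n_variants=20, region_start=1, region_length=5000,
            F_between_groups=0.1, F_between_pops_within_group=0.05,
            ancestral_maf={"low": 0.1, "high": 0.5, "rare_fraction": 0.0})
        geno, _, manifest, _ = simulate_balding_nichols(cfg)
        res = amova(geno, manifest, n_permutations=0, seed=None)

        # oracle: loop over gene copies, populations and groups
        pops = manifest.populations
        pop_of = manifest.aligned_labels(geno.samples, "population")
        group_of_pop = manifest.table.drop_duplicates("population").set_index(
            "population")["group"]
        H = geno.haplotype_matrix()  # loci x copies
        copy_pop = np.repeat(pop_of, 2)
        s2a_t = s2b_t = s2c_t = 0.0
        for locus in range(H.shape[0]):
            y = H[locus].astype(float)
            ss_wp = ss_ap = ss_ag = 0.0
            gmeans = {}
            for g in manifest.groups:
                sel = np.array([group_of_pop[p] == g for p in copy_pop])
                gmeans[g] = y[sel].mean()
                ss_ag += sel.sum() * (gmeans[g] - y.mean()) ** 2
            for p in pops:
                sel = copy_pop == p
                pm = y[sel].mean()
                ss_wp += ((y[sel] - pm) ** 2).sum()
                ss_ap += sel.sum() * (pm - gmeans[group_of_pop[p]]) ** 2
            N = len(y)
            P, G = len(pops), len(manifest.groups)
            ms_wp = ss_wp / (N - P)
            ms_ap = ss_ap / (P - G)
            ms_ag = ss_ag / (G - 1)
            n_p = np.array([(copy_pop == p).sum() for p in pops], float)
            n_g = np.array([sum(n_p[i] for i, p in enumerate(pops)
                                if group_of_pop[p] == g)
                            for g in manifest.groups])
            npg = sum((n_p[i] ** 2) / n_g[list(manifest.groups).index(
                group_of_pop[pops[i]])] for i in range(P))
            n1 = (N - npg) / (P - G)
            n2 = (npg - (n_p**2).sum() / N) / (G - 1)
            n3 = (N - (n_g**2).sum() / N) / (G - 1)
            c = ms_wp
            b = (ms_ap - c) / n1
            a = (ms_ag - c - n2 * b) / n3
            s2a_t += a
            s2b_t += b
            s2c_t += c
        assert res.sigma2_a == pytest.approx(s2a_t, abs=1e-10)
        assert res.sigma2_b == pytest.approx(s2b_t, abs=1e-10)
        assert res.sigma2_c == pytest.approx(s2c_t, abs=1e-10)

    def test_phi_st_identity(self, small_sim):
        geno, _, manifest, _ = small_sim
        res = amova(geno, manifest, n_permutations=0, seed=None)
        tot = res.sigma2_a + res.sigma2_b + res.sigma2_c
        assert res.phi_st == pytest.approx(
            (res.sigma2_a + res.sigma2_b) / tot, abs=1e-12)

    def test_panmictic_pool_gives_null_phis(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, (80, 1)),
                           (80, 80)).astype(np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(80)], dos)
        pops = np.repeat(["P1", "P2", "P3", "P4"], 20)
        groups = np.repeat(["G1", "G2"], 40)
        manifest = manifest_from_labels(geno.samples, pops, groups)
        res = amova(geno, manifest, n_permutations=0, seed=None)
        for phi in (res.phi_ct, res.phi_sc, res.phi_st):
            assert abs(phi) < 0.03

    def test_fixed_group_difference(self):
        """Groups fixed for alternative alleles, populations identical
        within group: Phi_CT -> 1 and Phi_SC ~ 0. A couple of loci with
        identical within-population variation keep the SC denominator
        defined without adding between-population differences."""
        fixed = [[2] * 40 + [0] * 40] * 20
        shared = [[0, 1, 2, 1] * 20]  # same pattern in every population
        dos = np.vstack(fixed + shared).astype(np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(80)], dos)
        pops = np.repeat(["P1", "P2", "P3", "P4"], 20)
        groups = np.repeat(["G1", "G2"], 40)
        manifest = manifest_from_labels(geno.samples, pops, groups)
        res = amova(geno, manifest, n_permutations=0, seed=None)
        assert res.phi_ct > 0.95
        assert res.phi_sc == pytest.approx(0.0, abs=0.05)

    def test_single_group_degenerate(self, small_sim):
        geno, _, manifest, _ = small_sim
        t = manifest.table.copy()
        t["group"] = "G1"
        from locuspop.genotype_io import SampleManifest
        with pytest.raises(ValueError, match="2 groups"):
            amova(geno, SampleManifest(t), n_permutations=0)

    def test_one_population_per_group_matches_two_group_fst(self):
        """With one population per group the design collapses to two levels
        and Phi_CT tracks the pairwise-style WC fst on the same data."""
        cfg = SimulationConfig(
            seed=9, groups=[("G1", [("P1", 50)]), ("G2", [("P2", 50)])],
            n_variants=300, region_start=1, region_length=50_000,
            F_between_groups=0.1, F_between_pops_within_group=0.0,
            ancestral_maf={"low": 0.05, "high": 0.5, "rare_fraction": 0.0})
        geno, _, manifest, _ = simulate_balding_nichols(cfg)
        res = amova(geno, manifest, n_permutations=0, seed=None)
        labels = manifest.aligned_labels(geno.samples, "group")
        ml = multilocus_fst(wc_fst_per_locus(geno, labels))
        assert res.sigma2_b == 0.0
        assert res.phi_ct == pytest.approx(ml.ratio_of_sums, abs=0.02)

    def test_permutation_p_values_detect_structure(self, small_sim):
        geno, _, manifest, _ = small_sim
        res = amova(geno, manifest, n_permutations=99, seed=12)
        assert res.p_phi_st == pytest.approx(0.01, abs=0.005)


class TestSpectrumSummary:
    def test_constant_values(self):
        df = pd.DataFrame({"fst": [0.2] * 5})
        s = fst_spectrum_summary(df)
        assert s["median_fst"] == 0.2
        assert s["fraction_below"] == 0.0

    def test_mixed_values(self):
        s = fst_spectrum_summary(pd.DataFrame({"fst": [0.0, 0.05, 0.2]}))
        assert s["median_fst"] == 0.05
        assert s["fraction_below"] == pytest.approx(2 / 3)

    def test_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.random(1000)
        vals[rng.random(1000) < 0.05] = np.nan  # undefined loci excluded
        s = fst_spectrum_summary(pd.DataFrame({"fst": vals}))
        clean = np.sort(vals[~np.isnan(vals)])
        mid = (clean[len(clean) // 2 - 1] + clean[len(clean) // 2]) / 2 \
            if len(clean) % 2 == 0 else clean[len(clean) // 2]
        assert s["median_fst"] == pytest.approx(mid, abs=1e-12)
        assert s["fraction_below"] == pytest.approx(
            (clean < 0.10).sum() / len(clean), abs=1e-12)
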