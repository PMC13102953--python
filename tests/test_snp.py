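"""SNP statistics against independent oracles, and window integration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from sexscan.simulate import SimulationConfig, simulate_cohort
from sexscan.snp import (
    ScanParameters,
    density_permutation_test,
    integrate_windows,
    per_sex_pi,
    per_sex_snp_density,
    randomisation_control,
    scaled_top_k,
    sex_association,
    site_fst,
    snp_scan,
)
from sexscan.variants import GenotypeTable

from conftest import make_cohort, make_table


def wc_theta_scalar(genos_m, genos_f):
    """Independent scalar evaluation of the two-group Weir–Cockerham (1984)
    per-site estimator, written directly from the textbook formulas."""
    g1 = [g for g in genos_m if g >= 0]
    g2 = [g for g in genos_f if g >= 0]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return None
    r = 2
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a / (a + b + c)


class TestSiteFst:
    def test_all_male_het_gives_half(self, cohort_13v13):
        """13 males het vs 13 females hom-ref: a=0.125, b=−0.125, c=0.25,
        θ̂ = 0.5."""
        g = make_table([[1] * 13 + [0] * 13], cohort_13v13.ids)
        row = site_fst(g, cohort_13v13).iloc[0]
        assert row["a"] == pytest.approx(0.125)
        assert row["b"] == pytest.approx(-0.125)
        assert row["c"] == pytest.approx(0.25)
        assert row["theta"] == pytest.approx(0.5)

    def test_fixed_difference_gives_one(self, cohort_13v13):
        g = make_table([[2] * 13 + [0] * 13], cohort_13v13.ids)
        assert site_fst(g, cohort_13v13)["theta"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_site_undefined(self, cohort_13v13):
        g = make_table([[0] * 26], cohort_13v13.ids)
        row = site_fst(g, cohort_13v13).iloc[0]
        assert not row["defined"]
        assert np.isnan(row["theta"])

    def test_too_few_calls_in_one_sex_undefined(self):
        cohort = make_cohort(3, 3)
        g = make_table([[1, -1, -1, 0, 0, 2]], cohort.ids)
        assert not site_fst(g, cohort)["defined"].iloc[0]

    def test_matches_independent_scalar_oracle(self):
        """Vectorised θ̂ equals the independently coded per-site formula on
        random genotype fixtures with missingness."""
        rng = np.random.default_rng(7)
        cohort = make_cohort(8, 9)
        rows = rng.choice([-1, 0, 1, 2], size=(60, 17), p=[0.05, 0.45, 0.3, 0.2])
        g = make_table(rows, cohort.ids)
        out = site_fst(g, cohort)
        males = cohort.male_mask()
        for i in range(60):
            expected = wc_theta_scalar(rows[i][males], rows[i][~males])
            if expected is None:
                assert not out["defined"].iloc[i]
            else:
                assert out["theta"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_allele_swap(self):
        rng = np.random.default_rng(8)
        cohort = make_cohort(6, 6)
        rows = rng.choice([0, 1, 2], size=(40, 12))
        g = make_table(rows, cohort.ids)
        swapped = make_table(2 - rows, cohort.ids)
        a = site_fst(g, cohort)["theta"]
        b = site_fst(swapped, cohort)["theta"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invariant_under_sex_swap(self):
        rng = np.random.default_rng(9)
        cohort = make_cohort(5, 7)
        rows = rng.choice([0, 1, 2], size=(30, 12))
        g = make_table(rows, cohort.ids)
        flipped = cohort.with_sexes(["F" if s == "M" else "M" for s in cohort.sexes])
        np.testing.assert_allclose(
            site_fst(g, cohort)["theta"], site_fst(g, flipped)["theta"], atol=1e-12
        )


class TestSexAssociation:
    def test_perfect_separation_16_samples(self):
        """8 females hom-alt vs 8 males hom-ref: χ² equals the 32 alleles,
        p = 1.542e-08."""
        cohort = make_cohort(8, 8)
        g = make_table([[0] * 8 + [2] * 8], cohort.ids)
        row = sex_association(g, cohort).iloc[0]
        assert row["chi2"] == pytest.approx(32.0)
        assert row["p"] == pytest.approx(1.542e-8, rel=1e-3)

    def test_all_male_het_13v13(self, cohort_13v13):
        g = make_table([[1] * 13 + [0] * 13], cohort_13v13.ids)
        row = sex_association(g, cohort_13v13).iloc[0]
        assert row["chi2"] == pytest.approx(52 * (13 * 26) ** 2 / (26 * 26 * 13 * 39))
        assert row["p"] == pytest.approx(3.1e-5, rel=0.02)

    def test_equal_frequencies_give_null(self, cohort_3v3):
        g = make_table([[1, 0, 2, 1, 0, 2]], cohort_3v3.ids)
        row = sex_association(g, cohort_3v3).iloc[0]
        assert row["chi2"] == 0.0
        assert row["p"] == 1.0

    def test_degenerate_margin_gives_p_one(self, cohort_3v3):
        g = make_table([[0] * 6], cohort_3v3.ids)
        assert sex_association(g, cohort_3v3)["p"].iloc[0] == 1.0

    def test_matches_generic_contingency_oracle(self):
        """χ² agrees with scipy's contingency test (no continuity
        correction) on random allele tables."""
        rng = np.random.default_rng(10)
        cohort = make_cohort(7, 9)
        rows = rng.choice([-1, 0, 1, 2], size=(40, 16), p=[0.05, 0.4, 0.3, 0.25])
        g = make_table(rows, cohort.ids)
        out = sex_association(g, cohort)
        males = cohort.male_mask()
        for i in range(40):
            gm = rows[i][males]
            gf = rows[i][~males]
            table = np.array(
                [
                    [2 * (gm >= 0).sum() - gm[gm >= 0].sum(), gm[gm >= 0].sum()],
                    [2 * (gf >= 0).sum() - gf[gf >= 0].sum(), gf[gf >= 0].sum()],
                ]
            )
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                assert out["p"].iloc[i] == 1.0
                continue
            chi2, p, _, _ = chi2_contingency(table, correction=False)
            assert out["chi2"].iloc[i] == pytest.approx(chi2, abs=1e-9)
            assert out["p"].iloc[i] == pytest.approx(p, rel=1e-9)


class TestDensityAndPi:
    def test_density_counts_by_construction(self, cohort_3v3):
        rows = [[1, 1, 1, 0, 0, 0]] * 7  # het in males only
        g = make_table(rows, cohort_3v3.ids)
        d = per_sex_snp_density(g, cohort_3v3, w=10_000)
        assert d["density_m"].iloc[0] == 7
        assert d["density_f"].iloc[0] == 0

    def test_pi_matches_pairwise_enumeration(self):
        """Window π equals the mean pairwise difference over haplotypes,
        enumerated brute-force on ≤8 haplotypes."""
        rng = np.random.default_rng(11)
        cohort = make_cohort(4, 4)
        rows = rng.choice([0, 1, 2], size=(25, 8))
        g = make_table(rows, cohort.ids, spacing=10)
        out = per_sex_pi(g, cohort, w=1000)
        males = cohort.male_mask()
        for label, mask in (("pi_m", males), ("pi_f", ~males)):
            total = 0.0
            for row in rows:
                # expand genotypes into haplotype alleles (0/1)
                haps = []
                for code in row[mask]:
                    haps += [[0, 0], [0, 1], [1, 1]][code]
                n = len(haps)
                pairs = n * (n - 1) / 2
                diff = sum(
                    1
                    for i in range(n)
                    for j in range(i + 1, n)
                    if haps[i] != haps[j]
                )
                total += diff / pairs
            assert out[label].iloc[0] == pytest.approx(total / 1000, abs=1e-12)

    def test_single_site_two_diploids(self):
        """One site, 4 haplotypes, two alt alleles: π = 2·(1/2)·(1/2)·(4/3)
        = 2/3, matching 4 differing pairs / 6."""
        cohort = make_cohort(2, 2)
        g = make_table([[1, 1, 0, 0]], cohort.ids)
        out = per_sex_pi(g, cohort, w=1)
        assert out["pi_m"].iloc[0] == pytest.approx(2 / 3)
        assert out["pi_f"].iloc[0] == 0.0

    def test_sex_swap_swaps_columns(self):
        rng = np.random.default_rng(12)
        cohort = make_cohort(5, 5)
        rows = rng.choice([0, 1, 2], size=(30, 10))
        g = make_table(rows, cohort.ids)
        flipped = cohort.with_sexes(["F" if s == "M" else "M" for s in cohort.sexes])
        d1 = per_sex_snp_density(g, cohort, w=10_000)
        d2 = per_sex_snp_density(g, flipped, w=10_000)
        assert d1["density_m"].tolist() == d2["density_f"].tolist()
        p1 = per_sex_pi(g, cohort, w=10_000)
        p2 = per_sex_pi(g, flipped, w=10_000)
        np.testing.assert_allclose(p1["pi_m"], p2["pi_f"])


class TestDensityPermutation:
    def test_exhaustive_3v3_fixture(self, cohort_3v3):
        """Exactly the 3 males carry 5 het sites: of the C(6,3)=20 label
        assignments only the true one and its complement reach D=5,
        so p = 2/20 = 0.1."""
        g = make_table([[1, 1, 1, 0, 0, 0]] * 5, cohort_3v3.ids)
        out = density_permutation_test(g, cohort_3v3, w=10_000, exhaustive=True)
        assert out["d_obs"].iloc[0] == 5
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_zero_statistic_gives_p_one(self, cohort_3v3):
        g = make_table([[1, 0, 1, 1, 0, 1]] * 4, cohort_3v3.ids)
        out = density_permutation_test(g, cohort_3v3, w=10_000, exhaustive=True)
        assert out["d_obs"].iloc[0] == 0
        assert out["p"].iloc[0] == 1.0

    def test_monte_carlo_approaches_exhaustive(self, cohort_3v3):
        g = make_table([[1, 1, 1, 0, 0, 0]] * 5, cohort_3v3.ids)
        exact = density_permutation_test(g, cohort_3v3, w=10_000, exhaustive=True)
        mc = density_permutation_test(g, cohort_3v3, w=10_000, n_perm=20_000, seed=4)
        assert mc["p"].iloc[0] == pytest.approx(exact["p"].iloc[0], abs=0.01)

    def test_deterministic_under_seed(self, cohort_3v3):
        g = make_table([[1, 1, 0, 0, 0, 1]] * 6, cohort_3v3.ids)
        a = density_permutation_test(g, cohort_3v3, n_perm=500, seed=3)
        b = density_permutation_test(g, cohort_3v3, n_perm=500, seed=3)
        assert a["p"].tolist() == b["p"].tolist()


class TestIntegration:
    @staticmethod
    def _scan_sim(seed, penetrance=1.0, system="XY"):
        sim = simulate_cohort(
            SimulationConfig(system=system, seed=seed, penetrance=penetrance),
            with_sequences=False,
        )
        n_windows = 20  # 2 × 100 kb genome in 10 kb windows
        params = ScanParameters(n_perm=2000, seed=seed, top_k=scaled_top_k(n_windows))
        return sim, snp_scan(sim.genotypes, sim.cohort, params), params

    def test_implanted_window_is_candidate(self):
        sim, scan, _ = self._scan_sim(seed=31)
        (pop, chrom, start, end) = sim.truth.true_regions[0]
        assert any(
            r["chrom"] == chrom and r["start"] <= start and r["end"] >= end
            for r in scan.candidates
        )

    def test_density_difference_matches_implant(self):
        """With only the 50 fully sex-linked sites in the window (no
        background SNPs), density_M − density_F is exactly 50."""
        sim = simulate_cohort(
            SimulationConfig(system="XY", seed=32, background_snp_rate=0.0),
            with_sequences=False,
        )
        (_, chrom, start, _) = sim.truth.true_regions[0]
        d = per_sex_snp_density(sim.genotypes, sim.cohort, w=10_000)
        row = d[(d.chrom == chrom) & (d.start == start)].iloc[0]
        assert row["density_m"] - row["density_f"] == 50

    def test_adjacent_candidate_windows_merge(self):
        """A sex region spanning two windows yields one merged 2w region."""
        sim = simulate_cohort(
            SimulationConfig(
                system="XY", seed=33,
                sex_regions={"pop1": ("chr1", 20_000, 40_000)},
                n_sexlinked_snps=100,
            ),
            with_sequences=False,
        )
        params = ScanParameters(n_perm=2000, seed=33, top_k=2)
        scan = snp_scan(sim.genotypes, sim.cohort, params)
        assert len(scan.candidates) == 1
        region = scan.candidates[0]
        assert (region["start"], region["end"]) == (20_000, 40_000)
        assert region["n_windows"] == 2

    def test_randomisation_identity_labels_reproduce_candidates(self):
        """Re-running the scan with the true labels gives identical
        candidates (the control's degenerate round)."""
        sim, scan, params = self._scan_sim(seed=34)
        again = snp_scan(sim.genotypes, sim.cohort, params)
        assert again.candidates == scan.candidates

    def test_randomisation_control_reports_structure(self):
        sim, scan, params = self._scan_sim(seed=35)
        report = randomisation_control(
            sim.genotypes, sim.cohort, params, n_rounds=3, seed=1, original=scan
        )
        assert report["n_rounds"] == 3
        assert len(report["rounds"]) == 3
        assert set(report["rounds"][0]) >= {"n_candidates", "original_recurs"}
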