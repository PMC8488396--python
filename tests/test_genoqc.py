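"""QC cascade, exact HWE test, IBD duplicate detection and PCA structure."""

import numpy as np
import pandas as pd
import pytest
from math import comb

from conftest import founder_panel
from feedgenomics.data import MISSING, GenotypeData, chrom_label
from feedgenomics.genoqc import (
    QCThresholds,
    filter_genotypes,
    hwe_exact_test,
    ibd_estimates,
    pca_structure,
)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p-value from the conditional distribution."""
    n = n_AA + n_Aa + n_aa
    rare = 2 * min(n_AA, n_aa) + n_Aa
    common = 2 * n - rare
    probs = {}
    for het in range(rare % 2, min(rare, common) + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            continue
        # multinomial genotype probability given allele counts, up to the
        # shared 1/C(2n, rare) constant
        probs[het] = 2**het * comb(n, het) * comb(n - het, hom_r)
    # normalise (the expression above is proportional only)
    total = sum(probs.values())
    probs = {h: v / total for h, v in probs.items()}
    p_obs = probs[n_Aa]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        for counts in [(25, 50, 25), (40, 40, 20), (5, 10, 85), (12, 0, 12)]:
            assert hwe_exact_test(*counts) == pytest.approx(
                hwe_enumeration_oracle(*counts), rel=1e-9
            )

    def test_all_heterozygote_fails_filter(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 5, 5)


class TestFilterCascade:
    def test_low_maf_snp_removed_with_reason(self):
        geno = founder_panel(200, 50, seed=1)
        calls = geno.calls.copy()
        calls[:, 0] = 0
        calls[:4, 0] = 1  # MAF = 4/400 = 0.01
        geno = GenotypeData(geno.animals, geno.snp_map, calls)
        _, report = filter_genotypes(geno)
        row = report.snp_fail.loc[report.snp_fail["snp_id"] == "S0"]
        assert len(row) == 1 and row["reason"].iloc[0] == "maf"

    def test_monomorphic_snp_removed_despite_hwe_pass(self):
        geno = founder_panel(150, 40, seed=2)
        calls = geno.calls.copy()
        calls[:, 3] = 0
        geno = GenotypeData(geno.animals, geno.snp_map, calls)
        filtered, report = filter_genotypes(geno)
        assert "S3" not in set(filtered.snp_map["snp_id"])
        assert "maf" in report.snp_fail.set_index("snp_id").loc["S3", "reason"]

    def test_seeded_violations_recovered_exactly(self):
        rng = np.random.Generator(np.random.PCG64(11))
        geno = founder_panel(300, 2000, seed=3)
        calls = geno.calls.copy()
        # 20 SNPs: low MAF; 20 SNPs: low call rate; 20 SNPs: all-het HWE failure
        maf_snps = np.arange(0, 20)
        cr_snps = np.arange(20, 40)
        hwe_snps = np.arange(40, 60)
        for j in maf_snps:
            calls[:, j] = 0
            calls[rng.choice(300, 6, replace=False), j] = 1  # MAF 0.01
        for j in cr_snps:
            calls[rng.choice(300, 30, replace=False), j] = MISSING  # call rate 0.9
        for j in hwe_snps:
            calls[:, j] = 1
        # 3 samples with low call rate; 2 duplicated pairs
        bad_samples = [5, 17, 44]
        for i in bad_samples:
            calls[i, rng.choice(2000, 200, replace=False)] = MISSING
        calls[100] = calls[101]
        calls[200] = calls[201]
        geno = GenotypeData(geno.animals, geno.snp_map, calls)
        filtered, report = filter_genotypes(geno)
        assert report.counts_by_rule["sample_call_rate"] == 3
        assert report.counts_by_rule["maf"] == 20
        assert report.counts_by_rule["snp_call_rate"] == 20
        assert report.counts_by_rule["hwe"] == 20
        assert report.counts_by_rule["ibd_duplicate"] == 4
        assert filtered.n_animals == 300 - 3 - 4
        assert filtered.n_snps == 2000 - 60

    def test_cascade_idempotent(self):
        geno = founder_panel(120, 300, seed=4)
        calls = geno.calls.copy()
        calls[:, 5] = 0
        calls[10] = calls[11]
        geno = GenotypeData(geno.animals, geno.snp_map, calls)
        once, _ = filter_genotypes(geno)
        twice, report2 = filter_genotypes(once)
        assert np.array_equal(once.calls, twice.calls)
        assert sum(report2.counts_by_rule.values()) == 0

    def test_stage_counts_reconcile(self):
        geno = founder_panel(100, 200, seed=5)
        _, report = filter_genotypes(geno)
        sc = report.stage_counts.set_index("stage")
        assert (sc["n_samples"].diff().dropna() <= 0).all()
        assert (sc["n_snps"].diff().dropna() <= 0).all()


class TestIbd:
    def test_duplicate_sample_flagged_and_both_removed(self):
        geno = founder_panel(60, 800, seed=6)
        calls = geno.calls.copy()
        calls[1] = calls[0]
        geno = GenotypeData(geno.animals, geno.snp_map, calls)
        ibd = ibd_estimates(geno)
        pair = ibd.loc[(ibd["animal_1"] == "X0") & (ibd["animal_2"] == "X1")]
        assert pair["pi_hat"].iloc[0] > 0.95
        filtered, report = filter_genotypes(geno)
        assert {"X0", "X1"} & set(filtered.animals) == set()

    def test_unrelated_founders_mean_near_zero(self):
        # truncation of negative IBD-state estimates biases PI_HAT upward
        # at small panels, so a dense panel is needed for a tight mean
        geno = founder_panel(100, 6000, seed=7)
        ibd = ibd_estimates(geno)
        assert abs(ibd["pi_hat"].mean()) < 0.02

    def test_full_sibs_near_half(self, signal_population):
        _, _, geno, pheno, _ = signal_population
        fam = pheno.loc[pheno["family"] == "FAM002", "animal"].tolist()[:12]
        idx = [geno.animals.index(a) for a in fam]
        # estimate frequencies on the full panel context by keeping founders in
        ibd = ibd_estimates(geno.subset(animal_idx=idx + list(range(40))))
        sibs = ibd.loc[ibd["animal_1"].isin(fam) & ibd["animal_2"].isin(fam)]
        assert sibs["pi_hat"].mean() == pytest.approx(0.5, abs=0.08)

    def test_few_snps_warns(self):
        geno = founder_panel(10, 50, seed=8)
        with pytest.warns(UserWarning, match="unstable"):
            ibd_estimates(geno)


class TestPca:
    def test_diverged_subpopulations_separate_on_pc1(self):
        a = founder_panel(40, 600, seed=9, maf_range=(0.05, 0.15))
        b = founder_panel(40, 600, seed=10, maf_range=(0.35, 0.5))
        merged = GenotypeData(
            animals=[f"P{i}" for i in range(80)],
            snp_map=a.snp_map,
            calls=np.vstack([a.calls, b.calls]),
        )
        scores, _ = pca_structure(merged, n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert max(pc1[:40].min(), pc1[40:].min()) > min(pc1[:40].max(), pc1[40:].max()) or (
            pc1[:40].max() < pc1[40:].min() or pc1[40:].max() < pc1[:40].min()
        )

    def test_identical_rows_have_no_variance(self):
        calls = np.tile(np.array([0, 1, 2, 1, 0, 2], dtype=np.int8), (8, 1))
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"Q{i}" for i in range(6)],
                "chrom": chrom_label(1),
                "pos": np.arange(1, 7),
                "minor": "A",
                "major": "T",
            }
        )
        geno = GenotypeData([f"Z{i}" for i in range(8)], snp_map, calls)
        _, varexp = pca_structure(geno, n_components=2)
        assert np.allclose(varexp, 0.0)

    def test_variance_explained_is_monotone_and_bounded(self):
        geno = founder_panel(50, 300, seed=11)
        _, varexp = pca_structure(geno, n_components=5)
        assert (varexp >= 0).all()
        assert (np.diff(varexp) <= 1e-9).all()
        assert varexp.sum() <= 100.0 + 1e-9
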