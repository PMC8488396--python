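"""Genotype and sample quality control for SNP-array panels.

The cascade mirrors standard PLINK-style filtering for a family-structured
panel: sample call rate, then per-SNP call rate, minor allele frequency
and an exact Hardy-Weinberg test, and finally duplicate detection by
method-of-moments identity-by-descent, removing BOTH members of any pair
whose genome-wide IBD proportion (PI_HAT) exceeds the threshold.  All
thresholds are strict inequalities.  MAF and HWE are computed after the
sample filter by default (configurable, since the two orders differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from feedgenomics.data import GenotypeData


@dataclass
class QCThresholds:
    """Strict-inequality QC cut-offs.

    A SNP is removed when its call rate is below ``snp_call_rate``, its
    MAF is below ``maf_min`` or its exact HWE p-value is below
    ``hwe_p_min``; a sample is removed when its call rate is below
    ``sample_call_rate``; both members of a pair are removed when their
    PI_HAT exceeds ``ibd_max``.
    """

    snp_call_rate: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    sample_call_rate: float = 0.95
    ibd_max: float = 0.7

    def __post_init__(self) -> None:
        for name in ("snp_call_rate", "maf_min", "hwe_p_min", "sample_call_rate", "ibd_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class QCReport:
    """Per-stage survivor counts and per-SNP/sample failure reasons."""

    stage_counts: pd.DataFrame  # stage, n_samples, n_snps
    snp_fail: pd.DataFrame  # snp_id, reason
    sample_fail: pd.DataFrame  # animal, reason
    removed_pairs: pd.DataFrame  # animal_1, animal_2, pi_hat
    counts_by_rule: dict[str, int] = field(default_factory=dict)

    def write(self, prefix: str) -> None:
        self.stage_counts.to_csv(f"{prefix}.stages.tsv", sep="\t", index=False)
        self.snp_fail.to_csv(f"{prefix}.snp_fail.tsv", sep="\t", index=False)
        self.sample_fail.to_csv(f"{prefix}.sample_fail.tsv", sep="\t", index=False)
        self.removed_pairs.to_csv(f"{prefix}.removed_pairs.tsv", sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (of the same parity) that is no more probable
    than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples")
    rare = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    het_obs = n_Aa
    # admissible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - np.array([lgamma(h + 1) for h in hets])
        - np.array([lgamma(h + 1) for h in hom_r])
        - np.array([lgamma(h + 1) for h in hom_c])
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het_obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(geno: GenotypeData) -> np.ndarray:
    """Vector of exact HWE p-values, cached over repeated count triples."""
    counts = geno.genotype_counts()
    cache: dict[tuple[int, int, int], float] = {}
    out = np.empty(geno.n_snps)
    for i, (n0, n1, n2) in enumerate(counts):
        key = (int(n0), int(n1), int(n2))
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[i] = cache[key]
    return out


def ibd_estimates(geno: GenotypeData) -> pd.DataFrame:
    """Method-of-moments genome-wide IBD for every sample pair.

    Observed identity-by-state counts per pair are converted to
    P(IBD=0,1,2) using expectations under sample allele frequencies,
    truncated to [0,1] and renormalised; PI_HAT = P(IBD=1)/2 + P(IBD=2).
    Returns a table (animal_1, animal_2, pi_hat) over unordered pairs.
    """
    import warnings

    if geno.n_snps < 100:
        warnings.warn("fewer than 100 SNPs: IBD estimates will be unstable", stacklevel=2)
    obs_all = geno.observed()
    k_all = np.where(obs_all, geno.calls, 0).sum(axis=0).astype(float)
    Xn_all = 2.0 * obs_all.sum(axis=0)
    # only polymorphic SNPs with enough alleles carry IBD information
    ok = (k_all > 0) & (k_all < Xn_all) & (Xn_all >= 4)
    calls = geno.calls[:, ok]
    obs = obs_all[:, ok]

    # indicator matrices per genotype class, float32 for the big matmuls
    A = [np.asarray((calls == g) & obs, dtype=np.float32) for g in (0, 1, 2)]
    n_ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    n_ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    valid = np.asarray(obs, dtype=np.float32)
    n_valid = valid @ valid.T
    n_ibs1 = n_valid - n_ibs2 - n_ibs0

    def ff(x, r):
        """Falling factorial x (x-1) ... (x-r+1)."""
        out = np.ones_like(x)
        for i in range(r):
            out = out * (x - i)
        return out

    # unbiased estimators of the allele-frequency products (the plug-in
    # sample-frequency moments are biased at finite sample size and inflate
    # PI_HAT between unrelated pairs)
    kk, XX = k_all[ok], Xn_all[ok]
    qk = XX - kk

    def moment(a, b):
        return ff(kk, a) * ff(qk, b) / ff(XX, a + b)

    p2q2 = moment(2, 2)
    e0_ibd0 = float(np.sum(2 * p2q2))
    e1_ibd0 = float(np.sum(4 * moment(3, 1) + 4 * moment(1, 3)))
    e2_ibd0 = float(np.sum(moment(4, 0) + moment(0, 4) + 4 * p2q2))
    e1_ibd1 = float(np.sum(2 * moment(2, 1) + 2 * moment(1, 2)))
    e2_ibd1 = float(
        np.sum(moment(3, 0) + moment(0, 3) + moment(2, 1) + moment(1, 2))
    )
    m_eff = float(ok.sum())

    scale = np.where(n_valid > 0, m_eff / np.maximum(n_valid, 1), 0.0)
    N0, N1, N2 = n_ibs0 * scale, n_ibs1 * scale, n_ibs2 * scale
    P0 = N0 / e0_ibd0
    P1 = (N1 - P0 * e1_ibd0) / e1_ibd1
    P2 = (N2 - P0 * e2_ibd0 - P1 * e2_ibd1) / m_eff
    P = np.stack([P0, P1, P2]).clip(0, 1)
    P /= np.maximum(P.sum(axis=0), 1e-12)
    pi_hat = P[1] / 2 + P[2]

    iu = np.triu_indices(geno.n_animals, k=1)
    animals = np.asarray(geno.animals)
    return pd.DataFrame(
        {"animal_1": animals[iu[0]], "animal_2": animals[iu[1]], "pi_hat": pi_hat[iu]}
    )


def pca_structure(geno: GenotypeData, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centred, per-SNP-standardised genotype matrix.

    Missing calls are mean-imputed per SNP (never written back).  Returns
    per-animal component scores and percent variance explained.
    """
    if n_components > min(geno.n_animals, geno.n_snps):
        raise ValueError("n_components exceeds matrix rank bound")
    X = geno.dosage(impute_mean=True)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    cols = [f"PC{k + 1}" for k in range(n_components)]
    if not X.any():  # no variation at all after centring
        scores = np.zeros((geno.n_animals, n_components))
        varexp = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        varexp = pca.explained_variance_ratio_ * 100.0
    return (
        pd.DataFrame(scores, index=geno.animals, columns=cols).rename_axis("animal"),
        varexp,
    )


def filter_genotypes(
    geno: GenotypeData,
    thresholds: QCThresholds | None = None,
    maf_after_sample_filter: bool = True,
) -> tuple[GenotypeData, QCReport]:
    """Run the QC cascade: sample call rate -> SNP rules -> IBD duplicates.

    A SNP fails if it violates any of the active SNP rules (all violated
    rules are reported).  Raises if any stage empties the panel, naming
    the stage.
    """
    thresholds = thresholds or QCThresholds()
    stages = [("input", geno.n_animals, geno.n_snps)]
    sample_fail_rows: list[dict] = []
    snp_fail_rows: list[dict] = []
    counts_by_rule: dict[str, int] = {}

    # stage 1: sample call rate
    scr = geno.sample_call_rate()
    bad_sample = scr < thresholds.sample_call_rate
    for i in np.flatnonzero(bad_sample):
        sample_fail_rows.append({"animal": geno.animals[i], "reason": "sample_call_rate"})
    counts_by_rule["sample_call_rate"] = int(bad_sample.sum())
    work = geno.subset(animal_idx=np.flatnonzero(~bad_sample)) if bad_sample.any() else geno
    stages.append(("sample_call_rate", work.n_animals, work.n_snps))
    if work.n_animals == 0:
        raise ValueError("QC stage 'sample_call_rate' removed every sample")

    # stage 2: SNP rules on the post-sample-filter panel
    basis = work if maf_after_sample_filter else geno
    call = basis.snp_call_rate()
    maf = basis.allele_freq()
    maf = np.minimum(np.nan_to_num(maf), 1 - np.nan_to_num(maf))
    hwe = hwe_pvalues(basis)
    fail_call = call < thresholds.snp_call_rate
    fail_maf = maf < thresholds.maf_min
    fail_hwe = hwe < thresholds.hwe_p_min
    counts_by_rule["snp_call_rate"] = int(fail_call.sum())
    counts_by_rule["maf"] = int(fail_maf.sum())
    counts_by_rule["hwe"] = int(fail_hwe.sum())
    bad_snp = fail_call | fail_maf | fail_hwe
    for i in np.flatnonzero(bad_snp):
        reasons = [
            r
            for r, f in (("snp_call_rate", fail_call), ("maf", fail_maf), ("hwe", fail_hwe))
            if f[i]
        ]
        snp_fail_rows.append({"snp_id": work.snp_map.at[i, "snp_id"], "reason": ",".join(reasons)})
    work = work.subset(snp_idx=np.flatnonzero(~bad_snp)) if bad_snp.any() else work
    stages.append(("snp_rules", work.n_animals, work.n_snps))
    if work.n_snps == 0:
        raise ValueError("QC stage 'snp_rules' removed every SNP")

    # stage 3: IBD duplicates (both members of each flagged pair removed)
    ibd = ibd_estimates(work)
    flagged = ibd.loc[ibd["pi_hat"] > thresholds.ibd_max]
    to_drop = sorted(set(flagged["animal_1"]) | set(flagged["animal_2"]))
    for a in to_drop:
        sample_fail_rows.append({"animal": a, "reason": "ibd_duplicate"})
    counts_by_rule["ibd_duplicate"] = len(to_drop)
    if to_drop:
        keep = [i for i, a in enumerate(work.animals) if a not in set(to_drop)]
        work = work.subset(animal_idx=keep)
    stages.append(("ibd", work.n_animals, work.n_snps))
    if work.n_animals == 0:
        raise ValueError("QC stage 'ibd' removed every sample")

    report = QCReport(
        stage_counts=pd.DataFrame(stages, columns=["stage", "n_samples", "n_snps"]),
        snp_fail=pd.DataFrame(snp_fail_rows, columns=["snp_id", "reason"]),
        sample_fail=pd.DataFrame(sample_fail_rows, columns=["animal", "reason"]),
        removed_pairs=flagged.reset_index(drop=True),
        counts_by_rule=counts_by_rule,
    )
    return work, report
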