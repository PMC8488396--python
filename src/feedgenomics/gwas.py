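"""Mixed-linear-model association with leave-one-chromosome-out kinship.

For each chromosome the polygenic model (sex and batch fixed effects plus
a genomic random effect, no common-environment term) is refitted with a
genomic relationship matrix built from every OTHER chromosome, and each
SNP on the left-out chromosome is then scored as a fixed covariate (Wald
test on its GLS estimate).  Excluding the tested chromosome from the
kinship prevents the SNP's own signal from being absorbed by the
polygenic term.  SNPs without a reference position live on the artificial
chromosome (``Oni24``) and are tested against the kinship built from all
placed chromosomes.  Significance uses Bonferroni thresholds at
alpha = 1 (suggestive) and alpha = 0.05 (genome-wide) over the tested SNP
count, and QTL reporting lists annotation features overlapping a window
centred on each significant SNP.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from feedgenomics.data import GenotypeData, chrom_label
from feedgenomics.kinship import build_G
from feedgenomics.mixedmodel import MixedModelREML, design_matrix
from feedgenomics.traits import trait_values


def bonferroni_thresholds(n_snps: int) -> tuple[float, float]:
    """(suggestive, genome-wide) p-value cut-offs: 1/m and 0.05/m."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    return 1.0 / n_snps, 0.05 / n_snps


def assign_artificial_chromosome(snp_map: pd.DataFrame, n_chromosomes: int = 23) -> pd.DataFrame:
    """Relabel unplaced SNPs onto the artificial chromosome with ordinal positions.

    A SNP counts as unplaced when its chromosome is missing/empty/``0`` or
    its position is missing.  Placed SNPs are untouched.
    """
    out = snp_map.copy()
    chrom = out["chrom"].astype(object)
    unplaced = (
        chrom.isna()
        | (chrom.astype(str).str.strip().isin(["", "0", "NA", "nan", "None"]))
        | out["pos"].isna()
    )
    label = chrom_label(n_chromosomes + 1)
    out.loc[unplaced, "chrom"] = label
    out.loc[unplaced, "pos"] = np.arange(1, int(unplaced.sum()) + 1)
    out["pos"] = out["pos"].astype(int)
    return out


def loco_assoc(
    pheno: pd.DataFrame,
    geno: GenotypeData,
    trait: str,
    fixed=("sex", "batch"),
    chromosomes: list[str] | None = None,
    min_kinship_snps: int = 100,
) -> pd.DataFrame:
    """Leave-one-chromosome-out association scan for one trait.

    Returns one row per tested SNP: ``chr, snp, bp, a1, a2, freq, beta,
    se, p, tier``.  ``chromosomes`` restricts the scan (kinships still
    exclude only the tested chromosome).  Variance components are
    re-estimated once per left-out chromosome.
    """
    all_chroms = list(pd.unique(geno.snp_map["chrom"]))
    if len(all_chroms) < 2:
        raise ValueError("LOCO needs at least 2 chromosomes")
    scan = list(chromosomes) if chromosomes is not None else all_chroms

    rows = trait_values(pheno, trait).reset_index(drop=True)
    pos = {a: i for i, a in enumerate(geno.animals)}
    try:
        geno_idx = np.array([pos[str(a)] for a in rows["animal"]])
    except KeyError as e:
        raise ValueError(f"phenotyped animal {e} has no genotype") from None
    y = rows[trait].to_numpy(dtype=float)
    X = design_matrix(rows, fixed)

    n_tested = sum(int((geno.snp_map["chrom"] == c).sum()) for c in scan)
    sugg, gw = bonferroni_thresholds(n_tested)

    chrom_arr = geno.snp_map["chrom"].to_numpy()
    out = []
    for c in scan:
        on_c = np.flatnonzero(chrom_arr == c)
        off_c = np.flatnonzero(chrom_arr != c)
        if len(off_c) < min_kinship_snps:
            warnings.warn(
                f"only {len(off_c)} kinship SNPs remain when excluding {c}; "
                "polygenic control will be unstable",
                stacklevel=2,
            )
        K_loco = build_G(geno.subset(snp_idx=off_c))
        est = MixedModelREML(include_common_env=False).fit(
            X, y, kinship=K_loco, record_ids=rows["animal"].tolist()
        )
        V = (
            est.sigma_a2_ * K_loco.reindex(rows["animal"].tolist())
            + est.sigma_e2_ * np.eye(len(y))
        )
        chol = np.linalg.cholesky(V)
        Vinv = np.linalg.solve(chol.T, np.linalg.solve(chol, np.eye(len(y))))
        VinvX = Vinv @ X
        P = Vinv - VinvX @ np.linalg.solve(X.T @ VinvX, VinvX.T)
        Py = P @ y

        sub = geno.subset(snp_idx=on_c)
        M = sub.dosage(impute_mean=True)[geno_idx]
        M = M - M.mean(axis=0)
        PM = P @ M
        gPg = np.einsum("ij,ij->j", M, PM)
        gPy = M.T @ Py
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(gPg > 0, gPy / np.maximum(gPg, 1e-30), np.nan)
            se = np.where(gPg > 0, 1.0 / np.sqrt(np.maximum(gPg, 1e-30)), np.nan)
            chi2 = (beta / se) ** 2
        p = stats.chi2.sf(chi2, df=1)
        p = np.where(np.isfinite(p), p, 1.0).clip(min=np.nextafter(0, 1), max=1.0)

        freq = sub.allele_freq()
        tier = np.where(p < gw, "genome_wide", np.where(p < sugg, "suggestive", "none"))
        out.append(
            pd.DataFrame(
                {
                    "chr": sub.snp_map["chrom"],
                    "snp": sub.snp_map["snp_id"],
                    "bp": sub.snp_map["pos"],
                    "a1": sub.snp_map["minor"],
                    "a2": sub.snp_map["major"],
                    "freq": freq,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "tier": tier,
                }
            )
        )
    table = pd.concat(out, ignore_index=True)
    table.attrs["n_tested"] = n_tested
    table.attrs["thresholds"] = {"suggestive": sugg, "genome_wide": gw}
    return table


def read_bed_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED intervals (0-based half-open) into 1-based inclusive rows."""
    ann = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], comment="#",
    )
    ann["start"] = ann["start"].astype(int) + 1  # to 1-based inclusive
    ann["end"] = ann["end"].astype(int)
    return ann


def qtl_windows(
    gwas: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    window_bp: int = 500_000,
    tier: str = "genome_wide",
) -> pd.DataFrame:
    """One annotation window per SNP at or above the requested tier.

    Window bounds are ``position +- window_bp/2`` (1-based inclusive
    coordinates), left-clipped at 0.  Overlap uses the any-overlap rule: a
    feature touching a bound by a single base is included.
    """
    order = {"none": 0, "suggestive": 1, "genome_wide": 2}
    if tier not in order:
        raise ValueError(f"tier must be one of {sorted(order)}")
    hits = gwas.loc[gwas["tier"].map(order) >= order[tier]]
    half = window_bp // 2
    if annotation is not None:
        ann_chroms = set(annotation["chrom"].astype(str))
        snp_chroms = set(gwas["chr"].astype(str))
        if ann_chroms and not (ann_chroms & snp_chroms):
            raise ValueError(
                f"annotation chromosomes {sorted(ann_chroms)[:4]} do not match "
                f"SNP map chromosomes {sorted(snp_chroms)[:4]}"
            )
    rows = []
    for snp in hits.itertuples(index=False):
        left = max(int(snp.bp) - half, 0)
        right = int(snp.bp) + half
        feats = []
        if annotation is not None:
            on_c = annotation.loc[annotation["chrom"].astype(str) == str(snp.chr)]
            ov = on_c.loc[(on_c["end"] >= left) & (on_c["start"] <= right)]
            feats = list(ov["name"])
        rows.append(
            {
                "snp": snp.snp,
                "chr": snp.chr,
                "bp": int(snp.bp),
                "left": left,
                "right": right,
                "p": snp.p,
                "features": ",".join(map(str, feats)),
            }
        )
    return pd.DataFrame(rows, columns=["snp", "chr", "bp", "left", "right", "p", "features"])
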