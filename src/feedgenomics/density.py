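"""SNP-density reduction experiment for genomic prediction accuracy.

Random marker subsets are drawn at a ladder of fractions of the full
panel; for each fraction the genomic relationship matrix is rebuilt and a
random-animal fivefold cross-validation with GBLUP is repeated, while the
heritability in the accuracy denominator stays the FULL-panel estimate
(low-density heritability estimates are downward-biased, so a single
full-marker h is used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feedgenomics.data import GenotypeData
from feedgenomics.kinship import build_G
from feedgenomics.mixedmodel import _resolve_kinship, design_matrix, reml_fit
from feedgenomics.predict_cv import CVScheme, _adjusted_phenotype, _cv_replicate, make_folds
from feedgenomics.traits import trait_values

#: The 23 assessed fractions of the full SNP panel.
DEFAULT_FRACTIONS = (
    0.001, 0.003, 0.005, 0.007, 0.009,
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10,
    0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90,
)


@dataclass
class DensityCurve:
    """Accuracy summary at one marker density."""

    fraction: float
    n_snps: int
    accuracies: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se_accuracy(self) -> float:
        a = np.asarray(self.accuracies)
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan")


def subsample_snps(geno: GenotypeData, fraction: float, seed: int) -> GenotypeData:
    """Uniform random SNP subset, genome-wide, without replacement."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    m = geno.n_snps
    k = int(round(fraction * m))
    if k < 2:
        raise ValueError(f"fraction {fraction} keeps fewer than 2 of {m} SNPs")
    if k == m:
        return geno
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = np.sort(rng.choice(m, size=k, replace=False))
    return geno.subset(snp_idx=idx)


def run_density_experiment(
    pheno: pd.DataFrame,
    geno: GenotypeData,
    trait: str,
    fractions=DEFAULT_FRACTIONS,
    n_replicates: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    fixed=("sex", "batch"),
    common: str | None = "aquarium",
) -> list[DensityCurve]:
    """GBLUP cross-validation accuracy at each marker density.

    The variance components and the accuracy denominator h both come from
    one full-panel fit; each replicate draws a fresh SNP subset and a
    fresh random-animal fold partition.
    """
    fractions = sorted(fractions)
    rows = trait_values(pheno, trait).reset_index(drop=True)
    y = rows[trait].to_numpy(dtype=float)
    X = design_matrix(rows, fixed)
    groups = rows[common].to_numpy() if common is not None and common in rows.columns else None

    G_full = build_G(geno)
    vc, est = reml_fit(rows, trait, G_full, fixed=fixed, common=common)
    h = float(np.sqrt(max(vc.h2, 1e-6)))
    y_adj = _adjusted_phenotype(rows, trait, fixed, est.beta_)
    animal_list = rows["animal"].tolist()

    scheme = CVScheme(mode="random_animal", n_folds=n_folds, n_replicates=n_replicates, seed=seed)
    curves = []
    for fi, frac in enumerate(fractions):
        curve = DensityCurve(fraction=frac, n_snps=int(round(frac * geno.n_snps)))
        # same fold stream as the plain cross-validation, so the 100%
        # fraction reproduces the full-panel accuracy exactly
        fold_rng = np.random.Generator(np.random.PCG64(seed))
        for rep in range(n_replicates):
            sub = subsample_snps(geno, frac, seed=seed + 7919 * fi + rep)
            K = build_G(sub)
            Km, Kinv, _, idx = _resolve_kinship(K, animal_list, len(rows))
            folds = make_folds(rows, scheme, fold_rng)
            curve.accuracies.append(
                _cv_replicate(y, X, y_adj, Km, Kinv, idx, groups, vc, h, folds)
            )
        curves.append(curve)
    return curves


def curve_table(curves: list[DensityCurve]) -> pd.DataFrame:
    """Long-format summary ready for plotting accuracy against density."""
    return pd.DataFrame(
        {
            "fraction": [c.fraction for c in curves],
            "n_snps": [c.n_snps for c in curves],
            "mean_accuracy": [c.mean_accuracy for c in curves],
            "se_accuracy": [c.se_accuracy for c in curves],
            "n_replicates": [len(c.accuracies) for c in curves],
        }
    )
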