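"""Cross-validated prediction accuracy of PBLUP/GBLUP/ssGBLUP breeding values.

Two fivefold validation designs are supported: ``random_animal`` draws
validation fish irrespective of family, ``random_family`` holds out whole
full-sib families so validation animals share no family with training.
Per fold the validation phenotypes are masked, breeding values are
re-predicted through the relationship matrix, and accuracy is the
correlation between predicted EBV and the (fixed-effect-adjusted)
phenotype divided by the square root of the full-data heritability of the
same model.  Replicate-level accuracies (fold-averaged) feed the model
comparison: Shapiro-Wilk normality per model, pairwise mean tests with
Bonferroni adjustment, significance tiers at 0.05 / 1e-3 / 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from feedgenomics.data import GenotypeData
from feedgenomics.kinship import KinshipMatrix, build_A, build_G, build_Hinv
from feedgenomics.mixedmodel import (
    MixedModelREML,
    VarianceComponents,
    _group_incidence,
    _resolve_kinship,
    design_matrix,
    reml_fit,
    solve_mme,
)
from feedgenomics.traits import trait_values

MODELS = ("PBLUP", "GBLUP", "ssGBLUP")
TIER_CUTS = ((1e-5, "***"), (1e-3, "**"), (0.05, "*"))


@dataclass
class CVScheme:
    """Validation design: mode, fold count, replicates and seed."""

    mode: str = "random_animal"
    n_folds: int = 5
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random_animal", "random_family"):
            raise ValueError("mode must be 'random_animal' or 'random_family'")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


def make_folds(pheno: pd.DataFrame, scheme: CVScheme, rng: np.random.Generator) -> np.ndarray:
    """Fold label per phenotype row for one replicate.

    ``random_animal`` partitions animals; ``random_family`` partitions
    whole families so no full-sib pair straddles train/validation.
    """
    n = len(pheno)
    if scheme.mode == "random_animal":
        folds = np.resize(np.arange(scheme.n_folds), n)
        return folds[rng.permutation(n)]
    fams = pheno["family"].astype(str).to_numpy()
    levels = pd.unique(fams)
    if len(levels) < scheme.n_folds:
        raise ValueError(f"{len(levels)} families cannot fill {scheme.n_folds} folds")
    fam_fold = dict(
        zip(levels[rng.permutation(len(levels))], np.resize(np.arange(scheme.n_folds), len(levels)))
    )
    return np.array([fam_fold[f] for f in fams])


def build_model_kinships(
    ped: pd.DataFrame,
    geno: GenotypeData | None,
    models=MODELS,
    genotyped_ids: list[str] | None = None,
    g_blend: float = 0.0,
) -> dict[str, KinshipMatrix]:
    """The relationship matrix each evaluation model uses."""
    from feedgenomics.kinship import _safe_inverse

    out: dict[str, KinshipMatrix] = {}
    A = build_A(ped) if any(m in models for m in ("PBLUP", "ssGBLUP")) else None
    G = build_G(geno, blend=g_blend) if any(m in models for m in ("GBLUP", "ssGBLUP")) else None
    if G is not None and g_blend == 0.0:
        # G with observed frequencies is singular; adopt the blend the safe
        # inverse would use, so GBLUP and ssGBLUP share one G exactly
        _, eps = _safe_inverse(G.values, "G")
        if eps > 0:
            G = build_G(geno, blend=eps)
    if "PBLUP" in models:
        out["PBLUP"] = A
    if "GBLUP" in models:
        out["GBLUP"] = G
    if "ssGBLUP" in models:
        out["ssGBLUP"] = build_Hinv(A, G, genotyped_ids)
    return out


def _adjusted_phenotype(rows: pd.DataFrame, trait: str, fixed, beta: np.ndarray) -> np.ndarray:
    """Phenotype minus estimated fixed effects (the default y2)."""
    X = design_matrix(rows, fixed)
    return rows[trait].to_numpy(dtype=float) - X @ beta


def _fold_accuracy(
    y: np.ndarray,
    X: np.ndarray,
    y_adj: np.ndarray,
    K: np.ndarray | None,
    Kinv: np.ndarray | None,
    idx: np.ndarray,
    groups,
    vc: VarianceComponents,
    h: float,
    train: np.ndarray,
) -> float:
    """Accuracy r(EBV, adjusted phenotype)/h on the held-out records."""
    _, a_hat, _ = solve_mme(
        y[train],
        X[train],
        K,
        Kinv,
        idx[train],
        None if groups is None else np.asarray(groups)[train],
        vc.sigma_a2,
        vc.sigma_c2,
        vc.sigma_e2,
    )
    val = ~train
    pred = a_hat[idx[val]]
    # a constant prediction (e.g. pedigree EBVs of whole held-out families
    # under a shallow pedigree) has no ranking ability: accuracy 0
    if np.std(pred) == 0 or np.std(y_adj[val]) == 0:
        return 0.0
    r = np.corrcoef(pred, y_adj[val])[0, 1]
    return float(r / h)


def _cv_replicate(y, X, y_adj, K, Kinv, idx, groups, vc, h, folds) -> float:
    """Fold-averaged accuracy for one replicate at fixed variance components."""
    accs = [
        _fold_accuracy(y, X, y_adj, K, Kinv, idx, groups, vc, h, folds != f)
        for f in np.unique(folds)
    ]
    return float(np.mean(accs))


def run_cv(
    pheno: pd.DataFrame,
    ped: pd.DataFrame,
    geno: GenotypeData | None,
    trait: str,
    scheme: CVScheme,
    models=MODELS,
    kinships: dict[str, KinshipMatrix] | None = None,
    fixed=("sex", "batch"),
    common: str | None = "aquarium",
    genotyped_ids: list[str] | None = None,
    refit_vc: bool = False,
    raw_phenotype: bool = False,
) -> pd.DataFrame:
    """Accuracy table (replicate, model, trait, scheme, r, h, accuracy).

    Variance components come from one full-data REML fit per model and are
    held fixed across folds by default (``refit_vc=True`` refits them in
    every training set).  Non-convergent fold fits are excluded and
    counted in the ``n_failed`` attribute of the result.
    """
    if kinships is None:
        kinships = build_model_kinships(ped, geno, models, genotyped_ids)
    rows = trait_values(pheno, trait).reset_index(drop=True)
    y = rows[trait].to_numpy(dtype=float)
    X = design_matrix(rows, fixed)
    groups = rows[common].to_numpy() if common is not None and common in rows.columns else None

    full: dict[str, tuple] = {}
    for model in models:
        vc, est = reml_fit(rows, trait, kinships[model], fixed=fixed, common=common)
        h = float(np.sqrt(max(vc.h2, 1e-6)))
        y_adj = (
            rows[trait].to_numpy(dtype=float)
            if raw_phenotype
            else _adjusted_phenotype(rows, trait, fixed, est.beta_)
        )
        K, Kinv, _, idx = _resolve_kinship(kinships[model], rows["animal"].tolist(), len(rows))
        if Kinv is None:
            from feedgenomics.kinship import _safe_inverse

            Kinv, _ = _safe_inverse(K, "relationship matrix")
        full[model] = (vc, h, y_adj, K, Kinv, idx)

    rng = np.random.Generator(np.random.PCG64(scheme.seed))
    out, n_failed = [], 0
    for rep in range(scheme.n_replicates):
        folds = make_folds(rows, scheme, rng)
        for model in models:
            vc, h, y_adj, K, Kinv, idx = full[model]
            if refit_vc:
                accs = []
                for f in np.unique(folds):
                    train_rows = rows.loc[folds != f]
                    try:
                        vc_f, _ = reml_fit(train_rows, trait, kinships[model], fixed=fixed, common=common)
                    except Exception:
                        n_failed += 1
                        continue
                    if not vc_f.converged:
                        n_failed += 1
                        continue
                    accs.append(
                        _fold_accuracy(y, X, y_adj, K, Kinv, idx, groups, vc_f, h, folds != f)
                    )
                acc = float(np.mean(accs)) if accs else np.nan
            else:
                acc = _cv_replicate(y, X, y_adj, K, Kinv, idx, groups, vc, h, folds)
            out.append(
                {
                    "replicate": rep,
                    "model": model,
                    "trait": trait,
                    "scheme": scheme.mode,
                    "h": h,
                    "accuracy": acc,
                }
            )
    result = pd.DataFrame(out)
    result.attrs["n_failed"] = n_failed
    return result


def compare_accuracies(results: pd.DataFrame) -> pd.DataFrame:
    """Pairwise model comparison of replicate-level accuracies.

    Per (trait, scheme): Shapiro-Wilk normality check per model, paired
    t-test on each model pair, Bonferroni adjustment by the number of
    pairs, and a significance tier.  Identical accuracy vectors give an
    adjusted p of 1.
    """
    req = {"trait", "scheme", "model", "replicate", "accuracy"}
    if not req <= set(results.columns):
        raise ValueError(f"results table lacks columns {sorted(req - set(results.columns))}")
    rows = []
    for (trait, scheme), grp in results.groupby(["trait", "scheme"]):
        wide = grp.pivot(index="replicate", columns="model", values="accuracy").dropna()
        if len(wide) < 2:
            raise ValueError("need at least 2 replicates to compare models")
        models = list(wide.columns)
        pairs = list(combinations(models, 2))
        shapiro = {
            m: (stats.shapiro(wide[m]).pvalue if wide[m].nunique() > 1 else np.nan)
            for m in models
        }
        for m1, m2 in pairs:
            d = wide[m1] - wide[m2]
            if np.allclose(d, 0.0):
                p_raw = 1.0
            else:
                p_raw = float(stats.ttest_rel(wide[m1], wide[m2]).pvalue)
            p_adj = min(1.0, p_raw * len(pairs))
            tier = ""
            for cut, label in TIER_CUTS:
                if p_adj < cut:
                    tier = label
                    break
            rows.append(
                {
                    "trait": trait,
                    "scheme": scheme,
                    "model_1": m1,
                    "model_2": m2,
                    "mean_1": float(wide[m1].mean()),
                    "mean_2": float(wide[m2].mean()),
                    "diff": float(d.mean()),
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "tier": tier,
                    "shapiro_p_1": shapiro[m1],
                    "shapiro_p_2": shapiro[m2],
                }
            )
    return pd.DataFrame(rows)
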