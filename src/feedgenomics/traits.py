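"""Derivation of the four feed-efficiency traits and per-trait outlier flags.

Feed intake (FI) is pellet count times the mean pellet weight summed over
the 13 recorded meals; body-weight gain (BWG) is the weight difference
over the recording stage; feed conversion ratio (FCR) is FI/BWG; residual
feed intake (RFI) is the residual of an ordinary least-squares regression
of FI on production covariates (by default BWG and metabolic mid-weight,
``((bw_start + bw_end)/2)**0.8``), so that a negative RFI marks an
efficient fish.  Outliers are flagged per trait with the Tukey boxplot
rule on hinge quartiles and excluded from that trait's analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

N_MEALS = 13


@dataclass
class TraitConfig:
    """Constants of the trait definitions.

    pellet_weight is the mean weight of one feed pellet in grams (the
    recording protocol weighs a batch of pellets once and treats the
    per-pellet variation as negligible).  rfi_covariates picks the
    production traits that FI is regressed on; outlier_whisker is the
    boxplot whisker multiplier.
    """

    pellet_weight: float = 0.0164
    rfi_covariates: tuple[str, ...] = ("BWG", "metabolic_midweight")
    outlier_whisker: float = 1.5

    def __post_init__(self) -> None:
        if self.pellet_weight <= 0:
            raise ValueError("pellet_weight must be positive")
        if self.outlier_whisker <= 0:
            raise ValueError("outlier_whisker must be positive")
        known = {"BWG", "metabolic_midweight"}
        bad = set(self.rfi_covariates) - known
        if bad:
            raise ValueError(f"unknown RFI covariates {sorted(bad)}; choose from {sorted(known)}")


def compute_fi(pellets_per_meal, pellet_weight: float = 0.0164) -> float:
    """Feed intake in grams: pellet weight times total pellets over 13 meals."""
    counts = np.asarray(pellets_per_meal, dtype=float)
    if counts.shape != (N_MEALS,):
        raise ValueError(f"expected {N_MEALS} meal counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("pellet counts must be non-negative")
    return float(pellet_weight * counts.sum())


def compute_bwg(bw_start: float, bw_end: float) -> float:
    """Body-weight gain in grams over the recording stage (may be negative)."""
    if bw_start <= 0 or bw_end <= 0:
        raise ValueError("body weights must be positive")
    return float(bw_end - bw_start)


def compute_fcr(fi: float, bwg: float) -> float:
    """Feed conversion ratio FI/BWG; NaN when BWG <= 0 (flag-and-exclude)."""
    if bwg <= 0:
        return float("nan")
    return float(fi / bwg)


def metabolic_midweight(bw_start, bw_end) -> np.ndarray:
    """Mid-stage body weight raised to the 0.8 metabolic exponent."""
    return ((np.asarray(bw_start, dtype=float) + np.asarray(bw_end, dtype=float)) / 2.0) ** 0.8


def compute_rfi(pheno: pd.DataFrame, config: TraitConfig | None = None) -> pd.Series:
    """Residual feed intake: observed FI minus OLS-predicted FI.

    The regression (with intercept) is fitted jointly on all animals with
    complete FI and covariates; fitted residuals average zero.
    """
    config = config or TraitConfig()
    cov = pd.DataFrame(index=pheno.index)
    if "BWG" in config.rfi_covariates:
        cov["BWG"] = pheno["BWG"]
    if "metabolic_midweight" in config.rfi_covariates:
        cov["metabolic_midweight"] = metabolic_midweight(pheno["bw_start"], pheno["bw_end"])
    ok = pheno["FI"].notna() & cov.notna().all(axis=1)
    if ok.sum() < 10:
        raise ValueError("need at least 10 animals with FI and covariates to fit RFI")
    X = sm.add_constant(cov.loc[ok])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("RFI covariates are rank deficient")
    fit = sm.OLS(pheno.loc[ok, "FI"], X).fit()
    rfi = pd.Series(np.nan, index=pheno.index, name="RFI")
    rfi.loc[ok] = fit.resid
    return rfi


def _hinges(values: np.ndarray) -> tuple[float, float]:
    """Tukey hinges (the boxplot-statistics quartile convention).

    Lower/upper hinge = median of the lower/upper half of the sorted data,
    including the overall median in both halves when n is odd.
    """
    x = np.sort(values)
    n = x.size
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def flag_outliers(values, whisker: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside the Tukey boxplot fences.

    Missing values are never flagged (they are already excluded).
    """
    x = np.asarray(values, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 5:
        raise ValueError("need at least 5 non-missing values to place boxplot fences")
    q1, q3 = _hinges(x[obs])
    iqr = q3 - q1
    lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
    flags = np.zeros(x.shape, dtype=bool)
    flags[obs] = (x[obs] < lo) | (x[obs] > hi)
    return flags


def derive_traits(pheno: pd.DataFrame, config: TraitConfig | None = None) -> pd.DataFrame:
    """Add/overwrite FI, BWG, FCR, RFI and per-trait outlier-flag columns.

    Expects raw measurement columns ``bw_start``, ``bw_end`` and
    ``meal_1`` .. ``meal_13``.  Records whose BWG is non-positive get a
    missing FCR.  Outlier flags are per trait (``<trait>_outlier``), so a
    fish flagged for FCR still contributes its BWG record.
    """
    config = config or TraitConfig()
    out = pheno.copy()
    meal_cols = [f"meal_{k + 1}" for k in range(N_MEALS)]
    missing = [c for c in ["bw_start", "bw_end", *meal_cols] if c not in out.columns]
    if missing:
        raise ValueError(f"phenotype table lacks raw measurement columns {missing}")
    meals = out[meal_cols].to_numpy(dtype=float)
    if (meals < 0).any():
        raise ValueError("pellet counts must be non-negative")
    out["FI"] = config.pellet_weight * meals.sum(axis=1)
    out["BWG"] = out["bw_end"] - out["bw_start"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["FCR"] = np.where(out["BWG"] > 0, out["FI"] / out["BWG"], np.nan)
    out["RFI"] = compute_rfi(out, config)
    for trait in ("FI", "BWG", "FCR", "RFI"):
        out[f"{trait}_outlier"] = flag_outliers(out[trait], config.outlier_whisker)
    return out


def trait_values(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Rows usable for analysing one trait: non-missing and not outlier-flagged."""
    ok = pheno[trait].notna()
    flag_col = f"{trait}_outlier"
    if flag_col in pheno.columns:
        ok &= ~pheno[flag_col].astype(bool)
    return pheno.loc[ok]
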