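"""In-memory containers for genotype panels and their SNP maps.

Genotype calls are stored animals x SNPs as ``int8`` counts of the minor
allele (0/1/2), with :data:`MISSING` (-1) as the missing sentinel.
Chromosomes are labelled ``Oni1`` .. ``Oni23`` for the placed linkage
groups and ``Oni24`` for the artificial chromosome that collects SNPs
without a reference position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "minor", "major"]


def chrom_label(k: int) -> str:
    """Numeric chromosome index (1-based) to its ``Oni`` label."""
    return f"Oni{int(k)}"


def chrom_number(label: str) -> int:
    """``Oni`` label back to its numeric index (for PLINK .bim output)."""
    if isinstance(label, str) and label.startswith("Oni"):
        return int(label[3:])
    return int(label)


@dataclass
class GenotypeData:
    """A biallelic SNP panel: ordered animals, SNP map and 0/1/2 calls.

    Parameters
    ----------
    animals : list of str
        Ordered animal identifiers (rows of ``calls``).
    snp_map : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, minor, major``.
    calls : numpy.ndarray of int8, shape (n_animals, n_snps)
        Minor-allele dosage; ``-1`` marks a missing call.
    """

    animals: list[str]
    snp_map: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.animals = list(self.animals)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != len(self.animals):
            raise ValueError(f"calls has {n} rows but {len(self.animals)} animals")
        if m != len(self.snp_map):
            raise ValueError(f"calls has {m} columns but {len(self.snp_map)} SNPs")
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ValueError(f"snp_map lacks columns {missing_cols}")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("snp_ids are not unique")
        if (self.snp_map["pos"] < 0).any():
            raise ValueError("snp_map positions must be non-negative")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls contain values outside {-1, 0, 1, 2}")
        if len(set(self.animals)) != len(self.animals):
            raise ValueError("animal identifiers are not unique")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Observed minor-allele frequency per SNP (missing calls ignored)."""
        obs = self.observed()
        counts = np.where(obs, self.calls, 0).sum(axis=0)
        denom = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
        return p

    def snp_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=1)

    def dosage(self, impute_mean: bool = True) -> np.ndarray:
        """Calls as float with missing entries mean-imputed per SNP.

        Imputation never writes back into :attr:`calls`.
        """
        X = self.calls.astype(float)
        if impute_mean:
            p = self.allele_freq()
            miss = ~self.observed()
            if miss.any():
                fill = np.broadcast_to(2.0 * np.nan_to_num(p), X.shape)
                X[miss] = fill[miss]
        return X

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeData":
        """New panel restricted to the given animal/SNP positional indices."""
        animal_idx = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeData(
            animals=[self.animals[i] for i in animal_idx],
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(animal_idx, snp_idx)],
        )

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP (n_major_hom, n_het, n_minor_hom) counts, shape (m, 3)."""
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for g, col in ((0, 0), (1, 1), (2, 2)):
            out[:, col] = (self.calls == g).sum(axis=0)
        return out
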