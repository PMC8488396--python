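"""Relationship matrices for pedigree, genomic and single-step evaluation.

Provides the numerator relationship matrix A (tabular method on a
parents-first pedigree), the genomic relationship matrix G (cross-products
of centred dosages scaled by total heterozygosity, with observed allele
frequencies), the genotyped-subset block A22, and the single-step inverse
H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]] used directly in the
mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from feedgenomics.data import GenotypeData
from feedgenomics.simpop import UNKNOWN_PARENT


@dataclass
class KinshipMatrix:
    """A symmetric relationship matrix with its animal ordering.

    ``kind`` is one of ``A``, ``G``, ``A22``, ``Hinv`` or ``I``; for
    ``Hinv`` the values are already the INVERSE relationship matrix (the
    form consumed by Henderson's equations).
    """

    kind: str
    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def reindex(self, ids: list[str]) -> np.ndarray:
        """Sub-matrix in the order of the requested ids."""
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[str(a)] for a in ids])
        return self.values[np.ix_(idx, idx)]

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "animal"
        df.to_csv(path, sep="\t")


def _topological_order(ped: pd.DataFrame) -> pd.DataFrame:
    """Sort a pedigree parents-before-offspring; raise on cycles."""
    known = set()
    rows = {r.animal: r for r in ped.itertuples(index=False)}
    remaining = list(ped["animal"])
    ordered = []
    while remaining:
        progressed = []
        for a in remaining:
            r = rows[a]
            s, d = str(r.sire), str(r.dam)
            if (s == UNKNOWN_PARENT or s in known) and (d == UNKNOWN_PARENT or d in known):
                ordered.append(a)
                known.add(a)
            else:
                progressed.append(a)
        if len(progressed) == len(remaining):
            raise ValueError(f"pedigree contains a cycle or missing parent records: {progressed[:5]}")
        remaining = progressed
    return ped.set_index("animal").loc[ordered].reset_index()


def build_A(ped: pd.DataFrame) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``a(i,i) = 1 + a(sire,dam)/2`` and ``a(i,j) = (a(j,sire)+a(j,dam))/2``
    for every earlier animal j; unknown parents contribute zero.  The
    pedigree is topologically sorted first, so record order need not be
    parents-first on input.  Every named parent must have its own record.
    """
    ped = ped.copy()
    ped["animal"] = ped["animal"].astype(str)
    ped["sire"] = ped["sire"].astype(str)
    ped["dam"] = ped["dam"].astype(str)
    animals = set(ped["animal"])
    for col in ("sire", "dam"):
        missing = set(ped[col]) - animals - {UNKNOWN_PARENT}
        if missing:
            raise ValueError(f"{col}s {sorted(missing)[:5]} have no animal record")
    ped = _topological_order(ped)
    ids = list(ped["animal"])
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sire_idx = [pos.get(s, -1) for s in ped["sire"]]
    dam_idx = [pos.get(d, -1) for d in ped["dam"]]
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return KinshipMatrix(kind="A", ids=ids, values=A)


def build_A22(A: KinshipMatrix, genotyped_ids: list[str]) -> KinshipMatrix:
    """Pedigree relationship block restricted to the genotyped animals."""
    return KinshipMatrix(kind="A22", ids=list(genotyped_ids), values=A.reindex(genotyped_ids))


def build_G(geno: GenotypeData, blend: float = 0.0) -> KinshipMatrix:
    """Genomic relationship matrix G = ZZ' / (2 sum p(1-p)).

    Z holds dosages centred by twice the observed allele frequency;
    missing calls are set to the centring value (zero contribution).  An
    optional blend replaces G by (1-blend) G + blend I to guarantee
    invertibility.
    """
    p = geno.allele_freq()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("all SNPs are monomorphic or unobserved; G denominator is zero")
    calls = geno.calls[:, usable].astype(float)
    p = p[usable]
    Z = calls - 2.0 * p
    Z[geno.calls[:, usable] == -1] = 0.0
    denom = 2.0 * float(np.sum(p * (1 - p)))
    G = (Z @ Z.T) / denom
    if blend > 0:
        G = (1 - blend) * G + blend * np.eye(len(G))
    return KinshipMatrix(kind="G", ids=list(geno.animals), values=G)


def _safe_inverse(
    M: np.ndarray, what: str, blend_eps: float = 0.01, max_cond: float = 1e8
) -> tuple[np.ndarray, float]:
    """Invert a relationship matrix, blending toward I only when needed.

    A Cholesky factorisation can succeed on a numerically singular matrix
    and return a meaningless inverse, so conditioning is checked on the
    factor's diagonal; ill-conditioned matrices are blended.
    """
    n = len(M)
    for eps in (0.0, blend_eps):
        Mb = (1 - eps) * M + eps * np.eye(n) if eps else M
        try:
            c = np.linalg.cholesky(Mb)
        except np.linalg.LinAlgError:
            continue
        d = np.diag(c)
        if (d.max() / d.min()) ** 2 > max_cond:
            continue
        inv = np.linalg.solve(c.T, np.linalg.solve(c, np.eye(n)))
        return inv, eps
    raise np.linalg.LinAlgError(
        f"{what} is singular or ill-conditioned even after blending toward I; "
        "increase the blend"
    )


def build_Hinv(
    A: KinshipMatrix, G: KinshipMatrix, genotyped_ids: list[str] | None = None
) -> KinshipMatrix:
    """Single-step inverse relationship matrix.

    H^-1 equals A^-1 plus the genotyped-block adjustment G^-1 - A22^-1.
    Ordering contract: non-genotyped animals first, genotyped animals
    second (the returned ``ids`` are the id map).
    """
    genotyped_ids = [str(a) for a in (genotyped_ids if genotyped_ids is not None else G.ids)]
    a_ids = set(A.ids)
    stray = [a for a in genotyped_ids if a not in a_ids]
    if stray:
        raise ValueError(f"genotyped animals {stray[:5]} are not in the pedigree matrix")
    non_geno = [a for a in A.ids if a not in set(genotyped_ids)]
    order = non_geno + genotyped_ids
    A_ord = A.reindex(order)
    Ainv, _ = _safe_inverse(A_ord, "A")
    Hinv = Ainv
    if genotyped_ids:
        Gm = G.reindex(genotyped_ids)
        Ginv, _ = _safe_inverse(Gm, "G")
        A22 = A.reindex(genotyped_ids)
        A22inv, _ = _safe_inverse(A22, "A22")
        k = len(non_geno)
        Hinv[k:, k:] += Ginv - A22inv
    Hinv = (Hinv + Hinv.T) / 2.0
    return KinshipMatrix(kind="Hinv", ids=order, values=Hinv)
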