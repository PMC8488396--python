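"""Relationship matrices against independent oracles and known pedigrees."""

import numpy as np
import pandas as pd
import pytest

from feedgenomics.data import GenotypeData, chrom_label
from feedgenomics.kinship import build_A, build_A22, build_G, build_Hinv, _safe_inverse


def _ped(rows):
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation"])


def coancestry_oracle(ped: pd.DataFrame):
    """Recursive kinship (coancestry) coefficients; A(i,j) = 2 f(i,j).

    Independent of the tabular construction: classic f-recursion with
    memoisation on an age-ordered pedigree.
    """
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order = {a: i for i, a in enumerate(ped["animal"])}
    cache = {}

    def f(i, j):
        if i == "0" or j == "0":
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        s, d = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, j) + f(d, j))
        cache[key] = val
        return val

    ids = list(ped["animal"])
    return ids, np.array([[2.0 * f(i, j) for j in ids] for i in ids])


def random_pedigree(n, n_founders, rng):
    rows = [(f"P{i}", "0", "0", 0) for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        rows.append((f"P{i}", f"P{s}", f"P{d}", 1))
    return _ped(rows)


class TestNumeratorMatrix:
    def test_two_founders_identity(self):
        A = build_A(_ped([("a", "0", "0", 0), ("b", "0", "0", 0)]))
        assert np.array_equal(A.values, np.eye(2))

    def test_parent_offspring_half(self):
        A = build_A(_ped([("s", "0", "0", 0), ("d", "0", "0", 0), ("o", "s", "d", 1)]))
        Adf = pd.DataFrame(A.values, index=A.ids, columns=A.ids)
        assert Adf.loc["s", "o"] == 0.5
        assert np.allclose(np.diag(A.values), 1.0)

    def test_full_sib_mating_inbreeding(self):
        # offspring of a full-sib pair: diagonal 1.25; sibs related 0.5
        ped = _ped(
            [
                ("s", "0", "0", 0),
                ("d", "0", "0", 0),
                ("x", "s", "d", 1),
                ("y", "s", "d", 1),
                ("z", "x", "y", 2),
            ]
        )
        A = build_A(ped)
        Adf = pd.DataFrame(A.values, index=A.ids, columns=A.ids)
        assert Adf.loc["z", "z"] == pytest.approx(1.25)
        assert Adf.loc["x", "y"] == pytest.approx(0.5)

    def test_matches_coancestry_oracle_on_random_pedigrees(self, rng):
        for _ in range(20):
            ped = random_pedigree(20, 6, rng)
            A = build_A(ped)
            ids, expected = coancestry_oracle(ped)
            assert A.ids == ids
            assert np.abs(A.values - expected).max() < 1e-8

    def test_unsorted_pedigree_is_sorted(self):
        ped = _ped([("o", "s", "d", 1), ("s", "0", "0", 0), ("d", "0", "0", 0)])
        A = build_A(ped)
        assert A.ids[-1] == "o"

    def test_cycle_detected(self):
        ped = _ped([("a", "b", "0", 0), ("b", "a", "0", 0)])
        with pytest.raises(ValueError, match="cycle"):
            build_A(ped)


def _tiny_geno(calls, chrom=1):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"S{i}" for i in range(m)],
            "chrom": chrom_label(chrom),
            "pos": np.arange(1, m + 1),
            "minor": "A",
            "major": "C",
        }
    )
    return GenotypeData([f"A{i}" for i in range(n)], snp_map, calls)


class TestGenomicMatrix:
    def test_single_locus_arithmetic(self):
        # two animals 2/0 at one SNP: p = 0.5, Z = (1, -1), denom = 0.5
        G = build_G(_tiny_geno([[2], [0]]))
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_all_heterozygous_gives_zero_matrix(self):
        G = build_G(_tiny_geno([[1, 1], [1, 1], [1, 1]]))
        assert np.allclose(G.values, 0.0)

    def test_matches_dense_recomputation(self, rng):
        for _ in range(10):
            calls = rng.integers(0, 3, size=(10, 50))
            geno = _tiny_geno(calls)
            G = build_G(geno)
            p = calls.mean(axis=0) / 2.0
            keep = (p > 0) & (p < 1)
            Z = calls[:, keep] - 2 * p[keep]
            expected = Z @ Z.T / (2 * np.sum(p[keep] * (1 - p[keep])))
            assert np.abs(G.values - expected).max() < 1e-8

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(_tiny_geno([[2, 0], [2, 0]]))

    def test_founder_panel_diagonal_near_one(self):
        from conftest import founder_panel

        geno = founder_panel(100, 3000, seed=13)
        G = build_G(geno)
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)
        off = G.values[np.triu_indices(100, k=1)]
        assert abs(off.mean()) < 0.02


class TestSingleStep:
    def test_all_genotyped_reduces_to_G_inverse(self, signal_population):
        _, ped, geno, _, _ = signal_population
        A = build_A(ped)
        G = build_G(geno)
        H = build_Hinv(A, G)
        Ginv, _ = _safe_inverse(G.reindex(H.ids), "G")
        assert np.abs(H.values - Ginv).max() < 1e-8

    def test_none_genotyped_reduces_to_A_inverse(self):
        ped = _ped([("s", "0", "0", 0), ("d", "0", "0", 0), ("o", "s", "d", 1)])
        A = build_A(ped)
        G = build_G(_tiny_geno([[2], [0]]))  # unused block
        H = build_Hinv(A, G, genotyped_ids=[])
        assert np.abs(H.values - np.linalg.inv(A.values)).max() < 1e-10

    def test_matches_brute_force_H_assembly(self, signal_population):
        _, ped, geno, _, _ = signal_population
        A = build_A(ped)
        sub_idx = list(range(0, 60))
        sub_ids = [geno.animals[i] for i in sub_idx]
        G = build_G(geno.subset(animal_idx=sub_idx), blend=0.02)
        H = build_Hinv(A, G, sub_ids)
        k = len(A.ids) - len(sub_ids)
        Aord = A.reindex(H.ids)
        A11, A12, A22 = Aord[:k, :k], Aord[:k, k:], Aord[k:, k:]
        Gm = G.reindex(H.ids[k:])
        A22i = np.linalg.inv(A22)
        # conditional-expectation construction of the joined matrix
        H11 = A11 + A12 @ A22i @ (Gm - A22) @ A22i @ A12.T
        H12 = A12 @ A22i @ Gm
        Hfull = np.block([[H11, H12], [H12.T, Gm]])
        assert np.abs(np.linalg.inv(Hfull) - H.values).max() < 1e-8

    def test_ordering_contract(self, signal_population):
        _, ped, geno, _, _ = signal_population
        A = build_A(ped)
        sub_ids = [geno.animals[i] for i in range(10)]
        G = build_G(geno.subset(animal_idx=list(range(10))), blend=0.05)
        H = build_Hinv(A, G, sub_ids)
        assert H.ids[-10:] == sub_ids
        assert set(H.ids) == set(A.ids)

    def test_a22_is_sub_block(self):
        ped = _ped(
            [("s", "0", "0", 0), ("d", "0", "0", 0), ("o", "s", "d", 1), ("p", "s", "d", 1)]
        )
        A = build_A(ped)
        A22 = build_A22(A, ["o", "p"])
        assert A22.values[0, 1] == pytest.approx(0.5)
        assert A22.kind == "A22"
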