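"""Synthetic full-sib breeding populations with known genetic truth.

The simulator emulates the experimental design of a feed-efficiency
recording trial in a tilapia breeding program: full-sib families produced
by single-pair matings, each family split across two shared aquaria within
a batch, phenotypes driven by a polygenic multi-trait architecture with
optional planted QTL, a common-environment (aquarium) variance component,
and raw measurement columns (start/end body weight, pellets eaten per
meal) from which the analysis traits can be re-derived.

Founder SNPs are simulated in linkage equilibrium; linkage disequilibrium
arises only from family co-segregation during the gene-drop.  True
breeding values, effects and variances are kept in a :class:`TruthRecord`
for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from feedgenomics.data import GenotypeData, chrom_label

UNKNOWN_PARENT = "0"

#: Genetic correlations among the four default traits (FCR, BWG, RFI, FI):
#: strongly shared architecture between the two feed-efficiency measures,
#: favourable (negative) correlation of both with growth.
DEFAULT_GENETIC_CORR = (
    (1.00, -0.60, 0.98, 0.24),
    (-0.60, 1.00, -0.63, 0.61),
    (0.98, -0.63, 1.00, 0.21),
    (0.24, 0.61, 0.21, 1.00),
)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, keyed by stage name."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class SimConfig:
    """Design and genetic architecture of a simulated population.

    Defaults mirror the recording trial the package targets: 40 full-sib
    families of 30 fish split over two 15-fish aquaria, four batches,
    ~5 K SNPs on 23 chromosomes plus a small unplaced set, and per-trait
    heritabilities/common-environment ratios and genetic correlations in
    the range estimated for feed-efficiency traits with a genomic
    relationship matrix (h2 0.12-0.22, c2 0.05-0.07).
    """

    n_families: int = 40
    fish_per_aquarium: int = 15
    aquaria_per_family: int = 2
    n_batches: int = 4
    n_snps: int = 5000
    n_chromosomes: int = 23
    frac_unplaced: float = 0.02
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    traits: tuple[str, ...] = ("FCR", "BWG", "RFI", "FI")
    true_h2: tuple[float, ...] = (0.12, 0.22, 0.19, 0.16)
    true_c2: tuple[float, ...] = (0.07, 0.05, 0.07, 0.07)
    genetic_corr: tuple[tuple[float, ...], ...] = DEFAULT_GENETIC_CORR
    trait_means: tuple[float, ...] = (0.94, 9.18, -0.40, 8.30)
    trait_sds: tuple[float, ...] = (0.20, 2.98, 1.49, 2.28)
    #: (trait, chromosome number, bp position, fraction of genetic variance)
    qtl_spec: tuple[tuple[str, int, int, float], ...] = ()
    #: male-minus-female offset per trait, in phenotypic SD units
    sex_effect_sd: float = 0.30
    #: SD of per-batch offsets, in phenotypic SD units
    batch_effect_sd: float = 0.20
    pellet_weight: float = 0.0164
    chromosome_bp: int = 40_000_000
    #: ancestral haplotypes per chromosome that founders draw from; a
    #: finite pool creates the population-level LD of a closed, long-bred
    #: strain.  None gives linkage-equilibrium founders.
    founder_haplotypes: int | None = 40
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.genetic_corr, dtype=float)

    def validate(self) -> None:
        if self.n_families < 1 or self.fish_per_aquarium < 1 or self.aquaria_per_family < 1:
            raise ValueError("family/aquarium counts must be positive")
        if not (0 <= self.frac_unplaced < 1):
            raise ValueError("frac_unplaced must be in [0, 1)")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        t = self.n_traits
        for name, arr in [
            ("true_h2", self.true_h2),
            ("true_c2", self.true_c2),
            ("trait_means", self.trait_means),
            ("trait_sds", self.trait_sds),
        ]:
            if len(arr) != t:
                raise ValueError(f"{name} must have one entry per trait")
        for h2, c2 in zip(self.true_h2, self.true_c2):
            if not (0 <= h2 < 1) or not (0 <= c2 < 1) or h2 + c2 >= 1:
                raise ValueError("per-trait h2 and c2 must satisfy 0 <= h2, c2 and h2 + c2 < 1")
        C = self.corr_matrix()
        if C.shape != (t, t) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("genetic_corr must be positive semi-definite")
        for trait, chrom, pos, frac in self.qtl_spec:
            if trait not in self.traits:
                raise ValueError(f"qtl trait {trait!r} not among configured traits")
            if not (0 < frac <= 1):
                raise ValueError("qtl variance fraction must be in (0, 1]")
            if not (1 <= chrom <= self.n_chromosomes) or pos < 0:
                raise ValueError("qtl chromosome/position outside the simulated map")


@dataclass
class TruthRecord:
    """Ground truth behind a simulated population."""

    breeding_values: pd.DataFrame  # animal x trait
    aquarium_effects: pd.DataFrame  # aquarium x trait
    residuals: pd.DataFrame  # animal x trait (phenotyped animals)
    sex_effects: pd.DataFrame  # trait -> male offset (female = 0)
    batch_effects: pd.DataFrame  # batch x trait
    variances: pd.DataFrame  # trait x (sigma_a2, sigma_c2, sigma_e2, h2, c2)
    qtl: pd.DataFrame  # trait, snp_id, chrom, pos, effect, frac_genetic_var

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.breeding_values.to_csv(str(prefix) + ".true_bv.tsv", sep="\t")
        self.aquarium_effects.to_csv(str(prefix) + ".aquarium_effects.tsv", sep="\t")
        self.variances.to_csv(str(prefix) + ".variances.tsv", sep="\t")
        self.qtl.to_csv(str(prefix) + ".qtl.tsv", sep="\t", index=False)


def _snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_snps
    n_unplaced = int(round(config.frac_unplaced * m))
    n_placed = m - n_unplaced
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_placed)
    pos = rng.integers(1, config.chromosome_bp, size=n_placed)
    order = np.lexsort((pos, chroms))
    chrom_labels = [chrom_label(c) for c in chroms[order]]
    positions = pos[order].tolist()
    # unplaced SNPs: artificial chromosome, ordinal positions
    chrom_labels += [chrom_label(config.n_chromosomes + 1)] * n_unplaced
    positions += list(range(1, n_unplaced + 1))
    alleles = rng.integers(0, 4, size=(m, 2))
    alleles[:, 1] = (alleles[:, 0] + 1 + rng.integers(0, 3, size=m)) % 4
    bases = np.array(list("ACGT"))
    return pd.DataFrame(
        {
            "snp_id": [f"SNP{i + 1:06d}" for i in range(m)],
            "chrom": chrom_labels,
            "pos": positions,
            "minor": bases[alleles[:, 0]],
            "major": bases[alleles[:, 1]],
        }
    )


class _LinkageMap:
    """Per-chromosome SNP indices and genetic positions for the gene-drop.

    Placed chromosomes are taken as 1 Morgan each; SNPs on the artificial
    (unplaced) chromosome segregate independently.
    """

    def __init__(self, snp_map: pd.DataFrame, chromosome_bp: int, morgans: float = 1.0):
        self.blocks: list[tuple[np.ndarray, np.ndarray, float]] = []
        self.unlinked = np.array([], dtype=int)
        for chrom, grp in snp_map.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            if chrom.endswith("24") or len(idx) == 1:
                self.unlinked = np.concatenate([self.unlinked, idx])
            else:
                cm = grp["pos"].to_numpy(dtype=float) / chromosome_bp * morgans
                self.blocks.append((idx, cm, morgans))


def _gamete(hap1: np.ndarray, hap2: np.ndarray, lmap: _LinkageMap, rng: np.random.Generator) -> np.ndarray:
    """One meiosis: recombination mosaic of the parent's two haplotypes."""
    out = np.empty_like(hap1)
    for idx, cm, morgans in lmap.blocks:
        n_x = rng.poisson(morgans)
        start = rng.integers(0, 2)
        if n_x == 0:
            phase = np.full(len(idx), start)
        else:
            points = np.sort(rng.uniform(0, morgans, size=n_x))
            phase = (start + np.searchsorted(points, cm)) % 2
        out[idx] = np.where(phase == 0, hap1[idx], hap2[idx])
    if len(lmap.unlinked):
        pick = rng.integers(0, 2, size=len(lmap.unlinked))
        out[lmap.unlinked] = np.where(
            pick == 0, hap1[lmap.unlinked], hap2[lmap.unlinked]
        )
    return out


def _gene_drop(
    sire_haps: np.ndarray,
    dam_haps: np.ndarray,
    n_off: int,
    lmap: _LinkageMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring genotypes as sums of two recombinant parental gametes."""
    out = np.empty((n_off, sire_haps.shape[1]), dtype=np.int8)
    for k in range(n_off):
        out[k] = _gamete(sire_haps[0], sire_haps[1], lmap, rng) + _gamete(
            dam_haps[0], dam_haps[1], lmap, rng
        )
    return out


def simulate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, GenotypeData, pd.DataFrame, TruthRecord]:
    """Simulate pedigree, genotypes, phenotypes and their generating truth.

    Returns
    -------
    pedigree : DataFrame with columns animal, sire, dam, generation
        (``"0"`` marks an unknown parent), parents before offspring.
    genotypes : GenotypeData for founders and offspring.
    phenotypes : DataFrame with one row per offspring carrying design
        columns (family, sex, batch, aquarium), raw measurements
        (bw_start, bw_end, meal_1..meal_13) and the simulated trait values.
    truth : TruthRecord with true breeding values, effects and variances.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(derive_seed(config.seed, "simulate")))
    t = config.n_traits
    n_fam = config.n_families
    n_off_per_fam = config.fish_per_aquarium * config.aquaria_per_family
    n_off = n_fam * n_off_per_fam

    snp_map = _snp_map(config, rng)
    m = config.n_snps
    lo, hi = config.founder_maf_range
    p_founder = rng.uniform(lo, hi, size=m)

    sires = [f"S{i + 1:03d}" for i in range(n_fam)]
    dams = [f"D{i + 1:03d}" for i in range(n_fam)]
    founders = sires + dams
    lmap = _LinkageMap(snp_map, config.chromosome_bp)
    if config.founder_haplotypes is None:
        # founders in linkage equilibrium: no population-level LD
        founder_haps = (rng.random((2 * n_fam, 2, m)) < p_founder).astype(np.int8)
    else:
        # founder chromosomes drawn from a finite ancestral haplotype pool,
        # giving the haplotype-block LD of a closed breeding population
        K = int(config.founder_haplotypes)
        pool = (rng.random((K, m)) < p_founder).astype(np.int8)
        founder_haps = np.empty((2 * n_fam, 2, m), dtype=np.int8)
        blocks = [idx for idx, _, _ in lmap.blocks]
        if len(lmap.unlinked):
            blocks.append(lmap.unlinked)
        for idx in blocks:
            picks = rng.integers(0, K, size=(2 * n_fam, 2))
            founder_haps[:, :, idx] = pool[picks][:, :, idx]
    founder_g = founder_haps.sum(axis=1, dtype=np.int8)

    offspring, off_rows, fam_of = [], [], []
    for f in range(n_fam):
        kids = [f"F{f + 1:03d}_{k + 1:02d}" for k in range(n_off_per_fam)]
        offspring.extend(kids)
        fam_of.extend([f] * n_off_per_fam)
        off_rows.append(
            _gene_drop(founder_haps[f], founder_haps[n_fam + f], n_off_per_fam, lmap, rng)
        )
    off_g = np.vstack(off_rows)
    fam_of = np.asarray(fam_of)

    animals = founders + offspring
    calls = np.vstack([founder_g, off_g])
    geno = GenotypeData(animals=animals, snp_map=snp_map, calls=calls)

    pedigree = pd.DataFrame(
        {
            "animal": animals,
            "sire": [UNKNOWN_PARENT] * len(founders)
            + [sires[f] for f in fam_of],
            "dam": [UNKNOWN_PARENT] * len(founders)
            + [dams[f] for f in fam_of],
            "generation": [0] * len(founders) + [1] * n_off,
        }
    )

    # --- polygenic breeding values across traits -------------------------
    C = config.corr_matrix()
    # PSD square root of the trait correlation matrix
    w, Q = np.linalg.eigh(C)
    L = Q @ np.diag(np.sqrt(np.clip(w, 0, None)))
    sigma_a2 = np.array([h2 * sd**2 for h2, sd in zip(config.true_h2, config.trait_sds)])
    sigma_c2 = np.array([c2 * sd**2 for c2, sd in zip(config.true_c2, config.trait_sds)])
    sigma_e2 = np.array(
        [
            (1 - h2 - c2) * sd**2
            for h2, c2, sd in zip(config.true_h2, config.true_c2, config.trait_sds)
        ]
    )

    p_all = geno.allele_freq()
    Zc = calls.astype(float) - 2.0 * p_all  # centred dosages, all animals

    qtl_rows: list[dict] = []
    qtl_idx_per_trait: dict[int, list[int]] = {j: [] for j in range(t)}
    qtl_frac = np.zeros(t)
    for trait, chrom, pos, frac in config.qtl_spec:
        j = config.traits.index(trait)
        on_chrom = snp_map.index[snp_map["chrom"] == chrom_label(chrom)]
        if len(on_chrom) == 0:
            raise ValueError(f"no SNPs on chromosome {chrom} to host a QTL")
        k = on_chrom[np.argmin(np.abs(snp_map.loc[on_chrom, "pos"] - pos))]
        qtl_idx_per_trait[j].append(int(k))
        qtl_frac[j] += frac
        qtl_rows.append(
            {
                "trait": trait,
                "snp_id": snp_map.at[k, "snp_id"],
                "chrom": snp_map.at[k, "chrom"],
                "pos": int(snp_map.at[k, "pos"]),
                "effect": np.nan,  # filled after scaling
                "frac_genetic_var": frac,
            }
        )
    if (qtl_frac > 1).any():
        raise ValueError("QTL variance fractions exceed 1 for some trait")

    off_slice = slice(len(founders), len(animals))
    bv = np.zeros((len(animals), t))
    if sigma_a2.max() > 0:
        u = rng.standard_normal((m, t)) @ L.T  # per-SNP effects, corr ~ C
        bv_raw = Zc @ u
        for j in range(t):
            if sigma_a2[j] == 0:
                bv[:, j] = 0.0
                continue
            poly = bv_raw[:, j].copy()
            for k in qtl_idx_per_trait[j]:
                poly -= Zc[:, k] * u[k, j]  # QTL handled separately
            sd_poly = poly[off_slice].std()
            target_poly = np.sqrt(sigma_a2[j] * (1 - qtl_frac[j]))
            bv[:, j] = poly * (target_poly / sd_poly if sd_poly > 0 else 0.0)
        for row in qtl_rows:
            j = config.traits.index(row["trait"])
            k = int(snp_map.index[snp_map["snp_id"] == row["snp_id"]][0])
            g = Zc[:, k]
            sd_g = g[off_slice].std()
            beta = np.sqrt(row["frac_genetic_var"] * sigma_a2[j]) / sd_g
            bv[:, j] += g * beta
            row["effect"] = beta

    # --- design: batches, aquaria, sexes ---------------------------------
    fam_batch = np.repeat(np.arange(config.n_batches), int(np.ceil(n_fam / config.n_batches)))[:n_fam]
    aqua_ids, aqua_of_fish = [], []
    for f in range(n_fam):
        for a in range(config.aquaria_per_family):
            aq = f"AQ{f + 1:03d}_{a + 1}"
            aqua_ids.append(aq)
            aqua_of_fish.extend([aq] * config.fish_per_aquarium)
    sex = rng.integers(0, 2, size=n_off)  # 0 female, 1 male

    sex_eff = config.sex_effect_sd * np.asarray(config.trait_sds)
    batch_eff = rng.standard_normal((config.n_batches, t)) * config.batch_effect_sd * np.asarray(config.trait_sds)
    aqua_eff = rng.standard_normal((len(aqua_ids), t)) * np.sqrt(sigma_c2)
    resid = rng.standard_normal((n_off, t)) * np.sqrt(sigma_e2)

    aqua_index = {aq: i for i, aq in enumerate(aqua_ids)}
    aq_of = np.array([aqua_index[a] for a in aqua_of_fish])
    pheno_vals = (
        np.asarray(config.trait_means)
        + sex[:, None] * sex_eff
        + batch_eff[fam_batch[fam_of]]
        + bv[off_slice]
        + aqua_eff[aq_of]
        + resid
    )

    pheno = pd.DataFrame(
        {
            "animal": offspring,
            "family": [f"FAM{f + 1:03d}" for f in fam_of],
            "sex": np.where(sex == 1, "M", "F"),
            "batch": [f"B{b + 1}" for b in fam_batch[fam_of]],
            "aquarium": aqua_of_fish,
        }
    )

    # --- raw measurements consistent with simulated FI and BWG -----------
    bw_start = np.clip(rng.normal(25.0, 3.0, size=n_off), 5.0, None)
    if "BWG" in config.traits:
        bwg = pheno_vals[:, config.traits.index("BWG")]
    else:
        bwg = rng.normal(9.0, 3.0, size=n_off)
    bw_end = np.maximum(bw_start + bwg, 0.5)
    pheno["bw_start"] = np.round(bw_start, 2)
    pheno["bw_end"] = np.round(bw_end, 2)

    if "FI" in config.traits:
        fi = pheno_vals[:, config.traits.index("FI")]
    else:
        fi = rng.normal(8.0, 2.0, size=n_off)
    total_pellets = np.maximum(np.round(fi / config.pellet_weight), 0).astype(int)
    meals = np.vstack(
        [rng.multinomial(tp, np.full(13, 1 / 13)) for tp in total_pellets]
    )
    for k in range(13):
        pheno[f"meal_{k + 1}"] = meals[:, k]

    for j, trait in enumerate(config.traits):
        pheno[trait] = pheno_vals[:, j]

    truth = TruthRecord(
        breeding_values=pd.DataFrame(bv, index=animals, columns=list(config.traits)).rename_axis("animal"),
        aquarium_effects=pd.DataFrame(aqua_eff, index=aqua_ids, columns=list(config.traits)).rename_axis("aquarium"),
        residuals=pd.DataFrame(resid, index=offspring, columns=list(config.traits)).rename_axis("animal"),
        sex_effects=pd.DataFrame({"male_offset": sex_eff}, index=list(config.traits)).rename_axis("trait"),
        batch_effects=pd.DataFrame(
            batch_eff, index=[f"B{b + 1}" for b in range(config.n_batches)], columns=list(config.traits)
        ).rename_axis("batch"),
        variances=pd.DataFrame(
            {
                "sigma_a2": sigma_a2,
                "sigma_c2": sigma_c2,
                "sigma_e2": sigma_e2,
                "h2": list(config.true_h2),
                "c2": list(config.true_c2),
            },
            index=list(config.traits),
        ).rename_axis("trait"),
        qtl=pd.DataFrame(qtl_rows, columns=["trait", "snp_id", "chrom", "pos", "effect", "frac_genetic_var"]),
    )
    return pedigree, geno, pheno, truth


def apply_attrition(pheno: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Remove a uniform random fraction of fish, sparing sole family survivors.

    Emulates losses (aggression, mortality) between tagging and the feed
    intake stage.  A family only loses its last member when the requested
    rate cannot otherwise be met.
    """
    if not (0 <= rate < 1):
        raise ValueError("attrition rate must be in [0, 1)")
    if rate == 0:
        return pheno.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    n = len(pheno)
    n_remove = int(round(rate * n))
    fam = pheno["family"].to_numpy()
    remaining = pd.Series(fam).value_counts().to_dict()
    order = rng.permutation(n)
    drop: list[int] = []
    deferred: list[int] = []
    for i in order:
        if len(drop) >= n_remove:
            break
        if remaining[fam[i]] > 1:
            drop.append(i)
            remaining[fam[i]] -= 1
        else:
            deferred.append(i)
    for i in deferred:  # only reached if the rate forces emptying families
        if len(drop) >= n_remove:
            break
        drop.append(i)
    keep = np.setdiff1d(np.arange(n), np.array(drop, dtype=int))
    return pheno.iloc[np.sort(keep)].reset_index(drop=True)


def write_population(
    outdir: str | Path,
    pedigree: pd.DataFrame,
    geno: GenotypeData,
    pheno: pd.DataFrame,
    truth: TruthRecord | None = None,
) -> None:
    """Write pedigree/phenotype CSVs, PLINK files, TSV mirror and truth."""
    from feedgenomics import plink

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree.to_csv(outdir / "pedigree.csv", index=False)
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    plink.write_bed(geno, outdir / "genotypes")
    plink.write_tsv(geno, outdir / "genotypes")
    if truth is not None:
        truth.write(outdir / "truth")
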