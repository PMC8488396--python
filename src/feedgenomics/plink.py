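"""Minimal PLINK 1 .bed/.bim/.fam reader/writer plus a TSV mirror format.

The .bed codec is the SNP-major 2-bit layout: magic bytes ``6c 1b 01``,
then one byte block per SNP holding four samples, coded
``00`` = two minor alleles, ``10`` = heterozygote, ``11`` = zero minor
alleles, ``01`` = missing.  Chromosome labels ``Oni1..Oni24`` are written
to the .bim chromosome column as the integers 1-24; a sidecar
``<prefix>.chrmap.tsv`` records the label map.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from feedgenomics.data import MISSING, GenotypeData, chrom_label, chrom_number

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage (0/1/2/missing) -> 2-bit code, and back
_CODE_FOR_DOSAGE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}
_DOSAGE_FOR_CODE = np.full(4, MISSING, dtype=np.int8)
_DOSAGE_FOR_CODE[0b11] = 0
_DOSAGE_FOR_CODE[0b10] = 1
_DOSAGE_FOR_CODE[0b00] = 2
_DOSAGE_FOR_CODE[0b01] = MISSING


def write_bed(geno: GenotypeData, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam and the chromosome-label sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.calls.shape

    code = np.empty((m, n), dtype=np.uint8)
    calls_t = geno.calls.T
    for dosage, c in _CODE_FOR_DOSAGE.items():
        code[calls_t == dosage] = c
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = code
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": [chrom_number(c) for c in geno.snp_map["chrom"]],
            "snp_id": geno.snp_map["snp_id"],
            "cm": 0,
            "pos": geno.snp_map["pos"],
            "a1": geno.snp_map["minor"],
            "a2": geno.snp_map["major"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": geno.animals,
            "iid": geno.animals,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    labels = sorted({chrom_number(c) for c in geno.snp_map["chrom"]})
    pd.DataFrame({"number": labels, "label": [chrom_label(k) for k in labels]}).to_csv(
        str(prefix) + ".chrmap.tsv", sep="\t", index=False
    )


def read_bed(prefix: str | Path) -> GenotypeData:
    """Read a ``prefix``.bed/.bim/.fam triplet back into :class:`GenotypeData`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _MAGIC:
        raise ValueError(f"{prefix}.bed lacks the PLINK SNP-major magic bytes")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed has {body.size} body bytes, expected {m * n_bytes}")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    calls = _DOSAGE_FOR_CODE[codes[:, :n]].T

    snp_map = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": [chrom_label(c) for c in bim["chrom"]],
            "pos": bim["pos"],
            "minor": bim["a1"],
            "major": bim["a2"],
        }
    )
    return GenotypeData(animals=list(fam["iid"]), snp_map=snp_map, calls=calls)


def write_tsv(geno: GenotypeData, prefix: str | Path) -> None:
    """Plain-text mirror: ``prefix``.calls.tsv (animals x SNPs) and .snps.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    calls = pd.DataFrame(geno.calls, index=geno.animals, columns=geno.snp_map["snp_id"])
    calls.index.name = "animal"
    calls.to_csv(str(prefix) + ".calls.tsv", sep="\t")
    geno.snp_map.to_csv(str(prefix) + ".snps.tsv", sep="\t", index=False)


def read_tsv(prefix: str | Path) -> GenotypeData:
    prefix = Path(prefix)
    calls = pd.read_csv(str(prefix) + ".calls.tsv", sep="\t", index_col=0)
    snp_map = pd.read_csv(str(prefix) + ".snps.tsv", sep="\t", dtype={"snp_id": str})
    return GenotypeData(
        animals=[str(a) for a in calls.index],
        snp_map=snp_map,
        calls=calls.to_numpy(dtype=np.int8),
    )
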