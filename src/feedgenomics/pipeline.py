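"""End-to-end pipeline: simulate -> qc -> traits -> fit -> cv -> gwas -> density.

A run is declared by a :class:`RunConfig` (loadable from YAML).  Each
stochastic stage receives its own seed derived from the global seed keyed
by the stage name, so adding a stage never perturbs the randomness of
earlier ones.  Every stage writes its tabular artifacts into the output
directory and the run ends with a manifest (versions, seeds, stage
counts, SHA-256 checksums of every written file).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import feedgenomics
from feedgenomics import plink
from feedgenomics.data import GenotypeData
from feedgenomics.density import DEFAULT_FRACTIONS, curve_table, run_density_experiment
from feedgenomics.genoqc import QCThresholds, filter_genotypes, pca_structure
from feedgenomics.gwas import loco_assoc, qtl_windows, read_bed_annotation
from feedgenomics.kinship import build_A, build_G, build_Hinv
from feedgenomics.mixedmodel import reml_fit
from feedgenomics.predict_cv import CVScheme, MODELS, compare_accuracies, run_cv
from feedgenomics.simpop import SimConfig, apply_attrition, derive_seed, simulate_population, write_population
from feedgenomics.traits import TraitConfig, derive_traits

log = logging.getLogger("feedgenomics")

ALL_STAGES = ("simulate", "qc", "traits", "fit", "cv", "gwas", "density")


@dataclass
class RunConfig:
    """Declarative description of a full analysis run."""

    outdir: str = "runs/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # either a simulation block or paths to existing inputs
    simulation: SimConfig | None = field(default_factory=SimConfig)
    pedigree_path: str | None = None
    genotype_prefix: str | None = None  # PLINK prefix
    phenotype_path: str | None = None
    annotation_bed: str | None = None
    attrition_rate: float = 0.14
    qc: QCThresholds = field(default_factory=QCThresholds)
    trait_config: TraitConfig = field(default_factory=TraitConfig)
    traits: tuple[str, ...] = ("FCR", "BWG", "RFI", "FI")
    models: tuple[str, ...] = MODELS
    cv_mode: str = "random_animal"
    cv_replicates: int = 100
    cv_folds: int = 5
    gwas_tier: str = "genome_wide"
    density_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    density_replicates: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "genetic_corr" in sim:
                sim["genetic_corr"] = tuple(tuple(r) for r in sim["genetic_corr"])
            for key in ("traits", "true_h2", "true_c2", "trait_means", "trait_sds"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimConfig(**sim)
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "trait_config" in raw:
            raw["trait_config"] = TraitConfig(**raw["trait_config"])
        for key in ("stages", "traits", "models", "density_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        needs_geno = {"qc", "cv", "gwas", "density"} & set(self.stages)
        if self.simulation is None:
            if needs_geno and self.genotype_prefix is None:
                raise ValueError(
                    f"stages {sorted(needs_geno)} need genotypes: provide a "
                    "simulation block or genotype_prefix"
                )
            if self.phenotype_path is None and needs_geno:
                raise ValueError("phenotypes required: provide phenotype_path or a simulation block")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    manifest: dict = {
        "package_version": feedgenomics.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {},
        "stages": {},
        "checksums": {},
    }

    ped = geno = pheno = truth = None
    written: list[Path] = []

    def note(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"wall_seconds": round(time.time() - t0, 3), **counts}
        log.info("stage %s done: %s", stage, counts)

    if "simulate" in config.stages:
        t0 = time.time()
        sim = config.simulation or SimConfig()
        sim.seed = derive_seed(config.seed, "simulate-config")
        manifest["stage_seeds"]["simulate"] = sim.seed
        ped, geno, pheno, truth = simulate_population(sim)
        if config.attrition_rate > 0:
            att_seed = derive_seed(config.seed, "attrition")
            manifest["stage_seeds"]["attrition"] = att_seed
            pheno = apply_attrition(pheno, config.attrition_rate, att_seed)
        write_population(outdir, ped, geno, pheno, truth)
        written += sorted(outdir.glob("pedigree.csv")) + sorted(outdir.glob("phenotypes.csv"))
        written += sorted(outdir.glob("genotypes.*")) + sorted(outdir.glob("truth.*"))
        note("simulate", t0, n_animals=geno.n_animals, n_snps=geno.n_snps, n_phenotyped=len(pheno))
    else:
        if config.pedigree_path:
            ped = pd.read_csv(config.pedigree_path, dtype=str)
            ped["generation"] = ped.get("generation", 0)
        if config.genotype_prefix:
            geno = plink.read_bed(config.genotype_prefix)
        if config.phenotype_path:
            pheno = pd.read_csv(config.phenotype_path)
            pheno["animal"] = pheno["animal"].astype(str)

    if "qc" in config.stages:
        t0 = time.time()
        geno, report = filter_genotypes(geno, config.qc)
        report.write(str(outdir / "qc_report"))
        scores, varexp = pca_structure(geno, n_components=2)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.DataFrame({"component": ["PC1", "PC2"], "pct_variance": varexp[:2]}).to_csv(
            outdir / "pca_variance.tsv", sep="\t", index=False
        )
        written += sorted(outdir.glob("qc_report.*")) + [outdir / "pca_scores.tsv", outdir / "pca_variance.tsv"]
        kept = pheno["animal"].isin(geno.animals) if pheno is not None else None
        if pheno is not None:
            pheno = pheno.loc[kept].reset_index(drop=True)
        note("qc", t0, n_animals=geno.n_animals, n_snps=geno.n_snps,
             **{f"removed_{k}": v for k, v in report.counts_by_rule.items()})

    if "traits" in config.stages:
        t0 = time.time()
        pheno = derive_traits(pheno, config.trait_config)
        pheno.to_csv(outdir / "phenotypes_derived.csv", index=False)
        written.append(outdir / "phenotypes_derived.csv")
        note("traits", t0, n_records=len(pheno),
             **{f"n_outliers_{t}": int(pheno[f"{t}_outlier"].sum()) for t in config.traits})

    kinships = None

    def get_kinships():
        nonlocal kinships
        if kinships is None:
            genotyped = [a for a in geno.animals if a in set(pheno["animal"])] if geno is not None else None
            from feedgenomics.predict_cv import build_model_kinships

            kin_geno = geno.subset(
                animal_idx=[i for i, a in enumerate(geno.animals) if a in set(pheno["animal"])]
            ) if geno is not None else None
            kinships = build_model_kinships(ped, kin_geno, config.models, genotyped)
        return kinships

    if "fit" in config.stages:
        t0 = time.time()
        ks = get_kinships()
        rows = []
        for trait in config.traits:
            for model in config.models:
                vc, _ = reml_fit(pheno, trait, ks[model])
                rows.append({"trait": trait, "model": model, **vc.as_row()})
        vc_table = pd.DataFrame(rows)
        vc_table.to_csv(outdir / "variance_components.tsv", sep="\t", index=False)
        written.append(outdir / "variance_components.tsv")
        note("fit", t0, n_fits=len(rows))

    if "cv" in config.stages:
        t0 = time.time()
        ks = get_kinships()
        scheme = CVScheme(
            mode=config.cv_mode, n_folds=config.cv_folds,
            n_replicates=config.cv_replicates, seed=derive_seed(config.seed, "cv"),
        )
        manifest["stage_seeds"]["cv"] = scheme.seed
        tables = [
            run_cv(pheno, ped, geno, trait, scheme, models=config.models, kinships=ks)
            for trait in config.traits
        ]
        acc = pd.concat(tables, ignore_index=True)
        acc.to_csv(outdir / "cv_accuracy.tsv", sep="\t", index=False)
        comparison = compare_accuracies(acc)
        comparison.to_csv(outdir / "cv_comparison.tsv", sep="\t", index=False)
        written += [outdir / "cv_accuracy.tsv", outdir / "cv_comparison.tsv"]
        note("cv", t0, n_replicates=config.cv_replicates, n_rows=len(acc))

    if "gwas" in config.stages:
        t0 = time.time()
        analysed = geno.subset(
            animal_idx=[i for i, a in enumerate(geno.animals) if a in set(pheno["animal"])]
        )
        annotation = read_bed_annotation(config.annotation_bed) if config.annotation_bed else None
        n_sig = {}
        for trait in config.traits:
            table = loco_assoc(pheno, analysed, trait)
            table.to_csv(outdir / f"gwas_{trait}.tsv", sep="\t", index=False)
            written.append(outdir / f"gwas_{trait}.tsv")
            windows = qtl_windows(table, annotation, tier=config.gwas_tier)
            windows.to_csv(outdir / f"qtl_windows_{trait}.tsv", sep="\t", index=False)
            written.append(outdir / f"qtl_windows_{trait}.tsv")
            n_sig[trait] = int((table["tier"] == "genome_wide").sum())
        note("gwas", t0, n_tested=int(table.attrs["n_tested"]),
             **{f"n_genomewide_{t}": v for t, v in n_sig.items()})

    if "density" in config.stages:
        t0 = time.time()
        analysed = geno.subset(
            animal_idx=[i for i, a in enumerate(geno.animals) if a in set(pheno["animal"])]
        )
        dseed = derive_seed(config.seed, "density")
        manifest["stage_seeds"]["density"] = dseed
        for trait in config.traits:
            curves = run_density_experiment(
                pheno, analysed, trait,
                fractions=config.density_fractions,
                n_replicates=config.density_replicates,
                seed=dseed,
            )
            curve_table(curves).to_csv(outdir / f"density_{trait}.tsv", sep="\t", index=False)
            written.append(outdir / f"density_{trait}.tsv")
        note("density", t0, n_fractions=len(config.density_fractions))

    for path in written:
        if Path(path).exists():
            manifest["checksums"][Path(path).name] = _sha256(Path(path))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
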