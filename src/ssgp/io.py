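"""Delimited-text interchange formats, config files and run manifests.

All interchange is plain tab-separated text with header rows: a pedigree
table (id, sire, dam, generation, sex; 0 = unknown parent), a genotype
matrix (individuals as rows, allele counts 0/1/2), a locus map, a
phenotype table and an optional phased-haplotype export.  Schemas are
validated strictly: bad values are rejected with their location, ids are
cross-checked against the pedigree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import ScenarioConfig
from .pedigree import Pedigree
from .simulation import (
    HaplotypeSet,
    LocusMap,
    SimulationConfig,
    StudyDataset,
    TraitArchitecture,
)

__all__ = [
    "write_study_dataset",
    "read_study_dataset",
    "write_genotype_table",
    "read_genotype_table",
    "load_scenario_config",
    "dump_scenario_config",
    "config_hash",
]

SEP = "\t"


class SchemaError(ValueError):
    pass


def write_genotype_table(path, ids, genotypes, locus_ids) -> None:
    """Genotype matrix: one row per individual, columns = loci, values 0/1/2."""
    frame = pd.DataFrame(np.asarray(genotypes), columns=list(locus_ids))
    frame.insert(0, "id", list(ids))
    frame.to_csv(path, sep=SEP, index=False)


def read_genotype_table(path, pedigree: Pedigree | None = None) -> pd.DataFrame:
    """Read and validate a genotype matrix (index = id)."""
    frame = pd.read_csv(path, sep=SEP)
    if "id" not in frame.columns:
        raise SchemaError(f"{path}: missing 'id' column")
    frame = frame.set_index("id")
    values = frame.to_numpy()
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaError(
            f"{path}: genotype value {values[r, c]!r} not in {{0,1,2}} at "
            f"row id {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    if pedigree is not None:
        known = set(pedigree.ids.tolist())
        missing = [i for i in frame.index if i not in known]
        if missing:
            raise SchemaError(f"{path}: individual {missing[0]!r} not in pedigree")
    return frame


def write_study_dataset(dataset: StudyDataset, outdir, haplotypes: bool = True) -> Path:
    """Persist a study dataset as a directory of delimited tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = dataset.pedigree
    ped.to_frame().to_csv(outdir / "pedigree.tsv", sep=SEP, index=False)
    lm = dataset.haplotypes.locus_map
    lm.to_frame().to_csv(outdir / "locus_map.tsv", sep=SEP, index=False)
    pd.DataFrame(
        {
            "id": ped.ids,
            "generation": ped.generation,
            "phenotype": dataset.phenotype,
            "tbv": dataset.tbv,
            "genotyped": dataset.genotyped.astype(int),
        }
    ).to_csv(outdir / "phenotypes.tsv", sep=SEP, index=False)
    write_genotype_table(
        outdir / "genotypes.tsv",
        dataset.genotyped_ids,
        dataset.haplotypes.genotypes()[dataset.genotyped],
        lm.locus_ids(),
    )
    if haplotypes:
        hap = dataset.haplotypes.haplotypes
        flat = hap.reshape(-1, hap.shape[-1])  # two rows per individual
        frame = pd.DataFrame(flat, columns=lm.locus_ids())
        frame.insert(0, "id", np.repeat(ped.ids, 2))
        frame.insert(1, "hap", np.tile([1, 2], ped.n))
        frame.to_csv(outdir / "haplotypes.tsv", sep=SEP, index=False)
    manifest = {
        "seed": int(dataset.seed),
        "config": dataclasses.asdict(dataset.config),
        "trait": {
            "alpha": dataset.trait.alpha.tolist(),
            "mu_alpha": float(dataset.trait.mu_alpha),
            "beta": float(dataset.trait.beta),
            "h2": float(dataset.trait.h2),
            "sigma2_g": float(dataset.trait.sigma2_g),
            "sigma2_e": float(dataset.trait.sigma2_e),
            "k": None if dataset.trait.k is None else dataset.trait.k.tolist(),
        },
    }
    manifest["config_hash"] = config_hash(manifest["config"])
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir


def read_study_dataset(indir) -> StudyDataset:
    """Inverse of :func:`write_study_dataset` (requires the haplotype file)."""
    indir = Path(indir)
    ped = Pedigree.from_frame(pd.read_csv(indir / "pedigree.tsv", sep=SEP))
    lm = LocusMap.from_frame(pd.read_csv(indir / "locus_map.tsv", sep=SEP))
    pheno = pd.read_csv(indir / "phenotypes.tsv", sep=SEP).set_index("id")
    pheno = pheno.loc[ped.ids]
    hap_path = indir / "haplotypes.tsv"
    if not hap_path.exists():
        raise SchemaError(f"{hap_path} missing; dataset was written without haplotypes")
    hf = pd.read_csv(hap_path, sep=SEP)
    order = {v: i for i, v in enumerate(ped.ids.tolist())}
    hf = hf.sort_values(["id", "hap"], key=lambda s: s.map(order) if s.name == "id" else s)
    values = hf.drop(columns=["id", "hap"]).to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise SchemaError(f"{hap_path}: haplotype alleles must be 0/1")
    hap = values.reshape(ped.n, 2, lm.n_loci)
    with open(indir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    trait = TraitArchitecture(
        alpha=np.array(manifest["trait"]["alpha"]),
        mu_alpha=manifest["trait"]["mu_alpha"],
        beta=manifest["trait"]["beta"],
        h2=manifest["trait"]["h2"],
        sigma2_g=manifest["trait"]["sigma2_g"],
        sigma2_e=manifest["trait"]["sigma2_e"],
        k=None if manifest["trait"]["k"] is None else np.array(manifest["trait"]["k"]),
    )
    ds = StudyDataset(
        pedigree=ped,
        haplotypes=HaplotypeSet(hap, lm),
        tbv=pheno["tbv"].to_numpy(),
        phenotype=pheno["phenotype"].to_numpy(),
        genotyped=pheno["genotyped"].to_numpy().astype(bool),
        trait=trait,
        config=SimulationConfig(**manifest["config"]),
        seed=manifest["seed"],
    )
    # cross-check the observed-genotype table against the haplotypes
    geno = read_genotype_table(indir / "genotypes.tsv", pedigree=ped)
    expect = ds.haplotypes.genotypes()[ds.genotyped]
    if not np.array_equal(geno.to_numpy(), expect):
        raise SchemaError("genotypes.tsv disagrees with haplotypes.tsv")
    return ds


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _from_mapping(cls, mapping: dict, path):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_scenario_config(path) -> ScenarioConfig:
    """Read a scenario config from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _from_mapping(ScenarioConfig, raw, path)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _from_mapping(SimulationConfig, raw, path)


def dump_scenario_config(config: ScenarioConfig, path) -> None:
    data = dataclasses.asdict(config)
    data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
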