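"""Readers and writers for the pipeline's on-disk formats.

Summary statistics, gene annotation, known-hit regions, phenotypes and score
matrices travel as tab-separated text with a header; genotypes as either a
plain dosage-matrix TSV (with variant/sample sidecars) or a VCF with a DS
FORMAT field (written as text here, read back through cyvcf2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, SimulationConfig
from .simulate import GenotypeMatrix
from .sumstats import SUMSTAT_COLUMNS, validate_sumstats

EQTLGEN_COLUMN_MAP = {
    "SNP": "variant_id", "SNPChr": "chrom", "SNPPos": "pos",
    "AssessedAllele": "effect_allele", "OtherAllele": "other_allele",
    "Zscore": "zscore", "Pvalue": "pvalue", "Gene": "target_id",
    "NrSamples": "n",
}


def write_sumstats(records: pd.DataFrame, path: str | Path) -> None:
    validate_sumstats(records)[SUMSTAT_COLUMNS].to_csv(
        path, sep="\t", index=False)


def read_sumstats(path: str | Path,
                  column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV, optionally renaming dialect headers.

    When a z-score column is mapped instead of beta/se, beta is taken as
    z/sqrt(n) and se as 1/sqrt(n) (the standardized-scale convention used by
    large expression meta-analyses that publish z-scores only).
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        table = table.rename(columns=column_map)
    if "beta" not in table.columns and "zscore" in table.columns:
        table["se"] = 1.0 / np.sqrt(table["n"].astype(float))
        table["beta"] = table["zscore"].astype(float) * table["se"]
    table["chrom"] = table["chrom"].astype(str)
    return validate_sumstats(table)


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["target_id", "chrom", "site_start", "site_end"]].to_csv(
        path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return table


def read_known_hits(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"known-hit table needs columns {sorted(required)}")
    return table


def read_monogenic_list(path: str | Path) -> set[str]:
    text = Path(path).read_text().split()
    return {line.strip() for line in text if line.strip()}


# ---------------------------------------------------------------------------
# genotype matrices

def write_genotypes(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write dosages plus variant/sample sidecars as `<prefix>.*.tsv`."""
    prefix = Path(prefix)
    geno.dosage_frame().to_csv(f"{prefix}.dosages.tsv", sep="\t",
                               index_label="sample_id", float_format="%g")
    geno.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    geno.samples.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dosages = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t",
                          index_col="sample_id")
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t",
                           dtype={"chrom": str})
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    return GenotypeMatrix(dosages.to_numpy(dtype=float), variants, samples)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a VCF 4.2 text file with a DS dosage FORMAT field."""
    samples = list(geno.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        for chrom in pd.unique(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, v in enumerate(geno.variants.itertuples()):
            ds = "\t".join(f"{d:g}" for d in geno.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                     f"{v.effect_allele}\t.\tPASS\t.\tDS\t{ds}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from the DS field of a VCF (effect allele = ALT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows, columns = [], []
    for record in vcf:
        rows.append({
            "variant_id": record.ID,
            "chrom": record.CHROM,
            "pos": record.POS,
            "effect_allele": record.ALT[0],
            "other_allele": record.REF,
        })
        columns.append(np.asarray(record.format("DS"),
                                  dtype=float).reshape(-1))
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, pd.DataFrame(rows),
                          pd.DataFrame({"sample_id": samples}))


# ---------------------------------------------------------------------------
# configuration files

def load_configs(path: str | Path) -> tuple[SimulationConfig, PipelineConfig]:
    """Load `simulation:` and `pipeline:` sections from one YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = raw.get("simulation", {})
    for key in ("maf_range", "hla_block_ids"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    return (SimulationConfig(**sim_kwargs),
            PipelineConfig(**raw.get("pipeline", {})))


def write_scores(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="sample_id",
                  float_format="%.6g")
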