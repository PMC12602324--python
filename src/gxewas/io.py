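"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as PLINK .bed/.bim/.fam, as VCF (hard calls from GT),
or as a transparent tabular format: a SNP-major TSV whose first five columns
are the .bim-style record (snp, chrom, pos, allele1, allele2[, info]) and
whose remaining columns are subjects (calls count allele1; NA = missing).
Methylation, covariates, stress items and all result tables are TSV; the
truth registry is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MethylationMatrix, TruthRegistry

_GENO_META = ["snp", "chrom", "pos", "allele1", "allele2", "info"]


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    meta = geno.snps.copy()
    if "info" not in meta.columns:
        meta["info"] = 1.0
    table = pd.concat(
        [meta[_GENO_META].reset_index(drop=True),
         pd.DataFrame(geno.calls.T, columns=geno.subjects)], axis=1)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t")
    meta = table[_GENO_META].copy()
    calls = table.drop(columns=_GENO_META).to_numpy(dtype=float).T
    subjects = pd.Index(table.columns[len(_GENO_META):])
    return GenotypeMatrix(subjects, meta, calls)


def read_plink(prefix) -> GenotypeMatrix:
    """Read PLINK .bed/.bim/.fam (SNP-major .bed, magic 6c 1b 01).

    Calls count the .bim A1 allele; code 01 (binary) is missing.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "allele1", "allele2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[0] != 0x6C or raw[1] != 0x1B or raw[2] != 0x01:
        raise ValueError("not a SNP-major PLINK .bed file")
    n, m = len(fam), len(bim)
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:3 + bpv * m].reshape(m, bpv)
    bits = np.unpackbits(body, axis=1, bitorder="little").reshape(m, -1)
    codes = bits[:, 0::2] + 2 * bits[:, 1::2]
    codes = codes[:, :n]
    # 00 = hom A1 (2 copies), 10 = het, 11 = hom A2, 01 = missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    calls = lut[codes].T
    meta = bim[["snp", "chrom", "pos", "allele1", "allele2"]].copy()
    return GenotypeMatrix(pd.Index(fam["iid"].astype(str)), meta, calls)


def read_vcf(path) -> GenotypeMatrix:
    """Hard calls from a VCF's GT field via cyvcf2 (counting the ALT allele)."""
    from cyvcf2 import VCF  # optional dependency, imported on use

    vcf = VCF(str(path))
    subjects = pd.Index(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        calls = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(calls)
        meta.append({"snp": var.ID or f"{var.CHROM}:{var.POS}", "chrom": var.CHROM,
                     "pos": var.POS, "allele1": var.ALT[0], "allele2": var.REF})
    return GenotypeMatrix(subjects, pd.DataFrame(meta), np.array(rows).T)


def write_methylation_tsv(meth: MethylationMatrix, beta_path, manifest_path) -> None:
    pd.DataFrame(meth.betas.T, index=meth.probes["cpg"], columns=meth.subjects) \
        .to_csv(beta_path, sep="\t", index_label="cpg", na_rep="NA")
    meth.probes.to_csv(manifest_path, sep="\t", index=False)


def read_methylation_tsv(beta_path, manifest_path) -> MethylationMatrix:
    betas = pd.read_csv(beta_path, sep="\t", index_col="cpg")
    probes = pd.read_csv(manifest_path, sep="\t")
    probes = probes.set_index("cpg").loc[betas.index].reset_index()
    return MethylationMatrix(pd.Index(betas.columns), probes, betas.to_numpy(dtype=float).T)


def write_registry(reg: TruthRegistry, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "planted_g": reg.planted_g, "planted_e": reg.planted_e,
            "planted_gxe": reg.planted_gxe, "planted_mediated": reg.planted_mediated,
        }, fh, indent=1)


def read_registry(path) -> TruthRegistry:
    with open(path) as fh:
        d = json.load(fh)
    return TruthRegistry(
        planted_g=[tuple(x) for x in d["planted_g"]],
        planted_e=[tuple(x) for x in d["planted_e"]],
        planted_gxe=[tuple(x) for x in d["planted_gxe"]],
        planted_mediated=[tuple(x) for x in d["planted_mediated"]],
    )


def write_summary_stats(records: pd.DataFrame, path, coded_allele: pd.Series | None = None,
                        header_comment: str | None = None) -> None:
    """METAL-ready per-cohort summary statistics TSV."""
    out = records.copy()
    if coded_allele is not None:
        out = out.merge(coded_allele.rename("coded_allele"), left_on="snp", right_index=True, how="left")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
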