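"""Core in-memory containers shared across the pipeline.

Genotypes, methylation and covariates are kept as plain numpy arrays plus
pandas metadata tables, aligned on subject order.  Missing genotype calls are
encoded as NaN in float arrays (hard calls are otherwise {0, 1, 2}, counting
copies of ``allele1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["snp", "chrom", "pos", "allele1", "allele2"]
PROBE_META_COLUMNS = ["cpg", "chrom", "pos", "cross_reactive"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs hard-call matrix with per-SNP metadata.

    calls[i, j] counts copies of ``snps.allele1[j]`` in subject i; NaN marks a
    missing call.  ``snps`` may carry extra columns (e.g. ``info`` imputation
    quality, ``maf``).
    """

    subjects: pd.Index
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = pd.Index(self.subjects)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table lacks columns: {missing}")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype calls must be in {0, 1, 2} or missing")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            af1 = np.nanmean(self.calls, axis=0) / 2.0
        return np.minimum(af1, 1.0 - af1)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def subset(self, subject_mask=None, snp_mask=None) -> "GenotypeMatrix":
        calls = self.calls
        subjects = self.subjects
        snps = self.snps
        if subject_mask is not None:
            subjects = subjects[subject_mask]
            calls = calls[np.asarray(subject_mask)]
        if snp_mask is not None:
            snps = snps.loc[snp_mask].reset_index(drop=True)
            calls = calls[:, np.asarray(snp_mask)]
        return GenotypeMatrix(subjects, snps, calls)


@dataclass
class MethylationMatrix:
    """Subjects x CpGs beta-value matrix with a probe manifest.

    Beta values lie in [0, 1]; ``probes`` carries chrom/pos and the
    cross-reactive flag, plus optional ``mad`` once scored.
    """

    subjects: pd.Index
    probes: pd.DataFrame
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = pd.Index(self.subjects)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.subjects), len(self.probes)):
            raise ValueError(
                f"betas shape {self.betas.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.probes)} probes"
            )
        missing = [c for c in PROBE_META_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe manifest lacks columns: {missing}")
        if self.probes["cpg"].duplicated().any():
            raise ValueError("duplicate probe ids")
        finite = self.betas[np.isfinite(self.betas)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def subset(self, subject_mask=None, probe_mask=None) -> "MethylationMatrix":
        betas = self.betas
        subjects = self.subjects
        probes = self.probes
        if subject_mask is not None:
            subjects = subjects[subject_mask]
            betas = betas[np.asarray(subject_mask)]
        if probe_mask is not None:
            probes = probes.loc[probe_mask].reset_index(drop=True)
            betas = betas[:, np.asarray(probe_mask)]
        return MethylationMatrix(subjects, probes, betas)


@dataclass
class TruthRegistry:
    """Book-keeping of effects planted by the simulator, for recovery tests.

    Each entry records ids and the latent (logit-scale) coefficient used at
    generation time.  A CpG appears in at most one effect class.
    """

    planted_g: list = field(default_factory=list)      # (snp, cpg, beta)
    planted_e: list = field(default_factory=list)      # (cpg, beta)
    planted_gxe: list = field(default_factory=list)    # (snp, cpg, beta)
    planted_mediated: list = field(default_factory=list)  # (cpg, a_path, b_path)

    def cpgs(self) -> set:
        out = set()
        for lst in (self.planted_g, self.planted_gxe):
            out.update(rec[1] for rec in lst)
        out.update(rec[0] for rec in self.planted_e)
        out.update(rec[0] for rec in self.planted_mediated)
        return out

    def validate_disjoint(self) -> None:
        classes = [
            {rec[1] for rec in self.planted_g},
            {rec[0] for rec in self.planted_e},
            {rec[1] for rec in self.planted_gxe},
            {rec[0] for rec in self.planted_mediated},
        ]
        seen: set = set()
        for cls in classes:
            if cls & seen:
                raise ValueError(f"CpGs in more than one effect class: {cls & seen}")
            seen |= cls
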