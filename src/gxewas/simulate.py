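"""Synthetic multi-cohort data with the structure the analysis assumes.

The generator emulates a two-cohort / three-dataset birth-cohort design:

* genotypes in Hardy-Weinberg equilibrium with tunable LD blocks (haplotype
  copy-with-probability down a block, which preserves marginal allele
  frequencies) and MAF >= 0.05,
* ~50 binary prenatal-stress items in four domains (life events, contextual,
  personal, interpersonal) with a shared per-subject liability and
  cohort-specific target mean total scores (defaults 0.36 / 0.44 / 0.51),
* covariates: child sex, 5 genetic PCs, 7 cell-type proportions, and a
  cohort-specific batch structure,
* mediators: a continuous smoking score on the stress -> smoking -> DNAm
  path, plus alcohol, gestational age and birth weight with null paths,
* beta-value methylation built on the logit scale (Gaussian latent squashed
  through the inverse logit, keeping betas in (0,1) without truncation) with
  planted G-only, E-only, GxE and smoking-mediated effects sized to a target
  adjusted-R^2 increment (default 0.02, the magnitude typical of significant
  interaction terms in cohort data of this size).

All randomness fans out from one global seed into per-component child seeds,
so components are reproducible and independently perturbable.  A
TruthRegistry records every planted effect for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .datatypes import GenotypeMatrix, MethylationMatrix, TruthRegistry
from .stress import DOMAINS

# Table-1-style domain composition of the mean total score: relative weight
# of life events / contextual / personal / interpersonal.
_DOMAIN_WEIGHTS = np.array([0.28, 0.44, 0.09, 0.19])


@dataclass
class SimulationConfig:
    n_cohorts: int = 3
    n_subjects: tuple = (1224, 949, 790)
    n_snps: int = 200
    n_cpgs: int = 200
    n_items: int = 50
    domain_sizes: tuple = (17, 13, 10, 10)
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 5
    ld_copy_prob: float = 0.8
    stress_means: tuple = (0.36, 0.44, 0.51)
    stress_loading: float = 0.5
    missing_rate_items: float = 0.05
    effect_registry_sizes: dict = field(
        default_factory=lambda: {"g": 3, "e": 3, "gxe": 3, "mediated": 2})
    effect_r2: float = 0.02
    noise_sd: float = 0.35
    smoking_a_path: float = 0.5
    cohort_effect_multipliers: tuple | None = None
    n_batches: tuple = (25, 12, 20)
    geno_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cohorts < 1 or self.n_snps < 1 or self.n_cpgs < 1 or self.n_items < 1:
            raise ValueError("dimensions must be positive")
        if len(self.n_subjects) != self.n_cohorts or any(n < 1 for n in self.n_subjects):
            raise ValueError("n_subjects must give a positive count per cohort")
        if sum(self.domain_sizes) != self.n_items or len(self.domain_sizes) != 4:
            raise ValueError("domain_sizes must be 4 counts summing to n_items")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for p in (self.ld_copy_prob, self.missing_rate_items, self.geno_missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if len(self.stress_means) != self.n_cohorts:
            raise ValueError("stress_means must give one target per cohort")
        for m in self.stress_means:
            prev = m * _DOMAIN_WEIGHTS / _DOMAIN_WEIGHTS.sum()
            if (prev <= 0).any() or (prev >= 1).any():
                raise ValueError(f"stress mean {m} unreachable with 4 domain scores in [0,1]")
        if not 0.0 < self.effect_r2 < 0.5:
            raise ValueError("effect_r2 must be in (0, 0.5)")
        total = sum(self.effect_registry_sizes.values())
        if total > self.n_cpgs:
            raise ValueError("more planted effects than CpGs")

    def child_seed(self, component: str, cohort: int = 0) -> int:
        """Deterministic per-component seed below 2^31 (process-independent)."""
        tag = zlib.crc32(component.encode()) % (2 ** 31)
        h = np.random.SeedSequence([self.seed, cohort, tag])
        return int(h.generate_state(1)[0] % (2 ** 31))


def _snp_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared SNP metadata: ids, positions and block allele frequencies."""
    n_blocks = int(np.ceil(cfg.n_snps / cfg.ld_block_size))
    block_maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_blocks)
    block = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[: cfg.n_snps]
    n_chrom = min(22, n_blocks)
    chrom = (block % n_chrom) + 1
    pos = np.zeros(cfg.n_snps, dtype=int)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1_000_000 + np.arange(len(idx)) * 5_000
    alleles = rng.choice(["A", "C", "G"], size=cfg.n_snps)
    allele2 = np.where(alleles == "A", "G", np.where(alleles == "C", "T", "A"))
    return pd.DataFrame({
        "snp": [f"snp{j:06d}" for j in range(cfg.n_snps)],
        "chrom": chrom, "pos": pos,
        "allele1": alleles, "allele2": allele2,
        "maf": block_maf[block], "block": block,
        "info": 1.0,
    })


def simulate_genotypes(cfg: SimulationConfig, cohort: int) -> GenotypeMatrix:
    """Hard calls in HWE with copy-with-probability LD down each block.

    Two haplotypes per subject; within a block every SNP shares the block
    allele frequency, and each haplotype allele copies the previous SNP's
    allele with probability ``ld_copy_prob`` (else a fresh Bernoulli draw),
    so marginal frequencies are preserved while adjacent SNPs correlate.
    SNP ids and positions are identical across cohorts.
    """
    meta = _snp_table(cfg, np.random.default_rng(cfg.child_seed("snp_table")))
    rng = np.random.default_rng(cfg.child_seed("genotypes", cohort))
    n = cfg.n_subjects[cohort]
    freqs = meta["maf"].to_numpy()
    blocks = meta["block"].to_numpy()
    hap = np.empty((2, n, cfg.n_snps), dtype=np.int8)
    for j in range(cfg.n_snps):
        fresh = (rng.random((2, n)) < freqs[j]).astype(np.int8)
        if j > 0 and blocks[j] == blocks[j - 1]:
            copy = rng.random((2, n)) < cfg.ld_copy_prob
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
        else:
            hap[:, :, j] = fresh
    calls = (hap[0] + hap[1]).astype(float)
    if cfg.geno_missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.geno_missing_rate] = np.nan
    subjects = pd.Index([f"c{cohort}_s{i:05d}" for i in range(n)])
    return GenotypeMatrix(subjects, meta.drop(columns="block"), calls)


def simulate_stress_items(cfg: SimulationConfig, cohort: int) -> pd.DataFrame:
    """Binary stress items with a shared latent liability per subject.

    Item j in domain d fires when lam*z_i + sqrt(1-lam^2)*eps exceeds the
    probit threshold of the domain prevalence, so the marginal item
    prevalence is exact and the per-cohort mean total score targets
    ``stress_means[cohort]``.  Missingness is injected completely at random.
    """
    rng = np.random.default_rng(cfg.child_seed("stress", cohort))
    n = cfg.n_subjects[cohort]
    target = cfg.stress_means[cohort]
    prev = target * _DOMAIN_WEIGHTS / _DOMAIN_WEIGHTS.sum()
    lam = cfg.stress_loading
    z = rng.standard_normal(n)
    cols = {}
    item_idx = 0
    for d, size in enumerate(cfg.domain_sizes):
        tau = norm.ppf(prev[d])
        for _ in range(size):
            u = lam * z + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            vals = (u < tau).astype(float)
            cols[f"item{item_idx:03d}"] = vals
            item_idx += 1
    items = pd.DataFrame(cols, index=pd.Index([f"c{cohort}_s{i:05d}" for i in range(n)]))
    if cfg.missing_rate_items > 0:
        mask = rng.random(items.shape) < cfg.missing_rate_items
        items = items.mask(mask)
    return items


def item_domain_mapping(cfg: SimulationConfig) -> dict[str, str]:
    mapping = {}
    item_idx = 0
    for d, size in enumerate(cfg.domain_sizes):
        for _ in range(size):
            mapping[f"item{item_idx:03d}"] = DOMAINS[d]
            item_idx += 1
    return mapping


def simulate_covariates(cfg: SimulationConfig, cohort: int) -> pd.DataFrame:
    """Sex, 5 genetic PCs, 7 cell proportions and batch dummies."""
    rng = np.random.default_rng(cfg.child_seed("covariates", cohort))
    n = cfg.n_subjects[cohort]
    idx = pd.Index([f"c{cohort}_s{i:05d}" for i in range(n)])
    out = pd.DataFrame(index=idx)
    out["sex"] = rng.integers(0, 2, size=n).astype(float)
    for k in range(5):
        out[f"pc{k + 1}"] = rng.standard_normal(n)
    cells = rng.dirichlet(np.array([8, 4, 2, 2, 2, 10, 1], dtype=float), size=n)
    for k in range(7):
        out[f"cell{k + 1}"] = cells[:, k]
    n_batches = cfg.n_batches[cohort] if cohort < len(cfg.n_batches) else 5
    batch = rng.integers(0, n_batches, size=n)
    for b in range(1, n_batches):  # reference-coded dummies
        out[f"batch{b}"] = (batch == b).astype(float)
    return out


def simulate_mediators(cfg: SimulationConfig, cohort: int, stress_z: pd.Series,
                       registry: TruthRegistry | None = None) -> pd.DataFrame:
    """Smoking correlated with stress via the a-path; null alcohol/GA/BW.

    Smoking and alcohol are continuous average-over-trimester scores;
    gestational age (weeks) and birth weight (grams) are on natural scales
    with null stress paths.
    """
    rng = np.random.default_rng(cfg.child_seed("mediators", cohort))
    z = np.asarray(stress_z, dtype=float)
    n = len(z)
    a = cfg.smoking_a_path
    smoking = a * z + np.sqrt(max(1 - a ** 2, 1e-9)) * rng.standard_normal(n)
    alcohol = rng.standard_normal(n)
    gest_age = 40.0 + 1.5 * rng.standard_normal(n)
    birth_weight = 3500.0 + 500.0 * rng.standard_normal(n)
    return pd.DataFrame({
        "smoking": smoking, "alcohol": alcohol,
        "gestational_age": gest_age, "birth_weight": birth_weight,
    }, index=stress_z.index)


def _effect_size(beta_sd_x: float, resid_sd: float, r2: float) -> float:
    """Latent-scale coefficient giving the target R^2 increment.

    Solves b^2 var(x) / (b^2 var(x) + sd^2) = r2 for b, with x standardized
    to sd ``beta_sd_x``.
    """
    return resid_sd * np.sqrt(r2 / (1 - r2)) / beta_sd_x


def plan_effects(cfg: SimulationConfig) -> TruthRegistry:
    """Choose planted (SNP, CpG) assignments and latent coefficients.

    Shared across cohorts; CpG classes are disjoint.  Signs alternate and
    magnitudes are spread 0.5x-1.5x around the common target so planted
    effects are rank-distinguishable against estimation noise.
    """
    rng = np.random.default_rng(cfg.child_seed("effects"))
    sizes = cfg.effect_registry_sizes
    total = sum(sizes.values())
    cpgs = rng.choice(cfg.n_cpgs, size=total, replace=False)
    snp_pool = rng.choice(cfg.n_snps, size=sizes.get("g", 0) + sizes.get("gxe", 0), replace=False)
    cpg_iter = iter(cpgs)
    snp_iter = iter(snp_pool)
    reg = TruthRegistry()
    base = _effect_size(0.5, cfg.noise_sd, cfg.effect_r2)  # dominant G has sd ~0.5

    def spread(i, k):
        scale = 0.5 + 1.0 * (i / max(k - 1, 1))
        return base * scale * (1 if i % 2 == 0 else -1)

    for i in range(sizes.get("g", 0)):
        reg.planted_g.append((f"snp{next(snp_iter):06d}", f"cg{next(cpg_iter):06d}", spread(i, sizes["g"])))
    ebase = _effect_size(1.0, cfg.noise_sd, cfg.effect_r2)
    for i in range(sizes.get("e", 0)):
        reg.planted_e.append((f"cg{next(cpg_iter):06d}", ebase * (0.5 + 1.0 * i / max(sizes["e"] - 1, 1)) * (1 if i % 2 else -1)))
    for i in range(sizes.get("gxe", 0)):
        reg.planted_gxe.append((f"snp{next(snp_iter):06d}", f"cg{next(cpg_iter):06d}", spread(i, sizes["gxe"])))
    for i in range(sizes.get("mediated", 0)):
        b_path = _effect_size(1.0, cfg.noise_sd, cfg.effect_r2) * (1 if i % 2 == 0 else -1)
        reg.planted_mediated.append((f"cg{next(cpg_iter):06d}", cfg.smoking_a_path, b_path))
    reg.validate_disjoint()
    return reg


def _probe_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_chrom = min(22, cfg.n_cpgs)
    chrom = (np.arange(cfg.n_cpgs) % n_chrom) + 1
    pos = np.zeros(cfg.n_cpgs, dtype=int)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1_200_000 + np.arange(len(idx)) * 7_500
    return pd.DataFrame({
        "cpg": [f"cg{k:06d}" for k in range(cfg.n_cpgs)],
        "chrom": chrom, "pos": pos,
        "cross_reactive": False,
        "baseline_logit": rng.normal(0.0, 1.2, size=cfg.n_cpgs),
    })


def simulate_methylation(
    cfg: SimulationConfig,
    cohort: int,
    genotypes: GenotypeMatrix,
    stress_z: pd.Series,
    covariates: pd.DataFrame,
    mediators: pd.DataFrame | None = None,
    registry: TruthRegistry | None = None,
) -> tuple[MethylationMatrix, TruthRegistry]:
    """Beta-value methylation with planted effects on the logit scale.

    Latent = probe baseline + small sex/cell/batch effects + planted terms +
    Gaussian noise; beta = expit(latent).  Planted genotype terms use the
    dominant coding (carrier of a minor allele), matching the analysis model.
    """
    if registry is None:
        registry = plan_effects(cfg)
    probes = _probe_table(cfg, np.random.default_rng(cfg.child_seed("probe_table")))
    rng = np.random.default_rng(cfg.child_seed("methylation", cohort))
    n = cfg.n_subjects[cohort]
    if not (len(stress_z) == n == genotypes.n_subjects == len(covariates)):
        raise ValueError("inputs are not subject-aligned")
    mult = 1.0
    if cfg.cohort_effect_multipliers is not None:
        mult = cfg.cohort_effect_multipliers[cohort]

    latent = np.tile(probes["baseline_logit"].to_numpy(), (n, 1))
    sex = covariates["sex"].to_numpy()
    cell1 = covariates["cell1"].to_numpy()
    sex_eff = rng.normal(0.0, 0.05, size=cfg.n_cpgs)
    cell_eff = rng.normal(0.0, 0.3, size=cfg.n_cpgs)
    latent += sex[:, None] * sex_eff[None, :] + cell1[:, None] * cell_eff[None, :]
    batch_cols = [c for c in covariates.columns if c.startswith("batch")]
    if batch_cols:
        batch_eff = rng.normal(0.0, 0.05, size=(len(batch_cols), cfg.n_cpgs))
        latent += covariates[batch_cols].to_numpy() @ batch_eff

    snp_pos = {s: j for j, s in enumerate(genotypes.snps["snp"])}
    cpg_pos = {c: k for k, c in enumerate(probes["cpg"])}
    z = np.asarray(stress_z, dtype=float)

    def dominant(snp_id):
        calls = genotypes.calls[:, snp_pos[snp_id]]
        dom = (np.nan_to_num(calls, nan=0.0) >= 1).astype(float)
        return dom

    for snp_id, cpg_id, beta in registry.planted_g:
        latent[:, cpg_pos[cpg_id]] += mult * beta * dominant(snp_id)
    for cpg_id, beta in registry.planted_e:
        latent[:, cpg_pos[cpg_id]] += mult * beta * z
    for snp_id, cpg_id, beta in registry.planted_gxe:
        latent[:, cpg_pos[cpg_id]] += mult * beta * dominant(snp_id) * z
    if mediators is not None:
        smoking = mediators["smoking"].to_numpy()
        for cpg_id, _a, b_path in registry.planted_mediated:
            latent[:, cpg_pos[cpg_id]] += mult * b_path * smoking

    latent += rng.normal(0.0, cfg.noise_sd, size=latent.shape)
    betas = expit(latent)
    meth = MethylationMatrix(genotypes.subjects, probes.drop(columns="baseline_logit"), betas)
    return meth, registry


@dataclass
class CohortData:
    name: str
    genotypes: GenotypeMatrix
    stress_items: pd.DataFrame
    stress_z: pd.Series
    covariates: pd.DataFrame
    mediators: pd.DataFrame
    methylation: MethylationMatrix


def simulate_study(cfg: SimulationConfig) -> tuple[list[CohortData], TruthRegistry]:
    """Generate all cohorts plus the shared truth registry.

    The exposure used to generate methylation is the standardized total
    stress score computed from the items (mean-imputing any MCAR gaps), so
    the registry's effects refer to the generative exposure; the scoring
    pipeline re-derives its own estimate from the masked items downstream.
    """
    registry = plan_effects(cfg)
    cohorts = []
    mapping = item_domain_mapping(cfg)
    for c in range(cfg.n_cohorts):
        geno = simulate_genotypes(cfg, c)
        items = simulate_stress_items(cfg, c)
        dom_means = {}
        # mean-impute per item for the generative exposure only
        filled = items.apply(lambda s: s.fillna(s.mean()))
        for dom in DOMAINS:
            cols = [i for i, d in mapping.items() if d == dom]
            dom_means[dom] = filled[cols].mean(axis=1)
        total = sum(dom_means.values())
        zed = (total - total.mean()) / total.std(ddof=1)
        cov = simulate_covariates(cfg, c)
        med = simulate_mediators(cfg, c, zed, registry)
        meth, _ = simulate_methylation(cfg, c, geno, zed, cov, med, registry)
        cohorts.append(CohortData(
            name=f"cohort{c}", genotypes=geno, stress_items=items, stress_z=zed,
            covariates=cov, mediators=med, methylation=meth,
        ))
    return cohorts, registry
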