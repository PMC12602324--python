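"""Genotype quality control: SNP/sample filters, relatedness exclusion,
VIF-based LD pruning, dominant recoding and cross-cohort allele harmonization.

Filters follow meQTL-study practice: SNP call rate >= 95%, Hardy-Weinberg
exact p >= 1e-7, MAF >= 5%, imputation info score above a per-cohort floor;
sample call rate >= 97.5%; one of each cryptically related pair (IBD > 0.15)
removed.  Pruning uses a 50-SNP sliding window (step 5) capping the variance
inflation factor at 2, on additive dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class QCThresholds:
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-7
    maf_min: float = 0.05
    info_min: float = 0.3
    sample_call_rate_min: float = 0.975
    ibd_max: float = 0.15


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count at least as improbable as the observed one.
    Returns p in (0, 1].
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # P(het | n, n_minor) under HWE, conditional on allele counts
    logp = (
        gammaln(n + 1) - gammaln(hets + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
        + hets * np.log(2)
        + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def is_indel_or_multiallelic(snps: pd.DataFrame) -> np.ndarray:
    """Flag records whose alleles are not two distinct single bases."""
    a1 = snps["allele1"].astype(str).str.upper()
    a2 = snps["allele2"].astype(str).str.upper()
    ok = a1.isin(_BASES) & a2.isin(_BASES) & (a1 != a2)
    return ~ok.to_numpy()


def sample_filter(geno: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()):
    """Drop samples with call rate below the threshold; returns (matrix, drop_log)."""
    rate = 1.0 - np.isnan(geno.calls).mean(axis=1)
    keep = rate >= thresholds.sample_call_rate_min
    log = pd.DataFrame(
        {"subject": geno.subjects[~keep], "call_rate": rate[~keep], "reason": "sample_call_rate"}
    )
    return geno.subset(subject_mask=keep), log


def snp_filter(geno: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()):
    """Apply SNP filters in fixed order: indel/multi-allelic -> call rate ->
    HWE -> MAF -> info; returns (retained GenotypeMatrix, drop_log DataFrame).

    HWE and MAF are computed on the non-missing calls of the current sample.
    The ``info`` filter only applies when the metadata carries an ``info``
    column.  Each SNP is logged once, under the first filter it fails.
    """
    n_snps = geno.n_snps
    alive = np.ones(n_snps, dtype=bool)
    reasons = np.full(n_snps, "", dtype=object)

    bad = is_indel_or_multiallelic(geno.snps)
    reasons[alive & bad] = "indel_multiallelic"
    alive &= ~bad

    low_cr = geno.call_rate() < thresholds.call_rate_min
    reasons[alive & low_cr] = "call_rate"
    alive &= ~low_cr

    hwe_fail = np.zeros(n_snps, dtype=bool)
    for j in np.flatnonzero(alive):
        calls = geno.calls[:, j]
        calls = calls[~np.isnan(calls)]
        n2 = int((calls == 2).sum())
        n1 = int((calls == 1).sum())
        n0 = int((calls == 0).sum())
        if hwe_exact_test(n2, n1, n0) < thresholds.hwe_p_min:
            hwe_fail[j] = True
    reasons[alive & hwe_fail] = "hwe"
    alive &= ~hwe_fail

    low_maf = geno.maf() < thresholds.maf_min
    reasons[alive & low_maf] = "maf"
    alive &= ~low_maf

    if "info" in geno.snps.columns:
        low_info = geno.snps["info"].to_numpy() < thresholds.info_min
        reasons[alive & low_info] = "info"
        alive &= ~low_info

    log = pd.DataFrame({"snp": geno.snps["snp"][~alive], "reason": reasons[~alive]})
    return geno.subset(snp_mask=alive), log


def relatedness_exclude(
    subjects: pd.Index,
    ibd_pairs: pd.DataFrame,
    data_completeness: pd.Series,
    ibd_max: float = 0.15,
    seed: int = 0,
) -> pd.Index:
    """Greedy exclusion of cryptic relatives.

    ``ibd_pairs`` has columns id1, id2, ibd.  Pairs with IBD above ``ibd_max``
    are resolved from the highest IBD down, keeping the member with more
    complete data (ties broken by a seeded random draw), until no retained
    pair is flagged.
    """
    subjects = pd.Index(subjects)
    unknown = (set(ibd_pairs["id1"]) | set(ibd_pairs["id2"])) - set(subjects)
    if unknown:
        raise ValueError(f"IBD pairs reference unknown subjects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    flagged = ibd_pairs.loc[ibd_pairs["ibd"] > ibd_max].sort_values(
        ["ibd", "id1", "id2"], ascending=[False, True, True]
    )
    removed: set = set()
    for _, row in flagged.iterrows():
        a, b = row["id1"], row["id2"]
        if a in removed or b in removed:
            continue
        ca, cb = data_completeness.get(a, 0.0), data_completeness.get(b, 0.0)
        if ca > cb:
            removed.add(b)
        elif cb > ca:
            removed.add(a)
        else:
            removed.add(a if rng.integers(2) == 0 else b)
    return subjects[[s not in removed for s in subjects]]


def _vif(dosages: np.ndarray) -> np.ndarray:
    """VIF of each column given the others, via per-column OLS R^2."""
    n, k = dosages.shape
    X = dosages - dosages.mean(axis=0)
    out = np.empty(k)
    for i in range(k):
        y = X[:, i]
        ssy = y @ y
        if ssy == 0:
            out[i] = np.inf  # constant column: degenerate, treat as prunable
            continue
        Z = np.delete(X, i, axis=1)
        if Z.shape[1] == 0:
            out[i] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss = y - Z @ coef
        r2 = 1.0 - (rss @ rss) / ssy
        out[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> pd.Index:
    """LD pruning on additive dosages with a sliding window and VIF cap.

    Within every window the highest-VIF SNP is removed iteratively until all
    retained SNPs have VIF <= ``vif_max`` (ties: the later-position SNP is
    dropped).  Windows slide by ``step`` within each chromosome; input must be
    position-sorted within chromosome.  Missing calls are mean-imputed for the
    pruning regressions only.  Returns the retained SNP ids.
    """
    snps = geno.snps
    for _, grp in snps.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("SNPs must be position-sorted within chromosome")
    calls = geno.calls.copy()
    col_mean = np.nanmean(calls, axis=0)
    nan_r, nan_c = np.where(np.isnan(calls))
    calls[nan_r, nan_c] = col_mean[nan_c]

    keep = np.ones(geno.n_snps, dtype=bool)
    for _, grp in snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            win = idx[start:start + window]
            if len(win) == 0:
                break
            while True:
                active = win[keep[win]]
                if len(active) < 2:
                    break
                vifs = _vif(calls[:, active])
                worst = vifs.max()
                if worst <= vif_max:
                    break
                # ties -> later position dropped
                drop_local = np.flatnonzero(vifs >= worst - 1e-12).max()
                keep[active[drop_local]] = False
            if start + window >= len(idx):
                break
            start += step
    return pd.Index(snps.loc[keep, "snp"])


def harmonize_alleles(snps: pd.DataFrame, reference: pd.DataFrame):
    """Align a cohort's allele labels with a reference cohort.

    Returns (flip, drop) boolean arrays over the cohort SNPs: ``flip`` marks
    SNPs whose allele1/allele2 labels are swapped relative to the reference
    (their calls must be recoded as 2 - calls), ``drop`` marks strand-ambiguous
    A/T / C/G SNPs, which cannot be harmonized safely and are discarded.
    A SNP whose alleles match neither directly nor swapped raises an error.
    """
    ref = reference.set_index("snp")
    flip = np.zeros(len(snps), dtype=bool)
    drop = np.zeros(len(snps), dtype=bool)
    for i, row in enumerate(snps.itertuples(index=False)):
        a1, a2 = row.allele1.upper(), row.allele2.upper()
        if _COMPLEMENT.get(a1) == a2:
            drop[i] = True  # ambiguous A/T or C/G
            continue
        if row.snp not in ref.index:
            drop[i] = True
            continue
        r = ref.loc[row.snp]
        r1, r2 = r["allele1"].upper(), r["allele2"].upper()
        if (a1, a2) == (r1, r2):
            continue
        if (a1, a2) == (r2, r1):
            flip[i] = True
        else:
            raise ValueError(f"allele mismatch for SNP {row.snp}: ({a1},{a2}) vs ({r1},{r2})")
    return flip, drop


def dominant_code(calls: np.ndarray, minor_is_allele1: np.ndarray):
    """Recode additive calls to a dominant contrast.

    Homozygous major -> 0; carriers of at least one minor allele -> 1; missing
    stays NaN.  ``minor_is_allele1`` says, per SNP, whether the counted allele
    (allele1) is the minor allele in the designated reference cohort.
    Returns (coded matrix, monomorphic flags) where a flagged SNP is constant
    after coding (over non-missing calls).
    """
    calls = np.asarray(calls, dtype=float)
    minor_is_allele1 = np.asarray(minor_is_allele1, dtype=bool)
    minor_count = np.where(minor_is_allele1[None, :], calls, 2.0 - calls)
    coded = np.where(np.isnan(calls), np.nan, (minor_count >= 1).astype(float))
    with np.errstate(invalid="ignore"):
        mono = np.array([
            len(np.unique(col[~np.isnan(col)])) <= 1 for col in coded.T
    ])
    return coded, mono
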