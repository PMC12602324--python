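"""Inverse-variance-weighted fixed-effects meta-analysis across sub-cohorts.

Per-cohort estimates b_i with standard errors s_i are combined with weights
w_i = 1/s_i^2:

    B  = sum(w_i b_i) / sum(w_i)        SE = (sum w_i)^(-1/2)
    z  = B / SE                         p  = 2 * Phi(-|z|)    (normal, METAL-style)
    Q  = sum w_i (b_i - B)^2            I^2 = max(0, (Q - (k-1)) / Q) * 100

Direction strings carry one character per configured cohort (+ / - / ?) and
Bonferroni thresholds are alpha divided by the number of tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

# Suggestive thresholds used for the model-comparison enrichment step.
SUGGESTIVE_P_G = 5e-8
SUGGESTIVE_P_GXE = 5e-8
SUGGESTIVE_P_E = 1e-5

I2_CONSIDERABLE = 75.0


def ivw_fixed(betas, ses):
    """Combine estimates by inverse-variance weighting; returns (B, SE, z, p)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 1:
        raise ValueError("need at least one estimate")
    if (ses <= 0).any() or np.isnan(ses).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    B = float((w * betas).sum() / w.sum())
    SE = float(w.sum() ** -0.5)
    z = B / SE
    p = 2 * stats.norm.sf(abs(z))
    return B, SE, float(z), float(p)


def heterogeneity(betas, ses):
    """Cochran's Q and I^2 (percent, clipped to [0, 100]); k<2 -> (nan, nan)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = betas.size
    if k < 2:
        return np.nan, np.nan
    w = 1.0 / ses ** 2
    B = (w * betas).sum() / w.sum()
    Q = float((w * (betas - B) ** 2).sum())
    i2 = 0.0 if Q == 0 else max(0.0, (Q - (k - 1)) / Q) * 100.0
    return Q, float(i2)


def direction_string(betas_in_order) -> str:
    """'+'/'-' per cohort in configured order; '?' for absent or zero estimates."""
    chars = []
    for b in betas_in_order:
        if b is None or (isinstance(b, float) and (np.isnan(b) or b == 0)):
            chars.append("?")
        elif b > 0:
            chars.append("+")
        else:
            chars.append("-")
    return "".join(chars)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def weighted_average(values, weights) -> float:
    """Weighted mean, e.g. the sample-size weighted adjusted R^2 across cohorts."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if weights.sum() == 0:
        raise ValueError("weights must not all be zero")
    return float((values * weights).sum() / weights.sum())


def meta_analyze(
    cohort_tables: dict[str, pd.DataFrame],
    cohort_order: list[str] | None = None,
    require_all: bool = False,
) -> pd.DataFrame:
    """Meta-analyze per-cohort association tables keyed on (snp, cpg).

    Tables carry the scan-record columns (beta, se, n, delta_adj_r2, flag);
    flagged or NaN records contribute '?' to the direction string and are not
    combined.  By default a record is combined over however many cohorts
    report it (METAL behavior); ``require_all`` restricts output to records
    present in every configured cohort.
    """
    order = cohort_order or list(cohort_tables)
    frames = []
    for name in order:
        t = cohort_tables[name].copy()
        t["cohort"] = name
        frames.append(t)
    allt = pd.concat(frames, ignore_index=True)
    allt["snp"] = allt["snp"].fillna("")
    usable = allt["beta"].notna() & allt["se"].notna() & (allt["se"] > 0)
    allt.loc[~usable, ["beta", "se", "n", "delta_adj_r2"]] = np.nan

    def pivot(col):
        return allt.pivot_table(index=["snp", "cpg"], columns="cohort", values=col,
                                aggfunc="first").reindex(columns=order)

    B = pivot("beta")
    S = pivot("se")
    N = pivot("n")
    R2 = pivot("delta_adj_r2")
    b = B.to_numpy()
    w = 1.0 / S.to_numpy() ** 2
    k = np.isfinite(w).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sw = np.nansum(w, axis=1)
        Bc = np.nansum(w * b, axis=1) / sw
        SEc = sw ** -0.5
        z = Bc / SEc
        p = 2 * stats.norm.sf(np.abs(z))
        Q = np.nansum(w * (b - Bc[:, None]) ** 2, axis=1)
        i2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / np.where(Q > 0, Q, 1)) * 100.0, 0.0)
    i2 = np.where(k < 2, np.nan, i2)
    Q = np.where(k < 2, np.nan, Q)
    signs = np.where(np.isnan(b) | (b == 0), "?", np.where(b > 0, "+", "-"))
    direction = ["".join(row) for row in signs]
    ntot = np.nansum(N.to_numpy(), axis=1).astype(int)
    nmat = N.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r2w = np.nansum(R2.to_numpy() * nmat, axis=1) / np.nansum(
            np.where(np.isfinite(R2.to_numpy()), nmat, np.nan), axis=1)
    snp_idx = B.index.get_level_values("snp")
    out = pd.DataFrame({
        "snp": np.where(snp_idx == "", None, snp_idx),
        "cpg": B.index.get_level_values("cpg"),
        "beta": Bc, "se": SEc, "z": z, "p": p, "q_het": Q, "i2": i2,
        "direction": direction, "k_cohorts": k, "n_total": ntot,
        "adj_r2_weighted": r2w,
    })
    out = out[k > 0]
    if require_all:
        out = out[out["k_cohorts"] == len(order)]
    return out.reset_index(drop=True)
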