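"""Fast OLS association scans over all (SNP, CpG) pairs.

Three models are fit per cohort, with DNA methylation beta values as the
outcome and a shared nuisance design C (sex, 5 genetic PCs, 7 cell
proportions, batch indicators):

* Emodel:   M_k ~ 1 + E + C              (E = standardized winsorized stress)
* Gmodel:   M_k ~ 1 + G_j + C            (G_j = dominant-coded genotype)
* GxEmodel: M_k ~ 1 + G_j + E + G_j*E + C  (interaction term is tested)

Speed comes from the Frisch-Waugh-Lovell theorem: outcomes and tested
regressors are projected off the nuisance columns once, after which every
pair reduces to a one- or two-regressor fit expressible as matrix products.
Missing genotypes are handled exactly by per-SNP complete-case analysis:
SNPs are grouped by missingness pattern and the projection is recomputed per
pattern.  ``naive_ols_oracle`` provides the slow textbook reference fit used
to verify the scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

RECORD_COLUMNS = ["model", "snp", "cpg", "beta", "se", "t", "p", "n", "delta_adj_r2", "flag"]


def drop_collinear(C: np.ndarray, names=None, tol: float = 1e-8):
    """Remove linearly dependent columns by pivoted-QR rank detection.

    Returns (reduced matrix, kept indices, dropped names).  Tolerance is
    relative to the leading R diagonal.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] == 0:
        return C, np.arange(C.shape[1] if C.ndim == 2 else 0), []
    _, R, piv = linalg.qr(C, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    dropped = [names[i] if names is not None else i for i in sorted(set(range(C.shape[1])) - set(keep))]
    return C[:, keep], keep, dropped


def residualize(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Project the columns of Y off the column space of Z.

    Z must be full column rank (clean it with :func:`drop_collinear` first);
    a rank-deficient Z raises with the dependent column indices.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    _, keep, dropped = drop_collinear(Z)
    if dropped:
        raise ValueError(f"nuisance design is rank deficient; dependent columns {dropped}")
    Q, _ = np.linalg.qr(Z)
    return Y - Q @ (Q.T @ Y)


@dataclass
class ScanDesign:
    """Aligned inputs for one cohort's scans.

    M: (n, K) winsorized betas; C: (n, p) covariates WITHOUT intercept
    (collinear columns are dropped at validation); E: (n,) standardized
    winsorized stress or None; G: (n, J) dominant-coded calls with NaN for
    missing, or None.
    """

    M: np.ndarray
    cpg_ids: list
    C: np.ndarray
    E: np.ndarray | None = None
    G: np.ndarray | None = None
    snp_ids: list | None = None
    covariate_names: list | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        n = self.M.shape[0]
        self.C = np.asarray(self.C, dtype=float).reshape(n, -1)
        if np.isnan(self.M).any() or np.isnan(self.C).any():
            raise ValueError("M and C must be complete; drop incomplete subjects first")
        # clean C jointly with the intercept (cell proportions summing to 1,
        # exhaustive batch dummies etc. are only collinear once 1 is included)
        names = ["__intercept__"] + list(self.covariate_names or range(self.C.shape[1]))
        full = np.column_stack([np.ones(n), self.C])
        _, keep, dropped = drop_collinear(full, names)
        if 0 not in keep:
            raise ValueError("intercept dropped during collinearity cleanup")
        self.C = self.C[:, [i - 1 for i in keep if i > 0]]
        self.dropped_covariates = dropped
        if self.E is not None:
            self.E = np.asarray(self.E, dtype=float).reshape(n)
            if np.isnan(self.E).any():
                raise ValueError("E must be complete")
            if np.std(self.E) == 0:
                raise ValueError("exposure E has zero variance")
        if self.G is not None:
            self.G = np.asarray(self.G, dtype=float).reshape(n, -1)
        if len(self.cpg_ids) != self.M.shape[1]:
            raise ValueError("cpg_ids do not match M")
        if self.G is not None and (self.snp_ids is None or len(self.snp_ids) != self.G.shape[1]):
            raise ValueError("snp_ids do not match G")

    @property
    def n(self) -> int:
        return self.M.shape[0]


def _records(model, snp, cpgs, beta, se, t, p, n, dadj, flag=""):
    K = len(cpgs)
    return pd.DataFrame({
        "model": model, "snp": snp, "cpg": cpgs,
        "beta": beta, "se": se, "t": t, "p": p,
        "n": n, "delta_adj_r2": dadj, "flag": flag,
    }, columns=RECORD_COLUMNS)


def _flagged(model, snp, cpgs, n, flag):
    nan = np.full(len(cpgs), np.nan)
    return _records(model, snp, cpgs, nan, nan, nan, nan, n, nan, flag)


def _adj(rss, tss, n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - (rss / (n - p)) / (tss / (n - 1))


def emodel_scan(design: ScanDesign) -> pd.DataFrame:
    """Stress-on-methylation scan: one record per CpG for M_k ~ 1 + E + C."""
    if design.E is None:
        raise ValueError("Emodel requires E")
    n = design.n
    Z = np.column_stack([np.ones(n), design.C])
    RM = residualize(design.M, Z)
    rE = residualize(design.E[:, None], Z)[:, 0]
    ee = rE @ rE
    tss = ((design.M - design.M.mean(axis=0)) ** 2).sum(axis=0)
    zero_var = tss == 0
    xy = RM.T @ rE
    b = xy / ee
    yy = (RM ** 2).sum(axis=0)
    rss_full = yy - b * xy
    p_full = Z.shape[1] + 1
    df = n - p_full
    se = np.sqrt(np.maximum(rss_full, 0) / df / ee)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = b / se
    pval = 2 * stats.t.sf(np.abs(tval), df)
    with np.errstate(divide="ignore", invalid="ignore"):
        dadj = _adj(rss_full, tss, n, p_full) - _adj(yy, tss, n, p_full - 1)
    out = _records("E", None, design.cpg_ids, b, se, tval, pval, n, dadj)
    if zero_var.any():
        out.loc[zero_var, ["beta", "se", "t", "p", "delta_adj_r2"]] = np.nan
        out.loc[zero_var, "flag"] = "zero_variance_cpg"
    return out


def _pattern_groups(G: np.ndarray):
    """Group SNP column indices by their missingness pattern."""
    miss = np.isnan(G)
    groups: dict[bytes, list[int]] = {}
    for j in range(G.shape[1]):
        groups.setdefault(miss[:, j].tobytes(), []).append(j)
    for key, cols in groups.items():
        yield ~np.frombuffer(key, dtype=bool), np.array(cols)


def _pair_scan(design: ScanDesign, model: str, chunk_size: int | None) -> pd.DataFrame:
    if design.G is None:
        raise ValueError(f"{model}model requires G")
    interaction = model == "GxE"
    if interaction and design.E is None:
        raise ValueError("GxEmodel requires E")
    J = design.G.shape[1]
    chunk = J if not chunk_size else int(chunk_size)
    parts = []
    for lo in range(0, J, max(chunk, 1)):
        cols = np.arange(lo, min(lo + chunk, J))
        for rows, sub in _pattern_groups(design.G[:, cols]):
            parts.append(_pair_scan_pattern(design, model, rows, cols[sub]))
    if not parts:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    # restore SNP-major order regardless of chunk/pattern grouping
    snp_order = {s: i for i, s in enumerate(design.snp_ids)}
    cpg_order = {c: i for i, c in enumerate(design.cpg_ids)}
    out = out.sort_values(["snp", "cpg"], key=lambda s: s.map(snp_order if s.name == "snp" else cpg_order))
    return out.reset_index(drop=True)


def _pair_scan_pattern(design: ScanDesign, model: str, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
    """Exact scan for the SNP columns sharing one missingness pattern."""
    interaction = model == "GxE"
    M = design.M[rows]
    C = design.C[rows]
    G = design.G[np.ix_(np.flatnonzero(rows), cols)]
    n = M.shape[0]
    nuis = [np.ones(n), C]
    if interaction:
        nuis.append(design.E[rows, None])
    Z = np.column_stack(nuis)
    p_full = Z.shape[1] + (2 if interaction else 1)
    if n < p_full + 2:
        return pd.concat([
            _flagged(model, design.snp_ids[j], design.cpg_ids, n, "insufficient_n") for j in cols
        ], ignore_index=True)
    Q, _ = np.linalg.qr(Z)
    RM = M - Q @ (Q.T @ M)
    RG = G - Q @ (Q.T @ G)
    tss = ((M - M.mean(axis=0)) ** 2).sum(axis=0)
    zero_var = tss == 0
    yy = (RM ** 2).sum(axis=0)
    df = n - p_full

    gg = (RG ** 2).sum(axis=0)
    mono = gg <= 1e-12 * n  # constant genotype after complete-case restriction
    GtM = RG.T @ RM

    parts = []
    if not interaction:
        with np.errstate(divide="ignore", invalid="ignore"):
            b = GtM / gg[:, None]
            rss = yy[None, :] - b * GtM
            se = np.sqrt(np.maximum(rss, 0) / df / gg[:, None])
            tval = b / se
        pval = 2 * stats.t.sf(np.abs(tval), df)
        dadj = _adj(rss, tss[None, :], n, p_full) - _adj(yy[None, :], tss[None, :], n, p_full - 1)
        for jj, j in enumerate(cols):
            sid = design.snp_ids[j]
            if mono[jj]:
                parts.append(_flagged(model, sid, design.cpg_ids, n, "monomorphic_after_coding"))
                continue
            rec = _records(model, sid, design.cpg_ids, b[jj], se[jj], tval[jj], pval[jj], n, dadj[jj])
            if zero_var.any():
                rec.loc[zero_var, ["beta", "se", "t", "p", "delta_adj_r2"]] = np.nan
                rec.loc[zero_var, "flag"] = "zero_variance_cpg"
            parts.append(rec)
        return pd.concat(parts, ignore_index=True)

    I = G * design.E[rows, None]
    RI = I - Q @ (Q.T @ I)
    ii = (RI ** 2).sum(axis=0)
    gi = (RG * RI).sum(axis=0)
    ItM = RI.T @ RM
    det = gg * ii - gi * gi
    collinear = det <= 1e-12 * np.maximum(gg * ii, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        b_g = (ii[:, None] * GtM - gi[:, None] * ItM) / det[:, None]
        b_i = (gg[:, None] * ItM - gi[:, None] * GtM) / det[:, None]
        rss_full = yy[None, :] - b_g * GtM - b_i * ItM
        se = np.sqrt(np.maximum(rss_full, 0) / df * (gg / det)[:, None])
        tval = b_i / se
        rss_red = yy[None, :] - GtM ** 2 / gg[:, None]
    pval = 2 * stats.t.sf(np.abs(tval), df)
    dadj = _adj(rss_full, tss[None, :], n, p_full) - _adj(rss_red, tss[None, :], n, p_full - 1)
    for jj, j in enumerate(cols):
        sid = design.snp_ids[j]
        if mono[jj]:
            parts.append(_flagged(model, sid, design.cpg_ids, n, "monomorphic_after_coding"))
            continue
        if collinear[jj]:
            parts.append(_flagged(model, sid, design.cpg_ids, n, "collinear_interaction"))
            continue
        rec = _records(model, sid, design.cpg_ids, b_i[jj], se[jj], tval[jj], pval[jj], n, dadj[jj])
        if zero_var.any():
            rec.loc[zero_var, ["beta", "se", "t", "p", "delta_adj_r2"]] = np.nan
            rec.loc[zero_var, "flag"] = "zero_variance_cpg"
        parts.append(rec)
    return pd.concat(parts, ignore_index=True)


def gmodel_scan(design: ScanDesign, chunk_size: int | None = None) -> pd.DataFrame:
    """Genotype-on-methylation scan: one record per (SNP, CpG) pair."""
    return _pair_scan(design, "G", chunk_size)


def gxe_scan(design: ScanDesign, chunk_size: int | None = None) -> pd.DataFrame:
    """Genotype-by-stress interaction scan; the interaction term is reported."""
    return _pair_scan(design, "GxE", chunk_size)


@dataclass
class OracleFit:
    beta: float
    se: float
    t: float
    p: float
    adj_r2_full: float
    adj_r2_reduced: float

    @property
    def delta_adj_r2(self) -> float:
        return self.adj_r2_full - self.adj_r2_reduced


def naive_ols_oracle(y: np.ndarray, X: np.ndarray, term_index: int) -> OracleFit:
    """Textbook per-pair OLS fit used as the scans' independent reference.

    X must include an intercept column and be full rank.  The reduced model
    for the adjusted-R^2 increment drops column ``term_index``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design is rank deficient")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = resid @ resid
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * XtX_inv[term_index, term_index])
    tval = beta[term_index] / se
    pval = 2 * stats.t.sf(abs(tval), n - p)
    tss = ((y - y.mean()) ** 2).sum()

    Xr = np.delete(X, term_index, axis=1)
    br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    rr = y - Xr @ br
    rss_r = rr @ rr

    def adj(r, k):
        return 1.0 - (r / (n - k)) / (tss / (n - 1))

    return OracleFit(float(beta[term_index]), float(se), float(tval), float(pval),
                     float(adj(rss, p)), float(adj(rss_r, p - 1)))
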