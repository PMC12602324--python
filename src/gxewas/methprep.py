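"""Methylation probe filtering and beta-value winsorization.

Probes are reduced to a variable, clean, cross-platform set before scanning:
a variability rule (top-K by MAD, or a MAD floor), removal of cross-reactive
probes, and restriction to probes shared across array types.  Beta values of
each retained CpG are then winsorized at Q1 - 3*IQR / Q3 + 3*IQR.
"""

from __future__ import annotations

import numpy as np

from .datatypes import MethylationMatrix
from .stress import winsorize_iqr


def mad_score(betas: np.ndarray) -> np.ndarray:
    """Median absolute deviation from the probe median, per probe (column).

    Missing values are ignored; an all-missing probe raises.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if betas.shape[0] < 2:
        raise ValueError("MAD needs at least 2 values per probe")
    if np.isnan(betas).all(axis=0).any():
        raise ValueError("all-missing probe")
    med = np.nanmedian(betas, axis=0)
    return np.nanmedian(np.abs(betas - med), axis=0)


def mad_summary(mads: np.ndarray, sample_sizes=None) -> dict:
    """Median MAD with IQR and range, optionally sample-size weighted over
    cohorts (``mads`` then being a list of per-cohort vectors)."""
    if sample_sizes is not None:
        pooled = np.concatenate([np.asarray(m, dtype=float) for m in mads])
        weights = np.concatenate(
            [np.full(len(m), n, dtype=float) for m, n in zip(mads, sample_sizes)]
        )
        order = np.argsort(pooled)
        pooled, weights = pooled[order], weights[order]
        cum = np.cumsum(weights) / weights.sum()
        q = np.interp([0.25, 0.5, 0.75], cum, pooled)
        return {
            "median": float(q[1]),
            "iqr": (float(q[0]), float(q[2])),
            "range": (float(pooled.min()), float(pooled.max())),
        }
    mads = np.asarray(mads, dtype=float)
    q1, med, q3 = np.quantile(mads, [0.25, 0.5, 0.75])
    return {"median": float(med), "iqr": (float(q1), float(q3)),
            "range": (float(mads.min()), float(mads.max()))}


def probe_filter(
    matrix: MethylationMatrix,
    cross_reactive: set | None = None,
    variability_rule: dict | None = None,
    shared_probes: set | None = None,
):
    """Sequential probe filtering with per-step counts.

    Order: variability rule -> cross-reactive removal -> shared-probe
    restriction.  ``variability_rule`` is ``{"kind": "top_k", "k": int}``
    (keep the K most variable by MAD; ties by probe order) or
    ``{"kind": "mad_min", "threshold": float}``.  Returns
    (filtered MethylationMatrix with a ``mad`` column, counts dict) where
    counts satisfy input = retained + sum of per-step drops.
    """
    counts = {"input": matrix.n_probes}
    probes = matrix.probes.copy()
    probes["mad"] = mad_score(matrix.betas)
    keep = np.ones(matrix.n_probes, dtype=bool)

    if variability_rule is not None:
        if variability_rule["kind"] == "top_k":
            k = int(variability_rule["k"])
            order = np.argsort(-probes["mad"].to_numpy(), kind="stable")
            sel = np.zeros(matrix.n_probes, dtype=bool)
            sel[order[:k]] = True
        elif variability_rule["kind"] == "mad_min":
            sel = probes["mad"].to_numpy() >= variability_rule["threshold"]
        else:
            raise ValueError(f"unknown variability rule {variability_rule['kind']!r}")
        counts["low_variability"] = int((keep & ~sel).sum())
        keep &= sel
    else:
        counts["low_variability"] = 0

    if cross_reactive:
        xr = probes["cpg"].isin(cross_reactive).to_numpy()
        counts["cross_reactive"] = int((keep & xr).sum())
        keep &= ~xr
    else:
        counts["cross_reactive"] = 0

    if shared_probes is not None:
        sh = probes["cpg"].isin(shared_probes).to_numpy()
        counts["not_shared"] = int((keep & ~sh).sum())
        keep &= sh
    else:
        counts["not_shared"] = 0

    counts["retained"] = int(keep.sum())
    out = MethylationMatrix(matrix.subjects, probes.loc[keep].reset_index(drop=True),
                            matrix.betas[:, keep])
    return out, counts


def winsorize_betas(matrix: MethylationMatrix, multiplier: float = 3.0) -> MethylationMatrix:
    """Winsorize each probe's betas at Q1 - m*IQR / Q3 + m*IQR independently."""
    if matrix.n_subjects < 4:
        raise ValueError("beta winsorization needs at least 4 subjects")
    betas = np.column_stack(
        [winsorize_iqr(matrix.betas[:, j], multiplier) for j in range(matrix.n_probes)]
    ) if matrix.n_probes else matrix.betas.copy()
    return MethylationMatrix(matrix.subjects, matrix.probes.copy(), betas)
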