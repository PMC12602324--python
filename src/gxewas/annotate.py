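"""Genomic annotation of scan results and enrichment statistics.

Covers cis/trans classification of SNP-CpG pairs (cis = same chromosome and
within 1 Mb), nearest-gene lookup against a BED annotation, Fisher 2x2
model-overlap tests, and flat gene-set over-representation with a
resampling-based family-wise error rate.

A reporting quirk is kept on purpose: the SNP-CpG distance is the absolute
base-pair difference of the raw positions even for inter-chromosomal pairs,
matching how such distances are conventionally printed; the cis flag itself
additionally requires the same chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CIS_WINDOW = 1_000_000


def classify_cis_trans(snp_chrom, snp_pos, cpg_chrom, cpg_pos, window: int = CIS_WINDOW):
    """Distance and cis/trans call for one pair of 1-based loci.

    Returns (distance, "cis"|"trans"); symmetric in its two loci.
    """
    distance = abs(int(cpg_pos) - int(snp_pos))
    cis = str(snp_chrom) == str(cpg_chrom) and distance <= window
    return distance, "cis" if cis else "trans"


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED file of genes (0-based half-open) to 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"])
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int)
    return bed


def nearest_gene(chrom, pos, genes: pd.DataFrame):
    """Nearest gene to a 1-based locus: (name, distance), 0 if inside.

    ``genes`` has 1-based inclusive chrom/start/end/name, sorted by start
    within chromosome; ties are broken by the lower start coordinate.
    """
    sub = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return None, np.nan
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
    best = np.lexsort((start, dist))[0]
    return sub.iloc[best]["name"], int(dist[best])


def annotate_pairs(meta: pd.DataFrame, snp_meta: pd.DataFrame, probe_meta: pd.DataFrame,
                   genes: pd.DataFrame | None = None, window: int = CIS_WINDOW) -> pd.DataFrame:
    """Attach distance, cis flag and (optionally) nearest genes to meta records."""
    out = meta.merge(snp_meta[["snp", "chrom", "pos"]], on="snp", how="left") \
              .rename(columns={"chrom": "snp_chrom", "pos": "snp_pos"})
    out = out.merge(probe_meta[["cpg", "chrom", "pos"]], on="cpg", how="left") \
             .rename(columns={"chrom": "cpg_chrom", "pos": "cpg_pos"})
    res = [classify_cis_trans(a, b, c, d, window)
           for a, b, c, d in zip(out["snp_chrom"], out["snp_pos"], out["cpg_chrom"], out["cpg_pos"])]
    out["distance_bp"] = [r[0] for r in res]
    out["cis_trans"] = [r[1] for r in res]
    if genes is not None:
        out["snp_gene"] = [nearest_gene(c, p, genes)[0] for c, p in zip(out["snp_chrom"], out["snp_pos"])]
        out["cpg_gene"] = [nearest_gene(c, p, genes)[0] for c, p in zip(out["cpg_chrom"], out["cpg_pos"])]
    return out


def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    p sums hypergeometric tables no more probable than the observed one; the
    odds ratio is the sample cross-product ratio with a Haldane +0.5 on every
    cell when any cell is zero, and the 95% CI is Woolf's log-OR interval on
    the same (corrected) cells.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any() or not np.allclose(cells, np.round(cells)):
        raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("empty margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    orr = (a2 * d2) / (b2 * c2)
    se_log = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci = (orr * np.exp(-1.96 * se_log), orr * np.exp(1.96 * se_log))
    return {"table": (a, b, c, d), "odds_ratio": float(orr),
            "ci95": (float(ci[0]), float(ci[1])), "p": float(p)}


def suggestive_overlap_tables(results_a: pd.DataFrame, results_b: pd.DataFrame,
                              entity: str, threshold_a: float, threshold_b: float) -> dict:
    """Cross-classify unique entities (snp or cpg) by suggestive status in two
    models and run the Fisher test.

    An entity is suggestive in a model if ANY of its associations there has
    p below that model's threshold.  The entity universes must coincide.
    """
    ua = set(results_a[entity].dropna())
    ub = set(results_b[entity].dropna())
    if ua != ub:
        raise ValueError(f"{entity} universes differ between models")
    sug_a = set(results_a.loc[results_a["p"] < threshold_a, entity].dropna())
    sug_b = set(results_b.loc[results_b["p"] < threshold_b, entity].dropna())
    a = len(sug_a & sug_b)
    b = len(sug_a - sug_b)
    c = len(sug_b - sug_a)
    d = len(ua - sug_a - sug_b)
    res = fisher_2x2(a, b, c, d)
    res["entity"] = entity
    return res


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file (name <tab> description <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def geneset_enrichment(candidates, background, sets: dict[str, set],
                       n_random: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Hypergeometric over-representation with resampling FWER.

    For each set, p is the hypergeometric upper tail of the candidate/set
    overlap given candidate and universe sizes (universe = background union
    candidates).  The FWER-adjusted p of a set is the fraction of ``n_random``
    seeded random candidate sets (same size, drawn from the universe) whose
    minimum raw p across sets is <= the observed set's raw p, floored at the
    raw p so that adjusted >= raw always holds.
    """
    candidates = set(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    universe = sorted(set(background) | candidates)
    universe_set = set(universe)
    N = len(universe)
    n_cand = len(candidates)
    set_in_universe = {name: set(genes) & universe_set for name, genes in sets.items()}

    def raw_pvals(cand: set) -> np.ndarray:
        ps = np.empty(len(sets))
        for i, genes in enumerate(set_in_universe.values()):
            ps[i] = stats.hypergeom.sf(len(cand & genes) - 1, N, len(genes), n_cand)
        return ps

    observed = raw_pvals(candidates)
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe, dtype=object)
    min_ps = np.empty(n_random)
    for r in range(n_random):
        rand = set(rng.choice(universe_arr, size=n_cand, replace=False))
        min_ps[r] = raw_pvals(rand).min()
    fwer = np.array([(min_ps <= p).mean() for p in observed])
    fwer = np.maximum(fwer, observed)
    return pd.DataFrame({
        "set": list(sets),
        "set_size": [len(s) for s in sets.values()],
        "overlap": [len(candidates & s) for s in sets.values()],
        "n_candidates": n_cand,
        "n_universe": N,
        "p": observed,
        "p_fwer": fwer,
    })
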