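"""Cumulative prenatal stress scoring.

Raw questionnaire items are dichotomized into risk indicators (0 = no risk,
1 = risk), assigned to one of four domains (life events, contextual risk,
personal stress, interpersonal stress), and aggregated:

* subjects missing more than half of all items are excluded,
* remaining gaps are single-imputed by predictive-mean-matching chained
  equations,
* each domain score is the mean of its binary items (in [0, 1]),
* the total score is the sum of the four domain scores (in [0, 4]),
* totals are z-standardized within cohort and winsorized at
  Q1 - 3*IQR / Q3 + 3*IQR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DOMAINS = ("life_events", "contextual", "personal", "interpersonal")

_OPS = {
    ">=": np.greater_equal,
    ">": np.greater,
    "<=": np.less_equal,
    "<": np.less,
    "==": np.equal,
}


@dataclass(frozen=True)
class ItemRule:
    """Dichotomization rule for one raw item.

    ``op`` is one of >=, >, <=, <, == (value compared to ``threshold`` maps to
    risk = 1); ``op='identity'`` passes an already-binary item through.
    """

    domain: str
    op: str = "identity"
    threshold: float | None = None

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        if self.op != "identity" and self.op not in _OPS:
            raise ValueError(f"unknown dichotomization op {self.op!r}")


def dichotomize(raw: pd.DataFrame, rules: dict[str, ItemRule]) -> pd.DataFrame:
    """Map raw items to {0, 1, NaN} risk indicators.

    Every column of ``raw`` must have a rule; missing values propagate.
    """
    missing_rules = [c for c in raw.columns if c not in rules]
    if missing_rules:
        raise ValueError(f"items without a dichotomization rule: {missing_rules}")
    out = {}
    for col in raw.columns:
        rule = rules[col]
        vals = raw[col].astype(float)
        if rule.op == "identity":
            bad = vals.dropna()[~vals.dropna().isin([0.0, 1.0])]
            if len(bad):
                raise ValueError(f"item {col!r} marked binary but has values {set(bad)}")
            coded = vals
        else:
            coded = pd.Series(
                np.where(vals.isna(), np.nan, _OPS[rule.op](vals, rule.threshold).astype(float)),
                index=raw.index,
            )
        out[col] = coded
    return pd.DataFrame(out, index=raw.index)


def exclude_high_missingness(items: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Drop subjects with missing fraction strictly above ``threshold``.

    A subject missing exactly half the items is retained; order is preserved.
    """
    frac = items.isna().mean(axis=1)
    return items.loc[frac <= threshold]


def impute_pmm(
    items: pd.DataFrame,
    k_donors: int = 5,
    n_iter: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Single imputation by predictive-mean-matching chained equations.

    Each incomplete item is regressed (OLS) on all other items over its
    observed rows; for every missing cell the ``k_donors`` observed rows with
    the closest predicted value form the donor pool (ties broken by lowest row
    index) and one donor's observed value is copied at random.  Imputed values
    are therefore always observed values, hence binary for binary items.
    Deterministic given ``seed``; cycles run ``n_iter`` times.
    """
    rng = np.random.default_rng(seed)
    X = items.to_numpy(dtype=float).copy()
    n, p = X.shape
    miss = np.isnan(X)
    for j, col in enumerate(items.columns):
        if miss[:, j].all():
            raise ValueError(f"item {col!r} is 100% missing; cannot impute")
        if (~miss[:, j]).sum() < k_donors:
            raise ValueError(f"item {col!r} has fewer than {k_donors} observed donors")
    if not miss.any():
        return items.copy()

    # initial fill: random observed donor per missing cell
    for j in range(p):
        mj = miss[:, j]
        if mj.any():
            obs_vals = X[~mj, j]
            X[mj, j] = rng.choice(obs_vals, size=mj.sum(), replace=True)

    incomplete = [j for j in range(p) if miss[:, j].any()]
    for _ in range(n_iter):
        for j in incomplete:
            obs = ~miss[:, j]
            Z = np.delete(X, j, axis=1)
            D = np.column_stack([np.ones(n), Z])
            beta, *_ = np.linalg.lstsq(D[obs], X[obs, j], rcond=None)
            yhat = D @ beta
            yhat_obs = yhat[obs]
            obs_idx = np.flatnonzero(obs)
            y_obs = X[obs, j]
            mis_idx = np.flatnonzero(miss[:, j])
            # donor pool: k nearest predicted means, ties -> lowest row index
            d = np.abs(yhat[mis_idx][:, None] - yhat_obs[None, :])
            order = np.lexsort((obs_idx[None, :].repeat(len(mis_idx), 0), d), axis=1)
            pool = order[:, :k_donors]
            pick = rng.integers(0, k_donors, size=len(mis_idx))
            X[mis_idx, j] = y_obs[pool[np.arange(len(mis_idx)), pick]]
    return pd.DataFrame(X, index=items.index, columns=items.columns)


def domain_and_total(items: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Domain means and their sum.

    Returns a frame with one column per domain (each in [0, 1]) and ``total``
    (their sum, in [0, 4]).  ``mapping`` sends item name -> domain; every
    domain must receive at least one item.
    """
    unmapped = [c for c in items.columns if c not in mapping]
    if unmapped:
        raise ValueError(f"items without a domain: {unmapped}")
    if items.isna().any().any():
        raise ValueError("domain scoring requires complete items (impute first)")
    out = {}
    for dom in DOMAINS:
        cols = [c for c in items.columns if mapping[c] == dom]
        if not cols:
            raise ValueError(f"domain {dom!r} has no items")
        out[dom] = items[cols].mean(axis=1)
    scores = pd.DataFrame(out, index=items.index)
    scores["total"] = scores[list(DOMAINS)].sum(axis=1)
    return scores


def standardize_within_cohort(values: pd.Series, cohorts: pd.Series) -> pd.Series:
    """Z-score within each cohort (mean 0, SD 1 with the n-1 denominator)."""
    values = pd.Series(values)
    cohorts = pd.Series(cohorts, index=values.index)
    out = pd.Series(index=values.index, dtype=float)
    for cohort, idx in values.groupby(cohorts).groups.items():
        v = values.loc[idx]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cohort {cohort!r} has zero variance; cannot standardize")
        out.loc[idx] = (v - v.mean()) / sd
    return out


def winsorize_iqr(values, multiplier: float = 3.0):
    """Clip values outside [Q1 - m*IQR, Q3 + m*IQR] to those bounds.

    Quantiles use linear interpolation between order statistics.  Idempotent;
    requires at least 4 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("winsorization needs at least 4 values")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    clipped = np.clip(arr, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name)
    return clipped


def score_cohorts(
    raw: pd.DataFrame,
    rules: dict[str, ItemRule],
    cohorts: pd.Series,
    missing_threshold: float = 0.5,
    k_donors: int = 5,
    n_iter: int = 60,
    winsor_multiplier: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Full scoring pipeline: dichotomize -> exclude -> impute (per cohort)
    -> domain/total -> standardize within cohort -> winsorize.

    Returns a frame indexed by retained subjects with the four domain scores,
    ``total``, ``z`` and ``z_winsorized``.
    """
    items = dichotomize(raw, rules)
    items = exclude_high_missingness(items, missing_threshold)
    cohorts = pd.Series(cohorts).loc[items.index]
    mapping = {name: rule.domain for name, rule in rules.items()}
    parts = []
    for i, (_, idx) in enumerate(items.groupby(cohorts).groups.items()):
        sub = impute_pmm(items.loc[idx], k_donors=k_donors, n_iter=n_iter, seed=seed + i)
        parts.append(domain_and_total(sub, mapping))
    scores = pd.concat(parts).loc[items.index]
    scores["z"] = standardize_within_cohort(scores["total"], cohorts)
    scores["z_winsorized"] = pd.concat(
        [winsorize_iqr(scores.loc[idx, "z"], winsor_multiplier)
         for _, idx in scores.groupby(cohorts).groups.items()]
    ).loc[scores.index]
    return scores
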