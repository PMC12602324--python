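"""Follow-up of significant hits: stress-domain decomposition and mediation.

Domain decomposition refits a hit with all four stress domains (and, for
interaction hits, all four genotype-by-domain products) in one model, so each
domain's coefficient is its contribution net of the co-occurring domains.

Mediation uses the product-of-coefficients approach on two linear fits:
a from  mediator ~ X + C,  b and the direct effect from  Y ~ X + mediator + C.
The indirect effect is a*b with first-order delta-method standard error
sqrt(a^2 SE_b^2 + b^2 SE_a^2) and a normal two-sided p (Sobel test); an
optional percentile bootstrap replaces the delta interval.  Four mediators
(smoking, alcohol, gestational age, birth weight) are modeled separately,
hence the Bonferroni significance threshold 0.05/4 = 0.0125 on the ab path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stress import DOMAINS

MEDIATION_ALPHA = 0.0125  # 0.05 / 4 mediators


def domain_decomposition(y, domain_scores: pd.DataFrame, covariates, g=None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-domain statistics for one CpG outcome.

    Without ``g``: fit  y ~ 1 + D1..D4 + C  and report each domain's main
    effect.  With ``g`` (dominant-coded genotype): fit
    y ~ 1 + g + D1..D4 + g*D1..g*D4 + C  and report each G-by-domain
    interaction.  ``unique_contribution`` flags p < alpha.
    """
    y = np.asarray(y, dtype=float)
    D = domain_scores[list(DOMAINS)].to_numpy(dtype=float)
    corr = np.corrcoef(D, rowvar=False)
    off = corr[~np.eye(4, dtype=bool)]
    if np.any(np.abs(off) > 1 - 1e-12):
        raise ValueError("stress domains are perfectly collinear")
    C = np.asarray(covariates, dtype=float).reshape(len(y), -1)
    if g is None:
        X = np.column_stack([np.ones(len(y)), D, C])
        idx = range(1, 5)
    else:
        g = np.asarray(g, dtype=float)
        X = np.column_stack([np.ones(len(y)), g, D, g[:, None] * D, C])
        idx = range(6, 10)
    fit = sm.OLS(y, X).fit()
    rows = []
    for dom, i in zip(DOMAINS, idx):
        rows.append({
            "domain": dom,
            "term": "main" if g is None else "interaction",
            "beta": fit.params[i],
            "se": fit.bse[i],
            "p": fit.pvalues[i],
            "unique_contribution": bool(fit.pvalues[i] < alpha),
        })
    return pd.DataFrame(rows)


@dataclass
class MediationResult:
    mediator: str
    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float
    se_indirect: float
    p_indirect: float
    direct: float
    total: float
    significant: bool
    ci95: tuple | None = None


def mediate(X, mediator, Y, covariates, mediator_name: str = "mediator",
            bootstrap_reps: int | None = None, seed: int = 0,
            alpha: float = MEDIATION_ALPHA) -> MediationResult:
    """Product-of-coefficients mediation of the X -> Y effect via ``mediator``.

    Complete cases only.  With ``bootstrap_reps`` the 95% CI comes from a
    seeded percentile bootstrap of a*b (the Sobel p is still reported).
    On complete data total = direct + indirect holds exactly (OLS identity).
    """
    X = np.asarray(X, dtype=float)
    med = np.asarray(mediator, dtype=float)
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(covariates, dtype=float).reshape(len(X), -1)
    if np.std(med) == 0:
        raise ValueError("mediator is constant")

    def paths(x, m, y, c):
        Da = np.column_stack([np.ones(len(x)), x, c])
        fa = sm.OLS(m, Da).fit()
        Db = np.column_stack([np.ones(len(x)), x, m, c])
        fb = sm.OLS(y, Db).fit()
        return fa.params[1], fa.bse[1], fb.params[2], fb.bse[2], fb.params[1]

    a, se_a, b, se_b, direct = paths(X, med, Y, C)
    indirect = a * b
    se_ab = np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2)
    z = indirect / se_ab if se_ab > 0 else 0.0
    p_ab = 2 * stats.norm.sf(abs(z))
    ftot = sm.OLS(Y, np.column_stack([np.ones(len(X)), X, C])).fit()
    total = ftot.params[1]

    ci = None
    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        n = len(X)
        draws = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            idx = rng.integers(0, n, size=n)
            ar, _, br, _, _ = paths(X[idx], med[idx], Y[idx], C[idx])
            draws[r] = ar * br
        ci = (float(np.quantile(draws, 0.025)), float(np.quantile(draws, 0.975)))

    return MediationResult(
        mediator=mediator_name, a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b),
        indirect=float(indirect), se_indirect=float(se_ab), p_indirect=float(p_ab),
        direct=float(direct), total=float(total),
        significant=bool(p_ab < alpha), ci95=ci,
    )


def mediate_all(X, mediators: pd.DataFrame, Y, covariates,
                bootstrap_reps: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Run :func:`mediate` for each mediator column separately."""
    rows = []
    for i, name in enumerate(mediators.columns):
        res = mediate(X, mediators[name].to_numpy(), Y, covariates,
                      mediator_name=name, bootstrap_reps=bootstrap_reps, seed=seed + i)
        rows.append(vars(res))
    return pd.DataFrame(rows)
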