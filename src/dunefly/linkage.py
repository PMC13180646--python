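"""Courtship divergence versus genetic divergence across populations.

Joins the courtship distance matrix (Dirichlet-smoothed KL divergence
between individual transition chains) with the inter-individual genetic
distance matrix (Kosman) at the population-pair level, and summarizes their
relationship with an ordinary least-squares fit (R^2) plus a Spearman
rank alternative.  The individuals behind the two matrices need not be the
same animals — only their populations must match, because the join is on
population-pair means.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps


def _between_pop_means(D: pd.DataFrame, populations: pd.Series):
    """Mean and SE of symmetrized distances per unordered population pair."""
    sym = (D + D.T) / 2.0
    pops = sorted(populations.loc[D.index].unique())
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            ia = [x for x in D.index if populations[x] == a]
            ib = [x for x in D.index if populations[x] == b]
            vals = sym.loc[ia, ib].to_numpy().ravel()
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else np.nan,
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame(rows)


def courtship_vs_genetic(
    courtship: pd.DataFrame,
    courtship_pops: Mapping | pd.Series,
    genetic: pd.DataFrame,
    genetic_pops: Mapping | pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Population-pair records and the courtship-on-genetic OLS fit.

    Returns one record per unordered population pair (mean_kl, se_kl,
    mean_kosman, se_kosman) and a fit summary with R^2, slope, intercept,
    Spearman rho/p, and a small-sample caveat flag when fewer than 10
    population pairs contribute.
    """
    courtship_pops = pd.Series(courtship_pops)
    genetic_pops = pd.Series(genetic_pops)
    kl = _between_pop_means(courtship, courtship_pops)
    ko = _between_pop_means(genetic, genetic_pops)
    kl = kl.rename(columns={"mean": "mean_kl", "se": "se_kl", "n_pairs": "n_kl_pairs"})
    ko = ko.rename(
        columns={"mean": "mean_kosman", "se": "se_kosman", "n_pairs": "n_kosman_pairs"}
    )
    records = kl.merge(ko, on=["pop_a", "pop_b"], how="inner")
    if len(records) < 2:
        raise ValueError("need at least two shared population pairs")

    import statsmodels.api as sm

    x = records["mean_kosman"].to_numpy()
    y = records["mean_kl"].to_numpy()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if np.allclose(y, y[0]):
        r2 = 0.0  # zero variance explained by definition
    else:
        r2 = float(model.rsquared)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        rho, rho_p = np.nan, np.nan  # rank correlation undefined
    else:
        rho, rho_p = sps.spearmanr(x, y)
    fit = {
        "r_squared": r2,
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "n_pop_pairs": int(len(records)),
        "small_n_caveat": bool(len(records) < 10),
    }
    return records, fit
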