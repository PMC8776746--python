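"""Selection-signature statistics on per-gene dN/dS codon summaries.

The upstream codon model (external to this package) reports, per gene, the
number of codons, the proportion of codons with dN/dS credibly below 1
(purifying selection) and a flag for any codon credibly above 1 (positive
selection).  This module asks two questions:

1. gene level — do genes whose occurrence strongly decreases / increases
   with stress carry different selection signatures than stress-neutral
   genes?  (stratified subsample; beta regression for the purifying
   proportion, logistic regression for the positive-selection flag);
2. population level — does the mean purifying proportion across core genes
   in a soil sample change along the stress gradients?  (multiple beta
   regression on the four stresses).

Proportions on the closed unit interval are squeezed to the open interval by
(y*(n-1)+0.5)/n before beta fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from stresspan.environment import STRESS_COLUMNS

CATEGORIES = ("decrease", "none", "increase")


def stratify_genes_by_z(
    responses: pd.DataFrame,
    n_per_cat: int = 1000,
    cut_lo: float = -2.0,
    cut_hi: float = 2.0,
    neutral_band: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Stratify genes into decrease / none / increase stress-response categories.

    Pools: *decrease* = any stress z below ``cut_lo``; *increase* = any z
    above ``cut_hi`` (and not already in decrease); *none* = all |z| below
    ``neutral_band``.  Each pool is subsampled uniformly at random down to
    ``n_per_cat`` genes (all kept with a warning when smaller).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    zcols = [f"z_{s}" for s in STRESS_COLUMNS]
    ok = responses[responses["status"] == "ok"].dropna(subset=zcols)
    zmat = ok[zcols].to_numpy(dtype=float)
    zmin, zmax = zmat.min(axis=1), zmat.max(axis=1)
    pools = {
        "decrease": ok["gene_id"].to_numpy()[zmin < cut_lo],
        "increase": ok["gene_id"].to_numpy()[(zmax > cut_hi) & ~(zmin < cut_lo)],
        "none": ok["gene_id"].to_numpy()[np.abs(zmat).max(axis=1) < neutral_band],
    }
    rows = []
    for cat in CATEGORIES:
        pool = pools[cat]
        if len(pool) == 0:
            raise ValueError(f"empty stratification pool: {cat!r}")
        if len(pool) < n_per_cat:
            warnings.warn(
                f"pool {cat!r} has only {len(pool)} genes (< {n_per_cat}); taking all"
            )
            chosen = pool
        else:
            chosen = rng.choice(pool, size=n_per_cat, replace=False)
        rows.append(pd.DataFrame({"gene_id": chosen, "category": cat}))
    return pd.concat(rows, ignore_index=True)


def squeeze_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Map proportions on [0,1] to (0,1) via (y*(n-1)+0.5)/n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(
    y: np.ndarray, X: np.ndarray, term_names: list[str] | None = None
) -> dict:
    """Beta regression (logit mean link, common precision) of proportions on X.

    ``y`` in [0,1] is squeezed off the boundary before fitting; ``X`` must
    include an intercept column.  Returns coefficient table (with the log
    precision as the last row), log-likelihood, fitted means and a
    convergence flag.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    ys = squeeze_proportions(y)
    if np.allclose(y, y[0]):
        warnings.warn("constant response: beta precision diverges; fit flagged")
    model = BetaModel(ys, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=500)
    k = X.shape[1]
    if term_names is None:
        term_names = [f"x{j}" for j in range(k)]
    names = list(term_names) + ["log_precision"]
    coefs = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        },
        index=names,
    )
    return {
        "coefficients": coefs,
        "loglik": float(res.llf),
        "fitted_mean": np.asarray(res.predict()),
        "converged": bool(res.mle_retvals.get("converged", True)),
        "result": res,
    }


def _category_design(categories: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design with 'none' as the reference category."""
    cats = pd.Categorical(categories, categories=["none", "decrease", "increase"])
    if cats.isna().any():
        raise ValueError("unknown category labels")
    X = np.column_stack(
        [
            np.ones(len(cats)),
            (cats == "decrease").astype(float),
            (cats == "increase").astype(float),
        ]
    )
    return X, ["intercept", "decrease_vs_none", "increase_vs_none"]


def fit_purifying_model(summaries: pd.DataFrame, strata: pd.DataFrame) -> dict:
    """Beta regression of the purifying-codon proportion on response category."""
    tbl = summaries.merge(strata, on="gene_id", validate="one_to_one")
    X, names = _category_design(tbl["category"])
    return fit_beta_regression(tbl["prop_purifying"].to_numpy(), X, names)


def fit_positive_selection_model(
    summaries: pd.DataFrame, strata: pd.DataFrame
) -> dict:
    """Logistic regression of the any-positive-codon flag on response category.

    Returns the coefficient table plus per-category predicted proportions
    with 95% intervals.  A category with all-0 or all-1 outcomes is a
    separation; its contrast is flagged and its interval is one-sided.
    """
    tbl = summaries.merge(strata, on="gene_id", validate="one_to_one")
    y = tbl["any_positive"].to_numpy(dtype=float)
    X, names = _category_design(tbl["category"])
    separated = []
    for cat in CATEGORIES:
        sub = y[tbl["category"].to_numpy() == cat]
        if len(sub) and (sub.min() == sub.max()):
            separated.append(cat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    coefs = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues},
        index=names,
    )
    pred_rows = []
    Xc, _ = _category_design(pd.Series(list(CATEGORIES)))
    pred = res.get_prediction(Xc)
    ci = pred.conf_int()
    for i, cat in enumerate(CATEGORIES):
        pred_rows.append(
            {
                "category": cat,
                "proportion": float(pred.predicted_mean[i]),
                "lower": float(ci[i, 0]),
                "upper": float(ci[i, 1]),
            }
        )
    return {
        "coefficients": coefs,
        "predicted": pd.DataFrame(pred_rows),
        "separated_categories": separated,
        "converged": res.converged if hasattr(res, "converged") else True,
    }


def population_dnds_model(population_summaries: pd.DataFrame, stress: pd.DataFrame) -> dict:
    """Multiple beta regression of per-sample mean purifying proportion on stress.

    ``population_summaries`` has one row per soil sample with columns
    sample_id and mean_prop_purifying (mean over the core-gene subsample).
    All four stresses enter simultaneously.
    """
    tbl = population_summaries.merge(stress, on="sample_id", validate="one_to_one")
    if len(tbl) < 10:
        raise ValueError("need at least 10 soil samples for the population model")
    X = np.column_stack(
        [np.ones(len(tbl))] + [tbl[s].to_numpy(dtype=float) for s in STRESS_COLUMNS]
    )
    names = ["intercept"] + list(STRESS_COLUMNS)
    return fit_beta_regression(tbl["mean_prop_purifying"].to_numpy(), X, names)
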