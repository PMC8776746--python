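"""Trait meta-regression of z-scores, category tests and loss weighting.

Second stage of the gene-level analysis: per-gene stress-response z-scores
are regressed on gene functional traits (mean cosine similarity, betweenness,
duplication level) with stress type as a categorical factor, so the
stress x trait interaction coefficients say which traits predict loss
(negative interaction) versus retention (positive) under each stress.

Genes with a strong propensity for loss (any z below a threshold) are
embedded in a regular tetrahedron whose vertices are the four stresses, via
barycentric weights proportional to the rectified negative z-scores; genes at
a vertex are lost exclusively under one stress, genes at the centroid are
lost equally under all four.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from stresspan.environment import STRESS_COLUMNS

TRAITS = ("mean_cosine", "betweenness", "duplication")

#: vertices of a regular tetrahedron (unit vectors from the centroid)
TETRA_VERTICES = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass
class TraitRegressionResult:
    """OLS fit of z on stress type and stress x trait interactions.

    ``params``/``bse``/``pvalues`` are indexed by term: ``"<stress>"`` for the
    per-stress mean z (no global intercept) and ``"<stress>:<trait>"`` for
    interactions.  ``trait_center``/``trait_scale`` record the
    standardization applied to traits before fitting.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    cov_params: pd.DataFrame
    trait_center: pd.Series
    trait_scale: pd.Series
    trait_range: pd.DataFrame
    n_obs: int

    def main_effect(self, stress: str) -> float:
        return float(self.params[stress])

    def interaction(self, stress: str, trait: str) -> float:
        return float(self.params[f"{stress}:{trait}"])


def _build_design(z_long: pd.DataFrame, traits_std: pd.DataFrame):
    tbl = z_long.merge(traits_std, left_on="gene_id", right_index=True, how="inner")
    cols, names = [], []
    for s in STRESS_COLUMNS:
        ind = (tbl["stress"] == s).to_numpy(dtype=float)
        cols.append(ind)
        names.append(s)
    for s in STRESS_COLUMNS:
        ind = (tbl["stress"] == s).to_numpy(dtype=float)
        for t in TRAITS:
            cols.append(ind * tbl[t].to_numpy(dtype=float))
            names.append(f"{s}:{t}")
    return np.column_stack(cols), names, tbl


def fit_trait_regression(
    z_long: pd.DataFrame, traits: pd.DataFrame, standardize: bool = True
) -> TraitRegressionResult:
    """OLS of z on stress type (4 levels, no intercept) and stress x trait terms.

    ``z_long`` has columns gene_id / stress / z; ``traits`` is indexed by
    gene_id with columns mean_cosine, betweenness, duplication.  Traits are
    standardized to mean 0, SD 1 before fitting (so interaction coefficients
    are per-SD effects).  Standard errors are heteroskedasticity-robust (HC1)
    because per-gene z variances are heterogeneous.
    """
    traits = traits.loc[:, list(TRAITS)].dropna()
    center = traits.mean()
    scale = traits.std(ddof=1)
    if (scale == 0).any() or scale.isna().any():
        bad = list(scale.index[(scale == 0) | scale.isna()])
        raise ValueError(f"constant trait column(s) make the design rank deficient: {bad}")
    traits_std = (traits - center) / scale if standardize else traits
    X, names, tbl = _build_design(z_long, traits_std)
    y = tbl["z"].to_numpy(dtype=float)
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient trait design; check for collinear traits")
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    ci = fit.conf_int()
    return TraitRegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["lower", "upper"]),
        cov_params=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        trait_center=center,
        trait_scale=scale,
        trait_range=pd.DataFrame(
            {"min": traits_std.min(), "max": traits_std.max()}
        ),
        n_obs=int(fit.nobs),
    )


def predict_z(
    result: TraitRegressionResult,
    trait_grid: pd.DataFrame,
    stress: str | None = None,
) -> pd.DataFrame:
    """Predicted z (with 95% CI) over a grid of standardized trait values.

    ``trait_grid`` columns are a subset of the traits (missing traits are held
    at 0 = their mean).  Predictions are returned for each stress (or just
    ``stress``).  Grid values outside the observed standardized trait range
    trigger a warning.
    """
    stresses = [stress] if stress else list(STRESS_COLUMNS)
    for t in trait_grid.columns:
        lo, hi = result.trait_range.loc[t, "min"], result.trait_range.loc[t, "max"]
        g = trait_grid[t]
        if (g < lo).any() or (g > hi).any():
            warnings.warn(f"trait grid for {t!r} extends beyond the observed range")
    names = list(result.params.index)
    V = result.cov_params.to_numpy()
    rows = []
    for s in stresses:
        for _, grow in trait_grid.iterrows():
            x = np.zeros(len(names))
            x[names.index(s)] = 1.0
            for t in TRAITS:
                val = float(grow[t]) if t in trait_grid.columns else 0.0
                x[names.index(f"{s}:{t}")] = val
            pred = float(x @ result.params.to_numpy())
            se = float(np.sqrt(x @ V @ x))
            rows.append(
                {
                    "stress": s,
                    **{t: (float(grow[t]) if t in trait_grid.columns else 0.0) for t in TRAITS},
                    "predicted_z": pred,
                    "lower": pred - 1.96 * se,
                    "upper": pred + 1.96 * se,
                }
            )
    return pd.DataFrame(rows)


def category_effect_test(
    responses: pd.DataFrame, categories: pd.Series | dict
) -> pd.DataFrame:
    """One-way ANOVA of z by functional category, per environment.

    Tests whether gene z-scores differ by an annotation category (e.g. COG
    class).  ``categories`` maps gene_id to a label; genes without a label are
    dropped.  Requires >= 2 categories with >= 2 genes each.
    """
    cat = pd.Series(categories)
    tbl = responses[responses["status"] == "ok"].copy()
    tbl["category"] = tbl["gene_id"].map(cat)
    tbl = tbl.dropna(subset=["category"])
    sizes = tbl["category"].value_counts()
    usable = sizes[sizes >= 2].index
    if len(usable) < 2:
        raise ValueError("need >=2 categories with >=2 genes each for the ANOVA")
    tbl = tbl[tbl["category"].isin(usable)]
    rows = []
    for s in STRESS_COLUMNS:
        groups = [
            g[f"z_{s}"].dropna().to_numpy() for _, g in tbl.groupby("category", observed=True)
        ]
        F, p = stats.f_oneway(*groups)
        rows.append({"stress": s, "F": float(F), "p": float(p), "n_categories": len(groups)})
    return pd.DataFrame(rows)


def loss_weights(
    responses: pd.DataFrame, z_threshold: float = -2.0, dominance: float = 0.75
) -> pd.DataFrame:
    """Barycentric loss weights on the stress tetrahedron for strongly-lost genes.

    A gene is included when its minimum z across the four stresses is below
    ``z_threshold``.  Weights are the rectified negative z-scores normalized
    to sum 1 (scale-invariant in z); ``tetra_x/y/z`` is the barycentric
    embedding; ``dominant`` is the stress with the largest weight when that
    weight reaches ``dominance``, else ``"shared"``.
    """
    zcols = [f"z_{s}" for s in STRESS_COLUMNS]
    Z = responses.loc[responses["status"] == "ok", ["gene_id"] + zcols].dropna()
    zmat = Z[zcols].to_numpy(dtype=float)
    include = zmat.min(axis=1) < z_threshold
    Z = Z[include]
    zmat = zmat[include]
    neg = np.maximum(-zmat, 0.0)
    total = neg.sum(axis=1)
    assert np.all(total > 0), "included gene with no negative z (inclusion rule violated)"
    W = neg / total[:, None]
    xyz = W @ TETRA_VERTICES
    wmax = W.max(axis=1)
    dom_idx = W.argmax(axis=1)
    dominant = np.where(
        wmax >= dominance, np.asarray(STRESS_COLUMNS)[dom_idx], "shared"
    )
    out = pd.DataFrame({"gene_id": Z["gene_id"].to_numpy()})
    for i, s in enumerate(STRESS_COLUMNS):
        out[f"w_{s}"] = W[:, i]
    out[["tetra_x", "tetra_y", "tetra_z"]] = xyz
    out["dominant"] = dominant
    return out


def specificity_summary(weights: pd.DataFrame) -> dict:
    """Counts of exclusively-lost genes per environment + uniformity test.

    Counts genes whose dominant environment is a single stress (not
    "shared"), and chi-square-tests those counts against uniformity across
    the four stresses.
    """
    counts = {s: int((weights["dominant"] == s).sum()) for s in STRESS_COLUMNS}
    n_shared = int((weights["dominant"] == "shared").sum())
    total = sum(counts.values())
    table = pd.DataFrame(
        {
            "stress": list(STRESS_COLUMNS),
            "n_exclusive": [counts[s] for s in STRESS_COLUMNS],
            "proportion": [counts[s] / total if total else 0.0 for s in STRESS_COLUMNS],
        }
    )
    if total > 0:
        chi2, p = stats.chisquare(table["n_exclusive"].to_numpy())
    else:
        chi2, p = np.nan, np.nan
    return {
        "table": table,
        "n_shared": n_shared,
        "chi2": float(chi2),
        "p": float(p),
    }
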