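"""Hierarchical richness/diversity models and per-gene occurrence models.

Strain-level gene richness is a count and is modelled with a negative
binomial GLMM (log link) on the four standardized stress gradients, with
nested random intercepts for site and soil sample.  Soil-sample pangenome
diversity uses the same model with a site intercept only (one observation per
sample).  Per gene, presence/absence across strains is modelled with a
binomial GLMM of identical structure; the headline statistic is the per-gene,
per-stress z-score = coefficient / SE, negative when the gene is more likely
absent under high stress.

All four stresses enter each model simultaneously, so each coefficient is
adjusted for collinearity among the gradients.

Per-gene fits use a three-tier strategy: full GLMM; if that fails to
converge, a fixed-effects GLM flagged ``no_random_effects_fallback``; genes
with (quasi-)separation are flagged ``separation`` with undefined z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from stresspan.environment import STRESS_COLUMNS
from stresspan.glmm import (
    FAILED,
    FALLBACK,
    OK,
    SEPARATION,
    MixedModelFit,
    fit_glmm,
)
from stresspan.pangenome import PangenomeMatrix

TERMS = ("intercept",) + STRESS_COLUMNS


def _design_codes(design: pd.DataFrame, random: tuple[str, ...]) -> dict[str, np.ndarray]:
    groups = {}
    for factor in random:
        col = f"{factor}_id"
        if col not in design.columns:
            raise ValueError(f"design table lacks column {col!r}")
        groups[factor] = pd.factorize(design[col])[0]
    return groups


def _stress_design(unit_table: pd.DataFrame, stress: pd.DataFrame) -> np.ndarray:
    merged = unit_table.merge(stress, on="sample_id", how="left", validate="many_to_one")
    block = merged.loc[:, list(STRESS_COLUMNS)]
    if block.isna().any().any():
        missing = merged.loc[block.isna().any(axis=1), "sample_id"].unique()
        raise ValueError(f"no stress profile for samples {list(missing)[:5]}")
    X = np.column_stack([np.ones(len(merged)), block.to_numpy(dtype=float)])
    return X


def fit_count_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray] | None,
    term_names: list[str] | None = None,
) -> MixedModelFit:
    """Negative-binomial GLMM with the given design matrix and random intercepts.

    ``y`` must be non-negative integers; ``groups`` maps factor name to
    per-observation integer codes (None for a plain NB regression).  Factors
    with a single level are dropped and the fit flagged
    ``no_random_effects_fallback``.
    """
    y = np.asarray(y)
    if np.any(np.asarray(y, dtype=float) != np.round(y)) or np.any(np.asarray(y) < 0):
        raise ValueError("count response must be non-negative integers")
    return fit_glmm(y, X, groups, family="negbin", term_names=term_names)


def fit_richness_model(
    richness: pd.DataFrame, stress: pd.DataFrame, design: pd.DataFrame
) -> MixedModelFit:
    """NB GLMM of per-strain gene richness on the four stresses (site + sample RE)."""
    tbl = richness.merge(design, on="strain_id", validate="one_to_one")
    X = _stress_design(tbl, stress)
    groups = _design_codes(tbl, ("site", "sample"))
    return fit_count_glmm(tbl["richness"].to_numpy(), X, groups, term_names=list(TERMS))


def fit_diversity_model(
    diversity: pd.DataFrame, stress: pd.DataFrame, design: pd.DataFrame
) -> MixedModelFit:
    """NB GLMM of per-soil-sample pangenome diversity on the stresses (site RE only)."""
    sample_site = design.drop_duplicates("sample_id")[["sample_id", "site_id"]]
    tbl = diversity.merge(sample_site, on="sample_id", validate="one_to_one")
    X = _stress_design(tbl, stress)
    groups = _design_codes(tbl, ("site",))
    return fit_count_glmm(tbl["diversity"].to_numpy(), X, groups, term_names=list(TERMS))


def fit_gene_occurrence_models(
    matrix: PangenomeMatrix,
    stress: pd.DataFrame,
    design: pd.DataFrame,
    random_effects: bool = True,
    nm_maxfev: int = 20,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene binomial (logit) models of presence on the four stresses.

    Returns one row per gene with columns ``coef_<stress>``, ``se_<stress>``,
    ``z_<stress>`` and ``status``.  With ``random_effects=False`` all genes
    are fitted by plain logistic GLM (used for speed or as an oracle limit).
    """
    tbl = pd.DataFrame({"strain_id": matrix.strains}).merge(
        design, on="strain_id", validate="one_to_one"
    )
    if len(tbl) != len(matrix.strains):
        raise ValueError("design does not cover all strains in the matrix")
    X = _stress_design(tbl, stress)
    groups = _design_codes(tbl, ("site", "sample")) if random_effects else None
    presence = matrix.presence.astype(float)
    gene_list = list(matrix.genes) if genes is None else list(genes)
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}

    rows = []
    carry = {"sds": None}  # warm-start the variance search from the last gene
    for g in gene_list:
        y = presence[:, gene_idx[g]]
        rows.append(_fit_one_gene(g, y, X, groups, nm_maxfev, carry))
    out = pd.DataFrame(rows)
    return out


def _fit_one_gene(gene, y, X, groups, nm_maxfev, carry=None):
    row = {"gene_id": gene}
    carry = carry if carry is not None else {"sds": None}

    def fill(fit: MixedModelFit | None, status: str):
        for i, s in enumerate(STRESS_COLUMNS):
            if fit is None or status in (SEPARATION, FAILED):
                row[f"coef_{s}"] = np.nan
                row[f"se_{s}"] = np.nan
                row[f"z_{s}"] = np.nan
            else:
                row[f"coef_{s}"] = fit.coefficients.iloc[i + 1]
                row[f"se_{s}"] = fit.standard_errors.iloc[i + 1]
                row[f"z_{s}"] = fit.zvalues.iloc[i + 1]
        row["status"] = status
        return row

    if y.min() == y.max():  # gene present or absent everywhere: no information
        return fill(None, SEPARATION)
    # tier 2 first: a cheap fixed-effects GLM doubles as the separation screen
    try:
        glm = fit_glmm(y, X, None, family="binomial", term_names=list(TERMS))
    except Exception:
        return fill(None, FAILED)
    if glm.status == SEPARATION:
        return fill(None, SEPARATION)
    if groups is None:
        return fill(glm, OK if glm.converged else FAILED)
    try:
        fit = fit_glmm(
            y, X, groups, family="binomial", term_names=list(TERMS),
            nm_maxfev=nm_maxfev, start_sds=carry["sds"],
        )
    except Exception:
        fit = None
    if fit is not None and fit.status == OK and fit.converged:
        carry["sds"] = fit.random_effect_sds
        return fill(fit, OK)
    if fit is not None and fit.status == SEPARATION:
        return fill(None, SEPARATION)
    if glm.converged:
        return fill(glm, FALLBACK)
    return fill(None, FAILED)


def z_long(
    responses: pd.DataFrame,
    status: tuple[str, ...] = (OK,),
    winsorize: float | None = None,
) -> pd.DataFrame:
    """Reshape a per-gene response table to long format (gene_id, stress, z).

    ``winsorize`` optionally clips extreme z at +/- the given value before
    downstream regressions (off by default; z-scores are otherwise passed
    through untransformed).
    """
    keep = responses[responses["status"].isin(status)]
    frames = []
    for s in STRESS_COLUMNS:
        z = keep[f"z_{s}"]
        if winsorize is not None:
            z = z.clip(-abs(winsorize), abs(winsorize))
        frames.append(pd.DataFrame({"gene_id": keep["gene_id"], "stress": s, "z": z}))
    return pd.concat(frames, ignore_index=True)


def summarize_z(responses: pd.DataFrame, kde_grid: int = 512) -> dict:
    """Per-environment summary of gene z-scores.

    Returns a dict with a ``table`` (mean, SD, t statistic and p-value of the
    one-sample test against 0, per stress) and a ``density`` DataFrame with a
    smoothed kernel density estimate of the z distribution per stress.
    """
    ok = responses[responses["status"] == OK]
    if len(ok) < 2:
        raise ValueError("need at least 2 genes with status ok to summarize z-scores")
    rows, dens_frames = [], []
    for s in STRESS_COLUMNS:
        z = ok[f"z_{s}"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        t, p = stats.ttest_1samp(z, 0.0)
        rows.append(
            {
                "stress": s,
                "mean_z": z.mean(),
                "sd_z": z.std(ddof=1),
                "n": len(z),
                "t": float(t),
                "p": float(p),
            }
        )
        kde = stats.gaussian_kde(z)
        grid = np.linspace(z.min() - 1, z.max() + 1, kde_grid)
        dens_frames.append(
            pd.DataFrame({"stress": s, "z": grid, "density": kde(grid)})
        )
    return {"table": pd.DataFrame(rows), "density": pd.concat(dens_frames, ignore_index=True)}
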