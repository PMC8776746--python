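import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from stresspan.environment import STRESS_COLUMNS
from stresspan.glmm import fit_glmm
from stresspan.occurrence import (
    fit_count_glmm,
    fit_diversity_model,
    fit_gene_occurrence_models,
    fit_richness_model,
    summarize_z,
)
from stresspan.pangenome import PangenomeMatrix


def make_matrix(presence, design):
    strains = list(design["strain_id"])
    genes = [f"g{j}" for j in range(presence.shape[1])]
    return PangenomeMatrix(strains, genes, presence.astype(int))


# ---------------------------------------------------------------------------
# GLM-limit oracles
# ---------------------------------------------------------------------------

def test_binomial_glm_limit_matches_statsmodels(rng):
    n = 300
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = rng.binomial(1, expit(X @ np.array([0.2, -0.8, 0.5])))
    ours = fit_glmm(y, X, None, family="binomial")
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.coefficients.to_numpy(), oracle.params, atol=1e-6)
    np.testing.assert_allclose(ours.standard_errors.to_numpy(), oracle.bse, atol=1e-5)


def test_negbin_glm_limit_matches_statsmodels(rng):
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    mu = np.exp(X @ np.array([2.0, -0.3, 0.2]))
    y = rng.negative_binomial(5, 5 / (5 + mu))
    ours = fit_glmm(y, X, None, family="negbin")
    oracle = sm.NegativeBinomial(y, X).fit(disp=0)
    np.testing.assert_allclose(
        ours.coefficients.to_numpy(), oracle.params[:3], atol=1e-4
    )
    assert abs(ours.dispersion - oracle.params[-1]) < 0.05


def test_glmm_with_zero_grouping_variance_matches_glm(study_design, stress_design_matrix, rng):
    """With no true random effects the GLMM collapses to the GLM (z within 0.05)."""
    X, site, samp = stress_design_matrix
    y = rng.binomial(1, expit(X @ np.array([0.0, -1.0, 0.0, 0.5, 0.0])))
    glmm = fit_glmm(
        y, X, {"site": site, "sample": samp}, family="binomial",
        fixed_sds={"site": 0.0, "sample": 0.0},
    )
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    z_glmm = glmm.coefficients.to_numpy() / glmm.standard_errors.to_numpy()
    z_glm = glm.params / glm.bse
    np.testing.assert_allclose(z_glmm, z_glm, atol=0.05)


# ---------------------------------------------------------------------------
# count models
# ---------------------------------------------------------------------------

def test_count_glmm_rejects_non_integer():
    X = np.ones((10, 1))
    with pytest.raises(ValueError, match="integer"):
        fit_count_glmm(np.full(10, 1.5), X, None)


def test_richness_model_recovers_planted_slopes(study_design, stress_design_matrix, rng):
    design, stress = study_design
    X, site, samp = stress_design_matrix
    slopes = np.array([-0.05, -0.07, -0.05, -0.10])
    eta = (
        np.log(7000)
        + X[:, 1:] @ slopes
        + rng.normal(0, 0.05, 20)[site]
        + rng.normal(0, 0.05, 60)[samp]
    )
    mu = np.exp(eta)
    y = rng.negative_binomial(200, 200 / (200 + mu))
    richness = pd.DataFrame({"strain_id": design["strain_id"], "richness": y})
    fit = fit_richness_model(richness, stress, design)
    assert fit.converged
    assert all(fit.coefficients[s] < 0 for s in STRESS_COLUMNS)
    assert set(fit.random_effect_sds) == {"site", "sample"}


def test_intercept_only_mean_recovered(study_design, rng):
    """Intercept-only NB truth with mean 7000: fitted mean within 2% at n=360."""
    design, stress = study_design
    y = rng.negative_binomial(100, 100 / (100 + 7000.0)) * np.ones(len(design), dtype=int)
    y = rng.negative_binomial(100, 100 / (100 + 7000.0) * np.ones(len(design)))
    richness = pd.DataFrame({"strain_id": design["strain_id"], "richness": y})
    fit = fit_richness_model(richness, stress, design)
    assert abs(np.exp(fit.coefficients["intercept"]) - 7000) / 7000 < 0.02


def test_diversity_model_uses_site_effect_only(small_dataset):
    from stresspan.pangenome import classify_genes, filter_for_richness, pangenome_diversity

    d = small_dataset
    filtered = filter_for_richness(classify_genes(d["matrix"]))
    diversity = pangenome_diversity(filtered, d["design"])
    fit = fit_diversity_model(diversity, d["stress"], d["design"])
    assert set(fit.random_effect_sds) == {"site"}
    assert fit.n_obs == 60


def test_single_site_single_sample_falls_back():
    rng = np.random.default_rng(0)
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.binomial(1, expit(X @ np.array([0.0, 1.0])))
    fit = fit_glmm(y, X, {"site": np.zeros(n, int), "sample": np.zeros(n, int)})
    assert fit.status == "no_random_effects_fallback"
    assert not fit.random_effect_sds


# ---------------------------------------------------------------------------
# per-gene occurrence models
# ---------------------------------------------------------------------------

def test_perfect_separation_flagged(study_design):
    design, stress = study_design
    merged = design.merge(stress, on="sample_id")
    presence = (merged["heat"].to_numpy() > 0).astype(int)[:, None]
    matrix = make_matrix(presence, design)
    out = fit_gene_occurrence_models(matrix, stress, design)
    assert out.loc[0, "status"] == "separation"
    assert np.isnan(out.loc[0, "z_heat"])


def test_constant_gene_flagged():
    design = pd.DataFrame(
        {
            "strain_id": ["a", "b", "c", "d"],
            "sample_id": ["p", "p", "q", "q"],
            "site_id": ["s", "s", "s", "s"],
        }
    )
    stress = pd.DataFrame(
        {
            "sample_id": ["p", "q"],
            "acidity": [-1.0, 1.0],
            "aridity": [1.0, -1.0],
            "heat": [-1.0, 1.0],
            "salinity": [1.0, -1.0],
        }
    )
    matrix = make_matrix(np.ones((4, 1)), design)
    out = fit_gene_occurrence_models(matrix, stress, design, random_effects=False)
    assert out.loc[0, "status"] == "separation"


def test_planted_negative_salinity_slope_gives_negative_z(study_design, rng):
    design, stress = study_design
    merged = design.merge(stress, on="sample_id")
    n_genes = 40
    eta = -2.0 * merged["salinity"].to_numpy()[:, None] + rng.uniform(-0.5, 0.5, n_genes)
    presence = rng.random(eta.shape) < expit(eta)
    matrix = make_matrix(presence, design)
    out = fit_gene_occurrence_models(matrix, stress, design)
    ok = out[out["status"].isin(["ok", "no_random_effects_fallback"])]
    assert (ok["z_salinity"] < 0).mean() >= 0.95


def test_doubling_beta_increases_median_abs_z(study_design, rng):
    design, stress = study_design
    merged = design.merge(stress, on="sample_id")
    meds = []
    for beta in (-0.75, -1.5):
        eta = beta * merged["heat"].to_numpy()[:, None] * np.ones((1, 30))
        presence = rng.random(eta.shape) < expit(eta)
        out = fit_gene_occurrence_models(
            make_matrix(presence, design), stress, design, random_effects=False
        )
        meds.append(out["z_heat"].abs().median())
    assert meds[1] >= meds[0]


# ---------------------------------------------------------------------------
# z summaries
# ---------------------------------------------------------------------------

def _fake_responses(z, status="ok"):
    out = pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(z))]})
    for j, s in enumerate(STRESS_COLUMNS):
        out[f"coef_{s}"] = z[:, j]
        out[f"se_{s}"] = 1.0
        out[f"z_{s}"] = z[:, j]
    out["status"] = status
    return out


def test_summarize_z_symmetric_and_shifted(rng):
    z = rng.normal(0, 1, size=(3000, 4))
    table = summarize_z(_fake_responses(z))["table"].set_index("stress")
    assert np.all(np.abs(table["mean_z"]) < 0.1)
    zneg = rng.normal(-1, 1, size=(500, 4))
    tneg = summarize_z(_fake_responses(zneg))["table"]
    assert (tneg["mean_z"] < 0).all() and (tneg["p"] < 0.05).all()


def test_summarize_z_single_gene_errors(rng):
    with pytest.raises(ValueError, match="at least 2"):
        summarize_z(_fake_responses(np.zeros((1, 4))))
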