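import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stresspan.environment import STRESS_COLUMNS
from stresspan.trait_loss import (
    TETRA_VERTICES,
    category_effect_test,
    fit_trait_regression,
    loss_weights,
    predict_z,
    specificity_summary,
)


def make_traits(n, rng):
    return pd.DataFrame(
        {
            "mean_cosine": rng.normal(size=n),
            "betweenness": rng.normal(size=n),
            "duplication": rng.normal(size=n),
        },
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )


def simulate_z_long(traits, main, inter, noise_sd, rng):
    """z = main_e + sum_t inter[t][e] * trait_t + noise, in long format."""
    rows = []
    for e, s in enumerate(STRESS_COLUMNS):
        z = main[e] + sum(
            inter[t][e] * traits[t].to_numpy() for t in traits.columns
        ) + rng.normal(0, noise_sd, len(traits))
        rows.append(pd.DataFrame({"gene_id": traits.index, "stress": s, "z": z}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# trait regression
# ---------------------------------------------------------------------------

def test_trait_regression_recovers_planted_interactions(rng):
    traits = make_traits(4000, rng)
    inter = {
        "mean_cosine": [-0.5] * 4,
        "betweenness": [0.5] * 4,
        "duplication": [-0.3] * 4,
    }
    zl = simulate_z_long(traits, [-1.0] * 4, inter, 1.0, rng)
    res = fit_trait_regression(zl, traits)
    for s in STRESS_COLUMNS:
        assert res.interaction(s, "mean_cosine") < 0
        assert res.interaction(s, "betweenness") > 0
        assert res.interaction(s, "duplication") < 0
        assert abs(res.main_effect(s) - (-1.0)) < 0.1


def test_trait_regression_null_interactions_cover_zero(rng):
    traits = make_traits(2000, rng)
    inter = {t: [0.0] * 4 for t in traits.columns}
    zl = simulate_z_long(traits, [-1.0] * 4, inter, 1.0, rng)
    res = fit_trait_regression(zl, traits)
    covered = sum(
        res.conf_int.loc[f"{s}:{t}", "lower"] <= 0 <= res.conf_int.loc[f"{s}:{t}", "upper"]
        for s in STRESS_COLUMNS
        for t in traits.columns
    )
    assert covered >= 9  # ~95% of 12 intervals


def test_constant_trait_raises(rng):
    traits = make_traits(100, rng)
    traits["duplication"] = 1.0
    zl = simulate_z_long(traits, [0] * 4, {t: [0] * 4 for t in traits.columns}, 1, rng)
    with pytest.raises(ValueError, match="duplication"):
        fit_trait_regression(zl, traits)


def test_predictions_match_design_matrix_oracle(rng):
    traits = make_traits(800, rng)
    inter = {"mean_cosine": [-0.4] * 4, "betweenness": [0.2] * 4, "duplication": [0.0] * 4}
    zl = simulate_z_long(traits, [-0.5] * 4, inter, 0.5, rng)
    res = fit_trait_regression(zl, traits, standardize=False)
    grid = pd.DataFrame({"mean_cosine": [0.0, 0.5], "betweenness": [0.0, 0.0], "duplication": [0.0, 0.0]})
    pred = predict_z(res, grid, stress="heat")
    # at trait = 0 the prediction is the main effect
    assert np.isclose(pred.loc[0, "predicted_z"], res.main_effect("heat"))
    # slope in mean_cosine equals the interaction coefficient
    slope = (pred.loc[1, "predicted_z"] - pred.loc[0, "predicted_z"]) / 0.5
    assert np.isclose(slope, res.interaction("heat", "mean_cosine"))
    # design-matrix oracle
    x = np.zeros(len(res.params))
    names = list(res.params.index)
    x[names.index("heat")] = 1.0
    x[names.index("heat:mean_cosine")] = 0.5
    assert np.isclose(pred.loc[1, "predicted_z"], x @ res.params.to_numpy())


def test_prediction_extrapolation_warns(rng):
    traits = make_traits(200, rng)
    zl = simulate_z_long(traits, [0] * 4, {t: [0] * 4 for t in traits.columns}, 1, rng)
    res = fit_trait_regression(zl, traits)
    with pytest.warns(UserWarning, match="beyond the observed range"):
        predict_z(res, pd.DataFrame({"mean_cosine": [99.0]}))


# ---------------------------------------------------------------------------
# categorical (COG-style) test
# ---------------------------------------------------------------------------

def _responses_from_z(zmat):
    out = pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(zmat))]})
    for j, s in enumerate(STRESS_COLUMNS):
        out[f"z_{s}"] = zmat[:, j]
    out["status"] = "ok"
    return out


def test_category_anova_null_and_power(rng):
    n = 1000
    z = rng.normal(-1, 1, size=(n, 4))
    cats = pd.Series(rng.choice(["A", "B", "C"], n), index=[f"g{i}" for i in range(n)])
    null = category_effect_test(_responses_from_z(z), cats)
    assert (null["p"] > 0.001).all()  # no systematic signal
    z_shift = z.copy()
    z_shift[cats.to_numpy() == "A"] += 1.0  # 1 SD shift in one category
    power = category_effect_test(_responses_from_z(z_shift), cats)
    assert (power["p"] < 0.05).all()


def test_category_anova_needs_two_categories(rng):
    z = rng.normal(size=(10, 4))
    cats = pd.Series(["A"] * 10, index=[f"g{i}" for i in range(10)])
    with pytest.raises(ValueError, match="2 categories"):
        category_effect_test(_responses_from_z(z), cats)


# ---------------------------------------------------------------------------
# loss weights / tetrahedron
# ---------------------------------------------------------------------------

def test_loss_weight_vertex_centroid_edge():
    z = np.array([
        [-4.0, 0.0, 1.0, 2.0],   # pure acidity loss -> acidity vertex
        [-3.0, -3.0, -3.0, -3.0],  # equal loss -> centroid
        [-3.0, -1.0, 0.0, 0.0],  # acidity/aridity edge at 0.75/0.25
    ])
    lw = loss_weights(_responses_from_z(z))
    np.testing.assert_allclose(
        lw.loc[0, ["w_acidity", "w_aridity", "w_heat", "w_salinity"]].astype(float),
        [1, 0, 0, 0], atol=1e-15,
    )
    np.testing.assert_allclose(
        lw.loc[0, ["tetra_x", "tetra_y", "tetra_z"]].astype(float),
        TETRA_VERTICES[0], atol=1e-15,
    )
    np.testing.assert_allclose(
        lw.loc[1, ["w_acidity", "w_aridity", "w_heat", "w_salinity"]].astype(float),
        [0.25] * 4, atol=1e-15,
    )
    np.testing.assert_allclose(
        lw.loc[1, ["tetra_x", "tetra_y", "tetra_z"]].astype(float), [0, 0, 0], atol=1e-15
    )
    np.testing.assert_allclose(
        lw.loc[2, ["w_acidity", "w_aridity", "w_heat", "w_salinity"]].astype(float),
        [0.75, 0.25, 0, 0], atol=1e-15,
    )
    assert lw.loc[0, "dominant"] == "acidity"
    assert lw.loc[1, "dominant"] == "shared"


def test_inclusion_rule():
    z = np.array([[-1.5, 0.0, 0.0, 0.0], [-2.5, 0.0, 0.0, 0.0]])
    lw = loss_weights(_responses_from_z(z), z_threshold=-2.0)
    assert list(lw["gene_id"]) == ["g1"]


@settings(max_examples=50, deadline=None)
@given(
    z=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
    c=st.floats(0.1, 10),
)
def test_weights_scale_invariant(z, c):
    z = np.asarray(z)
    if z.min() >= -2.0 or (c * z).min() >= -2.0:
        return
    w1 = loss_weights(_responses_from_z(z[None, :]))
    w2 = loss_weights(_responses_from_z(c * z[None, :]))
    cols = [f"w_{s}" for s in STRESS_COLUMNS]
    np.testing.assert_allclose(
        w1[cols].to_numpy().astype(float), w2[cols].to_numpy().astype(float), atol=1e-12
    )


def test_weights_sum_to_one_and_embedding_injective(rng):
    z = -rng.exponential(2, size=(200, 4)) - 0.1
    z[:, 0] -= 2.5  # ensure inclusion
    lw = loss_weights(_responses_from_z(z))
    W = lw[[f"w_{s}" for s in STRESS_COLUMNS]].to_numpy().astype(float)
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
    assert (W >= 0).all()
    # barycentric embedding is injective: distinct weights -> distinct points
    xyz = lw[["tetra_x", "tetra_y", "tetra_z"]].to_numpy().astype(float)
    back = xyz @ np.linalg.pinv(TETRA_VERTICES)
    # recover weights up to the sum-1 constraint
    np.testing.assert_allclose(back - back.mean(1, keepdims=True),
                               W - W.mean(1, keepdims=True), atol=1e-8)


def test_specificity_flags_planted_acid_arid_excess(rng):
    n = 600
    z = rng.normal(-1, 0.3, size=(n, 4))
    exclusive = rng.random(n) < 0.5
    z[exclusive, 0] = -6.0  # acidity-exclusive strong loss
    lw = loss_weights(_responses_from_z(z))
    spec = specificity_summary(lw)
    tbl = spec["table"].set_index("stress")
    assert tbl.loc["acidity", "n_exclusive"] == tbl["n_exclusive"].max()
    assert spec["p"] < 0.05
    np.testing.assert_allclose(tbl["proportion"].sum(), 1.0)


def test_specificity_empty_input():
    lw = loss_weights(_responses_from_z(np.zeros((0, 4)).reshape(0, 4)))
    spec = specificity_summary(lw)
    assert spec["table"]["n_exclusive"].sum() == 0
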