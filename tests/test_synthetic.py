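import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from stresspan.environment import STRESS_COLUMNS, standardize_environment
from stresspan.network_traits import betweenness, mean_cosine
from stresspan.synthetic import (
    SimulationConfig,
    simulate_dataset,
    simulate_design,
    simulate_genome_map,
    simulate_network,
    simulate_pangenome,
    simulate_selection_summaries,
    simulate_snp_data,
    simulate_traits,
)


# ---------------------------------------------------------------------------
# design + environment
# ---------------------------------------------------------------------------

def test_design_dimensions_match_study():
    design, raw = simulate_design(SimulationConfig(seed=0))
    assert len(raw) == 60
    assert len(design) == 360
    assert design["sample_id"].nunique() == 60
    assert design["site_id"].nunique() == 20


def test_degenerate_minimum_design():
    cfg = SimulationConfig(n_sites=1, samples_per_site=1, strains_per_sample=1, seed=0)
    design, raw = simulate_design(cfg)
    assert len(raw) == 1 and len(design) == 1


def test_salinity_zero_mass_fraction():
    cfg = SimulationConfig(
        n_sites=3334, samples_per_site=3, strains_per_sample=1, salinity_zero_p=0.3, seed=2
    )
    _, raw = simulate_design(cfg)
    assert abs((raw["salinity"] == 0).mean() - 0.3) < 0.02


def test_invalid_correlation_rejected():
    C = np.full((4, 4), 0.99)
    np.fill_diagonal(C, 1.0)
    C[0, 1] = C[1, 0] = -0.99  # not positive definite
    with pytest.raises(ValueError, match="positive-definite"):
        SimulationConfig(stress_correlation=C).validate()


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def test_network_deterministic():
    G1 = simulate_network(100, seed=5)
    G2 = simulate_network(100, seed=5)
    assert set(G1.edges()) == set(G2.edges())


def test_pure_duplication_produces_cosine_one_pair():
    G = simulate_network(4, retain_p=1.0, anchor_p=0.0, bridge_p=0.0, seed=0)
    cos = nx.to_numpy_array(G)
    deg = cos.sum(1)
    found = any(
        np.isclose((cos[i] @ cos[j]) / np.sqrt(deg[i] * deg[j]), 1.0)
        for i in range(4)
        for j in range(i + 1, 4)
    )
    assert found


def test_trait_spread_at_200_genes():
    G = simulate_network(200, seed=1)
    btw = betweenness(G)
    cos = mean_cosine(G)
    assert btw.std() / btw.mean() > 0.2
    assert cos.std() / cos.mean() > 0.2


# ---------------------------------------------------------------------------
# pangenome
# ---------------------------------------------------------------------------

def null_config(**kw):
    base = dict(
        occurrence_intercept_range=(0.0, 0.0),
        responsive_fraction=1.0,
        baseline_slope=0.0,
        trait_effect_map={"mean_cosine": 0.0, "betweenness": 0.0, "duplication": 0.0},
        slope_noise_sd=0.0,
        site_sd=0.0,
        sample_sd=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def flat_design(n_strains):
    design = pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(n_strains)],
            "sample_id": "p0",
            "site_id": "s0",
        }
    )
    stress = pd.DataFrame({"sample_id": ["p0"], **{s: [0.0] for s in STRESS_COLUMNS}})
    return design, stress


def test_null_model_presence_frequency_half(rng):
    cfg = null_config(n_genes=50, core_fraction=0.02, seed=3)
    design, stress = flat_design(10_000)
    traits = simulate_traits(simulate_network(50, seed=3), rng, [f"g{i:05d}" for i in range(50)])
    matrix, truth = simulate_pangenome(design, stress, traits, cfg, rng)
    acc_freq = matrix.presence[:, 1:].mean(axis=0)  # first gene is core
    assert np.all(np.abs(acc_freq - 0.5) < 0.02)


def test_core_genes_present_everywhere(small_dataset):
    d = small_dataset
    n_core = int(round(d["config"].core_fraction * d["config"].n_genes))
    assert d["matrix"].presence[:, :n_core].all()


def test_planted_heat_slope_matches_logistic_closed_form(rng):
    """beta_heat = -2, alpha = 0, x_heat = +1: presence freq = expit(-2) = 0.1192."""
    cfg = null_config(n_genes=40, core_fraction=0.025, baseline_slope=-2.0, seed=4)
    design, stress = flat_design(20_000)
    stress["heat"] = 1.0  # all other stresses stay 0
    traits = simulate_traits(simulate_network(40, seed=4), rng, [f"g{i:05d}" for i in range(40)])
    matrix, truth = simulate_pangenome(design, stress, traits, cfg, rng)
    freq = matrix.presence[:, 1:].mean()
    assert abs(freq - expit(-2.0)) < 0.01
    assert np.allclose(truth.true_beta.to_numpy(), -2.0)


def test_missing_trait_errors(rng):
    cfg = null_config(n_genes=10, core_fraction=0.1, seed=0)
    design, stress = flat_design(5)
    traits = simulate_traits(simulate_network(10, seed=0), rng, [f"g{i:05d}" for i in range(9)])
    with pytest.raises(ValueError, match="missing traits"):
        simulate_pangenome(design, stress, traits, cfg, rng)


def test_planted_category_consistent_with_dominant_beta(small_dataset):
    truth = small_dataset["truth"]
    beta = truth.true_beta.to_numpy()
    dominant = beta[np.arange(len(beta)), np.abs(beta).argmax(axis=1)]
    cat = truth.planted_category.to_numpy()
    assert np.all(dominant[cat == "loss"] < 0)
    assert np.all(dominant[cat == "gain"] > 0)


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def test_zero_differentiation_limit_recovers_ancestral_freqs():
    cfg = SimulationConfig(fst_base=1e-12, fst_stress_slope=0.0, n_snp_loci=50, seed=6)
    design, raw = simulate_design(cfg)
    stress = standardize_environment(raw)
    snp, F = simulate_snp_data(design, stress, cfg)
    assert np.all(F < 1e-9)
    # per-sample expected frequencies identical across samples -> genotype
    # means differ only by binomial noise around a common p0 per locus
    rng = np.random.default_rng(cfg.seed + 2)
    p0 = rng.uniform(0.1, 0.9, size=cfg.n_snp_loci)
    overall = snp.genotypes.mean(axis=0)
    assert np.corrcoef(overall, p0)[0, 1] > 0.9


def test_snp_matrix_well_formed(small_dataset):
    snp = small_dataset["snp"]
    vals = snp.genotypes
    assert set(np.unique(vals)) <= {0.0, 1.0}
    assert all(s in snp.sample_of for s in snp.strains)


# ---------------------------------------------------------------------------
# selection summaries
# ---------------------------------------------------------------------------

def test_category_means_recovered(rng):
    cats = pd.Series(
        ["loss"] * 1000 + ["neutral"] * 1000 + ["gain"] * 1000,
        index=[f"g{i}" for i in range(3000)],
    )
    cfg = SimulationConfig(seed=8)
    stress = pd.DataFrame({"sample_id": [f"p{i}" for i in range(60)],
                           **{s: np.zeros(60) for s in STRESS_COLUMNS}})
    genes, pop = simulate_selection_summaries(cats, stress, cfg)
    tbl = genes.merge(cats.rename("cat"), left_on="gene_id", right_index=True)
    means = tbl.groupby("cat")["prop_purifying"].mean()
    assert abs(means["loss"] - 0.8) < 0.03
    assert abs(means["neutral"] - 0.6) < 0.03
    assert abs(means["gain"] - 0.75) < 0.03
    pos = tbl.groupby("cat")["any_positive"].mean()
    assert pos["loss"] > pos["neutral"] + 0.05


def test_zero_codon_genes_excluded():
    cats = pd.Series(["loss"] * 20, index=[f"g{i}" for i in range(20)])
    cfg = SimulationConfig(n_codons_range=(0, 0), seed=0)
    stress = pd.DataFrame({"sample_id": ["p0", "p1"],
                           **{s: [0.0, 0.0] for s in STRESS_COLUMNS}})
    genes, _ = simulate_selection_summaries(cats, stress, cfg)
    assert len(genes) == 0


def test_selection_summaries_deterministic():
    cats = pd.Series(["loss", "gain", "neutral"], index=["a", "b", "c"])
    stress = pd.DataFrame({"sample_id": ["p0", "p1"],
                           **{s: [0.5, -0.5] for s in STRESS_COLUMNS}})
    cfg = SimulationConfig(seed=12)
    g1, p1 = simulate_selection_summaries(cats, stress, cfg)
    g2, p2 = simulate_selection_summaries(cats, stress, cfg)
    pd.testing.assert_frame_equal(g1, g2)
    pd.testing.assert_frame_equal(p1, p2)


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------

def test_core_enrichment_in_hotspot(rng):
    cfg = SimulationConfig(
        genome_length=8_000_000, hotspot_interval=(0, 850_000), hotspot_enrichment=5.0, seed=0
    )
    genes = [f"g{i}" for i in range(2000)]
    labels = pd.Series(["core"] * 1000 + ["accessory"] * 1000, index=genes)
    mag = pd.Series(rng.exponential(1, 2000), index=genes)
    gmap = simulate_genome_map(genes, labels, mag, cfg, rng)
    core = gmap[gmap["label"] == "core"]
    L, h = 8_000_000, 850_000
    inside = ((core["position"] >= 0) & (core["position"] < h)).sum()
    dens_in = inside / h
    dens_out = (len(core) - inside) / (L - h)
    assert dens_in >= 3 * dens_out
    assert gmap["position"].is_unique
    assert gmap["position"].between(0, L - 1).all()


def test_genome_map_core_only():
    cfg = SimulationConfig(seed=0)
    genes = ["g0", "g1"]
    labels = pd.Series(["core", "core"], index=genes)
    gmap = simulate_genome_map(genes, labels, pd.Series(dtype=float), cfg)
    assert (gmap["label"] == "core").all()


def test_more_genes_than_positions_rejected():
    cfg = SimulationConfig(genome_length=10, hotspot_interval=(0, 5), seed=0)
    genes = [f"g{i}" for i in range(11)]
    labels = pd.Series(["accessory"] * 11, index=genes)
    with pytest.raises(ValueError, match="more genes"):
        simulate_genome_map(genes, labels, pd.Series(np.ones(11), index=genes), cfg)


# ---------------------------------------------------------------------------
# whole-dataset determinism
# ---------------------------------------------------------------------------

def test_dataset_bit_identical_under_same_seed():
    cfg = SimulationConfig(n_genes=80, n_snp_loci=40, seed=77)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(SimulationConfig(n_genes=80, n_snp_loci=40, seed=77))
    np.testing.assert_array_equal(d1["matrix"].counts, d2["matrix"].counts)
    np.testing.assert_array_equal(d1["snp"].genotypes, d2["snp"].genotypes)
    pd.testing.assert_frame_equal(d1["raw_env"], d2["raw_env"])
    pd.testing.assert_frame_equal(d1["genome_map"], d2["genome_map"])
    assert set(d1["network"].edges()) == set(d2["network"].edges())
    pd.testing.assert_frame_equal(d1["truth"].true_beta, d2["truth"].true_beta)
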