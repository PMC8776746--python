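"""Synthetic landscape-pangenomics data with planted ground truth.

Emulates the hierarchical field design — 20 sites x 3 soil samples x 6
strains by default — and every input the analysis pipeline consumes:

* a site/soil-sample/strain design table and a raw environment table
  (temperature, rainfall, pH, salinity; salinity has a point mass at zero);
* a gene interaction network grown by duplication-divergence plus bridge
  vertices, so cosine-similarity and betweenness traits both have spread;
* a strain x gene copy-count matrix in which each accessory gene's presence
  follows a logistic model of the four standardized stresses with site and
  soil-sample random intercepts, and the per-gene stress slopes are built
  from the gene's traits (high similarity / duplication -> negative slopes,
  i.e. loss under stress; high betweenness -> positive, i.e. retention);
* binary SNP genotypes for core genes whose Balding-Nichols differentiation
  rises with heat and salinity stress;
* per-gene and per-population dN/dS codon summaries whose purifying
  proportions depend on the planted stress-response category;
* a circular genome map with core genes and weakly-responding accessory
  genes enriched inside a planted retention hotspot.

Everything derives from one seeded generator, so an identical config yields
bit-identical outputs, and the planted parameters are returned as a
:class:`SyntheticTruth` for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import expit, logit

from stresspan.environment import STRESS_COLUMNS, standardize_environment
from stresspan.fst import SNPMatrix
from stresspan.pangenome import PangenomeMatrix

_TRAITS = ("mean_cosine", "betweenness", "duplication")


def _default_corr() -> np.ndarray:
    C = np.full((4, 4), 0.3)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the field design."""

    n_sites: int = 20
    samples_per_site: int = 3
    strains_per_sample: int = 6
    n_genes: int = 5000
    core_fraction: float = 0.1
    stress_correlation: np.ndarray = field(default_factory=_default_corr)
    salinity_zero_p: float = 0.3
    occurrence_intercept_range: tuple[float, float] = (-1.0, 1.0)
    responsive_fraction: float = 0.5
    baseline_slope: float = -0.5
    trait_effect_map: dict = field(
        default_factory=lambda: {"mean_cosine": -0.5, "betweenness": 0.3, "duplication": -0.5}
    )
    slope_noise_sd: float = 0.3
    site_sd: float = 0.3
    sample_sd: float = 0.3
    n_snp_loci: int = 2000
    fst_base: float = 0.1
    fst_stress_slope: float = 0.5
    genome_length: int = 8_000_000
    hotspot_interval: tuple[int, int] = (0, 850_000)
    hotspot_enrichment: float = 5.0
    n_codons_range: tuple[int, int] = (100, 500)
    purifying_means: dict = field(
        default_factory=lambda: {"loss": 0.8, "neutral": 0.6, "gain": 0.75}
    )
    purifying_precision: float = 20.0
    positive_rates: dict = field(
        default_factory=lambda: {"loss": 0.15, "neutral": 0.05, "gain": 0.05}
    )
    pop_purifying_base: float = 0.97
    pop_purifying_slopes: dict = field(
        default_factory=lambda: {"acidity": 0.0, "aridity": 0.0, "heat": -0.4, "salinity": -0.4}
    )
    pop_purifying_precision: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sites", "samples_per_site", "strains_per_sample", "n_genes", "n_snp_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.core_fraction < 1.0):
            raise ValueError("core_fraction must be in (0, 1)")
        C = np.asarray(self.stress_correlation, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("stress_correlation must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("stress_correlation must be positive-definite")
        if not (0.0 < self.fst_base < 1.0):
            raise ValueError("fst_base must be in (0, 1)")
        lo, hi = self.hotspot_interval
        if not (0 <= lo < hi <= self.genome_length):
            raise ValueError("hotspot_interval must lie within [0, genome_length)")


@dataclass
class SyntheticTruth:
    """Planted parameters for parameter-recovery testing."""

    true_beta: pd.DataFrame  # accessory gene x 4 occurrence log-odds slopes
    true_intercepts: pd.Series
    #: instantaneous d log E[richness]/d x_e at x = 0.  The *fitted* global
    #: log-linear slope is smaller under gene-heterogeneous slopes because
    #: strong-loss genes saturate out and gain genes grow (logistic
    #: curvature); only the sign is comparable.
    true_richness_slopes: pd.Series
    true_fst_by_pair: dict  # (sample_a, sample_b) -> expected pairwise Fst
    fst_by_sample: pd.Series  # Balding-Nichols F per soil sample
    planted_hotspot: tuple[int, int]
    planted_category: pd.Series  # gene -> loss | neutral | gain


# ---------------------------------------------------------------------------
# design + raw environment
# ---------------------------------------------------------------------------

def simulate_design(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site/soil-sample/strain hierarchy plus the raw environment table.

    Latent stress 4-vectors per soil sample are multivariate normal with the
    configured correlation and mapped monotonically to raw variables so that
    the standardization step recovers them: temperature rises with heat,
    rainfall falls with aridity, pH falls with acidity, and salinity is zero
    for the lowest-salinity samples (point mass, exercising the
    ln(x + 0.01) transform) and log-linear above.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n_samples = config.n_sites * config.samples_per_site
    C = np.asarray(config.stress_correlation, dtype=float)
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("stress_correlation is not positive-definite") from exc
    latent = rng.standard_normal((n_samples, 4)) @ chol.T  # acidity, aridity, heat, salinity
    sal_zero = latent[:, 3] < np.quantile(latent[:, 3], config.salinity_zero_p)

    sample_ids, site_ids = [], []
    for s in range(config.n_sites):
        for j in range(config.samples_per_site):
            site_ids.append(f"site{s + 1:02d}")
            sample_ids.append(f"site{s + 1:02d}_samp{j + 1}")
    raw = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "temperature": 22.0 + 4.0 * latent[:, 2],
            "rainfall": np.maximum(600.0 - 180.0 * latent[:, 1], 5.0),
            "ph": 6.5 - 0.8 * latent[:, 0],
            "salinity": np.where(sal_zero, 0.0, np.exp(-1.0 + latent[:, 3])),
        }
    )
    rows = []
    for site, samp in zip(site_ids, sample_ids):
        for t in range(config.strains_per_sample):
            rows.append(
                {
                    "strain_id": f"{samp}_str{t + 1}",
                    "sample_id": samp,
                    "site_id": site,
                }
            )
    design = pd.DataFrame(rows)
    return design, raw


# ---------------------------------------------------------------------------
# gene interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    n_genes: int,
    retain_p: float = 0.6,
    anchor_p: float = 0.15,
    bridge_p: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> nx.Graph:
    """Duplication-divergence graph with bridge vertices over gene ids.

    Growth: with probability ``1 - bridge_p`` a new vertex copies a random
    template's neighbourhood (each neighbour kept with ``retain_p``, plus the
    template itself with ``anchor_p``) — duplicated genes share neighbours
    and get high cosine similarity; with probability ``bridge_p`` the new
    vertex attaches to two vertices chosen uniformly — long-range bridges
    with high betweenness.  ``retain_p=1, anchor_p=0, bridge_p=0`` is pure
    duplication (copies share the full neighbourhood, cosine similarity 1).
    """
    if n_genes < 4:
        raise ValueError("need at least 4 genes for the network model")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = [f"g{i:05d}" for i in range(n_genes)]
    G = nx.Graph()
    G.add_edges_from([(ids[0], ids[1]), (ids[1], ids[2]), (ids[2], ids[3]), (ids[3], ids[0])])
    for i in range(4, n_genes):
        new = ids[i]
        existing = ids[:i]
        if bridge_p > 0 and rng.random() < bridge_p and i >= 2:
            targets = rng.choice(i, size=min(2, i), replace=False)
            for t in targets:
                G.add_edge(new, ids[t])
            continue
        template = ids[int(rng.integers(i))]
        nbrs = list(G.neighbors(template)) if template in G else []
        kept = [v for v in nbrs if rng.random() < retain_p]
        for v in kept:
            G.add_edge(new, v)
        if rng.random() < anchor_p or not kept:
            G.add_edge(new, template)
    return G


# ---------------------------------------------------------------------------
# pangenome matrix
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_pangenome(
    design: pd.DataFrame,
    stress: pd.DataFrame,
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PangenomeMatrix, SyntheticTruth]:
    """Strain x gene copy counts under the logistic occurrence model.

    ``traits`` is indexed by gene id with the three trait columns (e.g. the
    planted traits from :func:`simulate_traits` or measured ones); every
    accessory gene must have a row.  P(gene present in strain) =
    logistic(alpha_g + sum_e beta_ge * x_e(sample) + u_site + u_sample); the
    slopes are the trait-weighted effects plus noise.  Core genes (the first
    ``core_fraction`` of the id space) are present in every strain.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n_core = int(round(config.core_fraction * config.n_genes))
    core_genes, acc_genes = genes[:n_core], genes[n_core:]
    missing = [g for g in acc_genes if g not in traits.index]
    if missing:
        raise ValueError(f"missing traits for accessory genes: {missing[:5]}")

    strains = list(design["strain_id"])
    n_strains = len(strains)
    x = (
        design.merge(stress, on="sample_id", how="left")
        .loc[:, list(STRESS_COLUMNS)]
        .to_numpy(dtype=float)
    )
    site_codes = pd.factorize(design["site_id"])[0]
    samp_codes = pd.factorize(design["sample_id"])[0]

    T = traits.loc[acc_genes, list(_TRAITS)].to_numpy(dtype=float)
    T_std = np.column_stack([_standardize(T[:, j]) for j in range(T.shape[1])])
    eff = np.array([config.trait_effect_map.get(t, 0.0) for t in _TRAITS])
    n_acc = len(acc_genes)
    beta = (
        config.baseline_slope
        + (T_std * eff).sum(axis=1)[:, None]
        + rng.normal(0.0, config.slope_noise_sd, size=(n_acc, 4))
    )
    # spike-and-slab: most accessory genes are not stress-responsive
    responsive = rng.random(n_acc) < config.responsive_fraction
    beta[~responsive] = 0.0
    lo, hi = config.occurrence_intercept_range
    alpha = rng.uniform(lo, hi, size=n_acc)
    u_site = rng.normal(0.0, config.site_sd, size=site_codes.max() + 1)
    u_samp = rng.normal(0.0, config.sample_sd, size=samp_codes.max() + 1)

    eta = alpha[None, :] + x @ beta.T + (u_site[site_codes] + u_samp[samp_codes])[:, None]
    present = rng.random((n_strains, n_acc)) < expit(eta)

    # copy counts: planted duplication rate = trait duplication level - 1
    dup_rate = np.clip(traits.loc[acc_genes, "duplication"].to_numpy(dtype=float) - 1.0, 0.0, None)
    counts_acc = np.where(present, 1 + rng.poisson(dup_rate[None, :], size=present.shape), 0)
    counts_core = 1 + rng.poisson(0.02, size=(n_strains, n_core))
    counts = np.hstack([counts_core, counts_acc])
    matrix = PangenomeMatrix(strains, genes, counts)

    dominant = beta[np.arange(n_acc), np.abs(beta).argmax(axis=1)]
    category = np.where(dominant < -0.5, "loss", np.where(dominant > 0.5, "gain", "neutral"))

    # analytic small-effect richness slope: d log E[richness]/d x_e at x = 0
    p0 = expit(alpha)
    slopes = (beta * (p0 * (1 - p0))[:, None]).sum(axis=0) / p0.sum()
    truth = SyntheticTruth(
        true_beta=pd.DataFrame(beta, index=acc_genes, columns=list(STRESS_COLUMNS)),
        true_intercepts=pd.Series(alpha, index=acc_genes),
        true_richness_slopes=pd.Series(slopes, index=list(STRESS_COLUMNS)),
        true_fst_by_pair={},
        fst_by_sample=pd.Series(dtype=float),
        planted_hotspot=tuple(config.hotspot_interval),
        planted_category=pd.Series(category, index=acc_genes),
    )
    return matrix, truth


def simulate_traits(
    network: nx.Graph, rng: np.random.Generator, genes: list[str]
) -> pd.DataFrame:
    """Planted trait table: network-derived similarity/betweenness + duplication."""
    from stresspan.network_traits import betweenness as btw_fn, mean_cosine as cos_fn

    btw = btw_fn(network).reindex(genes).fillna(0.0)
    cos = cos_fn(network).reindex(genes).fillna(0.0)
    dup = 1.0 + rng.exponential(0.2, size=len(genes))
    return pd.DataFrame(
        {"mean_cosine": cos.to_numpy(), "betweenness": btw.to_numpy(), "duplication": dup},
        index=pd.Index(genes, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# SNP data
# ---------------------------------------------------------------------------

def simulate_snp_data(
    design: pd.DataFrame,
    stress: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SNPMatrix, pd.Series]:
    """Balding-Nichols SNP genotypes with stress-dependent differentiation.

    Per soil sample, F(sample) = logistic(logit(fst_base) +
    fst_stress_slope * (heat + salinity)/2); per locus, the sample allele
    frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F) around an ancestral
    frequency p0 ~ U(0.1, 0.9), and haploid strain genotypes are Bernoulli
    draws.  Returns the matrix and the per-sample F values.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    stress_idx = stress.set_index("sample_id")
    samples = list(stress_idx.index)
    xs = stress_idx.loc[samples, ["heat", "salinity"]].to_numpy(dtype=float)
    F = expit(logit(config.fst_base) + config.fst_stress_slope * xs.mean(axis=1))
    p0 = rng.uniform(0.1, 0.9, size=config.n_snp_loci)

    freq = np.empty((len(samples), config.n_snp_loci))
    for i, f in enumerate(F):
        if f < 1e-9:
            freq[i] = p0
        else:
            a = p0 * (1 - f) / f
            b = (1 - p0) * (1 - f) / f
            freq[i] = rng.beta(a, b)
    strains = list(design["strain_id"])
    samp_of = dict(zip(design["strain_id"], design["sample_id"]))
    samp_pos = {s: i for i, s in enumerate(samples)}
    rows = np.asarray([samp_pos[samp_of[s]] for s in strains])
    G = (rng.random((len(strains), config.n_snp_loci)) < freq[rows]).astype(float)
    loci = [f"snp{i:05d}" for i in range(config.n_snp_loci)]
    snp = SNPMatrix(strains, loci, G, samp_of)
    return snp, pd.Series(F, index=samples, name="bn_fst")


def expected_pairwise_fst(fst_by_sample: pd.Series) -> dict:
    """Expected Hudson Fst per sample pair under the Balding-Nichols truth."""
    out = {}
    samples = list(fst_by_sample.index)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            out[(samples[i], samples[j])] = float(
                0.5 * (fst_by_sample.iloc[i] + fst_by_sample.iloc[j])
            )
    return out


# ---------------------------------------------------------------------------
# dN/dS codon summaries
# ---------------------------------------------------------------------------

def simulate_selection_summaries(
    categories: pd.Series,
    stress: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level and population-level dN/dS codon summaries.

    Gene level: per gene with a planted category, the purifying proportion
    is Beta-distributed with a category-specific mean (loss/gain above
    neutral) and the any-positive flag is Bernoulli with an elevated rate
    only for the loss category.  Genes drawing zero codons are excluded.
    Population level: per-soil-sample mean purifying proportion over a core
    gene subsample, declining on the logit scale with heat and salinity.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    lo, hi = config.n_codons_range
    cat_map = {"loss": "loss", "decrease": "loss", "neutral": "neutral",
               "none": "neutral", "gain": "gain", "increase": "gain"}
    genes = list(categories.index)
    cats = [cat_map[c] for c in categories]
    n = len(genes)
    n_codons = rng.integers(lo, hi + 1, size=n)
    means = np.asarray([config.purifying_means[c] for c in cats])
    phi = config.purifying_precision
    prop = rng.beta(means * phi, (1 - means) * phi)
    rates = np.asarray([config.positive_rates[c] for c in cats])
    any_pos = rng.random(n) < rates
    gene_tbl = pd.DataFrame(
        {
            "gene_id": genes,
            "n_codons": n_codons,
            "prop_purifying": prop,
            "any_positive": any_pos,
        }
    )
    gene_tbl = gene_tbl[gene_tbl["n_codons"] > 0].reset_index(drop=True)

    X = stress.loc[:, list(STRESS_COLUMNS)].to_numpy(dtype=float)
    slopes = np.asarray([config.pop_purifying_slopes.get(s, 0.0) for s in STRESS_COLUMNS])
    mu = expit(logit(config.pop_purifying_base) + X @ slopes)
    phi_pop = config.pop_purifying_precision
    pop = rng.beta(mu * phi_pop, (1 - mu) * phi_pop)
    pop_tbl = pd.DataFrame(
        {"sample_id": stress["sample_id"].to_numpy(), "mean_prop_purifying": pop}
    )
    return gene_tbl, pop_tbl


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------

def simulate_genome_map(
    gene_ids: list[str],
    labels: pd.Series,
    response_magnitude: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Unique 0-based half-open positions on the circular chromosome.

    Core genes and weakly-responding accessory genes (|response| below the
    accessory median) are enriched inside the planted hotspot interval by
    ``hotspot_enrichment``; everything else is uniform on the circle.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 4)
    L = config.genome_length
    if len(gene_ids) > L:
        raise ValueError("more genes than representable positions")
    lo, hi = config.hotspot_interval
    h = hi - lo
    acc_mag = response_magnitude.reindex(gene_ids)
    acc_vals = acc_mag[labels.reindex(gene_ids) == "accessory"].dropna()
    med = float(acc_vals.median()) if len(acc_vals) else 0.0
    enr = config.hotspot_enrichment
    p_in_enriched = enr * h / (enr * h + (L - h))
    p_in_uniform = h / L

    taken: set[int] = set()
    positions = []
    for g in gene_ids:
        is_core = labels.get(g) == "core"
        low_resp = (
            labels.get(g) == "accessory"
            and np.isfinite(acc_mag.get(g, np.nan))
            and acc_mag[g] <= med
        )
        p_in = p_in_enriched if (is_core or low_resp) else p_in_uniform
        while True:
            if rng.random() < p_in:
                pos = int(rng.integers(lo, hi))
            else:
                pos = int(rng.integers(0, L))
                if lo <= pos < hi:
                    continue
            if pos not in taken:
                taken.add(pos)
                break
        positions.append(pos)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "position": positions,
            "label": [labels.get(g, "accessory") for g in gene_ids],
            "genome_length": L,
        }
    )


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None) -> dict:
    """Generate the full linked dataset (all seven inputs + ground truth)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    design, raw_env = simulate_design(config, rng)
    stress = standardize_environment(raw_env)
    network = simulate_network(config.n_genes, seed=rng)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    traits = simulate_traits(network, rng, genes)
    matrix, truth = simulate_pangenome(design, stress, traits, config, rng)
    snp, fst_by_sample = simulate_snp_data(design, stress, config, rng)
    truth.fst_by_sample = fst_by_sample
    truth.true_fst_by_pair = expected_pairwise_fst(fst_by_sample)
    gene_dnds, pop_dnds = simulate_selection_summaries(
        truth.planted_category, stress, config, rng
    )
    n_core = int(round(config.core_fraction * config.n_genes))
    labels = pd.Series(
        ["core"] * n_core + ["accessory"] * (config.n_genes - n_core), index=genes
    )
    magnitude = truth.true_beta.abs().max(axis=1)
    genome_map = simulate_genome_map(genes, labels, magnitude, config, rng)
    return {
        "config": config,
        "design": design,
        "raw_env": raw_env,
        "stress": stress,
        "network": network,
        "traits": traits,
        "matrix": matrix,
        "snp": snp,
        "gene_dnds": gene_dnds,
        "pop_dnds": pop_dnds,
        "genome_map": genome_map,
        "truth": truth,
    }


def write_dataset(data: dict, outdir: str | Path) -> None:
    """Write the seven input tables as TSV plus a JSON ground-truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data["design"].to_csv(out / "design.tsv", sep="\t", index=False)
    data["raw_env"].to_csv(out / "environment_raw.tsv", sep="\t", index=False)
    data["matrix"].to_frame().rename_axis("strain_id").to_csv(
        out / "gene_counts.tsv", sep="\t"
    )
    edges = pd.DataFrame(list(data["network"].edges()), columns=["gene_a", "gene_b"])
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    data["gene_dnds"].to_csv(out / "gene_dnds.tsv", sep="\t", index=False)
    data["pop_dnds"].to_csv(out / "population_dnds.tsv", sep="\t", index=False)
    snp = data["snp"]
    snp_df = pd.DataFrame(snp.genotypes, index=snp.strains, columns=snp.loci)
    snp_df.rename_axis("strain_id").to_csv(out / "snp_matrix.tsv", sep="\t")
    data["genome_map"].to_csv(out / "genome_map.tsv", sep="\t", index=False)
    truth = data["truth"]
    sidecar = {
        "true_richness_slopes": truth.true_richness_slopes.to_dict(),
        "planted_hotspot": list(truth.planted_hotspot),
        "fst_by_sample": truth.fst_by_sample.to_dict(),
        "category_counts": truth.planted_category.value_counts().to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
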