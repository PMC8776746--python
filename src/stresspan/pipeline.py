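"""End-to-end orchestration: simulate/load inputs, run all stages, report.

Stages run in dependency order: environment -> pangenome -> occurrence ->
traits -> meta-regression/loss -> selection -> fst -> smoothing -> report.
Each stage writes its key tables to the output directory as TSV; the run
report collects per-stage status plus a four-column summary in the shape of
a key-results table (per stress: richness trend, dominant trait predictor,
environment-specific loss signal, Fst trend).  The expensive per-gene
occurrence stage is cached on a content hash of its inputs so partial runs
resume cheaply.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stresspan import io as spio
from stresspan.environment import STRESS_COLUMNS, standardize_environment
from stresspan.network_traits import compute_gene_traits
from stresspan.occurrence import (
    fit_diversity_model,
    fit_gene_occurrence_models,
    fit_richness_model,
    summarize_z,
    z_long,
)
from stresspan.pangenome import classify_genes, filter_for_richness, gene_richness, pangenome_diversity
from stresspan.trait_loss import fit_trait_regression, loss_weights, specificity_summary
from stresspan.selection import (
    fit_positive_selection_model,
    fit_purifying_model,
    population_dnds_model,
    stratify_genes_by_z,
)
from stresspan.fst import bin_samples_by_stress, fst_stress_regression, pairwise_fst
from stresspan.smoothing import colocation_test, detect_retention_hotspots, fit_circular_smoother
from stresspan.synthetic import SimulationConfig, simulate_dataset

log = logging.getLogger("stresspan")

ALL_STAGES = (
    "environment",
    "pangenome",
    "occurrence",
    "traits",
    "loss",
    "selection",
    "fst",
    "smoothing",
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``input_dir`` (a
    directory with the seven input TSVs) must be provided.  ``stages`` may
    switch individual stages off; dependencies of later stages are computed
    regardless of the toggle only when required.
    """

    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    output_dir: str = "stresspan_out"
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage -> bool, default True
    core_threshold: float = 0.99
    z_threshold: float = -2.0
    dominance: float = 0.75
    bins_k: int = 5
    n_perm: int = 999
    n_per_cat: int = 1000
    neutral_band: float = 0.5
    per_gene_random_effects: bool = True
    smoother_max_train: int = 800
    colocation_perms: int = 99
    use_cache: bool = True

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "stress_correlation" in sim:
                sim["stress_correlation"] = np.asarray(sim["stress_correlation"], float)
            for key in ("occurrence_intercept_range", "hotspot_interval", "n_codons_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        if cfg.simulate is None and cfg.input_dir is None:
            raise ValueError("config must provide either a simulate block or input_dir")
        return cfg


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, pd.DataFrame):
            h.update(pd.util.hash_pandas_object(p, index=True).to_numpy().tobytes())
        elif isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report (also on disk)."""
    import networkx
    import scipy
    import statsmodels

    import stresspan

    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "stages": {},
        "seed": config.seed,
        "timings_s": {},
        "versions": {
            "stresspan": stresspan.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "networkx": networkx.__version__,
        },
    }
    summary_rows = {s: {"stress": s} for s in STRESS_COLUMNS}

    def run_stage(name, fn):
        if not config.enabled(name):
            report["stages"][name] = "skipped"
            log.info("stage %s skipped", name)
            return None
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            report["stages"][name] = f"error: {exc}"
            raise RuntimeError(
                f"pipeline stage {name!r} failed: {exc}; "
                "inspect earlier stage outputs in the output directory"
            ) from exc
        report["stages"][name] = "ok"
        report["timings_s"][name] = round(time.time() - t0, 2)
        log.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    # ---- inputs --------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim.seed = config.seed
        data = simulate_dataset(sim)
    elif config.input_dir:
        data = spio.load_dataset(config.input_dir)
    else:
        raise ValueError("no input source configured")

    # ---- environment ---------------------------------------------------
    def stage_environment():
        stress = data.get("stress")
        if stress is None:
            stress = standardize_environment(data["raw_env"])
        stress.to_csv(out / "stress_profiles.tsv", sep="\t", index=False)
        return stress

    stress = run_stage("environment", stage_environment)
    if stress is None:
        raise RuntimeError("the environment stage cannot be skipped")

    # ---- pangenome -----------------------------------------------------
    def stage_pangenome():
        matrix = classify_genes(data["matrix"], core_threshold=config.core_threshold)
        filtered = filter_for_richness(matrix)
        richness = gene_richness(filtered)
        diversity = pangenome_diversity(filtered, data["design"])
        richness.to_csv(out / "richness.tsv", sep="\t", index=False)
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        return matrix, filtered, richness, diversity

    pg = run_stage("pangenome", stage_pangenome)
    matrix, filtered, richness, diversity = pg if pg else (None,) * 4

    # ---- occurrence ----------------------------------------------------
    def stage_occurrence():
        rich_fit = fit_richness_model(richness, stress, data["design"])
        div_fit = fit_diversity_model(diversity, stress, data["design"])
        cache_key = _hash_inputs(
            filtered.counts, stress, config.per_gene_random_effects
        )
        cache_file = out / "gene_z.tsv"
        meta_file = out / "gene_z.hash"
        if (
            config.use_cache
            and cache_file.exists()
            and meta_file.exists()
            and meta_file.read_text().strip() == cache_key
        ):
            responses = pd.read_csv(cache_file, sep="\t")
            log.info("per-gene occurrence models loaded from cache")
        else:
            responses = fit_gene_occurrence_models(
                filtered, stress, data["design"],
                random_effects=config.per_gene_random_effects,
            )
            responses.to_csv(cache_file, sep="\t", index=False)
            meta_file.write_text(cache_key)
        zsum = summarize_z(responses)
        zsum["table"].to_csv(out / "z_summary.tsv", sep="\t", index=False)
        rich_tbl = pd.DataFrame(
            {
                "coef": rich_fit.coefficients,
                "se": rich_fit.standard_errors,
                "p": rich_fit.pvalues,
            }
        )
        rich_tbl.to_csv(out / "richness_model.tsv", sep="\t")
        for s in STRESS_COLUMNS:
            b = rich_fit.coefficients[s]
            summary_rows[s]["richness_slope"] = float(b)
            summary_rows[s]["richness_p"] = float(rich_fit.pvalues[s])
            summary_rows[s]["gene_loss_pct_per_sd"] = float((1.0 - np.exp(b)) * 100.0)
            summary_rows[s]["mean_z"] = float(
                zsum["table"].set_index("stress").loc[s, "mean_z"]
            )
        return rich_fit, div_fit, responses, zsum

    occ = run_stage("occurrence", stage_occurrence)
    rich_fit, div_fit, responses, zsum = occ if occ else (None,) * 4

    # ---- traits + meta-regression -------------------------------------
    def stage_traits():
        traits = compute_gene_traits(data["network"], matrix)
        traits.to_csv(out / "gene_traits.tsv", sep="\t")
        zl = z_long(responses)
        zl = zl[zl["gene_id"].isin(traits.index)]
        reg = fit_trait_regression(zl, traits)
        reg_tbl = pd.DataFrame(
            {
                "coef": reg.params,
                "se": reg.bse,
                "p": reg.pvalues,
                "lower": reg.conf_int["lower"],
                "upper": reg.conf_int["upper"],
            }
        )
        reg_tbl.to_csv(out / "trait_regression.tsv", sep="\t")
        for s in STRESS_COLUMNS:
            inter = {
                t: reg.interaction(s, t)
                for t in ("mean_cosine", "betweenness", "duplication")
            }
            loss_traits = [t for t, v in inter.items() if v < 0]
            summary_rows[s]["trait_interactions"] = {k: float(v) for k, v in inter.items()}
            summary_rows[s]["loss_predictors"] = loss_traits
        return traits, reg

    tr = run_stage("traits", stage_traits)
    traits, trait_reg = tr if tr else (None, None)

    # ---- loss weighting ------------------------------------------------
    def stage_loss():
        lw = loss_weights(responses, z_threshold=config.z_threshold, dominance=config.dominance)
        lw.to_csv(out / "loss_weights.tsv", sep="\t", index=False)
        spec = specificity_summary(lw)
        spec["table"].to_csv(out / "loss_specificity.tsv", sep="\t", index=False)
        for s in STRESS_COLUMNS:
            row = spec["table"].set_index("stress").loc[s]
            summary_rows[s]["exclusive_loss_n"] = int(row["n_exclusive"])
            summary_rows[s]["exclusive_loss_prop"] = float(row["proportion"])
        return lw, spec

    ls = run_stage("loss", stage_loss)
    lw, spec = ls if ls else (None, None)

    # ---- selection -----------------------------------------------------
    def stage_selection():
        strata = stratify_genes_by_z(
            responses, n_per_cat=config.n_per_cat,
            neutral_band=config.neutral_band, seed=config.seed + 11,
        )
        strata.to_csv(out / "z_strata.tsv", sep="\t", index=False)
        summaries = data["gene_dnds"]
        strata_m = strata[strata["gene_id"].isin(summaries["gene_id"])]
        purifying = fit_purifying_model(summaries, strata_m)
        positive = fit_positive_selection_model(summaries, strata_m)
        pop = population_dnds_model(data["pop_dnds"], stress)
        purifying["coefficients"].to_csv(out / "purifying_model.tsv", sep="\t")
        positive["coefficients"].to_csv(out / "positive_model.tsv", sep="\t")
        pop["coefficients"].to_csv(out / "population_dnds_model.tsv", sep="\t")
        for s in STRESS_COLUMNS:
            row = pop["coefficients"].loc[s]
            summary_rows[s]["dnds_slope"] = float(row["coef"])
            summary_rows[s]["dnds_p"] = float(row["p"])
        return purifying, positive, pop

    sel = run_stage("selection", stage_selection)
    purifying, positive, pop_fit = sel if sel else (None, None, None)

    # ---- fst -----------------------------------------------------------
    def stage_fst():
        bins = bin_samples_by_stress(stress, k=config.bins_k)
        bins.to_csv(out / "stress_bins.tsv", sep="\t", index=False)
        pairs = pairwise_fst(data["snp"], bins, stress)
        pairs.to_csv(out / "fst_pairs.tsv", sep="\t", index=False)
        reg = fst_stress_regression(
            pairs, stress, n_perm=config.n_perm, seed=config.seed + 13,
            snp=data["snp"], bins_k=config.bins_k,
        )
        reg.to_csv(out / "fst_regression.tsv", sep="\t", index=False)
        for s in STRESS_COLUMNS:
            row = reg.set_index("term").loc[s]
            summary_rows[s]["fst_slope"] = float(row["slope"])
            summary_rows[s]["fst_p_perm"] = float(row["p_perm"])
        return bins, pairs, reg

    fst_res = run_stage("fst", stage_fst)
    bins, fst_pairs, fst_reg = fst_res if fst_res else (None, None, None)

    # ---- smoothing -----------------------------------------------------
    def stage_smoothing():
        gmap = data["genome_map"]
        L = float(gmap["genome_length"].iloc[0])
        acc = gmap[gmap["label"] == "accessory"].merge(
            responses[responses["status"] == "ok"], on="gene_id"
        )
        core_pos = gmap.loc[gmap["label"] == "core", "position"].to_numpy(dtype=float)
        tracks, hotspots, coloc = {}, {}, {}
        for s in STRESS_COLUMNS:
            track = fit_circular_smoother(
                acc["position"].to_numpy(dtype=float),
                acc[f"z_{s}"].to_numpy(dtype=float),
                L,
                max_train=config.smoother_max_train,
            )
            spio.write_track(track, out / f"z_track_{s}.tsv")
            hs = detect_retention_hotspots(track)
            hs.to_csv(out / f"hotspots_{s}.tsv", sep="\t", index=False)
            tracks[s] = track
            hotspots[s] = hs
            if len(hs) and len(core_pos):
                coloc[s] = colocation_test(
                    hs, core_pos, L, n_perm=config.colocation_perms,
                    seed=config.seed + 17,
                )
            else:
                coloc[s] = {"jaccard": np.nan, "p_perm": np.nan, "n_perm": 0}
        for s in STRESS_COLUMNS:
            summary_rows[s]["hotspot_core_jaccard"] = coloc[s]["jaccard"]
            summary_rows[s]["hotspot_core_p"] = coloc[s]["p_perm"]
        return tracks, hotspots, coloc

    sm = run_stage("smoothing", stage_smoothing)
    tracks, hotspots, coloc = sm if sm else (None, None, None)

    # ---- report --------------------------------------------------------
    report["summary"] = [summary_rows[s] for s in STRESS_COLUMNS]
    report["total_time_s"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    results = {
        "report": report,
        "stress": stress,
        "matrix": matrix,
        "filtered": filtered,
        "richness_fit": rich_fit,
        "diversity_fit": div_fit,
        "responses": responses,
        "z_summary": zsum,
        "traits": traits,
        "trait_regression": trait_reg,
        "loss_weights": lw,
        "specificity": spec,
        "purifying": purifying,
        "positive": positive,
        "population_dnds": pop_fit,
        "fst_bins": bins,
        "fst_pairs": fst_pairs,
        "fst_regression": fst_reg,
        "tracks": tracks,
        "hotspots": hotspots,
        "colocation": coloc,
    }
    if "truth" in data:
        results["truth"] = data["truth"]
    return results
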