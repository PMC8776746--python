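"""Stress-stratified pairwise Fst between soil-sample populations.

Soil samples are grouped into k environmental-stress bins (Ward clustering in
the 4-D stress space with greedy size rebalancing), and pairwise Fst is
computed only between samples in the same bin, so that Fst comparisons are
made between environmentally similar populations and the residual Fst-stress
relationship reflects the gradient rather than gross habitat turnover.

Fst uses a Hudson-style estimator for haploid data: per locus the
within-population gene diversity Hw = 2*p*(1-p)*n/(n-1) (unbiased, averaged
over the two populations) and the between-population diversity
Hb = pa*(1-pb) + pb*(1-pa); loci are combined as a ratio of averages,
F = 1 - mean(Hw)/mean(Hb).  Loci monomorphic in both populations are
excluded.  Negative per-pair values are retained by default (unbiased for
the downstream regression).

Significance of the Fst ~ mean-stress regression uses a permutation test
that permutes whole stress profiles across soil samples (respecting the
dependence structure of pairwise data and preserving stress collinearity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from stresspan.environment import STRESS_COLUMNS


@dataclass
class SNPMatrix:
    """Binary haploid SNP genotypes: strains x loci, with missing as NaN."""

    strains: list[str]
    loci: list[str]
    genotypes: np.ndarray  # float array with values {0, 1, nan}
    sample_of: dict[str, str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.strains), len(self.loci)):
            raise ValueError("genotype shape does not match strain/locus lists")
        vals = self.genotypes[np.isfinite(self.genotypes)]
        if vals.size and not np.all((vals == 0) | (vals == 1)):
            raise ValueError("genotypes must be 0/1/missing")
        unmapped = [s for s in self.strains if s not in self.sample_of]
        if unmapped:
            raise ValueError(f"strains without a soil sample: {unmapped[:5]}")


def bin_samples_by_stress(stress: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Assign soil samples to k stress bins (balanced Ward clusters).

    Ward hierarchical clustering on Euclidean distance in the 4-D stress
    space, cut to k clusters, then greedily rebalanced: samples from
    over-full clusters move to the nearest (by centroid) under-full cluster
    until sizes differ by at most one.  The result carries the within/between
    mean-distance ratio in ``.attrs["distance_ratio"]`` (must be < 1).
    """
    X = stress.loc[:, list(STRESS_COLUMNS)].to_numpy(dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    lab = _ward_balanced_labels(X, k)
    D = squareform(pdist(X))
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(n, 1)
    within = D[iu][same[iu]]
    between = D[iu][~same[iu]]
    ratio = within.mean() / between.mean() if len(between) else np.nan
    out = pd.DataFrame({"sample_id": stress["sample_id"].to_numpy(), "bin_id": lab})
    out.attrs["distance_ratio"] = float(ratio)
    return out


def _pop_freqs(snp: SNPMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-sample allele frequencies and effective sizes at every locus."""
    samples = sorted(set(snp.sample_of[s] for s in snp.strains))
    G = snp.genotypes
    freqs = np.empty((len(samples), len(snp.loci)))
    sizes = np.empty((len(samples), len(snp.loci)))
    strain_samples = np.asarray([snp.sample_of[s] for s in snp.strains])
    for i, samp in enumerate(samples):
        g = G[strain_samples == samp]
        valid = np.isfinite(g)
        cnt = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freqs[i] = np.where(cnt > 0, np.nansum(g, axis=0) / np.maximum(cnt, 1), np.nan)
        sizes[i] = cnt
    return samples, freqs, sizes


def hudson_fst(pa, pb, na, nb) -> float:
    """Hudson ratio-of-averages Fst for one haploid population pair.

    ``pa``/``pb`` are per-locus allele frequencies, ``na``/``nb`` per-locus
    haploid sample sizes.  Returns NaN when no usable polymorphic locus.
    """
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    na, nb = np.asarray(na, float), np.asarray(nb, float)
    usable = np.isfinite(pa) & np.isfinite(pb) & (na >= 2) & (nb >= 2)
    pa, pb, na, nb = pa[usable], pb[usable], na[usable], nb[usable]
    hw = pa * (1 - pa) * na / (na - 1) + pb * (1 - pb) * nb / (nb - 1)  # = mean of 2p(1-p)*n/(n-1)
    hb = pa * (1 - pb) + pb * (1 - pa)
    poly = (hb > 0) | (hw > 0)
    if not poly.any():
        return np.nan
    hw_bar = hw[poly].mean()
    hb_bar = hb[poly].mean()
    if hb_bar <= 0:
        return np.nan
    return float(1.0 - hw_bar / hb_bar)


def pairwise_fst(
    snp: SNPMatrix,
    bins: pd.DataFrame,
    stress: pd.DataFrame | None = None,
    min_strains: int = 2,
) -> pd.DataFrame:
    """Hudson Fst for every within-bin pair of soil samples.

    Returns a row per pair with fst, n_loci_used and, when ``stress`` is
    given, the pair's mean stress 4-vector (elementwise mean of the two
    samples' profiles).  Pairs with no usable locus get fst = NaN and are
    flagged by ``usable = False``.
    """
    samples, freqs, sizes = _pop_freqs(snp)
    sample_idx = {s: i for i, s in enumerate(samples)}
    bin_of = dict(zip(bins["sample_id"], bins["bin_id"]))
    stress_of = None
    if stress is not None:
        stress_of = {
            r["sample_id"]: np.array([r[s] for s in STRESS_COLUMNS])
            for _, r in stress.iterrows()
        }
    pair_list = []
    for b in sorted(set(bin_of.values())):
        members = [s for s in samples if bin_of.get(s) == b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, c = members[i], members[j]
                ia, ic = sample_idx[a], sample_idx[c]
                if sizes[ia].max() < min_strains or sizes[ic].max() < min_strains:
                    continue
                pair_list.append((a, c, b, ia, ic))
    if not pair_list:
        return pd.DataFrame(
            columns=["sample_a", "sample_b", "bin_id", "fst", "n_loci_used", "usable"]
        )
    ia = np.asarray([p[3] for p in pair_list])
    ib = np.asarray([p[4] for p in pair_list])
    fst_vals = _fst_matrix(freqs, sizes, ia, ib)
    n_loci = (np.isfinite(freqs[ia]) & np.isfinite(freqs[ib])).sum(axis=1)
    out = pd.DataFrame(
        {
            "sample_a": [p[0] for p in pair_list],
            "sample_b": [p[1] for p in pair_list],
            "bin_id": [p[2] for p in pair_list],
            "fst": fst_vals,
            "n_loci_used": n_loci.astype(int),
            "usable": np.isfinite(fst_vals),
        }
    )
    if stress_of is not None:
        ms = np.vstack(
            [0.5 * (stress_of[p[0]] + stress_of[p[1]]) for p in pair_list]
        )
        for j, s_name in enumerate(STRESS_COLUMNS):
            out[f"mean_{s_name}"] = ms[:, j]
    return out


def _fst_matrix(freqs: np.ndarray, sizes: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Vectorized Hudson Fst for many population pairs at once."""
    pa, pb = freqs[ia], freqs[ib]
    na, nb = sizes[ia], sizes[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = pa * (1 - pa) * na / np.maximum(na - 1, 1) + pb * (1 - pb) * nb / np.maximum(nb - 1, 1)
        hb = pa * (1 - pb) + pb * (1 - pa)
    usable = np.isfinite(pa) & np.isfinite(pb) & (na >= 2) & (nb >= 2)
    poly = usable & ((hb > 0) | (hw > 0))
    hw_sum = np.where(poly, hw, 0.0).sum(axis=1)
    hb_sum = np.where(poly, hb, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hb_sum > 0, 1.0 - hw_sum / np.maximum(hb_sum, 1e-300), np.nan)


def _within_bin_pairs(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = [], []
    for b in np.unique(lab):
        members = np.flatnonzero(lab == b)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ia.append(members[i])
                ib.append(members[j])
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def _ward_balanced_labels(X: np.ndarray, k: int) -> np.ndarray:
    """Ward labels cut to k clusters, greedily rebalanced to sizes within 1."""
    n = len(X)
    lab = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust") - 1
    target_hi = int(np.ceil(n / k))
    target_lo = int(np.floor(n / k))
    for _ in range(n):
        sizes = np.bincount(lab, minlength=k)
        over = np.flatnonzero(sizes > target_hi)
        under = np.flatnonzero(sizes < target_lo)
        if len(over) == 0 and len(under) == 0:
            break
        donors = over if len(over) else np.flatnonzero(sizes == sizes.max())
        receivers = under if len(under) else np.flatnonzero(sizes == sizes.min())
        centroids = np.vstack([X[lab == c].mean(axis=0) for c in range(k)])
        best = None
        for c in donors:
            members = np.flatnonzero(lab == c)
            d = np.linalg.norm(X[members][:, None, :] - centroids[receivers][None, :, :], axis=2)
            pos = np.unravel_index(np.argmin(d), d.shape)
            cand = (d[pos], members[pos[0]], receivers[pos[1]])
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            break
        lab[best[1]] = best[2]
        sizes = np.bincount(lab, minlength=k)
        if sizes.max() - sizes.min() <= 1:
            break
    return lab


def _ols_t(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and t statistics of an OLS fit (intercept included in X)."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    return beta, t


def fst_stress_regression(
    pairs: pd.DataFrame | None,
    stress: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    snp: SNPMatrix | None = None,
    bins_k: int = 5,
) -> pd.DataFrame:
    """OLS of pairwise Fst on the four mean-stress covariates, permutation p-values.

    The null permutes the assignment of whole stress 4-vectors to soil
    samples (preserving stress collinearity and the shared-sample dependence
    among pairs) and uses the add-one two-sided estimator
    p = (1 + #{|t*| >= |t|}) / (n_perm + 1).

    Two permutation schemes:

    * ``snp`` given (preferred) — the *whole procedure* (stress binning, pair
      formation, Fst, regression) is recomputed per permutation.  Because the
      within-bin pair set itself depends on the stress assignment, this is the
      exact test of sample exchangeability; re-using the observed pair set
      while permuting stress is mildly anti-conservative.
    * ``snp`` omitted — the observed pair set and Fst values are held fixed
      and only pair mean stresses are recomputed (cheaper; adequate when
      pairs are not restricted to stress bins).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples = list(stress["sample_id"])
    S = stress.loc[:, list(STRESS_COLUMNS)].to_numpy(dtype=float)
    idx = {s: i for i, s in enumerate(samples)}
    terms = ["intercept"] + list(STRESS_COLUMNS)

    if snp is not None:
        pop_samples, freqs, sizes = _pop_freqs(snp)
        order = [pop_samples.index(s) for s in samples]
        freqs, sizes = freqs[order], sizes[order]
        # pair Fst does not depend on the stress assignment: precompute the
        # full sample x sample matrix once; permutations only re-pair
        n_s = len(samples)
        iu_a, iu_b = np.triu_indices(n_s, 1)
        F_full = np.full((n_s, n_s), np.nan)
        F_full[iu_a, iu_b] = _fst_matrix(freqs, sizes, iu_a, iu_b)
        F_full[iu_b, iu_a] = F_full[iu_a, iu_b]

        def statistic(Sm):
            lab = _ward_balanced_labels(Sm, bins_k)
            ia, ib = _within_bin_pairs(lab)
            y = F_full[ia, ib]
            good = np.isfinite(y)
            M = 0.5 * (Sm[ia[good]] + Sm[ib[good]])
            X = np.column_stack([np.ones(good.sum()), M])
            return _ols_t(X, y[good]), good.sum()

        (beta_obs, t_obs), n_pairs = statistic(S)
        if n_pairs < 10:
            raise ValueError("need at least 10 usable pairs for the regression")
        exceed = np.zeros(5)
        for _ in range(n_perm):
            (_, t_star), _ = statistic(S[rng.permutation(len(samples))])
            exceed += np.abs(t_star) >= np.abs(t_obs) - 1e-12
        pvals = (1.0 + exceed) / (n_perm + 1.0)
        return pd.DataFrame({"term": terms, "slope": beta_obs, "t": t_obs, "p_perm": pvals})

    pairs = pairs[pairs["usable"]].reset_index(drop=True)
    if len(pairs) < 10:
        raise ValueError("need at least 10 usable pairs for the regression")
    ia = np.asarray([idx[s] for s in pairs["sample_a"]])
    ib = np.asarray([idx[s] for s in pairs["sample_b"]])
    y = pairs["fst"].to_numpy(dtype=float)

    def design(Sm):
        M = 0.5 * (Sm[ia] + Sm[ib])
        return np.column_stack([np.ones(len(M)), M])

    X = design(S)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: mean-stress covariates are collinear")
    beta_obs, t_obs = _ols_t(X, y)
    exceed = np.zeros(5)
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        _, t_star = _ols_t(design(S[perm]), y)
        exceed += np.abs(t_star) >= np.abs(t_obs) - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"term": terms, "slope": beta_obs, "t": t_obs, "p_perm": pvals})
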