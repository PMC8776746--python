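"""Generalized linear mixed models via penalized IRLS + Laplace approximation.

Implements the two model families the analysis needs:

* binomial (logit link) — per-gene presence/absence occurrence models;
* negative binomial NB2 (log link, variance mu + alpha*mu^2) — gene-richness
  and pangenome-diversity count models.

Random effects are independent Gaussian intercepts for one or more grouping
factors (site, soil sample), with one variance per factor.  For fixed
variance parameters the joint mode of (beta, u) is found by penalized
iteratively-reweighted least squares (Fisher scoring with step halving); the
marginal likelihood of the variance parameters (and NB dispersion) is the
Laplace approximation at that mode and is maximized by Nelder-Mead on the log
scale.  Fixed-effect standard errors come from the beta block of the inverse
joint Hessian.  With no grouping factors the same machinery reduces to an
ordinary GLM fit (used as the fallback tier and as the zero-variance limit).

This is deliberately a small, fast implementation specialised to nested
random intercepts — adequate for the hierarchical sampling design (sites and
soil samples) and cheap enough to run per gene across thousands of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_ETA_CLIP = 30.0

# fit_status values
OK = "ok"
FALLBACK = "no_random_effects_fallback"
SEPARATION = "separation"
FAILED = "failed"


@dataclass
class MixedModelFit:
    """Result of a (mixed) GLM fit.

    ``coefficients`` / ``standard_errors`` / ``pvalues`` are indexed by term
    name.  ``random_effect_sds`` maps grouping-factor name to the estimated
    random-intercept SD (empty for plain GLM fits).  ``dispersion`` is the
    NB2 alpha (variance = mu + alpha mu^2); None for binomial models.
    """

    coefficients: pd.Series
    standard_errors: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    random_effect_sds: dict[str, float]
    dispersion: float | None
    loglik: float
    converged: bool
    n_obs: int
    status: str = OK
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# family functions: given eta (and NB size k) return mu, score dl/deta,
# Fisher weight -E[d2l/deta2], and the log-likelihood contribution
# ---------------------------------------------------------------------------

def _binom_parts(y, eta, k=None):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = special.expit(eta)
    score = y - mu
    w = mu * (1.0 - mu)
    ll = y * eta - np.logaddexp(0.0, eta)
    return mu, score, w, ll


def _negbin_parts(y, eta, k):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    score = (y - mu) * k / (k + mu)
    w = mu * k / (k + mu)
    ll = (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * np.log(k / (k + mu))
        + y * (eta - np.log(k + mu))
    )
    return mu, score, w, ll


_FAMILIES = {"binomial": _binom_parts, "negbin": _negbin_parts}


def _pirls(y, Xf, penalty, family_fn, k, theta0, max_iter=60, tol=1e-9):
    """Maximize sum ll(eta) - 0.5 theta' P theta; return mode, Hessian, value."""
    theta = theta0.copy()
    eta = Xf @ theta
    _, score, w, ll = family_fn(y, eta, k)
    obj = ll.sum() - 0.5 * (penalty * theta**2).sum()
    H = None
    converged = False
    for _ in range(max_iter):
        grad = Xf.T @ score - penalty * theta
        H = (Xf * w[:, None]).T @ Xf
        H[np.diag_indices_from(H)] += penalty + 1e-10
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return theta, H, obj, False
        # step halving on the penalized objective
        step = 1.0
        for _ in range(25):
            cand = theta + step * delta
            eta = Xf @ cand
            _, score_c, w_c, ll_c = family_fn(y, eta, k)
            obj_c = ll_c.sum() - 0.5 * (penalty * cand**2).sum()
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12:
                break
            step *= 0.5
        else:
            break
        improve = obj_c - obj
        theta, score, w, obj = cand, score_c, w_c, obj_c
        if improve < tol * (abs(obj) + 1.0) and np.abs(grad).max() < 1e-5 * (1 + abs(obj)):
            converged = True
            break
    # final Hessian at the mode
    H = (Xf * w[:, None]).T @ Xf
    H[np.diag_indices_from(H)] += penalty + 1e-10
    return theta, H, obj, converged


def _pirls_grouped(y, X, codes, qs, prec, family_fn, k, theta0, max_iter=60, tol=1e-9):
    """Grouped-structure penalized IRLS: Hessian assembled via bincount/add.at.

    ``codes`` is a list of per-factor integer code arrays, ``qs`` their level
    counts, ``prec`` the per-factor precision (1/sd^2).  Functionally
    identical to :func:`_pirls` on the stacked [X | Z] design but avoids
    materialising Z: per-iteration cost is O(n p^2 + q) instead of
    O(n (p+q)^2).
    """
    n, p = X.shape
    q = int(sum(qs))
    offs = np.concatenate([[0], np.cumsum(qs)]).astype(int)
    pen = np.concatenate([np.zeros(p)] + [np.full(qi, pr) for qi, pr in zip(qs, prec)])
    theta = theta0.copy()

    def eta_of(th):
        e = X @ th[:p]
        for f, c in enumerate(codes):
            e = e + th[p + offs[f] : p + offs[f + 1]][c]
        return e

    def obj_of(th, ll):
        return ll.sum() - 0.5 * (pen * th**2).sum()

    eta = eta_of(theta)
    _, score, w, ll = family_fn(y, eta, k)
    obj = obj_of(theta, ll)
    m = p + q
    H = np.zeros((m, m))
    converged = False
    # combined cross-factor indices are iteration-invariant
    cross_idx = {
        (f, g): codes[f] * qs[g] + codes[g]
        for f in range(len(codes))
        for g in range(f)
    }

    def build_H(w):
        H.fill(0.0)
        Xw = X * w[:, None]
        H[:p, :p] = X.T @ Xw
        for f, c in enumerate(codes):
            a, b = p + offs[f], p + offs[f + 1]
            for j in range(p):  # X' W Z_f block, one bincount per column
                H[j, a:b] = np.bincount(c, weights=Xw[:, j], minlength=qs[f])
            H[a:b, :p] = H[:p, a:b].T
            H[a:b, a:b][np.diag_indices(qs[f])] = np.bincount(c, weights=w, minlength=qs[f])
            for g in range(f):
                a2, b2 = p + offs[g], p + offs[g + 1]
                M = np.bincount(
                    cross_idx[(f, g)], weights=w, minlength=qs[f] * qs[g]
                ).reshape(qs[f], qs[g])
                H[a:b, a2:b2] = M
                H[a2:b2, a:b] = M.T
        H[np.diag_indices(m)] += pen + 1e-10
        return H

    for _ in range(max_iter):
        grad = np.empty(m)
        grad[:p] = X.T @ score
        for f, c in enumerate(codes):
            grad[p + offs[f] : p + offs[f + 1]] = np.bincount(c, weights=score, minlength=qs[f])
        grad -= pen * theta
        build_H(w)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return theta, H, obj, False
        step = 1.0
        for _ in range(25):
            cand = theta + step * delta
            eta = eta_of(cand)
            _, score_c, w_c, ll_c = family_fn(y, eta, k)
            obj_c = obj_of(cand, ll_c)
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12:
                break
            step *= 0.5
        else:
            break
        improve = obj_c - obj
        theta, score, w, obj = cand, score_c, w_c, obj_c
        if improve < tol * (abs(obj) + 1.0) and np.abs(grad).max() < 1e-5 * (1 + abs(obj)):
            converged = True
            break
    build_H(w)
    return theta, H, obj, converged


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    family: str = "binomial",
    term_names: list[str] | None = None,
    start_sd: float = 0.3,
    nm_maxfev: int | None = None,
    fixed_sds: dict[str, float] | None = None,
    start_sds: dict[str, float] | None = None,
) -> MixedModelFit:
    """Fit a GLMM with independent random intercepts per grouping factor.

    Parameters
    ----------
    y
        Response vector (0/1 for binomial; non-negative integers for negbin).
    X
        (n, p) fixed-effects design matrix (include the intercept column).
    groups
        Mapping factor name -> integer codes (0..q-1) per observation.  Empty
        or None gives a plain GLM.  Factors with a single level are dropped
        with a fallback status.
    family
        "binomial" or "negbin".
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "negbin":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negative-binomial response must be non-negative integers")
    family_fn = _FAMILIES[family]
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]

    groups = dict(groups or {})
    status = OK
    for name in list(groups):
        if np.asarray(groups[name]).max() == 0:
            del groups[name]  # single level: variance inestimable
            status = FALLBACK

    factor_names = list(groups)
    codes = [np.asarray(groups[name]) for name in factor_names]
    qs = [int(c.max()) + 1 for c in codes]
    owner = np.concatenate(
        [np.full(qi, fi) for fi, qi in enumerate(qs)]
    ).astype(int) if qs else np.asarray([], dtype=int)
    q = int(sum(qs))

    # starting values: intercept at link(mean), slopes 0
    theta0 = np.zeros(p + q)
    ybar = float(np.clip(y.mean(), 1e-6, None))
    if family == "binomial":
        pbar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        theta0[0] = np.log(pbar / (1 - pbar))
        k0 = None
    else:
        theta0[0] = np.log(max(ybar, 1e-3))
        v = y.var()
        alpha0 = max((v - ybar) / max(ybar**2, 1e-12), 1e-3)
        k0 = 1.0 / alpha0

    # ----- plain GLM path (also the fallback target) --------------------
    def fit_glm(k_fixed=None):
        pen = np.zeros(p)
        if family == "binomial":
            th, H, obj, conv = _pirls(y, X, pen, family_fn, None, theta0[:p].copy())
            return th, H, obj, conv, None
        # negbin: profile the size parameter k
        th_cell = [theta0[:p].copy()]

        def nll(logk):
            th, _, obj, _ = _pirls(y, X, pen, family_fn, np.exp(logk[0]), th_cell[0])
            th_cell[0] = th
            return -obj

        res = optimize.minimize_scalar(
            lambda lk: nll([lk]), bounds=(np.log(1e-2), np.log(1e4)), method="bounded",
            options={"xatol": 1e-3},
        )
        k_hat = float(np.exp(res.x))
        th, H, obj, conv = _pirls(y, X, pen, family_fn, k_hat, th_cell[0])
        return th, H, obj, conv, k_hat

    if q == 0:
        theta, H, obj, conv, k_hat = fit_glm()
        return _pack(
            theta, H, obj, conv, p, term_names, {}, {}, k_hat, n, status, family,
            df=max(n - p, 1),
        )

    # ----- Laplace marginal likelihood over variance params -------------
    n_fac = len(factor_names)
    warm = [theta0.copy()]

    def neg_laplace(params):
        log_sd = params[:n_fac]
        sd = np.exp(np.clip(log_sd, -8.0, 3.0))
        k = np.exp(np.clip(params[n_fac], np.log(1e-2), np.log(1e4))) if family == "negbin" else None
        prec_fac = 1.0 / np.maximum(sd**2, 1e-12)
        theta, H, obj_pen, conv = _pirls_grouped(
            y, X, codes, qs, prec_fac, family_fn, k, warm[0]
        )
        if not np.all(np.isfinite(theta)):
            return 1e10
        warm[0] = theta
        u = theta[p:]
        Huu = H[p:, p:]
        sign, logdet_h = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e10
        logdet_d = 2.0 * np.sum(np.log(sd[owner]))
        # obj_pen already equals ll(eta_hat) - 0.5 u' D^-1 u
        marg = obj_pen - 0.5 * (logdet_h + logdet_d)
        return -marg

    if fixed_sds is not None:
        # variance parameters pinned (e.g. 0 for the GLM limit); only the NB
        # size is profiled when applicable
        log_sd_fixed = np.log(np.maximum([fixed_sds[f] for f in factor_names], 3e-4))
        if family == "negbin":
            res_k = optimize.minimize_scalar(
                lambda lk: neg_laplace(np.append(log_sd_fixed, lk)),
                bounds=(np.log(1e-2), np.log(1e4)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            res_x = np.append(log_sd_fixed, res_k.x)
        else:
            res_x = log_sd_fixed
        res = optimize.OptimizeResult(x=res_x, fun=neg_laplace(res_x), success=True)
    else:
        if start_sds is not None:
            x0 = np.log(
                np.clip([start_sds.get(f, start_sd) for f in factor_names], 0.02, 3.0)
            )
        else:
            x0 = np.full(n_fac, np.log(start_sd))
        if family == "negbin":
            x0 = np.append(x0, np.log(k0))
        maxfev = nm_maxfev or (50 * len(x0))
        res = optimize.minimize(
            neg_laplace,
            x0,
            method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-3, "maxfev": maxfev},
        )
    log_sd = res.x[:n_fac]
    sd = np.exp(np.clip(log_sd, -8.0, 3.0))
    k_hat = float(np.exp(np.clip(res.x[n_fac], np.log(1e-2), np.log(1e4)))) if family == "negbin" else None

    prec_fac = 1.0 / np.maximum(sd**2, 1e-12)
    theta, H, obj_pen, conv = _pirls_grouped(
        y, X, codes, qs, prec_fac, family_fn, k_hat, warm[0]
    )
    re_sds = {name: float(s) for name, s in zip(factor_names, sd)}
    re_modes = {}
    for fi, name in enumerate(factor_names):
        re_modes[name] = theta[p:][owner == fi]
    marg_ll = -neg_laplace(res.x)
    # convergence judged at the inner mode; Nelder-Mead routinely stops on
    # maxfev with the variance params already located to ample precision.
    # p-values use a t reference with between-cluster df at the finest
    # grouping level (covariates are constant within soil samples), the
    # standard finite-sample correction to the anti-conservative normal Wald
    df = max(max(qs) - p, 1)
    fit = _pack(
        theta, H, marg_ll, conv, p, term_names, re_sds, re_modes,
        k_hat, n, status, family, df=df,
    )
    return fit


def _pack(theta, H, loglik, converged, p, term_names, re_sds, re_modes, k_hat, n, status, family, df=None):
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    beta = theta[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    if df is None:
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(z), df)
    idx = pd.Index(term_names)
    alpha = (1.0 / k_hat) if k_hat else None
    # crude separation heuristic: runaway coefficients on the logit scale
    if family == "binomial" and np.any(np.abs(beta) > 12.0):
        status = SEPARATION
        converged = False
    return MixedModelFit(
        coefficients=pd.Series(beta, index=idx),
        standard_errors=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        random_effect_sds=re_sds,
        dispersion=alpha,
        loglik=float(loglik),
        converged=bool(converged),
        n_obs=int(n),
        status=status,
        random_effects=re_modes,
    )
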