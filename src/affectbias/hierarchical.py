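"""Hierarchical Bayesian estimation by adaptive Metropolis-within-Gibbs.

Subject-level parameters live on an unconstrained scale where the population
distribution is normal, ``theta_ip ~ N(mu_p, sigma_p)``.  Componentwise
random-walk Metropolis updates (vectorised across subjects, so one
behavioural-likelihood evaluation updates every subject at once) alternate
with conjugate Gibbs draws for the group mean and variance:

* ``mu_p ~ N(0, 5^2)``
* ``sigma_p^2 ~ Inv-Gamma(1.5, 0.5)``

Proposal scales adapt per (subject, parameter) coordinate during warmup
(Robbins-Monro on a 0.44 acceptance target) and are frozen afterwards.

The joint two-session variant models each parameter's subject-level pair
``(theta_ip1, theta_ip2)`` as bivariate normal with a per-parameter
cross-session correlation ``r_p`` under a uniform (LKJ shape 1) prior;
session means and variances keep the priors above so the implied
single-session marginal model is unchanged.

Convergence is summarised by split-chain R-hat on the group-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import FitResult
from .transforms import ParamTransform, to_native_matrix

# group-level priors (unconstrained scale)
_MU_PRIOR_SD = 5.0
_SIGMA2_PRIOR_A = 1.5
_SIGMA2_PRIOR_B = 0.5

_TARGET_ACC = 0.44  # componentwise random-walk optimum


@dataclass
class McmcConfig:
    """Sampler settings; defaults favour quick, reproducible fits."""

    chains: int = 2
    warmup: int = 400
    draws: int = 400
    seed: int = 0
    rhat_threshold: float = 1.05
    thin_theta: int = 1  # thinning applied when storing subject-level draws
    progress: bool = False


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for a (chains, draws) array."""
    c, d = x.shape
    half = d // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    w = segs.var(axis=1, ddof=1).mean()
    b = half * segs.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _sample_group(rng, theta_col: np.ndarray, sigma2: float) -> tuple[float, float]:
    """Conjugate draw of (mu, sigma2) for one parameter column."""
    n = theta_col.size
    prec = n / sigma2 + 1.0 / _MU_PRIOR_SD**2
    mean = (theta_col.sum() / sigma2) / prec
    mu = rng.normal(mean, np.sqrt(1.0 / prec))
    a = _SIGMA2_PRIOR_A + 0.5 * n
    b = _SIGMA2_PRIOR_B + 0.5 * np.sum((theta_col - mu) ** 2)
    sigma2_new = b / rng.gamma(a)
    return mu, sigma2_new


def fit_hierarchical(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    transforms: Sequence[ParamTransform],
    n_subjects: int,
    mcmc: McmcConfig,
    model_id: str,
    subject_ids: Sequence,
    data_hash: str,
    pointwise_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    init_mu: np.ndarray | None = None,
) -> FitResult:
    """Fit a hierarchical model to one session of behavioural data.

    ``loglik_fn`` maps a native-scale (n_subjects, P) parameter matrix to the
    per-subject log-likelihood vector; ``pointwise_fn`` (optional) returns a
    flattened per-trial log-likelihood vector used for information criteria.
    """
    P = len(transforms)
    n = n_subjects
    root = np.random.SeedSequence(mcmc.seed)
    chain_seeds = root.spawn(mcmc.chains)

    mu_draws = np.empty((mcmc.chains, mcmc.draws, P))
    sigma_draws = np.empty((mcmc.chains, mcmc.draws, P))
    n_theta = (mcmc.draws + mcmc.thin_theta - 1) // mcmc.thin_theta
    theta_draws = np.empty((mcmc.chains, n_theta, n, P))

    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        mu = np.zeros(P) if init_mu is None else np.array(init_mu, dtype=float)
        sigma2 = np.ones(P)
        theta = mu + 0.2 * rng.standard_normal((n, P))
        cur_ll = loglik_fn(to_native_matrix(theta, transforms))
        log_step = np.full((n, P), np.log(0.5))
        shift_step = np.full(P, np.log(0.1))
        scale_step = np.full(P, np.log(0.1))
        subj_scale = np.full(n, np.log(0.3))
        block_scale = np.log(0.5)
        theta_hist: list[np.ndarray] = []
        group_hist: list[np.ndarray] = []
        subj_chol: np.ndarray | None = None  # (n, P, P)
        block_chol: np.ndarray | None = None  # (2P, 2P)

        total = mcmc.warmup + mcmc.draws
        kept = 0
        for sweep in range(total):
            adapting = sweep < mcmc.warmup
            gamma = min(0.25, 2.0 / np.sqrt(sweep + 1.0)) if adapting else 0.0

            # componentwise subject-level random walk
            for p in range(P):
                prop = theta.copy()
                prop[:, p] = theta[:, p] + np.exp(log_step[:, p]) * \
                    rng.standard_normal(n)
                new_ll = loglik_fn(to_native_matrix(prop, transforms))
                d_prior = (
                    (theta[:, p] - mu[p]) ** 2 - (prop[:, p] - mu[p]) ** 2
                ) / (2.0 * sigma2[p])
                log_r = new_ll - cur_ll + d_prior
                accept = np.log(rng.random(n)) < log_r
                theta[accept, p] = prop[accept, p]
                cur_ll = np.where(accept, new_ll, cur_ll)
                if adapting:
                    log_step[:, p] += gamma * (accept.astype(float) - _TARGET_ACC)

            # multivariate subject-level move along each subject's adapted
            # posterior covariance (crosses within-subject trade-offs such
            # as learning rate vs sensitivity)
            if subj_chol is not None:
                for _ in range(2):
                    step = np.exp(subj_scale)[:, None] * np.einsum(
                        "ipq,iq->ip", subj_chol, rng.standard_normal((n, P)))
                    prop = theta + step
                    new_ll = loglik_fn(to_native_matrix(prop, transforms))
                    d_prior = np.sum(
                        ((theta - mu) ** 2 - (prop - mu) ** 2)
                        / (2.0 * sigma2), axis=1)
                    accept = np.log(rng.random(n)) < new_ll - cur_ll + d_prior
                    theta[accept] = prop[accept]
                    cur_ll = np.where(accept, new_ll, cur_ll)
                    if adapting:
                        subj_scale += gamma * (accept.astype(float) - 0.234)

            # conjugate group updates
            for p in range(P):
                mu[p], sigma2[p] = _sample_group(rng, theta[:, p], sigma2[p])

            # interweaving: non-centred translation of mu_p (subject
            # z-scores fixed) and joint rescale of (deviations, sigma_p)
            for p in range(P):
                delta = np.exp(shift_step[p]) * rng.standard_normal()
                prop = theta.copy()
                prop[:, p] = theta[:, p] + delta
                new_ll = loglik_fn(to_native_matrix(prop, transforms))
                d_mu = (mu[p] ** 2 - (mu[p] + delta) ** 2) / (
                    2.0 * _MU_PRIOR_SD**2)
                log_r = float(np.sum(new_ll - cur_ll)) + d_mu
                acc = np.log(rng.random()) < log_r
                if acc:
                    theta = prop
                    cur_ll = new_ll
                    mu[p] += delta
                if adapting:
                    shift_step[p] += gamma * (float(acc) - _TARGET_ACC)
            for p in range(P):
                fac = np.exp(np.exp(scale_step[p]) * rng.standard_normal())
                prop = theta.copy()
                prop[:, p] = mu[p] + fac * (theta[:, p] - mu[p])
                new_ll = loglik_fn(to_native_matrix(prop, transforms))
                log_r = (
                    float(np.sum(new_ll - cur_ll))
                    - 2.0 * _SIGMA2_PRIOR_A * np.log(fac)
                    - _SIGMA2_PRIOR_B / sigma2[p] * (1.0 / fac**2 - 1.0)
                )
                acc = np.log(rng.random()) < log_r
                if acc:
                    theta = prop
                    cur_ll = new_ll
                    sigma2[p] *= fac**2
                if adapting:
                    scale_step[p] += gamma * (float(acc) - _TARGET_ACC)

            # non-centred block move over all (mu_p, log sigma_p) with
            # subject z-scores fixed, along the adapted group covariance;
            # crosses group-level ridges (e.g. lapse vs sensitivity)
            if block_chol is not None:
                for _ in range(4):
                    g = (2.38 / np.sqrt(2 * P)) * np.exp(block_scale) * (
                        block_chol @ rng.standard_normal(2 * P))
                    d_mu_vec, d_ls = g[:P], g[P:]
                    fac = np.exp(d_ls)
                    prop = (mu + d_mu_vec)[None, :] + \
                        fac[None, :] * (theta - mu[None, :])
                    new_ll = loglik_fn(to_native_matrix(prop, transforms))
                    log_r = float(np.sum(new_ll - cur_ll))
                    log_r += float(np.sum(
                        (mu**2 - (mu + d_mu_vec) ** 2)
                        / (2.0 * _MU_PRIOR_SD**2)))
                    log_r += float(np.sum(
                        -2.0 * _SIGMA2_PRIOR_A * d_ls
                        - _SIGMA2_PRIOR_B / sigma2 * (1.0 / fac**2 - 1.0)))
                    acc = np.log(rng.random()) < log_r
                    if acc:
                        theta = prop
                        cur_ll = new_ll
                        mu = mu + d_mu_vec
                        sigma2 = sigma2 * fac**2
                    if adapting:
                        block_scale += gamma * (float(acc) - 0.234)

            # covariance adaptation from warmup history
            if adapting:
                group_hist.append(np.concatenate([mu, 0.5 * np.log(sigma2)]))
                theta_hist.append(theta.copy())
                if sweep >= 100 and sweep % 50 == 0:
                    gh = np.array(group_hist[-600:])
                    cov = np.atleast_2d(np.cov(gh.T)) + 1e-8 * np.eye(2 * P)
                    block_chol = np.linalg.cholesky(cov)
                    th = np.array(theta_hist[-600:])  # (h, n, P)
                    dev = th - th.mean(axis=0, keepdims=True)
                    scov = np.einsum("hip,hiq->ipq", dev, dev) / (len(th) - 1)
                    scov += 1e-8 * np.eye(P)[None, :, :]
                    subj_chol = np.linalg.cholesky(scov)

            if not adapting:
                d = sweep - mcmc.warmup
                mu_draws[c, d] = mu
                sigma_draws[c, d] = np.sqrt(sigma2)
                if d % mcmc.thin_theta == 0:
                    theta_draws[c, kept] = theta
                    kept += 1

    # diagnostics on group-level draws
    rhats = {}
    for p, tr in enumerate(transforms):
        rhats[f"mu_{tr.name}"] = split_rhat(mu_draws[:, :, p])
        rhats[f"sigma_{tr.name}"] = split_rhat(sigma_draws[:, :, p])
    max_rhat = float(np.nanmax(list(rhats.values())))
    diagnostics = {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "converged": max_rhat <= mcmc.rhat_threshold,
        "chains": mcmc.chains,
        "warmup": mcmc.warmup,
        "draws": mcmc.draws,
    }

    flat_theta = theta_draws.reshape(-1, n, P)
    native = np.stack(
        [to_native_matrix(flat_theta[d], transforms)
         for d in range(flat_theta.shape[0])]
    )
    subject_means = pd.DataFrame(
        native.mean(axis=0), columns=[tr.name for tr in transforms]
    )
    subject_means.insert(0, "subject", list(subject_ids))

    group_rows = []
    for p, tr in enumerate(transforms):
        group_rows.append({
            "parameter": tr.name,
            "mu_mean": mu_draws[:, :, p].mean(),
            "mu_sd": mu_draws[:, :, p].std(),
            "sigma_mean": sigma_draws[:, :, p].mean(),
            "rhat_mu": rhats[f"mu_{tr.name}"],
        })

    pointwise = None
    if pointwise_fn is not None:
        # thin to at most 200 draws for information criteria
        step = max(1, flat_theta.shape[0] // 200)
        idx = np.arange(0, flat_theta.shape[0], step)
        pw = np.stack(
            [pointwise_fn(to_native_matrix(flat_theta[d], transforms))
             for d in idx]
        )
        pointwise = pw[None, :, :]  # single pseudo-chain

    return FitResult(
        model_id=model_id,
        param_names=[tr.name for tr in transforms],
        subject_ids=list(subject_ids),
        draws={"mu": mu_draws, "sigma": sigma_draws, "theta": theta_draws},
        subject_means=subject_means,
        group_summary=pd.DataFrame(group_rows),
        diagnostics=diagnostics,
        data_hash=data_hash,
        pointwise_loglik=pointwise,
    )


# ---------------------------------------------------------------------------
# joint two-session model with embedded cross-session correlations
# ---------------------------------------------------------------------------

def _bvn_logpdf_terms(z1, z2, r):
    """Standardised bivariate-normal quadratic form + normaliser."""
    om = 1.0 - r * r
    quad = (z1 * z1 - 2.0 * r * z1 * z2 + z2 * z2) / om
    return -0.5 * quad - 0.5 * np.log(om)


def _group_logpost(g: np.ndarray, pairs: np.ndarray) -> float:
    """Log posterior of (mu1, mu2, log s1, log s2, atanh r) given pairs."""
    mu1, mu2, ls1, ls2, zr = g
    r = np.tanh(zr)
    s1, s2 = np.exp(ls1), np.exp(ls2)
    z1 = (pairs[:, 0] - mu1) / s1
    z2 = (pairs[:, 1] - mu2) / s2
    ll = np.sum(_bvn_logpdf_terms(z1, z2, r)) - pairs.shape[0] * (ls1 + ls2)
    lp = -(mu1**2 + mu2**2) / (2.0 * _MU_PRIOR_SD**2)
    for ls in (ls1, ls2):  # Inv-Gamma on sigma^2, with log-scale jacobian
        lp += -2.0 * _SIGMA2_PRIOR_A * ls - _SIGMA2_PRIOR_B * np.exp(-2.0 * ls)
    lp += np.log1p(-r * r)  # uniform prior on r, jacobian of atanh
    return ll + lp


@dataclass
class EmbeddedDraws:
    """Posterior draws from the joint two-session fit."""

    param_names: list[str]
    r: np.ndarray          # (chains, draws, P)
    mu: np.ndarray         # (chains, draws, P, 2)
    sigma: np.ndarray      # (chains, draws, P, 2)
    theta: np.ndarray      # (chains, kept, n, P, 2)
    diagnostics: dict = field(default_factory=dict)


def fit_embedded_hierarchical(
    loglik_fns: Sequence[Callable[[np.ndarray], np.ndarray]],
    transforms: Sequence[ParamTransform],
    n_subjects: int,
    mcmc: McmcConfig,
    init_mu: np.ndarray | None = None,
) -> EmbeddedDraws:
    """Fit both sessions jointly, estimating per-parameter cross-session r.

    ``loglik_fns`` is a pair of per-session likelihood callbacks, each
    mapping a native (n, P) matrix to per-subject log-likelihoods.
    """
    P = len(transforms)
    n = n_subjects
    root = np.random.SeedSequence(mcmc.seed)
    chain_seeds = root.spawn(mcmc.chains)

    r_draws = np.empty((mcmc.chains, mcmc.draws, P))
    mu_draws = np.empty((mcmc.chains, mcmc.draws, P, 2))
    sigma_draws = np.empty((mcmc.chains, mcmc.draws, P, 2))
    n_theta = (mcmc.draws + mcmc.thin_theta - 1) // mcmc.thin_theta
    theta_draws = np.empty((mcmc.chains, n_theta, n, P, 2))

    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        mu0 = np.zeros(P) if init_mu is None else np.asarray(init_mu, float)
        theta = mu0[None, :, None] + 0.2 * rng.standard_normal((n, P, 2))
        group = np.zeros((P, 5))  # mu1, mu2, ls1, ls2, atanh r
        group[:, 0] = group[:, 1] = mu0
        cur_ll = [
            loglik_fns[s](to_native_matrix(theta[:, :, s], transforms))
            for s in (0, 1)
        ]
        log_step = np.full((n, P, 2), np.log(0.5))
        group_step = np.full(P, np.log(0.2))
        shift_step = np.full((P, 2), np.log(0.1))
        scale_step = np.full((P, 2), np.log(0.1))
        recorr_step = np.full(P, np.log(0.3))
        subj_scale = np.full((n, 2), np.log(0.3))
        theta_hist: list[np.ndarray] = []
        group_hist: list[np.ndarray] = []
        subj_chol: np.ndarray | None = None   # (2, n, P, P)
        group_chol: np.ndarray | None = None  # (P, 5, 5)

        def _prior_cols(vals_s, other, p, s):
            """Bivariate-prior terms for session s values of parameter p."""
            o = 1 - s
            mu_s, mu_o = group[p, s], group[p, o]
            sd_s, sd_o = np.exp(group[p, 2 + s]), np.exp(group[p, 2 + o])
            r = np.tanh(group[p, 4])
            return _bvn_logpdf_terms((vals_s - mu_s) / sd_s,
                                     (other - mu_o) / sd_o, r)

        total = mcmc.warmup + mcmc.draws
        kept = 0
        for sweep in range(total):
            adapting = sweep < mcmc.warmup
            gamma = min(0.25, 2.0 / np.sqrt(sweep + 1.0)) if adapting else 0.0

            for s in (0, 1):
                o = 1 - s
                # componentwise subject updates
                for p in range(P):
                    prop = theta[:, :, s].copy()
                    prop[:, p] = theta[:, p, s] + \
                        np.exp(log_step[:, p, s]) * rng.standard_normal(n)
                    new_ll = loglik_fns[s](to_native_matrix(prop, transforms))
                    d_prior = (
                        _prior_cols(prop[:, p], theta[:, p, o], p, s)
                        - _prior_cols(theta[:, p, s], theta[:, p, o], p, s)
                    )
                    log_r = new_ll - cur_ll[s] + d_prior
                    accept = np.log(rng.random(n)) < log_r
                    theta[accept, p, s] = prop[accept, p]
                    cur_ll[s] = np.where(accept, new_ll, cur_ll[s])
                    if adapting:
                        log_step[:, p, s] += gamma * (
                            accept.astype(float) - _TARGET_ACC)
                # multivariate subject move along adapted covariance
                if subj_chol is not None:
                    step = np.exp(subj_scale[:, s])[:, None] * np.einsum(
                        "ipq,iq->ip", subj_chol[s],
                        rng.standard_normal((n, P)))
                    prop = theta[:, :, s] + step
                    new_ll = loglik_fns[s](to_native_matrix(prop, transforms))
                    d_prior = np.zeros(n)
                    for p in range(P):
                        d_prior += (
                            _prior_cols(prop[:, p], theta[:, p, o], p, s)
                            - _prior_cols(theta[:, p, s], theta[:, p, o], p, s)
                        )
                    accept = np.log(rng.random(n)) < new_ll - cur_ll[s] + d_prior
                    theta[accept, :, s] = prop[accept]
                    cur_ll[s] = np.where(accept, new_ll, cur_ll[s])
                    if adapting:
                        subj_scale[:, s] += gamma * (
                            accept.astype(float) - 0.234)
                # non-centred translation: z-scores fixed, so the bivariate
                # prior is invariant; only likelihood and mu prior change
                for p in range(P):
                    delta = np.exp(shift_step[p, s]) * rng.standard_normal()
                    prop = theta[:, :, s].copy()
                    prop[:, p] = theta[:, p, s] + delta
                    new_ll = loglik_fns[s](to_native_matrix(prop, transforms))
                    mu_s = group[p, s]
                    d_mu = (mu_s**2 - (mu_s + delta) ** 2) / (
                        2.0 * _MU_PRIOR_SD**2)
                    log_r = float(np.sum(new_ll - cur_ll[s])) + d_mu
                    acc = np.log(rng.random()) < log_r
                    if acc:
                        theta[:, p, s] = prop[:, p]
                        cur_ll[s] = new_ll
                        group[p, s] += delta
                    if adapting:
                        shift_step[p, s] += gamma * (float(acc) - _TARGET_ACC)
                # non-centred scale: deviations and sigma_{p,s} rescale
                # together (same ratio as the single-session engine)
                for p in range(P):
                    fac = np.exp(np.exp(scale_step[p, s]) *
                                 rng.standard_normal())
                    mu_s = group[p, s]
                    sigma2_s = np.exp(2.0 * group[p, 2 + s])
                    prop = theta[:, :, s].copy()
                    prop[:, p] = mu_s + fac * (theta[:, p, s] - mu_s)
                    new_ll = loglik_fns[s](to_native_matrix(prop, transforms))
                    log_r = (
                        float(np.sum(new_ll - cur_ll[s]))
                        - 2.0 * _SIGMA2_PRIOR_A * np.log(fac)
                        - _SIGMA2_PRIOR_B / sigma2_s * (1.0 / fac**2 - 1.0)
                    )
                    acc = np.log(rng.random()) < log_r
                    if acc:
                        theta[:, p, s] = prop[:, p]
                        cur_ll[s] = new_ll
                        group[p, 2 + s] += np.log(fac)
                    if adapting:
                        scale_step[p, s] += gamma * (float(acc) - _TARGET_ACC)

            # group-level M-H per parameter, along adapted 5-d covariance
            for p in range(P):
                pairs = theta[:, p, :]
                cur_lp = _group_logpost(group[p], pairs)
                for _ in range(3):
                    if group_chol is not None:
                        eps = (2.38 / np.sqrt(5.0)) * (
                            group_chol[p] @ rng.standard_normal(5))
                    else:
                        eps = rng.standard_normal(5)
                    prop_g = group[p] + np.exp(group_step[p]) * eps
                    new_lp = _group_logpost(prop_g, pairs)
                    acc = np.log(rng.random()) < new_lp - cur_lp
                    if acc:
                        group[p] = prop_g
                        cur_lp = new_lp
                    if adapting:
                        group_step[p] += gamma * (float(acc) - 0.234)

            # re-correlation move: propose r_p and remap session-2
            # deviations so the whitened residuals are preserved; the
            # bivariate-prior ratio cancels against the jacobian, leaving
            # the session-2 likelihood and the correlation prior
            for p in range(P):
                zr_old = group[p, 4]
                zr_new = zr_old + np.exp(recorr_step[p]) * \
                    rng.standard_normal()
                r_old, r_new = np.tanh(zr_old), np.tanh(zr_new)
                mu1, mu2 = group[p, 0], group[p, 1]
                sd1, sd2 = np.exp(group[p, 2]), np.exp(group[p, 3])
                z1 = (theta[:, p, 0] - mu1) / sd1
                z2 = (theta[:, p, 1] - mu2) / sd2
                resid = (z2 - r_old * z1) / np.sqrt(1.0 - r_old**2)
                z2_new = r_new * z1 + np.sqrt(1.0 - r_new**2) * resid
                prop = theta[:, :, 1].copy()
                prop[:, p] = mu2 + sd2 * z2_new
                new_ll = loglik_fns[1](to_native_matrix(prop, transforms))
                d_prior = np.log1p(-r_new**2) - np.log1p(-r_old**2)
                log_r = float(np.sum(new_ll - cur_ll[1])) + d_prior
                acc = np.log(rng.random()) < log_r
                if acc:
                    theta[:, p, 1] = prop[:, p]
                    cur_ll[1] = new_ll
                    group[p, 4] = zr_new
                if adapting:
                    recorr_step[p] += gamma * (float(acc) - _TARGET_ACC)

            if adapting:
                group_hist.append(group.copy())
                theta_hist.append(theta.copy())
                if sweep >= 100 and sweep % 50 == 0:
                    gh = np.array(group_hist[-600:])  # (h, P, 5)
                    gdev = gh - gh.mean(axis=0, keepdims=True)
                    gcov = np.einsum("hpa,hpb->pab", gdev, gdev) / \
                        (len(gh) - 1) + 1e-8 * np.eye(5)[None]
                    if group_chol is None:
                        group_step = np.full(P, np.log(1.0))
                    group_chol = np.linalg.cholesky(gcov)
                    th = np.array(theta_hist[-600:])  # (h, n, P, 2)
                    dev = th - th.mean(axis=0, keepdims=True)
                    scov = np.einsum("hips,hiqs->sipq", dev, dev) / \
                        (len(th) - 1) + 1e-8 * np.eye(P)[None, None]
                    subj_chol = np.linalg.cholesky(scov)

            if not adapting:
                d = sweep - mcmc.warmup
                r_draws[c, d] = np.tanh(group[:, 4])
                mu_draws[c, d] = group[:, :2]
                sigma_draws[c, d] = np.exp(group[:, 2:4])
                if d % mcmc.thin_theta == 0:
                    theta_draws[c, kept] = theta
                    kept += 1

    rhats = {}
    for p, tr in enumerate(transforms):
        rhats[f"r_{tr.name}"] = split_rhat(np.arctanh(
            np.clip(r_draws[:, :, p], -0.9999, 0.9999)))
        for s in (0, 1):
            rhats[f"mu_{tr.name}_s{s + 1}"] = split_rhat(mu_draws[:, :, p, s])
    max_rhat = float(np.nanmax(list(rhats.values())))
    diagnostics = {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "converged": max_rhat <= mcmc.rhat_threshold,
    }
    return EmbeddedDraws(
        param_names=[tr.name for tr in transforms],
        r=r_draws, mu=mu_draws, sigma=sigma_draws, theta=theta_draws,
        diagnostics=diagnostics,
    )
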