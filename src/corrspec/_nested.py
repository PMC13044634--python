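"""Static nested sampling with slice-sampled likelihood-constrained steps.

Computes the Bayesian evidence Z = ∫ L(θ) π(θ) dθ and weighted posterior
samples by the classic shrinking-prior-volume scheme: at each iteration
the worst live point (lowest log L) is removed with prior-volume weight
w_i = X_{i-1} − X_i, X_i = exp(−i/n_live), and replaced by a point drawn
from the prior subject to L > L_worst, generated by slice sampling
(stepping-out and shrinkage) along random directions shaped by the live
points' covariance — robust on the elongated, funnel-shaped constrained
regions that correlation-model posteriors produce.

The reported evidence uncertainty is the information-based estimate
sqrt(H/n_live).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class NestedResult:
    samples: np.ndarray        # equal-weight posterior samples (n, ndim)
    log_z: float
    log_z_err: float
    log_l: np.ndarray          # log-likelihood of the dead points
    n_iter: int
    n_call: int
    efficiency: float


def run_nested(loglike, prior_transform, ndim: int, n_live: int = 300,
               n_slices: int = None, dlogz: float = 0.05,
               max_iter: int = 200000, rng=None,
               n_posterior: int = 2000, min_efolds: float = 15.0,
               log_weight_fn=None) -> NestedResult:
    """Run nested sampling.

    Parameters
    ----------
    loglike:
        Callable θ → log L(θ) with θ in physical units.
    prior_transform:
        Callable u ∈ [0,1)^ndim → θ mapping the unit cube to the prior.
    dlogz:
        Termination tolerance on the remaining evidence fraction.
    min_efolds:
        Minimum prior-volume shrinkage (in e-folds) before termination is
        allowed; guards against plateau-dominated likelihoods whose
        high-likelihood basin occupies a tiny prior fraction and would
        otherwise be missed by the remaining-evidence criterion.
    log_weight_fn:
        Optional callable u → log[π_target(θ(u)) / π_sampling(θ(u))] for
        importance-sampling nested runs: when the unit-cube mapping draws
        from a non-uniform sampling density, the evidence and posterior
        weights are corrected to the declared (target) prior.
    """
    rng = np.random.default_rng(rng)
    u_live = rng.uniform(size=(n_live, ndim))
    theta_live = np.array([prior_transform(u) for u in u_live])
    logl_live = np.array([loglike(t) for t in theta_live])
    n_call = n_live

    dead_u, dead_logl = [], []
    log_w = []                       # ln(prior-volume shell width)
    if n_slices is None:
        n_slices = max(5, 2 * ndim)
    prop_chol = np.eye(ndim)
    log_x_prev = 0.0
    log_z = -np.inf
    h = 0.0
    it = 0
    while it < max_iter:
        worst = int(np.argmin(logl_live))
        logl_star = logl_live[worst]
        log_x = -(it + 1) / n_live
        # ln(X_{i-1} - X_i)
        log_wt = log_x_prev + np.log1p(-np.exp(log_x - log_x_prev))
        dead_u.append(u_live[worst].copy())
        dead_logl.append(logl_star)
        log_w.append(log_wt)

        # update running evidence and information
        log_z_new = np.logaddexp(log_z, logl_star + log_wt)
        if np.isfinite(log_z_new):
            prev = (np.exp(log_z - log_z_new) * (h + log_z)
                    if np.isfinite(log_z) else 0.0)
            h = (np.exp(logl_star + log_wt - log_z_new) * logl_star
                 + prev - log_z_new)
        log_z = log_z_new
        log_x_prev = log_x

        # termination: remaining evidence negligible (after the minimum
        # shrinkage floor)
        logl_max = float(np.max(logl_live))
        if (it + 1 >= min_efolds * n_live and np.isfinite(log_z)
                and logl_max + log_x - log_z < np.log(dlogz)):
            it += 1
            break

        # refresh the proposal shape from the live-point covariance so the
        # walk tracks elongated/narrowing likelihood ridges
        if it % max(n_live // 2, 50) == 0:
            cov = np.cov(u_live, rowvar=False)
            cov = np.atleast_2d(cov) + 1e-10 * np.eye(ndim)
            try:
                prop_chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                prop_chol = np.sqrt(np.diag(np.diag(cov)))

        # replace the worst point: likelihood-constrained slice sampling
        # (stepping-out + shrinkage along covariance-shaped random
        # directions) from a random surviving live point — mixes well on
        # the elongated ridges these posteriors produce
        start = rng.integers(n_live)
        while n_live > 1 and start == worst:
            start = rng.integers(n_live)
        u = u_live[start].copy()
        theta_u = theta_live[start].copy()
        logl_u = logl_live[start]

        def _eval(point):
            nonlocal n_call
            if np.any((point <= 0.0) | (point >= 1.0)):
                return None, -np.inf
            th = prior_transform(point)
            n_call += 1
            return th, loglike(th)

        for _slice in range(n_slices):
            dvec = prop_chol @ rng.standard_normal(ndim)
            # stepping out
            left, right = -1.0, 1.0
            for _ in range(5):
                _, ll_l = _eval(u + left * dvec)
                if ll_l <= logl_star:
                    break
                left *= 2.0
            for _ in range(5):
                _, ll_r = _eval(u + right * dvec)
                if ll_r <= logl_star:
                    break
                right *= 2.0
            # shrinkage
            while right - left > 1e-10:
                t = rng.uniform(left, right)
                th_p, ll_p = _eval(u + t * dvec)
                if ll_p > logl_star:
                    u = u + t * dvec
                    theta_u, logl_u = th_p, ll_p
                    break
                if t < 0:
                    left = t
                else:
                    right = t

        u_live[worst] = u
        theta_live[worst] = theta_u
        logl_live[worst] = logl_u
        it += 1

    # add the remaining live points, each with weight X_final/n_live
    log_x_final = -it / n_live - np.log(n_live)
    order = np.argsort(logl_live)
    for idx in order:
        dead_u.append(u_live[idx].copy())
        dead_logl.append(logl_live[idx])
        log_w.append(log_x_final)
        log_z_new = np.logaddexp(log_z, logl_live[idx] + log_x_final)
        if np.isfinite(log_z_new):
            prev = (np.exp(log_z - log_z_new) * (h + log_z)
                    if np.isfinite(log_z) else 0.0)
            h = (np.exp(logl_live[idx] + log_x_final - log_z_new)
                 * logl_live[idx] + prev - log_z_new)
        log_z = log_z_new

    dead_logl = np.asarray(dead_logl)
    dead_u = np.asarray(dead_u)
    log_w = np.asarray(log_w)

    if log_weight_fn is not None:
        # importance correction to the declared prior:
        # Z_target = Σ w_i L_i · [π_t/π_s](u_i)
        log_ratio = np.array([log_weight_fn(u) for u in dead_u])
        log_terms = dead_logl + log_w + log_ratio
        log_z = float(logsumexp(log_terms))
        log_post = log_terms - log_z
        # recompute the information H = E_post[ln L] − ln Z for the error
        p = np.exp(log_post - logsumexp(log_post))
        h = float(np.sum(p * dead_logl) - log_z)
    else:
        log_post = dead_logl + log_w - log_z
    log_post = log_post - logsumexp(log_post)
    weights = np.exp(log_post)
    weights /= weights.sum()

    # equal-weight resampling of the dead points
    idx = rng.choice(len(weights), size=n_posterior, p=weights)
    thetas = np.array([prior_transform(u) for u in dead_u[idx]])

    h = max(h, 0.0)
    return NestedResult(
        samples=thetas,
        log_z=float(log_z),
        log_z_err=float(np.sqrt(h / n_live)),
        log_l=dead_logl,
        n_iter=it,
        n_call=n_call,
        efficiency=it / max(n_call - n_live, 1),
    )
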