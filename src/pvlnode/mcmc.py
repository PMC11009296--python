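"""No-U-Turn sampler (NUTS) on a differentiable log density.

A dependency-light Hamiltonian Monte Carlo implementation used by the
calibration module: multinomial NUTS with recursive tree doubling,
dual-averaging step-size adaptation toward a target acceptance statistic,
and diagonal *or dense* mass-matrix adaptation (dense matters for the
strongly correlated posteriors that parameter trade-offs produce).  The
target is supplied as a callable ``logp_and_grad(x) -> (logp, grad)`` on
an unconstrained space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DEPTH = 10
_DIVERGENCE = 1000.0


class _Mass:
    """Kinetic-energy bookkeeping for a diagonal or dense mass matrix.

    ``cov`` plays the role of the inverse mass (an estimate of the
    posterior covariance): momenta are drawn with covariance ``cov^{-1}``
    and positions move along ``cov @ p``.
    """

    def __init__(self, cov: np.ndarray):
        cov = np.asarray(cov, float)
        self.diag = cov.ndim == 1
        self.cov = cov
        if not self.diag:
            cov = 0.5 * (cov + cov.T)
            w, V = np.linalg.eigh(cov)
            w = np.clip(w, 1e-12 * w.max(), None)
            self.cov = (V * w) @ V.T
            self._chol = np.linalg.cholesky(self.cov)

    def sample_momentum(self, rng, dim):
        z = rng.standard_normal(dim)
        if self.diag:
            return z / np.sqrt(self.cov)
        # cov = L L^T  =>  p = L^{-T} z has covariance cov^{-1}
        from scipy.linalg import solve_triangular

        return solve_triangular(self._chol.T, z, lower=False)

    def velocity(self, p):
        return self.cov * p if self.diag else self.cov @ p

    def kinetic(self, p):
        return 0.5 * float(p @ self.velocity(p))

    def jitter_scale(self):
        d = self.cov if self.diag else np.diag(self.cov)
        return np.sqrt(d)


@dataclass
class NutsResult:
    """Posterior draws and sampler diagnostics.

    ``samples`` has shape ``(n_chains, n_samples, dim)``; ``accept_stat``
    and ``divergences`` are per-chain summaries; ``step_size`` is the
    adapted value per chain.
    """

    samples: np.ndarray
    accept_stat: np.ndarray
    divergences: np.ndarray
    step_size: np.ndarray


@dataclass
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    proposal: np.ndarray
    proposal_logp: float
    log_weight: float
    turning: bool
    diverged: bool
    alpha_sum: float
    n_leaf: int


def _leapfrog(logp_and_grad, q, p, g, eps, mass: _Mass):
    p_half = p + 0.5 * eps * g
    q_new = q + eps * mass.velocity(p_half)
    logp_new, g_new = logp_and_grad(q_new)
    p_new = p_half + 0.5 * eps * g_new
    return q_new, p_new, g_new, logp_new


def _is_turning(q_minus, q_plus, p_minus, p_plus, mass: _Mass):
    dq = q_plus - q_minus
    return (np.dot(dq, mass.velocity(p_minus)) < 0
            or np.dot(dq, mass.velocity(p_plus)) < 0)


def _build_tree(logp_and_grad, q, p, g, direction, depth, eps, H0, mass, rng):
    if depth == 0:
        q1, p1, g1, logp1 = _leapfrog(logp_and_grad, q, p, g, direction * eps,
                                      mass)
        H1 = -logp1 + mass.kinetic(p1) if np.isfinite(logp1) else np.inf
        dH = H0 - H1
        diverged = not np.isfinite(H1) or (H1 - H0) > _DIVERGENCE
        log_w = -np.inf if diverged else dH
        alpha = 0.0 if diverged else min(1.0, float(np.exp(min(dH, 0.0))))
        return _Tree(q1, p1, g1, q1, p1, g1, q1, logp1, log_w,
                     False, diverged, alpha, 1)
    first = _build_tree(logp_and_grad, q, p, g, direction, depth - 1, eps, H0,
                        mass, rng)
    if first.diverged or first.turning:
        return first
    if direction > 0:
        second = _build_tree(logp_and_grad, first.q_plus, first.p_plus,
                             first.g_plus, direction, depth - 1, eps, H0,
                             mass, rng)
        edges = (first.q_minus, first.p_minus, first.g_minus,
                 second.q_plus, second.p_plus, second.g_plus)
    else:
        second = _build_tree(logp_and_grad, first.q_minus, first.p_minus,
                             first.g_minus, direction, depth - 1, eps, H0,
                             mass, rng)
        edges = (second.q_minus, second.p_minus, second.g_minus,
                 first.q_plus, first.p_plus, first.g_plus)
    q_minus, p_minus, g_minus, q_plus, p_plus, g_plus = edges
    total = np.logaddexp(first.log_weight, second.log_weight)
    take_second = np.log(rng.uniform()) < second.log_weight - total
    prop, prop_lp = ((second.proposal, second.proposal_logp) if take_second
                     else (first.proposal, first.proposal_logp))
    turning = (second.turning or second.diverged
               or _is_turning(q_minus, q_plus, p_minus, p_plus, mass))
    return _Tree(q_minus, p_minus, g_minus, q_plus, p_plus, g_plus,
                 prop, prop_lp, total, turning, second.diverged,
                 first.alpha_sum + second.alpha_sum,
                 first.n_leaf + second.n_leaf)


def _nuts_step(logp_and_grad, q, logp, g, eps, mass: _Mass, rng, max_depth):
    p0 = mass.sample_momentum(rng, q.size)
    H0 = -logp + mass.kinetic(p0)
    tree = _Tree(q, p0, g, q, p0, g, q, logp, 0.0, False, False, 0.0, 0)
    log_w = 0.0  # weight of the initial point relative to exp(-H0)
    alpha_sum, n_leaf, diverged = 0.0, 0, False
    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            sub = _build_tree(logp_and_grad, tree.q_plus, tree.p_plus,
                              tree.g_plus, direction, depth, eps, H0, mass, rng)
            tree.q_plus, tree.p_plus, tree.g_plus = (sub.q_plus, sub.p_plus,
                                                     sub.g_plus)
        else:
            sub = _build_tree(logp_and_grad, tree.q_minus, tree.p_minus,
                              tree.g_minus, direction, depth, eps, H0, mass, rng)
            tree.q_minus, tree.p_minus, tree.g_minus = (sub.q_minus,
                                                        sub.p_minus,
                                                        sub.g_minus)
        alpha_sum += sub.alpha_sum
        n_leaf += sub.n_leaf
        if sub.diverged:
            diverged = True
            break
        if not sub.turning:
            total = np.logaddexp(log_w, sub.log_weight)
            if np.log(rng.uniform()) < sub.log_weight - total:
                tree.proposal, tree.proposal_logp = sub.proposal, sub.proposal_logp
            log_w = total
        if sub.turning or _is_turning(tree.q_minus, tree.q_plus, tree.p_minus,
                                      tree.p_plus, mass):
            break
    q_new = tree.proposal
    logp_new = tree.proposal_logp
    if not np.all(q_new == q):
        _, g_new = logp_and_grad(q_new)
    else:
        g_new = g
    accept_stat = alpha_sum / max(n_leaf, 1)
    return q_new, logp_new, g_new, accept_stat, diverged


def _find_initial_step(logp_and_grad, q, logp, g, mass: _Mass, rng):
    eps = 1.0
    p = mass.sample_momentum(rng, q.size)
    H0 = -logp + mass.kinetic(p)

    def H_after(eps):
        _, p1, _, logp1 = _leapfrog(logp_and_grad, q, p, g, eps, mass)
        return -logp1 + mass.kinetic(p1) if np.isfinite(logp1) else np.inf

    direction = 1.0 if (H0 - H_after(eps)) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        if direction * (H0 - H_after(eps)) < direction * np.log(0.5):
            break
    return eps


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray | list[np.ndarray],
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_samples: int = 1000,
    seed: int = 0,
    target_accept: float = 0.8,
    jitter: float = 0.0,
    max_depth: int = _MAX_DEPTH,
    inv_mass0: np.ndarray | None = None,
    dense_mass: bool = False,
) -> NutsResult:
    """Run multinomial NUTS chains on an unconstrained log density.

    ``x0`` is either one initial point (jittered per chain, scaled by the
    mass estimate) or a list of per-chain initial points.  Step size is
    adapted by dual averaging during warmup.  The mass matrix starts from
    ``inv_mass0`` — a vector (diagonal) or matrix (dense) estimate of the
    posterior covariance, e.g. inverse curvature at the mode — and is
    re-estimated from the middle warmup draws (diagonal by default, dense
    if ``dense_mass`` or if ``inv_mass0`` is a matrix).
    """
    x0 = np.asarray(x0, float)
    dim = x0.shape[-1]
    dense = dense_mass or (inv_mass0 is not None
                           and np.asarray(inv_mass0).ndim == 2)
    samples = np.empty((n_chains, n_samples, dim))
    accept = np.empty(n_chains)
    divs = np.zeros(n_chains, int)
    eps_out = np.empty(n_chains)

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chain]))
        mass = _Mass(np.ones(dim) if inv_mass0 is None
                     else np.asarray(inv_mass0, float))
        q = (x0[chain].copy() if x0.ndim == 2
             else x0 + jitter * mass.jitter_scale() * rng.standard_normal(dim))
        logp, g = logp_and_grad(q)
        if not np.isfinite(logp):
            raise ValueError("initial point has non-finite log density")
        eps = _find_initial_step(logp_and_grad, q, logp, g, mass, rng)
        # dual averaging (Hoffman & Gelman 2014 defaults)
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        window: list[np.ndarray] = []
        mass_at = n_warmup // 2
        t_adapt = 0
        accept_sum = 0.0
        for it in range(n_warmup + n_samples):
            q, logp, g, a_stat, div = _nuts_step(
                logp_and_grad, q, logp, g, eps, mass, rng, max_depth)
            if it < n_warmup:
                t_adapt += 1
                frac = 1.0 / (t_adapt + t0)
                h_bar = (1 - frac) * h_bar + frac * (target_accept - a_stat)
                log_eps = mu - np.sqrt(t_adapt) / gamma * h_bar
                w = t_adapt**-kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if n_warmup >= 100 and n_warmup // 4 <= it < mass_at:
                    window.append(q.copy())
                # a dense estimate from few draws is worse than the prior
                # mass guess; require enough data before replacing it
                min_draws = (20 * dim if dense else 10) if inv_mass0 is not None \
                    else 10
                if it == mass_at and len(window) > min_draws:
                    draws = np.stack(window)
                    if dense:
                        cov = np.atleast_2d(np.cov(draws.T))
                        cov += 1e-6 * np.trace(cov) / dim * np.eye(dim)
                        mass = _Mass(cov)
                    else:
                        mass = _Mass(np.maximum(np.var(draws, axis=0), 1e-10))
                    eps = _find_initial_step(logp_and_grad, q, logp, g, mass,
                                             rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, t_adapt = 0.0, 0.0, 0
                if it == n_warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                samples[chain, it - n_warmup] = q
                divs[chain] += int(div)
                accept_sum += a_stat
        accept[chain] = accept_sum / n_samples
        eps_out[chain] = eps
    return NutsResult(samples, accept, divs, eps_out)
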