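"""Posterior sampler: HMC within Gibbs with a slice-sampled scale.

A small, self-contained sampler suited to smooth low-dimensional posteriors
(here: ~12-18 parameters, log-concave likelihood given the random-effect
scale).  Each iteration performs

1. a stepping-out slice-sampler update of one designated coordinate
   (the log random-effect scale, whose conditional is 1-D and cheap), and
2. one Hamiltonian update of all remaining coordinates, using a fixed dense
   metric - the corresponding block of a supplied covariance estimate (the
   Laplace approximation at the posterior mode) - with dual-averaging
   step-size adaptation during warmup and jittered trajectory lengths.

Conditioning on the scale removes the funnel geometry a joint fixed-metric
HMC would face; the remaining block is close to Gaussian, where fixed-metric
HMC mixes rapidly.  With ``slice_dim=None`` the sampler reduces to plain
HMC over all coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_keep, d) post-warmup positions
    accept_rate: float         # post-warmup mean HMC acceptance probability
    step_size: float
    divergences: int


def _regularize(cov):
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 1e-8, None)
    return (V * w) @ V.T


def _slice_update_1d(logp, x, j, rng, width=1.0, max_steps=30):
    """Stepping-out + shrinkage slice sampler for coordinate j (Neal 2003)."""
    lp0 = logp(x)
    log_y = lp0 - rng.exponential()
    left = x[j] - width * rng.random()
    right = left + width

    def lp_at(v):
        z = x.copy()
        z[j] = v
        return logp(z)

    steps = max_steps
    while steps > 0 and lp_at(left) > log_y:
        left -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and lp_at(right) > log_y:
        right += width
        steps -= 1
    for _ in range(100):
        prop = rng.uniform(left, right)
        if lp_at(prop) > log_y:
            x[j] = prop
            return x
        if prop < x[j]:
            left = prop
        else:
            right = prop
    return x  # shrinkage exhausted: keep current point


class _HmcBlock:
    """Fixed-metric HMC update of a coordinate subset."""

    def __init__(self, idx, cov):
        self.idx = idx
        self.cov = _regularize(cov[np.ix_(idx, idx)])
        self.chol = np.linalg.cholesky(self.cov)

    def momentum(self, rng):
        z = rng.standard_normal(len(self.idx))
        return np.linalg.solve(self.chol.T, z)

    def kinetic(self, p):
        return 0.5 * p @ (self.cov @ p)

    def leapfrog(self, logp_grad, x, p, eps, n_steps):
        x = x.copy()
        lp, g = logp_grad(x)
        for _ in range(n_steps):
            p = p + 0.5 * eps * g[self.idx]
            x[self.idx] = x[self.idx] + eps * (self.cov @ p)
            lp, g = logp_grad(x)
            p = p + 0.5 * eps * g[self.idx]
        return x, p, lp

    def step(self, logp_grad, x, eps, n_steps, rng):
        """One proposal; returns (x_new, acceptance_prob, divergent)."""
        p0 = self.momentum(rng)
        lp0, _ = logp_grad(x)
        h0 = -lp0 + self.kinetic(p0)
        x1, p1, lp1 = self.leapfrog(logp_grad, x, p0, eps, n_steps)
        if not np.isfinite(lp1):
            return x, 0.0, True
        dh = h0 - (-lp1 + self.kinetic(p1))
        alpha = float(np.exp(min(0.0, dh)))
        divergent = dh < -1000.0
        if rng.random() < alpha:
            return x1, alpha, divergent
        return x, alpha, divergent


def _find_initial_step(block, logp_grad, x, rng):
    eps = 0.1
    for _ in range(40):
        _, alpha, _ = block.step(logp_grad, x, eps, 1, rng)
        if alpha > 0.9:
            eps *= 2.0
        elif alpha < 0.5:
            eps *= 0.5
        else:
            break
    return float(np.clip(eps, 1e-6, 10.0))


def hmc_chain(logp_grad, x0, cov, n_iter, warmup, rng, target_accept=0.9,
              trajectory_length=1.6, max_leapfrog=64,
              slice_dim: int | None = None,
              slice_width: float = 1.0) -> ChainResult:
    """Run one chain; returns post-warmup draws of the full vector.

    ``logp_grad(x) -> (logp, grad)`` must be finite at ``x0``; ``cov`` is a
    dense covariance estimate of the target whose block over the non-slice
    coordinates serves as the (inverse) HMC metric.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp, _ = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at the initial point")

    hmc_idx = np.array([i for i in range(d) if i != slice_dim], dtype=int)
    block = _HmcBlock(hmc_idx, np.asarray(cov, dtype=float))
    logp_only = lambda z: logp_grad(z)[0]

    eps = _find_initial_step(block, logp_grad, x, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_iter - warmup, d))
    accepts, divergences, kept = [], 0, 0

    for it in range(n_iter):
        if slice_dim is not None:
            x = _slice_update_1d(logp_only, x, slice_dim, rng, width=slice_width)
        n_steps = max(1, min(int(round(trajectory_length / eps)), max_leapfrog))
        n_steps = int(rng.integers(max(1, n_steps // 2), n_steps + 1))
        x, alpha, div = block.step(logp_grad, x, eps, n_steps, rng)
        divergences += int(div)

        if it < warmup:
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if m == warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[kept] = x
            kept += 1
            accepts.append(alpha)

    accept_rate = float(np.mean(accepts)) if accepts else 0.0
    if accept_rate < 0.1:
        raise RuntimeError(
            f"HMC adaptation failed: post-warmup acceptance {accept_rate:.3f}, "
            f"step size {eps:.2e}, {divergences} divergences")
    return ChainResult(draws=draws, accept_rate=accept_rate,
                       step_size=eps, divergences=divergences)
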