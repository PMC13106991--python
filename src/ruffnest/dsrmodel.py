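"""Hierarchical Bayesian daily nest survival model.

The daily survival probability of nest i on transition t follows a
Bernoulli-chain likelihood: conditional on being alive at t-1, the nest
survives day t with probability

    S_it = inv_logit( x_it' beta + sigma_year * u_year(i) )

where x_it stacks the within-year scaled covariates (nest/lek distances
with quadratics, lay date, nest age, the artificial-incubation indicator,
and path/edge/shore distances) and the year effect is non-centred:
u_year ~ N(0, 1) scaled by sigma_year.  Failure on day T contributes
log(1 - S_iT); censored histories contribute survival terms only.

Priors: Gaussian (0, 2) on the continuous fixed effects (intercept
included), Cauchy (0, 2) on the categorical incubation effect, N(0, 1) on
the u_year deviates, and a half-Cauchy (0, 5) on sigma_year, sampled on the
log scale with its Jacobian.

Sampling uses in-package Hamiltonian Monte Carlo (see :mod:`ruffnest.mcmc`)
preconditioned with a Laplace approximation at the posterior mode; the
sampling contract is the posterior, seed-reproducibility and the
Gelman-Rubin diagnostics, not a particular engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

from .exposure import DesignMatrices

#: prior scales
PRIOR_SD_CONTINUOUS = 2.0
PRIOR_SD_U = 1.0
PRIOR_SCALE_CATEGORICAL = 2.0
PRIOR_SCALE_SIGMA = 5.0

CATEGORICAL_EFFECTS = ("incubation",)


def daily_survival_probability(covariates, coefficients,
                               year_effect: float = 0.0) -> float:
    """inv-logit of the linear predictor for one nest-day.

    ``covariates`` maps design-column names (already scaled) to values;
    ``coefficients`` maps the same names plus ``intercept`` to effects on
    the log-odds scale.
    """
    eta = float(coefficients.get("intercept", 0.0)) + year_effect
    for name, value in covariates.items():
        if name == "intercept":
            continue
        eta += float(coefficients.get(name, 0.0)) * float(value)
    if not np.isfinite(eta):
        raise ValueError(f"non-finite linear predictor: {eta}")
    return float(expit(eta))


def _bernoulli_chain_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y*log S + (1-y)*log(1-S) = y*eta - softplus(eta) for S = expit(eta)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def scenario_log_likelihood(histories, survival) -> float:
    """Log likelihood of a set of exposure histories.

    ``survival`` gives S_it: a scalar (constant daily survival), a mapping
    ``nest_id -> sequence of S_t`` (t = 1..T), or a callable
    ``(nest_id, t) -> S``.  Survived transitions contribute log S_it,
    terminal failures log(1 - S_iT); an S of exactly 0 or 1 at an observed
    transition yields -inf.
    """
    total = 0.0
    for h in histories:
        for t, outcome in enumerate(h.y, start=1):
            if np.isscalar(survival):
                s = float(survival)
            elif callable(survival):
                s = float(survival(h.nest_id, t))
            else:
                s = float(survival[h.nest_id][t - 1])
            with np.errstate(divide="ignore"):
                total += np.log(s) if outcome == 1 else np.log1p(-s)
    return float(total)


@dataclass
class DsrModelSpec:
    """MCMC protocol for one scenario x variant fit."""

    scenario: str = "overall"
    variant: str = "all_nests"
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    convergence_threshold: float = 1.10
    rng_seed: int = 0
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")


@dataclass
class PosteriorDraws:
    """Post-warmup draws, chain by chain, for all reported parameters.

    ``array`` has shape (chains, draws_per_chain, n_params); ``names`` holds
    the fixed effects (design columns), ``sigma_year``, the raw ``u_<year>``
    deviates and the composite ``year_<year>`` effects (sigma_year * u).
    """

    array: np.ndarray
    names: tuple[str, ...]
    spec: DsrModelSpec
    columns: tuple[str, ...]
    years: tuple[int, ...]
    scaling: dict
    age_scaling: dict
    diagnostics: dict = field(default_factory=dict)

    def _idx(self, name: str) -> int:
        return self.names.index(name)

    def draws(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.array[:, :, self._idx(name)].reshape(-1)

    def per_chain(self, name: str) -> np.ndarray:
        return self.array[:, :, self._idx(name)]

    @property
    def n_draws(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def credible_interval(self, name: str, level: float = 0.95):
        a = (1.0 - level) / 2.0
        x = self.draws(name)
        return float(np.quantile(x, a)), float(np.quantile(x, 1 - a))


def _prior_logp_grad(beta, columns):
    lp, g = 0.0, np.zeros_like(beta)
    for j, name in enumerate(columns):
        if name in CATEGORICAL_EFFECTS:
            s2 = PRIOR_SCALE_CATEGORICAL ** 2
            lp += -np.log1p(beta[j] ** 2 / s2)
            g[j] = -2.0 * beta[j] / (s2 + beta[j] ** 2)
        else:
            lp += -0.5 * beta[j] ** 2 / PRIOR_SD_CONTINUOUS ** 2
            g[j] = -beta[j] / PRIOR_SD_CONTINUOUS ** 2
    return lp, g


def _make_logpost(design: DesignMatrices):
    """Joint log posterior and gradient over theta = (beta, a, log_sigma).

    The year effect is non-centred: u_year ~ N(0,1) scaled by
    sigma_year = exp(log_sigma), with the half-Cauchy prior on sigma_year
    expressed on the log scale including its Jacobian.
    """
    X, y, yi = design.X, design.y, design.year_index
    p, k = X.shape[1], len(design.years)
    s2c = PRIOR_SCALE_SIGMA ** 2

    def logp_grad(theta):
        beta, u, ls = theta[:p], theta[p:p + k], theta[p + k]
        sigma = np.exp(ls)
        eta = X @ beta + sigma * u[yi]
        s = expit(eta)
        ll = _bernoulli_chain_loglik(y, eta)
        resid = y - s
        g_beta = X.T @ resid
        g_u = sigma * np.bincount(yi, weights=resid, minlength=k)
        g_ls = sigma * float(u[yi] @ resid)

        lp_b, gp_b = _prior_logp_grad(beta, design.columns)
        lp = ll + lp_b - 0.5 * float(u @ u)
        g_beta += gp_b
        g_u -= u
        # half-Cauchy(0, 5) on sigma with log-scale Jacobian
        lp += -np.log1p(sigma ** 2 / s2c) + ls
        g_ls += 1.0 - 2.0 * sigma ** 2 / (s2c + sigma ** 2)

        grad = np.concatenate([g_beta, g_u, [g_ls]])
        return lp, grad

    return logp_grad, p, k


def mle_oracle_fit(design: DesignMatrices):
    """Maximum-likelihood fit without year effects (testing oracle).

    Maximizes the Bernoulli-chain likelihood over the fixed effects by
    numerical optimization.  Returns (coefficients dict, info dict); under
    complete separation the estimates are bounded only by a tiny ridge and
    a warning is issued.
    """
    X, y = design.X, design.y
    ridge = 1e-8

    def negll(beta):
        eta = X @ beta
        s = expit(eta)
        nll = -_bernoulli_chain_loglik(y, eta) + 0.5 * ridge * beta @ beta
        grad = -(X.T @ (y - s)) + ridge * beta
        return nll, grad

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(negll, beta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    beta = res.x
    separated = bool(np.any(np.abs(beta) > 15.0)) or design.n_failures == 0
    if separated:
        warnings.warn("possible separation or zero failures: MLE at or near "
                      "the boundary; estimates are prior/ridge bounded")
    coef = dict(zip(design.columns, beta))
    return coef, {"converged": bool(res.success), "loglik": -float(res.fun),
                  "separated": separated, "n_failures": design.n_failures,
                  "n_exposure_days": design.n_exposure_days}


def _laplace_approximation(logp_grad, dim, x0=None):
    """Posterior mode and inverse-Hessian covariance for preconditioning."""
    x0 = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float)

    def neg(theta):
        lp, g = logp_grad(theta)
        return -lp, -g

    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 1000})
    mode = res.x
    h = 1e-5
    H = np.empty((dim, dim))
    for i in range(dim):
        e = np.zeros(dim)
        e[i] = h
        _, gp = logp_grad(mode + e)
        _, gm = logp_grad(mode - e)
        H[:, i] = -(gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.clip(w, 1e-6, None)
    cov = (V / w) @ V.T
    return mode, cov


def _run_chain(design: DesignMatrices, spec: DsrModelSpec, start, cov, rng):
    """One Gibbs chain: HMC on the fixed effects, slice updates for the
    year deviates and the log random-effect scale.

    Given (u, sigma), the fixed-effect conditional is log-concave and close
    to Gaussian, where fixed-metric HMC mixes rapidly; given the fixed
    effects, the u_year are conditionally independent with cheap 1-D
    conditionals, and sigma_year's 1-D conditional is handled by a
    stepping-out slice sampler.  This sidesteps the u-sigma funnel a joint
    fixed-metric HMC would face.
    """
    from .mcmc import ChainResult, _find_initial_step, _HmcBlock, _slice_update_1d

    X, y, yi = design.X, design.y, design.year_index
    p, k = X.shape[1], len(design.years)
    s2c = PRIOR_SCALE_SIGMA ** 2
    rows = [np.where(yi == j)[0] for j in range(k)]
    y_by = [y[r] for r in rows]

    beta = start[:p].copy()
    u = start[p:p + k].copy()
    ls = np.array([start[p + k]])
    xb = X @ beta
    intercept_col = (design.columns.index("intercept")
                     if "intercept" in design.columns else None)

    def beta_logp_grad(b):
        eta = X @ b + np.exp(ls[0]) * u[yi]
        s = expit(eta)
        lp_b, gp_b = _prior_logp_grad(b, design.columns)
        return (_bernoulli_chain_loglik(y, eta) + lp_b,
                X.T @ (y - s) + gp_b)

    def u_logp(j):
        def lp(uvec):
            eta = xb[rows[j]] + np.exp(ls[0]) * uvec[j]
            return _bernoulli_chain_loglik(y_by[j], eta) - 0.5 * uvec[j] ** 2
        return lp

    def ls_logp(lsvec):
        sigma = np.exp(lsvec[0])
        eta = xb + sigma * u[yi]
        return (_bernoulli_chain_loglik(y, eta)
                - np.log1p(sigma ** 2 / s2c) + lsvec[0])

    def ls_logp_centred(a):
        # conditional of log_sigma given the *centred* effects a = sigma*u:
        # product of N(a_j; 0, sigma^2) densities, the half-Cauchy prior and
        # the log-scale Jacobian; likelihood-free since eta depends on a only
        aa = float(a @ a)

        def lp(lsvec):
            sigma2 = np.exp(2.0 * lsvec[0])
            return (-(k - 1) * lsvec[0] - 0.5 * aa / sigma2
                    - np.log1p(sigma2 / s2c))
        return lp

    # metric: covariance of beta *conditional* on (u, log_sigma) - the Schur
    # complement of the Laplace covariance - since u and sigma are held
    # fixed during the HMC update
    cov_cond = cov[:p, :p] - cov[:p, p:] @ np.linalg.solve(cov[p:, p:],
                                                           cov[p:, :p])
    block = _HmcBlock(np.arange(p), cov_cond)
    eps = _find_initial_step(block, beta_logp_grad, beta, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    n_keep = spec.iterations - spec.warmup
    draws = np.empty((n_keep, p + k + 1))
    accepts, divergences, kept = [], 0, 0
    for it in range(spec.iterations):
        ls = _slice_update_1d(ls_logp, ls, 0, rng, width=1.0)
        for j in range(k):
            u = _slice_update_1d(u_logp(j), u, j, rng, width=1.0)
        # interweaving (ASIS): re-update sigma in centred coordinates, which
        # ties it to the realized year-effect magnitudes and prevents the
        # (sigma large, u small) funnel arm from trapping the chain
        a = np.exp(ls[0]) * u
        ls = _slice_update_1d(ls_logp_centred(a), ls, 0, rng, width=1.0)
        u = a * np.exp(-ls[0])
        # location interweave: the shift (b0 + sigma*d, u - d) leaves the
        # likelihood invariant; its conditional under the priors is Gaussian,
        # so resampling d exactly decorrelates the intercept from a common
        # drift of the year deviates
        if intercept_col is not None:
            sigma = np.exp(ls[0])
            var_d = 1.0 / (sigma ** 2 / PRIOR_SD_CONTINUOUS ** 2 + k)
            mean_d = var_d * (u.sum() - beta[intercept_col] * sigma
                              / PRIOR_SD_CONTINUOUS ** 2)
            d = mean_d + np.sqrt(var_d) * rng.standard_normal()
            beta[intercept_col] += sigma * d
            u -= d
            xb = X @ beta
        n_steps = max(1, min(int(round(1.6 / eps)), 64))
        n_steps = int(rng.integers(max(1, n_steps // 2), n_steps + 1))
        beta, alpha, div = block.step(beta_logp_grad, beta, eps, n_steps, rng)
        xb = X @ beta
        if it >= spec.warmup:
            divergences += int(div)
        if it < spec.warmup:
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (spec.target_accept - alpha) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if m == spec.warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[kept] = np.concatenate([beta, u, ls])
            kept += 1
            accepts.append(alpha)

    accept_rate = float(np.mean(accepts))
    if accept_rate < 0.1:
        raise RuntimeError(
            f"sampler adaptation failed: acceptance {accept_rate:.3f}, "
            f"step size {eps:.2e}, {divergences} divergences")
    return ChainResult(draws=draws, accept_rate=accept_rate,
                       step_size=eps, divergences=divergences)


def sample_posterior(spec: DsrModelSpec, design: DesignMatrices) -> PosteriorDraws:
    """Draw from the posterior of the daily-survival model.

    Runs ``spec.chains`` independent chains (seeded from ``spec.rng_seed``),
    each for ``spec.iterations`` iterations with the first ``spec.warmup``
    discarded as adaptation, preconditioned by a Laplace approximation at
    the posterior mode.  Identical seeds give identical draws.  The
    returned object carries a Gelman-Rubin convergence report in
    ``diagnostics``.
    """
    if design.n_failures == 0:
        warnings.warn("no failure events in the data: the intercept is only "
                      "weakly identified by the prior")
    logp_grad, p, k = _make_logpost(design)
    dim = p + k + 1
    x0 = np.zeros(dim)
    x0[-1] = np.log(0.5)
    mode, cov = _laplace_approximation(logp_grad, dim, x0)

    chains = []
    for c in range(spec.chains):
        rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, c)))
        start = mode + cov @ rng.standard_normal(dim) * 0.3
        lp, _ = logp_grad(start)
        if not np.isfinite(lp):
            start = mode
        chains.append(_run_chain(design, spec, start, cov, rng))

    raw = np.stack([c.draws for c in chains])     # (m, n_keep, dim)
    beta = raw[:, :, :p]
    u = raw[:, :, p:p + k]
    sigma = np.exp(raw[:, :, p + k:p + k + 1])
    year_comp = sigma * u
    array = np.concatenate([beta, sigma, u, year_comp], axis=2)
    names = (tuple(design.columns) + ("sigma_year",)
             + tuple(f"u_{yr}" for yr in design.years)
             + tuple(f"year_{yr}" for yr in design.years))

    draws = PosteriorDraws(array=array, names=names, spec=spec,
                           columns=design.columns, years=design.years,
                           scaling=design.scaling,
                           age_scaling=design.age_scaling)
    rhat = {name: gelman_rubin(draws.per_chain(name)) for name in names}
    draws.diagnostics = {
        "rhat": rhat,
        "max_rhat": float(np.nanmax(list(rhat.values()))),
        "converged": all(r < spec.convergence_threshold
                         for r in rhat.values() if np.isfinite(r)),
        "accept_rates": [c.accept_rate for c in chains],
        "divergences": [c.divergences for c in chains],
        "step_sizes": [c.step_size for c in chains],
    }
    return draws


def gelman_rubin(chain_draws) -> float:
    """Potential scale reduction factor (split-chain, rank-free).

    ``chain_draws`` is an (m_chains, n_draws) array.  Chains of length >= 4
    are split in half (middle element dropped when odd) before computing

        R-hat = sqrt( ((n-1)/n * W + B/n) / W )

    with W the mean within-chain variance and B/n the variance of the chain
    means.  Identical constant chains give 1.0; zero within-chain variance
    with distinct means gives +inf.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    if n >= 4:
        half = n // 2
        x = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)
        m, n = x.shape
    means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def classify_effects(draws: PosteriorDraws, level: float = 0.95,
                     names=None) -> dict[str, str]:
    """Label each parameter 'clear' iff its central credible interval
    excludes zero (both endpoints share a sign)."""
    names = names or draws.names
    out = {}
    for name in names:
        lo, hi = draws.credible_interval(name, level)
        out[name] = "clear" if (lo > 0 and hi > 0) or (lo < 0 and hi < 0) \
            else "not_clear"
    return out
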