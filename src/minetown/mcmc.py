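"""Building blocks for the Bayesian logit samplers.

Two kernels are shared by the additive (P-spline) and the parametric
distance-risk models:

* :func:`iwls_mh_update` — a Metropolis–Hastings step for a Gaussian-prior
  coefficient block of a Bernoulli-logit model, proposing from the iteratively
  weighted least squares (IWLS) approximation to the full conditional
  (Gamerman-style).  The proposal is recomputed at the proposed point so the
  acceptance ratio is exact.
* :class:`AdaptiveRW` — a random-walk Metropolis kernel whose proposal scale
  and covariance adapt during burn-in toward a target acceptance rate.

Both operate on a log-likelihood that callers supply through precomputed
design/offset structures, keeping the kernels model-agnostic.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

# floor on the IWLS weights; keeps the working-response step stable when
# fitted probabilities approach 0 or 1
_W_MIN = 1e-6


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def bernoulli_loglik(y, eta):
    """Sum log p(y | logit p = eta), numerically stable."""
    eta = np.asarray(eta, dtype=float)
    # log(1 + e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _iwls_moments(y, X, offset, beta, prior_prec, prior_mean):
    """Gaussian approximation N(m, Q^{-1}) to the full conditional at *beta*."""
    eta = offset + X @ beta
    pi = sigmoid(eta)
    w = np.clip(pi * (1.0 - pi), _W_MIN, None)
    z = (eta - offset) + (y - pi) / w
    Xw = X * w[:, None]
    Q = X.T @ Xw + prior_prec
    rhs = X.T @ (w * z) + prior_prec @ prior_mean
    cf = cho_factor(Q, lower=True)
    m = cho_solve(cf, rhs)
    return m, cf, Q


def _mvn_logpdf_chol(x, m, cf):
    """log N(x | m, Q^{-1}) given the Cholesky factorisation *cf* of Q."""
    L = np.tril(cf[0])
    diff = x - m
    quad = diff @ cho_solve(cf, diff)
    logdet_q = 2.0 * np.sum(np.log(np.diag(L)))
    k = len(x)
    return 0.5 * (logdet_q - quad - k * np.log(2.0 * np.pi))


def _mvn_draw_chol(m, cf, rng):
    """Draw from N(m, Q^{-1}) where cf is a Cholesky factorisation of Q."""
    L = np.tril(cf[0])
    z = rng.standard_normal(len(m))
    # solve L^T x = z  =>  x ~ N(0, Q^{-1})
    from scipy.linalg import solve_triangular

    return m + solve_triangular(L, z, lower=True, trans="T")


def iwls_mh_update(y, X, offset, beta, prior_prec, prior_mean, rng):
    """One IWLS-proposal Metropolis–Hastings update of a coefficient block.

    Model: y_i ~ Bernoulli(logit^{-1}(offset_i + x_i' beta)),
    prior: beta ~ N(prior_mean, prior_prec^{-1}).

    Returns ``(beta_new, accepted)``.
    """
    m_cur, cf_cur, _ = _iwls_moments(y, X, offset, beta, prior_prec, prior_mean)
    prop = _mvn_draw_chol(m_cur, cf_cur, rng)
    m_prop, cf_prop, _ = _iwls_moments(y, X, offset, prop, prior_prec, prior_mean)

    def logpost(b):
        ll = bernoulli_loglik(y, offset + X @ b)
        diff = b - prior_mean
        return ll - 0.5 * diff @ prior_prec @ diff

    log_acc = (
        logpost(prop)
        - logpost(beta)
        + _mvn_logpdf_chol(beta, m_prop, cf_prop)
        - _mvn_logpdf_chol(prop, m_cur, cf_cur)
    )
    if np.log(rng.uniform()) < log_acc:
        return prop, True
    return beta, False


def mala_update(y, X, offset, beta, prior_prec, prior_mean, rng, eps):
    """Preconditioned MALA step for a Gaussian-prior logit coefficient block.

    Proposal N(beta + (eps^2/2) Q^{-1} grad, eps^2 Q^{-1}) with Q the IWLS
    curvature at the current point (simplified manifold MALA).  Unlike the
    full IWLS proposal of :func:`iwls_mh_update` — whose acceptance collapses
    in high dimension — the step size eps can be tuned to keep acceptance
    healthy for large blocks.  Returns ``(beta_new, accepted)``.
    """
    from scipy.linalg import solve_triangular

    def moments(b):
        eta = offset + X @ b
        pi = sigmoid(eta)
        w = np.clip(pi * (1.0 - pi), _W_MIN, None)
        Q = X.T @ (X * w[:, None]) + prior_prec
        grad = X.T @ (y - pi) - prior_prec @ (b - prior_mean)
        cf = cho_factor(Q, lower=True)
        mean = b + 0.5 * eps**2 * cho_solve(cf, grad)
        return mean, cf

    def logq(x, mean, cf):
        L = np.tril(cf[0])
        diff = x - mean
        quad = diff @ cho_solve(cf, diff) / eps**2
        k = len(x)
        logdet = 2.0 * np.sum(np.log(np.diag(L))) - 2.0 * k * np.log(eps)
        return 0.5 * (logdet - quad - k * np.log(2.0 * np.pi))

    def logpost(b):
        ll = bernoulli_loglik(y, offset + X @ b)
        diff = b - prior_mean
        return ll - 0.5 * diff @ prior_prec @ diff

    m_cur, cf_cur = moments(beta)
    L = np.tril(cf_cur[0])
    z = rng.standard_normal(len(beta))
    from scipy.linalg import solve_triangular as _st

    prop = m_cur + eps * _st(L, z, lower=True, trans="T")
    m_prop, cf_prop = moments(prop)
    log_acc = (
        logpost(prop) - logpost(beta)
        + logq(beta, m_prop, cf_prop) - logq(prop, m_cur, cf_cur)
    )
    if np.log(rng.uniform()) < log_acc:
        return prop, True
    return beta, False


class AdaptiveRW:
    """Adaptive random-walk Metropolis for a small parameter block.

    During burn-in the global scale follows a Robbins–Monro recursion toward
    ``target`` acceptance and the proposal covariance tracks the empirical
    covariance of the chain (Haario-style).  After ``adapt_until`` steps the
    kernel is frozen, so the chain is a valid Markov chain from then on.
    """

    def __init__(self, dim, scale=0.1, target=0.3, adapt_until=np.inf):
        self.dim = dim
        self.log_scale = np.log(scale)
        self.target = target
        self.adapt_until = adapt_until
        self.cov = np.eye(dim)
        self._mean = np.zeros(dim)
        self._n = 0
        self.accepted = 0
        self.steps = 0

    def propose(self, x, rng):
        L = np.linalg.cholesky(self.cov + 1e-10 * np.eye(self.dim))
        return x + np.exp(self.log_scale) * (L @ rng.standard_normal(self.dim))

    def update(self, x, accepted):
        self.steps += 1
        self.accepted += bool(accepted)
        if self.steps >= self.adapt_until:
            return
        g = 1.0 / max(20, self.steps) ** 0.6
        self.log_scale += g * ((1.0 if accepted else 0.0) - self.target)
        self._n += 1
        d = x - self._mean
        self._mean += d / self._n
        if self._n > 2 * self.dim:
            self.cov += g * (np.outer(d, d) - self.cov)

    @property
    def acceptance_rate(self):
        return self.accepted / max(1, self.steps)


def sample_invgamma(a, b, rng):
    """Draw from InvGamma(shape=a, rate... scale=b) i.e. x ~ 1/Gamma(a, 1/b)."""
    return b / rng.gamma(a)


def sample_invgamma_truncated(a, b, rng, lo, hi, max_tries=100):
    """Rejection draw from InvGamma(a, scale=b) truncated to [lo, hi].

    In the bulk the bound never binds and this costs one gamma draw; when the
    conditional mass sits almost entirely above ``hi`` the draw is pinned to
    the bound.
    """
    for _ in range(max_tries):
        x = b / rng.gamma(a)
        if lo <= x <= hi:
            return float(x)
    return float(hi if b / max(a - 1.0, 1e-3) > hi else lo)


def split_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for draws (n_chains, n_draws)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m, nn = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = nn * chain_means.var(ddof=1)
    if W <= 0:
        return np.nan
    var_plus = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_plus / W))


def effective_size(draws: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of a 1-d chain."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) < 1e-300:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 1.0
    for k in range(1, n - 2, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        s += 2 * pair
    return float(n / max(s, 1.0))
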