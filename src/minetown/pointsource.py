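"""Parametric Bayesian distance-risk models around a point source.

The central object is the distance–odds function

    f(d | alpha, phi, delta) = 1 + alpha,                              d <= delta
                               1 + alpha * exp(-((d - delta)/phi)^2),  d >  delta

a plateau of elevated odds (odds ratio 1 + alpha at the source) of radius
delta km, decaying as a Gaussian with scale phi km toward the far-field odds
ratio of 1.  It enters a Bernoulli-logit model on the log scale,

    logit(pi_i) = beta0 + log f(d_i) + x_i' beta + S(s_i),

so that 1 + alpha is exactly the odds ratio between a child at the source and
a far-field child with the same covariates.  (A literal additive-f predictor
is available via ``f_mode="additive"`` for comparison.)  S is a low-rank
Gaussian-kernel spatial field on k-means knots with a sum-to-zero constraint
on the knot weights (identifiability against the intercept).

Four nested models are fitted by MCMC and compared by DIC:

* Model 0: beta0 + x'beta                       (confounders only)
* Model 1: beta0 + x'beta + S(s)                (spatial variation)
* Model 2: beta0 + log f(d) + x'beta            (distance-risk function)
* Model 3: beta0 + log f(d) + x'beta + S(s)     (both)

The threshold distance — the largest distance up to which the pointwise lower
95% credible bound of f stays above 1 — summarises where proximity carries a
non-negligible health impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import svd

from . import geodesy
from .mcmc import (
    AdaptiveRW,
    bernoulli_loglik,
    mala_update,
    sample_invgamma_truncated,
    split_rhat,
    effective_size,
)

EXPOSURE_MODES = ("gold", "copper", "average")

# hyperprior for the spatial-weight variance tau^2: moderately informative on
# the scale of log-odds spatial fields (mode ~0.017); vague IG(eps, eps)
# choices either collapse the field or admit overfit regions where the
# weight-block sampler mixes terribly.  Support truncated: an unbounded tail
# lets the variance run away with weakly identified weight directions.
_IG_A = 2.0
_IG_B = 0.05
_TAU2_MAX = 5.0


def distance_risk(d, alpha, phi, delta):
    """Distance–odds function f(d): plateau 1+alpha, then Gaussian decay to 1."""
    if np.any(np.asarray(phi) <= 0):
        raise ValueError("phi must be > 0")
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(delta) < 0):
        raise ValueError("alpha and delta must be >= 0")
    d = np.asarray(d, dtype=float)
    excess = np.where(d <= delta, 1.0, np.exp(-(((d - delta) / phi) ** 2)))
    return 1.0 + alpha * excess


def model_linpred(d, X, beta0, beta, params=None, s=None, f_mode="log"):
    """Linear predictor beta0 + [log] f(d) + X beta + S.

    ``params`` is ``(alpha, phi, delta)`` or None for the no-distance models;
    ``s`` the spatial effect per child or None.
    """
    d = np.asarray(d, dtype=float)
    eta = beta0 + (np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
                   if np.size(beta) else 0.0)
    if params is not None:
        f = distance_risk(d, *params)
        eta = eta + (np.log(f) if f_mode == "log" else f)
    if s is not None:
        eta = eta + s
    return eta


# ---------------------------------------------------------------------------
# low-rank spatial field


@dataclass
class SpatialEffect:
    """Gaussian-kernel basis on k-means knots with sum-to-zero knot weights."""

    center: tuple[float, float]
    knots_xy: np.ndarray          # (T, 2) planar km
    bandwidth: float              # kernel sd, km
    contrast: np.ndarray          # (T, T-1) orthonormal basis of the sum-zero space
    design: np.ndarray            # (n, T-1) = kernel matrix @ contrast

    @property
    def n_knots(self) -> int:
        return len(self.knots_xy)

    @property
    def n_effective(self) -> int:
        return self.contrast.shape[1]

    def kernel(self, xy: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - self.knots_xy[None, :, :]) ** 2).sum(-1)
        return np.exp(-0.5 * d2 / self.bandwidth**2)

    def basis_for(self, lat, lon) -> np.ndarray:
        xy = geodesy.to_planar_km(np.asarray(lat), np.asarray(lon), self.center)
        return self.kernel(xy) @ self.contrast

    def weights_from_u(self, u: np.ndarray) -> np.ndarray:
        """Knot weights (sum exactly zero) from unconstrained coordinates."""
        return self.contrast @ u


def build_spatial_basis(
    table: pd.DataFrame,
    n_knots: int = 40,
    seed: int = 0,
    bandwidth: float | None = None,
    center: tuple[float, float] | None = None,
) -> SpatialEffect:
    """K-means knots over planar-projected residences + Gaussian kernel basis.

    Bandwidth defaults to the median inter-knot distance.  If fewer residences
    than knots are available the knot count is reduced with a warning.
    """
    from sklearn.cluster import KMeans

    lat = table["lat"].to_numpy(float)
    lon = table["lon"].to_numpy(float)
    if center is None:
        center = (float(np.mean(lat)), float(np.mean(lon)))
    xy = geodesy.to_planar_km(lat, lon, center)
    uniq = np.unique(xy, axis=0)
    if len(uniq) < 2:
        raise ValueError("degenerate geometry: all residences at one location")
    T = int(n_knots)
    if T > len(uniq):
        warnings.warn(f"reducing spatial knots from {T} to {len(uniq)} (too few residences)")
        T = len(uniq)
    if T == 1:
        knots = uniq.mean(axis=0, keepdims=True)
        contrast = np.zeros((1, 0))
        return SpatialEffect(center, knots, 1.0, contrast, np.zeros((len(xy), 0)))
    km = KMeans(n_clusters=T, n_init=4, random_state=seed).fit(xy)
    knots = km.cluster_centers_
    if bandwidth is None:
        # scale with neighbour spacing: a bandwidth tied to the overall knot
        # cloud makes all kernels nearly identical (condition numbers ~1e9)
        # and the weight block unidentifiable
        dk = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dk, np.inf)
        bandwidth = float(1.5 * np.median(dk.min(axis=1)))
    # orthonormal basis of {w : sum(w) = 0}
    H = np.eye(T) - np.full((T, T), 1.0 / T)
    U, s, _ = svd(H)
    contrast = U[:, : T - 1]
    eff = SpatialEffect(center, knots, float(bandwidth), contrast, np.empty((0, 0)))
    eff.design = eff.kernel(xy) @ contrast
    return eff


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class McmcSettings:
    chains: int = 4
    iterations: int = 20000
    burnin: int = 5000
    thin: int = 5

    def __post_init__(self):
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be < iterations")


class Threshold(NamedTuple):
    km: float
    censored: bool  # True when the lower bound stays above 1 out to the grid end


@dataclass
class ModelFit:
    """Posterior draws and summaries for one of Models 0–3."""

    model_id: int
    coef_names: list[str]
    draws: dict[str, np.ndarray]
    n_chains: int
    rhat: dict[str, float]
    ess: dict[str, float]
    warning: bool
    accept: dict[str, float] | None = None
    f_mode: str = "log"
    dic: float = np.nan
    pd_eff: float = np.nan
    dbar: float = np.nan
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _d: np.ndarray | None = None
    _spatial: SpatialEffect | None = None

    @property
    def has_distance(self) -> bool:
        return self.model_id in (2, 3)

    @property
    def has_spatial(self) -> bool:
        return self.model_id in (1, 3)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("alpha", "phi", "delta"):
            if name in self.draws:
                v = self.draws[name]
                rows.append(
                    {"param": name, "mean": v.mean(), "median": np.median(v),
                     "lcl": np.percentile(v, 2.5), "ucl": np.percentile(v, 97.5)}
                )
        B = self.draws["beta"]
        for j, nm in enumerate(self.coef_names):
            v = B[:, j]
            rows.append(
                {"param": nm, "mean": v.mean(), "median": np.median(v),
                 "lcl": np.percentile(v, 2.5), "ucl": np.percentile(v, 97.5)}
            )
        return pd.DataFrame(rows)


def _linpred_terms(Xfull, beta, d, theta, spatial_design, u, f_mode):
    eta = Xfull @ beta
    if theta is not None:
        f = distance_risk(d, np.exp(theta[0]), np.exp(theta[1]), theta[2])
        eta = eta + (np.log(f) if f_mode == "log" else f)
    if u is not None and u.size:
        eta = eta + spatial_design @ u
    return eta


def fit_model(
    y: np.ndarray,
    X: np.ndarray,
    distances: np.ndarray | None,
    model_id: int,
    priors=None,
    spatial: SpatialEffect | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    f_mode: str = "log",
    coef_names: list[str] | None = None,
    beta_prior_sd: float = 100.0,
) -> ModelFit:
    """MCMC posterior for one of Models 0–3.

    ``X`` holds the confounder design without intercept (may have 0 columns);
    an intercept column is added internally.  ``priors`` (a
    :class:`minetown.star.PriorSpec`) is required for Models 2–3: alpha and phi
    are sampled on the log scale with the calibrated log-normal priors, delta
    uniformly on its support.  Models 1 and 3 need ``spatial``.
    """
    from .star import PriorSpec

    if model_id not in (0, 1, 2, 3):
        raise ValueError("model_id must be in {0,1,2,3}")
    has_dist = model_id in (2, 3)
    has_spat = model_id in (1, 3)
    if has_dist:
        if distances is None:
            raise ValueError("distance models need distances")
        if priors is None:
            priors = PriorSpec.default(float(np.max(distances)))
    if has_spat and spatial is None:
        raise ValueError("spatial models need a SpatialEffect basis")
    mcmc = mcmc or McmcSettings()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("outcome or design contains non-finite values")
    n = len(y)
    Xfull = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    p = Xfull.shape[1]
    names = ["(Intercept)"] + (coef_names if coef_names is not None
                               else [f"x{j}" for j in range(p - 1)])
    P_beta = np.eye(p) / beta_prior_sd**2
    mu_beta = np.zeros(p)
    d = np.asarray(distances, dtype=float) if has_dist else None
    Zd = spatial.design if has_spat else None
    ku = Zd.shape[1] if has_spat else 0

    n_keep = (mcmc.iterations - mcmc.burnin) // mcmc.thin
    per_chain: list[dict[str, np.ndarray]] = []
    accept_info: list[dict[str, float]] = []
    ss = np.random.SeedSequence(seed)
    for chain, child in enumerate(ss.spawn(mcmc.chains)):
        rng = np.random.default_rng(child)
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        beta += 0.1 * rng.standard_normal(p)  # overdispersed starts across chains
        u = np.zeros(ku)
        tau2 = 0.1
        if has_dist:
            theta = np.array([
                priors.alpha_mu + 0.2 * rng.standard_normal(),
                priors.phi_mu + 0.2 * rng.standard_normal(),
                0.25 * (priors.delta_lo + priors.delta_hi)
                + 0.1 * rng.uniform() * (priors.delta_hi - priors.delta_lo),
            ])
            rw = AdaptiveRW(3, scale=0.15, adapt_until=mcmc.burnin)
        else:
            theta = None
        store = {
            "beta": np.empty((n_keep, p)),
            "deviance": np.empty(n_keep),
        }
        if has_dist:
            for nm in ("alpha", "phi", "delta"):
                store[nm] = np.empty(n_keep)
        if has_spat:
            store["u"] = np.empty((n_keep, ku))
            store["tau2"] = np.empty(n_keep)
        kept = 0
        # (beta, u) form one joint IWLS block: the intercept and the level of
        # the spatial field are strongly correlated a posteriori and mix
        # poorly when updated separately
        J = np.column_stack([Xfull, Zd]) if has_spat and ku else Xfull
        coef = np.concatenate([beta, u])
        n_acc_coef = 0
        # preconditioned MALA with adapted step: the full-IWLS independence
        # proposal both collapses in high dimension (spatial blocks) and can
        # freeze at metastable near-separation states it cannot escape
        log_eps = np.log(0.5)
        for it in range(mcmc.iterations):
            f_offset = np.zeros(n)
            if has_dist:
                f = distance_risk(d, np.exp(theta[0]), np.exp(theta[1]), theta[2])
                f_offset = np.log(f) if f_mode == "log" else f
            if has_spat and ku:
                prior_prec = np.zeros((p + ku, p + ku))
                prior_prec[:p, :p] = P_beta
                prior_prec[p:, p:] = np.eye(ku) / tau2
            else:
                prior_prec = P_beta
            coef, acc_c = mala_update(y, J, f_offset, coef, prior_prec,
                                      np.zeros(len(coef)), rng, np.exp(log_eps))
            if it < mcmc.burnin:
                log_eps += ((1.0 if acc_c else 0.0) - 0.5) / max(20, it) ** 0.6
            n_acc_coef += acc_c
            beta, u = coef[:p], coef[p:]

            if has_dist:
                base = J @ coef  # includes the current intercept

                def theta_logpost(th, b0_shift=0.0):
                    if not (priors.delta_lo <= th[2] <= priors.delta_hi):
                        return -np.inf
                    f = distance_risk(d, np.exp(th[0]), np.exp(th[1]), th[2])
                    eta = base + b0_shift + (np.log(f) if f_mode == "log" else f)
                    lp = bernoulli_loglik(y, eta)
                    lp += -0.5 * ((th[0] - priors.alpha_mu) / priors.alpha_sigma) ** 2
                    lp += -0.5 * ((th[1] - priors.phi_mu) / priors.phi_sigma) ** 2
                    b0 = coef[0] + b0_shift
                    lp += -0.5 * P_beta[0, 0] * b0 * b0
                    return lp

                def mean_f_term(th):
                    f = distance_risk(d, np.exp(th[0]), np.exp(th[1]), th[2])
                    return float(np.mean(np.log(f) if f_mode == "log" else f))

                # propose theta together with a compensating intercept shift
                # (a volume-preserving shear along the beta0 <-> level-of-f
                # ridge, which otherwise dominates the autocorrelation)
                cur_lp = theta_logpost(theta)
                prop = rw.propose(theta, rng)
                if priors.delta_lo <= prop[2] <= priors.delta_hi:
                    shift = mean_f_term(theta) - mean_f_term(prop)
                    prop_lp = theta_logpost(prop, b0_shift=shift)
                else:
                    shift, prop_lp = 0.0, -np.inf
                acc = np.log(rng.uniform()) < prop_lp - cur_lp
                if acc:
                    theta = prop
                    coef[0] += shift
                rw.update(theta, acc)

            if has_spat and ku:
                tau2 = sample_invgamma_truncated(
                    _IG_A + 0.5 * ku, _IG_B + 0.5 * (u @ u), rng, 1e-8, _TAU2_MAX)

            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and kept < n_keep:
                eta = _linpred_terms(Xfull, beta, d, theta, Zd, u, f_mode)
                store["beta"][kept] = beta
                store["deviance"][kept] = -2.0 * bernoulli_loglik(y, eta)
                if has_dist:
                    store["alpha"][kept] = np.exp(theta[0])
                    store["phi"][kept] = np.exp(theta[1])
                    store["delta"][kept] = theta[2]
                if has_spat:
                    store["u"][kept] = u
                    store["tau2"][kept] = tau2
                kept += 1
        rates = {"coef": n_acc_coef / mcmc.iterations}
        if has_dist:
            rates["theta"] = rw.acceptance_rate
        accept_info.append(rates)
        per_chain.append({k: v[:kept] for k, v in store.items()})

    draws = {k: np.concatenate([c[k] for c in per_chain], axis=0) for k in per_chain[0]}
    rhat, ess = {}, {}
    scalars = ["beta0"] + (["alpha", "phi", "delta"] if has_dist else [])
    chains_b0 = np.stack([c["beta"][:, 0] for c in per_chain])
    rhat["beta0"] = split_rhat(chains_b0)
    ess["beta0"] = effective_size(draws["beta"][:, 0])
    for nm in scalars[1:]:
        rhat[nm] = split_rhat(np.stack([c[nm] for c in per_chain]))
        ess[nm] = effective_size(draws[nm])
    warning = any((not np.isfinite(v)) or v > 1.1 for v in rhat.values())

    accept = {k: float(np.mean([r[k] for r in accept_info]))
              for k in accept_info[0]}
    fit = ModelFit(
        model_id=model_id, coef_names=names, draws=draws, n_chains=mcmc.chains,
        rhat=rhat, ess=ess, warning=warning, accept=accept, f_mode=f_mode,
        _y=y, _X=Xfull, _d=d, _spatial=spatial,
    )
    fit.dic, fit.pd_eff, fit.dbar = compute_dic(fit)
    return fit


def compute_dic(fit: ModelFit) -> tuple[float, float, float]:
    """DIC = Dbar + pD with pD = Dbar - D(posterior-median parameters).

    The plug-in uses componentwise posterior medians: for the strongly skewed
    nonlinear parameters (alpha especially) the mean can land in a region of
    terrible fit and make pD meaningless, while the median stays with the
    bulk of the posterior.  For symmetric posteriors the two coincide.
    """
    dev = fit.draws["deviance"]
    dbar = float(dev.mean())
    beta_bar = np.median(fit.draws["beta"], axis=0)
    theta_bar = None
    if fit.has_distance:
        theta_bar = np.array([
            np.log(np.median(fit.draws["alpha"])),
            np.log(np.median(fit.draws["phi"])),
            np.median(fit.draws["delta"]),
        ])
    u_bar = np.median(fit.draws["u"], axis=0) if fit.has_spatial else None
    Zd = fit._spatial.design if fit.has_spatial else None
    eta = _linpred_terms(fit._X, beta_bar, fit._d, theta_bar, Zd, u_bar, fit.f_mode)
    d_hat = -2.0 * bernoulli_loglik(fit._y, eta)
    p_eff = dbar - d_hat
    if p_eff < 0:
        warnings.warn("negative effective number of parameters (pD); reported as-is")
    return dbar + p_eff, p_eff, dbar


def posterior_f_curve(fit: ModelFit, grid: np.ndarray) -> pd.DataFrame:
    """Pointwise posterior mean and 95% credible band of f on a distance grid."""
    if not fit.has_distance:
        raise ValueError("f curve only defined for Models 2 and 3")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty distance grid")
    a = fit.draws["alpha"][:, None]
    ph = fit.draws["phi"][:, None]
    de = fit.draws["delta"][:, None]
    g = grid[None, :]
    excess = np.where(g <= de, 1.0, np.exp(-(((g - de) / ph) ** 2)))
    fdraws = 1.0 + a * excess
    return pd.DataFrame({
        "distance_km": grid,
        "mean": fdraws.mean(axis=0),
        "lcl": np.percentile(fdraws, 2.5, axis=0),
        "ucl": np.percentile(fdraws, 97.5, axis=0),
    })


def threshold_distance(curve: pd.DataFrame, tol: float = 0.05) -> Threshold | None:
    """Largest distance below which the lower 95% bound of f exceeds 1 everywhere.

    Because f > 1 strictly at every finite distance, "reaches 1" is judged
    with a negligibility tolerance: the crossing is where the lower bound
    drops to 1 + ``tol`` (default: excess odds of 5% or less counts as
    negligible).  Linear interpolation locates the crossing between grid
    points.  Returns None when the lower bound is already at or below the
    tolerance at the first grid point; a ``censored`` threshold equal to the
    grid end when it never drops that far.
    """
    d = curve["distance_km"].to_numpy(float)
    low = curve["lcl"].to_numpy(float)
    above = low > 1.0 + tol
    if not above[0]:
        return None
    if above.all():
        return Threshold(float(d[-1]), censored=True)
    i = int(np.argmin(above))  # first False
    d0, d1 = d[i - 1], d[i]
    l0, l1 = low[i - 1], low[i]
    t = (l0 - (1.0 + tol)) / (l0 - l1) if l0 != l1 else 0.0
    return Threshold(float(d0 + t * (d1 - d0)), censored=False)
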