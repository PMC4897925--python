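"""Stage 1 — dichotomized logistic regression with multiple imputation.

Crude and adjusted logistic models relate each binary respiratory outcome to
the closest-quartile proximity indicator.  Covariates whose crude association
with the outcome reaches Wald p < 0.05 are kept as potential confounders for
all adjusted models.  Item nonresponse is handled by multiple imputation under
a missing-at-random assumption: m completed datasets are produced by
bootstrap-EM on a joint multivariate-normal latent model (categoricals as
rounded dummies), the analysis model is fitted on each, and estimates are
pooled with Rubin's rules using Barnard–Rubin small-sample degrees of freedom.

Maximum-likelihood logistic fits delegate to statsmodels (IRLS); this module
owns the design building, screening, imputation and pooling logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import CATEGORIES, OUTCOME_COLUMNS


@dataclass
class LogisticFit:
    """ML logistic fit: coefficients, covariance, OR table, bookkeeping."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_total: int
    converged: bool
    separation: bool = False

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.se
        return pd.DataFrame({
            "estimate": self.params,
            "OR": np.exp(self.params),
            "lcl": np.exp(self.params - z * se),
            "ucl": np.exp(self.params + z * se),
            "p": 2 * stats.norm.sf(np.abs(self.params / se)),
        })


@dataclass
class PooledFit:
    """Rubin's-rules combination of m logistic fits on identical designs."""

    estimate: pd.Series
    within: pd.Series      # W: mean within-imputation variance
    between: pd.Series     # B: between-imputation variance
    total: pd.Series       # T = W + (1 + 1/m) B
    df: pd.Series          # Barnard–Rubin degrees of freedom
    m: int

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        se = np.sqrt(self.total)
        tq = pd.Series(
            [stats.t.ppf(0.5 + level / 2, v) if np.isfinite(v) else stats.norm.ppf(0.5 + level / 2)
             for v in self.df], index=self.df.index,
        )
        return pd.DataFrame({
            "estimate": self.estimate,
            "OR": np.exp(self.estimate),
            "lcl": np.exp(self.estimate - tq * se),
            "ucl": np.exp(self.estimate + tq * se),
        })


def build_design(
    table: pd.DataFrame,
    outcome: str,
    terms: list[str],
    extra: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Complete-case outcome vector and dummy-coded design for *terms*.

    Categorical covariates are expanded against their reference level (the
    first level in :data:`minetown.synthetic.CATEGORIES`); numeric columns
    (e.g. a q1 exposure indicator merged in via *extra*) pass through.
    Returns ``(y, X, n_dropped)``.
    """
    tab = table.copy()
    if extra is not None:
        tab = tab.join(extra, on="child_id") if "child_id" in tab.columns else tab.join(extra)
    cols = [outcome] + list(terms)
    sub = tab[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    y = sub[outcome].astype(float)
    parts = []
    for t in terms:
        if t in CATEGORIES:
            levels = CATEGORIES[t]
            cat = pd.Categorical(sub[t], categories=levels)
            dm = pd.get_dummies(cat, prefix=t, drop_first=True, dtype=float)
            dm.index = sub.index  # Categorical dummies come back with a bare RangeIndex
            parts.append(dm)
        else:
            parts.append(sub[[t]].astype(float))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=sub.index)
    return y, X, n0 - len(sub)


def fit_logistic(y: pd.Series, X: pd.DataFrame, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression (statsmodels IRLS) with Wald CIs.

    Complete separation is flagged (no usable estimate) rather than returning
    divergent coefficients.
    """
    Xd = sm.add_constant(X.astype(float), has_constant="add") if add_intercept else X.astype(float)
    if not np.all(np.isfinite(np.asarray(Xd, float))) or not np.all(np.isfinite(np.asarray(y, float))):
        raise ValueError("logistic design or outcome contains non-finite values")
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(np.asarray(y, float), np.asarray(Xd, float),
                         family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            nan = pd.Series(np.nan, index=Xd.columns)
            return LogisticFit(nan, pd.DataFrame(np.nan, index=Xd.columns, columns=Xd.columns),
                               n, n, converged=False, separation=True)
    params = pd.Series(res.params, index=Xd.columns)
    cov = pd.DataFrame(res.cov_params(), index=Xd.columns, columns=Xd.columns)
    se = np.sqrt(np.diag(cov))
    separation = bool(np.any(~np.isfinite(se)) or np.any(np.abs(params) > 15) or np.any(se > 50))
    return LogisticFit(params, cov, n_used=n, n_total=n,
                       converged=bool(res.converged), separation=separation)


def screen_confounders(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    p_threshold: float = 0.05,
) -> list[str]:
    """Crude-association screen: keep candidates with joint Wald p < threshold.

    Each candidate is tested alone against the outcome (complete cases for
    that pair); multi-level categoricals use a joint Wald chi-square across
    their dummy block.
    """
    kept = []
    for cand in candidates:
        y, X, _ = build_design(table, outcome, [cand])
        if X.shape[1] == 0 or y.nunique() < 2:
            continue
        fit = fit_logistic(y, X)
        if fit.separation or not fit.converged:
            continue
        idx = [c for c in fit.params.index if c != "const"]
        b = fit.params[idx].to_numpy()
        V = fit.cov.loc[idx, idx].to_numpy()
        try:
            w = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            continue
        p = stats.chi2.sf(w, df=len(idx))
        if p < p_threshold:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# multiple imputation: bootstrap-EM on a joint multivariate-normal latent model


def _encode(table: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[tuple]]:
    """Map categorical/binary columns onto a numeric latent matrix.

    Binary categoricals and outcomes become 0/1; multi-level categoricals
    become one dummy per non-reference level.  Returns the matrix (NaN for
    missing) and a per-column decode recipe.
    """
    mats, recipe = [], []
    for col in columns:
        if col in CATEGORIES:
            levels = CATEGORIES[col]
            if len(levels) == 2:
                v = table[col].map({levels[0]: 0.0, levels[1]: 1.0}).astype(float)
                mats.append(v.to_numpy()[:, None])
                recipe.append((col, "binary", levels))
            else:
                cat = pd.Categorical(table[col], categories=levels)
                dm = pd.get_dummies(cat, drop_first=True, dtype=float).to_numpy()
                dm[table[col].isna().to_numpy()] = np.nan
                mats.append(dm)
                recipe.append((col, "multi", levels))
        else:  # numeric (outcome 0/1 or a distance column)
            v = pd.to_numeric(table[col], errors="coerce").astype(float)
            kind = "binary01" if col in OUTCOME_COLUMNS else "numeric"
            mats.append(v.to_numpy()[:, None])
            recipe.append((col, kind, None))
    return np.hstack(mats), recipe


def _decode(Z: np.ndarray, recipe: list[tuple], index) -> pd.DataFrame:
    out = {}
    j = 0
    for col, kind, levels in recipe:
        if kind == "binary":
            out[col] = np.where(Z[:, j] >= 0.5, levels[1], levels[0])
            j += 1
        elif kind == "multi":
            k = len(levels) - 1
            block = Z[:, j : j + k]
            # winning dummy, or the reference level when none exceeds 1/2
            best = block.argmax(axis=1)
            ref = block.max(axis=1) < 0.5
            lab = np.array(levels[1:], dtype=object)[best]
            lab[ref] = levels[0]
            out[col] = lab
            j += k
        elif kind == "binary01":
            out[col] = np.clip(np.round(Z[:, j]), 0, 1)
            j += 1
        else:
            out[col] = Z[:, j]
            j += 1
    return pd.DataFrame(out, index=index)


def _em_mvnorm(Z: np.ndarray, max_iter: int = 60, tol: float = 1e-5, ridge: float = 1e-6):
    """EM for the mean and covariance of a multivariate normal with missing data."""
    n, p = Z.shape
    mu = np.nanmean(Z, axis=0)
    filled = np.where(np.isnan(Z), mu, Z)
    sigma = np.cov(filled, rowvar=False) + ridge * np.eye(p)
    patterns: dict[bytes, np.ndarray] = {}
    isna = np.isnan(Z)
    for i in range(n):
        patterns.setdefault(isna[i].tobytes(), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}
    for _ in range(max_iter):
        ex = np.empty_like(filled)
        exx_corr = np.zeros((p, p))
        for key, rows in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            obs = ~miss
            zo = Z[np.ix_(rows, obs)]
            if not miss.any():
                ex[rows] = Z[rows]
                continue
            Soo = sigma[np.ix_(obs, obs)] + ridge * np.eye(obs.sum())
            Smo = sigma[np.ix_(miss, obs)]
            W = np.linalg.solve(Soo, Smo.T).T        # (n_miss, n_obs)
            cond_mu = mu[miss] + (zo - mu[obs]) @ W.T
            cond_cov = sigma[np.ix_(miss, miss)] - W @ Smo.T
            block = np.zeros((len(rows), p))
            block[:, obs] = zo
            block[:, miss] = cond_mu
            ex[rows] = block
            exx_corr[np.ix_(miss, miss)] += len(rows) * cond_cov
        mu_new = ex.mean(axis=0)
        diff = ex - mu_new
        sigma_new = (diff.T @ diff + exx_corr) / n + ridge * np.eye(p)
        done = np.max(np.abs(mu_new - mu)) < tol and np.max(np.abs(sigma_new - sigma)) < tol
        mu, sigma = mu_new, sigma_new
        if done:
            break
    return mu, sigma


def _draw_missing(Z: np.ndarray, mu: np.ndarray, sigma: np.ndarray, rng, ridge=1e-6):
    """Impute NaN cells from their conditional normal given the observed cells."""
    out = Z.copy()
    for i in np.flatnonzero(np.isnan(Z).any(axis=1)):
        miss = np.isnan(Z[i])
        obs = ~miss
        Soo = sigma[np.ix_(obs, obs)] + ridge * np.eye(obs.sum())
        Smo = sigma[np.ix_(miss, obs)]
        W = np.linalg.solve(Soo, Smo.T).T
        cmu = mu[miss] + W @ (Z[i, obs] - mu[obs])
        ccov = sigma[np.ix_(miss, miss)] - W @ Smo.T
        ccov = 0.5 * (ccov + ccov.T) + ridge * np.eye(miss.sum())
        out[i, miss] = rng.multivariate_normal(cmu, ccov, method="cholesky")
    return out


def multiple_impute(
    table: pd.DataFrame,
    m: int = 7,
    seed: int = 0,
    columns: list[str] | None = None,
    max_missing_frac: float = 0.9,
) -> list[pd.DataFrame]:
    """m completed tables via bootstrap-EM multivariate-normal imputation.

    For each imputation the MVN parameters are estimated by EM on a bootstrap
    resample (propagating estimation uncertainty, as in the Amelia class of
    algorithms), then every missing cell of the *original* table is drawn from
    its conditional normal and rounded back to a valid category.
    Coordinates are never imputed.  Deterministic given ``seed``.
    """
    if m < 2:
        raise ValueError("need m >= 2 imputations")
    cols = columns or [c for c in table.columns
                       if c in CATEGORIES or c in OUTCOME_COLUMNS]
    frac = table[cols].isna().mean()
    too_missing = frac[frac > max_missing_frac]
    if len(too_missing):
        raise ValueError(f"columns over {max_missing_frac:.0%} missing: "
                         f"{list(too_missing.index)}")
    Z, recipe = _encode(table, cols)
    if not np.isnan(Z).any():
        return [table.copy() for _ in range(m)]
    rng = np.random.default_rng(seed)
    n = len(Z)
    out = []
    for _ in range(m):
        boot = rng.integers(0, n, size=n)
        # guard: the bootstrap must keep at least one observed value per column
        for _retry in range(20):
            if not np.isnan(Z[boot]).all(axis=0).any():
                break
            boot = rng.integers(0, n, size=n)
        mu, sigma = _em_mvnorm(Z[boot])
        Zi = _draw_missing(Z, mu, sigma, rng)
        dec = _decode(Zi, recipe, table.index)
        tab = table.copy()
        for col in cols:
            filled = tab[col].copy()
            mask = filled.isna()
            filled[mask] = dec.loc[mask, col]
            tab[col] = filled
        out.append(tab)
    return out


def pool_rubin(fits: list[LogisticFit]) -> PooledFit:
    """Rubin's rules with Barnard–Rubin small-sample degrees of freedom."""
    if len(fits) < 2:
        raise ValueError("pooling needs at least 2 fits")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError("fits have mismatched coefficient sets")
    m = len(fits)
    Q = np.vstack([f.params.to_numpy() for f in fits])
    U = np.vstack([np.diag(f.cov.to_numpy()) for f in fits])
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    B[B < 1e-12 * np.maximum(W, 1e-12)] = 0.0  # identical fits pool exactly
    T = W + (1 + 1 / m) * B
    n_used = min(f.n_used for f in fits)
    k = len(names)
    nu_com = max(n_used - k, 1)
    df = np.empty(k)
    for j in range(k):
        if B[j] <= 0:
            df[j] = np.inf
            continue
        lam = (1 + 1 / m) * B[j] / T[j]
        df_old = (m - 1) / lam**2
        df_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
        df[j] = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    idx = pd.Index(names)
    return PooledFit(
        estimate=pd.Series(qbar, idx), within=pd.Series(W, idx),
        between=pd.Series(B, idx), total=pd.Series(T, idx),
        df=pd.Series(df, idx), m=m,
    )


def tidy_or_table(fits: dict[str, LogisticFit | PooledFit]) -> pd.DataFrame:
    """Long-format OR table (model_id, term, estimate, OR, lcl, ucl) for export."""
    rows = []
    for model_id, fit in fits.items():
        tab = fit.or_table()
        n_used = getattr(fit, "n_used", np.nan)
        for term, r in tab.iterrows():
            rows.append({"model_id": model_id, "term": term, "estimate": r["estimate"],
                         "OR": r["OR"], "lcl": r["lcl"], "ucl": r["ucl"], "n_used": n_used})
    return pd.DataFrame(rows)
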