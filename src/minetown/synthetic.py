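"""Synthetic study-town generator.

The analyses in this package were designed for an individual-level
cross-sectional dataset (children in a small mining town, geocoded residences,
two respiratory outcomes, questionnaire covariates) that is not publicly
available.  This module generates tables with the same statistical structure
from known ground-truth parameters, so every downstream stage — dichotomized
logistic regression, the P-spline additive model, and the parametric
distance-risk models — can be validated by parameter recovery.

Geometry: residences are drawn from an isotropic Gaussian on a local tangent
plane around the town centre and converted back to latitude/longitude; the two
mines sit 1–3 km away.  Outcomes are Bernoulli draws from

    logit(pi_i) = beta0 + log f(d_i | alpha, phi, delta) + x_i' beta + S(s_i)

where f is the plateau/Gaussian-decay distance-odds function (see
:mod:`minetown.pointsource`) and S is a zero-mean spatial field.  Covariate
marginals and item-nonresponse rates default to values typical of a
~275-child questionnaire study in this setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geodesy

OUTCOME_COLUMNS = ["asthma", "rhinoconjunctivitis"]

#: allowed category levels per covariate; first level is the reference
CATEGORIES: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "age_group": ["6-7", "8-9", "10-11", "12+"],
    "parental_atopy": ["no", "yes"],
    "mother_working": ["no", "yes"],
    "father_working": ["no", "yes"],
    "lives_with_both_parents": ["no", "yes"],
    "smoking_at_home": ["no", "yes"],
    "heater_type": ["other", "coal_gas"],
    "paved_street": ["no", "yes"],
    "play_area": ["inside", "outside"],
    "hours_at_home": ["<3h", "3-6h", ">6h"],
}

COVARIATE_COLUMNS = list(CATEGORIES)
STUDY_COLUMNS = ["child_id", "lat", "lon"] + OUTCOME_COLUMNS + COVARIATE_COLUMNS

#: default covariate marginals: observed percentages renormalized to sum to 1
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.46, "male": 0.54},
    "age_group": {"6-7": 0.27, "8-9": 0.31, "10-11": 0.30, "12+": 0.12},
    "lives_with_both_parents": {"no": 29 / 96, "yes": 67 / 96},
    "parental_atopy": {"no": 58 / 89, "yes": 31 / 89},
    "mother_working": {"no": 69 / 94, "yes": 25 / 94},
    "father_working": {"no": 8 / 92, "yes": 84 / 92},
    "hours_at_home": {"<3h": 7 / 78, "3-6h": 17 / 78, ">6h": 54 / 78},
    "play_area": {"inside": 38 / 97, "outside": 59 / 97},
    "smoking_at_home": {"no": 65 / 89, "yes": 24 / 89},
    "paved_street": {"no": 21 / 97, "yes": 76 / 97},
    "heater_type": {"other": 29 / 75, "coal_gas": 46 / 75},
}

#: default item-nonresponse probabilities (counts out of 275)
DEFAULT_MISSING_RATES: dict[str, float] = {
    "lives_with_both_parents": 9 / 275,
    "parental_atopy": 30 / 275,
    "mother_working": 14 / 275,
    "father_working": 22 / 275,
    "hours_at_home": 61 / 275,
    "play_area": 9 / 275,
    "smoking_at_home": 28 / 275,
    "paved_street": 10 / 275,
    "heater_type": 69 / 275,
}

# synthetic town centre in a semi-arid mining region (stand-in; the real
# community's coordinates are not published)
DEFAULT_TOWN_CENTER = (-30.30, -71.10)


def default_sources(center: tuple[float, float] = DEFAULT_TOWN_CENTER) -> pd.DataFrame:
    """Two mines: gold 2.1 km due north of the centre, copper 1.9 km at 40 deg.

    The bearings are close so the two distances correlate positively across
    town, keeping the average-distance spread near the per-mine spread (as the
    study reports) instead of cancelling.
    """
    offsets = np.array(
        [
            [0.0, 2.1],  # gold: east, north km
            [1.9 * np.sin(np.radians(40.0)), 1.9 * np.cos(np.radians(40.0))],
        ]
    )
    lat, lon = geodesy.from_planar_km(offsets, center)
    return pd.DataFrame({"source_id": ["gold", "copper"], "lat": lat, "lon": lon})


@dataclass
class TownConfig:
    """Geometry and size of the synthetic town."""

    n_children: int = 275
    town_center: tuple[float, float] = DEFAULT_TOWN_CENTER
    mine_locations: pd.DataFrame | None = None  # defaults to :func:`default_sources`
    residence_spread_km: float = 0.26
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.residence_spread_km <= 0:
            raise ValueError("residence_spread_km must be > 0")
        if self.mine_locations is None:
            self.mine_locations = default_sources(self.town_center)
        if len(self.mine_locations) < 1:
            raise ValueError("at least one mine required")


@dataclass
class TruthParams:
    """Generative truth for one outcome.

    ``alpha`` is the excess odds at the source (odds ratio at the mine is
    1 + alpha), ``phi`` the Gaussian decay scale in km beyond the plateau,
    ``delta`` the plateau radius in km.  ``beta`` maps covariate -> category ->
    log-odds effect (reference categories carry 0).  When ``beta0`` is None the
    intercept is calibrated at simulation time so the expected prevalence hits
    ``target_prevalence``.
    """

    alpha: float = 2.0
    phi: float = 1.1
    delta: float = 0.8
    beta0: float | None = None
    target_prevalence: float | None = None
    beta: dict[str, dict[str, float]] = field(default_factory=dict)
    spatial_sd: float = 0.0
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.delta < 0 or self.alpha < 0:
            raise ValueError("alpha and delta must be >= 0")
        for col, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {col} outside [0, 1]")


def default_truth(outcome: str = "asthma") -> TruthParams:
    """Default generative truth for either outcome, emulating the study conditions.

    Asthma carries effects of parental atopy, living with both parents and a
    working mother; rhinoconjunctivitis only parental atopy.  Prevalence
    targets are 24% and 34%.
    """
    if outcome == "asthma":
        beta = {
            "parental_atopy": {"yes": 1.1},
            "lives_with_both_parents": {"yes": -0.8},
            "mother_working": {"yes": 0.8},
        }
        target = 0.24
    elif outcome == "rhinoconjunctivitis":
        beta = {"parental_atopy": {"yes": 0.9}}
        target = 0.34
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return TruthParams(
        alpha=2.0,
        phi=1.1,
        delta=0.8,
        beta0=None,
        target_prevalence=target,
        beta=beta,
        spatial_sd=0.2,
        missing_rates=dict(DEFAULT_MISSING_RATES),
    )


def generate_town(config: TownConfig) -> pd.DataFrame:
    """Residence coordinates only: isotropic Gaussian scatter on the tangent plane."""
    rng = np.random.default_rng(config.seed)
    xy = rng.normal(0.0, config.residence_spread_km, size=(config.n_children, 2))
    lat, lon = geodesy.from_planar_km(xy, config.town_center)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("generated non-finite coordinates; check town_center/spread")
    return pd.DataFrame(
        {"child_id": [f"c{i:04d}" for i in range(config.n_children)], "lat": lat, "lon": lon}
    )


def draw_covariates(
    table: pd.DataFrame,
    marginals: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent categorical draws per child from the given marginals."""
    marginals = DEFAULT_MARGINALS if marginals is None else marginals
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, probs in marginals.items():
        if col not in CATEGORIES:
            raise ValueError(f"unknown covariate {col!r}")
        levels = list(probs)
        p = np.array([probs[l] for l in levels], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"marginal probabilities for {col!r} must be >= 0 and sum to 1")
        unknown = set(levels) - set(CATEGORIES[col])
        if unknown:
            raise ValueError(f"unknown categories {unknown} for {col!r}")
        out[col] = rng.choice(levels, size=len(out), p=p)
    return out


def covariate_logodds(table: pd.DataFrame, beta: dict[str, dict[str, float]]) -> np.ndarray:
    """x_i' beta for category-coded covariates (reference levels contribute 0)."""
    xb = np.zeros(len(table))
    for col, effects in beta.items():
        vals = table[col]
        if vals.isna().any():
            raise ValueError(f"covariate {col!r} has missing values at simulation time")
        for cat, b in effects.items():
            xb += np.where(vals == cat, b, 0.0)
    return xb


def _spatial_field(table, center, spatial_sd, mode, rng, n_knots=40, gp_lengthscale=0.5):
    """Zero-mean spatial effect over residences, scaled to sd = spatial_sd."""
    if spatial_sd == 0 or len(table) < 3:
        return np.zeros(len(table))
    xy = geodesy.to_planar_km(table["lat"].to_numpy(), table["lon"].to_numpy(), center)
    if mode == "lowrank":
        from .pointsource import build_spatial_basis

        basis = build_spatial_basis(
            table, n_knots=min(n_knots, len(table)), center=center,
            seed=int(rng.integers(2**31 - 1)),
        )
        w = rng.standard_normal(basis.n_effective)
        s = basis.design @ w
    elif mode == "gp":
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        K = np.exp(-0.5 * d2 / gp_lengthscale**2) + 1e-8 * np.eye(len(xy))
        s = np.linalg.cholesky(K) @ rng.standard_normal(len(xy))
    else:
        raise ValueError(f"unknown spatial mode {mode!r}")
    s = s - s.mean()
    sd = s.std()
    return s * (spatial_sd / sd) if sd > 0 else s


def simulate_outcomes(
    table: pd.DataFrame,
    truth: TruthParams,
    sources: pd.DataFrame,
    outcome: str = "asthma",
    exposure_mode: str = "average",
    seed: int = 0,
    spatial_mode: str = "lowrank",
    f_mode: str = "log",
) -> pd.DataFrame:
    """Bernoulli outcomes from the distance-risk logit model.

    The linear predictor is beta0 + log f(d) + x'beta + S(s); with
    ``f_mode="additive"`` the literal additive form beta0 + f(d) + x'beta + S
    is used instead.
    """
    from .pointsource import distance_risk

    rng = np.random.default_rng(seed)
    exp_set = geodesy.build_exposures(table, sources)
    col = f"d_{exposure_mode}"
    if col not in exp_set.table.columns:
        raise ValueError(
            f"exposure_mode {exposure_mode!r} not among {sorted(exp_set.cutoffs)}"
        )
    d = exp_set.table[col].reindex(table["child_id"]).to_numpy()

    f = distance_risk(d, truth.alpha, truth.phi, truth.delta)
    f_term = np.log(f) if f_mode == "log" else f
    xb = covariate_logodds(table, truth.beta) if truth.beta else np.zeros(len(table))
    center = (float(table["lat"].mean()), float(table["lon"].mean()))
    s = _spatial_field(table, center, truth.spatial_sd, spatial_mode, rng)
    eta_rest = f_term + xb + s

    if truth.beta0 is None:
        if truth.target_prevalence is None:
            raise ValueError("need beta0 or target_prevalence")
        beta0 = calibrate_beta0(eta_rest, truth.target_prevalence)
    else:
        beta0 = truth.beta0
    pi = 1.0 / (1.0 + np.exp(-(beta0 + eta_rest)))
    out = table.copy()
    out[outcome] = (rng.uniform(size=len(table)) < pi).astype(int)
    out.attrs[f"beta0_{outcome}"] = float(beta0)
    return out


def calibrate_beta0(eta_rest: np.ndarray, target_prevalence: float) -> float:
    """Intercept such that mean expit(beta0 + eta_rest) equals the target."""
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")

    def gap(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_rest)))) - target_prevalence

    return float(brentq(gap, -30.0, 30.0))


def impose_missingness(
    table: pd.DataFrame,
    missing_rates: dict[str, float] | None = None,
    seed: int = 0,
    mechanism: str = "MAR",
) -> pd.DataFrame:
    """Inject NA values missing-at-random.

    Under MAR the missingness probability depends only on the fully observed
    columns sex and age_group (a mild logistic dependence), with the intercept
    calibrated so the marginal rate matches the requested one; never on the
    masked value itself.  ``mechanism="MCAR"`` drops the dependence.
    """
    if mechanism not in {"MAR", "MCAR"}:
        raise ValueError("mechanism must be MAR or MCAR")
    rates = DEFAULT_MISSING_RATES if missing_rates is None else missing_rates
    rng = np.random.default_rng(seed)
    out = table.copy()
    if mechanism == "MAR":
        female = (table["sex"] == "female").to_numpy(dtype=float)
        older = table["age_group"].isin(["10-11", "12+"]).to_numpy(dtype=float)
        driver = 0.5 * female - 0.4 * older
    else:
        driver = np.zeros(len(table))
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        if rate == 0.0:
            continue
        if col not in out.columns:
            raise ValueError(f"no column {col!r} to make missing")
        b0 = brentq(
            lambda b: np.mean(1.0 / (1.0 + np.exp(-(b + driver)))) - rate, -30.0, 30.0
        )
        mask = rng.uniform(size=len(out)) < 1.0 / (1.0 + np.exp(-(b0 + driver)))
        out.loc[mask, col] = pd.NA if out[col].dtype == object else np.nan
    return out


def simulate_study(
    config: TownConfig | None = None,
    truths: dict[str, TruthParams] | None = None,
    exposure_mode: str = "average",
    with_missingness: bool = True,
    spatial_mode: str = "lowrank",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end default fixture: town + covariates + both outcomes (+ NA gaps).

    Returns ``(study_table, sources)``.  All randomness derives from
    ``config.seed``.
    """
    config = config or TownConfig()
    truths = truths or {o: default_truth(o) for o in OUTCOME_COLUMNS}
    sources = config.mine_locations
    table = generate_town(config)
    table = draw_covariates(table, seed=config.seed + 1)
    for i, (outcome, truth) in enumerate(truths.items()):
        table = simulate_outcomes(
            table, truth, sources, outcome=outcome, exposure_mode=exposure_mode,
            seed=config.seed + 2 + i, spatial_mode=spatial_mode,
        )
    if with_missingness:
        any_truth = next(iter(truths.values()))
        table = impose_missingness(table, any_truth.missing_rates or None,
                                   seed=config.seed + 10)
    # column order per schema
    cols = [c for c in STUDY_COLUMNS if c in table.columns]
    return table[cols], sources


# ---------------------------------------------------------------------------
# CSV round-trip


def write_study(table: pd.DataFrame, path) -> None:
    """Write a study table as UTF-8 CSV with empty-string NA encoding."""
    _validate_schema(table)
    out = table.copy()
    for c in OUTCOME_COLUMNS:
        out[c] = out[c].astype("Int64")  # avoids "0.0" in the CSV when NA forced floats
    out.to_csv(path, index=False, na_rep="")


def read_study(path) -> pd.DataFrame:
    """Read a study table CSV, validating schema and category sets."""
    tab = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[""],
    )
    missing = [c for c in STUDY_COLUMNS if c not in tab.columns]
    extra = [c for c in tab.columns if c not in STUDY_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"study CSV schema error; missing columns: {missing}, unknown columns: {extra}"
        )
    for c in ("lat", "lon"):
        try:
            tab[c] = tab[c].astype(float)
        except ValueError as e:
            raise ValueError(f"malformed coordinates in column {c!r}: {e}") from e
    for c in OUTCOME_COLUMNS:
        vals = tab[c].dropna()
        if not set(vals.unique()) <= {"0", "1"}:
            raise ValueError(f"outcome {c!r} has values outside {{0,1,NA}}")
        tab[c] = tab[c].astype(float).astype("Int64")
    _validate_schema(tab)
    return tab


def _validate_schema(table: pd.DataFrame) -> None:
    bad = []
    for c in STUDY_COLUMNS:
        if c not in table.columns:
            bad.append(c)
    if bad:
        raise ValueError(f"study table missing columns: {bad}")
    if table["child_id"].duplicated().any():
        raise ValueError("child_id values must be unique")
    for col, levels in CATEGORIES.items():
        vals = set(table[col].dropna().unique())
        if not vals <= set(levels):
            raise ValueError(f"column {col!r} has values outside {levels}: {vals - set(levels)}")
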