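"""Predictor models for sigma: random-intercept LMM and species-level OLS.

The lot-level model relates ln(sigma) to within-species-scaled seed
mass, mean annual temperature (MAT) and annual precipitation (MAP) at
the lot origin, with a species random intercept:

    ln(sigma_ls) = b0 + b1 * mass_scaled + b2 * MAT + b3 * MAP
                   + u_s + e_ls,   u_s ~ N(0, tau^2),  e ~ N(0, s^2).

Variance components come from restricted maximum likelihood, profiled
over the single variance ratio lambda = tau^2 / s^2; fixed effects are
generalized least squares at the REML optimum.  Type-III tests are Wald
chi-square (each continuous term has 1 df).  Explained-variance shares
use the random-intercept R^2 decomposition:

    R2_marginal    = var(Xb) / (var(Xb) + tau^2 + s^2)
    R2_conditional = (var(Xb) + tau^2) / (var(Xb) + tau^2 + s^2)

so R2_conditional - R2_marginal is the share carried by species
identity alone, and R2_marginal / (1 - (R2c - R2m)) is the share of the
non-species variance that the lot-level predictors explain.

Species-level models are ordinary least squares on ln(sigma) with
sum-to-zero factor contrasts and type-III (drop-term) F tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SeedLotMeta, SpeciesMeta

__all__ = [
    "MixedModelResult",
    "LinearModelResult",
    "scale_within_group",
    "fit_random_intercept_lmm",
    "fit_lot_predictor_lmm",
    "r2_nakagawa",
    "within_species_share",
    "species_share",
    "fit_species_lm",
]


@dataclass(frozen=True)
class MixedModelResult:
    fixed_effects: Mapping[str, tuple[float, float]]  # term -> (estimate, se)
    random_intercept_variance: float
    residual_variance: float
    reml_loglik: float
    type3_tests: Mapping[str, tuple[float, int, float]]  # term -> (chi2, df, p)
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    singular: bool = False
    n_dropped_missing: int = 0


@dataclass(frozen=True)
class LinearModelResult:
    coefficients: Mapping[str, float]
    type3_tests: Mapping[str, tuple[float, int, int, float]]  # (F, df_num, df_den, p)
    r_squared: float
    n_obs: int
    warnings: tuple[str, ...] = ()


def scale_within_group(values: Sequence[float], groups: Sequence) -> np.ndarray:
    """Center and standardize values within each group (sample SD, n-1).

    Groups whose values have zero spread are set to 0 with a warning;
    a group of size 1 is an error — the caller must pre-filter to
    groups with at least two members."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if np.any(np.isnan(x)):
        raise ValueError("missing values must be removed before scaling")
    out = np.empty_like(x)
    for grp in np.unique(g):
        m = g == grp
        if m.sum() < 2:
            raise ValueError(f"group {grp!r} has a single member; cannot standardize")
        sd = float(np.std(x[m], ddof=1))
        if sd == 0.0:
            warnings.warn(f"group {grp!r} has zero spread; scaled values set to 0")
            out[m] = 0.0
        else:
            out[m] = (x[m] - x[m].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Random-intercept LMM by profiled REML


def _reml_pieces(y, X, gi, n_groups, lam):
    """GLS pieces for V* = I + lam * Z Z' (block J per group), via Woodbury."""
    n, p = X.shape
    ng = np.bincount(gi, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * ng)  # per group
    Xg = np.zeros((n_groups, p))
    yg = np.zeros(n_groups)
    for j in range(p):
        Xg[:, j] = np.bincount(gi, weights=X[:, j], minlength=n_groups)
    yg = np.bincount(gi, weights=y, minlength=n_groups)
    A = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    b = X.T @ y - Xg.T @ (shrink * yg)
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    rg = np.bincount(gi, weights=r, minlength=n_groups)
    q = float(r @ r - np.sum(shrink * rg**2))
    logdet_v = float(np.sum(np.log1p(lam * ng)))
    sign, logdet_a = np.linalg.slogdet(A)
    return beta, A, q, logdet_v, float(logdet_a)


def _reml_criterion(y, X, gi, n_groups, lam):
    n, p = X.shape
    _, _, q, logdet_v, logdet_a = _reml_pieces(y, X, gi, n_groups, lam)
    s2 = q / (n - p)
    return (n - p) * math.log(s2) + logdet_v + logdet_a


def fit_random_intercept_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    term_names: Sequence[str],
) -> MixedModelResult:
    """REML fit of y = X b + u_group + e with a scalar random intercept.

    X must include an intercept column named 'intercept' in term_names.
    Returns Wald type-III chi-square tests for every non-intercept term
    and the marginal/conditional R^2 pair."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(term_names) != p:
        raise ValueError("term_names must match design columns")
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(f"collinear fixed-effect design (condition number {cond:.2g})")
    labels, gi = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = len(labels)

    crit = lambda loglam: _reml_criterion(y, X, gi, n_groups, math.exp(loglam))
    res = optimize.minimize_scalar(crit, bounds=(-12.0, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam_opt = math.exp(res.x)
    crit0 = _reml_criterion(y, X, gi, n_groups, 0.0)
    singular = False
    if crit0 <= res.fun + 1e-9:
        lam_opt = 0.0
        singular = True

    beta, A, q, logdet_v, logdet_a = _reml_pieces(y, X, gi, n_groups, lam_opt)
    s2 = q / (n - p)
    tau2 = lam_opt * s2
    cov = s2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    reml_ll = -0.5 * (
        (n - p) * (math.log(2 * math.pi * s2) + 1.0) + logdet_v + logdet_a
    )

    type3: dict[str, tuple[float, int, float]] = {}
    for j, name in enumerate(term_names):
        if name == "intercept":
            continue
        chi2 = (beta[j] / se[j]) ** 2
        type3[name] = (float(chi2), 1, float(stats.chi2.sf(chi2, 1)))

    r2m, r2c = r2_nakagawa_components(X, beta, term_names, tau2, s2)
    return MixedModelResult(
        fixed_effects={nm: (float(beta[j]), float(se[j])) for j, nm in enumerate(term_names)},
        random_intercept_variance=float(tau2),
        residual_variance=float(s2),
        reml_loglik=float(reml_ll),
        type3_tests=type3,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=n,
        n_groups=n_groups,
        singular=singular,
    )


def r2_nakagawa_components(
    X: np.ndarray,
    beta: np.ndarray,
    term_names: Sequence[str],
    tau2: float,
    s2: float,
) -> tuple[float, float]:
    """Marginal/conditional R^2 from the fixed-effect predictor variance."""
    fixed = X @ beta
    var_f = float(np.var(fixed, ddof=1)) if len(fixed) > 1 else 0.0
    denom = var_f + tau2 + s2
    if denom <= 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + tau2) / denom


def r2_nakagawa(fit: MixedModelResult) -> tuple[float, float]:
    """The fitted model's (marginal, conditional) R^2 pair."""
    return fit.r2_marginal, fit.r2_conditional


def within_species_share(r2_marginal: float, r2_conditional: float) -> float:
    """Share of the non-species variance explained by lot-level predictors:
    R2m / (1 - (R2c - R2m))."""
    if not 0 <= r2_marginal <= r2_conditional <= 1:
        raise ValueError("need 0 <= R2m <= R2c <= 1")
    denom = 1.0 - (r2_conditional - r2_marginal)
    if denom <= 0:
        raise ValueError("species identity absorbs all variance; share undefined")
    return r2_marginal / denom


def species_share(r2_marginal: float, r2_conditional: float) -> float:
    """Variance share carried by species identity alone: R2c - R2m."""
    if not 0 <= r2_marginal <= r2_conditional <= 1:
        raise ValueError("need 0 <= R2m <= R2c <= 1")
    return r2_conditional - r2_marginal


def fit_lot_predictor_lmm(
    sigma_table: pd.DataFrame,
    metadata: Sequence[SeedLotMeta],
    log_response: bool = True,
) -> MixedModelResult:
    """Fit the lot-level predictor LMM from a sigma table and lot metadata.

    ``sigma_table`` needs columns lot_id, species_id, sigma_days.  Seed
    mass is standardized within species (so only species with >= 2 lots
    carrying mass enter); MAT and MAP enter on their natural scales.
    Lots with any missing covariate are dropped listwise."""
    meta = {m.lot_id: m for m in metadata}
    rows = []
    for r in sigma_table.itertuples():
        m = meta.get(str(r.lot_id))
        if m is None:
            continue
        if (
            m.thousand_seed_mass_g is None
            or m.mat_c is None
            or m.map_mm is None
            or r.sigma_days is None
            or (isinstance(r.sigma_days, float) and math.isnan(r.sigma_days))
        ):
            continue
        rows.append(
            (str(r.lot_id), str(r.species_id), float(r.sigma_days),
             m.thousand_seed_mass_g, m.mat_c, m.map_mm)
        )
    n_dropped = len(sigma_table) - len(rows)
    df = pd.DataFrame(
        rows, columns=["lot_id", "species_id", "sigma_days", "mass", "mat", "map"]
    )
    counts = df.groupby("species_id")["lot_id"].transform("count")
    df = df[counts >= 2].reset_index(drop=True)
    if df["species_id"].nunique() < 2:
        raise ValueError("LMM needs >= 2 species each with >= 2 lots")
    y = np.log(df["sigma_days"].to_numpy()) if log_response else df["sigma_days"].to_numpy()
    mass_scaled = scale_within_group(df["mass"].to_numpy(), df["species_id"].to_numpy())
    X = np.column_stack(
        [np.ones(len(df)), mass_scaled, df["mat"].to_numpy(), df["map"].to_numpy()]
    )
    names = ["intercept", "mass_scaled", "mat_c", "map_mm"]
    fit = fit_random_intercept_lmm(y, X, df["species_id"].to_numpy(), names)
    return MixedModelResult(
        **{**fit.__dict__, "n_dropped_missing": n_dropped}
    )


# ---------------------------------------------------------------------------
# Species-level OLS with sum-to-zero contrasts and type-III F tests


def _sum_to_zero(levels: Sequence[str], values: Sequence[str]) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor (k levels -> k-1 columns)."""
    levels = list(levels)
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    for i, v in enumerate(values):
        j = levels.index(v)
        if j < k - 1:
            cols[i, j] = 1.0
        else:
            cols[i, :] = -1.0
    return cols


def _ols_type3(
    y: np.ndarray, blocks: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict[str, tuple[float, int, int, float]], float]:
    """OLS with named column blocks; type-III F by dropping each block."""
    X = np.column_stack(list(blocks.values()))
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("aliased terms in the design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    tests: dict[str, tuple[float, int, int, float]] = {}
    df_den = n - p
    for name, cols in blocks.items():
        if name == "intercept":
            continue
        others = np.column_stack([v for k, v in blocks.items() if k != name])
        beta_r, *_ = np.linalg.lstsq(others, y, rcond=None)
        sse_r = float(np.sum((y - others @ beta_r) ** 2))
        df_num = cols.shape[1]
        f_stat = ((sse_r - sse) / df_num) / (sse / df_den)
        tests[name] = (
            float(f_stat), df_num, df_den, float(stats.f.sf(f_stat, df_num, df_den))
        )
    return beta, tests, r2


def fit_species_lm(
    species_sigma: pd.DataFrame,
    species_meta: Sequence[SpeciesMeta],
    model: str = "family_mass",
    log_response: bool = True,
) -> LinearModelResult:
    """OLS of species ln(sigma) on (A) family + mean seed mass, or
    (B) protein + oil content.

    ``species_sigma`` needs columns species_id, sigma_days.  Families
    represented by a single species are kept — they still inform the
    family contrasts.  A single-family dataset drops the family term
    with a warning and fits mass alone."""
    if model not in ("family_mass", "protein_oil"):
        raise ValueError("model must be 'family_mass' or 'protein_oil'")
    meta = {m.species_id: m for m in species_meta}
    warns: list[str] = []
    rows = []
    for r in species_sigma.itertuples():
        m = meta.get(str(r.species_id))
        if m is None or r.sigma_days is None or (
            isinstance(r.sigma_days, float) and math.isnan(r.sigma_days)
        ):
            continue
        if model == "family_mass":
            if m.mean_thousand_seed_mass_g is None or not m.family:
                continue
            rows.append((str(r.species_id), float(r.sigma_days), m.family,
                         m.mean_thousand_seed_mass_g))
        else:
            if m.protein_content_pct is None or m.oil_content_pct is None:
                continue
            rows.append((str(r.species_id), float(r.sigma_days),
                         m.protein_content_pct, m.oil_content_pct))
    if not rows:
        raise ValueError("no species with complete data for this model")
    y = np.array([r[1] for r in rows])
    if log_response:
        y = np.log(y)
    n = len(rows)
    blocks: dict[str, np.ndarray] = {"intercept": np.ones((n, 1))}
    coef_names = ["intercept"]
    if model == "family_mass":
        families = sorted({r[2] for r in rows})
        if len(families) >= 2:
            blocks["family"] = _sum_to_zero(families, [r[2] for r in rows])
            coef_names += [f"family[{f}]" for f in families[:-1]]
        else:
            warns.append("single family in data: family term dropped")
        blocks["mass"] = np.log(np.array([[r[3]] for r in rows]))
        coef_names.append("log_mass")
    else:
        blocks["protein"] = np.array([[r[2]] for r in rows])
        blocks["oil"] = np.array([[r[3]] for r in rows])
        coef_names += ["protein_pct", "oil_pct"]
    beta, tests, r2 = _ols_type3(y, blocks)
    return LinearModelResult(
        coefficients=dict(zip(coef_names, map(float, beta))),
        type3_tests=tests,
        r_squared=r2,
        n_obs=n,
        warnings=tuple(warns),
    )
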