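"""Quasi-binomial probit regression for viability time courses.

Seed viability under aging declines approximately linearly on the probit
(normal equivalent deviate) scale:

    probit(v(t)) = Ki + b * t,      b < 0,

so the germinable fraction at aging day t is v(t) = Phi(Ki + b t).
The longevity measure sigma is the number of days for viability to fall
by one probit, sigma = -1/b, and the intercept Ki is the initial
viability in probits.  Replicate dish counts are binomial in expectation
but typically overdispersed; fits therefore use the binomial likelihood
for point estimates and a Pearson dispersion factor (quasi-binomial
convention) for all uncertainty statements.

Three design kinds cover the analyses needed:

``single_lot``
    intercept + slope for one seed lot;
``lot_intercepts_common_slope``
    one intercept per lot, one shared slope (species-level sigma);
``lot_intercepts_lot_slopes``
    one intercept and one slope per lot (heterogeneity test's full model).

Fitting is iteratively reweighted least squares on the probit link with
prior weights equal to seeds sown.  The time-to-50%-viability is
p50 = Ki * sigma, since probit viability reaches 0 (= 50%) after Ki/|b|
days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import GerminationObservation

__all__ = [
    "DesignMatrixSpec",
    "ProbitFitResult",
    "SigmaEstimate",
    "FitError",
    "probit",
    "inv_probit",
    "fit_probit",
    "dispersion_pearson",
    "slope_wald_test",
    "nested_f_test",
    "sigma_from_fit",
    "p50",
]

_ETA_CAP = 8.0
_ZERO_TOL = 1e-12  # coefficients below this are numerical zero
_MAX_ITER = 100
_DEV_RTOL = 1e-10

_KINDS = ("single_lot", "lot_intercepts_common_slope", "lot_intercepts_lot_slopes")


class FitError(RuntimeError):
    """Raised when a probit fit cannot be formed (rank deficiency etc.)."""


def probit(p: float) -> float:
    """Normal equivalent deviate Phi^{-1}(p) for p in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probit requires p in (0,1), got {p}")
    return float(stats.norm.ppf(p))


def inv_probit(x: float) -> float:
    """Phi(x): back-transform from the probit scale to a proportion."""
    return float(stats.norm.cdf(x))


@dataclass(frozen=True)
class DesignMatrixSpec:
    """Which coefficients a viability fit estimates, and for which lots."""

    kind: str
    lot_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        object.__setattr__(self, "lot_order", tuple(self.lot_order))
        if len(self.lot_order) == 0:
            raise ValueError("lot_order must be non-empty")
        if self.kind == "single_lot" and len(self.lot_order) != 1:
            raise ValueError("single_lot design requires exactly one lot")
        if len(set(self.lot_order)) != len(self.lot_order):
            raise ValueError("lot_order must be unique")

    @property
    def n_params(self) -> int:
        k = len(self.lot_order)
        if self.kind == "single_lot":
            return 2
        if self.kind == "lot_intercepts_common_slope":
            return k + 1
        return 2 * k

    def coefficient_names(self) -> list[str]:
        if self.kind == "single_lot":
            return [f"ki[{self.lot_order[0]}]", f"slope[{self.lot_order[0]}]"]
        names = [f"ki[{lot}]" for lot in self.lot_order]
        if self.kind == "lot_intercepts_common_slope":
            return names + ["slope"]
        return names + [f"slope[{lot}]" for lot in self.lot_order]

    def slope_index(self, lot_id: str) -> int:
        k = len(self.lot_order)
        if self.kind == "single_lot":
            return 1
        if self.kind == "lot_intercepts_common_slope":
            return k
        return k + self.lot_order.index(lot_id)

    def intercept_index(self, lot_id: str) -> int:
        if self.kind == "single_lot":
            return 0
        return self.lot_order.index(lot_id)


@dataclass(frozen=True)
class ProbitFitResult:
    """A fitted probit viability model with quasi-likelihood dispersion."""

    coefficients: np.ndarray
    covariance: np.ndarray  # dispersion-scaled
    cov_unscaled: np.ndarray
    dispersion_phi: float
    deviance: float
    pearson_chi2: float
    residual_df: int
    n_obs: int
    converged: bool
    spec: DesignMatrixSpec
    message: str = ""

    def coefficient_names(self) -> list[str]:
        return self.spec.coefficient_names()


@dataclass(frozen=True)
class SigmaEstimate:
    """sigma = -1/slope with a t-based interval mapped through x -> -1/x."""

    lot_id: str
    sigma_days: Optional[float]
    ci_low_days: Optional[float]
    ci_high_days: Optional[float]
    slope: float
    slope_se: float
    slope_p: float
    ki_probits: float
    ki_pct: float
    flag: str = ""


def build_design(
    observations: Sequence[GerminationObservation], spec: DesignMatrixSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (X, observed proportions, seed counts) for a design spec."""
    lots = [o.lot_id for o in observations]
    extra = set(lots) - set(spec.lot_order)
    if extra:
        raise FitError(f"observations for lots outside the design: {sorted(extra)}")
    t = np.array([o.aging_days for o in observations], dtype=float)
    n = np.array([o.n_seeds for o in observations], dtype=float)
    y = np.array([o.n_germinated for o in observations], dtype=float) / n
    k = len(spec.lot_order)
    idx = np.array([spec.lot_order.index(l) for l in lots])
    if spec.kind == "single_lot":
        X = np.column_stack([np.ones_like(t), t])
    elif spec.kind == "lot_intercepts_common_slope":
        X = np.zeros((len(t), k + 1))
        X[np.arange(len(t)), idx] = 1.0
        X[:, k] = t
    else:
        X = np.zeros((len(t), 2 * k))
        X[np.arange(len(t)), idx] = 1.0
        X[np.arange(len(t)), k + idx] = t
    # every slope column needs >= 2 distinct time points behind it
    for lot in spec.lot_order if spec.kind != "lot_intercepts_common_slope" else []:
        tl = {o.aging_days for o in observations if o.lot_id == lot}
        if len(tl) < 2:
            raise FitError(f"lot {lot}: fewer than 2 distinct aging durations")
    if spec.kind == "lot_intercepts_common_slope" and len(set(t)) < 2:
        raise FitError("fewer than 2 distinct aging durations")
    if len(observations) < spec.n_params:
        raise FitError(
            f"{len(observations)} observations cannot identify {spec.n_params} parameters"
        )
    return X, y, n


def _binom_deviance(y: np.ndarray, mu: np.ndarray, n: np.ndarray) -> float:
    from scipy.special import xlogy

    term = xlogy(y, y) - xlogy(y, mu) + xlogy(1 - y, 1 - y) - xlogy(1 - y, 1 - mu)
    return float(2.0 * np.sum(n * term))


def _pearson_chi2(y: np.ndarray, mu: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(n * (y - mu) ** 2 / (mu * (1 - mu))))


def fit_probit(
    observations: Sequence[GerminationObservation], spec: DesignMatrixSpec
) -> ProbitFitResult:
    """Fit the binomial probit model by IRLS with prior weights = seeds sown.

    The coefficient covariance is (X'WX)^{-1} scaled by the Pearson
    dispersion (quasi-binomial).  Degenerate data (every dish fully
    germinated, or none at all — complete separation along any line) are
    reported with ``converged=False`` rather than a silent estimate.
    """
    X, y, n = build_design(observations, spec)
    n_obs, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise FitError("rank-deficient design (confounded lots/durations)")

    degenerate = bool(np.all(y == 0.0) or np.all(y == 1.0))

    # working start: shrunk empirical proportions
    counts = y * n
    mu = (counts + 0.5) / (n + 1.0)
    eta = stats.norm.ppf(mu)
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    dev = np.inf
    beta = np.zeros(p)
    converged = False
    message = ""
    for _ in range(_MAX_ITER):
        dens = stats.norm.pdf(eta)
        mu = stats.norm.cdf(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = n * dens**2 / (mu * (1 - mu))
        z = eta + (y - mu) / dens
        xw = X * w[:, None]
        try:
            beta = np.linalg.solve(xw.T @ X, xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"IRLS normal equations singular: {exc}") from exc
        eta_raw = X @ beta
        eta = np.clip(eta_raw, -_ETA_CAP, _ETA_CAP)
        new_dev = _binom_deviance(y, np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12), n)
        if abs(new_dev - dev) <= _DEV_RTOL * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    else:
        message = "iteration cap reached"

    mu = np.clip(stats.norm.cdf(np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)), 1e-12, 1 - 1e-12)
    dens = stats.norm.pdf(np.clip(X @ beta, -_ETA_CAP, _ETA_CAP))
    w = n * dens**2 / (mu * (1 - mu))
    xtwx = (X * w[:, None]).T @ X
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov_unscaled = np.linalg.pinv(xtwx)
    chi2 = _pearson_chi2(y, mu, n)
    residual_df = n_obs - p
    phi = chi2 / residual_df if residual_df > 0 else float("nan")
    if degenerate:
        converged = False
        message = "degenerate response (all-zero or all-full germination)"
    cov = cov_unscaled * (phi if residual_df > 0 else np.nan)
    return ProbitFitResult(
        coefficients=beta,
        covariance=cov,
        cov_unscaled=cov_unscaled,
        dispersion_phi=float(phi),
        deviance=float(dev),
        pearson_chi2=float(chi2),
        residual_df=residual_df,
        n_obs=n_obs,
        converged=converged,
        spec=spec,
        message=message,
    )


def dispersion_pearson(fit: ProbitFitResult) -> float:
    """Pearson chi^2 / residual df; the quasi-binomial variance inflation."""
    if fit.residual_df < 1:
        raise ValueError("dispersion undefined with zero residual df")
    return fit.pearson_chi2 / fit.residual_df


def slope_wald_test(fit: ProbitFitResult, coefficient_index: int) -> tuple[float, float]:
    """Dispersion-scaled t test of one coefficient against zero.

    Returns (t statistic, two-sided p).  A coefficient that is exactly
    zero has p = 1 regardless of its standard error; a nonzero estimate
    with zero standard error (noise-free data) is reported as p = 0.
    """
    b = float(fit.coefficients[coefficient_index])
    se = math.sqrt(max(float(fit.covariance[coefficient_index, coefficient_index]), 0.0))
    if abs(b) < _ZERO_TOL:
        # a coefficient at numerical zero carries no signal
        return 0.0, 1.0
    if se == 0.0:
        # noise-free data with a real slope: measured without error
        return math.copysign(math.inf, b), 0.0
    t = b / se
    pval = 2.0 * stats.t.sf(abs(t), fit.residual_df)
    return float(t), float(pval)


def nested_f_test(
    full: ProbitFitResult, reduced: ProbitFitResult
) -> tuple[float, int, int, float]:
    """Quasi-likelihood F test of a reduced design against a nesting full one.

    F = ((D_reduced - D_full)/df_num) / phi_full with phi_full the full
    model's Pearson dispersion; df_den is the full model's residual df.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits use different observations")
    nesting_ok = (
        (full.spec.kind == "lot_intercepts_lot_slopes"
         and reduced.spec.kind in ("lot_intercepts_common_slope", "single_lot"))
        or (full.spec.kind == "lot_intercepts_common_slope"
            and reduced.spec.kind == "single_lot")
        or full.spec.kind == reduced.spec.kind
    ) and set(reduced.spec.lot_order) <= set(full.spec.lot_order)
    if not nesting_ok or reduced.spec.n_params > full.spec.n_params:
        raise ValueError("reduced design is not nested in the full design")
    df_num = full.spec.n_params - reduced.spec.n_params
    if df_num == 0:
        return 0.0, 0, full.residual_df, 1.0
    ddev = reduced.deviance - full.deviance
    if ddev < -1e-6 * (abs(full.deviance) + 1.0):
        raise FitError(
            f"reduced deviance {reduced.deviance} below full {full.deviance}: "
            "convergence failure"
        )
    ddev = max(ddev, 0.0)
    phi = full.dispersion_phi
    if phi <= 0.0:
        # noise-free data: any deviance gap is decisive, none means no signal
        return (math.inf, df_num, full.residual_df, 0.0) if ddev > 0 else (
            0.0, df_num, full.residual_df, 1.0
        )
    f_stat = (ddev / df_num) / phi
    pval = float(stats.f.sf(f_stat, df_num, full.residual_df))
    return float(f_stat), df_num, full.residual_df, pval


def sigma_from_fit(
    fit: ProbitFitResult, lot_id: str, confidence_level: float = 0.95
) -> SigmaEstimate:
    """Back-transform a lot's slope to sigma = -1/slope with its CI.

    The CI maps the slope's t interval through x -> -1/x, which is
    monotone on the negative half-line; when the slope interval reaches
    zero the sigma interval is unbounded and left undefined (flagged).
    """
    si = fit.spec.slope_index(lot_id)
    ii = fit.spec.intercept_index(lot_id)
    b = float(fit.coefficients[si])
    ki = float(fit.coefficients[ii])
    _, pval = slope_wald_test(fit, si)
    se = math.sqrt(max(float(fit.covariance[si, si]), 0.0))
    ki_pct = 100.0 * inv_probit(ki)
    if not fit.converged:
        return SigmaEstimate(lot_id, None, None, None, b, se, pval, ki, ki_pct,
                             flag="fit did not converge")
    if b >= -_ZERO_TOL:
        return SigmaEstimate(lot_id, None, None, None, b, se, pval, ki, ki_pct,
                             flag="non-negative slope: sigma undefined")
    sigma = -1.0 / b
    tq = float(stats.t.ppf(0.5 + confidence_level / 2.0, fit.residual_df))
    lo_b, hi_b = b - tq * se, b + tq * se
    if hi_b >= 0.0:
        return SigmaEstimate(lot_id, sigma, None, None, b, se, pval, ki, ki_pct,
                             flag="slope interval reaches 0: CI undefined")
    return SigmaEstimate(
        lot_id, sigma, -1.0 / lo_b, -1.0 / hi_b, b, se, pval, ki, ki_pct
    )


def p50(ki_probits: float, sigma_days: float) -> float:
    """Days until viability falls to 50%: p50 = Ki * sigma on the NED scale.

    Non-positive when initial viability is at or below 50% (Ki <= 0)."""
    if sigma_days <= 0:
        raise ValueError("sigma_days must be positive")
    return ki_probits * sigma_days
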