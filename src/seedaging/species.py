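"""Within-species heterogeneity tests and species-level sigma estimates.

For a species with several retained seed lots, heterogeneity in the rate
of viability loss is tested by comparing a full probit model (per-lot
intercepts and per-lot slopes) against a reduced one (per-lot intercepts,
one shared slope) with the quasi-likelihood F test.  A significant
lot x duration interaction means the lots lose viability at genuinely
different rates.  The species-level sigma comes from the reduced model's
shared slope, computed for every species whether or not heterogeneity
was detected.

Across species, the probability of detecting heterogeneity is related to
the number of lots sampled per species with a binomial (logistic) GLM:
more lots, more power, so detected heterogeneity understates the true
prevalence of within-species variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GerminationObservation
from .probit import (
    DesignMatrixSpec,
    SigmaEstimate,
    fit_probit,
    nested_f_test,
    sigma_from_fit,
)

__all__ = [
    "SpeciesComparisonResult",
    "DetectionModelResult",
    "test_lot_differences",
    "fit_species_sigma",
    "detection_probability_model",
    "comparisons_to_frame",
]


@dataclass(frozen=True)
class SpeciesComparisonResult:
    species_id: str
    n_lots: int
    interaction_F: float
    df_num: int
    df_den: int
    p_value: float
    significant: bool
    lot_sigmas: Mapping[str, SigmaEstimate]
    species_sigma: SigmaEstimate


@dataclass(frozen=True)
class DetectionModelResult:
    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    pseudo_r2_mcfadden: float
    pseudo_r2_nagelkerke: float
    n_species: int
    reliable: bool = True
    message: str = ""


def _lot_order(observations: Sequence[GerminationObservation]) -> tuple[str, ...]:
    seen: list[str] = []
    for o in observations:
        if o.lot_id not in seen:
            seen.append(o.lot_id)
    return tuple(sorted(seen))


def test_lot_differences(
    observations: Sequence[GerminationObservation],
    alpha: float = 0.05,
    confidence_level: float = 0.95,
) -> SpeciesComparisonResult:
    """Interaction F test of lot-specific vs shared viability-loss slopes.

    ``observations`` must already be restricted to one species' retained
    lots, each observed at >= 2 distinct aging durations."""
    lots = _lot_order(observations)
    if len(lots) < 2:
        raise ValueError("heterogeneity test needs >= 2 retained lots")
    for lot in lots:
        days = {o.aging_days for o in observations if o.lot_id == lot}
        if len(days) < 2:
            raise ValueError(f"lot {lot}: a single aging duration cannot identify a slope")
    species_id = observations[0].species_id
    full = fit_probit(observations, DesignMatrixSpec("lot_intercepts_lot_slopes", lots))
    reduced = fit_probit(
        observations, DesignMatrixSpec("lot_intercepts_common_slope", lots)
    )
    f_stat, df_num, df_den, pval = nested_f_test(full, reduced)
    lot_sigmas = {lot: sigma_from_fit(full, lot, confidence_level) for lot in lots}
    species_sigma = sigma_from_fit(reduced, lots[0], confidence_level)
    return SpeciesComparisonResult(
        species_id=species_id,
        n_lots=len(lots),
        interaction_F=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=pval,
        significant=pval < alpha,
        lot_sigmas=lot_sigmas,
        species_sigma=species_sigma,
    )


def fit_species_sigma(
    observations: Sequence[GerminationObservation],
    confidence_level: float = 0.95,
) -> SigmaEstimate:
    """One sigma per species from a shared slope across its retained lots.

    With one lot this is the plain single-lot fit; with several, lot
    identity enters as per-lot intercepts (different initial
    viabilities) while the decay slope is common."""
    lots = _lot_order(observations)
    if len(lots) == 1:
        fit = fit_probit(observations, DesignMatrixSpec("single_lot", lots))
    else:
        fit = fit_probit(
            observations, DesignMatrixSpec("lot_intercepts_common_slope", lots)
        )
    return sigma_from_fit(fit, lots[0], confidence_level)


def _logistic_irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(60):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.pinv((X * w[:, None]).T @ X)
    return beta, cov, converged


def detection_probability_model(
    results: Sequence[SpeciesComparisonResult],
) -> DetectionModelResult:
    """Logistic regression of heterogeneity detection (0/1) on lots per species."""
    if len(results) < 3:
        raise ValueError("detection model needs >= 3 species")
    y = np.array([1.0 if r.significant else 0.0 for r in results])
    n_lots = np.array([float(r.n_lots) for r in results])
    if len(set(n_lots)) < 2:
        raise ValueError("n_lots must vary across species")
    if y.min() == y.max():
        raise ValueError("all detection outcomes identical: model undefined")
    X = np.column_stack([np.ones_like(n_lots), n_lots])
    beta, cov, converged = _logistic_irls(X, y)
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    p0 = float(np.mean(y))
    n = len(y)
    ll0 = n * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0))
    mcfadden = 1.0 - ll / ll0
    nagelkerke = (1.0 - math.exp(2.0 * (ll0 - ll) / n)) / (1.0 - math.exp(2.0 * ll0 / n))
    se = math.sqrt(max(cov[1, 1], 0.0))
    reliable = converged and abs(beta[1]) < 15.0 and se < 50.0
    if se > 0:
        z = beta[1] / se
        pval = 2.0 * stats.norm.sf(abs(z))
    else:
        pval = float("nan")
    return DetectionModelResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_se=se,
        slope_p=float(pval),
        pseudo_r2_mcfadden=float(mcfadden),
        pseudo_r2_nagelkerke=float(nagelkerke),
        n_species=n,
        reliable=reliable,
        message="" if reliable else "possible complete separation: coefficients unreliable",
    )


def comparisons_to_frame(results: Sequence[SpeciesComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.species_sigma
        rows.append(
            {
                "species_id": r.species_id,
                "n_lots": r.n_lots,
                "F": r.interaction_F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p": r.p_value,
                "significant": r.significant,
                "species_sigma_days": s.sigma_days,
                "sigma_ci_low": s.ci_low_days,
                "sigma_ci_high": s.ci_high_days,
            }
        )
    return pd.DataFrame(rows)
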