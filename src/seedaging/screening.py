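"""Seed-lot inclusion rules applied before any cross-lot analysis.

A lot enters the comparative analyses only if (in this order) it is not
flagged as fungus-contaminated, its initial germination reaches the
viability threshold, its viability-decay slope is significantly
negative, and the implied sigma does not exceed the longest aging
duration actually observed (beyond which the experiment saw too little
of the survival curve to trust the extrapolation).  The first matching
rule wins and is recorded as the lot's exclusion status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import AgingDesign, GerminationObservation
from .probit import (
    DesignMatrixSpec,
    FitError,
    ProbitFitResult,
    SigmaEstimate,
    fit_probit,
    sigma_from_fit,
)

__all__ = [
    "ScreeningThresholds",
    "ScreeningOutcome",
    "initial_germination",
    "screen_lot",
    "screen_dataset",
    "outcomes_to_frame",
]

STATUS_RETAINED = "retained"
STATUS_CONTAMINATED = "excluded_contaminated"
STATUS_LOW_VIABILITY = "excluded_low_viability"
STATUS_NO_SLOPE = "excluded_no_significant_slope"
STATUS_SIGMA_MAX = "excluded_sigma_exceeds_max"


@dataclass(frozen=True)
class ScreeningThresholds:
    min_initial_pct: float = 50.0
    alpha: float = 0.05
    confidence_level: float = 0.95


@dataclass(frozen=True)
class ScreeningOutcome:
    lot_id: str
    species_id: str
    initial_germination_pct: float
    status: str
    sigma_estimate: Optional[SigmaEstimate] = None
    rule_detail: str = ""


def initial_germination(
    observations: Sequence[GerminationObservation], design: AgingDesign
) -> float:
    """Initial germination %: the max over the dormancy-window durations of
    the replicate-mean germination percentage.

    Taking the maximum over the shortest exposures (not just day 0)
    tolerates dormancy that a brief heat treatment breaks."""
    best = None
    for day in design.dormancy_window:
        props = [100.0 * o.proportion for o in observations if o.aging_days == day]
        if props:
            m = sum(props) / len(props)
            best = m if best is None or m > best else best
    if best is None:
        raise ValueError("no observations at any dormancy-window duration")
    return best


def screen_lot(
    observations: Sequence[GerminationObservation],
    fit: Optional[ProbitFitResult],
    design: AgingDesign,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> ScreeningOutcome:
    """Apply the inclusion rules to one lot given its single-lot fit."""
    lot_id = observations[0].lot_id
    species_id = observations[0].species_id
    init = initial_germination(observations, design)
    if any(o.contaminated for o in observations):
        return ScreeningOutcome(
            lot_id, species_id, init, STATUS_CONTAMINATED,
            rule_detail="contaminated replicate flagged",
        )
    if init < thresholds.min_initial_pct:
        return ScreeningOutcome(
            lot_id, species_id, init, STATUS_LOW_VIABILITY,
            rule_detail=f"initial germination {init:.1f}% < {thresholds.min_initial_pct}%",
        )
    if fit is None:
        raise ValueError(f"lot {lot_id}: fit required once the viability rule passes")
    est = sigma_from_fit(fit, lot_id, thresholds.confidence_level)
    if (
        not fit.converged
        or est.sigma_days is None
        or est.slope >= 0
        or est.slope_p >= thresholds.alpha
    ):
        return ScreeningOutcome(
            lot_id, species_id, init, STATUS_NO_SLOPE, sigma_estimate=None,
            rule_detail=est.flag or f"slope p={est.slope_p:.3g} >= {thresholds.alpha}",
        )
    if est.sigma_days > design.max_duration:
        return ScreeningOutcome(
            lot_id, species_id, init, STATUS_SIGMA_MAX, sigma_estimate=est,
            rule_detail=f"sigma {est.sigma_days:.1f} d > max duration {design.max_duration} d",
        )
    return ScreeningOutcome(lot_id, species_id, init, STATUS_RETAINED, sigma_estimate=est)


def screen_dataset(
    observations: Sequence[GerminationObservation],
    design: AgingDesign,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> tuple[list[str], list[ScreeningOutcome]]:
    """Screen every lot; returns (retained lot ids, per-lot outcomes).

    Deterministic given inputs and thresholds; lots are processed in
    first-appearance order.  Lots failing the contamination or viability
    rules are never fitted."""
    order: list[str] = []
    by_lot: dict[str, list[GerminationObservation]] = {}
    for o in observations:
        if o.lot_id not in by_lot:
            by_lot[o.lot_id] = []
            order.append(o.lot_id)
        by_lot[o.lot_id].append(o)
    outcomes: list[ScreeningOutcome] = []
    retained: list[str] = []
    for lot in order:
        obs = by_lot[lot]
        init = initial_germination(obs, design)
        contaminated = any(o.contaminated for o in obs)
        fit = None
        if not contaminated and init >= thresholds.min_initial_pct:
            try:
                fit = fit_probit(obs, DesignMatrixSpec("single_lot", (lot,)))
            except FitError as exc:
                outcomes.append(
                    ScreeningOutcome(
                        lot, obs[0].species_id, init, STATUS_NO_SLOPE,
                        rule_detail=f"fit failed: {exc}",
                    )
                )
                continue
        out = screen_lot(obs, fit, design, thresholds)
        outcomes.append(out)
        if out.status == STATUS_RETAINED:
            retained.append(lot)
    return retained, outcomes


def outcomes_to_frame(outcomes: Sequence[ScreeningOutcome]) -> pd.DataFrame:
    """Screening table: one row per lot with sigma and its CI when defined."""
    rows = []
    for o in outcomes:
        est = o.sigma_estimate
        rows.append(
            {
                "lot_id": o.lot_id,
                "species_id": o.species_id,
                "initial_germination_pct": o.initial_germination_pct,
                "status": o.status,
                "sigma_days": est.sigma_days if est else None,
                "sigma_ci_low": est.ci_low_days if est else None,
                "sigma_ci_high": est.ci_high_days if est else None,
                "slope": est.slope if est else None,
                "slope_p": est.slope_p if est else None,
                "ki_probits": est.ki_probits if est else None,
                "ki_pct": est.ki_pct if est else None,
                "rule_detail": o.rule_detail,
            }
        )
    return pd.DataFrame(rows)
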