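"""Stage orchestration: per-lot fits -> screening -> species comparisons
-> detection model -> lot-level LMM -> species-level models.

Each stage reads/writes plain CSV or JSON under a run directory, and a
JSON manifest (inputs, thresholds, seed, package version) plus a
timestamped log make any run reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    AgingDesign,
    GerminationObservation,
    SeedLotMeta,
    SpeciesMeta,
    paper_design,
    read_germination_table,
    read_lot_metadata,
    read_species_metadata,
)
from .models import (
    fit_lot_predictor_lmm,
    fit_species_lm,
    species_share,
    within_species_share,
)
from .screening import (
    STATUS_RETAINED,
    ScreeningThresholds,
    outcomes_to_frame,
    screen_dataset,
)
from .species import (
    comparisons_to_frame,
    detection_probability_model,
    fit_species_sigma,
    test_lot_differences,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    germination_path: str
    lot_metadata_path: Optional[str] = None
    species_metadata_path: Optional[str] = None
    output_dir: str = "runs/latest"
    design: AgingDesign = field(default_factory=paper_design)
    min_initial_pct: float = 50.0
    alpha: float = 0.05
    confidence_level: float = 0.95
    log_response: bool = True
    rng_seed: int = 0


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{stamp} {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _thresholds(config: PipelineConfig) -> ScreeningThresholds:
    return ScreeningThresholds(
        min_initial_pct=config.min_initial_pct,
        alpha=config.alpha,
        confidence_level=config.confidence_level,
    )


def stage_screen(
    observations: Sequence[GerminationObservation],
    config: PipelineConfig,
) -> tuple[list[str], pd.DataFrame]:
    retained, outcomes = screen_dataset(observations, config.design, _thresholds(config))
    return retained, outcomes_to_frame(outcomes)


def stage_compare_species(
    observations: Sequence[GerminationObservation],
    retained: Sequence[str],
    config: PipelineConfig,
    log: Optional[_Log] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species comparison table and the species-level sigma table."""
    retained_set = set(retained)
    by_species: dict[str, list[GerminationObservation]] = {}
    for o in observations:
        if o.lot_id in retained_set:
            by_species.setdefault(o.species_id, []).append(o)
    comparisons = []
    sigma_rows = []
    for sp in sorted(by_species):
        obs = by_species[sp]
        n_lots = len({o.lot_id for o in obs})
        if n_lots >= 2:
            res = test_lot_differences(obs, config.alpha, config.confidence_level)
            comparisons.append(res)
            est = res.species_sigma
        else:
            est = fit_species_sigma(obs, config.confidence_level)
        sigma_rows.append(
            {
                "species_id": sp,
                "n_lots": n_lots,
                "sigma_days": est.sigma_days,
                "sigma_ci_low": est.ci_low_days,
                "sigma_ci_high": est.ci_high_days,
            }
        )
        if log:
            log.info(f"species {sp}: {n_lots} retained lots, sigma={est.sigma_days}")
    return comparisons_to_frame(comparisons), pd.DataFrame(sigma_rows)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage, writing CSV/JSON outputs and a manifest.

    Stages whose preconditions fail (e.g. missing covariates for the
    LMM) are skipped with a logged warning; hard errors in an earlier
    stage abort the run naming the stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")

    log.info(f"seedaging {__version__}: reading {config.germination_path}")
    try:
        observations = read_germination_table(config.germination_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    if not observations:
        raise PipelineError("read", "empty germination table")
    lot_meta: list[SeedLotMeta] = []
    species_meta: list[SpeciesMeta] = []
    if config.lot_metadata_path:
        lot_meta = read_lot_metadata(config.lot_metadata_path)
    if config.species_metadata_path:
        species_meta = read_species_metadata(config.species_metadata_path)

    # screening (includes per-lot fits)
    try:
        retained, screening_table = stage_screen(observations, config)
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc
    screening_table.to_csv(out / "screening.csv", index=False)
    for row in screening_table.itertuples():
        if row.status != STATUS_RETAINED:
            log.info(f"excluded lot {row.lot_id}: {row.status} ({row.rule_detail})")
    log.info(f"retained {len(retained)} / {len(screening_table)} lots")

    lot_sigma = screening_table[screening_table["status"] == STATUS_RETAINED][
        ["lot_id", "species_id", "sigma_days", "sigma_ci_low", "sigma_ci_high",
         "slope", "slope_p", "ki_probits", "ki_pct"]
    ].reset_index(drop=True)
    lot_sigma.to_csv(out / "lot_sigma.csv", index=False)

    # species comparisons + species sigma
    try:
        comparison_table, species_sigma = stage_compare_species(
            observations, retained, config, log
        )
    except Exception as exc:
        raise PipelineError("compare-species", str(exc)) from exc
    comparison_table.to_csv(out / "species_comparisons.csv", index=False)
    species_sigma.to_csv(out / "species_sigma.csv", index=False)

    # detection-probability model
    detection: Optional[dict] = None
    if len(comparison_table) >= 3 and comparison_table["significant"].nunique() == 2:
        from .species import SpeciesComparisonResult  # local to avoid cycle confusion

        results = []
        for row in comparison_table.itertuples():
            results.append(
                SpeciesComparisonResult(
                    species_id=row.species_id, n_lots=int(row.n_lots),
                    interaction_F=row.F, df_num=int(row.df_num),
                    df_den=int(row.df_den), p_value=row.p,
                    significant=bool(row.significant), lot_sigmas={},
                    species_sigma=None,  # type: ignore[arg-type]
                )
            )
        try:
            det = detection_probability_model(results)
            detection = dataclasses.asdict(det)
            (out / "detection_model.json").write_text(json.dumps(detection, indent=2))
        except ValueError as exc:
            log.info(f"detection model skipped: {exc}")
    else:
        log.info("detection model skipped: needs >= 3 multi-lot species and both outcomes")

    # lot-level LMM
    if lot_meta and len(lot_sigma) >= 4:
        try:
            lmm = fit_lot_predictor_lmm(lot_sigma, lot_meta, config.log_response)
            lmm_out = {
                "fixed_effects": {k: list(v) for k, v in lmm.fixed_effects.items()},
                "random_intercept_variance": lmm.random_intercept_variance,
                "residual_variance": lmm.residual_variance,
                "reml_loglik": lmm.reml_loglik,
                "type3_tests": {k: list(v) for k, v in lmm.type3_tests.items()},
                "r2_marginal": lmm.r2_marginal,
                "r2_conditional": lmm.r2_conditional,
                "species_share": species_share(lmm.r2_marginal, lmm.r2_conditional),
                "within_species_share": within_species_share(
                    lmm.r2_marginal, lmm.r2_conditional
                ),
                "n_obs": lmm.n_obs,
                "n_groups": lmm.n_groups,
                "singular": lmm.singular,
            }
            (out / "lmm_summary.json").write_text(json.dumps(lmm_out, indent=2))
            pd.DataFrame(
                [
                    {"term": k, "df": v[1], "chi2": v[0], "p": v[2]}
                    for k, v in lmm.type3_tests.items()
                ]
            ).to_csv(out / "lmm_type3.csv", index=False)
        except ValueError as exc:
            log.info(f"LMM stage skipped: {exc}")
    else:
        log.info("LMM stage skipped: lot metadata or enough retained lots missing")

    # species-level linear models
    if species_meta and len(species_sigma) >= 3:
        for model in ("family_mass", "protein_oil"):
            try:
                lm = fit_species_lm(
                    species_sigma, species_meta, model, config.log_response
                )
                payload = {
                    "coefficients": lm.coefficients,
                    "type3_tests": {k: list(v) for k, v in lm.type3_tests.items()},
                    "r_squared": lm.r_squared,
                    "n_obs": lm.n_obs,
                    "warnings": list(lm.warnings),
                }
                (out / f"species_model_{model}.json").write_text(
                    json.dumps(payload, indent=2)
                )
            except ValueError as exc:
                log.info(f"species model {model} skipped: {exc}")
    else:
        log.info("species models skipped: species metadata missing")

    manifest = {
        "package_version": __version__,
        "germination_path": str(config.germination_path),
        "lot_metadata_path": config.lot_metadata_path,
        "species_metadata_path": config.species_metadata_path,
        "design": {
            "durations": list(config.design.durations),
            "replicates_per_duration": config.design.replicates_per_duration,
            "seeds_per_replicate": config.design.seeds_per_replicate,
            "temperature_c": config.design.temperature_c,
            "relative_humidity_pct": config.design.relative_humidity_pct,
            "dormancy_window": list(config.design.dormancy_window),
        },
        "thresholds": {
            "min_initial_pct": config.min_initial_pct,
            "alpha": config.alpha,
            "confidence_level": config.confidence_level,
        },
        "log_response": config.log_response,
        "rng_seed": config.rng_seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.flush()
    return out


def plot_lot_fit(observations, fit, path) -> None:
    """Optional diagnostic figure: observed proportions and the fitted
    probit viability curve for one lot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as _st

    t = np.array([o.aging_days for o in observations])
    p = np.array([o.proportion for o in observations])
    ki, slope = fit.coefficients[:2]
    grid = np.linspace(0, t.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t, p, "o", alpha=0.6, label="replicates")
    ax.plot(grid, _st.norm.cdf(ki + slope * grid), "-", label="probit fit")
    ax.set_xlabel("aging duration (days)")
    ax.set_ylabel("germinated fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
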