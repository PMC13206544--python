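"""Synthetic germination datasets with the structure the analyses assume.

The generator inverts the analysis model: every seed lot has a latent
initial viability Ki (probits) and a decay rate sigma (days/probit), so
its germinable fraction at aging day t is Phi(Ki - t/sigma).  Replicate
dish counts are beta-binomial around that mean with intraclass
correlation rho (the generative counterpart of quasi-binomial
overdispersion; rho = 0 recovers pure binomial sampling).  Lot-level
ln(sigma) values follow a species hierarchy with covariate effects:

    ln sigma_ls = mu + u_s + family_offset + b_mat (MAT - mean MAT)
                  + b_mass * mass_scaled + e_ls,

with u_s a species random intercept.  Dormancy is modelled as a
day-0-only germination deficit, which exercises the max-over-{0,1,5}
initial-germination rule.

Default parameters describe a plausible multi-species grassland aging
study: median sigma 20 days, Ki near 2 probits (~98% initial
viability), mild overdispersion (rho = 0.05), a positive MAT effect and
a negative within-species seed-mass effect on ln sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import (
    AgingDesign,
    GerminationObservation,
    SeedLotMeta,
    SpeciesMeta,
    paper_design,
)
from .probit import inv_probit, probit

__all__ = [
    "SimulationConfig",
    "simulate_lot",
    "simulate_dataset",
    "make_screening_fixture",
    "variance_share_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the hierarchical germination-data generator."""

    n_species: int = 40
    lots_per_species: Union[int, tuple[int, ...]] = 5
    design: AgingDesign = field(default_factory=paper_design)
    species_log_sigma_mean: float = math.log(20.0)
    species_log_sigma_sd: float = 0.5
    family_effects: Optional[dict[str, float]] = None
    beta_mat: float = 0.03
    beta_mass_scaled: float = -0.1
    lot_log_sigma_resid_sd: float = 0.2
    ki_mean: float = 2.0
    ki_sd: float = 0.3
    overdispersion_rho: float = 0.05
    dormancy_fraction: float = 0.0
    mat_range_c: tuple[float, float] = (5.0, 15.0)
    map_range_mm: tuple[float, float] = (500.0, 1000.0)
    mass_cv: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.species_log_sigma_sd < 0 or self.lot_log_sigma_resid_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if not 0 <= self.dormancy_fraction < 1:
            raise ValueError("dormancy_fraction must be in [0, 1)")

    def lots_for(self, species_index: int) -> int:
        if isinstance(self.lots_per_species, int):
            return self.lots_per_species
        return self.lots_per_species[species_index]


def _beta_binomial(rng: np.random.Generator, n: int, mean: float, rho: float) -> int:
    """Beta-binomial draw with mean ``mean`` and intraclass correlation rho."""
    mean = min(max(mean, 0.0), 1.0)
    if mean in (0.0, 1.0):
        return int(round(mean * n))
    if rho <= 0.0:
        return int(rng.binomial(n, mean))
    conc = (1.0 - rho) / rho
    p = rng.beta(mean * conc, (1.0 - mean) * conc)
    return int(rng.binomial(n, p))


def simulate_lot(
    ki: float,
    sigma: float,
    design: AgingDesign,
    rho: float = 0.0,
    dormancy_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    lot_id: str = "lot",
    species_id: str = "sp",
) -> list[GerminationObservation]:
    """Simulate one lot's replicate counts across the aging design.

    True viability is Phi(ki - t/sigma); at t = 0 the germinable
    fraction is additionally multiplied by (1 - dormancy_fraction)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng() if rng is None else rng
    obs = []
    for t in design.durations:
        v = inv_probit(ki - t / sigma)
        if t == 0.0:
            v *= 1.0 - dormancy_fraction
        for r in range(design.replicates_per_duration):
            g = _beta_binomial(rng, design.seeds_per_replicate, v, rho)
            obs.append(
                GerminationObservation(
                    lot_id=lot_id,
                    species_id=species_id,
                    aging_days=t,
                    replicate_id=f"r{r + 1}",
                    n_seeds=design.seeds_per_replicate,
                    n_germinated=g,
                )
            )
    return obs


def variance_share_config(
    fixed_share: float = 0.05,
    species_share: float = 0.67,
    residual_share: float = 0.28,
    total_ln_sigma_var: float = 0.3,
    n_species: int = 40,
    lots_per_species: int = 5,
    rng_seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """A config whose ln(sigma) variance decomposes into given shares.

    The fixed-effect share is split evenly between the MAT effect
    (uniform MAT, variance range^2/12) and the within-species-scaled
    mass effect (unit variance by construction); the species random
    intercept and lot residual SDs carry the remaining shares.  Useful
    for studying how well the mixed model recovers a known
    marginal/conditional R^2 decomposition."""
    if abs(fixed_share + species_share + residual_share - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    c = total_ln_sigma_var
    base = SimulationConfig(rng_seed=rng_seed)
    mat_lo, mat_hi = kwargs.get("mat_range_c", base.mat_range_c)
    mat_var = (mat_hi - mat_lo) ** 2 / 12.0
    beta_mat = math.sqrt(fixed_share * c / 2.0 / mat_var)
    beta_mass = -math.sqrt(fixed_share * c / 2.0)
    return SimulationConfig(
        n_species=n_species,
        lots_per_species=lots_per_species,
        beta_mat=beta_mat,
        beta_mass_scaled=beta_mass,
        species_log_sigma_sd=math.sqrt(species_share * c),
        lot_log_sigma_resid_sd=math.sqrt(residual_share * c),
        rng_seed=rng_seed,
        **kwargs,
    )


_DEFAULT_FAMILIES = (
    "Asteraceae", "Poaceae", "Fabaceae", "Caryophyllaceae",
    "Brassicaceae", "Lamiaceae", "Plantaginaceae", "Apiaceae",
)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GerminationObservation], list[SeedLotMeta], list[SpeciesMeta], pd.DataFrame]:
    """Simulate a full multi-species dataset plus its latent truth table.

    All randomness flows from ``config.rng_seed``; identical configs
    give bit-identical datasets."""
    rng = np.random.default_rng(config.rng_seed)
    fam_effects = config.family_effects or {}
    fam_names = tuple(fam_effects) if fam_effects else _DEFAULT_FAMILIES

    observations: list[GerminationObservation] = []
    lot_meta: list[SeedLotMeta] = []
    species_meta: list[SpeciesMeta] = []
    truth_rows = []
    mat_lo, mat_hi = config.mat_range_c
    mat_mid = 0.5 * (mat_lo + mat_hi)
    # lognormal multiplier with the configured CV and unit mean
    s_ln = math.sqrt(math.log(1.0 + config.mass_cv**2)) if config.mass_cv > 0 else 0.0

    for s in range(config.n_species):
        species_id = f"S{s + 1:03d}"
        family = fam_names[s % len(fam_names)]
        fam_off = fam_effects.get(family, 0.0)
        u_s = rng.normal(0.0, config.species_log_sigma_sd)
        n_lots = config.lots_for(s)
        species_mean_mass = float(np.exp(rng.normal(math.log(0.8), 1.0)))
        masses = species_mean_mass * np.exp(
            rng.normal(-0.5 * s_ln**2, s_ln, size=n_lots)
        )
        if n_lots >= 2 and np.std(masses, ddof=1) > 0:
            mass_scaled = (masses - masses.mean()) / np.std(masses, ddof=1)
        else:
            mass_scaled = np.zeros(n_lots)
        mats = rng.uniform(mat_lo, mat_hi, size=n_lots)
        maps_ = rng.uniform(*config.map_range_mm, size=n_lots)
        for l in range(n_lots):
            lot_id = f"{species_id}-L{l + 1:02d}"
            e = rng.normal(0.0, config.lot_log_sigma_resid_sd)
            log_sigma = (
                config.species_log_sigma_mean
                + u_s
                + fam_off
                + config.beta_mat * (mats[l] - mat_mid)
                + config.beta_mass_scaled * mass_scaled[l]
                + e
            )
            sigma = math.exp(log_sigma)
            ki = rng.normal(config.ki_mean, config.ki_sd)
            observations.extend(
                simulate_lot(
                    ki,
                    sigma,
                    config.design,
                    rho=config.overdispersion_rho,
                    dormancy_fraction=config.dormancy_fraction,
                    rng=rng,
                    lot_id=lot_id,
                    species_id=species_id,
                )
            )
            lot_meta.append(
                SeedLotMeta(
                    lot_id=lot_id,
                    species_id=species_id,
                    family=family,
                    thousand_seed_mass_g=float(masses[l]),
                    mat_c=float(mats[l]),
                    map_mm=float(maps_[l]),
                    latitude=50.0,
                    longitude=10.0,
                    provenance="farm",
                )
            )
            truth_rows.append(
                {
                    "lot_id": lot_id,
                    "species_id": species_id,
                    "family": family,
                    "true_sigma": sigma,
                    "true_ki": ki,
                    "u_species": u_s,
                    "family_effect": fam_off,
                    "mat_effect": config.beta_mat * (mats[l] - mat_mid),
                    "mass_effect": config.beta_mass_scaled * float(mass_scaled[l]),
                    "lot_residual": e,
                }
            )
        species_meta.append(
            SpeciesMeta(
                species_id=species_id,
                family=family,
                mean_thousand_seed_mass_g=float(np.mean(masses)),
                oil_content_pct=float(rng.uniform(2.0, 35.0)),
                protein_content_pct=float(rng.uniform(15.0, 36.0)),
                life_cycle="P",
            )
        )
    return observations, lot_meta, species_meta, pd.DataFrame(truth_rows)


def make_screening_fixture(
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GerminationObservation], pd.DataFrame]:
    """A small labelled dataset exercising every screening status.

    Counts are the rounded expected counts (near-noiseless), so the
    screening outcome of every lot is deterministic and recorded as its
    ground-truth label.  Includes a dormancy lot whose day-0 mean is
    below 50% but whose day-5 mean clears the threshold."""
    design = paper_design()
    rng = np.random.default_rng(0) if rng is None else rng

    def expected_lot(lot_id, species_id, ki, sigma, dormancy=0.0, contaminated=False):
        obs = []
        for t in design.durations:
            v = inv_probit(ki - t / sigma)
            if t == 0.0:
                v *= 1.0 - dormancy
            g = int(round(design.seeds_per_replicate * v))
            for r in range(design.replicates_per_duration):
                obs.append(
                    GerminationObservation(
                        lot_id=lot_id,
                        species_id=species_id,
                        aging_days=t,
                        replicate_id=f"r{r + 1}",
                        n_seeds=design.seeds_per_replicate,
                        n_germinated=g,
                        contaminated=contaminated,
                    )
                )
        return obs

    ki_ok = 2.0
    lots = [
        # (lot_id, species, ki, sigma, dormancy, contaminated, expected status)
        ("ret-1", "SPA", ki_ok, 20.0, 0.0, False, "retained"),
        ("ret-2", "SPA", ki_ok, 12.0, 0.0, False, "retained"),
        ("ret-3", "SPB", 1.6, 30.0, 0.0, False, "retained"),
        ("dorm-1", "SPB", ki_ok, 25.0, 0.52, False, "retained"),
        ("lowv-1", "SPC", probit(0.35), 20.0, 0.0, False, "excluded_low_viability"),
        ("lowv-2", "SPC", probit(0.25), 15.0, 0.0, False, "excluded_low_viability"),
        ("lowv-3", "SPC", probit(0.40), 25.0, 0.0, False, "excluded_low_viability"),
        ("long-1", "SPD", ki_ok, 90.0, 0.0, False, "excluded_sigma_exceeds_max"),
        ("long-2", "SPD", 1.8, 110.0, 0.0, False, "excluded_sigma_exceeds_max"),
        ("flat-1", "SPE", 1.5, 1e9, 0.0, False, "excluded_no_significant_slope"),
        ("cont-1", "SPE", ki_ok, 20.0, 0.0, True, "excluded_contaminated"),
    ]
    observations: list[GerminationObservation] = []
    truth_rows = []
    for lot_id, sp, ki, sigma, dorm, cont, status in lots:
        observations.extend(expected_lot(lot_id, sp, ki, sigma, dorm, cont))
        truth_rows.append(
            {
                "lot_id": lot_id,
                "species_id": sp,
                "true_ki": ki,
                "true_sigma": sigma,
                "dormancy_fraction": dorm,
                "contaminated": cont,
                "expected_status": status,
            }
        )
    return observations, pd.DataFrame(truth_rows)
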