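"""Data model, CSV readers/writers and design constants for aging trials.

The tables mirror what a germination lab deposits: one CSV row per
replicate dish per aging duration, plus a seed-lot metadata table with
origin climate and seed mass.  All numeric missing values are empty
cells on disk and ``None``/NaN in memory; nothing is silently
zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AgingDesign",
    "GerminationObservation",
    "SeedLotMeta",
    "SpeciesMeta",
    "ValidationError",
    "paper_design",
    "design_total_seeds",
    "read_germination_table",
    "write_germination_table",
    "read_lot_metadata",
    "write_lot_metadata",
    "read_species_metadata",
    "write_species_metadata",
    "observations_to_frame",
    "frame_to_observations",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class AgingDesign:
    """Layout of an accelerated-aging experiment.

    ``durations`` are the aging exposures in days (strictly increasing,
    starting at 0 for the fresh-seed control).  ``dormancy_window`` is
    the subset of short durations over which "initial germination" is
    taken as a maximum, so that dormancy broken by a brief heat exposure
    does not read as low viability.
    """

    durations: tuple[float, ...]
    replicates_per_duration: int = 3
    seeds_per_replicate: int = 30
    temperature_c: float = 45.0
    relative_humidity_pct: float = 60.0
    dormancy_window: tuple[float, ...] = (0.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.durations)
        object.__setattr__(self, "durations", d)
        object.__setattr__(
            self, "dormancy_window", tuple(float(x) for x in self.dormancy_window)
        )
        if len(d) < 1 or d[0] != 0.0:
            raise ValidationError("durations must start at 0 (fresh-seed control)")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("durations must be strictly increasing and unique")
        if not set(self.dormancy_window) <= set(d):
            raise ValidationError("dormancy_window must be a subset of durations")
        if 0.0 not in self.dormancy_window:
            raise ValidationError("dormancy_window must contain 0")
        if self.replicates_per_duration < 1 or self.seeds_per_replicate < 1:
            raise ValidationError("replicates and seeds per replicate must be >= 1")

    @property
    def max_duration(self) -> float:
        return self.durations[-1]


@dataclass(frozen=True)
class GerminationObservation:
    """One replicate dish: germinated / sown counts at one aging duration."""

    lot_id: str
    species_id: str
    aging_days: float
    replicate_id: str
    n_seeds: int
    n_germinated: int
    contaminated: bool = False

    def __post_init__(self) -> None:
        if self.aging_days < 0:
            raise ValidationError(f"lot {self.lot_id}: negative aging_days")
        if self.n_seeds < 1:
            raise ValidationError(f"lot {self.lot_id}: n_seeds must be >= 1")
        if not 0 <= self.n_germinated <= self.n_seeds:
            raise ValidationError(
                f"lot {self.lot_id}, day {self.aging_days}, replicate "
                f"{self.replicate_id}: n_germinated={self.n_germinated} outside "
                f"[0, n_seeds={self.n_seeds}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_germinated / self.n_seeds


@dataclass(frozen=True)
class SeedLotMeta:
    """Seed-lot covariates: origin climate and 1000-seed mass."""

    lot_id: str
    species_id: str
    family: str = ""
    thousand_seed_mass_g: Optional[float] = None
    mat_c: Optional[float] = None
    map_mm: Optional[float] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    provenance: str = "farm"

    def __post_init__(self) -> None:
        if self.thousand_seed_mass_g is not None and self.thousand_seed_mass_g <= 0:
            raise ValidationError(f"lot {self.lot_id}: non-positive seed mass")
        if self.map_mm is not None and self.map_mm < 0:
            raise ValidationError(f"lot {self.lot_id}: negative precipitation")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValidationError(f"lot {self.lot_id}: latitude outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValidationError(f"lot {self.lot_id}: longitude outside [-180, 180]")
        if self.provenance not in ("wild", "farm"):
            raise ValidationError(f"lot {self.lot_id}: provenance must be wild|farm")


@dataclass(frozen=True)
class SpeciesMeta:
    """Species-level traits (mean seed mass, optional oil/protein content)."""

    species_id: str
    family: str = ""
    mean_thousand_seed_mass_g: Optional[float] = None
    oil_content_pct: Optional[float] = None
    protein_content_pct: Optional[float] = None
    life_cycle: str = "P"

    def __post_init__(self) -> None:
        if (
            self.mean_thousand_seed_mass_g is not None
            and self.mean_thousand_seed_mass_g <= 0
        ):
            raise ValidationError(f"species {self.species_id}: non-positive mass")


def paper_design() -> AgingDesign:
    """The reference aging design: 45 degC / 60% RH, ten durations from 0 to
    72 days, three replicate dishes of 30 seeds per duration, with the
    initial-germination rule taken over days {0, 1, 5}."""
    return AgingDesign(
        durations=(0, 1, 5, 9, 15, 20, 30, 40, 57, 72),
        replicates_per_duration=3,
        seeds_per_replicate=30,
        temperature_c=45.0,
        relative_humidity_pct=60.0,
        dormancy_window=(0, 1, 5),
    )


def design_total_seeds(design: AgingDesign, n_lots: int) -> int:
    """Total seeds required: lots x durations x replicates x seeds/replicate."""
    if n_lots < 1:
        raise ValueError("n_lots must be >= 1")
    return (
        len(design.durations)
        * design.replicates_per_duration
        * design.seeds_per_replicate
        * n_lots
    )


# ---------------------------------------------------------------------------
# CSV readers / writers

_GERM_COLUMNS = (
    "lot_id",
    "species_id",
    "aging_days",
    "replicate_id",
    "n_seeds",
    "n_germinated",
)


def _apply_mapping(df: pd.DataFrame, column_map: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_germination_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[GerminationObservation]:
    """Read a germination trial CSV into validated observations.

    ``column_map`` maps canonical names to the file's column names, so
    deposited tables with other headers can be consumed without editing.
    A missing ``contaminated`` column defaults to False.
    """
    df = _apply_mapping(pd.read_csv(path), column_map)
    missing = [c for c in _GERM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"germination table missing columns: {missing}")
    if "contaminated" not in df.columns:
        df["contaminated"] = False
    df["contaminated"] = df["contaminated"].fillna(False).astype(bool)
    obs: list[GerminationObservation] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        try:
            o = GerminationObservation(
                lot_id=str(row["lot_id"]),
                species_id=str(row["species_id"]),
                aging_days=float(row["aging_days"]),
                replicate_id=str(row["replicate_id"]),
                n_seeds=int(row["n_seeds"]),
                n_germinated=int(row["n_germinated"]),
                contaminated=bool(row["contaminated"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        key = (o.lot_id, o.aging_days, o.replicate_id)
        if key in seen:
            raise ValidationError(
                f"row {i}: duplicate (lot, day, replicate) = {key}"
            )
        seen.add(key)
        obs.append(o)
    return obs


def observations_to_frame(observations: Iterable[GerminationObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lot_id": o.lot_id,
                "species_id": o.species_id,
                "aging_days": o.aging_days,
                "replicate_id": o.replicate_id,
                "n_seeds": o.n_seeds,
                "n_germinated": o.n_germinated,
                "contaminated": o.contaminated,
            }
            for o in observations
        ]
    )


def frame_to_observations(df: pd.DataFrame) -> list[GerminationObservation]:
    return [
        GerminationObservation(
            lot_id=str(r.lot_id),
            species_id=str(r.species_id),
            aging_days=float(r.aging_days),
            replicate_id=str(r.replicate_id),
            n_seeds=int(r.n_seeds),
            n_germinated=int(r.n_germinated),
            contaminated=bool(r.contaminated),
        )
        for r in df.itertuples()
    ]


def write_germination_table(observations: Iterable[GerminationObservation], path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_lot_metadata(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[SeedLotMeta]:
    """Read the seed-lot metadata CSV; empty numeric cells become None."""
    df = _apply_mapping(pd.read_csv(path), column_map)
    required = ("lot_id", "species_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"lot metadata missing columns: {missing}")
    lots: list[SeedLotMeta] = []
    species_of: dict[str, str] = {}
    for i, row in df.iterrows():
        lot_id = str(row["lot_id"])
        species_id = str(row["species_id"])
        if lot_id in species_of and species_of[lot_id] != species_id:
            raise ValidationError(
                f"row {i}: lot {lot_id} mapped to both "
                f"{species_of[lot_id]} and {species_id}"
            )
        species_of[lot_id] = species_id
        lots.append(
            SeedLotMeta(
                lot_id=lot_id,
                species_id=species_id,
                family=str(row.get("family", "") or ""),
                thousand_seed_mass_g=_opt_float(row.get("thousand_seed_mass_g")),
                mat_c=_opt_float(row.get("mat_c")),
                map_mm=_opt_float(row.get("map_mm")),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                provenance=str(row.get("provenance", "farm") or "farm"),
            )
        )
    return lots


def write_lot_metadata(lots: Iterable[SeedLotMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "lot_id": m.lot_id,
                "species_id": m.species_id,
                "family": m.family,
                "thousand_seed_mass_g": m.thousand_seed_mass_g,
                "mat_c": m.mat_c,
                "map_mm": m.map_mm,
                "latitude": m.latitude,
                "longitude": m.longitude,
                "provenance": m.provenance,
            }
            for m in lots
        ]
    ).to_csv(path, index=False)


def read_species_metadata(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[SpeciesMeta]:
    df = _apply_mapping(pd.read_csv(path), column_map)
    if "species_id" not in df.columns:
        raise ValidationError("species metadata missing species_id column")
    return [
        SpeciesMeta(
            species_id=str(row["species_id"]),
            family=str(row.get("family", "") or ""),
            mean_thousand_seed_mass_g=_opt_float(row.get("mean_thousand_seed_mass_g")),
            oil_content_pct=_opt_float(row.get("oil_content_pct")),
            protein_content_pct=_opt_float(row.get("protein_content_pct")),
            life_cycle=str(row.get("life_cycle", "P") or "P"),
        )
        for _, row in df.iterrows()
    ]


def write_species_metadata(species: Iterable[SpeciesMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "family": s.family,
                "mean_thousand_seed_mass_g": s.mean_thousand_seed_mass_g,
                "oil_content_pct": s.oil_content_pct,
                "protein_content_pct": s.protein_content_pct,
                "life_cycle": s.life_cycle,
            }
            for s in species
        ]
    ).to_csv(path, index=False)
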