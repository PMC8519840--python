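"""Feeder-tube mass accounting: raw cage-day masses to per-bee nutrient intake.

Daily consumption of a micro-colony is the 24-h mass loss of its two food
tubes minus the mean evaporative loss measured in a bee-free control cage on
the same diet.  Mass is converted to volume with the solution density
(1.06 g/ml), scaled per bee alive during the preceding 24 h, and converted to
millimoles via volume (ml) x molarity (mol/L) = mmol.  Cumulative intake is
the sum of the daily per-bee values over the feeding period.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diet_design import Diet

__all__ = [
    "DENSITY_G_PER_ML",
    "FeedingRecord",
    "ControlRecord",
    "IntakePoint",
    "evaporation_mean",
    "daily_consumption_mass",
    "per_bee_volume",
    "nutrient_intake",
    "cumulative_intake",
    "compute_intake_table",
]

log = logging.getLogger(__name__)

#: Density of the sucrose/AA solutions, g/ml; a single value for all diets.
DENSITY_G_PER_ML = 1.06


class MissingControlError(ValueError):
    """No evaporation-control records exist for a diet."""


@dataclass(frozen=True)
class FeedingRecord:
    """One cage-day: pre/post masses of both tubes and bees alive that day."""

    cage_id: str
    diet_id: str
    day: int
    tube1_pre_g: float
    tube1_post_g: float
    tube2_pre_g: float
    tube2_post_g: float
    n_alive: int

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("day must be >= 1")
        if self.n_alive < 0:
            raise ValueError("n_alive must be >= 0")


@dataclass(frozen=True)
class ControlRecord:
    """One bee-free control cage-day: 24-h mass loss (any sign; weighing noise)."""

    diet_id: str
    day: int
    mass_loss_g: float


@dataclass(frozen=True)
class IntakePoint:
    """Cumulative per-bee intake of one cage, in ml and mmol."""

    cage_id: str
    diet_id: str
    aa_mmol: float
    c_mmol: float
    volume_ml: float


def evaporation_mean(controls: Iterable[ControlRecord], diet_id: str) -> float:
    """Mean daily evaporative mass loss of a diet's control series (g/day)."""
    losses = [c.mass_loss_g for c in controls if c.diet_id == diet_id]
    if not losses:
        raise MissingControlError(f"no evaporation controls for diet {diet_id!r}")
    return float(np.mean(losses))


def daily_consumption_mass(rec: FeedingRecord, evap: float) -> float:
    """Evaporation-corrected mass consumed by a cage in one day (grams).

    May be negative when the correction exceeds the measured change; the value
    is retained (unbiased) and a warning issued.
    """
    change = (rec.tube1_pre_g - rec.tube1_post_g) + (rec.tube2_pre_g - rec.tube2_post_g)
    corrected = change - evap
    if corrected < 0:
        warnings.warn(
            f"negative corrected consumption ({corrected:.4f} g) for cage "
            f"{rec.cage_id} day {rec.day}; retained",
            stacklevel=2,
        )
    return corrected


def per_bee_volume(mass_g: float, n_alive: int, density: float = DENSITY_G_PER_ML) -> float:
    """Convert a cage-day mass to ml consumed per bee alive that day."""
    if density <= 0:
        raise ValueError("density must be positive")
    if n_alive < 1:
        raise ValueError("per_bee_volume requires n_alive >= 1; skip empty cage-days")
    return (mass_g / n_alive) / density


def nutrient_intake(volume_ml: float, diet: Diet) -> tuple[float, float]:
    """(AA mmol, carbohydrate mmol) in a consumed volume of a diet.

    ml x mol/L = mmol, applied to the diet's total-AA and sucrose molarities.
    """
    return volume_ml * diet.aa_total_molarity, volume_ml * diet.sucrose_molarity


def cumulative_intake(
    records: Sequence[FeedingRecord],
    controls: Iterable[ControlRecord],
    diet: Diet,
    density: float = DENSITY_G_PER_ML,
    floor_at_zero: bool = False,
) -> IntakePoint:
    """Cumulative per-bee intake of one cage over its feeding period.

    Each day's corrected mass is scaled by that day's ``n_alive`` before
    summing; cage-days with no bees alive contribute nothing (logged).  With
    ``floor_at_zero`` negative daily values are clipped instead of retained.
    """
    records = sorted(records, key=lambda r: r.day)
    if not records:
        raise ValueError("no feeding records supplied")
    cages = {r.cage_id for r in records}
    if len(cages) != 1:
        raise ValueError(f"records span multiple cages: {sorted(cages)}")
    days = [r.day for r in records]
    if set(np.diff(days)) - {1}:
        warnings.warn(
            f"gap in feeding days for cage {records[0].cage_id}: {days}",
            stacklevel=2,
        )
    evap = evaporation_mean(controls, diet.id)
    total_volume = 0.0
    for rec in records:
        if rec.n_alive == 0:
            log.info("cage %s day %d: no bees alive, skipped", rec.cage_id, rec.day)
            continue
        mass = daily_consumption_mass(rec, evap)
        if floor_at_zero:
            mass = max(mass, 0.0)
        total_volume += per_bee_volume(mass, rec.n_alive, density)
    if total_volume < 0:
        warnings.warn(
            f"negative cumulative volume for cage {records[0].cage_id}; retained",
            stacklevel=2,
        )
    aa, c = nutrient_intake(total_volume, diet)
    return IntakePoint(
        cage_id=records[0].cage_id,
        diet_id=diet.id,
        aa_mmol=aa,
        c_mmol=c,
        volume_ml=total_volume,
    )


def compute_intake_table(
    feeding: pd.DataFrame,
    controls: pd.DataFrame,
    diets: Sequence[Diet],
    density: float = DENSITY_G_PER_ML,
    floor_at_zero: bool = False,
) -> pd.DataFrame:
    """Vectorized pipeline over the feeding_records.csv / controls.csv schemas.

    Returns the intake.csv schema: one row per cage with cumulative per-bee
    volume (ml) and AA/C intake (mmol).  Equivalent to calling
    :func:`cumulative_intake` cage by cage.
    """
    diet_map = {d.id: d for d in diets}
    unknown = set(feeding["diet_id"]) - set(diet_map)
    if unknown:
        raise KeyError(f"feeding records reference unknown diets: {sorted(unknown)}")
    evap = controls.groupby("diet_id")["mass_loss_g"].mean()
    missing = set(feeding["diet_id"]) - set(evap.index)
    if missing:
        raise MissingControlError(f"no evaporation controls for diets: {sorted(missing)}")

    df = feeding.copy()
    df["corrected_g"] = (
        (df["tube1_pre_g"] - df["tube1_post_g"])
        + (df["tube2_pre_g"] - df["tube2_post_g"])
        - df["diet_id"].map(evap)
    )
    if floor_at_zero:
        df["corrected_g"] = df["corrected_g"].clip(lower=0.0)
    alive = df["n_alive"] > 0
    df["volume_ml"] = 0.0
    df.loc[alive, "volume_ml"] = (
        df.loc[alive, "corrected_g"] / df.loc[alive, "n_alive"] / density
    )
    out = (
        df.groupby(["cage_id", "diet_id"], as_index=False)["volume_ml"]
        .sum()
        .rename(columns={"volume_ml": "volume_ml_per_bee"})
    )
    aa_m = out["diet_id"].map(lambda d: diet_map[d].aa_total_molarity)
    c_m = out["diet_id"].map(lambda d: diet_map[d].sucrose_molarity)
    out["aa_mmol_per_bee"] = out["volume_ml_per_bee"] * aa_m
    out["c_mmol_per_bee"] = out["volume_ml_per_bee"] * c_m
    return out
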