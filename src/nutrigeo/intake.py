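"""Mass-balance intake accounting for colony feeding assays.

Raw observations are wet-weighed diet cubes offered daily and dry-weighed
leftovers; paired control cubes calibrate the wet→dry evaporation loss.  Per
day, dry harvest is ``initial_wet × control_ratio − leftover_dry`` (clamped
at zero).  Cumulative harvest per diet is then partitioned into hoarded
(piled in the nest), scattered (discarded in the foraging arena) and
consumed mass, with the identity

    consumed = harvested − hoarded − scattered

holding exactly, and nutrient contents are attributed from diet recipes:
protein/carbohydrate dry-mass fractions for 2-D diets, energy fractions for
3-D diets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diets import DietComposition2D, DietComposition3D
from .simulate import ColonyDayRecord, ColonyExperiment

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidControlError",
    "ControlQualityError",
    "MassBalanceError",
    "DietIntake",
    "IntakeSummary",
    "ProcessedFractions",
    "dry_harvest_per_day",
    "control_ratio_for_day",
    "summarize_colony",
    "summarize_experiments",
    "percent_processed",
    "summaries_to_frame",
]


class InvalidControlError(ValueError):
    """Control ratio outside (0, 1]."""


class ControlQualityError(ValueError):
    """Control cube gained mass on drying (dry > wet)."""


class MassBalanceError(ValueError):
    """Hoarded + scattered mass exceeds harvested mass."""


def dry_harvest_per_day(
    initial_wet: float, leftover_dry: float, control_ratio: float
) -> float:
    """Dry mass harvested from one cube in one day.

    ``initial_wet × control_ratio`` estimates the cube's dry mass as offered;
    subtracting the leftover dry mass gives harvest.  Small negative values
    (measurement noise on untouched cubes) clamp to zero with a warning.
    """
    if control_ratio <= 0 or control_ratio > 1:
        raise InvalidControlError(f"control ratio {control_ratio} outside (0, 1]")
    if initial_wet < 0 or leftover_dry < 0:
        raise ValueError("masses must be >= 0")
    raw = initial_wet * control_ratio - leftover_dry
    if raw < 0:
        logger.warning("negative computed harvest %.4g mg clamped to 0", raw)
        return 0.0
    return raw


def control_ratio_for_day(control_wet: float, control_dry: float) -> float:
    """Dry:wet mass ratio of a control cube after oven drying."""
    if control_wet <= 0:
        raise InvalidControlError("control wet mass must be > 0")
    ratio = control_dry / control_wet
    if ratio > 1:
        raise ControlQualityError(
            f"control dry mass {control_dry} exceeds wet mass {control_wet}"
        )
    return ratio


@dataclass
class DietIntake:
    """Cumulative dry-mass accounting for one diet color in one colony."""

    harvested: float = 0.0
    hoarded: float = 0.0
    scattered: float = 0.0

    @property
    def consumed(self) -> float:
        return self.harvested - self.hoarded - self.scattered


@dataclass
class IntakeSummary:
    """Per-colony cumulative intake partitioned by diet and nutrient."""

    colony_id: str
    treatment: str
    n_days: int
    per_diet: dict[str, DietIntake]
    # nutrient partitions (mg dry mass)
    protein_harvested: float
    carb_harvested: float
    protein_consumed: float
    carb_consumed: float
    #: (P, C, L) joules consumed; None for 2-D colonies
    energy_consumed: tuple[float, float, float] | None = None

    @property
    def harvested(self) -> float:
        return sum(d.harvested for d in self.per_diet.values())

    @property
    def hoarded(self) -> float:
        return sum(d.hoarded for d in self.per_diet.values())

    @property
    def scattered(self) -> float:
        return sum(d.scattered for d in self.per_diet.values())

    @property
    def consumed(self) -> float:
        return self.harvested - self.hoarded - self.scattered


@dataclass
class ProcessedFractions:
    """Hoarded/scattered percentages of harvested mass for one colony."""

    hoarded_pct: float
    scattered_pct: float
    defined: bool = True


def _record_ratio(rec: ColonyDayRecord) -> float:
    if rec.control_wet > 0 and not math.isnan(rec.control_dry):
        return control_ratio_for_day(rec.control_wet, rec.control_dry)
    return math.nan


def summarize_colony(
    records: Sequence[ColonyDayRecord],
    hoarded_by_diet: Mapping[str, float],
    scattered_by_diet: Mapping[str, float],
    recipes: Mapping[str, DietComposition2D | DietComposition3D],
) -> IntakeSummary:
    """Cumulate one colony's per-day records into an :class:`IntakeSummary`.

    Control ratios are taken per record (one control per day per diet type);
    records with missing controls fall back to the colony-wide mean ratio.
    Raises :class:`MassBalanceError` if hoarded + scattered exceeds harvest
    for any diet.
    """
    if not records:
        raise ValueError("no records given")
    ids = {r.colony_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple colonies: {sorted(ids)}")
    colony_id = records[0].colony_id

    ratios = np.array([_record_ratio(r) for r in records])
    finite = ratios[~np.isnan(ratios)]
    fallback = float(finite.mean()) if finite.size else math.nan
    if np.isnan(ratios).any():
        if math.isnan(fallback):
            raise InvalidControlError(f"colony {colony_id}: no usable control cubes")
        ratios = np.where(np.isnan(ratios), fallback, ratios)

    per_diet: dict[str, DietIntake] = {}
    for rec, ratio in zip(records, ratios):
        if rec.diet_label not in recipes:
            raise KeyError(f"no recipe for diet {rec.diet_label!r}")
        d = per_diet.setdefault(rec.diet_label, DietIntake())
        d.harvested += dry_harvest_per_day(
            rec.cube_initial_wet, rec.cube_leftover_dry, ratio
        )
    for label, d in per_diet.items():
        d.hoarded = float(hoarded_by_diet.get(label, 0.0))
        d.scattered = float(scattered_by_diet.get(label, 0.0))
        if d.hoarded + d.scattered > d.harvested + 1e-9:
            raise MassBalanceError(
                f"colony {colony_id}, diet {label}: hoarded+scattered "
                f"{d.hoarded + d.scattered:.4g} mg exceeds harvested "
                f"{d.harvested:.4g} mg"
            )

    pH = cH = pC = cC = 0.0
    energy = np.zeros(3)
    any3d = False
    for label, d in per_diet.items():
        recipe = recipes[label]
        if isinstance(recipe, DietComposition2D):
            fp, fc = recipe.mass_fractions()
            pH += d.harvested * fp
            cH += d.harvested * fc
            pC += d.consumed * fp
            cC += d.consumed * fc
        else:
            any3d = True
            fracs = np.asarray(recipe.mass_fractions())
            # joules per mg of diet, split by nutrient
            e_per_mg = np.asarray(recipe.energy_per_nutrient) / recipe.total_dry_mass
            energy += d.consumed * e_per_mg
            pC += d.consumed * fracs[0]
            cC += d.consumed * fracs[1]
            pH += d.harvested * fracs[0]
            cH += d.harvested * fracs[1]
    return IntakeSummary(
        colony_id=colony_id,
        treatment="",
        n_days=len({r.day for r in records}),
        per_diet=per_diet,
        protein_harvested=pH,
        carb_harvested=cH,
        protein_consumed=pC,
        carb_consumed=cC,
        energy_consumed=tuple(energy) if any3d else None,
    )


def summarize_experiments(
    experiments: Iterable[ColonyExperiment],
    recipes: Mapping[str, DietComposition2D | DietComposition3D],
) -> list[IntakeSummary]:
    """Summarize each colony of an experiment set."""
    out = []
    for e in experiments:
        s = summarize_colony(e.records, e.hoarded_by_diet, e.scattered_by_diet, recipes)
        s.treatment = e.treatment
        s.n_days = e.n_days
        out.append(s)
    return out


def percent_processed(summary: IntakeSummary) -> ProcessedFractions:
    """Hoarded and scattered mass as percentages of total harvest.

    A zero-harvest colony yields an undefined percentage: flagged
    (``defined=False``, NaN values) and meant to be excluded from means.
    """
    if summary.harvested <= 0:
        logger.warning(
            "colony %s harvested nothing; processed percentages undefined",
            summary.colony_id,
        )
        return ProcessedFractions(math.nan, math.nan, defined=False)
    return ProcessedFractions(
        hoarded_pct=100.0 * summary.hoarded / summary.harvested,
        scattered_pct=100.0 * summary.scattered / summary.harvested,
    )


def summaries_to_frame(summaries: Sequence[IntakeSummary]) -> pd.DataFrame:
    """One-row-per-colony table of the intake summaries (for CSV export)."""
    rows = []
    for s in summaries:
        row = dict(
            colony_id=s.colony_id,
            treatment=s.treatment,
            n_days=s.n_days,
            harvested=s.harvested,
            hoarded=s.hoarded,
            scattered=s.scattered,
            consumed=s.consumed,
            protein_harvested=s.protein_harvested,
            carb_harvested=s.carb_harvested,
            protein_consumed=s.protein_consumed,
            carb_consumed=s.carb_consumed,
        )
        if s.energy_consumed is not None:
            row.update(
                energy_protein=s.energy_consumed[0],
                energy_carb=s.energy_consumed[1],
                energy_lipid=s.energy_consumed[2],
            )
        rows.append(row)
    return pd.DataFrame(rows)
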