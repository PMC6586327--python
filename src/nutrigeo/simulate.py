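"""Synthetic colony-foraging experiments with known ground truth.

Generates complete feeding experiments — per-day diet-cube masses, control
cubes, daily dead-worker counts, end-of-experiment hoarded/scattered masses
sorted by diet color, final worker and egg counts — from a configurable
ground-truth model:

* colonies in choice experiments regulate cumulative consumed (P, C) intake
  around an intake target, mixing the two complementary diets;
* colonies in no-choice experiments settle on their diet's rail at the point
  a rule of compromise predicts (equal total intake, or closest distance to
  the target), with multiplicative lognormal noise;
* in the 3-D experiment, consumed dry mass follows a quadratic response
  surface in (P%, C%) energy composition;
* worker deaths are daily binomial draws with a logistic per-day hazard in
  diet composition plus a colony-bin random intercept (logit scale);
* egg counts are Poisson in composition;
* hoarded and scattered masses are Beta-distributed fractions of harvest;
* observed cube masses are back-computed through a wet→dry evaporation model
  calibrated by per-day control cubes.

Mass conservation (consumed + hoarded + scattered = harvested) holds by
construction, and all draws are reproducible: random streams are keyed by
(seed, stream domain, colony index) so a colony's data do not depend on
generation order.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .diets import (
    DietComposition2D,
    DietComposition3D,
    ExperimentDesign,
    make_2d_diet,
    diet3d_from_label,
    nutritional_rail,
    reference_designs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "ColonyDayRecord",
    "ColonyExperiment",
    "InfeasibleTargetError",
    "default_death_hazard",
    "default_egg_rate",
    "generate",
    "gen_choice_experiment",
    "gen_nochoice_experiment",
    "gen_rmt_experiment",
    "write_fixture",
    "read_fixture",
]


class InfeasibleTargetError(ValueError):
    """The intake target lies outside the cone spanned by the offered rails."""


def default_death_hazard(p_pct: float, c_pct: float) -> float:
    """Default per-day per-worker death probability.

    Logistic in the protein share of macronutrient energy/mass: ~2.1%/day on
    low-protein diets rising to ~8%/day at 80% protein, so 14-day survival
    spans roughly 30–75% across the design — the contrast seen in colony
    feeding assays.
    """
    return 1.0 / (1.0 + math.exp(3.83 - 0.0174 * p_pct))


def default_egg_rate(p_pct: float, c_pct: float) -> float:
    """Default Poisson mean egg count: a quadratic surface peaking at
    balanced protein:carbohydrate and low lipid."""
    lam = 60.0 - 0.166 * p_pct - 0.400 * c_pct + 0.020 * p_pct * c_pct
    return max(0.0, lam)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for a synthetic feeding experiment.

    Defaults encode the reference study conditions: a carbohydrate-biased
    1:1.5 P:C intake target, lognormal total-intake noise, hoarding ~10% and
    scattering ~5.2% of harvest, and response/hazard surfaces shaped like the
    observed 3-D landscapes.
    """

    design: ExperimentDesign
    #: cumulative consumed (protein, carbohydrate) mg per colony; C:P = 1.5
    intake_target: tuple[float, float] = (40.0, 60.0)
    total_intake_cv: float = 0.15
    rule: str = "equal_distance"  # or "closest_distance"
    hoard_frac: float = 0.10
    hoard_sd: float = 0.078
    scatter_frac: float = 0.052
    scatter_sd: float = 0.025
    control_dry_wet_ratio: float = 0.35
    control_ratio_jitter_sd: float = 0.02
    cube_wet_mass: float = 300.0  # mg
    #: (b0, bP, bC, bPP, bCC, bPC) for consumed dry mass vs (P%, C%)
    surface_coeffs: tuple[float, float, float, float, float, float] = (
        10.0,
        0.501,
        1.323,
        0.0,
        -0.011,
        0.009,
    )
    surface_noise_sd: float = 10.0
    death_hazard_fn: Callable[[float, float], float] = default_death_hazard
    egg_rate_fn: Callable[[float, float], float] = default_egg_rate
    bin_effect_sd: float = 0.5
    n_bins: int = 6
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hoard_frac", "scatter_frac", "misclassification_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hoard_frac + self.scatter_frac > 1.0:
            raise ValueError("hoard_frac + scatter_frac must be <= 1")
        if self.total_intake_cv < 0:
            raise ValueError("total_intake_cv must be >= 0")
        if self.rule not in ("equal_distance", "closest_distance"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class ColonyDayRecord:
    """One diet cube offered to one colony on one day, plus its control."""

    colony_id: str
    day: int
    diet_label: str
    cube_initial_wet: float  # mg
    cube_leftover_dry: float  # mg
    control_wet: float  # mg
    control_dry: float  # mg
    deaths: int  # dead workers collected that day (0 on secondary cubes)


@dataclass
class ColonyExperiment:
    """All raw observations for one colony under one treatment."""

    colony_id: str
    kind: str
    treatment: str
    diet_labels: tuple[str, ...]
    bin_id: int
    n_workers_initial: int
    n_days: int
    records: list[ColonyDayRecord]
    hoarded_by_diet: dict[str, float]  # mg dry per diet color
    scattered_by_diet: dict[str, float]
    final_workers: int
    eggs: int


# ---------------------------------------------------------------------------
# random-stream plumbing

_STREAM_BIN = 0
_STREAM_COLONY = 1


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _bin_effects(cfg: GeneratorConfig) -> np.ndarray:
    rng = _rng(cfg.seed, _STREAM_BIN)
    if cfg.bin_effect_sd == 0:
        return np.zeros(cfg.n_bins)
    return rng.normal(0.0, cfg.bin_effect_sd, cfg.n_bins)


def _lognormal_mult(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _beta_frac(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with the given mean/sd; degenerate at the mean when sd=0."""
    if mean <= 0.0:
        return 0.0
    if sd == 0.0:
        return mean
    var = min(sd * sd, 0.99 * mean * (1.0 - mean))
    kappa = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * kappa, (1.0 - mean) * kappa))


def _daily_split(rng: np.random.Generator, total: float, n_days: int) -> np.ndarray:
    """Split a cumulative mass over days (Dirichlet weights, concentration 5)."""
    if total <= 0:
        return np.zeros(n_days)
    return total * rng.dirichlet(np.full(n_days, 5.0))


def _day_ratios(rng: np.random.Generator, cfg: GeneratorConfig, n_days: int) -> np.ndarray:
    r = cfg.control_dry_wet_ratio + rng.normal(0.0, cfg.control_ratio_jitter_sd, n_days)
    return np.clip(r, 0.05, 0.95)


def _records_for_diet(
    colony_id: str,
    diet_label: str,
    daily_harvest: np.ndarray,
    ratios: np.ndarray,
    cube_wet: float,
    deaths: np.ndarray | None,
) -> list[ColonyDayRecord]:
    """Back-compute observed cube masses from per-day dry harvest through the
    evaporation model: leftover_dry = wet * ratio − harvested_dry."""
    recs = []
    for d, (h, r) in enumerate(zip(daily_harvest, ratios), start=1):
        wet = cube_wet
        if h > 0.9 * wet * r:  # offer a bigger cube than was eaten
            wet = h / r + cube_wet
        recs.append(
            ColonyDayRecord(
                colony_id=colony_id,
                day=d,
                diet_label=diet_label,
                cube_initial_wet=wet,
                cube_leftover_dry=wet * r - h,
                control_wet=cube_wet,
                control_dry=cube_wet * r,
                deaths=int(deaths[d - 1]) if deaths is not None else 0,
            )
        )
    return recs


def _draw_deaths(
    rng: np.random.Generator,
    n_workers: int,
    n_days: int,
    hazard: float,
    bin_effect: float,
) -> tuple[np.ndarray, int]:
    """Daily binomial deaths at a bin-shifted logistic hazard; dead workers
    are not replaced after day 1."""
    if hazard <= 0.0:
        return np.zeros(n_days, dtype=int), n_workers
    hazard = min(hazard, 1.0 - 1e-12)
    logit = math.log(hazard / (1.0 - hazard)) + bin_effect
    p = 1.0 / (1.0 + math.exp(-logit))
    deaths = np.zeros(n_days, dtype=int)
    alive = n_workers
    for d in range(n_days):
        deaths[d] = rng.binomial(alive, p)
        alive -= deaths[d]
    return deaths, alive


def _partition_harvest(
    rng: np.random.Generator, cfg: GeneratorConfig, consumed_by_diet: dict[str, float]
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Draw colony-level hoard/scatter fractions and scale harvest so that
    consumed + hoarded + scattered = harvested exactly.

    Fractions are drawn once per colony (applied to every diet color), so a
    colony's pooled hoarded/scattered percentage of harvest equals the draw
    and the across-colony mean is an unbiased estimate of the configured
    fraction."""
    h = _beta_frac(rng, cfg.hoard_frac, cfg.hoard_sd)
    s = _beta_frac(rng, cfg.scatter_frac, cfg.scatter_sd)
    if h + s >= 0.95:  # keep some consumption
        scale = 0.95 / (h + s)
        h, s = h * scale, s * scale
    harvested, hoarded, scattered = {}, {}, {}
    for label, consumed in consumed_by_diet.items():
        total = consumed / (1.0 - h - s)
        hoarded[label] = h * total
        scattered[label] = s * total
        harvested[label] = consumed + hoarded[label] + scattered[label]
    if cfg.misclassification_rate > 0 and len(consumed_by_diet) == 2:
        a, b = list(consumed_by_diet)
        for pile in (hoarded, scattered):
            swap_ab = cfg.misclassification_rate * pile[a]
            swap_ba = cfg.misclassification_rate * pile[b]
            pile[a] += swap_ba - swap_ab
            pile[b] += swap_ab - swap_ba
    return harvested, hoarded, scattered


# ---------------------------------------------------------------------------
# choice experiment


def _mixing_masses(
    target: np.ndarray, d1: DietComposition2D, d2: DietComposition2D
) -> np.ndarray:
    """Dry masses (m1, m2) of each diet whose nutrient sum equals ``target``.

    Solves the 2×2 mass-fraction system; draws outside the cone spanned by
    the two rails are projected onto the nearest rail.
    """
    M = np.array(
        [
            [d1.protein_mass_fraction, d2.protein_mass_fraction],
            [d1.carb_mass_fraction, d2.carb_mass_fraction],
        ]
    )
    m = np.linalg.solve(M, target)
    if (m < 0).any():
        best = None
        for j in range(2):
            v = M[:, j]
            t = max(0.0, float(v @ target))
            resid = float(np.linalg.norm(target - t * v))
            if best is None or resid < best[0]:
                best = (resid, j, t)
        m = np.zeros(2)
        m[best[1]] = best[2]
    return m


def gen_choice_experiment(config: GeneratorConfig) -> list[ColonyExperiment]:
    """Simulate a 2-D choice experiment.

    Each colony's cumulative consumed (P, C) is its lognormal draw around the
    intake target, realized by mixing the two offered diets in the unique
    nonnegative proportions whose nutrient sums hit the draw.
    """
    cfg = config
    if cfg.design.kind != "choice_2d":
        raise ValueError("design.kind must be 'choice_2d'")
    target = np.asarray(cfg.intake_target, dtype=float)
    bins = _bin_effects(cfg)
    colonies = []
    uid = 0
    for ti, (d1, d2) in enumerate(cfg.design.treatments):
        # the configured mean target must be reachable from this pairing
        M = np.array(
            [
                [d1.protein_mass_fraction, d2.protein_mass_fraction],
                [d1.carb_mass_fraction, d2.carb_mass_fraction],
            ]
        )
        if (np.linalg.solve(M, target) < -1e-9).any():
            raise InfeasibleTargetError(
                f"intake target {tuple(target)} lies outside the "
                f"{d1.label} / {d2.label} rail cone"
            )
        for rep in range(cfg.design.replicates_per_treatment):
            rng = _rng(cfg.seed, _STREAM_COLONY, uid)
            draw = target * np.asarray(_lognormal_mult(rng, cfg.total_intake_cv, 2))
            m = _mixing_masses(draw, d1, d2)
            consumed = {d1.label: float(m[0]), d2.label: float(m[1])}
            harvested, hoarded, scattered = _partition_harvest(rng, cfg, consumed)
            colony_id = f"C{ti}-{rep:02d}"
            bin_id = uid % cfg.n_bins
            p_share = 100.0 * draw[0] / draw.sum()
            deaths, alive = _draw_deaths(
                rng,
                cfg.design.n_workers_initial,
                cfg.design.n_days,
                cfg.death_hazard_fn(p_share, 100.0 - p_share),
                bins[bin_id],
            )
            ratios = _day_ratios(rng, cfg, cfg.design.n_days)
            records = []
            for k, diet in enumerate((d1, d2)):
                daily = _daily_split(rng, harvested[diet.label], cfg.design.n_days)
                records.extend(
                    _records_for_diet(
                        colony_id,
                        diet.label,
                        daily,
                        ratios,
                        cfg.cube_wet_mass,
                        deaths if k == 0 else None,
                    )
                )
            eggs = 0
            if cfg.design.n_queens > 0:
                eggs = int(rng.poisson(cfg.egg_rate_fn(p_share, 100.0 - p_share)))
            colonies.append(
                ColonyExperiment(
                    colony_id=colony_id,
                    kind=cfg.design.kind,
                    treatment=cfg.design.treatment_label(ti),
                    diet_labels=(d1.label, d2.label),
                    bin_id=bin_id,
                    n_workers_initial=cfg.design.n_workers_initial,
                    n_days=cfg.design.n_days,
                    records=records,
                    hoarded_by_diet=hoarded,
                    scattered_by_diet=scattered,
                    final_workers=alive,
                    eggs=eggs,
                )
            )
            uid += 1
    return colonies


# ---------------------------------------------------------------------------
# no-choice 2-D experiment


def _rule_point(cfg: GeneratorConfig, diet: DietComposition2D) -> np.ndarray:
    """Ground-truth on-rail intake point under the configured rule."""
    from .geometry2d import predict_closest_distance, predict_equal_distance

    rail = nutritional_rail(diet.p_parts, diet.c_parts)
    if cfg.rule == "equal_distance":
        return np.asarray(predict_equal_distance(cfg.intake_target, rail))
    return np.asarray(predict_closest_distance(cfg.intake_target, rail))


def gen_nochoice_experiment(config: GeneratorConfig) -> list[ColonyExperiment]:
    """Simulate a 2-D no-choice experiment: each colony's cumulative intake
    sits on its diet's rail at the configured rule's prediction, scaled by a
    mean-1 lognormal multiplier."""
    cfg = config
    if cfg.design.kind != "nochoice_2d":
        raise ValueError("design.kind must be 'nochoice_2d'")
    bins = _bin_effects(cfg)
    colonies = []
    uid = 0
    for ti, diet in enumerate(cfg.design.treatments):
        base = _rule_point(cfg, diet)
        p_share = 100.0 * diet.protein_mass_fraction
        for rep in range(cfg.design.replicates_per_treatment):
            rng = _rng(cfg.seed, _STREAM_COLONY, 10_000 + uid)
            point = base * _lognormal_mult(rng, cfg.total_intake_cv)
            consumed = {diet.label: float(point.sum())}
            harvested, hoarded, scattered = _partition_harvest(rng, cfg, consumed)
            colony_id = f"N{ti}-{rep:02d}"
            bin_id = uid % cfg.n_bins
            deaths, alive = _draw_deaths(
                rng,
                cfg.design.n_workers_initial,
                cfg.design.n_days,
                cfg.death_hazard_fn(p_share, 100.0 - p_share),
                bins[bin_id],
            )
            ratios = _day_ratios(rng, cfg, cfg.design.n_days)
            daily = _daily_split(rng, harvested[diet.label], cfg.design.n_days)
            records = _records_for_diet(
                colony_id, diet.label, daily, ratios, cfg.cube_wet_mass, deaths
            )
            colonies.append(
                ColonyExperiment(
                    colony_id=colony_id,
                    kind=cfg.design.kind,
                    treatment=diet.label,
                    diet_labels=(diet.label,),
                    bin_id=bin_id,
                    n_workers_initial=cfg.design.n_workers_initial,
                    n_days=cfg.design.n_days,
                    records=records,
                    hoarded_by_diet=hoarded,
                    scattered_by_diet=scattered,
                    final_workers=alive,
                    eggs=0,
                )
            )
            uid += 1
    return colonies


# ---------------------------------------------------------------------------
# 3-D RMT experiment


def _surface_value(coeffs: Sequence[float], p: float, c: float) -> float:
    b0, bP, bC, bPP, bCC, bPC = coeffs
    return b0 + bP * p + bC * c + bPP * p * p + bCC * c * c + bPC * p * c


def gen_rmt_experiment(config: GeneratorConfig) -> list[ColonyExperiment]:
    """Simulate the 3-D P:C:L no-choice experiment: consumed dry mass drawn
    from the configured quadratic surface in energy composition, binomial
    worker survival with bin random intercepts, Poisson egg counts."""
    cfg = config
    if cfg.design.kind != "nochoice_3d":
        raise ValueError("design.kind must be 'nochoice_3d'")
    bins = _bin_effects(cfg)
    colonies = []
    uid = 0
    for ti, diet in enumerate(cfg.design.treatments):
        mean = _surface_value(cfg.surface_coeffs, diet.p_frac, diet.c_frac)
        if mean < 0:
            logger.warning(
                "surface mean %.3g < 0 at %s; truncating to 0", mean, diet.label
            )
            mean = 0.0
        for rep in range(cfg.design.replicates_per_treatment):
            rng = _rng(cfg.seed, _STREAM_COLONY, 20_000 + uid)
            consumed_total = max(0.0, mean + rng.normal(0.0, cfg.surface_noise_sd))
            consumed = {diet.label: consumed_total}
            harvested, hoarded, scattered = _partition_harvest(rng, cfg, consumed)
            colony_id = f"R{ti}-{rep:02d}"
            bin_id = uid % cfg.n_bins
            deaths, alive = _draw_deaths(
                rng,
                cfg.design.n_workers_initial,
                cfg.design.n_days,
                cfg.death_hazard_fn(diet.p_frac, diet.c_frac),
                bins[bin_id],
            )
            ratios = _day_ratios(rng, cfg, cfg.design.n_days)
            daily = _daily_split(rng, harvested[diet.label], cfg.design.n_days)
            records = _records_for_diet(
                colony_id, diet.label, daily, ratios, cfg.cube_wet_mass, deaths
            )
            eggs = int(rng.poisson(max(0.0, cfg.egg_rate_fn(diet.p_frac, diet.c_frac))))
            colonies.append(
                ColonyExperiment(
                    colony_id=colony_id,
                    kind=cfg.design.kind,
                    treatment=diet.label,
                    diet_labels=(diet.label,),
                    bin_id=bin_id,
                    n_workers_initial=cfg.design.n_workers_initial,
                    n_days=cfg.design.n_days,
                    records=records,
                    hoarded_by_diet=hoarded,
                    scattered_by_diet=scattered,
                    final_workers=alive,
                    eggs=eggs,
                )
            )
            uid += 1
    return colonies


def generate(config: GeneratorConfig) -> list[ColonyExperiment]:
    """Dispatch to the generator matching ``config.design.kind``."""
    return {
        "choice_2d": gen_choice_experiment,
        "nochoice_2d": gen_nochoice_experiment,
        "nochoice_3d": gen_rmt_experiment,
    }[config.design.kind](config)


# ---------------------------------------------------------------------------
# fixture I/O


def _diets_frame(design: ExperimentDesign) -> pd.DataFrame:
    rows = []
    for label, d in design.diets().items():
        if isinstance(d, DietComposition2D):
            rows.append(
                dict(label=label, kind="2d", p_parts=d.p_parts, c_parts=d.c_parts,
                     p_frac=np.nan, c_frac=np.nan, l_frac=np.nan)
            )
        else:
            rows.append(
                dict(label=label, kind="3d", p_parts=np.nan, c_parts=np.nan,
                     p_frac=d.p_frac, c_frac=d.c_frac, l_frac=d.l_frac)
            )
    return pd.DataFrame(rows)


def experiments_to_frames(
    experiments: Sequence[ColonyExperiment],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten experiments into (colony_days, colony_end) tables."""
    day_rows, end_rows = [], []
    for e in experiments:
        for r in e.records:
            day_rows.append(dataclasses.asdict(r))
        for label in e.diet_labels:
            end_rows.append(
                dict(
                    colony_id=e.colony_id,
                    kind=e.kind,
                    treatment=e.treatment,
                    diet_label=label,
                    bin_id=e.bin_id,
                    n_workers_initial=e.n_workers_initial,
                    n_days=e.n_days,
                    hoarded_dry=e.hoarded_by_diet.get(label, 0.0),
                    scattered_dry=e.scattered_by_diet.get(label, 0.0),
                    final_workers=e.final_workers,
                    eggs=e.eggs,
                )
            )
    day_cols = [
        "colony_id", "day", "diet_label", "cube_initial_wet",
        "cube_leftover_dry", "control_wet", "control_dry", "deaths",
    ]
    days = pd.DataFrame(day_rows, columns=day_cols)
    end = pd.DataFrame(
        end_rows,
        columns=[
            "colony_id", "kind", "treatment", "diet_label", "bin_id",
            "n_workers_initial", "n_days", "hoarded_dry", "scattered_dry",
            "final_workers", "eggs",
        ],
    )
    return days, end


def write_fixture(
    experiments: Sequence[ColonyExperiment],
    path: str | Path,
    config: GeneratorConfig | None = None,
) -> Path:
    """Serialize experiments to ``colony_days.csv``, ``colony_end.csv``,
    ``diets.csv`` and (when the config is given) ``truth.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    days, end = experiments_to_frames(experiments)
    # %.17g round-trips float64 exactly
    days.to_csv(path / "colony_days.csv", index=False, float_format="%.17g")
    end.to_csv(path / "colony_end.csv", index=False, float_format="%.17g")
    if config is not None:
        _diets_frame(config.design).to_csv(path / "diets.csv", index=False)
        truth = {
            "design_kind": config.design.kind,
            "intake_target": [float(x) for x in config.intake_target],
            "total_intake_cv": config.total_intake_cv,
            "rule": config.rule,
            "hoard_frac": config.hoard_frac,
            "hoard_sd": config.hoard_sd,
            "scatter_frac": config.scatter_frac,
            "scatter_sd": config.scatter_sd,
            "control_dry_wet_ratio": config.control_dry_wet_ratio,
            "surface_coeffs": [float(x) for x in config.surface_coeffs],
            "surface_noise_sd": config.surface_noise_sd,
            "bin_effect_sd": config.bin_effect_sd,
            "seed": config.seed,
        }
        with open(path / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
    return path


def read_fixture(path: str | Path) -> list[ColonyExperiment]:
    """Read experiments back from the fixture schema (lossless round-trip)."""
    path = Path(path)
    days = pd.read_csv(path / "colony_days.csv", float_precision="round_trip")
    end = pd.read_csv(path / "colony_end.csv", float_precision="round_trip")
    experiments = []
    if end.empty:
        return experiments
    for colony_id, meta in end.groupby("colony_id", sort=False):
        first = meta.iloc[0]
        sub = days[days["colony_id"] == colony_id]
        records = [
            ColonyDayRecord(
                colony_id=colony_id,
                day=int(r.day),
                diet_label=str(r.diet_label),
                cube_initial_wet=float(r.cube_initial_wet),
                cube_leftover_dry=float(r.cube_leftover_dry),
                control_wet=float(r.control_wet),
                control_dry=float(r.control_dry),
                deaths=int(r.deaths),
            )
            for r in sub.itertuples()
        ]
        experiments.append(
            ColonyExperiment(
                colony_id=str(colony_id),
                kind=str(first["kind"]),
                treatment=str(first["treatment"]),
                diet_labels=tuple(meta["diet_label"].astype(str)),
                bin_id=int(first["bin_id"]),
                n_workers_initial=int(first["n_workers_initial"]),
                n_days=int(first["n_days"]),
                records=records,
                hoarded_by_diet=dict(
                    zip(meta["diet_label"].astype(str), meta["hoarded_dry"].astype(float))
                ),
                scattered_by_diet=dict(
                    zip(meta["diet_label"].astype(str), meta["scattered_dry"].astype(float))
                ),
                final_workers=int(first["final_workers"]),
                eggs=int(first["eggs"]),
            )
        )
    return experiments


def read_diets(path: str | Path) -> dict[str, object]:
    """Read the ``diets.csv`` recipe table into diet objects keyed by label."""
    df = pd.read_csv(Path(path) / "diets.csv")
    out: dict[str, object] = {}
    for r in df.itertuples():
        if r.kind == "2d":
            out[str(r.label)] = make_2d_diet(r.p_parts, r.c_parts, label=str(r.label))
        else:
            out[str(r.label)] = diet3d_from_label(str(r.label))
    return out
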