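"""Diet systems and experiment geometry for colony feeding experiments.

Two diet systems are supported:

* **2-D protein:carbohydrate (P:C) diets**, standardized for total
  macronutrient concentration (default 100 g/L) while the P:C ratio is
  manipulated.  Because protein and carbohydrate have roughly equal energy
  per gram, dry-mass intake is the natural currency and each diet defines a
  *nutritional rail* — the ray from the origin of (protein, carbohydrate)
  intake space with slope fixed by the diet's ratio.

* **3-D protein:carbohydrate:lipid (P:C:L) diets**, standardized for total
  energy (default ~675 J per cube) while the fraction of energy supplied by
  each macronutrient is manipulated.  Lipid carries roughly twice the energy
  per unit dry mass of protein or carbohydrate, so energy fractions — not
  masses — are the natural currency.  Three-component mixtures are displayed
  on a right-angled mixture triangle (RMT): protein and carbohydrate energy
  percentages on orthogonal axes, lipid implicit along negative-slope
  isoclines ``P + C = 100 − L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

__all__ = [
    "PC_ENERGY_DENSITY_J_PER_MG",
    "LIPID_ENERGY_MULTIPLIER",
    "DietError",
    "InvalidRatioError",
    "CompositionError",
    "DietComposition2D",
    "DietComposition3D",
    "NutritionalRail",
    "ExperimentDesign",
    "RmtPoint",
    "make_2d_diet",
    "make_3d_diet",
    "diet3d_from_label",
    "rmt_coordinates",
    "rmt_composition",
    "nutritional_rail",
    "reference_designs",
]

# Energy density of protein/carbohydrate in joules per mg dry mass
# (~4 kcal/g).  Only the 2:1 lipid:carbohydrate ratio matters downstream.
PC_ENERGY_DENSITY_J_PER_MG: float = 17.0
LIPID_ENERGY_MULTIPLIER: float = 2.0


class DietError(ValueError):
    """Base class for invalid diet specifications."""


class InvalidRatioError(DietError):
    """A nutrient ratio with no defined direction (e.g. 0:0)."""


class CompositionError(DietError):
    """Nutrient fractions that do not form a valid composition."""


@dataclass(frozen=True)
class DietComposition2D:
    """A concentration-standardized protein:carbohydrate diet.

    ``p_conc + c_conc == total_conc`` and ``p_conc : c_conc == p_parts :
    c_parts`` by construction.
    """

    label: str
    p_parts: float
    c_parts: float
    total_conc: float  # g/L
    p_conc: float  # g/L
    c_conc: float  # g/L

    @property
    def protein_mass_fraction(self) -> float:
        """Fraction of dry macronutrient mass that is protein."""
        return self.p_conc / self.total_conc

    @property
    def carb_mass_fraction(self) -> float:
        return self.c_conc / self.total_conc

    def mass_fractions(self) -> tuple[float, float]:
        return (self.protein_mass_fraction, self.carb_mass_fraction)


@dataclass(frozen=True)
class DietComposition3D:
    """An energy-standardized protein:carbohydrate:lipid diet.

    ``p_frac``, ``c_frac``, ``l_frac`` are percentages of macronutrient
    energy summing to 100.  ``mass_per_nutrient`` follows from the energy
    densities (lipid twice as energy-dense as protein or carbohydrate).
    """

    label: str
    p_frac: float  # % of macronutrient energy
    c_frac: float
    l_frac: float
    total_energy: float  # joules
    energy_per_nutrient: tuple[float, float, float]  # joules (P, C, L)
    mass_per_nutrient: tuple[float, float, float]  # mg dry (P, C, L)

    @property
    def total_dry_mass(self) -> float:
        return sum(self.mass_per_nutrient)

    def mass_fractions(self) -> tuple[float, float, float]:
        """Fractions of dry macronutrient mass for (P, C, L)."""
        m = self.total_dry_mass
        return tuple(x / m for x in self.mass_per_nutrient)  # type: ignore[return-value]


class RmtPoint(NamedTuple):
    """Position of a three-component mixture on the right-angled mixture
    triangle: ``x`` = protein %, ``y`` = carbohydrate %, and the implicit
    lipid isocline ``x + y = isocline`` (slope −1)."""

    x: float
    y: float
    isocline: float


@dataclass(frozen=True)
class NutritionalRail:
    """The ray from the origin of (protein, carbohydrate) intake space on
    which intake of a fixed-ratio food is confined."""

    p_parts: float
    c_parts: float
    direction: tuple[float, float]  # unit vector in (P, C) space

    def point_at(self, t: float) -> tuple[float, float]:
        """Point at distance ``t`` along the rail."""
        return (t * self.direction[0], t * self.direction[1])


DesignKind = Literal["choice_2d", "nochoice_2d", "nochoice_3d"]


@dataclass(frozen=True)
class ExperimentDesign:
    """A colony feeding-experiment layout.

    ``treatments`` holds single diets for no-choice designs and pairs of
    complementary diets for choice designs.
    """

    kind: DesignKind
    treatments: tuple
    replicates_per_treatment: int
    n_workers_initial: int
    n_days: int
    n_queens: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 1:
            raise ValueError("replicates_per_treatment must be >= 1")
        if self.kind == "choice_2d":
            for pair in self.treatments:
                if len(pair) != 2 or pair[0].label == pair[1].label:
                    raise ValueError(
                        "choice treatments must be pairs of distinct diets"
                    )

    @property
    def n_colonies(self) -> int:
        return len(self.treatments) * self.replicates_per_treatment

    def treatment_label(self, i: int) -> str:
        t = self.treatments[i]
        if self.kind == "choice_2d":
            return f"{t[0].label}+{t[1].label}"
        return t.label

    def diets(self) -> dict[str, object]:
        """All distinct diets in the design, keyed by label."""
        out: dict[str, object] = {}
        for t in self.treatments:
            for d in t if self.kind == "choice_2d" else (t,):
                out[d.label] = d
        return out


# ---------------------------------------------------------------------------
# constructors


def make_2d_diet(
    p_parts: float, c_parts: float, total_conc: float = 100.0, label: str | None = None
) -> DietComposition2D:
    """Build a concentration-standardized P:C diet.

    Parameters
    ----------
    p_parts, c_parts
        Ratio parts of protein and carbohydrate (e.g. 1 and 6 for a 1:6 diet).
    total_conc
        Total macronutrient concentration in g/L (100 g/L standard).
    """
    if p_parts < 0 or c_parts < 0 or total_conc <= 0:
        raise DietError("ratio parts must be >= 0 and total_conc > 0")
    if p_parts + c_parts == 0:
        raise InvalidRatioError("a 0:0 diet has no defined composition")
    s = p_parts + c_parts
    if label is None:
        label = f"{p_parts:g}:{c_parts:g}"
    return DietComposition2D(
        label=label,
        p_parts=float(p_parts),
        c_parts=float(c_parts),
        total_conc=float(total_conc),
        p_conc=total_conc * p_parts / s,
        c_conc=total_conc * c_parts / s,
    )


def make_3d_diet(
    p_frac: float,
    c_frac: float,
    l_frac: float,
    total_energy: float = 675.0,
    label: str | None = None,
    pc_energy_density: float = PC_ENERGY_DENSITY_J_PER_MG,
) -> DietComposition3D:
    """Build an energy-standardized P:C:L diet from energy percentages.

    Fractions must sum to 100 (within 1e-6); use :func:`diet3d_from_label`
    for printed labels such as ``"33:33:33"`` that need renormalization.
    """
    if min(p_frac, c_frac, l_frac) < 0:
        raise CompositionError("energy fractions must be >= 0")
    if total_energy <= 0:
        raise DietError("total_energy must be > 0")
    if abs(p_frac + c_frac + l_frac - 100.0) > 1e-6:
        raise CompositionError(
            f"energy fractions sum to {p_frac + c_frac + l_frac:g}, expected 100"
        )
    if label is None:
        label = f"{p_frac:g}:{c_frac:g}:{l_frac:g}"
    energies = (
        p_frac / 100.0 * total_energy,
        c_frac / 100.0 * total_energy,
        l_frac / 100.0 * total_energy,
    )
    eps = pc_energy_density
    masses = (
        energies[0] / eps,
        energies[1] / eps,
        energies[2] / (LIPID_ENERGY_MULTIPLIER * eps),
    )
    return DietComposition3D(
        label=label,
        p_frac=float(p_frac),
        c_frac=float(c_frac),
        l_frac=float(l_frac),
        total_energy=float(total_energy),
        energy_per_nutrient=energies,
        mass_per_nutrient=masses,
    )


def diet3d_from_label(label: str, total_energy: float = 675.0) -> DietComposition3D:
    """Build a 3-D diet from a printed ``"P:C:L"`` label.

    Labels whose parts already sum to 100 are taken at face value; others
    (the ``33:33:33`` case, summing to 99) are renormalized proportionally so
    the composition closes to 100%.
    """
    parts = [float(x) for x in label.split(":")]
    if len(parts) != 3:
        raise CompositionError(f"expected P:C:L label, got {label!r}")
    s = sum(parts)
    if s <= 0:
        raise InvalidRatioError(f"label {label!r} has zero total")
    if abs(s - 100.0) > 1e-6:
        parts = [x * 100.0 / s for x in parts]
    return make_3d_diet(*parts, total_energy=total_energy, label=label)


# ---------------------------------------------------------------------------
# geometry


def rmt_coordinates(diet: DietComposition3D) -> RmtPoint:
    """Right-angled mixture-triangle coordinates of a 3-D diet.

    Protein on x, carbohydrate on y; the lipid fraction is implicit as the
    negative-slope isocline ``x + y = 100 − L``.
    """
    return RmtPoint(x=diet.p_frac, y=diet.c_frac, isocline=100.0 - diet.l_frac)


def rmt_composition(x: float, y: float) -> tuple[float, float, float]:
    """Invert RMT coordinates back to a (P, C, L) composition."""
    if x < 0 or y < 0 or x + y > 100.0 + 1e-9:
        raise CompositionError(f"({x}, {y}) lies outside the mixture triangle")
    return (x, y, 100.0 - x - y)


def nutritional_rail(p_parts: float, c_parts: float) -> NutritionalRail:
    """Unit-direction nutritional rail for a P:C ratio.

    Any point ``t * direction`` (t > 0) on the rail has protein:carbohydrate
    ratio exactly ``p_parts : c_parts``.
    """
    if p_parts < 0 or c_parts < 0:
        raise DietError("ratio parts must be >= 0")
    norm = math.hypot(p_parts, c_parts)
    if norm == 0:
        raise InvalidRatioError("a 0:0 rail has no direction")
    return NutritionalRail(
        p_parts=float(p_parts),
        c_parts=float(c_parts),
        direction=(p_parts / norm, c_parts / norm),
    )


def rail_for_diet(diet: DietComposition2D) -> NutritionalRail:
    return nutritional_rail(diet.p_parts, diet.c_parts)


# ---------------------------------------------------------------------------
# reference experimental designs


#: P:C ratios of the five no-choice diets, carbohydrate-biased to
#: protein-biased.
NOCHOICE_2D_RATIOS: tuple[tuple[int, int], ...] = ((1, 6), (1, 3), (1, 1), (3, 1), (6, 1))

#: Complementary pairings offered in the choice experiment.
CHOICE_2D_PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((1, 6), (3, 1)),
    ((1, 3), (6, 1)),
)

#: Energy-percentage labels of the seven P:C:L diets.
RMT_3D_LABELS: tuple[str, ...] = (
    "33:33:33",
    "80:10:10",
    "10:80:10",
    "10:10:80",
    "45:45:10",
    "10:45:45",
    "45:10:45",
)


def reference_designs() -> dict[str, ExperimentDesign]:
    """The three standard colony feeding-experiment designs.

    * ``choice_2d`` — two complementary pairings (1:6 with 3:1, and 1:3 with
      6:1 P:C), 12 colonies each, 200 workers, 12 days.
    * ``nochoice_2d`` — five P:C diets (1:6 … 6:1), 8 colonies each, 12 days.
    * ``nochoice_3d`` — seven P:C:L diets, 5 colonies each, 200 workers plus
      4 queens, 14 days.
    """
    choice = ExperimentDesign(
        kind="choice_2d",
        treatments=tuple(
            (make_2d_diet(*a), make_2d_diet(*b)) for a, b in CHOICE_2D_PAIRINGS
        ),
        replicates_per_treatment=12,
        n_workers_initial=200,
        n_days=12,
    )
    nochoice = ExperimentDesign(
        kind="nochoice_2d",
        treatments=tuple(make_2d_diet(p, c) for p, c in NOCHOICE_2D_RATIOS),
        replicates_per_treatment=8,
        n_workers_initial=200,
        n_days=12,
    )
    rmt = ExperimentDesign(
        kind="nochoice_3d",
        treatments=tuple(diet3d_from_label(lbl) for lbl in RMT_3D_LABELS),
        replicates_per_treatment=5,
        n_workers_initial=200,
        n_days=14,
        n_queens=4,
    )
    return {"choice_2d": choice, "nochoice_2d": nochoice, "nochoice_3d": rmt}
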