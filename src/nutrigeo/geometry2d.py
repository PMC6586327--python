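"""Intake targets, intake arrays, and rules of compromise in 2-D P:C space.

A choice experiment (two complementary imbalanced foods) reveals the *intake
target* — the (protein, carbohydrate) blend colonies self-select.  A
no-choice experiment confines colonies to single rails; the shape of the
resulting *intake array* across rails reveals the rule of compromise:

* **equal distance** — constant total intake P + C on every rail (a
  straight-line array with slope −1 through the target isocline), the
  generalist strategy of overharvesting both nutrients alike;
* **closest distance** — the on-rail point nearest the target (a convex
  array), the specialist strategy.

The classifier here compares summed squared distances of observed per-rail
mean intakes to each rule's predictions, declaring the smaller SSE the rule
unless the two are within a factor-1.5 band (indeterminate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .diets import NutritionalRail
from .intake import IntakeSummary

__all__ = [
    "InsufficientDataError",
    "IntakeTarget",
    "RailErrorBar",
    "RuleOfCompromiseResult",
    "estimate_intake_target",
    "predict_equal_distance",
    "predict_closest_distance",
    "classify_rule",
    "pythagorean_se",
]


class InsufficientDataError(ValueError):
    """Too few colonies or rails for the requested estimate."""


@dataclass(frozen=True)
class IntakeTarget:
    """Mean self-selected cumulative intake point with per-axis SEs.

    ``ratio_c_over_p`` is the headline C:P ratio of mean intakes;
    ``ratio_mean_of_ratios`` averages per-colony C/P ratios instead.
    """

    P_T: float  # mg protein
    C_T: float  # mg carbohydrate
    ratio_c_over_p: float
    se: tuple[float, float]
    n_colonies: int
    ratio_mean_of_ratios: float = math.nan

    @property
    def point(self) -> tuple[float, float]:
        return (self.P_T, self.C_T)


@dataclass(frozen=True)
class RailErrorBar:
    """A standard-error bar drawn along a rail through the mean intake point
    (pythagorean SE: the quadrature sum of per-axis standard errors)."""

    center: tuple[float, float]
    se_along_rail: float
    rail: NutritionalRail

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center
        dx, dy = self.rail.direction
        s = self.se_along_rail
        return ((cx - s * dx, cy - s * dy), (cx + s * dx, cy + s * dy))


@dataclass
class RuleOfCompromiseResult:
    """Observed per-rail intake means against both rules' predictions."""

    observed: dict  # rail key -> (P, C) mean
    predicted_equal_distance: dict
    predicted_closest_distance: dict
    sse_equal_distance: float
    sse_closest_distance: float
    linearity_r2: float
    classification: str  # equal_distance | closest_distance | indeterminate
    total_intake_anova: object | None = None


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def estimate_intake_target(
    summaries: Sequence[IntakeSummary] | np.ndarray,
) -> IntakeTarget:
    """Estimate the intake target from choice-experiment colonies.

    Accepts intake summaries or an ``(n, 2)`` array of per-colony cumulative
    consumed (protein, carbohydrate) mg.  The target is the across-colony
    mean point; SEs are per-axis standard errors.
    """
    if len(summaries) and isinstance(summaries[0], IntakeSummary):
        pts = np.array(
            [(s.protein_consumed, s.carb_consumed) for s in summaries], dtype=float
        )
    else:
        pts = np.asarray(summaries, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 colonies to estimate an intake target, got {len(pts)}"
        )
    P_T, C_T = pts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_colony = pts[:, 1] / pts[:, 0]
    return IntakeTarget(
        P_T=float(P_T),
        C_T=float(C_T),
        ratio_c_over_p=float(C_T / P_T) if P_T > 0 else math.inf,
        se=(_se(pts[:, 0]), _se(pts[:, 1])),
        n_colonies=len(pts),
        ratio_mean_of_ratios=float(np.mean(per_colony[np.isfinite(per_colony)])),
    )


def _target_point(target) -> np.ndarray:
    if isinstance(target, IntakeTarget):
        return np.array(target.point)
    return np.asarray(target, dtype=float)


def predict_equal_distance(target, rail: NutritionalRail) -> tuple[float, float]:
    """Equal-distance prediction: the on-rail point with the same total
    intake P + C as the target."""
    t = _target_point(target)
    dx, dy = rail.direction
    k = (t[0] + t[1]) / (dx + dy)
    return (k * dx, k * dy)


def predict_closest_distance(target, rail: NutritionalRail) -> tuple[float, float]:
    """Closest-distance prediction: the orthogonal projection of the target
    onto the rail (clamped to the nonnegative ray)."""
    t = _target_point(target)
    d = np.array(rail.direction)
    k = max(0.0, float(t @ d))
    return (k * d[0], k * d[1])


def _linearity_r2(points: np.ndarray) -> float:
    """R² of the best straight line through the observed array points,
    via total least squares (first principal component)."""
    centered = points - points.mean(axis=0)
    if np.allclose(centered, 0):
        return 1.0
    s = np.linalg.svd(centered, compute_uv=False)
    total = float((s**2).sum())
    return float(s[0] ** 2 / total) if total > 0 else 1.0


def classify_rule(
    points_by_rail: Mapping[object, np.ndarray],
    target,
    indeterminate_band: float = 1.5,
    run_anova: bool = True,
) -> RuleOfCompromiseResult:
    """Classify the rule of compromise from no-choice intake points.

    Parameters
    ----------
    points_by_rail
        Mapping of :class:`NutritionalRail` (or any key with a ``direction``)
        to per-colony ``(n_i, 2)`` arrays of cumulative (P, C) intakes.
    target
        The intake target (an :class:`IntakeTarget` or a length-2 point).
    indeterminate_band
        The classification is *indeterminate* when the SSE ratio between
        rules falls within ``[1/band, band]``.
    """
    if len(points_by_rail) < 3:
        raise InsufficientDataError(
            f"need >= 3 rails to classify a rule, got {len(points_by_rail)}"
        )
    observed, pred_ed, pred_cd = {}, {}, {}
    sse_ed = sse_cd = 0.0
    for rail, pts in points_by_rail.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        mean = pts.mean(axis=0)
        observed[rail] = tuple(mean)
        pred_ed[rail] = predict_equal_distance(target, rail)
        pred_cd[rail] = predict_closest_distance(target, rail)
        sse_ed += float(((mean - np.array(pred_ed[rail])) ** 2).sum())
        sse_cd += float(((mean - np.array(pred_cd[rail])) ** 2).sum())

    if sse_ed == sse_cd == 0.0:
        # the target lies on every rail; both rules coincide
        classification = "equal_distance"
    else:
        lo, hi = sorted((sse_ed, sse_cd))
        if lo > 0 and hi / lo <= indeterminate_band:
            classification = "indeterminate"
        else:
            classification = (
                "equal_distance" if sse_ed < sse_cd else "closest_distance"
            )

    anova = None
    if run_anova and all(len(np.atleast_2d(p)) >= 2 for p in points_by_rail.values()):
        from .stats import anova_tukey

        def rail_key(r, i):
            if hasattr(r, "p_parts"):
                return f"{r.p_parts:g}:{r.c_parts:g}"
            return i

        totals = {
            rail_key(r, i): np.asarray(p, float).reshape(-1, 2).sum(axis=1)
            for i, (r, p) in enumerate(points_by_rail.items())
        }
        anova = anova_tukey(totals)

    return RuleOfCompromiseResult(
        observed=observed,
        predicted_equal_distance=pred_ed,
        predicted_closest_distance=pred_cd,
        sse_equal_distance=sse_ed,
        sse_closest_distance=sse_cd,
        linearity_r2=_linearity_r2(np.array(list(observed.values()))),
        classification=classification,
        total_intake_anova=anova,
    )


def pythagorean_se(points: np.ndarray, rail: NutritionalRail) -> RailErrorBar:
    """Rail-aligned standard-error bar for per-colony intakes on one rail.

    ``se_along_rail = sqrt(SE_P² + SE_C²)``; the bar runs along the rail
    direction through the mean intake point.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 colonies for a standard error")
    se_p, se_c = _se(pts[:, 0]), _se(pts[:, 1])
    return RailErrorBar(
        center=tuple(pts.mean(axis=0)),
        se_along_rail=math.hypot(se_p, se_c),
        rail=rail,
    )
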