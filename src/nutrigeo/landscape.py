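"""Response-surface landscapes on the P:C:L simplex.

Responses measured on the seven-diet right-angled mixture-triangle design
are modeled as second-degree polynomials in the protein and carbohydrate
energy percentages (lipid is implicit, ``L = 100 − P − C``):

    y = β0 + βP·P + βC·C + βPP·P² + βCC·C² + βPC·P·C + ε

Quadratic terms that are not significant at ``alpha`` are removed and the
model refit once (linear and cross-product terms always stay).  A classical
lack-of-fit F-test splits residual variation into pure replicate error and
systematic deviation of design-point means from the surface.  The fitted
quadratic is maximized over the closed simplex {P ≥ 0, C ≥ 0, P + C ≤ 100}
by closed-form enumeration of the interior stationary point, the three
edges, and the three vertices.  Smooth landscapes for display come from
thin-plate splines (radial basis r²·log r with affine part, smoothing λ),
and the fundamental macronutrient niche (FMN) is delineated as the
top-quantile region of the consumption landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import RBFInterpolator

import statsmodels.api as sm

__all__ = [
    "DesignMatrixError",
    "NoPureErrorError",
    "DegenerateSplineError",
    "ResponseSurfaceFit",
    "LackOfFit",
    "LandscapeGrid",
    "FmnRegion",
    "fit_rsm",
    "lack_of_fit",
    "maximize_surface",
    "tps_landscape",
    "fmn_region",
]

TERMS = ("const", "P", "C", "P2", "C2", "PC")
QUADRATIC_TERMS = ("P2", "C2")


class DesignMatrixError(ValueError):
    """Rank-deficient or undersized response-surface design."""


class NoPureErrorError(ValueError):
    """Lack-of-fit requested without replicated design points."""


class DegenerateSplineError(ValueError):
    """Thin-plate spline requested on collinear design points."""


@dataclass
class LackOfFit:
    F: float
    df_lof: int
    df_pure: int
    p: float
    ss_lof: float
    ss_pure: float


@dataclass
class ResponseSurfaceFit:
    """A fitted (possibly pruned) second-degree surface on the simplex."""

    response_name: str
    coefficients: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    overall_p: float
    r_squared: float
    dropped_terms: list[str]
    max_composition: tuple[float, float, float]
    max_value: float
    lack_of_fit: LackOfFit | None = None
    alpha: float = 0.05
    n_obs: int = 0

    def coeff_tuple(self) -> tuple[float, float, float, float, float, float]:
        """(β0, βP, βC, βPP, βCC, βPC), dropped terms as 0."""
        c = self.coefficients
        return tuple(c.get(t, 0.0) for t in TERMS)  # type: ignore[return-value]

    def predict(self, P, C):
        b0, bP, bC, bPP, bCC, bPC = self.coeff_tuple()
        P = np.asarray(P, float)
        C = np.asarray(C, float)
        return b0 + bP * P + bC * C + bPP * P * P + bCC * C * C + bPC * P * C


def _design_matrix(P: np.ndarray, C: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    cols = {
        "const": np.ones_like(P),
        "P": P,
        "C": C,
        "P2": P * P,
        "C2": C * C,
        "PC": P * C,
    }
    return np.column_stack([cols[t] for t in terms])


def _ols(X: np.ndarray, y: np.ndarray, terms: Sequence[str]):
    res = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignMatrixError(
            f"collinear design: terms {list(terms)} are not estimable"
        )
    return res


def fit_rsm(
    points: np.ndarray,
    values: np.ndarray,
    alpha: float = 0.05,
    response_name: str = "response",
    with_lack_of_fit: bool = True,
) -> ResponseSurfaceFit:
    """Fit the second-degree response surface with quadratic pruning.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (protein %, carbohydrate %) energy compositions.
    values
        Response per observation (mg, %, counts — any units).
    alpha
        Significance level for dropping quadratic terms: both ``P²`` and
        ``C²`` with p > alpha are removed simultaneously and the model refit
        once.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    y = np.asarray(values, float)
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    if len(np.unique(pts, axis=0)) < 6:
        raise DesignMatrixError(
            "need >= 6 distinct design compositions for a quadratic surface"
        )
    P, C = pts[:, 0], pts[:, 1]

    terms = list(TERMS)
    res = _ols(_design_matrix(P, C, terms), y, terms)
    pvals = dict(zip(terms, res.pvalues))
    dropped = [t for t in QUADRATIC_TERMS if pvals[t] > alpha]
    if dropped:
        terms = [t for t in terms if t not in dropped]
        res = _ols(_design_matrix(P, C, terms), y, terms)

    coefficients = dict(zip(terms, res.params))
    fit = ResponseSurfaceFit(
        response_name=response_name,
        coefficients=coefficients,
        se=dict(zip(terms, res.bse)),
        t=dict(zip(terms, res.tvalues)),
        p=dict(zip(terms, res.pvalues)),
        overall_p=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        dropped_terms=dropped,
        max_composition=(math.nan,) * 3,
        max_value=math.nan,
        alpha=alpha,
        n_obs=len(y),
    )
    comp, val = maximize_surface(fit)
    fit.max_composition = comp
    fit.max_value = val
    if with_lack_of_fit:
        try:
            fit.lack_of_fit = lack_of_fit(fit, pts, y)
        except NoPureErrorError:
            fit.lack_of_fit = None
    return fit


def lack_of_fit(fit: ResponseSurfaceFit, points: np.ndarray, values: np.ndarray) -> LackOfFit:
    """Classical lack-of-fit F-test against pure replicate error.

    Residual sums of squares decompose into pure error (within replicated
    design points) and lack of fit (design-point means vs the surface);
    ``F = (SS_lof/df_lof) / (SS_pe/df_pe)``.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    y = np.asarray(values, float)
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    m = len(uniq)
    n = len(y)
    if n <= m:
        raise NoPureErrorError("no replicated design points: pure error undefined")
    n_params = len(fit.coefficients)
    df_lof = m - n_params
    df_pure = n - m
    if df_lof <= 0:
        raise NoPureErrorError(
            f"no residual degrees of freedom for lack of fit "
            f"({m} design points, {n_params} parameters)"
        )
    ss_pure = 0.0
    ss_lof = 0.0
    for g in range(m):
        yy = y[inv == g]
        mean = yy.mean()
        ss_pure += float(((yy - mean) ** 2).sum())
        pred = float(fit.predict(uniq[g, 0], uniq[g, 1]))
        ss_lof += len(yy) * (mean - pred) ** 2
    if ss_pure == 0.0:
        F = math.inf if ss_lof > 0 else 0.0
        p = 0.0 if ss_lof > 0 else 1.0
    else:
        F = (ss_lof / df_lof) / (ss_pure / df_pure)
        p = float(scipy.stats.f.sf(F, df_lof, df_pure))
    return LackOfFit(F=float(F), df_lof=df_lof, df_pure=df_pure, p=p,
                     ss_lof=float(ss_lof), ss_pure=float(ss_pure))


# ---------------------------------------------------------------------------
# constrained maximization over the simplex


def _edge_candidates(a: float, b: float, lo: float, hi: float) -> list[float]:
    """Stationary point of q(t) = a·t² + b·t + const on [lo, hi], plus ends."""
    cand = [lo, hi]
    if a != 0.0:
        t = -b / (2.0 * a)
        if lo < t < hi:
            cand.append(t)
    return cand


def maximize_surface(fit, domain: tuple[float, float] | None = None):
    """Global maximizer of a quadratic surface on the closed simplex.

    Accepts a :class:`ResponseSurfaceFit` or a coefficient 6-tuple
    (β0, βP, βC, βPP, βCC, βPC).  Enumerates the interior stationary point
    (when the Hessian is nonsingular and the point feasible), the three
    edges (1-D quadratics in closed form) and the three vertices, and
    returns ``((P*, C*, L*), value)``.  ``domain=(lo, hi)`` optionally
    restricts P and C to the observed design range instead of the full
    simplex.
    """
    if isinstance(fit, ResponseSurfaceFit):
        b0, bP, bC, bPP, bCC, bPC = fit.coeff_tuple()
    else:
        b0, bP, bC, bPP, bCC, bPC = fit
    lo, hi = (0.0, 100.0) if domain is None else domain

    def f(p, c):
        return b0 + bP * p + bC * c + bPP * p * p + bCC * c * c + bPC * p * c

    cand: list[tuple[float, float]] = []
    # interior stationary point: ∇f = 0
    H = np.array([[2 * bPP, bPC], [bPC, 2 * bCC]])
    if abs(np.linalg.det(H)) > 1e-14:
        sp = np.linalg.solve(H, [-bP, -bC])
        if lo <= sp[0] <= hi and lo <= sp[1] <= hi and sp.sum() <= 100.0:
            cand.append((float(sp[0]), float(sp[1])))
    # edge C = lo
    for p in _edge_candidates(bPP, bP + bPC * lo, lo, min(hi, 100.0 - lo)):
        cand.append((p, lo))
    # edge P = lo
    for c in _edge_candidates(bCC, bC + bPC * lo, lo, min(hi, 100.0 - lo)):
        cand.append((lo, c))
    # hypotenuse P + C = 100 (only reachable when hi covers it)
    if lo + hi >= 100.0:
        # substitute c = 100 − p: coefficients of p² and p
        a = bPP + bCC - bPC
        b = bP - bC - 200.0 * bCC + 100.0 * bPC
        for p in _edge_candidates(a, b, max(lo, 100.0 - hi), min(hi, 100.0 - lo)):
            cand.append((p, 100.0 - p))
    # remaining box corners when the domain is a restricted hull
    if domain is not None:
        for p, c in ((hi, hi), (lo, hi), (hi, lo)):
            if p + c <= 100.0:
                cand.append((p, c))

    vals = [f(p, c) for p, c in cand]
    i = int(np.argmax(vals))
    p_star, c_star = cand[i]
    return (p_star, c_star, 100.0 - p_star - c_star), float(vals[i])


# ---------------------------------------------------------------------------
# thin-plate-spline landscapes and the FMN


@dataclass
class LandscapeGrid:
    """A smoothed response surface evaluated on the masked simplex grid."""

    P: np.ndarray  # (ny, nx) protein % grid
    C: np.ndarray
    values: np.ndarray  # NaN outside the simplex mask
    lam: float
    resolution: float

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class FmnRegion:
    """Top-quantile region of a landscape: the fundamental macronutrient
    niche when computed on the consumption surface."""

    grid: LandscapeGrid
    quantile: float
    threshold: float
    mask: np.ndarray
    area_pct: float


def tps_landscape(
    points: np.ndarray,
    values: np.ndarray,
    lam: float = 0.001,
    grid_resolution: float = 1.0,
) -> LandscapeGrid:
    """Thin-plate-spline landscape over the simplex.

    Replicated design points are aggregated to their means before fitting,
    so as λ → 0 the spline interpolates design-point means.  ``lam`` is the
    roughness-penalty weight (0.001 standard), ``grid_resolution`` the grid
    step in composition percent.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    y = np.asarray(values, float)
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    means = np.array([y[inv == g].mean() for g in range(len(uniq))])
    if len(uniq) < 3 or np.linalg.matrix_rank(uniq - uniq.mean(axis=0)) < 2:
        raise DegenerateSplineError(
            "thin-plate spline needs >= 3 non-collinear design points"
        )
    if lam <= 0:
        raise ValueError("smoothing parameter must be > 0")
    rbf = RBFInterpolator(uniq, means, kernel="thin_plate_spline", smoothing=lam)
    axis = np.arange(0.0, 100.0 + 1e-9, grid_resolution)
    P, C = np.meshgrid(axis, axis)
    flat = np.column_stack([P.ravel(), C.ravel()])
    z = rbf(flat).reshape(P.shape)
    z = np.where(P + C <= 100.0 + 1e-9, z, np.nan)
    return LandscapeGrid(P=P, C=C, values=z, lam=lam, resolution=grid_resolution)


def fmn_region(grid: LandscapeGrid, q: float = 0.9) -> FmnRegion:
    """Cells at or above the q-quantile of in-mask landscape values.

    ``area_pct`` is the region's share of the simplex (in-mask cells).
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    vals = grid.values[grid.mask]
    threshold = float(np.quantile(vals, q))
    region = grid.mask & (grid.values >= threshold)
    area_pct = 100.0 * region.sum() / grid.mask.sum()
    return FmnRegion(
        grid=grid, quantile=q, threshold=threshold, mask=region, area_pct=float(area_pct)
    )


def table_summary(fits: Sequence[ResponseSurfaceFit]) -> pd.DataFrame:
    """Flat per-term summary of several surface fits (effect, estimate, SE,
    t, p, R², lack-of-fit p, maximum response) for delimited-text export."""
    rows = []
    for fit in fits:
        lof_p = fit.lack_of_fit.p if fit.lack_of_fit else math.nan
        rows.append(
            dict(response=fit.response_name, effect="(model)", estimate=math.nan,
                 se=math.nan, t=math.nan, p=fit.overall_p, r_squared=fit.r_squared,
                 lack_of_fit_p=lof_p,
                 max_P=fit.max_composition[0], max_C=fit.max_composition[1],
                 max_L=fit.max_composition[2])
        )
        for term in TERMS:
            if term == "const":
                continue
            if term in fit.coefficients:
                rows.append(
                    dict(response=fit.response_name, effect=term,
                         estimate=fit.coefficients[term], se=fit.se[term],
                         t=fit.t[term], p=fit.p[term], r_squared=math.nan,
                         lack_of_fit_p=math.nan, max_P=math.nan, max_C=math.nan,
                         max_L=math.nan)
                )
            elif term in fit.dropped_terms:
                rows.append(
                    dict(response=fit.response_name, effect=term, estimate=math.nan,
                         se=math.nan, t=math.nan, p=math.nan, r_squared=math.nan,
                         lack_of_fit_p=math.nan, max_P=math.nan, max_C=math.nan,
                         max_L=math.nan)
                )
    return pd.DataFrame(rows)
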