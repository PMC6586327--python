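"""Treatment-comparison statistics for colony feeding experiments.

* one-way ANOVA with post-hoc Tukey HSD and compact letter displays, for
  harvest/consumption/hoard/scatter comparisons across diet treatments;
* paired t-tests for within-colony comparisons of colored-diet hoarded or
  scattered masses;
* binomial-logit mixed models of the proportion of living workers
  (alive / (alive + dead)) against day, diet and their interaction, with a
  colony-source-bin random intercept.  The mixed model maximizes the exact
  marginal likelihood by Gauss–Hermite quadrature over the random effect
  (21 nodes); at zero random-effect variance it reduces to the ordinary
  fixed-effects binomial GLM.  Term tests are likelihood-ratio chi-squares.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.numdiff import approx_hess

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientReplicationError",
    "DegenerateVarianceError",
    "AnovaResult",
    "PairedTestResult",
    "SurvivalModelResult",
    "anova_tukey",
    "paired_ttest",
    "survival_glmm",
    "survival_curves",
]


class InsufficientReplicationError(ValueError):
    """A group with too few observations for the requested test."""


class DegenerateVarianceError(ValueError):
    """Paired differences with zero variance but nonzero mean."""


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    tukey_pairs: dict  # (a, b) -> (mean difference b-a, adjusted p)
    letters: dict  # group -> compact letter display
    alpha: float = 0.05


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    n_pairs: int


@dataclass
class SurvivalModelResult:
    params: dict[str, float]  # fixed effects, logit scale
    se: dict[str, float]
    random_intercept_sd: float
    random_intercept_var: float
    term_tests: dict[str, tuple[float, int, float]]  # term -> (chi2, df, p)
    fitted: np.ndarray  # fitted daily survival proportions
    loglik: float
    converged: bool
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ANOVA + Tukey + compact letters


def _compact_letters(groups: Sequence, nonsig_pairs: set[frozenset], alpha: float) -> dict:
    """Compact letter display by the insert-and-absorb algorithm: groups
    sharing a letter are not significantly different."""
    letters_sets: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) in nonsig_pairs:
            continue
        # a and b differ: no letter set may contain both
        new_sets = []
        for s in letters_sets:
            if a in s and b in s:
                new_sets.append(s - {b})
                new_sets.append(s - {a})
            else:
                new_sets.append(s)
        # absorb subsets
        letters_sets = [
            s for s in new_sets
            if not any(s < t for t in new_sets) and s
        ]
        # dedupe
        seen, dedup = [], []
        for s in letters_sets:
            if s not in seen:
                seen.append(s)
                dedup.append(s)
        letters_sets = dedup
    if not letters_sets:
        letters_sets = [set(groups)]
    # ensure every group appears somewhere
    for g in groups:
        if not any(g in s for s in letters_sets):
            letters_sets.append({g})
    # letters ordered by group means order given
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i]
    return out


def anova_tukey(groups: Mapping[object, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across treatments, with Tukey HSD and letter display.

    ``groups`` maps treatment labels to 1-D observation arrays (one value
    per colony); every group needs at least two observations.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], float).ravel() for g in labels]
    if len(labels) < 2:
        raise InsufficientReplicationError("need >= 2 groups")
    for g, a in zip(labels, arrays):
        if len(a) < 2:
            raise InsufficientReplicationError(
                f"group {g!r} has {len(a)} observation(s); need >= 2"
            )
    k = len(labels)
    N = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb, dfw = k - 1, N - k
    if ssw == 0.0:
        F = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(scipy.stats.f.sf(F, dfb, dfw))

    values = np.concatenate(arrays)
    codes = np.concatenate([[str(g)] * len(a) for g, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)
    pairs: dict = {}
    nonsig: set[frozenset] = set()
    res = tukey.summary().data[1:]
    for row in res:
        a, b, diff, p_adj = row[0], row[1], float(row[2]), float(row[3])
        pairs[(a, b)] = (diff, p_adj)
        if p_adj > alpha:
            nonsig.add(frozenset((a, b)))
    str_labels = [str(g) for g in labels]
    letters = _compact_letters(str_labels, nonsig, alpha)
    return AnovaResult(
        F=float(F),
        df_between=dfb,
        df_within=dfw,
        p=p,
        group_means={g: float(a.mean()) for g, a in zip(labels, arrays)},
        tukey_pairs=pairs,
        letters={g: letters[str(g)] for g in labels},
        alpha=alpha,
    )


def paired_ttest(mass_a: np.ndarray, mass_b: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test on per-colony masses ``a − b``."""
    a = np.asarray(mass_a, float).ravel()
    b = np.asarray(mass_b, float).ravel()
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise InsufficientReplicationError("need >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0.0:
        if d.mean() != 0.0:
            raise DegenerateVarianceError(
                "paired differences are constant and nonzero"
            )
        return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_difference=0.0, n_pairs=n)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
    return PairedTestResult(
        t=float(t), df=n - 1, p=p, mean_difference=float(d.mean()), n_pairs=n
    )


# ---------------------------------------------------------------------------
# binomial random-intercept GLMM


def _binom_logpmf_const(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    return (
        scipy.special.gammaln(n + 1)
        - scipy.special.gammaln(y + 1)
        - scipy.special.gammaln(n - y + 1)
    )


class _BinomialRandomIntercept:
    """Marginal likelihood of a binomial-logit model with one Gaussian
    random intercept, integrated by Gauss–Hermite quadrature."""

    def __init__(self, X: np.ndarray, y: np.ndarray, n: np.ndarray,
                 group_idx: np.ndarray, n_nodes: int = 21):
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = math.sqrt(2.0) * nodes  # standard-normal abscissae
        self.logw = np.log(weights / math.sqrt(math.pi))
        self.X, self.y, self.n = X, y, n
        self.group_idx = group_idx
        self.n_groups = int(group_idx.max()) + 1 if len(group_idx) else 0
        self.const = _binom_logpmf_const(y, n)

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta = self.X @ beta
        if sigma == 0.0:
            lp = self.const + self.y * eta - self.n * np.logaddexp(0.0, eta)
            return float(lp.sum())
        e = eta[:, None] + sigma * self.z[None, :]  # (rows, K)
        lp = (
            self.const[:, None]
            + self.y[:, None] * e
            - self.n[:, None] * np.logaddexp(0.0, e)
        )
        # sum rows within cluster, then integrate per cluster
        by_group = np.zeros((self.n_groups, len(self.z)))
        np.add.at(by_group, self.group_idx, lp)
        return float(scipy.special.logsumexp(by_group + self.logw[None, :], axis=1).sum())

    def negll(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        return -self.loglik(beta, math.exp(log_sigma))


def _fit_glmm(X, y, n, group_idx, fix_sigma: float | None = None):
    """Fit by marginal ML; returns (beta, sigma, loglik, converged)."""
    # fixed-effects GLM start values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    beta0 = np.asarray(glm.params)
    model = _BinomialRandomIntercept(X, y, n, group_idx)
    if fix_sigma is not None:
        def nll(b):
            return -model.loglik(b, fix_sigma)

        res = scipy.optimize.minimize(nll, beta0, method="BFGS",
                                      options={"maxiter": 500, "gtol": 1e-8})
        return res.x, fix_sigma, -res.fun, res.success, model
    x0 = np.append(beta0, math.log(0.3))
    res = scipy.optimize.minimize(model.negll, x0, method="BFGS",
                                  options={"maxiter": 1000, "gtol": 1e-8})
    beta, sigma = res.x[:-1], math.exp(res.x[-1])
    ll = -res.fun
    # a vanishing random effect: compare against the sigma = 0 boundary
    ll0 = model.loglik(beta, 0.0)
    if sigma < 1e-4 or ll0 >= ll - 1e-10:
        b, s, l2, ok, _ = _fit_glmm(X, y, n, group_idx, fix_sigma=0.0)
        if l2 >= ll - 1e-8:
            return b, 0.0, l2, ok, model
    return beta, sigma, ll, res.success, model


def _survival_design(
    df: pd.DataFrame,
    day: str,
    diet: str,
    include_interaction: bool,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix with intercept, numeric day, diet dummies and the
    day×diet interaction; returns column names and term→column-index map."""
    names = ["const"]
    cols = [np.ones(len(df))]
    term_cols: dict[str, list[int]] = {"day": [], "diet": [], "day:diet": []}
    cols.append(df[day].to_numpy(float))
    names.append("day")
    term_cols["day"] = [1]
    levels = sorted(df[diet].astype(str).unique())
    for lev in levels[1:]:
        term_cols["diet"].append(len(cols))
        cols.append((df[diet].astype(str) == lev).to_numpy(float))
        names.append(f"diet[{lev}]")
    if include_interaction:
        for lev in levels[1:]:
            term_cols["day:diet"].append(len(cols))
            cols.append(
                df[day].to_numpy(float) * (df[diet].astype(str) == lev).to_numpy(float)
            )
            names.append(f"day:diet[{lev}]")
    else:
        term_cols.pop("day:diet")
    return np.column_stack(cols), names, term_cols


def survival_glmm(
    data: pd.DataFrame,
    alive: str = "alive",
    dead: str = "dead",
    day: str = "day",
    diet: str = "diet",
    group: str = "bin",
    include_interaction: bool = True,
    var_fixed: float | None = None,
) -> SurvivalModelResult:
    """Binomial-logit mixed model of the proportion of living workers.

    Fixed effects: numeric day, diet treatment, and (optionally) their
    interaction; random intercept per colony-source bin.  Term significance
    is tested by likelihood-ratio chi-squares against the model without the
    term.  ``var_fixed=0`` pins the random-intercept variance, reproducing
    the ordinary fixed-effects GLM.
    """
    df = data.copy()
    y = df[alive].to_numpy(float)
    n = y + df[dead].to_numpy(float)
    if (y < 0).any() or (df[dead] < 0).any():
        raise ValueError("alive/dead counts must be nonnegative")
    warnings_list: list[str] = []
    if df[dead].sum() == 0 or df[alive].sum() == 0:
        # the likelihood has no interior maximum; report the saturated answer
        all_alive = df[dead].sum() == 0
        msg = "degenerate-fit: all workers " + ("alive" if all_alive else "dead")
        logger.warning(msg)
        return SurvivalModelResult(
            params={},
            se={},
            random_intercept_sd=0.0,
            random_intercept_var=0.0,
            term_tests={},
            fitted=np.full(len(df), 1.0 if all_alive else 0.0),
            loglik=0.0,
            converged=True,
            warnings=[msg],
        )
    groups_codes, _ = pd.factorize(df[group])
    X, names, term_cols = _survival_design(df, day, diet, include_interaction)

    fix_sigma = None if var_fixed is None else math.sqrt(var_fixed)
    beta, sigma, ll, ok, model = _fit_glmm(X, y, n, groups_codes, fix_sigma)
    if np.abs(beta).max() > 30:
        warnings_list.append("possible complete separation: infinite-SE coefficients")
        logger.warning(warnings_list[-1])

    # standard errors from the observed information of the fixed effects
    def nll_beta(b):
        return -model.loglik(b, sigma)

    se = np.full(len(beta), math.nan)
    try:
        H = approx_hess(beta, nll_beta)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, math.nan))
    except np.linalg.LinAlgError:
        warnings_list.append("singular information matrix: SEs unavailable")

    term_tests: dict[str, tuple[float, int, float]] = {}
    for term, idx in term_cols.items():
        if not idx:
            continue
        keep = [j for j in range(X.shape[1]) if j not in idx]
        b_r, s_r, ll_r, _, _ = _fit_glmm(X[:, keep], y, n, groups_codes, fix_sigma)
        chi2 = max(0.0, 2.0 * (ll - ll_r))
        dof = len(idx)
        term_tests[term] = (chi2, dof, float(scipy.stats.chi2.sf(chi2, dof)))

    eta = X @ beta
    fitted = 1.0 / (1.0 + np.exp(-eta))
    return SurvivalModelResult(
        params=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        random_intercept_sd=float(sigma),
        random_intercept_var=float(sigma * sigma),
        term_tests=term_tests,
        fitted=fitted,
        loglik=float(ll),
        converged=bool(ok),
        warnings=warnings_list,
    )


def survival_curves(
    deaths_by_colony: Mapping[object, np.ndarray],
    n_initial: int,
    treatments: Mapping[object, object] | None = None,
) -> pd.DataFrame:
    """Per-treatment mean proportion of workers alive by day.

    ``deaths_by_colony`` maps colony id to its per-day dead-worker counts;
    ``treatments`` maps colony id to treatment label (one pooled curve when
    omitted).
    """
    rows = []
    for cid, deaths in deaths_by_colony.items():
        deaths = np.asarray(deaths, float)
        cum = deaths.cumsum()
        if cum[-1] > n_initial:
            raise ValueError(f"colony {cid}: cumulative deaths exceed n_initial")
        alive = 1.0 - cum / n_initial
        t = treatments[cid] if treatments else "all"
        for d, a in enumerate(alive, start=1):
            rows.append(dict(treatment=t, colony_id=cid, day=d, prop_alive=a))
    df = pd.DataFrame(rows)
    return (
        df.groupby(["treatment", "day"], sort=True)["prop_alive"]
        .mean()
        .reset_index()
    )
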