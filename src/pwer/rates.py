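"""Population-wise, strata-wise and family-wise error rates and their
critical values.

For a common one-sided threshold ``c`` the population-wise error rate is the
prevalence-weighted average of strata-wise family-wise error rates,

    PWER(c) = sum_J pi_J * (1 - F_{0, Sigma_J}(c, ..., c)),

with ``F`` the centered multivariate normal or t cdf on the correlation
submatrix ``Sigma_J`` of the populations the stratum belongs to.  PWER is
continuous and strictly decreasing in ``c``, so the critical value solving
``PWER(c) = alpha`` is found by a bracketed root search; the family-wise
error rate is the equicoordinate tail of the full matrix and always demands
the larger threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri, stdtrit

from .design import TestStatisticModel
from .mvtail import StrataTails, TailEvaluator, default_evaluator
from .populations import PrevalenceVector, min_prevalence_adjust

__all__ = [
    "CriticalValueResult",
    "MinPrevalenceResult",
    "equicoordinate_tail",
    "pwer",
    "fwer",
    "swer",
    "swer_summary",
    "solve_common_c",
    "solve_fwer_c",
    "solve_min_prevalence_c",
    "solve_per_population_c",
]


@dataclass(frozen=True)
class CriticalValueResult:
    """A solved rejection boundary with solver diagnostics."""

    mode: str  # "common" | "fwer" | "per-population"
    c: float | np.ndarray
    achieved: float | np.ndarray
    iterations: int
    bracket: tuple[float, float]
    tol: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.c)):
            raise ValueError("critical value must be finite")


@dataclass(frozen=True)
class MinPrevalenceResult:
    """Unadjusted and minimal-prevalence-adjusted boundaries.

    The operative boundary for error control is the larger of the two, since
    the adjustment is not guaranteed to raise the boundary on every design.
    """

    unadjusted: CriticalValueResult
    adjusted: CriticalValueResult
    pi_min: float

    @property
    def operative(self) -> float:
        return max(float(self.unadjusted.c), float(self.adjusted.c))


def equicoordinate_tail(
    corr: np.ndarray,
    c: float | Sequence[float],
    family: str = "gaussian",
    df: float | None = None,
    evaluator: TailEvaluator | None = None,
) -> float:
    """``1 - F(c, ..., c)`` for a centered MVN/MVT with correlation ``corr``."""
    ev = evaluator if evaluator is not None else default_evaluator()
    if family == "gaussian":
        df = None
    elif family == "student-t":
        if df is None:
            raise ValueError("student-t tail needs degrees of freedom")
    else:
        raise ValueError(f"unknown family {family!r}")
    return ev.tail(corr, c, df)


def _strata_tails(
    prev_or_weights,
    model: TestStatisticModel,
    evaluator: TailEvaluator | None,
    df: float | None = None,
    skip_zero_weight: bool = True,
) -> tuple[np.ndarray, StrataTails, list[int]]:
    """Weights and a batched tail evaluator over the (nonzero-weight) strata."""
    prev = prev_or_weights
    system = prev.system
    if model.m != system.m:
        raise ValueError("prevalence vector and statistic model disagree on m")
    if df is None:
        df = model.df if model.family == "student-t" else None
        if df is not None and np.ndim(df) > 0:
            raise ValueError(
                "per-population degrees of freedom need solve_per_population_c"
            )
    weights, masks = [], []
    for k, J in enumerate(system.strata):
        w = prev.weights[k]
        if skip_zero_weight and w == 0.0:
            continue
        weights.append(w)
        masks.append(J)
    mats = [model.submatrix(system.members(J)) for J in masks]
    return np.asarray(weights), StrataTails(mats, df=df, evaluator=evaluator), masks


def pwer(
    prev: PrevalenceVector,
    model: TestStatisticModel,
    c: float,
    evaluator: TailEvaluator | None = None,
) -> float:
    """Population-wise error rate at threshold ``c`` (zero-weight strata skipped)."""
    weights, tails, _ = _strata_tails(prev, model, evaluator)
    return float(weights @ tails.tails(c))


def fwer(
    model: TestStatisticModel,
    c: float,
    evaluator: TailEvaluator | None = None,
) -> float:
    """Family-wise error rate: equicoordinate tail of the full correlation matrix."""
    df = model.df if model.family == "student-t" else None
    ev = evaluator if evaluator is not None else default_evaluator()
    return ev.tail(model.corr, c, None if df is None else float(np.max(df)))


def swer(
    model: TestStatisticModel,
    members: Sequence[int],
    c: float,
    evaluator: TailEvaluator | None = None,
) -> float:
    """Strata-wise FWER of the stratum belonging to populations ``members``."""
    members = tuple(members)
    if not members:
        raise ValueError("stratum must belong to at least one population")
    df = model.df if model.family == "student-t" else None
    ev = evaluator if evaluator is not None else default_evaluator()
    return ev.tail(model.submatrix(members), c, df)


def swer_summary(
    prev: PrevalenceVector,
    model: TestStatisticModel,
    c: float,
    evaluator: TailEvaluator | None = None,
) -> tuple[float, float]:
    """Maximum and unweighted mean of the strata-wise FWERs over the strata
    with positive prevalence."""
    weights, tails, _ = _strata_tails(prev, model, evaluator)
    values = tails.tails(c)
    return float(values.max()), float(values.mean())


def _bracketed_solve(
    objective: Callable[[float], float],
    alpha: float,
    lo: float,
    hi: float,
    tol: float,
) -> tuple[float, float, int, tuple[float, float]]:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    evals = [0]

    def g(c: float) -> float:
        evals[0] += 1
        return objective(c) - alpha

    if g(max(lo, 0.0)) < 0:
        raise ValueError(
            f"alpha={alpha} is not attainable: error rate at c={max(lo, 0.0)} is below alpha"
        )
    lo = max(lo, 0.0)
    expansions = 0
    while g(hi) > 0:
        hi *= 2.0
        expansions += 1
        if expansions > 10:
            raise ValueError("failed to bracket the critical value")
    root = brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16)
    achieved = objective(root)
    if abs(achieved - alpha) > tol:
        raise RuntimeError(
            f"solver residual {abs(achieved - alpha):.2e} exceeds tolerance {tol:.2e}"
        )
    return float(root), float(achieved), evals[0], (lo, hi)


def _family_quantile(p: float, family: str, df: float | None) -> float:
    if family == "student-t":
        return float(stdtrit(df, p))
    return float(ndtri(p))


def solve_common_c(
    prev: PrevalenceVector,
    model: TestStatisticModel,
    alpha: float,
    tol: float = 1e-6,
    evaluator: TailEvaluator | None = None,
) -> CriticalValueResult:
    """Common threshold with PWER (under the given prevalences) equal to ``alpha``.

    The solution is bracketed between the univariate quantile (PWER of any
    design is at least the univariate tail) and the Bonferroni quantile.
    """
    weights, tails, _ = _strata_tails(prev, model, evaluator)
    df = tails.df
    lo = _family_quantile(1.0 - alpha, model.family, df)
    hi = max(_family_quantile(1.0 - alpha / model.m, model.family, df), lo + 0.25)
    c, achieved, evals, bracket = _bracketed_solve(
        lambda c: float(weights @ tails.tails(c)), alpha, lo, hi, tol
    )
    return CriticalValueResult("common", c, achieved, evals, bracket, tol)


def solve_fwer_c(
    model: TestStatisticModel,
    alpha: float,
    tol: float = 1e-6,
    evaluator: TailEvaluator | None = None,
) -> CriticalValueResult:
    """Threshold controlling the family-wise error rate at ``alpha``."""
    ev = evaluator if evaluator is not None else default_evaluator()
    df = model.df if model.family == "student-t" else None
    if df is not None and np.ndim(df) > 0:
        df = float(np.max(df))
    tails = StrataTails([model.corr], df=df, evaluator=ev)
    lo = _family_quantile(1.0 - alpha, model.family, df)
    hi = max(_family_quantile(1.0 - alpha / model.m, model.family, df), lo + 0.25)
    c, achieved, evals, bracket = _bracketed_solve(
        lambda c: float(tails.tails(c)[0]), alpha, lo, hi, tol
    )
    return CriticalValueResult("fwer", c, achieved, evals, bracket, tol)


def solve_min_prevalence_c(
    prev_hat: PrevalenceVector,
    model: TestStatisticModel,
    alpha: float,
    pi_min: float | str = "auto",
    tol: float = 1e-6,
    evaluator: TailEvaluator | None = None,
) -> MinPrevalenceResult:
    """Boundary from the estimated prevalences and from their
    minimal-prevalence adjustment; the operative boundary is the maximum."""
    unadj = solve_common_c(prev_hat, model, alpha, tol, evaluator)
    adjusted_prev = min_prevalence_adjust(prev_hat, pi_min)
    adj = solve_common_c(adjusted_prev, model, alpha, tol, evaluator)
    from .populations import auto_min_prevalence

    value = auto_min_prevalence(prev_hat.system.m) if pi_min == "auto" else float(pi_min)
    return MinPrevalenceResult(unadjusted=unadj, adjusted=adj, pi_min=value)


def solve_per_population_c(
    prev_hat: PrevalenceVector,
    model: TestStatisticModel,
    alpha: float,
    tol: float = 1e-6,
    evaluator: TailEvaluator | None = None,
) -> CriticalValueResult:
    """Per-population boundaries for the Satterthwaite t approximation.

    Population ``i`` solves the estimated-PWER equation with every stratum
    tail taken from the multivariate t at ``df_i``; the root-finds are
    independent across populations.
    """
    if model.family != "student-t" or model.df is None:
        raise ValueError("per-population boundaries require a student-t model")
    dfs = np.broadcast_to(np.asarray(model.df, dtype=float), (model.m,))
    cs = np.empty(model.m)
    achieved = np.empty(model.m)
    total_evals = 0
    bracket = (np.inf, -np.inf)
    for i in range(model.m):
        weights, tails, _ = _strata_tails(prev_hat, model, evaluator, df=float(dfs[i]))
        lo = _family_quantile(1.0 - alpha, "student-t", dfs[i])
        hi = max(_family_quantile(1.0 - alpha / model.m, "student-t", dfs[i]), lo + 0.25)
        c, a, evals, b = _bracketed_solve(
            lambda c: float(weights @ tails.tails(c)), alpha, lo, hi, tol
        )
        cs[i], achieved[i] = c, a
        total_evals += evals
        bracket = (min(bracket[0], b[0]), max(bracket[1], b[1]))
    return CriticalValueResult("per-population", cs, achieved, total_evals, bracket, tol)
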