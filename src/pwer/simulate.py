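"""Synthetic-data generation and the plug-in prevalence simulation study.

The generator emulates a biomarker-stratified umbrella trial: ``m`` binary
biomarkers define overlapping populations; patients carrying no biomarker are
screened out, so the enrolled strata counts are multinomial over the
``2**m - 1`` nonempty biomarker configurations; patients are randomized to
their stratum's eligible arms; responses are independent normals per
(stratum, arm) cell.

A study replicate mirrors trial practice under the global null: draw the
biomarker probabilities (when not fixed), draw strata counts, allocate,
estimate the prevalences from the sample, solve the rejection boundary so the
*estimated* PWER equals ``alpha``, and then score that boundary against the
*true* prevalences.  The spread of the true PWER around ``alpha`` across
replicates quantifies the cost of not knowing the prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    AllocationTable,
    AnalysisError,
    TestStatisticModel,
    TreatmentPattern,
    TrialData,
    VarianceModel,
    correlation_matrix,
    random_allocation,
    stratified_allocation,
)
from .mvtail import StrataTails, TailEvaluator
from .populations import (
    PopulationSystem,
    PrevalenceVector,
    StrataCounts,
    enumerate_strata,
    marginal_sum_prevalences,
    min_prevalence_adjust,
    mle_prevalences,
)
from .rates import solve_common_c, solve_per_population_c

__all__ = [
    "BiomarkerModel",
    "SimulationConfig",
    "ReplicateResult",
    "ConfigError",
    "true_prevalences",
    "draw_strata_counts",
    "draw_responses",
    "run_replicate",
    "run_study",
    "conditioned_study",
    "summarize_replicates",
]


class ConfigError(ValueError):
    """A simulation configuration the engine cannot honour."""


@dataclass(frozen=True)
class BiomarkerModel:
    """Binary biomarkers defining the overlapping populations.

    ``probs`` fixes the expression probabilities; when ``None`` they are
    redrawn uniformly on ``support`` for every replicate.  ``latent_corr``
    switches to dependent biomarkers: marker ``i`` is expressed iff a latent
    standard normal vector with this correlation matrix falls below the
    ``probs``-quantile in coordinate ``i`` (a Gaussian threshold copula, which
    preserves the stated marginal probabilities).
    """

    m: int
    probs: np.ndarray | None = None
    support: tuple[float, float] = (0.0, 1.0)
    latent_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (self.m,) or np.any(p <= 0) or np.any(p >= 1):
                raise ConfigError("biomarker probabilities must lie in (0, 1)")
            object.__setattr__(self, "probs", p)
        a, b = self.support
        if not 0.0 <= a < b <= 1.0:
            raise ConfigError("probability support must be a subinterval of [0, 1]")
        if self.latent_corr is not None:
            R = np.asarray(self.latent_corr, dtype=float)
            if R.shape != (self.m, self.m) or not np.allclose(R, R.T):
                raise ConfigError("latent correlation matrix must be symmetric m x m")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ConfigError("latent correlation matrix must be PSD")

    def draw_probs(self, rng: np.random.Generator) -> np.ndarray:
        if self.probs is not None:
            return self.probs
        a, b = self.support
        return rng.uniform(a, b, size=self.m)


def _independent_strata_mass(system: PopulationSystem, p: np.ndarray) -> np.ndarray:
    masks = np.asarray(system.strata)
    bits = (masks[:, None] >> np.arange(system.m)[None, :]) & 1
    return np.prod(np.where(bits == 1, p[None, :], 1.0 - p[None, :]), axis=1)


def _latent_strata_mass(
    system: PopulationSystem,
    p: np.ndarray,
    R: np.ndarray,
    evaluator: TailEvaluator,
) -> np.ndarray:
    """Orthant probabilities of the thresholded Gaussian, by inclusion-exclusion
    over the complement of each stratum."""
    from scipy.special import ndtri

    b = ndtri(p)
    raw = np.empty(system.n_strata)
    for k, J in enumerate(system.strata):
        inside = [i - 1 for i in system.members(J)]
        outside = [i for i in range(system.m) if i not in inside]
        total = 0.0
        for r in range(len(outside) + 1):
            for S in combinations(outside, r):
                idx = inside + list(S)
                total += (-1) ** r * evaluator.cdf(R[np.ix_(idx, idx)], b[idx])
        raw[k] = max(total, 0.0)
    return raw


def true_prevalences(
    bm: BiomarkerModel,
    probs: np.ndarray | None = None,
    evaluator: TailEvaluator | None = None,
) -> tuple[PrevalenceVector, float]:
    """True strata prevalences of the enrolled population, and the screened-out
    mass ``tau_empty`` of the no-biomarker configuration."""
    system = enumerate_strata(bm.m)
    p = np.asarray(probs if probs is not None else bm.probs, dtype=float)
    if p is None or p.shape != (bm.m,):
        raise ConfigError("biomarker probabilities required")
    if np.all(p == 0):
        raise ConfigError("at least one biomarker probability must be positive")
    if bm.latent_corr is None:
        raw = _independent_strata_mass(system, p)
    else:
        ev = evaluator if evaluator is not None else TailEvaluator()
        raw = _latent_strata_mass(system, p, np.asarray(bm.latent_corr), ev)
    total = raw.sum()
    if total <= 0:
        raise ConfigError("no mass on the nonempty strata")
    return PrevalenceVector(system, raw / total), float(max(1.0 - total, 0.0))


def draw_strata_counts(
    prev: PrevalenceVector,
    N: int,
    rng: np.random.Generator,
    tau_empty: float = 0.0,
    include_screened: bool = False,
) -> StrataCounts:
    """Multinomial strata counts.

    Without screening, ``N`` enrolled patients are drawn from the truncated
    strata law.  With ``include_screened``, ``N`` counts screened patients:
    the draw covers the empty stratum (mass ``tau_empty``) and records it as
    ``screened_empty`` while the enrolled total becomes ``N - n_empty``.
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    if not include_screened:
        counts = rng.multinomial(N, prev.weights)
        return StrataCounts(prev.system, counts)
    law = np.concatenate([[tau_empty], prev.weights * (1.0 - tau_empty)])
    draw = rng.multinomial(N, law / law.sum())
    return StrataCounts(prev.system, draw[1:], screened_empty=int(draw[0]))


def draw_responses(
    alloc: AllocationTable,
    means: Mapping[tuple[int, str], float],
    vm: VarianceModel,
    rng: np.random.Generator,
) -> TrialData:
    """Independent normal responses per (stratum, arm) cell."""
    strata, arms, values = [], [], []
    for J in alloc.system.strata:
        for T, n in alloc.counts.get(J, {}).items():
            if n == 0:
                continue
            var = vm.variance(J, T)
            if var <= 0:
                raise ValueError("response variance must be positive")
            x = rng.normal(means.get((J, T), 0.0), np.sqrt(var), size=n)
            strata.extend([J] * n)
            arms.extend([T] * n)
            values.extend(x.tolist())
    return TrialData(
        alloc.system,
        alloc.pattern,
        np.asarray(strata, dtype=np.int64),
        np.asarray(arms, dtype=object),
        np.asarray(values, dtype=float),
    )


_REGIMES = (
    "known-heterogeneous",
    "known-homogeneous",
    "unknown-homogeneous",
    "unknown-heterogeneous",
)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation-study configuration.

    Defaults follow the reference study conditions: ``N = 500`` patients,
    ``alpha = 0.025``, pairwise-different treatments, stratified allocation,
    maximum-likelihood prevalence estimation, pooled-variance t statistics,
    biomarker probabilities redrawn uniformly on (0, 1) each replicate.
    """

    m: int
    N: int = 500
    alpha: float = 0.025
    replicates: int = 10_000
    seed: int = 0
    regime: str = "unknown-homogeneous"
    sigma2: float = 1.0
    sigma2_law: tuple[str, float, float] | None = None  # e.g. ("uniform", 0.5, 2.0)
    shared_treatment: bool = False
    allocation: str = "stratified"
    estimator: str = "mle"
    pi_min: float | str | None = None
    conditioning: str | None = None  # None | "empty-stratum"
    probs: Sequence[float] | None = None
    prob_support: tuple[float, float] = (0.0, 1.0)
    latent_corr: Sequence[Sequence[float]] | None = None
    prevalence_override: Sequence[float] | None = None
    mc_truth_draws: int = 10_000
    tail_points: int = 2**11
    tol: float = 1e-6
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        problems = []
        if not 1 <= self.m <= 12:
            problems.append(f"m={self.m} outside [1, 12]")
        if self.N < self.m + 1:
            problems.append(f"N={self.N} below m+1")
        if not 0.0 < self.alpha < 1.0:
            problems.append(f"alpha={self.alpha} outside (0, 1)")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.regime not in _REGIMES:
            problems.append(f"unknown variance regime {self.regime!r}")
        if self.allocation not in ("stratified", "random"):
            problems.append(f"unknown allocation rule {self.allocation!r}")
        if self.estimator not in ("mle", "marginal"):
            problems.append(f"unknown prevalence estimator {self.estimator!r}")
        if self.conditioning not in (None, "empty-stratum"):
            problems.append(f"unknown conditioning {self.conditioning!r}")
        if self.sigma2 <= 0:
            problems.append("sigma2 must be positive")
        if self.sigma2_law is not None:
            name, lo, hi = self.sigma2_law
            if name != "uniform" or not 0 < lo < hi:
                problems.append(f"unsupported variance law {self.sigma2_law!r}")
        if self.estimator == "marginal" and self.prevalence_override is not None:
            problems.append("marginal estimator needs a biomarker model, not an override")
        if self.mc_truth_draws < 1:
            problems.append("mc_truth_draws must be >= 1")
        if problems:
            raise ConfigError("; ".join(problems))

    def biomarker_model(self) -> BiomarkerModel | None:
        if self.prevalence_override is not None:
            return None
        return BiomarkerModel(
            m=self.m,
            probs=None if self.probs is None else np.asarray(self.probs, dtype=float),
            support=self.prob_support,
            latent_corr=None
            if self.latent_corr is None
            else np.asarray(self.latent_corr, dtype=float),
        )

    def pattern(self) -> TreatmentPattern:
        if self.shared_treatment:
            return TreatmentPattern.shared(self.m)
        return TreatmentPattern.distinct(self.m)


@dataclass(frozen=True)
class ReplicateResult:
    """Error rates of one simulated trial, scored with the true prevalences."""

    true_pwer: float
    c_hat: float | np.ndarray
    max_swer: float
    mean_swer: float
    counts: np.ndarray = field(repr=False)
    df: float | np.ndarray | None = None
    c_min: float | None = None
    c_operative: float | None = None
    true_pwer_adj: float | None = None
    max_swer_adj: float | None = None
    mean_swer_adj: float | None = None
    n_empty_strata: int = 0
    redraws: int = 0
    condition_attempts: int = 1

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "true_pwer": self.true_pwer,
            "max_swer": self.max_swer,
            "mean_swer": self.mean_swer,
            "n_empty_strata": self.n_empty_strata,
            "redraws": self.redraws,
            "condition_attempts": self.condition_attempts,
        }
        if np.ndim(self.c_hat) == 0:
            row["c_hat"] = float(self.c_hat)
        else:
            for i, c in enumerate(np.atleast_1d(self.c_hat), start=1):
                row[f"c_hat_{i}"] = float(c)
        if self.c_min is not None:
            row.update(
                c_min=self.c_min,
                c_operative=self.c_operative,
                true_pwer_adj=self.true_pwer_adj,
                max_swer_adj=self.max_swer_adj,
                mean_swer_adj=self.mean_swer_adj,
            )
        return row


def _draw_sigma_map(
    cfg: SimulationConfig,
    system: PopulationSystem,
    pattern: TreatmentPattern,
    rng: np.random.Generator,
) -> dict[tuple[int, str], float]:
    lo, hi = cfg.sigma2_law[1], cfg.sigma2_law[2]
    out = {}
    for J in system.strata:
        for T in pattern.arms_for(system, J):
            out[(J, T)] = float(rng.uniform(lo, hi))
    return out


def _variance_model(
    cfg: SimulationConfig,
    system: PopulationSystem,
    pattern: TreatmentPattern,
    rng: np.random.Generator,
) -> VarianceModel:
    if cfg.regime in ("known-heterogeneous", "unknown-heterogeneous"):
        if cfg.sigma2_law is not None:
            return VarianceModel(cfg.regime, sigma2_map=_draw_sigma_map(cfg, system, pattern, rng))
        return VarianceModel(cfg.regime, sigma2=cfg.sigma2)
    if cfg.regime == "known-homogeneous":
        return VarianceModel(cfg.regime, sigma2=cfg.sigma2)
    return VarianceModel(cfg.regime)


def _estimate_prevalences(cfg: SimulationConfig, counts: StrataCounts) -> PrevalenceVector:
    if cfg.estimator == "marginal":
        return marginal_sum_prevalences(counts)
    return mle_prevalences(counts)


def _swer_stats(
    tails: np.ndarray, positive: np.ndarray
) -> tuple[float, float]:
    vals = tails[positive]
    return float(vals.max()), float(vals.mean())


def _mc_true_pwer_heterogeneous(
    cfg: SimulationConfig,
    alloc: AllocationTable,
    vm_true: VarianceModel,
    c_per_pop: np.ndarray,
    true_prev: PrevalenceVector,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo true PWER for Welch-type tests at fixed per-population
    boundaries: fresh global-null datasets are summarized by their sufficient
    statistics (cell means and variances), tested, and the strata-wise
    any-rejection proportions are averaged with the true prevalences."""
    system, pattern = alloc.system, alloc.pattern
    D = cfg.mc_truth_draws
    cells = [
        (J, T, n)
        for J in system.strata
        for T, n in alloc.counts.get(J, {}).items()
        if n > 0
    ]
    n_cells = len(cells)
    n_arr = np.array([n for _, _, n in cells], dtype=float)
    var_arr = np.array([vm_true.variance(J, T) for J, T, _ in cells])
    mean_draws = rng.normal(0.0, np.sqrt(var_arr / n_arr), size=(D, n_cells))
    var_draws = np.ones((D, n_cells))
    big = n_arr > 1
    dfs_cells = n_arr[big] - 1.0
    var_draws[:, big] = (
        var_arr[big] * rng.chisquare(dfs_cells, size=(D, big.sum())) / dfs_cells
    )
    N = alloc.total
    s = int(big.sum())
    pooled = (var_draws[:, big] * dfs_cells).sum(axis=1) / (N - s)
    var_eff = np.where(big[None, :], var_draws, pooled[:, None])

    m = system.m
    diff_coef = np.zeros((m, n_cells))
    var_coef = np.zeros((m, n_cells))
    for i in range(1, m + 1):
        Ti, C = pattern.treatment_of(i), pattern.control
        n_iT = alloc.population_arm_total(i, Ti)
        n_iC = alloc.population_arm_total(i, C)
        bit = 1 << (i - 1)
        for k, (J, T, n) in enumerate(cells):
            if not J & bit:
                continue
            if T == Ti:
                diff_coef[i - 1, k] += n / n_iT
                var_coef[i - 1, k] += n / n_iT**2
            elif T == C:
                diff_coef[i - 1, k] -= n / n_iC
                var_coef[i - 1, k] += n / n_iC**2
    diffs = mean_draws @ diff_coef.T
    V_hat = var_eff @ var_coef.T
    stats = diffs / np.sqrt(V_hat)
    reject = stats > c_per_pop[None, :]

    masks = np.asarray(system.strata)
    bits = ((masks[:, None] >> np.arange(m)[None, :]) & 1).astype(bool)
    any_reject = reject @ bits.T.astype(float) > 0  # (D, n_strata)
    return float(true_prev.weights @ any_reject.mean(axis=0))


def run_replicate(
    cfg: SimulationConfig,
    seed: int | np.random.SeedSequence,
    evaluator: TailEvaluator | None = None,
) -> ReplicateResult:
    """Run one replicate of the plug-in prevalence pipeline under the global null."""
    rng = np.random.default_rng(seed)
    ev = evaluator if evaluator is not None else TailEvaluator(cfg.tail_points)
    system = enumerate_strata(cfg.m)
    pattern = cfg.pattern()
    bm = cfg.biomarker_model()
    if cfg.prevalence_override is not None:
        override = PrevalenceVector(system, np.asarray(cfg.prevalence_override, float))
    else:
        override = None

    redraws = 0
    condition_attempts = 0
    while True:
        condition_attempts += 1
        if condition_attempts > 10**5:
            raise ConfigError("conditioning acceptance below 0.1% after 1e5 attempts")
        if override is not None:
            true_prev, tau_empty = override, 0.0
        else:
            p = bm.draw_probs(rng)
            true_prev, tau_empty = true_prevalences(bm, p, evaluator=ev)
        counts = draw_strata_counts(
            true_prev,
            cfg.N,
            rng,
            tau_empty=tau_empty,
            include_screened=cfg.estimator == "marginal",
        )
        if cfg.conditioning == "empty-stratum" and not np.any(counts.counts == 0):
            continue

        if cfg.allocation == "stratified":
            alloc = stratified_allocation(counts, pattern, seed=rng)
        else:
            alloc = random_allocation(counts, pattern, seed=rng)
        vm = _variance_model(cfg, system, pattern, rng)
        try:
            result = _score_replicate(cfg, alloc, vm, true_prev, counts, ev, rng)
        except AnalysisError:
            redraws += 1
            if redraws > cfg.max_redraws:
                raise ConfigError(
                    f"exceeded {cfg.max_redraws} redraws from empty population arms"
                )
            continue
        return replace(
            result,
            redraws=redraws,
            condition_attempts=condition_attempts,
            n_empty_strata=int(np.sum(counts.counts == 0)),
        )


def _score_replicate(
    cfg: SimulationConfig,
    alloc: AllocationTable,
    vm: VarianceModel,
    true_prev: PrevalenceVector,
    counts: StrataCounts,
    ev: TailEvaluator,
    rng: np.random.Generator,
) -> ReplicateResult:
    system = alloc.system
    prev_hat = _estimate_prevalences(cfg, counts)

    if cfg.regime == "unknown-heterogeneous":
        # realize one dataset to obtain plug-in variances and Welch df
        data = draw_responses(alloc, {}, vm, rng)
        from .design import test_statistics

        _, model = test_statistics(data, VarianceModel("unknown-heterogeneous"))
        cv = solve_per_population_c(prev_hat, model, cfg.alpha, cfg.tol, ev)
        c_vec = np.asarray(cv.c)
        true_pwer = _mc_true_pwer_heterogeneous(
            cfg, alloc, vm, c_vec, true_prev, rng
        )
        # strata-wise tails at per-population bounds; the smallest member df
        # is used for the shared t scale (slightly conservative)
        positive = true_prev.weights > 0
        dfs = np.asarray(model.df, dtype=float)
        strata_tails = np.array(
            [
                ev.tail(
                    model.submatrix(members),
                    c_vec[[i - 1 for i in members]],
                    df=float(dfs[[i - 1 for i in members]].min()),
                )
                for members in (system.members(J) for J in system.strata)
            ]
        )
        max_swer, mean_swer = _swer_stats(strata_tails, positive)
        return ReplicateResult(
            true_pwer=true_pwer,
            c_hat=c_vec,
            max_swer=max_swer,
            mean_swer=mean_swer,
            counts=counts.counts.copy(),
            df=np.asarray(model.df),
        )

    model = correlation_matrix(alloc, vm)
    df = model.df if model.family == "student-t" else None
    cv = solve_common_c(prev_hat, model, cfg.alpha, cfg.tol, ev)

    all_tails = StrataTails(
        [model.submatrix(system.members(J)) for J in system.strata],
        df=df,
        evaluator=ev,
    )
    positive = true_prev.weights > 0
    t_hat = all_tails.tails(float(cv.c))
    true_pwer = float(true_prev.weights @ t_hat)
    max_swer, mean_swer = _swer_stats(t_hat, positive)

    if cfg.pi_min is None:
        return ReplicateResult(
            true_pwer=true_pwer,
            c_hat=float(cv.c),
            max_swer=max_swer,
            mean_swer=mean_swer,
            counts=counts.counts.copy(),
            df=df,
        )

    adj_prev = min_prevalence_adjust(prev_hat, cfg.pi_min)
    cv_adj = solve_common_c(adj_prev, model, cfg.alpha, cfg.tol, ev)
    t_adj = all_tails.tails(float(cv_adj.c))
    max_adj, mean_adj = _swer_stats(t_adj, positive)
    return ReplicateResult(
        true_pwer=true_pwer,
        c_hat=float(cv.c),
        max_swer=max_swer,
        mean_swer=mean_swer,
        counts=counts.counts.copy(),
        df=df,
        c_min=float(cv_adj.c),
        c_operative=max(float(cv.c), float(cv_adj.c)),
        true_pwer_adj=float(true_prev.weights @ t_adj),
        max_swer_adj=max_adj,
        mean_swer_adj=mean_adj,
    )


def run_study(
    cfg: SimulationConfig,
    seed: int | None = None,
    evaluator: TailEvaluator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``cfg.replicates`` seeded replicates; per-replicate table and summary.

    Per-replicate seeds are spawned deterministically from the master seed, so
    a single replicate can be re-run in isolation with
    ``run_replicate(cfg, np.random.SeedSequence(master).spawn(k+1)[k])``.
    """
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(cfg.replicates)
    ev = evaluator if evaluator is not None else TailEvaluator(cfg.tail_points)
    rows = []
    total_attempts = 0
    accepted = 0
    for child in children:
        r = run_replicate(cfg, child, evaluator=ev)
        total_attempts += r.condition_attempts
        accepted += 1
        if (
            cfg.conditioning is not None
            and total_attempts >= 10**5
            and accepted / total_attempts < 1e-3
        ):
            raise ConfigError(
                "conditioning acceptance below 0.1% after 1e5 attempts"
            )
        rows.append(r.to_row())
    reps = pd.DataFrame(rows)
    return reps, summarize_replicates(reps, cfg.alpha)


def summarize_replicates(reps: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Summary statistics of the per-replicate error rates.

    For every rate column: mean, SD, min, quartiles, max; for the true-PWER
    columns additionally the fraction of replicates whose relative deviation
    from ``alpha`` exceeds 5/10/15%.
    """
    metrics = [
        c
        for c in (
            "true_pwer",
            "max_swer",
            "mean_swer",
            "true_pwer_adj",
            "max_swer_adj",
            "mean_swer_adj",
            "c_hat",
            "c_min",
        )
        if c in reps.columns
    ]
    out = {}
    for c in metrics:
        x = reps[c].to_numpy(dtype=float)
        row = {
            "mean": x.mean(),
            "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
            "min": x.min(),
            "q25": np.quantile(x, 0.25),
            "median": np.quantile(x, 0.5),
            "q75": np.quantile(x, 0.75),
            "max": x.max(),
        }
        if c.startswith("true_pwer"):
            rel = np.abs(x - alpha) / alpha
            for thr in (0.05, 0.10, 0.15):
                row[f"frac_dev_gt_{int(thr * 100)}pct"] = float(np.mean(rel > thr))
        out[c] = row
    return pd.DataFrame(out).T


def conditioned_study(
    cfg: SimulationConfig,
    seed: int | None = None,
    evaluator: TailEvaluator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study restricted to replicates with at least one empty stratum, scoring
    each accepted replicate under both the unadjusted and the
    minimal-prevalence-adjusted boundary."""
    if cfg.conditioning != "empty-stratum":
        cfg = replace(cfg, conditioning="empty-stratum")
    if cfg.pi_min is None:
        cfg = replace(cfg, pi_min="auto")
    return run_study(cfg, seed=seed, evaluator=evaluator)
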