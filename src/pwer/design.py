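"""Sample allocation, effect and variance estimation, and test statistics.

Each population ``P_i`` pairs a candidate treatment ``T_i`` against the
common control ``C``.  Within a stratum ``P_J`` the eligible arms are the
treatments of the populations in ``J`` plus the control.  Population-level
mean estimates are prevalence-weighted combinations of the strata-arm means,
and the one-sided statistics ``Z_i = (mu_i,Ti - mu_i,C) / sqrt(V_i)`` are
jointly multivariate normal (known variances) or multivariate t (pooled
unknown variance, ``df = N - s``), with a correlation matrix driven by the
sharing of control (and possibly treatment) patients across populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .populations import PopulationSystem, StrataCounts

__all__ = [
    "CONTROL",
    "AnalysisError",
    "TreatmentPattern",
    "AllocationTable",
    "VarianceModel",
    "TrialData",
    "TestStatisticModel",
    "stratified_allocation",
    "random_allocation",
    "correlation_matrix",
    "location_vector",
    "pooled_variance",
    "test_statistics",
    "satterthwaite_df",
]

CONTROL = "C"


class AnalysisError(RuntimeError):
    """A design/data configuration the statistics are undefined for."""


@dataclass(frozen=True)
class TreatmentPattern:
    """Assignment of a treatment label to each population; control is shared.

    Distinct labels give the pairwise-different-treatments design; assigning
    one label to several populations gives the shared-treatment design.
    """

    treatments: tuple[str, ...]
    control: str = CONTROL

    def __post_init__(self) -> None:
        if self.control in self.treatments:
            raise ValueError("control label must differ from every treatment label")

    @classmethod
    def distinct(cls, m: int) -> "TreatmentPattern":
        return cls(tuple(f"T{i}" for i in range(1, m + 1)))

    @classmethod
    def shared(cls, m: int, label: str = "T") -> "TreatmentPattern":
        return cls((label,) * m)

    @property
    def m(self) -> int:
        return len(self.treatments)

    def treatment_of(self, population: int) -> str:
        return self.treatments[population - 1]

    def arms_for(self, system: PopulationSystem, mask: int) -> tuple[str, ...]:
        """Eligible arms of stratum ``mask``: member treatments (deduplicated,
        population order) plus control."""
        labels: list[str] = []
        for i in system.members(mask):
            t = self.treatment_of(i)
            if t not in labels:
                labels.append(t)
        labels.append(self.control)
        return tuple(labels)


@dataclass(frozen=True)
class AllocationTable:
    """Per-stratum per-arm sample counts ``n_{J,T}``."""

    system: PopulationSystem
    pattern: TreatmentPattern
    counts: dict[int, dict[str, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.pattern.m != self.system.m:
            raise ValueError("treatment pattern and population system disagree on m")
        for J, per_arm in self.counts.items():
            arms = self.pattern.arms_for(self.system, J)
            if set(per_arm) - set(arms):
                raise ValueError(f"stratum {J} assigned to an ineligible arm")
            if any(n < 0 for n in per_arm.values()):
                raise ValueError("allocation counts must be nonnegative")

    def n(self, mask: int, arm: str) -> int:
        return int(self.counts.get(mask, {}).get(arm, 0))

    def n_stratum(self, mask: int) -> int:
        return int(sum(self.counts.get(mask, {}).values()))

    @property
    def total(self) -> int:
        return sum(self.n_stratum(J) for J in self.system.strata)

    def population_arm_total(self, population: int, arm: str) -> int:
        """``n_{i,T}``: patients on ``arm`` across all strata of population ``population``."""
        return sum(
            self.n(J, arm) for J in self.system.strata_containing(population)
        )

    def to_strata_counts(self) -> StrataCounts:
        return StrataCounts(
            self.system,
            np.array([self.n_stratum(J) for J in self.system.strata], dtype=np.int64),
        )


_REGIMES = (
    "known-heterogeneous",
    "known-homogeneous",
    "unknown-homogeneous",
    "unknown-heterogeneous",
)


@dataclass(frozen=True)
class VarianceModel:
    """One of four residual-variance regimes.

    ``known-heterogeneous`` carries per-(stratum, arm) variances;
    ``known-homogeneous`` a single common variance; the unknown regimes carry
    no values (they are estimated from data), though simulation configs may
    attach the generating values via ``sigma2`` / ``sigma2_map``.
    """

    regime: str
    sigma2: float | None = None
    sigma2_map: Mapping[tuple[int, str], float] | None = None

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(f"unknown variance regime {self.regime!r}")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("variance must be positive")
        if self.sigma2_map is not None and any(
            v <= 0 for v in self.sigma2_map.values()
        ):
            raise ValueError("variance must be positive")

    @property
    def known(self) -> bool:
        return self.regime.startswith("known")

    @property
    def homogeneous(self) -> bool:
        return self.regime.endswith("homogeneous")

    def variance(self, mask: int, arm: str) -> float:
        if self.sigma2_map is not None and (mask, arm) in self.sigma2_map:
            return float(self.sigma2_map[(mask, arm)])
        if self.sigma2 is not None:
            return float(self.sigma2)
        # unknown regimes: the correlation matrix is variance-free under
        # homogeneity, so a unit placeholder is exact there.
        return 1.0


@dataclass(frozen=True)
class TrialData:
    """Patient-level responses: stratum bitmask, arm label, numeric response."""

    system: PopulationSystem
    pattern: TreatmentPattern
    stratum: np.ndarray = field(repr=False)
    arm: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.response)
        if len(self.stratum) != n or len(self.arm) != n:
            raise ValueError("stratum, arm and response must have equal length")
        for J, T in zip(self.stratum, self.arm):
            if T not in self.pattern.arms_for(self.system, int(J)):
                raise ValueError(
                    f"arm {T!r} not eligible for stratum {self.system.label(int(J))}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.response)

    def cells(self) -> dict[tuple[int, str], np.ndarray]:
        """Responses grouped by (stratum, arm)."""
        out: dict[tuple[int, str], list[float]] = {}
        for J, T, x in zip(self.stratum, self.arm, self.response):
            out.setdefault((int(J), str(T)), []).append(float(x))
        return {k: np.asarray(v) for k, v in out.items()}

    def allocation(self) -> AllocationTable:
        counts: dict[int, dict[str, int]] = {}
        for J, T in zip(self.stratum, self.arm):
            counts.setdefault(int(J), {}).setdefault(str(T), 0)
            counts[int(J)][str(T)] += 1
        return AllocationTable(self.system, self.pattern, counts)

    def to_csv(self, path: str | Path) -> None:
        lines = ["stratum,arm,response"]
        for J, T, x in zip(self.stratum, self.arm, self.response):
            lines.append(f"{self.system.label(int(J))},{T},{float(x)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(
        cls, path: str | Path, pattern: TreatmentPattern | None = None
    ) -> "TrialData":
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if lineno == 1 and parts[0].lower() == "stratum":
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                rows.append((parts[0], parts[1], float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad response value") from exc
        if not rows:
            raise ValueError(f"{path}: no data rows")
        m = len(rows[0][0])
        from .populations import enumerate_strata

        system = enumerate_strata(m)
        if pattern is None:
            pattern = TreatmentPattern.distinct(m)
        stratum = np.array([system.parse_label(r[0]) for r in rows])
        arm = np.array([r[1] for r in rows], dtype=object)
        response = np.array([r[2] for r in rows])
        return cls(system, pattern, stratum, arm, response)


@dataclass(frozen=True)
class TestStatisticModel:
    """Joint null model of the statistics: location, correlation, family, df.

    ``family`` is ``"gaussian"`` or ``"student-t"``; ``df`` is a scalar for
    the pooled-variance t model and a per-population vector for the
    Satterthwaite approximation.  ``V`` holds the variances of the estimated
    effect differences.
    """

    __test__ = False  # keep pytest from collecting the domain class

    corr: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    family: str = "gaussian"
    df: float | np.ndarray | None = None
    location: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.corr, dtype=float)
        m = S.shape[0]
        if S.shape != (m, m) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("correlation matrix must be square symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        if np.any(np.asarray(self.V) <= 0):
            raise ValueError("effect-difference variances must be positive")
        if self.family not in ("gaussian", "student-t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "student-t" and self.df is None:
            raise ValueError("student-t model needs degrees of freedom")

    @property
    def m(self) -> int:
        return self.corr.shape[0]

    def submatrix(self, members: tuple[int, ...]) -> np.ndarray:
        idx = [i - 1 for i in members]
        return self.corr[np.ix_(idx, idx)]


def _even_split(n: int, arms: tuple[str, ...], rng: np.random.Generator | None) -> dict[str, int]:
    k = len(arms)
    base, rem = divmod(n, k)
    out = {T: base for T in arms}
    if rem:
        order = list(range(k)) if rng is None else list(rng.permutation(k))
        for j in order[:rem]:
            out[arms[j]] += 1
    return out


def stratified_allocation(
    counts: StrataCounts,
    pattern: TreatmentPattern,
    seed: int | np.random.Generator | None = None,
) -> AllocationTable:
    """Split each stratum's patients as evenly as possible over its arms.

    With ``k`` eligible arms every arm receives ``floor(n_J/k)`` patients and
    the remainder goes to a seeded-random subset of arms (listed order when no
    seed is given), so ``|n_{J,T} - n_J/k| < 1`` always.
    """
    rng = None if seed is None else (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    table: dict[int, dict[str, int]] = {}
    for J in counts.system.strata:
        arms = pattern.arms_for(counts.system, J)
        table[J] = _even_split(counts.count(J), arms, rng)
    return AllocationTable(counts.system, pattern, table)


def random_allocation(
    counts: StrataCounts,
    pattern: TreatmentPattern,
    seed: int | np.random.Generator,
) -> AllocationTable:
    """Assign each patient independently and uniformly over the eligible arms."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table: dict[int, dict[str, int]] = {}
    for J in counts.system.strata:
        arms = pattern.arms_for(counts.system, J)
        draws = rng.multinomial(counts.count(J), np.full(len(arms), 1.0 / len(arms)))
        table[J] = {T: int(n) for T, n in zip(arms, draws)}
    return AllocationTable(counts.system, pattern, table)


def _check_population_arms(alloc: AllocationTable) -> None:
    for i in range(1, alloc.system.m + 1):
        for arm in (alloc.pattern.treatment_of(i), alloc.pattern.control):
            if alloc.population_arm_total(i, arm) == 0:
                raise AnalysisError(
                    f"population {i} has no patients on arm {arm!r}"
                )


def effect_variances(alloc: AllocationTable, vm: VarianceModel) -> np.ndarray:
    """``V_i``: variance of the estimated effect difference in each population."""
    _check_population_arms(alloc)
    system, pattern = alloc.system, alloc.pattern
    V = np.zeros(system.m)
    for i in range(1, system.m + 1):
        Ti = pattern.treatment_of(i)
        n_iT = alloc.population_arm_total(i, Ti)
        n_iC = alloc.population_arm_total(i, pattern.control)
        acc = 0.0
        for J in system.strata_containing(i):
            acc += alloc.n(J, Ti) * vm.variance(J, Ti) / n_iT**2
            acc += alloc.n(J, pattern.control) * vm.variance(J, pattern.control) / n_iC**2
        V[i - 1] = acc
    return V


def correlation_matrix(
    alloc: AllocationTable, vm: VarianceModel
) -> TestStatisticModel:
    """Correlation matrix of the population statistics for a realized allocation.

    Off-diagonal entries accumulate the shared-control covariance over the
    strata common to both populations; populations sharing a treatment arm
    additionally accumulate the shared-treatment covariance.  Under a
    homogeneous variance the matrix is free of the variance value.
    """
    system, pattern = alloc.system, alloc.pattern
    m = system.m
    V = effect_variances(alloc, vm)
    C = pattern.control
    S = np.eye(m)
    for i in range(1, m + 1):
        for j in range(i + 1, m + 1):
            common = [J for J in system.strata if (J >> (i - 1) & 1) and (J >> (j - 1) & 1)]
            n_iC = alloc.population_arm_total(i, C)
            n_jC = alloc.population_arm_total(j, C)
            cov = sum(
                alloc.n(J, C) * vm.variance(J, C) for J in common
            ) / (n_iC * n_jC)
            Ti, Tj = pattern.treatment_of(i), pattern.treatment_of(j)
            if Ti == Tj:
                n_iT = alloc.population_arm_total(i, Ti)
                n_jT = alloc.population_arm_total(j, Tj)
                cov += sum(
                    alloc.n(J, Ti) * vm.variance(J, Ti) for J in common
                ) / (n_iT * n_jT)
            S[i - 1, j - 1] = S[j - 1, i - 1] = cov / np.sqrt(V[i - 1] * V[j - 1])
    family = "gaussian" if vm.known else "student-t"
    df = None
    if vm.regime == "unknown-homogeneous":
        df = pooled_df_from_allocation(alloc)
    return TestStatisticModel(corr=S, V=V, family=family, df=df)


def pooled_df_from_allocation(alloc: AllocationTable) -> int:
    """``N - s`` with ``s`` the number of (stratum, arm) cells holding more than one patient."""
    N = alloc.total
    s = sum(
        1
        for J in alloc.system.strata
        for n in alloc.counts.get(J, {}).values()
        if n > 1
    )
    if N <= s:
        raise AnalysisError(f"pooled variance undefined: N={N} <= s={s}")
    return N - s


def location_vector(
    alloc: AllocationTable,
    vm: VarianceModel,
    means: Mapping[tuple[int, str], float],
) -> np.ndarray:
    """Noncentrality of the statistics for given strata-arm means ``mu_{J,T}``."""
    system, pattern = alloc.system, alloc.pattern
    V = effect_variances(alloc, vm)
    nu = np.zeros(system.m)
    for i in range(1, system.m + 1):
        Ti, C = pattern.treatment_of(i), pattern.control
        n_iT = alloc.population_arm_total(i, Ti)
        n_iC = alloc.population_arm_total(i, C)
        acc = 0.0
        for J in system.strata_containing(i):
            acc += alloc.n(J, Ti) / n_iT * means.get((J, Ti), 0.0)
            acc -= alloc.n(J, C) / n_iC * means.get((J, C), 0.0)
        nu[i - 1] = acc / np.sqrt(V[i - 1])
    return nu


def pooled_variance(data: TrialData) -> tuple[float, int, int]:
    """Pooled residual variance estimate, the cell count ``s``, and ``df = N - s``.

    Cells with a single patient contribute nothing to the numerator and are
    not counted in ``s``.
    """
    cells = data.cells()
    N = data.n_patients
    s = sum(1 for x in cells.values() if len(x) > 1)
    if N <= s:
        raise AnalysisError(f"pooled variance undefined: N={N} <= s={s}")
    num = sum((len(x) - 1) * np.var(x, ddof=1) for x in cells.values() if len(x) > 1)
    return float(num) / (N - s), s, N - s


def _population_cell(data: TrialData, population: int, arm: str) -> np.ndarray:
    bit = 1 << (population - 1)
    sel = [(int(J) & bit) and str(T) == arm for J, T in zip(data.stratum, data.arm)]
    return data.response[np.asarray(sel, dtype=bool)]


def satterthwaite_df(data: TrialData, population: int) -> float:
    """Welch-Satterthwaite degrees of freedom of a population's two-arm contrast."""
    Ti = data.pattern.treatment_of(population)
    xs = {arm: _population_cell(data, population, arm) for arm in (Ti, data.pattern.control)}
    for arm, x in xs.items():
        if len(x) < 2:
            raise AnalysisError(
                f"population {population} arm {arm!r} has fewer than 2 observations"
            )
    terms = {arm: np.var(x, ddof=1) / len(x) for arm, x in xs.items()}
    num = sum(terms.values()) ** 2
    den = sum(t**2 / (len(xs[arm]) - 1) for arm, t in terms.items())
    return float(num / den)


def _cell_variances(
    data: TrialData, fallback: float
) -> dict[tuple[int, str], float]:
    out = {}
    for key, x in data.cells().items():
        out[key] = float(np.var(x, ddof=1)) if len(x) > 1 else fallback
    return out


def test_statistics(
    data: TrialData, vm: VarianceModel
) -> tuple[np.ndarray, TestStatisticModel]:
    """Observed statistics and the null model they follow, per variance regime.

    Known variances give gaussian ``Z_i``; unknown-homogeneous gives the
    pooled-variance t statistics with ``df = N - s``; unknown-heterogeneous
    gives Welch-type statistics with per-population Satterthwaite df and a
    plug-in correlation matrix (cells too small for a variance estimate use
    the pooled value).
    """
    system, pattern = data.system, data.pattern
    alloc = data.allocation()
    _check_population_arms(alloc)
    cells = data.cells()
    means = {k: float(np.mean(x)) for k, x in cells.items()}

    def effect_diff(i: int) -> float:
        Ti, C = pattern.treatment_of(i), pattern.control
        n_iT = alloc.population_arm_total(i, Ti)
        n_iC = alloc.population_arm_total(i, C)
        acc = 0.0
        for J in system.strata_containing(i):
            if alloc.n(J, Ti):
                acc += alloc.n(J, Ti) / n_iT * means[(J, Ti)]
            if alloc.n(J, C):
                acc -= alloc.n(J, C) / n_iC * means[(J, C)]
        return acc

    diffs = np.array([effect_diff(i) for i in range(1, system.m + 1)])

    if vm.known:
        model = correlation_matrix(alloc, vm)
        stats = diffs / np.sqrt(model.V)
        return stats, model

    if vm.regime == "unknown-homogeneous":
        sigma2_hat, _, df = pooled_variance(data)
        model = correlation_matrix(alloc, VarianceModel("unknown-homogeneous"))
        H = np.array(
            [
                1.0 / alloc.population_arm_total(i, pattern.treatment_of(i))
                + 1.0 / alloc.population_arm_total(i, pattern.control)
                for i in range(1, system.m + 1)
            ]
        )
        stats = diffs / np.sqrt(sigma2_hat * H)
        model = TestStatisticModel(
            corr=model.corr, V=sigma2_hat * H, family="student-t", df=df
        )
        return stats, model

    # unknown-heterogeneous: plug-in variances, Welch df per population
    pooled, _, _ = pooled_variance(data)
    plug = VarianceModel("known-heterogeneous", sigma2_map=_cell_variances(data, pooled))
    plug_model = correlation_matrix(alloc, plug)
    stats = diffs / np.sqrt(plug_model.V)
    dfs = np.array([satterthwaite_df(data, i) for i in range(1, system.m + 1)])
    model = TestStatisticModel(
        corr=plug_model.corr, V=plug_model.V, family="student-t", df=dfs
    )
    return stats, model
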