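"""Combinatorics of overlapping populations and prevalence estimation.

A trial with ``m`` overlapping target populations ``P_1, ..., P_m`` induces a
partition of the enrolled population into the ``2**m - 1`` nonempty disjoint
strata ``P_J``, ``J`` a nonempty subset of ``{1, ..., m}``: the patients that
belong to exactly the populations indexed by ``J``.  Strata are encoded as
bitmasks, population ``i`` corresponding to bit ``i - 1``.

This module holds the stratum enumeration, relative-prevalence vectors over
the strata, observed strata counts, the multinomial maximum-likelihood and
marginal-sum prevalence estimators, and the minimal-prevalence adjustment for
strata that the sample missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "PopulationSystem",
    "PrevalenceVector",
    "StrataCounts",
    "enumerate_strata",
    "mle_prevalences",
    "marginal_sum_prevalences",
    "min_prevalence_adjust",
    "population_margins",
    "auto_min_prevalence",
    "read_strata_counts",
    "write_strata_counts",
]

_MAX_POPULATIONS = 12
_SUM_TOL = 1e-12


@dataclass(frozen=True)
class PopulationSystem:
    """The ``2**m - 1`` nonempty strata of ``m`` overlapping populations.

    Strata are bitmasks in increasing order; bit ``i - 1`` set means the
    stratum lies inside population ``i``.
    """

    m: int
    strata: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.m <= _MAX_POPULATIONS:
            raise ValueError(f"m must be in [1, {_MAX_POPULATIONS}], got {self.m}")
        if self.strata != tuple(range(1, 2**self.m)):
            raise ValueError("strata must be the nonempty subsets in bitmask order")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def index(self, mask: int) -> int:
        """Position of stratum ``mask`` in the canonical order."""
        if not 1 <= mask < 2**self.m:
            raise KeyError(f"stratum {mask} not in system with m={self.m}")
        return mask - 1

    def members(self, mask: int) -> tuple[int, ...]:
        """Populations (1-based) that stratum ``mask`` belongs to."""
        self.index(mask)
        return tuple(i + 1 for i in range(self.m) if mask >> i & 1)

    def strata_containing(self, population: int) -> tuple[int, ...]:
        """All strata lying inside population ``population`` (1-based)."""
        if not 1 <= population <= self.m:
            raise ValueError(f"population index {population} out of range")
        bit = 1 << (population - 1)
        return tuple(J for J in self.strata if J & bit)

    def label(self, mask: int) -> str:
        """Biomarker bitstring for ``mask``; character ``i`` is population ``i+1``."""
        self.index(mask)
        return "".join("1" if mask >> i & 1 else "0" for i in range(self.m))

    def parse_label(self, label: str) -> int:
        if len(label) != self.m or set(label) - {"0", "1"}:
            raise ValueError(f"bad biomarker bitstring {label!r} for m={self.m}")
        return sum(1 << i for i, ch in enumerate(label) if ch == "1")


def enumerate_strata(m: int) -> PopulationSystem:
    """Enumerate all nonempty strata of ``m`` overlapping populations."""
    if not isinstance(m, (int, np.integer)) or not 1 <= m <= _MAX_POPULATIONS:
        raise ValueError(f"m must be an integer in [1, {_MAX_POPULATIONS}], got {m!r}")
    return PopulationSystem(m=int(m), strata=tuple(range(1, 2**m)))


@dataclass(frozen=True)
class PrevalenceVector:
    """Relative prevalences ``pi_J >= 0`` over the strata, summing to one."""

    system: PopulationSystem
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.system.n_strata,):
            raise ValueError(
                f"expected {self.system.n_strata} weights, got shape {w.shape}"
            )
        if np.any(w < -_SUM_TOL):
            raise ValueError("prevalences must be nonnegative")
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {total!r}")
        # remove the residual float error so downstream sums are exact
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def from_mapping(
        cls, system: PopulationSystem, weights: Mapping[int, float]
    ) -> "PrevalenceVector":
        w = np.zeros(system.n_strata)
        for mask, value in weights.items():
            w[system.index(mask)] = value
        return cls(system, w)

    def weight(self, mask: int) -> float:
        return float(self.weights[self.system.index(mask)])

    def as_dict(self) -> dict[int, float]:
        return {J: float(self.weights[i]) for i, J in enumerate(self.system.strata)}


@dataclass(frozen=True)
class StrataCounts:
    """Observed patient counts ``n_J`` per stratum, optionally with the number
    of screened patients carrying no biomarker (the empty stratum, which is
    screened but not enrolled)."""

    system: PopulationSystem
    counts: np.ndarray = field(repr=False)
    screened_empty: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.system.n_strata,):
            raise ValueError(
                f"expected {self.system.n_strata} counts, got shape {c.shape}"
            )
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)) or np.any(c < 0):
                raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.screened_empty is not None and self.screened_empty < 0:
            raise ValueError("screened_empty must be nonnegative")

    @classmethod
    def from_mapping(
        cls,
        system: PopulationSystem,
        counts: Mapping[int, int],
        screened_empty: int | None = None,
    ) -> "StrataCounts":
        c = np.zeros(system.n_strata, dtype=np.int64)
        for mask, value in counts.items():
            c[system.index(mask)] = value
        return cls(system, c, screened_empty)

    @property
    def total(self) -> int:
        """Enrolled sample size ``N`` (excludes the empty stratum)."""
        return int(self.counts.sum())

    @property
    def screened_total(self) -> int:
        """Screened sample size including the empty stratum when recorded."""
        return self.total + (self.screened_empty or 0)

    def count(self, mask: int) -> int:
        return int(self.counts[self.system.index(mask)])


def mle_prevalences(counts: StrataCounts) -> PrevalenceVector:
    """Multinomial maximum-likelihood prevalence estimate ``n_J / N``."""
    N = counts.total
    if N <= 0:
        raise ValueError("cannot estimate prevalences from an empty sample")
    return PrevalenceVector(counts.system, counts.counts / N)


def marginal_sum_prevalences(counts: StrataCounts) -> PrevalenceVector:
    """Marginal-sum prevalence estimator for independent biomarkers.

    Uses the screened sample (enrolled plus the empty stratum) to estimate the
    marginal expression frequency ``p_j`` of each biomarker, then forms the
    product distribution over strata, truncated to remove the empty stratum,
    and renormalizes.  Requires ``screened_empty`` to be recorded.
    """
    if counts.screened_empty is None:
        raise ValueError("marginal-sum estimator needs the screened empty-stratum count")
    system = counts.system
    n_screen = counts.screened_total
    if n_screen <= 0:
        raise ValueError("no screened patients")
    if counts.total == 0:
        raise ValueError("no enrolled patients: empty-stratum fraction is 1")
    tau = counts.counts / n_screen  # tau_J over nonempty strata
    p_hat = np.array(
        [tau[[J - 1 for J in system.strata_containing(i)]].sum() for i in range(1, system.m + 1)]
    )
    masks = np.asarray(system.strata)
    bits = (masks[:, None] >> np.arange(system.m)[None, :]) & 1
    raw = np.prod(np.where(bits == 1, p_hat[None, :], 1.0 - p_hat[None, :]), axis=1)
    total = raw.sum()
    if total <= 0:
        raise ValueError("marginal frequencies give zero mass to every nonempty stratum")
    return PrevalenceVector(system, raw / total)


def auto_min_prevalence(m: int) -> float:
    """Default minimal prevalence: half the uniform stratum weight, ``1/(2**(m+1)-2)``."""
    return 1.0 / (2 ** (m + 1) - 2)


def min_prevalence_adjust(
    prev: PrevalenceVector, pi_min: float | str = "auto"
) -> PrevalenceVector:
    """Raise every stratum weight below ``pi_min`` to ``pi_min``.

    Strata with estimated prevalence below the floor (including the strata the
    sample missed entirely) are set to ``pi_min``; the remaining strata are
    scaled by a common factor so the vector sums to one again.  One single
    pass: strata pushed below the floor by the rescaling are not re-raised.
    """
    system = prev.system
    if pi_min == "auto":
        pi_min = auto_min_prevalence(system.m)
    pi_min = float(pi_min)
    if not 0.0 < pi_min < 1.0 / system.n_strata:
        raise ValueError(
            f"pi_min must lie in (0, 1/{system.n_strata}) for m={system.m}, got {pi_min}"
        )
    w = prev.weights
    raised = w < pi_min
    if not raised.any():
        return prev
    raised_mass = pi_min * raised.sum()
    if raised_mass >= 1.0:
        raise ValueError("minimal prevalence leaves no mass for the observed strata")
    kept_mass = w[~raised].sum()
    out = np.where(raised, pi_min, w * (1.0 - raised_mass) / kept_mass)
    return PrevalenceVector(system, out)


def population_margins(prev: PrevalenceVector) -> np.ndarray:
    """Marginal prevalence ``pi_i`` of each population: sum of ``pi_J`` over ``J`` containing ``i``."""
    system = prev.system
    masks = np.asarray(system.strata)
    bits = (masks[:, None] >> np.arange(system.m)[None, :]) & 1
    return bits.T @ prev.weights


def read_strata_counts(path: str | Path, delimiter: str = ",") -> StrataCounts:
    """Read strata counts from two-column text: biomarker bitstring, count.

    A row whose bitstring is all zeros is interpreted as the screened
    empty-stratum count.
    """
    path = Path(path)
    rows: list[tuple[str, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delimiter)]
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        rows.append((parts[0], int(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    m = len(rows[0][0])
    system = enumerate_strata(m)
    counts: dict[int, int] = {}
    screened_empty = None
    for label, n in rows:
        if set(label) == {"0"}:
            screened_empty = n
            continue
        counts[system.parse_label(label)] = n
    return StrataCounts.from_mapping(system, counts, screened_empty)


def write_strata_counts(
    counts: StrataCounts, path: str | Path, delimiter: str = ","
) -> None:
    system = counts.system
    lines = []
    if counts.screened_empty is not None:
        lines.append(f"{'0' * system.m}{delimiter}{counts.screened_empty}")
    for J in system.strata:
        lines.append(f"{system.label(J)}{delimiter}{counts.count(J)}")
    Path(path).write_text("\n".join(lines) + "\n")
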