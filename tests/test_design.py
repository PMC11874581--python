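"""Allocation, variance estimation, test statistics and correlation structure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pwer import (
    AnalysisError,
    StrataCounts,
    TreatmentPattern,
    TrialData,
    VarianceModel,
    correlation_matrix,
    draw_responses,
    enumerate_strata,
    location_vector,
    pooled_variance,
    random_allocation,
    satterthwaite_df,
    stratified_allocation,
)
from pwer import test_statistics as compute_statistics
from pwer.design import effect_variances

from .conftest import random_design


def brute_force_correlation(alloc, vm):
    """Independent oracle: represent each effect difference as a linear
    combination of independent cell means and compute the covariance matrix
    directly from the coefficients."""
    system, pattern = alloc.system, alloc.pattern
    cells = [
        (J, T, n)
        for J in system.strata
        for T, n in alloc.counts.get(J, {}).items()
        if n > 0
    ]
    A = np.zeros((system.m, len(cells)))
    var = np.array([vm.variance(J, T) / n for J, T, n in cells])
    for i in range(1, system.m + 1):
        Ti, C = pattern.treatment_of(i), pattern.control
        n_iT = alloc.population_arm_total(i, Ti)
        n_iC = alloc.population_arm_total(i, C)
        bit = 1 << (i - 1)
        for k, (J, T, n) in enumerate(cells):
            if not J & bit:
                continue
            if T == Ti:
                A[i - 1, k] += n / n_iT
            elif T == C:
                A[i - 1, k] -= n / n_iC
    cov = A @ np.diag(var) @ A.T
    d = 1 / np.sqrt(np.diag(cov))
    return cov * d[:, None] * d[None, :], np.diag(cov), A, var


class TestStratifiedAllocation:
    def test_exact_even_split(self):
        sys2 = enumerate_strata(2)
        counts = StrataCounts.from_mapping(sys2, {0b11: 12})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(2))
        assert [alloc.n(0b11, T) for T in ("T1", "T2", "C")] == [4, 4, 4]

    def test_empty_stratum_gets_zeros(self):
        sys1 = enumerate_strata(1)
        counts = StrataCounts.from_mapping(sys1, {1: 0})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(1))
        assert alloc.n(1, "T1") == 0 and alloc.n(1, "C") == 0

    def test_remainder_rule(self):
        sys2 = enumerate_strata(2)
        counts = StrataCounts.from_mapping(sys2, {0b11: 7})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(2), seed=3)
        ns = sorted(alloc.counts[0b11].values())
        assert ns == [2, 2, 3]

    @given(st.integers(0, 200), st.integers(0, 2**31 - 1))
    def test_totals_conserved_and_balanced(self, n, seed):
        sys3 = enumerate_strata(3)
        counts = StrataCounts.from_mapping(sys3, {0b111: n})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(3), seed=seed)
        per_arm = list(alloc.counts[0b111].values())
        assert sum(per_arm) == n
        assert all(abs(x - n / 4) < 1 for x in per_arm)


class TestRandomAllocation:
    def test_deterministic_under_seed(self):
        sys2 = enumerate_strata(2)
        counts = StrataCounts(sys2, np.array([20, 30, 25]))
        pat = TreatmentPattern.distinct(2)
        a1 = random_allocation(counts, pat, seed=99)
        a2 = random_allocation(counts, pat, seed=99)
        assert a1.counts == a2.counts

    def test_marginally_uniform_over_arms(self, rng):
        """Arm frequencies over repeated randomizations match the uniform
        multinomial within Monte-Carlo error."""
        sys1 = enumerate_strata(1)
        counts = StrataCounts(sys1, np.array([30]))
        pat = TreatmentPattern.distinct(1)
        reps = 10_000
        tally = np.zeros(2)
        for _ in range(reps):
            a = random_allocation(counts, pat, seed=rng)
            tally += [a.n(1, "T1"), a.n(1, "C")]
        freq = tally / (30 * reps)
        se = np.sqrt(0.25 / (30 * reps))
        assert np.all(np.abs(freq - 0.5) <= 3 * se)


class TestCorrelationMatrix:
    def test_disjoint_populations_give_identity(self):
        sys2 = enumerate_strata(2)
        counts = StrataCounts(sys2, np.array([40, 40, 0]))
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(2))
        model = correlation_matrix(alloc, VarianceModel("known-homogeneous", sigma2=2.0))
        assert np.allclose(model.corr, np.eye(2))

    def test_homogeneous_formula_is_variance_free(self, rng):
        """The general variance-carrying formula collapses to the
        variance-free homogeneous form, entrywise to 1e-12."""
        for _ in range(10):
            _, _, alloc, _ = random_design(3, 200, rng)
            sigma2 = float(rng.uniform(0.2, 5.0))
            het = correlation_matrix(
                alloc, VarianceModel("known-heterogeneous", sigma2=sigma2)
            )
            hom = correlation_matrix(alloc, VarianceModel("known-homogeneous", sigma2=1.0))
            assert np.allclose(het.corr, hom.corr, atol=1e-12)

    def test_matches_brute_force_covariance_oracle(self, rng):
        for m in (2, 3):
            for _ in range(5):
                _, _, alloc, _ = random_design(m, 150, rng)
                sig_map = {
                    (J, T): float(rng.uniform(0.5, 2.0))
                    for J in alloc.system.strata
                    for T in alloc.pattern.arms_for(alloc.system, J)
                }
                vm = VarianceModel("known-heterogeneous", sigma2_map=sig_map)
                model = correlation_matrix(alloc, vm)
                ref_corr, ref_V, _, _ = brute_force_correlation(alloc, vm)
                assert np.allclose(model.corr, ref_corr, atol=1e-12)
                assert np.allclose(model.V, ref_V, atol=1e-12)

    def test_shared_treatment_covariance_oracle(self, rng):
        """Populations sharing one treatment also share treatment patients;
        the oracle covariance picks the extra term up automatically."""
        sys2 = enumerate_strata(2)
        counts = StrataCounts(sys2, np.array([30, 30, 30]))
        pat = TreatmentPattern.shared(2)
        alloc = stratified_allocation(counts, pat, seed=1)
        vm = VarianceModel("known-homogeneous", sigma2=1.3)
        model = correlation_matrix(alloc, vm)
        ref_corr, _, _, _ = brute_force_correlation(alloc, vm)
        assert np.allclose(model.corr, ref_corr, atol=1e-12)
        # sharing a treatment strictly increases the correlation
        distinct = correlation_matrix(
            stratified_allocation(counts, TreatmentPattern.distinct(2), seed=1), vm
        )
        assert model.corr[0, 1] > distinct.corr[0, 1]

    def test_psd_and_unit_interval_on_random_designs(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 5))
            _, _, alloc, model = random_design(m, 120, rng)
            eig = np.linalg.eigvalsh(model.corr)
            assert eig.min() > -1e-10
            off = model.corr[~np.eye(m, dtype=bool)]
            assert np.all(off >= 0.0) and np.all(off <= 1.0)

    def test_empty_population_arm_reported(self):
        sys2 = enumerate_strata(2)
        counts = StrataCounts(sys2, np.array([0, 40, 0]))
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(2))
        with pytest.raises(AnalysisError, match="population 1"):
            correlation_matrix(alloc, VarianceModel("known-homogeneous", sigma2=1.0))


class TestLocationVector:
    def test_null_means_give_zero(self, rng):
        _, _, alloc, _ = random_design(2, 100, rng)
        vm = VarianceModel("known-homogeneous", sigma2=1.0)
        nu = location_vector(alloc, vm, {})
        assert np.allclose(nu, 0.0)

    def test_single_population_z_location(self):
        sys1 = enumerate_strata(1)
        counts = StrataCounts.from_mapping(sys1, {1: 40})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(1))
        vm = VarianceModel("known-homogeneous", sigma2=1.0)
        delta = 0.7
        nu = location_vector(alloc, vm, {(1, "T1"): delta})
        V = 1.0 / 20 + 1.0 / 20
        assert nu[0] == pytest.approx(delta / np.sqrt(V))

    def test_mixed_strata_means_formula_oracle(self, rng):
        _, _, alloc, _ = random_design(2, 120, rng)
        vm = VarianceModel("known-heterogeneous", sigma2=1.7)
        means = {
            (J, T): float(rng.normal())
            for J in alloc.system.strata
            for T in alloc.pattern.arms_for(alloc.system, J)
        }
        nu = location_vector(alloc, vm, means)
        _, ref_V, A, _ = brute_force_correlation(alloc, vm)
        cells = [
            (J, T)
            for J in alloc.system.strata
            for T, n in alloc.counts.get(J, {}).items()
            if n > 0
        ]
        mu = np.array([means[c] for c in cells])
        assert np.allclose(nu, (A @ mu) / np.sqrt(ref_V), atol=1e-12)


class TestPooledVariance:
    def test_two_equal_groups(self):
        sys1 = enumerate_strata(1)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        data = TrialData(
            sys1,
            TreatmentPattern.distinct(1),
            np.ones(8, dtype=int),
            np.array(["T1"] * 4 + ["C"] * 4, dtype=object),
            np.concatenate([x, x + 10]),
        )
        s2, s, df = pooled_variance(data)
        assert s2 == pytest.approx(np.var(x, ddof=1))
        assert (s, df) == (2, 6)

    def test_constant_responses(self):
        sys1 = enumerate_strata(1)
        data = TrialData(
            sys1,
            TreatmentPattern.distinct(1),
            np.ones(6, dtype=int),
            np.array(["T1"] * 3 + ["C"] * 3, dtype=object),
            np.full(6, 5.0),
        )
        assert pooled_variance(data)[0] == 0.0

    def test_formula_oracle_with_singleton_cells(self, rng):
        """Singleton cells are excluded from s and contribute nothing."""
        sys2 = enumerate_strata(2)
        strata = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3, 3])
        arms = np.array(
            ["T1", "T1", "C", "T2", "C", "C", "T1", "T2", "T2", "C", "C"], dtype=object
        )
        resp = rng.normal(size=len(strata))
        data = TrialData(sys2, TreatmentPattern.distinct(2), strata, arms, resp)
        s2, s, df = pooled_variance(data)
        num, s_ref = 0.0, 0
        for key, x in data.cells().items():
            if len(x) > 1:
                num += (len(x) - 1) * np.var(x, ddof=1)
                s_ref += 1
        assert s == s_ref and df == len(strata) - s_ref
        assert s2 == pytest.approx(num / df)


class TestTestStatistics:
    def _single_pop_data(self, rng, n=30, delta=0.0):
        sys1 = enumerate_strata(1)
        counts = StrataCounts.from_mapping(sys1, {1: 2 * n})
        alloc = stratified_allocation(counts, TreatmentPattern.distinct(1))
        vm = VarianceModel("known-homogeneous", sigma2=1.0)
        return draw_responses(alloc, {(1, "T1"): delta}, vm, rng)

    def test_single_population_z(self, rng):
        data = self._single_pop_data(rng, delta=0.5)
        z, model = compute_statistics(data, VarianceModel("known-homogeneous", sigma2=1.0))
        xs = data.cells()
        diff = xs[(1, "T1")].mean() - xs[(1, "C")].mean()
        n = len(xs[(1, "T1")])
        assert z[0] == pytest.approx(diff / np.sqrt(2 / n))
        assert model.family == "gaussian"

    def test_single_population_pooled_t(self, rng):
        data = self._single_pop_data(rng)
        tstat, model = compute_statistics(data, VarianceModel("unknown-homogeneous"))
        xs = data.cells()
        ref = stats.ttest_ind(xs[(1, "T1")], xs[(1, "C")], equal_var=True)
        assert tstat[0] == pytest.approx(ref.statistic)
        assert model.df == len(data.response) - 2

    def test_null_statistics_covariance_matches_model(self, rng):
        """Empirical covariance of simulated null statistic vectors matches
        the analytic correlation matrix, gaussian and t regimes."""
        _, _, alloc, model = random_design(2, 120, rng)
        sigma2 = 1.0
        _, V, A, var = brute_force_correlation(
            alloc, VarianceModel("known-homogeneous", sigma2=sigma2)
        )
        reps = 10_000
        means = rng.normal(0.0, np.sqrt(var), size=(reps, len(var)))
        Z = (means @ A.T) / np.sqrt(V)
        # t statistics share the correlation matrix; divide by an independent
        # pooled variance draw
        N_minus_s = 100
        chi = rng.chisquare(N_minus_s, size=reps) / N_minus_s
        T = Z / np.sqrt(chi)[:, None]
        se = 3.0 / np.sqrt(reps)
        for mat in (Z, T):
            emp = np.corrcoef(mat.T)
            assert np.all(np.abs(emp - model.corr) <= 3 * se + 0.02)
            assert np.all(np.abs(mat.mean(axis=0)) <= 3.5 / np.sqrt(reps) * mat.std(axis=0))

    def test_empty_arm_rejected(self):
        sys1 = enumerate_strata(1)
        data = TrialData(
            sys1,
            TreatmentPattern.distinct(1),
            np.ones(4, dtype=int),
            np.array(["T1"] * 4, dtype=object),
            np.zeros(4),
        )
        with pytest.raises(AnalysisError):
            compute_statistics(data, VarianceModel("known-homogeneous", sigma2=1.0))


class TestSatterthwaite:
    def _welch_data(self, rng, n_t, n_c, sd_t, sd_c):
        sys1 = enumerate_strata(1)
        strata = np.ones(n_t + n_c, dtype=int)
        arms = np.array(["T1"] * n_t + ["C"] * n_c, dtype=object)
        resp = np.concatenate(
            [rng.normal(0, sd_t, n_t), rng.normal(0, sd_c, n_c)]
        )
        return TrialData(sys1, TreatmentPattern.distinct(1), strata, arms, resp)

    def test_equal_variance_equal_n_closed_form(self):
        sys1 = enumerate_strata(1)
        n0 = 12
        x = np.linspace(-1, 1, n0)
        data = TrialData(
            sys1,
            TreatmentPattern.distinct(1),
            np.ones(2 * n0, dtype=int),
            np.array(["T1"] * n0 + ["C"] * n0, dtype=object),
            np.concatenate([x, x + 3]),
        )
        assert satterthwaite_df(data, 1) == pytest.approx(2 * (n0 - 1))

    def test_extreme_variance_ratio_limit(self, rng):
        data = self._welch_data(rng, n_t=8, n_c=50, sd_t=30.0, sd_c=0.01)
        df = satterthwaite_df(data, 1)
        assert 7 - 0.2 <= df <= 8.0  # tends to the small noisy arm's n-1

    def test_random_instance_matches_direct_quotient(self, rng):
        data = self._welch_data(rng, 15, 9, 1.4, 0.6)
        cells = data.cells()
        vt, vc = (np.var(cells[(1, a)], ddof=1) for a in ("T1", "C"))
        nt, nc = len(cells[(1, "T1")]), len(cells[(1, "C")])
        ref = (vt / nt + vc / nc) ** 2 / (
            (vt / nt) ** 2 / (nt - 1) + (vc / nc) ** 2 / (nc - 1)
        )
        assert satterthwaite_df(data, 1) == pytest.approx(ref)
        assert min(nt, nc) - 1 <= satterthwaite_df(data, 1) <= nt + nc - 2

    def test_tiny_arm_rejected(self, rng):
        data = self._welch_data(rng, 1, 10, 1.0, 1.0)
        with pytest.raises(AnalysisError):
            satterthwaite_df(data, 1)


def test_effect_variance_formula(rng):
    _, _, alloc, _ = random_design(3, 200, rng)
    vm = VarianceModel("known-homogeneous", sigma2=2.5)
    V = effect_variances(alloc, vm)
    _, ref_V, _, _ = brute_force_correlation(alloc, vm)
    assert np.allclose(V, ref_V, atol=1e-12)
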