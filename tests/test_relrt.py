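import numpy as np
import pytest
from scipy import integrate, stats

from rvtrio.io import TrioCohort
from rvtrio.relrt import (
    PenetranceModel,
    RandomEffectsSpec,
    _fit_pi_rows,
    _ratio_tables,
    delta_bound,
    estimate_maf,
    fit_pi,
    lrt_test,
    mixture_log_pmf,
    pseudo_loglik,
    transmission_probability,
)
from rvtrio.transmission import TransmissionSummary, summarize_transmission

from conftest import random_mendelian_cohort


class TestTransmissionProbability:
    @pytest.mark.parametrize("form", ["dominant", "multiplicative", "recessive"])
    @pytest.mark.parametrize("q", [0.001, 0.2, 0.7])
    def test_null_identity(self, q, form):
        assert transmission_probability(q, 1.0, form) == pytest.approx(0.5)

    def test_rare_limit_is_rr_over_one_plus_rr(self):
        assert transmission_probability(1e-6, 5.0, "dominant") == pytest.approx(5 / 6, abs=1e-5)

    def test_monotone_in_rr(self):
        ps = [transmission_probability(0.2, r, "dominant") for r in (1.0, 1.5, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_matches_ascertained_trio_simulation(self):
        """Monte-Carlo oracle: simulate 10^6 families with a het focal parent,
        transmit alleles, keep affected children, compare transmitted fraction."""
        q, rr = 0.3, 2.0
        rng = np.random.default_rng(42)
        n = 1_000_000
        focal_transmits = rng.integers(0, 2, n)            # het parent: mutant w.p. 1/2
        other_geno = rng.binomial(2, q, n)                 # HWE
        other_transmits = (other_geno == 2) | ((other_geno == 1) & (rng.random(n) < 0.5))
        child = focal_transmits + other_transmits
        pen = np.where(child >= 1, rr, 1.0) * 0.05         # dominant, baseline cancels
        affected = rng.random(n) < pen
        p_emp = focal_transmits[affected].mean()
        p_th = transmission_probability(q, rr, "dominant")
        assert 0.5 < p_th < 2 / 3
        se = np.sqrt(p_th * (1 - p_th) / affected.sum())
        assert abs(p_emp - p_th) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            transmission_probability(0.0, 2.0)
        with pytest.raises(ValueError):
            transmission_probability(0.2, 2.0, "additive")

    def test_penetrance_model_fields(self):
        m = PenetranceModel(q=0.2, rr=3.0, form="dominant")
        assert m.p == pytest.approx(transmission_probability(0.2, 3.0, "dominant"))
        assert m.p == pytest.approx(m.b1 / (m.b1 + m.b2))


class TestMafEstimate:
    def test_counting(self):
        n = 100
        father = np.zeros((n, 1), dtype=int)
        father[0, 0] = 1
        mother = np.zeros((n, 1), dtype=int)
        child = np.zeros((n, 1), dtype=int)
        cohort = TrioCohort(father, mother, child, ["v1"])
        assert estimate_maf(cohort)[0] == pytest.approx(1 / 400)

    def test_monomorphic_clamped(self):
        n = 10
        z = np.zeros((n, 1), dtype=int)
        cohort = TrioCohort(z, z, z, ["v1"])
        assert estimate_maf(cohort)[0] == pytest.approx(1 / (4 * n + 2))

    def test_recovers_hwe_frequency(self):
        q, n = 0.01, 2000
        rng = np.random.default_rng(3)
        cohort = random_mendelian_cohort(rng, n, 1, q=q)
        q_hat = estimate_maf(cohort)[0]
        assert abs(q_hat - q) < 3 * np.sqrt(q * (1 - q) / (4 * n))


class TestDeltaBound:
    def test_requires_gamma_above_one(self):
        with pytest.raises(ValueError):
            delta_bound(0.01, 1.0)

    def test_rare_limit(self):
        assert delta_bound(1e-9, 5.0) == pytest.approx(5 / 6)

    def test_decreasing_in_maf(self):
        qs = [0.001, 0.01, 0.05, 0.2]
        ds = [delta_bound(q, 5.0) for q in qs]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        assert all(0.5 < d < 1 for d in ds)


class TestMixturePmf:
    def test_pi_zero_is_binomial(self):
        for t in range(11):
            assert mixture_log_pmf(t, 10, 0.8, 0.0) == pytest.approx(
                stats.binom.logpmf(t, 10, 0.5)
            )

    def test_h1_closed_form(self):
        # mean of Uniform(0.5, 0.8) is the transmit probability
        assert np.exp(mixture_log_pmf(1, 1, 0.8, 1.0)) == pytest.approx(0.65)

    @pytest.mark.parametrize("H", [1, 7, 50])
    @pytest.mark.parametrize("delta", [0.55, 0.8])
    @pytest.mark.parametrize("pi", [0.0, 0.3, 1.0])
    def test_normalization(self, H, delta, pi):
        total = sum(np.exp(mixture_log_pmf(t, H, delta, pi)) for t in range(H + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_oracle(self):
        """Numerical integration of Binomial(t; H, p) over p ~ Uniform(0.5, delta)."""
        t, H, delta, pi = 8, 10, 0.8, 0.5
        mix, _ = integrate.quad(lambda p: stats.binom.pmf(t, H, p) / (delta - 0.5), 0.5, delta)
        expected = (1 - pi) * stats.binom.pmf(t, H, 0.5) + pi * mix
        assert np.exp(mixture_log_pmf(t, H, delta, pi)) == pytest.approx(expected, abs=1e-10)

    def test_large_h_stable(self):
        val = mixture_log_pmf(6000, 10000, 0.8, 0.5)
        assert np.isfinite(val)

    def test_monotone_upper_tail_in_pi(self):
        """Raising pi shifts mass to t > H/2 (more functional signal)."""
        H, delta = 20, 0.8
        t_hi = np.arange(11, 21)
        tails = [np.exp(mixture_log_pmf(t_hi, H, delta, pi)).sum() for pi in (0.0, 0.3, 0.7, 1.0)]
        assert all(a < b for a, b in zip(tails, tails[1:]))

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            mixture_log_pmf(1, 2, 0.5, 0.5)


def summary_from_counts(T, H):
    """Build a single-family-per-transmission summary with given (T_j, H_j)."""
    T, H = np.asarray(T), np.asarray(H)
    L = len(T)
    n = int(H.max()) if H.size else 1
    X = np.zeros((max(n, 1), L), dtype=int)
    het = np.zeros((max(n, 1), L), dtype=int)
    for j in range(L):
        het[: H[j], j] = 1
        X[: T[j], j] = 1
        X[T[j]: H[j], j] = -1
    return TransmissionSummary(X=X, het_parents=het)


class TestPseudoLoglikAndFit:
    def test_pi_zero_reduces_to_binomial_sum(self):
        s = summary_from_counts([3, 5], [6, 8])
        spec = RandomEffectsSpec(gamma=5.0, q_hat=np.array([0.01, 0.01]),
                                 delta=np.array([0.8, 0.8]))
        expected = stats.binom.logpmf(3, 6, 0.5) + stats.binom.logpmf(5, 8, 0.5)
        assert pseudo_loglik(0.0, s, spec) == pytest.approx(expected)

    def test_uninformative_variants_contribute_zero(self):
        s = summary_from_counts([3, 0], [6, 0])
        spec = RandomEffectsSpec(gamma=5.0, q_hat=np.array([0.01, 0.01]),
                                 delta=np.array([0.8, 0.8]))
        s1 = summary_from_counts([3], [6])
        spec1 = RandomEffectsSpec(gamma=5.0, q_hat=np.array([0.01]), delta=np.array([0.8]))
        for pi in (0.0, 0.4, 1.0):
            assert pseudo_loglik(pi, s, spec) == pytest.approx(pseudo_loglik(pi, s1, spec1))

    def test_deficit_of_transmissions_gives_zero(self):
        """T_j <= H_j/2 everywhere: the dense grid confirms the max is at 0."""
        s = summary_from_counts([2, 3, 1], [6, 8, 4])
        spec = RandomEffectsSpec(gamma=5.0, q_hat=np.full(3, 0.01), delta=np.full(3, 0.8))
        grid = np.linspace(0, 1, 201)
        vals = [pseudo_loglik(p, s, spec) for p in grid]
        assert int(np.argmax(vals)) == 0
        assert fit_pi(s, spec) == 0.0

    def test_saturated_signal_gives_pi_near_one(self):
        rng = np.random.default_rng(8)
        H = np.full(40, 200)
        delta = np.full(40, 0.8)
        p = rng.uniform(0.72, 0.78, 40)  # all functional, near the bound
        T = rng.binomial(H, p)
        s = summary_from_counts(T, H)
        spec = RandomEffectsSpec(gamma=5.0, q_hat=np.full(40, 0.01), delta=delta)
        assert fit_pi(s, spec) > 0.9

    def test_all_uninformative_errors(self):
        s = summary_from_counts([0], [0])
        spec = RandomEffectsSpec(gamma=5.0, q_hat=np.array([0.01]), delta=np.array([0.8]))
        with pytest.raises(ValueError):
            fit_pi(s, spec)

    def test_vectorized_solver_matches_grid_refine(self, rng):
        """Concave-bisection engine and the public grid+refine agree."""
        for trial in range(10):
            L = int(rng.integers(3, 12))
            H = rng.integers(2, 60, L)
            T = np.array([rng.binomial(h, rng.uniform(0.4, 0.8)) for h in H])
            s = summary_from_counts(T, H)
            delta = rng.uniform(0.6, 0.85, L)
            spec = RandomEffectsSpec(gamma=5.0, q_hat=np.full(L, 0.01), delta=delta)
            pi_grid = fit_pi(s, spec)
            R = _ratio_tables(s.H, delta)
            r = R[np.arange(L), s.T]
            pi_vec, lam_vec = _fit_pi_rows(r[None, :])
            assert pi_vec[0] == pytest.approx(pi_grid, abs=2e-4)
            lam_grid = 2 * (pseudo_loglik(pi_grid, s, spec) - pseudo_loglik(0.0, s, spec))
            assert lam_vec[0] == pytest.approx(max(lam_grid, 0.0), abs=1e-6)

    def test_pi_recovery_within_bootstrap_error(self):
        """Known mixture: L=100 variants, H=200, half functional with
        p ~ Uniform(0.5, delta); pi_hat within 3 bootstrap SEs of 0.5."""
        rng = np.random.default_rng(17)
        L, Hval, pi0, dlt = 100, 200, 0.5, 0.75
        H = np.full(L, Hval)
        delta = np.full(L, dlt)
        functional = rng.random(L) < pi0
        p = np.where(functional, rng.uniform(0.5, dlt, L), 0.5)
        T = rng.binomial(H, p)
        R = _ratio_tables(H, delta)
        r = R[np.arange(L), T]
        pi_hat = _fit_pi_rows(r[None, :])[0][0]
        boot = []
        for _ in range(200):
            idx = rng.integers(0, L, L)
            boot.append(_fit_pi_rows(r[idx][None, :])[0][0])
        se = float(np.std(boot))
        assert abs(pi_hat - pi0) < 3 * max(se, 0.02)


class TestLrtTest:
    def test_all_homozygous_parents_error(self):
        # homozygous parents only -> H = 0 everywhere, nothing to test
        n = 12
        cohort = TrioCohort(2 * np.ones((n, 1), dtype=int), np.zeros((n, 1), dtype=int),
                            np.ones((n, 1), dtype=int), ["v1"])
        with pytest.raises(ValueError):
            lrt_test(cohort, n_perm=50, seed=0)

    def test_lambda_nonnegative_and_deterministic(self, rng):
        cohort = random_mendelian_cohort(rng, 80, 4, q=0.1)
        r1 = lrt_test(cohort, gamma=5.0, n_perm=300, seed=9)
        r2 = lrt_test(cohort, gamma=5.0, n_perm=300, seed=9)
        assert r1.statistic >= 0.0
        assert (r1.statistic, r1.p_value, r1.pi_hat) == (r2.statistic, r2.p_value, r2.pi_hat)
        assert 0 < r1.p_value <= 1

    def test_balanced_transmissions_give_p_one(self):
        """Every family with X=0 at every variant: Lambda equals every
        permuted Lambda, so the permutation p-value is 1."""
        n = 10
        father = np.ones((n, 2), dtype=int)
        mother = np.ones((n, 2), dtype=int)
        child = np.ones((n, 2), dtype=int)  # both parents het, child het: X=0
        cohort = TrioCohort(father, mother, child, ["v1", "v2"])
        res = lrt_test(cohort, n_perm=100, seed=2)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_delta_fixed_across_permutations(self, rng):
        """delta depends on parents only, so any complement swap of the
        children leaves the spec unchanged."""
        cohort = random_mendelian_cohort(rng, 30, 3, q=0.2)
        spec = RandomEffectsSpec.from_cohort(cohort)
        swapped = TrioCohort(cohort.father.copy(), cohort.mother.copy(),
                             cohort.father + cohort.mother - cohort.child,
                             cohort.variant_ids)
        spec2 = RandomEffectsSpec.from_cohort(swapped)
        np.testing.assert_allclose(spec.delta, spec2.delta)
        np.testing.assert_allclose(spec.q_hat, spec2.q_hat)
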