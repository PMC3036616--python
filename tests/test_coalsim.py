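"""Hudson coalescent simulator: analytic expectations, msprime cross-check, null machinery."""

import math

import msprime
import numpy as np
import pytest

from rcdkit.coalsim import (
    CoalescentConfig,
    NullSummary,
    ci_overlap_test,
    null_distribution,
    sim_tajimas_d,
    simulate_replicates,
    simulate_sample,
)
from rcdkit.polymorphism import harmonic_a


class TestSimulator:
    def test_theta_zero_always_monomorphic(self):
        cfg = CoalescentConfig(n=8, theta_gene=0.0, reps=20, seed=1)
        for s in simulate_replicates(cfg):
            assert s.S == 0

    def test_seeded_determinism(self):
        cfg = CoalescentConfig(n=10, theta_gene=5.0, rho_gene=2.0, reps=5, seed=99)
        a = simulate_replicates(cfg)
        b = simulate_replicates(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.genotypes, y.genotypes)
            assert np.array_equal(x.positions, y.positions)

    @pytest.mark.parametrize("n,theta", [(2, 5.0), (10, 5.0), (16, 10.0)])
    def test_expected_s_and_pi(self, n, theta):
        reps = 2000
        cfg = CoalescentConfig(n=n, theta_gene=theta, reps=reps, seed=7)
        samples = simulate_replicates(cfg)
        S = np.array([s.S for s in samples], dtype=float)
        pi = np.array([s.pi_gene for s in samples])
        se_S = 3 * S.std(ddof=1) / math.sqrt(reps)
        se_pi = 3 * pi.std(ddof=1) / math.sqrt(reps)
        assert abs(S.mean() - theta * harmonic_a(n)) <= se_S
        assert abs(pi.mean() - theta) <= se_pi

    def test_recombination_preserves_means(self):
        reps = 2000
        cfg = CoalescentConfig(n=10, theta_gene=5.0, rho_gene=5.0, reps=reps, seed=13)
        samples = simulate_replicates(cfg)
        S = np.array([s.S for s in samples], dtype=float)
        pi = np.array([s.pi_gene for s in samples])
        assert abs(S.mean() - 5.0 * harmonic_a(10)) <= 3 * S.std(ddof=1) / math.sqrt(reps)
        assert abs(pi.mean() - 5.0) <= 3 * pi.std(ddof=1) / math.sqrt(reps)

    def test_recombination_reduces_pi_variance(self):
        reps = 2000
        v = {}
        for rho in (0.0, 5.0):
            cfg = CoalescentConfig(n=10, theta_gene=5.0, rho_gene=rho, reps=reps, seed=29)
            v[rho] = np.var([s.pi_gene for s in simulate_replicates(cfg)])
        assert v[5.0] < v[0.0]

    def test_sfs_matches_msprime_oracle(self):
        """Site-frequency spectrum agrees with msprime at matched parameters."""
        n, theta, reps = 8, 6.0, 1500
        cfg = CoalescentConfig(n=n, theta_gene=theta, reps=reps, seed=3)
        own = np.zeros(n - 1)
        for s in simulate_replicates(cfg):
            for c in s.derived_counts:
                own[c - 1] += 1
        own /= reps
        ref = np.zeros(n - 1)
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1.0, sequence_length=1,
                discrete_genome=False, num_replicates=reps, random_seed=5,
            )
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, discrete_genome=False, random_seed=11 + i
            )
            sfs = mts.allele_frequency_spectrum(
                mode="site", polarised=True, span_normalise=False
            )
            ref += sfs[1:n]
        ref /= reps
        # per-class agreement within 4 binomial-ish standard errors
        for k in range(n - 1):
            se = 4 * math.sqrt((own[k] + ref[k]) / reps + 1e-9)
            assert abs(own[k] - ref[k]) <= max(se, 0.25), (k, own, ref)


class TestNullDistribution:
    def test_observed_at_median_gives_half(self):
        cfg = CoalescentConfig(n=10, theta_gene=5.0, reps=400, seed=17)
        rng = np.random.default_rng(17)
        vals = [sim_tajimas_d(simulate_sample(cfg, rng)) for _ in range(400)]
        med = float(np.median([v for v in vals if not math.isnan(v)]))
        null = null_distribution(sim_tajimas_d, med, cfg)
        assert 0.35 <= null.p_value <= 0.65

    def test_extreme_observation_floor(self):
        cfg = CoalescentConfig(n=10, theta_gene=5.0, reps=200, seed=23)
        null = null_distribution(sim_tajimas_d, 50.0, cfg)
        assert null.p_value == pytest.approx(1 / 201)

    def test_too_many_na_refused(self):
        cfg = CoalescentConfig(n=10, theta_gene=0.01, reps=100, seed=31)
        with pytest.raises(RuntimeError):
            null_distribution(sim_tajimas_d, 0.0, cfg)

    def test_ci_ordering(self):
        cfg = CoalescentConfig(n=12, theta_gene=6.0, reps=300, seed=41)
        null = null_distribution(sim_tajimas_d, 0.0, cfg)
        assert null.ci_low <= null.null_mean <= null.ci_high


class TestCIOverlapRule:
    def _summary(self, lo, hi, obs):
        return NullSummary("D", obs, (lo + hi) / 2, lo, hi, 0.5, 100, 0)

    def test_identical_populations_not_significant(self):
        a = self._summary(-1.5, 1.5, 0.1)
        assert ci_overlap_test(a, a) is False

    def test_disjoint_cis_significant(self):
        sym = self._summary(-2.0, -1.0, -1.5)
        allo = self._summary(1.0, 2.0, 1.5)
        assert ci_overlap_test(sym, allo) is True

    def test_one_direction_only_not_significant(self):
        # sympatric CI excludes allopatric observed, but not vice versa
        sym = self._summary(-1.0, 0.5, 0.0)
        allo = self._summary(-3.0, 3.0, 1.0)
        assert ci_overlap_test(sym, allo) is False

    def test_na_not_evaluable(self):
        sym = self._summary(-1.0, 1.0, math.nan)
        allo = self._summary(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ci_overlap_test(sym, allo)
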