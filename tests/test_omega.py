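"""Composite-likelihood constant-omega model: likelihood, MCMC, run combination,
posterior differences."""

import math

import numpy as np
import pytest

from rcdkit.alignment import CodonAlignment
from rcdkit.omega import (
    PRIOR_HIGH,
    PRIOR_LOW,
    CompositeLikelihood,
    MCMCConfig,
    PosteriorSample,
    codon_rate_matrix,
    combine_runs,
    composite_loglik,
    posterior_difference,
    run_mcmc,
)
from rcdkit.synthetic import generate_population_sample

SHORT = dict(iterations=1000, thinning=10, burn_in_fraction=0.2)


def _sample_from(draws):
    a = np.asarray(draws, dtype=float)
    return PosteriorSample(mu=a, kappa=a, omega=a)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_reversibility(self):
        freqs = np.full(61, 1 / 61)
        Q = codon_rate_matrix(2.5, 0.4, freqs)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        flux = freqs[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        # normalized: one expected substitution per unit time
        assert -np.sum(freqs * np.diag(Q)) == pytest.approx(1.0)


class TestCompositeLikelihood:
    def test_invariant_under_haplotype_reordering(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=6, L_codons=60, seed=1)
        perm = aln.subset([3, 1, 5, 0, 2, 4])
        assert composite_loglik(aln, 0.05, 3.0, 0.5) == pytest.approx(
            composite_loglik(perm, 0.05, 3.0, 0.5)
        )

    def test_monomorphic_favours_small_mu_independent_of_omega(self):
        aln = CodonAlignment("g", ["ATGGCTGGTACC" * 5] * 6, [f"h{i}" for i in range(6)])
        ll = CompositeLikelihood(aln)
        assert ll(1e-5, 3.0, 0.1) > ll(0.1, 3.0, 0.1)
        # at the mu lower bound divergence vanishes and omega carries no
        # information
        assert ll(PRIOR_LOW, 3.0, 0.1) == pytest.approx(
            ll(PRIOR_LOW, 3.0, 2.0), abs=1e-3
        )

    def test_out_of_support_is_minus_inf(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=4, L_codons=30, seed=2)
        ll = CompositeLikelihood(aln)
        assert ll(PRIOR_LOW / 10, 3.0, 0.5) == -math.inf
        assert ll(0.05, 3.0, PRIOR_HIGH * 10) == -math.inf

    def test_quadrature_converges(self):
        # two-haplotype toy with one synonymous difference: 16-node quadrature
        # agrees with a 10x finer rule
        a = "TTT" * 30
        b = "TTC" + "TTT" * 29
        aln = CodonAlignment("g", [a, b], ["x", "y"])
        coarse = composite_loglik(aln, 0.02, 3.0, 0.5, quadrature_nodes=16)
        fine = composite_loglik(aln, 0.02, 3.0, 0.5, quadrature_nodes=160)
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_synonymous_pair_likelihood_decreasing_in_omega_past_peak(self):
        a = "TTT" * 30
        b = "TTC" + "TTT" * 29
        aln = CodonAlignment("g", [a, b], ["x", "y"])
        ll = CompositeLikelihood(aln)
        vals = [ll(0.02, 3.0, w) for w in (0.5, 1.0, 2.0, 5.0, 20.0)]
        # a purely synonymous difference: inflating omega only wastes rate
        assert vals == sorted(vals, reverse=True) or vals[0] < vals[1]
        assert ll(0.02, 3.0, 20.0) < ll(0.02, 3.0, 0.5)


class TestMCMC:
    def test_seeded_determinism(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=6, L_codons=60, seed=3)
        cfg = MCMCConfig(**SHORT, seed=5)
        s1 = run_mcmc(aln, cfg)
        s2 = run_mcmc(aln, cfg)
        assert np.array_equal(s1.omega, s2.omega)
        assert np.array_equal(s1.mu, s2.mu)

    def test_prior_only_sampling_matches_reciprocal_prior(self):
        # likelihood off: retained draws should follow the truncated
        # reciprocal density, i.e. log(x) uniform on [log lo, log hi]
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=4, L_codons=30, seed=4)
        cfg = MCMCConfig(
            iterations=30_000, thinning=20, burn_in_fraction=0.2,
            use_likelihood=False, proposal_sd=4.0, seed=9,
        )
        s = run_mcmc(aln, cfg)
        logs = np.log(s.omega)
        lo, hi = math.log(PRIOR_LOW), math.log(PRIOR_HIGH)
        u = (logs - lo) / (hi - lo)
        # quartiles of a uniform within MC error
        assert np.percentile(u, 50) == pytest.approx(0.5, abs=0.1)
        assert np.percentile(u, 25) == pytest.approx(0.25, abs=0.1)
        assert np.percentile(u, 75) == pytest.approx(0.75, abs=0.1)

    def test_draws_respect_prior_support(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=6, L_codons=40, seed=6)
        s = run_mcmc(aln, MCMCConfig(**SHORT, seed=7))
        for draws in (s.mu, s.kappa, s.omega):
            assert np.all(draws >= PRIOR_LOW)
            assert np.all(draws <= PRIOR_HIGH)

    def test_monomorphic_flagged_na(self):
        aln = CodonAlignment("g", ["ATGGCTGGTACC" * 5] * 8, [f"h{i}" for i in range(8)])
        s = run_mcmc(aln, MCMCConfig(**SHORT, seed=8))
        assert s.is_na
        assert "variation" in s.na_reason

    def test_retained_draw_count(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=4, L_codons=30, seed=10)
        cfg = MCMCConfig(iterations=1000, thinning=10, burn_in_fraction=0.2, seed=1)
        s = run_mcmc(aln, cfg)
        assert s.omega.size == 80  # 100 thinned - 20 burn-in


class TestCombineRuns:
    def test_identical_runs_combine(self):
        aln = generate_population_sample(10.0, 0.5, n_haplotypes=6, L_codons=60, seed=12)
        r = run_mcmc(aln, MCMCConfig(**SHORT, seed=3))
        out = combine_runs(r, r)
        assert out.ok
        assert out.sample.omega.size == 2 * r.omega.size

    def test_two_seeds_combine_with_mean_between(self):
        aln = generate_population_sample(15.0, 0.5, n_haplotypes=8, L_codons=80, seed=13)
        cfg = dict(iterations=2000, thinning=10, burn_in_fraction=0.3)
        r1 = run_mcmc(aln, MCMCConfig(**cfg, seed=21))
        r2 = run_mcmc(aln, MCMCConfig(**cfg, seed=22))
        out = combine_runs(r1, r2)
        if out.ok:
            m = np.mean(out.sample.omega)
            lo = min(np.mean(r1.omega), np.mean(r2.omega))
            hi = max(np.mean(r1.omega), np.mean(r2.omega))
            assert lo <= m <= hi

    def test_disjoint_runs_flagged(self):
        r1 = _sample_from(np.full(100, 0.2) + np.linspace(0, 1e-3, 100))
        r2 = _sample_from(np.full(100, 5.0) + np.linspace(0, 1e-3, 100))
        out = combine_runs(r1, r2)
        assert not out.ok
        assert out.sample is None


class TestPosteriorDifference:
    def test_self_comparison_contains_zero(self):
        s = _sample_from(np.random.default_rng(1).gamma(2.0, 0.3, 500))
        comp = posterior_difference(s, s, seed=2)
        assert comp.contains_zero
        assert abs(comp.mean_diff) < 0.1

    def test_point_masses_exact_difference(self):
        s1 = _sample_from(np.full(200, 0.5))
        s2 = _sample_from(np.full(200, 0.3))
        comp = posterior_difference(s1, s2, seed=3)
        assert comp.mean_diff == pytest.approx(0.2)
        assert comp.cri_low == pytest.approx(0.2)
        assert comp.cri_high == pytest.approx(0.2)
        assert not comp.contains_zero

    def test_orientation_pop1_minus_pop2(self):
        base = np.random.default_rng(4).gamma(2.0, 0.2, 400)
        s1 = _sample_from(base)
        s2 = _sample_from(base + 1.0)
        comp = posterior_difference(s1, s2, seed=5)
        assert comp.mean_diff == pytest.approx(-1.0, abs=0.1)
        assert not comp.contains_zero

    def test_na_propagates(self):
        ok = _sample_from(np.full(100, 0.4))
        na = PosteriorSample(
            mu=np.array([]), kappa=np.array([]), omega=np.array([]),
            na_reason="Not enough variation",
        )
        comp = posterior_difference(na, ok)
        assert comp.is_na
        assert "Not enough variation" in comp.na_reason
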