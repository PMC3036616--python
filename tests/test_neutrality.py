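"""Tajima's D, Fu & Li's D*/F*, Fay & Wu's H against direct-formula oracles."""

import math

import numpy as np
import pytest

from rcdkit.alignment import CodonAlignment
from rcdkit.neutrality import (
    consensus_sequence,
    fay_wu_h,
    fay_wu_h_from_counts,
    fu_li_star,
    fu_li_star_from_summary,
    neutrality_coefficients,
    neutrality_stats,
    tajimas_d,
    tajimas_d_from_summary,
    theta_h_from_counts,
)
from rcdkit.polymorphism import harmonic_a, mean_pairwise_differences


def _aln(seqs, **kw):
    return CodonAlignment("g", list(seqs), [f"s{i}" for i in range(len(seqs))], **kw)


def test_coefficients_finite_and_a1_matches_summation():
    for n in (4, 8, 16, 30):
        c = neutrality_coefficients(n)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, n)))
        for v in (c.e1, c.e2, c.u_d_star, c.v_d_star, c.u_f_star, c.v_f_star):
            assert math.isfinite(v)
            assert v != 0.0


class TestTajimasD:
    def test_na_when_no_segregation(self):
        assert math.isnan(tajimas_d(_aln(["ATGGCT"] * 5)))

    def test_n2_numerator_identically_zero(self):
        # a_2 = 1 forces pi = theta for n = 2: D's numerator is exactly 0
        a = "ATG" + "GCT" * 9
        b = "TTG" + "GCC" + "GCT" * 8
        aln = _aln([a, b])
        pi = mean_pairwise_differences(aln)
        assert pi - 2 / harmonic_a(2) == pytest.approx(0.0)

    def test_singleton_heavy_alignment_matches_formula_oracle(self):
        # n = 10, 5 singleton columns: D computed independently from the
        # coefficient formulas
        base = "GCT" * 20
        seqs = [base] * 10
        # introduce 5 singletons in distinct codons' third positions (syn)
        for k in range(5):
            s = list(seqs[k])
            s[3 * k + 2] = "A"  # GCT->GCA synonymous
            seqs[k] = "".join(s)
        aln = _aln(seqs)
        n, S = 10, 5
        pi = mean_pairwise_differences(aln)
        c = neutrality_coefficients(n)
        expected = (pi - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
        d = tajimas_d(aln)
        assert d == pytest.approx(expected)
        assert d < 0  # singleton excess pushes D negative


class TestFuLiStar:
    def test_na_when_no_segregation(self):
        ds, fs = fu_li_star(_aln(["ATGGCT"] * 6))
        assert math.isnan(ds) and math.isnan(fs)

    def test_all_singletons_negative(self):
        base = "GCT" * 20
        seqs = [base] * 10
        for k in range(6):
            s = list(seqs[k])
            s[3 * k + 2] = "A"
            seqs[k] = "".join(s)
        ds, fs = fu_li_star(_aln(seqs))
        assert ds < 0
        assert fs < 0

    def test_intermediate_frequency_positive(self):
        base = "GCT" * 20
        half = ["GCA" + base[3:]] * 5 + [base] * 5  # one site at frequency 5/10
        seqs = []
        for i, s in enumerate(half):
            s = list(s)
            if i < 5:
                s[5] = "C"  # second shared intermediate variant (GCT->GCC syn)
            seqs.append("".join(s))
        ds, fs = fu_li_star(_aln(seqs))
        assert ds > 0
        assert fs > 0

    def test_matches_direct_formula(self):
        n, S, eta_s, pi = 12, 9, 3, 4.2
        c = neutrality_coefficients(n)
        ds, fs = fu_li_star_from_summary(n, S, eta_s, pi)
        exp_ds = ((n / (n - 1)) * S - c.a1 * eta_s) / math.sqrt(
            c.u_d_star * S + c.v_d_star * S * S
        )
        exp_fs = (pi - ((n - 1) / n) * eta_s) / math.sqrt(
            c.u_f_star * S + c.v_f_star * S * S
        )
        assert ds == pytest.approx(exp_ds)
        assert fs == pytest.approx(exp_fs)


class TestFayWuH:
    def test_theta_h_brute_force(self):
        n = 10
        counts = np.array([1, 1, 4, 9, 5])
        oracle = sum(2 * i * i for i in counts) / (n * (n - 1))
        assert theta_h_from_counts(n, counts) == pytest.approx(oracle)

    def test_derived_singletons_give_positive_h(self):
        h, _ = fay_wu_h_from_counts(10, np.array([1, 1, 1, 1]))
        assert h > 0  # theta_H < pi when derived variants are rare

    def test_high_frequency_derived_gives_negative_h(self):
        h, hn = fay_wu_h_from_counts(10, np.array([9, 9, 8]))
        assert h < 0
        assert hn < 0

    def test_polarization_against_outgroup(self):
        base = "GCT" * 10
        seqs = [base] * 8
        # derived variant at count 7 (outgroup carries ancestral T)
        for i in range(7):
            s = list(seqs[i])
            s[2] = "A"
            seqs[i] = "".join(s)
        aln = _aln(seqs)
        h, _ = fay_wu_h(aln, base)
        n = 8
        expected_pi = 2 * 7 * 1 / (n * (n - 1))
        expected_th = 2 * 49 / (n * (n - 1))
        assert h == pytest.approx(expected_pi - expected_th)

    def test_unpolarizable_site_excluded(self):
        base = "GCT" * 10
        seqs = [base] * 6
        for i in range(3):
            s = list(seqs[i])
            s[2] = "A"
            seqs[i] = "".join(s)
        aln = _aln(seqs)
        # outgroup has G at the segregating site: allele absent from sample
        out = list(base)
        out[2] = "G"
        h, hn = fay_wu_h(aln, "".join(out))
        assert math.isnan(h) and math.isnan(hn)

    def test_na_without_segregation(self):
        aln = _aln(["GCT" * 10] * 6)
        h, _ = fay_wu_h(aln, "GCT" * 10)
        assert math.isnan(h)


def test_statistics_invariant_to_sequence_reordering(rng):
    from rcdkit.synthetic import generate_population_sample

    aln = generate_population_sample(10.0, 0.5, n_haplotypes=8, L_codons=50, seed=21)
    perm = rng.permutation(aln.n)
    shuffled = aln.subset(list(perm))
    assert tajimas_d(aln) == pytest.approx(tajimas_d(shuffled))
    assert fu_li_star(aln) == pytest.approx(fu_li_star(shuffled))


def test_consensus_majority():
    aln = _aln(["ATGGCT", "ATGGCC", "ATGGCC"])
    assert consensus_sequence(aln) == "ATGGCC"


def test_neutrality_stats_bundle():
    from rcdkit.synthetic import generate_population_sample

    aln = generate_population_sample(10.0, 0.5, n_haplotypes=8, L_codons=50, seed=33)
    out = consensus_sequence(aln)
    stats = neutrality_stats(aln, outgroup=out)
    assert stats.S > 0
    assert math.isfinite(stats.D)
    assert math.isfinite(stats.D_star)
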