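"""Pairwise NG86 divergence, cross-type averaging, candidate rule, rank test."""

import itertools
import math

import numpy as np
import pytest

from rcdkit import divergence, synthetic
from rcdkit.divergence import (
    classify_candidate,
    jukes_cantor,
    mann_whitney_one_tailed,
    mean_cross_type_omega,
    ng86_pairwise,
)


class TestNG86Pairwise:
    def test_identical_sequences(self):
        seq = "ATGGCTGGTACC" * 5
        d = ng86_pairwise(seq, seq)
        assert d.dN == 0.0 and d.dS == 0.0
        assert d.omega is None  # dS = 0 leaves omega undefined, not zero

    def test_single_synonymous_difference(self):
        x = "TTT" * 10
        y = "TTT" * 9 + "TTC"
        d = ng86_pairwise(x, y)
        # 10/3 synonymous sites; p = 0.3; JC correction
        assert d.dS == pytest.approx(-0.75 * math.log(1 - 4 * 0.3 / 3), rel=1e-9)
        assert d.dS == pytest.approx(0.3831, abs=2e-4)
        assert d.dN == 0.0

    def test_single_nonsynonymous_difference(self):
        x = "TTT" * 10
        y = "TTT" * 9 + "GTT"
        d = ng86_pairwise(x, y)
        assert d.dN == pytest.approx(0.0390, abs=1e-4)
        assert d.dS == 0.0

    def test_symmetry(self, rng):
        from rcdkit.synthetic import generate_population_sample

        aln = generate_population_sample(15.0, 0.8, n_haplotypes=2, L_codons=60, seed=2)
        x, y = aln.sequences
        d1, d2 = ng86_pairwise(x, y), ng86_pairwise(y, x)
        assert d1.dN == pytest.approx(d2.dN)
        assert d1.dS == pytest.approx(d2.dS)

    def test_ambiguous_codons_skipped(self):
        x = "TTTNNNGGG"
        y = "TTCAAAGGG"  # middle codon unusable in x
        d = ng86_pairwise(x, y)
        # only TTT/TTC and GGG/GGG are compared: one synonymous difference
        assert d.syn_diffs == pytest.approx(1.0)
        assert d.nonsyn_diffs == 0.0

    def test_saturation_flagged(self):
        # every codon differs synonymously: p_S = 1 >= 3/4
        x = "TTT" * 10
        y = "TTC" * 10
        d = ng86_pairwise(x, y)
        assert d.saturated
        assert d.pS == pytest.approx(3.0)  # 1 diff per 1/3 syn site per codon
        assert math.isnan(d.dS)

    def test_jc_first_order_agreement(self):
        assert jukes_cantor(0.01) == pytest.approx(0.01, rel=0.01)


class TestCrossTypeAverage:
    def test_identical_panels(self):
        seq = "ATGGCTGGTACC" * 5
        d = mean_cross_type_omega([seq, seq], [seq, seq])
        assert d.dN == 0.0 and d.dS == 0.0
        assert d.omega is None
        assert d.n_undefined_omega == 4

    def test_mean_of_pair_omegas(self):
        # construct pairs with distinct omega values and check arithmetic mean
        a1 = "TTT" * 30
        a2 = "TTT" * 30
        # b1 gives omega x1 against both a's; b2 gives omega x2
        b1 = "GTT" + "TTC" * 2 + "TTT" * 27       # 1 nonsyn, 2 syn
        b2 = "GTT" * 2 + "TTC" * 2 + "TTT" * 26   # 2 nonsyn, 2 syn
        o1 = ng86_pairwise(a1, b1).omega
        o2 = ng86_pairwise(a1, b2).omega
        d = mean_cross_type_omega([a1, a2], [b1, b2])
        assert d.omega == pytest.approx((o1 + o2) / 2)

    def test_mean_matches_brute_force(self, rng):
        g = synthetic.generate_gene_dataset(
            synthetic.SyntheticConfig(), "GRP", seed=9
        )
        pa, pb = g.divergence_panel_A, g.divergence_panel_B
        pairs = [
            ng86_pairwise(a, b)
            for a, b in itertools.product(pa.sequences, pb.sequences)
        ]
        d = mean_cross_type_omega(pa, pb)
        assert d.dN == pytest.approx(np.mean([p.dN for p in pairs]))
        omegas = [p.omega for p in pairs if p.omega is not None]
        assert d.omega == pytest.approx(np.mean(omegas))


class TestCandidateRule:
    @pytest.mark.parametrize(
        "omega,expected", [(0.618, True), (0.366, False), (0.5, False)]
    )
    def test_strict_threshold(self, omega, expected):
        assert classify_candidate(omega) is expected

    def test_undefined_not_classifiable(self):
        with pytest.raises(ValueError):
            classify_candidate(None)


class TestMannWhitney:
    def test_exact_enumeration_extreme(self):
        # all C(6,3)=20 labelings; perfectly separated groups -> p = 1/20
        _, p = mann_whitney_one_tailed([4, 5, 6], [1, 2, 3])
        assert p == pytest.approx(1 / 20)

    def test_exact_small(self):
        _, p = mann_whitney_one_tailed([3, 4], [1, 2])
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney_one_tailed([1, 2, 3, 7], [1, 2, 3, 7])
        assert p >= 0.5

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning):
            _, p = mann_whitney_one_tailed([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self):
        # oracle: enumerate all labelings of the pooled values
        grp, ctl = [0.9, 0.7, 0.4], [0.3, 0.5]
        pooled = grp + ctl
        n1 = len(grp)
        u_obs = sum((a > b) + 0.5 * (a == b) for a in grp for b in ctl)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            g = [pooled[i] for i in combo]
            c = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = sum((a > b) + 0.5 * (a == b) for a in g for b in c)
            total += 1
            count += u >= u_obs
        _, p = mann_whitney_one_tailed(grp, ctl)
        assert p == pytest.approx(count / total)


class TestEstimatorRecovery:
    @pytest.mark.parametrize("omega_true", [0.25, 1.0])
    def test_mean_omega_within_twenty_percent(self, omega_true):
        """Cross-type NG86 omega recovers the generator's acceptance multiplier."""
        cfg = synthetic.SyntheticConfig(
            omega_grp=omega_true, omega_control=omega_true
        )
        vals = []
        for rep in range(50):
            g = synthetic.generate_gene_dataset(cfg, "GRP", seed=3000 + rep)
            d = mean_cross_type_omega(g.divergence_panel_A, g.divergence_panel_B)
            if d.omega is not None:
                vals.append(d.omega)
        assert abs(np.mean(vals) - omega_true) <= 0.2 * omega_true
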