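import json

import numpy as np
import pytest

from mutfold import (
    FoldingParams,
    ScanConfig,
    apply_mutations,
    background_scores,
    build_impact_report,
    empirical_pvalue,
    ensemble_relative_entropy,
    make_fixture_sequences,
    pair_probabilities_global,
    parse_mutation_code,
    region_distance_scan,
    validate_sequence,
)
from tests.conftest import relent_bruteforce

E = np.e

# closed form for GAAAC -> GAAAU under toy-pairtype (GC e^3 vs GU e^1):
# common space = {open, (1,5)}; both ensembles fully covered
_Q_WT = np.array([1, E**3]) / (1 + E**3)
_Q_MUT = np.array([1, E]) / (1 + E)
D_GAAAC_C5U = float(np.sum(_Q_WT * np.log(_Q_WT / _Q_MUT)))


class TestRelativeEntropy:
    def test_identical_sequences(self, all_models):
        seq = validate_sequence("GGAAACC")
        for model in all_models:
            res = ensemble_relative_entropy(seq, seq, model)
            assert res.d_common == 0.0
            assert res.coverage_wt == res.coverage_mut == 1.0
            assert not res.infinite_flag

    def test_gaaac_to_gaaau_closed_form(self, pairtype):
        res = ensemble_relative_entropy(
            validate_sequence("GAAAC"), validate_sequence("GAAAU"), pairtype
        )
        assert res.d_common == pytest.approx(D_GAAAC_C5U, abs=1e-9)
        assert res.coverage_wt == pytest.approx(1.0, abs=1e-12)
        assert res.coverage_mut == pytest.approx(1.0, abs=1e-12)
        assert not res.infinite_flag
        assert res.d_bits == pytest.approx(res.d_common / np.log(2))

    def test_lost_support_flags_infinity(self, uniform):
        res = ensemble_relative_entropy(
            validate_sequence("GAAAC"), validate_sequence("AAAAC"), uniform
        )
        assert res.d_common == 0.0  # common space is the open chain only
        assert res.coverage_wt == pytest.approx(1 / (1 + E), abs=1e-12)
        assert res.coverage_mut == pytest.approx(1.0, abs=1e-12)
        assert res.infinite_flag

    def test_dp_matches_enumeration(self, all_models):
        """DP relative entropy equals the brute-force common-space oracle."""
        rng = np.random.default_rng(5)
        cases = 0
        for k in range(40):
            seq = make_fixture_sequences(2000 + k, 1, int(rng.integers(9, 14)))[0]
            pos = int(rng.integers(1, seq.n + 1))
            ref = seq.base(pos)
            alt = str(rng.choice([b for b in "ACGU" if b != ref]))
            mut = apply_mutations(seq, parse_mutation_code(f"{ref}{pos}{alt}"))
            for model in all_models:
                res = ensemble_relative_entropy(seq, mut, model)
                d_bf, cov_bf = relent_bruteforce(seq, mut, model)
                assert res.d_common == pytest.approx(d_bf, abs=1e-9)
                assert res.coverage_wt == pytest.approx(cov_bf, abs=1e-9)
                cases += 1
        assert cases == 120

    def test_length_mismatch_rejected(self, uniform):
        with pytest.raises(ValueError, match="length mismatch"):
            ensemble_relative_entropy(
                validate_sequence("GAAAC"), validate_sequence("GAAACA"), uniform
            )


class TestRegionScan:
    def test_identical_matrices(self, uniform):
        P = pair_probabilities_global(validate_sequence("GGAAACCAAGG"), uniform)
        scan = region_distance_scan(P, P, window_lengths=[5, 8], step=1)
        assert scan.d_max == 0.0
        assert scan.r_min == 1.0
        # tie-break: smallest start, then smallest length
        assert scan.best_d_interval == (1, 5)
        assert scan.best_r_interval == (1, 5)

    def test_single_lost_pair(self, uniform):
        wt = pair_probabilities_global(validate_sequence("GAAAC"), uniform)
        mut = pair_probabilities_global(validate_sequence("AAAAC"), uniform)
        scan = region_distance_scan(wt, mut, window_lengths=[5], step=1)
        assert scan.best_d_interval == (1, 5)
        assert scan.d_max == pytest.approx(E / (1 + E), abs=1e-12)
        # WT vector has variance, mutant is all-zero => r = 0 by convention
        assert scan.r_min == 0.0

    def test_full_length_window_is_whole_matrix_distance(self, uniform):
        wt = pair_probabilities_global(validate_sequence("GGAAACCAAGG"), uniform)
        mut = pair_probabilities_global(validate_sequence("GGAAACCAAGA"), uniform)
        scan = region_distance_scan(wt, mut, window_lengths=[wt.n], step=1)
        iu = np.triu_indices(wt.n, k=1)
        expected = np.sqrt(np.sum((wt.P[iu] - mut.P[iu]) ** 2))
        assert scan.d_max == pytest.approx(expected, abs=1e-12)

    def test_d_max_monotone_in_window_lengths(self, uniform):
        wt = pair_probabilities_global(validate_sequence("GGGAAACGAAACCC"), uniform)
        mut = pair_probabilities_global(validate_sequence("GGGAAACGAAACCA"), uniform)
        d_vals = []
        for lengths in ([6], [6, 10], [6, 10, 14]):
            scan = region_distance_scan(wt, mut, window_lengths=lengths, step=1)
            d_vals.append(scan.d_max)
        assert d_vals == sorted(d_vals)

    def test_window_too_small_rejected(self, uniform):
        P = pair_probabilities_global(validate_sequence("GAAAC"), uniform)
        with pytest.raises(ValueError, match=">= 4"):
            region_distance_scan(P, P, window_lengths=[3], step=1)


@pytest.fixture(scope="module")
def small_background(uniform):
    wt = validate_sequence("GAAAC")
    config = ScanConfig(model=uniform, window_lengths=(5,), step=1)
    return wt, config, background_scores(wt, config)


class TestEmpiricalPvalue:
    def test_background_size_is_3n(self, small_background):
        wt, config, bg = small_background
        assert len(bg) == 3 * wt.n == 15

    def test_observed_above_all_background(self, small_background):
        wt, config, bg = small_background
        big = max(d for d, _ in bg.values()) + 1.0
        p, size = empirical_pvalue(big, wt, config, "d", background=bg)
        assert size == 15
        assert p == pytest.approx(1 / 16)

    def test_observed_at_background_minimum(self, small_background):
        wt, config, bg = small_background
        small = min(d for d, _ in bg.values())
        p, _ = empirical_pvalue(small, wt, config, "d", background=bg)
        assert p == 1.0

    def test_mode_r_uses_lower_tail(self, small_background):
        wt, config, bg = small_background
        below = min(r for _, r in bg.values()) - 0.5
        p, _ = empirical_pvalue(below, wt, config, "r", background=bg)
        assert p == pytest.approx(1 / 16)

    def test_self_exclusion_for_background_members(self, small_background):
        # excluding a mutation's own background entry removes exactly its
        # one self-count; the denominator stays 3n + 1
        wt, config, bg = small_background
        best = max(bg, key=lambda c: bg[c][0])
        p_excl, _ = empirical_pvalue(
            bg[best][0], wt, config, "d", exclude=best, background=bg
        )
        p_incl, _ = empirical_pvalue(bg[best][0], wt, config, "d", background=bg)
        assert p_incl == pytest.approx(p_excl + 1 / 16)
        ties = sum(d >= bg[best][0] for d, _ in bg.values()) - 1
        assert p_excl == pytest.approx((1 + ties) / 16)


class TestImpactReport:
    def test_identity_mutation_null(self, uniform):
        wt = validate_sequence("GAAAC")
        report = build_impact_report(
            wt, parse_mutation_code("A3A"), uniform,
            window_lengths=(5,), step=1,
        )
        assert report.relent.d_common == 0.0
        assert report.scan.d_max == 0.0
        assert report.scan.p_d == 1.0

    def test_worked_example_relative_entropy(self, pairtype):
        report = build_impact_report(
            validate_sequence("GAAAC"), parse_mutation_code("C5U"), pairtype,
            window_lengths=(5,), step=1,
        )
        assert report.relent.d_common == pytest.approx(D_GAAAC_C5U, abs=1e-9)

    def test_report_json_round_trip(self, pairtype):
        report = build_impact_report(
            validate_sequence("GGAAACC"), parse_mutation_code("G2A"), pairtype,
            window_lengths=(7,), step=1,
        )
        payload = report.to_dict()
        assert json.loads(json.dumps(payload)) == payload
        assert payload["mutation"] == "G2A"
        assert payload["region_scan"]["background_size"] == 21
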