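from itertools import product

import numpy as np
import pytest

from vdlin.errors import ConfigurationError, EmptyInputError, SchemaError
from vdlin.screen import (
    PrimaryCriteria,
    ScoreBreakdown,
    ScreenResult,
    hard_score,
    permutation_null_scores,
    primary_screen,
    rank_candidates,
    results_to_frame,
    screen_library,
    secondary_screen,
    soft_score,
)

ALL_SIGN_PATTERNS = list(product((-1, 0, 1), repeat=10))  # 3^10 = 59049


def oracle_score(pattern):
    """Independent loop-and-count indicator oracle."""
    score = 0
    for i in range(5):
        if pattern[i] > 0:
            score += 10
    for j in range(5, 10):
        if pattern[j] < 0:
            score += 10
    return score


class TestHardScore:
    def test_ideal_profile_scores_100(self):
        delta = np.array([1.0] * 5 + [-1.0] * 5)
        assert hard_score(delta).total_score == 100

    def test_null_profile_scores_0(self):
        assert hard_score(np.zeros(10)).total_score == 0

    def test_single_ifn_gene_scores_10(self):
        delta = np.zeros(10)
        delta[1] = 1.0
        b = hard_score(delta)
        assert (b.ifn_up_count, b.inflame_down_count, b.total_score) == (1, 0, 10)

    def test_three_up_two_down_scores_50(self):
        delta = np.array([1, 1, 1, 0, 0, -1, -1, 0, 0, 0], dtype=float)
        assert hard_score(delta).total_score == 50

    def test_exhaustive_oracle_equivalence(self):
        for pattern in ALL_SIGN_PATTERNS:
            got = hard_score(np.array(pattern, dtype=float)).total_score
            assert got == oracle_score(pattern)

    def test_scores_are_multiples_of_ten(self, rng):
        for _ in range(200):
            s = hard_score(rng.normal(size=10)).total_score
            assert s in set(range(0, 101, 10))

    def test_antisymmetry_on_zero_free_delta(self, rng):
        for _ in range(200):
            d = rng.normal(size=10)
            d[d == 0] = 0.1
            assert hard_score(d).total_score + hard_score(-d).total_score == 100

    def test_score_70_implies_two_per_class(self):
        # pigeonhole, checked exhaustively
        for pattern in ALL_SIGN_PATTERNS:
            b = hard_score(np.array(pattern, dtype=float))
            if b.total_score >= 70:
                assert b.ifn_up_count >= 2 and b.inflame_down_count >= 2

    def test_wrong_length_errors(self):
        with pytest.raises(SchemaError):
            hard_score(np.zeros(9))


class TestSoftScore:
    def test_all_zero_is_exactly_50(self):
        assert soft_score(np.zeros(10)) == pytest.approx(50.0, abs=1e-12)

    def test_large_beta_ideal_profile_near_100(self):
        delta = np.array([1.0] * 5 + [-1.0] * 5)
        assert soft_score(delta, temperature=1000.0) == pytest.approx(100.0, abs=1e-6)

    def test_symmetry_sums_to_100(self, rng):
        for _ in range(100):
            d = rng.normal(size=10)
            assert soft_score(d) + soft_score(-d) == pytest.approx(100.0, abs=1e-9)

    def test_converges_to_hard_score(self, rng):
        d = rng.normal(size=10)
        d[np.abs(d) < 0.05] = 0.2
        hard = hard_score(d).total_score
        assert soft_score(d, temperature=1e4) == pytest.approx(hard, abs=1e-6)

    def test_bad_temperature_errors(self):
        with pytest.raises(ConfigurationError):
            soft_score(np.zeros(10), temperature=0.0)


def _breakdowns(scores):
    out = []
    for s in scores:
        up = min(s // 10, 5)
        down = s // 10 - up
        out.append(ScoreBreakdown(ifn_up_count=up, inflame_down_count=down))
    assert [b.total_score for b in out] == list(scores)
    return out


class TestPrimaryScreen:
    def test_threshold_only(self):
        crit = PrimaryCriteria(sd_multiplier=0.0)
        flags = primary_screen(
            _breakdowns([100, 80, 60]), crit, background_scores=np.array([0.0])
        )
        assert flags == [True, True, False]

    def test_all_zero_scores_none_pass(self):
        crit = PrimaryCriteria(sd_multiplier=0.0)
        assert primary_screen(_breakdowns([0, 0, 0]), crit) == [False, False, False]

    def test_sd_clause_overrides_threshold(self):
        # background mean 50, population SD 10 -> cutoff 85; 80 fails despite >= 70
        bg = np.array([40.0, 60.0])
        flags = primary_screen(_breakdowns([80]), PrimaryCriteria(), background_scores=bg)
        assert flags == [False]
        flags = primary_screen(_breakdowns([90]), PrimaryCriteria(), background_scores=bg)
        assert flags == [True]

    def test_empty_input_errors(self):
        with pytest.raises(EmptyInputError):
            primary_screen([], PrimaryCriteria())

    def test_monotone_in_satisfied_indicators(self):
        crit = PrimaryCriteria(sd_multiplier=0.0)
        bg = np.array([0.0])
        for s in range(0, 100, 10):
            lo = primary_screen(_breakdowns([s]), crit, background_scores=bg)[0]
            hi = primary_screen(_breakdowns([s + 10]), crit, background_scores=bg)[0]
            assert hi >= lo


class TestSecondaryScreen:
    def test_three_three_passes(self):
        d = np.array([1, 1, 1, 0, 0, -1, -1, -1, 0, 0], dtype=float)
        assert secondary_screen(d) == [True]

    def test_five_down_two_up_scores_70_but_fails(self):
        d = np.array([1, 1, 0, 0, 0, -1, -1, -1, -1, -1], dtype=float)
        assert hard_score(d).total_score == 70
        assert secondary_screen(d) == [False]

    def test_five_five_passes(self):
        d = np.array([1.0] * 5 + [-1.0] * 5)
        assert secondary_screen(d) == [True]

    def test_wrong_shape_errors(self):
        with pytest.raises(SchemaError):
            secondary_screen(np.zeros((2, 9)))

    def test_monotone(self):
        base = np.array([1, 1, 1, 0, 0, -1, -1, -1, 0, 0], dtype=float)
        assert secondary_screen(base) == [True]
        better = base.copy()
        better[3] = 1.0
        assert secondary_screen(better) == [True]


class TestRankCandidates:
    @staticmethod
    def _result(cid, score, primary=True, secondary=True):
        up = min(score // 10, 5)
        return ScreenResult(
            cid,
            ScoreBreakdown(up, score // 10 - up),
            passes_primary=primary,
            passes_secondary=secondary,
        )

    def test_fail_secondary_excluded(self):
        results = [
            self._result("A", 100),
            self._result("B", 80),
            self._result("C", 90, secondary=False),
        ]
        ranked = rank_candidates(results)
        assert [r.compound_id for r in ranked] == ["A", "B"]
        assert [r.rank for r in ranked] == [1, 2]
        assert results[2].rank is None

    def test_no_dual_pass_empty(self):
        assert rank_candidates([self._result("A", 90, primary=False)]) == []

    def test_tie_broken_by_id(self):
        ranked = rank_candidates([self._result("B", 90), self._result("A", 90)])
        assert [r.compound_id for r in ranked] == ["A", "B"]

    def test_dense_ranks(self):
        ranked = rank_candidates(
            [self._result(c, s) for c, s in [("a", 100), ("b", 90), ("c", 90), ("d", 70)]]
        )
        assert [r.rank for r in ranked] == [1, 2, 3, 4]


class TestScreenLibrary:
    def test_end_to_end_summary(self, rng):
        deltas = rng.normal(size=(50, 10))
        deltas[:5] = np.array([1.0] * 5 + [-1.0] * 5)  # plant ideal profiles
        ids = [f"c{i:02d}" for i in range(50)]
        results, summary = screen_library(ids, deltas, PrimaryCriteria(sd_multiplier=2.0))
        frame = results_to_frame(results)
        assert summary["n_compounds"] == 50
        assert summary["n_ranked"] == len([r for r in results if r.rank is not None])
        assert set(frame.columns) >= {"compound_id", "score", "rank"}

    def test_permutation_null_preserves_gene_marginals(self, rng):
        deltas = rng.normal(size=(40, 10))
        null = permutation_null_scores(deltas, seed=1)
        assert null.shape == (40,)
        assert set(null) <= set(range(0, 101, 10))

    def test_id_count_mismatch_errors(self, rng):
        with pytest.raises(SchemaError):
            screen_library(["a"], rng.normal(size=(2, 10)))
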