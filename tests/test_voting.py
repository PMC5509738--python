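import numpy as np
import pandas as pd
import pytest

from jointcov import (DEFAULT_VOTE_TABLE, accumulate, euclidean_rank_screen,
                      round_scores, select_candidates, vote)
from jointcov.errors import ScreenError, ValidationError
from jointcov.voting import ascending_ranks


class TestVote:
    @pytest.mark.parametrize("rank,expected", [
        (1, 20), (2, 20), (3, 20),
        (4, 15), (5, 15),
        (6, 10), (10, 10),
        (11, 5), (15, 5),
        (16, 1), (17, 1), (20, 1),
        (21, 0), (100, 0),
    ])
    def test_band_map(self, rank, expected):
        assert vote(rank) == expected

    def test_rank_zero_rejected(self):
        with pytest.raises(ValidationError):
            vote(0)


class TestAscendingRanks:
    def test_ties_break_on_secondary_then_position(self):
        p = np.array([0.1, 0.1, 0.2, 0.1])
        e = np.array([0.3, 0.2, 0.1, 0.2])
        ranks = ascending_ranks(p, e)
        # p ties at 0.1: err orders (idx1, idx3 tie at 0.2 -> position), idx0
        np.testing.assert_array_equal(ranks, [3, 1, 4, 2])

    def test_permutation_of_inputs_permutes_ranks(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        e = rng.random(30)
        ranks = ascending_ranks(p, e)
        perm = rng.permutation(30)
        ranks_p = ascending_ranks(p[perm], e[perm])
        np.testing.assert_array_equal(ranks_p, ranks[perm])


class TestRoundScores:
    def test_spec_band_combinations(self):
        # ranks (p, err): (2, 4) -> 35; (20, 20) -> 2; off-gate -> 0
        p = np.array([0.02, 0.5])
        e = np.array([0.1, 0.4])
        scores, rp, re = round_scores(p, e)
        assert rp[0] == 1 and re[0] == 1
        assert scores[0] == 40

    def test_gate_zeroes_when_either_rank_above_twenty(self):
        F = 30
        p = np.linspace(0.01, 0.99, F)
        e = np.linspace(0.99, 0.01, F)  # best err = worst p
        scores, rp, re = round_scores(p, e)
        for s, a, b in zip(scores, rp, re):
            if a > 20 or b > 20:
                assert s == 0
            else:
                assert s == vote(a) + vote(b)

    def test_hand_built_votes(self):
        # construct ranks directly through values: 25 features, feature k has
        # p-rank k+1; err equal so err ranks follow p (tie-break on p)
        p = np.arange(25) / 100.0
        e = np.zeros(25)
        scores, rp, re = round_scores(p, e)
        np.testing.assert_array_equal(rp, np.arange(1, 26))
        np.testing.assert_array_equal(re, np.arange(1, 26))
        assert scores[1] == 40          # rank 2 on both
        assert scores[3] == 30          # rank 4 on both
        assert scores[19] == 2          # rank 20 on both
        assert scores[20] == 0          # rank 21: off gate

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        e = rng.random(40)
        scores, _, _ = round_scores(p, e)
        perm = rng.permutation(40)
        scores_p, _, _ = round_scores(p[perm], e[perm])
        np.testing.assert_array_equal(scores_p, scores[perm])

    def test_dominance_monotonicity(self):
        rng = np.random.default_rng(9)
        p = rng.random(30)
        e = rng.random(30)
        scores, _, _ = round_scores(p, e)
        # improving feature 0 to dominate everything can only raise its score
        p2 = p.copy(); e2 = e.copy()
        p2[0] = -1.0; e2[0] = -1.0
        scores2, _, _ = round_scores(p2, e2)
        assert scores2[0] >= scores[0]
        assert scores2[0] == 40


class TestSelectCandidates:
    def test_threshold_is_strict(self):
        df = pd.DataFrame({"feature": ["a", "b"], "total_score": [200, 201]})
        out = select_candidates(df, rounds=100, threshold=200)
        assert list(out["feature"]) == ["b"]

    def test_threshold_scales_with_rounds(self):
        df = pd.DataFrame({"feature": ["a", "b"], "total_score": [100, 101]})
        out = select_candidates(df, rounds=50)  # threshold 2 * 50 = 100
        assert list(out["feature"]) == ["b"]


class TestAccumulate:
    def test_single_full_round_consistent_with_round_scores(self, toy):
        trip, labels, _ = toy
        out = accumulate(trip, labels, individuals=list(trip.probe_ids),
                         rounds=1, fraction=1.0, B=99, n_splits=30, seed=0)
        df = out["individuals"]
        expect, _, _ = round_scores(df["p_perm"].to_numpy(),
                                    df["mean_error"].to_numpy())
        np.testing.assert_array_equal(df["total_score"].to_numpy(), expect)

    def test_strong_probe_attains_maximum(self, toy):
        trip, labels, manifest = toy
        rounds = 3
        out = accumulate(trip, labels, individuals=list(trip.probe_ids),
                         rounds=rounds, fraction=0.9, B=99, n_splits=30, seed=0)
        df = out["individuals"].set_index("feature")
        strong = manifest["marginal"][0]
        assert df.loc[strong, "total_score"] == 40 * rounds
        assert df["total_score"].idxmax() == strong

    def test_feature_order_invariance(self, toy):
        trip, labels, _ = toy
        ids = list(trip.probe_ids)
        a = accumulate(trip, labels, individuals=ids, rounds=2, fraction=0.9,
                       B=49, n_splits=20, seed=3)["individuals"]
        b = accumulate(trip, labels, individuals=ids[::-1], rounds=2,
                       fraction=0.9, B=49, n_splits=20, seed=3)["individuals"]
        a = a.set_index("feature")["total_score"]
        b = b.set_index("feature")["total_score"]
        assert a.sort_index().equals(b.sort_index())

    def test_pair_pool_ranked_separately(self, small_planted):
        trip, labels, manifest = small_planted
        pair = manifest["pairs"][0]
        out = accumulate(trip, labels,
                         individuals=[manifest["marginal"][0], manifest["null"][0]],
                         pairs=[pair, (manifest["null"][0], manifest["null"][1])],
                         rounds=2, fraction=0.9, B=49, n_splits=20, seed=0)
        assert set(out) == {"individuals", "pairs"}
        pr = out["pairs"]
        top = (pr.iloc[0]["feature_a"], pr.iloc[0]["feature_b"])
        assert top == pair

    def test_duplicate_pair_rejected(self, toy):
        trip, labels, _ = toy
        with pytest.raises(ValidationError):
            accumulate(trip, labels, pairs=[(trip.probe_ids[0], trip.probe_ids[0])],
                       rounds=1, fraction=1.0, B=9, n_splits=5, seed=0)

    def test_score_bounded_by_forty_per_round(self, toy):
        trip, labels, _ = toy
        rounds = 2
        out = accumulate(trip, labels, individuals=list(trip.probe_ids),
                         rounds=rounds, fraction=1.0, B=49, n_splits=20, seed=1)
        assert (out["individuals"]["total_score"] <= 40 * rounds).all()


class TestEuclideanRankScreen:
    def _records(self, p, e):
        return pd.DataFrame({
            "feature": [f"f{i}" for i in range(len(p))],
            "p_perm": p, "mean_error": e,
        })

    def test_all_identical_keeps_stable_order(self):
        df = self._records([0.1] * 4, [0.2] * 4)
        out = euclidean_rank_screen(df, top_p_fraction=1.0)
        assert list(out["feature"]) == ["f0", "f1", "f2", "f3"]

    def test_dominant_feature_ranks_first(self):
        df = self._records([0.01, 0.05, 0.2, 0.5], [0.05, 0.3, 0.2, 0.4])
        out = euclidean_rank_screen(df, top_p_fraction=1.0)
        assert out.iloc[0]["feature"] == "f0"

    def test_hand_computed_distances(self):
        p = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        e = np.array([0.4, 0.0, 0.2, 0.1, 0.4])
        df = self._records(p, e)
        out = euclidean_rank_screen(df, top_p_fraction=1.0)
        # normalisation is min-max on both axes; distances to the origin:
        d = np.hypot((p - 0) / 1.0, (e - 0) / 0.4)
        expect = [f"f{i}" for i in np.argsort(d, kind="stable")]
        assert list(out["feature"]) == expect
        np.testing.assert_allclose(np.sort(out["distance"]), np.sort(d))

    def test_small_subset_raises(self):
        df = self._records([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        with pytest.raises(ScreenError):
            euclidean_rank_screen(df, top_p_fraction=0.05)
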