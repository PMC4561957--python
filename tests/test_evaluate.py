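import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from mirbm import (
    AssociationRecord,
    EvaluationError,
    LeakageError,
    RBMParams,
    ScoreMatrix,
    TrainConfig,
    VisibleConfig,
    evaluate_holdout,
    init_params,
    loocv,
    rank_candidates,
    roc_auc,
    score_mirna,
    score_tensor,
    top_k_predictions,
    train,
)
from mirbm.datamodel import MultiTypeNetwork
import helpers_oracle as oracle


class TestScoreMirna:
    def test_half_at_zero_params(self):
        params = init_params(2, 2, 3, sd=0.0)
        obs = VisibleConfig.from_slice(np.zeros((2, 2), np.int8))
        assert np.allclose(score_mirna(params, obs).probs, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_straight_line_oracle(self, seed):
        """probs = sigma(a + W . sigma(b + W^T v + D^T r)) computed by an
        independent flat calculation."""
        rng = np.random.default_rng(seed)
        n, t, m = 3, 2, 4
        params = init_params(n, t, m, sd=0.4, seed=rng)
        v = rng.integers(0, 2, (n, t)).astype(np.int8)
        obs = VisibleConfig.from_slice(v)
        got = score_mirna(params, obs).probs

        W2 = params.W.reshape(n * t, m)
        h = 1.0 / (1.0 + np.exp(-(params.b + W2.T @ v.reshape(-1) + params.D.T @ obs.r)))
        want = (1.0 / (1.0 + np.exp(-(params.a.reshape(-1) + W2 @ h)))).reshape(n, t)
        assert np.allclose(got, want, atol=1e-12)

    def test_monotone_in_visible_bias(self):
        rng = np.random.default_rng(2)
        params = init_params(2, 2, 3, sd=0.3, seed=rng)
        obs = VisibleConfig.from_slice(rng.integers(0, 2, (2, 2)).astype(np.int8))
        base = score_mirna(params, obs).probs[1, 0]
        a2 = params.a.copy()
        a2[1, 0] += 0.7
        bumped = RBMParams(W=params.W, a=a2, b=params.b, D=params.D)
        assert score_mirna(bumped, obs).probs[1, 0] > base

    def test_invariant_under_disease_permutation(self):
        rng = np.random.default_rng(7)
        n, t, m = 4, 2, 3
        params = init_params(n, t, m, sd=0.4, seed=rng)
        v = rng.integers(0, 2, (n, t)).astype(np.int8)
        perm = rng.permutation(n)
        probs = score_mirna(params, VisibleConfig.from_slice(v)).probs
        p_perm = RBMParams(
            W=params.W[perm], a=params.a[perm], b=params.b, D=params.D[perm]
        )
        probs_perm = score_mirna(p_perm, VisibleConfig.from_slice(v[perm])).probs
        assert np.allclose(probs[perm], probs_perm, atol=1e-14)


def simple_net():
    # 2 diseases x 2 miRNAs x 1 type with a single known triple
    tensor = np.zeros((2, 2, 1), np.int8)
    tensor[0, 0, 0] = 1
    return MultiTypeNetwork(["dA", "dB"], ["m1", "m2"], ["target"], tensor)


class TestRankCandidates:
    def make_scores(self, values):
        return np.asarray(values, dtype=float).reshape(2, 2, 1)

    def test_highest_score_ranks_first(self):
        net = simple_net()
        scores = self.make_scores([[0.1, 0.9], [0.2, 0.3]])
        rank, n_cand = rank_candidates(
            scores, net, AssociationRecord("m2", "dA", "target")
        )
        assert rank == 1.0
        assert n_cand == 2  # (dB,m1) and (dB,m2); known cell excluded

    def test_lowest_score_ranks_last(self):
        net = simple_net()
        scores = self.make_scores([[0.9, 0.01], [0.2, 0.3]])
        rank, n_cand = rank_candidates(
            scores, net, AssociationRecord("m2", "dA", "target")
        )
        assert rank == n_cand + 1 == 3

    def test_tie_at_top_gets_average_rank(self):
        net = simple_net()
        scores = self.make_scores([[0.1, 0.7], [0.7, 0.3]])
        rank, _ = rank_candidates(
            scores, net, AssociationRecord("m2", "dA", "target")
        )
        assert rank == 1.5
        rank_min, _ = rank_candidates(
            scores, net, AssociationRecord("m2", "dA", "target"), ties="min"
        )
        assert rank_min == 1.0

    def test_known_test_triple_is_leakage(self):
        net = simple_net()
        scores = self.make_scores([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(LeakageError):
            rank_candidates(scores, net, AssociationRecord("m1", "dA", "target"))

    def test_score_matrix_collection_input(self):
        net = simple_net()
        sms = [
            ScoreMatrix("m1", np.full((2, 1), 0.4)),
            ScoreMatrix("m2", np.array([[0.9], [0.1]])),
        ]
        rank, n_cand = rank_candidates(sms, net, AssociationRecord("m2", "dA", "target"))
        assert rank == 1.0 and n_cand == 2


class TestRocAuc:
    def test_perfect_ranking(self):
        curve = roc_auc([(1, 10)] * 5)
        assert curve.auc == pytest.approx(1.0, abs=1e-12)
        assert curve.fpr[0] == 0 and curve.fpr[-1] == 1
        assert curve.tpr[0] == 0 and curve.tpr[-1] == 1

    def test_uniform_ranks_approach_half(self):
        n_cand = 1000
        ranks = [(r, n_cand) for r in range(1, n_cand + 2)]
        assert roc_auc(ranks).auc == pytest.approx(0.5, abs=1e-3)

    def test_matches_threshold_sweep_oracle(self):
        ranks = [(1, 4), (3, 4)]
        assert roc_auc(ranks).auc == pytest.approx(
            oracle.auc_threshold_sweep(ranks), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([])

    def test_single_fold_matches_sklearn(self):
        """Rank-based AUC for one held-out triple equals scikit-learn's
        roc_auc_score on the pooled (test vs candidate) scores."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        net = simple_net()
        scores = rng.random((2, 2, 1)) * 0.98 + 0.01
        test = AssociationRecord("m2", "dA", "target")
        rank, n_cand = rank_candidates(scores, net, test)
        got = roc_auc([(rank, n_cand)]).auc

        mask = net.tensor == 0
        mask[net.triple_index(test)] = False
        i, u, k = net.triple_index(test)
        y = np.r_[1, np.zeros(n_cand)]
        s = np.r_[scores[i, u, k], scores[mask]]
        assert got == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    @given(
        st.lists(
            st.tuples(st.integers(1, 51), st.just(50)), min_size=1, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rank_sum_identity(self, ranks):
        """Trapezoidal AUC equals 1 - mean((rank-1)/candidates) exactly."""
        curve = roc_auc(ranks)
        want = 1.0 - np.mean([(r - 1) / nc for r, nc in ranks])
        assert curve.auc == pytest.approx(want, abs=1e-10)

    @given(
        st.lists(
            st.tuples(st.integers(1, 101), st.just(100)), min_size=2, max_size=20
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_curve_is_monotone_step_from_origin(self, ranks):
        curve = roc_auc(ranks)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)


class TestLoocv:
    def test_full_mode_on_tiny_network(self, tiny_net):
        cfg = TrainConfig(hidden_units=2, epochs=10, seed=0)
        result = loocv(tiny_net, cfg, mode="full")
        assert 0.0 <= result.auc <= 1.0
        assert len(result.records) == tiny_net.n_associations
        for _, row in result.records.iterrows():
            assert 1 <= row["rank"] <= row["candidates"] + 1

    def test_fast_mode_agrees_in_shape_and_is_deterministic(self, tiny_net):
        cfg = TrainConfig(hidden_units=2, epochs=10, seed=0)
        r1 = loocv(tiny_net, cfg, mode="fast")
        r2 = loocv(tiny_net, cfg, mode="fast")
        assert r1.records.equals(r2.records)
        assert r1.mode == "fast"

    def test_undersized_network_rejected(self):
        net = simple_net()
        with pytest.raises(EvaluationError):
            loocv(net, TrainConfig())

    def test_random_scorer_near_half(self, tiny_net):
        rng = np.random.default_rng(0)

        def scorer(net, fold):
            return rng.random(net.tensor.shape) * 0.999998 + 1e-6

        result = loocv(tiny_net, score_fn=scorer)
        assert 0.0 <= result.auc <= 1.0
        assert result.mode == "custom"


class TestEvaluateHoldout:
    def test_matches_per_fold_rank_candidates(self, tiny_net):
        """The vectorised hold-out ranker gives the same ranks as ranking
        each held-out triple independently."""
        held_idx = np.argwhere(tiny_net.tensor == 1)[:2]
        train_net = tiny_net.copy()
        held = []
        for i, u, k in held_idx:
            train_net.tensor[i, u, k] = 0
            held.append(
                AssociationRecord(
                    tiny_net.mirna_ids[u], tiny_net.disease_ids[i], tiny_net.type_ids[k]
                )
            )
        cfg = TrainConfig(hidden_units=2, epochs=5, seed=1)
        result = evaluate_holdout(train_net, held, cfg)

        params, _ = train(train_net, cfg)
        scores = score_tensor(params, train_net)
        # mask other held triples out of the candidate set before comparing
        ref_net = train_net.copy()
        for rec, (_, row) in zip(held, result.records.iterrows()):
            others = [h for h in held if h != rec]
            masked = ref_net.copy()
            for o in others:
                masked.tensor[masked.triple_index(o)] = 1  # exclude from candidates
            rank, n_cand = rank_candidates(scores, masked, rec)
            assert row["rank"] == rank
            assert row["candidates"] == n_cand

    def test_leaked_holdout_rejected(self, tiny_net):
        rec = tiny_net.records()[0]
        with pytest.raises(LeakageError):
            evaluate_holdout(tiny_net, [rec], TrainConfig(hidden_units=2, epochs=1))


class TestTopK:
    def test_unique_maximum_is_first(self):
        net = simple_net()
        scores = np.array([[0.1, 0.9], [0.2, 0.3]]).reshape(2, 2, 1)
        params = init_params(2, 1, 2, sd=0.0)
        table = top_k_predictions(net, params, k=1, scores=scores)
        assert len(table) == 1
        assert tuple(table.iloc[0][["mirna", "disease", "type"]]) == (
            "m2", "dA", "target",
        )

    def test_known_triples_never_appear(self, tiny_net):
        params, _ = train(tiny_net, TrainConfig(hidden_units=2, epochs=5, seed=0))
        table = top_k_predictions(tiny_net, params, k=10_000)
        known = {(r.mirna, r.disease, r.assoc_type) for r in tiny_net.records()}
        got = {tuple(row) for row in table[["mirna", "disease", "type"]].itertuples(index=False)}
        assert not (known & got)

    def test_matches_full_sort_oracle(self, tiny_net):
        params, _ = train(tiny_net, TrainConfig(hidden_units=2, epochs=5, seed=0))
        scores = score_tensor(params, tiny_net)
        table = top_k_predictions(tiny_net, params, k=4, scores=scores)
        cand = [
            (
                float(scores[i, u, k]),
                tiny_net.mirna_ids[u],
                tiny_net.disease_ids[i],
                tiny_net.type_ids[k],
            )
            for i, u, k in np.argwhere(tiny_net.tensor == 0)
        ]
        cand.sort(key=lambda x: (-x[0], x[1], x[2], x[3]))
        want = [(m, d, t) for _, m, d, t in cand[:4]]
        got = [tuple(row) for row in table[["mirna", "disease", "type"]].itertuples(index=False)]
        assert got == want

    def test_oversized_k_returns_all_candidates(self, tiny_net):
        params, _ = train(tiny_net, TrainConfig(hidden_units=2, epochs=2, seed=0))
        n_cand = int((tiny_net.tensor == 0).sum())
        table = top_k_predictions(tiny_net, params, k=n_cand + 50)
        assert len(table) == n_cand

    def test_disease_restriction(self, tiny_net):
        params, _ = train(tiny_net, TrainConfig(hidden_units=2, epochs=2, seed=0))
        disease = tiny_net.disease_ids[0]
        table = top_k_predictions(tiny_net, params, k=100, disease=disease)
        assert (table["disease"] == disease).all()
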