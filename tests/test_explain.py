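import numpy as np
import pandas as pd
import pytest

from srna_augment import classify_dl, explain
from srna_augment.classify_dl import build_network, predict
from srna_augment.explain import (
    ablate_until_flip,
    class_average_scores,
    deeplift_attribute,
    pairwise_differences,
    per_sample_score_table,
    stability_similarity_matrices,
    top_n_features,
    topn_expression_summary,
)
from conftest import random_relu_net


def linear_model(W, b):
    W = np.asarray(W, dtype=float)
    net = build_network(W.shape[1], W.shape[0], hidden=[], dropout=[], seed=0)
    net.weights[0] = W.T
    net.biases[0] = np.asarray(b, dtype=float)
    return net


class TestDeepLift:
    def test_linear_closed_form(self):
        # out = Wx + b with W row (2, -1): C for x=(3,1) is (6, -1)
        net = linear_model([[2.0, -1.0], [0.5, 1.0]], [0.3, -0.2])
        t = deeplift_attribute(net, np.array([[3.0, 1.0]]))
        assert np.array_equal(t.scores[0, :, 0], [6.0, -1.0])
        assert np.array_equal(t.scores[0, :, 1], [1.5, 1.0])

    def test_reference_input_gives_zero_scores(self):
        net = random_relu_net(6, 3, [5, 4], seed=1)
        t = deeplift_attribute(net, np.zeros((1, 6)))
        assert np.array_equal(t.scores, np.zeros((1, 6, 3)))

    def test_summation_to_delta_two_layer(self):
        net = random_relu_net(12, 4, [10, 6], seed=2)
        X = np.random.default_rng(3).random((20, 12))
        t = deeplift_attribute(net, X)
        delta = net.logits(X) - net.logits(np.zeros(12))
        assert np.abs(t.scores.sum(axis=1) - delta).max() < 1e-5

    def test_summation_to_delta_nonzero_reference(self):
        net = random_relu_net(8, 3, [7], seed=4)
        rng = np.random.default_rng(5)
        ref = rng.random(8)
        X = rng.random((10, 8))
        t = deeplift_attribute(net, X, reference=ref)
        delta = net.logits(X) - net.logits(ref)
        assert np.abs(t.scores.sum(axis=1) - delta).max() < 1e-5

    def test_linear_network_equals_weight_times_input(self):
        rng = np.random.default_rng(6)
        W = rng.normal(size=(3, 5))
        net = linear_model(W, rng.normal(size=3))
        X = rng.random((7, 5))
        t = deeplift_attribute(net, X)
        for k in range(3):
            assert np.allclose(t.scores[:, :, k], X * W[k][None, :], atol=1e-12)

    def test_reference_width_checked(self):
        net = random_relu_net(4, 2, [3], seed=0)
        with pytest.raises(ValueError, match="reference"):
            deeplift_attribute(net, np.zeros((1, 4)), reference=np.zeros(9))


class TestClassAverageScores:
    def test_two_class_single_sample_collapse(self):
        C = np.random.default_rng(0).normal(size=(1, 4, 2))
        t = explain.AttributionTensor(
            scores=C, reference=np.zeros(4), ref_output=np.zeros(2),
            classes=np.array([0, 1]),
        )
        D1 = class_average_scores(t, [0])
        assert np.allclose(D1[:, 0], C[0, :, 0] - C[0, :, 1])
        assert np.all(np.isnan(D1[:, 1]))  # class 1 has no samples

    def test_identical_scores_give_zero(self):
        C = np.ones((3, 5, 4))
        t = explain.AttributionTensor(
            scores=C, reference=np.zeros(5), ref_output=np.zeros(4),
            classes=np.arange(4),
        )
        D1 = class_average_scores(t, [0, 1, 2])
        assert np.allclose(np.nan_to_num(D1), 0)

    def test_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        n, p, K = 12, 6, 3
        C = rng.normal(size=(n, p, K))
        y = rng.integers(0, K, n)
        t = explain.AttributionTensor(
            scores=C, reference=np.zeros(p), ref_output=np.zeros(K),
            classes=np.arange(K),
        )
        D1 = class_average_scores(t, y)
        for k in range(K):
            rows = [i for i in range(n) if y[i] == k]
            for j in range(p):
                vals = []
                for i in rows:
                    others = np.mean([C[i, j, kk] for kk in range(K) if kk != k])
                    vals.append(C[i, j, k] - others)
                assert D1[j, k] == pytest.approx(np.mean(vals))


class TestTopN:
    def test_n_larger_than_p_returns_all_ordered(self):
        D1 = np.array([[1.0, 0.0], [3.0, 0.0], [2.0, 0.0]])
        top = top_n_features(D1, [0, 1], ["a", "b", "c"], n=10)
        assert top[0] == ["b", "c", "a"]

    def test_one_hot_column_ranks_single_feature_first(self):
        D1 = np.zeros((5, 2))
        D1[3, 1] = 1.0
        top = top_n_features(D1, ["x", "y"], list("abcde"), n=2)
        assert top["y"][0] == "d"

    def test_ties_break_by_feature_order(self):
        D1 = np.zeros((4, 1))
        top = top_n_features(D1, ["k"], list("abcd"), n=4)
        assert top["k"] == list("abcd")


class TestTopNExpressionSummary:
    def test_single_sample_class(self):
        X = np.array([[0.1, 0.9], [0.4, 0.2]])
        top = {"A": ["f0", "f1"], "B": ["f1"]}
        out = topn_expression_summary(top, X, ["A", "B"], ["f0", "f1"])
        assert out.loc["A", "f0"] == 0.1
        assert out.loc["A", "f1"] == 0.9

    def test_brute_force_group_means(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 6))
        y = rng.choice(["A", "B"], size=20)
        fids = [f"f{i}" for i in range(6)]
        top = {"A": fids[:4], "B": fids[2:]}
        out = topn_expression_summary(top, X, y, fids)
        for cls in ("A", "B"):
            for f in out.columns:
                j = fids.index(f)
                assert out.loc[cls, f] == pytest.approx(X[y == cls, j].mean())

    def test_constant_feature_identical_means(self):
        X = np.ones((10, 2)) * 0.7
        y = np.array(["A"] * 5 + ["B"] * 5)
        out = topn_expression_summary({"A": ["f0"], "B": ["f0"]}, X, y, ["f0", "f1"])
        assert out.loc["A", "f0"] == out.loc["B", "f0"]


class TestPairwiseDifferences:
    def _tensor(self, C):
        return explain.AttributionTensor(
            scores=C, reference=np.zeros(C.shape[1]), ref_output=np.zeros(C.shape[2]),
            classes=np.arange(C.shape[2]),
        )

    def test_equal_scores_zero_and_feature_order(self):
        C = np.ones((1, 4, 2))
        order, d2 = pairwise_differences(self._tensor(C), 0, 0, 1)
        assert np.allclose(d2, 0)
        assert order.tolist() == [0, 1, 2, 3]

    def test_two_feature_order(self):
        C = np.zeros((1, 2, 2))
        C[0, :, 0] = [5.0, -1.0]
        order, d2 = pairwise_differences(self._tensor(C), 0, 0, 1)
        assert order.tolist() == [0, 1]
        assert d2.tolist() == [5.0, -1.0]

    def test_sort_matches_brute_force(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(2, 15, 3))
        t = self._tensor(C)
        order, d2 = pairwise_differences(t, 1, 2, 0)
        brute = sorted(range(15), key=lambda j: (-d2[j], j))
        assert order.tolist() == brute

    def test_same_class_rejected(self):
        C = np.zeros((1, 2, 2))
        with pytest.raises(ValueError):
            pairwise_differences(self._tensor(C), 0, 1, 1)


class TestAblation:
    def test_single_decisive_feature(self):
        # class 0 wins iff feature 0 is on
        net = linear_model([[4.0, 0.0], [0.0, 1.0]], [0.0, 0.0])
        r = ablate_until_flip(
            net, np.array([1.0, 0.5]), np.array([0, 1]), k_source=0, mode="stability"
        )
        assert r.steps == 1 and not r.censored

    def test_wrong_initial_prediction_rejected(self):
        net = linear_model([[4.0, 0.0], [0.0, 1.0]], [0.0, 0.0])
        with pytest.raises(ValueError, match="does not predict"):
            ablate_until_flip(net, np.array([1.0, 0.5]), np.array([0]), k_source=1)

    def test_censoring_when_no_flip(self):
        # class 0 wins on the bias alone; zeroing everything cannot flip
        net = linear_model([[1.0], [1.0]], [5.0, 0.0])
        r = ablate_until_flip(net, np.array([1.0]), np.array([0]), k_source=0)
        assert r.censored and r.steps == r.cap == 1

    def test_stability_dominates_similarity(self):
        """Leaving k happens no later than reaching any specific rival."""
        rng = np.random.default_rng(4)
        net = random_relu_net(8, 3, [6], seed=5)
        X = rng.random((15, 8))
        t = deeplift_attribute(net, X)
        preds = predict(net, X)
        checked = 0
        for i in range(15):
            k = preds[i]
            for kp in net.classes_:
                if kp == k:
                    continue
                order, d2 = pairwise_differences(t, i, k, kp)
                order = order[d2[order] > 0]
                sim = ablate_until_flip(net, X[i], order, k, k_target=kp,
                                        mode="similarity")
                stab = ablate_until_flip(net, X[i], order, k, mode="stability")
                if not sim.censored:
                    assert stab.steps <= sim.steps
                    checked += 1
        assert checked > 0

    def test_chunked_path_equals_stepwise(self):
        """The batched ablation path must equal literal one-at-a-time zeroing."""
        rng = np.random.default_rng(6)
        net = random_relu_net(10, 3, [8], seed=7)
        x = rng.random(10)
        k = predict(net, x[None, :])[0]
        order = rng.permutation(10)
        r = ablate_until_flip(net, x, order, k, mode="stability", chunk=3)
        # brute force: fresh forward pass after each zeroing
        cur = x.copy()
        brute = None
        for step, j in enumerate(order, start=1):
            cur[j] = 0.0
            if predict(net, cur[None, :])[0] != k:
                brute = step
                break
        if brute is None:
            assert r.censored
        else:
            assert r.steps == brute and not r.censored


class TestStabilityMatrices:
    def test_shapes_two_class(self):
        # seed chosen so both classes are predicted on this input
        net = random_relu_net(6, 2, [5], seed=4)
        X = np.random.default_rng(104).random((12, 6))
        y = predict(net, X)  # everything "correct" by construction
        assert len(np.unique(y)) == 2
        t = deeplift_attribute(net, X)
        report = stability_similarity_matrices(net, X, y, t)
        assert report.similarity.shape == (2, 2)
        assert np.isnan(report.similarity[0, 0]) and np.isnan(report.similarity[1, 1])
        assert report.stability.shape == (2,)

    def test_never_flipping_model_reports_censoring(self):
        net = linear_model([[1.0, 1.0], [0.0, 0.0]], [5.0, 0.0])
        X = np.random.default_rng(10).random((4, 2))
        y = np.zeros(4, dtype=int)
        t = deeplift_attribute(net, X)
        report = stability_similarity_matrices(net, X, y, t)
        assert np.all(np.isnan(report.similarity[0]))
        assert np.isnan(report.stability[0])
        assert report.censored_stability[0] == 4

    def test_stability_bounded_by_similarity(self, tiny_trained_net):
        """Per run, leaving k cannot take longer than reaching k'; and on
        the shared (fully uncensored) sample set the class aggregates obey
        stability[k] <= min_k' similarity[k, k']."""
        net, X, y = tiny_trained_net
        sub = np.arange(0, len(y), 3)
        t = deeplift_attribute(net, X[sub])
        report = stability_similarity_matrices(net, X[sub], y[sub], t)
        logs = pd.DataFrame(report.sample_logs)
        assert len(logs)
        uncensored = logs[~logs["similarity_censored"] & ~logs["stability_censored"]]
        assert (uncensored["stability_steps"] <= uncensored["similarity_steps"]).all()
        # aggregate bound on samples with no censored run at all
        clean = logs.groupby("sample").filter(
            lambda g: not (g["similarity_censored"].any() or g["stability_censored"].any())
        )
        for cls, grp in clean.groupby("class"):
            stab = grp.groupby("sample")["stability_steps"].min().mean()
            sim_min = grp.groupby("rival")["similarity_steps"].mean().min()
            assert stab <= sim_min + 1e-12


class TestPerSampleTable:
    def test_shape_and_values(self):
        rng = np.random.default_rng(11)
        C = rng.normal(size=(3, 7, 2))
        t = explain.AttributionTensor(
            scores=C, reference=np.zeros(7), ref_output=np.zeros(2),
            classes=np.array(["a", "b"]),
        )
        df = per_sample_score_table(t, 1)
        assert df.shape == (7, 2)
        assert np.array_equal(df.to_numpy(), C[1])

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        C = rng.normal(size=(2, 5, 3))
        t = explain.AttributionTensor(
            scores=C, reference=np.zeros(5), ref_output=np.zeros(3),
            classes=np.arange(3), feature_ids=[f"f{i}" for i in range(5)],
        )
        df = per_sample_score_table(t, 0)
        p = tmp_path / "scores.tsv"
        df.to_csv(p, sep="\t", index_label="feature_id")
        back = pd.read_csv(p, sep="\t", index_col="feature_id")
        assert np.abs(back.to_numpy() - C[0]).max() < 1e-12

    def test_out_of_range_index(self):
        t = explain.AttributionTensor(
            scores=np.zeros((1, 2, 2)), reference=np.zeros(2),
            ref_output=np.zeros(2), classes=np.arange(2),
        )
        with pytest.raises(IndexError):
            per_sample_score_table(t, 5)


def test_conservation_across_many_random_networks():
    """Summation-to-delta property over a spread of architectures."""
    rng = np.random.default_rng(13)
    for seed in range(8):
        hidden = [int(rng.integers(3, 12)) for _ in range(int(rng.integers(1, 4)))]
        n_in = int(rng.integers(4, 15))
        K = int(rng.integers(2, 5))
        net = random_relu_net(n_in, K, hidden, seed=seed)
        X = rng.random((5, n_in))
        t = deeplift_attribute(net, X)
        delta = net.logits(X) - net.logits(np.zeros(n_in))
        assert np.abs(t.scores.sum(axis=1) - delta).max() < 1e-5
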