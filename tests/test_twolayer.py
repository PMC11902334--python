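"""Two-layer framework: kNN and discriminant against exhaustive oracles,
composition counting, tie contracts, and end-to-end model behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from impedquant import (InputError, SplitSpec, composition_features,
                        fit_discriminant, fit_knn, fit_two_layer, load_model,
                        null_regime, assay_regime, predict_discriminant,
                        predict_knn, predict_sample, save_model,
                        simulate_study)
from impedquant.resample import (MockExperiment, layer_split,
                                 make_training_mocks, train_test_split)
from impedquant.tables import make_peak_table
from impedquant.twolayer import KNN_COARSE_K


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_knn(train_x, train_y, query, k, class_order):
    """Exhaustive kNN with the documented tie rules, written from scratch."""
    mean, sd = train_x.mean(axis=0), train_x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    tz = (train_x - mean) / sd
    qz = (query - mean) / sd
    k = min(k, len(train_x))
    out_labels, out_scores = [], []
    for q in qz:
        d = np.sqrt(((tz - q) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        counts = {c: 0 for c in class_order}
        sums = {c: 0.0 for c in class_order}
        for i in nn:
            counts[train_y[i]] += 1
            sums[train_y[i]] += d[i]
        best = max(counts.values())
        cands = [c for c in class_order if counts[c] == best]
        if len(cands) > 1:
            m = min(sums[c] for c in cands)
            cands = [c for c in cands if sums[c] == m]
        out_labels.append(cands[0])
        out_scores.append([counts[c] / k for c in class_order])
    return np.array(out_labels), np.array(out_scores)


def closed_form_lda_posteriors(train_x, train_y, query, class_order):
    """Direct evaluation of the Gaussian shared-covariance posterior."""
    n, d = train_x.shape
    means = {c: train_x[train_y == c].mean(axis=0) for c in class_order}
    resid = np.vstack([train_x[train_y == c] - means[c] for c in class_order])
    cov = resid.T @ resid / (n - len(class_order))
    priors = {c: (train_y == c).mean() for c in class_order}
    post = []
    for q in query:
        logl = [stats.multivariate_normal.logpdf(q, means[c], cov,
                                                 allow_singular=True)
                + np.log(priors[c]) for c in class_order]
        logl = np.array(logl)
        logl -= logl.max()
        p = np.exp(logl)
        post.append(p / p.sum())
    return np.array(post)


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------

class TestKnn:
    def test_k_capped_at_training_size(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        model = fit_knn(x, y, k=100)
        _, scores = predict_knn(model, rng.normal(size=(5, 3)))
        # vote over all 40 points -> every query sees the global fractions
        assert np.allclose(scores, 0.5)

    def test_k1_returns_self_label(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        y = np.array(["a", "b", "c"])
        model = fit_knn(x, y, k=1)
        labels, scores = predict_knn(model, x)
        assert list(labels) == ["a", "b", "c"]
        assert np.allclose(scores.max(axis=1), 1.0)

    def test_tie_broken_by_class_order_for_equidistant_singletons(self):
        x = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array(["b", "a"])
        model = fit_knn(x, y, k=2)
        for _ in range(3):
            labels, scores = predict_knn(model, np.array([[0.0, 0.0]]))
            assert labels[0] == "a"  # counts and distances tie; "a" < "b"
            assert np.allclose(scores[0], [0.5, 0.5])

    def test_tie_broken_by_summed_neighbour_distance(self):
        # 1-D: class a at {0, 4}, class b at {1.9, -1.9}; query at 0.95 with
        # k=4 sees all points: counts tie 2-2, sum |d| a = 0.95+3.05 = 4.0,
        # b = 0.95+2.85 = 3.8 -> b wins
        x = np.array([[0.0], [4.0], [1.9], [-1.9]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_knn(x, y, k=4)
        labels, _ = predict_knn(model, np.array([[0.95]]))
        assert labels[0] == "b"

    def test_agrees_with_exhaustive_oracle_on_random_instances(self):
        """>= 100 random small instances: labels and score matrices match
        the from-scratch all-pairs-distance oracle exactly."""
        rng = np.random.default_rng(2024)
        for trial in range(110):
            n = int(rng.integers(5, 40))
            d = int(rng.integers(1, 5))
            k = int(rng.integers(1, 12))
            n_classes = int(rng.integers(2, 5))
            x = rng.normal(size=(n, d)).round(3)  # rounding invites ties
            y = rng.integers(0, n_classes, size=n)
            q = rng.normal(size=(6, d)).round(3)
            model = fit_knn(x, y, k=k)
            labels, scores = predict_knn(model, q)
            olabels, oscores = brute_knn(x, y, q, k, model.class_order)
            assert np.array_equal(labels, olabels), f"trial {trial}"
            assert np.allclose(scores, oscores), f"trial {trial}"

    def test_scores_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = fit_knn(rng.normal(size=(50, 4)),
                        rng.integers(0, 3, size=50), k=7)
        _, scores = predict_knn(model, rng.normal(size=(20, 4)))
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        model = fit_knn(np.zeros((5, 3)), np.arange(5), k=1)
        with pytest.raises(InputError):
            predict_knn(model, np.zeros((2, 4)))


# ---------------------------------------------------------------------------
# linear discriminant
# ---------------------------------------------------------------------------

class TestDiscriminant:
    def _symmetric_model(self):
        rng = np.random.default_rng(7)
        a = rng.normal(loc=(-2, 0), scale=0.5, size=(60, 2))
        b = rng.normal(loc=(+2, 0), scale=0.5, size=(60, 2))
        x = np.vstack([a, b])
        y = np.array([0] * 60 + [1] * 60)
        return fit_discriminant(x, y), x, y

    def test_midpoint_posterior_is_half(self):
        model, _, _ = self._symmetric_model()
        mid = model.class_means.mean(axis=0)
        _, post = predict_discriminant(model, mid[None, :])
        assert np.allclose(post[0], [0.5, 0.5], atol=1e-12)

    def test_class_mean_query_confident(self):
        model, _, _ = self._symmetric_model()
        _, post = predict_discriminant(model, model.class_means[0][None, :])
        assert post[0, 0] > 0.99

    def test_matches_closed_form_on_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_classes = int(rng.integers(2, 4))
            d = int(rng.integers(1, 4))
            blocks, sizes = [], []
            for c in range(n_classes):
                m = int(rng.integers(3, 9))
                sizes.append(m)
                blocks.append(rng.normal(loc=3 * c, size=(m, d)))
            x = np.vstack(blocks)
            y = np.concatenate([[c] * m for c, m in enumerate(sizes)])
            q = rng.normal(loc=1.5, size=(4, d))
            model = fit_discriminant(x, y)
            labels, post = predict_discriminant(model, q)
            oracle = closed_form_lda_posteriors(x, y, q, model.class_order)
            assert np.allclose(post, oracle, atol=1e-8)
            assert np.array_equal(labels,
                                  model.class_order[oracle.argmax(axis=1)])

    def test_agrees_with_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(13)
        x = np.vstack([rng.normal(loc=0, size=(80, 4)),
                       rng.normal(loc=1.0, size=(120, 4))])
        y = np.array([0] * 80 + [1] * 120)
        q = rng.normal(loc=0.5, size=(30, 4))
        model = fit_discriminant(x, y)
        _, post = predict_discriminant(model, q)
        sk = LinearDiscriminantAnalysis(solver="svd").fit(x, y)
        # sklearn's pooled covariance uses 1/(n) vs our 1/(n-C): posteriors
        # agree closely but not exactly
        assert np.allclose(post, sk.predict_proba(q), atol=5e-3)

    def test_singleton_class_rejected(self):
        with pytest.raises(InputError):
            fit_discriminant(np.zeros((3, 2)), np.array([0, 0, 1]))


# ---------------------------------------------------------------------------
# composition features
# ---------------------------------------------------------------------------

def _forced_model(points, labels):
    """A k=1 kNN whose training points are the mock's own peaks: layer-1
    predictions then equal the chosen labels exactly."""
    return fit_knn(points, labels, k=1)


class TestComposition:
    def test_counting_example(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        assigned = np.array([0.0, 0.0, 10.0, 50.0])
        extra = np.array([[10.0], [11.0]])  # carry classes 100, 500
        model = fit_knn(np.vstack([pts, extra]),
                        np.concatenate([assigned, [100.0, 500.0]]), k=1)
        mock = MockExperiment(make_peak_table(pts, 0.0, "c", "e"), 0.0, "m1")
        comp = composition_features(mock, model)
        assert np.allclose(comp, [50.0, 25.0, 25.0, 0.0, 0.0])

    def test_single_class_mock_is_100_percent(self):
        pts = np.arange(5, dtype=float)[:, None]
        model = _forced_model(pts, np.full(5, 7.0))
        # a second class so class_order has two slots
        model = fit_knn(np.vstack([pts, [[99.0]]]),
                        np.concatenate([np.full(5, 7.0), [8.0]]), k=1)
        mock = MockExperiment(make_peak_table(pts, 7.0, "c", "e"), 7.0, "m")
        comp = composition_features(mock, model)
        assert comp[0] == 100.0 and comp[1] == 0.0

    def test_sums_to_100_for_random_assignments(self):
        """Exhaustive count oracle over many random assignments."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            pts = rng.normal(size=(n, 2)) + 10 * np.arange(n)[:, None]
            labels = rng.integers(0, 5, size=n).astype(float)
            all_pts = np.vstack([pts, 1000 + np.arange(5)[:, None] * [1, 1]])
            all_labels = np.concatenate([labels, np.arange(5, dtype=float)])
            model = fit_knn(all_pts, all_labels, k=1)
            mock = MockExperiment(make_peak_table(pts, 0.0, "c", "e"), 0.0, "m")
            comp = composition_features(mock, model)
            assert comp.sum() == pytest.approx(100.0, abs=1e-9)
            for c in range(5):
                assert comp[c] == pytest.approx(100.0 * (labels == c).mean(),
                                                abs=1e-9)

    def test_empty_mock_rejected(self):
        with pytest.raises(InputError):
            MockExperiment(make_peak_table(np.empty((0, 8)), None, None, None),
                           0.0, "m")


# ---------------------------------------------------------------------------
# full two-layer model
# ---------------------------------------------------------------------------

def _fitted_model_and_mocks(gen, seed=77, kind="coarse_knn"):
    from impedquant.resample import make_test_mocks
    design = {c: (3, 150) for c in (0.0, 10.0, 50.0, 100.0, 500.0)}
    table = simulate_study(gen, design, seed=seed)
    spec = SplitSpec(seed=seed)
    train, test = train_test_split(table, spec)
    l1, l2 = layer_split(train, spec)
    model = fit_two_layer(l1, l2, spec, layer1_kind=kind)
    mocks = make_test_mocks(test, spec)
    return model, mocks, l2, spec


class TestTwoLayer:
    def test_separable_limit_refit_accuracy_100(self):
        """With a huge analyte effect the training mocks are perfectly
        re-classified by the fitted layer 2."""
        concs = (0.0, 10.0, 25.0, 50.0, 100.0, 300.0, 500.0)
        gen = dataclasses.replace(
            assay_regime(), effect_size=1.0,
            bound_fraction_curve={c: 1.0 for c in concs},
            bound_degree_curve={c: 0.1 + 0.1 * i
                                for i, c in enumerate(concs)})
        model, _, l2_train, spec = _fitted_model_and_mocks(gen, seed=5)
        mocks = make_training_mocks(l2_train, spec)
        correct = sum(predict_sample(model, m)[0] == m.sample_label
                      for m in mocks)
        assert correct == len(mocks)

    def test_null_compositions_indistinguishable_across_classes(self):
        """delta = 0: training-mock compositions of any two classes pass
        per-component t-tests (alpha = 0.01, Bonferroni)."""
        model, _, l2_train, spec = _fitted_model_and_mocks(null_regime(),
                                                           seed=19)
        mocks = make_training_mocks(l2_train, spec)
        comps = {}
        for m in mocks:
            comps.setdefault(m.sample_label, []).append(
                composition_features(m, model.layer1))
        a = np.array(comps[0.0])
        b = np.array(comps[500.0])
        n_comp = a.shape[1]
        for j in range(n_comp):
            p = stats.ttest_ind(a[:, j], b[:, j]).pvalue
            assert p > 0.01 / n_comp

    def test_predict_sample_deterministic_and_matches_oracle(self, preset):
        model, mocks, _, _ = _fitted_model_and_mocks(preset, seed=23)
        mock = mocks[7]
        lab1, s1 = predict_sample(model, mock)
        lab2, s2 = predict_sample(model, mock)
        assert lab1 == lab2 and np.array_equal(s1, s2)
        # from-scratch oracle: recompute composition, then brute-force kNN
        comp = composition_features(mock, model.layer1)
        train_comp = model.layer2.train_z * model.layer2.feature_scale \
            + model.layer2.feature_mean
        olab, _ = brute_knn(train_comp,
                            model.layer2.class_order[
                                model.layer2.train_labels_idx],
                            comp[None, :], KNN_COARSE_K,
                            model.layer2.class_order)
        assert lab1 == olab[0]

    def test_model_roundtrips_through_serialization(self, tmp_path, preset):
        model, mocks, _, _ = _fitted_model_and_mocks(preset, seed=29)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        loaded = load_model(p1)
        save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for m in mocks[:5]:
            assert predict_sample(model, m)[0] == predict_sample(loaded, m)[0]
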