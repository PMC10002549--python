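import numpy as np
import pytest

from retinacoach import contrastive as ct


def brute_force_supcon(Z, label_sets, tau):
    """Independent oracle: literal anchor/positive double summation."""
    n = len(label_sets)
    terms = []
    for i in range(n):
        positives = [j for j in range(n)
                     if j != i and set(label_sets[i]) & set(label_sets[j])]
        if not positives:
            continue
        acc = 0.0
        for p in positives:
            denom = sum(np.exp(np.dot(Z[i], Z[a]) / tau)
                        for a in range(n) if a != i)
            acc += np.log(np.exp(np.dot(Z[i], Z[p]) / tau) / denom)
        terms.append(-acc / len(positives))
    return float(np.mean(terms)) if terms else 0.0


def reference_singlelabel_supcon(Z, labels, tau):
    """Reference single-label supervised contrastive loss (L_out form),
    written directly from the standard definition with integer labels."""
    Z = np.asarray(Z)
    labels = np.asarray(labels)
    n = len(labels)
    losses = []
    for i in range(n):
        P = np.where((labels == labels[i]) & (np.arange(n) != i))[0]
        if P.size == 0:
            continue
        logits = Z @ Z[i] / tau
        mask = np.arange(n) != i
        log_denom = np.log(np.exp(logits[mask]).sum())
        losses.append(-np.mean(logits[P] - log_denom))
    return float(np.mean(losses)) if losses else 0.0


def random_unit(rng, n, d):
    Z = rng.normal(size=(n, d))
    return Z / np.linalg.norm(Z, axis=1, keepdims=True)


class TestSupConLoss:
    def test_two_identical_vectors_sharing_class_give_zero(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert ct.supcon_multilabel_loss(z, [{"a"}, {"a"}], 0.1) \
            == pytest.approx(0.0, abs=1e-9)

    def test_matches_singlelabel_reference_on_singleton_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            Z = random_unit(rng, n, 8)
            labels = rng.integers(0, 3, size=n)
            mine = ct.supcon_multilabel_loss(
                Z, [{int(l)} for l in labels], 0.1)
            ref = reference_singlelabel_supcon(Z, labels, 0.1)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_matches_brute_force_on_multilabel_batches(self):
        rng = np.random.default_rng(1)
        alphabet = ["a", "b", "c", "d"]
        for _ in range(20):
            n = int(rng.integers(2, 17))
            Z = random_unit(rng, n, 6)
            label_sets = [
                set(rng.choice(alphabet, size=rng.integers(1, 3),
                               replace=False))
                for _ in range(n)
            ]
            mine = ct.supcon_multilabel_loss(Z, label_sets, 0.1)
            assert mine == pytest.approx(
                brute_force_supcon(Z, label_sets, 0.1), abs=1e-8)

    def test_four_handset_vectors(self):
        Z = np.array([[1, 0], [0, 1],
                      [-1, 0], [0, -1]], dtype=float)
        label_sets = [{1}, {1, 2}, {2}, {3}]
        mine = ct.supcon_multilabel_loss(Z, label_sets, 0.1)
        assert mine == pytest.approx(
            brute_force_supcon(Z, label_sets, 0.1), abs=1e-10)

    def test_invalid_inputs(self):
        z = np.eye(2)
        with pytest.raises(ValueError):
            ct.supcon_multilabel_loss(z, [{"a"}, {"a"}], temperature=0.0)
        with pytest.raises(ValueError):
            ct.supcon_multilabel_loss(z[:1], [{"a"}], temperature=0.1)

    def test_orthogonal_rotation_invariance(self):
        rng = np.random.default_rng(2)
        Z = random_unit(rng, 8, 5)
        labels = [{"a"}, {"b"}, {"a"}, {"c"}, {"b", "c"}, {"a"}, {"c"}, {"b"}]
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert ct.supcon_multilabel_loss(Z @ Q, labels, 0.1) == pytest.approx(
            ct.supcon_multilabel_loss(Z, labels, 0.1), abs=1e-9)

    def test_monotone_in_positive_pair_similarity(self):
        # rotate a positive toward its anchor in a plane orthogonal to the
        # other batch members, so only the positive-pair similarity moves
        def batch(angle):
            return np.array([
                [1.0, 0.0, 0.0],
                [np.cos(angle), np.sin(angle), 0.0],
                [0.0, 0.0, 1.0],
                [0.0, 0.0, -1.0],
            ])

        labels = [{"a"}, {"a"}, {"b"}, {"b"}]
        losses = [ct.supcon_multilabel_loss(batch(t), labels, 0.1)
                  for t in (1.5, 1.0, 0.5, 0.1)]
        assert losses == sorted(losses, reverse=True)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        Z = random_unit(rng, 5, 4)
        labels = [{"a"}, {"a", "b"}, {"b"}, {"c"}, {"c"}]
        _, grad, _ = ct.supcon_loss_and_grad(Z, labels, 0.1)
        eps = 1e-6
        for i in range(5):
            for j in range(4):
                zp, zm = Z.copy(), Z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (ct.supcon_multilabel_loss(zp, labels, 0.1)
                       - ct.supcon_multilabel_loss(zm, labels, 0.1)) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-5)


class TestTrainingPipeline:
    def test_contrastive_loss_decreases(self, desk_model):
        assert desk_model.loss_history[-1] < desk_model.loss_history[0]

    def test_training_is_reproducible(self, desk_dataset, desk_model):
        again = ct.train(desk_dataset,
                         ct.TrainConfig(epochs=60, lr=0.01, batch_size=64,
                                        seed=0))
        assert again.loss_history[-1] == pytest.approx(
            desk_model.loss_history[-1], abs=1e-4)

    def test_degenerate_single_class_dataset_rejected(self, desk_dataset):
        one_class = [(img, {"C0"}) for img, _ in desk_dataset[:10]]
        with pytest.raises(ValueError):
            ct.train(one_class, ct.TrainConfig(epochs=1))

    def test_prediction_contract(self, desk_model, desk_test_set):
        img, _ = desk_test_set[0]
        pv = ct.predict(img, desk_model)
        pv2 = ct.predict(img, desk_model)
        assert np.array_equal(pv.probs, pv2.probs)
        assert len(pv.probs) == len(desk_model.classes)
        assert np.all((pv.probs >= 0) & (pv.probs <= 1))

    def test_macro_precision_on_separable_classes(self, desk_model,
                                                  desk_test_set):
        from sklearn.metrics import precision_score
        Y, P = [], []
        for img, lab in desk_test_set:
            pv = ct.predict(img, desk_model)
            Y.append([c in lab for c in desk_model.classes])
            P.append(list(pv.probs >= 0.5))
        assert precision_score(np.asarray(Y), np.asarray(P),
                               average="macro", zero_division=0) >= 0.9

    def test_embedding_contract_and_clustering(self, desk_model,
                                               desk_test_set):
        import itertools
        by_class = {}
        for img, lab in desk_test_set:
            z = ct.embed(img, desk_model)
            assert np.linalg.norm(z) == pytest.approx(1.0, abs=1e-6)
            by_class.setdefault(next(iter(lab)), []).append(z)
        intra = np.mean([a @ b for zs in by_class.values()
                         for a, b in itertools.combinations(zs, 2)])
        inter = np.mean([a @ b
                         for c1, c2 in itertools.combinations(by_class, 2)
                         for a in by_class[c1] for b in by_class[c2]])
        assert intra > inter

    def test_multilabel_image_lights_both_classes(self, desk_dataset):
        from retinacoach.imaging import synth_fundus
        mixed = [(synth_fundus({"C14", "C11"}, size=64, seed=500 + i),
                  {"C14", "C11"}) for i in range(40)]
        model = ct.train(desk_dataset + mixed,
                         ct.TrainConfig(epochs=60, lr=0.01, seed=1))
        hits = 0
        for i in range(10):
            img = synth_fundus({"C14", "C11"}, size=64, seed=800 + i)
            pv = ct.predict(img, model)
            hits += {"C14", "C11"} <= pv.predicted_set
        assert hits >= 8

    def test_model_round_trip(self, desk_model, desk_test_set, tmp_path):
        path = tmp_path / "model.json"
        desk_model.save(path)
        loaded = ct.FundusModel.load(path)
        img, _ = desk_test_set[0]
        assert np.allclose(ct.predict(img, desk_model).probs,
                           ct.predict(img, loaded).probs)

    def test_untrained_model_rejected(self, desk_test_set):
        with pytest.raises(TypeError):
            ct.predict(desk_test_set[0][0], model="not a model")
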