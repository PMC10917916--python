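"""Splitting, augmentation, SGD training and Bayesian hyperparameter search."""

import numpy as np
import pytest

from mammofuse.architectures import build_small_network
from mammofuse.synthetic import generate_images
from mammofuse.training import (
    HyperParams, TrainingFailure, augment, bayes_optimize, split_dataset,
    train_network, training_accuracy,
)


class TestSplit:
    def test_even_counts_halve_exactly(self):
        imgs = generate_images(10, (64, 64), 0.5, seed=0)
        plan = split_dataset(imgs, seed=1)
        y = imgs.y
        for ids in (plan.train_ids, plan.test_ids):
            assert len(ids) == 10
            assert (y[ids] == 0).sum() == 5
        assert sorted(plan.train_ids + plan.test_ids) == list(range(20))

    def test_odd_counts_round_within_one(self):
        imgs = generate_images(11, (64, 64), 0.5, seed=0)
        plan = split_dataset(imgs, seed=1)
        y = imgs.y
        for cls in (0, 1):
            n_train = (y[plan.train_ids] == cls).sum()
            assert n_train in (5, 6)

    def test_deterministic(self):
        imgs = generate_images(8, (64, 64), 0.5, seed=0)
        a = split_dataset(imgs, seed=3)
        b = split_dataset(imgs, seed=3)
        assert a.train_ids == b.train_ids

    def test_tiny_class_rejected(self):
        from mammofuse.synthetic import ImageSet
        bad = ImageSet(images=np.zeros((3, 64, 64, 3), dtype=np.float32),
                       labels=["benign", "benign", "malignant"])
        with pytest.raises(ValueError):
            split_dataset(bad)


class TestAugment:
    def test_five_fold_expansion_with_labels(self, small_images):
        aug = augment(small_images)
        assert len(aug) == 5 * len(small_images)
        assert aug.labels == small_images.labels * 5
        assert aug.lesion_masks.shape[0] == len(aug)

    def test_flip_is_involution(self, small_images):
        once = augment(small_images, ops=("hflip",))
        twice = augment(once.subset(range(len(small_images),
                                          2 * len(small_images))),
                        ops=("hflip",))
        restored = twice.images[len(small_images):]
        assert np.array_equal(restored, small_images.images)

    def test_provenance_recorded(self, small_images):
        aug = augment(small_images, ops=("vflip",))
        assert aug.sample_ids[len(small_images)].endswith(".vflip")

    def test_empty_set_rejected(self, small_images):
        with pytest.raises(ValueError):
            augment(small_images.subset([]))


class TestTrainNetwork:
    def test_zero_learning_rate_is_a_no_op(self, small_images):
        net = build_small_network(seed=0)
        before = [p.value.copy() for p in net.params()]
        hp = HyperParams(learning_rate=0.0, momentum=0.0, epochs=2,
                         minibatch=len(small_images))  # full batch
        train_network(net, small_images, hp, seed=0)
        for old, p in zip(before, net.params()):
            assert np.array_equal(old, p.value)
        # loss is mathematically identical across epochs; tolerance covers
        # float32 summation-order effects from reshuffling
        assert net.train_history[0] == pytest.approx(net.train_history[1],
                                                     abs=1e-4)

    def test_learns_separable_phantoms(self, small_images):
        net = build_small_network(seed=0)
        hp = HyperParams(learning_rate=0.01, momentum=0.9, epochs=8,
                         minibatch=16)
        train_network(net, small_images, hp, seed=0)
        assert training_accuracy(net, small_images) >= 0.9
        assert net.train_history[-1] <= net.train_history[0]

    def test_deterministic_given_seed(self, small_images):
        hists = []
        for _ in range(2):
            net = build_small_network(seed=1)
            hp = HyperParams(learning_rate=0.005, momentum=0.8, epochs=2,
                             minibatch=16)
            train_network(net, small_images, hp, seed=2)
            hists.append(net.train_history)
        assert hists[0] == hists[1]

    def test_divergence_raises_training_failure(self, small_images):
        net = build_small_network(seed=0)
        # poison a weight: the first non-finite loss must abort with
        # diagnostics rather than silently continuing
        first = next(iter(net.params()))
        first.value[0] = np.nan
        hp = HyperParams(learning_rate=0.01, momentum=0.9, epochs=2,
                         minibatch=16)
        with pytest.raises(TrainingFailure) as err, \
                np.errstate(invalid="ignore"):
            train_network(net, small_images, hp, seed=0)
        assert err.value.history == []

    def test_hyperparams_validation(self):
        with pytest.raises(ValueError):
            HyperParams(learning_rate=-1.0)
        with pytest.raises(ValueError):
            HyperParams(momentum=1.0)
        with pytest.raises(ValueError):
            HyperParams(optimizer="adam")


class TestBayesOptimize:
    def _build(self, name, seed):
        return build_small_network(seed=seed)

    def test_budget_one_returns_single_point_in_box(self, small_images):
        hp = bayes_optimize("small", small_images, budget=1, seed=0,
                            proxy_epochs=1, build_fn=self._build)
        assert 1e-5 <= hp.learning_rate <= 1e-2
        assert 0.5 <= hp.momentum <= 0.99
        assert len(hp.search_history) == 1

    def test_best_so_far_beats_chance_and_is_monotone(self, small_images):
        hp = bayes_optimize("small", small_images, budget=3, seed=1,
                            proxy_epochs=2, build_fn=self._build)
        scores = [s for _, s in hp.search_history]
        best_so_far = np.maximum.accumulate(scores)
        assert all(b2 >= b1 for b1, b2 in zip(best_so_far, best_so_far[1:]))
        assert max(scores) >= 0.5  # majority-class baseline

    def test_invalid_budget(self, small_images):
        with pytest.raises(ValueError):
            bayes_optimize("small", small_images, budget=0, seed=0,
                           build_fn=self._build)
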