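"""Dataset split, scorer contract, augmentation and class-weight remedies."""

import numpy as np
import pandas as pd
import pytest

from rccpath.scorer import (ReferenceScorer, ScorerConfig, augment_minority,
                            extract_embeddings, split_dataset, train_scorer,
                            weighted_sample_weights)
from rccpath.synthetic import SyntheticSlideSpec, TextureParams, generate_slide
from rccpath.tiling import Patch, TileGrid, filter_patches, tile_slide


def _texture_patches(label, base_color, n, seed, tile=16):
    """Small labeled tissue patches of one texture class."""
    spec = SyntheticSlideSpec(
        width=tile * n, height=tile, tissue_fraction=1.0, tumor_fraction=1.0,
        textures={"tumor": TextureParams(base_color=base_color,
                                         blob_density=6.0),
                  "normal": TextureParams()},
        seed=seed)
    img, _, _ = generate_slide(spec)
    patches = tile_slide(img, TileGrid(tile, 0.0), f"slide_{label}_{seed}",
                         label)
    return patches[:n]


def _two_class_set(n_per_class, seed, colors=((90, 60, 120), (200, 170, 150))):
    a = _texture_patches("A", colors[0], n_per_class, seed)
    b = _texture_patches("B", colors[1], n_per_class, seed + 1)
    return a + b


_FAST = dict(resize=8, learning_rate=1e-3, batch_size=32, max_epochs=10,
             patience=3, embed_dim=32)


class TestSplit:
    def _manifest(self, n, label="x"):
        return pd.DataFrame({"slide_id": [f"{label}{i}" for i in range(n)],
                             "label": label})

    def test_twenty_slides_fourteen_three_three(self):
        folds = split_dataset(self._manifest(20), seed=0)
        assert (len(folds["train"]), len(folds["val"]), len(folds["test"])) \
            == (14, 3, 3)

    def test_partition_property(self):
        m = pd.concat([self._manifest(11, "a"), self._manifest(7, "b")])
        folds = split_dataset(m, seed=3)
        all_ids = set(m["slide_id"])
        assert folds["train"] | folds["val"] | folds["test"] == all_ids
        assert not folds["train"] & folds["val"]
        assert not folds["train"] & folds["test"]
        assert not folds["val"] & folds["test"]

    def test_determinism(self):
        m = self._manifest(15)
        assert split_dataset(m, seed=5) == split_dataset(m, seed=5)
        assert split_dataset(m, seed=5) != split_dataset(m, seed=6)

    def test_too_few_slides_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._manifest(2), seed=0)


class TestTrainScorer:
    def test_separable_textures_high_accuracy(self):
        train = _two_class_set(40, seed=0)
        val = _two_class_set(10, seed=10)
        test = _two_class_set(30, seed=20)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, val, cfg)
        pred = [sc.classes_[k] for k in sc.score(test).argmax(axis=1)]
        acc = np.mean([p == q.label for p, q in zip(pred, test)])
        assert acc >= 0.95

    def test_probabilities_sum_to_one(self):
        train = _two_class_set(20, seed=1)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, _two_class_set(6, seed=2), cfg)
        probs = sc.score(train[:9])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_trace_bounded_by_max_epochs(self):
        train = _two_class_set(20, seed=3)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, _two_class_set(6, seed=4), cfg)
        assert len(sc.val_accuracy_trace) <= cfg.max_epochs

    def test_single_class_rejected(self):
        a = _texture_patches("A", (90, 60, 120), 10, seed=5)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        with pytest.raises(ValueError):
            train_scorer(a, a, cfg)

    def test_constant_images_chance_accuracy(self):
        blank = [Patch("s", 0, k, 0, 0,
                       np.full((16, 16, 3), 128, np.uint8), l)
                 for k in range(40) for l in ("A", "B")]
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(blank, blank[:20], cfg)
        acc = max(sc.val_accuracy_trace)
        assert acc <= 0.75  # nothing learnable beyond the majority rate

    def test_untrained_scorer_rejected(self):
        sc = ReferenceScorer(ScorerConfig(n_output_classes=2, **_FAST))
        with pytest.raises(RuntimeError):
            extract_embeddings(sc, [np.zeros((16, 16, 3), np.uint8)])


class TestEmbeddings:
    def test_shape_and_duplicates(self):
        train = _two_class_set(25, seed=6)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, _two_class_set(6, seed=7), cfg)
        E = extract_embeddings(sc, train[:10] + train[:1])
        assert E.shape == (11, cfg.embed_dim)
        np.testing.assert_array_equal(E[0], E[10])  # same pixels, same row

    def test_downstream_separability(self):
        train = _two_class_set(40, seed=8)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, _two_class_set(10, seed=9), cfg)
        test = _two_class_set(30, seed=30)
        E = extract_embeddings(sc, test)
        y = np.array([p.label for p in test])
        centers = {l: E[y == l].mean(axis=0) for l in ("A", "B")}
        pred = ["A" if np.linalg.norm(e - centers["A"])
                < np.linalg.norm(e - centers["B"]) else "B" for e in E]
        assert np.mean(np.array(pred) == y) >= 0.95

    def test_checkpoint_roundtrip(self, tmp_path):
        train = _two_class_set(20, seed=11)
        cfg = ScorerConfig(n_output_classes=2, seed=0, **_FAST)
        sc = train_scorer(train, _two_class_set(6, seed=12), cfg)
        sc.save(tmp_path / "model.npz")
        loaded = ReferenceScorer.load(tmp_path / "model.npz")
        np.testing.assert_allclose(loaded.score(train[:8]), sc.score(train[:8]))
        np.testing.assert_allclose(loaded.embed(train[:8]), sc.embed(train[:8]))


class TestAugmentation:
    def _patches(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        return [Patch("s", 0, k, 0, 0,
                      rng.integers(0, 255, (32, 32, 3)).astype(np.uint8), "m")
                for k in range(n)]

    def test_count_contract(self):
        src = self._patches(5)
        assert len(augment_minority(src, 5, seed=0)) == 5
        assert len(augment_minority(src, 17, seed=0)) == 17

    def test_determinism(self):
        src = self._patches(4)
        a = augment_minority(src, 12, seed=3)
        b = augment_minority(src, 12, seed=3)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_vertical_flip_involution(self):
        img = self._patches(1)[0].image
        assert np.array_equal(img[::-1][::-1], img)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_minority([], 5)

    def test_target_below_count_rejected(self):
        with pytest.raises(ValueError):
            augment_minority(self._patches(5), 3)


class TestSampleWeights:
    def test_inverse_frequency_example(self):
        np.testing.assert_allclose(weighted_sample_weights(["A", "A", "B"]),
                                   [0.25, 0.25, 0.5])

    def test_balanced_uniform(self):
        w = weighted_sample_weights(["a", "b", "a", "b"])
        np.testing.assert_allclose(w, 0.25)

    def test_imbalanced_mix_equalizes_draws(self, rng):
        # 43/14/43 subtype mix: weighted draws should come out ~uniform
        labels = np.repeat(["KIRC", "KIRP", "KICH"], [430, 140, 430])
        w = weighted_sample_weights(labels)
        draws = rng.choice(labels, size=10000, p=w)
        for cls in ("KIRC", "KIRP", "KICH"):
            assert np.mean(draws == cls) == pytest.approx(1 / 3, abs=0.02)


class TestImbalanceRemedy:
    def test_augmentation_improves_minority_recall(self):
        """Minority recall with augmentation beats the unbalanced baseline
        (paired across seeded runs)."""
        wins = better = 0
        for seed in range(6):
            maj = _texture_patches("A", (100, 70, 130), 48, seed=seed * 7)
            minority = _texture_patches("B", (135, 105, 110), 6,
                                        seed=seed * 7 + 1)
            val = _two_class_set(8, seed=seed * 7 + 2,
                                 colors=((100, 70, 130), (135, 105, 110)))
            test = _two_class_set(25, seed=seed * 7 + 3,
                                  colors=((100, 70, 130), (135, 105, 110)))
            cfg = ScorerConfig(n_output_classes=2, seed=seed, **_FAST)

            def minority_recall(train):
                sc = train_scorer(train, val, cfg)
                pred = [sc.classes_[k]
                        for k in sc.score(test).argmax(axis=1)]
                truth = [p.label for p in test]
                hits = [p == t for p, t in zip(pred, truth) if t == "B"]
                return float(np.mean(hits))

            base = minority_recall(maj + minority)
            aug = minority_recall(
                maj + augment_minority(minority, len(maj), seed=seed))
            better += aug > base
            wins += aug >= base
        assert wins >= 5 and better >= 3
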