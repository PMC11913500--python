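import hashlib
import os

import numpy as np
import pytest
from scipy import ndimage as ndi

from dermrestore import (
    CLASS_STYLES,
    HairParams,
    LesionPhantomParams,
    NoiseParams,
    add_gaussian_noise,
    draw_procedural_hairs,
    extract_hair_mask,
    generate_corpus,
    generate_lesion_phantom,
    generate_phantom_corpus,
    superimpose_hair,
)


class TestGaussianNoise:
    def test_zero_sigma_identity(self, small_phantom):
        img, _ = small_phantom
        np.testing.assert_array_equal(
            add_gaussian_noise(img, NoiseParams(sigma=0, seed=1)), img
        )

    def test_moments_at_clt_scale(self):
        img = np.full((183, 183, 3), 128, dtype=np.uint8)  # ~1e5 px
        out = add_gaussian_noise(img, NoiseParams(sigma=15, seed=3))
        diff = out.astype(float) - 128.0
        assert diff.mean() == pytest.approx(0.0, abs=0.15)
        assert diff.std() == pytest.approx(15.0, abs=0.75)

    def test_seed_determinism(self, small_phantom):
        img, _ = small_phantom
        p = NoiseParams(sigma=12, seed=9)
        np.testing.assert_array_equal(
            add_gaussian_noise(img, p), add_gaussian_noise(img, p)
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(sigma=-1)


class TestProceduralHairs:
    def test_zero_hairs_identity(self, small_phantom):
        img, _ = small_phantom
        pair = draw_procedural_hairs(img, HairParams(n_hairs=0, seed=0))
        np.testing.assert_array_equal(pair.corrupted, img)
        assert not pair.truth_mask.any()

    def test_disjoint_hairs_have_expected_component_count(self, small_phantom):
        img, _ = small_phantom
        pair = draw_procedural_hairs(
            img,
            HairParams(n_hairs=5, thickness_range=(2, 2), seed=21,
                       allow_overlap=False),
        )
        _, n = ndi.label(pair.truth_mask)
        assert n == 5

    def test_off_mask_pixels_identical(self, hairy_pair):
        off = ~hairy_pair.truth_mask
        np.testing.assert_array_equal(
            hairy_pair.corrupted[off], hairy_pair.clean[off]
        )

    def test_seed_determinism(self, small_phantom):
        img, _ = small_phantom
        p = HairParams(n_hairs=8, seed=5)
        a = draw_procedural_hairs(img, p)
        b = draw_procedural_hairs(img, p)
        np.testing.assert_array_equal(a.corrupted, b.corrupted)
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)

    def test_hairs_are_dark(self, hairy_pair):
        on = hairy_pair.truth_mask
        assert hairy_pair.corrupted[on].mean() < hairy_pair.clean[on].mean()


class TestSuperimpose:
    def test_empty_mask_copies_clean(self, small_phantom, rng):
        img, _ = small_phantom
        donor = rng.integers(0, 256, size=img.shape, dtype=np.uint8)
        pair = superimpose_hair(img, donor, np.zeros(img.shape[:2], dtype=bool))
        np.testing.assert_array_equal(pair.corrupted, img)

    def test_full_row_mask_takes_donor_row(self, small_phantom, rng):
        img, _ = small_phantom
        donor = rng.integers(0, 256, size=img.shape, dtype=np.uint8)
        mask = np.zeros(img.shape[:2], dtype=bool)
        mask[5] = True
        pair = superimpose_hair(img, donor, mask)
        np.testing.assert_array_equal(pair.corrupted[5], donor[5])
        np.testing.assert_array_equal(pair.corrupted[6:], img[6:])

    def test_shape_mismatch_rejected(self, small_phantom):
        img, _ = small_phantom
        with pytest.raises(ValueError):
            superimpose_hair(img, img[:-1], np.zeros(img.shape[:2], dtype=bool))


class TestHairMaskExtraction:
    def test_constant_donor_empty(self):
        donor = np.full((40, 40, 3), 180, dtype=np.uint8)
        assert not extract_hair_mask(donor).any()

    def test_recovers_procedural_truth(self, hairy_pair):
        detected = extract_hair_mask(hairy_pair.corrupted)
        truth = hairy_pair.truth_mask
        dice = 2 * (detected & truth).sum() / (detected.sum() + truth.sum())
        assert dice >= 0.6
        assert detected.sum() < detected.size


class TestLesionPhantom:
    def test_lesion_colour_dominates_inside(self):
        p = LesionPhantomParams(image_size=(64, 64), class_id=6, seed=2,
                                texture_scale=0.0)
        img, label = generate_lesion_phantom(p)
        assert label == 6
        style = np.array(CLASS_STYLES[6]["color"], dtype=float)
        skin = np.array(p.skin_tone, dtype=float)
        centre = img[28:36, 28:36].reshape(-1, 3).mean(axis=0)
        assert np.linalg.norm(centre - style) < np.linalg.norm(centre - skin)
        corner = img[:4, :4].reshape(-1, 3).mean(axis=0)
        assert np.linalg.norm(corner - skin) < np.linalg.norm(corner - style)

    def test_texture_free_phantom_uses_two_colours_plus_blend(self):
        p = LesionPhantomParams(image_size=(48, 48), class_id=1, seed=4,
                                texture_scale=0.0)
        img, _ = generate_lesion_phantom(p)
        colours = {tuple(px) for px in img.reshape(-1, 3)}
        assert tuple(p.skin_tone) in colours
        assert tuple(CLASS_STYLES[1]["color"]) in colours

    def test_seed_determinism(self):
        p = LesionPhantomParams(seed=11, class_id=0)
        np.testing.assert_array_equal(
            generate_lesion_phantom(p)[0], generate_lesion_phantom(p)[0]
        )

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError):
            generate_lesion_phantom(
                LesionPhantomParams(image_size=(32, 32), lesion_axes=(20, 10))
            )

    def test_classes_separable_by_nearest_centroid(self):
        # mean colour of the lesion region (pixels far from the skin tone)
        images, labels = generate_phantom_corpus(10, image_size=(48, 48), seed=0)
        skin = np.array(LesionPhantomParams().skin_tone, dtype=float)
        feats = []
        for img in images:
            px = img.reshape(-1, 3).astype(float)
            lesion = px[np.linalg.norm(px - skin, axis=1) > 40]
            feats.append(lesion.mean(axis=0) if len(lesion) else px.mean(axis=0))
        feats = np.stack(feats)
        centroids = np.stack(
            [feats[labels == c].mean(axis=0) for c in range(7)]
        )
        pred = np.argmin(
            np.linalg.norm(feats[:, None] - centroids[None], axis=2), axis=1
        )
        assert (pred == labels).mean() >= 0.95


class TestCorpusGeneration:
    def test_clean_corpus_counts(self, tmp_path):
        manifest = generate_corpus(2, "none", tmp_path / "c", seed=1,
                                   image_size=(32, 32))
        assert len(manifest) == 14
        assert len(os.listdir(tmp_path / "c" / "clean")) == 14
        assert not (tmp_path / "c" / "masks").exists()

    def test_noise_corpus_schema(self, tmp_path):
        manifest = generate_corpus(1, "noise", tmp_path / "n", seed=2,
                                   image_size=(32, 32))
        assert manifest["sigma"].between(1, 30).all()
        assert not (tmp_path / "n" / "masks").exists()
        assert len(os.listdir(tmp_path / "n" / "corrupted")) == 7

    def test_regeneration_is_byte_identical(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for dirpath, _, files in sorted(os.walk(root)):
                for name in sorted(files):
                    h.update(open(os.path.join(dirpath, name), "rb").read())
            return h.hexdigest()

        generate_corpus(1, "hair", tmp_path / "a", seed=3, image_size=(32, 32))
        generate_corpus(1, "hair", tmp_path / "b", seed=3, image_size=(32, 32))
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_bad_corruption_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_corpus(1, "rulers", tmp_path / "x")
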