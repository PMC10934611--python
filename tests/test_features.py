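"""Connected-region features against pixel-enumeration oracles, and BoVW."""

import math
from collections import deque

import numpy as np
import pytest
from skimage.draw import disk
from skimage.morphology import convex_hull_image
from skimage.transform import rotate

from wanderlens import features
from wanderlens.features import (
    CRF_FIELDS,
    EmptyRegionError,
    VisualVocabulary,
    assemble_feature_vector,
    assign_words,
    build_vocabulary,
    encode_bovw,
    extract_descriptors,
    region_feature_vector,
    region_features,
)

# ---------------------------------------------------------------------------
# brute-force pixel-enumeration oracles (independent of skimage.measure)

N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _components(mask, neigh):
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                comp = []
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                comps.append(comp)
    return comps


def oracle_largest_component(binary):
    comps = _components(binary.astype(bool), N8)
    return max(comps, key=len)


def oracle_euler(binary):
    """objects (8-connected) minus holes (4-connected background islands)."""
    binary = binary.astype(bool)
    n_obj = len(_components(binary, N8))
    bg = ~np.pad(binary, 1)
    bg_comps = _components(bg, N4)
    # the one background component touching the border is not a hole
    return n_obj - (len(bg_comps) - 1)


def oracle_filled_area(binary, comp):
    """Component area plus enclosed background, within the component bbox."""
    rows = [r for r, _ in comp]
    cols = [c for _, c in comp]
    r0, r1, c0, c1 = min(rows), max(rows) + 1, min(cols), max(cols) + 1
    sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for r, c in comp:
        sub[r - r0, c - c0] = True
    bg = ~np.pad(sub, 1)
    bg_comps = _components(bg, N4)
    border_touching = max(bg_comps, key=len)  # padded frame is always largest
    enclosed = sum(len(b) for b in bg_comps if b is not border_touching)
    return sub.sum() + enclosed


def oracle_boundary_walk_perimeter(comp):
    """Sum of exposed 4-neighbour edges as a simple boundary-length proxy."""
    cells = set(comp)
    edges = 0
    for r, c in cells:
        for dr, dc in N4:
            if (r + dr, c + dc) not in cells:
                edges += 1
    return edges


def random_binary_image(rng, size=48):
    img = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(1, 5)):
        r, c = rng.integers(4, size - 12, size=2)
        h, w = rng.integers(3, 12, size=2)
        img[r : r + h, c : c + w] = True
    if rng.uniform() < 0.5:  # punch a hole
        r, c = rng.integers(8, size - 8, size=2)
        img[r : r + 2, c : c + 2] = False
    return img


# ---------------------------------------------------------------------------


class TestRegionFeatures:
    def test_solid_square(self):
        img = np.zeros((14, 14), dtype=bool)
        img[2:12, 2:12] = True
        f = region_features(img, img.astype(float))
        assert f.area == 100
        assert f.extent == pytest.approx(1.0)
        assert f.euler_number == 1
        assert f.solidity == pytest.approx(1.0)
        assert f.perimeter == pytest.approx(36.0)
        # closed-form roundness at A=100, P=36
        assert f.circularity == pytest.approx(0.8202, abs=1e-4)
        assert f.equiv_diameter == pytest.approx(11.2838, abs=1e-4)

    def test_disk_is_round(self):
        img = np.zeros((40, 40), dtype=bool)
        rr, cc = disk((20, 20), 15)
        img[rr, cc] = True
        f = region_features(img, img.astype(float))
        assert f.eccentricity <= 0.2
        assert f.circularity == pytest.approx(1.0, abs=0.15)

    def test_square_with_hole_euler_zero(self):
        img = np.zeros((16, 16), dtype=bool)
        img[2:12, 2:12] = True
        img[6:8, 6:8] = False
        f = region_features(img, img.astype(float))
        assert f.euler_number == 0
        assert f.filled_area == 100
        assert f.area == 96

    def test_intensity_stats_over_region(self):
        img = np.zeros((8, 8), dtype=bool)
        img[2:5, 2:5] = True
        gray = np.zeros((8, 8))
        gray[2:5, 2:5] = 0.5
        gray[3, 3] = 0.9
        gray[4, 4] = 0.1
        f = region_features(img, gray)
        assert f.max_intensity == pytest.approx(0.9)
        assert f.min_intensity == pytest.approx(0.1)
        assert f.min_intensity <= f.mean_intensity <= f.max_intensity

    def test_matches_bruteforce_oracles(self, rng):
        """Exact agreement with pixel enumeration on 20 random images."""
        for _ in range(20):
            img = random_binary_image(rng)
            f = region_features(img, img.astype(float))
            comp = oracle_largest_component(img)
            assert f.area == len(comp)
            assert f.euler_number == oracle_euler(img)
            assert f.filled_area == oracle_filled_area(img, comp)
            rows = [r for r, _ in comp]
            cols = [c for _, c in comp]
            bbox_area = (max(rows) - min(rows) + 1) * (max(cols) - min(cols) + 1)
            assert f.extent == pytest.approx(len(comp) / bbox_area)
            # convex hull of the largest component only
            mask = np.zeros_like(img)
            for r, c in comp:
                mask[r, c] = True
            assert f.solidity == pytest.approx(len(comp) / convex_hull_image(mask).sum())
            # perimeter estimators legitimately differ; boundary walk within 15%
            walk = oracle_boundary_walk_perimeter(comp)
            assert f.perimeter <= walk
            assert f.perimeter >= 0.55 * walk  # exposed-edge count over-measures

    def test_scale_behavior(self):
        small = np.zeros((20, 20), dtype=bool)
        small[5:11, 5:11] = True
        big = np.zeros((40, 40), dtype=bool)
        big[10:22, 10:22] = True
        fs = region_features(small, small.astype(float))
        fb = region_features(big, big.astype(float))
        assert fb.area == pytest.approx(4 * fs.area, rel=0.05)
        assert fb.equiv_diameter == pytest.approx(2 * fs.equiv_diameter, rel=0.05)

    def test_orientation_convention(self):
        diag = np.fliplr(np.eye(20, dtype=bool))  # up-right in a y-up frame
        f = region_features(diag, diag.astype(float))
        assert f.orientation == pytest.approx(45.0, abs=2.0)

    def test_empty_image_signals(self):
        img = np.zeros((5, 5), dtype=bool)
        with pytest.raises(EmptyRegionError):
            region_features(img, img.astype(float))
        assert region_feature_vector(img, img.astype(float)).tolist() == [0.0] * 15

    def test_largest_component_selected(self):
        img = np.zeros((20, 20), dtype=bool)
        img[1:3, 1:3] = True  # area 4
        img[8:14, 8:14] = True  # area 36
        f = region_features(img, np.where(img, 0.8, 0.0))
        assert f.area == 36


def synthetic_keypoint_image(rng, size=96):
    """Line-art image with corners, similar in character to trajectory plots."""
    img = np.zeros((size, size, 3), dtype=np.uint8)
    for _ in range(6):
        r, c = rng.integers(10, size - 20, size=2)
        h, w = rng.integers(8, 18, size=2)
        color = tuple(int(v) for v in rng.integers(120, 255, size=3))
        img[r : r + h, c] = color
        img[r, c : c + w] = color
        img[r : r + h, c + w - 1] = color
        img[r + h - 1, c : c + w] = color
    return img


class TestBagOfVisualWords:
    def vocab_images(self, rng, n=12):
        return [synthetic_keypoint_image(rng) for _ in range(n)]

    def test_vocabulary_deterministic(self, rng):
        imgs = self.vocab_images(rng)
        v1 = build_vocabulary(imgs, K=8, seed=3)
        v2 = build_vocabulary(imgs, K=8, seed=3)
        assert v1.K == 8
        assert np.array_equal(v1.centers, v2.centers)

    def test_detection_deterministic(self, rng):
        img = self.vocab_images(rng, n=1)[0]
        assert np.array_equal(extract_descriptors(img), extract_descriptors(img))

    def test_k_clamped_when_descriptors_scarce(self, rng):
        img = self.vocab_images(rng, n=1)[0]
        d = extract_descriptors(img)
        vocab = build_vocabulary(None, K=len(d) + 50, seed=0, descriptors=[d])
        assert 2 <= vocab.K <= len(d)

    def test_no_keypoints_anywhere_is_fatal(self):
        blank = [np.zeros((64, 64, 3), dtype=np.uint8)]
        with pytest.raises(RuntimeError, match="keypoint"):
            build_vocabulary(blank, K=5, seed=0)

    def test_histogram_l2_normalised(self, rng):
        imgs = self.vocab_images(rng)
        vocab = build_vocabulary(imgs, K=8, seed=0)
        h = encode_bovw(imgs[0], vocab)
        assert np.linalg.norm(h) == pytest.approx(1.0)

    def test_zero_keypoint_image_zero_histogram(self, rng):
        vocab = build_vocabulary(self.vocab_images(rng), K=8, seed=0)
        h = encode_bovw(np.zeros((64, 64, 3), dtype=np.uint8), vocab)
        assert np.all(h == 0)

    def test_assignments_match_bruteforce(self, rng):
        centers = rng.normal(size=(10, 256))
        vocab = VisualVocabulary(K=10, centers=centers)
        descs = rng.integers(0, 2, size=(40, 256)).astype(float)
        got = assign_words(descs, vocab)
        want = [
            int(np.argmin([np.linalg.norm(d - c) for c in centers])) for d in descs
        ]
        assert got.tolist() == want

    def test_rotation_robustness_smoke(self, rng):
        """Histograms of an image and its 90-degree rotation stay similar."""
        img = synthetic_keypoint_image(rng)
        imgs = self.vocab_images(rng)
        vocab = build_vocabulary(imgs + [img], K=10, seed=0)
        h1 = encode_bovw(img, vocab)
        rot = (rotate(img.astype(float) / 255.0, 90) * 255).astype(np.uint8)
        h2 = encode_bovw(rot, vocab)
        cos = float(h1 @ h2)
        assert cos > 0.7

    def test_vocabulary_roundtrip(self, rng, tmp_path):
        vocab = build_vocabulary(self.vocab_images(rng), K=6, seed=1)
        vocab.save(tmp_path / "vocab.json")
        back = VisualVocabulary.load(tmp_path / "vocab.json")
        assert back.K == vocab.K
        assert np.allclose(back.centers, vocab.centers)


class TestFeatureVector:
    def test_length_and_field_order(self):
        vec = assemble_feature_vector(np.arange(15.0), np.zeros(500), "s1", "CH")
        assert len(vec) == 515
        assert CRF_FIELDS[0] == "area"
        assert CRF_FIELDS[9] == "equiv_diameter"
        arr = vec.as_array()
        assert arr[0] == 0.0 and arr[9] == 9.0

    def test_zero_region_fallback_block(self):
        empty = np.zeros((4, 4), dtype=bool)
        vec = assemble_feature_vector(
            region_feature_vector(empty, empty.astype(float)), np.ones(5), "s1", "PwD"
        )
        assert vec.as_array()[:15].tolist() == [0.0] * 15

    def test_wrong_crf_length_fatal(self):
        with pytest.raises(ValueError):
            assemble_feature_vector(np.zeros(14), np.zeros(5), "s1", "CH")

    def test_frame_schema(self):
        vecs = [
            assemble_feature_vector(np.zeros(15), np.zeros(3), "s1", "CH"),
            assemble_feature_vector(np.ones(15), np.ones(3), "s2", "PwD"),
        ]
        df = features.feature_frame(vecs)
        assert list(df.columns[:2]) == ["subject_id", "label"]
        assert list(df.columns[2:5]) == ["area", "major_axis_length", "minor_axis_length"]
        assert df.shape == (2, 2 + 15 + 3)

    def test_inconsistent_bovw_length_fatal(self):
        vecs = [
            assemble_feature_vector(np.zeros(15), np.zeros(3), "s1", "CH"),
            assemble_feature_vector(np.zeros(15), np.zeros(4), "s2", "PwD"),
        ]
        with pytest.raises(ValueError):
            features.feature_frame(vecs)
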