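"""Detection pipeline: pooling, maxima, curvature, patches, classifier."""

import numpy as np
import pytest

from engramap import (
    CellCentroid,
    DetectionParams,
    ImageVolume,
    VolumeSpec,
    classify_candidates,
    extract_patches,
    downsample_xy,
    filter_curvature_intensity,
    generate_volume,
    match_detections,
    patch_physical_extent,
    propose_candidates,
    train_patch_classifier,
)
from engramap.detection import blobness_score, hessian_at, smooth
from engramap.simulate import generate_training_patches


class TestDownsample:
    def test_factor_one_identity(self, small_volume):
        _, vol, _ = small_volume
        out = downsample_xy(vol, 1)
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.voxel_size == vol.voxel_size

    def test_constant_volume_stays_constant(self):
        vol = ImageVolume(np.full((8, 8, 4), 7.0), (1, 1, 1))
        out = downsample_xy(vol, 4)
        assert np.allclose(out.data, 7.0)
        assert out.shape == (2, 2, 4)
        assert out.voxel_size == (4.0, 4.0, 1.0)

    def test_block_mean_arithmetic(self):
        # values 1..16 in one xy plane pool to their arithmetic mean 8.5
        vol = ImageVolume(np.arange(1.0, 17.0).reshape(4, 4, 1), (1, 1, 1))
        out = downsample_xy(vol, 4)
        assert out.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == pytest.approx(8.5)

    def test_non_divisible_rejected_with_crop_hint(self):
        vol = ImageVolume(np.zeros((10, 10, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="crop to \\(8, 8\\)"):
            downsample_xy(vol, 4)


class TestProposeCandidates:
    def test_single_noiseless_blob_found_exactly(self, noiseless_single_blob, default_params):
        _, vol, truth = noiseless_single_blob
        cands = propose_candidates(vol, default_params)
        assert len(cands) == 1
        assert np.linalg.norm(np.array(cands[0].position) - np.array(truth[0].position)) <= 1

    def test_floor_above_noise_gives_no_candidates(self):
        spec = VolumeSpec(shape=(32, 32, 16), n_cells=0, seed=1)
        vol, _ = generate_volume(spec)
        cands = propose_candidates(vol, DetectionParams(intensity_floor=1.0))
        assert cands == []

    def test_candidate_recall_on_benchmark(self, default_params):
        spec = VolumeSpec(seed=1)  # 50 cells, SNR 10
        vol, truth = generate_volume(spec)
        cands = propose_candidates(vol, default_params)
        m = match_detections(cands, truth, 2 * spec.blob_sigma, spec.voxel_size)
        assert m["recall"] >= 0.95

    def test_translation_equivariance(self, default_params):
        spec = VolumeSpec(shape=(32, 32, 16), n_cells=1, background_sd=0.0, seed=3)
        vol, truth = generate_volume(spec)
        shift = (3, 2, 1)
        shifted = ImageVolume(np.roll(vol.data, shift, axis=(0, 1, 2)), vol.voxel_size)
        a = propose_candidates(vol, default_params)[0].position
        b = propose_candidates(shifted, default_params)[0].position
        assert tuple(np.array(a) + shift) == b

    def test_raising_floor_never_adds_candidates(self, small_volume):
        _, vol, _ = small_volume
        counts = [
            len(propose_candidates(vol, DetectionParams(intensity_floor=f)))
            for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_scan(self, default_params):
        spec = VolumeSpec(shape=(32, 32, 16), n_cells=5, seed=11)
        vol, _ = generate_volume(spec)
        got = sorted(c.position for c in propose_candidates(vol, default_params))
        assert got == sorted(brute_force_maxima(vol, default_params))


def brute_force_maxima(vol, params):
    """Independent exhaustive scan: above-floor voxels that dominate their 26
    in-bounds neighbours, then greedy brightest-first physical separation."""
    sm = smooth(vol, params.smoothing_sigma)
    floor = params.intensity_floor * sm.max()
    nx, ny, nz = sm.shape
    peaks = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = sm[x, y, z]
                if v <= floor:
                    continue
                neigh = sm[
                    max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
                ]
                if v >= neigh.max() and (neigh == v).sum() == 1:
                    peaks.append((x, y, z))
    vs = np.asarray(vol.voxel_size)
    kept = []
    for p in sorted(peaks, key=lambda p: (-sm[p], p)):
        pu = np.asarray(p) * vs
        if all(np.linalg.norm(pu - np.asarray(q) * vs) >= params.min_peak_separation for q in kept):
            kept.append(p)
    return kept


class TestCurvatureFilter:
    def test_gaussian_peak_passes(self, noiseless_single_blob, default_params):
        _, vol, _ = noiseless_single_blob
        cands = propose_candidates(vol, default_params)
        out = filter_curvature_intensity(vol, cands, default_params)
        assert out[0].state == "candidate"
        assert out[0].blobness > 0

    def test_ridge_rejected(self):
        # a line of Gaussian cross-section: zero curvature along the ridge
        x = np.arange(32)[:, None, None]
        data = 100 + 1000 * np.exp(-0.5 * ((x - 16) / 3.0) ** 2) * np.ones((32, 32, 16))
        vol = ImageVolume(np.broadcast_to(data, (32, 32, 16)).copy(), (1.0, 1.0, 1.0))
        params = DetectionParams(smoothing_sigma=1.0, intensity_floor=0.5)
        cand = CellCentroid(position=(16, 16, 8), peak_intensity=float(vol.data.max()))
        out = filter_curvature_intensity(vol, [cand], params)
        assert out[0].blobness == 0.0
        assert out[0].state == "rejected_filter"

    def test_hessian_matches_quadratic_oracle(self):
        # f = 5 - a x^2 - b y^2 - c z^2 + d x y has a constant known Hessian
        a, b, c, d = 0.7, 0.4, 0.9, 0.2
        g = np.mgrid[-2:3, -2:3, -2:3].astype(float)
        f = 5.0 - a * g[0] ** 2 - b * g[1] ** 2 - c * g[2] ** 2 + d * g[0] * g[1]
        H = hessian_at(f, (1.0, 1.0, 1.0), (2, 2, 2))
        expected = np.array([[-2 * a, d, 0], [d, -2 * b, 0], [0, 0, -2 * c]])
        np.testing.assert_allclose(H, expected, atol=1e-10)
        eig = np.linalg.eigvalsh(expected)
        assert blobness_score(H) == pytest.approx(np.cbrt(abs(np.prod(eig))))


class TestPatches:
    def test_patch_shape_exact(self, small_volume):
        _, vol, truth = small_volume
        pairs, rejected = extract_patches(vol, truth, (16, 16, 8))
        assert rejected == []
        assert all(p.shape == (16, 16, 8) for _, p in pairs)
        assert all(0.0 <= p.min() and p.max() <= 1.0 for _, p in pairs)

    def test_corner_centroid_border_rejected(self, small_volume):
        _, vol, _ = small_volume
        pairs, rejected = extract_patches(vol, [CellCentroid(position=(0, 0, 0))], (16, 16, 8))
        assert pairs == []
        assert rejected[0].state == "rejected_border"

    def test_constant_patch_normalises_to_zeros(self):
        vol = ImageVolume(np.full((20, 20, 10), 3.0), (1, 1, 1))
        pairs, _ = extract_patches(vol, [CellCentroid(position=(10, 10, 5))], (8, 8, 4))
        assert np.all(pairs[0][1] == 0.0)

    def test_oversized_patch_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="exceeds"):
            extract_patches(vol, [], (16, 16, 8))


@pytest.mark.parametrize(
    "voxel_size, patch_shape, expected",
    [
        ((1.8, 1.8, 2.0), (16, 16, 8), (28.8, 28.8, 16.0)),
        ((1, 1, 1), (16, 16, 8), (16.0, 16.0, 8.0)),
        ((2.34, 2.34, 5), (16, 16, 8), (37.44, 37.44, 40.0)),
    ],
)
def test_patch_physical_extent(voxel_size, patch_shape, expected):
    assert patch_physical_extent(voxel_size, patch_shape) == pytest.approx(expected)


@pytest.fixture(scope="module")
def training_patches():
    return generate_training_patches(VolumeSpec(n_distractors=40), seeds=(11, 12))


class TestPatchClassifier:
    def test_holdout_accuracy_on_synthetic(self, training_patches):
        pos, neg = training_patches
        clf = train_patch_classifier(pos, neg, seed=0)
        assert clf.holdout_accuracy_ >= 0.85

    def test_deterministic_given_seed(self, training_patches):
        pos, neg = training_patches
        a = train_patch_classifier(pos, neg, seed=3).holdout_accuracy_
        b = train_patch_classifier(pos, neg, seed=3).holdout_accuracy_
        assert a == b

    def test_too_few_examples_rejected(self, training_patches):
        pos, neg = training_patches
        with pytest.raises(ValueError, match=">= 50"):
            train_patch_classifier(pos[:10], neg[:10])

    def test_gross_imbalance_rejected(self, training_patches):
        pos, neg = training_patches
        with pytest.raises(ValueError, match="imbalance"):
            train_patch_classifier(pos * 15, neg[:60])

    def test_threshold_extremes(self, small_volume, training_patches):
        _, vol, truth = small_volume
        pos, neg = training_patches
        clf = train_patch_classifier(pos, neg, seed=0)
        pairs, _ = extract_patches(vol, truth, (16, 16, 8))
        everyone = classify_candidates(clf, pairs, classifier_threshold=0.0)
        nobody = classify_candidates(clf, pairs, classifier_threshold=1.0 + 1e-9)
        assert all(c.state == "accepted" for c in everyone)
        assert all(c.state == "rejected_classifier" for c in nobody)
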