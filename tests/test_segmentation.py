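import numpy as np
import pytest

from brainmatch.errors import SegmentationError
from brainmatch.registration import RigidParams, build_rigid_matrix
from brainmatch.segmentation import (
    CSF,
    GM,
    OTHER,
    WM,
    SegmentationConfig,
    TissueProbabilities,
    binarize_gray_matter,
    em_segment,
    gaussian_density,
    map_priors,
    otsu_threshold,
    update_cluster_stats,
)
from brainmatch.volume_io import TissuePriorSet, Volume


def _smooth_priors(rng, shape=(8, 8, 8)):
    raw = rng.random(shape + (4,)) * 0.8 + 0.1
    return TissuePriorSet(raw)


class TestMapPriors:
    def test_identity_returns_priors(self, rng):
        ps = _smooth_priors(rng)
        target = Volume(np.zeros(ps.shape))
        out = map_priors(ps, np.eye(4), target)
        np.testing.assert_allclose(out.p, ps.priors, atol=1e-12)

    def test_integer_translation_shifts(self, rng):
        ps = _smooth_priors(rng, (10, 10, 10))
        target = Volume(np.zeros(ps.shape))
        # template -> image translation by +2 voxels along x: sampled at x - 2
        m = build_rigid_matrix(RigidParams(tx=2.0))
        out = map_priors(ps, m, target)
        np.testing.assert_allclose(out.p[2:, :, :, :], ps.priors[:-2, :, :, :], atol=1e-12)
        # voxels mapping outside the prior field become pure "other"
        np.testing.assert_allclose(out.p[:2, :, :, OTHER], 1.0)

    def test_pointwise_interpolation_oracle(self, rng):
        from scipy import ndimage

        ps = _smooth_priors(rng, (12, 12, 12))
        target = Volume(np.zeros(ps.shape))
        m = build_rigid_matrix(RigidParams(0.4, -0.7, 0.2, 0.03, -0.02, 0.05))
        out = map_priors(ps, m, target)
        minv = np.linalg.inv(m)
        pts = rng.integers(3, 9, size=(20, 3)).astype(float)
        src = (minv[:3, :3] @ pts.T + minv[:3, 3:4])
        vals = np.stack(
            [
                ndimage.map_coordinates(ps.priors[..., k], src, order=1)
                for k in range(4)
            ]
        )
        vals /= vals.sum(axis=0, keepdims=True)
        for j, (i0, i1, i2) in enumerate(pts.astype(int)):
            np.testing.assert_allclose(out.p[i0, i1, i2], vals[:, j], atol=1e-6)

    def test_singular_transform_rejected(self, rng):
        ps = _smooth_priors(rng)
        with pytest.raises(SegmentationError):
            map_priors(ps, np.zeros((4, 4)), Volume(np.zeros(ps.shape)))


class TestClusterStats:
    def test_single_class_constant_image(self):
        p = np.zeros((4, 4, 4, 4))
        p[..., GM] = 1.0
        stats = update_cluster_stats(p, np.full((4, 4, 4), 42.0), sigma_floor=1e-4)
        assert stats.m[GM] == pytest.approx(64)
        assert stats.mu[GM] == pytest.approx(42.0)
        assert stats.sigma[GM] == pytest.approx(1e-4)

    def test_hard_half_split(self):
        n = 64
        p = np.zeros((n, 4))
        p[: n // 2, GM] = 1.0
        p[n // 2 :, WM] = 1.0
        f = np.concatenate([np.zeros(n // 2), np.full(n // 2, 10.0)])
        stats = update_cluster_stats(p, f)
        assert stats.mu[GM] == pytest.approx(0.0)
        assert stats.mu[WM] == pytest.approx(10.0)
        assert stats.m[GM] == stats.m[WM] == pytest.approx(n / 2)

    def test_matches_loop_oracle(self, rng):
        p = rng.random((200, 4))
        p /= p.sum(axis=1, keepdims=True)
        f = rng.normal(50, 10, 200)
        stats = update_cluster_stats(p, f)
        for k in range(4):
            m = sum(p[n, k] for n in range(200))
            mu = sum(p[n, k] * f[n] for n in range(200)) / m
            var = sum(p[n, k] * (f[n] - mu) ** 2 for n in range(200)) / m
            assert stats.m[k] == pytest.approx(m, abs=1e-9)
            assert stats.mu[k] == pytest.approx(mu, abs=1e-9)
            assert stats.sigma[k] == pytest.approx(var, abs=1e-9)

    def test_mass_conservation(self, rng):
        p = rng.random((500, 4))
        p /= p.sum(axis=1, keepdims=True)
        stats = update_cluster_stats(p, rng.random(500))
        assert stats.m.sum() == pytest.approx(500, rel=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(SegmentationError):
            update_cluster_stats(np.zeros((10, 4)), np.zeros(10))


class TestGaussianDensity:
    def test_peak_value_closed_form(self):
        assert gaussian_density(0.0, 0.0, 1.0 / (2 * np.pi)) == pytest.approx(1.0)

    def test_one_sigma_closed_form(self):
        sigma = 4.0  # variance
        peak = gaussian_density(0.0, 0.0, sigma)
        assert gaussian_density(np.sqrt(sigma), 0.0, sigma) == pytest.approx(
            peak * np.exp(-0.5)
        )

    def test_integrates_to_one(self):
        x = np.linspace(-30, 30, 20001)
        dens = gaussian_density(x, 0.0, 4.0)
        assert np.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_density(0.0, 0.0, 0.0)


def _two_class_fixture(rng, n=16):
    """Left half ~ N(30, 2^2) tagged GM, right half ~ N(70, 2^2) tagged WM.

    The priors are informative in the spatial sense of the pipeline's
    template priors: the two unused classes carry no prior mass anywhere.
    """
    data = np.empty((n, n, n))
    data[: n // 2] = rng.normal(30, 2, (n // 2, n, n))
    data[n // 2 :] = rng.normal(70, 2, (n // 2, n, n))
    truth = np.zeros((n, n, n), dtype=int)
    truth[n // 2 :] = 1
    priors = np.zeros((n, n, n, 4))
    priors[: n // 2, :, :, GM] = 0.9
    priors[: n // 2, :, :, WM] = 0.1
    priors[n // 2 :, :, :, WM] = 0.9
    priors[n // 2 :, :, :, GM] = 0.1
    return Volume(data), TissuePriorSet(priors), truth


class TestEmSegment:
    def test_two_class_parameter_recovery(self, rng):
        image, priors, truth = _two_class_fixture(rng)
        seg = em_segment(
            image, priors, np.eye(4), SegmentationConfig(prior_floor=0.0)
        )
        assert seg.stats.mu[GM] == pytest.approx(30, abs=1.0)
        assert seg.stats.mu[WM] == pytest.approx(70, abs=1.0)
        hard = np.argmax(seg.probabilities.p, axis=3)
        accuracy = np.mean((hard == WM) == (truth == 1))
        assert accuracy >= 0.99

    def test_one_hot_priors_fixed_point(self, rng):
        image, _, truth = _two_class_fixture(rng)
        onehot = np.zeros(image.shape + (4,))
        onehot[truth == 0, GM] = 1.0
        onehot[truth == 1, WM] = 1.0
        seg = em_segment(
            image,
            TissuePriorSet(onehot),
            np.eye(4),
            SegmentationConfig(prior_floor=0.0),
        )
        assert seg.converged
        np.testing.assert_allclose(seg.probabilities.p, onehot, atol=1e-3)

    def test_probabilities_sum_to_one_every_iteration(self, rng):
        image, priors, _ = _two_class_fixture(rng)
        seg = em_segment(image, priors, np.eye(4))
        assert seg.sum_dev_trace and max(seg.sum_dev_trace) < 1e-6
        p = seg.probabilities.p
        assert p.min() >= 0 and p.max() <= 1

    def test_constant_image_flagged_not_crashed(self, rng):
        priors = TissuePriorSet(rng.random((6, 6, 6, 4)) * 0.8 + 0.1)
        seg = em_segment(Volume(np.full((6, 6, 6), 3.0)), priors, np.eye(4))
        assert not seg.converged
        assert seg.n_iter == 0

    def test_monotone_stabilization(self, small_cfg, small_template, small_visit):
        """On phantom inputs the probability updates stabilize: each mean
        |delta p| lies below its value three iterations earlier."""
        from brainmatch.registration import estimate_rigid

        template, priors = small_template
        reg = estimate_rigid(small_visit.volume, template)
        seg = em_segment(
            small_visit.volume, priors, np.linalg.inv(reg.matrix),
            SegmentationConfig(tol=1e-12, max_iter=20),
        )
        d = seg.delta_trace
        assert len(d) >= 4
        for i in range(3, len(d)):
            assert d[i] < d[i - 3]

    def test_flat_priors_match_reference_gmm(self, rng):
        """Bimodal limit: with flat priors over two admitted classes the
        update reduces to unsupervised Gaussian mixture fitting."""
        from sklearn.mixture import GaussianMixture

        image, _, _ = _two_class_fixture(rng, n=12)
        flat = np.zeros(image.shape + (4,))
        # flat up to a tiny symmetry-breaking jitter (the exactly-flat field
        # is a symmetric fixed point of any mixture update)
        jitter = 0.02 * rng.random(image.shape)
        flat[..., GM] = 0.5 + jitter
        flat[..., WM] = 0.5 - jitter
        seg = em_segment(
            image,
            TissuePriorSet(flat),
            np.eye(4),
            SegmentationConfig(prior_floor=0.0, max_iter=100, tol=1e-7),
        )
        gmm = GaussianMixture(n_components=2, random_state=0, tol=1e-7).fit(
            image.astype_float().reshape(-1, 1)
        )
        ref = np.sort(gmm.means_.ravel())
        est = np.sort([seg.stats.mu[GM], seg.stats.mu[WM]])
        np.testing.assert_allclose(est, ref, rtol=0.01)


class TestOtsu:
    def test_separates_two_levels(self):
        vals = np.array([0.05] * 50 + [0.95] * 50)
        thr = otsu_threshold(vals)
        assert 0.05 < thr < 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.beta(2, 8, 400), rng.beta(8, 2, 300)]
        )
        counts, edges = np.histogram(vals, bins=256, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_var = None, -1.0
        total = counts.sum()
        for cut in range(1, 256):
            w0 = counts[:cut].sum()
            w1 = total - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (counts[:cut] * centers[:cut]).sum() / w0
            mu1 = (counts[cut:] * centers[cut:]).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
            if var > best_var:
                best_var, best = var, edges[cut]
        assert otsu_threshold(vals) == pytest.approx(best, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(SegmentationError):
            otsu_threshold(np.full(100, 0.5))


class TestBinarize:
    def _result_from_gm(self, gm):
        p = np.zeros(gm.shape + (4,))
        p[..., GM] = gm
        p[..., OTHER] = 1 - gm
        from brainmatch.segmentation import ClusterStats, SegmentationResult

        return SegmentationResult(
            probabilities=TissueProbabilities(p),
            stats=ClusterStats(np.ones(4), np.zeros(4), np.ones(4)),
            n_iter=1,
            converged=True,
            delta_trace=[0.0],
        )

    def test_one_hot_mask_recovered(self, rng):
        gm = (rng.random((8, 8, 8)) > 0.6).astype(float)
        mask = binarize_gray_matter(self._result_from_gm(gm))
        np.testing.assert_array_equal(mask.mask, gm.astype(np.uint8))
        assert 0 < mask.threshold < 1

    def test_all_zero_gm_rejected(self):
        with pytest.raises(SegmentationError, match="empty gray matter"):
            binarize_gray_matter(self._result_from_gm(np.zeros((6, 6, 6))))


def test_phantom_segmentation_gm_dice(small_cfg, small_template, small_visit):
    """End-to-end on a phantom: GM mask overlaps ground truth."""
    from brainmatch.phantom import LABEL_GM
    from brainmatch.registration import estimate_rigid

    template, priors = small_template
    reg = estimate_rigid(small_visit.volume, template)
    seg = em_segment(small_visit.volume, priors, np.linalg.inv(reg.matrix))
    mask = binarize_gray_matter(seg)
    truth = small_visit.labels == LABEL_GM
    est = mask.mask.astype(bool)
    dice = 2 * np.logical_and(est, truth).sum() / (est.sum() + truth.sum())
    assert dice >= 0.90
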