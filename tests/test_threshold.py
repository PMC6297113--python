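"""Thresholding criteria vs brute-force and reference implementations."""

import numpy as np
import pytest

import mfbiclust as mb
from mfbiclust.factorize import FactorizationResult

METHODS = ["otsu", "fcm", "iter", "maxen"]


def _apply(method, values, **kw):
    return mb.apply_threshold(values, mb.ThresholdSpec(method=method, **kw))


def _blobs(rng, n_low=30, n_high=12, low=(0.0, 0.2), high=(0.7, 1.0)):
    v = np.concatenate(
        [rng.uniform(*low, size=n_low), rng.uniform(*high, size=n_high)]
    )
    rng.shuffle(v)
    return v


@pytest.mark.parametrize("method", METHODS)
class TestCommonBehaviour:
    def test_two_point_masses_select_the_high_group(self, method):
        values = np.array([0.0] * 4 + [1.0] * 4)
        mv = _apply(method, values)
        np.testing.assert_array_equal(mv.mask, values == 1.0)

    def test_constant_vector_yields_empty_mask_with_warning(self, method):
        with pytest.warns(UserWarning):
            mv = _apply(method, np.full(10, 3.3))
        assert not mv.mask.any()

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 3.0), (10.0, -5.0)])
    def test_invariant_to_positive_affine_rescaling(self, method, a, b):
        rng = np.random.default_rng(99)
        values = _blobs(rng)
        base = _apply(method, values)
        scaled = _apply(method, a * values + b)
        np.testing.assert_array_equal(base.mask, scaled.mask)

    def test_mask_marks_values_strictly_above_threshold(self, method):
        rng = np.random.default_rng(7)
        values = _blobs(rng)
        mv = _apply(method, values)
        if mv.threshold is not None:
            np.testing.assert_array_equal(mv.mask, values > mv.threshold)


@pytest.mark.parametrize("method", ["otsu", "iter", "fcm"])
def test_clearly_separated_blobs_are_split_at_the_gap(method):
    # Kapur's entropy criterion is excluded: on unbalanced blobs it may
    # legitimately place the cut inside the larger group
    rng = np.random.default_rng(7)
    values = _blobs(rng)
    mv = _apply(method, values)
    np.testing.assert_array_equal(mv.mask, values > 0.5)


class TestOtsu:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_exhaustive_between_class_variance_search(self, seed):
        rng = np.random.default_rng(seed)
        v = _blobs(rng, n_low=25, n_high=15)
        s = (v - v.min()) / np.ptp(v)
        # oracle: try every midpoint between consecutive distinct values and
        # maximize w0*w1*(mu0-mu1)^2 computed from the raw points
        best_cut, best_score = None, -1.0
        for cut in (np.unique(s)[:-1] + np.unique(s)[1:]) / 2:
            hi = s > cut
            w1 = hi.mean()
            w0 = 1 - w1
            score = w0 * w1 * (s[hi].mean() - s[~hi].mean()) ** 2
            if score > best_score:
                best_cut, best_score = cut, score
        mv = mb.otsu_threshold(v, n_bins=512)
        np.testing.assert_array_equal(mv.mask, s > best_cut)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_agrees_with_skimage_reference(self, seed):
        filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(seed)
        v = _blobs(rng)
        s = (v - v.min()) / np.ptp(v)
        ref = filters.threshold_otsu(s, nbins=256)
        mv = mb.otsu_threshold(v, n_bins=256)
        mine = (mv.threshold - v.min()) / np.ptp(v)
        # skimage reports the bin center, we report the bin edge: the two
        # cuts agree to within one histogram bin and induce the same split
        # away from that bin
        lo_t, hi_t = sorted([ref, mine])
        assert hi_t - lo_t <= 1.0 / 256 + 1e-12
        outside = (s <= lo_t) | (s > hi_t)
        np.testing.assert_array_equal(mv.mask[outside], (s > ref)[outside])


class TestIterativeSelection:
    def test_symmetric_two_point_fixed_point_is_half(self):
        values = np.array([0.0] * 4 + [1.0] * 4)
        mv = mb.iterative_threshold(values)
        assert mv.threshold == pytest.approx(0.5)
        np.testing.assert_array_equal(mv.mask, values == 1.0)

    def test_matches_otsu_on_separated_levels(self):
        values = np.array([0.0, 10.0] * 6)
        np.testing.assert_array_equal(
            mb.iterative_threshold(values).mask, mb.otsu_threshold(values).mask
        )

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_agrees_with_skimage_isodata_on_blobs(self, seed):
        filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(seed)
        v = _blobs(rng)
        s = (v - v.min()) / np.ptp(v)
        ref = filters.threshold_isodata(s, nbins=512)
        np.testing.assert_array_equal(mb.iterative_threshold(v).mask, s > ref)


class TestMaxEntropy:
    def test_even_two_level_histogram_splits_between_levels(self):
        values = np.array([0.1] * 8 + [0.9] * 8)
        mv = mb.maxent_threshold(values)
        np.testing.assert_array_equal(mv.mask, values > 0.5)

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_agrees_with_plain_loop_kapur_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = _blobs(rng, n_low=20, n_high=20)
        n_bins = 64
        s = (v - v.min()) / np.ptp(v)
        counts, edges = np.histogram(s, bins=n_bins, range=(0, 1))
        p = counts / counts.sum()
        best_cut, best = None, -np.inf
        for t in range(1, n_bins):
            p0, p1 = p[:t], p[t:]
            P0, P1 = p0.sum(), p1.sum()
            if P0 <= 0 or P1 <= 0:
                continue
            h0 = -sum(q / P0 * np.log(q / P0) for q in p0 if q > 0)
            h1 = -sum(q / P1 * np.log(q / P1) for q in p1 if q > 0)
            if h0 + h1 > best:
                best, best_cut = h0 + h1, edges[t]
        mv = mb.maxent_threshold(v, n_bins=n_bins)
        np.testing.assert_array_equal(mv.mask, s > best_cut)


class TestFCM:
    def test_well_separated_clusters_assign_high_group(self):
        values = np.array([0.0, 0.01, -0.01, 0.005, 1.0, 0.99, 1.01, 0.995])
        mv = mb.fcm_membership(values)
        np.testing.assert_array_equal(mv.mask, values > 0.5)

    def test_small_fuzzifier_limit_matches_hard_two_means(self):
        rng = np.random.default_rng(5)
        values = np.sort(rng.uniform(0, 1, size=10))
        # exhaustive 2-means: best contiguous split of the sorted values
        best_split, best_sse = None, np.inf
        for cut in range(1, 10):
            lo, hi = values[:cut], values[cut:]
            sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if sse < best_sse:
                best_sse, best_split = sse, cut
        expected = np.arange(10) >= best_split
        mv = mb.fcm_membership(values, fuzzifier=1.05)
        np.testing.assert_array_equal(mv.mask, expected)


class TestExtractBiclusters:
    def test_noiseless_blocks_recovered_exactly(self, blocks_noiseless, blocks_noiseless_fit):
        found = mb.extract_biclusters(blocks_noiseless_fit, mb.ThresholdSpec(method="otsu"))
        report = mb.overall_match_score(found, blocks_noiseless.truth)
        assert report.overall == 1.0

    def test_constant_factor_is_dropped(self):
        W = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])
        H = np.vstack([np.ones(5), np.array([1, 1, 0, 0, 0.0])])
        fit = FactorizationResult(
            W=W, H=H, k=2, objective_trace=np.array([0.0]), method="nmf",
            seed=0, restarts=1, converged=True,
            row_labels=[f"S{i}" for i in range(6)], col_labels=[f"V{j}" for j in range(5)],
        )
        found = mb.extract_biclusters(fit)
        assert found.k == 1
        assert found[0].rows == frozenset({3, 4, 5})
        assert found[0].cols == frozenset({0, 1})

    def test_single_planted_block_at_rank_one(self):
        values = np.zeros((10, 12))
        rows, cols = range(2, 6), range(3, 8)
        values[np.ix_(rows, cols)] = 2.0
        fit = mb.nmf_fit(values, 1, seed=0, tol=1e-12, max_iter=1000)
        found = mb.extract_biclusters(fit)
        assert found.k == 1
        assert found[0].rows == frozenset(rows)
        assert found[0].cols == frozenset(cols)

    def test_pca_factors_use_dominant_positive_side(self, blocks_noiseless):
        fit = mb.pca_fit(blocks_noiseless.matrix, 3)
        found = mb.extract_biclusters(fit, mb.ThresholdSpec(method="otsu"))
        report = mb.overall_match_score(found, blocks_noiseless.truth)
        assert report.overall == 1.0
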