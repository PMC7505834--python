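"""Threshold algorithms against independent brute-force / fixpoint oracles."""

import numpy as np
import pytest

from octarep.images import GrayImage
from octarep.ops import adjust_contrast
from octarep.synthetic import NO_CLIP_RANGE, SubjectParams, make_retinal_template
from octarep.thresholding import (
    ALL_METHODS,
    GLOBAL_METHODS,
    LOCAL_METHODS,
    Histogram256,
    ThresholdSpec,
    binarize,
    binarize_global,
    binarize_local,
    disk_footprint,
    global_threshold,
)

# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def oracle_otsu(counts):
    """Exhaustive search of the between-class variance criterion."""
    n = counts.sum()
    best_t, best = 0, -1.0
    for t in range(256):
        c0 = counts[: t + 1].sum()
        c1 = n - c0
        if c0 == 0 or c1 == 0:
            continue
        mu0 = sum(v * counts[v] for v in range(t + 1)) / c0
        mu1 = sum(v * counts[v] for v in range(t + 1, 256)) / c1
        crit = c0 * c1 * (mu0 - mu1) ** 2
        if crit > best + 1e-9:
            best, best_t = crit, t
    return best_t


def oracle_intermeans_fixpoint(counts):
    """Smallest t in the occupied range with t == floor((mb + ma)/2)."""
    occ = np.nonzero(counts)[0]
    for t in range(occ[0], occ[-1]):
        nb = counts[: t + 1].sum()
        na = counts[t + 1:].sum()
        if nb == 0 or na == 0:
            continue
        mb = sum(v * counts[v] for v in range(t + 1)) / nb
        ma = sum(v * counts[v] for v in range(t + 1, 256)) / na
        if t == int((mb + ma) / 2):
            return t
    return (occ[0] + occ[-1]) // 2


def oracle_huang(counts):
    """Brute-force minimization of Huang's fuzzy-membership entropy."""
    occ = np.nonzero(counts)[0]
    lo, hi = occ[0], occ[-1]
    best_t, best = lo, np.inf
    for t in range(lo, hi):
        nb = counts[: t + 1].sum()
        na = counts[t + 1:].sum()
        mu0 = sum(v * counts[v] for v in range(t + 1)) / nb
        mu1 = sum(v * counts[v] for v in range(t + 1, 256)) / na
        s = 0.0
        for v in range(256):
            mu = mu0 if v <= t else mu1
            u = 1.0 / (1.0 + abs(v - mu) / (hi - lo))
            if 0 < u < 1:
                s -= counts[v] * (u * np.log(u) + (1 - u) * np.log(1 - u))
        if s < best - 1e-12:
            best, best_t = s, t
    return best_t


def random_histograms(n, rng):
    """Mixture of sparse and dense random 256-bin histograms."""
    out = []
    for _ in range(n):
        h = np.zeros(256, dtype=np.int64)
        k = rng.integers(2, 40)
        bins = rng.choice(256, size=k, replace=False)
        h[bins] = rng.integers(1, 500, size=k)
        out.append(h)
        out.append(rng.integers(0, 60, size=256).astype(np.int64))
    return out


class TestGlobalOracles:
    def test_otsu_matches_exhaustive_search(self, rng):
        for h in random_histograms(50, rng):
            got = global_threshold(Histogram256(h), "global_otsu")
            assert got == oracle_otsu(h)

    def test_isodata_matches_fixpoint_scan(self, rng):
        for h in random_histograms(50, rng):
            got = global_threshold(Histogram256(h), "global_isodata")
            assert got == oracle_intermeans_fixpoint(h)

    def test_default_matches_fixpoint_on_trimmed_histogram(self, rng):
        for h in random_histograms(50, rng):
            occ = np.nonzero(h)[0]
            trimmed = h.copy()
            trimmed[occ[0]] = 0
            trimmed[occ[-1]] = 0
            if trimmed.sum() == 0 or len(np.nonzero(trimmed)[0]) == 1:
                expected = (occ[0] + occ[-1]) // 2
            else:
                expected = oracle_intermeans_fixpoint(trimmed)
            assert global_threshold(Histogram256(h), "global_default") == expected

    def test_huang_matches_brute_force(self, rng):
        for h in random_histograms(15, rng):
            got = global_threshold(Histogram256(h), "global_huang")
            assert got == oracle_huang(h)

    def test_mean_is_floor_of_mean(self, rng):
        uniform = np.ones(256, dtype=np.int64)
        assert global_threshold(Histogram256(uniform), "global_mean") == 127
        for h in random_histograms(20, rng):
            expected = int(np.floor((np.arange(256) * h).sum() / h.sum()))
            assert global_threshold(Histogram256(h), "global_mean") == expected

    def test_default_differs_from_isodata_on_skewed_histogram(self):
        h = np.zeros(256, dtype=np.int64)
        h[0] = 10_000  # heavy mass at the darkest occupied bin
        h[80] = 50
        h[200] = 60
        h[255] = 5
        t_def = global_threshold(Histogram256(h), "global_default")
        t_iso = global_threshold(Histogram256(h), "global_isodata")
        assert t_def != t_iso

    def test_single_bin_histogram_warns(self):
        h = np.zeros(256, dtype=np.int64)
        h[42] = 100
        for method in GLOBAL_METHODS:
            with pytest.warns(UserWarning, match="degenerate"):
                assert global_threshold(Histogram256(h), method) == 42


class TestBinarizeGlobal:
    def test_single_bright_pixel_otsu(self):
        arr = np.zeros((8, 8), dtype=np.uint8)
        arr[3, 4] = 255
        out = binarize_global(GrayImage(arr, 10.0), ThresholdSpec("global_otsu"))
        assert out.pixels.sum() == 1
        assert out.pixels[3, 4] == 1

    def test_tie_rule_pixel_equal_threshold_is_black(self):
        # craft an image whose otsu threshold value itself occurs in the image
        arr = np.array([[10] * 4, [10] * 4, [200] * 4, [200] * 4], dtype=np.uint8)
        img = GrayImage(arr, 10.0)
        t = global_threshold(Histogram256.from_image(img), "global_otsu")
        out = binarize_global(img, ThresholdSpec("global_otsu"))
        assert ((arr > t) == out.mask).all()
        assert out.mask[arr == t].sum() == 0  # p == t -> black

    def test_constant_image_all_black(self):
        arr = np.full((8, 8), 99, dtype=np.uint8)
        with pytest.warns(UserWarning):
            out = binarize_global(GrayImage(arr, 10.0),
                                  ThresholdSpec("global_mean"))
        assert out.pixels.sum() == 0


def oracle_local(image, method, radius, params):
    """Direct per-pixel disc-neighborhood computation with replicate padding."""
    p = image.pixels.astype(float)
    h, w = p.shape
    pad = np.pad(image.pixels, radius, mode="edge")
    fp = disk_footprint(radius)
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            nb = pad[y:y + 2 * radius + 1, x:x + 2 * radius + 1][fp].astype(float)
            v = p[y, x]
            if method == "local_mean":
                t = nb.mean() - params["mean_c"]
            elif method == "local_median":
                t = np.median(nb) - params["median_c"]
            elif method == "local_niblack":
                t = nb.mean() + params["niblack_k"] * nb.std() - params["niblack_c"]
            elif method == "local_phansalkar":
                m, s = nb.mean() / 255, nb.std() / 255
                t = 255 * m * (1 + params["phansalkar_p"]
                               * np.exp(-params["phansalkar_q"] * m)
                               + params["phansalkar_k"]
                               * (s / params["phansalkar_r"] - 1))
            elif method == "local_otsu":
                t = oracle_otsu(np.bincount(nb.astype(int), minlength=256))
            elif method == "local_bernsen":
                mx, mn = nb.max(), nb.min()
                mid = (mx + mn) / 2
                if mx - mn < params["bernsen_contrast"]:
                    out[y, x] = mid > 128
                    continue
                t = mid
            out[y, x] = v > t
    return out


class TestLocalOracles:
    @pytest.mark.parametrize("method", LOCAL_METHODS)
    @pytest.mark.parametrize("radius", [3, 5])
    def test_matches_direct_neighborhood_computation(self, method, radius, rng):
        from octarep.thresholding import DEFAULT_METHOD_PARAMS

        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(np.uint8), 10.0)
        got = binarize_local(img, ThresholdSpec(method, radius_px=radius)).mask
        expected = oracle_local(img, method, radius, DEFAULT_METHOD_PARAMS)
        assert (got == expected).all()

    def test_low_contrast_image_exercises_ties(self, rng):
        img = GrayImage((rng.integers(0, 6, (24, 24)) * 3).astype(np.uint8), 10.0)
        from octarep.thresholding import DEFAULT_METHOD_PARAMS

        for method in ("local_otsu", "local_median", "local_bernsen"):
            got = binarize_local(img, ThresholdSpec(method, radius_px=4)).mask
            assert (got == oracle_local(img, method, 4,
                                        DEFAULT_METHOD_PARAMS)).all()


class TestLocalProperties:
    def test_constant_image_local_mean_all_black(self):
        img = GrayImage(np.full((32, 32), 120, dtype=np.uint8), 10.0)
        out = binarize_local(img, ThresholdSpec("local_mean", radius_px=5))
        assert out.pixels.sum() == 0  # p > p is false

    def test_bright_dot_on_dark_field_median(self):
        arr = np.full((40, 40), 30, dtype=np.uint8)
        arr[20, 20] = 250
        out = binarize_local(GrayImage(arr, 10.0),
                             ThresholdSpec("local_median", radius_px=15))
        assert out.pixels[20, 20] == 1
        assert out.pixels.sum() == 1

    def test_niblack_k0_equals_local_mean(self, random_image):
        a = binarize_local(random_image,
                           ThresholdSpec("local_niblack", radius_px=7,
                                         params={"niblack_k": 0.0}))
        b = binarize_local(random_image, ThresholdSpec("local_mean", radius_px=7))
        assert (a.pixels == b.pixels).all()

    def test_radius_larger_than_image_rejected(self, random_image):
        with pytest.raises(ValueError, match="radius"):
            binarize_local(random_image, ThresholdSpec("local_mean", radius_px=64))

    def test_median_invariant_under_monotone_transform(self):
        """Rank statistics commute with strictly increasing injective maps.

        On a no-clip phantom (intensities in [65, 191]) the contrast gains
        1.5 and 2.0 are strictly monotone and injective, so the local
        median binarization is bit-identical across gains — the mechanism
        behind perfect contrast-repeatability of rank-based thresholds.
        """
        img, _ = make_retinal_template(SubjectParams(rng_seed=7), 128,
                                       out_range=NO_CLIP_RANGE)
        assert img.pixels.min() >= 65 and img.pixels.max() <= 191
        spec = ThresholdSpec("local_median", radius_px=15)
        base = binarize_local(img, spec)
        for gain in (1.5, 2.0):
            out = binarize_local(adjust_contrast(img, gain), spec)
            assert (out.pixels == base.pixels).all()


class TestLocalGlobalConsistency:
    """With border='ignore' and radius >= diagonal, every neighborhood is the
    whole image, so local methods degenerate to their global formulas."""

    @pytest.fixture
    def small(self, rng):
        return GrayImage(rng.integers(0, 256, (16, 16)).astype(np.uint8), 10.0)

    def test_local_otsu_degenerates_to_global(self, small):
        radius = 2 * small.shape[0]  # > diagonal
        local = binarize_local(small, ThresholdSpec("local_otsu", radius_px=radius),
                               border="ignore")
        glob = binarize_global(small, ThresholdSpec("global_otsu"))
        assert (local.pixels == glob.pixels).all()

    def test_local_mean_degenerates_to_global(self, small):
        radius = 2 * small.shape[0]
        local = binarize_local(small, ThresholdSpec("local_mean", radius_px=radius),
                               border="ignore")
        glob = binarize_global(small, ThresholdSpec("global_mean"))
        assert (local.pixels == glob.pixels).all()

    def test_local_median_degenerates_to_image_median(self, small):
        radius = 2 * small.shape[0]
        local = binarize_local(small,
                               ThresholdSpec("local_median", radius_px=radius),
                               border="ignore")
        t = np.median(small.pixels)
        assert (local.mask == (small.pixels > t)).all()

    def test_local_niblack_k0_degenerates_to_global_mean(self, small):
        radius = 2 * small.shape[0]
        local = binarize_local(
            small,
            ThresholdSpec("local_niblack", radius_px=radius,
                          params={"niblack_k": 0.0}),
            border="ignore",
        )
        glob = binarize_global(small, ThresholdSpec("global_mean"))
        assert (local.pixels == glob.pixels).all()


def test_binarize_dispatch(random_image):
    for method in ALL_METHODS:
        out = binarize(random_image, ThresholdSpec(method, radius_px=5))
        assert out.shape == random_image.shape


def test_spec_validation():
    with pytest.raises(ValueError):
        ThresholdSpec("nonsense")
    with pytest.raises(ValueError):
        ThresholdSpec("local_mean", radius_px=0)
    with pytest.raises(ValueError):
        ThresholdSpec("local_mean", params={"bogus": 1.0})
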