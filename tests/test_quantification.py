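"""Thresholding against exhaustive oracles, co-localization, transects."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nafsim as nf
from nafsim.imaging import MODALITY_PRESETS
from nafsim.quantification import ThresholdError


# ---------------------------------------------------------------------------
# independent oracles


def otsu_exhaustive(image: np.ndarray, n_bins: int = 256) -> float:
    """Brute-force maximizer of between-class variance over histogram cuts."""
    counts, edges = np.histogram(image.ravel(), bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = None, -1.0
    for k in range(1, n_bins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:  # ties resolve to the lowest cut
            best_var, best_t = var, centers[k - 1]
    return best_t


def li_exhaustive_interval(
    image: np.ndarray, n_candidates: int = 512
) -> tuple[float, float]:
    """Brute-force minimization of the two-level cross entropy.

    Cross entropy depends on the induced partition only, so its minimizers
    form a plateau of thresholds; returns the (lowest, highest) minimizing
    candidate.
    """
    arr = image.ravel().astype(float)
    cands = np.linspace(arr.min(), arr.max(), n_candidates, endpoint=False)[1:]
    etas = []
    for t in cands:
        low, high = arr[arr <= t], arr[arr > t]
        if low.size == 0 or high.size == 0:
            etas.append(np.inf)
            continue
        eta = 0.0
        for cls in (low, high):
            mu = cls.mean()
            if mu > 0:
                pos = cls[cls > 0]
                eta += (pos * np.log(pos / mu)).sum()
        etas.append(eta)
    etas = np.asarray(etas)
    winners = cands[etas <= etas.min() + 1e-9 * (1.0 + abs(etas.min()))]
    return float(winners.min()), float(winners.max())


def random_bimodal(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """8-bit-like two-population image, the regime the thresholds target."""
    n = int(np.prod(shape))
    frac = rng.uniform(0.2, 0.8)
    lo = rng.normal(rng.uniform(30, 90), rng.uniform(5, 20), size=n)
    hi = rng.normal(rng.uniform(150, 220), rng.uniform(5, 20), size=n)
    pick = rng.random(n) < frac
    img = np.where(pick, lo, hi)
    return np.clip(np.round(img), 0, 255).reshape(shape)


# ---------------------------------------------------------------------------


class TestOtsuThreshold:
    def test_two_level_image_splits_the_levels(self):
        img = np.array([0.0] * 50 + [255.0] * 50)
        t = nf.otsu_threshold(img)
        assert 0.0 < t < 255.0
        assert abs(t - otsu_exhaustive(img)) <= 255.0 / 256.0

    def test_spec_histogram_matches_exhaustive_maximizer(self):
        levels = np.repeat(np.arange(8.0), [10, 8, 0, 0, 0, 0, 9, 11])
        t = nf.otsu_threshold(levels, n_bins=8)
        assert 1.0 <= t < 6.0
        assert abs(t - otsu_exhaustive(levels, n_bins=8)) <= 7.0 / 8.0

    def test_matches_oracle_on_random_images(self):
        rng = np.random.default_rng(42)
        bin_w = 255.0 / 256.0
        for _ in range(50):
            img = random_bimodal(rng)
            assert abs(nf.otsu_threshold(img) - otsu_exhaustive(img)) <= bin_w + 1e-9

    def test_constant_image_rejected(self):
        with pytest.raises(ThresholdError, match="constant"):
            nf.otsu_threshold(np.full((8, 8), 3.0))


class TestLiThreshold:
    def test_two_value_image_threshold_between_values(self):
        img = np.array([1.0] * 50 + [100.0] * 50)
        t = nf.li_threshold(img)
        assert 1.0 < t < 100.0
        lo, hi = li_exhaustive_interval(img)
        assert lo - 99.0 / 256.0 <= t <= hi + 99.0 / 256.0

    def test_matches_exhaustive_scan_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            img = random_bimodal(rng)
            bin_w = (img.max() - img.min()) / 256.0
            lo, hi = li_exhaustive_interval(img)
            assert lo - bin_w <= nf.li_threshold(img) <= hi + bin_w

    def test_agrees_with_reference_implementation(self):
        # scikit-image optimizes the min-shifted cross entropy (the objective
        # is not shift invariant), so compare on min-shifted images
        from skimage.filters import threshold_li

        rng = np.random.default_rng(11)
        for _ in range(10):
            img = random_bimodal(rng)
            ours = nf.li_threshold(img - img.min()) + img.min()
            assert ours == pytest.approx(float(threshold_li(img)), abs=1e-3)

    def test_constant_and_negative_images_rejected(self):
        with pytest.raises(ThresholdError, match="constant"):
            nf.li_threshold(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="non-negative"):
            nf.li_threshold(np.array([-1.0, 0.0, 5.0]))


class TestMaskPipeline:
    def test_zero_blur_equals_plain_threshold(self):
        rng = np.random.default_rng(3)
        img = random_bimodal(rng)
        plain = img > nf.otsu_threshold(img)
        mask = nf.mask_pipeline(img, "otsu", blur_sigma=0.0, second_threshold="otsu")
        assert np.array_equal(mask.grid, plain)

    def test_isolated_pixel_eliminated_but_structure_kept(self):
        img = np.zeros((256, 256))
        img[40:120, 40:120] = 200.0  # genuine structure
        img[220, 220] = 200.0  # isolated positive pixel
        mask = nf.mask_pipeline(img, ("manual", 100.0), blur_sigma=20.0,
                                second_threshold="li")
        assert not mask.grid[220, 220]
        assert mask.grid[80, 80]

    def test_provenance_records_both_stages(self):
        rng = np.random.default_rng(4)
        mask = nf.mask_pipeline(random_bimodal(rng))
        assert "otsu" in mask.provenance
        assert "sigma=20" in mask.provenance
        assert "li" in mask.provenance

    def test_constant_image_error_propagates(self):
        with pytest.raises(ThresholdError, match="constant"):
            nf.mask_pipeline(np.zeros((16, 16)))


class TestPearsonMasks:
    @staticmethod
    def mask(arr) -> nf.BinaryMask:
        return nf.BinaryMask(np.asarray(arr, bool), 1.0, "test")

    def test_identical_masks_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        m = self.mask(rng.random((20, 20)) > 0.5)
        assert nf.pearson_masks(m, m) == pytest.approx(1.0)

    def test_complementary_masks_anticorrelate(self):
        a = self.mask([[1, 1], [0, 0]])
        b = self.mask([[0, 0], [1, 1]])
        assert nf.pearson_masks(a, b) == pytest.approx(-1.0)

    def test_orthogonal_hand_case_is_zero(self):
        a = self.mask([1, 1, 0, 0])
        b = self.mask([1, 0, 1, 0])
        assert nf.pearson_masks(a, b) == pytest.approx(0.0)

    def test_shape_mismatch_and_constant_mask_rejected(self):
        a = self.mask([1, 0, 1])
        with pytest.raises(ValueError, match="shapes"):
            nf.pearson_masks(a, self.mask([1, 0]))
        with pytest.raises(ValueError, match="constant"):
            nf.pearson_masks(a, self.mask([1, 1, 1]))


class TestTriClass:
    @staticmethod
    def mask(arr) -> nf.BinaryMask:
        return nf.BinaryMask(np.asarray(arr, bool), 1.0, "test")

    def test_hand_counted_partition(self):
        res = nf.tri_class(self.mask([1, 1, 0, 0]), self.mask([0, 1, 1, 0]))
        assert res.counts == {"pet_only": 1, "both": 1, "ct_only": 1}
        for v in res.percentages.values():
            assert v == pytest.approx(100.0 / 3.0)

    @pytest.mark.parametrize(
        "pet, ct, expected",
        [
            ([1, 1, 1], [0, 0, 0], (100.0, 0.0, 0.0)),
            ([1, 0, 1], [1, 0, 1], (0.0, 100.0, 0.0)),
            ([0, 0, 0], [1, 1, 0], (0.0, 0.0, 100.0)),
        ],
    )
    def test_degenerate_overlaps(self, pet, ct, expected):
        res = nf.tri_class(self.mask(pet), self.mask(ct))
        got = tuple(res.percentages[k] for k in ("pet_only", "both", "ct_only"))
        assert got == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nf.tri_class(self.mask([0, 0]), self.mask([0, 0]))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_percentages_always_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        pet = rng.random((12, 12)) > rng.uniform(0.05, 0.95)
        ct = rng.random((12, 12)) > rng.uniform(0.05, 0.95)
        if not (pet.any() or ct.any()):
            return
        res = nf.tri_class(self.mask(pet), self.mask(ct))
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.1)


class TestHuCalcificationMask:
    def test_inclusive_1000_hu_boundary(self):
        img = nf.ImageVolume(
            np.array([[999.0, 1000.0, 1001.0]]),
            22.0,
            MODALITY_PRESETS["truth_hu"],
        )
        mask = nf.hu_calcification_mask(img)
        assert mask.grid.tolist() == [[False, True, True]]

    def test_air_volume_yields_empty_mask(self):
        img = nf.ImageVolume(np.full((4, 4), -1000.0), 500.0, MODALITY_PRESETS["truth_hu"])
        assert nf.hu_calcification_mask(img).n_positive == 0

    def test_activity_image_rejected(self):
        img = nf.ImageVolume(np.ones((4, 4)), 300.0, MODALITY_PRESETS["micro_pet"])
        with pytest.raises(ValueError, match="non-CT"):
            nf.hu_calcification_mask(img)

    def test_micro_ct_render_recovers_macro_deposit_voxels(self, default_study):
        phantom, _, hu = default_study
        prof = replace(MODALITY_PRESETS["micro_ct"], noise_model="none")
        ct = nf.apply_modality(hu, prof)
        mask = nf.hu_calcification_mask(ct)
        up = nf.upsample_mask(mask, phantom.grid.shape, phantom.voxel_size)
        macro_ids = [
            i + 1
            for i, d in enumerate(phantom.deposits)
            if nf.classify_deposit(d) == "macro"
        ]
        macro = np.isin(phantom.deposit_map, macro_ids)
        recovered = (up.grid & macro).sum() / macro.sum()
        assert recovered >= 0.95


class TestTransectProfile:
    @staticmethod
    def uniform_pair(value=3.0, hu=40.0):
        pet = nf.ImageVolume(np.full((40, 40), value), 100.0, MODALITY_PRESETS["truth_activity"])
        ct = nf.ImageVolume(np.full((40, 40), hu), 100.0, MODALITY_PRESETS["truth_hu"])
        return pet, ct

    def test_uniform_field_gives_constant_profile(self):
        pet, ct = self.uniform_pair()
        tp = nf.transect_profile(pet, ct, (500.0, 500.0), (3500.0, 3500.0), 50)
        assert np.allclose(tp.pet_values, 3.0)
        assert np.allclose(tp.ct_values, 40.0)
        assert np.all(np.diff(tp.positions_mm) > 0)

    def test_two_samples_are_the_endpoints(self):
        pet, ct = self.uniform_pair()
        tp = nf.transect_profile(pet, ct, (0.0, 0.0), (4000.0, 0.0), 2)
        assert tp.positions_mm.tolist() == [0.0, 4.0]

    def test_line_exiting_volume_rejected(self):
        pet, ct = self.uniform_pair()
        with pytest.raises(ValueError, match="exits"):
            nf.transect_profile(pet, ct, (0.0, 0.0), (9000.0, 0.0), 10)

    def test_unsectioned_macro_deposit_shows_rim_maxima_and_ct_plateau(
        self, printed_params
    ):
        cfg = nf.PhantomConfig(
            domain_size_um=(4000.0, 4000.0), voxel_size_um=5.0, n_micro=0, n_macro=1,
            macro_radius_um=(500.0, 500.0), mineral_density_range=(1.0, 1.0),
        )
        ph = nf.generate_phantom(cfg, seed=7)
        dep = ph.deposits[0]
        amap = nf.simulate_uptake(ph, printed_params, penetration_depth=20.0)
        hu = nf.mineral_to_hu(ph)
        pet = nf.apply_modality(
            amap, replace(MODALITY_PRESETS["micro_pet"], noise_model="none")
        )
        ct = nf.apply_modality(
            hu, replace(MODALITY_PRESETS["micro_ct"], noise_model="none")
        )
        c = np.asarray(dep.center)
        tp = nf.transect_profile(pet, ct, c - [800.0, 0.0], c + [800.0, 0.0], 161)
        pos = tp.positions_mm
        core = tp.pet_values[(pos > 0.7) & (pos < 0.9)].mean()
        left = tp.pet_values[pos < 0.8].max()
        right = tp.pet_values[pos >= 0.8].max()
        assert left > core and right > core
        # CT: a single >=1000 HU plateau across the deposit interior
        assert tp.ct_values[(pos > 0.5) & (pos < 1.1)].min() >= 1000.0
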