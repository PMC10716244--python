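"""Preprocessing chain: denoise, background removal, contour, splitting,
MSRCR, discolor-region segmentation."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk

from leafkdx import synthgen
from leafkdx.preprocess import (
    DegenerateContourError,
    EmptySegmentationError,
    MSRCRParams,
    MultipleComponentsError,
    SegmentationParams,
    contour_perimeter,
    extract_contour,
    gaussian_denoise,
    msrcr,
    segment_green,
    segment_leaf,
    segment_regions,
    split_leaves,
)


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


# ---------------------------------------------------------------- denoise


def test_denoise_preserves_constant_image():
    img = np.full((32, 32, 3), 77, np.uint8)
    assert np.array_equal(gaussian_denoise(img), img)


def test_denoise_shrinks_impulse():
    img = np.zeros((21, 21), np.uint8)
    img[10, 10] = 255
    out = gaussian_denoise(img)
    assert out.max() < img.max()
    assert out.shape == img.shape


def test_denoise_reduces_noise_variance(symptomatic_leaf):
    _, img, truth = symptomatic_leaf
    rng = np.random.default_rng(0)
    noisy = img.astype(float).copy()
    salt = rng.random(img.shape[:2]) < 0.05
    pepper = rng.random(img.shape[:2]) < 0.05
    noisy[salt] = 255
    noisy[pepper] = 0
    noisy = noisy.astype(np.uint8)
    den = gaussian_denoise(noisy)
    for c in range(3):
        assert den[..., c][truth.leaf_mask].var() < noisy[..., c][truth.leaf_mask].var()


def test_denoise_rejects_even_ksize():
    with pytest.raises(ValueError, match="odd"):
        gaussian_denoise(np.zeros((8, 8, 3), np.uint8), ksize=4)


def test_denoise_is_linear_up_to_rounding():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 100, (24, 24, 3)).astype(np.uint8)
    a2 = gaussian_denoise((2 * img.astype(int)).astype(np.uint8))
    twice = 2 * gaussian_denoise(img).astype(int)
    assert np.abs(a2.astype(int) - twice).max() <= 2  # ±1 rounding on each side


# ---------------------------------------------------------------- background


def test_segment_leaf_matches_truth(symptomatic_leaf):
    _, img, truth = symptomatic_leaf
    mask = segment_leaf(gaussian_denoise(img))
    assert iou(mask, truth.leaf_mask) >= 0.95


def test_segment_leaf_pure_background_errors():
    img = np.full((64, 64, 3), (214, 214, 210), np.uint8)
    with pytest.raises(EmptySegmentationError):
        segment_leaf(img)


def test_segment_leaf_full_green_frame():
    img = np.full((64, 64, 3), (58, 138, 62), np.uint8)
    assert segment_leaf(img).all()


# ---------------------------------------------------------------- contour


def test_square_contour_is_the_36_boundary_pixels():
    """Brute-force oracle: boundary = mask minus its 8-connected erosion."""
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    boundary = mask & ~ndi.binary_erosion(mask, structure=np.ones((3, 3)))
    contour = extract_contour(mask)
    assert len(contour) == boundary.sum() == 36
    assert {tuple(p) for p in contour} == set(map(tuple, np.argwhere(boundary)))
    assert contour_perimeter(contour) == 36.0


def test_tiny_mask_raises():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    with pytest.raises(DegenerateContourError):
        extract_contour(mask)


def test_multi_component_mask_raises():
    mask = np.zeros((10, 10), bool)
    mask[1:4, 1:4] = True
    mask[6:9, 6:9] = True
    with pytest.raises(MultipleComponentsError):
        extract_contour(mask)


def test_disk_perimeter_near_circumference():
    mask = np.zeros((120, 120), bool)
    rr, cc = draw_disk((60, 60), 50)
    mask[rr, cc] = True
    per = contour_perimeter(extract_contour(mask))
    assert abs(per - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.10


def test_contour_fill_roundtrip(random_leaf_batch):
    """Tracing then hole-filling reconstructs simply-connected masks exactly."""
    for _, _, truth in random_leaf_batch[:10]:
        mask = truth.leaf_mask
        contour = extract_contour(mask)
        boundary = np.zeros_like(mask)
        boundary[contour[:, 0], contour[:, 1]] = True
        assert np.array_equal(ndi.binary_fill_holes(boundary), mask)


# ---------------------------------------------------------------- splitting


def test_split_finds_all_placed_leaves():
    rng = np.random.default_rng(4)
    board = np.full((420, 420, 3), (214, 214, 210), np.uint8)
    centers = [(70 + 140 * i, 70 + 140 * j) for i in range(3) for j in range(3)]
    for k, (cy, cx) in enumerate(centers):
        img, truth = synthgen.make_leaf(
            synthgen.LeafParams(image_size=(128, 128), leaf_axes=(40, 25), seed=k)
        )
        sl = np.s_[cy - 64 : cy + 64, cx - 64 : cx + 64]
        board[sl] = np.where(truth.leaf_mask[..., None], img, board[sl])
    mask = segment_leaf(board)
    # the board holds 9 disjoint leaves but segment_leaf keeps only the largest;
    # split on the full foreground instead
    from skimage import filters

    exg = 2.0 * board[..., 1].astype(float) - board[..., 0] - board[..., 2]
    fg = ndi.binary_fill_holes(exg > filters.threshold_otsu(exg))
    parts = split_leaves(fg, board)
    assert len(parts) == 9
    assert mask.sum() <= fg.sum()


def test_split_empty_mask_gives_empty_list():
    assert split_leaves(np.zeros((10, 10), bool), np.zeros((10, 10, 3), np.uint8)) == []


def test_split_ordering_top_then_left():
    mask = np.zeros((60, 60), bool)
    mask[2:12, 40:50] = True  # top-right
    mask[30:40, 2:12] = True  # bottom-left
    parts = split_leaves(mask, np.zeros((60, 60, 3), np.uint8), pad=0)
    assert parts[0][1].shape == (10, 10)
    # first crop corresponds to the topmost component
    assert parts[0][1].sum() == 100 and parts[1][1].sum() == 100


def test_split_discards_tiny_components():
    mask = np.zeros((40, 40), bool)
    mask[5:25, 5:25] = True
    mask[35, 35] = True  # 1-px speck
    parts = split_leaves(mask, np.zeros((40, 40, 3), np.uint8))
    assert len(parts) == 1


# ---------------------------------------------------------------- msrcr


def test_msrcr_constant_image_stays_flat():
    img = np.full((48, 48, 3), 128, np.uint8)
    out = msrcr(img)
    assert out.astype(float).std() < 2.0


def test_msrcr_flattens_illumination_ramp():
    """Along-ramp quartile luminance ratio moves strictly toward 1."""
    ang = 30.0
    p = synthgen.LeafParams(
        illum_gradient=(ang, 0.4), margin_fraction=0.0, spot_count=0, seed=3
    )
    img, truth = synthgen.make_leaf(p)

    def ramp_ratio(im):
        yy, xx = np.nonzero(truth.leaf_mask)
        proj = xx * np.cos(np.deg2rad(ang)) + yy * np.sin(np.deg2rad(ang))
        lum = im.astype(float).mean(axis=2)[truth.leaf_mask]
        qlo, qhi = np.quantile(proj, [0.25, 0.75])
        return lum[proj >= qhi].mean() / lum[proj <= qlo].mean()

    out = msrcr(img, MSRCRParams.for_image_size(img.shape))
    assert abs(ramp_ratio(out) - 1) < abs(ramp_ratio(img) - 1)


def test_msrcr_channel_permutation_symmetry(symptomatic_leaf):
    _, img, _ = symptomatic_leaf
    perm, inv = [2, 0, 1], [1, 2, 0]
    assert np.array_equal(msrcr(img[..., perm])[..., inv], msrcr(img))


def test_msrcr_deterministic(symptomatic_leaf):
    _, img, _ = symptomatic_leaf
    assert np.array_equal(msrcr(img), msrcr(img))


def test_msrcr_param_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        MSRCRParams(scales=(10, 20), weights=(0.7, 0.7)).validate()
    with pytest.raises(ValueError, match="positive"):
        MSRCRParams(alpha=-1).validate()


# ---------------------------------------------------------------- regions


def test_green_segmentation_on_healthy_leaf(plain_leaf):
    _, img, truth = plain_leaf
    green = segment_green(img, truth.leaf_mask)
    assert green.sum() / truth.leaf_mask.sum() >= 0.98


def test_green_segmentation_on_fully_yellow_leaf():
    p = synthgen.LeafParams(margin_fraction=0.0, spot_count=0, seed=2)
    img, truth = synthgen.make_leaf(p)
    yellow = img.copy()
    yellow[truth.leaf_mask] = (222, 208, 92)
    green = segment_green(yellow, truth.leaf_mask)
    assert green.sum() / truth.leaf_mask.sum() <= 0.02


def test_half_green_half_yellow_card():
    card = np.empty((60, 60, 3), np.uint8)
    card[:, :30] = (58, 138, 62)
    card[:, 30:] = (222, 208, 92)
    leaf = np.ones((60, 60), bool)
    green = segment_green(card, leaf)
    truth = np.zeros((60, 60), bool)
    truth[:, :30] = True
    assert iou(green, truth) >= 0.95


def test_regions_zero_severity(plain_leaf):
    _, img, truth = plain_leaf
    masks = segment_regions(img, truth.leaf_mask)
    assert masks.margin.sum() / masks.leaf.sum() < 0.02
    assert masks.spot.sum() == 0


def test_regions_margin_fraction_recovered(symptomatic_leaf):
    params, img, truth = symptomatic_leaf
    masks = segment_regions(img, truth.leaf_mask)
    realized = masks.margin.sum() / masks.leaf.sum()
    assert abs(realized - params.margin_fraction) <= 0.03


def test_regions_spot_count_recovered():
    p = synthgen.LeafParams(margin_fraction=0.1, spot_count=5, spot_radius=6, seed=13)
    img, truth = synthgen.make_leaf(p)
    masks = segment_regions(img, truth.leaf_mask)
    _, n = ndi.label(masks.spot, structure=np.ones((3, 3)))
    assert n == 5


def test_region_invariants_on_random_leaves(random_leaf_batch):
    for _, img, truth in random_leaf_batch:
        masks = segment_regions(img, truth.leaf_mask)
        masks.check()  # nesting + pairwise disjointness
        union = masks.green | masks.margin | masks.spot
        assert np.array_equal(union, masks.leaf)
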