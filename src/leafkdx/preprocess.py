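"""Image chain: denoise → background removal → contour → splitting → MSRCR →
discolor-region segmentation.

Conventions (fixed here and used by every downstream stage):

* rasters are row-major, origin top-left, 0-based; crops are half-open;
* contours are 8-connected closed pixel chains traced Moore-style;
* perimeter = Σ steps weighted 1 (axial) and √2 (diagonal);
* HSV hue is reported on the half-degree scale H ∈ [0, 180), S and V on
  [0, 255] (the common 8-bit imaging convention);
* the green body is the hue interval H ∈ [35, 77] with saturation/value
  floors; brown spots live in H ∈ [0, 25] with V < 120; the yellowing
  margin is defined by subtraction: leaf minus green minus spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters, morphology

__all__ = [
    "MSRCRParams",
    "RegionMasks",
    "SegmentationParams",
    "gaussian_denoise",
    "segment_leaf",
    "extract_contour",
    "contour_perimeter",
    "split_leaves",
    "msrcr",
    "segment_green",
    "segment_regions",
]


class EmptySegmentationError(RuntimeError):
    """No vegetation-colored component of sufficient area was found."""


class DegenerateContourError(ValueError):
    """Mask too small to carry a closed boundary (area < 4 px)."""


class MultipleComponentsError(ValueError):
    """extract_contour requires a single connected component."""


@dataclass(frozen=True)
class MSRCRParams:
    """Multi-scale retinex with color restoration constants.

    Standard constants: surround sigmas (15, 80, 250) px with equal
    weights, color-restoration α=125, β=46, output map gain=192,
    offset=−30, then a 1 %/99 % percentile clip per channel rescaled to
    [0, 255].
    """

    scales: tuple[float, ...] = (15.0, 80.0, 250.0)
    weights: tuple[float, ...] | None = None
    alpha: float = 125.0
    beta: float = 46.0
    gain: float = 192.0
    offset: float = -30.0
    clip_percentiles: tuple[float, float] = (1.0, 99.0)

    def resolved_weights(self) -> np.ndarray:
        if not self.scales:
            raise ValueError("MSRCR needs at least one surround scale")
        w = (
            np.full(len(self.scales), 1.0 / len(self.scales))
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        if len(w) != len(self.scales):
            raise ValueError("weights and scales length mismatch")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        return w

    def validate(self) -> None:
        self.resolved_weights()
        if self.alpha <= 0 or self.beta <= 0 or self.gain <= 0:
            raise ValueError("alpha, beta and gain must be strictly positive")

    @classmethod
    def for_image_size(cls, shape: tuple[int, ...], **kw) -> "MSRCRParams":
        """Surround scales proportional to the frame.

        The standard (15, 80, 250) constants assume ~1000 px photographs;
        smaller frames need proportionally smaller surrounds or the leaf
        is dwarfed by its surround and boundary halos dominate.
        """
        f = min(shape[:2]) / 1000.0
        scales = tuple(max(2.0, s * f) for s in (15.0, 80.0, 250.0))
        return cls(scales=scales, **kw)


@dataclass(frozen=True)
class SegmentationParams:
    """Hue/saturation/value boxes for the region segmentation."""

    green_hue: tuple[float, float] = (35.0, 77.0)  # H on [0, 180)
    sat_floor: float = 30.0  # S on [0, 255]
    val_floor: float = 30.0  # V on [0, 255]
    brown_hue: tuple[float, float] = (0.0, 25.0)
    brown_val_max: float = 120.0
    spot_opening_radius: int = 1
    min_area: int = 25


@dataclass
class RegionMasks:
    """Nested boolean rasters: green ∪ margin ∪ spot = leaf, pairwise disjoint."""

    leaf: np.ndarray
    green: np.ndarray
    margin: np.ndarray
    spot: np.ndarray

    def check(self) -> None:
        assert not (self.green & ~self.leaf).any()
        assert not (self.margin & ~self.leaf).any()
        assert not (self.spot & ~self.leaf).any()
        assert not (self.margin & self.green).any()
        assert not (self.margin & self.spot).any()
        assert not (self.green & self.spot).any()


# ---------------------------------------------------------------------------
# denoise


def gaussian_denoise(img: np.ndarray, sigma: float = 1.0, ksize: int = 5) -> np.ndarray:
    """Gaussian blur with a normalized, finite (ksize × ksize) kernel.

    Output has the source dtype and shape; constants are preserved exactly
    up to rounding because the kernel weights sum to 1.
    """
    if ksize % 2 == 0:
        raise ValueError(f"ksize must be odd, got {ksize}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = ksize // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    k1 /= k1.sum()
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        tmp = ndi.convolve1d(arr[..., c], k1, axis=0, mode="nearest")
        out[..., c] = ndi.convolve1d(tmp, k1, axis=1, mode="nearest")
    out = out[..., 0] if np.asarray(img).ndim == 2 else out
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(np.asarray(img).dtype)
    return out


# ---------------------------------------------------------------------------
# background removal


def segment_leaf(img: np.ndarray, min_area: int = 25) -> np.ndarray:
    """Threshold-segment the leaf from the board background.

    Uses the excess-green index 2G−R−B with an Otsu cut, keeps the largest
    connected component and fills holes (brown spots fall below the
    vegetation threshold and would otherwise punch holes).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    exg = 2.0 * arr[..., 1] - arr[..., 0] - arr[..., 2]
    if exg.max() - exg.min() < 10.0:  # (near-)uniform image: no contrast to threshold
        if exg.mean() > 20.0:
            return np.ones(exg.shape, dtype=bool)
        raise EmptySegmentationError("no vegetation-colored region found")
    t = filters.threshold_otsu(exg)
    fg = exg > t
    lab, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptySegmentationError("no vegetation-colored region found")
    sizes = ndi.sum(fg, lab, index=np.arange(1, n + 1))
    if sizes.max() < min_area:
        raise EmptySegmentationError(
            f"largest vegetation component has area {int(sizes.max())} < min_area={min_area}"
        )
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# contour tracing

# clockwise Moore neighborhood, starting due west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the closed 8-connected boundary of a single-component mask.

    Returns an (m, 2) array of (row, col) pixel coordinates in traversal
    order; the chain is closed (last connects to first).  Masks with area
    < 4 px raise :class:`DegenerateContourError`; masks with more than one
    component must go through :func:`split_leaves` first.
    """
    mask = np.asarray(mask, dtype=bool)
    _, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        raise MultipleComponentsError(f"mask has {n} components; call split_leaves first")
    if mask.sum() < 4:
        raise DegenerateContourError(f"mask area {int(mask.sum())} < 4 px")

    pad = np.pad(mask, 1)
    rs, cs = np.nonzero(pad)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost
    start_backtrack = (start[0], start[1] - 1)
    # Moore-neighbor tracing; stop on re-entering the start pixel from the
    # initial backtrack direction (Jacob's criterion)
    contour: list[tuple[int, int]] = [start]
    cur, backtrack = start, start_backtrack
    for _ in range(8 * int(pad.sum()) + 8):
        bi = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            off = _MOORE[(bi + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if pad[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel: degenerate, already excluded above
            break
        if nxt == start and backtrack == start_backtrack:
            break
        contour.append(nxt)
        cur = nxt
    out = np.asarray(contour, dtype=int) - 1  # undo padding
    return out


def contour_perimeter(contour: np.ndarray) -> float:
    """Closed-chain length: 1 per axial step, √2 per diagonal step."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 2:
        return 0.0
    d = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
    steps = d.max(axis=1)
    diag = (d[:, 0] == 1) & (d[:, 1] == 1)
    return float(np.sum(np.where(diag, np.sqrt(2.0), steps)))


# ---------------------------------------------------------------------------
# single-leaf splitting


def split_leaves(
    mask: np.ndarray,
    img: np.ndarray,
    min_area: int = 25,
    pad: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a multi-leaf mask into per-leaf (image crop, mask crop) pairs.

    One entry per 8-connected component with area ≥ ``min_area``, cropped
    with a fixed ``pad`` margin (clipped at the frame), ordered
    top-to-bottom then left-to-right by bounding-box origin.  Touching
    leaves merge into one component — a documented limitation.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    entries = []
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < min_area:
            continue
        rs, cs = np.nonzero(comp)
        r0, r1 = max(rs.min() - pad, 0), min(rs.max() + pad + 1, mask.shape[0])
        c0, c1 = max(cs.min() - pad, 0), min(cs.max() + pad + 1, mask.shape[1])
        entries.append(((r0, c0), img[r0:r1, c0:c1].copy(), comp[r0:r1, c0:c1]))
    entries.sort(key=lambda e: e[0])
    return [(im, m) for _, im, m in entries]


# ---------------------------------------------------------------------------
# multi-scale retinex with color restoration


def msrcr(img: np.ndarray, params: MSRCRParams | None = None) -> np.ndarray:
    """Illumination correction by multi-scale retinex with color restoration.

    Per channel i:  R_i = gain·[C_i · Σ_k w_k (log(I_i+1) − log(G_{σk}∗I_i+1))] + offset
    with the chromatic factor C_i = β·(log(α·I_i+1) − log(ΣI_j+1)), followed
    by a per-channel percentile clip and linear rescale to [0, 255].
    Deterministic and symmetric under channel permutation.
    """
    params = params or MSRCRParams()
    params.validate()
    w = params.resolved_weights()
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")

    log_i = np.log(arr + 1.0)
    retinex = np.zeros_like(arr)
    for wk, sigma in zip(w, params.scales):
        for c in range(3):
            surround = ndi.gaussian_filter(arr[..., c], sigma, mode="nearest")
            retinex[..., c] += wk * (log_i[..., c] - np.log(surround + 1.0))
    chroma = params.beta * (
        np.log(params.alpha * arr + 1.0) - np.log(arr.sum(axis=2, keepdims=True) + 1.0)
    )
    out = params.gain * chroma * retinex + params.offset

    lo_p, hi_p = params.clip_percentiles
    rescaled = np.empty_like(out)
    for c in range(3):
        lo, hi = np.percentile(out[..., c], [lo_p, hi_p])
        if hi - lo < 1e-12:
            rescaled[..., c] = 127.5
        else:
            rescaled[..., c] = np.clip((out[..., c] - lo) / (hi - lo), 0, 1) * 255.0
    return np.clip(np.round(rescaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# region segmentation


def _hsv_180_255(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hsv = skcolor.rgb2hsv(np.asarray(img, dtype=np.uint8))
    return hsv[..., 0] * 180.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0


def segment_green(
    img: np.ndarray, leaf: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Green leaf body: hue in the green interval with S and V above floors."""
    p = params or SegmentationParams()
    if not np.asarray(leaf, dtype=bool).any():
        raise ValueError("leaf mask is empty")
    h, s, v = _hsv_180_255(img)
    return (
        np.asarray(leaf, dtype=bool)
        & (h >= p.green_hue[0])
        & (h <= p.green_hue[1])
        & (s >= p.sat_floor)
        & (v >= p.val_floor)
    )


def segment_regions(
    img: np.ndarray, leaf: np.ndarray, params: SegmentationParams | None = None
) -> RegionMasks:
    """Split the leaf into green body, brown spots and the yellowing margin.

    The margin is obtained by subtraction (leaf minus green minus spots),
    mirroring how the yellowing area along the leaf edge is isolated from
    the whole leaf.  Spots are morphologically opened to drop speckle.
    """
    p = params or SegmentationParams()
    leaf = np.asarray(leaf, dtype=bool)
    green = segment_green(img, leaf, p)
    h, s, v = _hsv_180_255(img)
    spot = leaf & (h >= p.brown_hue[0]) & (h <= p.brown_hue[1]) & (v < p.brown_val_max)
    if p.spot_opening_radius > 0:
        spot = morphology.opening(spot, morphology.disk(p.spot_opening_radius))
        spot &= leaf
    green &= ~spot
    margin = leaf & ~green & ~spot
    masks = RegionMasks(leaf=leaf, green=green, margin=margin, spot=spot)
    masks.check()
    return masks
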