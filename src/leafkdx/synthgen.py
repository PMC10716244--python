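"""Synthetic apple-leaf image generator with exact ground truth.

Renders single detached leaves on a light calibration board: a green body,
a yellowing margin band whose area fraction tracks deficiency severity,
brown necrotic spots, per-channel color noise and a smooth multiplicative
illumination ramp.  Every sample carries pixel-exact masks, geometry and a
potassium-content label, so the whole downstream chain (segmentation,
feature extraction, screening, projection, classification) can be tested
without any field photographs.

Severity is a scalar in [0, 1]: 0 is a fully green leaf, larger values
grow the yellow margin band and add spots.  Leaf potassium content (% of
dry mass) is an affine, monotonically decreasing function of severity plus
Gaussian noise; a leaf is labeled 1 (deficient) when its K content falls
below a configurable grading cutoff, else 2 (normal).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "LeafParams",
    "GroundTruth",
    "make_leaf",
    "make_dataset",
    "severity_to_params",
    "PERIODS",
]

PERIODS = ("flowering", "young_fruit", "fruit_enlarging", "mature")


class LeafParamError(ValueError):
    """Raised when requested leaf geometry/coloring is infeasible."""


@dataclass(frozen=True)
class LeafParams:
    """Rendering parameters for one synthetic leaf.

    The silhouette is an ellipse with half-axes ``leaf_axes`` perturbed by a
    low-order sinusoidal radial wobble of relative amplitude
    ``boundary_wobble``.  ``margin_fraction`` is the target fraction of leaf
    area occupied by the yellowing margin band; spots are disks of radius
    ``spot_radius`` placed inside the green body.
    """

    image_size: tuple[int, int] = (128, 128)
    leaf_axes: tuple[float, float] = (45.0, 28.0)
    boundary_wobble: float = 0.06
    green_color: tuple[float, float, float] = (58.0, 138.0, 62.0)
    color_noise_sd: float = 6.0
    margin_fraction: float = 0.0
    yellow_color: tuple[float, float, float] = (222.0, 208.0, 92.0)
    spot_count: int = 0
    spot_radius: float = 3.5
    spot_color: tuple[float, float, float] = (110.0, 62.0, 36.0)
    illum_gradient: tuple[float, float] = (30.0, 0.15)
    background_color: tuple[float, float, float] = (214.0, 214.0, 210.0)
    seed: int = 0

    def validate(self) -> None:
        a, b = self.leaf_axes
        if not (a >= b > 0):
            raise LeafParamError(f"leaf_axes must satisfy a >= b > 0, got {self.leaf_axes}")
        if not (0 <= self.margin_fraction < 1):
            raise LeafParamError(f"margin_fraction must be in [0, 1), got {self.margin_fraction}")
        if self.spot_count < 0:
            raise LeafParamError("spot_count must be >= 0")
        for name in ("green_color", "yellow_color", "spot_color", "background_color"):
            c = getattr(self, name)
            if min(c) < 0 or max(c) > 255:
                raise LeafParamError(f"{name} components must lie in [0, 255], got {c}")
        amp = self.illum_gradient[1]
        if not (0 <= amp <= 0.5):
            raise LeafParamError(f"illumination amplitude must be in [0, 0.5], got {amp}")
        # feasibility: margin band + spots must fit inside the leaf
        leaf_area = np.pi * a * b
        spot_area = self.spot_count * np.pi * self.spot_radius**2
        if self.margin_fraction + spot_area / leaf_area >= 1.0:
            raise LeafParamError(
                "requested margin_fraction plus total spot area exceeds the leaf area"
            )


@dataclass
class GroundTruth:
    """Pixel-exact truth for one rendered leaf."""

    leaf_mask: np.ndarray
    green_mask: np.ndarray
    margin_mask: np.ndarray
    spot_mask: np.ndarray
    true_geometry: dict[str, float]  # l1, l2, C, S, S1, S2
    severity: float
    k_content: float
    label: int  # 1 deficient, 2 normal


def _silhouette(params: LeafParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the wobbled ellipse: dist(p) < r_ellipse(theta)·(1 + w(theta))."""
    h, w = params.image_size
    a, b = params.leaf_axes
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    # ellipse boundary radius in polar form
    r_e = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if params.boundary_wobble > 0:
        orders = rng.choice(np.arange(3, 8), size=3, replace=False)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.dirichlet(np.ones(3)) * params.boundary_wobble
        wob = np.zeros_like(theta)
        for k, ph, am in zip(orders, phases, amps):
            wob += am * np.sin(k * theta + ph)
    else:
        wob = 0.0
    mask = rho < r_e * (1.0 + wob)
    # keep it a single filled component
    mask = ndi.binary_fill_holes(mask)
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _margin_band(leaf: np.ndarray, fraction: float) -> np.ndarray:
    """Inward offset ring covering ``fraction`` of the leaf area.

    Uses the Euclidean distance-to-background transform and picks the depth
    quantile that yields the requested area fraction, so the realized
    fraction is exact up to pixel-count ties.
    """
    if fraction <= 0:
        return np.zeros_like(leaf)
    edt = ndi.distance_transform_edt(leaf)
    rs, cs = np.nonzero(leaf)
    depths = edt[rs, cs]
    k = int(round(fraction * len(rs)))
    # exact area: take the k shallowest pixels, raster order breaking ties
    order = np.lexsort((cs, rs, depths))[:k]
    band = np.zeros_like(leaf)
    band[rs[order], cs[order]] = True
    return band


def _place_spots(
    leaf: np.ndarray, margin: np.ndarray, params: LeafParams, rng: np.random.Generator
) -> np.ndarray:
    """Place non-overlapping disks inside the green interior where possible."""
    spot = np.zeros_like(leaf)
    if params.spot_count == 0:
        return spot
    r = params.spot_radius
    interior = leaf & ~margin
    # candidate centers keep the full disk inside the interior region
    safe = ndi.distance_transform_edt(interior) > (r + 1.0)
    if not safe.any():  # fall back: allow overlap with the margin band
        safe = ndi.distance_transform_edt(leaf) > (r + 1.0)
    coords = np.argwhere(safe)
    yy, xx = np.mgrid[0 : leaf.shape[0], 0 : leaf.shape[1]]
    placed = 0
    attempts = 0
    centers: list[tuple[int, int]] = []
    while placed < params.spot_count and attempts < 200 * params.spot_count:
        attempts += 1
        cy, cx = coords[rng.integers(len(coords))]
        if any(np.hypot(cy - py, cx - px) < 2 * r + 2 for py, px in centers):
            continue
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        spot |= disk & leaf
        centers.append((cy, cx))
        placed += 1
    return spot


def _illumination(shape: tuple[int, int], direction_deg: float, amplitude: float) -> np.ndarray:
    """Multiplicative linear luminance ramp in [1-a, 1+a] along a direction."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.deg2rad(direction_deg)
    proj = xx * np.cos(th) + yy * np.sin(th)
    lo, hi = proj.min(), proj.max()
    t = (proj - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return 1.0 - amplitude + 2.0 * amplitude * t


def _mask_geometry(leaf: np.ndarray, s1: int, s2: int) -> dict[str, float]:
    props = measure.regionprops(leaf.astype(np.uint8))[0]
    return {
        "l1": float(props.axis_major_length),
        "l2": float(props.axis_minor_length),
        "C": float(props.perimeter),  # truth-side estimator; downstream has its own
        "S": float(leaf.sum()),
        "S1": float(s1),
        "S2": float(s2),
    }


def make_leaf(params: LeafParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one leaf image (uint8 H×W×3) with its :class:`GroundTruth`.

    Deterministic for a fixed ``params.seed``: two calls with identical
    parameters return bit-identical images and masks.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size

    leaf = _silhouette(params, rng)
    margin = _margin_band(leaf, params.margin_fraction)
    spot = _place_spots(leaf, margin, params, rng)
    margin &= ~spot  # spots win where the fallback placement overlapped
    green = leaf & ~margin & ~spot

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = params.background_color
    # faint 2x2-style calibration grid on the board
    step = max(h, w) // 8
    grid = np.zeros((h, w), dtype=bool)
    grid[::step, :] = True
    grid[:, ::step] = True
    img[grid & ~leaf] -= 12.0
    img[green] = params.green_color
    img[margin] = params.yellow_color
    img[spot] = params.spot_color

    if params.color_noise_sd > 0:
        img += rng.normal(0.0, params.color_noise_sd, size=img.shape)
    ramp = _illumination((h, w), *params.illum_gradient)
    img *= ramp[..., None]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    sev = min(1.0, params.margin_fraction + (spot.sum() / max(leaf.sum(), 1)))
    truth = GroundTruth(
        leaf_mask=leaf,
        green_mask=green,
        margin_mask=margin,
        spot_mask=spot,
        true_geometry=_mask_geometry(leaf, int(margin.sum()), int(spot.sum())),
        severity=sev,
        k_content=float("nan"),  # filled by make_dataset
        label=0,
    )
    return img, truth


# ---------------------------------------------------------------------------
# dataset-level generation


@dataclass(frozen=True)
class SeverityLaw:
    """Two-component truncated-normal severity mixture on [0, 1].

    The defaults describe the study design the generator emulates: half the
    leaves come from well-fertilized trees (near-zero severity) and half
    from K-starved trees with clearly expressed symptoms.
    """

    weights: tuple[float, ...] = (0.5, 0.5)
    means: tuple[float, ...] = (0.08, 0.70)
    sds: tuple[float, ...] = (0.03, 0.08)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights) / sum(self.weights))
        s = rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])
        return np.clip(s, 0.0, 1.0)


@dataclass(frozen=True)
class KLaw:
    """Affine severity→K map with Gaussian noise: k = a + b·severity + N(0, sd)."""

    intercept: float = 1.2
    slope: float = -0.8
    noise_sd: float = 0.05

    def __call__(self, severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.intercept + self.slope * severity + rng.normal(0, self.noise_sd, severity.shape)


def severity_to_params(
    severity: float, base: LeafParams, seed: int, rng: np.random.Generator
) -> LeafParams:
    """Map a severity scalar onto rendering parameters.

    The margin band grows linearly to 70 % of leaf area at severity 1; spot
    count grows to 8 disks.  Axes are jittered ±15 % so every leaf has its
    own geometry.
    """
    a0, b0 = base.leaf_axes
    scale = rng.uniform(0.85, 1.15)
    elong = rng.uniform(0.9, 1.1)
    return dataclasses.replace(
        base,
        leaf_axes=(a0 * scale * elong, min(b0 * scale / elong, a0 * scale * elong)),
        margin_fraction=0.70 * severity,
        spot_count=int(round(8 * severity)),
        illum_gradient=(rng.uniform(0, 360), base.illum_gradient[1]),
        seed=seed,
    )


def make_dataset(
    n: int,
    severity_law: SeverityLaw | None = None,
    k_law: KLaw | None = None,
    label_threshold: float = 0.8,
    period: str = "flowering",
    seed: int = 0,
    base_params: LeafParams | None = None,
    return_truths: bool = False,
):
    """Generate ``n`` leaves and their truth table.

    Returns ``(images, table)`` where ``table`` is a DataFrame with columns
    sample_id, period, severity, k_content, label, l1, l2, C, S, S1, S2.
    Labels: 1 where K content < ``label_threshold`` (% dry mass), else 2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    severity_law = severity_law or SeverityLaw()
    k_law = k_law or KLaw()
    base = base_params or LeafParams()
    rng = np.random.default_rng(seed)

    sev = severity_law.draw(n, rng)
    k = k_law(sev, rng)
    labels = np.where(k < label_threshold, 1, 2)
    if len(np.unique(labels)) == 1:
        warnings.warn(
            f"degenerate dataset: all {n} samples have label {labels[0]}",
            stacklevel=2,
        )

    images: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    rows = []
    for i in range(n):
        p = severity_to_params(sev[i], base, seed=int(rng.integers(2**31)), rng=rng)
        img, truth = make_leaf(p)
        truth.severity = float(sev[i])
        truth.k_content = float(k[i])
        truth.label = int(labels[i])
        images.append(img)
        truths.append(truth)
        rows.append(
            {
                "sample_id": f"{period}_{i:04d}",
                "period": period,
                "severity": float(sev[i]),
                "k_content": float(k[i]),
                "label": int(labels[i]),
                **truth.true_geometry,
            }
        )
    table = pd.DataFrame(rows)
    if return_truths:
        return images, table, truths
    return images, table
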