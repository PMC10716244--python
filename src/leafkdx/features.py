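"""The 22 shape–color features computed per single leaf.

Canonical feature order (fixed; every table and model uses it):

    [R, G, B, H, S, V, L, A, Bb, NRI, NGI, NBI,
     l1, l2, C, S_area, S1, S2, E, F, CR, SR]

Color features are channel means over the leaf mask in RGB, HSV and LAB
plus the chromaticity coordinates NRI/NGI/NBI (masked RGB means each
divided by their sum).  Scales: H on [0, 180), S, V on [0, 255]; LAB on
the 8-bit offset scale (L ∈ [0, 255], A and Bb offset by +128).

Shape features: long/short axis (l1, l2) of the mask's second-moment
equivalent ellipse, perimeter C under the weighted-chain convention,
areas S, S1 (yellowing margin), S2 (spots), and the derived descriptors

    E  = sqrt(1 − (l2/l1)²)   eccentricity, 0 for a circle
    F  = 4πS / C²             circularity, 1 for a perfect disk
    CR = S1 / S               color change ratio
    SR = S2 / S               spot change ratio
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage import measure

from .preprocess import RegionMasks, contour_perimeter, extract_contour

__all__ = [
    "FEATURE_NAMES",
    "COLOR_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "ColorFeatures",
    "ShapeFeatures",
    "color_features",
    "geometry",
    "derived_shape",
    "assemble_features",
    "extract_leaf_features",
]

COLOR_FEATURE_NAMES = ["R", "G", "B", "H", "S", "V", "L", "A", "Bb", "NRI", "NGI", "NBI"]
SHAPE_FEATURE_NAMES = ["l1", "l2", "C", "S_area", "S1", "S2", "E", "F", "CR", "SR"]
FEATURE_NAMES = COLOR_FEATURE_NAMES + SHAPE_FEATURE_NAMES

META_COLUMNS = ["sample_id", "period", "label", "k_content"]


@dataclass(frozen=True)
class ColorFeatures:
    mean_R: float
    mean_G: float
    mean_B: float
    mean_H: float
    mean_S: float
    mean_V: float
    mean_L: float
    mean_A: float
    mean_Bb: float
    NRI: float
    NGI: float
    NBI: float

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(
                COLOR_FEATURE_NAMES,
                (
                    self.mean_R,
                    self.mean_G,
                    self.mean_B,
                    self.mean_H,
                    self.mean_S,
                    self.mean_V,
                    self.mean_L,
                    self.mean_A,
                    self.mean_Bb,
                    self.NRI,
                    self.NGI,
                    self.NBI,
                ),
            )
        )


@dataclass(frozen=True)
class ShapeFeatures:
    l1: float
    l2: float
    C: float
    S: float
    S1: float
    S2: float
    E: float
    F: float
    CR: float
    SR: float

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(
                SHAPE_FEATURE_NAMES,
                (self.l1, self.l2, self.C, self.S, self.S1, self.S2, self.E, self.F, self.CR, self.SR),
            )
        )


def color_features(img: np.ndarray, leaf: np.ndarray) -> ColorFeatures:
    """Nine masked channel means (RGB, HSV, LAB) plus NRI/NGI/NBI."""
    leaf = np.asarray(leaf, dtype=bool)
    if not leaf.any():
        raise ValueError("leaf mask is empty")
    rgb = np.asarray(img, dtype=np.uint8)
    pix = rgb[leaf].astype(float)  # (n, 3)
    r, g, b = pix.mean(axis=0)
    total = r + g + b
    if total == 0:
        raise ValueError("NRI/NGI/NBI undefined: mean R+G+B is zero over the mask")

    hsv = skcolor.rgb2hsv(rgb)[leaf]
    lab = skcolor.rgb2lab(rgb)[leaf]
    return ColorFeatures(
        mean_R=r,
        mean_G=g,
        mean_B=b,
        mean_H=float(hsv[:, 0].mean() * 180.0),
        mean_S=float(hsv[:, 1].mean() * 255.0),
        mean_V=float(hsv[:, 2].mean() * 255.0),
        mean_L=float(lab[:, 0].mean() * 255.0 / 100.0),
        mean_A=float(lab[:, 1].mean() + 128.0),
        mean_Bb=float(lab[:, 2].mean() + 128.0),
        NRI=r / total,
        NGI=g / total,
        NBI=b / total,
    )


def geometry(
    leaf: np.ndarray, contour: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """(l1, l2, C, S) of a simply connected mask.

    S is the exact pixel count; C the weighted boundary-chain length;
    l1 ≥ l2 the axis lengths of the second-moment equivalent ellipse.
    """
    leaf = np.asarray(leaf, dtype=bool)
    if contour is None:
        contour = extract_contour(leaf)
    props = measure.regionprops(leaf.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    p = props[0]
    l1 = float(p.axis_major_length)
    l2 = float(p.axis_minor_length)
    if l2 <= 0:  # collinear / degenerate mask
        raise ValueError("degenerate mask: zero minor axis")
    return l1, l2, contour_perimeter(contour), float(leaf.sum())


def derived_shape(
    l1: float, l2: float, C: float, S: float, S1: float, S2: float
) -> tuple[float, float, float, float]:
    """Eccentricity, circularity and the two discoloration ratios."""
    if not (l1 >= l2 > 0):
        raise ValueError(f"axes must satisfy l1 >= l2 > 0, got ({l1}, {l2})")
    if S <= 0:
        raise ValueError("leaf area S must be > 0")
    if S1 > S or S2 > S:
        raise ValueError("discolor areas cannot exceed the leaf area")
    E = float(np.sqrt(1.0 - (l2 / l1) ** 2))
    F = float(4.0 * np.pi * S / C**2)
    return E, F, float(S1 / S), float(S2 / S)


def assemble_features(
    color: ColorFeatures,
    shape: ShapeFeatures,
    sample_id: str = "",
    period: str = "",
    label: int | None = None,
    k_content: float | None = None,
) -> dict[str, float | str | int | None]:
    """One flat record in canonical feature order plus metadata columns."""
    rec: dict = {"sample_id": sample_id, "period": period}
    rec.update(color.as_dict())
    rec.update(shape.as_dict())
    rec["label"] = label
    rec["k_content"] = k_content
    for name in FEATURE_NAMES:
        if rec.get(name) is None:
            raise ValueError(f"missing feature {name}")
    return rec


def extract_leaf_features(
    img: np.ndarray,
    masks: RegionMasks,
    color_img: np.ndarray | None = None,
    **meta,
) -> dict:
    """Full 22-feature record for one segmented leaf.

    ``color_img`` lets the caller supply an illumination-corrected raster
    for the color means while geometry comes from ``masks`` (the default
    uses ``img`` for both).
    """
    cf = color_features(color_img if color_img is not None else img, masks.leaf)
    l1, l2, C, S = geometry(masks.leaf)
    S1, S2 = float(masks.margin.sum()), float(masks.spot.sum())
    E, F, CR, SR = derived_shape(l1, l2, C, S, S1, S2)
    sf = ShapeFeatures(l1=l1, l2=l2, C=C, S=S, S1=S1, S2=S2, E=E, F=F, CR=CR, SR=SR)
    return assemble_features(cf, sf, **meta)


def features_to_frame(records: list[dict]) -> pd.DataFrame:
    """Stack records into a FeatureTable with the canonical column order."""
    df = pd.DataFrame(records)
    cols = ["sample_id", "period"] + FEATURE_NAMES + ["label", "k_content"]
    return df[[c for c in cols if c in df.columns]]
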