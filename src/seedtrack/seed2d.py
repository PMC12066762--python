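"""2D-station seed traits: segmentation, projected area, HSV colour.

Seeds lie singly on a bright glass plate; the seed is segmented from
the background, its projected area is the pixel count times the pixel
area, and colour traits come from a 5×5-pixel patch at the mask
centroid (≈80×80 µm at the 2D station's magnification) so that darker
edge pixels do not bias the brightness of the seed coat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .errors import AmbiguityError, DomainError
from .seedstats import fit_mass_area_model  # noqa: F401  (2D-station trait model)

__all__ = ["ColorTraits", "segment_seed_2d", "color_traits", "fit_mass_area_model"]

# plausible projected-area range for a single Arabidopsis seed
PLAUSIBLE_AREA_MM2 = (0.05, 0.5)
PATCH_SIZE = 5  # px; ≈ 80×80 µm at 16 µm/px


@dataclass
class ColorTraits:
    """Colour and area traits of one seed from the 2D station."""

    projected_area: float  # mm²
    brightness_mean: float  # % of full V scale
    brightness_sd: float  # %
    hue_mean: float  # degrees
    saturation_mean: float  # %
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "projected_area_mm2": self.projected_area,
            "brightness_mean_pct": self.brightness_mean,
            "brightness_sd_pct": self.brightness_sd,
            "hue_mean_deg": self.hue_mean,
            "saturation_mean_pct": self.saturation_mean,
            "flags": ";".join(self.flags),
        }


def segment_seed_2d(image: np.ndarray, min_area_px: int = 50) -> np.ndarray:
    """Segment a single dark seed from a near-uniform bright background.

    Otsu threshold on the HSV value channel, hole filling, and a
    single-large-component check.  Raises :class:`AmbiguityError`
    carrying the component count when zero or several seeds are found.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        v = img[..., :3].max(axis=2).astype(float)
    else:
        v = img.astype(float)
    if v.max() == v.min():
        raise AmbiguityError(0, "blank image: found 0 seeds")
    fg = v < threshold_otsu(v)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise AmbiguityError(0, "found 0 seeds")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    large = np.flatnonzero(areas >= max(min_area_px, 0.1 * areas.max())) + 1
    if len(large) != 1:
        raise AmbiguityError(len(large), f"found {len(large)} seeds, expected 1")
    return ndimage.binary_fill_holes(labels == large[0])


def color_traits(
    image: np.ndarray, mask: np.ndarray, pixel_size: float = 16.0
) -> ColorTraits:
    """Colour traits from a 5×5 px patch at the mask centroid.

    ``pixel_size`` is in µm/px.  Brightness is the HSV value channel in
    percent of full scale; the patch is shrunk (with an edge-effect
    flag) if it would extend beyond the mask or image.
    """
    img = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if img.ndim != 3 or img.shape[2] < 3:
        raise DomainError("expected an RGB image")
    if not mask.any():
        raise DomainError("empty mask")
    area_mm2 = mask.sum() * (pixel_size / 1000.0) ** 2

    flags = []
    if not PLAUSIBLE_AREA_MM2[0] <= area_mm2 <= PLAUSIBLE_AREA_MM2[1]:
        flags.append("implausible_area")

    cy, cx = ndimage.center_of_mass(mask)
    cy, cx = int(round(cy)), int(round(cx))
    half = PATCH_SIZE // 2
    # shrink the patch while it reaches outside the mask (edge effect)
    for h in range(half, -1, -1):
        sl = (slice(cy - h, cy + h + 1), slice(cx - h, cx + h + 1))
        if (0 <= cy - h and cy + h < mask.shape[0]
                and 0 <= cx - h and cx + h < mask.shape[1]
                and mask[sl].all()):
            break
    if h < half:
        flags.append("edge_effect")

    hsv = rgb2hsv(img[..., :3])
    patch = hsv[sl]
    return ColorTraits(
        projected_area=float(area_mm2),
        brightness_mean=float(patch[..., 2].mean() * 100.0),
        brightness_sd=float(patch[..., 2].std() * 100.0),
        hue_mean=float(patch[..., 0].mean() * 360.0),
        saturation_mean=float(patch[..., 1].mean() * 100.0),
        flags=flags,
    )
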