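"""GFAP-positive area segmentation.

The chain mirrors the standard immunofluorescence workflow for reactive
astrocytes: rolling-ball background subtraction (radius 3.25 um), linear
8-bit conversion, Otsu intensity thresholding on the 256-bin histogram, and
connected-component filtering that keeps segments with areas between 7 and
1000 um^2 inclusive.  Erythrocyte-like and autofluorescent punctae are *not*
removed by design; they fall inside the size band and are part of the
measured signal, as in the underlying assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "SliceImage",
    "SegmentationParams",
    "SegmentSet",
    "subtract_background",
    "to_8bit",
    "otsu_threshold",
    "filter_segments",
    "segment_slice",
    "ball_structure",
]


@dataclass
class SliceImage:
    """A single-channel 2-D intensity raster with physical pixel size.

    Parameters
    ----------
    values : ndarray
        Non-negative intensities, shape (rows, cols).
    pixel_size : float
        Edge length of a pixel in um (isotropic).
    channel : str
        Stain label, e.g. ``"GFAP"`` or ``"DAPI"``.
    slice_id : str
        Identifier of the physical slice.
    quality_score : int
        Grading from 1 (poor) to 5 (excellent); metadata only, never used
        in computations.
    """

    values: np.ndarray
    pixel_size: float
    channel: str = "GFAP"
    slice_id: str = ""
    quality_score: int = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("SliceImage.values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.nanmin(self.values) < 0:
            raise ValueError("intensities must be non-negative")
        if not 1 <= int(self.quality_score) <= 5:
            raise ValueError("quality_score must be in 1..5")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "SliceImage":
        return SliceImage(
            values=values,
            pixel_size=self.pixel_size,
            channel=self.channel,
            slice_id=self.slice_id,
            quality_score=self.quality_score,
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation chain (defaults are the assay values)."""

    rolling_ball_radius_um: float = 3.25
    min_area_um2: float = 7.0
    max_area_um2: float = 1000.0
    connectivity: int = 8  # 4 or 8 neighbours

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_um <= 0:
            raise ValueError("rolling_ball_radius_um must be positive")
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SegmentSet:
    """Labelled GFAP-positive segments after size filtering.

    ``label_map`` holds consecutive labels 1..n (0 = background);
    ``areas_um2[k]`` is the area of label k+1.  Retained labels always
    satisfy ``min_area_um2 <= area <= max_area_um2`` (inclusive bounds).
    """

    label_map: np.ndarray
    areas_um2: np.ndarray
    pixel_size: float
    params_used: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)

    @property
    def n_segments(self) -> int:
        return int(self.areas_um2.size)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    @property
    def total_area_um2(self) -> float:
        return float(self.areas_um2.sum())


def ball_structure(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball of the given pixel radius.

    Height at offset d from the center is sqrt(r^2 - d^2); offsets with
    d > r are outside the footprint.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    ax = np.arange(-radius_px, radius_px + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    footprint = d2 <= radius_px**2
    height = np.zeros(d2.shape, dtype=float)
    height[footprint] = np.sqrt(radius_px**2 - d2[footprint])
    return footprint, height


def _radius_to_px(radius_um: float, pixel_size: float) -> int:
    # round half away from zero; a radius below one pixel would be a no-op
    radius_px = int(np.floor(radius_um / pixel_size + 0.5))
    if radius_px < 1:
        raise ValueError(
            f"rolling-ball radius {radius_um} um is below one pixel at "
            f"pixel size {pixel_size} um"
        )
    return radius_px


def subtract_background(image: SliceImage, radius_um: float = 3.25) -> SliceImage:
    """Rolling-ball background subtraction.

    The background is the morphological grayscale opening of the image with
    a non-flat ball structuring element of the given radius (the ball rolled
    under the intensity landscape); the result is ``image - background``,
    clipped at zero.  Constant images (and any constant offset) map to zero
    background residue; bright features narrower than the ball are
    preserved.
    """
    radius_px = _radius_to_px(radius_um, image.pixel_size)
    footprint, height = ball_structure(radius_px)
    img = image.values.astype(np.float32, copy=False)
    eroded = ndi.grey_erosion(img, footprint=footprint, structure=height)
    background = ndi.grey_dilation(eroded, footprint=footprint, structure=height)
    out = np.clip(img - background, 0.0, None)
    return image.with_values(out)


def to_8bit(image: SliceImage) -> SliceImage:
    """Linear min-max rescale of intensities to the integer range 0..255.

    Rounding is half-away-from-zero.  A constant image cannot be rescaled;
    it maps to all zeros with a warning (the thresholding stage will then
    reject it).
    """
    vals = image.values.astype(np.float64, copy=False)
    lo = float(vals.min())
    hi = float(vals.max())
    if hi == lo:
        warnings.warn("constant image: 8-bit conversion yields all zeros", stacklevel=2)
        return image.with_values(np.zeros(vals.shape, dtype=np.uint8))
    scaled = 255.0 * (vals - lo) / (hi - lo)
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return image.with_values(out)


def otsu_threshold(image: SliceImage) -> tuple[int, np.ndarray]:
    """Otsu threshold of an 8-bit image over the 256-bin histogram.

    Returns the integer threshold t maximizing the between-class variance
    (ties broken toward the lower threshold) and the binary mask
    ``values > t``.
    """
    vals = np.asarray(image.values)
    if vals.min() == vals.max():
        raise ValueError("constant image: no valid Otsu threshold")
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("otsu_threshold expects an 8-bit image (values in 0..255)")
    counts = np.bincount(vals.astype(np.int64).ravel(), minlength=256)
    t = int(threshold_otsu(hist=(counts, np.arange(256))))
    mask = vals > t
    return t, mask


def filter_segments(
    mask: np.ndarray,
    params: SegmentationParams,
    pixel_size: float,
) -> SegmentSet:
    """Label connected components and keep those inside the area band.

    Components are labelled with the configured connectivity (8-neighbour
    by default, so 1-px-wide diagonal processes stay connected).  Areas are
    pixel counts times ``pixel_size**2``; components with area strictly
    below ``min_area_um2`` or strictly above ``max_area_um2`` are removed
    (the bounds themselves are retained).
    """
    mask = np.asarray(mask).astype(bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    conn = 1 if params.connectivity == 4 else 2
    lab = sk_label(mask, connectivity=conn)
    n = int(lab.max())
    if n == 0:
        return SegmentSet(
            label_map=np.zeros(mask.shape, dtype=np.int32),
            areas_um2=np.empty(0),
            pixel_size=pixel_size,
            params_used=params,
        )
    counts_px = np.bincount(lab.ravel(), minlength=n + 1)
    areas = counts_px.astype(np.float64) * pixel_size**2
    keep = (areas >= params.min_area_um2) & (areas <= params.max_area_um2)
    keep[0] = False
    mapping = np.zeros(n + 1, dtype=np.int32)
    kept_labels = np.flatnonzero(keep)
    mapping[kept_labels] = np.arange(1, kept_labels.size + 1, dtype=np.int32)
    return SegmentSet(
        label_map=mapping[lab],
        areas_um2=areas[kept_labels],
        pixel_size=pixel_size,
        params_used=params,
    )


def segment_slice(
    image: SliceImage,
    params: SegmentationParams | None = None,
) -> tuple[SegmentSet, int]:
    """Full segmentation chain on a GFAP slice.

    Background subtraction -> 8-bit conversion -> whole-slice Otsu
    threshold -> connected-component area filter.  Returns the retained
    segments and the Otsu threshold used.
    """
    params = params or SegmentationParams()
    bg_sub = subtract_background(image, params.rolling_ball_radius_um)
    img8 = to_8bit(bg_sub)
    threshold, mask = otsu_threshold(img8)
    segments = filter_segments(mask, params, image.pixel_size)
    return segments, threshold
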