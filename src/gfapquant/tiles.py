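"""Tile fraction maps, mirrored hemisphere ROIs, and beam-axis profiles.

The GFAP+ fraction of a tile is the summed area of all retained segments in
the tile divided by the tile area (250 um x 250 um by default).  ROIs are
axis-aligned rectangles; the contralateral ROI is the exact reflection of
the irradiated-side ROI about the midline column.  Profiles average tiles
perpendicular to the beam axis (which is assumed aligned with the image
column axis; rotated acquisitions should be rotated upright first).

Tile lattice convention: anchored at the image origin, tile (i, j) covers
pixels [i*t, (i+1)*t) x [j*t, (j+1)*t); its center is at pixel coordinate
((i + 0.5)*t - 0.5, (j + 0.5)*t - 0.5).  Partial tiles at the lower/right
edges are flagged and excluded from ROI means and profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segment import SegmentSet

__all__ = [
    "TileFractionMap",
    "ROISpec",
    "Profile",
    "compute_tile_fractions",
    "tile_means",
    "define_mirrored_rois",
    "mean_roi_fraction",
    "beam_axis_profile",
    "transverse_band_profiles",
]


@dataclass
class TileFractionMap:
    """Per-tile GFAP+ area fractions on a regular lattice.

    ``positive_px`` and ``tile_area_px`` are integer pixel counts, so
    ``fractions = positive_px / tile_area_px`` is exact; ``full`` flags
    tiles fully inside the image.
    """

    positive_px: np.ndarray
    tile_area_px: np.ndarray
    tile_size_um: float
    tile_px: int
    pixel_size: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.positive_px = np.asarray(self.positive_px, dtype=np.int64)
        self.tile_area_px = np.asarray(self.tile_area_px, dtype=np.int64)
        if self.positive_px.shape != self.tile_area_px.shape:
            raise ValueError("positive_px and tile_area_px shapes differ")
        if np.any(self.positive_px > self.tile_area_px):
            raise ValueError("tile fraction would exceed 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.positive_px.shape

    @property
    def fractions(self) -> np.ndarray:
        return self.positive_px / self.tile_area_px

    @property
    def full(self) -> np.ndarray:
        return self.tile_area_px == self.tile_px**2

    def tile_center_rows(self) -> np.ndarray:
        """Pixel row coordinate of each tile-row center."""
        i = np.arange(self.shape[0])
        return self.origin[0] + (i + 0.5) * self.tile_px - 0.5

    def tile_center_cols(self) -> np.ndarray:
        j = np.arange(self.shape[1])
        return self.origin[1] + (j + 0.5) * self.tile_px - 0.5


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular ROI in slice pixel coordinates.

    ``rectangle`` is (row_min, row_max, col_min, col_max); membership of a
    point (e.g. a tile center) is inclusive on both bounds.  ``side``
    labels the hemisphere relative to ``mirror_axis_col``.
    """

    rectangle: tuple[float, float, float, float]
    side: str
    mirror_axis_col: float

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.rectangle
        if not (r0 < r1 and c0 < c1):
            raise ValueError("rectangle must have positive extent")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        m = self.mirror_axis_col
        if min(c0, c1) < m < max(c0, c1):
            raise ValueError("ROI crosses the mirror axis")

    def mirrored(self) -> "ROISpec":
        """Exact reflection about the mirror axis (an involution)."""
        r0, r1, c0, c1 = self.rectangle
        m = self.mirror_axis_col
        return ROISpec(
            rectangle=(r0, r1, 2 * m - c1, 2 * m - c0),
            side="left" if self.side == "right" else "right",
            mirror_axis_col=m,
        )

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r0, r1, c0, c1 = self.rectangle
        return (rows >= r0) & (rows <= r1) & (cols >= c0) & (cols <= c1)


@dataclass
class Profile:
    """Mean GFAP+ fraction and mean dose per tile position along one axis."""

    positions_um: np.ndarray
    gfap_means: np.ndarray
    dose_means: np.ndarray
    axis: str  # "along-beam" | "transverse"
    band: str  # "ROI" | "cortex" | "central"

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.gfap_means = np.asarray(self.gfap_means, dtype=float)
        self.dose_means = np.asarray(self.dose_means, dtype=float)
        n = self.positions_um.size
        if self.gfap_means.size != n or self.dose_means.size != n:
            raise ValueError("profile arrays must have equal length")


def _block_sums(arr: np.ndarray, tile_px: int) -> np.ndarray:
    r_edges = np.arange(0, arr.shape[0], tile_px)
    c_edges = np.arange(0, arr.shape[1], tile_px)
    return np.add.reduceat(np.add.reduceat(arr, r_edges, axis=0), c_edges, axis=1)


def compute_tile_fractions(
    segments: SegmentSet,
    tile_size_um: float = 250.0,
) -> TileFractionMap:
    """GFAP+ area fraction per tile from a filtered segment set.

    Each full tile's fraction is (retained segmented pixels in the tile x
    pixel_size^2) / tile_size^2; partial edge tiles use their actual
    covered area as denominator and are flagged as not full.
    """
    ps = segments.pixel_size
    if tile_size_um < 10 * ps:
        raise ValueError("tile_size_um must be at least 10 pixels")
    rows, cols = segments.label_map.shape
    tile_px = int(round(tile_size_um / ps))
    if tile_px > rows or tile_px > cols:
        warnings.warn("tile larger than image: single-tile map", stacklevel=2)
    mask = segments.mask
    positive = _block_sums(mask.astype(np.int64), tile_px)
    area = _block_sums(np.ones((rows, cols), dtype=np.int64), tile_px)
    return TileFractionMap(
        positive_px=positive,
        tile_area_px=area,
        tile_size_um=tile_size_um,
        tile_px=tile_px,
        pixel_size=ps,
    )


def tile_means(raster: np.ndarray, tile_map: TileFractionMap) -> np.ndarray:
    """Mean of a slice-resolution raster (e.g. dose in Gy) per tile of the map."""
    raster = np.asarray(raster, dtype=np.float64)
    sums = _block_sums(raster, tile_map.tile_px)
    return sums / tile_map.tile_area_px


def define_mirrored_rois(
    image_shape: tuple[int, int],
    beam_axis_row: float,
    mirror_axis_col: float,
    roi_size_um: float,
    center_col_px: float,
    pixel_size: float,
    center_row_px: float | None = None,
) -> tuple[ROISpec, ROISpec]:
    """A square ROI centered on the beam axis plus its mirrored twin.

    The irradiated-side ROI of ``roi_size_um`` x ``roi_size_um`` is centered
    at (``beam_axis_row`` unless overridden, ``center_col_px``); the
    contralateral ROI is its exact reflection about ``mirror_axis_col``.
    Raises if the ROI crosses the mirror axis or does not fit the image on
    both sides.
    """
    rows, cols = image_shape
    half = roi_size_um / pixel_size / 2.0
    cr = beam_axis_row if center_row_px is None else center_row_px
    rect = (cr - half, cr + half, center_col_px - half, center_col_px + half)
    side = "right" if center_col_px > mirror_axis_col else "left"
    primary = ROISpec(rectangle=rect, side=side, mirror_axis_col=mirror_axis_col)
    secondary = primary.mirrored()
    for roi in (primary, secondary):
        r0, r1, c0, c1 = roi.rectangle
        if r0 < -0.5 or r1 > rows - 0.5 or c0 < -0.5 or c1 > cols - 0.5:
            raise ValueError("ROI does not fit inside the image in both hemispheres")
    if primary.side == "right":
        return primary, secondary
    return secondary, primary


def _center_selection(tile_map: TileFractionMap, roi: ROISpec) -> tuple[np.ndarray, np.ndarray]:
    rows_c = tile_map.tile_center_rows()
    cols_c = tile_map.tile_center_cols()
    r0, r1, c0, c1 = roi.rectangle
    row_sel = (rows_c >= r0) & (rows_c <= r1)
    col_sel = (cols_c >= c0) & (cols_c <= c1)
    return row_sel, col_sel


def mean_roi_fraction(tile_map: TileFractionMap, roi: ROISpec) -> float:
    """Unweighted mean fraction over all full tiles whose centers fall in the ROI."""
    row_sel, col_sel = _center_selection(tile_map, roi)
    sel = np.outer(row_sel, col_sel) & tile_map.full
    if not sel.any():
        raise ValueError("no full tile centers inside the ROI")
    return float(tile_map.fractions[sel].mean())


def beam_axis_profile(
    tile_map: TileFractionMap,
    dose_raster: np.ndarray,
    roi: ROISpec,
) -> Profile:
    """Depth profiles of GFAP+ fraction and dose along the beam axis.

    For every tile column across the whole slice, the mean fraction and
    mean dose are taken over the full tiles whose centers lie inside the
    ROI's transverse (row) extent.
    """
    row_sel, _ = _center_selection(tile_map, roi)
    if not row_sel.any():
        raise ValueError("ROI transverse extent contains no tile centers")
    dose_tiles = tile_means(dose_raster, tile_map)
    frac = tile_map.fractions
    full = tile_map.full
    positions = []
    gfap = []
    dose = []
    cols_c = tile_map.tile_center_cols()
    for j in range(tile_map.shape[1]):
        sel = row_sel & full[:, j]
        if not sel.any():
            continue
        positions.append(cols_c[j] * tile_map.pixel_size)
        gfap.append(frac[sel, j].mean())
        dose.append(dose_tiles[sel, j].mean())
    return Profile(
        positions_um=np.array(positions),
        gfap_means=np.array(gfap),
        dose_means=np.array(dose),
        axis="along-beam",
        band="ROI",
    )


def _rects_overlap(a: ROISpec, b: ROISpec) -> bool:
    ar0, ar1, ac0, ac1 = a.rectangle
    br0, br1, bc0, bc1 = b.rectangle
    return not (ar1 < br0 or br1 < ar0 or ac1 < bc0 or bc1 < ac0)


def _band_profile(
    tile_map: TileFractionMap,
    dose_tiles: np.ndarray,
    band: ROISpec,
    label: str,
) -> Profile:
    row_sel, col_sel = _center_selection(tile_map, band)
    if not col_sel.any() or not row_sel.any():
        raise ValueError(f"band '{label}' contains no tile centers")
    frac = tile_map.fractions
    full = tile_map.full
    rows_c = tile_map.tile_center_rows()
    positions = []
    gfap = []
    dose = []
    for i in np.flatnonzero(row_sel):
        sel = col_sel & full[i, :]
        if not sel.any():
            continue
        positions.append(rows_c[i] * tile_map.pixel_size)
        gfap.append(frac[i, sel].mean())
        dose.append(dose_tiles[i, sel].mean())
    return Profile(
        positions_um=np.array(positions),
        gfap_means=np.array(gfap),
        dose_means=np.array(dose),
        axis="transverse",
        band=label,
    )


def transverse_band_profiles(
    tile_map: TileFractionMap,
    dose_raster: np.ndarray,
    cortex_band: ROISpec,
    central_band: ROISpec,
) -> tuple[Profile, Profile]:
    """Transverse profiles averaged along the beam within two depth bands.

    For each tile row, the mean GFAP+ fraction and mean dose are computed
    over the full tiles whose centers fall inside the cortex band and the
    central-brain band, respectively.  The bands must not overlap.
    """
    if _rects_overlap(cortex_band, central_band):
        raise ValueError("cortex and central bands overlap")
    dose_tiles = tile_means(dose_raster, tile_map)
    cortex = _band_profile(tile_map, dose_tiles, cortex_band, "cortex")
    central = _band_profile(tile_map, dose_tiles, central_band, "central")
    return cortex, central
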