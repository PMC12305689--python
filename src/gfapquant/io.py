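"""TIFF / CSV / JSON input-output helpers.

Slice channels are written as single-channel TIFF with the pixel size in
ImageJ-style resolution metadata plus a sidecar JSON (channel, slice id,
pixel size, and any extra metadata such as prescription dose or seed).
Dose grids are 32-bit float TIFF in Gy with the grid-to-slice affine in
the sidecar.  The sidecar is the authoritative source when reading.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .dosemap import AffineTransform2D, DoseGrid
from .segment import SegmentSet, SliceImage
from .tiles import Profile, TileFractionMap

__all__ = [
    "write_slice",
    "read_slice",
    "write_dose",
    "read_dose",
    "write_label_map",
    "segments_to_dataframe",
    "tile_map_to_dataframe",
    "profile_to_dataframe",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_slice(path: str | Path, image: SliceImage, extra: dict | None = None) -> Path:
    """Write a slice channel as 16-bit TIFF plus sidecar JSON."""
    path = Path(path)
    values = np.clip(np.asarray(image.values), 0, 65535)
    tifffile.imwrite(
        path,
        values.astype(np.uint16),
        resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        metadata={"unit": "um"},
    )
    meta = {
        "pixel_size_um": image.pixel_size,
        "channel": image.channel,
        "slice_id": image.slice_id,
        "quality_score": image.quality_score,
    }
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_slice(path: str | Path, pixel_size: float | None = None) -> SliceImage:
    """Read a slice TIFF; pixel size comes from the sidecar unless given."""
    path = Path(path)
    values = tifffile.imread(path)
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValueError(f"no pixel size for {path}: pass pixel_size or provide a sidecar")
    return SliceImage(
        values=values,
        pixel_size=float(ps),
        channel=meta.get("channel", "GFAP"),
        slice_id=meta.get("slice_id", path.stem),
        quality_score=int(meta.get("quality_score", 5)),
    )


def write_dose(
    path: str | Path,
    dose: DoseGrid,
    transform: AffineTransform2D | None = None,
) -> Path:
    """Write a dose grid as 32-bit float TIFF (Gy) plus sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, dose.values.astype(np.float32))
    meta = {
        "spacing_um": dose.spacing_um,
        "beam_direction": list(dose.beam_direction),
        "prescription_dose_Gy": dose.prescription_dose,
    }
    if transform is not None:
        meta["affine_to_slice"] = transform.matrix.tolist()  # 2x3, row-major
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_dose(path: str | Path) -> tuple[DoseGrid, AffineTransform2D | None]:
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    dose = DoseGrid(
        values=values,
        spacing_um=float(meta["spacing_um"]),
        beam_direction=tuple(meta["beam_direction"]),
        prescription_dose=float(meta["prescription_dose_Gy"]),
    )
    transform = None
    if "affine_to_slice" in meta:
        transform = AffineTransform2D(np.asarray(meta["affine_to_slice"], dtype=float))
    return dose, transform


def write_label_map(path: str | Path, segments: SegmentSet) -> Path:
    path = Path(path)
    label_map = segments.label_map
    dtype = np.uint16 if label_map.max() < 2**16 else np.uint32
    tifffile.imwrite(path, label_map.astype(dtype))
    return path


def segments_to_dataframe(segments: SegmentSet) -> pd.DataFrame:
    """Per-segment table: label, area in um^2, centroid (row, col)."""
    n = segments.n_segments
    if n == 0:
        return pd.DataFrame(columns=["label", "area_um2", "centroid_row", "centroid_col"])
    centroids = ndi.center_of_mass(
        segments.label_map > 0, segments.label_map, index=np.arange(1, n + 1)
    )
    centroids = np.asarray(centroids, dtype=float)
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "area_um2": segments.areas_um2,
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
        }
    )


def tile_map_to_dataframe(
    tile_map: TileFractionMap,
    dose_means: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format tile table (tile_row, tile_col, fraction, mean dose, full flag)."""
    nr, nc = tile_map.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    data = {
        "tile_row": rows.ravel(),
        "tile_col": cols.ravel(),
        "fraction": tile_map.fractions.ravel(),
        "full_tile": tile_map.full.ravel(),
    }
    if dose_means is not None:
        data["mean_dose_Gy"] = np.asarray(dose_means, dtype=float).ravel()
    return pd.DataFrame(data)


def profile_to_dataframe(profile: Profile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position_um": profile.positions_um,
            "gfap_mean": profile.gfap_means,
            "dose_mean_Gy": profile.dose_means,
            "axis": profile.axis,
            "band": profile.band,
        }
    )
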