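"""End-to-end orchestration: phantom cohort -> segmentation -> tiles -> stats.

The pipeline reproduces the study design on synthetic data: a cohort of
brain-slice images at several prescription-dose levels (plus sham), each
segmented for GFAP+ area, tiled, reduced to mirrored hemisphere ROI means,
profiled along and transverse to the beam axis, and finally fed into the
dose-response regression for both hemispheres.  All randomness derives
from a single seed; identical configurations produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import io as gio
from .dosemap import resample_dose
from .phantom import PhantomConfig, generate_phantom
from .segment import SegmentationParams, segment_slice
from .stats import DoseResponseFit, HemisphereSummary, fit_dose_response, summarize_hemispheres
from .tiles import (
    Profile,
    ROISpec,
    TileFractionMap,
    compute_tile_fractions,
    define_mirrored_rois,
    mean_roi_fraction,
    beam_axis_profile,
    tile_means,
    transverse_band_profiles,
)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


class PipelineConfig(BaseModel, frozen=True):
    """Configuration of a full phantom-cohort analysis run."""

    seed: int = 0
    phantom: PhantomConfig = PhantomConfig()
    dose_levels_gy: tuple[float, ...] = (0.0, 45.0, 65.0, 85.0)
    slices_per_level: int = 3
    rolling_ball_radius_um: float = 3.25
    min_area_um2: float = 7.0
    max_area_um2: float = 1000.0
    connectivity: int = 8
    tile_size_um: float = 250.0
    roi_size_um: float = 2400.0
    roi_center_col_px: float | None = None  # default: Bragg-peak column, clamped
    central_band_halfwidth_um: float = 300.0
    include_sham_in_fit: bool = True
    compute_profiles: bool = True
    outdir: str | None = None

    @classmethod
    def small(cls, **overrides) -> "PipelineConfig":
        """Reduced-scale configuration matching :meth:`PhantomConfig.small`."""
        base = dict(
            phantom=PhantomConfig.small(),
            tile_size_um=100.0,
            roi_size_um=600.0,
            central_band_halfwidth_um=100.0,
        )
        base.update(overrides)
        return cls(**base)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            rolling_ball_radius_um=self.rolling_ball_radius_um,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            connectivity=self.connectivity,
        )


@dataclass
class PipelineResult:
    """Everything a full run produces, in memory."""

    per_slice: pd.DataFrame
    right_fit: DoseResponseFit
    left_fit: DoseResponseFit
    summary: HemisphereSummary
    rois: tuple[ROISpec, ROISpec]
    tile_maps: dict[str, TileFractionMap]
    profiles: dict[str, dict[str, Profile]]
    config: PipelineConfig


def default_rois(config: PipelineConfig) -> tuple[ROISpec, ROISpec]:
    """Mirrored ROIs centered on the beam axis near the Bragg peak.

    The irradiated-side ROI is centered on the Bragg-peak column, clamped
    so that it stays inside the irradiated hemisphere and clear of the
    lateral cortex band (the anatomical ROI excludes the cortex).
    """
    ph = config.phantom
    rows, cols = ph.image_shape
    ps = ph.pixel_size
    half = config.roi_size_um / ps / 2.0
    margin_px = ph.cortex_margin_um / ps
    peak_col = (cols - 1) - ph.peak_depth_um / ps
    center = config.roi_center_col_px
    if center is None:
        # ROI may touch the midline and the cortex band but not enter either
        lo = ph.midline + half
        hi = (cols - 1) - margin_px - half + 0.5
        if lo > hi:
            raise ValueError("ROI does not fit between midline and cortex band")
        center = float(np.clip(peak_col, lo, hi))
    return define_mirrored_rois(
        image_shape=(rows, cols),
        beam_axis_row=ph.axis_row,
        mirror_axis_col=ph.midline,
        roi_size_um=config.roi_size_um,
        center_col_px=center,
        pixel_size=ps,
    )


def default_bands(config: PipelineConfig) -> tuple[ROISpec, ROISpec]:
    """Cortex (beam-entry side) and central-brain depth bands for profiles."""
    ph = config.phantom
    rows, cols = ph.image_shape
    ps = ph.pixel_size
    m = ph.midline
    margin_px = ph.cortex_margin_um / ps
    peak_col = (cols - 1) - ph.peak_depth_um / ps
    hw = config.central_band_halfwidth_um / ps
    cortex = ROISpec(
        rectangle=(-0.5, rows - 0.5, cols - 1 - margin_px, cols - 0.5),
        side="right",
        mirror_axis_col=m,
    )
    central = ROISpec(
        rectangle=(-0.5, rows - 0.5, peak_col - hw, peak_col + hw),
        side="right",
        mirror_axis_col=m,
    )
    return cortex, central


def _slice_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on a phantom cohort.

    For each slice: phantom generation, dose resampling into slice
    coordinates, GFAP segmentation, tile fraction map, mirrored ROI means,
    and (optionally) beam-axis and transverse band profiles.  Across
    slices: per-dose-level hemisphere summaries and the right/left
    dose-response fits.  If ``config.outdir`` is set, tables and a
    provenance record are written there; partial outputs are retained on
    stage failure.
    """
    n_slices = len(config.dose_levels_gy) * config.slices_per_level
    seeds = _slice_seeds(config.seed, n_slices)
    seg_params = config.segmentation_params()
    rois = default_rois(config)
    bands = default_bands(config)
    right_roi, left_roi = rois

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    records = []
    tile_maps: dict[str, TileFractionMap] = {}
    profiles: dict[str, dict[str, Profile]] = {}
    k = 0
    for dose_level in config.dose_levels_gy:
        for rep in range(config.slices_per_level):
            slice_seed = seeds[k]
            k += 1
            try:
                ph_cfg = config.phantom.model_copy(
                    update={"seed": slice_seed, "prescription_dose": float(dose_level)}
                )
                bundle = generate_phantom(ph_cfg)
            except Exception as exc:
                raise StageError("phantom", exc) from exc
            slice_id = f"d{dose_level:g}-r{rep}"
            try:
                dose_px = resample_dose(
                    bundle.dose, bundle.dose_transform, ph_cfg.image_shape
                )
            except Exception as exc:
                raise StageError("dosemap", exc) from exc
            try:
                segments, threshold = segment_slice(bundle.gfap, seg_params)
            except Exception as exc:
                raise StageError("segment", exc) from exc
            try:
                tmap = compute_tile_fractions(segments, config.tile_size_um)
                right = mean_roi_fraction(tmap, right_roi)
                left = mean_roi_fraction(tmap, left_roi)
            except Exception as exc:
                raise StageError("tiles", exc) from exc
            tile_maps[slice_id] = tmap
            if config.compute_profiles:
                try:
                    beam = beam_axis_profile(tmap, dose_px, right_roi)
                    cortex_p, central_p = transverse_band_profiles(
                        tmap, dose_px, bands[0], bands[1]
                    )
                except Exception as exc:
                    raise StageError("profiles", exc) from exc
                profiles[slice_id] = {
                    "beam": beam,
                    "cortex": cortex_p,
                    "central": central_p,
                }
            records.append(
                {
                    "slice_id": slice_id,
                    "prescription_dose_Gy": float(dose_level),
                    "phantom_seed": slice_seed,
                    "right_fraction": right,
                    "left_fraction": left,
                    "otsu_threshold": threshold,
                    "n_segments": segments.n_segments,
                    "total_area_um2": segments.total_area_um2,
                }
            )
            if outdir:
                dose_tiles = tile_means(dose_px, tmap)
                gio.tile_map_to_dataframe(tmap, dose_tiles).to_csv(
                    outdir / f"tiles_{slice_id}.csv", index=False
                )

    per_slice = pd.DataFrame.from_records(records)
    try:
        summary = summarize_hemispheres(per_slice)
        fit_df = per_slice
        if not config.include_sham_in_fit:
            fit_df = per_slice[per_slice["prescription_dose_Gy"] > 0]
        right_fit = fit_dose_response(
            fit_df["prescription_dose_Gy"], fit_df["right_fraction"]
        )
        left_fit = fit_dose_response(
            fit_df["prescription_dose_Gy"], fit_df["left_fraction"]
        )
    except Exception as exc:
        if outdir:
            per_slice.to_csv(outdir / "slices.csv", index=False)
        raise StageError("stats", exc) from exc

    result = PipelineResult(
        per_slice=per_slice,
        right_fit=right_fit,
        left_fit=left_fit,
        summary=summary,
        rois=rois,
        tile_maps=tile_maps,
        profiles=profiles,
        config=config,
    )
    if outdir:
        _persist(result, outdir)
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    result.per_slice.to_csv(outdir / "slices.csv", index=False)
    result.summary.per_level.to_csv(outdir / "per_level_summary.csv", index=False)
    report = {
        "right_roi_fit": result.right_fit.to_dict(),
        "left_roi_fit": result.left_fit.to_dict(),
    }
    (outdir / "dose_response.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    for slice_id, profs in result.profiles.items():
        frames = [gio.profile_to_dataframe(p) for p in profs.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"profiles_{slice_id}.csv", index=False
        )
    config_json = result.config.model_dump_json()
    provenance = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": result.config.seed,
        "package": "gfapquant",
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
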