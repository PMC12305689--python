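#!/usr/bin/env python
"""Generate the synthetic slice cohort: 0/45/65/85 Gy, three slices each.

Writes GFAP/DAPI channels (16-bit TIFF), the planning-grid dose (32-bit
float TIFF with its affine-to-slice transform), and the ground-truth mask
per slice under scratch/phantoms/ (large binary rasters are scratch, not
results), plus the cohort configuration JSON that the later stages read.

    python analysis/01_simulate_cohort.py --seed 1 [--small]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from gfapquant import io as gio
from gfapquant.phantom import generate_phantom
from gfapquant.pipeline import PipelineConfig, _slice_seeds


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("scratch/phantoms"))
    parser.add_argument("--small", action="store_true", help="reduced-scale cohort")
    args = parser.parse_args()

    config = (PipelineConfig.small if args.small else PipelineConfig)(seed=args.seed)
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "cohort.json").write_text(config.model_dump_json(indent=2))

    n = len(config.dose_levels_gy) * config.slices_per_level
    seeds = _slice_seeds(config.seed, n)
    k = 0
    for dose in config.dose_levels_gy:
        for rep in range(config.slices_per_level):
            ph = config.phantom.model_copy(
                update={"seed": seeds[k], "prescription_dose": float(dose)}
            )
            k += 1
            bundle = generate_phantom(ph)
            slice_dir = args.outdir / f"d{dose:g}-r{rep}"
            slice_dir.mkdir(exist_ok=True)
            extra = {"prescription_dose_Gy": float(dose), "seed": ph.seed}
            gio.write_slice(slice_dir / "gfap.tif", bundle.gfap, extra)
            gio.write_slice(slice_dir / "dapi.tif", bundle.dapi, extra)
            gio.write_dose(slice_dir / "dose.tif", bundle.dose, bundle.dose_transform)
            np.save(slice_dir / "truth_mask.npy", bundle.truth.gfap_mask)
            print(
                f"{slice_dir.name}: {bundle.truth.object_count} objects, "
                f"true GFAP+ fraction {bundle.truth.gfap_mask.mean():.4f}"
            )
    print(f"\ncohort of {n} slices written to {args.outdir}")


if __name__ == "__main__":
    main()
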