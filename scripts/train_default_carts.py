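"""Train the default hole and structure CARTs on synthetic ground truth.

Writes the fitted trees as JSON fixtures into ``src/shgfib/models/`` so the
segmentation pipeline works out of the box.  Re-run after changing the
synthetic-tile generator or the hole/structure feature definitions:

    python scripts/train_default_carts.py [--seed 20240615] [--tiles-per-stage 6]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from shgfib import preprocess, regions, synthdata

MODELS_DIR = Path(__file__).resolve().parents[1] / "src" / "shgfib" / "models"


def collect_training_data(seed: int, tiles_per_stage: int):
    hole_records, hole_labels = [], []
    struct_records, struct_labels = [], []
    idx = 0
    for stage in range(5):
        for rep in range(tiles_per_stage):
            spec = synthdata.TileSpec(stage=stage, seed=seed + 97 * idx)
            idx += 1
            tile, truth = synthdata.generate_tile(spec)
            clean = preprocess.remove_noise(tile)
            collagen = preprocess.detect_collagen(clean.shg)
            tissue = regions.tissue_mask_from_tpef(clean.tpef)
            holes = regions.detect_holes(
                clean.tpef, tissue, tile.pixel_size, collagen_mask=collagen.mask
            )
            labels = synthdata.label_detected_holes(holes, truth)
            hole_records += holes
            hole_labels += labels
            vessel = [h for h, lab in zip(holes, labels)
                      if lab == "vessel_or_duct"]
            structures = regions.build_structures(
                vessel, collagen.mask, tile.pixel_size
            )
            struct_records += structures
            struct_labels += synthdata.label_detected_structures(
                structures, truth
            )
    return hole_records, hole_labels, struct_records, struct_labels


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240615)
    ap.add_argument("--tiles-per-stage", type=int, default=6)
    args = ap.parse_args()

    holes, hlab, structs, slab = collect_training_data(
        args.seed, args.tiles_per_stage
    )
    print(f"training holes: {len(holes)} "
          f"({hlab.count('vessel_or_duct')} vessel_or_duct)")
    print(f"training structures: {len(structs)} "
          f"({slab.count('central_vein')} central_vein)")

    hole_cart = regions.train_hole_cart(holes, hlab, seed=0)
    structure_cart = regions.train_structure_cart(structs, slab, seed=0,
                                                  min_samples_leaf=3)
    print(f"hole CART training accuracy: {hole_cart.accuracy(holes, hlab):.3f}")
    print("structure CART training accuracy: "
          f"{structure_cart.accuracy(structs, slab):.3f}")

    MODELS_DIR.mkdir(parents=True, exist_ok=True)
    hole_cart.save(MODELS_DIR / "hole_cart.json")
    structure_cart.save(MODELS_DIR / "structure_cart.json")
    print(f"wrote fixtures to {MODELS_DIR}")


if __name__ == "__main__":
    main()
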