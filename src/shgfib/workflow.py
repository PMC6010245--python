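"""End-to-end pipelines: simulate → extract → train → validate.

Each step is a plain function over a :class:`PipelineConfig`; the ``shgfib``
command-line tool in :mod:`shgfib.cli` is a thin wrapper.  A run is fully
determined by its config and seed: tiles are written as two-page 16-bit
TIFF (page 1 SHG, page 2 TPEF), ground-truth region maps as indexed PNG
(0 background, 1 CV, 2 PT, 3 PS), manifests as JSON/CSV, features and
reports as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import diagnostics, featureset, morphometry, regions, staging, synthdata
from .preprocess import PIXEL_SIZE_UM, TileImage

log = logging.getLogger("shgfib")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serialisable to YAML."""

    # simulation
    n_subjects: int = 83
    tiles_per_subject: int = 3
    stage_probabilities: tuple = synthdata.STAGE_PROBABILITIES
    seed: int = 0
    tile_spec: dict = field(default_factory=dict)
    # segmentation
    min_hole_area_um2: float = 10.0
    density_radius_um: float = 100.0
    collagen_annulus_um: float = 15.0
    link_distance_um: float = 50.0
    halo_radius_um: float = 25.0
    # morphometry
    min_string_pixels: int = 4
    length_cutoff_um: float | None = None   # None → per-subject median
    # staging
    k_features: int = 14
    reselect_per_fold: bool = False
    standardize: bool = True
    # provenance
    version: str = __version__

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("version", None)
        data["stage_probabilities"] = tuple(
            data.get("stage_probabilities", synthdata.STAGE_PROBABILITIES)
        )
        return cls(**data)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def write_tile(path, tile: TileImage) -> None:
    stack = np.stack([
        np.clip(tile.shg, 0, 65535).astype(np.uint16),
        np.clip(tile.tpef, 0, 65535).astype(np.uint16),
    ])
    tifffile.imwrite(path, stack)


def read_tile(path) -> TileImage:
    stack = tifffile.imread(path)
    return TileImage(shg=stack[0], tpef=stack[1], pixel_size=PIXEL_SIZE_UM)


def run_simulate(config: PipelineConfig, outdir) -> Path:
    """Generate a cohort on disk; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthdata.generate_cohort(
        config.n_subjects,
        stage_probabilities=config.stage_probabilities,
        tiles_per_subject=config.tiles_per_subject,
        seed=config.seed,
        tile_spec_kw=dict(config.tile_spec),
    )
    rows = []
    for subject in cohort:
        sdir = outdir / subject.subject_id
        sdir.mkdir(exist_ok=True)
        tile_paths = []
        for t, (tile, truth) in enumerate(subject.tiles):
            tile_path = sdir / f"tile{t:02d}.tiff"
            write_tile(tile_path, tile)
            iio.imwrite(sdir / f"tile{t:02d}_regions.png",
                        truth.region_map.labels.astype(np.uint8))
            manifest = {
                "stage": truth.stage,
                "holes": [
                    {"class": h.hole_class,
                     "structure_class": h.structure_class,
                     "n_pixels": int(len(h.coords))}
                    for h in truth.holes
                ],
                "n_strings": len(truth.strings),
            }
            (sdir / f"tile{t:02d}_truth.json").write_text(
                json.dumps(manifest, indent=1))
            tile_paths.append(str(tile_path.relative_to(outdir)))
        rows.append({"subject_id": subject.subject_id, "stage": subject.stage,
                     "tiles": ";".join(tile_paths)})
        log.info("simulated %s (stage %d, %d tiles)", subject.subject_id,
                 subject.stage, len(subject.tiles))
    manifest_path = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    config.to_yaml(outdir / "config.yaml")
    return manifest_path


# ---------------------------------------------------------------------------
# extract
# ---------------------------------------------------------------------------

def extract_tile_features(tile: TileImage, config: PipelineConfig,
                          hole_model=None, structure_model=None) -> pd.Series:
    """Segment one tile and compute its 100-feature vector (before the
    subject-level short/long split and aggregation)."""
    seg = regions.segment_tile(
        tile,
        hole_model=hole_model,
        structure_model=structure_model,
        min_hole_area_um2=config.min_hole_area_um2,
        link_distance_um=config.link_distance_um,
        halo_radius_um=config.halo_radius_um,
        density_radius_um=config.density_radius_um,
        collagen_annulus_um=config.collagen_annulus_um,
    )
    strings = morphometry.extract_strings(
        seg.collagen, seg.region_map, tile.pixel_size,
        min_pixels=config.min_string_pixels,
    )
    morphometry.classify_length(strings, config.length_cutoff_um)
    return morphometry.compute_features(
        strings, seg.region_map, seg.tissue_mask, tile.pixel_size
    )


def extract_subject_features(tiles, config: PipelineConfig,
                             hole_model=None, structure_model=None) -> pd.Series:
    rows = [
        extract_tile_features(t, config, hole_model, structure_model)
        for t in tiles
    ]
    return morphometry.aggregate_tiles(rows)


def run_extract(config: PipelineConfig, cohort_dir, out_csv) -> Path:
    """Compute the subject × 100-feature table for a cohort on disk."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "cohort.csv")
    hole_model = regions.load_default_hole_cart()
    structure_model = regions.load_default_structure_cart()
    rows = []
    for _, rec in manifest.iterrows():
        tiles = []
        skip = False
        for rel in str(rec["tiles"]).split(";"):
            try:
                tiles.append(read_tile(cohort_dir / rel))
            except (OSError, ValueError) as exc:
                log.warning("unreadable tile %s (%s); skipping subject %s",
                            rel, exc, rec["subject_id"])
                skip = True
                break
        if skip or not tiles:
            continue
        feats = extract_subject_features(tiles, config, hole_model,
                                         structure_model)
        row = feats.to_dict()
        row["subject_id"] = rec["subject_id"]
        row["stage"] = int(rec["stage"])
        rows.append(row)
        log.info("extracted %s: %d tiles, collagen %.2f%%",
                 rec["subject_id"], len(tiles), feats["Col"])
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    columns = ["subject_id", "stage"] + list(featureset.FEATURE_NAMES)
    pd.DataFrame(rows, columns=columns).to_csv(out_csv, index=False)
    return out_csv


# ---------------------------------------------------------------------------
# train / validate
# ---------------------------------------------------------------------------

def load_feature_table(path):
    df = pd.read_csv(path)
    feature_cols = [c for c in df.columns if c in featureset.FEATURE_NAMES]
    return df, df.loc[:, feature_cols], df["stage"].to_numpy()


def run_train(config: PipelineConfig, features_csv, model_json) -> staging.BIndexRegressor:
    _, X, y = load_feature_table(features_csv)
    model = staging.BIndexRegressor(
        k=config.k_features, standardize=config.standardize
    ).fit(X, y)
    Path(model_json).write_text(model.to_json())
    return model


def run_validate(config: PipelineConfig, features_csv, outdir,
                 make_plot: bool = True) -> pd.DataFrame:
    """Leave-one-out validation and the per-grouping performance report."""
    df, X, y = load_feature_table(features_csv)
    if len(np.unique(y)) < 2:
        raise ValueError("validation needs at least two distinct stages")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores = staging.loocv_predict(
        X, y, k=config.k_features,
        reselect_per_fold=config.reselect_per_fold,
        standardize=config.standardize,
    )
    pd.DataFrame({
        "subject_id": df["subject_id"], "stage": y, "b_index": scores,
    }).to_csv(outdir / "loocv_scores.csv", index=False)
    valid = np.isfinite(scores)
    if not valid.all():
        log.warning("%d fold(s) had singular designs; their scores are "
                    "excluded from the report", int((~valid).sum()))
    scores, y = scores[valid], y[valid]
    rho = diagnostics.spearman(scores, y)
    report = diagnostics.staging_performance_report(scores, y)
    report.to_csv(outdir / "staging_report.csv", index=False)
    md = [f"Spearman correlation of index with stage: {rho:.3f}", "",
          diagnostics.report_to_markdown(report)]
    (outdir / "staging_report.md").write_text("\n".join(md))
    if make_plot:
        _boxplot_by_stage(scores, y, outdir / "b_index_by_stage.png")
    log.info("validated %d subjects, Spearman %.3f", len(y), rho)
    return report


def _boxplot_by_stage(scores, stages, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = np.asarray(stages)
    groups = [np.asarray(scores)[stages == s] for s in range(5)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([g if len(g) else [np.nan] for g in groups],
               tick_labels=[str(s) for s in range(5)])
    ax.set_xlabel("Brunt fibrosis stage")
    ax.set_ylabel("fibrosis index (LOOCV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
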