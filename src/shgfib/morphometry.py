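"""Collagen-string extraction, classification and the 100-feature vector.

A collagen *string* is an 8-connected component of the segmented collagen
mask.  Its skeleton gives the geodesic length (orthogonal steps count one
pixel pitch, diagonal steps √2; a point-like skeleton is floored at one
pixel), the width is area/length (ribbon model), and three binary classes
are assigned:

* aggregated vs distributed — a string is aggregated (cross-linked) when
  its skeleton has at least one branch point, i.e. a skeleton pixel with
  three or more skeleton neighbours;
* thick vs thin — thick when width/length > 0.25 (strict);
* long vs short — long when the skeleton length exceeds a cutoff, by
  default the median length over the subject's strings.

Per-string measurements are then pooled into the 100 named features of
:mod:`shgfib.featureset`: for each of the CV/PT/PS regions a 28-feature
block of collagen-percentage, per-mm² string counts and mean string
statistics, plus a 16-feature whole-tissue block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from . import featureset
from .regions import BACKGROUND, REGION_NAMES, RegionMap

#: components smaller than this have no meaningful skeleton
MIN_STRING_PIXELS = 4

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class CollagenString:
    """One connected collagen object and its morphometric classes."""

    label: int
    coords: np.ndarray          # (k, 2) pixel coordinates
    area: float                 # μm²
    length: float               # μm, skeleton geodesic length
    width: float                # μm, area / length
    n_branch_points: int
    region: str | None          # "CV" | "PT" | "PS" | None
    aggregation: str = ""       # "aggregated" | "distributed"
    thickness: str = ""         # "thick" | "thin"
    length_class: str = ""      # "short" | "long"

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


def skeleton_metrics(component_mask: np.ndarray, pixel_size: float):
    """(length_um, n_branch_points) of a component's skeleton.

    Length sums inter-pixel steps along the skeleton (1 per orthogonal
    neighbour pair, √2 per diagonal pair) and is floored at one pixel pitch
    so single-pixel skeletons have nonzero length.
    """
    sk = skeletonize(component_mask)
    if not sk.any():
        return pixel_size, 0
    neighbors = _skeleton_neighbor_counts(sk)
    orth = _pair_count(sk, ((0, 1), (1, 0)))
    diag = _pair_count(sk, ((1, 1), (1, -1)))
    length = (orth + _SQRT2 * diag) * pixel_size
    n_branch = int((neighbors[sk] >= 3).sum())
    return max(length, pixel_size), n_branch


def _pair_count(sk: np.ndarray, offsets) -> int:
    total = 0
    for dr, dc in offsets:
        a = sk[max(dr, 0): sk.shape[0] + min(dr, 0),
               max(dc, 0): sk.shape[1] + min(dc, 0)]
        b = sk[max(-dr, 0): sk.shape[0] + min(-dr, 0),
               max(-dc, 0): sk.shape[1] + min(-dc, 0)]
        total += int((a & b).sum())
    return total


def _skeleton_neighbor_counts(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndi.convolve(sk.astype(int), kernel, mode="constant")


def extract_strings(
    mask,
    region_map: RegionMap | None = None,
    pixel_size: float = 1.0,
    min_pixels: int = MIN_STRING_PIXELS,
) -> list[CollagenString]:
    """Extract classified collagen strings from a binary mask.

    Components are 8-connected; those below ``min_pixels`` are treated as
    noise.  A string's region is the majority region label over its pixels.
    Aggregation and thickness are assigned here; the short/long split needs
    the whole population and is applied by :func:`classify_length`.
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask_arr.any():
        return []
    labeled, n = ndi.label(mask_arr, structure=np.ones((3, 3), dtype=int))
    strings: list[CollagenString] = []
    slices = ndi.find_objects(labeled)
    for lab, sl in zip(range(1, n + 1), slices):
        comp = labeled[sl] == lab
        k = int(comp.sum())
        if k < min_pixels:
            continue
        length, n_branch = skeleton_metrics(comp, pixel_size)
        area = k * pixel_size**2
        coords = np.argwhere(comp) + np.array([sl[0].start, sl[1].start])
        region = None
        if region_map is not None:
            labels = region_map.labels[coords[:, 0], coords[:, 1]]
            labels = labels[labels != BACKGROUND]
            if labels.size:
                region = REGION_NAMES[int(np.bincount(labels).argmax())]
        s = CollagenString(
            label=lab,
            coords=coords,
            area=float(area),
            length=float(length),
            width=float(area / length),
            n_branch_points=n_branch,
            region=region,
        )
        s.aggregation = classify_aggregation(s)
        s.thickness = classify_thickness(s)
        strings.append(s)
    return strings


def classify_aggregation(string: CollagenString) -> str:
    """Aggregated ⇔ cross-linked ⇔ the skeleton has ≥ 1 branch point."""
    return "aggregated" if string.n_branch_points >= 1 else "distributed"


def classify_thickness(string: CollagenString) -> str:
    """Thick ⇔ width/length > 0.25, strictly (a ratio of exactly 0.25 is thin)."""
    return "thick" if string.width / string.length > 0.25 else "thin"


def classify_length(
    strings: list[CollagenString], cutoff_um: float | None = None
) -> None:
    """Assign short/long in place: long ⇔ length > cutoff (strict).

    With ``cutoff_um=None`` the cutoff is the median length over the given
    strings, so in an all-equal population nothing exceeds the median and
    every string is short.
    """
    if not strings:
        return
    cutoff = (
        float(np.median([s.length for s in strings]))
        if cutoff_um is None
        else float(cutoff_um)
    )
    for s in strings:
        s.length_class = "long" if s.length > cutoff else "short"


# ---------------------------------------------------------------------------
# feature vector
# ---------------------------------------------------------------------------

def _scope_features(strings, area_mm2, region_share, prefix_region=None):
    """The count/percentage/statistic block for one scope (a region or the
    whole tissue).  ``area_mm2`` normalises counts; percentages are collagen
    area over scope area."""
    out: dict[str, float] = {}
    scope_area_um2 = area_mm2 * 1e6

    def pct(sel):
        if scope_area_um2 <= 0:
            return 0.0
        return 100.0 * sum(s.area for s in sel) / scope_area_um2

    agg = [s for s in strings if s.aggregation == "aggregated"]
    dis = [s for s in strings if s.aggregation == "distributed"]
    r = prefix_region or ""
    out[f"Col{r}"] = pct(strings)
    out[f"Agg{r}"] = pct(agg)
    out[f"Dis{r}"] = pct(dis)
    if prefix_region is not None:
        out[prefix_region] = region_share

    def counts(sel, suffix):
        def per_mm2(subset):
            return len(subset) / area_mm2 if area_mm2 > 0 else 0.0

        out[f"NoStr{r}{suffix}"] = per_mm2(sel)
        out[f"NoShortStr{r}{suffix}"] = per_mm2(
            [s for s in sel if s.length_class == "short"])
        out[f"NoLongStr{r}{suffix}"] = per_mm2(
            [s for s in sel if s.length_class == "long"])
        out[f"NoThickStr{r}{suffix}"] = per_mm2(
            [s for s in sel if s.thickness == "thick"])
        out[f"NoThinStr{r}{suffix}"] = per_mm2(
            [s for s in sel if s.thickness == "thin"])

    def stats(sel, suffix):
        out[f"StrArea{r}{suffix}"] = float(np.mean([s.area for s in sel])) if sel else 0.0
        out[f"StrLength{r}{suffix}"] = float(np.mean([s.length for s in sel])) if sel else 0.0
        out[f"StrWidth{r}{suffix}"] = float(np.mean([s.width for s in sel])) if sel else 0.0

    if prefix_region is not None:
        for sel, suffix in ((strings, ""), (agg, "A"), (dis, "D")):
            counts(sel, suffix)
        for sel, suffix in ((strings, ""), (agg, "A"), (dis, "D")):
            stats(sel, suffix)
    else:
        counts(strings, "")
        out["NoStrA"] = len(agg) / area_mm2 if area_mm2 > 0 else 0.0
        out["NoStrD"] = len(dis) / area_mm2 if area_mm2 > 0 else 0.0
        stats(strings, "")
        stats(agg, "A")
    return out


def compute_features(
    strings: list[CollagenString],
    region_map: RegionMap,
    tissue_mask: np.ndarray,
    pixel_size: float,
) -> pd.Series:
    """Assemble the 100-feature vector for one tile (or one pooled field).

    Strings must already carry all three classes.  Counts are normalised per
    mm² of the scope's area; percentages are collagen-area shares of the
    scope; string statistics are plain means (0 for an empty scope).  Regions
    absent from the tile yield all-zero blocks and are listed in
    ``result.attrs["missing_regions"]``.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    px_mm2 = (pixel_size / 1000.0) ** 2
    tissue_mm2 = float(tissue_mask.sum()) * px_mm2
    values: dict[str, float] = {}
    missing: list[str] = []
    for region in featureset.REGIONS:
        code = {"CV": 1, "PT": 2, "PS": 3}[region]
        region_mm2 = float((region_map.labels == code).sum()) * px_mm2
        sel = [s for s in strings if s.region == region]
        share = (
            100.0 * sum(s.area for s in sel) / (tissue_mm2 * 1e6)
            if tissue_mm2 > 0
            else 0.0
        )
        if region_mm2 <= 0:
            missing.append(region)
        values.update(
            _scope_features(sel, region_mm2, share, prefix_region=region)
        )
    values.update(_scope_features(strings, tissue_mm2, None))
    out = pd.Series(values, dtype=float).reindex(list(featureset.FEATURE_NAMES))
    out.attrs["missing_regions"] = missing
    out.attrs["tissue_mm2"] = tissue_mm2
    return out


def aggregate_tiles(feature_rows: list[pd.Series]) -> pd.Series:
    """Subject-level vector: tissue-area-weighted mean over tile vectors.

    Tiles are equal-area, so with full-tissue tiles this is the plain mean;
    the weighting keeps the aggregate sensible if tiles differ in tissue
    content.
    """
    if not feature_rows:
        raise ValueError("no tiles to aggregate")
    weights = np.array([r.attrs.get("tissue_mm2", 1.0) for r in feature_rows])
    if weights.sum() <= 0:
        weights = np.ones(len(feature_rows))
    mat = pd.concat(feature_rows, axis=1).to_numpy()
    agg = mat @ (weights / weights.sum())
    out = pd.Series(agg, index=feature_rows[0].index)
    missing = set.intersection(
        *(set(r.attrs.get("missing_regions", [])) for r in feature_rows)
    )
    out.attrs["missing_regions"] = sorted(missing)
    return out
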