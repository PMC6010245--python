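"""Hole detection, CART classification and the CV/PT/PS region map.

Liver lobule regions are recovered from the TPEF channel in four steps:

1. holes — vessels, bile ducts, steatosis vacuoles and preparation cracks —
   are detected as dark connected components inside the tissue;
2. a classification tree (CART) trained on hole morphology (density, width,
   length, solidity, surrounding collagen) separates vessel/bile-duct holes
   from the rest;
3. vessel-type holes are grouped into structures by single-linkage on
   centroid distance, optionally bridged by contiguous collagen;
4. a second CART classifies each structure as portal tract (typically a
   vessel plus bile ducts and a collagen patch) or central vein (typically
   one large hole), and the structure's holes plus a halo are painted into
   the region map.  All remaining tissue is perisinusoidal.

The decision trees published with the original method are not available, so
this module trains both CARTs (Gini impurity, depth ≤ 4, ≥ 5 samples per
leaf) on synthetic ground truth and ships the fitted trees as JSON fixtures
(see ``scripts/train_default_carts.py``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from sklearn.tree import DecisionTreeClassifier

from .preprocess import CollagenMask, TileImage, otsu_threshold

# region-map label codes
BACKGROUND, CV, PT, PS = 0, 1, 2, 3
REGION_CODES = {"CV": CV, "PT": PT, "PS": PS}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

HOLE_FEATURES = (
    "density",
    "width",
    "length",
    "solidity",
    "surrounding_collagen_area",
)
STRUCTURE_FEATURES = (
    "n_holes",
    "total_hole_area",
    "max_hole_area",
    "collagen_area",
)


@dataclass
class Hole:
    """A dark connected component inside the tissue, with the morphological
    features used by the hole CART.  Lengths in μm, areas in μm²."""

    label: int
    coords: np.ndarray            # (k, 2) pixel coordinates, row-major
    centroid: tuple[float, float]  # pixel units
    area: float
    width: float                  # minor axis of the best-fit ellipse
    length: float                 # major axis
    solidity: float
    density: float = 0.0          # neighbouring holes within a fixed radius
    surrounding_collagen_area: float = 0.0
    hole_class: str | None = None

    def features(self) -> dict[str, float]:
        return {
            "density": self.density,
            "width": self.width,
            "length": self.length,
            "solidity": self.solidity,
            "surrounding_collagen_area": self.surrounding_collagen_area,
        }


@dataclass
class Structure:
    """A group of vessel-type holes forming one portal tract or central
    vein candidate."""

    holes: list[Hole]
    collagen_area: float = 0.0
    structure_class: str | None = None

    @property
    def n_holes(self) -> int:
        return len(self.holes)

    @property
    def total_hole_area(self) -> float:
        return float(sum(h.area for h in self.holes))

    @property
    def max_hole_area(self) -> float:
        return float(max(h.area for h in self.holes))

    def features(self) -> dict[str, float]:
        return {
            "n_holes": float(self.n_holes),
            "total_hole_area": self.total_hole_area,
            "max_hole_area": self.max_hole_area,
            "collagen_area": self.collagen_area,
        }


@dataclass
class RegionMap:
    """Per-pixel region labels (0 background, 1 CV, 2 PT, 3 PS) and, for
    CV/PT pixels, the index of the structure that produced them."""

    labels: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.provenance is None:
            self.provenance = np.full(self.labels.shape, -1, dtype=np.int32)

    def area_px(self, code: int) -> int:
        return int((self.labels == code).sum())

    @property
    def tissue_px(self) -> int:
        return int((self.labels != BACKGROUND).sum())


class CartModel:
    """Binary CART over named features, JSON-serialisable.

    Wraps a fitted :class:`sklearn.tree.DecisionTreeClassifier`; prediction
    traverses the exported node arrays so that a serialised/reloaded model
    reproduces predictions exactly and input records may list features in
    any order (lookup is by name).
    """

    def __init__(self, feature_names, classes, nodes, meta=None):
        self.feature_names = list(feature_names)
        self.classes = list(classes)
        self.nodes = nodes  # dict of parallel lists
        self.meta = meta or {}

    # -- training -----------------------------------------------------
    @classmethod
    def train(
        cls,
        records,
        labels,
        feature_names,
        max_depth: int = 4,
        min_samples_leaf: int = 5,
        seed: int = 0,
    ) -> "CartModel":
        X = _records_to_matrix(records, feature_names)
        y = np.asarray(labels)
        classes = sorted(set(map(str, y)))
        if len(classes) < 2:
            warnings.warn(
                "single-class training set: trivial one-leaf CART", stacklevel=2
            )
            nodes = {
                "children_left": [-1],
                "children_right": [-1],
                "feature": [-1],
                "threshold": [0.0],
                "leaf_class": [0],
            }
            return cls(feature_names, classes, nodes,
                       {"max_depth": max_depth, "min_samples_leaf": min_samples_leaf})
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=seed,
        ).fit(X, y)
        t = tree.tree_
        leaf_class = np.argmax(t.value[:, 0, :], axis=1)
        nodes = {
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "leaf_class": leaf_class.tolist(),
        }
        return cls(
            list(feature_names),
            [str(c) for c in tree.classes_],
            nodes,
            {"criterion": "gini", "max_depth": max_depth,
             "min_samples_leaf": min_samples_leaf, "seed": seed},
        )

    # -- prediction ---------------------------------------------------
    def predict_one(self, record) -> str:
        if hasattr(record, "features"):
            record = record.features()
        node = 0
        left = self.nodes["children_left"]
        right = self.nodes["children_right"]
        feat = self.nodes["feature"]
        thr = self.nodes["threshold"]
        while left[node] != -1:
            value = float(record[self.feature_names[feat[node]]])
            node = left[node] if value <= thr[node] else right[node]
        return self.classes[self.nodes["leaf_class"][node]] if len(self.classes) > 1 \
            else self.classes[0]

    def predict(self, records) -> list[str]:
        if isinstance(records, pd.DataFrame):
            records = records.to_dict("records")
        return [self.predict_one(r) for r in records]

    def accuracy(self, records, labels) -> float:
        pred = self.predict(records)
        labels = [str(y) for y in labels]
        return float(np.mean([p == y for p, y in zip(pred, labels)]))

    # -- serialisation ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "classes": self.classes,
                "nodes": self.nodes,
                "meta": self.meta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CartModel":
        obj = json.loads(text)
        return cls(obj["feature_names"], obj["classes"], obj["nodes"], obj.get("meta"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CartModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _records_to_matrix(records, feature_names) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records.loc[:, list(feature_names)].to_numpy(dtype=float)
    rows = []
    for r in records:
        if hasattr(r, "features"):
            r = r.features()
        rows.append([float(r[name]) for name in feature_names])
    return np.asarray(rows, dtype=float)


def load_default_hole_cart() -> CartModel:
    """Hole CART fitted on synthetic ground truth, shipped with the package."""
    text = resources.files("shgfib").joinpath("models/hole_cart.json").read_text()
    return CartModel.from_json(text)


def load_default_structure_cart() -> CartModel:
    text = resources.files("shgfib").joinpath("models/structure_cart.json").read_text()
    return CartModel.from_json(text)


# ---------------------------------------------------------------------------
# hole detection
# ---------------------------------------------------------------------------

def tissue_mask_from_tpef(tpef: np.ndarray) -> np.ndarray:
    """Tissue extent: bright TPEF pixels with enclosed holes filled."""
    threshold, degenerate = otsu_threshold(tpef)
    if degenerate:
        return np.zeros_like(np.asarray(tpef), dtype=bool)
    bright = np.asarray(tpef) > threshold
    if bright.mean() < 0.05:
        return np.zeros_like(bright)
    return ndi.binary_fill_holes(bright)


def detect_holes(
    tpef: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 10.0,
    collagen_mask: np.ndarray | None = None,
    density_radius_um: float = 100.0,
    collagen_annulus_um: float = 15.0,
) -> list[Hole]:
    """Detect holes (dark connected components) fully inside the tissue.

    Components touching the image border are discarded — a truncated hole
    cannot be told apart from the field edge and its shape features would be
    biased.  Each hole carries the five CART features; the neighbour-count
    density and the surrounding-collagen annulus radii are configurable.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        return []
    tpef = np.asarray(tpef, dtype=float)
    threshold, degenerate = otsu_threshold(tpef[tissue_mask])
    if degenerate:
        return []
    dark = (tpef <= threshold) & tissue_mask
    if dark.mean() > 0.4:  # thresholding split noise, not holes
        return []
    labeled, _ = ndi.label(dark, structure=np.ones((3, 3), dtype=int))
    holes: list[Hole] = []
    nrow, ncol = tpef.shape
    for prop in measure.regionprops(labeled):
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == nrow or maxc == ncol:
            continue  # touches the field border
        area_um2 = prop.area * pixel_size**2
        if area_um2 < min_area_um2:
            continue
        holes.append(
            Hole(
                label=prop.label,
                coords=prop.coords,
                centroid=tuple(prop.centroid),
                area=float(area_um2),
                width=float(prop.axis_minor_length * pixel_size),
                length=float(prop.axis_major_length * pixel_size),
                solidity=float(prop.solidity),
            )
        )
    _fill_hole_context(
        holes, tpef.shape, pixel_size, collagen_mask,
        density_radius_um, collagen_annulus_um,
    )
    return holes


def _fill_hole_context(
    holes, shape, pixel_size, collagen_mask, density_radius_um, collagen_annulus_um
) -> None:
    """Populate density (neighbours within radius) and surrounding collagen."""
    if not holes:
        return
    centroids = np.array([h.centroid for h in holes])
    if len(holes) > 1:
        d = np.linalg.norm(
            centroids[:, None, :] - centroids[None, :, :], axis=-1
        ) * pixel_size
        np.fill_diagonal(d, np.inf)
        counts = (d <= density_radius_um).sum(axis=1)
    else:
        counts = np.zeros(1, dtype=int)
    for h, c in zip(holes, counts):
        h.density = float(c)
    if collagen_mask is None:
        return
    collagen_mask = np.asarray(collagen_mask, dtype=bool)
    r_px = max(1, int(round(collagen_annulus_um / pixel_size)))
    for h in holes:
        h.surrounding_collagen_area = _annulus_collagen(
            h, shape, collagen_mask, r_px
        ) * pixel_size**2


def _annulus_collagen(hole: Hole, shape, collagen_mask, r_px: int) -> int:
    """Collagen pixel count within ``r_px`` of the hole, outside the hole."""
    rows, cols = hole.coords[:, 0], hole.coords[:, 1]
    r0 = max(rows.min() - r_px, 0)
    r1 = min(rows.max() + r_px + 1, shape[0])
    c0 = max(cols.min() - r_px, 0)
    c1 = min(cols.max() + r_px + 1, shape[1])
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rows - r0, cols - c0] = True
    dist = ndi.distance_transform_edt(~local)
    annulus = (dist > 0) & (dist <= r_px)
    return int((annulus & collagen_mask[r0:r1, c0:c1]).sum())


def train_hole_cart(holes, labels, seed: int = 0, **tree_kw) -> CartModel:
    """Train the vessel/bile-duct vs other hole classifier."""
    return CartModel.train(holes, labels, HOLE_FEATURES, seed=seed, **tree_kw)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def build_structures(
    holes: list[Hole],
    collagen_mask: np.ndarray | None,
    pixel_size: float,
    link_distance_um: float = 50.0,
    collagen_annulus_um: float = 15.0,
    collagen_bridge_max_um: float | None = 100.0,
) -> list[Structure]:
    """Group holes into structures by single-linkage closure.

    Two holes share a structure when their centroids are within
    ``link_distance_um``, or when a single contiguous collagen component
    touches both of their surrounding annuli and they are no farther apart
    than ``collagen_bridge_max_um`` (the cap keeps long bridging septa from
    welding every structure in a cirrhotic field into one).
    """
    if not holes:
        return []
    n = len(holes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    centroids = np.array([h.centroid for h in holes])
    dist_um = np.linalg.norm(
        centroids[:, None, :] - centroids[None, :, :], axis=-1
    ) * pixel_size
    for i in range(n):
        for j in range(i + 1, n):
            if dist_um[i, j] <= link_distance_um:
                union(i, j)

    comp_sets, comp_areas = None, {}
    if collagen_mask is not None and np.asarray(collagen_mask).any():
        comp_sets, comp_areas = _touching_collagen_components(
            holes, np.asarray(collagen_mask, dtype=bool), pixel_size,
            collagen_annulus_um,
        )
        cap = np.inf if collagen_bridge_max_um is None else collagen_bridge_max_um
        for i in range(n):
            for j in range(i + 1, n):
                if dist_um[i, j] <= cap and comp_sets[i] & comp_sets[j]:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    structures = []
    for members in groups.values():
        s = Structure(holes=[holes[i] for i in members])
        if comp_sets is not None:
            comps = set().union(*(comp_sets[i] for i in members))
            s.collagen_area = sum(comp_areas.get(c, 0) for c in comps) * pixel_size**2
        structures.append(s)
    structures.sort(key=lambda s: (s.holes[0].centroid[0], s.holes[0].centroid[1]))
    return structures


def _touching_collagen_components(holes, collagen_mask, pixel_size, annulus_um):
    """For each hole, the labels of collagen components inside its annulus,
    plus a label → pixel-area map."""
    labeled, nlab = ndi.label(collagen_mask, structure=np.ones((3, 3), dtype=int))
    comp_areas = dict(
        zip(range(1, nlab + 1), ndi.sum_labels(
            np.ones_like(labeled), labeled, index=range(1, nlab + 1)
        ).astype(int))
    )
    r_px = max(1, int(round(annulus_um / pixel_size)))
    out = []
    for h in holes:
        rows, cols = h.coords[:, 0], h.coords[:, 1]
        r0 = max(rows.min() - r_px, 0)
        r1 = min(rows.max() + r_px + 1, labeled.shape[0])
        c0 = max(cols.min() - r_px, 0)
        c1 = min(cols.max() + r_px + 1, labeled.shape[1])
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[rows - r0, cols - c0] = True
        dist = ndi.distance_transform_edt(~local)
        ring = dist <= r_px
        out.append(set(np.unique(labeled[r0:r1, c0:c1][ring])) - {0})
    return out, comp_areas


def train_structure_cart(structures, labels, seed: int = 0, **tree_kw) -> CartModel:
    """Train the portal-tract vs central-vein structure classifier."""
    return CartModel.train(structures, labels, STRUCTURE_FEATURES, seed=seed, **tree_kw)


def classify_structures(model: CartModel, structures: list[Structure]) -> None:
    """Assign ``structure_class`` in place by CART traversal."""
    if model is None:
        raise ValueError("untrained structure model")
    for s in structures:
        s.structure_class = model.predict_one(s)


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def assign_regions(
    structures: list[Structure],
    tissue_mask: np.ndarray,
    pixel_size: float,
    halo_radius_um: float = 25.0,
) -> RegionMap:
    """Paint classified structures (holes + halo) into a region map.

    Pixels within ``halo_radius_um`` of a structure's holes take that
    structure's class; where halos overlap the pixel goes to the nearer
    structure (ties to the lower structure index).  Every remaining tissue
    pixel is perisinusoidal, so CV + PT + PS partitions the tissue exactly.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    labels = np.where(tissue_mask, PS, BACKGROUND).astype(np.uint8)
    provenance = np.full(tissue_mask.shape, -1, dtype=np.int32)
    if structures:
        halo_px = halo_radius_um / pixel_size
        best = np.full(tissue_mask.shape, np.inf)
        for idx, s in enumerate(structures):
            smask = np.zeros(tissue_mask.shape, dtype=bool)
            for h in s.holes:
                smask[h.coords[:, 0], h.coords[:, 1]] = True
            dist = ndi.distance_transform_edt(~smask)
            covered = (dist <= halo_px) & tissue_mask & (dist < best)
            code = CV if s.structure_class == "central_vein" else PT
            labels[covered] = code
            provenance[covered] = idx
            best = np.minimum(best, np.where(dist <= halo_px, dist, np.inf))
    return RegionMap(labels=labels, provenance=provenance)


def region_accuracy(predicted: RegionMap, truth: RegionMap) -> float:
    """Pixel-level agreement over the union of both tissue areas."""
    t = (predicted.labels != BACKGROUND) | (truth.labels != BACKGROUND)
    if not t.any():
        return 1.0
    return float((predicted.labels[t] == truth.labels[t]).mean())


# ---------------------------------------------------------------------------
# full per-tile segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    region_map: RegionMap
    collagen: CollagenMask
    tissue_mask: np.ndarray
    holes: list[Hole] = field(default_factory=list)
    structures: list[Structure] = field(default_factory=list)


def segment_tile(
    tile: TileImage,
    hole_model: CartModel | None = None,
    structure_model: CartModel | None = None,
    min_hole_area_um2: float = 10.0,
    link_distance_um: float = 50.0,
    halo_radius_um: float = 25.0,
    density_radius_um: float = 100.0,
    collagen_annulus_um: float = 15.0,
) -> SegmentationResult:
    """Noise removal → Otsu collagen mask → holes → CARTs → region map."""
    from .preprocess import detect_collagen, remove_noise

    if hole_model is None:
        hole_model = load_default_hole_cart()
    if structure_model is None:
        structure_model = load_default_structure_cart()
    clean = remove_noise(tile)
    collagen = detect_collagen(clean.shg)
    tissue = tissue_mask_from_tpef(clean.tpef)
    holes = detect_holes(
        clean.tpef, tissue, tile.pixel_size,
        min_area_um2=min_hole_area_um2, collagen_mask=collagen.mask,
        density_radius_um=density_radius_um,
        collagen_annulus_um=collagen_annulus_um,
    )
    for h in holes:
        h.hole_class = hole_model.predict_one(h)
    vessel_holes = [h for h in holes if h.hole_class == "vessel_or_duct"]
    structures = build_structures(
        vessel_holes, collagen.mask, tile.pixel_size,
        link_distance_um=link_distance_um,
        collagen_annulus_um=collagen_annulus_um,
    )
    if structures:
        classify_structures(structure_model, structures)
    region_map = assign_regions(
        structures, tissue, tile.pixel_size, halo_radius_um=halo_radius_um
    )
    return SegmentationResult(region_map, collagen, tissue, holes, structures)
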