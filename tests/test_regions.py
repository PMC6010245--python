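import numpy as np
import pytest

from shgfib import regions, synthdata
from shgfib.preprocess import PIXEL_SIZE_UM
from shgfib.regions import (
    CartModel,
    Hole,
    RegionMap,
    assign_regions,
    build_structures,
    detect_holes,
    train_hole_cart,
    train_structure_cart,
)


def _make_hole(y, x, n=5, area=50.0):
    coords = np.array([[y + i, x] for i in range(n)])
    return Hole(label=0, coords=coords, centroid=(y + (n - 1) / 2.0, x),
                area=area, width=1.0, length=float(n), solidity=1.0)


def _tissue_with_disc(radius=10, value=5000.0, center=(32, 32), shape=(64, 64)):
    tpef = np.full(shape, value)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    tpef[disc] = 0.0
    return tpef, disc


class TestDetectHoles:
    def test_circular_disc_detected_with_analytic_properties(self):
        tpef, disc = _tissue_with_disc(radius=14)
        holes = detect_holes(tpef, np.ones_like(tpef, bool), PIXEL_SIZE_UM)
        assert len(holes) == 1
        h = holes[0]
        assert h.solidity >= 0.95
        assert h.area == pytest.approx(disc.sum() * PIXEL_SIZE_UM**2)
        # a disc's best-fit ellipse is a circle of the same diameter
        assert h.width == pytest.approx(h.length, rel=0.1)
        assert h.length == pytest.approx(28 * PIXEL_SIZE_UM, rel=0.15)

    def test_border_hole_excluded(self):
        tpef, _ = _tissue_with_disc(radius=10, center=(0, 32))
        holes = detect_holes(tpef, np.ones_like(tpef, bool), PIXEL_SIZE_UM)
        assert holes == []

    def test_uniform_bright_tissue_has_no_holes(self):
        tpef = np.full((64, 64), 5000.0)
        assert detect_holes(tpef, np.ones_like(tpef, bool), PIXEL_SIZE_UM) == []

    def test_empty_tissue_mask(self):
        tpef, _ = _tissue_with_disc()
        assert detect_holes(tpef, np.zeros_like(tpef, bool), PIXEL_SIZE_UM) == []

    def test_surrounding_collagen_measured_in_annulus(self):
        tpef, disc = _tissue_with_disc(radius=6)
        rim = np.zeros_like(disc)
        yy, xx = np.ogrid[:64, :64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        rim[(r2 > 36) & (r2 <= 81)] = True
        holes = detect_holes(tpef, np.ones_like(tpef, bool), PIXEL_SIZE_UM,
                             collagen_mask=rim)
        assert holes[0].surrounding_collagen_area == pytest.approx(
            rim.sum() * PIXEL_SIZE_UM**2, rel=0.05
        )


class TestCartModel:
    @pytest.fixture()
    def separable_holes(self, rng):
        holes, labels = [], []
        for i in range(40):
            h = _make_hole(5 + i % 20, 5 + i % 30)
            if i % 2:
                h.surrounding_collagen_area = rng.uniform(50, 200)
                labels.append("vessel_or_duct")
            else:
                h.surrounding_collagen_area = 0.0
                labels.append("other")
            holes.append(h)
        return holes, labels

    def test_separable_training_is_perfect(self, separable_holes):
        holes, labels = separable_holes
        model = train_hole_cart(holes, labels)
        assert model.accuracy(holes, labels) == 1.0

    def test_shuffled_labels_score_near_prior(self, separable_holes, rng):
        """Permutation control: with random labels, held-out accuracy stays
        near the majority-class prior."""
        holes, labels = separable_holes
        accs = []
        for _ in range(100):
            perm = rng.permutation(labels)
            model = train_hole_cart(holes[:20], perm[:20])
            accs.append(model.accuracy(holes[20:], perm[20:]))
        prior = 0.5
        # binomial error around the prior on 20 held-out holes
        assert abs(np.mean(accs) - prior) < 3 * np.sqrt(prior * 0.5 / 20)

    def test_serialization_round_trip(self, separable_holes):
        holes, labels = separable_holes
        model = train_hole_cart(holes, labels)
        clone = CartModel.from_json(model.to_json())
        assert clone.predict(holes) == model.predict(holes)

    def test_prediction_invariant_to_feature_order(self, separable_holes):
        holes, labels = separable_holes
        model = train_hole_cart(holes, labels)
        record = holes[3].features()
        reversed_record = dict(reversed(list(record.items())))
        assert model.predict_one(record) == model.predict_one(reversed_record)

    def test_single_class_gives_constant_model(self, separable_holes):
        holes, _ = separable_holes
        with pytest.warns(UserWarning):
            model = train_hole_cart(holes, ["other"] * len(holes))
        assert set(model.predict(holes)) == {"other"}


class TestBuildStructures:
    def test_nearby_holes_share_structure(self):
        px = PIXEL_SIZE_UM
        holes = [_make_hole(30, 30), _make_hole(30, 30 + int(5 / px))]
        structures = build_structures(holes, None, px, link_distance_um=50)
        assert len(structures) == 1 and structures[0].n_holes == 2

    def test_distant_holes_split(self):
        holes = [_make_hole(10, 10), _make_hole(400, 400)]
        structures = build_structures(holes, None, PIXEL_SIZE_UM,
                                      link_distance_um=50)
        assert len(structures) == 2

    def test_chain_transitivity_matches_union_find_oracle(self, rng):
        """Single linkage is transitive: A–B and B–C linked ⇒ one structure,
        agreeing with a brute-force union-find over pairwise distances."""
        px = 1.0
        pts = rng.uniform(0, 300, size=(12, 2))
        holes = [_make_hole(int(p[0]), int(p[1])) for p in pts]
        link = 60.0
        structures = build_structures(holes, None, px, link_distance_um=link)

        # oracle: naive repeated merging
        groups = [{i} for i in range(len(holes))]
        merged = True
        while merged:
            merged = False
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    if any(
                        np.linalg.norm(
                            np.array(holes[i].centroid)
                            - np.array(holes[j].centroid)
                        ) <= link
                        for i in groups[a] for j in groups[b]
                    ):
                        groups[a] |= groups.pop(b)
                        merged = True
                        break
                if merged:
                    break
        assert len(structures) == len(groups)

    def test_explicit_chain(self):
        holes = [_make_hole(50, 50), _make_hole(50, 90), _make_hole(50, 130)]
        structures = build_structures(holes, None, 1.0, link_distance_um=45)
        assert len(structures) == 1 and structures[0].n_holes == 3

    def test_collagen_bridge_links_holes(self):
        px = 1.0
        holes = [_make_hole(50, 20), _make_hole(50, 90)]
        collagen = np.zeros((128, 128), dtype=bool)
        collagen[52, 10:100] = True  # one component touching both annuli
        with_bridge = build_structures(holes, collagen, px, link_distance_um=40)
        without = build_structures(holes, None, px, link_distance_um=40)
        assert len(with_bridge) == 1 and len(without) == 2

    def test_structure_feature_invariant(self):
        holes = [_make_hole(30, 30, area=80.0), _make_hole(32, 40, area=30.0)]
        (s,) = build_structures(holes, None, PIXEL_SIZE_UM, link_distance_um=50)
        assert s.max_hole_area <= s.total_hole_area
        assert s.n_holes == 2


class TestAssignRegions:
    def test_no_structures_all_perisinusoidal(self):
        tissue = np.ones((64, 64), dtype=bool)
        rmap = assign_regions([], tissue, 1.0)
        assert (rmap.labels == regions.PS).all()

    def test_partition_is_exact(self):
        tissue = np.ones((128, 128), dtype=bool)
        tissue[:5] = False
        h = _make_hole(60, 60, n=8)
        s = regions.Structure(holes=[h], structure_class="central_vein")
        rmap = assign_regions([s], tissue, 1.0, halo_radius_um=20)
        counted = sum(rmap.area_px(c) for c in (regions.CV, regions.PT, regions.PS))
        assert counted == tissue.sum()
        assert rmap.area_px(regions.CV) > 0
        assert (rmap.labels[~tissue] == regions.BACKGROUND).all()

    def test_overlap_goes_to_nearer_structure(self):
        """Where CV and PT halos overlap, each pixel matches a per-pixel
        nearest-structure oracle."""
        tissue = np.ones((100, 100), dtype=bool)
        cv = regions.Structure(holes=[_make_hole(50, 30)],
                               structure_class="central_vein")
        pt = regions.Structure(holes=[_make_hole(50, 60)],
                               structure_class="portal_tract")
        rmap = assign_regions([cv, pt], tissue, 1.0, halo_radius_um=25)
        from scipy import ndimage as ndi

        masks = []
        for s in (cv, pt):
            m = np.zeros_like(tissue)
            for h in s.holes:
                m[h.coords[:, 0], h.coords[:, 1]] = True
            masks.append(ndi.distance_transform_edt(~m))
        d_cv, d_pt = masks
        both = (d_cv <= 25) & (d_pt <= 25)
        assert both.any()
        expect = np.where(d_cv <= d_pt, regions.CV, regions.PT)
        assert (rmap.labels[both] == expect[both]).all()
        counted = sum(rmap.area_px(c) for c in (regions.CV, regions.PT, regions.PS))
        assert counted == tissue.sum()


class TestOnSyntheticTiles:
    def test_structure_classification_held_out(self):
        """Structure CART trained on half the synthetic tiles classifies the
        other half's portal tracts and central veins with ≥ 0.9 accuracy."""
        records, labels = [], []
        per_tile = []
        for i in range(14):
            tile, truth = synthdata.generate_tile(
                synthdata.TileSpec(stage=i % 5, seed=900 + i)
            )
            seg = regions.segment_tile(tile)
            lab = synthdata.label_detected_structures(seg.structures, truth)
            per_tile.append((seg.structures, lab))
        train = per_tile[:7]
        test = per_tile[7:]
        tr_s = [s for st, _ in train for s in st]
        tr_l = [l for _, ls in train for l in ls]
        model = train_structure_cart(tr_s, tr_l, min_samples_leaf=3)
        te_s = [s for st, _ in test for s in st]
        te_l = [l for _, ls in test for l in ls]
        assert len(te_s) >= 10
        assert model.accuracy(te_s, te_l) >= 0.9

    def test_pixel_region_accuracy_on_default_geometry(self, tiles_by_stage):
        """Regression: the shipped CARTs recover ≥ 0.85 of region pixels on
        seed-fixed tiles of every stage."""
        for stage, (tile, truth) in tiles_by_stage.items():
            seg = regions.segment_tile(tile)
            acc = regions.region_accuracy(seg.region_map, truth.region_map)
            assert acc >= 0.85, f"stage {stage}: accuracy {acc:.3f}"

    def test_untrained_structure_model_rejected(self):
        with pytest.raises(ValueError):
            regions.classify_structures(None, [])


def test_region_map_partition_property(stage3_tile):
    tile, truth = stage3_tile
    rmap = truth.region_map
    assert isinstance(rmap, RegionMap)
    total = sum(rmap.area_px(c) for c in (regions.CV, regions.PT, regions.PS))
    assert total == rmap.tissue_px
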