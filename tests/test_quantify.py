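"""Quantification pipeline tests: segmentation, spot calling, classification.

Synthetic inputs are built directly (disks, Gaussians) or produced by the
simulator with ground truth; oracles are brute-force (nearest-nucleus per
pixel, disk-overlap arithmetic, direct morphology).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from conftest import SMALL_GEOMETRY
from molboolean.quantify import (
    ClassificationThresholds,
    SegmentationParams,
    consolidate_spots,
    delineate_cells,
    detect_spots,
    enhance_speckles,
    mask_and_assign,
    measure_and_classify,
    per_cell_counts,
    pooled_fractions,
    quantify_field,
    quantify_pla,
    segment_nuclei,
)
from molboolean.render import RenderParams, render_field
from molboolean.simulate import AssayParams, PopulationSpec, make_field, place_molecules, simulate_molecular_events, substreams

SMALL_SEG = SegmentationParams(
    nucleus_diameter_range=(10.0, 40.0), nucleus_smooth_px=2.0, cell_expand_n=20.0
)


def disk_image(shape, centers, radius, value=300.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


def gaussian_spot(img, y, x, sigma=1.2, amp=600.0):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


class TestSegmentNuclei:
    def test_counts_well_separated_nuclei(self):
        img = disk_image((128, 128), [(30, 30), (30, 90), (90, 60)], radius=10)
        labels = segment_nuclei(img, SMALL_SEG)
        assert labels.max() == 3

    def test_blank_image_zero_labels(self):
        assert segment_nuclei(np.zeros((64, 64)), SMALL_SEG).max() == 0

    def test_too_small_object_excluded(self):
        img = disk_image((128, 128), [(30, 30)], radius=10)
        img = np.maximum(img, disk_image((128, 128), [(90, 90)], radius=3))
        labels = segment_nuclei(img, SMALL_SEG)
        assert labels.max() == 1
        assert labels[90, 90] == 0

    def test_labels_in_raster_order(self):
        img = disk_image((128, 128), [(90, 20), (20, 90)], radius=10)
        labels = segment_nuclei(img, SMALL_SEG)
        assert labels[20, 90] == 1 and labels[90, 20] == 2


class TestDelineateCells:
    def test_single_nucleus_dilation(self):
        nuclei = disk_image((64, 64), [(32, 32)], radius=5).astype(bool).astype(np.int32)
        cells = delineate_cells(nuclei, 10)
        dist = ndimage.distance_transform_edt(nuclei == 0)
        expected = (dist <= 10) | (nuclei > 0)
        assert np.array_equal(cells > 0, expected)

    def test_two_nuclei_split_at_equidistant_line(self):
        nuclei = np.zeros((60, 60), dtype=np.int32)
        nuclei[30, 20] = 1
        nuclei[30, 40] = 2
        cells = delineate_cells(nuclei, 20)
        # brute-force nearest-seed oracle
        yy, xx = np.mgrid[:60, :60]
        d1 = np.hypot(yy - 30, xx - 20)
        d2 = np.hypot(yy - 30, xx - 40)
        both = (np.minimum(d1, d2) <= 20) & (d1 != d2)
        assert np.array_equal(cells[both] == 1, (d1 < d2)[both])

    def test_zero_nuclei_empty_map(self):
        assert delineate_cells(np.zeros((32, 32), dtype=np.int32), 5).max() == 0

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            delineate_cells(np.zeros((8, 8), dtype=np.int32), 0)


class TestEnhanceSpeckles:
    def test_constant_image_all_zeros(self):
        out = enhance_speckles(np.full((40, 40), 17.0), 4)
        assert np.allclose(out, 0.0)

    def test_small_spot_preserved_background_removed(self):
        img = np.full((64, 64), 40.0)
        gaussian_spot(img, 32, 32, sigma=1.2, amp=500.0)
        out = enhance_speckles(img, 5)
        assert out[32, 32] > 400.0
        assert out[5, 5] == pytest.approx(0.0, abs=1e-9)

    def test_gradient_only_residual_small(self):
        yy, _ = np.mgrid[:64, :64]
        out = enhance_speckles(yy.astype(float) * 2.0, 5)
        assert out.max() < 25.0  # well below any spot amplitude

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            enhance_speckles(np.zeros((8, 8)), 0)


class TestDetectSpots:
    def test_counts_isolated_spots(self):
        img = np.zeros((128, 128))
        centers = [(20, 20), (20, 100), (64, 64), (100, 30), (108, 108)]
        for y, x in centers:
            gaussian_spot(img, y, x)
        labels = detect_spots(img, SegmentationParams(spot_threshold=("manual", 50.0)))
        assert labels.max() == len(centers)

    def test_blank_zero_labels(self):
        assert detect_spots(np.zeros((64, 64))).max() == 0

    def test_oversized_object_excluded(self):
        img = disk_image((64, 64), [(32, 32)], radius=12, value=500.0)
        labels = detect_spots(img, SegmentationParams(spot_threshold=("manual", 50.0)))
        assert labels.max() == 0

    def test_adjacent_spots_declumped(self):
        img = np.zeros((64, 64))
        gaussian_spot(img, 30, 28)
        gaussian_spot(img, 30, 34)
        labels = detect_spots(img, SegmentationParams(spot_threshold=("manual", 50.0)))
        assert labels.max() == 2


class TestConsolidateSpots:
    def make_labels(self, centers, shape=(64, 64)):
        img = np.zeros(shape, dtype=np.int32)
        for i, (y, x) in enumerate(centers, start=1):
            img[y, x] = i
        return img

    def test_coincident_centroids_merge(self):
        a = self.make_labels([(30, 30)])
        b = self.make_labels([(30, 30)])
        objects, table = consolidate_spots(a, b, 2)
        assert len(table) == 1
        assert table.iloc[0]["from_a"] and table.iloc[0]["from_b"]

    def test_distant_spots_stay_separate(self):
        B = 2
        a = self.make_labels([(30, 20)])
        b = self.make_labels([(30, 20 + 2 * B + 2)])
        _, table = consolidate_spots(a, b, B)
        assert len(table) == 2
        assert table["from_a"].sum() == 1 and table["from_b"].sum() == 1

    def test_empty_channel_passthrough(self):
        a = self.make_labels([(10, 10), (40, 40)])
        b = np.zeros_like(a)
        _, table = consolidate_spots(a, b, 2)
        assert len(table) == 2 and not table["from_b"].any()


class TestMaskAndAssign:
    def test_outside_removed_inside_assigned(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        cells[10:30, 10:30] = 3
        objects = pd.DataFrame(
            {"object_id": [1, 2], "y": [20.0, 50.0], "x": [20.0, 50.0],
             "area": [5.0, 5.0], "from_a": [True, True], "from_b": [False, False]}
        )
        out = mask_and_assign(objects, cells)
        assert list(out["object_id"]) == [1]
        assert out.iloc[0]["cell_id"] == 3

    def test_zero_cells_all_removed(self):
        objects = pd.DataFrame(
            {"object_id": [1], "y": [5.0], "x": [5.0], "area": [4.0],
             "from_a": [True], "from_b": [False]}
        )
        assert mask_and_assign(objects, np.zeros((16, 16), dtype=np.int32)).empty


class TestMeasureAndClassify:
    def setup_objects(self, intens_a, intens_b):
        objects_img = np.zeros((32, 32), dtype=np.int32)
        objects_img[5:8, 5:8] = 1
        chan_a = np.zeros((32, 32))
        chan_b = np.zeros((32, 32))
        chan_a[5:8, 5:8] = intens_a
        chan_b[5:8, 5:8] = intens_b
        objects = pd.DataFrame(
            {"object_id": [1], "y": [6.0], "x": [6.0], "area": [9.0],
             "from_a": [True], "from_b": [True], "cell_id": [1]}
        )
        return objects_img, objects, chan_a, chan_b

    @pytest.mark.parametrize(
        "ia,ib,expected",
        [(100.0, 0.0, "freeA"), (0.0, 100.0, "freeB"), (100.0, 100.0, "complex")],
        ids=["axis-A", "axis-B", "diagonal"],
    )
    def test_axis_and_diagonal_cases(self, ia, ib, expected):
        objects_img, objects, chan_a, chan_b = self.setup_objects(ia, ib)
        table = measure_and_classify(
            objects_img, objects, chan_a, chan_b,
            ClassificationThresholds(t_a=0.0, t_b=0.0),
        )
        assert table.iloc[0]["rcp_class"] == expected

    def test_background_object_discarded(self):
        objects_img, objects, chan_a, chan_b = self.setup_objects(0.0, 0.0)
        table = measure_and_classify(
            objects_img, objects, chan_a, chan_b,
            ClassificationThresholds(t_a=5.0, t_b=5.0),
        )
        assert table.empty

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(theta_low=70.0, theta_high=60.0)
        with pytest.raises(ValueError):
            ClassificationThresholds(t_a=-1.0)


class TestPerCellCounts:
    def test_fractions(self):
        spots = pd.DataFrame(
            {"cell_id": [1] * 10,
             "rcp_class": ["freeA"] * 2 + ["freeB"] * 3 + ["complex"] * 5}
        )
        out = per_cell_counts(spots)
        row = out.iloc[0]
        assert (row["f_free_a"], row["f_free_b"], row["f_complex"]) == (0.2, 0.3, 0.5)

    def test_zero_spot_cell_flagged(self):
        spots = pd.DataFrame({"cell_id": [1], "rcp_class": ["freeA"]})
        out = per_cell_counts(spots, cell_ids=[1, 2])
        empty = out[out["cell_id"] == 2].iloc[0]
        assert empty["n_total"] == 0 and np.isnan(empty["f_complex"])

    def test_fractions_sum_to_one_and_conserve(self):
        rng = np.random.default_rng(0)
        spots = pd.DataFrame(
            {"cell_id": rng.integers(1, 6, 200),
             "rcp_class": rng.choice(["freeA", "freeB", "complex"], 200)}
        )
        out = per_cell_counts(spots)
        assert (out["n_free_a"] + out["n_free_b"] + out["n_complex"] == out["n_total"]).all()
        assert np.allclose(out["f_free_a"] + out["f_free_b"] + out["f_complex"], 1.0)
        pooled = pooled_fractions(spots)
        assert sum(pooled.values()) == pytest.approx(100.0)


def _simulated_stack(seed, mode="molboolean", n_cells=2, spec=None):
    rngs = substreams(seed, ("field", "placement", "binding", "render"))
    field = make_field(n_cells, SMALL_GEOMETRY, rngs["field"])
    spec = spec or PopulationSpec(n_free_a=6, n_free_b=6, n_complex=8)
    mols = place_molecules(field, spec, rngs["placement"])
    ev = simulate_molecular_events(mols, AssayParams(mode=mode), rngs["binding"])
    stack, truth = render_field(ev, field, RenderParams(), rngs["render"])
    return field, ev, stack, truth


class TestEndToEnd:
    def test_blank_stack_yields_nothing(self):
        stack = np.zeros((3, 64, 64), dtype=np.uint16)
        res = quantify_field(stack, SMALL_SEG)
        assert res["spot_table"].empty and res["cell_table"].empty

    def test_pipeline_conservation(self):
        field, ev, stack, truth = _simulated_stack(31)
        res = quantify_field(stack, SMALL_SEG)
        st, ct = res["spot_table"], res["cell_table"]
        assert set(st["rcp_class"]) <= {"freeA", "freeB", "complex"}
        assert (ct["n_free_a"] + ct["n_free_b"] + ct["n_complex"] == ct["n_total"]).all()
        assert ct["n_total"].sum() == len(st)

    def test_density_inflates_complex_class_monotonically(self):
        """All-singleton fields: measured 'complex' calls are pure chance
        colocalization and grow with event density."""
        fractions = []
        for density in (8, 30, 110):
            spec = PopulationSpec(n_free_a=density, n_free_b=density, n_complex=0)
            field, ev, stack, truth = _simulated_stack(33, spec=spec)
            res = quantify_field(stack, SMALL_SEG)
            st = res["spot_table"]
            fractions.append((st["rcp_class"] == "complex").mean())
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]

    def test_pla_count_recovery(self):
        # full-size cells: low spot density, so counts recover within 5 %
        from molboolean.simulate import GeometryConfig

        geo = GeometryConfig(shape=(256, 512))
        rngs = substreams(35, ("field", "placement", "binding", "render"))
        field = make_field(2, geo, rngs["field"])
        spec = PopulationSpec(n_free_a=5, n_free_b=5, n_complex=25)
        mols = place_molecules(field, spec, rngs["placement"])
        ev = simulate_molecular_events(mols, AssayParams(mode="pla"), rngs["binding"])
        stack, _ = render_field(ev, field, RenderParams(), rngs["render"])
        res = quantify_pla(stack[0], stack[1], SegmentationParams())
        measured = res["cell_table"]["n_rcp"].sum()
        assert measured == pytest.approx(len(ev), rel=0.05)

    def test_pla_blank_signal_zero_counts(self):
        field, ev, stack, truth = _simulated_stack(36)
        blank = np.zeros_like(stack[1])
        res = quantify_pla(stack[0], blank, SMALL_SEG)
        assert (res["cell_table"]["n_rcp"] == 0).all()
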