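"""Region assignment, point edits, tallies, 3D lifting, and atlas comparison."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

from histoslice_quant import (
    OUTSIDE_BRAIN,
    AtlasBundle,
    PointSet,
    RegionCountTable,
    SlicePlane,
    assign_regions,
    compare_atlases,
    edit_points,
    fit_transform,
    tally_regions,
    to_ccf3d,
    warp_points,
)
from histoslice_quant.quantify import (
    AddPoint,
    DeletePoint,
    MovePoint,
    PolygonDelete,
    PolygonTranslate,
)

from conftest import TOY_CANVAS


@pytest.fixture(scope="module")
def assigned_record(fixture_truth, toy_bundle, center_plane):
    """Pipeline-assigned record using the exact (noise-free) landmark fit."""
    t = fit_transform(fixture_truth.landmarks, "projective", center_plane)
    padded = fixture_truth.cell_points_raw.with_points(
        fixture_truth.canvas_record.raw_to_padded(fixture_truth.cell_points_raw.points),
        frame="padded",
    )
    atlas_pts = warp_points(padded, t)
    return assign_regions(
        atlas_pts, toy_bundle, center_plane, canvas_shape=TOY_CANVAS, slice_id="s0"
    )


class TestAssignRegions:
    def test_noise_free_fixture_assignments_match_truth(
        self, assigned_record, fixture_truth
    ):
        got = [a.id for a in assigned_record.assignments]
        want = [a.id for a in fixture_truth.true_assignments]
        assert got == want

    def test_canvas_corner_point_is_outside(self, toy_bundle, center_plane):
        ps = PointSet(points=[(0.0, 0.0), (-50.0, 9000.0)], frame="atlas")
        rec = assign_regions(ps, toy_bundle, center_plane, TOY_CANVAS)
        assert all(a is OUTSIDE_BRAIN for a in rec.assignments)

    def test_sagittal_chon_restriction(self, chon_bundle):
        ps = PointSet(points=[(10.0, 10.0)], frame="atlas")
        with pytest.raises(ValueError, match="sagittal"):
            assign_regions(ps, chon_bundle, SlicePlane("sagittal", 0.0), (100, 60))

    def test_frame_mismatch_rejected(self, toy_bundle, center_plane):
        ps = PointSet(points=[(1.0, 1.0)], frame="raw")
        with pytest.raises(ValueError, match="frame"):
            assign_regions(ps, toy_bundle, center_plane, TOY_CANVAS)

    def test_brute_force_oracle_agreement(self, toy_bundle, center_plane):
        """Every point independently traced through the full geometric chain."""
        import math

        from histoslice_quant.atlas_model import mm_to_index

        rng = np.random.default_rng(5)
        xy = rng.uniform([-10, -10], [TOY_CANVAS[1] + 10, TOY_CANVAS[0] + 10], (300, 2))
        plane = SlicePlane("coronal", 0.05, dv_tilt_deg=3.0, ml_tilt_deg=-2.0)
        rec = assign_regions(
            PointSet(points=xy, frame="atlas"), toy_bundle, plane, TOY_CANVAS
        )
        base = mm_to_index(toy_bundle, 0.05, "coronal")
        rc, cc = (TOY_CANVAS[0] - 1) / 2.0, (TOY_CANVAS[1] - 1) / 2.0
        shape = toy_bundle.annotation.shape
        for (x, y), node in zip(xy, rec.assignments):
            c, r = int(np.floor(x + 0.5)), int(np.floor(y + 0.5))
            if not (0 <= r < TOY_CANVAS[0] and 0 <= c < TOY_CANVAS[1]):
                assert node.id == 0
                continue
            ap = int(
                np.floor(
                    base
                    + math.tan(math.radians(-2.0)) * (c - cc)
                    + math.tan(math.radians(3.0)) * (r - rc)
                    + 0.5
                )
            )
            if not (0 <= ap < shape[0] and r < shape[1] and c < shape[2]):
                assert node.id == 0
            else:
                assert node.id == int(toy_bundle.annotation[ap, r, c])


class TestEditPoints:
    def test_delete_keeps_other_points(self, rng):
        xy = rng.uniform(0, 50, size=(10, 2))
        ps = PointSet(points=xy, frame="atlas")
        out = edit_points(ps, [DeletePoint(3)])
        assert len(out) == 9
        assert np.array_equal(out.points, np.delete(xy, 3, axis=0))

    def test_add_and_move(self):
        ps = PointSet(points=[(1.0, 1.0)], frame="atlas")
        out = edit_points(ps, [AddPoint(5.0, 6.0), MovePoint(0, 2.0, 2.0)])
        assert out.points.tolist() == [[2.0, 2.0], [5.0, 6.0]]

    def test_polygon_delete_matches_point_in_polygon_oracle(self, rng):
        xy = rng.uniform(0, 100, size=(10, 2))
        poly = [(20.0, 20.0), (80.0, 25.0), (70.0, 90.0), (15.0, 70.0)]
        inside = MplPath(poly).contains_points(xy, radius=1e-9)
        out = edit_points(
            PointSet(points=xy, frame="atlas"), [PolygonDelete(tuple(poly))]
        )
        assert len(out) == 10 - inside.sum()
        assert np.array_equal(out.points, xy[~inside])

    def test_polygon_translate_moves_only_enclosed(self, rng):
        xy = np.array([[10.0, 10.0], [50.0, 50.0], [90.0, 90.0]])
        poly = [(40.0, 40.0), (60.0, 40.0), (60.0, 60.0), (40.0, 60.0)]
        out = edit_points(
            PointSet(points=xy, frame="atlas"), [PolygonTranslate(tuple(poly), 3.0, -2.0)]
        )
        assert out.points[1].tolist() == [53.0, 48.0]
        assert out.points[0].tolist() == [10.0, 10.0]

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0.0, 0.0), (10.0, 10.0), (10.0, 0.0), (0.0, 10.0)]
        with pytest.raises(ValueError, match="polygon"):
            edit_points(
                PointSet(points=[(5.0, 5.0)], frame="atlas"), [PolygonDelete(tuple(bowtie))]
            )

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            edit_points(PointSet(points=[(1.0, 1.0)], frame="atlas"), [DeletePoint(5)])

    def test_record_edit_reassigns_and_logs(self, assigned_record, toy_bundle):
        # move one cell from region 1 into region 4's interior; assignment follows
        target = next(
            i for i, a in enumerate(assigned_record.assignments) if a.id == 1
        )
        r4 = next(
            (x, y)
            for (x, y), a in zip(
                assigned_record.points.points, assigned_record.assignments
            )
            if a.id == 4
        )
        out = edit_points(
            assigned_record, [MovePoint(target, r4[0], r4[1])], bundle=toy_bundle
        )
        assert out.assignments[target].id == 4
        assert out.edit_log[-1]["op"] == "move"
        # original record untouched
        assert assigned_record.assignments[target].id == 1


class TestTally:
    def test_single_record_total(self, assigned_record, fixture_truth):
        table = tally_regions([assigned_record], "per_brain")
        assert table.total == 200
        assert table.counts == fixture_truth.true_counts.counts

    def test_additivity_across_records(self, assigned_record):
        t1 = tally_regions([assigned_record], "per_brain")
        t2 = tally_regions([assigned_record, assigned_record], "per_brain")
        assert t2.total == 2 * t1.total
        assert all(t2.counts[k] == 2 * v for k, v in t1.counts.items())

    def test_empty_record_list(self):
        table = tally_regions([], "per_brain")
        assert table.total == 0 and len(table.rows) == 0

    def test_mixed_variants_rejected(self, assigned_record):
        import copy

        other = copy.copy(assigned_record)
        other.atlas_variant = "chon"
        with pytest.raises(ValueError, match="variant"):
            tally_regions([assigned_record, other], "per_brain")

    def test_per_slice_scope_returns_one_table_per_record(self, assigned_record):
        tables = tally_regions([assigned_record, assigned_record], "per_slice")
        assert len(tables) == 2
        assert tables[0].total == 200


class TestCcf3d:
    def test_zero_tilt_micron_arithmetic(self):
        # coronal plane at AP index 405: a point at pixel (r=100, c=200)
        # lifts to (4050, 1000, 2000) um
        annotation = np.zeros((410, 150, 250), dtype=np.int8)
        annotation[405, 100, 200] = 1
        bundle = AtlasBundle(
            variant="allen",
            annotation=annotation,
            structure_tree={1: __import__("histoslice_quant").StructureNode(1, "A", "a")},
            bregma_voxel=(405, 0, 125),
        )
        plane = SlicePlane("coronal", 0.0)
        rec = assign_regions(
            PointSet(points=[(200.0, 100.0)], frame="atlas"), bundle, plane, (150, 250)
        )
        cloud = to_ccf3d(rec, bundle)
        assert cloud.loc[0, ["AP_um", "DV_um", "ML_um"]].tolist() == [4050.0, 1000.0, 2000.0]

    def test_reexported_voxels_lookup_to_same_assignment(
        self, assigned_record, toy_bundle
    ):
        from histoslice_quant import lookup_region

        cloud = to_ccf3d(assigned_record, toy_bundle)
        for voxel_cols, node in zip(
            cloud[["voxel_ap", "voxel_dv", "voxel_ml"]].to_numpy(),
            assigned_record.assignments,
        ):
            assert lookup_region(toy_bundle, voxel_cols).id == node.id

    def test_empty_record_gives_empty_cloud(self, toy_bundle, center_plane):
        rec = assign_regions(
            PointSet(points=np.empty((0, 2)), frame="atlas"),
            toy_bundle,
            center_plane,
            TOY_CANVAS,
        )
        assert len(to_ccf3d(rec, toy_bundle)) == 0


def _table(counts: dict, variant="allen") -> RegionCountTable:
    rows = pd.DataFrame(
        [(sid, f"S{sid}", f"structure {sid}", c) for sid, c in counts.items()],
        columns=["structure_id", "acronym", "name", "count"],
    )
    return RegionCountTable(rows=rows, scope="per_slice", atlas_variant=variant)


class TestCompareAtlases:
    def test_identical_tables_give_r1_t0(self):
        tables = [_table({1: 10, 2: 5}), _table({1: 7, 3: 2}), _table({2: 20})]
        rep = compare_atlases(tables, tables)
        assert rep.pearson_r_totals == pytest.approx(1.0)
        assert rep.t_structures == 0.0

    def test_pearson_matches_closed_form_oracle(self, rng):
        totals_a = rng.integers(10, 200, size=8)
        totals_b = (0.7 * totals_a + rng.normal(0, 10, 8)).round().astype(int).clip(1)
        tables_a = [_table({1: int(t)}) for t in totals_a]
        tables_b = [_table({1: int(t)}) for t in totals_b]
        rep = compare_atlases(tables_a, tables_b)
        a, b = totals_a.astype(float), totals_b.astype(float)
        r_oracle = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert rep.pearson_r_totals == pytest.approx(r_oracle, abs=1e-12)

    def test_paired_t_matches_closed_form(self, rng):
        ns_a = [3, 5, 4, 6, 7]
        ns_b = [2, 4, 4, 5, 5]
        tables_a = [_table({i + 1: 1 for i in range(n)}) for n in ns_a]
        tables_b = [_table({i + 1: 1 for i in range(n)}) for n in ns_b]
        rep = compare_atlases(tables_a, tables_b)
        d = np.array(ns_a, float) - np.array(ns_b, float)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert rep.t_structures == pytest.approx(t_oracle, abs=1e-12)
        assert rep.t_dof == 4

    def test_name_overlap_exact_matching(self):
        a = [_table({1: 1}), _table({2: 1}), _table({3: 1})]
        b_rows = pd.DataFrame(
            [(9, "X", "structure 2", 1)],
            columns=["structure_id", "acronym", "name", "count"],
        )
        b = [
            RegionCountTable(rows=b_rows, scope="per_slice", atlas_variant="chon"),
            _table({4: 1}, "chon"),
            _table({5: 1}, "chon"),
        ]
        rep = compare_atlases(a, b)
        assert rep.name_overlap == 1  # only "structure 2" shared

    def test_insufficient_slices_rejected(self):
        with pytest.raises(ValueError, match="3"):
            compare_atlases([_table({1: 1})], [_table({1: 1})])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compare_atlases([_table({1: 1})] * 3, [_table({1: 1})] * 4)


class TestConservation:
    def test_allen_and_chon_totals_identical_on_shared_points(
        self, assigned_record, chon_bundle, center_plane
    ):
        rec_chon = assign_regions(
            assigned_record.points, chon_bundle, center_plane, TOY_CANVAS, "s0"
        )
        t_allen = tally_regions([assigned_record], "per_brain")
        t_chon = tally_regions([rec_chon], "per_brain")
        assert t_allen.total == t_chon.total == len(assigned_record.points)
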