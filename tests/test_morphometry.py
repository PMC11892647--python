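"""Per-cell measurement: process removal, distances, classification."""

import dataclasses
import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, strategies as st

from somamorph import (
    CellRecord,
    MorphConfig,
    SimConfig,
    assign_side_and_face,
    classify_depth,
    equivalent_sphere_diameter,
    filter_small_somata,
    generate_ganglion_pair,
    measure_all,
    min_surface_distance,
    records_to_frame,
    remove_fine_processes,
)


def _ball_mask(shape, center, radius, spacing=0.5):
    idx = (np.indices(shape, dtype=float) + 0.5) * spacing
    return sum((idx[a] - center[a]) ** 2 for a in range(3)) <= radius**2


class TestRemoveFineProcesses:
    spacing = (0.5, 0.5, 0.5)

    def test_thin_neurite_is_stripped_from_soma(self):
        shape = (48, 32, 32)
        soma = _ball_mask(shape, (8.0, 8.0, 8.0), 5.0)
        mask = soma.copy()
        # 1.3 µm diameter tube along x, attached to the soma
        idx = (np.indices(shape, dtype=float) + 0.5) * 0.5
        tube = ((idx[1] - 8.0) ** 2 + (idx[2] - 8.0) ** 2 <= 0.65**2) & (idx[0] < 22)
        mask |= tube
        cleaned = remove_fine_processes(mask, self.spacing, 2.5)
        assert cleaned[soma].sum() / soma.sum() > 0.8
        v_clean, v_soma = cleaned.sum(), soma.sum()
        assert abs(v_clean - v_soma) / v_soma < 0.10
        assert not cleaned[~(soma | tube)].any()

    def test_opening_barely_changes_a_fat_sphere(self):
        soma = _ball_mask((32, 32, 32), (8.0, 8.0, 8.0), 5.0)
        cleaned = remove_fine_processes(soma, self.spacing, 2.5)
        assert abs(int(cleaned.sum()) - int(soma.sum())) / soma.sum() < 0.05

    def test_pure_fine_process_is_an_error(self):
        shape = (48, 16, 16)
        idx = (np.indices(shape, dtype=float) + 0.5) * 0.5
        tube = ((idx[1] - 4.0) ** 2 + (idx[2] - 4.0) ** 2 <= 0.65**2)
        with pytest.raises(ValueError, match="fine process"):
            remove_fine_processes(tube, self.spacing, 2.5)

    def test_output_is_subset_of_input(self):
        soma = _ball_mask((32, 32, 32), (8.0, 8.0, 8.0), 4.0)
        cleaned = remove_fine_processes(soma, self.spacing, 2.5)
        assert not cleaned[~soma].any()


class TestSizeFilter:
    def _rec(self, v):
        return CellRecord(cell_id=1, volume_voxel_um3=v, volume_mesh_um3=v)

    def test_boundary_diameter_is_excluded(self):
        v8 = 4 / 3 * math.pi * 4.0**3  # equivalent diameter exactly 8 µm
        assert equivalent_sphere_diameter(v8) == pytest.approx(8.0)
        out = filter_small_somata([self._rec(v8)], 8.0)
        assert out[0].included is False

    def test_above_boundary_is_included(self):
        out = filter_small_somata([self._rec(300.0)], 8.0)
        assert out[0].included is True

    def test_empty_list_passes_through(self):
        assert filter_small_somata([], 8.0) == []

    def test_flagging_preserves_length_and_order(self):
        recs = [self._rec(100.0), self._rec(5000.0), self._rec(200.0)]
        out = filter_small_somata(recs, 8.0)
        assert [r.cell_id for r in out] == [r.cell_id for r in recs]
        assert [r.included for r in out] == [False, True, False]


class TestClassifyDepth:
    @pytest.mark.parametrize(
        "distance,expected",
        [(0.0, "superficial"), (8.124, "superficial"), (8.125, "internalized"), (10.0, "internalized")],
    )
    def test_strict_threshold(self, distance, expected):
        assert classify_depth(distance, 8.125) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_depth(-0.1, 8.125)

    @given(st.floats(0, 50), st.floats(0, 50))
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        if classify_depth(lo, 8.125) == "internalized":
            assert classify_depth(hi, 8.125) == "internalized"

    @given(st.floats(0, 50), st.floats(0.5, 20), st.floats(0.5, 20))
    def test_shrinking_tau_never_makes_a_cell_superficial(self, d, t1, t2):
        lo, hi = sorted([t1, t2])
        if classify_depth(d, hi) == "internalized":
            assert classify_depth(d, lo) == "internalized"


class TestMinSurfaceDistance:
    def _plane_patch(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        return trimesh.Trimesh(verts, faces, process=False)

    def test_shared_vertex_gives_zero(self):
        surface = self._plane_patch()
        cell = trimesh.Trimesh(
            np.array([[0, 0, 0], [0, 0, 2], [0, 1, 2]], float),
            np.array([[0, 1, 2]]),
            process=False,
        )
        assert min_surface_distance(cell, surface) == 0.0

    def test_point_above_plane_vertex(self):
        surface = self._plane_patch()
        cell = trimesh.Trimesh(
            np.array([[0, 0, 5], [0, 0.001, 5], [0.001, 0, 5]], float),
            np.array([[0, 1, 2]]),
            process=False,
        )
        assert min_surface_distance(cell, surface, "vertex_to_vertex") == pytest.approx(5.0)

    def test_point_to_triangle_sees_face_interiors(self):
        surface = self._plane_patch()
        # directly above the middle of the patch: vertex distance > true distance
        cell = trimesh.Trimesh(
            np.array([[0.5, 0.5, 2.0], [0.5, 0.6, 2.0], [0.6, 0.5, 2.0]], float),
            np.array([[0, 1, 2]]),
            process=False,
        )
        d_pt = min_surface_distance(cell, surface, "point_to_triangle")
        d_vv = min_surface_distance(cell, surface, "vertex_to_vertex")
        assert d_pt == pytest.approx(2.0, abs=1e-9)
        assert d_vv > d_pt

    def test_point_to_triangle_matches_exhaustive_triangle_search(self):
        from somamorph.morphometry import _point_triangle_distances

        rng = np.random.default_rng(7)
        for _ in range(10):
            surf = trimesh.convex.convex_hull(rng.normal(size=(30, 3)) * 5)
            cell = trimesh.convex.convex_hull(rng.normal(size=(12, 3)) + np.array([12.0, 0, 0]))
            got = min_surface_distance(cell, surf, "point_to_triangle")
            brute = np.inf
            tris = np.asarray(surf.triangles, float)
            for p in np.asarray(cell.vertices, float):
                d = _point_triangle_distances(np.repeat(p[None], len(tris), 0), tris).min()
                brute = min(brute, d)
            assert got == pytest.approx(brute, abs=1e-9)

    def test_empty_mesh_is_an_error(self):
        surface = self._plane_patch()
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), int), process=False)
        with pytest.raises(ValueError):
            min_surface_distance(empty, surface)


class TestSideAndFace:
    def test_side_follows_sign_against_midsagittal_plane(self, measured_reduced):
        _, _, _, surface, _, _ = measured_reduced
        cfg = MorphConfig(midsagittal_point_um=(100.0, 0.0, 0.0))
        side, face = assign_side_and_face((150.0, 10.0, 10.0), "internalized", cfg, surface)
        assert side == "right" and face == "none"
        side, _ = assign_side_and_face((50.0, 10.0, 10.0), "internalized", cfg, surface)
        assert side == "left"

    def test_planted_sides_recovered_exactly(self, measured_reduced):
        *_, merged = measured_reduced
        assert (merged.side == merged.side_gt).all()

    def test_planted_faces_recovered_for_superficial_cells(self, measured_reduced):
        *_, merged = measured_reduced
        sup = merged[merged.depth_class_gt == "superficial"]
        assert (sup.face == sup.face_gt).mean() >= 0.90


class TestMeasureAll:
    def test_one_record_per_planted_cell(self, measured_reduced):
        _, truth, _, _, records, _ = measured_reduced
        assert len(records) == len(truth) == 1099

    def test_depth_class_recovery_on_default_phantom(self, measured_reduced):
        *_, merged = measured_reduced
        assert (merged.depth_class == merged.depth_class_gt).mean() >= 0.92

    def test_all_surface_touching_phantom_is_all_superficial(self):
        # a small ellipsoid keeps the 80 superficial somata densely tiled,
        # so the operational surface wraps them all
        cfg = dataclasses.replace(
            SimConfig.reduced(),
            n_cells_left=40,
            n_cells_right=40,
            internal_fraction=0.0,
            ganglion_semi_axes_um=(48.0, 50.0, 52.0),
            grid_shape=(112, 72, 76),
        )
        from somamorph import derive_ganglion_mask, ganglion_surface

        volume, truth = generate_ganglion_pair(cfg, seed=2)
        mask = derive_ganglion_mask(volume)
        surface = ganglion_surface(mask, volume.spacing_um)
        df = records_to_frame(measure_all(volume, surface))
        assert (df.depth_class == "superficial").all()

    def test_relabeling_permutation_only_permutes_records(self):
        cfg = dataclasses.replace(
            SimConfig.reduced(), n_cells_left=15, n_cells_right=15
        )
        from somamorph import derive_ganglion_mask, ganglion_surface

        volume, _ = generate_ganglion_pair(cfg, seed=5)
        mask = derive_ganglion_mask(volume)
        surface = ganglion_surface(mask, volume.spacing_um)
        df1 = records_to_frame(measure_all(volume, surface))

        ids = volume.label_ids()
        perm = {int(a): int(b) for a, b in zip(ids, np.roll(ids, 7))}
        relabeled = np.zeros_like(volume.labels)
        for a, b in perm.items():
            relabeled[volume.labels == a] = b
        volume2 = dataclasses.replace(volume, labels=relabeled)
        df2 = records_to_frame(measure_all(volume2, surface))

        df1 = df1.assign(cell_id=[perm[int(i)] for i in df1.cell_id])
        cols = [c for c in df1.columns]
        a = df1.sort_values("cell_id").reset_index(drop=True)[cols]
        b = df2.sort_values("cell_id").reset_index(drop=True)[cols]
        assert a.equals(b)
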