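"""Annotation I/O: label maps, LabelMe JSON, rasterization, angle CSV."""

import json

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from PIL import Image

from molaraxis.annotations_io import (
    BinaryMask,
    Scene,
    ToothLabel,
    mask_to_boundary,
    mask_to_polygon,
    parse_label_table,
    polygon_to_mask,
    read_angle_csv,
    read_label_map,
    read_labelme,
    write_angle_csv,
    write_label_map,
    write_labelme,
)
from molaraxis.errors import (
    AnnotationError,
    EmptyMaskError,
    GeometryError,
    UnknownLabelError,
)
from molaraxis.seg_metrics import confusion_counts, iou

from conftest import block_mask, instance_from_mask, mask_from_array


def brute_force_polygon_area(points, height, width):
    """Even-odd point-in-polygon count over all pixel centers, boundary
    points counted as inside. Independent of shapely."""

    def on_segment(px, py, ax, ay, bx, by):
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if abs(cross) > 1e-9:
            return False
        return min(ax, bx) - 1e-9 <= px <= max(ax, bx) + 1e-9 and (
            min(ay, by) - 1e-9 <= py <= max(ay, by) + 1e-9
        )

    def inside(px, py):
        n = len(points)
        crossings = 0
        for i in range(n):
            ax, ay = points[i]
            bx, by = points[(i + 1) % n]
            if on_segment(px, py, ax, ay, bx, by):
                return True
            if (ay > py) != (by > py):
                x_int = ax + (py - ay) * (bx - ax) / (by - ay)
                if px < x_int:
                    crossings += 1
        return crossings % 2 == 1

    return sum(inside(c, r) for r in range(height) for c in range(width))


class TestToothLabel:
    @pytest.mark.parametrize(
        "fdi,position,side",
        [(36, "M1", "left"), (37, "M2", "left"), (38, "M3", "left"),
         (46, "M1", "right"), (47, "M2", "right"), (48, "M3", "right")],
    )
    def test_fdi_mapping(self, fdi, position, side):
        label = ToothLabel.from_fdi(fdi)
        assert label.position.value == position
        assert label.side.value == side

    def test_non_molar_code_rejected(self):
        with pytest.raises(UnknownLabelError):
            ToothLabel.from_fdi(11)

    def test_inconsistent_triple_rejected(self):
        from molaraxis.annotations_io import Position, Side

        with pytest.raises(AnnotationError):
            ToothLabel(position=Position.M1, side=Side.LEFT, fdi_code=46)


class TestPolygonToMask:
    def test_square_includes_boundary_centers(self):
        # centers 0..5 on both axes lie inside or on the square
        mask = polygon_to_mask([(0, 0), (5, 0), (5, 5), (0, 5)], 8, 8)
        assert mask.area == 36

    def test_triangle_matches_brute_force(self):
        pts = [(0, 0), (4, 0), (0, 4)]
        mask = polygon_to_mask(pts, 6, 6)
        assert mask.area == brute_force_polygon_area(pts, 6, 6)

    def test_degenerate_collinear_rejected(self):
        with pytest.raises(GeometryError):
            polygon_to_mask([(0, 0), (2, 2), (4, 4)], 6, 6)

    def test_self_intersecting_rejected(self):
        with pytest.raises(GeometryError):
            polygon_to_mask([(0, 0), (4, 4), (4, 0), (0, 4)], 6, 6)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_random_convex_polygons_match_brute_force(self, data):
        rng_seed = data.draw(st.integers(0, 10**6))
        rng = np.random.default_rng(rng_seed)
        pts = rng.uniform(1, 15, size=(6, 2))
        hull_order = np.argsort(
            np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
        )
        pts = pts[hull_order]
        try:
            mask = polygon_to_mask(pts, 16, 16)
        except GeometryError:
            return  # angular sort can still yield a non-simple polygon
        assert mask.area == brute_force_polygon_area(pts.tolist(), 16, 16)


class TestMaskToBoundary:
    def test_single_pixel(self):
        mask = block_mask(3, 3, 1, 2, 1, 2)
        np.testing.assert_array_equal(mask_to_boundary(mask), [[1.0, 1.0]])

    def test_solid_block_excludes_center(self):
        mask = block_mask(5, 5, 1, 4, 1, 4)
        boundary = mask_to_boundary(mask)
        assert len(boundary) == 8
        assert [2.0, 2.0] not in boundary.tolist()

    def test_full_frame_keeps_border(self):
        mask = BinaryMask(np.ones((4, 5), dtype=bool))
        boundary = mask_to_boundary(mask)
        assert len(boundary) == 2 * 4 + 2 * 5 - 4  # frame pixels only

    def test_boundary_is_nonempty_foreground_subset(self):
        mask = block_mask(10, 10, 2, 8, 3, 7)
        boundary = mask_to_boundary(mask)
        assert len(boundary) > 0
        for x, y in boundary:
            assert mask.pixels[int(y), int(x)]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            mask_to_boundary(BinaryMask(np.zeros((3, 3), dtype=bool)))


class TestLabelMapIO:
    def test_all_zero_map_gives_empty_scene(self, tmp_path):
        path = tmp_path / "empty.png"
        Image.fromarray(np.zeros((10, 10), dtype=np.uint8), "L").save(path)
        scene = read_label_map(path, {1: 36})
        assert scene.instances == []

    def test_single_block_instance(self, tmp_path):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[2:5, 3:6] = 1
        path = tmp_path / "one.png"
        Image.fromarray(arr, "L").save(path)
        scene = read_label_map(path, {1: 36})
        assert len(scene.instances) == 1
        inst = scene.instances[0]
        assert inst.label.fdi_code == 36
        assert inst.mask.area == 9

    def test_unknown_index_names_the_index(self, tmp_path):
        arr = np.zeros((5, 5), dtype=np.uint8)
        arr[1, 1] = 9
        path = tmp_path / "bad.png"
        Image.fromarray(arr, "L").save(path)
        with pytest.raises(UnknownLabelError, match="9"):
            read_label_map(path, {i: fdi for i, fdi in enumerate([36, 37, 38, 46, 47, 48], 1)})

    def test_rgb_image_rejected(self, tmp_path):
        path = tmp_path / "rgb.png"
        Image.fromarray(np.zeros((5, 5, 3), dtype=np.uint8), "RGB").save(path)
        with pytest.raises(AnnotationError):
            read_label_map(path, {1: 36})

    def test_write_read_roundtrip(self, tmp_path):
        table = {1: 36, 2: 47}
        scene = Scene(
            image_id="s",
            instances=[
                instance_from_mask(block_mask(12, 12, 1, 4, 1, 4), fdi=36),
                instance_from_mask(block_mask(12, 12, 6, 10, 6, 11), fdi=47),
            ],
            image_height=12,
            image_width=12,
        )
        path = tmp_path / "s.png"
        write_label_map(scene, path, table)
        back = read_label_map(path, table)
        assert {i.label.fdi_code for i in back.instances} == {36, 47}
        for inst in scene.instances:
            np.testing.assert_array_equal(
                back.get(inst.label.fdi_code).mask.pixels, inst.mask.pixels
            )


class TestLabelMe:
    def _write(self, tmp_path, shapes, h=12, w=12):
        path = tmp_path / "a.json"
        path.write_text(
            json.dumps({"imageHeight": h, "imageWidth": w, "shapes": shapes})
        )
        return path

    def test_empty_shapes(self, tmp_path):
        scene = read_labelme(self._write(tmp_path, []))
        assert scene.instances == []
        assert scene.image_height == 12

    def test_square_polygon_area(self, tmp_path):
        shapes = [{"label": "46",
                   "points": [[2, 2], [7, 2], [7, 7], [2, 7]],
                   "shape_type": "polygon"}]
        scene = read_labelme(self._write(tmp_path, shapes))
        # pixel centers 2..7 on both axes: 6x6
        assert scene.instances[0].mask.area == 36

    def test_unsupported_shape_type(self, tmp_path):
        shapes = [{"label": "46", "points": [[2, 2], [5, 5]],
                   "shape_type": "circle"}]
        with pytest.raises(AnnotationError, match="circle"):
            read_labelme(self._write(tmp_path, shapes))

    def test_unparseable_label(self, tmp_path):
        shapes = [{"label": "incisor",
                   "points": [[2, 2], [7, 2], [7, 7], [2, 7]],
                   "shape_type": "polygon"}]
        with pytest.raises(UnknownLabelError):
            read_labelme(self._write(tmp_path, shapes))

    def test_overlap_later_shape_wins_with_warning(self, tmp_path):
        shapes = [
            {"label": "36", "points": [[1, 1], [6, 1], [6, 6], [1, 6]],
             "shape_type": "polygon"},
            {"label": "37", "points": [[4, 1], [9, 1], [9, 6], [4, 6]],
             "shape_type": "polygon"},
        ]
        with pytest.warns(UserWarning, match="overlap"):
            scene = read_labelme(self._write(tmp_path, shapes))
        first = scene.get(36).mask.pixels
        second = scene.get(37).mask.pixels
        assert not (first & second).any()
        assert second[2, 4]  # overlap pixels belong to the later shape

    def test_labelme_roundtrip_preserves_shape(self, tmp_path):
        scene = Scene(
            image_id="s",
            instances=[instance_from_mask(block_mask(20, 20, 3, 15, 5, 14), fdi=38)],
            image_height=20,
            image_width=20,
        )
        path = tmp_path / "s.json"
        write_labelme(scene, path)
        back = read_labelme(path)
        counts = confusion_counts(back.get(38).mask, scene.get(38).mask)
        assert iou(counts) >= 0.95


class TestMaskPolygonRoundtrip:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_convex_polygon_rerasterizes_close(self, seed):
        rng = np.random.default_rng(seed)
        # random convex polygon with area >= 100 px^2
        center = rng.uniform(15, 25, 2)
        radii = rng.uniform(8, 14, 8)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
        pts = center + np.column_stack(
            [radii * np.cos(angles), radii * np.sin(angles)]
        )
        mask = polygon_to_mask(pts, 40, 40)
        assume(mask.area >= 100)
        re_mask = polygon_to_mask(mask_to_polygon(mask), 40, 40)
        assert iou(confusion_counts(re_mask, mask)) >= 0.95


class TestAngleCsv:
    RECORD = {
        "image_id": "s0", "fdi": 38, "position": "M3", "side": "left",
        "angle_signed_deg": -44.123456789, "angle_magnitude_deg": 44.123456789,
        "n_iterations": 10, "converged": True,
    }

    def test_empty_gives_header_only(self, tmp_path):
        path = tmp_path / "a.csv"
        write_angle_csv([], path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_roundtrip_to_1e6(self, tmp_path):
        path = tmp_path / "a.csv"
        write_angle_csv([self.RECORD], path)
        df = read_angle_csv(path)
        assert len(df) == 1
        assert df.loc[0, "angle_signed_deg"] == pytest.approx(
            self.RECORD["angle_signed_deg"], abs=1e-6
        )
        assert df.loc[0, "fdi"] == 38

    def test_six_records_seven_lines(self, tmp_path):
        path = tmp_path / "a.csv"
        write_angle_csv([self.RECORD] * 1 + [
            dict(self.RECORD, fdi=fdi) for fdi in (36, 37, 46, 47, 48)
        ], path)
        assert len(path.read_text().strip().splitlines()) == 7


def test_parse_label_table_text_and_comments(tmp_path):
    path = tmp_path / "t.txt"
    path.write_text("# map\n1=36\n2 = 37\n\n")
    assert parse_label_table(path) == {1: 36, 2: 37}
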