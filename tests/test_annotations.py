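import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasselkit import (
    AnnotationSet,
    BBox,
    ImageSpec,
    TasselCategory,
    crop_annotations_to_block,
    dataset_stats,
    plan_pattern1,
    read_yolo,
    standardize_boxes,
    sweep_sizes,
    write_yolo,
)
from tasselkit.annotations import STANDARD_TARGETS, YoloFormatError, split_dataset

IMG = ImageSpec(1024, 1024, 0.25)


class TestReadYolo:
    def test_single_box_unit_conversion(self):
        anns = read_yolo("0 0.5 0.5 0.1 0.1", IMG)
        assert len(anns) == 1
        b = anns.boxes[0]
        assert b.category is TasselCategory.TASSEL_N
        assert (b.cx, b.cy) == (512.0, 512.0)
        assert b.w == pytest.approx(102.4)
        assert b.h == pytest.approx(102.4)

    def test_empty_file(self):
        assert len(read_yolo("", IMG)) == 0
        assert len(read_yolo("\n\n", IMG)) == 0

    def test_bad_class_code(self):
        with pytest.raises(YoloFormatError, match="class code 5"):
            read_yolo("5 0.5 0.5 0.1 0.1", IMG)

    def test_out_of_range_value_names_line(self):
        with pytest.raises(YoloFormatError, match="line 2"):
            read_yolo("0 0.5 0.5 0.1 0.1\n1 1.5 0.5 0.1 0.1", IMG)

    def test_wrong_field_count(self):
        with pytest.raises(YoloFormatError, match="5 fields"):
            read_yolo("0 0.5 0.5 0.1", IMG)

    @given(
        boxes=st.lists(
            st.tuples(
                st.integers(0, 2),
                st.floats(0.1, 0.9),
                st.floats(0.1, 0.9),
                st.floats(0.01, 0.2),
                st.floats(0.01, 0.2),
            ),
            min_size=0,
            max_size=100,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, boxes):
        anns = AnnotationSet(
            "rt",
            IMG,
            tuple(
                BBox(
                    TasselCategory(c),
                    cx * IMG.width_px,
                    cy * IMG.height_px,
                    w * IMG.width_px,
                    h * IMG.height_px,
                )
                for c, cx, cy, w, h in boxes
            ),
        )
        back = read_yolo(write_yolo(anns), IMG, image_id="rt")
        assert len(back) == len(anns)
        for a, b in zip(anns.boxes, back.boxes):
            assert a.category == b.category
            assert abs(a.cx - b.cx) / IMG.width_px < 1e-6
            assert abs(a.cy - b.cy) / IMG.height_px < 1e-6
            assert abs(a.w - b.w) / IMG.width_px < 1e-6
            assert abs(a.h - b.h) / IMG.height_px < 1e-6


class TestStandardize:
    def test_n_box_resized_to_140(self):
        anns = AnnotationSet(
            "a", IMG, (BBox(TasselCategory.TASSEL_N, 512, 512, 76, 76),)
        )
        out = standardize_boxes(anns, STANDARD_TARGETS)
        b = out.boxes[0]
        assert (b.w, b.h) == (140.0, 140.0)
        assert (b.cx, b.cy) == (512.0, 512.0)

    def test_tassel_l_passes_through(self):
        orig = BBox(TasselCategory.TASSEL_L, 300, 300, 90, 120)
        anns = AnnotationSet("a", IMG, (orig,))
        assert standardize_boxes(anns, STANDARD_TARGETS).boxes[0] == orig

    def test_edge_box_clipped(self):
        anns = AnnotationSet(
            "a", IMG, (BBox(TasselCategory.TASSEL_S, 10, 512, 40, 40),)
        )
        b = standardize_boxes(anns, STANDARD_TARGETS).boxes[0]
        assert b.w == pytest.approx(80.0)  # clipped at the left edge
        assert b.h == pytest.approx(140.0)

    def test_count_and_centers_preserved(self, rng):
        from conftest import make_random_annotations

        anns = make_random_annotations(rng, IMG, 60)
        out = standardize_boxes(anns, STANDARD_TARGETS)
        assert len(out) == len(anns)
        for a, b in zip(anns.boxes, out.boxes):
            if a.category is TasselCategory.TASSEL_L:
                assert a == b
            elif 70 <= a.cx <= IMG.width_px - 70 and 70 <= a.cy <= IMG.height_px - 70:
                assert (b.cx, b.cy) == (a.cx, a.cy)

    def test_idempotent_away_from_edges(self, rng):
        from conftest import make_random_annotations

        anns = make_random_annotations(rng, ImageSpec(4096, 4096, 0.25), 50)
        inner = AnnotationSet(
            anns.image_id,
            anns.image_spec,
            tuple(b for b in anns.boxes if 200 < b.cx < 3896 and 200 < b.cy < 3896),
        )
        once = standardize_boxes(inner, STANDARD_TARGETS)
        twice = standardize_boxes(once, STANDARD_TARGETS)
        assert once.boxes == twice.boxes


class TestSweep:
    def _dataset(self):
        return [
            AnnotationSet(
                "a", IMG, (BBox(TasselCategory.TASSEL_N, 500, 500, 100, 100),)
            )
        ]

    def test_coarse_sweep_yields_ten_datasets(self):
        out = sweep_sizes(self._dataset(), list(range(50, 501, 50)))
        assert len(out) == 10
        assert [s for s, _ in out] == list(range(50, 501, 50))

    def test_fine_sweep_yields_26_datasets(self):
        out = sweep_sizes(self._dataset(), list(range(50, 301, 10)))
        assert len(out) == 26

    def test_identity_side(self):
        ds = self._dataset()
        (side, derived), = sweep_sizes(ds, [100])
        assert derived[0].boxes == ds[0].boxes

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            sweep_sizes(self._dataset(), [100, 100])


class TestDatasetStats:
    def test_mean_side_of_5784_area(self):
        anns = AnnotationSet(
            "a",
            IMG,
            tuple(
                BBox(TasselCategory.TASSEL_N, 200 + 50 * i, 200, math.sqrt(5784), math.sqrt(5784))
                for i in range(10)
            ),
        )
        stats = dataset_stats([anns])
        assert stats.row("All")["area_mean"] == pytest.approx(5784.0)
        assert round(stats.row("All")["side_mean"]) == 76

    def test_square_boxes_ratio_one(self):
        anns = AnnotationSet(
            "a", IMG, (BBox(TasselCategory.TASSEL_S, 100, 100, 50, 50),) * 3
        )
        stats = dataset_stats([anns])
        assert stats.row("S")["ratio_mean"] == 1.0
        assert stats.row("S")["ratio_sd"] == 0.0

    def test_hand_computed_two_boxes(self):
        anns = AnnotationSet(
            "a",
            IMG,
            (
                BBox(TasselCategory.TASSEL_N, 200, 200, 100, 100),
                BBox(TasselCategory.TASSEL_N, 500, 500, 50, 200),
            ),
        )
        stats = dataset_stats([anns])
        assert stats.row("N")["area_mean"] == pytest.approx(10000.0)
        assert stats.row("N")["ratio_mean"] == pytest.approx(0.625)

    def test_overall_mean_is_count_weighted(self, rng):
        from conftest import make_random_annotations

        dataset = [make_random_annotations(rng, IMG, 40, f"im{i}") for i in range(5)]
        stats = dataset_stats(dataset)
        weighted = sum(
            stats.row(c.short_name)["count"] * stats.row(c.short_name)["area_mean"]
            for c in TasselCategory
        ) / stats.row("All")["count"]
        assert stats.row("All")["area_mean"] == pytest.approx(weighted)

    def test_proportions_sum_to_one(self, rng):
        from conftest import make_random_annotations

        stats = dataset_stats([make_random_annotations(rng, IMG, 100)])
        total = sum(stats.row(c.short_name)["proportion"] for c in TasselCategory)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="no annotation"):
            dataset_stats([AnnotationSet("a", IMG, ())])


class TestCropToBlock:
    def test_interior_box_shifted(self, uav_frame):
        plan = plan_pattern1(uav_frame)
        block = plan.blocks[0]
        box = BBox(
            TasselCategory.TASSEL_N, block.x0 + 300, block.y0 + 300, 100, 100
        )
        anns = AnnotationSet("a", uav_frame, (box,))
        out = crop_annotations_to_block(anns, block)
        assert len(out) == 1
        assert (out.boxes[0].cx, out.boxes[0].cy) == (300.0, 300.0)

    def test_30pct_visible_dropped(self, uav_frame):
        plan = plan_pattern1(uav_frame)
        block = plan.blocks[0]
        # 100-wide box with 30 px inside the left edge of the block
        box = BBox(TasselCategory.TASSEL_S, block.x0 - 20, block.y0 + 500, 100, 100)
        anns = AnnotationSet("a", uav_frame, (box,))
        assert len(crop_annotations_to_block(anns, block, 0.5)) == 0
        assert len(crop_annotations_to_block(anns, block, 0.25)) == 1

    def test_straddling_box_in_both_overlapping_blocks(self, uav_frame):
        plan = plan_pattern1(uav_frame)
        left, right = plan.blocks[0], plan.blocks[1]
        # center of the 200-px overlap strip; an 80-px box is fully inside both
        cx = (right.x0 + left.x1) / 2
        cy = left.y0 + 512
        anns = AnnotationSet(
            "a", uav_frame, (BBox(TasselCategory.TASSEL_L, cx, cy, 80, 80),)
        )
        assert len(crop_annotations_to_block(anns, left)) == 1
        assert len(crop_annotations_to_block(anns, right)) == 1

    def test_center_owned_boxes_survive_somewhere(self, rng, uav_frame):
        # a box whose center lies in a block is at least 25% visible there,
        # so any threshold <= 0.25 keeps it in at least one block
        from conftest import make_random_annotations

        plan = plan_pattern1(uav_frame)
        anns = make_random_annotations(rng, uav_frame, 300)
        for b in anns.boxes:
            in_some_block = any(blk.contains_point(b.cx, b.cy) for blk in plan.blocks)
            if not in_some_block:
                continue
            kept_somewhere = any(
                len(
                    crop_annotations_to_block(
                        AnnotationSet("a", uav_frame, (b,)), blk, 0.25
                    )
                )
                > 0
                for blk in plan.blocks
            )
            assert kept_somewhere


class TestSplit:
    def test_8_1_1_split(self):
        ids = [f"im{i}" for i in range(100)]
        assignment = split_dataset(ids, seed=0)
        counts = {s: 0 for s in ("train", "val", "test")}
        for s in assignment.values():
            counts[s] += 1
        assert counts == {"train": 80, "val": 10, "test": 10}

    def test_split_is_seeded(self):
        ids = [f"im{i}" for i in range(50)]
        assert split_dataset(ids, seed=3) == split_dataset(ids, seed=3)
        assert split_dataset(ids, seed=3) != split_dataset(ids, seed=4)
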