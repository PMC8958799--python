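"""Seed instance detection, box expansion, overlap flags, submasks."""

import numpy as np
import pytest

from rhizolapse.segmentation import SegmentationModel, segment
from rhizolapse.tracking import (
    SeedInstance,
    detect_seed_instances,
    root_pixels_of,
    update_tracks,
)


def flood_fill_components(mask):
    """Brute-force 8-connected components (oracle for scipy labelling)."""
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack, pixels = [(sy, sx)], []
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and mask[ny, nx]
                            and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(frozenset(pixels))
    return comps


class TestDetectSeedInstances:
    def test_two_blobs_get_tight_boxes(self):
        mask = np.zeros((20, 30), np.uint8)
        mask[2:5, 3:6] = 1
        mask[12:15, 20:23] = 1
        inst = detect_seed_instances(mask, (2, 1))
        assert len(inst) == 2
        assert inst[0].bbox == (3, 2, 6, 5)
        assert inst[1].bbox == (20, 12, 23, 15)

    def test_empty_mask_gives_empty_list(self):
        assert detect_seed_instances(np.zeros((10, 10)), (2, 2)) == []

    def test_full_plate_ids_match_grid(self, germination_run):
        cfg, records, result = germination_run
        # one instance per sown seed, labelled row-major like the truth
        ids = sorted(i.seed_id for i in result.instances)
        assert ids == sorted(r.seed_id for r in records)

    def test_missing_seed_flags_cell_lost(self):
        mask = np.zeros((40, 40), np.uint8)
        # 2x2 grid with one corner missing
        for y, x in [(5, 5), (5, 30), (30, 5)]:
            mask[y : y + 3, x : x + 3] = 1
        with pytest.warns(UserWarning, match="best-effort"):
            inst = detect_seed_instances(mask, (2, 2))
        assert len(inst) == 4
        statuses = {i.seed_id: i.status for i in inst}
        assert statuses[(1, 1)] == "lost"
        assert sum(1 for s in statuses.values() if s == "lost") == 1


class TestUpdateTracks:
    def test_root_extension_grows_only_that_box(self):
        mask0 = np.zeros((100, 60), np.uint8)
        mask0[5:8, 10:13] = 1
        mask0[5:8, 40:43] = 1
        inst = detect_seed_instances(mask0, (1, 2))
        grown = mask0.copy()
        grown[8:48, 10:13] = 1  # 40 px of root under the first seed
        update_tracks(inst, grown, 1.0, margin_px=2)
        assert inst[0].bbox[3] >= 48
        assert inst[1].bbox == inst[1].initial_bbox

    def test_empty_mask_leaves_boxes_unchanged(self):
        mask0 = np.zeros((30, 30), np.uint8)
        mask0[5:8, 5:8] = 1
        inst = detect_seed_instances(mask0, (1, 1))
        before = inst[0].bbox
        update_tracks(inst, np.zeros_like(mask0), 1.0)
        assert inst[0].bbox == before

    def test_box_expansion_is_monotone(self, small_plate):
        _, series, _, masks = small_plate
        inst = detect_seed_instances(masks[0].astype(np.uint8), (2, 2))
        areas = {i.seed_id: 0 for i in inst}
        for t, hour in enumerate(series.hours):
            update_tracks(inst, masks[t], float(hour), margin_px=1)
            for i in inst:
                x0, y0, x1, y1 = i.bbox
                area = (x1 - x0) * (y1 - y0)
                assert area >= areas[i.seed_id]
                areas[i.seed_id] = area

    def test_boxes_contain_own_truth_and_not_neighbors(self, small_plate):
        cfg, series, records, masks = small_plate
        from rhizolapse.synthetic import rasterize_root

        inst = detect_seed_instances(masks[0].astype(np.uint8), (2, 2))
        for t, hour in enumerate(series.hours):
            update_tracks(inst, masks[t], float(hour), margin_px=1)
        by_id = {i.seed_id: i for i in inst}
        shape = series.frame_shape
        tubes = {
            r.seed_id: rasterize_root(
                r.polyline_at(series.n_frames - 1),
                cfg.root_width_px,
                cfg.scale_px_per_mm,
                shape,
            )
            for r in records
        }
        for r in records:
            x0, y0, x1, y1 = by_id[r.seed_id].bbox
            inside = tubes[r.seed_id][y0:y1, x0:x1].sum()
            assert inside == tubes[r.seed_id].sum()  # all own pixels inside
            for other, tube in tubes.items():
                if other != r.seed_id:
                    assert tube[y0:y1, x0:x1].sum() == 0

    def test_engineered_collision_flags_both_tracks(self):
        from rhizolapse.pipeline import PipelineParams, run_pipeline
        from rhizolapse.synthetic import SyntheticConfig, generate_plate_series

        cfg = SyntheticConfig(
            rows=2,
            cols=1,
            scale_px_per_mm=12.0,
            n_frames=90,
            rng_seed=5,
            germ_delay_h=0.0,
            rate_mm_per_h=0.15,
            germ_prob=1.0,
        )
        series, records = generate_plate_series(cfg)
        result = run_pipeline(series, params=PipelineParams(rows=2, cols=1))
        truth_h = records[0].overlapped_from_h
        assert truth_h is not None
        for inst in result.instances:
            assert inst.status == "overlapped"
            assert abs(inst.overlap_h - truth_h) <= 1.0
            assert inst.overlap_h <= truth_h + 1.0

    def test_drifting_seed_without_root_is_lost(self):
        mask0 = np.zeros((40, 40), np.uint8)
        mask0[5:8, 5:8] = 1
        inst = detect_seed_instances(mask0, (1, 1))
        # the seed drifts away: nothing near the box for 3 frames
        gone = np.zeros_like(mask0)
        gone[30:33, 30:33] = 1
        for h in (1.0, 2.0, 3.0):
            update_tracks(inst, gone, h, margin_px=2)
        assert inst[0].status == "lost"


class TestRootPixelsOf:
    def test_membership_inside_bbox(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[5:7, 5:7] = 1  # fragment A inside
        mask[10:12, 10:12] = 1  # fragment B inside
        mask[25:27, 25:27] = 1  # fragment outside
        inst = SeedInstance((0, 0), (3, 3, 15, 15))
        sub = root_pixels_of(inst, mask)
        assert sub.sum() == 8
        assert sub[25:27, 25:27].sum() == 0

    def test_empty_mask_gives_empty_submask(self):
        inst = SeedInstance((0, 0), (0, 0, 5, 5))
        assert root_pixels_of(inst, np.zeros((10, 10))).sum() == 0

    def test_full_bbox_returns_whole_mask(self, rng):
        mask = (rng.uniform(size=(20, 20)) > 0.5).astype(np.uint8)
        inst = SeedInstance((0, 0), (0, 0, 20, 20))
        assert np.array_equal(root_pixels_of(inst, mask), mask)


class TestComponentOracle:
    def test_labelling_matches_brute_force_flood_fill(self, rng):
        from scipy import ndimage as ndi

        for _ in range(20):
            mask = rng.uniform(size=(32, 32)) > 0.7
            labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
            scipy_comps = {
                frozenset(zip(*np.nonzero(labels == k))) for k in range(1, n + 1)
            }
            brute = set(flood_fill_components(mask))
            assert scipy_comps == brute
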