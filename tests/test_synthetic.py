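"""The synthetic face generator: determinism, identity signal, dataset layout."""

import numpy as np
import pytest

from wildface.dataio import read_yolo_annotation, scan_identity_folders
from wildface.synthetic import (
    FIELD_STUDY_COUNTS,
    IDENTITY_NUISANCE,
    MIN_MARKING_SEP,
    NUISANCE_JITTER_AMP,
    draw_nuisance,
    generate_dataset,
    make_identity_bank,
    render_face,
    write_dataset,
)


class TestIdentityBank:
    def test_deterministic_given_seed(self):
        b1, b2 = make_identity_bank(18, seed=7), make_identity_bank(18, seed=7)
        for p, q in zip(b1, b2):
            assert p.identity_id == q.identity_id
            assert p.skin_hue == q.skin_hue
            assert np.array_equal(p.marking_pattern, q.marking_pattern)
            assert np.array_equal(p.landmark_geometry, q.landmark_geometry)
            assert p.texture_seed == q.texture_seed

    def test_pairwise_distinguishable_beyond_jitter(self):
        bank = make_identity_bank(2, seed=0)
        dist = np.max(np.abs(bank[0].marking_pattern - bank[1].marking_pattern))
        assert dist > MIN_MARKING_SEP > NUISANCE_JITTER_AMP

    def test_all_identity_ids_unique(self):
        bank = make_identity_bank(18, seed=1)
        assert len(bank) == 18
        assert len({p.identity_id for p in bank}) == 18

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            make_identity_bank(1, seed=0)


class TestRenderFace:
    def test_bitwise_deterministic(self, small_bank, rng):
        nuis = draw_nuisance(rng)
        a = render_face(small_bank[0], nuis, size=64)
        b = render_face(small_bank[0], nuis, size=64)
        assert np.array_equal(a.image, b.image)
        assert a.face_box == b.face_box

    def test_identity_nuisance_gives_canonical_extent(self, small_bank):
        s = 64
        sample = render_face(small_bank[0], IDENTITY_NUISANCE, size=s)
        # recompute the canonical ellipse extent by brute force
        yy, xx = np.mgrid[0:s, 0:s] + 0.5
        ell = ((xx - s / 2) / (0.32 * s)) ** 2 + ((yy - s / 2) / (0.38 * s)) ** 2 <= 1.0
        ys, xs = np.nonzero(ell)
        expected = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        assert sample.face_box == expected
        assert np.array_equal(sample.face_mask, ell)

    def test_box_contains_mask_and_mask_nonempty(self, small_bank, rng):
        sample = render_face(small_bank[1], draw_nuisance(rng), size=64)
        x0, y0, x1, y1 = sample.face_box
        ys, xs = np.nonzero(sample.face_mask)
        assert ys.size > 0
        assert x0 <= xs.min() and xs.max() < x1
        assert y0 <= ys.min() and ys.max() < y1

    def test_identity_difference_concentrates_in_face(self, small_bank):
        a = render_face(small_bank[0], IDENTITY_NUISANCE, size=64)
        b = render_face(small_bank[1], IDENTITY_NUISANCE, size=64)
        diff = np.any(a.image != b.image, axis=2)
        inside = (diff & a.face_mask).sum()
        assert inside / max(diff.sum(), 1) >= 0.80

    def test_rejects_tiny_canvas(self, small_bank):
        with pytest.raises(ValueError):
            render_face(small_bank[0], IDENTITY_NUISANCE, size=16)


class TestGenerateDataset:
    def test_counts_and_group_blocks(self):
        bank = make_identity_bank(2, seed=0)
        ds = generate_dataset(bank, [10, 10], seed=1, size=32)
        assert len(ds) == 20
        assert np.bincount(ds.labels).tolist() == [10, 10]

        ds2 = generate_dataset(bank, [12, 3], images_per_group=5, seed=1, size=32)
        assert ds2.groups[:12].tolist() == [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2]
        # numbering continues across identities: next identity starts a new group
        assert ds2.groups[12] == 3

    def test_field_study_preset_total(self):
        bank = make_identity_bank(18, seed=7)
        ds = generate_dataset(bank, list(FIELD_STUDY_COUNTS), seed=0, size=32)
        assert len(ds) == 3385
        assert ds.class_counts().tolist() == list(FIELD_STUDY_COUNTS)

    def test_deterministic_given_seed(self):
        bank = make_identity_bank(2, seed=5)
        d1 = generate_dataset(bank, [4, 4], seed=9, size=32)
        d2 = generate_dataset(bank, [4, 4], seed=9, size=32)
        for i in range(len(d1)):
            assert np.array_equal(d1.get_image(i), d2.get_image(i))

    def test_count_mismatch_rejected(self, small_bank):
        with pytest.raises(ValueError):
            generate_dataset(small_bank, [5, 5], seed=0, size=32)

    def test_identity_signal_above_chance(self):
        """Nearest-centroid on masked mean color separates identities (floor
        guarantee that downstream training tests are solvable)."""
        bank = make_identity_bank(6, seed=3)
        ds = generate_dataset(bank, [30] * 6, seed=4, size=64)
        feats = np.array([ds.get_image(i)[ds.masks[i]].mean(axis=0) for i in range(len(ds))])
        train = np.concatenate([np.flatnonzero(ds.labels == c)[:20] for c in range(6)])
        test = np.concatenate([np.flatnonzero(ds.labels == c)[20:] for c in range(6)])
        cents = np.array([feats[train][ds.labels[train] == c].mean(axis=0) for c in range(6)])
        pred = np.argmin(((feats[test][:, None, :] - cents[None]) ** 2).sum(-1), axis=1)
        acc = (pred == ds.labels[test]).mean()
        assert acc > 0.5  # chance is 1/6


class TestOnDiskLayout:
    def test_write_then_scan_round_trip(self, small_ds, tmp_path):
        write_dataset(small_ds, tmp_path)
        scanned = scan_identity_folders(tmp_path)
        assert scanned.class_names == small_ds.class_names
        assert len(scanned) == len(small_ds)
        assert np.array_equal(np.sort(np.unique(scanned.groups)), np.unique(small_ds.groups))
        # identity folders follow the <index>.<id> convention
        assert all("." in name and name.split(".")[0].isdigit() for name in scanned.class_names)

    def test_yolo_labels_describe_face_boxes(self, small_ds, tmp_path):
        write_dataset(small_ds, tmp_path)
        label = tmp_path / "labels" / small_ds.class_names[0] / "img_00000.txt"
        h, w = small_ds.get_image(0).shape[:2]
        (ann, pixel_box) = read_yolo_annotation(label.read_text(), (w, h))[0]
        assert ann.class_id == 0
        x0, y0, x1, y1 = small_ds.boxes[0]
        px0, py0, px1, py1 = pixel_box
        assert abs(px0 - x0) <= 1 and abs(py0 - y0) <= 1
        assert abs(px1 - x1) <= 1 and abs(py1 - y1) <= 1
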