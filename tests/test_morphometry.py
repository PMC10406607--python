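"""Morphometry: skeletons, spine lengths, puncta, traces, volumes."""

import numpy as np
import pytest
from scipy import ndimage

from shadowseg import acquisition as acq
from shadowseg import morphometry as mm
from shadowseg import phantom as ph


@pytest.fixture(scope="module")
def digital_cylinder():
    vol = np.zeros((40, 21, 21), np.int64)
    zz, yy, xx = np.ogrid[:40, :21, :21]
    vol[((yy - 10) ** 2 + (xx - 10) ** 2 <= 36) & (zz >= 5) & (zz < 35)] = 1
    return vol  # axis length 29 voxels = 1.45 um at 50 nm


class TestSkeletonize:
    def test_cylinder_axis_recovered(self, digital_cylinder):
        skel = mm.skeletonize_segment(digital_cylinder, 1)
        path, arc = mm.principal_path(skel)
        pts = skel.nodes[path] / 50.0
        lateral = np.hypot(pts[:, 1] - 10, pts[:, 2] - 10)
        assert lateral.max() <= 1.0  # within one voxel of the true axis
        true_len = 1.45
        assert abs(arc[-1] / 1e3 - true_len) <= 0.05 * true_len

    def test_sphere_collapses_to_center(self):
        vol = np.zeros((31, 31, 31), np.int64)
        zz, yy, xx = np.ogrid[:31, :31, :31]
        vol[((zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2) <= 100] = 1
        skel = mm.skeletonize_segment(vol, 1)
        assert len(skel.nodes) <= 5

    def test_skeleton_voxels_inside_segment(self, digital_cylinder):
        skel = mm.skeletonize_segment(digital_cylinder, 1)
        vox = np.round(skel.nodes / 50.0).astype(int)
        assert np.all(digital_cylinder[vox[:, 0], vox[:, 1], vox[:, 2]] == 1)

    def test_absent_id_rejected(self, digital_cylinder):
        with pytest.raises(KeyError):
            mm.skeletonize_segment(digital_cylinder, 99)


class TestSpineLength:
    def _straight_skeleton(self, length_nm, n=16):
        ts = np.linspace(0.0, 1.0, n)
        nodes = np.stack([np.full(n, 500.0),
                          500.0 + ts * length_nm,
                          np.full(n, 500.0)], axis=1)
        return ph.Skeleton(nodes, [(i, i + 1) for i in range(n - 1)],
                           np.full(n, 100.0))

    def test_base_equals_tip_gives_zero(self):
        skel = self._straight_skeleton(1500.0)
        assert mm.spine_length(skel, skel.nodes[0], skel.nodes[0]) == 0.0

    def test_straight_spine_length_recovered(self):
        skel = self._straight_skeleton(1500.0)
        L = mm.spine_length(skel, skel.nodes[0], skel.nodes[-1])
        assert L == pytest.approx(1.50, abs=0.10)

    def test_geodesic_bounded_below_by_chord(self):
        rng = np.random.default_rng(0)
        nodes = np.cumsum(rng.normal(scale=80.0, size=(20, 3)), axis=0) + 2000
        skel = ph.Skeleton(nodes, [(i, i + 1) for i in range(19)],
                           np.full(20, 80.0))
        L = mm.spine_length(skel, nodes[0], nodes[-1])
        chord = np.linalg.norm(nodes[-1] - nodes[0]) / 1e3
        assert L >= chord - 1e-9

    def test_disconnected_skeleton_rejected(self):
        nodes = np.array([[0.0, 0, 0], [0, 100, 0],
                          [0, 5000, 0], [0, 5100, 0]])
        skel = ph.Skeleton(nodes, [(0, 1), (2, 3)], np.full(4, 80.0))
        with pytest.raises(ValueError):
            mm.spine_length(skel, nodes[0], nodes[-1])


class TestCentralAxisRecovery:
    def test_spine_length_recovery_on_default_phantom(self, default_phantom):
        # oracle: the generating parameterization of each spine
        errors = []
        for s in default_phantom.spines():
            measured = mm.central_axis_length(
                default_phantom.labels, s.id,
                s.skeleton.nodes[0], s.skeleton.nodes[-1])
            errors.append(measured - s.skeleton.path_length_nm / 1e3)
        errors = np.array(errors)
        assert len(errors) >= 30
        assert np.abs(errors).mean() < 0.15
        assert abs(errors.mean()) < 0.05


class TestSpineDensity:
    def test_worked_example(self):
        assert mm.spine_density(38, 22.0) == 1.7

    def test_zero_spines(self):
        assert mm.spine_density(0, 7.0) == 0.0

    def test_plain_arithmetic(self):
        assert mm.spine_density(10, 5.0) == 2.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mm.spine_density(5, 0.0)


class TestAbstractDendrite:
    def _dendrite(self, length_um=12.0, n=121):
        ts = np.linspace(0.0, 1.0, n)
        nodes = np.stack([np.full(n, 1000.0),
                          ts * length_um * 1e3,
                          np.full(n, 1000.0)], axis=1)
        return ph.Skeleton(nodes, [(i, i + 1) for i in range(n - 1)],
                           np.full(n, 350.0))

    def _spines_at(self, arcs_um, lengths_um):
        return [mm.SpineRecord(
            spine_id=i + 1, dendrite_id=1,
            base_nm=np.array([1000.0, a * 1e3, 1350.0]),
            tip_nm=np.array([1000.0, a * 1e3, 1350.0 + L * 1e3]),
            length_um=L) for i, (a, L) in enumerate(zip(arcs_um, lengths_um))]

    def test_arclength_positions_recovered(self):
        spines = self._spines_at([2.0, 5.0, 9.0], [1.0, 2.5, 1.4])
        out = mm.abstract_dendrite(self._dendrite(), spines)
        rec = np.sort(out.arclength_positions_um)
        np.testing.assert_allclose(rec, [2.0, 5.0, 9.0], atol=0.15)

    def test_longest_spine_normalized_to_one(self):
        spines = self._spines_at([2.0, 5.0, 9.0], [1.0, 2.5, 1.4])
        out = mm.abstract_dendrite(self._dendrite(), spines)
        assert out.relative_lengths.max() == 1.0
        assert np.sum(out.relative_lengths == 1.0) == 1
        assert out.longest_spine_um == 2.5

    def test_pairwise_distances_preserved(self):
        arcs = [1.5, 4.0, 7.25, 10.0]
        spines = self._spines_at(arcs, [1.0] * 4)
        out = mm.abstract_dendrite(self._dendrite(), spines)
        rec = out.arclength_positions_um
        for i in range(len(arcs)):
            for j in range(i + 1, len(arcs)):
                assert abs((rec[j] - rec[i]) - (arcs[j] - arcs[i])) < 0.2

    def test_base_far_off_path_rejected(self):
        spines = [mm.SpineRecord(1, 1, np.array([9000.0, 2000.0, 9000.0]),
                                 np.array([9000.0, 2000.0, 10000.0]), 1.0)]
        with pytest.raises(ValueError):
            mm.abstract_dendrite(self._dendrite(), spines)


class TestSegmentVolume:
    def test_voxel_count_arithmetic(self):
        labels = np.zeros((20, 20, 20), np.int64)
        labels[:8, :10, :100] = 1  # 8*10*20 = 1600... use explicit count
        labels[:] = 0
        labels.ravel()[:8000] = 1
        assert mm.segment_volume(labels, 1, 50.0) == pytest.approx(1.0)

    def test_additive_over_disjoint_segments(self, small_phantom):
        labels = small_phantom.labels
        ids = np.unique(labels[labels > 0])
        total = sum(mm.segment_volume(labels, int(i)) for i in ids)
        _, _, ecs_vol = __import__("shadowseg.segmentation",
                                   fromlist=["ecs_mask"]).ecs_mask(labels)
        grid_vol = labels.size * 0.05 ** 3
        assert total + ecs_vol == pytest.approx(grid_vol)

    def test_rasterized_sphere_volume(self):
        r_um = 0.62
        r_vox = r_um / 0.05
        n = 31
        labels = np.zeros((n, n, n), np.int64)
        zz, yy, xx = np.ogrid[:n, :n, :n]
        c = n // 2
        labels[((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
               <= r_vox ** 2] = 1
        vol = mm.segment_volume(labels, 1, 50.0)
        analytic = 4.0 / 3.0 * np.pi * r_um ** 3
        assert abs(vol - analytic) < 0.05 * analytic

    def test_absent_id_rejected(self):
        with pytest.raises(KeyError):
            mm.segment_volume(np.zeros((3, 3, 3), np.int64), 1)


@pytest.fixture(scope="module")
def puncta_image():
    """25 diffraction-limited spots at known positions, peak SNR ~10."""
    rng = np.random.default_rng(7)
    shape = (40, 120, 120)
    positions = []
    for i in range(5):
        for j in range(5):
            positions.append([20 + rng.uniform(-6, 6),
                              20 + 20 * i + rng.uniform(-3, 3),
                              20 + 20 * j + rng.uniform(-3, 3)])
    positions = np.array(positions) * 50.0  # nm
    density = np.zeros(shape)
    for p in positions:
        v = np.round(p / 50.0).astype(int)
        density[tuple(v)] = 400.0
    kernel = np.zeros((25, 13, 13))
    kernel[12, 6, 6] = 1.0
    kernel = ndimage.gaussian_filter(kernel, (6.0, 2.4, 2.4))
    img = acq.image_volume(density, kernel, dwell_us=10.0,
                           brightness_scale=1.0, background_rate=0.04,
                           seed=3)
    return img.counts, positions


class TestDetectPuncta:
    def test_blank_image_yields_nothing(self):
        assert mm.detect_puncta(np.zeros((10, 20, 20))) == []

    def test_simulated_puncta_recovered(self, puncta_image):
        counts, positions = puncta_image
        detections = mm.detect_puncta(counts, log_scale_nm=150.0)
        hits, used = 0, set()
        spurious = 0
        for pos, _ in detections:
            d = np.linalg.norm(positions - pos, axis=1)
            i = int(np.argmin(d))
            if d[i] <= 100.0 and i not in used:
                hits += 1
                used.add(i)
            else:
                spurious += 1
        assert hits >= 24
        assert spurious <= 1

    def test_detection_equivariant_under_translation(self, puncta_image):
        counts, _ = puncta_image
        shift = (0, 5, -3)
        shifted = np.roll(counts, shift, axis=(0, 1, 2))
        base = {tuple(np.round(p / 50).astype(int))
                for p, _ in mm.detect_puncta(counts, 150.0)}
        moved = {tuple(np.round(p / 50).astype(int) - np.array(shift))
                 for p, _ in mm.detect_puncta(shifted, 150.0)}
        overlap = len(base & moved) / max(len(base), 1)
        assert overlap >= 0.9  # roll wrap-around may disturb edge spots


class TestAssignPuncta:
    def test_phantom_puncta_assigned_to_generators(self, default_phantom):
        assignments = mm.assign_puncta(default_phantom.puncta,
                                       default_phantom.labels,
                                       default_phantom.structures)
        correct = sum(
            1 for a, q in zip(assignments, default_phantom.puncta)
            if a.assigned_segment_id == q.target_structure_id)
        assert correct / len(assignments) >= 0.95

    def test_head_puncta_classified_as_spine_head(self, default_phantom):
        assignments = mm.assign_puncta(default_phantom.puncta,
                                       default_phantom.labels,
                                       default_phantom.structures)
        head_cases = [(a, q) for a, q in
                      zip(assignments, default_phantom.puncta)
                      if q.site == "spine_head"
                      and a.assigned_segment_id == q.target_structure_id]
        ok = sum(1 for a, _ in head_cases if a.site == "spine_head")
        assert ok / len(head_cases) >= 0.9

    def test_remote_punctum_unassigned(self, small_phantom):
        # a synthetic punctum far outside every structure's reach
        labels = np.zeros((20, 20, 20), np.int64)
        labels[0, 0, 0] = 1
        out = mm.assign_puncta([np.array([900.0, 900.0, 900.0])], labels)
        assert out[0].site == "unassigned"
        assert out[0].assigned_segment_id is None


class TestNormalizeTrace:
    def test_constant_movie_is_unity(self):
        frames = np.full((5, 8, 8), 13.0)
        np.testing.assert_allclose(mm.normalize_trace(frames), 1.0)

    def test_frame_mean_arithmetic(self):
        frames = np.stack([np.full((4, 4), v) for v in (10.0, 15.0, 5.0)])
        np.testing.assert_allclose(mm.normalize_trace(frames),
                                   [1.0, 1.5, 0.5])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        frames = rng.random((6, 10, 10)) + 0.5
        roi = np.zeros((10, 10), bool)
        roi[3:7, 3:7] = True
        a = mm.normalize_trace(frames, roi)
        b = mm.normalize_trace(3.7 * frames, roi)
        np.testing.assert_allclose(a, b)

    def test_zero_first_frame_rejected(self):
        frames = np.zeros((3, 4, 4))
        with pytest.raises(ValueError):
            mm.normalize_trace(frames)
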