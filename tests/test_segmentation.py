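"""Segmentation: preprocessing, affinities, watershed, agglomeration."""

import numpy as np
import pytest

from shadowseg import acquisition as acq
from shadowseg import phantom as ph
from shadowseg import segmentation as seg
from skimage.metrics import adapted_rand_error


class TestPreprocess:
    def test_full_range_integers_pass_through(self):
        v = np.arange(256, dtype=float).reshape(4, 8, 8)
        out = seg.preprocess(v)
        np.testing.assert_array_equal(out.ravel(), np.arange(256))

    def test_linear_map_arithmetic(self):
        out = seg.preprocess(np.array([[[2.0, 6.0, 10.0]]]))
        np.testing.assert_array_equal(out, [[[0, 128, 255]]])

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.random((5, 5, 5))
        out = seg.preprocess(v)
        order = np.argsort(v.ravel())
        assert np.all(np.diff(out.ravel()[order].astype(int)) >= 0)

    def test_constant_volume_maps_to_zero(self):
        out = seg.preprocess(np.full((3, 3, 3), 7.0))
        assert out.max() == 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            seg.preprocess(np.array([[[np.nan, 1.0]]]))


class TestIntensityAffinities:
    def test_all_dark_volume_gives_unit_affinities(self):
        aff = seg.affinities_from_intensity(np.zeros((4, 4, 4), np.uint8))
        # in-bounds edges all 1, volume-leaving edges 0
        assert np.all(aff.values[0, :-1] == 1.0)
        assert np.all(aff.values[0, -1] == 0.0)

    def test_bright_plane_blocks_z_edges(self):
        v = np.zeros((6, 6, 6), np.uint8)
        v[3] = 255
        aff = seg.affinities_from_intensity(v)
        assert np.all(aff.values[0, 2] < 0.05)  # edges into the plane
        assert np.all(aff.values[0, 3] < 0.05)  # edges out of the plane
        assert np.all(aff.values[0, 0] > 0.95)

    def test_instance_edges_separate_from_cleft_edges(self, small_phantom,
                                                      acquisition_psf):
        # oracle: ground-truth edge classes from the phantom
        density = ph.dye_density(small_phantom)
        high = acq.image_volume(density, acquisition_psf, 70.0, seed=1)
        from shadowseg import restoration as res
        restored = res.restore_baseline(high, 1.0)
        vol8 = seg.preprocess(restored)
        aff = seg.affinities_from_intensity(vol8).values
        labels = small_phantom.labels
        within_vals, cross_vals = [], []
        for c in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[c] = slice(0, -1)
            sl_b[c] = slice(1, None)
            a, b = labels[tuple(sl_a)], labels[tuple(sl_b)]
            av = aff[(c,) + tuple(sl_a)]
            within_vals.append(av[(a == b) & (a > 0)])
            cross_vals.append(av[(a > 0) ^ (b > 0)])  # instance-ECS edges
        within = np.concatenate(within_vals).mean()
        cross = np.concatenate(cross_vals).mean()
        assert within - cross >= 0.5


@pytest.fixture(scope="module")
def trained_setup(small_phantom, acquisition_psf):
    density = ph.dye_density(small_phantom)
    high = acq.image_volume(density, acquisition_psf, 70.0, seed=1)
    from shadowseg import restoration as res
    vol8 = seg.preprocess(res.restore_baseline(high, 1.0))
    gt = ph.ground_truth_affinities(small_phantom.labels)
    model = seg.train_affinity_model([vol8], [gt], n_samples=30000, seed=0)
    return vol8, gt, model


class TestModelAffinities:
    def test_outputs_clipped_to_unit_interval(self, trained_setup):
        vol8, _, model = trained_setup
        aff = seg.affinities_from_model(vol8, model)
        assert aff.values.min() >= 0.0 and aff.values.max() <= 1.0

    def test_tta_of_mirror_symmetric_input_matches_single_pass(self):
        # symmetric texture: TTA average must equal the single inference
        v = np.zeros((6, 8, 8), np.uint8)
        v[:, 3:5, :] = 200  # mirror-symmetric along every axis
        model = seg.AffinityModel(
            weights=[np.full(54, 0.01)] * 3, biases=[0.1, 0.2, 0.3])
        plain = seg.affinities_from_model(v, model, tta_mirror=False)
        tta = seg.affinities_from_model(v, model, tta_mirror=True)
        np.testing.assert_allclose(tta.values, plain.values, atol=1e-6)

    def test_trained_backend_beats_intensity_on_edge_auc(
            self, trained_setup, small_phantom_config, acquisition_psf):
        # held-out phantom; oracle = its ground-truth edge labels
        import dataclasses
        from sklearn.metrics import roc_auc_score
        from shadowseg import restoration as res
        _, _, model = trained_setup
        cfg = dataclasses.replace(small_phantom_config, seed=17)
        other = ph.generate_phantom(cfg)
        high = acq.image_volume(ph.dye_density(other), acquisition_psf, 70.0,
                                seed=2)
        vol8 = seg.preprocess(res.restore_baseline(high, 1.0))
        gt = ph.ground_truth_affinities(other.labels)
        pred_model = seg.affinities_from_model(vol8, model).values
        pred_intensity = seg.affinities_from_intensity(vol8).values
        rng = np.random.default_rng(0)
        idx = rng.integers(0, gt.size, size=200000)
        y = gt.ravel()[idx]
        auc_model = roc_auc_score(y, pred_model.ravel()[idx])
        auc_intensity = roc_auc_score(y, pred_intensity.ravel()[idx])
        assert auc_model > auc_intensity

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            seg.affinities_from_model(np.zeros((4, 4, 4), np.uint8),
                                      seg.AffinityModel())


class TestSliceWatershed:
    def test_zero_affinity_gives_no_fragments(self):
        aff = seg.AffinityMap(np.zeros((3, 4, 8, 8), np.float32))
        frags = seg.slice_watershed(aff)
        assert frags.labels.max() == 0

    def test_two_separated_squares_give_two_fragments(self):
        # oracle: brute-force connected components at the seed threshold
        b = np.ones((1, 9, 9), np.float32)  # bright everywhere
        b[0, 2:7, 1:4] = 0.0
        b[0, 2:7, 5:8] = 0.0
        aff = seg.AffinityMap(seg._edge_affinities(b))
        frags = seg.slice_watershed(aff)
        ids = np.unique(frags.labels[frags.labels > 0])
        assert len(ids) == 2
        from scipy import ndimage
        support = seg._in_slice_boundaryness(aff)
        _, n_cc = ndimage.label(support[0] > 0.6)
        assert n_cc == 2

    def test_fragments_live_in_single_slices(self, small_phantom):
        aff = seg.AffinityMap(ph.ground_truth_affinities(small_phantom.labels))
        frags = seg.slice_watershed(aff)
        for fid in np.unique(frags.labels[frags.labels > 0])[:50]:
            zs = np.unique(np.nonzero(frags.labels == fid)[0])
            assert len(zs) == 1


def brute_force_agglomerate(edges, theta):
    """Exhaustive simulation of the greedy merge rule on a tiny graph.

    edges: {(a, b): (affinity_sum, edge_count)}; returns the final
    partition as a mapping fragment -> group representative.
    """
    groups = {}
    for a, b in edges:
        groups.setdefault(a, {a})
        groups.setdefault(b, {b})
    pool = {frozenset((a, b)): list(sn) for (a, b), sn in edges.items()}

    def rep(x):
        return min(groups[x])

    while True:
        best = None
        for key, (s, n) in pool.items():
            ga, gb = (rep(x) for x in sorted(key))
            if ga == gb:
                continue
            score = s / n
            cand = (-score, min(ga, gb), max(ga, gb))
            if best is None or cand < best[0]:
                best = (cand, key)
        if best is None or -best[0][0] < theta:
            break
        key = best[1]
        a, b = sorted(key)
        merged = groups[rep(a)] | groups[rep(b)]
        for m in merged:
            groups[m] = merged
        # recompute pooled edges between the new group and the rest
        new_pool = {}
        for k, (s, n) in pool.items():
            x, y = sorted(k)
            gx, gy = rep(x), rep(y)
            if gx == gy:
                continue
            nk = frozenset((gx, gy))
            if nk in new_pool:
                new_pool[nk][0] += s
                new_pool[nk][1] += n
            else:
                new_pool[nk] = [s, n]
        pool = new_pool
    return {x: rep(x) for x in groups}


class TestAgglomerate:
    def _run_pair(self, fragment_labels, affinities, theta):
        frags = seg.FragmentVolume(fragment_labels)
        amap = seg.AffinityMap(affinities)
        result = seg.agglomerate(frags, amap, theta)
        edges = seg._fragment_graph(fragment_labels, affinities)
        oracle = brute_force_agglomerate(
            {k: list(v) for k, v in edges.items()}, theta)
        return result, oracle

    def test_no_merges_when_threshold_unreachable(self):
        frag = np.zeros((2, 2, 4), np.int64)
        frag[:, :, :2] = 1
        frag[:, :, 2:] = 2
        aff = np.full((3, 2, 2, 4), 0.5, np.float32)
        result = seg.agglomerate(seg.FragmentVolume(frag),
                                 seg.AffinityMap(aff), 0.9)
        assert result.labels.max() == 2  # nothing merged

    def test_total_merge_at_low_threshold(self):
        frag = np.zeros((2, 2, 4), np.int64)
        frag[:, :, :2] = 1
        frag[:, :, 2:] = 2
        aff = np.full((3, 2, 2, 4), 0.9, np.float32)
        result = seg.agglomerate(seg.FragmentVolume(frag),
                                 seg.AffinityMap(aff), 0.01)
        assert len(np.unique(result.labels[result.labels > 0])) == 1

    @pytest.mark.parametrize("graph_seed", range(6))
    def test_matches_brute_force_oracle_on_small_graphs(self, graph_seed):
        # <= 6 fragments laid out as z-columns with random affinities
        rng = np.random.default_rng(graph_seed)
        n_frag = int(rng.integers(3, 7))
        frag = np.zeros((1, 1, 2 * n_frag), np.int64)
        for i in range(n_frag):
            frag[0, 0, 2 * i:2 * i + 2] = i + 1
        aff = np.zeros((3, 1, 1, 2 * n_frag), np.float32)
        aff[2] = rng.random((1, 1, 2 * n_frag)).astype(np.float32)
        result, oracle = self._run_pair(frag, aff, theta=0.3)
        # compare partitions up to relabeling
        for i in range(1, n_frag + 1):
            for j in range(i + 1, n_frag + 1):
                together = oracle[i] == oracle[j]
                lab_i = result.labels[frag == i][0]
                lab_j = result.labels[frag == j][0]
                assert (lab_i == lab_j) == together

    def test_threshold_monotonicity_refinement(self, small_phantom):
        aff = seg.AffinityMap(
            ph.ground_truth_affinities(small_phantom.labels)
            * 0.9)  # scale so scores spread below 1
        frags = seg.slice_watershed(aff)
        low = seg.agglomerate(frags, aff, 0.2)
        high = seg.agglomerate(frags, aff, 0.4)
        # the theta=0.4 partition refines the theta=0.2 partition
        fg = frags.labels > 0
        pairs = set(zip(high.labels[fg].ravel(), low.labels[fg].ravel()))
        mapping = {}
        for h, lo_l in pairs:
            assert mapping.setdefault(h, lo_l) == lo_l
        assert high.n_instances >= low.n_instances

    def test_invalid_threshold_rejected(self, small_phantom):
        aff = seg.AffinityMap(ph.ground_truth_affinities(small_phantom.labels))
        frags = seg.slice_watershed(aff)
        with pytest.raises(ValueError):
            seg.agglomerate(frags, aff, 0.0)


class TestPostprocess:
    def _toy(self):
        # segments: 5 voxels; 9 voxels; 10 voxels in 1 slice;
        # 10 voxels in 2 slices; 200 voxels
        labels = np.zeros((4, 10, 40), np.int64)
        labels[0, 0, :5] = 1
        labels[0, 1, :9] = 2
        labels[0, 2, :10] = 3
        labels[0:2, 3, :5] = 4
        labels[1:3, 5:10, 0:20] = 5
        return labels

    def test_hand_counted_survivors(self):
        out = seg.postprocess(seg.InstanceSegmentation(self._toy()),
                              min_voxels=10, min_slices=2)
        survivors = np.unique(out.labels[out.labels > 0])
        assert len(survivors) == 2  # only the 10-voxel/2-slice and the 200

    def test_boundary_cases_of_voxel_filter(self):
        labels = np.zeros((3, 5, 10), np.int64)
        labels[0:2, 0, :5] = 1  # 10 voxels across 2 slices -> kept
        labels[0, 2, :9] = 2    # 9 voxels -> removed
        out = seg.postprocess(seg.InstanceSegmentation(labels))
        kept = np.unique(out.labels[out.labels > 0])
        assert len(kept) == 1
        assert np.all(out.labels[labels == 2] == 0)

    def test_single_slice_segment_removed(self):
        labels = np.zeros((3, 5, 10), np.int64)
        labels[1, 1, :20 // 2] = 1
        labels[1, 2, :10] = 1  # 20 voxels, all in z-plane 1
        out = seg.postprocess(seg.InstanceSegmentation(labels))
        assert out.labels.max() == 0

    def test_ids_compacted_in_size_order(self):
        labels = np.zeros((4, 8, 30), np.int64)
        labels[0:2, 0, :10] = 7   # 20 voxels
        labels[0:3, 3, :20] = 9   # 60 voxels
        out = seg.postprocess(seg.InstanceSegmentation(labels))
        assert set(np.unique(out.labels)) == {0, 1, 2}
        assert np.all(out.labels[labels == 9] == 1)  # biggest first

    def test_disconnected_label_split_before_filtering(self):
        labels = np.zeros((4, 6, 20), np.int64)
        labels[0:2, 0, :8] = 3
        labels[0:2, 4, 12:] = 3  # same id, far apart -> two components
        out = seg.postprocess(seg.InstanceSegmentation(labels),
                              min_voxels=10, min_slices=2)
        assert out.n_instances == 2


class TestECS:
    def test_empty_segmentation_is_all_ecs(self):
        mask, fraction, volume = seg.ecs_mask(np.zeros((4, 4, 4), np.int64))
        assert fraction == 1.0
        assert mask.all()

    def test_printed_organoid_numbers_give_13_percent(self):
        report = seg.summarize_ecs(unoccupied_um3=225.0, total_um3=1737.0)
        assert report["percent"] == 13

    def test_mask_and_labels_partition_grid(self, small_phantom):
        mask, fraction, volume = seg.ecs_mask(small_phantom.labels)
        assert np.all(mask ^ (small_phantom.labels > 0))
        assert fraction == pytest.approx(small_phantom.ecs_fraction)

    def test_volume_arithmetic(self):
        labels = np.zeros((10, 10, 10), np.int64)
        labels[:5] = 1
        _, fraction, volume = seg.ecs_mask(labels, voxel_size_nm=50.0)
        assert fraction == 0.5
        assert volume == pytest.approx(500 * (0.05 ** 3))

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            seg.summarize_ecs(10.0, 5.0)


class TestSegmentPipeline:
    def test_deterministic_given_seed(self, small_phantom, acquisition_psf):
        density = ph.dye_density(small_phantom)
        high = acq.image_volume(density, acquisition_psf, 70.0, seed=1)
        a = seg.segment_pipeline(high)
        b = seg.segment_pipeline(high)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_ground_truth_affinity_recovery(self, small_phantom):
        # oracle equivalence: noiseless affinities recover the phantom
        # partition up to postprocessing-removed tiny segments
        aff = seg.AffinityMap(ph.ground_truth_affinities(small_phantom.labels))
        frags = seg.slice_watershed(aff)
        result = seg.postprocess(seg.agglomerate(frags, aff, 0.3))
        mask = (small_phantom.labels > 0) & (result.labels > 0)
        are = adapted_rand_error(small_phantom.labels[mask].astype(int),
                                 result.labels[mask].astype(int))[0]
        assert are < 0.02

    def test_lower_threshold_merges_more(self, small_phantom,
                                         acquisition_psf):
        density = ph.dye_density(small_phantom)
        high = acq.image_volume(density, acquisition_psf, 70.0, seed=1)
        n_02 = seg.segment_pipeline(
            high, seg.SegmentationParams(threshold=0.2)).n_instances
        n_04 = seg.segment_pipeline(
            high, seg.SegmentationParams(threshold=0.4)).n_instances
        assert n_02 <= n_04

    def test_inverted_input_handled(self, small_phantom, acquisition_psf):
        density = ph.dye_density(small_phantom)
        high = acq.image_volume(density, acquisition_psf, 70.0, seed=1)
        direct = seg.segment_pipeline(high)
        via_inverted = seg.segment_pipeline(acq.invert_counts(high))
        np.testing.assert_array_equal(direct.labels, via_inverted.labels)
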