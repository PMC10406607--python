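"""Evaluation of segmentations and tracings against ground truth.

Partition metrics (adapted Rand error, variation of information, split
ratios), spine-detection scoring with the +1 / -1 / +0.5 rule,
skeleton-walk tracing metrics (error-free path length, corrections per
mm), and morphodynamics comparison of single-structure masks
(IoU and surface displacement after optional rigid alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import adapted_rand_error, variation_of_information

from .phantom import Skeleton


@dataclass
class PartitionMetrics:
    adapted_rand_error: float
    voi_split: float  # bits, oversegmentation term H(pred | gt)
    voi_merge: float  # bits, undersegmentation term H(gt | pred)
    split_ratios: dict[int, int]  # GT id -> number of covering pred labels
    size_histogram: np.ndarray  # predicted segment sizes (voxels)

    @property
    def voi_total(self) -> float:
        return self.voi_split + self.voi_merge

    @property
    def split_ratio_mean(self) -> float:
        if not self.split_ratios:
            return 0.0
        return float(np.mean(list(self.split_ratios.values())))


@dataclass
class SpineScore:
    """+1 per correct spine, -1 per false positive, +0.5 when the spine
    was found but its head missed."""

    n_ground_truth: int
    n_correct: int
    n_false_positive: int
    n_half: int

    @property
    def percent(self) -> float:
        if self.n_ground_truth == 0:
            return 0.0
        return 100.0 * (self.n_correct + 0.5 * self.n_half
                        - self.n_false_positive) / self.n_ground_truth


@dataclass
class TracingResult:
    total_gt_length_um: float
    correctly_traced_um: float
    error_free_segments_um: list[float]
    n_events: int

    @property
    def corrections_per_mm(self) -> float:
        mm = self.total_gt_length_um / 1e3
        return self.n_events / mm if mm > 0 else 0.0

    @property
    def mean_error_free_um(self) -> float:
        if not self.error_free_segments_um:
            return 0.0
        return float(np.mean(self.error_free_segments_um))


def _labels_of(seg) -> np.ndarray:
    return seg.labels if hasattr(seg, "labels") else np.asarray(seg)


def partition_metrics(gt, pred, overlap_floor: float = 0.02
                      ) -> PartitionMetrics:
    """Compare two instance segmentations on their joint foreground.

    Background (0) is excluded from both volumes.  The split ratio of a
    ground-truth segment is the number of distinct predicted labels each
    covering at least ``overlap_floor`` of its voxels.
    """
    g = _labels_of(gt)
    p = _labels_of(pred)
    if g.shape != p.shape:
        raise ValueError("segmentations must share the same grid")
    mask = (g > 0) & (p > 0)
    gm = g[mask].astype(np.int64)
    pm = p[mask].astype(np.int64)
    if gm.size == 0:
        raise ValueError("no joint foreground to compare")
    are = adapted_rand_error(gm.reshape(1, -1), pm.reshape(1, -1))[0]
    # skimage returns (H(im1|im0), H(im0|im1)) in that order
    voi_split, voi_merge = variation_of_information(gm.reshape(1, -1),
                                                    pm.reshape(1, -1))
    split_ratios: dict[int, int] = {}
    for gid in np.unique(gm):
        sub = pm[gm == gid]
        vals, counts = np.unique(sub, return_counts=True)
        split_ratios[int(gid)] = int(np.sum(counts >= overlap_floor
                                            * len(sub)))
    sizes = np.bincount(p[p > 0].ravel())
    return PartitionMetrics(float(are), float(voi_split), float(voi_merge),
                            split_ratios, sizes[sizes > 0])


def spine_detection_score(gt_spines, detections,
                          match_radius_nm: float = 500.0) -> SpineScore:
    """Score detected spines against ground truth.

    ``gt_spines``: base positions (nm).  ``detections``: (position,
    has_head) pairs.  Matching is one-to-one, greedy by distance within
    ``match_radius_nm``.  Matched with head -> +1; matched but head
    missed -> +0.5; unmatched detection -> -1 (false positive).
    """
    gt_pos = np.asarray([np.asarray(p, dtype=float) for p in gt_spines])
    det_pos = [np.asarray(p, dtype=float) for p, _ in detections]
    det_head = [bool(h) for _, h in detections]
    pairs = []
    for i, gp in enumerate(gt_pos):
        for j, dp in enumerate(det_pos):
            d = float(np.linalg.norm(gp - dp))
            if d <= match_radius_nm:
                pairs.append((d, i, j))
    pairs.sort()
    used_gt, used_det = set(), set()
    n_correct = n_half = 0
    for d, i, j in pairs:
        if i in used_gt or j in used_det:
            continue
        used_gt.add(i)
        used_det.add(j)
        if det_head[j]:
            n_correct += 1
        else:
            n_half += 1
    n_fp = len(det_pos) - len(used_det)
    return SpineScore(n_ground_truth=len(gt_pos), n_correct=n_correct,
                      n_false_positive=n_fp, n_half=n_half)


def aggregate_spine_scores(scores: list[SpineScore]) -> dict:
    """Mean and s.d. of per-stretch percentages (as reported per
    dendrite stretch in validation figures)."""
    percents = np.array([s.percent for s in scores])
    return {"mean_percent": float(percents.mean()),
            "sd_percent": float(percents.std(ddof=1)) if len(percents) > 1
            else 0.0,
            "n_stretches": len(percents)}


def _walk_skeleton(skel: Skeleton, step_nm: float) -> np.ndarray:
    """Resample the skeleton's principal path at step_nm spacing (nm)."""
    # follow the node order for path skeletons; fall back to node list
    nodes = skel.nodes
    pts = [nodes[0]]
    for i, j in skel.edges:
        pts.append(nodes[j])
    pts = np.asarray(pts)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    samples = np.arange(0.0, arc[-1] + step_nm / 2, step_nm)
    out = np.empty((len(samples), 3))
    for a in range(3):
        out[:, a] = np.interp(samples, arc, pts[:, a])
    return out


def tracing_metrics(gt_skeletons: list[Skeleton] | Skeleton, pred,
                    step_nm: float = 100.0,
                    voxel_size_nm: float = 50.0) -> TracingResult:
    """Walk ground-truth skeletons through a predicted segmentation.

    At each step the dominant predicted label in a 1-voxel-radius
    neighborhood is recorded.  A split event occurs where the dominant
    label hands over to a different positive label; a merge event is
    counted for every extra skeleton sharing a predicted label.
    Error-free segments are maximal runs between events whose label is
    not shared across skeletons; with a single skeleton only splits are
    detected.
    """
    if isinstance(gt_skeletons, Skeleton):
        gt_skeletons = [gt_skeletons]
    labels = _labels_of(pred)
    shape = np.array(labels.shape)
    nbr_offsets = np.array([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]])

    per_skel_runs = []  # list of lists of (label, length_um)
    total_um = 0.0
    for skel in gt_skeletons:
        pts = _walk_skeleton(skel, step_nm)
        if np.any(pts < 0) or np.any(pts / voxel_size_nm >= shape):
            raise ValueError("skeleton leaves the segmented volume")
        total_um += (len(pts) - 1) * step_nm / 1e3
        runs: list[list] = []  # [label, length_um]
        for p in pts:
            vox = np.round(p / voxel_size_nm).astype(int)
            nbrs = np.clip(vox + nbr_offsets, 0, shape - 1)
            vals = labels[nbrs[:, 0], nbrs[:, 1], nbrs[:, 2]]
            vals = vals[vals > 0]
            if len(vals) == 0:
                continue  # unlabeled gap: does not establish an identity
            dom = int(np.bincount(vals).argmax())
            if runs and runs[-1][0] == dom:
                runs[-1][1] += step_nm / 1e3
            else:
                runs.append([dom, step_nm / 1e3])
        per_skel_runs.append(runs)

    # merges: predicted labels claimed by more than one skeleton
    claims: dict[int, int] = {}
    for runs in per_skel_runs:
        for lab in {lab for lab, _ in runs}:
            claims[lab] = claims.get(lab, 0) + 1
    shared = {lab for lab, n in claims.items() if n > 1}
    n_merge = sum(n - 1 for n in claims.values() if n > 1)
    n_split = sum(max(len(runs) - 1, 0) for runs in per_skel_runs)

    segments = [length for runs in per_skel_runs
                for lab, length in runs if lab not in shared]
    return TracingResult(
        total_gt_length_um=total_um,
        correctly_traced_um=float(sum(segments)),
        error_free_segments_um=segments,
        n_events=n_split + n_merge,
    )


@dataclass
class MorphoComparison:
    iou: float
    p95_displacement_nm: float
    shift_voxels: tuple[int, int, int] = (0, 0, 0)


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def morphodynamics_compare(mask_a: np.ndarray, mask_b: np.ndarray,
                           align: bool = True, search_voxels: int = 4,
                           voxel_size_nm: float = 50.0) -> MorphoComparison:
    """Compare two single-structure masks (e.g. the same spine at two
    time points, or a duplicate-split restoration control).

    Optionally aligns by the integer translation maximizing IoU, then
    reports IoU and the 95th-percentile surface displacement (symmetric,
    via distance transforms of both surfaces).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("masks must be non-empty")
    best_shift = (0, 0, 0)
    if align:
        best = -1.0
        for dz in range(-search_voxels, search_voxels + 1):
            for dy in range(-search_voxels, search_voxels + 1):
                for dx in range(-search_voxels, search_voxels + 1):
                    shifted = np.roll(b, (dz, dy, dx), axis=(0, 1, 2))
                    score = _iou(a, shifted)
                    if score > best:
                        best, best_shift = score, (dz, dy, dx)
        b = np.roll(b, best_shift, axis=(0, 1, 2))
    iou = _iou(a, b)

    def surface(m):
        return m & ~ndimage.binary_erosion(m)

    sa, sb = surface(a), surface(b)
    disp = []
    for src, dst in ((sa, sb), (sb, sa)):
        dist = ndimage.distance_transform_edt(~dst)
        disp.append(dist[src])
    disp = np.concatenate(disp) * voxel_size_nm
    p95 = float(np.percentile(disp, 95)) if disp.size else 0.0
    return MorphoComparison(iou=iou, p95_displacement_nm=p95,
                            shift_voxels=best_shift)
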