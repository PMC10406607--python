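"""Restoration of low-exposure photon-count volumes.

Two restorers share one interface:

* a deterministic variance-stabilizing baseline (Anscombe transform,
  Gaussian smoothing, exact unbiased inverse) that needs no training and
  anchors all downstream validation, and
* a trainable patch-regressor ensemble: linear 3D receptive-field models
  fitted on voxel-exact low/high dwell pairs (target = high / dwell
  ratio, so input and target share the count-rate scale).  Ensemble
  members differ only by training seed; their per-voxel disagreement is
  the restoration-uncertainty readout.

A blind-spot mode (self-supervised, center voxel excluded from its own
prediction) covers denoising of single confocal channels where no paired
high-SNR acquisition exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import PairedAcquisition, PhotonImage


@dataclass
class RestoredVolume:
    """Restored intensity on the photon-count scale of the input dwell."""

    values: np.ndarray  # float, >= 0
    source_dwell_us: float
    model_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("restored volume must be finite")


@dataclass
class RestorationModel:
    """Restorer description plus (for trained kinds) member kernels."""

    kind: str = "vst_baseline"  # vst_baseline | patch_regressor_ensemble | blind_spot
    patch_size: int = 32  # training patches are sampled inside such blocks
    receptive_field: int = 5  # linear kernel edge (voxels)
    n_members: int = 1
    smoothing_scale: float = 1.0  # baseline Gaussian sigma, voxels
    members: list[tuple[np.ndarray, float]] = field(default_factory=list)
    training_meta: dict = field(default_factory=dict)


@dataclass
class UncertaintyMap:
    values: np.ndarray  # >= 0
    kind: str = "ensemble_disagreement"


def anscombe(x: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform for Poisson counts."""
    return 2.0 * np.sqrt(np.asarray(x, dtype=float) + 3.0 / 8.0)


def anscombe_inverse_unbiased(d: np.ndarray) -> np.ndarray:
    """Closed-form exact unbiased inverse of the Anscombe transform."""
    d = np.asarray(d, dtype=float)
    d = np.maximum(d, 1e-8)
    inv = (0.25 * d ** 2 - 0.125
           + 0.25 * np.sqrt(1.5) / d
           - 1.375 / d ** 2
           + 0.625 * np.sqrt(1.5) / d ** 3)
    return np.clip(inv, 0.0, None)


def restore_baseline(low: PhotonImage | np.ndarray,
                     smoothing_scale: float = 1.0) -> RestoredVolume:
    """VST baseline: Anscombe -> Gaussian smoothing -> unbiased inverse.

    ``smoothing_scale`` is the Gaussian sigma in voxels (about half the
    effective-PSF sigma by default, trading residual noise against
    resolution loss); 0 returns the input unchanged.
    """
    if isinstance(low, PhotonImage):
        if low.inverted:
            raise ValueError("revert the count inversion before restoring")
        counts = low.counts
        dwell = low.dwell_us
    else:
        counts = np.asarray(low)
        dwell = float("nan")
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    if smoothing_scale == 0:
        return RestoredVolume(counts.astype(float), dwell, "vst_baseline:s0")
    vst = anscombe(counts)
    smoothed = ndimage.gaussian_filter(vst, smoothing_scale)
    out = anscombe_inverse_unbiased(smoothed)
    return RestoredVolume(out, dwell, f"vst_baseline:s{smoothing_scale:g}")


def _neighborhood_design(vst: np.ndarray, coords: np.ndarray,
                         rf: int) -> np.ndarray:
    half = rf // 2
    offs = np.mgrid[-half:half + 1, -half:half + 1, -half:half + 1]
    offs = offs.reshape(3, -1).T  # (rf^3, 3)
    cols = []
    for off in offs:
        idx = coords + off
        cols.append(vst[idx[:, 0], idx[:, 1], idx[:, 2]])
    return np.stack(cols, axis=1)


def train_restorer(pairs: list[PairedAcquisition],
                   model: RestorationModel | None = None,
                   n_members: int = 3, samples_per_member: int = 20000,
                   seed: int = 0) -> RestorationModel:
    """Fit the linear patch-regressor ensemble on low/high dwell pairs.

    Each member solves a ridge regression from the Anscombe-transformed
    low-exposure neighborhood (receptive field, default 5^3 voxels) to
    the Anscombe-transformed dwell-ratio-scaled high target; members
    differ only by the seed of their patch sample.  Deterministic per
    seed.
    """
    if not pairs:
        raise ValueError("at least one training pair is required")
    model = model or RestorationModel(kind="patch_regressor_ensemble",
                                      n_members=n_members)
    rf = model.receptive_field
    half = rf // 2
    blind = model.kind == "blind_spot"
    members = []
    for m in range(model.n_members):
        rng = np.random.default_rng([seed, 23, m])
        design_blocks, target_blocks = [], []
        for pair in pairs:
            low = pair.low.counts
            ratio = pair.low.dwell_us / pair.high.dwell_us
            target = anscombe(pair.high.counts * ratio)
            vst = anscombe(low)
            n = samples_per_member // len(pairs)
            coords = np.stack([
                rng.integers(half, s - half, size=n)
                for s in low.shape], axis=1)
            design_blocks.append(_neighborhood_design(vst, coords, rf))
            target_blocks.append(target[coords[:, 0], coords[:, 1],
                                        coords[:, 2]])
        x = np.concatenate(design_blocks)
        y = np.concatenate(target_blocks)
        if blind:
            x[:, x.shape[1] // 2] = 0.0  # mask the centre voxel
        xm, ym = x.mean(axis=0), y.mean()
        xc, yc = x - xm, y - ym
        gram = xc.T @ xc + 1e-3 * len(y) * np.eye(x.shape[1])
        w = np.linalg.solve(gram, xc.T @ yc)
        b = float(ym - xm @ w)
        kernel = w.reshape(rf, rf, rf)
        if blind:
            kernel[half, half, half] = 0.0
        members.append((kernel, b))
    model.members = members
    model.training_meta = {"n_pairs": len(pairs), "seed": seed,
                           "samples_per_member": samples_per_member}
    return model


def _predict_member(counts: np.ndarray, kernel: np.ndarray,
                    bias: float) -> np.ndarray:
    vst_pred = ndimage.correlate(anscombe(counts), kernel[::-1, ::-1, ::-1],
                                 mode="nearest") + bias
    return anscombe_inverse_unbiased(vst_pred)


def apply_restorer(model: RestorationModel,
                   low: PhotonImage | np.ndarray) -> RestoredVolume:
    """Restore a low-exposure volume; ensemble mean if n_members > 1."""
    if model.kind == "vst_baseline":
        return restore_baseline(low, model.smoothing_scale)
    if not model.members:
        raise ValueError("model has not been trained")
    counts = low.counts if isinstance(low, PhotonImage) else np.asarray(low)
    dwell = low.dwell_us if isinstance(low, PhotonImage) else float("nan")
    preds = [_predict_member(counts, k, b) for k, b in model.members]
    return RestoredVolume(np.mean(preds, axis=0), dwell,
                          f"{model.kind}:n{len(model.members)}")


def ensemble_disagreement(model: RestorationModel,
                          low: PhotonImage | np.ndarray) -> UncertaintyMap:
    """Per-voxel standard deviation across member predictions."""
    if model.kind == "vst_baseline" or len(model.members) < 2:
        raise ValueError("ensemble disagreement needs >= 2 trained members")
    counts = low.counts if isinstance(low, PhotonImage) else np.asarray(low)
    preds = np.stack([_predict_member(counts, k, b)
                      for k, b in model.members])
    return UncertaintyMap(preds.std(axis=0))


def restoration_report(restored: RestoredVolume | np.ndarray,
                       high_reference: PhotonImage | np.ndarray,
                       noiseless_rate: np.ndarray | None = None,
                       scale_to_reference: float = 1.0) -> dict:
    """MSE and normalized cross-correlation against the paired high-SNR
    reference, plus oracle MSE when the true noiseless rate is known."""
    r = restored.values if isinstance(restored, RestoredVolume) \
        else np.asarray(restored, dtype=float)
    h = high_reference.counts if isinstance(high_reference, PhotonImage) \
        else np.asarray(high_reference, dtype=float)
    if r.shape != h.shape:
        raise ValueError("restored and reference grids must match")
    rs = r * scale_to_reference
    mse = float(np.mean((rs - h) ** 2))
    rc = rs - rs.mean()
    hc = h - h.mean()
    denom = np.linalg.norm(rc) * np.linalg.norm(hc)
    ncc = float(rc.ravel() @ hc.ravel() / denom) if denom else 0.0
    report = {"mse": mse, "ncc": ncc}
    if noiseless_rate is not None:
        report["oracle_mse"] = float(np.mean((rs - noiseless_rate) ** 2))
    return report
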