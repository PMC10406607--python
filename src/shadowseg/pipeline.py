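"""End-to-end orchestration: phantom -> PSF -> paired acquisition ->
restoration -> segmentation -> morphometry -> evaluation.

Each stage writes its artifacts into the run directory and records a
digest in the manifest; re-running with an unchanged configuration
reuses cached stage outputs (matched by config hash), and disabling a
downstream stage leaves upstream digests untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as sio
from . import morphometry as mm
from .acquisition import image_volume, invert_counts, light_budget, split_dwell
from .config import RunConfig
from .evaluation import partition_metrics
from .optics import calibrate_isotropic
from .phantom import dye_density, generate_phantom
from .restoration import RestorationModel
from .segmentation import ecs_mask, segment_pipeline

log = logging.getLogger("shadowseg")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class RunManifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.data = {"config_hash": config_hash, "stages": {}}
        if path.exists():
            previous = json.loads(path.read_text())
            if previous.get("config_hash") == config_hash:
                self.data = previous

    def stage_done(self, name: str, files: list[Path]) -> bool:
        record = self.data["stages"].get(name)
        if not record:
            return False
        for f, d in record["files"].items():
            p = self.path.parent / f
            if not p.exists() or _digest(p) != d:
                return False
        return True

    def record(self, name: str, files: list[Path], seconds: float) -> None:
        self.data["stages"][name] = {
            "files": {f.name: _digest(f) for f in files},
            "wall_time_s": round(seconds, 2),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_end_to_end(config: RunConfig) -> RunManifest:
    """Execute all enabled stages; returns the manifest.

    Stage failures abort with :class:`StageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "manifest.json", config.config_hash())
    state: dict = {}

    def run_stage(name, fn, outputs):
        if not config.stages.get(name, True):
            log.info("stage %s disabled", name)
            return
        paths = [out / o for o in outputs]
        if manifest.stage_done(name, paths) and _reload(name, paths, state,
                                                        config):
            log.info("stage %s cached", name)
            return
        t0 = time.time()
        try:
            fn(state)
        except Exception as err:
            raise StageError(f"stage '{name}' failed: {err}") from err
        manifest.record(name, [p for p in paths if p.exists()],
                        time.time() - t0)
        log.info("stage %s done (%.1fs)", name, time.time() - t0)

    run_stage("phantom", lambda s: _stage_phantom(config, out, s),
              ["gt_labels.tif", "puncta.csv", "structures.csv"])
    run_stage("psf", lambda s: _stage_psf(config, out, s),
              ["psf.tif", "psf_report.json"])
    run_stage("acquire", lambda s: _stage_acquire(config, out, s),
              ["high.tif", "low.tif", "light_budget.json"])
    run_stage("restore", lambda s: _stage_restore(config, out, s),
              ["restored.tif"])
    run_stage("segment", lambda s: _stage_segment(config, out, s),
              ["segmentation.tif", "ecs_report.json"])
    run_stage("analyze", lambda s: _stage_analyze(config, out, s),
              ["spines.csv", "morphometry.json"])
    run_stage("evaluate", lambda s: _stage_evaluate(config, out, s),
              ["metrics.json"])
    return manifest


def _reload(name: str, paths: list[Path], state: dict,
            config: RunConfig) -> bool:
    """Re-hydrate in-memory state from cached stage outputs."""
    try:
        if name == "phantom":
            state["phantom"] = generate_phantom(_seeded_phantom_cfg(config))
        elif name == "psf":
            state["psf"] = sio.load_psf(paths[0])
        elif name == "acquire":
            state["high"] = _maybe_revert(sio.load_photon_image(paths[0]))
            state["low"] = _maybe_revert(sio.load_photon_image(paths[1]))
        elif name == "restore":
            pass  # segmentation re-derives restoration deterministically
        elif name == "segment":
            labels, _ = sio.load_labels(paths[0])
            from .segmentation import InstanceSegmentation
            state["segmentation"] = InstanceSegmentation(labels)
        return True
    except Exception:  # corrupted cache: recompute
        return False


def _maybe_revert(img):
    return invert_counts(img) if img.inverted else img


def _seeded_phantom_cfg(config: RunConfig):
    import dataclasses
    return dataclasses.replace(config.phantom,
                               seed=config.stage_seed("phantom"))


def _stage_phantom(config: RunConfig, out: Path, state: dict) -> None:
    phantom = generate_phantom(_seeded_phantom_cfg(config))
    state["phantom"] = phantom
    sio.save_labels(out / "gt_labels.tif", phantom.labels,
                    phantom.voxel_size_nm)
    sio.puncta_table(phantom).to_csv(out / "puncta.csv", index=False)
    sio.structure_table(phantom.structures).to_csv(out / "structures.csv",
                                                   index=False)
    swc_dir = out / "swc"
    swc_dir.mkdir(exist_ok=True)
    for s in phantom.structures:
        sio.write_swc(swc_dir / f"{s.kind}_{s.id}.swc", s.skeleton, s.kind)


def _stage_psf(config: RunConfig, out: Path, state: dict) -> None:
    oc = config.optics
    ext = (oc.extent_nm,) * 3
    vox = (oc.optics_voxel_nm,) * 3
    zeta, ratio, psf = calibrate_isotropic(oc.sted, oc.target_fwhm_nm,
                                           oc.pupil_samples, ext, vox)
    psf_acq = psf.resampled((config.phantom.voxel_size_nm,) * 3)
    state["psf"] = psf_acq
    sio.save_psf(out / "psf.tif", psf_acq)
    sio.save_json(out / "psf_report.json", {
        "zeta": zeta, "power_ratio_z_to_xy": list(ratio),
        "fwhm_lateral_nm": psf.fwhm_lateral,
        "fwhm_axial_nm": psf.fwhm_axial})


def _stage_acquire(config: RunConfig, out: Path, state: dict) -> None:
    ac = config.acquisition
    density = dye_density(state["phantom"])
    high = image_volume(density, state["psf"], ac.dwell_high_us,
                        ac.brightness_scale, ac.background_rate,
                        seed=config.stage_seed("acquire"),
                        voxel_size_nm=config.phantom.voxel_size_nm)
    pair = split_dwell(high, ac.dwell_low_us)
    state["high"], state["low"] = pair.high, pair.low
    for name, img in (("high.tif", pair.high), ("low.tif", pair.low)):
        stored = invert_counts(img) if ac.invert_on_save else img
        sio.save_photon_image(out / name, stored)
    sio.save_json(out / "light_budget.json",
                  light_budget(ac.dwell_low_us, ac.dwell_high_us).report())


def _restorer(config: RunConfig, dwell_us: float) -> RestorationModel:
    rc = config.restoration
    if rc.smoothing_scale is not None:
        return RestorationModel(kind=rc.kind,
                                smoothing_scale=rc.smoothing_scale)
    from .segmentation import default_restorer
    return default_restorer(dwell_us)


def _stage_restore(config: RunConfig, out: Path, state: dict) -> None:
    from .restoration import apply_restorer
    model = _restorer(config, state["low"].dwell_us)
    restored = apply_restorer(model, state["low"])
    import tifffile
    tifffile.imwrite(out / "restored.tif",
                     restored.values.astype(np.float32))


def _stage_segment(config: RunConfig, out: Path, state: dict) -> None:
    model = _restorer(config, state["low"].dwell_us)
    segmentation = segment_pipeline(state["low"], config.segmentation,
                                    restorer=model)
    state["segmentation"] = segmentation
    sio.save_labels(out / "segmentation.tif", segmentation.labels,
                    config.phantom.voxel_size_nm)
    _, fraction, volume = ecs_mask(segmentation.labels,
                                   config.phantom.voxel_size_nm)
    total = segmentation.labels.size \
        * (config.phantom.voxel_size_nm / 1e3) ** 3
    sio.save_json(out / "ecs_report.json", {
        "ecs_fraction": fraction, "ecs_volume_um3": volume,
        "total_volume_um3": total,
        "ecs_percent": int(round(100 * fraction))})


def _stage_analyze(config: RunConfig, out: Path, state: dict) -> None:
    phantom = state["phantom"]
    seg_labels = state["segmentation"].labels
    voxel = phantom.voxel_size_nm
    rows = []
    for s in phantom.spines():
        base, tip = s.skeleton.nodes[0], s.skeleton.nodes[-1]
        vox = np.clip(np.round(tip / voxel).astype(int), 0,
                      np.array(seg_labels.shape) - 1)
        pred_id = int(seg_labels[tuple(vox)])
        length = None
        if pred_id > 0:
            try:
                length = mm.central_axis_length(seg_labels, pred_id, base,
                                                tip, voxel)
            except (ValueError, KeyError):
                length = None
        rows.append({"spine_id": s.id, "dendrite_id": s.parent_id,
                     "gt_length_um": s.skeleton.path_length_nm / 1e3,
                     "predicted_segment": pred_id or None,
                     "measured_length_um": length,
                     "has_head": s.has_head})
    import pandas as pd
    table = pd.DataFrame(rows)
    table.to_csv(out / "spines.csv", index=False)
    dendrite_um = sum(s.skeleton.path_length_nm / 1e3
                      for s in phantom.structures if s.kind == "dendrite")
    measured = table["measured_length_um"].dropna() if len(table) \
        else pd.Series(dtype=float)
    sio.save_json(out / "morphometry.json", {
        "n_spines": len(rows),
        "dendrite_length_um": dendrite_um,
        "spine_density_per_um": mm.spine_density(len(rows), dendrite_um)
        if dendrite_um > 0 else None,
        "mean_spine_length_um": float(measured.mean()) if len(measured)
        else None,
    })


def _stage_evaluate(config: RunConfig, out: Path, state: dict) -> None:
    metrics = partition_metrics(state["phantom"].labels,
                                state["segmentation"].labels)
    sio.save_json(out / "metrics.json", {
        "adapted_rand_error": metrics.adapted_rand_error,
        "voi_split_bits": metrics.voi_split,
        "voi_merge_bits": metrics.voi_merge,
        "voi_total_bits": metrics.voi_total,
        "split_ratio_mean": metrics.split_ratio_mean,
        "n_predicted": int(len(metrics.size_histogram)),
    })
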