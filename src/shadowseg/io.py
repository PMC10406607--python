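"""File formats: TIFF volumes with JSON sidecars, SWC skeletons, CSV tables.

Photon-count volumes are 16-bit multi-page TIFFs (z as pages) with the
acquisition metadata (voxel size, dwell, inversion flag, seed, channel)
in a ``<name>.json`` sidecar; label volumes are 16/32-bit unsigned;
PSFs and affinities are 32-bit float.  Skeletons use SWC (one file per
structure, spine base as the root node, coordinates in nm).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import PhotonImage
from .optics import EffectivePSF
from .phantom import PhantomVolume, Skeleton, StructureRecord

_SWC_TYPES = {"soma": 1, "axon": 2, "dendrite": 3, "spine": 5, "glia": 7}


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def save_photon_image(path, img: PhotonImage) -> None:
    if img.counts.max() > 65535:
        raise OverflowError("counts exceed 16-bit TIFF range")
    tifffile.imwrite(path, img.counts.astype(np.uint16))
    meta = {"voxel_size_nm": img.voxel_size_nm, "dwell_us": img.dwell_us,
            "inverted": img.inverted, "seed": img.seed,
            "channel": img.channel,
            "detectors_summed": img.detectors_summed,
            "brightness_scale": img.brightness_scale,
            "background_rate": img.background_rate}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_photon_image(path) -> PhotonImage:
    counts = tifffile.imread(path).astype(np.int64)
    meta = json.loads(_sidecar(path).read_text())
    return PhotonImage(counts=counts, **meta)


def save_labels(path, labels: np.ndarray,
                voxel_size_nm: float = 50.0) -> None:
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 65536 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    _sidecar(path).write_text(json.dumps(
        {"voxel_size_nm": voxel_size_nm, "kind": "instance_labels"}))


def load_labels(path) -> tuple[np.ndarray, float]:
    labels = tifffile.imread(path).astype(np.int64)
    side = _sidecar(path)
    voxel = 50.0
    if side.exists():
        voxel = json.loads(side.read_text()).get("voxel_size_nm", 50.0)
    return labels, voxel


def save_psf(path, psf: EffectivePSF) -> None:
    tifffile.imwrite(path, psf.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps(
        {"voxel_size_nm": list(psf.voxel_size),
         "fwhm_lateral_nm": psf.fwhm_lateral,
         "fwhm_axial_nm": psf.fwhm_axial}, indent=1))


def load_psf(path) -> EffectivePSF:
    values = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    return EffectivePSF(values, tuple(meta["voxel_size_nm"]),
                        meta["fwhm_lateral_nm"], meta["fwhm_axial_nm"])


def save_affinities(path, affinities: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(affinities, dtype=np.float32))


def write_swc(path, skeleton: Skeleton, kind: str = "dendrite",
              root: int = 0) -> None:
    """One structure per file; parent links follow a BFS tree from the
    root node (the spine base for spines)."""
    import collections
    n = len(skeleton.nodes)
    adj = collections.defaultdict(list)
    for i, j in skeleton.edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = {root: -1}
    order = [root]
    queue = collections.deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                queue.append(v)
    swc_index = {node: k + 1 for k, node in enumerate(order)}
    t = _SWC_TYPES.get(kind, 0)
    lines = ["# SWC skeleton, coordinates in nm (x y z radius)",
             f"# kind: {kind}"]
    for node in order:
        z, y, x = skeleton.nodes[node]
        p = parent[node]
        lines.append(
            f"{swc_index[node]} {t} {x:.1f} {y:.1f} {z:.1f} "
            f"{skeleton.node_radius[node]:.1f} "
            f"{swc_index[p] if p >= 0 else -1}")
    Path(path).write_text("\n".join(lines) + "\n")
    if n and len(order) < n:
        raise ValueError("skeleton is disconnected; SWC requires a tree")


def read_swc(path) -> Skeleton:
    nodes, radii, parents = [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        _, _, x, y, z, r, parent = fields[:7]
        nodes.append([float(z), float(y), float(x)])
        radii.append(float(r))
        parents.append(int(parent))
    edges = [(p - 1, i) for i, p in enumerate(parents) if p > 0]
    return Skeleton(np.asarray(nodes), edges, np.asarray(radii))


def puncta_table(phantom: PhantomVolume) -> pd.DataFrame:
    rows = [{"punctum_id": i,
             "z_nm": p.position[0], "y_nm": p.position[1],
             "x_nm": p.position[2],
             "target_structure_id": p.target_structure_id,
             "site": p.site, "amplitude": p.amplitude}
            for i, p in enumerate(phantom.puncta)]
    return pd.DataFrame(rows)


def structure_table(structures: list[StructureRecord]) -> pd.DataFrame:
    rows = [{"id": s.id, "kind": s.kind, "parent_id": s.parent_id,
             "has_head": s.has_head,
             "path_length_um": s.skeleton.path_length_nm / 1e3,
             "mean_radius_nm": float(np.mean(s.skeleton.node_radius))}
            for s in structures]
    return pd.DataFrame(rows)


def save_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return asdict(o)

    Path(path).write_text(json.dumps(payload, indent=1, default=default))
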