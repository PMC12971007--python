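"""File interchange: cohort CSV, long-format TRUST CSV, velocity scenes.

Velocity scenes travel as a long-format CSV (subject, row, col, velocity)
with a JSON geometry sidecar (pixel area, venc, ROI pixel lists), or
optionally as NIfTI when nibabel is available.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .mri import TrustSeries, VelocityScene
from .synthetic import SimulationConfig

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_trust_csv",
    "read_trust_csv",
    "write_scenes",
    "read_scenes",
    "write_config_json",
    "read_config_json",
    "write_scene_nifti",
]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trust_csv(series: Mapping[str, TrustSeries], path) -> None:
    """Long format: one row per (subject, eTE)."""
    rows = []
    for sid, s in series.items():
        for ete, sig in zip(s.etes, s.signals):
            rows.append({"subject_id": sid, "ete_ms": ete, "signal": sig})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trust_csv(path) -> dict[str, TrustSeries]:
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("ete_ms")
        out[str(sid)] = TrustSeries(
            etes=tuple(grp["ete_ms"]), signals=tuple(grp["signal"]),
            subject_id=str(sid),
        )
    return out


def write_scenes(scenes: Mapping[str, VelocityScene], csv_path, sidecar_path) -> None:
    frames = []
    geometry = {}
    for sid, scene in scenes.items():
        h, w = scene.velocity_map.shape
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "row": ii.ravel(),
                    "col": jj.ravel(),
                    "velocity_cm_s": scene.velocity_map.ravel(),
                }
            )
        )
        geometry[sid] = {
            "shape": [h, w],
            "pixel_area_cm2": scene.pixel_area,
            "venc_cm_s": scene.venc,
            "rois": {
                name: np.argwhere(mask).tolist()
                for name, mask in scene.roi_masks.items()
            },
        }
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    Path(sidecar_path).write_text(json.dumps(geometry))


def read_scenes(csv_path, sidecar_path) -> dict[str, VelocityScene]:
    df = pd.read_csv(csv_path)
    geometry = json.loads(Path(sidecar_path).read_text())
    out = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        sid = str(sid)
        geo = geometry[sid]
        shape = tuple(geo["shape"])
        vmap = np.zeros(shape)
        vmap[grp["row"], grp["col"]] = grp["velocity_cm_s"]
        masks = {}
        for name, pixels in geo["rois"].items():
            mask = np.zeros(shape, dtype=bool)
            if pixels:
                idx = np.asarray(pixels)
                mask[idx[:, 0], idx[:, 1]] = True
            masks[name] = mask
        out[sid] = VelocityScene(
            velocity_map=vmap, roi_masks=masks,
            pixel_area=geo["pixel_area_cm2"], venc=geo["venc_cm_s"], subject_id=sid,
        )
    return out


def write_scene_nifti(scene: VelocityScene, path) -> None:
    """Optional NIfTI export of one velocity map (requires nibabel)."""
    import nibabel as nib

    img = nib.Nifti1Image(scene.velocity_map[..., None].astype(np.float32), np.eye(4))
    nib.save(img, str(path))


def write_config_json(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))


def read_config_json(path) -> SimulationConfig:
    return SimulationConfig.from_dict(json.loads(Path(path).read_text()))
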