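"""NIfTI / TSV / JSON input-output.

The on-disk layout is BIDS-flavored: one directory per subject with 4-D
BOLD NIfTIs and events TSVs per run, depth/layer-label NIfTIs, and JSON
sidecars for ground truth and provenance — so the pipeline can later
point at real laminar data unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BlockDesign, BoldRun, LaminarVolume


def _affine(volume: LaminarVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume.voxel_size_mm
    return aff


def write_run_nifti(run: BoldRun, volume: LaminarVolume, path) -> Path:
    """Write a run as 4-D NIfTI (gray voxels scattered into the grid)."""
    path = Path(path)
    vol4d = np.zeros(volume.shape + (run.n_trs,), dtype=np.float32)
    idx = volume.gray_indices()
    vol4d[idx[:, 0], idx[:, 1], idx[:, 2], :] = run.data
    nib.save(nib.Nifti1Image(vol4d, _affine(volume)), str(path))
    return path


def read_run_nifti(path, volume: LaminarVolume, design: BlockDesign,
                   run_id: int, session: str) -> BoldRun:
    img = nib.load(str(path))
    vol4d = np.asanyarray(img.dataobj)
    idx = volume.gray_indices()
    data = vol4d[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(float)
    return BoldRun(data=data, tr_s=design.tr_s, run_id=run_id,
                   session=session, design=design)


def write_events_tsv(design: BlockDesign, path) -> Path:
    """BIDS-events-like TSV: onset, duration, trial_type (+ extras)."""
    path = Path(path)
    cols = ["onset", "duration", "trial_type", "orientation", "location", "block"]
    design.events[cols].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, tr_s: float, n_trs: int) -> BlockDesign:
    events = pd.read_csv(path, sep="\t")
    return BlockDesign(events=events, tr_s=tr_s, n_trs=n_trs)


def write_volume_niftis(volume: LaminarVolume, outdir, prefix: str = "patch") -> dict:
    """Write depth, gray-matter mask, column ids and (if present) layer
    labels / vein mask as NIfTI volumes; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(volume)
    paths = {}

    def save(name, arr, dtype):
        p = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), str(p))
        paths[name] = p

    save("depth", np.nan_to_num(volume.depth, nan=-1.0), np.float32)
    save("gm_mask", volume.gm_mask, np.uint8)
    save("columns", volume.column_id, np.int32)
    if volume.layer_labels is not None:
        save("layers", volume.layer_labels, np.int8)
    if volume.vein_mask is not None:
        save("veins", volume.vein_mask, np.uint8)
    return paths


def write_ground_truth_json(gt, path) -> Path:
    """Serialize a :class:`layerlearn.synth.GroundTruth` sidecar."""
    path = Path(path)
    payload = {
        "depth": gt.depth.tolist(),
        "layer_of_voxel": gt.layer_of_voxel.tolist(),
        "vein_mask": gt.vein_mask.astype(int).tolist(),
        "patterns": {f"{o}_{l}": v.tolist() for (o, l), v in gt.patterns.items()},
        "latents": [{lay: v.tolist() for lay, v in lat.items()} for lat in gt.latents],
        "location_gain": gt.location_gain.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path
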