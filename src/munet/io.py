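"""Volume, sinogram and table I/O.

Volumes travel as NIfTI (voxel size in the header affine, axial/
sagittal/coronal axis order, 0-based voxel indexing). Sinograms and
realization sets are compressed ``.npz`` containers with a JSON sidecar
(same stem, ``.json``) recording geometry, count level, fractions and
seeds; metric tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .petsim import CountConfig, ProjectionGeometry, Sinogram

__all__ = ["save_nifti", "load_nifti", "save_sinogram", "load_sinogram"]


def save_nifti(path, volume: np.ndarray, voxel_size_mm) -> None:
    vs = np.broadcast_to(voxel_size_mm, (3,)).astype(float)
    affine = np.diag([*vs, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vs))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata(), dtype=np.float64)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return vol, vs


def save_sinogram(path, sino: Sinogram, extra_meta: dict | None = None) -> None:
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        prompts=sino.prompts, randoms_expected=sino.randoms_expected,
        scatter_expected=sino.scatter_expected, att_factors=sino.att_factors)
    g = sino.geometry
    meta = {
        "geometry": {
            "n_angles": g.n_angles, "n_radial_bins": g.n_radial_bins,
            "n_slices": g.n_slices, "bin_size_mm": g.bin_size_mm,
            "image_shape_2d": list(g.image_shape_2d),
            "voxel_size_mm": list(g.voxel_size_mm), "mode": g.mode,
        },
        "total_counts": sino.total_counts,
        "count_scale": sino.count_scale,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    gm = meta["geometry"]
    geom = ProjectionGeometry(
        n_angles=gm["n_angles"], n_radial_bins=gm["n_radial_bins"],
        n_slices=gm["n_slices"], bin_size_mm=gm["bin_size_mm"],
        image_shape_2d=tuple(gm["image_shape_2d"]),
        voxel_size_mm=tuple(gm["voxel_size_mm"]), mode=gm.get("mode", "parallel2d"))
    return Sinogram(prompts=data["prompts"], randoms_expected=data["randoms_expected"],
                    scatter_expected=data["scatter_expected"],
                    att_factors=data["att_factors"], geometry=geom,
                    total_counts=int(meta["total_counts"]),
                    count_scale=float(meta.get("count_scale", 1.0)))
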