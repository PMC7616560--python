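"""Disk formats: NIfTI images and sinograms with JSON sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .projector import ScannerGeometry
from .simulate import Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_checkpoint",
    "load_checkpoint",
]


def save_image(path: str | Path, data: np.ndarray, spacing_mm: float) -> Path:
    """Write a 2D image as NIfTI with the pixel size in the affine."""
    path = Path(path)
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def load_image(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = float(img.affine[0, 0])
    return np.squeeze(data), spacing


def save_sinogram(stem: str | Path, sino: Sinogram) -> Path:
    """Write counts/randoms as .npz next to a JSON sidecar with the geometry."""
    stem = Path(stem)
    np.savez_compressed(stem.with_suffix(".npz"), counts=sino.counts, randoms=sino.randoms)
    sidecar = {
        "geometry": asdict(sino.geometry),
        "total_prompts": sino.total_prompts,
        "seed": sino.seed,
        "arrays": stem.with_suffix(".npz").name,
    }
    out = Path(str(stem) + ".npz.json")
    out.write_text(json.dumps(sidecar, indent=2))
    return out


def load_sinogram(sidecar_path: str | Path) -> Sinogram:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    arrays = np.load(sidecar_path.parent / meta["arrays"])
    geom = ScannerGeometry(**meta["geometry"])
    return Sinogram(arrays["counts"], arrays["randoms"], geom, seed=meta["seed"])


def save_checkpoint(path: str | Path, net, extra: dict | None = None) -> Path:
    """Write network parameters/BN state as .npz plus a JSON manifest."""
    path = Path(path)
    arrays = {f"param:{k}": v for k, v in net.params.items()}
    arrays |= {f"state:{k}": v for k, v in net.state.items()}
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {"input_mode": net.input_mode, "arrays": path.with_suffix(".npz").name}
    if extra:
        manifest.update(extra)
    out = path.with_suffix(".json")
    out.write_text(json.dumps(manifest, indent=2, default=float))
    return out


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`; returns (NetParams, manifest)."""
    from .fbsemnet import NetParams

    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    meta = json.loads(path.read_text())
    arrays = np.load(path.parent / meta["arrays"])
    params = {k[6:]: arrays[k].copy() for k in arrays.files if k.startswith("param:")}
    state = {k[6:]: arrays[k].copy() for k in arrays.files if k.startswith("state:")}
    return NetParams(params, state, meta["input_mode"]), meta
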