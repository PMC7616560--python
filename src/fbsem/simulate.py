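"""Noisy emission-data simulation and paired low-dose/reference datasets.

A dataset sample couples a noise-free scaled phantom (the reconstruction
reference), a Poisson-sampled low-dose sinogram with a uniform
expected-randoms background, the guidance MR image and the per-sample system
model (shared geometry matrix, per-phantom attenuation).

The reference is the noise-free scaled phantom itself rather than a separate
very-high-count reconstruction: for parameter-recovery testing the ground
truth is the cleaner target, and a high-count reconstruction converges to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import EmissionImage
from .phantoms import PhantomSample, add_lesions, augment_rotations, make_base_phantom
from .projector import ScannerGeometry, SystemModel, build_system, default_geometry

__all__ = [
    "Sinogram",
    "DatasetRecord",
    "scale_to_counts",
    "sample_poisson",
    "simulate_dataset",
    "build_dataset",
]


@dataclass
class Sinogram:
    """Measured coincidence counts y with expected randoms per LOR."""

    counts: np.ndarray  # non-negative integers, flat (n_lors,)
    randoms: np.ndarray  # expected randoms b-bar, flat (n_lors,)
    geometry: ScannerGeometry
    total_prompts: int = 0
    seed: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.randoms = np.asarray(self.randoms, dtype=np.float64)
        if np.any(self.counts < 0) or np.any(self.randoms < 0):
            raise ValueError("counts and randoms must be non-negative")
        if self.counts.shape != (self.geometry.n_lors,):
            raise ValueError("sinogram length does not match geometry")
        self.total_prompts = int(self.counts.sum())


def scale_to_counts(
    model: SystemModel,
    x: EmissionImage | np.ndarray,
    target_counts: float,
    randoms_fraction: float = 0.2,
) -> tuple[EmissionImage, np.ndarray]:
    """Rescale activity so the expected total prompts hit ``target_counts``.

    The scaled image satisfies sum_i([Hx]_i + bbar_i) = target_counts with a
    spatially uniform bbar carrying ``randoms_fraction`` of the total.
    """
    if not 0.0 <= randoms_fraction < 1.0:
        raise ValueError("randoms_fraction must be in [0, 1)")
    data = x.data if isinstance(x, EmissionImage) else np.asarray(x, dtype=np.float64)
    spacing = x.spacing_mm if isinstance(x, EmissionImage) else model.geometry.image_spacing_mm
    total = float(model.forward(data).sum())
    if total <= 0:
        raise ValueError("phantom projects to zero counts; cannot scale")
    trues = target_counts * (1.0 - randoms_fraction)
    scaled = EmissionImage(data * (trues / total), spacing)
    bbar = np.full(
        model.geometry.n_lors, randoms_fraction * target_counts / model.geometry.n_lors
    )
    return scaled, bbar


def sample_poisson(
    model: SystemModel,
    x: EmissionImage | np.ndarray,
    bbar: np.ndarray | None = None,
    seed: int = 0,
) -> Sinogram:
    """Draw y_i ~ Poisson([Hx]_i + bbar_i), independently per LOR."""
    data = x.data if isinstance(x, EmissionImage) else np.asarray(x, dtype=np.float64)
    if np.any(data < 0):
        raise ValueError("activity must be non-negative")
    mean = model.forward(data)
    if bbar is not None:
        if np.any(bbar < 0):
            raise ValueError("randoms must be non-negative")
        mean = mean + bbar
    else:
        bbar = np.zeros_like(mean)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean)
    return Sinogram(counts, bbar, model.geometry, seed=seed)


@dataclass
class DatasetRecord:
    """One paired training/test sample."""

    sample: PhantomSample  # post-rotation phantom (activity is the scaled reference)
    reference: EmissionImage  # noise-free scaled activity (reconstruction target)
    sinogram: Sinogram
    model: SystemModel
    count_level: float
    index: int = 0


def simulate_dataset(
    n_slices: int,
    n_rotations: int = 5,
    size_px: int = 64,
    spacing_mm: float = 2.08,
    count_levels: list[float] | float = 2.5e5,
    split: str = "train",
    seed: int = 0,
    n_subsets: int = 6,
    n_lesions: int = 10,
    radius_range_mm: tuple[float, float] = (2.0, 10.0),
    mismatch_fraction: float = 0.0,
    randoms_fraction: float = 0.2,
    geometry: ScannerGeometry | None = None,
) -> list[DatasetRecord]:
    """Generate an in-memory paired dataset.

    ``split`` controls the rotation range (train: ±5°, test: ±10°) and the
    base-phantom seed stream, so test phantoms are anatomically distinct from
    training ones. Count levels cycle through ``count_levels`` across samples.
    Fully reproducible from the arguments.
    """
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    max_deg = 5.0 if split == "train" else 10.0
    if np.isscalar(count_levels):
        count_levels = [float(count_levels)]

    geometry = geometry or default_geometry(size_px, spacing_mm, n_subsets)
    base_model = build_system(geometry, mumap=None, n_subsets=n_subsets)

    root = np.random.default_rng(
        np.random.SeedSequence([seed, 0 if split == "train" else 1])
    )
    records: list[DatasetRecord] = []
    idx = 0
    for s in range(n_slices):
        seeds = root.integers(2**31, size=4)
        phantom = make_base_phantom(size_px, spacing_mm, seed=int(seeds[0]))
        phantom = add_lesions(
            phantom,
            n_lesions=n_lesions,
            radius_range_mm=radius_range_mm,
            mismatch_fraction=mismatch_fraction,
            seed=int(seeds[1]),
        )
        rotated = augment_rotations(phantom, n_rotations, max_deg, seed=int(seeds[2]))
        noise_rng = np.random.default_rng(int(seeds[3]))
        for sample in rotated:
            model = base_model.with_attenuation(sample.mumap)
            level = count_levels[idx % len(count_levels)]
            scaled, bbar = scale_to_counts(
                model, sample.activity, level, randoms_fraction
            )
            sino = sample_poisson(
                model, scaled, bbar, seed=int(noise_rng.integers(2**31))
            )
            sample = sample.__class__(
                activity=scaled,
                mr=sample.mr,
                mumap=sample.mumap,
                tissue_masks=sample.tissue_masks,
                lesions=sample.lesions,
                rotation_deg=sample.rotation_deg,
                seed=sample.seed,
            )
            records.append(
                DatasetRecord(sample, scaled, sino, model, float(level), index=idx)
            )
            idx += 1
    return records


def build_dataset(out_dir: str | Path, **kwargs) -> Path:
    """Simulate a dataset and write it to disk (NIfTI images, JSON sidecars).

    Returns the manifest path; the manifest lists one entry per sample.
    """
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = simulate_dataset(**kwargs)
    entries = []
    for rec in records:
        stem = f"sample_{rec.index:04d}"
        fio.save_image(out_dir / f"{stem}_ref.nii.gz", rec.reference.data, rec.sample.spacing_mm)
        fio.save_image(out_dir / f"{stem}_mr.nii.gz", rec.sample.mr, rec.sample.spacing_mm)
        fio.save_image(out_dir / f"{stem}_mumap.nii.gz", rec.sample.mumap, rec.sample.spacing_mm)
        fio.save_sinogram(out_dir / f"{stem}_sino", rec.sinogram)
        entries.append(
            {
                "index": rec.index,
                "count_level": rec.count_level,
                "rotation_deg": rec.sample.rotation_deg,
                "n_lesions": len(rec.sample.lesions),
                "files": {
                    "reference": f"{stem}_ref.nii.gz",
                    "mr": f"{stem}_mr.nii.gz",
                    "mumap": f"{stem}_mumap.nii.gz",
                    "sinogram": f"{stem}_sino.npz.json",
                },
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"n_samples": len(entries), "samples": entries}, indent=2))
    return manifest
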