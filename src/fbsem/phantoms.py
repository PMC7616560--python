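"""Procedural 2D brain-like phantoms for emission-tomography simulation.

Each sample bundles an FDG-like activity slice, a co-registered T1-like MR
slice, a 511-keV attenuation map and tissue/lesion bookkeeping, on a common
square-pixel grid (default 2.08 mm). The anatomy is generated procedurally
(jittered nested ellipses with a harmonically perturbed grey/white boundary),
so no external phantom data is ever needed; every operation is a pure function
of its arguments including the seed.

Activity contrast defaults are grey:white:background = 4:1:0 with hot lesions
scaling activity by 2 and cold by 0.25; these make lesions clearly visible at
low-dose count levels and are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import EmissionImage, centred_coords_mm

__all__ = [
    "Lesion",
    "PhantomSample",
    "make_base_phantom",
    "add_lesions",
    "augment_rotations",
]

# 511-keV linear attenuation, mm^-1
MU_TISSUE = 0.0096
MU_BONE = 0.0146

GREY_ACTIVITY = 4.0
WHITE_ACTIVITY = 1.0
HOT_CONTRAST = 2.0
COLD_CONTRAST = 0.25
MR_HOT_CONTRAST = 1.6
MR_COLD_CONTRAST = 0.4


@dataclass
class Lesion:
    """Bookkeeping for one circular lesion."""

    center_mm: tuple[float, float]  # (y, x) from grid centre
    radius_mm: float
    polarity: str  # "hot" | "cold"
    placement: str  # "shared" | "pet_only" | "mr_only"
    mask: np.ndarray  # boolean, single connected disk


@dataclass
class PhantomSample:
    """One phantom slice: activity, MR, attenuation and masks on a shared grid."""

    activity: EmissionImage
    mr: np.ndarray
    mumap: np.ndarray
    tissue_masks: dict[str, np.ndarray]
    lesions: list[Lesion] = field(default_factory=list)
    rotation_deg: float = 0.0
    seed: int = 0

    @property
    def spacing_mm(self) -> float:
        return self.activity.spacing_mm

    @property
    def shape(self) -> tuple[int, int]:
        return self.activity.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_masks["grey"] | self.tissue_masks["white"]


def _elliptical_radius(yy, xx, cy, cx, ay, ax, tilt_rad):
    """Normalised radius (=1 on the ellipse boundary) and polar angle."""
    y = yy - cy
    x = xx - cx
    yr = y * np.cos(tilt_rad) - x * np.sin(tilt_rad)
    xr = y * np.sin(tilt_rad) + x * np.cos(tilt_rad)
    rho = np.sqrt((yr / ay) ** 2 + (xr / ax) ** 2)
    phi = np.arctan2(yr / ay, xr / ax)
    return rho, phi


def make_base_phantom(
    size_px: int,
    spacing_mm: float = 2.08,
    seed: int = 0,
    grey_activity: float = GREY_ACTIVITY,
    white_activity: float = WHITE_ACTIVITY,
) -> PhantomSample:
    """Generate one lesion-free brain-like phantom slice.

    The slice is built from a jittered outer head ellipse, a skull ring, a
    brain ellipse, and an inner white-matter region whose boundary is
    perturbed by random low-order harmonics; the grey-matter ribbon is the
    remainder of the brain. Activity, MR intensity and the attenuation map
    are piecewise constant per tissue (activity and MR lightly smoothed for
    partial-volume realism), with an extra smooth multiplicative activity
    texture so different seeds give visibly different slices.

    Deterministic given ``seed``.
    """
    if size_px < 32:
        raise ValueError(f"size_px must be >= 32, got {size_px}")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")

    rng = np.random.default_rng(seed)
    yy, xx = centred_coords_mm(size_px, spacing_mm)
    fov = size_px * spacing_mm

    # head / brain geometry (mm), jittered per seed
    cy = rng.uniform(-0.02, 0.02) * fov
    cx = rng.uniform(-0.02, 0.02) * fov
    ay = fov * rng.uniform(0.36, 0.41)
    ax = fov * rng.uniform(0.30, 0.35)
    tilt = rng.uniform(-0.15, 0.15)

    rho, phi = _elliptical_radius(yy, xx, cy, cx, ay, ax, tilt)
    brain = rho < 1.0
    head = rho < 1.08  # brain + skull ring

    # white-matter boundary: scaled ellipse with harmonic perturbation
    n_harm = 4
    amp = rng.normal(0.0, 0.045, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    pert = np.zeros_like(phi)
    for k in range(n_harm):
        pert += amp[k] * np.cos((k + 2) * phi + phase[k])
    white = rho < 0.70 * (1.0 + pert)
    grey = brain & ~white

    activity = np.zeros((size_px, size_px))
    activity[white] = white_activity
    activity[grey] = grey_activity
    # smooth low-frequency texture so slices differ across seeds
    texture = ndimage.gaussian_filter(rng.standard_normal((size_px, size_px)), size_px / 8)
    texture /= max(np.abs(texture).max(), 1e-12)
    activity *= 1.0 + 0.08 * texture
    activity = ndimage.gaussian_filter(activity, 0.5)
    np.clip(activity, 0.0, None, out=activity)

    # MR: independent tissue contrast (white bright on T1)
    mr = np.zeros((size_px, size_px))
    mr[white] = 3.0
    mr[grey] = 1.5
    mr[head & ~brain] = 0.8
    mr = ndimage.gaussian_filter(mr, 0.5)

    mumap = np.zeros((size_px, size_px))
    mumap[head] = MU_BONE
    mumap[brain] = MU_TISSUE

    return PhantomSample(
        activity=EmissionImage(activity, spacing_mm),
        mr=mr,
        mumap=mumap,
        tissue_masks={"grey": grey, "white": white, "background": ~brain},
        lesions=[],
        rotation_deg=0.0,
        seed=seed,
    )


def add_lesions(
    sample: PhantomSample,
    n_lesions: int = 10,
    radius_range_mm: tuple[float, float] = (2.0, 10.0),
    mismatch_fraction: float = 0.0,
    seed: int = 0,
    max_attempts: int = 1000,
) -> PhantomSample:
    """Add circular hot/cold lesions at random in-brain locations.

    Each lesion is a disk with radius uniform in ``radius_range_mm``, hot
    (activity x2) or cold (x0.25) with equal probability, multiplicatively
    applied to activity and (with its own milder contrast) to MR. A
    ``mismatch_fraction`` subset of lesions is placed in only one modality
    (alternating pet_only / mr_only). Lesion centres are rejection-sampled so
    that each disk lies fully inside the brain mask; failure to place one
    within ``max_attempts`` raises ``RuntimeError``.

    Returns a new sample; the input is not modified.
    """
    lo, hi = radius_range_mm
    size_px = sample.shape[0]
    if not 0 < lo <= hi < size_px * sample.spacing_mm / 2:
        raise ValueError(f"radius range {radius_range_mm} outside (0, half-width)")
    if not 0.0 <= mismatch_fraction <= 1.0:
        raise ValueError("mismatch_fraction must be in [0, 1]")
    if n_lesions == 0:
        return sample

    rng = np.random.default_rng(seed)
    yy, xx = centred_coords_mm(size_px, sample.spacing_mm)
    brain = sample.brain_mask

    activity = sample.activity.data.copy()
    mr = sample.mr.copy()
    lesions = list(sample.lesions)

    n_mismatch = int(round(mismatch_fraction * n_lesions))
    for i in range(n_lesions):
        radius = rng.uniform(lo, hi)
        # erode brain mask by the lesion radius so the disk fits inside
        r_px = max(int(np.ceil(radius / sample.spacing_mm)), 1)
        allowed = ndimage.binary_erosion(brain, iterations=r_px)
        placed = False
        for _ in range(max_attempts):
            iy, ix = rng.integers(0, size_px, size=2)
            if allowed[iy, ix]:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {i} (radius {radius:.1f} mm) inside the brain"
            )
        cy, cx = yy[iy, ix], xx[iy, ix]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        polarity = "hot" if rng.uniform() < 0.5 else "cold"
        if i < n_mismatch:
            placement = "pet_only" if i % 2 == 0 else "mr_only"
        else:
            placement = "shared"
        if placement != "mr_only":
            activity[mask] *= HOT_CONTRAST if polarity == "hot" else COLD_CONTRAST
        if placement != "pet_only":
            mr[mask] *= MR_HOT_CONTRAST if polarity == "hot" else MR_COLD_CONTRAST
        lesions.append(Lesion((float(cy), float(cx)), float(radius), polarity, placement, mask))

    return replace(
        sample,
        activity=EmissionImage(activity, sample.spacing_mm),
        mr=mr,
        lesions=lesions,
    )


def _rotate_image(img: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    return ndimage.rotate(
        img, angle_deg, reshape=False, order=order, mode="constant", cval=0.0
    )


def rotate_sample(sample: PhantomSample, angle_deg: float) -> PhantomSample:
    """Rotate every grid of a sample by the same angle about the grid centre.

    Activity, MR and the attenuation map use bilinear interpolation (activity
    clipped at 0 afterwards); all masks use nearest-neighbour so they remain
    boolean and mutually consistent.
    """
    act = np.clip(_rotate_image(sample.activity.data, angle_deg, order=1), 0.0, None)
    mr = _rotate_image(sample.mr, angle_deg, order=1)
    mu = np.clip(_rotate_image(sample.mumap, angle_deg, order=1), 0.0, None)
    masks = {
        k: _rotate_image(v.astype(np.uint8), angle_deg, order=0).astype(bool)
        for k, v in sample.tissue_masks.items()
    }
    # background is the complement of the rotated brain (fill stays background)
    masks["background"] = ~(masks["grey"] | masks["white"])
    lesions = [
        replace(l, mask=_rotate_image(l.mask.astype(np.uint8), angle_deg, order=0).astype(bool))
        for l in sample.lesions
    ]
    return replace(
        sample,
        activity=EmissionImage(act, sample.spacing_mm),
        mr=mr,
        mumap=mu,
        tissue_masks=masks,
        lesions=lesions,
        rotation_deg=sample.rotation_deg + angle_deg,
    )


def augment_rotations(
    sample: PhantomSample,
    n_rotations: int,
    max_abs_deg: float,
    seed: int = 0,
) -> list[PhantomSample]:
    """Return ``n_rotations`` copies rotated by uniform angles in ±max_abs_deg."""
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-max_abs_deg, max_abs_deg, size=n_rotations)
    return [rotate_sample(sample, float(a)) for a in angles]
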