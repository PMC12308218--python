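"""Synthetic limb cross-section phantoms with known ground truth.

A phantom is a concentric-annulus limb extruded along the scan axis:
air background | skin annulus | subcutaneous fat annulus | muscle
compartment with circular bone inclusions. A tunable fraction ``f`` of
muscle-compartment voxels carries fat-tissue HU (intramuscular fat), either
scattered voxel-wise or clustered into blobs, and additive Gaussian noise
emulates detector noise. The exact voxel labels, compartment volumes and
noiseless mean muscle density are recorded so segmentation accuracy can be
measured against truth.

Geometry defaults mirror a second-generation HR-pQCT acquisition (isotropic
60.7 μm voxels, 168 slices ≈ 10.2 mm of limb length) at a reduced in-plane
extent so a phantom fits comfortably in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import (ADIPOSE, BACKGROUND, BONE, INTRAMUSCULAR_FAT, MUSCLE,
                     SKIN, CTVolume)


@dataclass
class PhantomSpec:
    """Geometry, tissue HU means and noise model of a limb phantom.

    Radii and thicknesses are in native voxels. Tissue means must stay inside
    the classification windows (muscle 100-600 HU, fat -600 to -200 HU, bone
    above the bone threshold) so the phantom is classifiable.
    """

    shape: tuple[int, int, int] = (260, 260, 168)
    voxel_um: float = 60.7
    limb_radius: float = 120.0
    skin_thickness: float = 16.0
    fat_thickness: float = 40.0
    bone_count: int = 2
    bone_radius: float = 12.0
    hu_muscle: float = 300.0
    hu_fat: float = -300.0
    hu_bone: float = 1500.0
    hu_skin: float = 20.0
    hu_air: float = -1000.0
    fat_fraction: float = 0.0      # f: fraction of muscle-compartment voxels with fat HU
    fat_placement: str = "random"  # "random" (voxel-wise) or "blobs" (clustered)
    fat_blob_count: int = 30
    noise_sd: float = 10.0         # HU
    calibration_slope: float = 0.08
    calibration_intercept: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.limb_radius <= self.skin_thickness + self.fat_thickness:
            raise ValueError(
                "impossible geometry: limb radius must exceed skin + subcutaneous "
                f"fat thickness ({self.limb_radius} <= "
                f"{self.skin_thickness + self.fat_thickness})")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat fraction must lie in [0, 1]")
        if not 100.0 <= self.hu_muscle <= 600.0:
            raise ValueError("muscle HU must lie within the 100-600 HU window")
        if not -600.0 <= self.hu_fat <= -200.0:
            raise ValueError("fat HU must lie within the -600 to -200 HU window")
        if self.hu_bone <= 600.0:
            raise ValueError("bone HU must exceed the 600 HU bone threshold")
        muscle_outer = self.limb_radius - self.skin_thickness - self.fat_thickness
        if self.bone_count > 0:
            ring = muscle_outer / 2.0
            if ring + self.bone_radius >= muscle_outer:
                raise ValueError("bone inclusions do not fit inside the muscle compartment")
        if min(self.shape) <= 0:
            raise ValueError("grid shape must be positive")
        if 2 * self.limb_radius >= min(self.shape[0], self.shape[1]):
            raise ValueError("limb does not fit inside the in-plane grid")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class GroundTruth:
    """Exact phantom composition for validating segmentation output."""

    labels: np.ndarray                 # per-voxel tissue code (volume.* constants)
    voxel_um: float
    muscle_compartment_voxels: int     # includes intramuscular-fat voxels
    soft_tissue_voxels: int            # subcutaneous fat + muscle compartment
    muscle_volume_cm3: float
    soft_tissue_volume_cm3: float
    mean_muscle_hu: float              # noiseless mean HU over the muscle compartment
    mean_muscle_density: float         # calibrated, mgHA/cm^3

    def to_json(self, path: str | Path) -> None:
        meta = {k: v for k, v in self.__dict__.items() if k != "labels"}
        Path(path).write_text(json.dumps(meta, indent=2))


def _label_slice(spec: PhantomSpec) -> np.ndarray:
    """Tissue labels for one cross-sectional slice (extruded along z)."""
    nx, ny, _ = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    r = np.hypot(x, y)

    labels = np.full((nx, ny), BACKGROUND, dtype=np.int8)
    labels[r < spec.limb_radius] = SKIN
    labels[r < spec.limb_radius - spec.skin_thickness] = ADIPOSE
    muscle_outer = spec.limb_radius - spec.skin_thickness - spec.fat_thickness
    labels[r < muscle_outer] = MUSCLE

    if spec.bone_count > 0:
        ring = muscle_outer / 2.0
        for k in range(spec.bone_count):
            theta = 2.0 * np.pi * k / spec.bone_count
            bx, by = ring * np.cos(theta), ring * np.sin(theta)
            rb = np.hypot(x - bx, y - by)
            labels[rb < spec.bone_radius] = BONE
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Build a seeded limb phantom and its exact ground truth.

    The same spec (including seed) always yields a bit-identical volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    labels2d = _label_slice(spec)
    labels = np.repeat(labels2d[:, :, None], spec.shape[2], axis=2).copy()

    # intramuscular fat: swap a fraction f of muscle voxels to fat HU
    muscle_idx = np.flatnonzero(labels.ravel() == MUSCLE)
    n_muscle = muscle_idx.size
    k = int(round(spec.fat_fraction * n_muscle))
    if k > 0:
        if spec.fat_placement == "random":
            chosen = rng.choice(muscle_idx, size=k, replace=False)
        elif spec.fat_placement == "blobs":
            chosen = _blob_voxels(labels, muscle_idx, k, spec.fat_blob_count, rng)
        else:
            raise ValueError(f"unknown fat placement {spec.fat_placement!r}")
        flat = labels.ravel()
        flat[chosen] = INTRAMUSCULAR_FAT
        labels = flat.reshape(labels.shape)

    hu_of = {BACKGROUND: spec.hu_air, SKIN: spec.hu_skin, ADIPOSE: spec.hu_fat,
             MUSCLE: spec.hu_muscle, BONE: spec.hu_bone,
             INTRAMUSCULAR_FAT: spec.hu_fat}
    lut = np.zeros(max(hu_of) + 1, dtype=np.float32)
    for code, hu in hu_of.items():
        lut[code] = hu
    data = lut[labels]

    compartment = (labels == MUSCLE) | (labels == INTRAMUSCULAR_FAT)
    mean_hu = float(data[compartment].mean())
    n_compartment = int(compartment.sum())
    n_soft = int(n_compartment + (labels == ADIPOSE).sum())

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    volume = CTVolume(data, voxel_um=spec.voxel_um, slope=spec.calibration_slope,
                      intercept=spec.calibration_intercept, provenance="native")
    vv = volume.voxel_volume_cm3
    truth = GroundTruth(
        labels=labels,
        voxel_um=spec.voxel_um,
        muscle_compartment_voxels=n_compartment,
        soft_tissue_voxels=n_soft,
        muscle_volume_cm3=n_compartment * vv,
        soft_tissue_volume_cm3=n_soft * vv,
        mean_muscle_hu=mean_hu,
        mean_muscle_density=float(volume.to_density(mean_hu)),
    )
    return volume, truth


def _blob_voxels(labels: np.ndarray, muscle_idx: np.ndarray, k: int,
                 n_blobs: int, rng: np.random.Generator) -> np.ndarray:
    """Pick k muscle voxels clustered around randomly seeded blob centres."""
    coords = np.array(np.unravel_index(muscle_idx, labels.shape)).T.astype(np.float64)
    centres = coords[rng.choice(coords.shape[0], size=min(n_blobs, coords.shape[0]),
                                replace=False)]
    # distance of every muscle voxel to its nearest blob centre
    d2 = np.min(((coords[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2), axis=1) \
        if coords.shape[0] * centres.shape[0] < 5e7 else _chunked_min_d2(coords, centres)
    order = np.argsort(d2, kind="stable")
    return muscle_idx[order[:k]]


def _chunked_min_d2(coords: np.ndarray, centres: np.ndarray) -> np.ndarray:
    out = np.empty(coords.shape[0])
    step = 200_000
    for i in range(0, coords.shape[0], step):
        block = coords[i:i + step]
        out[i:i + step] = np.min(((block[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2), axis=1)
    return out
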