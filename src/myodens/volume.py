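"""CT volume container and label-code table.

A :class:`CTVolume` is a 3-D grid of Hounsfield units (HU, water = 0) with an
isotropic voxel edge length and the linear HU -> density calibration
``density = slope * HU + intercept`` (mgHA/cm^3) obtained by scanning a
hydroxyapatite phantom of known concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

# Integer tissue codes shared by phantoms, segmentation and label-map I/O.
BACKGROUND = 0
SKIN = 1
BONE = 2
MUSCLE = 3
ADIPOSE = 4
UNCLASSIFIED = 5
INTRAMUSCULAR_FAT = 6  # phantom ground truth only: fat voxel inside the muscle compartment

LABEL_NAMES = {
    BACKGROUND: "background",
    SKIN: "skin",
    BONE: "bone",
    MUSCLE: "muscle",
    ADIPOSE: "adipose",
    UNCLASSIFIED: "unclassified",
    INTRAMUSCULAR_FAT: "intramuscular_fat",
}


@dataclass
class CTVolume:
    """3-D HU grid with voxel size (μm) and density calibration."""

    data: np.ndarray
    voxel_um: float = 60.7
    slope: float = 0.08       # mgHA/cm^3 per HU
    intercept: float = 0.0    # mgHA/cm^3
    provenance: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("CTVolume requires a non-empty 3-D grid")
        if self.voxel_um <= 0:
            raise ValueError("voxel edge length must be positive")
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_um * 1e-4) ** 3

    def to_density(self, hu: np.ndarray | float) -> np.ndarray | float:
        """Apply the linear HU -> mgHA/cm^3 calibration."""
        return self.slope * hu + self.intercept

    def with_data(self, data: np.ndarray, **kwargs) -> "CTVolume":
        return replace(self, data=data, **kwargs)


def save_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write the volume as NIfTI plus a JSON sidecar with the calibration."""
    import nibabel as nib

    path = Path(path)
    mm = volume.voxel_um / 1000.0
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine=np.diag([mm, mm, mm, 1.0]))
    img.header.set_zooms((mm, mm, mm))
    nib.save(img, str(path))
    sidecar = {
        "voxel_um": volume.voxel_um,
        "calibration": {"slope": volume.slope, "intercept": volume.intercept},
        "provenance": volume.provenance,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume; calibration comes from the JSON sidecar if present."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    voxel_um = float(img.header.get_zooms()[0]) * 1000.0
    slope, intercept, provenance = 0.08, 0.0, "native"
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_um = float(meta.get("voxel_um", voxel_um))
        cal = meta.get("calibration", {})
        slope = float(cal.get("slope", slope))
        intercept = float(cal.get("intercept", intercept))
        provenance = meta.get("provenance", provenance)
    return CTVolume(data, voxel_um=voxel_um, slope=slope, intercept=intercept,
                    provenance=provenance)
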