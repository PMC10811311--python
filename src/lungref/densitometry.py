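"""Quantitative-CT lung weight from Hounsfield-unit volumes.

CT attenuation in the lung reflects a linear gas/tissue mixture: -1000 HU
is pure gas, 0 HU water-equivalent tissue (parenchyma, blood, water) and
+1000 HU bone.  Under that model the tissue fraction of a voxel at CT
number ``hu`` is ``1 - hu / -1000``, and with tissue density taken as
1 g/cm^3 the lung weight is the sum of tissue fraction times voxel volume
over all lung-mask voxels.

Masks are inputs, not computed here: excluding airways, large vessels and
bone from the parenchymal mask is a segmentation problem outside this
module's scope.  HU outside [-1000, +1000] are clamped to the air/bone
anchors (fraction 0 and 2) with the clamped-voxel count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelVolume",
    "LungWeightMeasurement",
    "voxel_tissue_fraction",
    "lung_weight",
    "lung_weight_index",
    "make_phantom",
    "read_volume",
]

logger = logging.getLogger(__name__)

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class VoxelVolume:
    """A CT volume: HU array, per-voxel volume (mm^3) and a lung mask."""

    hu: np.ndarray
    voxel_volume_mm3: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if hu.shape != mask.shape:
            raise ValueError(
                f"hu shape {hu.shape} and mask shape {mask.shape} differ"
            )
        if not self.voxel_volume_mm3 > 0:
            raise ValueError(
                f"voxel_volume_mm3 must be > 0, got {self.voxel_volume_mm3}"
            )
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class LungWeightMeasurement:
    """Densitometric result: weight (g), gas/tissue volumes (mL), voxel count."""

    lung_weight: float
    lung_gas_volume: float
    lung_tissue_volume: float
    n_voxels: int


def voxel_tissue_fraction(hu):
    """Tissue fraction ``1 - hu / -1000`` of a voxel at CT number ``hu``.

    Clamped to [0, 2]: below -1000 HU a voxel is treated as pure gas,
    above +1000 HU as the bone endpoint.  Accepts scalars or arrays.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    frac = np.clip(1.0 - hu / -1000.0, 0.0, 2.0)
    return float(frac) if frac.ndim == 0 else frac


def lung_weight(vol: VoxelVolume) -> LungWeightMeasurement:
    """Lung weight (g) and gas/tissue volumes (mL) of the masked voxels.

    Weight is the sum over masked voxels of tissue fraction times voxel
    volume (mm^3 converted to cm^3, density 1 g/cm^3).  Gas volume uses
    the complementary gas fraction clipped to [0, 1]; tissue volume is
    the masked volume minus the gas volume, so the two partition the
    masked region exactly (voxels above 0 HU contribute extra *weight*
    but no extra volume).
    """
    hu = vol.hu[vol.mask]
    n = int(hu.size)
    if n == 0:
        logger.warning("empty lung mask: returning zero measurement")
        return LungWeightMeasurement(0.0, 0.0, 0.0, 0)
    n_clamped = int(np.count_nonzero((hu < -1000.0) | (hu > 1000.0)))
    if n_clamped:
        logger.warning(
            "%d of %d masked voxels outside [-1000, 1000] HU were clamped",
            n_clamped,
            n,
        )
    vv_cm3 = vol.voxel_volume_mm3 / MM3_PER_CM3
    weight = float(np.sum(voxel_tissue_fraction(hu)) * vv_cm3)
    gas = float(np.sum(np.clip(hu / -1000.0, 0.0, 1.0)) * vv_cm3)
    tissue = n * vv_cm3 - gas
    return LungWeightMeasurement(weight, gas, tissue, n)


def lung_weight_index(lung_weight_g: float, body_weight_kg: float) -> float:
    """Lung weight index (g/kg): lung weight (g) over body weight (kg)."""
    if not body_weight_kg > 0:
        raise ValueError(f"body weight must be > 0 kg, got {body_weight_kg}")
    if lung_weight_g < 0:
        raise ValueError(f"lung weight must be >= 0 g, got {lung_weight_g}")
    return lung_weight_g / body_weight_kg


def make_phantom(
    shape: tuple[int, ...] = (10, 10, 10),
    gas_fraction: float = 0.7,
    voxel_volume_mm3: float = 1.8,
    seed: int = 0,
    jitter_hu: float = 0.0,
) -> tuple[VoxelVolume, float]:
    """Uniform-density test phantom with a known analytic lung weight.

    All voxels are masked and set to ``-1000 * gas_fraction`` HU, plus
    optional zero-mean Gaussian jitter (centred exactly, so the analytic
    weight is preserved).  Returns the volume together with its analytic
    weight ``(1 - gas_fraction) * n_voxels * voxel_volume(cm^3)`` grams.
    Large jitter near the gas/bone endpoints can clip and break the
    analytic value; keep ``jitter_hu`` well inside the HU range.
    """
    if not 0.0 <= gas_fraction <= 1.0:
        raise ValueError(f"gas_fraction must be in [0, 1], got {gas_fraction}")
    hu = np.full(shape, -1000.0 * gas_fraction)
    if jitter_hu > 0:
        eps = np.random.default_rng(seed).normal(0.0, jitter_hu, shape)
        hu = hu + (eps - eps.mean())
    mask = np.ones(shape, dtype=bool)
    n_voxels = int(np.prod(shape))
    analytic = (1.0 - gas_fraction) * n_voxels * voxel_volume_mm3 / MM3_PER_CM3
    return VoxelVolume(hu, voxel_volume_mm3, mask), analytic


def read_volume(
    volume_path, mask_path, voxel_volume_mm3: float | None = None
) -> VoxelVolume:
    """Load an HU volume and lung mask from NIfTI files.

    When ``voxel_volume_mm3`` is not given it is taken from the volume's
    affine (absolute determinant of the 3x3 spatial part).
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    hu = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = float(abs(np.linalg.det(img.affine[:3, :3])))
    return VoxelVolume(hu, voxel_volume_mm3, mask)
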