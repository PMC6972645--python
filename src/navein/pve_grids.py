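"""Coarse-grid partial volume maps, analysis masks and the VH reference.

Fine-grid binary masks and tissue maps are reduced to the sodium grid by
taking the mean of each 7x7x7 block of sub-voxels; block averaging adds
no spatial smoothing because no interpolation occurs.  The resulting
per-class partial volume estimate (PVE) maps feed the analysis masks
(CSF-excluded brain tissue, GM/WM regions) and the vitreous humor (VH)
signal reference used to convert sodium signal to concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PVEMap",
    "MaskSet",
    "ReferenceValue",
    "block_downsample",
    "block_upsample",
    "voxel_count_ratio",
    "make_masks",
    "vh_reference",
    "to_concentration",
]


@dataclass
class PVEMap:
    """Per-class coarse-grid partial volume maps (values in [0, 1])."""

    vein: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    sss: np.ndarray
    vh: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.vein, self.gm, self.wm, self.csf, self.sss)}
        if len(shapes) != 1:
            raise ValueError("PVE maps must share one grid shape")
        for name in ("vein", "gm", "wm", "csf", "sss"):
            m = getattr(self, name)
            if m.min() < -1e-9 or m.max() > 1 + 1e-9:
                raise ValueError(f"{name} PVE values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.vein.shape


@dataclass
class MaskSet:
    """Analysis masks on the sodium grid."""

    brain_tissue_mask: np.ndarray
    gm_roi: np.ndarray
    wm_roi: np.ndarray
    csf_excl: float
    tissue_thresh: float


@dataclass(frozen=True)
class ReferenceValue:
    """Mean sodium signal of the eroded vitreous humor reference region."""

    vh_mean_signal: float
    na_vh_mM: float = 134.0
    eroded_voxel_count: int = 0

    def __post_init__(self) -> None:
        if self.vh_mean_signal <= 0:
            raise ValueError("VH mean signal must be positive")
        if self.eroded_voxel_count < 1:
            raise ValueError("eroded VH region must contain at least one voxel")


def block_downsample(fine_map: np.ndarray, factor: tuple[int, int, int] = (7, 7, 7)) -> np.ndarray:
    """Mean of each block of sub-voxels; no interpolation, no extra smoothing."""
    fine = np.asarray(fine_map, dtype=float)
    if fine.ndim != 3:
        raise ValueError("expected a 3D volume")
    if any(n % f for n, f in zip(fine.shape, factor)):
        raise ValueError(f"shape {fine.shape} not divisible by block factor {factor}")
    nx, ny, nz = (n // f for n, f in zip(fine.shape, factor))
    fx, fy, fz = factor
    return fine.reshape(nx, fx, ny, fy, nz, fz).mean(axis=(1, 3, 5))


def block_upsample(coarse_map: np.ndarray, factor: tuple[int, int, int] = (7, 7, 7)) -> np.ndarray:
    """Block-replicate a coarse map back onto the fine grid (round-trip inverse)."""
    c = np.asarray(coarse_map)
    out = c
    for ax, f in enumerate(factor):
        out = np.repeat(out, f, axis=ax)
    return out


def voxel_count_ratio(
    coarse_voxel_mm: tuple[float, float, float],
    fine_voxel_mm: tuple[float, float, float],
) -> int:
    """How many fine voxels fit one coarse voxel (volume ratio, rounded)."""
    cv = float(np.prod(coarse_voxel_mm))
    fv = float(np.prod(fine_voxel_mm))
    if cv <= 0 or fv <= 0:
        raise ValueError("voxel sizes must be positive")
    return int(round(cv / fv))


def make_masks(
    pve: PVEMap,
    csf_excl: float = 0.01,
    tissue_thresh: float = 0.5,
    brain_pve_min: float = 0.5,
) -> MaskSet:
    """Build the CSF-excluded brain tissue mask and GM/WM regions.

    A voxel belongs to the brain tissue mask when its summed brain-class
    PVE is at least ``brain_pve_min`` and its CSF PVE is strictly below
    ``csf_excl`` (the exclusion is inclusive at the threshold: CSF PVE
    exactly equal to ``csf_excl`` is excluded).  GM/WM regions use an
    inclusive ``>=`` at ``tissue_thresh`` and are intersected with the
    brain tissue mask; on the measure-zero tie where both classes sit
    exactly at the threshold the voxel is assigned to GM so the regions
    stay disjoint.
    """
    brain_total = pve.gm + pve.wm + pve.csf + pve.vein + pve.sss
    brain = brain_total >= brain_pve_min
    mask = brain & (pve.csf < csf_excl)
    if not mask.any():
        raise ValueError("brain tissue mask is empty after CSF exclusion")
    gm = (pve.gm >= tissue_thresh) & mask
    wm = (pve.wm >= tissue_thresh) & mask & ~gm
    return MaskSet(
        brain_tissue_mask=mask,
        gm_roi=gm,
        wm_roi=wm,
        csf_excl=csf_excl,
        tissue_thresh=tissue_thresh,
    )


def vh_reference(
    sodium_image: np.ndarray,
    vh_pve: np.ndarray,
    na_vh_mM: float = 134.0,
    pve_thresh: float = 0.5,
) -> ReferenceValue:
    """Mean sodium signal in the eroded vitreous humor region.

    The VH region (PVE >= ``pve_thresh``) is eroded once with a 3x3x3
    cubic structuring element so the mean is taken over voxels free from
    partial volume bias.
    """
    roi = np.asarray(vh_pve) >= pve_thresh
    eroded = ndimage.binary_erosion(roi, structure=np.ones((3, 3, 3), bool))
    n = int(eroded.sum())
    if n == 0:
        raise ValueError(
            "eroded VH region is empty; use a larger VH sphere or coarser erosion"
        )
    mean = float(np.asarray(sodium_image)[eroded].mean())
    return ReferenceValue(vh_mean_signal=mean, na_vh_mM=na_vh_mM, eroded_voxel_count=n)


def to_concentration(signal, ref: ReferenceValue):
    """Convert sodium signal to mM via the VH literature reference."""
    return np.asarray(signal, dtype=float) / ref.vh_mean_signal * ref.na_vh_mM
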