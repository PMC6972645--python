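"""Synthetic brain phantoms with known ground truth.

The phantom emulates the statistical structure the venous partial-volume
analysis assumes: an ellipsoidal brain with a CSF rim, central
ventricles, a gray-matter shell around a white-matter core; a tree of
curved-cylinder veins occupying a target fraction (~3%) of the brain;
one large midline surface cylinder standing in for the superior
sagittal sinus (SSS); and two vitreous-humor (VH) spheres fully outside
the brain so an eroded reference region is free of partial volume bias.
The fine grid is chosen so that a 7x7x7 block of fine voxels is exactly
one 3.2 x 3.2 x 6.4 mm sodium voxel, making coarse/fine alignment exact
by construction.  All geometry uses an identity affine, voxel-centred
coordinates and 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .pve_grids import block_downsample

__all__ = [
    "CLASS_NAMES",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "generate_flash",
    "cohort_specs",
    "generate_cohort",
]

# integer class labels of the fine-grid label volume
BACKGROUND, WM, GM, CSF, VEIN, SSS, VH = range(7)
CLASS_NAMES = {
    BACKGROUND: "background",
    WM: "wm",
    GM: "gm",
    CSF: "csf",
    VEIN: "vein",
    SSS: "sss",
    VH: "vh",
}


def _default_conc() -> dict[str, float]:
    # literature tissue sodium concentrations (mM); veins and SSS carry blood
    return {"wm": 37.8, "gm": 39.5, "csf": 150.0, "blood": 87.0, "vh": 134.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one synthetic subject (or a cohort)."""

    fine_grid_shape: tuple[int, int, int] = (224, 224, 224)
    fine_voxel_mm: tuple[float, float, float] = (3.2 / 7, 3.2 / 7, 6.4 / 7)
    tissue_conc_mM: dict[str, float] = field(default_factory=_default_conc)
    vein_count: int = 120
    vein_radius_mm: tuple[float, float] = (0.5, 1.4)
    vein_target_fraction: float = 0.031
    sss_radius_mm: float = 3.0
    vh_sphere_radius_mm: float = 14.0
    csf_rim_thickness_mm: float = 2.0
    gm_shell_thickness_mm: float = 6.0
    flash_tissue_level: float = 100.0
    flash_vein_drop_fraction: float = 0.5
    flash_noise_sd: float = 2.0
    vein_bloom_mm: float = 0.0
    cohort_n: int = 9
    intersubject_conc_sd_mM: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n % 7 for n in self.fine_grid_shape):
            raise ValueError("fine_grid_shape must be divisible by 7 on every axis")
        if any(v <= 0 for v in self.fine_voxel_mm):
            raise ValueError("fine voxel sizes must be positive")
        if any(c <= 0 for c in self.tissue_conc_mM.values()):
            raise ValueError("all concentrations must be positive")
        if not (0.0 < self.vein_target_fraction < 0.3):
            raise ValueError("vein_target_fraction must lie in (0, 0.3)")
        if self.vein_radius_mm[0] <= 0 or self.vein_radius_mm[1] < self.vein_radius_mm[0]:
            raise ValueError("vein_radius_mm must be a positive (lo, hi) range")
        if self.flash_vein_drop_fraction < 0:
            raise ValueError("flash_vein_drop_fraction must be nonnegative")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.fine_grid_shape) * np.asarray(self.fine_voxel_mm)


@dataclass
class Phantom:
    """One synthetic subject: fine-grid truth volumes and coarse-grid PVE maps."""

    label_volume: np.ndarray
    conc_volume: np.ndarray
    truth_pve: dict[str, np.ndarray]
    brain_mask_fine: np.ndarray
    spec: PhantomSpec
    seed: int
    flash_volume: np.ndarray | None = None

    @property
    def coarse_shape(self) -> tuple[int, ...]:
        return self.truth_pve["wm"].shape


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _axis_coords(spec: PhantomSpec):
    """Voxel-centre coordinates (mm) per axis, shaped for broadcasting."""
    out = []
    for ax, (n, v) in enumerate(zip(spec.fine_grid_shape, spec.fine_voxel_mm)):
        c = (np.arange(n) + 0.5) * v
        shape = [1, 1, 1]
        shape[ax] = n
        out.append(c.reshape(shape))
    return out


def _brain_geometry(spec: PhantomSpec):
    fov = spec.fov_mm
    centre = fov * np.array([0.5, 0.5, 0.55])
    semi = fov * np.array([0.31, 0.34, 0.21])
    return centre, semi


def _ball_offsets(radius_mm: float, voxel_mm) -> np.ndarray:
    """Integer offsets of fine voxels within radius_mm of a point (ellipsoidal in index space)."""
    r_vox = [max(1, int(np.ceil(radius_mm / v))) for v in voxel_mm]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    d2 = sum((g * v) ** 2 for g, v in zip(grids, voxel_mm))
    sel = d2 <= radius_mm**2
    return np.stack([g[sel] for g in grids], axis=1)


def _mark_tube(mask: np.ndarray, points_mm: np.ndarray, radius_mm: float, spec: PhantomSpec) -> None:
    """Set mask voxels within radius of a polyline sampled at points_mm."""
    vox = np.asarray(spec.fine_voxel_mm)
    idx = np.floor(points_mm / vox).astype(int)
    offs = _ball_offsets(radius_mm, spec.fine_voxel_mm)
    all_idx = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    shape = np.asarray(spec.fine_grid_shape)
    ok = np.all((all_idx >= 0) & (all_idx < shape), axis=1)
    all_idx = all_idx[ok]
    mask[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] = True


def _random_walk(
    rng: np.random.Generator,
    start_mm: np.ndarray,
    length_mm: float,
    spec: PhantomSpec,
    seg_len_mm: float = 4.0,
    wiggle: float = 0.45,
    sample_mm: float = 0.35,
) -> np.ndarray:
    """Sample points (mm) along a piecewise-linear random-walk centreline."""
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    pts = [start_mm]
    pos = start_mm.astype(float)
    travelled = 0.0
    while travelled < length_mm:
        seg = min(seg_len_mm, length_mm - travelled)
        direction = direction + wiggle * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        n_samp = max(2, int(np.ceil(seg / sample_mm)))
        t = np.linspace(0.0, seg, n_samp)[1:]
        pts.append(pos + np.outer(t, direction))
        pos = pos + seg * direction
        travelled += seg
    return np.vstack([p.reshape(-1, 3) for p in pts])


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> Phantom:
    """Generate one synthetic subject with known ground truth.

    Veins are placed as random-walk cylinders until the vein fraction of
    fine brain voxels lies within +/-0.005 of ``vein_target_fraction``;
    an explicit error names the achieved fraction if the target is
    unreachable with the given radius range and vein budget.
    """
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    x, y, z = _axis_coords(spec)
    centre, semi = _brain_geometry(spec)

    u = np.sqrt(
        ((x - centre[0]) / semi[0]) ** 2
        + ((y - centre[1]) / semi[1]) ** 2
        + ((z - centre[2]) / semi[2]) ** 2
    )
    brain = u <= 1.0
    min_semi = float(semi.min())
    rim_u = spec.csf_rim_thickness_mm / min_semi
    gm_u = spec.gm_shell_thickness_mm / min_semi

    labels = np.zeros(spec.fine_grid_shape, dtype=np.uint8)
    labels[brain] = CSF  # rim by default
    labels[u <= 1.0 - rim_u] = GM
    labels[u <= 1.0 - rim_u - gm_u] = WM

    # central ventricles (CSF) inside the WM core
    vent_semi = semi * np.array([0.22, 0.35, 0.18])
    uv = np.sqrt(
        ((x - centre[0]) / vent_semi[0]) ** 2
        + ((y - centre[1]) / vent_semi[1]) ** 2
        + ((z - centre[2]) / vent_semi[2]) ** 2
    )
    labels[uv <= 1.0] = CSF

    # superior sagittal sinus: midline tube following the top of the brain
    sss_scale = max(0.1, (semi[2] - spec.sss_radius_mm - 1.0) / semi[2])
    yy = y.reshape(1, -1, 1)
    inside_y = np.abs(yy - centre[1]) <= 0.8 * semi[1]
    zc = centre[2] + semi[2] * sss_scale * np.sqrt(
        np.clip(1.0 - ((yy - centre[1]) / semi[1]) ** 2, 0.0, None)
    )
    d2 = (x - centre[0]) ** 2 + (z - zc) ** 2
    sss_mask = (d2 <= spec.sss_radius_mm**2) & inside_y & brain
    labels[sss_mask] = SSS

    # veins: add random-walk cylinders until the target fraction is met
    tissue = (labels == WM) | (labels == GM)
    brain_vox = int(brain.sum())
    brain_vol_mm3 = brain_vox * float(np.prod(spec.fine_voxel_mm))
    vein_mask = np.zeros(spec.fine_grid_shape, dtype=bool)
    tissue_idx = np.argwhere(tissue)
    vox = np.asarray(spec.fine_voxel_mm)
    r_lo, r_hi = spec.vein_radius_mm
    placed = 0
    frac = 0.0
    while placed < spec.vein_count:
        frac = vein_mask.sum() / brain_vox
        deficit = spec.vein_target_fraction - frac
        if deficit <= 0.002:
            break
        r = float(rng.uniform(r_lo, r_hi))
        budget_mm3 = 0.9 * deficit * brain_vol_mm3
        length = float(rng.uniform(20.0, 60.0))
        if np.pi * r * r * length > budget_mm3:
            length = budget_mm3 / (np.pi * r * r)
            if length < 5.0:  # deficit too small for this radius: shrink radius
                r = max(r_lo, float(np.sqrt(budget_mm3 / (np.pi * 10.0))))
                length = max(3.0, budget_mm3 / (np.pi * r * r))
        start = (tissue_idx[rng.integers(len(tissue_idx))] + 0.5) * vox
        pts = _random_walk(rng, start, length, spec)
        cand = np.zeros(spec.fine_grid_shape, dtype=bool)
        _mark_tube(cand, pts, r, spec)
        vein_mask |= cand & tissue
        placed += 1
    frac = vein_mask.sum() / brain_vox
    if spec.vein_count > 0 and abs(frac - spec.vein_target_fraction) > 0.005:
        raise ValueError(
            f"vein target fraction {spec.vein_target_fraction} unreachable: achieved "
            f"{frac:.4f} with {placed} veins of radius {spec.vein_radius_mm} mm"
        )
    labels[vein_mask] = VEIN

    # two vitreous humor spheres fully outside (below) the brain
    r_vh = spec.vh_sphere_radius_mm
    fov = spec.fov_mm
    z_vh = centre[2] - semi[2] - r_vh - 2.0
    for fx in (0.27, 0.73):
        c_vh = np.array([fx * fov[0], 0.5 * fov[1], z_vh])
        d2 = (x - c_vh[0]) ** 2 + (y - c_vh[1]) ** 2 + (z - c_vh[2]) ** 2
        labels[(d2 <= r_vh**2) & ~brain] = VH

    conc_lut = np.array(
        [
            0.0,
            spec.tissue_conc_mM["wm"],
            spec.tissue_conc_mM["gm"],
            spec.tissue_conc_mM["csf"],
            spec.tissue_conc_mM["blood"],
            spec.tissue_conc_mM["blood"],
            spec.tissue_conc_mM["vh"],
        ]
    )
    conc = conc_lut[labels]

    truth_pve = {
        name: block_downsample((labels == cls).astype(float))
        for cls, name in CLASS_NAMES.items()
        if cls != BACKGROUND
    }
    return Phantom(
        label_volume=labels,
        conc_volume=conc,
        truth_pve=truth_pve,
        brain_mask_fine=brain,
        spec=spec,
        seed=seed,
    )


def generate_flash(
    phantom: Phantom, spec: PhantomSpec | None = None, seed: int | None = None
) -> np.ndarray:
    """Synthetic T2*-weighted (FLASH-like) fine-grid volume.

    Tissue (and VH) sit at ``flash_tissue_level``; vein and SSS voxels
    are darkened by ``flash_vein_drop_fraction``.  When
    ``vein_bloom_mm`` > 0 the darkened support is dilated by that
    radius, emulating the fringe-field overestimation of vein extent by
    intra-voxel dephasing.  Additive Gaussian noise with
    ``flash_noise_sd`` completes the volume.
    """
    spec = phantom.spec if spec is None else spec
    if spec.flash_vein_drop_fraction < 0:
        raise ValueError("flash_vein_drop_fraction must be nonnegative")
    seed = spec.seed + 1 if seed is None else int(seed)
    labels = phantom.label_volume
    flash = np.zeros(spec.fine_grid_shape, dtype=float)
    flash[labels != BACKGROUND] = spec.flash_tissue_level
    dark = (labels == VEIN) | (labels == SSS)
    if spec.vein_bloom_mm > 0:
        offs = _ball_offsets(spec.vein_bloom_mm, spec.fine_voxel_mm)
        r_vox = offs.max(axis=0)
        grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
        d2 = sum((g * v) ** 2 for g, v in zip(grids, spec.fine_voxel_mm))
        structure = d2 <= spec.vein_bloom_mm**2
        dark = ndimage.binary_dilation(dark, structure=structure)
        dark &= labels != BACKGROUND
    flash[dark] = spec.flash_tissue_level * (1.0 - spec.flash_vein_drop_fraction)
    if spec.flash_noise_sd > 0:
        rng = np.random.default_rng(seed)
        flash = flash + rng.normal(0.0, spec.flash_noise_sd, size=flash.shape)
    return flash


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def cohort_specs(spec: PhantomSpec) -> list[tuple[PhantomSpec, int]]:
    """Per-subject (spec, seed) pairs for a cohort.

    Gray- and white-matter concentrations are perturbed per subject with
    sd ``intersubject_conc_sd_mM``; per-subject seeds derive from the
    master seed, so a fixed master seed reproduces the whole cohort.
    """
    if spec.cohort_n < 2:
        raise ValueError("cohort_n must be >= 2 (paired tests are undefined below that)")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.cohort_n):
        subject_seed = int(rng.integers(2**31 - 1))
        conc = dict(spec.tissue_conc_mM)
        sd = spec.intersubject_conc_sd_mM
        if sd > 0:
            conc["wm"] = max(1.0, conc["wm"] + rng.normal(0.0, sd))
            conc["gm"] = max(1.0, conc["gm"] + rng.normal(0.0, sd))
        out.append((replace(spec, tissue_conc_mM=conc, seed=subject_seed), subject_seed))
    return out


def generate_cohort(spec: PhantomSpec) -> list[Phantom]:
    """Generate a cohort of subjects, each with its FLASH volume attached."""
    subjects = []
    for sub_spec, sub_seed in cohort_specs(spec):
        ph = generate_phantom(sub_spec, sub_seed)
        ph.flash_volume = generate_flash(ph, sub_spec, sub_seed + 1)
        subjects.append(ph)
    return subjects
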