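"""End-to-end orchestration: phantom -> acquisition -> segmentation -> regression.

One :class:`RunConfig` holds every stage's parameters plus the master
seed; a run is fully reproducible from config + seed alone.  Per-subject
results and a Figure-style cohort report (mean +/- SEM and
Bonferroni-corrected paired t-tests for the four venous/tissue
comparisons) are returned as DataFrames and optionally written as TSV,
with intermediate volumes as NIfTI-1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionParams,
    B1Maps,
    BiexpT2,
    apply_b1,
    apply_psf,
    b1_correct,
    double_angle_flip,
    simulate_b1,
)
from .phantom import Phantom, PhantomSpec, cohort_specs, generate_flash, generate_phantom
from .pve_grids import PVEMap, block_downsample, make_masks, to_concentration, vh_reference
from .regression import cohort_compare, regional_fits, sss_mean
from .veinseg import HighPassParams, erode_brain_mask, gaussian_highpass, segment_veins

__all__ = [
    "RunConfig",
    "SubjectResult",
    "run_subject",
    "run_cohort",
    "save_nifti",
    "load_nifti",
    "DEFAULT_CONFIG_TOML",
]

log = logging.getLogger("navein")

# Default run configuration.  Physical constants carry their provenance
# as comments; everything is overridable per run.
DEFAULT_CONFIG_TOML = """\
# navein run configuration (TOML)

seed = 0
out_dir = "navein_out"

[phantom]
fine_grid_shape = [224, 224, 224]   # divisible by 7: one coarse voxel = 7x7x7 fine voxels
# fine voxel = coarse voxel / 7 -> 3.2/7 x 3.2/7 x 6.4/7 mm
vein_target_fraction = 0.031        # veins occupy ~3.1% of brain volume
vein_count = 120
sss_radius_mm = 3.0
vh_sphere_radius_mm = 14.0
csf_rim_thickness_mm = 2.0
flash_tissue_level = 100.0
flash_vein_drop_fraction = 0.5
flash_noise_sd = 2.0
vein_bloom_mm = 0.0
cohort_n = 9                        # nine-subject cohort
intersubject_conc_sd_mM = 2.5

[phantom.tissue_conc_mM]
wm = 37.8       # white matter sodium concentration, mM
gm = 39.5       # gray matter sodium concentration, mM
csf = 150.0     # cerebrospinal fluid, mM
blood = 87.0    # whole blood (in vitro literature), mM
vh = 134.0      # vitreous humor literature reference, mM

[acquisition]
tr_ms = 85.0        # repetition time
te_ms = 0.11        # ultra-short echo time
flip_deg = 30.0
readout_ms = 18.0   # TPI readout duration
rho = 0.2           # radial fraction of the TPI trajectory
nominal_voxel_mm = [3.2, 3.2, 6.4]  # sodium voxel, 1/(2 k_max)
apodization = "hamming"             # density-weighted Hamming-like filtering

[t2]
t2_fast_ms = 2.0    # fast component of blood sodium T2
t2_slow_ms = 17.0   # slow component of blood sodium T2
fast_fraction = 0.6 # 3/5 satellite-transition amplitude share

[veinseg]
hp_fwhm_mm = 3.0    # Gaussian high-pass FWHM for vein enhancement
erosion_size = 7    # 7x7 in-plane brain-mask erosion (3-voxel rind)
robust_k = 3.5      # MAD multiplier of the automatic negative threshold

[analysis]
sodium_noise_sd = 1.5   # additive noise on the coarse sodium image (mM-equivalent)
b1_amplitude = 0.15
b1_smoothness = 2.0
csf_excl = 0.01         # exclude voxels with CSF PVE >= 0.01
tissue_thresh = 0.5     # GM/WM region PVE threshold
na_vh_mM = 134.0        # VH reference concentration
sss_pve_thresh = 0.5
use_truth_veins = false # regress against ground-truth vein PVE instead of segmentation
n_comparisons = 4       # Bonferroni family: all, GM, WM, SSS
"""


@dataclass(frozen=True)
class RunConfig:
    """All parameters of one reproducible analysis run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    t2: BiexpT2 = field(default_factory=BiexpT2)
    hp: HighPassParams = field(default_factory=HighPassParams)
    sodium_noise_sd: float = 1.5
    b1_amplitude: float = 0.15
    b1_smoothness: float = 2.0
    csf_excl: float = 0.01
    tissue_thresh: float = 0.5
    na_vh_mM: float = 134.0
    sss_pve_thresh: float = 0.5
    use_truth_veins: bool = False
    n_comparisons: int = 4
    seed: int = 0
    out_dir: str = "navein_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        ph = dict(raw.get("phantom", {}))
        if "fine_grid_shape" in ph:
            ph["fine_grid_shape"] = tuple(ph["fine_grid_shape"])
        if "fine_voxel_mm" in ph:
            ph["fine_voxel_mm"] = tuple(ph["fine_voxel_mm"])
        if "vein_radius_mm" in ph:
            ph["vein_radius_mm"] = tuple(ph["vein_radius_mm"])
        acq = dict(raw.get("acquisition", {}))
        if "nominal_voxel_mm" in acq:
            acq["nominal_voxel_mm"] = tuple(acq["nominal_voxel_mm"])
        ana = dict(raw.get("analysis", {}))
        ana = {
            {"sss_pve_thresh": "sss_pve_thresh"}.get(k, k): v for k, v in ana.items()
        }
        seed = int(raw.get("seed", 0))
        ph.setdefault("seed", seed)
        return cls(
            phantom=PhantomSpec(**ph),
            acq=AcquisitionParams(**acq),
            t2=BiexpT2(**raw.get("t2", {})),
            hp=HighPassParams(**raw.get("veinseg", {})),
            seed=seed,
            out_dir=str(raw.get("out_dir", "navein_out")),
            **ana,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(volume: np.ndarray, voxel_mm, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal (identity-orientation) affine."""
    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), tuple(img.header.get_zooms()[:3])


# ---------------------------------------------------------------------------
# per-subject pipeline
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    """Everything the cohort report needs from one subject."""

    subject: int
    table: pd.DataFrame
    venous_mM: dict[str, float]
    sss_mM: float
    tissue_mM: dict[str, float]
    phantom: Phantom | None = None


def synthesize_sodium(
    phantom: Phantom,
    config: RunConfig,
    b1: B1Maps | None = None,
    noise_seed: int | None = None,
) -> np.ndarray:
    """Forward model: PSF smearing, block averaging, B1 modulation, noise, magnitude."""
    coarse = apply_psf(
        phantom.conc_volume,
        config.acq,
        config.t2,
        phantom.spec.fine_voxel_mm,
        noise_sd=0.0,
    )
    if b1 is not None:
        coarse = apply_b1(coarse, b1, config.acq.flip_deg)
    if config.sodium_noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        coarse = coarse + rng.normal(0.0, config.sodium_noise_sd, size=coarse.shape)
    return np.abs(coarse)


def _correct_b1(sodium: np.ndarray, b1: B1Maps, flip_deg: float) -> np.ndarray:
    """Recover the flip map with the double-angle method, then divide B1 out."""
    alpha = np.deg2rad(flip_deg) * b1.transmit_scale
    flip_est = double_angle_flip(np.sin(alpha), np.sin(2.0 * alpha))
    est = B1Maps(
        transmit_scale=flip_est / flip_deg, receive_sens=b1.receive_sens
    )
    return b1_correct(sodium, est, flip_deg)


def run_subject(
    config: RunConfig,
    subject_index: int = 0,
    out_dir: str | Path | None = None,
    keep_phantom: bool = False,
) -> SubjectResult:
    """Run the full pipeline for one cohort subject.

    Stages: phantom generation, FLASH synthesis, sodium forward model
    with B1 fields, double-angle B1 correction, vein segmentation,
    PVE downsampling, mask construction, VH referencing, vein-PVE
    regression (all/GM/WM) and the SSS measurement.  Any stage failure
    propagates with the stage named.
    """
    spec0 = replace(config.phantom, seed=config.seed)
    subjects = cohort_specs(spec0)
    if not (0 <= subject_index < len(subjects)):
        raise IndexError(f"subject_index {subject_index} outside cohort of {len(subjects)}")
    sub_spec, sub_seed = subjects[subject_index]

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed for subject {subject_index}: {exc}") from exc

    log.info("subject %d: generating phantom (seed %d)", subject_index, sub_seed)
    ph = stage("phantom", generate_phantom, sub_spec, sub_seed)
    flash = stage("flash", generate_flash, ph, sub_spec, sub_seed + 1)
    ph.flash_volume = flash

    b1 = stage(
        "b1", simulate_b1, ph.coarse_shape, config.b1_smoothness, config.b1_amplitude,
        sub_seed + 2,
    )
    sodium = stage("acquire", synthesize_sodium, ph, config, b1, sub_seed + 3)
    sodium = stage("b1_correct", _correct_b1, sodium, b1, config.acq.flip_deg)

    hp = stage("highpass", gaussian_highpass, flash, config.hp, sub_spec.fine_voxel_mm)
    eroded = stage("erode", erode_brain_mask, ph.brain_mask_fine, config.hp)
    vein_fine, threshold = stage("segment", segment_veins, hp, eroded, config.hp)

    if config.use_truth_veins:
        vein_pve = ph.truth_pve["vein"]
    else:
        vein_pve = stage("downsample", block_downsample, vein_fine.astype(float))
    pve = PVEMap(
        vein=vein_pve,
        gm=ph.truth_pve["gm"],
        wm=ph.truth_pve["wm"],
        csf=ph.truth_pve["csf"],
        sss=ph.truth_pve["sss"],
        vh=ph.truth_pve["vh"],
        provenance={"subject": subject_index, "seed": sub_seed, "vein_threshold": threshold},
    )
    masks = stage("masks", make_masks, pve, config.csf_excl, config.tissue_thresh)
    ref = stage("vh_reference", vh_reference, sodium, pve.vh, config.na_vh_mM)
    sodium_rel = sodium / ref.vh_mean_signal

    fits = stage("regress", regional_fits, sodium_rel, pve, masks, config.na_vh_mM)
    sss = stage("sss", sss_mean, sodium, pve.sss, ref, config.sss_pve_thresh)

    conc_img = to_concentration(sodium, ref)
    tissue_mM = {
        "all": float(conc_img[masks.brain_tissue_mask].mean()),
        "gm": float(conc_img[masks.gm_roi].mean()),
        "wm": float(conc_img[masks.wm_roi].mean()),
    }
    venous_mM = {region: fit.apparent_conc_mM for region, fit in fits.items()}

    rows = [
        {
            "subject": subject_index,
            "region": region,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "value_at_pve1": fit.value_at_pve1,
            "apparent_mM": fit.apparent_conc_mM,
            "n_voxels": fit.n_voxels,
        }
        for region, fit in fits.items()
    ]
    rows.append(
        {
            "subject": subject_index,
            "region": "sss",
            "slope": np.nan,
            "intercept": np.nan,
            "value_at_pve1": sss / config.na_vh_mM,
            "apparent_mM": sss,
            "n_voxels": int((pve.sss >= config.sss_pve_thresh).sum()),
        }
    )
    table = pd.DataFrame(rows)

    result = SubjectResult(
        subject=subject_index,
        table=table,
        venous_mM=venous_mM,
        sss_mM=sss,
        tissue_mM=tissue_mM,
        phantom=ph if keep_phantom else None,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vm = sub_spec.fine_voxel_mm
        cm = tuple(7 * v for v in vm)
        save_nifti(ph.label_volume, vm, out / f"sub-{subject_index:02d}_labels.nii.gz")
        save_nifti(flash, vm, out / f"sub-{subject_index:02d}_flash.nii.gz")
        save_nifti(sodium, cm, out / f"sub-{subject_index:02d}_sodium.nii.gz")
        save_nifti(vein_pve, cm, out / f"sub-{subject_index:02d}_veinpve.nii.gz")
        table.to_csv(out / f"sub-{subject_index:02d}_results.tsv", sep="\t", index=False)
        (out / f"sub-{subject_index:02d}_meta.json").write_text(
            json.dumps({"seed": sub_seed, "vein_threshold": threshold}, indent=2)
        )
    return result


def run_cohort(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Run all cohort subjects and build the Figure-style summary report.

    Returns ``{"subjects": per-subject rows, "summary": mean +/- SEM per
    measure, "tests": paired t-test rows for the four comparisons}``.
    """
    n = config.phantom.cohort_n
    results = [run_subject(config, i, out_dir=out_dir) for i in range(n)]

    subject_rows = pd.concat([r.table for r in results], ignore_index=True)

    measures = {
        "vein_all": [r.venous_mM["all"] for r in results],
        "vein_gm": [r.venous_mM["gm"] for r in results],
        "vein_wm": [r.venous_mM["wm"] for r in results],
        "sss": [r.sss_mM for r in results],
        "tissue_gm": [r.tissue_mM["gm"] for r in results],
        "tissue_wm": [r.tissue_mM["wm"] for r in results],
    }
    tissue_all = [r.tissue_mM["all"] for r in results]
    summary = pd.DataFrame(
        {
            "measure": list(measures),
            "mean_mM": [float(np.mean(v)) for v in measures.values()],
            "sem_mM": [float(np.std(v, ddof=1) / np.sqrt(n)) for v in measures.values()],
        }
    )
    comparisons = {
        "vein_all_vs_tissue": (measures["vein_all"], tissue_all),
        "vein_gm_vs_gm": (measures["vein_gm"], measures["tissue_gm"]),
        "vein_wm_vs_wm": (measures["vein_wm"], measures["tissue_wm"]),
        "sss_vs_gm": (measures["sss"], measures["tissue_gm"]),
    }
    test_rows = []
    for name, (a, b) in comparisons.items():
        cs = cohort_compare(a, b, n_comparisons=config.n_comparisons)
        test_rows.append(
            {
                "comparison": name,
                "t_statistic": cs.t_statistic,
                "dof": cs.dof,
                "p_bonferroni": cs.p_bonferroni,
                "mean_venous_mM": cs.mean_venous,
                "mean_tissue_mM": cs.mean_tissue,
            }
        )
    tests = pd.DataFrame(test_rows)

    report = {"subjects": subject_rows, "summary": summary, "tests": tests}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            df.to_csv(out / f"cohort_{name}.tsv", sep="\t", index=False)
        (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    return report
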