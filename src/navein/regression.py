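"""Vein-PVE regression and cohort statistics.

The apparent venous sodium concentration is estimated by ordinary least
squares of the VH-normalized sodium signal on vein partial volume over
all voxels in the brain tissue mask (and separately within GM-only and
WM-only regions), extrapolated to vein PVE = 1.  The superior sagittal
sinus, too large to be captured by the high-pass vein mask, is measured
directly as the mean over voxels with SSS PVE >= 0.5.  Cohort-level
comparisons use Bonferroni-corrected paired two-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .pve_grids import MaskSet, PVEMap, ReferenceValue

__all__ = [
    "RegressionResult",
    "CohortStats",
    "fit_vein_pve",
    "regional_fits",
    "sss_mean",
    "cohort_compare",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of VH-normalized sodium signal against vein PVE."""

    region: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_voxels: int
    na_vh_mM: float = 134.0

    @property
    def value_at_pve1(self) -> float:
        """Extrapolated VH-relative signal of a pure-vein voxel."""
        return self.intercept + self.slope

    @property
    def apparent_conc_mM(self) -> float:
        """Apparent venous sodium concentration via the VH reference."""
        return self.value_at_pve1 * self.na_vh_mM


@dataclass(frozen=True)
class CohortStats:
    """Paired comparison of venous against tissue values across subjects."""

    venous_values: tuple[float, ...]
    tissue_values: tuple[float, ...]
    mean_venous: float
    sem_venous: float
    mean_tissue: float
    sem_tissue: float
    t_statistic: float
    dof: int
    p_uncorrected: float
    p_bonferroni: float
    n_comparisons: int = 4


def fit_vein_pve(
    sodium_rel: np.ndarray,
    vein_pve: np.ndarray,
    mask: np.ndarray,
    region: str = "all",
    na_vh_mM: float = 134.0,
) -> RegressionResult:
    """OLS with intercept of VH-normalized signal on vein PVE over masked voxels."""
    m = np.asarray(mask).astype(bool)
    y = np.asarray(sodium_rel, dtype=float)[m]
    x = np.asarray(vein_pve, dtype=float)[m]
    if y.size < 3:
        raise ValueError(f"regression in region '{region}' needs >= 3 voxels, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate design in region '{region}': vein PVE is constant")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        region=region,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        n_voxels=int(y.size),
        na_vh_mM=na_vh_mM,
    )


def regional_fits(
    sodium_rel: np.ndarray,
    pve: PVEMap,
    masks: MaskSet,
    na_vh_mM: float = 134.0,
) -> dict[str, RegressionResult]:
    """Vein-PVE fits over all brain tissue, GM-only and WM-only voxels."""
    out = {}
    for region, m in (
        ("all", masks.brain_tissue_mask),
        ("gm", masks.gm_roi),
        ("wm", masks.wm_roi),
    ):
        if not np.any(m):
            raise ValueError(f"empty region of interest: {region}")
        out[region] = fit_vein_pve(sodium_rel, pve.vein, m, region=region, na_vh_mM=na_vh_mM)
    return out


def sss_mean(
    sodium_image: np.ndarray,
    sss_pve: np.ndarray,
    ref: ReferenceValue,
    thresh: float = 0.5,
) -> float:
    """Mean SSS sodium concentration (mM) over voxels with SSS PVE >= thresh."""
    sel = np.asarray(sss_pve) >= thresh
    if not sel.any():
        raise ValueError(f"no voxel has SSS PVE >= {thresh}")
    mean_signal = float(np.asarray(sodium_image)[sel].mean())
    return mean_signal / ref.vh_mean_signal * ref.na_vh_mM


def cohort_compare(
    venous_values,
    tissue_values,
    n_comparisons: int = 4,
) -> CohortStats:
    """Paired two-tailed t-test of venous against tissue values, Bonferroni-corrected."""
    v = np.asarray(venous_values, dtype=float)
    t_ = np.asarray(tissue_values, dtype=float)
    if v.shape != t_.shape:
        raise ValueError("paired arrays must have equal length")
    n = v.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = v - t_
    if np.std(diff, ddof=1) == 0.0:
        # zero-variance differences: identical arrays give the null result,
        # a constant nonzero shift leaves t undefined and is flagged
        if diff[0] == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError(
                "degenerate paired t-test: differences have zero variance but "
                f"nonzero mean {diff[0]}"
            )
    else:
        res = stats.ttest_rel(v, t_)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return CohortStats(
        venous_values=tuple(v),
        tissue_values=tuple(t_),
        mean_venous=float(v.mean()),
        sem_venous=float(v.std(ddof=1) / np.sqrt(n)),
        mean_tissue=float(t_.mean()),
        sem_tissue=float(t_.std(ddof=1) / np.sqrt(n)),
        t_statistic=t_stat,
        dof=n - 1,
        p_uncorrected=p,
        p_bonferroni=min(1.0, p * n_comparisons),
        n_comparisons=n_comparisons,
    )
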