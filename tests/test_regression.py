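"""Vein-PVE regression, SSS measurement and cohort statistics."""

import numpy as np
import pytest

from navein import (
    MaskSet,
    ReferenceValue,
    cohort_compare,
    fit_vein_pve,
    regional_fits,
    sss_mean,
)


def _ols_normal_equations(x, y):
    """Independent closed-form oracle: (X'X)^-1 X'y with an intercept column."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]  # intercept, slope


class TestFitVeinPVE:
    def test_exact_line_extrapolates_exactly(self):
        x = np.array([0.0, 0.1, 0.2, 0.4]).reshape(2, 2, 1)
        y = 0.3 + 0.2 * x
        fit = fit_vein_pve(y, x, np.ones_like(x, bool))
        assert fit.value_at_pve1 == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        x = rng.random(n)
        y = 0.4 + 0.3 * x + rng.normal(0, 0.05, n)
        fit = fit_vein_pve(y.reshape(-1, 1, 1), x.reshape(-1, 1, 1),
                           np.ones((n, 1, 1), bool))
        b0, b1 = _ols_normal_equations(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)

    def test_constant_predictor_rejected(self):
        y = np.random.default_rng(0).random((2, 2, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_vein_pve(y, np.full((2, 2, 2), 0.3), np.ones((2, 2, 2), bool))

    def test_needs_three_voxels(self):
        x = np.array([[[0.0, 1.0]]])
        with pytest.raises(ValueError, match="3 voxels"):
            fit_vein_pve(x, x, np.ones_like(x, bool))

    def test_apparent_concentration_uses_vh_scale(self):
        x = np.linspace(0, 0.5, 8).reshape(2, 2, 2)
        y = 0.25 + 0.25 * x
        fit = fit_vein_pve(y, x, np.ones_like(x, bool))
        assert fit.apparent_conc_mM == pytest.approx(0.5 * 134.0)


class TestRegionalFits:
    @staticmethod
    def _masks(shape, gm, wm):
        return MaskSet(
            brain_tissue_mask=np.ones(shape, bool),
            gm_roi=gm,
            wm_roi=wm,
            csf_excl=0.01,
            tissue_thresh=0.5,
        )

    def test_identical_data_identical_fits(self, truth_pvemap):
        rng = np.random.default_rng(0)
        shape = truth_pvemap.shape
        y = 0.3 + 0.2 * truth_pvemap.vein + rng.normal(0, 0.01, shape)
        roi = truth_pvemap.vein >= 0.0  # everything
        masks = self._masks(shape, roi.copy(), roi.copy())
        fits = regional_fits(y, truth_pvemap, masks)
        assert fits["gm"].slope == pytest.approx(fits["wm"].slope)
        assert fits["gm"].intercept == pytest.approx(fits["wm"].intercept)

    def test_vein_free_region_has_near_zero_slope(self):
        rng = np.random.default_rng(1)
        shape = (6, 6, 6)
        vein = np.zeros(shape)
        gm = np.zeros(shape, bool)
        gm[:3] = True
        vein[gm] = rng.random(gm.sum()) * 0.4
        vein[~gm] = rng.normal(0, 1e-4, (~gm).sum()) ** 2  # tiny residual PVE
        y = np.full(shape, 0.3) + 0.2 * np.where(gm, vein, 0.0)
        from navein import PVEMap

        pve = PVEMap(vein=vein, gm=gm.astype(float), wm=(~gm).astype(float),
                     csf=np.zeros(shape), sss=np.zeros(shape))
        fits = regional_fits(y, pve, self._masks(shape, gm, ~gm))
        assert abs(fits["wm"].slope) < 1e-6
        assert fits["gm"].slope == pytest.approx(0.2, abs=1e-12)

    def test_region_voxel_counts_nest(self, truth_pvemap):
        from navein import make_masks

        rng = np.random.default_rng(2)
        masks = make_masks(truth_pvemap)
        y = 0.3 + 0.2 * truth_pvemap.vein + rng.normal(0, 0.01, truth_pvemap.shape)
        fits = regional_fits(y, truth_pvemap, masks)
        assert fits["all"].n_voxels >= fits["gm"].n_voxels + fits["wm"].n_voxels

    def test_empty_region_names_it(self, truth_pvemap):
        masks = self._masks(truth_pvemap.shape,
                            np.zeros(truth_pvemap.shape, bool),
                            np.ones(truth_pvemap.shape, bool))
        with pytest.raises(ValueError, match="gm"):
            regional_fits(np.ones(truth_pvemap.shape), truth_pvemap, masks)


class TestSSSMean:
    REF = ReferenceValue(vh_mean_signal=100.0, eroded_voxel_count=5)

    def test_uniform_sss_at_reference_level(self):
        sss = np.zeros((3, 3, 3))
        sss[1, 1, 1] = 0.8
        signal = np.full((3, 3, 3), 100.0)
        assert sss_mean(signal, sss, self.REF) == pytest.approx(134.0)

    def test_threshold_above_max_pve_errors(self):
        sss = np.full((2, 2, 2), 0.9)
        with pytest.raises(ValueError, match="SSS"):
            sss_mean(np.ones((2, 2, 2)), sss, self.REF, thresh=1.0)


class TestCohortCompare:
    def test_identical_arrays_give_null_result(self):
        cs = cohort_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cs.t_statistic == 0.0
        assert cs.p_bonferroni == 1.0

    def test_constant_nonzero_shift_flagged_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohort_compare([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_textbook_t_statistic(self):
        # differences [1, 2, 3]: t = mean/ (sd/sqrt(3)) = 2 / (1/sqrt(3)) = 2 sqrt(3)
        cs = cohort_compare([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert cs.t_statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert cs.dof == 2

    def test_bonferroni_caps_at_one(self):
        cs = cohort_compare([1.0, 2.1, 2.9, 4.2], [1.05, 2.0, 3.0, 4.1])
        assert cs.p_bonferroni == min(1.0, cs.p_uncorrected * 4)
        assert cs.p_bonferroni <= 1.0

    def test_mean_and_sem(self):
        cs = cohort_compare([1.0, 2.0, 3.0, 6.0], [0.0, 1.0, 2.0, 3.0])
        assert cs.mean_venous == 3.0
        assert cs.sem_venous == pytest.approx(np.std([1, 2, 3, 6], ddof=1) / 2)

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            cohort_compare([1.0], [2.0])
        with pytest.raises(ValueError):
            cohort_compare([1.0, 2.0], [1.0, 2.0, 3.0])
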