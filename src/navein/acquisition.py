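"""Sodium-image forward model for a density-weighted TPI acquisition.

The acquisition is a center-out twisted projection imaging (TPI) readout:
a straight radial segment out to a fraction ``rho`` of k_max, then a
twisted segment modelled with constant 3D sampling density
(k proportional to t^(1/3)).  The sampling density is designed to apply
an approximately Hamming-shaped apodization, and the fast biexponential
transverse relaxation of sodium decays the signal along the readout.
Together these define a k-space weighting; its inverse transform is the
real-space point spread function (PSF) that smears vein signal into
neighbouring voxels.  Convolution with that PSF plus block averaging to
the coarse sodium grid, noise, and multiplicative B1 fields constitute
the full image synthesis used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionParams",
    "BiexpT2",
    "PSFModel",
    "B1Maps",
    "tpi_time_map",
    "kspace_weighting",
    "build_psf",
    "apply_psf",
    "simulate_b1",
    "apply_b1",
    "double_angle_flip",
    "b1_correct",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Constants of the sodium acquisition.

    ``nominal_voxel_mm`` defines k_max per axis through 1/(2*k_max);
    ``rho`` is the radial fraction of the TPI trajectory and
    ``readout_ms`` the total readout duration.  TR/flip-angle saturation
    is treated as absorbed into the density-weighted design and does not
    enter the forward model.
    """

    tr_ms: float = 85.0
    te_ms: float = 0.11
    flip_deg: float = 30.0
    readout_ms: float = 18.0
    rho: float = 0.2
    nominal_voxel_mm: tuple[float, float, float] = (3.2, 3.2, 6.4)
    apodization: str = "hamming"

    def __post_init__(self) -> None:
        if not (self.readout_ms > self.te_ms >= 0):
            raise ValueError("require readout_ms > te_ms >= 0")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if any(v <= 0 for v in self.nominal_voxel_mm):
            raise ValueError("voxel sizes must be positive")
        if self.apodization not in ("hamming", "rectangular"):
            raise ValueError("apodization must be 'hamming' or 'rectangular'")

    @property
    def kmax_per_mm(self) -> np.ndarray:
        return 1.0 / (2.0 * np.asarray(self.nominal_voxel_mm, dtype=float))


@dataclass(frozen=True)
class BiexpT2:
    """Biexponential transverse relaxation of spin-3/2 sodium.

    Defaults are the fast/slow components of blood; the amplitude split
    defaults to the 3/5 satellite / 2/5 central quadrupolar partition.
    """

    t2_fast_ms: float = 2.0
    t2_slow_ms: float = 17.0
    fast_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.t2_fast_ms < self.t2_slow_ms):
            raise ValueError("require 0 < t2_fast < t2_slow")
        if not (0.0 <= self.fast_fraction <= 1.0):
            raise ValueError("fast_fraction must lie in [0, 1]")

    def decay(self, t_ms: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        f = self.fast_fraction
        return f * np.exp(-t / self.t2_fast_ms) + (1.0 - f) * np.exp(-t / self.t2_slow_ms)


@dataclass(frozen=True)
class PSFModel:
    """Real-space point spread function on a fine grid.

    ``kernel`` is centred (peak at the array centre), DC-normalized to
    unit sum; ``fwhm_mm`` holds the full width at half maximum measured
    on axis profiles through the peak.
    """

    kernel: np.ndarray
    fwhm_mm: tuple[float, float, float]
    fine_voxel_mm: tuple[float, float, float]


@dataclass(frozen=True)
class B1Maps:
    """Multiplicative transmit (actual/nominal flip) and receive fields."""

    transmit_scale: np.ndarray
    receive_sens: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.transmit_scale <= 0) or np.any(self.receive_sens <= 0):
            raise ValueError("B1 maps must be strictly positive")


# ---------------------------------------------------------------------------
# k-space trajectory timing and weighting
# ---------------------------------------------------------------------------

def tpi_time_map(k_norm: np.ndarray | float, acq: AcquisitionParams) -> np.ndarray:
    """Time (ms since readout start) at which normalized radius k_norm is sampled.

    Linear in k on the radial segment (k_norm <= rho); on the twisted
    segment k grows as t^(1/3) (constant 3D sampling density), scaled so
    the trajectory reaches k_norm = 1 at the end of the readout.  The
    two branches are continuous at rho and the map is monotone.
    """
    k = np.asarray(k_norm, dtype=float)
    if np.any(k < 0) or np.any(k > 1):
        raise ValueError("k_norm must lie in [0, 1]")
    t_rho = acq.readout_ms * acq.rho**3  # twisted branch evaluated at rho
    return np.where(k <= acq.rho, t_rho * k / acq.rho, acq.readout_ms * k**3)


def _apodization(k: np.ndarray, kind: str) -> np.ndarray:
    if kind == "hamming":
        return 0.54 + 0.46 * np.cos(np.pi * k)
    return np.ones_like(k)


def kspace_weighting(
    k_norm: np.ndarray | float, acq: AcquisitionParams, t2: BiexpT2
) -> np.ndarray:
    """Signal weighting at normalized k-space radius k_norm.

    Product of the apodization window (Hamming(x) = 0.54 + 0.46 cos(pi x)
    or rectangular) and the biexponential decay evaluated at
    TE + t(k_norm) along the readout.
    """
    k = np.asarray(k_norm, dtype=float)
    t = acq.te_ms + tpi_time_map(k, acq)
    return _apodization(k, acq.apodization) * t2.decay(t)


# ---------------------------------------------------------------------------
# PSF construction and measurement
# ---------------------------------------------------------------------------

def _weighting_on_grid(
    acq: AcquisitionParams,
    t2: BiexpT2,
    fine_voxel_mm: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """k-space weighting sampled on the FFT frequency grid, zero beyond k_max."""
    kmax = acq.kmax_per_mm
    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, fine_voxel_mm)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    knorm = np.sqrt(
        (kx / kmax[0]) ** 2 + (ky / kmax[1]) ** 2 + (kz / kmax[2]) ** 2
    )
    w = np.zeros(np.broadcast_shapes(kx.shape, ky.shape, kz.shape), dtype=float)
    inside = knorm <= 1.0
    kin = np.clip(knorm, 0.0, 1.0)
    w_all = kspace_weighting(kin, acq, t2)
    w[inside] = w_all[inside]
    return w / w[0, 0, 0]  # DC gain 1


def _profile_fwhm(profile: np.ndarray, spacing: float) -> float:
    """FWHM of a peaked 1D profile by linear interpolation at half maximum."""
    p = int(np.argmax(profile))
    half = profile[p] / 2.0

    def crossing(step: int) -> float:
        i = p
        while 0 < i + step < profile.size - 1 and profile[i + step] >= half:
            i += step
        a, b = profile[i], profile[i + step]
        if b >= half:  # never crossed inside the support
            raise ValueError("half-maximum crossing outside kernel support")
        frac = (a - half) / (a - b)
        return i + frac * step

    return (crossing(+1) - crossing(-1)) * spacing


def build_psf(
    acq: AcquisitionParams,
    t2: BiexpT2,
    fine_voxel_mm: tuple[float, float, float] = (3.2 / 7, 3.2 / 7, 6.4 / 7),
    support_shape: tuple[int, int, int] = (128, 128, 128),
    tail_tol: float = 2e-3,
) -> PSFModel:
    """Real-space PSF of the acquisition on a fine grid.

    The anisotropic k-space weighting (radius scaled by per-axis k_max)
    is inverse-transformed to real space, centred and DC-normalized.
    FWHM is measured per axis on profiles through the peak.  Raises if
    the support is too small to contain the kernel tails below
    ``tail_tol`` of the peak.  The hard sampling cutoff at k_max makes
    the ringing envelope decay only quadratically with distance, so the
    default tolerance is set where wrap-around bias is well below the
    noise floor rather than at machine precision.
    """
    w = _weighting_on_grid(acq, t2, fine_voxel_mm, support_shape)
    kernel = np.fft.fftshift(np.fft.ifftn(w).real)
    peak = kernel.max()
    # worst absolute tail over the six boundary faces
    tails = max(
        np.abs(kernel[0, :, :]).max(),
        np.abs(kernel[-1, :, :]).max(),
        np.abs(kernel[:, 0, :]).max(),
        np.abs(kernel[:, -1, :]).max(),
        np.abs(kernel[:, :, 0]).max(),
        np.abs(kernel[:, :, -1]).max(),
    )
    if tails > tail_tol * peak:
        raise ValueError(
            f"PSF support too small: boundary tail mass {tails / peak:.2e} of peak "
            f"exceeds {tail_tol:.0e}"
        )
    kernel = kernel / kernel.sum()
    centre = tuple(n // 2 for n in support_shape)
    fwhm = []
    for ax in range(3):
        idx = list(centre)
        idx[ax] = slice(None)
        fwhm.append(_profile_fwhm(kernel[tuple(idx)], fine_voxel_mm[ax]))
    return PSFModel(kernel=kernel, fwhm_mm=tuple(fwhm), fine_voxel_mm=tuple(fine_voxel_mm))


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def apply_psf(
    conc_volume: np.ndarray,
    acq: AcquisitionParams,
    t2: BiexpT2,
    fine_voxel_mm: tuple[float, float, float],
    coarse_factor: tuple[int, int, int] = (7, 7, 7),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Synthesize the coarse-grid sodium image from a fine-grid concentration map.

    Convolves with the acquisition PSF in the transform domain (periodic
    boundary; the phantom background is zero so wrap-around is
    negligible), block-averages each ``coarse_factor`` cell to the
    sodium grid, adds independent zero-mean Gaussian noise and returns
    the magnitude.  The weighting is DC-normalized, so a uniform volume
    is reproduced at its own level.  Noise-free synthesis returns the
    signed convolution (so linearity and signal conservation hold
    exactly); with noise the magnitude is returned, as in a
    reconstructed MR image.
    """
    vol = np.asarray(conc_volume, dtype=float)
    if any(n % f for n, f in zip(vol.shape, coarse_factor)):
        raise ValueError(
            f"fine shape {vol.shape} not divisible by coarse factor {coarse_factor}"
        )
    w = _weighting_on_grid(acq, t2, fine_voxel_mm, vol.shape)
    smeared = np.fft.ifftn(np.fft.fftn(vol) * w).real
    from .pve_grids import block_downsample  # local import avoids a cycle

    coarse = block_downsample(smeared, coarse_factor)
    if noise_sd:
        rng = np.random.default_rng(seed)
        coarse = np.abs(coarse + rng.normal(0.0, noise_sd, size=coarse.shape))
    return coarse


# ---------------------------------------------------------------------------
# B1 fields
# ---------------------------------------------------------------------------

def simulate_b1(
    coarse_shape: tuple[int, int, int],
    smoothness: float = 2.0,
    amplitude: float = 0.15,
    seed: int | None = None,
) -> B1Maps:
    """Smooth multiplicative transmit/receive fields centred on 1.

    Gaussian random fields smoothed with ``smoothness`` voxels sigma and
    rescaled so deviations from 1 are bounded by ``amplitude``.
    """
    if amplitude >= 0.5:
        raise ValueError("amplitude must be < 0.5")
    rng = np.random.default_rng(seed)

    def field() -> np.ndarray:
        if amplitude == 0.0:
            return np.ones(coarse_shape)
        g = ndimage.gaussian_filter(rng.standard_normal(coarse_shape), smoothness)
        g -= g.mean()
        peak = np.abs(g).max()
        if peak == 0.0:
            return np.ones(coarse_shape)
        return 1.0 + amplitude * g / peak

    return B1Maps(transmit_scale=field(), receive_sens=field())


def apply_b1(image: np.ndarray, b1: B1Maps, flip_deg: float) -> np.ndarray:
    """Forward B1 modulation: scale by receive sensitivity and flip-angle sine ratio."""
    actual = np.deg2rad(flip_deg) * b1.transmit_scale
    return image * b1.receive_sens * np.sin(actual) / np.sin(np.deg2rad(flip_deg))


def double_angle_flip(signal_alpha, signal_2alpha):
    """Actual flip angle (degrees) from a double flip-angle image pair.

    For signals proportional to sin(a) and sin(2a) the actual flip is
    arccos(S_2a / (2 S_a)).  Raises where the ratio is outside [-1, 1]
    (noise-dominated voxels).
    """
    s1 = np.asarray(signal_alpha, dtype=float)
    s2 = np.asarray(signal_2alpha, dtype=float)
    if np.any(s1 <= 0):
        raise ValueError("signal_alpha must be positive")
    ratio = s2 / (2.0 * s1)
    if np.any(np.abs(ratio) > 1.0):
        raise ValueError("|signal_2alpha / (2 signal_alpha)| > 1: noise-dominated voxel")
    return np.degrees(np.arccos(ratio))


def b1_correct(image: np.ndarray, b1: B1Maps, flip_deg: float) -> np.ndarray:
    """Undo B1 modulation: divide by receive sensitivity and sin(actual)/sin(nominal)."""
    if image.shape != b1.receive_sens.shape:
        raise ValueError("image and B1 map shapes differ")
    actual = np.deg2rad(flip_deg) * b1.transmit_scale
    return image / b1.receive_sens / (np.sin(actual) / np.sin(np.deg2rad(flip_deg)))
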