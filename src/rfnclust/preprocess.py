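"""Minimal temporal/spatial conditioning for desk-scale resting-state data.

Covers the light final steps of a typical resting-state preprocessing chain:
polynomial baseline removal, zero-phase low-pass filtering at 0.08 Hz, Gaussian
smoothing restricted to a gray-matter mask, and estimation of the effective
smoothness (FWHM) of the data by the classic variance-of-spatial-differences
formula.  Acquisition-side steps (motion correction, normalization, nuisance
regression) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import GrayMask, TimeSeriesVolume

__all__ = [
    "SmoothnessEstimate",
    "detrend_poly",
    "lowpass",
    "smooth_masked",
    "estimate_fwhm",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.355


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM of the effective spatial autocorrelation, in mm."""

    fwhm_mm: np.ndarray  # (3,) per axis
    geometric_mean_mm: float


def detrend_poly(vol: TimeSeriesVolume, order: int = 3) -> TimeSeriesVolume:
    """Remove a per-voxel least-squares polynomial baseline of given order.

    order 0 subtracts the per-voxel mean; order 3 is the conventional cubic
    baseline removal.  The residual has (approximately) zero mean per voxel.
    """
    t = vol.n_timepoints
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > t - 2:
        raise ValueError(f"order {order} too high for {t} timepoints")
    # Legendre-style orthonormal basis on [-1, 1] for numerical stability
    x = np.linspace(-1.0, 1.0, t)
    basis = np.polynomial.legendre.legvander(x, order)  # (t, order+1)
    q, _ = np.linalg.qr(basis)
    flat = vol.data.reshape(-1, t)
    fitted = (flat @ q) @ q.T
    out = (flat - fitted).reshape(vol.data.shape)
    return TimeSeriesVolume(data=out, affine=vol.affine.copy(), tr_s=vol.tr_s)


def lowpass(vol: TimeSeriesVolume, cutoff_hz: float = 0.08, transition_frac: float = 0.25) -> TimeSeriesVolume:
    """Zero-phase frequency-domain low-pass filter.

    The transfer function is 1 up to ``cutoff_hz`` and rolls off along a raised
    cosine over ``[cutoff, cutoff * (1 + transition_frac)]``; zero-phase
    filtering leaves correlation structure between voxels untouched.
    """
    nyquist = 1.0 / (2.0 * vol.tr_s)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    t = vol.n_timepoints
    freqs = np.fft.rfftfreq(t, d=vol.tr_s)
    hi = cutoff_hz * (1.0 + transition_frac)
    response = np.ones_like(freqs)
    roll = (freqs > cutoff_hz) & (freqs < hi)
    response[roll] = 0.5 * (1.0 + np.cos(np.pi * (freqs[roll] - cutoff_hz) / (hi - cutoff_hz)))
    response[freqs >= hi] = 0.0
    flat = vol.data.reshape(-1, t)
    filtered = np.fft.irfft(np.fft.rfft(flat, axis=1) * response, n=t, axis=1)
    return TimeSeriesVolume(
        data=filtered.reshape(vol.data.shape), affine=vol.affine.copy(), tr_s=vol.tr_s
    )


def _masked_gaussian_3d(field: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian smoothing renormalized over in-mask support (no mass borrowed
    from outside the mask)."""
    m = mask.astype(np.float64)
    num = gaussian_filter(field * m, sigma=sigma_vox)
    den = gaussian_filter(m, sigma=sigma_vox)
    out = np.zeros_like(field)
    good = mask & (den > 1e-12)
    out[good] = num[good] / den[good]
    return out


def smooth_masked(vol: TimeSeriesVolume, mask: GrayMask, fwhm_mm: float) -> TimeSeriesVolume:
    """Spatially smooth each timeframe with a Gaussian kernel restricted to the mask."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return TimeSeriesVolume(data=vol.data.copy(), affine=vol.affine.copy(), tr_s=vol.tr_s)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vol.voxel_size_mm
    out = np.zeros_like(vol.data)
    for ti in range(vol.n_timepoints):
        out[..., ti] = _masked_gaussian_3d(vol.data[..., ti], mask.data, sigma_vox)
    return TimeSeriesVolume(data=out, affine=vol.affine.copy(), tr_s=vol.tr_s)


def estimate_fwhm(vol: TimeSeriesVolume, mask: GrayMask) -> SmoothnessEstimate:
    """Estimate the effective spatial smoothness of the data.

    Uses the variance-of-differences formula per axis i:

        FWHM_i = dx_i * sqrt( -2 ln 2 / ln(1 - s2_diff_i / (2 s2)) )

    where s2 is the spatial variance of the field over in-mask voxels and
    s2_diff_i the variance of first differences between in-mask neighbors along
    axis i.  Estimates are averaged over timeframes; an axis whose ratio leaves
    the formula undefined (spatially uncorrelated data) reports 0.
    """
    m = mask.data
    dx = vol.voxel_size_mm
    per_axis: list[list[float]] = [[], [], []]
    any_valid_pairs = False
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair_mask = m[tuple(sl_a)] & m[tuple(sl_b)]
        if pair_mask.sum() < 1:
            continue
        any_valid_pairs = True
        for ti in range(vol.n_timepoints):
            field = vol.data[..., ti]
            vals = field[m]
            s2 = vals.var()
            if s2 < 1e-30:
                raise ValueError("zero spatial variance: smoothness is undefined")
            diff = field[tuple(sl_b)] - field[tuple(sl_a)]
            s2d = diff[pair_mask].var() + diff[pair_mask].mean() ** 2  # E[diff^2]
            ratio = 1.0 - s2d / (2.0 * s2)
            if ratio <= 0 or ratio >= 1:
                per_axis[axis].append(0.0)
            else:
                per_axis[axis].append(float(dx[axis] * np.sqrt(-2.0 * np.log(2.0) / np.log(ratio))))
    if not any_valid_pairs:
        raise ValueError("mask has no neighboring voxel pairs along any axis")
    fwhm = np.array([float(np.mean(v)) if v else 0.0 for v in per_axis])
    positive = fwhm[fwhm > 0]
    geo = float(np.exp(np.mean(np.log(positive)))) if positive.size else 0.0
    return SmoothnessEstimate(fwhm_mm=fwhm, geometric_mean_mm=geo)
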