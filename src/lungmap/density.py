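"""Lung water-density mapping from dual-echo acquisitions.

The dual-echo sequence samples the monoexponential T2* decay at two echo
times; back-extrapolating to TE = 0 gives the signal S0 proportional to
local proton (water) content, which the in-field reference phantom of known
density converts to absolute units (mL H2O per cm^3 lung).  Acquiring the
same slice with the scanner body coil (spatially flat) and the surface
torso coil yields their S0 ratio: the coil sensitivity profile used to
correct perfusion images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DensityMap",
    "CoilField",
    "extrapolate_s0",
    "calibrate_density",
    "estimate_coil_field",
    "fit_density",
]


@dataclass
class DensityMap:
    """Calibrated water density (mL H2O/cm^3) with the fitted T2* map."""

    density: np.ndarray
    t2star: np.ndarray                 # ms, NaN where the fit was flagged
    calibration_factor: float          # signal units per (mL H2O/cm^3)

    def __post_init__(self) -> None:
        if self.calibration_factor <= 0:
            raise ValueError("calibration factor must be positive")


@dataclass
class CoilField:
    """Smooth multiplicative coil sensitivity, median-normalised to 1 over
    its support."""

    sensitivity: np.ndarray
    smoothing_scale: float
    support: np.ndarray


def extrapolate_s0(s1, s2, te1: float, te2: float):
    """Two-point monoexponential back-extrapolation to TE = 0.

    With S(te) = S0 exp(-te/T2*)::

        T2* = (te2 - te1) / ln(s1/s2)
        S0  = s1 * (s1/s2) ** (te1 / (te2 - te1))

    Voxels where the signal does not decay (s1 <= s2) or is non-positive
    have no admissible T2*; they are flagged by returning NaN at that voxel.
    Accepts scalars or arrays; returns ``(s0, t2star)``.
    """
    if not 0 < te1 < te2:
        raise ValueError("echo times must satisfy 0 < te1 < te2")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (s2 > 0) & (s1 > s2)
        ratio = np.where(ok, s1 / s2, np.nan)
        t2star = (te2 - te1) / np.log(ratio)
        s0 = s1 * ratio ** (te1 / (te2 - te1))
    s0 = np.where(ok, s0, np.nan)
    if s0.ndim == 0:
        return float(s0), float(t2star)
    return s0, t2star


def calibrate_density(
    s0_map: np.ndarray,
    t2star_map: np.ndarray,
    phantom_roi: np.ndarray,
    phantom_known_density: float = 1.0,
) -> DensityMap:
    """Convert an S0 map to absolute density using the reference phantom.

    The calibration factor is the median S0 over the phantom ROI divided by
    its known density (median is robust to ROI edge voxels); density =
    S0 / factor.  Any global signal gain cancels in the ratio.
    """
    phantom_roi = np.asarray(phantom_roi, dtype=bool)
    roi_vals = np.asarray(s0_map, dtype=float)[phantom_roi]
    roi_vals = roi_vals[np.isfinite(roi_vals) & (roi_vals > 0)]
    if roi_vals.size < 10:
        raise ValueError(
            "reference phantom ROI needs at least 10 usable voxels "
            f"(got {roi_vals.size})"
        )
    factor = float(np.median(roi_vals)) / float(phantom_known_density)
    density = np.asarray(s0_map, dtype=float) / factor
    return DensityMap(density=density, t2star=np.asarray(t2star_map, dtype=float),
                      calibration_factor=factor)


def fit_density(
    echo1: np.ndarray,
    echo2: np.ndarray,
    te1: float,
    te2: float,
    phantom_roi: np.ndarray,
    phantom_known_density: float = 1.0,
) -> DensityMap:
    """Convenience chain: extrapolate S0 voxel-by-voxel, then calibrate."""
    s0, t2star = extrapolate_s0(echo1, echo2, te1, te2)
    return calibrate_density(s0, t2star, phantom_roi, phantom_known_density)


def estimate_coil_field(
    torso_s0: np.ndarray,
    body_s0: np.ndarray,
    support: np.ndarray,
    smoothing_scale: float = 5.0,
) -> CoilField:
    """Coil sensitivity from the torso/body S0 ratio.

    The ratio is formed where the body-coil S0 is positive within the
    support (lung + reference phantom).  A second-order 2D polynomial trend
    — the natural model for surface-coil falloff — is fitted to the ratio
    over the support, and the residual is smoothed with a Gaussian of the
    given scale by normalised convolution (so the irregular support does
    not bias edges).  The trend+residual field is normalised to median 1
    over the support.
    """
    support = np.asarray(support, dtype=bool)
    torso_s0 = np.asarray(torso_s0, dtype=float)
    body_s0 = np.asarray(body_s0, dtype=float)
    usable = support & np.isfinite(torso_s0) & np.isfinite(body_s0) & (body_s0 > 0)
    if usable.sum() < 50:
        raise ValueError(
            f"coil-field support too small: {int(usable.sum())} voxels (< 50)"
        )
    ratio = np.zeros_like(torso_s0)
    ratio[usable] = torso_s0[usable] / body_s0[usable]

    h, w_dim = ratio.shape
    yy, xx = np.mgrid[0:h, 0:w_dim]
    yy = (yy - h / 2.0) / h
    xx = (xx - w_dim / 2.0) / w_dim
    basis = np.stack(
        [np.ones_like(xx), xx, yy, xx * xx, xx * yy, yy * yy], axis=-1
    )
    coef, *_ = np.linalg.lstsq(basis[usable], ratio[usable], rcond=None)
    trend = basis @ coef
    resid = np.where(usable, ratio - trend, 0.0)

    w = usable.astype(float)
    num = gaussian_filter(resid * w, smoothing_scale)
    den = gaussian_filter(w, smoothing_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        field = trend + np.where(den > 1e-6, num / den, 0.0)
    med = np.nanmedian(field[support])
    if not np.isfinite(med) or med <= 0:
        raise ValueError("coil ratio is degenerate over the support")
    field = field / med
    return CoilField(sensitivity=field, smoothing_scale=float(smoothing_scale),
                     support=support)
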