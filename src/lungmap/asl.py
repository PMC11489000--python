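"""Pulmonary perfusion quantification from arterial spin labelling.

The selective/nonselective image pair differs by the magnetisation of blood
delivered to the slice during the preceding cardiac cycle.  Subtraction,
correction for coil heterogeneity, and calibration against the in-field
reference phantom convert the difference to delivered blood volume per mL
lung per cycle; multiplying by heart rate gives perfusion in mL/min/mL.
Large conduit vessels — which deliver blood onward rather than perfusing
local tissue — are removed with a threshold of 35% of the maximum delivered
blood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .density import CoilField

__all__ = ["QMap", "subtract_pair", "correct_and_calibrate", "filter_vessels", "q_summary"]


@dataclass
class QMap:
    """Per-voxel perfusion with its delivered-blood precursor.

    ``q = delivered * heart_rate`` holds voxelwise; ``retained_mask`` is the
    lung minus any vessel-filtered voxels.
    """

    q: np.ndarray                    # mL blood/min/mL lung
    delivered: np.ndarray            # mL blood/mL lung per cardiac cycle
    lung_mask: np.ndarray
    retained_mask: np.ndarray
    vessel_removed_mask: np.ndarray
    heart_rate: float
    threshold_fraction: float | None = None
    qc: dict = field(default_factory=dict)

    @property
    def retained_values(self) -> np.ndarray:
        return self.q[self.retained_mask]


def subtract_pair(selective: np.ndarray, nonselective: np.ndarray) -> np.ndarray:
    """Voxelwise (selective - nonselective) difference image.

    Negative values are noise and are preserved — clipping them would bias
    mean perfusion upward.
    """
    selective = np.asarray(selective, dtype=float)
    nonselective = np.asarray(nonselective, dtype=float)
    if selective.shape != nonselective.shape:
        raise ValueError(
            f"ASL pair shape mismatch: {selective.shape} vs {nonselective.shape}"
        )
    return selective - nonselective


def correct_and_calibrate(
    subtraction: np.ndarray,
    coil_field: CoilField | np.ndarray,
    phantom_roi: np.ndarray,
    calibration_image: np.ndarray,
    voxel_volume: float,
    heart_rate: float,
    lung_mask: np.ndarray,
    phantom_known_density: float = 1.0,
) -> QMap:
    """Convert a coil-corrected subtraction image to absolute perfusion.

    The reference phantom ROI in the (coil-corrected) static image supplies
    the signal of ``phantom_known_density * voxel_volume`` mL of water per
    voxel; dividing the corrected subtraction by the signal-per-mL-water and
    by the voxel volume yields delivered blood per mL lung per cardiac
    cycle, and ``q = delivered * heart_rate``.
    """
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    sens = coil_field.sensitivity if isinstance(coil_field, CoilField) else np.asarray(coil_field, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    phantom_roi = np.asarray(phantom_roi, dtype=bool)
    if np.any(~np.isfinite(sens[lung_mask])) or np.any(sens[lung_mask] <= 0):
        raise ValueError("coil field must be positive and finite over the lung")

    corrected = np.asarray(subtraction, dtype=float) / sens
    roi_signal = (np.asarray(calibration_image, dtype=float) / sens)[phantom_roi]
    roi_signal = roi_signal[np.isfinite(roi_signal)]
    if roi_signal.size == 0 or np.median(roi_signal) <= 0:
        raise ValueError("non-positive calibration signal in the phantom ROI")
    signal_per_ml_water = float(np.median(roi_signal)) / (
        phantom_known_density * voxel_volume
    )
    delivered_per_voxel = corrected / signal_per_ml_water        # mL blood/voxel
    delivered = delivered_per_voxel / voxel_volume               # mL/mL per cycle
    q = delivered * heart_rate

    background = ~lung_mask & ~phantom_roi
    qc = {
        "fraction_negative_lung": float(np.mean(delivered[lung_mask] < 0)),
        "background_mean_delivered": float(delivered[background].mean()),
        "signal_per_ml_water": signal_per_ml_water,
    }
    return QMap(
        q=q,
        delivered=delivered,
        lung_mask=lung_mask,
        retained_mask=lung_mask.copy(),
        vessel_removed_mask=np.zeros_like(lung_mask),
        heart_rate=float(heart_rate),
        qc=qc,
    )


def filter_vessels(qmap: QMap, threshold_fraction: float = 0.35) -> QMap:
    """Remove conduit-vessel voxels: delivered blood strictly above
    ``threshold_fraction`` of the maximum delivered blood over the lung.

    Boundary voxels exactly at the threshold are retained.  A uniform
    delivered map is degenerate (every voxel is "the maximum"; removing all
    would empty the lung): it is left untouched with a warning, since large
    vessels are definitionally outliers.  Total delivered blood is conserved
    across the split into retained and removed voxels.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    d = qmap.delivered[qmap.lung_mask]
    if d.size == 0 or not np.any(d > 0):
        raise ValueError("no positive delivered-blood voxels to filter")
    dmax = d.max()
    if np.ptp(d) <= 1e-12 * max(abs(dmax), 1.0):
        warnings.warn(
            "uniform delivered-blood map: vessel filtering skipped "
            "(no outliers to remove)",
            stacklevel=2,
        )
        removed = np.zeros_like(qmap.lung_mask)
    else:
        removed = qmap.lung_mask & (qmap.delivered > threshold_fraction * dmax)
    retained = qmap.lung_mask & ~removed
    qc = dict(qmap.qc)
    qc["n_vessel_removed"] = int(removed.sum())
    qc["max_delivered_prefilter"] = float(dmax)
    return replace(
        qmap,
        retained_mask=retained,
        vessel_removed_mask=removed,
        threshold_fraction=float(threshold_fraction),
        qc=qc,
    )


def q_summary(qmap: QMap) -> dict:
    """Spatial mean perfusion and relative dispersion (sample SD / mean)
    over retained (post-filter) lung voxels."""
    values = qmap.retained_values
    if values.size < 2:
        raise ValueError("need at least 2 retained voxels to summarise")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError("relative dispersion undefined for non-positive mean Q")
    sd = float(values.std(ddof=1))
    return {
        "mean_q": mean,
        "rd_q": sd / mean,
        "n_voxels": int(values.size),
        "n_vessel_removed": int(qmap.vessel_removed_mask.sum()),
    }
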