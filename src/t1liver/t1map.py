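"""B1-corrected variable-flip-angle T1 mapping from two SPGR images.

The forward model is the steady-state spoiled-gradient-echo signal

    S = M0 * sin(b1*a) * (1 - E1) / (1 - E1 * cos(b1*a)),   E1 = exp(-TR/T1)

and the inverse is the exact two-point linearisation: with
``y = S / sin(a_eff)`` and ``x = S / tan(a_eff)`` the two flip angles give a
line of slope E1, hence ``T1 = -TR / ln(E1)``.  Voxels whose slope falls
outside (0, 1) are flagged with :data:`INVALID_T1` and must be excluded
from any downstream mask statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = ["AcquisitionParams", "INVALID_T1", "spgr_signal", "fit_t1_vfa"]

#: Sentinel stored at voxels where the two-point fit is non-physical.
INVALID_T1 = -1.0


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR acquisition parameters: TR (ms), the two nominal flips (deg)."""

    tr: float = 4.61
    flip_angles: tuple[float, float] = (3.0, 15.0)
    te: float = 2.26  # metadata only

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.flip_angles) != 2:
            raise ValueError("exactly two flip angles are required")
        if any(not (0.0 < f < 90.0) for f in self.flip_angles):
            raise ValueError("flip angles must lie in (0, 90) degrees")


def spgr_signal(t1, m0, flip_nominal, b1=1.0, tr: float = 4.61):
    """Noiseless SPGR signal; the effective flip is ``b1 * flip_nominal``.

    All arguments broadcast.  ``t1`` and ``tr`` in ms, ``flip_nominal`` in
    degrees, ``b1`` a unitless transmit-efficiency fraction.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if tr <= 0:
        raise ValueError("tr must be positive")
    alpha = np.deg2rad(np.asarray(b1, dtype=float) * flip_nominal)
    e1 = np.exp(-tr / t1)
    return np.asarray(m0) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def _resample_b1(b1_map: VolumeGrid, target: VolumeGrid) -> np.ndarray:
    """Trilinearly resample a (possibly coarser) B1 map onto the T1 grid."""
    if b1_map.shape == target.shape:
        return np.asarray(b1_map.values, dtype=float)
    zoom = [t / s for t, s in zip(target.shape, b1_map.shape)]
    out = ndimage.zoom(np.asarray(b1_map.values, dtype=float), zoom, order=1,
                       mode="nearest", grid_mode=True)
    # guard against off-by-one from rounding inside ndimage.zoom
    if out.shape != target.shape:
        out = out[tuple(slice(0, n) for n in target.shape)]
    return out


def fit_t1_vfa(
    spgr_low: VolumeGrid,
    spgr_high: VolumeGrid,
    b1_map: VolumeGrid | None,
    acq: AcquisitionParams,
) -> VolumeGrid:
    """Per-voxel two-point linearised (DESPOT1-style) T1 fit.

    Parameters
    ----------
    spgr_low, spgr_high
        Magnitude images at the lower / higher nominal flip angle.
    b1_map
        Transmit-efficiency map (fraction of nominal flip).  Resampled
        trilinearly when its shape differs from the SPGR grid; ``None``
        means a uniform B1 of 1.
    acq
        TR and the flip-angle pair.

    Returns
    -------
    VolumeGrid
        T1 in ms; voxels with a non-physical slope carry :data:`INVALID_T1`.
    """
    if spgr_low.shape != spgr_high.shape:
        raise ValueError(
            f"SPGR grids have mismatched shapes {spgr_low.shape} vs {spgr_high.shape}"
        )
    if b1_map is None:
        b1 = np.ones(spgr_low.shape)
    else:
        b1 = _resample_b1(b1_map, spgr_low)
        n_bad = int(np.count_nonzero(b1 <= 0))
        if n_bad:
            raise ValueError(f"b1 map contains {n_bad} voxels with b1 <= 0")

    f_low, f_high = sorted(acq.flip_angles)
    a1 = np.deg2rad(b1 * f_low)
    a2 = np.deg2rad(b1 * f_high)
    s1 = np.asarray(spgr_low.values, dtype=float)
    s2 = np.asarray(spgr_high.values, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        slope = (y2 - y1) / (x2 - x1)
        valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
        t1 = np.where(valid, -acq.tr / np.log(np.where(valid, slope, 0.5)), INVALID_T1)

    return spgr_low.like(t1)
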