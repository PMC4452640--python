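"""Magnetization transfer ratio (MTR) mapping.

The MTR quantifies the fractional signal drop caused by an off-resonance
saturation pulse and is sensitive to the macromolecular-bound water pool:

    MTR(%) = (S0 - S_MT) / S0 * 100

per voxel, where S0 is acquired with the MT pulse train off and S_MT with
it on. Voxels whose S0 falls below a small floor (a division guard at
1e-3 of the robust brain-median intensity) are flagged invalid in the
output map instead of being zeroed; negative MTR values under noise are
kept so ROI means stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import ImageVolume, ParametricMap, ROIMask

__all__ = ["MTPair", "compute_mtr"]


@dataclass
class MTPair:
    """An MT-off / MT-on image pair on a common grid."""

    s0: ImageVolume       # MT pulse off
    smt: ImageVolume      # MT pulse on
    tr_ms: float = 2500.0
    te_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.s0.data.shape != self.smt.data.shape:
            raise ValueError(
                f"S0 and S_MT shapes differ: {self.s0.data.shape} vs "
                f"{self.smt.data.shape}"
            )
        if self.s0.voxel_size != self.smt.voxel_size:
            raise ValueError("S0 and S_MT voxel dimensions differ")


def compute_mtr(pair: MTPair, mask: ROIMask | None = None) -> ParametricMap:
    """Compute the MTR map (in %) from an MT pair.

    Parameters
    ----------
    pair
        MT-off (S0) and MT-on (S_MT) volumes on the same grid.
    mask
        Optional brain mask; voxels outside it are marked invalid and the
        S0 floor is estimated from inside it.

    Returns
    -------
    ParametricMap
        MTR in percent with a validity mask (False where S0 is below the
        floor or outside ``mask``).
    """
    s0 = pair.s0.data
    smt = pair.smt.data
    if mask is not None and mask.data.shape != s0.shape:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match image {s0.shape}"
        )
    region = mask.data if mask is not None else np.ones(s0.shape, bool)
    if not region.any():
        raise ValueError("mask selects no voxels")

    ref = np.median(s0[region])
    floor = max(np.finfo(float).eps, 1e-3 * ref)
    valid = region & (s0 > floor)
    if not valid.any():
        raise ValueError("all voxels invalid: S0 below floor everywhere")

    mtr = np.zeros_like(s0)
    np.divide(s0 - smt, s0, out=mtr, where=valid)
    mtr[valid] *= 100.0
    return ParametricMap(data=mtr, voxel_size=pair.s0.voxel_size,
                         unit="%", quantity="MTR", valid=valid)
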