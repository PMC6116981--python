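"""Transmit-field (B1+) estimation from an AFI acquisition.

The closed-form estimate uses the small-TR approximation
``alpha ~ arccos((r n - 1)/(n - r))`` with r = S2/S1 and n = TR2/TR1.  The
refinement step inverts the *exact* two-TR steady-state ratio, which is a
rational-linear function of cos(alpha) for a given T1, removing the
approximation bias (about 2 % at the default protocol) at the cost of
assuming a nominal T1 (default 1000 ms; the residual sensitivity to that
assumption is small and quantified in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signal_model import AFIPair

__all__ = [
    "FlipAngleMap",
    "B1PlusMap",
    "afi_flip_angle",
    "afi_refine",
    "b1plus_calibrate",
    "median_filter_b1",
]

#: clamping tolerance: |cos| excess below this is treated as noise and clamped
ARCCOS_CLAMP_TOL = 1e-3


@dataclass
class FlipAngleMap:
    """Effective flip angle map in degrees with a validity mask."""

    alpha_eff: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        ok = self.alpha_eff[self.valid_mask]
        if ok.size and (np.any(ok < 0) or np.any(ok > 180)):
            raise ValueError("alpha_eff must lie in [0, 180] deg on valid voxels")


@dataclass
class B1PlusMap:
    """Relative transmit field B1+ = alpha_eff / alpha_nominal."""

    b1plus: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.b1plus)
        ok = self.b1plus[self.valid_mask]
        if ok.size and np.any(ok <= 0):
            raise ValueError("b1plus must be positive on valid voxels")
        if ok.size and (ok.min() < 0.5 or ok.max() > 1.5):
            warnings.warn(
                "B1+ outside [0.5, 1.5] on some valid voxels; "
                "check AFI data or flip-angle calibration",
                stacklevel=2,
            )


def afi_flip_angle(afi_pair: AFIPair) -> FlipAngleMap:
    """Closed-form effective flip angle from the AFI signal ratio.

    Voxels with S1 = 0, or whose arccos argument needs clamping by more than
    ``ARCCOS_CLAMP_TOL``, are flagged invalid rather than raising.
    """
    n = afi_pair.protocol.n_ratio
    s1 = np.asarray(afi_pair.s1, dtype=float)
    s2 = np.asarray(afi_pair.s2, dtype=float)
    valid = s1 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, s2 / np.where(valid, s1, 1.0), np.nan)
        arg = (r * n - 1.0) / (n - r)
    excess = np.maximum(np.abs(arg) - 1.0, 0.0)
    valid &= np.isfinite(arg) & (excess <= ARCCOS_CLAMP_TOL)
    alpha = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))
    alpha = np.where(valid, alpha, np.nan)
    return FlipAngleMap(alpha_eff=alpha, valid_mask=valid)


def afi_refine(
    alpha0: FlipAngleMap,
    afi_pair: AFIPair,
    t1_assumed: float = 1000.0,
) -> FlipAngleMap:
    """Refine the flip-angle map by inverting the exact two-TR steady state.

    For fixed T1 the exact ratio r(alpha) = S2/S1 is rational-linear in
    cos(alpha), so the inversion is algebraic:

        cos(alpha) = [(1 - E1) - r (1 - E2)] / [r E2 (1 - E1) - E1 (1 - E2)]

    with E_i = exp(-TR_i/T1).  Voxels where the inverted cosine falls outside
    [-1, 1] beyond the clamping tolerance keep their initial estimate and are
    flagged invalid.
    """
    if t1_assumed <= 0:
        raise ValueError("t1_assumed must be positive")
    p = afi_pair.protocol
    e1 = np.exp(-p.tr1 / t1_assumed)
    e2 = np.exp(-p.tr2 / t1_assumed)
    s1 = np.asarray(afi_pair.s1, dtype=float)
    s2 = np.asarray(afi_pair.s2, dtype=float)
    valid = alpha0.valid_mask & (s1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, s2 / np.where(valid, s1, 1.0), np.nan)
        c = ((1.0 - e1) - r * (1.0 - e2)) / (r * e2 * (1.0 - e1) - e1 * (1.0 - e2))
    excess = np.maximum(np.abs(c) - 1.0, 0.0)
    ok = valid & np.isfinite(c) & (excess <= ARCCOS_CLAMP_TOL)
    alpha = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    # fall back to the closed-form initialiser where the exact inversion fails
    alpha = np.where(ok, alpha, alpha0.alpha_eff)
    return FlipAngleMap(alpha_eff=alpha, valid_mask=ok | alpha0.valid_mask)


def b1plus_calibrate(alpha: FlipAngleMap, flip_nominal: float) -> B1PlusMap:
    """Calibrate a flip-angle map to the nominal flip angle: B1+ = alpha/alpha_nom."""
    if flip_nominal <= 0:
        raise ValueError("flip_nominal must be positive")
    return B1PlusMap(b1plus=alpha.alpha_eff / flip_nominal, valid_mask=alpha.valid_mask.copy())


def median_filter_b1(b1: B1PlusMap, radius: int = 1) -> B1PlusMap:
    """Median-filter a B1+ map (box of half-width ``radius``; 0 disables).

    Transmit fields are smooth at the AFI resolution, so a small median
    filter suppresses speckle from the ratio operation without biasing the
    field.  Invalid voxels are excluded by nearest-neighbour fill before
    filtering and remain flagged invalid afterwards.
    """
    if radius <= 0:
        return b1
    data = b1.b1plus.copy()
    if not b1.valid_mask.all():
        if not b1.valid_mask.any():
            return b1
        idx = ndimage.distance_transform_edt(
            ~b1.valid_mask, return_distances=False, return_indices=True
        )
        data = data[tuple(idx)]
    filtered = ndimage.median_filter(data, size=2 * radius + 1)
    filtered = np.where(b1.valid_mask, filtered, np.nan)
    return B1PlusMap(b1plus=filtered, valid_mask=b1.valid_mask.copy())
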