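"""Voxel-wise T1 and T2* estimation from multi-echo GRE acquisitions.

T1 is obtained from the two flip-angle acquisitions by minimising, per voxel,

    sum_n | S_a1(TE_n)/C(T1, B1+, a1) - S_a2(TE_n)/C(T1, B1+, a2) |^2

over T1, where C is the SPGR saturation factor; because both acquisitions
share the echo times, the residual T2* weighting cancels.  The first three
echoes are used by default (highest SNR, least dephasing).  Estimates above
6 s are clipped.

T2* comes from a weighted log-linear fit (weights |S(TE_n)|) of ln S against
TE, restricted per voxel to echoes below TE_max, an echo-time bound derived
from the local gradient of the off-resonance field: echoes beyond the point
where through-voxel phase dispersion corrupts the mono-exponential model are
excluded.  Estimates above 1.5 s (or non-decaying voxels) are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .b1map import B1PlusMap
from .signal_model import EchoTrainVolume, t1_correction_factor

__all__ = [
    "T1Map",
    "T2StarMap",
    "FieldGradientMap",
    "ProtocolError",
    "fit_t1_two_point",
    "fieldmap_from_phase",
    "compute_te_max",
    "fit_t2star",
]

T1_CLIP_MS = 6000.0
T2STAR_CLIP_MS = 1500.0
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


class ProtocolError(ValueError):
    """The two acquisitions are not protocol-compatible."""


@dataclass
class T1Map:
    t1: np.ndarray  # ms
    residual: np.ndarray  # objective value at the minimiser
    clipped_mask: np.ndarray
    valid_mask: np.ndarray


@dataclass
class T2StarMap:
    t2star: np.ndarray  # ms
    s0: np.ndarray  # extrapolated TE=0 signal
    n_echoes_used: np.ndarray
    clipped_mask: np.ndarray
    valid_mask: np.ndarray
    floored_mask: np.ndarray | None = None  # TE_max demanded fewer echoes than the floor


@dataclass
class FieldGradientMap:
    """Off-resonance field, its spatial gradient magnitude and TE_max bound."""

    delta_f: np.ndarray  # Hz
    grad_magnitude: np.ndarray | None = None  # Hz/mm
    te_max: np.ndarray | None = None  # ms


def _two_point_objective(t1, tr, a1, a2, ss11, ss12, ss22):
    """Summed squared difference of the two saturation-corrected signals.

    Uses the precomputed per-voxel echo sums ss11 = sum S1^2,
    ss12 = sum S1 S2, ss22 = sum S2^2, so each evaluation is O(n_voxels).
    """
    c1 = t1_correction_factor(t1, tr, a1)
    c2 = t1_correction_factor(t1, tr, a2)
    return ss11 / c1**2 - 2.0 * ss12 / (c1 * c2) + ss22 / c2**2


def fit_t1_two_point(
    low: EchoTrainVolume,
    high: EchoTrainVolume,
    b1plus: B1PlusMap | np.ndarray,
    n_echoes: int = 3,
    t1_bounds: tuple[float, float] = (1.0, T1_CLIP_MS),
    xatol: float = 0.01,
    n_coarse: int = 128,
) -> T1Map:
    """Two-point variable-flip-angle T1 fit.

    A log-spaced coarse scan over ``t1_bounds`` brackets the global minimum
    (the objective can be non-convex for noisy voxels), followed by a
    vectorised golden-section refinement to ``xatol`` ms.  The fit is exact on
    noiseless SPGR data.  Voxels with zero signal in both acquisitions are
    invalid; minimisers at the upper bound are clipped to 6 s.

    Raises
    ------
    ProtocolError
        If the two acquisitions differ in TR or echo times.
    """
    if abs(low.protocol.tr - high.protocol.tr) > 1e-9:
        raise ProtocolError("both acquisitions must share TR")
    te_l, te_h = low.protocol.te_list[:n_echoes], high.protocol.te_list[:n_echoes]
    if te_l.size != te_h.size or not np.allclose(te_l, te_h):
        raise ProtocolError("both acquisitions must share the echo times used for T1")

    b1 = b1plus.b1plus if isinstance(b1plus, B1PlusMap) else np.asarray(b1plus, dtype=float)
    s1 = low.magnitude[..., :n_echoes].astype(float)
    s2 = high.magnitude[..., :n_echoes].astype(float)
    ss11 = np.sum(s1 * s1, axis=-1)
    ss12 = np.sum(s1 * s2, axis=-1)
    ss22 = np.sum(s2 * s2, axis=-1)
    a1 = b1 * low.protocol.flip_nominal
    a2 = b1 * high.protocol.flip_nominal

    valid = (ss11 + ss22 > 0) & np.isfinite(b1) & (b1 > 0)
    # neutral values keep the vectorised solver NaN-free on invalid voxels
    a1s = np.where(valid, a1, 1.0)
    a2s = np.where(valid, a2, 2.0)
    tr = low.protocol.tr

    grid = np.geomspace(t1_bounds[0], t1_bounds[1], n_coarse)
    best_val = np.full(ss11.shape, np.inf)
    best_idx = np.zeros(ss11.shape, dtype=np.int32)
    for i, t in enumerate(grid):
        val = _two_point_objective(t, tr, a1s, a2s, ss11, ss12, ss22)
        better = val < best_val
        best_val = np.where(better, val, best_val)
        best_idx = np.where(better, i, best_idx)

    lo = grid[np.maximum(best_idx - 1, 0)]
    hi = grid[np.minimum(best_idx + 1, n_coarse - 1)]
    max_width = float(np.max(hi - lo)) if hi.size else 1.0
    n_iter = max(int(np.ceil(np.log(xatol / max(max_width, xatol)) / np.log(_INVPHI))) + 2, 1)
    for _ in range(n_iter):
        x1 = hi - _INVPHI * (hi - lo)
        x2 = lo + _INVPHI * (hi - lo)
        f1 = _two_point_objective(x1, tr, a1s, a2s, ss11, ss12, ss22)
        f2 = _two_point_objective(x2, tr, a1s, a2s, ss11, ss12, ss22)
        take_low = f1 < f2
        hi = np.where(take_low, x2, hi)
        lo = np.where(take_low, lo, x1)

    t1 = 0.5 * (lo + hi)
    residual = _two_point_objective(t1, tr, a1s, a2s, ss11, ss12, ss22)
    clipped = valid & (t1 >= t1_bounds[1] - max(10 * xatol, 1.0))
    t1 = np.where(clipped, t1_bounds[1], t1)
    t1 = np.where(valid, t1, np.nan)
    residual = np.where(valid, residual, np.nan)
    return T1Map(t1=t1, residual=residual, clipped_mask=clipped, valid_mask=valid)


def _wrap(phase):
    return np.angle(np.exp(1j * phase))


def fieldmap_from_phase(echoes: EchoTrainVolume, n_candidates: int = 2) -> FieldGradientMap:
    """Off-resonance field Delta-f (Hz) from multi-echo phase images.

    The base estimate is the wrapped phase difference of the first two
    echoes, Delta-phi/(2 pi dTE).  With three or more echoes the estimate is
    temporally unwrapped: candidate frequencies offset by integer multiples
    of 1/dTE are scored against the wrapped phases of *all* echoes (the phase
    is assumed to be zero at TE = 0, i.e. phi_n = 2 pi f TE_n), the
    best-scoring candidate is kept, and the frequency is refitted by
    least squares through the origin on the unwrapped phases.  Because the
    first echo time is not a multiple of the echo spacing, this resolves
    aliases beyond the two-echo Nyquist limit 1/(2 dTE).

    Raises
    ------
    ValueError
        If the echo train carries no phase information.
    """
    if echoes.phase is None:
        raise ValueError(
            "echo train has no phase volumes; supply an external field map instead"
        )
    te_s = echoes.protocol.te_list * 1e-3
    if te_s.size < 2:
        raise ValueError("need at least two echoes to estimate the field")
    phase = echoes.phase
    dte = te_s[1] - te_s[0]
    f0 = _wrap(phase[..., 1] - phase[..., 0]) / (2.0 * np.pi * dte)
    if te_s.size < 3:
        return FieldGradientMap(delta_f=f0)

    ks = np.arange(-n_candidates, n_candidates + 1)
    best_f = f0
    best_score = np.full(f0.shape, np.inf)
    for k in ks:
        fk = f0 + k / dte
        resid = _wrap(phase - 2.0 * np.pi * fk[..., None] * te_s)
        score = np.sum(resid**2, axis=-1)
        better = score < best_score
        best_score = np.where(better, score, best_score)
        best_f = np.where(better, fk, best_f)

    # unwrap each echo against the winning candidate and refit the slope
    psi = 2.0 * np.pi * best_f[..., None] * te_s + _wrap(
        phase - 2.0 * np.pi * best_f[..., None] * te_s
    )
    f = np.sum(psi * te_s, axis=-1) / (2.0 * np.pi * np.sum(te_s**2))
    return FieldGradientMap(delta_f=f)


def compute_te_max(
    field: FieldGradientMap,
    voxel_size,
    q_threshold: float = 0.5,
) -> FieldGradientMap:
    """Voxel-wise echo-time bound from the local field gradient.

    The off-resonance gradient is estimated by central differences (one-sided
    at the borders).  With per-axis through-voxel frequency spreads
    G_i * d_i (Hz) combined in quadrature, TE_max is the echo time at which
    the phase dispersion across half the voxel reaches ``q_threshold``
    cycles:

        TE_max = q / (rate / 2),   rate = ||(G_i d_i)||_2.

    The default q = 0.5 places the bound exactly at the first null of the
    sinc attenuation model.  Where the gradient vanishes TE_max is infinite.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    grads = np.gradient(np.asarray(field.delta_f, dtype=float), *voxel_size)
    grad_mag = np.sqrt(sum(g**2 for g in grads))  # Hz/mm
    rate = np.sqrt(sum((g * d) ** 2 for g, d in zip(grads, voxel_size)))  # Hz across voxel
    with np.errstate(divide="ignore"):
        te_max = np.where(rate > 0, 2.0 * q_threshold / np.where(rate > 0, rate, 1.0), np.inf)
    te_max = te_max * 1e3  # s -> ms
    return FieldGradientMap(delta_f=field.delta_f, grad_magnitude=grad_mag, te_max=te_max)


def fit_t2star(
    echoes: EchoTrainVolume,
    te_max: FieldGradientMap | np.ndarray | None = None,
    min_echoes: int = 3,
    t2star_max: float = T2STAR_CLIP_MS,
) -> T2StarMap:
    """Weighted log-linear mono-exponential T2* fit.

    Closed-form weighted least squares of ln S on TE with weights |S(TE_n)|,
    per voxel over the eligible echoes (TE_n < TE_max where a bound is given,
    but never fewer than the first ``min_echoes`` echoes - such voxels are
    flagged in ``floored_mask``).  Returns S0 = exp(intercept) and
    T2* = -1/slope; non-decaying voxels and estimates above ``t2star_max``
    are clipped with the mask set.  Voxels with fewer than two usable echoes
    are invalid.
    """
    s = echoes.magnitude.astype(float)
    te = echoes.protocol.te_list
    ne = te.size
    if min_echoes < 2:
        raise ValueError("min_echoes must be at least 2")

    if te_max is None:
        eligible = np.ones(s.shape, dtype=bool)
        floored = np.zeros(s.shape[:3], dtype=bool)
    else:
        tm = te_max.te_max if isinstance(te_max, FieldGradientMap) else np.asarray(te_max)
        if tm is None:
            raise ValueError("FieldGradientMap has no te_max; run compute_te_max first")
        eligible = te[None, None, None, :] < tm[..., None]
        floored = np.sum(eligible, axis=-1) < min_echoes
        eligible[..., : min(min_echoes, ne)] |= True

    usable = eligible & (s > 0)
    n_used = np.sum(usable, axis=-1)
    valid = n_used >= 2

    w = np.where(usable, s, 0.0)
    y = np.where(usable, np.log(np.where(usable, s, 1.0)), 0.0)
    x = te[None, None, None, :]
    sw = np.sum(w, axis=-1)
    swx = np.sum(w * x, axis=-1)
    swy = np.sum(w * y, axis=-1)
    swxx = np.sum(w * x * x, axis=-1)
    swxy = np.sum(w * x * y, axis=-1)
    denom = sw * swxx - swx**2
    valid &= denom > 0
    denom_safe = np.where(valid, denom, 1.0)
    slope = (sw * swxy - swx * swy) / denom_safe
    intercept = (swxx * swy - swx * swxy) / denom_safe

    clipped = valid & (slope >= -1.0 / t2star_max)
    with np.errstate(divide="ignore"):
        t2 = np.where(clipped, t2star_max, -1.0 / np.where(slope < 0, slope, -1.0))
    t2 = np.where(valid, t2, np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    return T2StarMap(
        t2star=t2,
        s0=s0,
        n_echoes_used=n_used,
        clipped_mask=clipped,
        valid_mask=valid,
        floored_mask=floored,
    )
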