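"""Corrected magnetisation density and calibrated free-water-content maps.

The fully corrected, non-normalised magnetisation density averages the first
N = 3 echoes of the low-flip-angle acquisition after dividing out the three
multiplicative factors of the SPGR signal:

    M0 = (1/N) sum_n S(TE_n) / [ C_T2*(TE_n) * C_T1,B1+,alpha * C_B1- ].

Water content follows by calibrating to voxels of ~100 % water: the mean
corrected M0 over a ventricular CSF normalisation region (CSF probability
>= 0.99, T1 > 2900 ms, T2* > 500 ms, inside an ellipsoid around the lateral
ventricles) defines the scalar C_norm with H2O = C_norm * M0 and the region
mean pinned to 100 %.

The receive field B1- is either supplied externally or estimated by an
alternating intensity-clustering / polynomial bias-field scheme: k tissue
classes are fitted to the log-intensities while a smooth low-order 3-D
polynomial absorbs the residual multiplicative field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from itertools import combinations_with_replacement

import numpy as np

from .phantoms import Ellipsoid
from .geometry import world_coordinates
from .relaxometry import T1Map, T2StarMap, fit_t2star
from .signal_model import EchoTrainVolume, t1_correction_factor
from .b1map import B1PlusMap

__all__ = [
    "M0Map",
    "H2OMap",
    "NormalisationRule",
    "correct_m0",
    "estimate_receive_bias",
    "csf_normalization_mask",
    "normalize_h2o",
    "h2o_long_tr",
    "propagate_t1_error",
]


@dataclass
class M0Map:
    m0: np.ndarray
    corrections_applied: frozenset[str]
    valid_mask: np.ndarray


@dataclass
class H2OMap:
    h2o: np.ndarray  # percent of pure water
    c_norm: float
    norm_mask: np.ndarray


@dataclass(frozen=True)
class NormalisationRule:
    """Thresholds and region defining the CSF calibration mask."""

    csf_prob_min: float = 0.99
    t1_min: float = 2900.0  # ms
    t2star_min: float = 500.0  # ms
    ellipsoid: Ellipsoid | None = None

    def __post_init__(self) -> None:
        if self.csf_prob_min <= 0 or self.t1_min <= 0 or self.t2star_min <= 0:
            raise ValueError("normalisation thresholds must be positive")


def correct_m0(
    low: EchoTrainVolume,
    t2star: T2StarMap,
    t1: T1Map,
    b1plus: B1PlusMap | np.ndarray,
    b1minus: np.ndarray | None = None,
    n_echoes: int = 3,
) -> M0Map:
    """Fully corrected magnetisation density from the low-flip acquisition.

    Averages ``n_echoes`` echo signals divided by exp(-TE/T2*), the
    T1/B1+/alpha saturation factor and (when given) the receive field.
    Voxels where any correction factor is zero, negative or undefined are
    marked invalid (NaN), never propagated as division blow-ups.
    """
    te = low.protocol.te_list[:n_echoes]
    s = low.magnitude[..., :n_echoes].astype(float)
    b1 = b1plus.b1plus if isinstance(b1plus, B1PlusMap) else np.asarray(b1plus, dtype=float)

    valid = (
        t2star.valid_mask
        & t1.valid_mask
        & np.isfinite(b1)
        & (b1 > 0)
        & np.isfinite(t2star.t2star)
        & (np.nan_to_num(t2star.t2star) > 0)
        & np.isfinite(t1.t1)
        & (np.nan_to_num(t1.t1) > 0)
    )
    corrections = {"T2*", "T1B1a"}
    if b1minus is not None:
        b1m = np.asarray(b1minus, dtype=float)
        valid &= np.isfinite(b1m) & (b1m > 0)
        corrections.add("B1-")
    else:
        b1m = np.ones_like(b1)

    t2_safe = np.where(valid, t2star.t2star, 1.0)
    t1_safe = np.where(valid, t1.t1, 1.0)
    b1_safe = np.where(valid, b1, 1.0)
    b1m_safe = np.where(valid, b1m, 1.0)

    c_t2 = np.exp(-te[None, None, None, :] / t2_safe[..., None])
    c_t1 = t1_correction_factor(t1_safe, low.protocol.tr, b1_safe * low.protocol.flip_nominal)
    valid &= c_t1 > 0
    c_t1 = np.where(valid, c_t1, 1.0)
    m0 = np.mean(s / c_t2, axis=-1) / (c_t1 * b1m_safe)
    m0 = np.where(valid, m0, np.nan)
    return M0Map(m0=m0, corrections_applied=frozenset(corrections), valid_mask=valid)


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D Lloyd k-means with farthest-point initialisation.

    Quantile seeding fails when one class is rare (ventricular CSF is a
    percent of brain voxels); farthest-point seeding from the median always
    places a seed on an outlying class.  Returns the sorted class centres.
    """
    seeds = [float(np.median(values))]
    for _ in range(k - 1):
        d = np.min(np.abs(values[:, None] - np.asarray(seeds)[None, :]), axis=1)
        seeds.append(float(values[np.argmax(d)]))
    centers = np.sort(np.asarray(seeds))
    for _ in range(n_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[labels == c].mean() if np.any(labels == c) else centers[c] for c in range(k)]
        )
        if np.allclose(new, centers, atol=1e-10):
            break
        centers = new
    return np.sort(centers)


def _poly_design(coords_norm: np.ndarray, order: int) -> np.ndarray:
    """Design matrix of 3-D monomials with total degree <= order."""
    x, y, z = coords_norm
    cols = []
    for deg in range(order + 1):
        for combo in combinations_with_replacement(range(3), deg):
            col = np.ones_like(x)
            for axis in combo:
                col = col * (x, y, z)[axis]
            cols.append(col)
    return np.stack(cols, axis=-1)


def estimate_receive_bias(
    m0_partial: M0Map,
    brain_mask: np.ndarray,
    n_classes: int = 3,
    poly_order: int = 4,
    n_iter: int = 20,
    tol: float = 1e-4,
) -> np.ndarray:
    """Smooth multiplicative receive-field estimate from a T2*/T1-corrected M0 map.

    Alternates (a) ``n_classes``-class 1-D clustering of the bias-corrected
    log-intensities with (b) a least-squares fit of a 3-D polynomial of total
    degree <= ``poly_order`` to the log-residuals inside ``brain_mask``.  The
    returned field is defined on the full grid (polynomial extrapolation
    outside the mask) and normalised to mean 1 over the mask.

    Raises
    ------
    ValueError
        If the mask is empty (or empty after removing invalid voxels).
    """
    mask = np.asarray(brain_mask, dtype=bool) & m0_partial.valid_mask & (
        np.nan_to_num(m0_partial.m0) > 0
    )
    if not mask.any():
        raise ValueError("brain mask is empty; cannot estimate the receive field")

    shape = m0_partial.m0.shape
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"))
    coords = [2.0 * idx[i] / max(shape[i] - 1, 1) - 1.0 for i in range(3)]
    design_full = _poly_design(np.stack([c for c in coords]), poly_order)
    design = design_full[mask]

    log_i = np.log(m0_partial.m0[mask])
    log_b = np.zeros_like(log_i)
    coeffs = np.zeros(design.shape[-1])
    converged = False
    for _ in range(n_iter):
        centers = _kmeans_1d(log_i - log_b, n_classes)
        labels = np.argmin(np.abs((log_i - log_b)[:, None] - centers[None, :]), axis=1)
        resid = log_i - centers[labels]
        new_coeffs, *_ = np.linalg.lstsq(design, resid, rcond=None)
        new_log_b = design @ new_coeffs
        new_log_b -= new_log_b.mean()
        delta = float(np.max(np.abs(new_log_b - log_b)))
        log_b, coeffs = new_log_b, new_coeffs
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "receive-bias estimation did not fully converge; returning best iterate",
            stacklevel=2,
        )

    full = design_full.reshape(-1, design_full.shape[-1]) @ coeffs
    bias = np.exp(full.reshape(shape))
    bias /= bias[mask].mean()
    return bias


def csf_normalization_mask(
    csf_prob: np.ndarray,
    t1: T1Map,
    t2star: T2StarMap,
    rule: NormalisationRule,
    affine: np.ndarray | None = None,
) -> np.ndarray:
    """Ventricular-CSF calibration mask.

    Conjunction of CSF probability >= ``csf_prob_min``, T1 > ``t1_min``,
    T2* > ``t2star_min``, intersected with the interior of the rule's
    ellipsoid (given in world mm; ``affine`` maps voxel indices to world).

    Raises
    ------
    ValueError
        If the resulting mask is empty - normalisation is then impossible.
    """
    mask = (
        (np.asarray(csf_prob) >= rule.csf_prob_min)
        & t1.valid_mask
        & t2star.valid_mask
        & (np.nan_to_num(t1.t1) > rule.t1_min)
        & (np.nan_to_num(t2star.t2star) > rule.t2star_min)
    )
    if rule.ellipsoid is not None:
        if affine is None:
            affine = np.eye(4)
        x, y, z = world_coordinates(mask.shape, affine)
        mask &= rule.ellipsoid.contains(x, y, z)
    if not mask.any():
        raise ValueError(
            "normalisation mask is empty (check CSF probabilities, thresholds and ellipsoid)"
        )
    return mask


def normalize_h2o(m0: M0Map, norm_mask: np.ndarray) -> H2OMap:
    """Calibrate corrected M0 to percent water: C_norm = 100 / mean(M0 | mask)."""
    norm_mask = np.asarray(norm_mask, dtype=bool) & m0.valid_mask
    if not norm_mask.any():
        raise ValueError("normalisation mask is empty")
    mean_m0 = float(np.mean(m0.m0[norm_mask]))
    if mean_m0 <= 0:
        raise ValueError("mean M0 over the normalisation mask is non-positive")
    c_norm = 100.0 / mean_m0
    return H2OMap(h2o=c_norm * m0.m0, c_norm=c_norm, norm_mask=norm_mask)


def h2o_long_tr(
    echoes: EchoTrainVolume,
    norm_mask: np.ndarray,
    b1minus: np.ndarray | None = None,
    te_max=None,
    t1_longest: float = 2000.0,
) -> H2OMap:
    """Gold-standard single-flip-angle water content from a long-TR acquisition.

    With TR much longer than any tissue T1 the magnetisation relaxes fully,
    so no T1/B1+ correction is needed: S0 extrapolated to TE = 0 by the T2*
    fit, divided by the receive field (if supplied), is proportional to M0.
    Calibration proceeds exactly as for the two-point method.  A warning is
    issued when TR < 5 * ``t1_longest`` (default 2000 ms, typical brain
    parenchyma; pass the CSF T1 to be strict - even TR = 10 s leaves a
    percent-level saturation of ventricular CSF, a known limitation of the
    long-TR reference).
    """
    if echoes.protocol.tr < 5 * t1_longest:
        warnings.warn(
            f"TR = {echoes.protocol.tr} ms is not >> tissue T1; "
            "T1 saturation will bias the long-TR water content",
            stacklevel=2,
        )
    t2map = fit_t2star(echoes, te_max=te_max)
    m0_data = t2map.s0
    valid = t2map.valid_mask.copy()
    corrections = {"T2*"}
    if b1minus is not None:
        b1m = np.asarray(b1minus, dtype=float)
        valid &= np.isfinite(b1m) & (b1m > 0)
        m0_data = m0_data / np.where(valid, b1m, 1.0)
        corrections.add("B1-")
    m0 = M0Map(
        m0=np.where(valid, m0_data, np.nan),
        corrections_applied=frozenset(corrections),
        valid_mask=valid,
    )
    return normalize_h2o(m0, norm_mask)


def propagate_t1_error(t1, delta_t1, flip_eff, tr):
    """First-order relative water-content error from a T1 bias.

    H2O is proportional to S / C(T1) with C the SPGR saturation factor, so a
    T1 error delta_t1 propagates as |d ln C / d T1| * delta_t1.  With
    E = exp(-TR/T1),

        d ln C / d T1 = (TR E / T1^2) * [cos(a)/(1 - E cos a) - 1/(1 - E)].

    Returns the relative error as a fraction.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0) or tr <= 0:
        raise ValueError("t1 and tr must be positive")
    a = np.deg2rad(np.asarray(flip_eff, dtype=float))
    e = np.exp(-tr / t1)
    dlnc = (tr * e / t1**2) * (np.cos(a) / (1.0 - e * np.cos(a)) - 1.0 / (1.0 - e))
    return np.abs(dlnc) * np.asarray(delta_t1, dtype=float)
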