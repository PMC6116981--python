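"""Forward models of the spoiled multi-echo GRE and AFI steady-state signals.

The spoiled gradient-echo (SPGR) signal at echo time TE is

    S(TE) = M0 * exp(-TE/T2*) * sin(a) * (1 - E) / (1 - E cos a) * B1-,

with E = exp(-TR/T1) and effective flip angle a = B1+ * a_nom.  Perfect
spoiling of transverse magnetisation is assumed.  The AFI signals are the
exact periodic steady state of the alternating two-TR pulse train, not the
small-TR approximation used for the closed-form flip-angle estimate.

``simulate_megre`` turns a :class:`~mriwater.phantoms.PhantomSpec` into a 4-D
echo train: per-voxel SPGR signal, optional intravoxel-dephasing attenuation
driven by the local gradient of the off-resonance field (a separable sinc
factor per axis), and Rician magnitude noise obtained by adding complex
Gaussian noise before taking the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import PhantomSpec
from .protocols import AcquisitionProtocol, AFIProtocol
from .geometry import resample_to_grid, affine_from_voxel_size

__all__ = [
    "EchoTrainVolume",
    "AFIPair",
    "spgr_signal",
    "t1_correction_factor",
    "afi_signals",
    "afi_signal_ratio",
    "dephasing_attenuation",
    "simulate_megre",
    "simulate_afi",
    "sigma_for_snr",
]


@dataclass
class EchoTrainVolume:
    """4-D multi-echo magnitude (+ optional phase) volume with its protocol."""

    magnitude: np.ndarray  # (x, y, z, echo)
    protocol: AcquisitionProtocol
    phase: np.ndarray | None = None  # radians, same shape
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.magnitude.ndim != 4:
            raise ValueError(f"magnitude must be 4-D, got shape {self.magnitude.shape}")
        if self.magnitude.shape[-1] != self.protocol.n_echoes:
            raise ValueError(
                f"echo dimension {self.magnitude.shape[-1]} != "
                f"{self.protocol.n_echoes} echoes in protocol"
            )
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.phase is not None and self.phase.shape != self.magnitude.shape:
            raise ValueError("phase shape must match magnitude")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.magnitude.shape[:3]


@dataclass
class AFIPair:
    """The two steady-state AFI volumes S1 (after TR2 recovery) and S2."""

    s1: np.ndarray
    s2: np.ndarray
    protocol: AFIProtocol
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.s1.shape != self.s2.shape:
            raise ValueError("s1 and s2 must share a grid")
        if self.affine is None:
            self.affine = np.eye(4)


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def t1_correction_factor(t1, tr, flip_eff_deg):
    """Saturation/flip factor C = sin(a) (1 - E)/(1 - E cos a), E = exp(-TR/T1).

    This is the T1/B1+/alpha-dependent multiplicative factor of the SPGR
    signal; dividing the measured signal by it removes the T1 weighting.
    """
    t1 = np.asarray(t1, dtype=float)
    a = np.deg2rad(np.asarray(flip_eff_deg, dtype=float))
    e = np.exp(-tr / t1)
    return np.sin(a) * (1.0 - e) / (1.0 - e * np.cos(a))


def spgr_signal(m0, t1, t2star, te, tr, flip_eff, b1minus=1.0):
    """Spoiled GRE signal for given tissue and acquisition parameters.

    Parameters are broadcast together; times in ms, ``flip_eff`` in degrees.

    Raises
    ------
    ValueError
        If any of t1, t2star or tr is non-positive, or te is negative.
    """
    _check_positive(t1=t1, t2star=t2star, tr=tr)
    if np.any(np.asarray(te) < 0):
        raise ValueError("te must be non-negative")
    t2star = np.asarray(t2star, dtype=float)
    decay = np.exp(-np.asarray(te, dtype=float) / t2star)
    return np.asarray(m0) * decay * t1_correction_factor(t1, tr, flip_eff) * np.asarray(b1minus)


def afi_steady_state(m0, t1, flip_eff, afi: AFIProtocol):
    """Exact longitudinal steady state of the two-TR AFI pulse train.

    Returns (Mz1, Mz2): the longitudinal magnetisation immediately before the
    pulse that is followed by TR1 and TR2 respectively.
    """
    _check_positive(t1=t1)
    t1 = np.asarray(t1, dtype=float)
    c = np.cos(np.deg2rad(np.asarray(flip_eff, dtype=float)))
    e1 = np.exp(-afi.tr1 / t1)
    e2 = np.exp(-afi.tr2 / t1)
    denom = 1.0 - c**2 * e1 * e2
    mz1 = np.asarray(m0) * (1.0 - e2 + c * e2 * (1.0 - e1)) / denom
    mz2 = np.asarray(m0) * (1.0 - e1 + c * e1 * (1.0 - e2)) / denom
    return mz1, mz2


def afi_signals(m0, t1, flip_eff, afi: AFIProtocol, b1minus=1.0):
    """Exact steady-state AFI signal pair (S1, S2).

    S1 is acquired after the pulse followed by delay TR1, S2 after the pulse
    followed by TR2; both carry the same sin(alpha) excitation factor and any
    echo-time decay cancels in the ratio, so TE is not modelled.
    """
    mz1, mz2 = afi_steady_state(m0, t1, flip_eff, afi)
    s = np.abs(np.sin(np.deg2rad(np.asarray(flip_eff, dtype=float)))) * np.asarray(b1minus)
    return mz1 * s, mz2 * s


def afi_signal_ratio(flip_eff, t1, afi: AFIProtocol):
    """Exact steady-state ratio r = S2/S1 as a function of flip angle and T1."""
    mz1, mz2 = afi_steady_state(1.0, t1, flip_eff, afi)
    return mz2 / mz1


def dephasing_attenuation(delta_f: np.ndarray, voxel_size, te_ms) -> np.ndarray:
    """Intravoxel dephasing factor from a linear field gradient across the voxel.

    A linear off-resonance gradient G_i (Hz/mm) across voxel dimension d_i
    (mm) attenuates the magnitude by |sinc(G_i d_i TE)| per axis (normalised
    sinc; first null when the through-voxel dispersion G_i d_i TE reaches one
    cycle).  ``te_ms`` may be scalar or an array of echo times; the result has
    a trailing echo axis when it is an array.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    grads = np.gradient(np.asarray(delta_f, dtype=float), *voxel_size)
    te_s = np.atleast_1d(np.asarray(te_ms, dtype=float)) * 1e-3
    att = np.ones(delta_f.shape + (te_s.size,))
    for g, d in zip(grads, voxel_size):
        att *= np.abs(np.sinc(g[..., None] * d * te_s))
    if np.ndim(te_ms) == 0:
        att = att[..., 0]
    return att


def simulate_megre(
    phantom: PhantomSpec,
    protocol: AcquisitionProtocol,
    seed: int | None = None,
    with_phase: bool = True,
) -> EchoTrainVolume:
    """Simulate a multi-echo GRE acquisition of a phantom.

    Noiseless per-voxel signals follow the SPGR equation with effective flip
    angle B1+ * alpha_nom; if the phantom defines an off-resonance field, the
    sinc-type intravoxel dephasing attenuation is applied and the phase
    volumes encode 2*pi*delta_f*TE.  Complex Gaussian noise of standard
    deviation ``noise_sigma`` is added to the real and imaginary channels
    before the magnitude is taken (Rician magnitude statistics).

    ``seed`` defaults to ``phantom.seed``; pass distinct seeds when simulating
    several acquisitions of the same phantom so their noise is independent.
    """
    te = protocol.te_list
    flip_eff = phantom.b1plus_true * protocol.flip_nominal
    signal = spgr_signal(
        phantom.h2o_true[..., None],
        phantom.t1_true[..., None],
        phantom.t2star_true[..., None],
        te[None, None, None, :],
        protocol.tr,
        flip_eff[..., None],
        phantom.b1minus_true[..., None],
    )
    if phantom.delta_f_true is not None:
        signal = signal * dephasing_attenuation(phantom.delta_f_true, phantom.voxel_size, te)
        phase = 2.0 * np.pi * phantom.delta_f_true[..., None] * (te[None, None, None, :] * 1e-3)
    else:
        phase = np.zeros_like(signal)

    if phantom.noise_sigma > 0:
        rng = np.random.default_rng(phantom.seed if seed is None else seed)
        cplx = signal * np.exp(1j * phase)
        cplx = cplx + phantom.noise_sigma * (
            rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
        )
        magnitude = np.abs(cplx)
        phase = np.angle(cplx)
    else:
        magnitude = signal

    return EchoTrainVolume(
        magnitude=magnitude,
        phase=phase if with_phase else None,
        protocol=protocol,
        affine=phantom.affine,
    )


def simulate_afi(
    phantom: PhantomSpec,
    afi: AFIProtocol,
    grid=None,
    voxel_size=None,
    seed: int | None = None,
    noise_sigma: float | None = None,
) -> AFIPair:
    """Simulate a two-TR AFI acquisition, optionally on a coarser grid.

    When ``grid``/``voxel_size`` are given (AFI is typically acquired at lower
    resolution than the meGRE), the phantom truth maps are first resampled
    onto that grid by trilinear interpolation.
    """
    if grid is None:
        m0, t1, b1p, b1m = (
            phantom.h2o_true,
            phantom.t1_true,
            phantom.b1plus_true,
            phantom.b1minus_true,
        )
        affine = phantom.affine
    else:
        voxel_size = np.asarray(voxel_size, dtype=float)
        affine = affine_from_voxel_size(voxel_size, grid)
        src = phantom.affine

        def _res(vol):
            out = resample_to_grid(vol, src, grid, affine)
            return np.nan_to_num(out, nan=0.0)

        m0 = _res(phantom.h2o_true)
        t1 = np.maximum(_res(phantom.t1_true), 1.0)
        b1p = np.maximum(_res(phantom.b1plus_true), 1e-6)
        b1m = np.maximum(_res(phantom.b1minus_true), 1e-6)

    s1, s2 = afi_signals(m0, t1, b1p * afi.flip_nominal, afi, b1m)
    sigma = phantom.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(phantom.seed if seed is None else seed)
        s1 = np.abs(s1 + sigma * (rng.standard_normal(s1.shape) + 1j * rng.standard_normal(s1.shape)))
        s2 = np.abs(s2 + sigma * (rng.standard_normal(s2.shape) + 1j * rng.standard_normal(s2.shape)))
    return AFIPair(s1=s1, s2=s2, protocol=afi, affine=affine)


def sigma_for_snr(phantom: PhantomSpec, protocol: AcquisitionProtocol, snr: float,
                  reference_mask: np.ndarray | None = None) -> float:
    """Noise sigma giving the requested first-echo SNR.

    SNR is defined as (true first-echo signal)/sigma in the reference region
    (default: the voxel with the median non-zero signal, a WM-like reference
    on the brain phantom).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    flip_eff = phantom.b1plus_true * protocol.flip_nominal
    s1 = spgr_signal(
        phantom.h2o_true,
        phantom.t1_true,
        phantom.t2star_true,
        protocol.te_list[0],
        protocol.tr,
        flip_eff,
        phantom.b1minus_true,
    )
    if reference_mask is not None:
        ref = float(np.mean(s1[reference_mask]))
    else:
        nz = s1[s1 > 0]
        ref = float(np.median(nz)) if nz.size else 0.0
    if ref <= 0:
        raise ValueError("reference signal is zero; cannot define SNR")
    return ref / snr
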