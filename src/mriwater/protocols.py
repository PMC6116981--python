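"""Acquisition protocol descriptions for spoiled multi-echo GRE and AFI sequences.

The default instances reproduce the protocol of the two-point mapping method:
two 3D multi-echo gradient-echo acquisitions at TR = 50 ms with nominal flip
angles of 7 deg (M0-weighted) and 40 deg (T1-weighted), 18 echoes starting at
TE1 = 2.2 ms with 2.55 ms spacing, plus a two-TR AFI acquisition
(TR1 = 125 ms, TR2/TR1 = 5, 40 deg) for transmit-field mapping.  A long-TR
single-flip-angle reference protocol (TR = 10 s, 90 deg, 32 echoes) is also
provided for the gold-standard water-content variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "AFIProtocol",
    "MEGRE_LOW",
    "MEGRE_HIGH",
    "AFI_DEFAULT",
    "LONG_TR_REFERENCE",
    "default_te_list",
]


def default_te_list(n_echoes: int = 18, te1: float = 2.2, dte: float = 2.55) -> np.ndarray:
    """Echo times TE_n = TE1 + n*dTE in ms (n = 0 .. n_echoes-1)."""
    return te1 + dte * np.arange(n_echoes, dtype=float)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Spoiled multi-echo gradient-echo protocol.

    Parameters
    ----------
    tr : float
        Repetition time in ms.
    flip_nominal : float
        Nominal flip angle in degrees, 0 < alpha < 180.
    te_list : numpy.ndarray
        Strictly increasing echo times in ms.
    """

    tr: float
    flip_nominal: float
    te_list: np.ndarray = field(default_factory=default_te_list)

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list, dtype=float)
        object.__setattr__(self, "te_list", te)
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0 < self.flip_nominal < 180:
            raise ValueError(f"flip_nominal must be in (0, 180) deg, got {self.flip_nominal}")
        if te.ndim != 1 or te.size < 1:
            raise ValueError("te_list must be a non-empty 1-D sequence")
        if np.any(te < 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be non-negative and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.te_list.size)


@dataclass(frozen=True)
class AFIProtocol:
    """Actual-flip-angle-imaging protocol: one flip angle, two interleaved TRs.

    The TR ratio ``n = tr2/tr1`` enters the closed-form flip-angle estimate
    ``alpha ~ arccos((r n - 1)/(n - r))`` with r the signal ratio S2/S1.
    """

    tr1: float
    tr2: float
    flip_nominal: float

    def __post_init__(self) -> None:
        if not (self.tr2 > self.tr1 > 0):
            raise ValueError(f"need tr2 > tr1 > 0, got tr1={self.tr1}, tr2={self.tr2}")
        if not 0 < self.flip_nominal < 180:
            raise ValueError(f"flip_nominal must be in (0, 180) deg, got {self.flip_nominal}")

    @property
    def n_ratio(self) -> float:
        return self.tr2 / self.tr1


#: M0-weighted meGRE acquisition (low flip angle).
MEGRE_LOW = AcquisitionProtocol(tr=50.0, flip_nominal=7.0)

#: T1-weighted meGRE acquisition (high flip angle).
MEGRE_HIGH = AcquisitionProtocol(tr=50.0, flip_nominal=40.0)

#: Two-TR AFI transmit-field acquisition.
AFI_DEFAULT = AFIProtocol(tr1=125.0, tr2=625.0, flip_nominal=40.0)

#: Long-TR fully-relaxed reference acquisition (gold-standard water content).
LONG_TR_REFERENCE = AcquisitionProtocol(
    tr=10_000.0, flip_nominal=90.0, te_list=default_te_list(32, te1=3.84, dte=4.08)
)
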