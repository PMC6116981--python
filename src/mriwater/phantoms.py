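"""Digital phantoms with known ground truth for simulator-driven validation.

Two fixtures are provided:

* an 8-tube cylinder phantom emulating an H2O/D2O dilution series (50-100 %
  water, MnSO4-shortened T1), with one tube at 100 % water for calibration;
* a WM/GM/CSF brain phantom with smooth transmit (B1+) and receive (B1-)
  fields, a smooth B0 off-resonance field and a pair of ventricle ellipsoids
  labelled CSF for the normalisation region.

Both return a :class:`PhantomSpec`: per-voxel ground-truth maps plus the noise
level and seed that the forward simulator consumes.  Tissue defaults follow
typical 3 T brain values (WM ~70 % water / 988 ms / 52 ms, GM ~81 % / 1580 ms /
57 ms, ventricular CSF ~100 % / 4000 ms / 800 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import affine_from_voxel_size, world_coordinates

__all__ = [
    "PhantomSpec",
    "BrainPhantom",
    "Ellipsoid",
    "make_tube_phantom",
    "make_brain_phantom",
    "TISSUE_DEFAULTS",
]

#: Per-class (H2O %, T1 ms, T2* ms) ground-truth defaults.
TISSUE_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "wm": (69.9, 988.0, 52.0),
    "gm": (80.8, 1580.0, 57.0),
    "csf": (100.0, 4000.0, 800.0),
}


@dataclass
class PhantomSpec:
    """Ground-truth description consumed by the forward simulator.

    All truth volumes share one 3-D grid.  ``h2o_true`` is percent of pure
    water in [0, 100]; relaxation times are in ms and strictly positive
    (background voxels carry positive placeholder values and zero water).
    ``b1plus_true`` / ``b1minus_true`` are dimensionless relative fields,
    ``delta_f_true`` is B0 off-resonance in Hz (``None`` disables intravoxel
    dephasing in the simulator).
    """

    voxel_size: np.ndarray
    h2o_true: np.ndarray
    t1_true: np.ndarray
    t2star_true: np.ndarray
    b1plus_true: np.ndarray
    b1minus_true: np.ndarray
    delta_f_true: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        shape = self.h2o_true.shape
        for name in ("t1_true", "t2star_true", "b1plus_true", "b1minus_true"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if self.delta_f_true is not None and self.delta_f_true.shape != shape:
            raise ValueError("delta_f_true shape mismatch")
        if np.any(self.h2o_true < 0) or np.any(self.h2o_true > 100):
            raise ValueError("h2o_true must lie in [0, 100] percent")
        for name in ("t1_true", "t2star_true", "b1plus_true", "b1minus_true"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive everywhere")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.h2o_true.shape

    @property
    def affine(self) -> np.ndarray:
        return affine_from_voxel_size(self.voxel_size, self.shape)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world coordinates (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass
class BrainPhantom:
    """Brain phantom: spec plus class probabilities, masks and ventricle region."""

    spec: PhantomSpec
    probabilities: dict[str, np.ndarray] = field(default_factory=dict)
    labels: np.ndarray | None = None  # 0 background, 1 WM, 2 GM, 3 CSF
    ventricle_ellipsoid: Ellipsoid | None = None
    tissue_values: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def mask(self, tissue: str) -> np.ndarray:
        return self.probabilities[tissue] >= 0.5

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def make_tube_phantom(
    h2o_levels=None,
    t1_levels=None,
    t2star: float = 60.0,
    grid=(64, 64, 16),
    voxel_size=(2.0, 2.0, 4.0),
    tube_radius: float = 6.0,
    ring_radius: float = 40.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[PhantomSpec, list[np.ndarray]]:
    """Cylinder phantom of parallel tubes on a zero-signal background.

    Default: eight tubes spanning 50-100 % water with MnSO4-shortened T1
    between 400 and 2200 ms, arranged on a ring, one tube at exactly 100 %
    water for calibration.  Returns the phantom spec and the per-tube voxel
    masks.

    Raises
    ------
    ValueError
        If the level lists differ in length or the tube geometry overlaps.
    """
    if h2o_levels is None:
        h2o_levels = [50.0, 57.0, 64.0, 71.0, 79.0, 86.0, 93.0, 100.0]
    if t1_levels is None:
        t1_levels = [400.0, 600.0, 800.0, 1000.0, 1200.0, 1500.0, 1800.0, 2200.0]
    h2o_levels = list(map(float, h2o_levels))
    t1_levels = list(map(float, t1_levels))
    if len(h2o_levels) != len(t1_levels):
        raise ValueError("h2o_levels and t1_levels must have equal length")
    n_tubes = len(h2o_levels)

    voxel_size = np.asarray(voxel_size, dtype=float)
    affine = affine_from_voxel_size(voxel_size, grid)
    x, y, z = world_coordinates(grid, affine)

    angles = 2 * np.pi * np.arange(n_tubes) / n_tubes
    centers = np.stack([ring_radius * np.cos(angles), ring_radius * np.sin(angles)], axis=1)
    # tubes must be pairwise disjoint cylinders
    for i in range(n_tubes):
        for j in range(i + 1, n_tubes):
            if np.linalg.norm(centers[i] - centers[j]) < 2 * tube_radius:
                raise ValueError(
                    f"tubes {i} and {j} overlap: centre distance "
                    f"{np.linalg.norm(centers[i] - centers[j]):.1f} mm < {2 * tube_radius} mm"
                )

    h2o = np.zeros(grid)
    t1 = np.full(grid, 1000.0)  # positive placeholder outside tubes
    t2 = np.full(grid, float(t2star))
    masks = []
    for i in range(n_tubes):
        m = (x - centers[i, 0]) ** 2 + (y - centers[i, 1]) ** 2 <= tube_radius**2
        masks.append(m)
        h2o[m] = h2o_levels[i]
        t1[m] = t1_levels[i]

    spec = PhantomSpec(
        voxel_size=voxel_size,
        h2o_true=h2o,
        t1_true=t1,
        t2star_true=t2,
        b1plus_true=np.ones(grid),
        b1minus_true=np.ones(grid),
        delta_f_true=None,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return spec, masks


def _normalised_coords(grid, voxel_size):
    affine = affine_from_voxel_size(voxel_size, grid)
    x, y, z = world_coordinates(grid, affine)
    half = np.asarray(voxel_size) * (np.asarray(grid) - 1) / 2.0
    return x / half[0], y / half[1], z / half[2], (x, y, z)


def make_brain_phantom(
    grid=(64, 64, 64),
    voxel_size=(2.0, 2.0, 2.0),
    tissue_values: dict | None = None,
    b1plus_amplitude: float = 0.15,
    b1minus_amplitude: float = 0.15,
    delta_f_amplitude: float = 25.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BrainPhantom:
    """Piecewise-constant WM/GM/CSF brain phantom with smooth fields.

    Geometry: an outer GM shell over a WM core inside a brain ellipsoid, with
    two central ventricle ellipsoids labelled CSF.  The transmit field B1+ is
    a centre-bright quadratic (1 +/- ``b1plus_amplitude``), the receive field
    B1- a low-order polynomial spanning roughly ``1 +/- b1minus_amplitude``,
    and the off-resonance field a smooth quadratic-plus-cross-term surface of
    peak amplitude ``delta_f_amplitude`` Hz, representative of a well-shimmed
    brain at 3 T.  Class probability volumes are crisp (0/1); the CSF
    probability is exactly 1 inside the ventricles.
    """
    if tissue_values is None:
        tissue_values = dict(TISSUE_DEFAULTS)
    xn, yn, zn, (x, y, z) = _normalised_coords(grid, voxel_size)

    brain = (xn / 0.88) ** 2 + (yn / 0.8) ** 2 + (zn / 0.72) ** 2 <= 1.0
    inner = (xn / (0.88 * 0.82)) ** 2 + (yn / (0.8 * 0.82)) ** 2 + (zn / (0.72 * 0.82)) ** 2 <= 1.0

    half = np.asarray(voxel_size) * (np.asarray(grid) - 1) / 2.0
    vent_semi = (0.28 * half[0], 0.12 * half[1], 0.12 * half[2])
    offset = 0.22 * half[1]
    vent_l = Ellipsoid((0.0, -offset, 0.0), vent_semi)
    vent_r = Ellipsoid((0.0, +offset, 0.0), vent_semi)
    ventricles = vent_l.contains(x, y, z) | vent_r.contains(x, y, z)
    # one bounding ellipsoid around both lateral ventricles (normalisation region)
    bounding = Ellipsoid(
        (0.0, 0.0, 0.0),
        (vent_semi[0] * 1.3, offset + vent_semi[1] * 1.3, vent_semi[2] * 1.3),
    )

    labels = np.zeros(grid, dtype=np.int8)
    labels[brain] = 2  # GM shell
    labels[inner] = 1  # WM core
    labels[ventricles & brain] = 3  # CSF

    h2o = np.zeros(grid)
    t1 = np.full(grid, 1000.0)
    t2 = np.full(grid, 50.0)
    for lab, name in ((1, "wm"), (2, "gm"), (3, "csf")):
        w, a, b = tissue_values[name]
        m = labels == lab
        h2o[m], t1[m], t2[m] = w, a, b

    r2 = xn**2 + yn**2 + zn**2
    b1plus = 1.0 + b1plus_amplitude * (1.0 - r2) - b1plus_amplitude / 2.0
    b1minus = 1.0 + b1minus_amplitude * (xn**2 - 0.5 * yn**2) + 0.4 * b1minus_amplitude * xn * yn * zn
    delta_f = delta_f_amplitude * (zn**2 - 0.3) + 0.3 * delta_f_amplitude * xn * yn

    probabilities = {
        "wm": (labels == 1).astype(float),
        "gm": (labels == 2).astype(float),
        "csf": (labels == 3).astype(float),
    }

    spec = PhantomSpec(
        voxel_size=np.asarray(voxel_size, dtype=float),
        h2o_true=h2o,
        t1_true=t1,
        t2star_true=t2,
        b1plus_true=b1plus,
        b1minus_true=b1minus,
        delta_f_true=delta_f,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return BrainPhantom(
        spec=spec,
        probabilities=probabilities,
        labels=labels,
        ventricle_ellipsoid=bounding,
        tissue_values=dict(tissue_values),
    )
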