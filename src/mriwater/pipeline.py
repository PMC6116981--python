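"""The full mapping chain: B1+ -> T1 -> T2*/TE_max -> M0 corrections -> H2O.

``fit_pipeline`` is the in-memory engine working on arrays/objects;
``run_pipeline`` wraps it with NIfTI and YAML I/O for the command line.  Any
stage failure is re-raised as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .protocols import AcquisitionProtocol, AFIProtocol, default_te_list
from .signal_model import EchoTrainVolume, AFIPair
from .b1map import afi_flip_angle, afi_refine, b1plus_calibrate, median_filter_b1, B1PlusMap
from .relaxometry import (
    fit_t1_two_point,
    fieldmap_from_phase,
    compute_te_max,
    fit_t2star,
    T1Map,
    T2StarMap,
    FieldGradientMap,
    T1_CLIP_MS,
    T2STAR_CLIP_MS,
)
from .water_content import (
    correct_m0,
    estimate_receive_bias,
    csf_normalization_mask,
    normalize_h2o,
    NormalisationRule,
    M0Map,
    H2OMap,
)
from .phantoms import Ellipsoid
from .geometry import resample_to_grid
from . import io as mio

__all__ = ["FitConfig", "PipelineConfig", "ParameterMaps", "PipelineError",
           "fit_pipeline", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class FitConfig:
    """Every tunable of the fitting chain, at the method's default values."""

    n_echoes_t1: int = 3
    n_echoes_m0: int = 3
    t1_max: float = T1_CLIP_MS  # ms, clip bound
    t2star_max: float = T2STAR_CLIP_MS  # ms, clip bound
    min_echoes: int = 3
    q_threshold: float = 0.5  # cycles across half the voxel
    t1_xatol: float = 0.01  # ms, solver tolerance
    afi_t1_assumed: float = 1000.0  # ms
    b1_median_radius: int = 1  # voxels, 0 disables
    bias_poly_order: int = 4
    bias_n_classes: int = 3


@dataclass
class ParameterMaps:
    """Co-registered output maps of one pipeline run."""

    b1plus: np.ndarray
    t1: T1Map
    t2star: T2StarMap
    m0: M0Map
    h2o: H2OMap
    fieldmap: FieldGradientMap | None
    b1minus: np.ndarray
    report: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def fit_pipeline(
    low: EchoTrainVolume,
    high: EchoTrainVolume,
    b1plus_source: AFIPair | B1PlusMap | np.ndarray,
    csf_prob: np.ndarray,
    b1minus: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    config: FitConfig = FitConfig(),
    rule: NormalisationRule = NormalisationRule(),
) -> ParameterMaps:
    """Run the full chain on in-memory volumes.

    ``b1plus_source`` may be an AFI acquisition (fitted, filtered and
    resampled onto the meGRE grid) or an already-computed B1+ volume.  When
    ``b1minus`` is None the receive field is estimated from the partially
    corrected M0 map inside ``brain_mask`` (default: voxels with tissue
    probability mass).
    """
    report: dict = {}
    shape = low.shape

    with _stage("B1+ mapping"):
        if isinstance(b1plus_source, AFIPair):
            alpha0 = afi_flip_angle(b1plus_source)
            alpha = afi_refine(alpha0, b1plus_source, t1_assumed=config.afi_t1_assumed)
            b1 = b1plus_calibrate(alpha, b1plus_source.protocol.flip_nominal)
            b1 = median_filter_b1(b1, radius=config.b1_median_radius)
            b1_arr = resample_to_grid(
                np.where(b1.valid_mask, b1.b1plus, np.nan),
                b1plus_source.affine, shape, low.affine,
            )
        elif isinstance(b1plus_source, B1PlusMap):
            b1_arr = np.where(b1plus_source.valid_mask, b1plus_source.b1plus, np.nan)
        else:
            b1_arr = np.asarray(b1plus_source, dtype=float)
        if b1_arr.shape != shape:
            raise ValueError(f"B1+ shape {b1_arr.shape} does not match meGRE grid {shape}")
        report["b1plus_invalid_pct"] = 100.0 * float(np.mean(~np.isfinite(b1_arr)))

    with _stage("T1 fitting"):
        t1map = fit_t1_two_point(
            low, high, b1_arr,
            n_echoes=config.n_echoes_t1,
            t1_bounds=(1.0, config.t1_max),
            xatol=config.t1_xatol,
        )
        report["t1_clipped_pct"] = 100.0 * float(np.mean(t1map.clipped_mask))

    with _stage("T2* fitting"):
        fieldmap = None
        te_bound = None
        if low.phase is not None:
            fieldmap = fieldmap_from_phase(low)
            fieldmap = compute_te_max(
                fieldmap,
                np.linalg.norm(np.asarray(low.affine)[:3, :3], axis=0),
                q_threshold=config.q_threshold,
            )
            te_bound = fieldmap
        t2map = fit_t2star(
            low, te_max=te_bound,
            min_echoes=config.min_echoes, t2star_max=config.t2star_max,
        )
        report["t2star_clipped_pct"] = 100.0 * float(np.mean(t2map.clipped_mask))
        report["t2star_invalid_pct"] = 100.0 * float(np.mean(~t2map.valid_mask))

    with _stage("B1- estimation"):
        if b1minus is None:
            partial = correct_m0(
                low, t2map, t1map, b1_arr, b1minus=None, n_echoes=config.n_echoes_m0
            )
            if brain_mask is None:
                first = low.magnitude[..., 0]
                brain_mask = first > 0.05 * float(first.max())
            b1minus = estimate_receive_bias(
                partial, brain_mask,
                n_classes=config.bias_n_classes, poly_order=config.bias_poly_order,
            )
            report["b1minus_source"] = "estimated"
        else:
            b1minus = np.asarray(b1minus, dtype=float)
            report["b1minus_source"] = "supplied"

    with _stage("M0 correction"):
        m0map = correct_m0(
            low, t2map, t1map, b1_arr, b1minus=b1minus, n_echoes=config.n_echoes_m0
        )
        report["m0_invalid_pct"] = 100.0 * float(np.mean(~m0map.valid_mask))

    with _stage("CSF normalisation"):
        mask = csf_normalization_mask(csf_prob, t1map, t2map, rule, affine=low.affine)
        h2omap = normalize_h2o(m0map, mask)
        report["c_norm"] = h2omap.c_norm
        report["norm_mask_voxels"] = int(np.sum(h2omap.norm_mask))

    return ParameterMaps(
        b1plus=b1_arr, t1=t1map, t2star=t2map, m0=m0map, h2o=h2omap,
        fieldmap=fieldmap, b1minus=b1minus, report=report,
    )


@dataclass
class PipelineConfig:
    """File-level configuration for a pipeline run (YAML-serialisable)."""

    megre_low: AcquisitionProtocol = None
    megre_high: AcquisitionProtocol = None
    afi: AFIProtocol = None
    inputs: dict = field(default_factory=dict)
    fit: FitConfig = field(default_factory=FitConfig)
    rule: NormalisationRule = field(default_factory=NormalisationRule)
    output_dir: str = "maps"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.megre_low is None:
            self.megre_low = AcquisitionProtocol(tr=50.0, flip_nominal=7.0)
        if self.megre_high is None:
            self.megre_high = AcquisitionProtocol(tr=50.0, flip_nominal=40.0)
        if self.afi is None:
            self.afi = AFIProtocol(tr1=125.0, tr2=625.0, flip_nominal=40.0)

    def to_dict(self) -> dict:
        def proto(p: AcquisitionProtocol) -> dict:
            return {"tr": p.tr, "flip_nominal": p.flip_nominal, "te_list": p.te_list.tolist()}

        rule = {
            "csf_prob_min": self.rule.csf_prob_min,
            "t1_min": self.rule.t1_min,
            "t2star_min": self.rule.t2star_min,
            "ellipsoid": None
            if self.rule.ellipsoid is None
            else {
                "center": list(self.rule.ellipsoid.center),
                "semi_axes": list(self.rule.ellipsoid.semi_axes),
            },
        }
        return {
            "protocols": {
                "megre_low": proto(self.megre_low),
                "megre_high": proto(self.megre_high),
                "afi": {
                    "tr1": self.afi.tr1,
                    "tr2": self.afi.tr2,
                    "flip_nominal": self.afi.flip_nominal,
                },
            },
            "inputs": dict(self.inputs),
            "fit": asdict(self.fit),
            "normalisation": rule,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        protos = d.get("protocols", {})

        def proto(key, tr, flip):
            p = protos.get(key, {})
            te = p.get("te_list")
            return AcquisitionProtocol(
                tr=p.get("tr", tr),
                flip_nominal=p.get("flip_nominal", flip),
                te_list=np.asarray(te, dtype=float) if te is not None else default_te_list(),
            )

        afi_d = protos.get("afi", {})
        norm = d.get("normalisation", {})
        ell = norm.get("ellipsoid")
        rule = NormalisationRule(
            csf_prob_min=norm.get("csf_prob_min", 0.99),
            t1_min=norm.get("t1_min", 2900.0),
            t2star_min=norm.get("t2star_min", 500.0),
            ellipsoid=None
            if ell is None
            else Ellipsoid(tuple(ell["center"]), tuple(ell["semi_axes"])),
        )
        return cls(
            megre_low=proto("megre_low", 50.0, 7.0),
            megre_high=proto("megre_high", 50.0, 40.0),
            afi=AFIProtocol(
                tr1=afi_d.get("tr1", 125.0),
                tr2=afi_d.get("tr2", 625.0),
                flip_nominal=afi_d.get("flip_nominal", 40.0),
            ),
            inputs=dict(d.get("inputs", {})),
            fit=FitConfig(**d.get("fit", {})),
            rule=rule,
            output_dir=d.get("output_dir", "maps"),
            seed=d.get("seed", 0),
        )


def _load_echo_train(cfg: PipelineConfig, key: str, protocol: AcquisitionProtocol,
                     phase_key: str | None = None) -> EchoTrainVolume:
    path = cfg.inputs.get(key)
    if path is None:
        raise IOError(f"missing input '{key}' in config")
    data, affine = mio.read_volume(path)
    phase = None
    if phase_key and cfg.inputs.get(phase_key):
        phase, _ = mio.read_volume(cfg.inputs[phase_key])
    return EchoTrainVolume(magnitude=data, phase=phase, protocol=protocol, affine=affine)


def run_pipeline(config: PipelineConfig) -> ParameterMaps:
    """File-driven pipeline: read inputs, fit, write all maps and a JSON report."""
    with _stage("input loading"):
        low = _load_echo_train(config, "megre_low_magnitude", config.megre_low,
                               "megre_low_phase")
        high = _load_echo_train(config, "megre_high_magnitude", config.megre_high)

    with _stage("B1+ mapping"):
        if config.inputs.get("b1plus"):
            b1_src, _ = mio.read_volume(config.inputs["b1plus"])
        elif config.inputs.get("afi_s1") and config.inputs.get("afi_s2"):
            s1, aff = mio.read_volume(config.inputs["afi_s1"])
            s2, _ = mio.read_volume(config.inputs["afi_s2"])
            b1_src = AFIPair(s1=s1, s2=s2, protocol=config.afi, affine=aff)
        else:
            raise IOError(
                "B1+ stage needs either a 'b1plus' volume or an AFI pair "
                "('afi_s1' + 'afi_s2') in the config inputs"
            )

    csf_prob, _ = mio.read_volume(config.inputs["csf_prob"]) if config.inputs.get(
        "csf_prob") else (None, None)
    if csf_prob is None:
        raise PipelineError("stage 'CSF normalisation' failed: missing 'csf_prob' input")
    b1minus = None
    if config.inputs.get("b1minus"):
        b1minus, _ = mio.read_volume(config.inputs["b1minus"])
    brain_mask = None
    if config.inputs.get("brain_mask"):
        bm, _ = mio.read_volume(config.inputs["brain_mask"])
        brain_mask = bm > 0.5

    maps = fit_pipeline(
        low, high, b1_src, csf_prob,
        b1minus=b1minus, brain_mask=brain_mask,
        config=config.fit, rule=config.rule,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = low.affine
    mio.write_volume(maps.b1plus, aff, out / "b1plus.nii.gz")
    mio.write_volume(maps.t1.t1, aff, out / "t1_ms.nii.gz")
    mio.write_volume(maps.t2star.t2star, aff, out / "t2star_ms.nii.gz")
    mio.write_volume(maps.m0.m0, aff, out / "m0.nii.gz")
    mio.write_volume(maps.h2o.h2o, aff, out / "h2o_percent.nii.gz")
    mio.write_volume(maps.b1minus, aff, out / "b1minus.nii.gz")
    mio.write_volume(maps.h2o.norm_mask.astype(np.uint8), aff, out / "norm_mask.nii.gz")
    if maps.fieldmap is not None:
        mio.write_volume(maps.fieldmap.delta_f, aff, out / "delta_f_hz.nii.gz")
        mio.write_volume(maps.fieldmap.te_max, aff, out / "te_max_ms.nii.gz")
    with open(out / "report.json", "w") as fh:
        json.dump(maps.report, fh, indent=2)
    return maps
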