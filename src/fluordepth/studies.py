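"""Seeded replications of the simulation studies at desk scale.

Three study kinds are provided:

* ``depth_sweep`` — simulate dual-excitation fluorescence images of an
  inclusion over a grid of true depths with the voxel Monte Carlo, run the
  calibration/log-ratio/inversion pipeline, and compare the recovered depth
  against each configured forward model (planar vs point-source).
* ``geometry_size_study`` — the same sweep across inclusion shapes
  (cylinder, sphere, disk) and radii, quantifying how inclusion geometry
  degrades the point-fluorophore models.
* ``property_perturbation_study`` — generate the log-ratio with the
  analytic planar model at the true properties and invert with properties
  mis-scaled by +-25% (each coefficient alone, jointly, and with opposite
  signs).  The analytic forward isolates the property-mismatch effect from
  Monte Carlo noise; an MC forward is available as a switch.

Every study is reproducible from its config and seed; per-scene seeds are
spawned deterministically from the top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import icg_like_fluorophore, prostate_like_spectra
from .inversion import (
    CalibratedImage,
    depth_map,
    log_ratio_map,
    profile_stats,
)
from .mc import InclusionGeometry, TransportConfig, build_medium, simulate_fluorescence
from .models import (
    FluorophoreSpec,
    LinearRatioModel,
    RatioModelSpec,
    WavelengthChannel,
    linear_ratio_model,
    make_channel,
)
from .optics import OpticalProperties, Spectrum, band_average

__all__ = [
    "StudyConfig",
    "StudyResult",
    "PERTURBATION_CONDITIONS",
    "band_limited_properties",
    "dual_excitation_channels",
    "mc_scene_depth_estimate",
    "analytic_depth_estimate",
    "depth_sweep",
    "geometry_size_study",
    "property_perturbation_study",
]

# (mua factor, musp factor), applied at both wavelengths
PERTURBATION_CONDITIONS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "mua_under": (0.75, 1.0),
    "musp_under": (1.0, 0.75),
    "joint_under": (0.75, 0.75),
    "mua_over": (1.25, 1.0),
    "musp_over": (1.0, 1.25),
    "joint_over": (1.25, 1.25),
    "mua_under_musp_over": (0.75, 1.25),
    "mua_over_musp_under": (1.25, 0.75),
}


@dataclass(frozen=True)
class StudyConfig:
    """Declarative description of one study run."""

    kind: str = "depth_sweep"
    depths_mm: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    radii_mm: tuple[float, ...] = (0.5, 5.0)
    shapes: tuple[str, ...] = ("cylinder", "sphere", "disk")
    shape: str = "cylinder"
    radius_mm: float = 1.0
    target_nm: float = 640.0
    reference_nm: float = 760.0
    emission_nm: float = 820.0
    bandwidth_nm: float = 10.0
    n: float = 1.3
    g: float = 0.8
    dims_mm: tuple[float, float, float] = (60.0, 60.0, 30.0)
    voxel_mm: float = 1.0
    n_photons: int = 1_000_000
    emission_photons: int = 400_000
    convention: str = "with_mua"
    intercept_form: str = "rederived"
    model_sources: tuple[str, ...] = ("planar",)
    perturbation_conditions: tuple[str, ...] = tuple(PERTURBATION_CONDITIONS)
    forward: str = "analytic"  # perturbation study: analytic | mc
    profile_length_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "depth_sweep",
            "geometry_size",
            "property_perturbation",
            "wavelength_pairs",
        ):
            raise ValueError(f"unknown study kind {self.kind!r}")
        if not self.depths_mm:
            raise ValueError("depth grid must be nonempty")
        for name in self.perturbation_conditions:
            if name not in PERTURBATION_CONDITIONS:
                raise ValueError(f"unknown perturbation condition {name!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in sorted(self.__dict__.items())},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Per-condition records plus provenance."""

    config: StudyConfig
    records: pd.DataFrame
    seed: int

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Channel and model construction from the fixture spectra
# ---------------------------------------------------------------------------


def band_limited_properties(
    mua_spec: Spectrum,
    musp_spec: Spectrum,
    wavelength_nm: float,
    bandwidth_nm: float = 10.0,
    n: float = 1.3,
    g: float = 0.8,
) -> OpticalProperties:
    """Effective properties: band averages over a bandwidth around the line."""
    return OpticalProperties(
        wavelength_nm=wavelength_nm,
        mua=band_average(mua_spec, wavelength_nm, bandwidth_nm),
        musp=band_average(musp_spec, wavelength_nm, bandwidth_nm),
        n=n,
        g=g,
    )


def dual_excitation_channels(
    cfg: StudyConfig,
    spectra: tuple[Spectrum, Spectrum] | None = None,
    scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[WavelengthChannel, WavelengthChannel]:
    """(target, reference) channels from fixture spectra, optionally mis-scaled."""
    mua_spec, musp_spec = spectra if spectra is not None else prostate_like_spectra()
    chans = []
    for role, lam in (("target", cfg.target_nm), ("reference", cfg.reference_nm)):
        props = band_limited_properties(
            mua_spec, musp_spec, lam, cfg.bandwidth_nm, cfg.n, cfg.g
        ).scaled(*scale)
        chans.append(make_channel(role, props, cfg.convention))
    return tuple(chans)


def _ratio_model(cfg: StudyConfig, source: str, channels) -> LinearRatioModel:
    spec = RatioModelSpec(
        approach="dual_excitation",
        geometry="semi_infinite" if source == "planar" else "infinite",
        source=source,
        convention=cfg.convention,
        intercept_form=cfg.intercept_form,
    )
    return linear_ratio_model(spec, *channels)


# ---------------------------------------------------------------------------
# One MC scene -> one depth estimate
# ---------------------------------------------------------------------------


def mc_scene_depth_estimate(
    cfg: StudyConfig,
    inclusion: InclusionGeometry,
    models: dict[str, LinearRatioModel],
    channels: tuple[WavelengthChannel, WavelengthChannel],
    fluor: FluorophoreSpec,
    scene_seed: int,
    emission_props: OpticalProperties,
) -> dict[str, float]:
    """Simulate one scene at both excitation wavelengths and invert.

    Returns the profile-mean depth estimate per model, plus the profile
    standard deviation of the first model (pipeline noise indicator).
    """
    target, reference = channels
    background = {
        target.wavelength_nm: target.props,
        reference.wavelength_nm: reference.props,
        emission_props.wavelength_nm: emission_props,
    }
    medium = build_medium(
        cfg.dims_mm, cfg.voxel_mm, background, inclusion, fluor
    )
    seeds = np.random.SeedSequence(scene_seed).generate_state(2) % (2**31)
    images = []
    for ch, s in zip((target, reference), seeds):
        t_cfg = TransportConfig(
            n_photons=cfg.n_photons, seed=int(s), source="planar"
        )
        img = simulate_fluorescence(
            medium, t_cfg, ch.wavelength_nm, cfg.emission_nm,
            emission_photons=cfg.emission_photons,
        )
        images.append(img)

    # the calibration-well factor: equal source powers, fluorophore
    # absorption ratio at the two excitation lines
    well = fluor.mua_f(target.wavelength_nm) / fluor.mua_f(reference.wavelength_nm)
    cal = [
        CalibratedImage(img.pixels, img.wavelength_nm, img.pixel_mm)
        for img in images
    ]
    lrm = log_ratio_map(cal[0], cal[1], calib=well)

    nx, ny, _ = medium.labels.shape
    center = (nx // 2, ny // 2)
    direction = "x" if inclusion.shape != "cylinder" or inclusion.axis == "x" else "y"
    out: dict[str, float] = {}
    for name, model in models.items():
        dm = depth_map(lrm, model)
        stats = profile_stats(dm, center, direction, cfg.profile_length_mm)
        out[f"d_est_{name}"] = stats.mean_mm
        out[f"d_std_{name}"] = stats.std_mm
    return out


def _study_inputs(cfg: StudyConfig):
    spectra = prostate_like_spectra()
    channels = dual_excitation_channels(cfg, spectra)
    fluor = icg_like_fluorophore()
    emission_props = band_limited_properties(
        *spectra, cfg.emission_nm, cfg.bandwidth_nm, cfg.n, cfg.g
    )
    models = {src: _ratio_model(cfg, src, channels) for src in cfg.model_sources}
    return spectra, channels, fluor, emission_props, models


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------


def depth_sweep(cfg: StudyConfig) -> StudyResult:
    """MC depth sweep for one inclusion, inverted with each configured model."""
    _, channels, fluor, emission_props, models = _study_inputs(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    scene_seeds = ss.generate_state(len(cfg.depths_mm)) % (2**31)
    rows = []
    for d_true, s in zip(cfg.depths_mm, scene_seeds):
        inclusion = InclusionGeometry(
            shape=cfg.shape, radius=cfg.radius_mm, depth=float(d_true)
        )
        est = mc_scene_depth_estimate(
            cfg, inclusion, models, channels, fluor, int(s), emission_props
        )
        for name in models:
            d_est = est[f"d_est_{name}"]
            rows.append(
                {
                    "depth_true_mm": float(d_true),
                    "model": name,
                    "shape": cfg.shape,
                    "radius_mm": cfg.radius_mm,
                    "d_est_mm": d_est,
                    "d_std_mm": est[f"d_std_{name}"],
                    "error_mm": d_est - float(d_true),
                    "rel_error_pct": (
                        100.0 * (d_est - d_true) / d_true if d_true > 0 else np.nan
                    ),
                    "seed": int(s),
                }
            )
    return StudyResult(cfg, pd.DataFrame(rows), cfg.seed)


def geometry_size_study(cfg: StudyConfig) -> StudyResult:
    """Depth sweep across inclusion shapes and radii (MC forward)."""
    _, channels, fluor, emission_props, models = _study_inputs(cfg)
    combos = [(sh, r) for sh in cfg.shapes for r in cfg.radii_mm]
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(combos) * len(cfg.depths_mm)) % (2**31)
    rows = []
    k = 0
    for shape, radius in combos:
        for d_true in cfg.depths_mm:
            inclusion = InclusionGeometry(
                shape=shape, radius=float(radius), depth=float(d_true)
            )
            est = mc_scene_depth_estimate(
                cfg, inclusion, models, channels, fluor, int(seeds[k]),
                emission_props,
            )
            k += 1
            for name in models:
                d_est = est[f"d_est_{name}"]
                rows.append(
                    {
                        "shape": shape,
                        "radius_mm": float(radius),
                        "depth_true_mm": float(d_true),
                        "model": name,
                        "d_est_mm": d_est,
                        "error_mm": d_est - float(d_true),
                        "abs_error_mm": abs(d_est - float(d_true)),
                    }
                )
    return StudyResult(cfg, pd.DataFrame(rows), cfg.seed)


def analytic_depth_estimate(
    cfg: StudyConfig,
    d_true: float,
    condition: str,
    source: str = "planar",
) -> float:
    """Forward with true properties, invert with perturbed ones (analytic).

    The forward log-ratio is the affine planar (or point) model evaluated at
    the true properties; the inversion model is rebuilt after multiplying
    mua and musp by the condition's factors at both wavelengths.
    """
    spectra = prostate_like_spectra()
    true_channels = dual_excitation_channels(cfg, spectra)
    true_model = _ratio_model(cfg, source, true_channels)
    log_gamma = true_model(d_true)

    f_mua, f_musp = PERTURBATION_CONDITIONS[condition]
    pert_channels = dual_excitation_channels(cfg, spectra, scale=(f_mua, f_musp))
    pert_model = _ratio_model(cfg, source, pert_channels)
    return float((log_gamma - pert_model.intercept) / pert_model.slope)


def property_perturbation_study(cfg: StudyConfig) -> StudyResult:
    """Signed depth error under +-25% property misestimation.

    Default forward is the analytic planar model (deterministic; isolates
    the property-mismatch effect).  ``cfg.forward='mc'`` replaces the
    forward log-ratio with a Monte Carlo scene per depth.
    """
    rows = []
    if cfg.forward == "mc":
        spectra, channels, fluor, emission_props, _ = _study_inputs(cfg)
        ss = np.random.SeedSequence(cfg.seed)
        seeds = ss.generate_state(len(cfg.depths_mm)) % (2**31)
        pert_models = {}
        for name in cfg.perturbation_conditions:
            pert_channels = dual_excitation_channels(
                cfg, spectra, scale=PERTURBATION_CONDITIONS[name]
            )
            pert_models[name] = _ratio_model(cfg, "planar", pert_channels)
        for d_true, s in zip(cfg.depths_mm, seeds):
            inclusion = InclusionGeometry(
                shape=cfg.shape, radius=cfg.radius_mm, depth=float(d_true)
            )
            est = mc_scene_depth_estimate(
                cfg, inclusion, pert_models, channels, fluor, int(s),
                emission_props,
            )
            for name in cfg.perturbation_conditions:
                d_est = est[f"d_est_{name}"]
                rows.append(_pert_row(name, d_true, d_est))
    else:
        for d_true in cfg.depths_mm:
            for name in cfg.perturbation_conditions:
                d_est = analytic_depth_estimate(cfg, float(d_true), name)
                rows.append(_pert_row(name, float(d_true), d_est))
    return StudyResult(cfg, pd.DataFrame(rows), cfg.seed)


def _pert_row(condition: str, d_true: float, d_est: float) -> dict:
    f_mua, f_musp = PERTURBATION_CONDITIONS[condition]
    return {
        "condition": condition,
        "f_mua": f_mua,
        "f_musp": f_musp,
        "depth_true_mm": d_true,
        "d_est_mm": d_est,
        "error_mm": d_est - d_true,
        "rel_error_pct": 100.0 * (d_est - d_true) / d_true if d_true > 0 else np.nan,
    }
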