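"""Voxelized two-pass fluorescence Monte Carlo simulator.

The simulator produces the raw data of a wide-field fluorescence depth
measurement: 2D images of photon weight exiting the top surface of a
labeled voxel medium.  Fluorescence is simulated in two passes:

1. an **excitation** pass transports photons at the excitation wavelength
   and records the absorbed weight per voxel;
2. an **emission** pass launches photons isotropically from the inclusion
   voxels, with per-voxel launch weight proportional to the absorbed
   excitation weight times the fraction of that absorption attributable to
   the fluorophore (``mua_f / mua_inclusion``) times the quantum yield, and
   transports them at the emission wavelength.

The top-surface emission image is the simulated measurement; in the
ratiometric pipeline two such images (two excitation or two emission
wavelengths) are combined into a log-ratio map.

By default transport uses the *similarity* reduction: scattering at the
reduced coefficient ``musp`` with isotropic phase function, which leaves
the diffusive fluence unchanged while keeping step counts tractable at
desk-scale photon budgets.  Setting ``TransportConfig.use_anisotropy=True``
transports at ``mus = musp / (1 - g)`` with Henyey-Greenstein scattering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import _kernels as _k
from .models import FluorophoreSpec
from .optics import OpticalProperties

__all__ = [
    "InclusionGeometry",
    "VoxelMedium",
    "TransportConfig",
    "AbsorptionMap",
    "SurfaceImage",
    "WeightLedger",
    "build_medium",
    "run_excitation",
    "run_emission",
    "simulate_fluorescence",
    "run_homogeneous",
]


@dataclass(frozen=True)
class InclusionGeometry:
    """Analytic inclusion shape.

    ``depth`` is the shortest distance from the top surface (z = 0) to the
    inclusion boundary.  Cylinders lie horizontally, span the full lateral
    extent along ``axis``, and are laterally centered; spheres and disks are
    centered laterally.  Disks are flat horizontal cylinders of the given
    ``radius`` and vertical ``thickness``.
    """

    shape: str  # cylinder | sphere | disk
    radius: float  # mm
    depth: float  # mm, top surface to inclusion boundary
    thickness: float = 1.0  # mm, disk only
    axis: str = "x"  # cylinder axis, parallel to the surface

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere", "disk"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if self.shape == "disk" and not self.thickness > 0:
            raise ValueError("disk thickness must be positive")
        if self.axis not in ("x", "y"):
            raise ValueError("cylinder axis must be 'x' or 'y'")

    @property
    def vertical_extent(self) -> float:
        if self.shape == "disk":
            return self.thickness
        return 2.0 * self.radius


@dataclass
class VoxelMedium:
    """Labeled voxel grid with per-label, per-wavelength optical properties.

    Label 0 is background, label 1 the inclusion.  The inclusion shares the
    background's scattering and adds the fluorophore's absorption:
    ``mua_inc(lam) = mua_bg(lam) + mua_f(lam)``.
    """

    dims_mm: tuple[float, float, float]
    voxel_mm: float
    labels: np.ndarray  # uint8 (nx, ny, nz)
    background: Mapping[float, OpticalProperties]
    fluorophore: FluorophoreSpec | None = None
    inclusion: InclusionGeometry | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def background_at(self, wavelength_nm: float) -> OpticalProperties:
        try:
            return self.background[wavelength_nm]
        except KeyError:
            raise KeyError(
                f"no background optical properties at {wavelength_nm} nm"
            ) from None

    def mua_fluor(self, wavelength_nm: float) -> float:
        if self.fluorophore is None:
            return 0.0
        return float(self.fluorophore.mua_f(wavelength_nm))

    def label_properties(
        self, wavelength_nm: float, use_anisotropy: bool
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Per-label (mua, mus, g) arrays plus the relative index."""
        bg = self.background_at(wavelength_nm)
        mua_inc = bg.mua + self.mua_fluor(wavelength_nm)
        if use_anisotropy:
            mus_t = bg.musp / (1.0 - bg.g)
            g_t = bg.g
        else:  # similarity reduction: musp with isotropic scattering
            mus_t = bg.musp
            g_t = 0.0
        mua = np.array([bg.mua, mua_inc])
        mus = np.array([mus_t, mus_t])
        g = np.array([g_t, g_t])
        return mua, mus, g, float(bg.n)

    @property
    def center_xy_mm(self) -> tuple[float, float]:
        nx, ny, _ = self.labels.shape
        return (
            (nx // 2 + 0.5) * self.voxel_mm,
            (ny // 2 + 0.5) * self.voxel_mm,
        )


@dataclass(frozen=True)
class TransportConfig:
    """Photon-transport run configuration."""

    n_photons: int = 1_000_000
    seed: int = 0
    roulette_threshold: float = 1e-2
    roulette_survival: float = 0.1
    source: str = "planar"  # planar | pencil | point_isotropic
    use_anisotropy: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0 < self.roulette_threshold < 1):
            raise ValueError("roulette threshold must be in (0, 1)")
        if not (0 < self.roulette_survival < 1):
            raise ValueError("roulette survival must be in (0, 1)")
        if self.source not in ("planar", "pencil", "point_isotropic"):
            raise ValueError(f"unknown source type {self.source!r}")


@dataclass(frozen=True)
class WeightLedger:
    """Weight bookkeeping of one transport run (per unit launched weight)."""

    launched: float
    deposited: float
    escaped_top: float
    escaped_other: float
    specular: float
    roulette_killed: float
    roulette_created: float

    @property
    def balance(self) -> float:
        """launched + roulette gains - all sinks; ~0 for a correct run."""
        return (
            self.launched
            + self.roulette_created
            - self.deposited
            - self.escaped_top
            - self.escaped_other
            - self.specular
            - self.roulette_killed
        )


@dataclass
class AbsorptionMap:
    """Deposited photon weight per voxel, normalized per launched photon."""

    grid: np.ndarray  # float64 (nx, ny, nz)
    voxel_mm: float
    wavelength_nm: float
    ledger: WeightLedger
    n_photons: int
    seed: int


@dataclass
class SurfaceImage:
    """Photon weight exiting the top surface per pixel (pixel = voxel face)."""

    pixels: np.ndarray  # float64 (nx, ny)
    pixel_mm: float
    wavelength_nm: float
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.pixels.sum())


def build_medium(
    dims_mm: tuple[float, float, float],
    voxel_mm: float,
    background: Mapping[float, OpticalProperties],
    inclusion: InclusionGeometry | None = None,
    fluorophore: FluorophoreSpec | None = None,
) -> VoxelMedium:
    """Voxelize an analytic inclusion into a labeled medium.

    A voxel is labeled 1 iff its center lies inside the analytic shape; if
    the shape is smaller than the grid can resolve, the voxel(s) containing
    the shape's center (line) are labeled so that a point-like limit always
    has a source.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    n = tuple(int(round(d / voxel_mm)) for d in dims_mm)
    if any(v < 1 for v in n):
        raise ValueError("medium dimensions smaller than one voxel")
    if inclusion is not None:
        if inclusion.depth + inclusion.vertical_extent > dims_mm[2]:
            raise ValueError("inclusion extends below the medium")
        lateral = min(dims_mm[0], dims_mm[1])
        if 2 * inclusion.radius > lateral:
            raise ValueError("inclusion wider than the medium")
        labels = _voxelize(n, voxel_mm, inclusion)
    else:
        labels = np.zeros(n, dtype=np.uint8)
    return VoxelMedium(
        dims_mm=tuple(float(d) for d in dims_mm),
        voxel_mm=float(voxel_mm),
        labels=labels,
        background=dict(background),
        fluorophore=fluorophore,
        inclusion=inclusion,
    )


def _voxelize(
    n: tuple[int, int, int], voxel: float, inc: InclusionGeometry
) -> np.ndarray:
    nx, ny, nz = n
    cx = (nx // 2 + 0.5) * voxel
    cy = (ny // 2 + 0.5) * voxel
    xs = (np.arange(nx) + 0.5) * voxel
    ys = (np.arange(ny) + 0.5) * voxel
    zs = (np.arange(nz) + 0.5) * voxel
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    if inc.shape == "cylinder":
        zc = inc.depth + inc.radius
        if inc.axis == "x":
            mask = (ys[:, None] - cy) ** 2 + (zs[None, :] - zc) ** 2 <= inc.radius**2
            labels[:, :, :] = mask[None, :, :]
        else:
            mask = (xs[:, None] - cx) ** 2 + (zs[None, :] - zc) ** 2 <= inc.radius**2
            labels[:, :, :] = mask[:, None, :]
        if labels.sum() == 0:
            iz = min(int((inc.depth + inc.radius) / voxel), nz - 1)
            if inc.axis == "x":
                labels[:, ny // 2, iz] = 1
            else:
                labels[nx // 2, :, iz] = 1
    elif inc.shape == "sphere":
        zc = inc.depth + inc.radius
        r2 = (
            (xs[:, None, None] - cx) ** 2
            + (ys[None, :, None] - cy) ** 2
            + (zs[None, None, :] - zc) ** 2
        )
        labels[r2 <= inc.radius**2] = 1
        if labels.sum() == 0:
            iz = min(int(zc / voxel), nz - 1)
            labels[nx // 2, ny // 2, iz] = 1
    else:  # disk
        lat2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        z_in = (zs >= inc.depth) & (zs <= inc.depth + inc.thickness)
        lat_mask = lat2 <= inc.radius**2
        labels[:, :, z_in] = lat_mask[:, :, None]
        if labels.sum() == 0:
            iz = min(int((inc.depth + 0.5 * inc.thickness) / voxel), nz - 1)
            labels[nx // 2, ny // 2, iz] = 1
    return labels


_SRC_MODE = {"planar": _k.SRC_PLANAR, "pencil": _k.SRC_PENCIL,
             "point_isotropic": _k.SRC_POINT_ISO}

_EMPTY_CDF = np.ones(1)
_EMPTY_VOX = np.zeros((1, 3), dtype=np.int64)


def _make_ledger(raw: np.ndarray, deposited: float) -> WeightLedger:
    return WeightLedger(
        launched=float(raw[_k.LEDGER_LAUNCHED]),
        deposited=deposited,
        escaped_top=float(raw[_k.LEDGER_ESCAPED_TOP]),
        escaped_other=float(raw[_k.LEDGER_ESCAPED_OTHER]),
        specular=float(raw[_k.LEDGER_SPECULAR]),
        roulette_killed=float(raw[_k.LEDGER_ROULETTE_KILLED]),
        roulette_created=float(raw[_k.LEDGER_ROULETTE_CREATED]),
    )


def run_excitation(
    medium: VoxelMedium,
    cfg: TransportConfig,
    wavelength_nm: float,
    source_xy_mm: tuple[float, float] | None = None,
    source_z_mm: float = 0.0,
) -> tuple[AbsorptionMap, SurfaceImage]:
    """Excitation transport pass: absorbed-weight map and top-surface image.

    ``source_xy_mm`` positions pencil or isotropic point sources (defaults
    to the lateral center); planar sources uniformly illuminate the top
    face at normal incidence.
    """
    mua, mus, g, n_rel = medium.label_properties(wavelength_nm, cfg.use_anisotropy)
    nx, ny, nz = medium.shape
    absorb = np.zeros((nx, ny, nz))
    image = np.zeros((nx, ny))
    sx, sy = source_xy_mm if source_xy_mm is not None else medium.center_xy_mm
    raw = _k.transport(
        medium.labels, mua, mus, g, n_rel, medium.voxel_mm,
        cfg.n_photons, cfg.seed, _SRC_MODE[cfg.source],
        sx, sy, source_z_mm,
        _EMPTY_CDF, _EMPTY_VOX, 0.0,
        cfg.roulette_threshold, cfg.roulette_survival,
        absorb, image,
    )
    absorb /= cfg.n_photons
    image /= cfg.n_photons
    raw = raw / cfg.n_photons
    ledger = _make_ledger(raw, float(absorb.sum()))
    amap = AbsorptionMap(
        grid=absorb, voxel_mm=medium.voxel_mm, wavelength_nm=wavelength_nm,
        ledger=ledger, n_photons=cfg.n_photons, seed=cfg.seed,
    )
    img = SurfaceImage(
        pixels=image, pixel_mm=medium.voxel_mm, wavelength_nm=wavelength_nm,
        metadata={"pass": "excitation", "seed": cfg.seed,
                  "n_photons": cfg.n_photons, "ledger": ledger},
    )
    return amap, img


class EmptySourceError(RuntimeError):
    """The emission pass has no absorbed excitation weight to launch from."""


def run_emission(
    medium: VoxelMedium,
    absorption: AbsorptionMap,
    cfg: TransportConfig,
    wavelength_nm: float,
) -> SurfaceImage:
    """Emission transport pass from the fluorophore-weighted absorption map.

    Launch probability per inclusion voxel is proportional to the absorbed
    excitation weight scaled by ``mua_f(lam_x)/mua_inclusion(lam_x)`` (the
    fraction of absorption due to the fluorophore) and the quantum yield;
    total launched weight equals the total fluorescence source strength so
    that absolute image levels are comparable across excitation channels.
    """
    if medium.fluorophore is None:
        raise ValueError("medium has no fluorophore")
    if absorption.grid.shape != medium.labels.shape:
        raise ValueError("absorption map does not match the medium grid")
    lam_x = absorption.wavelength_nm
    bg_x = medium.background_at(lam_x)
    mua_f = medium.mua_fluor(lam_x)
    mua_inc = bg_x.mua + mua_f
    qf = medium.fluorophore.quantum_yield

    mask = medium.labels == 1
    weights = absorption.grid[mask] * (mua_f / mua_inc) * qf
    total = float(weights.sum())
    if total <= 0.0:
        if mua_f == 0.0 or medium.fluorophore.concentration_uM == 0.0:
            # no fluorophore absorption: legitimately a dark image
            nx, ny, _ = medium.shape
            return SurfaceImage(
                pixels=np.zeros((nx, ny)), pixel_mm=medium.voxel_mm,
                wavelength_nm=wavelength_nm,
                metadata={"pass": "emission", "excitation_nm": lam_x,
                          "source_weight": 0.0},
            )
        raise EmptySourceError(
            "no absorbed excitation weight inside the inclusion"
        )
    idx = np.argwhere(mask)
    keep = weights > 0
    idx = idx[keep]
    weights = weights[keep]
    cdf = np.cumsum(weights) / weights.sum()
    cdf[-1] = 1.0

    mua, mus, g, n_rel = medium.label_properties(wavelength_nm, cfg.use_anisotropy)
    nx, ny, nz = medium.shape
    absorb = np.zeros((nx, ny, nz))
    image = np.zeros((nx, ny))
    raw = _k.transport(
        medium.labels, mua, mus, g, n_rel, medium.voxel_mm,
        cfg.n_photons, cfg.seed, _k.SRC_VOXELS,
        0.0, 0.0, 0.0,
        cdf, np.ascontiguousarray(idx, dtype=np.int64), total,
        cfg.roulette_threshold, cfg.roulette_survival,
        absorb, image,
    )
    ledger = _make_ledger(raw, float(absorb.sum()))
    return SurfaceImage(
        pixels=image, pixel_mm=medium.voxel_mm, wavelength_nm=wavelength_nm,
        metadata={"pass": "emission", "excitation_nm": lam_x,
                  "seed": cfg.seed, "n_photons": cfg.n_photons,
                  "source_weight": total, "ledger": ledger},
    )


def simulate_fluorescence(
    medium: VoxelMedium,
    cfg: TransportConfig,
    excitation_nm: float,
    emission_nm: float,
    emission_photons: int | None = None,
) -> SurfaceImage:
    """Two-pass fluorescence simulation: excitation then emission.

    The emission pass uses a seed derived deterministically from
    ``cfg.seed`` so the two passes are independent streams.
    """
    amap, _ = run_excitation(medium, cfg, excitation_nm)
    em_seed = int(np.random.SeedSequence(cfg.seed).generate_state(2)[1] % (2**31))
    em_cfg = replace(
        cfg,
        seed=em_seed,
        n_photons=emission_photons or cfg.n_photons,
    )
    img = run_emission(medium, amap, em_cfg, emission_nm)
    img.metadata.update(
        {
            "excitation_seed": cfg.seed,
            "excitation_photons": cfg.n_photons,
            "excitation_nm": excitation_nm,
            "emission_nm": emission_nm,
        }
    )
    return img


def run_homogeneous(
    props: OpticalProperties,
    dims_mm: tuple[float, float, float],
    voxel_mm: float,
    cfg: TransportConfig,
    source_xy_mm: tuple[float, float] | None = None,
    source_z_mm: float = 0.0,
) -> tuple[AbsorptionMap, SurfaceImage]:
    """Convenience: transport in a homogeneous medium (oracle checks)."""
    medium = build_medium(dims_mm, voxel_mm, {props.wavelength_nm: props})
    return run_excitation(
        medium, cfg, props.wavelength_nm, source_xy_mm, source_z_mm
    )
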