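"""Closed-form diffusion forward models for ratiometric depth estimation.

The observable is the natural log of the ratio of surface fluorescence
intensities acquired at two wavelengths.  Two ratiometric strategies exist:

* **dual-emission** — one excitation wavelength, two emission wavelengths.
  The excitation fluence at the fluorophore cancels in the ratio, so the
  prediction is independent of the excitation source; the ratio is a ratio
  of emission Green's functions.
* **dual-excitation** — two excitation wavelengths, one emission wavelength.
  The emission Green's function cancels instead, and the ratio probes the
  excitation fluence at the fluorophore's depth, so the source geometry
  (point-like vs planar epi-illumination) and the medium boundary enter the
  model explicitly.

For a point fluorophore in an infinite medium both strategies give

    ln Gamma(d) = (1/delta_2 - 1/delta_1) * d + ln(D_2 / D_1),

an affine function of depth ``d``.  For planar epi-illumination of a
semi-infinite medium the dual-excitation log-ratio stays affine in ``d``
but with a different intercept built from the planar fluence

    psi(d) = (delta/D) * exp(-(d+zb)/delta) * sinh((z0+zb)/delta),   d > z0,

(the shallow branch, ``d <= z0``, is the continuous counterpart
``(delta/D) * exp(-(z0+zb)/delta) * sinh((d+zb)/delta)``).  The
semi-infinite *dual-emission* ratio is not affine; it multiplies the
infinite-medium ratio by a boundary correction with two printed limiting
regimes (shallow: no correction; deep: a constant factor).

All fluences drop wavelength-independent multiplicative constants: every
model output is consumed as a two-wavelength ratio, where such constants
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .optics import (
    DerivedDiffusion,
    OpticalProperties,
    Spectrum,
    derive_diffusion,
)

__all__ = [
    "WavelengthChannel",
    "RatioModelSpec",
    "SourceSpec",
    "FluorophoreSpec",
    "LinearRatioModel",
    "green_infinite",
    "green_semi_infinite",
    "fluence_planar_semi_infinite",
    "linear_ratio_model",
    "ratio_semi_infinite_emission",
    "calibration_factor",
    "make_channel",
]


@dataclass(frozen=True)
class WavelengthChannel:
    """One wavelength of a ratiometric pair with its derived quantities."""

    role: str  # "target" or "reference"
    wavelength_nm: float
    props: OpticalProperties
    derived: DerivedDiffusion

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise ValueError("role must be 'target' or 'reference'")


def make_channel(
    role: str,
    props: OpticalProperties,
    convention: str = "with_mua",
    n_outside: float = 1.0,
) -> WavelengthChannel:
    """Build a channel whose derived quantities are consistent with props."""
    return WavelengthChannel(
        role=role,
        wavelength_nm=props.wavelength_nm,
        props=props,
        derived=derive_diffusion(props, convention, n_outside),
    )


@dataclass(frozen=True)
class RatioModelSpec:
    """Which approach / geometry / source / convention variant to evaluate.

    ``intercept_form`` only matters for the (dual_excitation, semi_infinite,
    planar) combination: ``as_printed`` is the intercept written directly
    from the sinh prefactors, ``rederived`` additionally carries the
    ``zb/delta`` exponents so that the affine model coincides exactly with
    the log-ratio of the planar fluences it is derived from.
    """

    approach: str = "dual_excitation"  # dual_emission | dual_excitation
    geometry: str = "semi_infinite"  # infinite | semi_infinite
    source: str = "planar"  # point | planar
    convention: str = "with_mua"  # with_mua | without_mua
    intercept_form: str = "rederived"  # as_printed | rederived

    def __post_init__(self) -> None:
        if self.approach not in ("dual_emission", "dual_excitation"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.geometry not in ("infinite", "semi_infinite"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.source not in ("point", "planar"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.convention not in ("with_mua", "without_mua"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.intercept_form not in ("as_printed", "rederived"):
            raise ValueError(f"unknown intercept form {self.intercept_form!r}")
        if self.source == "planar" and self.geometry != "semi_infinite":
            raise ValueError("a planar source requires semi_infinite geometry")


@dataclass(frozen=True)
class SourceSpec:
    """Excitation source: type and per-wavelength output power (arb)."""

    type: str = "planar"  # point | planar
    power_per_wavelength: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in ("point", "planar"):
            raise ValueError("source type must be 'point' or 'planar'")
        for lam, p in self.power_per_wavelength.items():
            if not p > 0:
                raise ValueError(f"source power at {lam} nm must be positive")

    def power(self, wavelength_nm: float) -> float:
        if not self.power_per_wavelength:
            return 1.0
        try:
            return float(self.power_per_wavelength[wavelength_nm])
        except KeyError:
            raise KeyError(
                f"no source power defined at {wavelength_nm} nm"
            ) from None


@dataclass(frozen=True)
class FluorophoreSpec:
    """Fluorophore description: spectra (unit peak), yield, concentration.

    The fluorophore absorption coefficient is
    ``mua_f(lam) = ln(10) * eps_peak * excitation(lam) * C / 10`` in mm^-1,
    with ``eps_peak`` the molar extinction at the excitation peak
    (cm^-1 M^-1) and ``C`` the concentration in mol/L (stored in uM).
    """

    excitation: Spectrum
    emission: Spectrum
    quantum_yield: float = 0.12
    concentration_uM: float = 1.0
    peak_extinction_cm_M: float = 2.4e5

    def __post_init__(self) -> None:
        if not (0 < self.quantum_yield <= 1):
            raise ValueError("quantum yield must be in (0, 1]")
        if self.concentration_uM < 0:
            raise ValueError("concentration must be nonnegative")
        for name in ("excitation", "emission"):
            spec = getattr(self, name)
            if abs(spec.values.max() - 1.0) > 1e-9:
                raise ValueError(f"{name} spectrum must be normalized to unit peak")

    def mua_f(self, wavelength_nm) -> float:
        """Fluorophore absorption coefficient at an excitation wavelength, mm^-1."""
        c_molar = self.concentration_uM * 1e-6
        return (
            np.log(10.0)
            * self.peak_extinction_cm_M
            * self.excitation(wavelength_nm)
            * c_molar
            / 10.0
        )


@dataclass(frozen=True)
class LinearRatioModel:
    """Affine model ln Gamma(d) = slope * d + intercept for a channel pair."""

    slope: float  # mm^-1
    intercept: float  # dimensionless
    spec: RatioModelSpec
    channels: tuple[WavelengthChannel, WavelengthChannel]

    def __call__(self, depth_mm):
        return self.slope * np.asarray(depth_mm, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# Green's functions and fluences
# ---------------------------------------------------------------------------


def green_infinite(d: float, derived: DerivedDiffusion) -> float:
    """Point-source Green's function of an infinite medium, exp(-d/delta)/(4 pi D d)."""
    if not d > 0:
        raise ValueError("distance must be positive (point-source singularity)")
    return float(np.exp(-d / derived.delta) / (4.0 * np.pi * derived.D * d))


def green_semi_infinite(source_depth: float, derived: DerivedDiffusion) -> float:
    """Green's function of a semi-infinite medium, observed at the surface
    directly above a point source at depth ``source_depth``.

    Real source at depth ``z`` plus a negative image at ``-z - 2 zb``
    (extrapolated boundary condition): the two monopole distances from the
    surface origin are ``z`` and ``z + 2 zb``.
    """
    if not source_depth > 0:
        raise ValueError("source depth must be positive")
    r1 = source_depth
    r2 = source_depth + 2.0 * derived.zb
    pref = 1.0 / (4.0 * np.pi * derived.D)
    return float(
        pref
        * (
            np.exp(-r1 / derived.delta) / r1
            - np.exp(-r2 / derived.delta) / r2
        )
    )


def fluence_planar_semi_infinite(d: float, derived: DerivedDiffusion) -> float:
    """Excitation fluence at depth ``d`` for planar epi-illumination of a
    semi-infinite medium (arbitrary common normalization).

    Deep branch (d > z0): (delta/D) exp(-(d+zb)/delta) sinh((z0+zb)/delta).
    Shallow branch (d <= z0): (delta/D) exp(-(z0+zb)/delta) sinh((d+zb)/delta).
    The two branches agree at d = z0, making the fluence continuous.
    """
    if d < 0:
        raise ValueError("depth must be nonnegative")
    delta, D, z0, zb = derived.delta, derived.D, derived.z0, derived.zb
    if d > z0:
        return float(
            (delta / D) * np.exp(-(d + zb) / delta) * np.sinh((z0 + zb) / delta)
        )
    return float(
        (delta / D) * np.exp(-(z0 + zb) / delta) * np.sinh((d + zb) / delta)
    )


# ---------------------------------------------------------------------------
# Ratio models
# ---------------------------------------------------------------------------


def _check_pair(target: WavelengthChannel, reference: WavelengthChannel) -> None:
    if target.role != "target" or reference.role != "reference":
        raise ValueError("pass channels as (target, reference)")


def linear_ratio_model(
    spec: RatioModelSpec,
    target: WavelengthChannel,
    reference: WavelengthChannel,
) -> LinearRatioModel:
    """Affine ln-ratio-vs-depth model for the requested variant.

    The slope is ``1/delta_ref - 1/delta_target`` for every variant.  The
    intercept is ``ln(D_ref / D_target)`` for the point-source variants
    (infinite medium, either approach; the dual-excitation point source in a
    semi-infinite medium shares the same affine form).  For the
    (dual_excitation, semi_infinite, planar) variant the intercept follows
    from the planar fluence; ``as_printed`` keeps only the sinh prefactors,
    ``rederived`` adds ``zb_ref/delta_ref - zb_target/delta_target`` so the
    affine model equals the log planar-fluence ratio identically for
    ``d > max(z0)``.
    """
    _check_pair(target, reference)
    for ch in (target, reference):
        if ch.derived.convention != spec.convention:
            raise ValueError(
                "channel derived quantities use a different diffusion "
                "convention than the model spec"
            )
    d1, d2 = target.derived, reference.derived
    slope = 1.0 / d2.delta - 1.0 / d1.delta

    if spec.source == "planar":
        if spec.approach != "dual_excitation":
            raise ValueError(
                "the planar-source affine model applies to the dual_excitation "
                "approach; the dual-emission semi-infinite ratio is not affine "
                "(use ratio_semi_infinite_emission)"
            )
        as_printed = float(
            np.log(
                (d1.delta * d2.D * np.sinh((d1.z0 + d1.zb) / d1.delta))
                / (d2.delta * d1.D * np.sinh((d2.z0 + d2.zb) / d2.delta))
            )
        )
        if spec.intercept_form == "as_printed":
            intercept = as_printed
        else:
            intercept = as_printed + (d2.zb / d2.delta - d1.zb / d1.delta)
    else:
        if spec.approach == "dual_emission" and spec.geometry == "semi_infinite":
            raise ValueError(
                "the dual-emission semi-infinite ratio is not affine; use "
                "ratio_semi_infinite_emission"
            )
        intercept = float(np.log(d2.D / d1.D))

    return LinearRatioModel(
        slope=slope, intercept=intercept, spec=spec, channels=(target, reference)
    )


def ratio_semi_infinite_emission(
    d: float,
    target: WavelengthChannel,
    reference: WavelengthChannel,
) -> float:
    """Dual-emission intensity ratio for a semi-infinite medium.

    Multiplies the infinite-medium ratio by the boundary correction
    ``f_1(d)/f_2(d)`` with ``f_i(d) = 1 - exp(-4 A D_i/delta_i) / (1 + 4 A D_i/d)``.
    Reproduces both limiting regimes: no correction as ``d -> 0`` and the
    constant factor ``(1 - e^{-4AD_1/delta_1})/(1 - e^{-4AD_2/delta_2})``
    for ``d >> 4 A max(D_1, D_2)``.
    """
    _check_pair(target, reference)
    if not d > 0:
        raise ValueError("depth must be positive")
    d1, d2 = target.derived, reference.derived
    gamma_inf = green_infinite(d, d1) / green_infinite(d, d2)

    def f(der: DerivedDiffusion) -> float:
        four_ad = 4.0 * der.A * der.D
        return 1.0 - np.exp(-four_ad / der.delta) / (1.0 + four_ad / d)

    return float(gamma_inf * f(d1) / f(d2))


def calibration_factor(
    fluor: FluorophoreSpec | None,
    spec: RatioModelSpec,
    target_nm: float,
    reference_nm: float,
    source: SourceSpec | None = None,
    spectrum: str = "excitation",
    include_fluorophore_excitation: bool = False,
) -> float:
    """Factor converting a raw intensity ratio into the model's Gamma.

    dual_emission: the fluorophore spectral factor evaluated at the two
    *emission* wavelengths (which fluorophore spectrum carries that factor
    is a configuration choice via ``spectrum``).  dual_excitation: the
    source power ratio ``S0(target)/S0(reference)``; with
    ``include_fluorophore_excitation=True`` the fluorophore absorption
    ratio at the two excitation wavelengths is folded in as well — this is
    what a calibration-well measurement of the bare fluorophore captures.
    Divide a raw ratio by this factor to obtain the calibrated Gamma.
    """
    if spec.approach == "dual_emission":
        if fluor is None:
            raise ValueError("dual-emission calibration needs a fluorophore spec")
        curve = fluor.excitation if spectrum == "excitation" else fluor.emission
        denom = curve(reference_nm)
        if denom <= 0:
            raise ValueError("zero fluorophore spectral factor at reference")
        return float(curve(target_nm) / denom)

    src = source if source is not None else SourceSpec()
    denom = src.power(reference_nm)
    if denom <= 0:
        raise ValueError("zero source power at reference wavelength")
    factor = src.power(target_nm) / denom
    if include_fluorophore_excitation:
        if fluor is None:
            raise ValueError("fluorophore spec required to include its factor")
        mu_ref = fluor.mua_f(reference_nm)
        if mu_ref <= 0:
            raise ValueError("zero fluorophore absorption at reference")
        factor *= fluor.mua_f(target_nm) / mu_ref
    return float(factor)
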