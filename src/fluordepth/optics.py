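"""Wavelength-dependent tissue optical properties and spectral utilities.

This module holds the quantities that the diffusion approximation to photon
transport is built from: the absorption coefficient ``mua`` and reduced
scattering coefficient ``musp`` (both in mm^-1), the refractive index ``n``
and scattering anisotropy ``g``, and the derived diffusion quantities

* diffusion coefficient ``D`` (mm),
* effective penetration depth ``delta = sqrt(D / mua)`` (mm),
* effective attenuation coefficient ``mueff = 1 / delta`` (mm^-1),
* isotropic-source displacement depth ``z0 = 1 / musp`` (mm),
* extrapolated-boundary distance ``zb = 2 A D`` (mm), with ``A`` the
  refractive-index-mismatch factor of the extrapolated boundary condition.

Two conventions for ``D`` are supported: ``with_mua`` uses
``D = 1 / (3 (mua + musp))`` while ``without_mua`` uses ``D = 1 / (3 musp)``,
the common simplification valid deep in the diffusive regime
(``musp >> mua``).  The convention propagates to every derived quantity.

Tabulated spectra (chromophore extinction curves, fluorophore
excitation/emission, property spectra) are represented by :class:`Spectrum`,
which defines linear interpolation between knots and *refuses* to
extrapolate: depth estimation is sensitive enough to the properties that
silently inventing out-of-band values would be a trap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "OpticalProperties",
    "DerivedDiffusion",
    "boundary_factor_A",
    "derive_diffusion",
    "band_average",
    "build_tissue_spectra",
    "available_chromophores",
    "load_chromophore",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

SPECTRUM_KINDS = ("absorption", "reduced_scattering", "excitation", "emission")


@dataclass(frozen=True)
class Spectrum:
    """A tabulated wavelength/value curve with linear interpolation.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres.
    values : array-like
        Nonnegative, finite values; units depend on ``kind``.
    kind : str
        One of ``absorption`` (mm^-1), ``reduced_scattering`` (mm^-1),
        ``excitation`` (arb) or ``emission`` (arb).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "absorption"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and matching")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two knots")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def __call__(self, wavelength_nm):
        """Linearly interpolate; out-of-range evaluation is an error."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.range_nm
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside tabulated range [{lo}, {hi}] nm"
            )
        out = np.interp(lam, self.wavelengths_nm, self.values)
        return float(out) if np.isscalar(wavelength_nm) else out

    def normalized_to_peak(self) -> "Spectrum":
        peak = float(self.values.max())
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.wavelengths_nm, self.values / peak, self.kind)

    @property
    def peak_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])


@dataclass(frozen=True)
class OpticalProperties:
    """Background optical properties at a single wavelength."""

    wavelength_nm: float
    mua: float  # absorption coefficient, mm^-1
    musp: float  # reduced scattering coefficient, mm^-1
    n: float = 1.3  # refractive index of the medium (relative to air)
    g: float = 0.8  # scattering anisotropy (only the Monte Carlo uses it)

    def __post_init__(self) -> None:
        if not (self.mua > 0 and np.isfinite(self.mua)):
            raise ValueError("mua must be positive and finite")
        if not (self.musp > 0 and np.isfinite(self.musp)):
            raise ValueError("musp must be positive and finite")
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy g must satisfy 0 <= g < 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    def scaled(self, f_mua: float = 1.0, f_musp: float = 1.0) -> "OpticalProperties":
        """Return a copy with mua and musp multiplied by the given factors."""
        return OpticalProperties(
            self.wavelength_nm, self.mua * f_mua, self.musp * f_musp, self.n, self.g
        )


@dataclass(frozen=True)
class DerivedDiffusion:
    """Diffusion-theory quantities derived from :class:`OpticalProperties`."""

    D: float  # diffusion coefficient, mm
    delta: float  # effective penetration depth, mm
    mueff: float  # 1/delta, mm^-1
    z0: float  # source displacement depth, mm
    zb: float  # extrapolated boundary distance, mm
    A: float  # boundary mismatch factor, dimensionless
    convention: str = "with_mua"


def boundary_factor_A(n_relative: float) -> float:
    """Refractive-index mismatch factor of the extrapolated boundary condition.

    Uses the standard internal-reflection polynomial
    ``r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n`` and
    ``A = (1 + r_d) / (1 - r_d)``.  For a matched boundary (n = 1) the
    polynomial gives A within 1% of the exact value 1.
    """
    if not (n_relative > 0 and np.isfinite(n_relative)):
        raise ValueError("relative refractive index must be positive")
    n = float(n_relative)
    r_d = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    if r_d >= 1:
        raise ValueError("internal reflection polynomial out of validity range")
    return (1 + r_d) / (1 - r_d)


def derive_diffusion(
    props: OpticalProperties,
    convention: str = "with_mua",
    n_outside: float = 1.0,
) -> DerivedDiffusion:
    """Compute D, delta, mueff, z0, zb, A for a set of optical properties.

    ``convention`` selects ``D = 1/(3(mua+musp))`` (``with_mua``) or the
    diffusive-regime simplification ``D = 1/(3 musp)`` (``without_mua``).
    The penetration depth is ``delta = sqrt(D/mua)`` in both conventions.
    """
    if convention == "with_mua":
        D = 1.0 / (3.0 * (props.mua + props.musp))
    elif convention == "without_mua":
        D = 1.0 / (3.0 * props.musp)
    else:
        raise ValueError(f"unknown diffusion convention {convention!r}")
    delta = float(np.sqrt(D / props.mua))
    A = boundary_factor_A(props.n / n_outside)
    return DerivedDiffusion(
        D=D,
        delta=delta,
        mueff=1.0 / delta,
        z0=1.0 / props.musp,
        zb=2.0 * A * D,
        A=A,
        convention=convention,
    )


def band_average(spec: Spectrum, center_nm: float, bandwidth_nm: float = 10.0) -> float:
    """Mean of the linearly interpolated curve over a band.

    The band ``[center - bw/2, center + bw/2]`` must lie inside the
    tabulated range.  Returns the trapezoidal integral divided by the
    bandwidth, i.e. the average value the band-limited measurement sees.
    """
    if bandwidth_nm <= 0:
        raise ValueError("bandwidth must be positive")
    lo = center_nm - bandwidth_nm / 2.0
    hi = center_nm + bandwidth_nm / 2.0
    rng = spec.range_nm
    if lo < rng[0] or hi > rng[1]:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside tabulated range {rng}"
        )
    inner = spec.wavelengths_nm[
        (spec.wavelengths_nm > lo) & (spec.wavelengths_nm < hi)
    ]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = spec(grid)
    return float(np.trapezoid(vals, grid) / bandwidth_nm)


# ---------------------------------------------------------------------------
# Packaged chromophore tables and the tissue-spectra builder
# ---------------------------------------------------------------------------

# name -> (csv file, conversion factor applied to table value * concentration
# to obtain mua in mm^-1).  Hemoglobins are molar extinction (cm^-1/M, base
# 10) with concentration in mol/L: mua = ln(10) * eps * C / 10.  Water is a
# natural-log absorption coefficient (cm^-1) with "concentration" a volume
# fraction: mua = fraction * table / 10.
_CHROMOPHORES: dict[str, tuple[str, float]] = {
    "hb_oxy": ("hb_oxy_approx.csv", float(np.log(10.0)) / 10.0),
    "hb_deoxy": ("hb_deoxy_approx.csv", float(np.log(10.0)) / 10.0),
    "water": ("water_approx.csv", 1.0 / 10.0),
}


def available_chromophores() -> tuple[str, ...]:
    return tuple(_CHROMOPHORES)


def _read_two_column_csv(text: str) -> tuple[np.ndarray, np.ndarray]:
    wl, vals = [], []
    for row in csv.reader(text.splitlines()):
        if not row or row[0].lstrip().startswith("#"):
            continue
        try:
            wl.append(float(row[0]))
        except ValueError:
            continue  # header line
        vals.append(float(row[1]))
    return np.asarray(wl), np.asarray(vals)


def load_chromophore(name: str) -> Spectrum:
    """Load a packaged chromophore table as a Spectrum (table units)."""
    try:
        fname, _ = _CHROMOPHORES[name]
    except KeyError:
        raise KeyError(
            f"unknown chromophore {name!r}; available: {available_chromophores()}"
        ) from None
    text = resources.files("fluordepth.data").joinpath(fname).read_text()
    wl, vals = _read_two_column_csv(text)
    return Spectrum(wl, vals, "absorption")


def build_tissue_spectra(
    chromophore_concentrations: Mapping[str, float],
    scatter_amplitude: float,
    scatter_power: float,
    wavelength_grid,
    scatter_ref_nm: float = 500.0,
) -> tuple[Spectrum, Spectrum]:
    """Build (mua, musp) spectra from chromophores plus a scattering power law.

    ``mua(lam) = sum_i c_i * conversion_i * table_i(lam)`` over the packaged
    chromophore curves, and ``musp(lam) = a * (lam / lam_ref)^(-b)``.
    Concentrations: mol/L for the hemoglobins, volume fraction for water.
    """
    grid = np.asarray(wavelength_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be a 1-D array of >= 2 points")
    if scatter_amplitude <= 0 or scatter_power <= 0:
        raise ValueError("scatter amplitude and power must be positive")
    mua = np.zeros_like(grid)
    for name, conc in chromophore_concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        table = load_chromophore(name)
        _, conv = _CHROMOPHORES[name]
        mua = mua + conc * conv * table(grid)  # raises if grid exceeds table
    musp = scatter_amplitude * (grid / scatter_ref_nm) ** (-scatter_power)
    return (
        Spectrum(grid, mua, "absorption"),
        Spectrum(grid, musp, "reduced_scattering"),
    )


def read_spectrum_csv(path, kind: str = "absorption") -> Spectrum:
    """Read a 2-column (wavelength_nm, value) CSV with a one-line header."""
    with open(path, "r", newline="") as fh:
        wl, vals = _read_two_column_csv(fh.read())
    return Spectrum(wl, vals, kind)


def write_spectrum_csv(path, spec: Spectrum, value_name: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", value_name])
        for lam, val in zip(spec.wavelengths_nm, spec.values):
            writer.writerow([f"{lam:g}", f"{val:.8g}"])
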