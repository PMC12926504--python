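"""Seeded fixtures: prostate-like tissue spectra and an ICG-like fluorophore.

The package is exercised end-to-end on synthetic inputs.  The tissue
fixture builds absorption from packaged hemoglobin/water curves at a
perfusion typical of a well-vascularized pelvic organ, and reduced
scattering from a power law; the result has the features that matter for
ratiometric depth estimation: strong absorption contrast between 550 and
800 nm, weak contrast between 820 and 890 nm, and a scattering-dominated
(diffusive) regime across the NIR window.

The fluorophore fixture emulates indocyanine green in DMSO: excitation
peak at 779 nm with a short-wavelength shoulder, emission peak at 820 nm,
both normalized to unit peak.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .models import FluorophoreSpec
from .optics import Spectrum, build_tissue_spectra, write_spectrum_csv

__all__ = [
    "DEFAULT_GRID_NM",
    "prostate_like_spectra",
    "icg_like_excitation",
    "icg_like_emission",
    "icg_like_fluorophore",
    "generate_fixtures",
]

DEFAULT_GRID_NM = np.arange(550.0, 901.0, 1.0)

# Tissue composition of the prostate-like preset.  Blood volume fraction and
# oxygen saturation set the hemoglobin contrast that drives the
# dual-excitation slope; whole-blood hemoglobin is taken as 2.3 mM.
BLOOD_VOLUME_FRACTION = 0.04
OXYGEN_SATURATION = 0.75
WATER_FRACTION = 0.65
HEMOGLOBIN_WHOLE_BLOOD_M = 2.3e-3
SCATTER_AMPLITUDE = 2.2  # musp at 500 nm, mm^-1
SCATTER_POWER = 1.1


def prostate_like_spectra(grid_nm=None) -> tuple[Spectrum, Spectrum]:
    """(mua, musp) spectra of the prostate-like background preset."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    c_heme = BLOOD_VOLUME_FRACTION * HEMOGLOBIN_WHOLE_BLOOD_M
    return build_tissue_spectra(
        {
            "hb_oxy": OXYGEN_SATURATION * c_heme,
            "hb_deoxy": (1.0 - OXYGEN_SATURATION) * c_heme,
            "water": WATER_FRACTION,
        },
        scatter_amplitude=SCATTER_AMPLITUDE,
        scatter_power=SCATTER_POWER,
        wavelength_grid=grid,
        scatter_ref_nm=500.0,
    )


def _gauss(lam, center, sigma):
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def _composite_peaked_at(grid, peak_nm, main_sigma, extras):
    """Main Gaussian plus fixed side lobes, with the main-lobe center
    adjusted (fixed-point iteration on a fine grid) so the composite curve
    peaks exactly at ``peak_nm``."""
    fine = np.arange(grid[0], grid[-1] + 0.25, 0.25)
    side = np.zeros_like(fine)
    for amp, center, sigma in extras:
        side += amp * _gauss(fine, center, sigma)
    c = peak_nm
    for _ in range(20):
        total = _gauss(fine, c, main_sigma) + side
        argmax = fine[int(np.argmax(total))]
        if argmax == peak_nm:
            break
        c += peak_nm - argmax

    def evaluate(lam):
        out = _gauss(lam, c, main_sigma)
        for amp, center, sigma in extras:
            out = out + amp * _gauss(lam, center, sigma)
        return out

    return evaluate(np.asarray(grid, float)) / evaluate(np.array([peak_nm]))[0]


def icg_like_excitation(grid_nm=None) -> Spectrum:
    """ICG-like excitation spectrum: 779 nm peak plus a ~715 nm shoulder."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    vals = _composite_peaked_at(
        grid, 779.0, 28.0,
        [(0.45, 715.0, 38.0), (0.03, 620.0, 80.0)],
    )
    return Spectrum(grid, vals, "excitation")


def icg_like_emission(grid_nm=None) -> Spectrum:
    """ICG-like emission spectrum: 820 nm peak with a long red tail."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    vals = _composite_peaked_at(grid, 820.0, 26.0, [(0.35, 865.0, 45.0)])
    return Spectrum(grid, vals, "emission")


def icg_like_fluorophore(
    concentration_uM: float = 1.0,
    quantum_yield: float = 0.12,
    grid_nm=None,
) -> FluorophoreSpec:
    """ICG-like fluorophore at the study concentration (default 1 uM)."""
    return FluorophoreSpec(
        excitation=icg_like_excitation(grid_nm),
        emission=icg_like_emission(grid_nm),
        quantum_yield=quantum_yield,
        concentration_uM=concentration_uM,
        peak_extinction_cm_M=2.4e5,
    )


_SCENE_YAML = """\
# Default phantom scene: prostate-like background, ICG-like cylinder.
seed: {seed}
medium:
  dims_mm: [60, 60, 30]
  voxel_mm: 1.0
  n: 1.3
  g: 0.8
  mua_csv: prostate_like_mua.csv
  musp_csv: prostate_like_musp.csv
inclusion:
  shape: cylinder
  radius_mm: 1.0
  depth_mm: 5.0
  axis: x
fluorophore:
  excitation_csv: icg_like_excitation.csv
  emission_csv: icg_like_emission.csv
  concentration_uM: 1.0
  quantum_yield: 0.12
  peak_extinction_cm_M: 240000.0
channels:
  approach: dual_excitation
  target_nm: 640
  reference_nm: 760
  emission_nm: 820
  bandwidth_nm: 10
transport:
  n_photons: 1000000
  emission_photons: 400000
  roulette_threshold: 0.01
  roulette_survival: 0.1
  source: planar
model:
  geometry: semi_infinite
  source: planar
  convention: with_mua
  intercept_form: rederived
"""


def generate_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the fixture spectra CSVs and a default scene YAML.

    Deterministic given ``seed`` (the fixtures themselves are analytic; the
    seed is recorded in the scene config for downstream runs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mua, musp = prostate_like_spectra()
    paths = {
        "mua": out / "prostate_like_mua.csv",
        "musp": out / "prostate_like_musp.csv",
        "excitation": out / "icg_like_excitation.csv",
        "emission": out / "icg_like_emission.csv",
        "scene": out / "scene_default.yaml",
    }
    write_spectrum_csv(paths["mua"], mua, "mua_mm")
    write_spectrum_csv(paths["musp"], musp, "musp_mm")
    write_spectrum_csv(paths["excitation"], icg_like_excitation(), "relative")
    write_spectrum_csv(paths["emission"], icg_like_emission(), "relative")
    paths["scene"].write_text(_SCENE_YAML.format(seed=int(seed)))
    return paths
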