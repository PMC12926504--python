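"""Image calibration, log-ratio maps, and per-pixel depth inversion.

The measurement pipeline mirrors a wide-field fluorescence acquisition:

1. background-subtract each raw image and normalize by the median signal of
   a calibration-reference image at the same wavelength;
2. form the per-pixel natural-log ratio of the two calibrated images,
   dividing out the source/fluorophore calibration factor;
3. invert the log-ratio with a forward model to obtain a per-pixel depth
   map (affine models invert algebraically; the non-affine semi-infinite
   dual-emission ratio inverts by bisection);
4. summarize a scene by descriptive statistics (mean, population standard
   deviation) along a line profile over the inclusion.

Per-pixel inversion assumes every pixel sits directly above the
fluorophore, so depths are meaningful only over the inclusion footprint;
pixels below a relative intensity floor are masked by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .models import LinearRatioModel, WavelengthChannel, ratio_semi_infinite_emission

__all__ = [
    "CalibratedImage",
    "LogRatioMap",
    "DepthMap",
    "ProfileStats",
    "calibrate_image",
    "log_ratio_map",
    "invert_linear",
    "invert_semi_infinite_emission",
    "depth_map",
    "profile_stats",
    "depth_error",
]


@dataclass
class CalibratedImage:
    """Background-subtracted, reference-normalized intensity image."""

    pixels: np.ndarray
    wavelength_nm: float
    pixel_mm: float = 1.0
    normalization: float = 1.0


@dataclass
class LogRatioMap:
    """Per-pixel ln(I1/I2) with a validity mask (True = invalid)."""

    values: np.ndarray
    mask: np.ndarray
    pixel_mm: float = 1.0
    metadata: dict = field(default_factory=dict)


@dataclass
class DepthMap:
    """Per-pixel depth estimates (mm); mask marks invalid pixels."""

    depths_mm: np.ndarray
    mask: np.ndarray
    pixel_mm: float = 1.0
    clamped: np.ndarray | None = None  # True where negative depths were clamped
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProfileStats:
    """Descriptive statistics along a line profile of a depth map."""

    mean_mm: float
    std_mm: float  # population standard deviation
    n_pixels: int
    center_px: tuple[int, int]
    direction: str
    length_mm: float


class CalibrationError(ValueError):
    pass


def calibrate_image(
    raw: np.ndarray,
    background: np.ndarray,
    calibration_reference: np.ndarray,
    wavelength_nm: float = 0.0,
    pixel_mm: float = 1.0,
    calibration_background: np.ndarray | None = None,
) -> CalibratedImage:
    """Background-subtract and normalize by the calibration-well median.

    The divisor is the median of the background-subtracted calibration
    reference region; the median is used for robustness to hot pixels.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError("raw and background shapes differ")
    calib = np.asarray(calibration_reference, dtype=float)
    if calibration_background is not None:
        calib = calib - np.asarray(calibration_background, dtype=float)
    divisor = float(np.median(calib))
    if divisor <= 0:
        raise CalibrationError("nonpositive calibration median")
    pixels = np.clip(raw - background, 0.0, None) / divisor
    return CalibratedImage(
        pixels=pixels,
        wavelength_nm=wavelength_nm,
        pixel_mm=pixel_mm,
        normalization=divisor,
    )


def log_ratio_map(
    img1: CalibratedImage,
    img2: CalibratedImage,
    calib: float = 1.0,
    noise_floor_fraction: float = 0.01,
) -> LogRatioMap:
    """Per-pixel ln(img1/img2) - ln(calib), masking non-positive pixels.

    Pixels where either channel is <= 0 or below ``noise_floor_fraction``
    of that channel's maximum are masked rather than propagated as
    infinities.
    """
    a, b = img1.pixels, img2.pixels
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    if img1.pixel_mm != img2.pixel_mm:
        raise ValueError("pixel sizes differ")
    if calib <= 0:
        raise ValueError("calibration factor must be positive")
    floor_a = noise_floor_fraction * a.max() if a.size else 0.0
    floor_b = noise_floor_fraction * b.max() if b.size else 0.0
    mask = (a <= 0) | (b <= 0) | (a < floor_a) | (b < floor_b)
    values = np.zeros_like(a, dtype=float)
    ok = ~mask
    values[ok] = np.log(a[ok] / b[ok]) - np.log(calib)
    return LogRatioMap(
        values=values,
        mask=mask,
        pixel_mm=img1.pixel_mm,
        metadata={
            "wavelengths_nm": (img1.wavelength_nm, img2.wavelength_nm),
            "calibration_factor": calib,
        },
    )


def invert_linear(
    log_ratio: float, model: LinearRatioModel, clamp: bool = True
) -> tuple[float, bool]:
    """Invert the affine model: d = (ln Gamma - intercept) / slope.

    Returns ``(depth_mm, clamped)``; negative depths clamp to 0 with the
    flag set (shallow-noise pixels remain countable).
    """
    if model.slope == 0:
        raise ZeroDivisionError(
            "degenerate model: zero slope (channels optically identical)"
        )
    d = (log_ratio - model.intercept) / model.slope
    if clamp and d < 0:
        return 0.0, True
    return float(d), False


def invert_semi_infinite_emission(
    ratio: float,
    target: WavelengthChannel,
    reference: WavelengthChannel,
    bracket: tuple[float, float] = (1e-3, 50.0),
    xtol: float = 1e-4,
) -> float:
    """Invert the non-affine semi-infinite dual-emission ratio by bisection.

    Verifies the model is monotone on the bracket before solving; raises if
    the requested ratio is outside the attainable range.
    """
    lo, hi = bracket
    grid = np.linspace(lo, hi, 64)
    vals = np.array(
        [ratio_semi_infinite_emission(d, target, reference) for d in grid]
    )
    diffs = np.diff(vals)
    if not (np.all(diffs < 0) or np.all(diffs > 0)):
        raise ValueError("model not monotone on the bracket; inversion ambiguous")
    f_lo = vals[0] - ratio
    f_hi = vals[-1] - ratio
    if f_lo * f_hi > 0:
        raise ValueError(
            f"ratio {ratio:g} outside attainable range "
            f"[{min(vals[0], vals[-1]):g}, {max(vals[0], vals[-1]):g}]"
        )
    return float(
        brentq(
            lambda d: ratio_semi_infinite_emission(d, target, reference) - ratio,
            lo,
            hi,
            xtol=xtol,
        )
    )


def depth_map(lrm: LogRatioMap, model: LinearRatioModel) -> DepthMap:
    """Pixel-wise affine inversion of a log-ratio map; mask propagated."""
    if model.slope == 0:
        raise ZeroDivisionError("degenerate model: zero slope")
    depths = (lrm.values - model.intercept) / model.slope
    clamped = depths < 0
    depths = np.where(clamped, 0.0, depths)
    depths[lrm.mask] = np.nan
    return DepthMap(
        depths_mm=depths,
        mask=lrm.mask.copy(),
        pixel_mm=lrm.pixel_mm,
        clamped=clamped & ~lrm.mask,
        metadata={"model": model.spec, **lrm.metadata},
    )


def profile_stats(
    dm: DepthMap,
    center_px: tuple[int, int],
    direction: str = "x",
    length_mm: float = 10.0,
) -> ProfileStats:
    """Mean/std of unmasked pixels along a nearest-pixel line profile.

    The profile has ``round(length/pixel) + 1`` samples (inclusive
    endpoints), centered on ``center_px`` and aligned with an image axis.
    """
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    half = int(round(length_mm / dm.pixel_mm / 2))
    ci, cj = center_px
    ni, nj = dm.depths_mm.shape
    if direction == "x":
        idx = np.arange(ci - half, ci + half + 1)
        if idx[0] < 0 or idx[-1] >= ni:
            raise ValueError("profile exceeds image bounds")
        vals = dm.depths_mm[idx, cj]
        masked = dm.mask[idx, cj]
    else:
        idx = np.arange(cj - half, cj + half + 1)
        if idx[0] < 0 or idx[-1] >= nj:
            raise ValueError("profile exceeds image bounds")
        vals = dm.depths_mm[ci, idx]
        masked = dm.mask[ci, idx]
    vals = vals[~masked]
    if vals.size == 0:
        raise ValueError("all profile pixels are masked")
    return ProfileStats(
        mean_mm=float(np.mean(vals)),
        std_mm=float(np.std(vals)),  # population (n) standard deviation
        n_pixels=int(vals.size),
        center_px=(int(ci), int(cj)),
        direction=direction,
        length_mm=float(length_mm),
    )


def depth_error(d_est: float, d_true: float) -> tuple[float, float | None]:
    """Signed depth error (mm) and relative error (%) when defined.

    Returns ``(d_est - d_true, 100 * (d_est - d_true) / d_true)``; the
    relative form is None for ``d_true <= 0``.
    """
    eps = float(d_est - d_true)
    rel = 100.0 * eps / d_true if d_true > 0 else None
    return eps, rel
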