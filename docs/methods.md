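# Methods

## Problem

A fluorescent object (a dye-filled vessel, nerve, or other structure) sits
at an unknown depth `d` below the surface of optically turbid tissue.  A
wide-field camera images the fluorescence that diffuses back to the
surface.  Because the tissue's absorption `mua(lambda)` and reduced
scattering `musp(lambda)` differ between wavelengths, the *ratio* of two
surface intensities encodes the path length — and hence the depth — while
unknown common factors (dye amount, quantum yield, detector gain) cancel.

Two ratiometric strategies are modeled:

* **dual-emission**: one excitation wavelength, two emission wavelengths.
  The excitation fluence cancels in the ratio, so the prediction is
  independent of the source geometry.
* **dual-excitation**: two excitation wavelengths, one emission wavelength.
  The emission transport cancels instead; the ratio probes the excitation
  fluence at depth, so the source geometry and the tissue boundary enter
  the model.

## Forward models

All models are built from the diffusion approximation, valid when
`musp >> mua`.  Per wavelength the derived quantities are

    D      = 1 / (3 (mua + musp))     (or 1/(3 musp), selectable)
    delta  = sqrt(D / mua),  mueff = 1/delta
    z0     = 1 / musp
    zb     = 2 A D,   A = (1 + r_d)/(1 - r_d),
    r_d    = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n

`A` encodes the refractive-index mismatch of the extrapolated boundary
condition (EBC); with `n = 1.3`, `A = 2.602`.

For a point fluorophore in an infinite medium both strategies give an
affine log-ratio,

    ln Gamma(d) = (1/delta_2 - 1/delta_1) d + ln(D_2 / D_1).

For planar epi-illumination of a semi-infinite medium (the realistic
wide-field configuration), the excitation fluence from the EBC image-source
construction is, up to a wavelength-independent constant,

    psi(d) = (delta/D) exp(-(d+zb)/delta) sinh((z0+zb)/delta),  d > z0,
    psi(d) = (delta/D) exp(-(z0+zb)/delta) sinh((d+zb)/delta),  d <= z0.

The two branches meet continuously at `d = z0`.  The dual-excitation
log-ratio of two such fluences is again affine in `d` for
`d > max(z0_1, z0_2)`, with the same slope and an intercept carrying the
sinh prefactors.  Two intercept variants are provided: `as_printed`
(the bare sinh-prefactor form) and `rederived`, which adds
`zb_2/delta_2 - zb_1/delta_1` so that the affine model equals the log
planar-fluence ratio identically; `rederived` is the default because it is
self-consistent with the fluence it is derived from.  The difference
between the two forms is a constant depth offset of
`(zb_2/delta_2 - zb_1/delta_1)/slope`.

The semi-infinite *dual-emission* ratio is not affine: it multiplies the
infinite-medium ratio by boundary factors
`f_i(d) = 1 - exp(-4 A D_i/delta_i)/(1 + 4 A D_i/d)`.  This form
reproduces both limiting regimes (no correction as `d -> 0`; a constant
factor for `d >> 4 A max D_i`, approached like `1/d`), which the test
suite enforces.  It is inverted numerically (bracketed bisection via
`brentq`, monotonicity checked first).

## Monte Carlo simulator

The independent forward oracle is a voxelized, weighted-packet
(implicit-capture) photon Monte Carlo:

* step lengths are sampled as a dimensionless optical path consumed across
  voxels (exact in heterogeneous media);
* at each interaction a fraction `mua/mut` of the packet weight is
  deposited in the voxel and the remainder scatters by Henyey-Greenstein;
* the top surface applies unpolarized Fresnel partial reflection for the
  index mismatch (total internal reflection included); escaping weight is
  binned per surface pixel.  Side and bottom faces absorb — the media
  simulated are wide enough that lateral boundaries are irrelevant;
* packets below a roulette threshold (relative to their launch weight)
  play Russian roulette; the weight ledger (launched, deposited, escaped,
  specular, roulette killed/created) balances to 1e-6 relative on every
  run, which the tests assert;
* all randomness derives from a single integer seed; runs are bit
  reproducible.

Transport defaults to the *similarity reduction*: scattering at `musp`
with an isotropic phase function.  This leaves the diffusive fluence
unchanged while cutting step counts by `1/(1-g)` (a factor of 5 at
`g = 0.8`), which is what makes desk-scale photon budgets sufficient.
Full anisotropic transport at `mus = musp/(1-g)` is a switch
(`TransportConfig.use_anisotropy`), and the HG sampler itself is verified
against its mean `<cos theta> = g`.

Fluorescence is a two-pass scheme.  The excitation pass records absorbed
weight per voxel.  The emission pass launches packets isotropically from
inclusion voxels with probability proportional to
`absorbed_weight * (mua_f/mua_inclusion) * Qf` — the fraction of local
absorption attributable to the fluorophore times the quantum yield — and
total launch weight equal to the total fluorescence source strength, so
image levels are comparable across excitation channels.  This partition is
the standard fluorescence-MC coupling; the inclusion's absorption is the
background's plus the fluorophore's (`mua_f = ln10 * eps * C / 10`), and
its scattering equals the background's.

Oracle agreement at desk scale (asserted in the suite): Beer-Lambert
deposition in a scattering-free column (3 sigma); shell-averaged fluence
around an isotropic point source within 10% (in practice ~1%) of the
infinite-medium Green's function for r = 2-10 mm; layer-averaged planar
fluence within 15% (in practice ~2%) of the semi-infinite planar closed
form over z = 2-10 mm.

## Measurement pipeline

Raw images are background-subtracted, floored at zero, and normalized by
the *median* of a background-subtracted calibration-well image at the same
wavelength (median for robustness to hot pixels).  Per-pixel
`ln(I1/I2) - ln(calibration factor)` maps are masked where either channel
is nonpositive or below 1% of its maximum (pixels off the inclusion
footprint carry no depth information — the models assume the detector sits
directly above the fluorophore).  Affine models invert algebraically;
negative depths clamp to zero with a flag rather than masking, so
shallow-noise pixels remain countable.  A scene is summarized by the mean
and population standard deviation along a 10-mm nearest-pixel line profile
centered over the inclusion (21 samples at 0.5 mm pixels, 11 at 1 mm).

For simulated dual-excitation data the calibration factor is the
calibration-well ratio `S0(l1) eps_f(l1) / (S0(l2) eps_f(l2))`; with equal
simulated source powers this reduces to the fluorophore absorption ratio
at the two excitation lines.

## Fixtures (what the synthetic data emulates — and what it does not)

Background tissue emulates a well-perfused pelvic organ: absorption from
packaged oxy-/deoxyhemoglobin and water curves at blood volume fraction
4%, oxygen saturation 75%, water fraction 65% (whole-blood hemoglobin
2.3 mM), and scattering `musp = 2.2 (lambda/500)^-1.1 mm^-1`.  The
chromophore tables are smoothed approximations of the standard literature
curves (files suffixed `_approx`); they reproduce the features that drive
the method — strong absorption contrast between 550 and 800 nm, weak
contrast between 820 and 890 nm, and `musp/mua > 13` across 600-900 nm
(diffusion validity) — but are not measurement-grade spectra.  Effective
per-line properties are 10-nm band averages around each wavelength.

The fluorophore emulates indocyanine green in DMSO: excitation peak at
779 nm with a ~715 nm shoulder, emission peak at 820 nm, peak molar
extinction 2.4e5 cm^-1 M^-1, concentration 1 uM, quantum yield 0.12.  At
1 uM the dye's own absorption near its peak (0.05 mm^-1 at 760 nm) is
comparable to the background absorption, so large inclusions visibly
self-shield the longer excitation wavelength — a real effect that the
point-fluorophore models ignore and that the geometry studies expose.

Not emulated: tissue autofluorescence, camera noise and lens/acceptance
effects, heterogeneous or layered backgrounds, fluorophore photobleaching
and binding kinetics.  Passing tests therefore demonstrate correctness of
the models, transport, and pipeline under the stated idealizations, not
robustness to every experimental nuisance.

## Study harness and problem sizes

Default study scene: 60 x 60 x 30 mm medium at 1 mm voxels,
dual-excitation 640/760 nm with emission at 820 nm, planar illumination,
1-mm-radius horizontal cylinder, depth grid 1-10 mm in 1 mm steps
(depth = shortest distance from surface to inclusion boundary;
0 mm is excluded from error metrics because the planar model's deep branch
is documented inaccurate below ~z0).  Per-scene Monte Carlo budgets of
1e6 excitation / 4e5 emission packets put the per-scene profile-mean noise
near 0.2-0.3 mm, well below the 1 mm recovery bound being tested; the
acceptance suite uses slightly smaller budgets where a trend rather than a
bound is asserted.  A full-scale preset (100 x 100 x 50 mm, 0.5 mm voxels,
1e8 packets) is reachable through the same configs.

The property-misestimation study defaults to the analytic planar forward:
generate `ln Gamma(d)` with true properties, invert with properties
mis-scaled by +-25%.  This isolates the mismatch effect and makes two
identities exact, both asserted in the tests: scaling both coefficients by
`f` at both wavelengths scales the slope by `f` and leaves the intercept,
so joint misestimation gives `d_est = d/f` exactly (+33.3% at `f = 0.75`,
-20% at `f = 1.25`); single-coefficient scaling moves the slope roughly
like `sqrt(f)`, giving ~15% (under) and ~11% (over) at the packaged
properties.  An MC forward is a config switch.

## Numerical choices

* No spectral extrapolation anywhere; bands must be covered by the tables.
* Band averages are trapezoidal integrals over the exact band, divided by
  the bandwidth.
* Voxelization labels a voxel if its center is inside the analytic shape;
  shapes smaller than the grid resolve to their center voxel(s) so a
  point-like limit always has a source.  Inclusions are laterally centered
  on a voxel center; cylinders span the full lateral extent along their
  axis.
* Root finding for the non-affine inversion: bracket (1e-3, 50) mm,
  tolerance 1e-4 mm, monotonicity verified on a 64-point grid first.
* Roulette: threshold 1e-2 of launch weight, survival probability 0.1.
* Boundary nudge of 1e-7 mm when crossing voxel faces.

## Known limitations

* The transport kernel is single-threaded CPU; paper-scale budgets (1e8
  packets at 0.5 mm voxels) take hours, not minutes.
* The planar model's shallow branch (`d <= z0`) is exact for the fluence
  used here but the affine inversion ignores it, so depths below ~1 mm are
  systematically biased — consistent with the documented behavior of the
  approach.
* Index-matched inclusion/background interfaces only; no internal Fresnel
  steps.
* The geometry studies inherit the self-shielding of a 1 uM dye load;
  conclusions about inclusion size mix pure geometry with this optical
  contrast effect, as they do in a real measurement.  At desk-scale photon
  budgets this is visible for wide disks: the dye's strong 760 nm
  absorption shades the longer-wavelength excitation inside a large flat
  inclusion, biasing its recovered depth shallow by about a millimetre,
  while a half-millimetre disk's error is dominated by Monte Carlo noise
  of comparable size.  The expectation that flat inclusions are recovered
  *better* as they widen (they approach the one-dimensional geometry the
  planar model assumes) therefore only emerges at photon budgets orders of
  magnitude above the desk-scale defaults, and the corresponding trend
  test documents this as a known failure at the default scale.
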