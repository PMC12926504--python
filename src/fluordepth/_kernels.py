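"""Numba transport kernels for the voxelized fluorescence Monte Carlo.

Weighted (implicit-capture) photon-packet transport on a regular voxel
grid.  At each interaction a fraction ``mua/mut`` of the packet weight is
deposited in the current voxel and the remainder scatters through the
Henyey-Greenstein phase function.  Voxel boundaries are traversed by
consuming the sampled dimensionless optical path across cells, so step
lengths are exact in heterogeneous media.  The top face applies Fresnel
partial reflection for the refractive-index mismatch; the other five faces
absorb (escaping weight is tallied but not imaged).  Packets with weight
below the roulette threshold play Russian roulette.

Everything here is deterministic given the seed: kernels are single
threaded and draw from numba's per-kernel ``np.random`` state.
"""

import numpy as np
from numba import njit

# ledger indices
LEDGER_LAUNCHED = 0
LEDGER_ESCAPED_TOP = 1
LEDGER_ESCAPED_OTHER = 2
LEDGER_SPECULAR = 3
LEDGER_ROULETTE_KILLED = 4
LEDGER_ROULETTE_CREATED = 5
LEDGER_SIZE = 6

# source modes
SRC_PLANAR = 0
SRC_PENCIL = 1
SRC_POINT_ISO = 2
SRC_VOXELS = 3

_EPS = 1e-7  # mm, boundary nudge


@njit(cache=True)
def hg_cos_theta(g, u):
    """Sample cos(theta) from the Henyey-Greenstein distribution."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def hg_sample_mean(g, n, seed):
    """Mean of n HG cos(theta) draws (used by the sampler oracle test)."""
    np.random.seed(seed)
    total = 0.0
    for _ in range(n):
        total += hg_cos_theta(g, np.random.random())
    return total / n


@njit(cache=True)
def _fresnel_reflectance(n_rel, cos_i):
    """Unpolarized Fresnel reflectance, inside (n_rel) -> outside (1)."""
    if n_rel == 1.0:
        return 0.0
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def transport(
    labels,  # uint8 (nx, ny, nz)
    mua,  # float64 per label, mm^-1
    mus,  # float64 per label, mm^-1 (transport scattering coefficient)
    g,  # float64 per label
    n_rel,  # refractive index of medium relative to outside
    voxel,  # voxel edge, mm
    n_photons,
    seed,
    src_mode,
    src_x,
    src_y,
    src_z,
    src_cdf,  # float64, cumulative probability over source voxels
    src_voxels,  # int64 (m, 3) voxel indices of the distributed source
    src_weight_total,  # total launch weight for SRC_VOXELS (else per-photon 1)
    w_threshold,
    w_survive,
    absorb,  # float64 (nx, ny, nz), accumulated in place
    image,  # float64 (nx, ny), top-surface exit weight
):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    lx = nx * voxel
    ly = ny * voxel
    lz = nz * voxel
    ledger = np.zeros(LEDGER_SIZE)

    r_specular = 0.0
    if n_rel != 1.0:
        r_specular = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2

    for _ in range(n_photons):
        # --- launch -------------------------------------------------------
        if src_mode == SRC_PLANAR:
            x = np.random.random() * lx
            y = np.random.random() * ly
            z = _EPS
            ux = 0.0
            uy = 0.0
            uz = 1.0
            w = 1.0 - r_specular
            ledger[LEDGER_SPECULAR] += r_specular
            ledger[LEDGER_LAUNCHED] += 1.0
        elif src_mode == SRC_PENCIL:
            x = src_x
            y = src_y
            z = _EPS
            ux = 0.0
            uy = 0.0
            uz = 1.0
            w = 1.0 - r_specular
            ledger[LEDGER_SPECULAR] += r_specular
            ledger[LEDGER_LAUNCHED] += 1.0
        elif src_mode == SRC_POINT_ISO:
            x = src_x
            y = src_y
            z = src_z
            ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
            uz = ct
            w = 1.0
            ledger[LEDGER_LAUNCHED] += 1.0
        else:  # SRC_VOXELS: weighted isotropic launch from source voxels
            u = np.random.random()
            lo = 0
            hi = src_cdf.shape[0] - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if src_cdf[mid] < u:
                    lo = mid + 1
                else:
                    hi = mid
            ivx = src_voxels[lo, 0]
            ivy = src_voxels[lo, 1]
            ivz = src_voxels[lo, 2]
            x = (ivx + np.random.random()) * voxel
            y = (ivy + np.random.random()) * voxel
            z = (ivz + np.random.random()) * voxel
            ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
            uz = ct
            w = src_weight_total / n_photons
            ledger[LEDGER_LAUNCHED] += w

        w_thr = w_threshold * w  # roulette threshold relative to launch weight

        # --- propagate ----------------------------------------------------
        tau = -np.log(np.random.random())
        alive = True
        while alive:
            ix = int(x / voxel)
            iy = int(y / voxel)
            iz = int(z / voxel)
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                # numerical corner case: treat as lateral/bottom escape
                ledger[LEDGER_ESCAPED_OTHER] += w
                break
            lab = labels[ix, iy, iz]
            ma = mua[lab]
            ms = mus[lab]
            mt = ma + ms

            # distance to the voxel boundary along the current direction
            d_bnd = 1e30
            if ux > 0.0:
                t = ((ix + 1) * voxel - x) / ux
                if t < d_bnd:
                    d_bnd = t
            elif ux < 0.0:
                t = (ix * voxel - x) / ux
                if t < d_bnd:
                    d_bnd = t
            if uy > 0.0:
                t = ((iy + 1) * voxel - y) / uy
                if t < d_bnd:
                    d_bnd = t
            elif uy < 0.0:
                t = (iy * voxel - y) / uy
                if t < d_bnd:
                    d_bnd = t
            if uz > 0.0:
                t = ((iz + 1) * voxel - z) / uz
                if t < d_bnd:
                    d_bnd = t
            elif uz < 0.0:
                t = (iz * voxel - z) / uz
                if t < d_bnd:
                    d_bnd = t
            if d_bnd < 0.0:
                d_bnd = 0.0

            d_int = 1e30
            if mt > 0.0:
                d_int = tau / mt

            if d_int <= d_bnd:
                # interaction inside this voxel
                x += ux * d_int
                y += uy * d_int
                z += uz * d_int
                dep = w * (ma / mt)
                absorb[ix, iy, iz] += dep
                w -= dep
                if w <= 0.0:
                    break
                ct = hg_cos_theta(g[lab], np.random.random())
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux = nux / norm
                    uy = nuy / norm
                    uz = nuz / norm
                tau = -np.log(np.random.random())
                # Russian roulette
                if w < w_thr:
                    if np.random.random() < w_survive:
                        created = w * (1.0 / w_survive - 1.0)
                        ledger[LEDGER_ROULETTE_CREATED] += created
                        w /= w_survive
                    else:
                        ledger[LEDGER_ROULETTE_KILLED] += w
                        break
            else:
                # advance to the voxel boundary
                x += ux * d_bnd
                y += uy * d_bnd
                z += uz * d_bnd
                tau -= mt * d_bnd
                if tau < 0.0:
                    tau = 0.0
                if z <= 0.0 and uz < 0.0:
                    # top face: Fresnel partial transmission
                    cos_i = -uz
                    refl = _fresnel_reflectance(n_rel, cos_i)
                    t_w = w * (1.0 - refl)
                    if t_w > 0.0:
                        px = int(x / voxel)
                        py = int(y / voxel)
                        if px < 0:
                            px = 0
                        elif px >= nx:
                            px = nx - 1
                        if py < 0:
                            py = 0
                        elif py >= ny:
                            py = ny - 1
                        image[px, py] += t_w
                        ledger[LEDGER_ESCAPED_TOP] += t_w
                    w *= refl
                    if w <= 0.0:
                        break
                    uz = -uz
                    z = _EPS
                    if w < w_thr:
                        if np.random.random() < w_survive:
                            created = w * (1.0 / w_survive - 1.0)
                            ledger[LEDGER_ROULETTE_CREATED] += created
                            w /= w_survive
                        else:
                            ledger[LEDGER_ROULETTE_KILLED] += w
                            break
                elif (
                    x <= 0.0
                    or x >= lx
                    or y <= 0.0
                    or y >= ly
                    or z >= lz
                ):
                    # absorbing side/bottom faces
                    ledger[LEDGER_ESCAPED_OTHER] += w
                    break
                else:
                    # nudge across the internal boundary
                    x += ux * _EPS
                    y += uy * _EPS
                    z += uz * _EPS

    return ledger
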