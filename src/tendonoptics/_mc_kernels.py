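"""Numba-compiled Monte-Carlo photon transport kernels.

Weighted-packet (MCML-style) rule set: exponential steps -ln(xi)/mu_t,
per-collision absorption w*mua/mu_t, Henyey-Greenstein deflection with
uniform azimuth, Russian roulette below ``w_min`` with survival probability
``roulette_p``.  All kernels seed numba's RNG explicitly, so identical
(seed, n_photons, properties) give bit-identical tallies.

Two geometries:

* an infinite slab (integrating-sphere model) with Fresnel refraction at the
  faces and the specular component of the incident beam excluded from Rd;
* a finite rectangular voxel volume with index-matched transmissive
  ("escape") boundaries and a flat-top fiber source, scoring fluence with the
  collision estimator  phi = sum(w / mu_t) / (N * V_voxel)  [1/mm^2].
"""

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def _fresnel_r(n_i, n_t, mu_i):
    """Unpolarized Fresnel reflectance for |cos(incidence)| = mu_i."""
    if n_i == n_t:
        return 0.0
    sin_i2 = 1.0 - mu_i * mu_i
    ratio = n_i / n_t
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    mu_t = np.sqrt(1.0 - sin_t2)
    rs = (n_i * mu_i - n_t * mu_t) / (n_i * mu_i + n_t * mu_t)
    rp = (n_i * mu_t - n_t * mu_i) / (n_i * mu_t + n_t * mu_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _hg_cos(g):
    if g == 0.0:
        return 2.0 * np.random.random() - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct < -1.0:
        ct = -1.0
    elif ct > 1.0:
        ct = 1.0
    return ct


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, g):
    """New direction after an HG deflection with uniform azimuth."""
    ct = _hg_cos(g)
    st = np.sqrt(1.0 - ct * ct)
    phi = 2.0 * np.pi * np.random.random()
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = st * cp
        nuy = st * sp
        nuz = ct if uz >= 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nuz = -st * cp * den + uz * ct
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def slab_mc(mua, mus, g, thickness, n_tissue, n_above, n_below,
            n_photons, seed, w_min, roulette_p):
    """Pencil beam normally incident on an infinite slab.

    Returns (Rd, Tt, absorbed, specular), each as a fraction of the photons
    delivered.  The specular reflection of the incident beam at the top face
    is deducted at launch and excluded from Rd.
    """
    np.random.seed(seed)
    mut = mua + mus
    r = (n_above - n_tissue) / (n_above + n_tissue)
    rsp = r * r
    rd = 0.0
    tt = 0.0
    absorbed = 0.0
    for _ in range(n_photons):
        w = 1.0 - rsp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        alive = True
        while alive:
            if mut > 0.0:
                s = -np.log(np.random.random() + _TINY) / mut
            else:
                s = 1.0e30
            while s > 0.0 and alive:
                if uz > 0.0:
                    db = (thickness - z) / uz
                elif uz < 0.0:
                    db = -z / uz
                else:
                    db = 1.0e30
                if db <= s:
                    s -= db
                    if uz > 0.0:
                        z = thickness
                        n_out = n_below
                    else:
                        z = 0.0
                        n_out = n_above
                    refl = _fresnel_r(n_tissue, n_out, abs(uz))
                    if np.random.random() >= refl:
                        if uz > 0.0:
                            tt += w
                        else:
                            rd += w
                        alive = False
                    else:
                        uz = -uz
                else:
                    z += s * uz
                    s = 0.0
                    if mut > 0.0:
                        dw = w * mua / mut
                        absorbed += dw
                        w -= dw
                        ux, uy, uz = _spin(ux, uy, uz, g)
                    if w < w_min:
                        if np.random.random() < roulette_p:
                            w /= roulette_p
                        else:
                            alive = False
    inv = 1.0 / n_photons
    return rd * inv, tt * inv, absorbed * inv, rsp


@njit(cache=True)
def volume_mc(mua, mus, g, lx, ly, lz, dvox, src_radius, det_radius,
              n_photons, seed, w_min, roulette_p):
    """Fiber-illuminated homogeneous box with escaping boundaries.

    Source: flat-top disk of radius ``src_radius`` centered on the z=0 face,
    directed along +z.  Photons crossing any face leave the volume (index-
    matched escape) and are tallied; weight exiting the far face within
    ``det_radius`` of the axis counts as transmitted.

    Returns (phi_raw, transmitted, absorbed, escaped) where ``phi_raw`` must
    still be divided by N * dvox^3 to become fluence per delivered photon.
    """
    np.random.seed(seed)
    nx = int(round(lx / dvox))
    ny = int(round(ly / dvox))
    nz = int(round(lz / dvox))
    phi = np.zeros((nx, ny, nz))
    mut = mua + mus
    cx = 0.5 * lx
    cy = 0.5 * ly
    det2 = det_radius * det_radius
    transmitted = 0.0
    absorbed = 0.0
    escaped = 0.0
    for _ in range(n_photons):
        rr = src_radius * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        x = cx + rr * np.cos(ang)
        y = cy + rr * np.sin(ang)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        alive = True
        while alive:
            if mut > 0.0:
                s = -np.log(np.random.random() + _TINY) / mut
            else:
                s = 1.0e30
            # distance to the nearest face along the current direction
            t_exit = 1.0e30
            face = -1
            if ux > 0.0:
                t = (lx - x) / ux
                if t < t_exit:
                    t_exit = t
                    face = 0
            elif ux < 0.0:
                t = -x / ux
                if t < t_exit:
                    t_exit = t
                    face = 0
            if uy > 0.0:
                t = (ly - y) / uy
                if t < t_exit:
                    t_exit = t
                    face = 1
            elif uy < 0.0:
                t = -y / uy
                if t < t_exit:
                    t_exit = t
                    face = 1
            if uz > 0.0:
                t = (lz - z) / uz
                if t < t_exit:
                    t_exit = t
                    face = 2
            elif uz < 0.0:
                t = -z / uz
                if t < t_exit:
                    t_exit = t
                    face = 2
            if s >= t_exit:
                x += t_exit * ux
                y += t_exit * uy
                z += t_exit * uz
                if face == 2 and uz > 0.0:
                    dx = x - cx
                    dy = y - cy
                    if dx * dx + dy * dy <= det2:
                        transmitted += w
                    else:
                        escaped += w
                else:
                    escaped += w
                alive = False
            else:
                x += s * ux
                y += s * uy
                z += s * uz
                ix = int(x / dvox)
                iy = int(y / dvox)
                iz = int(z / dvox)
                if ix >= nx:
                    ix = nx - 1
                if iy >= ny:
                    iy = ny - 1
                if iz >= nz:
                    iz = nz - 1
                phi[ix, iy, iz] += w / mut
                dw = w * mua / mut
                absorbed += dw
                w -= dw
                ux, uy, uz = _spin(ux, uy, uz, g)
                if w < w_min:
                    if np.random.random() < roulette_p:
                        w /= roulette_p
                    else:
                        alive = False
    inv = 1.0 / n_photons
    return phi, transmitted * inv, absorbed * inv, escaped * inv
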