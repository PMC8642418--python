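"""Numba kernel for weight-based photon transport in a 1-D layered slab.

Follows the standard MCML realization: exponential free-path sampling,
Henyey-Greenstein deflection, unpolarized Fresnel boundaries with total
internal reflection, weight drop mu_a/mu_t per interaction, and Russian
roulette below a weight threshold.

Fluence is scored with a track-length estimator (weight x path length per
bin), which is unbiased, lower-variance than absorption scoring, and defined
in non-absorbing layers.  Two tallies are kept: depth-only (planar) and
depth x radius (cylindrical around the pencil-beam axis), the latter giving
the near-axis flux density of a narrow-beam illumination.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WEIGHT_THRESHOLD = 1.0e-4
ROULETTE_CHANCE = 0.1


@njit(cache=False)
def fresnel_unpolarized(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine cos_i in [0, 1]."""
    if n1 == n2:
        return 0.0
    if cos_i > 0.999999:
        r = (n1 - n2) / (n1 + n2)
        return r * r
    if cos_i < 1.0e-9:
        return 1.0  # grazing incidence
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def hg_cos_theta(g: float, u: float) -> float:
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if abs(g) < 1.0e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=False)
def _score_path(a_z, a_rz, x, y, z, ux, uy, uz, step, w, bin_w, n_bins, dr, nr):
    """Deposit weight x length along a straight sub-path into (z, r) bins.

    The path is split exactly at z-bin boundaries (unbiased depth binning);
    within each z sub-segment the radius is sampled at midpoints of lateral
    sub-divisions no wider than one radial bin."""
    uh = np.sqrt(ux * ux + uy * uy)
    t = 0.0
    while t < step - 1e-14:
        z_cur = z + t * uz
        b = int(z_cur / bin_w)
        if uz > 1.0e-12:
            t_next = t + ((b + 1) * bin_w - z_cur) / uz
        elif uz < -1.0e-12:
            if z_cur - b * bin_w < 1e-14 and b > 0:
                b -= 1
            t_next = t + (b * bin_w - z_cur) / uz
        else:
            t_next = step
        if t_next > step:
            t_next = step
        if t_next <= t:  # guard against float stalls at bin edges
            t_next = t + 1e-13
            if t_next > step:
                t_next = step
        if b < 0:
            b = 0
        elif b >= n_bins:
            b = n_bins - 1
        seg = t_next - t
        a_z[b] += w * seg
        nsub = int(seg * uh / dr) + 1
        ds = seg / nsub
        for j in range(nsub):
            tm = t + (j + 0.5) * ds
            xm = x + tm * ux
            ym = y + tm * uy
            rb = int(np.sqrt(xm * xm + ym * ym) / dr)
            if rb < nr:
                a_rz[b, rb] += w * ds
        t = t_next


@njit(cache=False)
def transport_kernel(
    n_photons: int,
    seed: int,
    zb: np.ndarray,        # layer boundaries, cm, length L+1, zb[0] = 0
    n_lay: np.ndarray,     # per-layer refractive index
    mu_a: np.ndarray,      # per-layer absorption, cm^-1
    mu_s: np.ndarray,      # per-layer scattering, cm^-1
    g_lay: np.ndarray,     # per-layer anisotropy
    n_top: float,
    n_bot: float,
    src_face: int,         # 0 = top, 1 = bottom (pencil beam entry face)
    src_iso: int,          # 0 = pencil beam, 1 = isotropic point at src_depth
    src_depth: float,      # cm (isotropic point only)
    bin_w: float,          # fluence z-bin width, cm
    n_bins: int,
    score: int,            # 0 = escape tallies only, 1 = also score fluence
    dr: float,             # radial bin width, cm
    nr: int,               # number of radial bins
):
    """Run the full hop/drop/spin walk.

    Returns (a_z, a_rz, escaped_top, escaped_bottom, absorbed), where a_z and
    a_rz are summed weight x path length (cm) per bin and the escape/absorbed
    tallies are summed photon weight; nothing is normalized by n_photons.
    Specular reflection at pencil-beam entry is deducted at launch and counted
    as escape through the entry face.
    """
    np.random.seed(seed)
    a_z = np.zeros(n_bins, dtype=np.float64)
    a_rz = np.zeros((n_bins, nr), dtype=np.float64)
    esc_top = 0.0
    esc_bot = 0.0
    absorbed = 0.0
    L = mu_a.shape[0]
    D = zb[L]

    for _ in range(n_photons):
        # ---- launch ----
        x = 0.0
        y = 0.0
        if src_iso == 0:
            if src_face == 0:
                z = 0.0
                layer = 0
                uz = 1.0
                rsp = fresnel_unpolarized(n_top, n_lay[0], 1.0)
                esc_top += rsp
            else:
                z = D
                layer = L - 1
                uz = -1.0
                rsp = fresnel_unpolarized(n_bot, n_lay[L - 1], 1.0)
                esc_bot += rsp
            w = 1.0 - rsp
            ux = 0.0
            uy = 0.0
        else:
            z = src_depth
            layer = L - 1
            for l in range(L):
                if z < zb[l + 1]:
                    layer = l
                    break
            uz = 2.0 * np.random.random() - 1.0
            st = np.sqrt(max(0.0, 1.0 - uz * uz))
            phi = 2.0 * np.pi * np.random.random()
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
            w = 1.0

        alive = True
        while alive:
            # ---- hop (with boundary handling) ----
            mt = mu_a[layer] + mu_s[layer]
            if mt > 0.0:
                s_left = -np.log(1.0 - np.random.random())  # dimensionless
            else:
                s_left = 0.0

            while True:
                mt = mu_a[layer] + mu_s[layer]
                if uz > 1.0e-12:
                    db = (zb[layer + 1] - z) / uz
                elif uz < -1.0e-12:
                    db = (zb[layer] - z) / uz  # positive
                else:
                    db = 1.0e30

                if mt <= 0.0:
                    if db >= 1.0e29:
                        alive = False  # horizontal in a void layer
                        break
                    hit = True
                    step = db
                else:
                    step = s_left / mt
                    if step < db:
                        hit = False
                    else:
                        hit = True
                        step = db
                        s_left -= db * mt

                if score == 1 and step > 0.0:
                    _score_path(
                        a_z, a_rz, x, y, z, ux, uy, uz, step, w,
                        bin_w, n_bins, dr, nr,
                    )
                x += step * ux
                y += step * uy
                z += step * uz

                if not hit:
                    break

                # boundary crossing
                if uz > 0.0:
                    z = zb[layer + 1]
                    n1 = n_lay[layer]
                    n2 = n_bot if layer == L - 1 else n_lay[layer + 1]
                    cos_i = uz
                    if np.random.random() > fresnel_unpolarized(n1, n2, cos_i):
                        if layer == L - 1:
                            esc_bot += w
                            alive = False
                            break
                        ratio = n1 / n2
                        sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                        uz = np.sqrt(max(0.0, 1.0 - sin_t2))
                        ux *= ratio
                        uy *= ratio
                        layer += 1
                    else:
                        uz = -uz
                else:
                    z = zb[layer]
                    n1 = n_lay[layer]
                    n2 = n_top if layer == 0 else n_lay[layer - 1]
                    cos_i = -uz
                    if np.random.random() > fresnel_unpolarized(n1, n2, cos_i):
                        if layer == 0:
                            esc_top += w
                            alive = False
                            break
                        ratio = n1 / n2
                        sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                        uz = -np.sqrt(max(0.0, 1.0 - sin_t2))
                        ux *= ratio
                        uy *= ratio
                        layer -= 1
                    else:
                        uz = -uz
                # keep propagating while optical path remains (or layer is void)
                if mu_a[layer] + mu_s[layer] <= 0.0 or s_left > 0.0:
                    continue
                break

            if not alive:
                break

            mt = mu_a[layer] + mu_s[layer]
            if mt <= 0.0:
                continue

            # ---- drop ----
            dw = w * mu_a[layer] / mt
            absorbed += dw
            w -= dw
            if w <= 0.0:
                alive = False
                break

            # ---- spin ----
            ct = hg_cos_theta(g_lay[layer], np.random.random())
            stq = np.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi)
            sp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = stq * cp
                uy = stq * sp
                uz = ct if uz >= 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                uxn = stq * (ux * uz * cp - uy * sp) / den + ux * ct
                uyn = stq * (uy * uz * cp + ux * sp) / den + uy * ct
                uzn = -den * stq * cp + uz * ct
                norm = np.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm

            # ---- roulette ----
            if w < WEIGHT_THRESHOLD:
                if np.random.random() <= ROULETTE_CHANCE:
                    w /= ROULETTE_CHANCE
                else:
                    alive = False

    return a_z, a_rz, esc_top, esc_bot, absorbed
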