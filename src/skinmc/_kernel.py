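"""Numba-compiled Monte Carlo photon-transport core.

RNG conventions (one seeded Mersenne stream per kernel call):
 * the free-path log draw uses R in (0, 1], obtained as 1 - random();
 * scattering-angle and boundary draws use random() in [0, 1).

Photons propagate in full 3-D; depositions are scored into the (z, y) grid
ignoring x (the beam is translation-invariant in x).  Free paths crossing
a layer interface are truncated at the interface, boundary physics
(Fresnel reflection / Snell refraction, with total internal reflection)
applied, and a fresh free path drawn in the new medium.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def hg_cos(g, r):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if g == 0.0:
        return 2.0 * r - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * r)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns (R, cos_t, n1/n2); R = 1 and cos_t = 0 beyond the critical
    angle (total internal reflection).
    """
    if cos_i > 1.0:
        cos_i = 1.0
    ratio = n1 / n2
    if n1 == n2:
        return 0.0, cos_i, ratio
    sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0, ratio
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n2 * cos_i - n1 * cos_t) / (n2 * cos_i + n1 * cos_t)
    return 0.5 * (rs * rs + rp * rp), cos_t, ratio


@njit(cache=True)
def rotate(ux, uy, uz, cos_t, phi):
    """Rotate a unit direction by deflection cosine cos_t and azimuth phi."""
    sin_t2 = 1.0 - cos_t * cos_t
    sin_t = np.sqrt(sin_t2) if sin_t2 > 0.0 else 0.0
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) > 1.0 - 1e-6:
        nx = sin_t * cphi
        ny = sin_t * sphi
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cphi - uy * sphi) / tmp + ux * cos_t
        ny = sin_t * (uy * uz * cphi + ux * sphi) / tmp + uy * cos_t
        nz = -sin_t * cphi * tmp + uz * cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def run_kernel(seed, n_photons, cell_um, n_y, n_z, y_min_um,
               layer_bot_um, layer_n, layer_g, mua, mus, n_ambient,
               spec_cdf, beam_half_um, w_threshold, use_roulette,
               roulette_p, max_events):
    """Trace n_photons through the layered medium and score depositions.

    Returns (absorbed[n_z, n_y], escaped_top, escaped_side,
    escaped_bottom, residual, n_capped).  ``max_events`` caps interactions
    plus boundary events per photon (guards pathological trapping); capped
    photons contribute their weight to the residual tally.
    """
    absorbed = np.zeros((n_z, n_y))
    esc_top = 0.0
    esc_side = 0.0
    esc_bottom = 0.0
    residual = 0.0
    n_capped = 0
    z_max = n_z * cell_um
    y_max = y_min_um + n_y * cell_um
    n_samples = spec_cdf.shape[0]
    np.random.seed(seed)
    # Specular reflection at normal incidence on the top surface.
    rsp, _, _ = fresnel(n_ambient, layer_n[0], 1.0)
    for _ in range(n_photons):
        s = np.searchsorted(spec_cdf, np.random.random())
        if s >= n_samples:
            s = n_samples - 1
        y = -beam_half_um + 2.0 * beam_half_um * np.random.random()
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        esc_top += rsp
        w = 1.0 - rsp
        n_ev = 0
        while True:
            if n_ev >= max_events:
                residual += w
                n_capped += 1
                break
            n_ev += 1
            mua_l = mua[layer, s]
            mut = mua_l + mus[layer, s]
            step = -np.log(1.0 - np.random.random()) / mut * 1000.0  # um
            # distance along the track to the nearest z-boundary
            if uz > 0.0:
                zb = layer_bot_um[layer]
                if zb > z_max:
                    zb = z_max
                d = (zb - z) / uz
            elif uz < 0.0:
                zb = layer_bot_um[layer - 1] if layer > 0 else 0.0
                d = (zb - z) / uz
            else:
                zb = z
                d = 1e300
            if step < d:
                y += uy * step
                z += uz * step
                if y < y_min_um or y >= y_max:
                    esc_side += w
                    break
                iz = int(z / cell_um)
                if iz >= n_z:
                    iz = n_z - 1
                jy = int((y - y_min_um) / cell_um)
                dw = w * mua_l / mut
                absorbed[iz, jy] += dw
                w -= dw
                if w < w_threshold:
                    if use_roulette:
                        if np.random.random() < roulette_p:
                            residual -= w * (1.0 / roulette_p - 1.0)
                            w = w / roulette_p
                        else:
                            residual += w
                            break
                    else:
                        residual += w
                        break
                ct = hg_cos(layer_g[layer], np.random.random())
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = rotate(ux, uy, uz, ct, phi)
            else:
                # move to the boundary and apply boundary physics there
                y += uy * d
                z = zb
                if y < y_min_um or y >= y_max:
                    esc_side += w
                    break
                if uz < 0.0 and layer == 0:
                    refl, _, _ = fresnel(layer_n[0], n_ambient, -uz)
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        esc_top += w
                        break
                elif uz > 0.0 and zb >= z_max:
                    esc_bottom += w
                    break
                else:
                    other = layer + 1 if uz > 0.0 else layer - 1
                    refl, cos_t, ratio = fresnel(layer_n[layer], layer_n[other], abs(uz))
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        ux *= ratio
                        uy *= ratio
                        uz = cos_t if uz > 0.0 else -cos_t
                        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        layer = other
    return absorbed, esc_top, esc_side, esc_bottom, residual, n_capped
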