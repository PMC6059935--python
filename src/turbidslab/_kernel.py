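"""Numba kernels for the photon-packet random walk.

Everything here operates on plain arrays/scalars so it can be jit-compiled;
the public surface lives in :mod:`turbidslab.mc`.

The RNG is a splitmix64 stream seeded per packet from (seed, packet index),
so results are independent of execution order and identical streams can be
replayed across parameter values (common random numbers).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .slab import C_UM_PS

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)

# exit / termination status codes
BACK = 0
FRONT = 1
KILLED = 2


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _u01(state):
    """Advance the splitmix64 state (1-element uint64 array); uniform in (0,1)."""
    state[0] = state[0] + _GOLDEN
    z = _mix64(state[0])
    return (np.float64(z >> _U64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def packet_stream_state(seed, packet_index):
    """Initial RNG state for one packet, decorrelated across packets and seeds."""
    s = _mix64(_U64(seed) * _GOLDEN + _GOLDEN)
    return _mix64(s ^ (_U64(packet_index) * _MIX1 + _MIX2))


@njit(cache=True, inline="always")
def sample_free_path(l_s, u):
    """Exponential free path -l_s*ln(u) for u in (0,1)."""
    return -l_s * np.log(u)


@njit(cache=True, inline="always")
def hg_cos_theta(g, u):
    """Henyey-Greenstein deflection cosine via the closed-form inverse CDF."""
    if g < 1e-6:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - s * s) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def rotate_direction(ux, uy, uz, cost, phi):
    """Rotate a unit vector by polar angle acos(cost) and azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz > 0.0 else -cost
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
        nz = -sint * cosp * tmp + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def fresnel_reflectance(cos_i, n1, n2):
    """Unpolarized Fresnel power reflectance at incidence cosine cos_i (>0)."""
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def refract_z(ux, uy, uz, n1, n2):
    """Snell-refract across a z-normal interface (guaranteed non-TIR)."""
    scale = n1 / n2
    cos_i = abs(uz)
    sin_t2 = scale * scale * (1.0 - cos_i * cos_i)
    cos_t = np.sqrt(max(0.0, 1.0 - sin_t2))
    nx = ux * scale
    ny = uy * scale
    nz = cos_t if uz > 0.0 else -cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def trace_one(state, z_edges, ls, gs, mua, nn, n_front, n_back,
              w0, w_min, p_survive, t_max):
    """Random-walk one packet through the layer stack.

    Returns (status, x, y, t, w, ux, uy, uz, absorbed, tail):
    ``status`` is BACK/FRONT/KILLED; ``absorbed`` the weight lost to
    continuous attenuation; ``tail`` the ledger of weight removed (or, for
    roulette boosts, injected: negative) by termination, so that for every
    packet  exit_w + absorbed + tail = w0  exactly.
    """
    nl = ls.shape[0]
    x = 0.0
    y = 0.0
    z = z_edges[0]
    ux = 0.0
    uy = 0.0
    uz = 1.0
    w = w0
    t = 0.0
    layer = 0
    absorbed = 0.0
    tail = 0.0

    tau = -np.log(_u01(state))
    while True:
        # distance to the layer boundary along the current direction
        if uz > 1e-12:
            db = (z_edges[layer + 1] - z) / uz
            toward = 1
        elif uz < -1e-12:
            db = (z - z_edges[layer]) / (-uz)
            toward = -1
        else:
            db = 1e300
            toward = 0
        s_phys = tau * ls[layer]
        if s_phys < db:
            # scattering event inside the layer
            x += ux * s_phys
            y += uy * s_phys
            z += uz * s_phys
            if mua[layer] > 0.0:
                w_new = w * np.exp(-mua[layer] * s_phys)
                absorbed += w - w_new
                w = w_new
            t += s_phys * nn[layer] / C_UM_PS
            if t > t_max:
                tail += w
                return KILLED, x, y, t, w, ux, uy, uz, absorbed, tail
            cost = hg_cos_theta(gs[layer], _u01(state))
            phi = 2.0 * np.pi * _u01(state)
            ux, uy, uz = rotate_direction(ux, uy, uz, cost, phi)
            if w < w_min:
                # Russian roulette; the boost is ledgered so bookkeeping
                # stays exact per packet
                if _u01(state) < p_survive:
                    tail += w - w / p_survive
                    w = w / p_survive
                else:
                    tail += w
                    return KILLED, x, y, t, w, ux, uy, uz, absorbed, tail
            tau = -np.log(_u01(state))
        else:
            # reach the boundary
            x += ux * db
            y += uy * db
            z = z_edges[layer + 1] if toward == 1 else z_edges[layer]
            if mua[layer] > 0.0:
                w_new = w * np.exp(-mua[layer] * db)
                absorbed += w - w_new
                w = w_new
            t += db * nn[layer] / C_UM_PS
            tau -= db / ls[layer]
            if tau < 0.0:
                tau = 0.0
            if t > t_max:
                tail += w
                return KILLED, x, y, t, w, ux, uy, uz, absorbed, tail
            n1 = nn[layer]
            if toward == 1:
                n2 = nn[layer + 1] if layer + 1 < nl else n_back
            else:
                n2 = nn[layer - 1] if layer > 0 else n_front
            if n1 == n2:
                crossed = True
            else:
                R = fresnel_reflectance(abs(uz), n1, n2)
                if _u01(state) < R:
                    uz = -uz
                    crossed = False
                else:
                    ux, uy, uz = refract_z(ux, uy, uz, n1, n2)
                    crossed = True
            if crossed:
                if toward == 1:
                    if layer + 1 >= nl:
                        return BACK, x, y, t, w, ux, uy, uz, absorbed, tail
                    layer += 1
                else:
                    if layer == 0:
                        return FRONT, x, y, t, w, ux, uy, uz, absorbed, tail
                    layer -= 1


@njit(cache=True)
def run_kernel(n_packets, seed,
               z_edges, ls, gs, mua, nn, n_front, n_back,
               t0, dt, nt,
               x0, dx, nx, ft0, fdt, fnt,
               w0, r_spec, w_min, p_survive, t_max,
               T_hist, R_hist, xyt, mom, scalars):
    """Trace ``n_packets`` packets and accumulate histograms in place.

    ``mom`` has shape (nt, 5): per time bin the back-exit sums of
    w, w^2, w*x, w*y, w*(x^2+y^2).  ``scalars`` is (absorbed, tail).
    ``r_spec`` is the deterministic specular entry weight added to the first
    reflection bin per packet (0 when the entry split is excluded).
    """
    state = np.empty(1, dtype=np.uint64)
    for i in range(n_packets):
        state[0] = packet_stream_state(seed, i)
        if r_spec > 0.0:
            R_hist[0] += r_spec
        status, x, y, t, w, ux, uy, uz, absorbed, tail = trace_one(
            state, z_edges, ls, gs, mua, nn, n_front, n_back,
            w0, w_min, p_survive, t_max)
        scalars[0] += absorbed
        scalars[1] += tail
        if status == KILLED:
            continue
        it = int((t - t0) / dt)
        if it < 0 or it >= nt:
            scalars[1] += w
            continue
        if status == FRONT:
            R_hist[it] += w
        else:
            T_hist[it] += w
            mom[it, 0] += w
            mom[it, 1] += w * w
            mom[it, 2] += w * x
            mom[it, 3] += w * y
            mom[it, 4] += w * (x * x + y * y)
            if fnt > 0:
                ift = int((t - ft0) / fdt)
                if 0 <= ift < fnt:
                    ix = int((x - x0) / dx)
                    iy = int((y - x0) / dx)
                    if 0 <= ix < nx and 0 <= iy < nx:
                        xyt[ift, iy, ix] += w
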