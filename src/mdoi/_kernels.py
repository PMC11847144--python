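"""Numba kernels for voxelized photon transport.

Weighted-photon Monte Carlo in a voxel grid: interaction distances are
sampled as an optical depth and marched through voxel faces with an
incremental DDA (the voxel index is updated face-by-face, never recomputed
from the position), consuming depth at the local total interaction
coefficient mut = mua + mus.  At each interaction site the photon deposits
the absorbed share w * mua/mut and scatters with the remainder
(hop-drop-spin); every weight change is tallied, so per-run weight
accounting is exact.  The z=0 plane is the air-tissue interface with
stochastic Fresnel reflection for the internal index mismatch; lateral and
bottom faces are escaping boundaries.

Counter-based RNG: each photon derives an independent xorshift64* stream from
(seed, photon index) via splitmix64, so results are independent of execution
order and reproducible for a given (seed, n_photons).
"""

import numpy as np
from numba import njit

# roulette parameters: standard weight threshold / survival probability
W_MIN = 1.0e-4
P_SURVIVE = 0.1
_MAX_EVENTS = 10_000_000
_BIG = 1.0e30


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _photon_state(seed, idx):
    # two rounds of splitmix64 over a (seed, idx) counter; never zero
    s = _splitmix64(np.uint64(seed) ^ (np.uint64(idx) * np.uint64(0xA3EC647659359ACD)))
    s = _splitmix64(s + np.uint64(idx))
    if s == np.uint64(0):
        s = np.uint64(0x1234567887654321)
    return s


@njit(cache=True, inline="always")
def _rand(state):
    # xorshift64* ; returns (new_state, uniform in (0,1))
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state = x
    r = (x * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    return state, (np.float64(r) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _fresnel_up(n_rel, uz_abs):
    """Unpolarized Fresnel reflectance for an internal photon hitting z=0.

    n_rel = n_tissue / n_air (> 1); uz_abs = |cos(angle to normal)|.
    """
    if n_rel == 1.0:
        return 0.0
    cos_i = uz_abs
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    # light goes tissue (n1=n_rel) -> air (n2=1)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always", fastmath=True)
def _spin(ux, uy, uz, g, state):
    """Henyey-Greenstein scatter of the direction vector."""
    state, r1 = _rand(state)
    if g == 0.0:
        cos_t = 2.0 * r1 - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * r1)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # uniform azimuth via Marsaglia rejection (avoids sin/cos)
    while True:
        state, ra = _rand(state)
        state, rb = _rand(state)
        va = 2.0 * ra - 1.0
        vb = 2.0 * rb - 1.0
        r2s = va * va + vb * vb
        if 0.0 < r2s <= 1.0:
            break
    cos_p = (va * va - vb * vb) / r2s
    sin_p = 2.0 * va * vb / r2s
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nuz = -sin_t * cos_p * den + uz * cos_t
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm, state


@njit(cache=True, fastmath=True)
def transport_kernel(
    mua, mus, g_arr, n_rel,
    dx, dy, dz,
    src_x, src_y, waist,
    n_photons, seed,
    refl_map, absorb_map, score_absorb,
    score_banana,
    rho_bins, rho_margin, maps, lx0, ly0, ldx, ldy, ldz,
    refl_ratio, bin_counts, seg_buf,
):
    """Trace ``n_photons`` from a collimated Gaussian beam entering at z=0.

    Accumulates the escaped weight per surface voxel into ``refl_map`` and
    the deposited weight per voxel into ``absorb_map``.  Returns totals
    (reflected, transmitted, side_loss, absorbed, n_flagged) where
    ``absorbed`` includes the net Russian-roulette bookkeeping so that
    reflected + transmitted + side_loss + absorbed == n_photons up to
    floating-point rounding.

    With ``score_banana`` true the kernel additionally records each photon's
    path segments (midpoints, visitation weight = photon weight * segment
    length) and, when the photon escapes through the top surface, rotates the
    trajectory so its exit azimuth lands on +x and deposits it into the local
    visitation grid ``maps[b]`` of the nearest exit-distance bin
    ``rho_bins[b]``; ``refl_ratio[b]`` accumulates escaped weight and
    ``bin_counts[b]`` photon counts.  ``n_flagged`` then also counts photons
    whose trajectory overflowed ``seg_buf`` (still scored for reflectance).
    """
    nx, ny, nz = mua.shape
    n_bins = rho_bins.shape[0]
    lnx, lny, lnz = maps.shape[1], maps.shape[2], maps.shape[3]
    seg_cap = seg_buf.shape[1]
    tot_refl = 0.0
    tot_trans = 0.0
    tot_side = 0.0
    tot_abs = 0.0
    n_flagged = 0
    eps = 1.0e-9

    for ip in range(n_photons):
        state = _photon_state(seed, ip)
        state, r1 = _rand(state)
        state, r2 = _rand(state)
        # Gaussian beam profile exp(-2 r^2 / w^2)
        rr = waist * np.sqrt(-np.log(r1) / 2.0)
        ang = 2.0 * np.pi * r2
        x = src_x + rr * np.cos(ang)
        y = src_y + rr * np.sin(ang)
        z = eps
        ux = 0.0
        uy = 0.0
        uz = 1.0
        ix = min(max(int(x / dx), 0), nx - 1)
        iy = min(max(int(y / dy), 0), ny - 1)
        iz = 0
        w = 1.0
        ph_abs = 0.0  # per-photon tally keeps the global sum well-conditioned
        alive = True
        escaped_top = False
        overflow = False
        n_seg = 0
        n_events = 0

        while alive:
            n_events += 1
            if n_events > _MAX_EVENTS:
                ph_abs += w
                n_flagged += 1
                break
            state, xi = _rand(state)
            tau = -np.log(xi)  # scattering optical depth to next event
            inv_ux = 1.0 / ux if ux != 0.0 else _BIG
            inv_uy = 1.0 / uy if uy != 0.0 else _BIG
            inv_uz = 1.0 / uz if uz != 0.0 else _BIG
            while alive:
                mua_v = mua[ix, iy, iz]
                mus_v = mus[ix, iy, iz]
                # distance to the nearest voxel face along the direction
                face = -1
                d_b = _BIG
                if ux > 0.0:
                    t = ((ix + 1) * dx - x) * inv_ux
                    if t < d_b:
                        d_b = t
                        face = 0
                elif ux < 0.0:
                    t = (ix * dx - x) * inv_ux
                    if t < d_b:
                        d_b = t
                        face = 1
                if uy > 0.0:
                    t = ((iy + 1) * dy - y) * inv_uy
                    if t < d_b:
                        d_b = t
                        face = 2
                elif uy < 0.0:
                    t = (iy * dy - y) * inv_uy
                    if t < d_b:
                        d_b = t
                        face = 3
                if uz > 0.0:
                    t = ((iz + 1) * dz - z) * inv_uz
                    if t < d_b:
                        d_b = t
                        face = 4
                elif uz < 0.0:
                    t = (iz * dz - z) * inv_uz
                    if t < d_b:
                        d_b = t
                        face = 5
                if d_b < 0.0:
                    d_b = 0.0
                mut_v = mua_v + mus_v
                d_tau = tau / mut_v
                hit = d_tau > d_b
                d = d_b if hit else d_tau
                if score_banana and d > 0.0 and not overflow:
                    if n_seg >= seg_cap:
                        overflow = True
                    else:
                        seg_buf[0, n_seg] = x + 0.5 * d * ux
                        seg_buf[1, n_seg] = y + 0.5 * d * uy
                        seg_buf[2, n_seg] = z + 0.5 * d * uz
                        seg_buf[3, n_seg] = w * d
                        n_seg += 1
                x += d * ux
                y += d * uy
                z += d * uz
                if not hit:
                    # interaction site: deposit the absorbed share mua/mut
                    dep = w * (mua_v / mut_v)
                    ph_abs += dep
                    if score_absorb:
                        absorb_map[ix, iy, iz] += dep
                    w -= dep
                    break  # then scatter at the current position
                tau -= d_b * mut_v
                if face == 0:
                    ix += 1
                    if ix >= nx:
                        tot_side += w
                        alive = False
                elif face == 1:
                    ix -= 1
                    if ix < 0:
                        tot_side += w
                        alive = False
                elif face == 2:
                    iy += 1
                    if iy >= ny:
                        tot_side += w
                        alive = False
                elif face == 3:
                    iy -= 1
                    if iy < 0:
                        tot_side += w
                        alive = False
                elif face == 4:
                    iz += 1
                    if iz >= nz:
                        tot_trans += w
                        alive = False
                else:
                    iz -= 1
                    if iz < 0:
                        R = _fresnel_up(n_rel, -uz)
                        state, xi2 = _rand(state)
                        if xi2 < R:
                            uz = -uz
                            inv_uz = -inv_uz
                            iz = 0
                            z = eps
                        else:
                            ex = min(max(ix, 0), nx - 1)
                            ey = min(max(iy, 0), ny - 1)
                            refl_map[ex, ey] += w
                            tot_refl += w
                            escaped_top = True
                            alive = False
                if tau <= 0.0:
                    # rounding guard: scatter at the face just crossed
                    break
            if not alive:
                break
            g_v = g_arr[ix, iy, iz]
            ux, uy, uz, state = _spin(ux, uy, uz, g_v, state)
            if w < W_MIN:
                state, xi3 = _rand(state)
                if xi3 < P_SURVIVE:
                    # exact bookkeeping: the amplified weight is borrowed
                    # from the absorbed tally (zero-mean in expectation)
                    ph_abs -= w * (1.0 / P_SURVIVE - 1.0)
                    w /= P_SURVIVE
                else:
                    ph_abs += w
                    alive = False

        tot_abs += ph_abs
        if not score_banana or not escaped_top:
            continue
        # --- banana scoring for this escaped photon ---
        exx = x - src_x
        exy = y - src_y
        rho = np.sqrt(exx * exx + exy * exy)
        ib = 0
        best = _BIG
        for k in range(n_bins):
            dd = abs(rho_bins[k] - rho)
            if dd < best:
                best = dd
                ib = k
        if best > rho_margin:
            continue  # exit distance outside the binned range
        refl_ratio[ib] += w
        bin_counts[ib] += 1
        if overflow:
            n_flagged += 1
            continue
        if rho > 0.0:
            c = exx / rho
            s = exy / rho
        else:
            c = 1.0
            s = 0.0
        for k in range(n_seg):
            px = seg_buf[0, k] - src_x
            py = seg_buf[1, k] - src_y
            pz = seg_buf[2, k]
            rx = c * px + s * py
            ry = -s * px + c * py
            jx = int((rx - lx0) / ldx)
            jy = int((ry - ly0) / ldy)
            jz = int(pz / ldz)
            if 0 <= jx < lnx and 0 <= jy < lny and 0 <= jz < lnz:
                maps[ib, jx, jy, jz] += seg_buf[3, k]

    return tot_refl, tot_trans, tot_side, tot_abs, n_flagged
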