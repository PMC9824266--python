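"""Numba kernels for the voxel Monte Carlo transport loop.

Everything here operates on plain arrays so the hot loop compiles to machine
code.  The per-photon random stream is a SplitMix64 generator seeded from
(run seed, photon index), which makes results independent of execution order.

Conventions: lengths mm, time ns, c = 299.792458 mm/ns.  Material property
rows are (mu_a, mu_s, g, n).  The composite (skin) label resolves its
sublayer row at every lookup from the distance between the photon position
and the nearest surface reference point, searched over a per-voxel candidate
list stored in CSR form.
"""

import numpy as np
from numba import njit

C_MM_NS = 299.792458
_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)

# reflectance model selectors
MODEL_AS_PRINTED = 0
MODEL_SCHLICK_DIRECT = 1
MODEL_FRESNEL_EXACT = 2

# step-carry rule selectors
STEP_RESAMPLE = 0
STEP_CARRY = 1

# totals vector slots
TOT_LAUNCHED = 0
TOT_EXITED = 1
TOT_ABSORBED = 2
TOT_ROULETTE = 3
TOT_TIMEOUT = 4
TOT_CAP = 5
N_TOTALS = 6


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def stream_init(seed, photon_index):
    return _mix64(_U64(seed) * _GOLDEN + _U64(photon_index) * _U64(0xD1B54A32D192ED03))


@njit(cache=True, inline="always")
def _next_u64(state):
    state = state + _GOLDEN
    return state, _mix64(state)


@njit(cache=True, inline="always")
def rand_open(state):
    """Uniform draw in (0, 1]; safe for -log."""
    state, z = _next_u64(state)
    return state, (np.float64(z >> _U64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def rand_halfopen(state):
    """Uniform draw in [0, 1)."""
    state, z = _next_u64(state)
    return state, np.float64(z >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def hg_cos(g, xi):
    """Henyey-Greenstein deflection cosine via the inverse CDF (squared form)."""
    if g == 0.0:
        return 1.0 - 2.0 * xi
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def rotate_direction(ux, uy, uz, cost, phi):
    """Rotate a unit vector by deflection cosine ``cost`` and azimuth ``phi``."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 1.0 - 1e-6:
        # polar special case: the general rotation is singular
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -den * sint * cosp + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def reflectance_coeff(cosi, n1, n2, model):
    """Power reflectance for incidence cosine ``cosi`` (>=0); includes TIR."""
    if cosi < 0.0:
        cosi = -cosi
    if cosi > 1.0:
        cosi = 1.0
    sini2 = 1.0 - cosi * cosi
    eta = n1 / n2
    sint2 = eta * eta * sini2
    if sint2 >= 1.0:
        return 1.0  # total internal reflection
    if model == MODEL_FRESNEL_EXACT:
        cost = np.sqrt(1.0 - sint2)
        rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
        rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
        return 0.5 * (rs * rs + rp * rp)
    r0 = ((n1 - n2) / (n1 + n2)) ** 2
    r = r0 + (1.0 - r0) * (1.0 - cosi) ** 5
    if model == MODEL_AS_PRINTED:
        return r * r
    return r


@njit(cache=True, inline="always")
def _refract_axis(ux, uy, uz, axis, eta, cost):
    """Vector Snell for an axis-aligned face: tangential components scale by
    eta, the normal component becomes cos(theta_t) with its sign preserved."""
    if axis == 0:
        return (1.0 if ux > 0.0 else -1.0) * cost, eta * uy, eta * uz
    if axis == 1:
        return eta * ux, (1.0 if uy > 0.0 else -1.0) * cost, eta * uz
    return eta * ux, eta * uy, (1.0 if uz > 0.0 else -1.0) * cost


@njit(cache=True, inline="always")
def _row_at(lab, x, y, z, ix, iy, iz, label_row, composite_label, sub_row0,
            ny, nz, refpts, cand_indptr, cand_idx, edges):
    """Material property row for label ``lab`` at a continuous position."""
    if lab != composite_label:
        return label_row[lab]
    v = (ix * ny + iy) * nz + iz
    a = cand_indptr[v]
    b = cand_indptr[v + 1]
    n_edges = edges.shape[0]
    if b == a:
        return sub_row0 + n_edges - 1
    best = 1e300
    for k in range(a, b):
        p = cand_idx[k]
        dx = x - refpts[p, 0]
        dy = y - refpts[p, 1]
        dz = z - refpts[p, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < best:
            best = d2
    depth = np.sqrt(best)
    s = 0
    while s < n_edges - 1 and depth > edges[s]:
        s += 1
    return sub_row0 + s


@njit(cache=True)
def traverse(labels, ix, iy, iz, x, y, z, ux, uy, uz, pitch, ox, oy, oz, smax):
    """Walk the voxel grid from (x,y,z) along u for at most ``smax`` mm.

    Returns (flag, d, axis, pix, piy, piz, nix, niy, niz):
      flag 0 — full distance consumed inside the starting label; n* is the
               voxel containing the end point,
      flag 1 — label change after distance d crossing a face on ``axis``
               (prev voxel p*, next voxel n*),
      flag 2 — left the grid bounds after distance d (p* is the last voxel).
    """
    nx, ny, nz = labels.shape
    cur = labels[ix, iy, iz]

    if ux > 0.0:
        step_x = 1
        tmax_x = ((ix + 1) * pitch + ox - x) / ux
        tdel_x = pitch / ux
    elif ux < 0.0:
        step_x = -1
        tmax_x = (ix * pitch + ox - x) / ux
        tdel_x = -pitch / ux
    else:
        step_x = 0
        tmax_x = 1e300
        tdel_x = 1e300
    if uy > 0.0:
        step_y = 1
        tmax_y = ((iy + 1) * pitch + oy - y) / uy
        tdel_y = pitch / uy
    elif uy < 0.0:
        step_y = -1
        tmax_y = (iy * pitch + oy - y) / uy
        tdel_y = -pitch / uy
    else:
        step_y = 0
        tmax_y = 1e300
        tdel_y = 1e300
    if uz > 0.0:
        step_z = 1
        tmax_z = ((iz + 1) * pitch + oz - z) / uz
        tdel_z = pitch / uz
    elif uz < 0.0:
        step_z = -1
        tmax_z = (iz * pitch + oz - z) / uz
        tdel_z = -pitch / uz
    else:
        step_z = 0
        tmax_z = 1e300
        tdel_z = 1e300

    while True:
        if tmax_x <= tmax_y and tmax_x <= tmax_z:
            axis = 0
            tnext = tmax_x
        elif tmax_y <= tmax_z:
            axis = 1
            tnext = tmax_y
        else:
            axis = 2
            tnext = tmax_z
        if tnext >= smax:
            return 0, smax, -1, ix, iy, iz, ix, iy, iz
        pix, piy, piz = ix, iy, iz
        if axis == 0:
            ix += step_x
            tmax_x += tdel_x
        elif axis == 1:
            iy += step_y
            tmax_y += tdel_y
        else:
            iz += step_z
            tmax_z += tdel_z
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            return 2, tnext, axis, pix, piy, piz, ix, iy, iz
        if labels[ix, iy, iz] != cur:
            return 1, tnext, axis, pix, piy, piz, ix, iy, iz


@njit(cache=True)
def run_kernel(
    labels,
    label_row,
    composite_label,
    sub_row0,
    props,
    edges,
    refpts,
    cand_indptr,
    cand_idx,
    origin,
    pitch,
    src_pos,
    src_dir,
    n_photons,
    seed,
    cutoff,
    rc,
    max_time,
    bin_width,
    model,
    step_rule,
    max_interactions,
    exit_w,
    exit_sq,
    exit_wt,
    absorbed,
    totals,
):
    """Propagate ``n_photons`` packets and accumulate detection grids in place.

    ``exit_wt`` has shape (nx, ny, nz, n_bins); exit weight is recorded at the
    tissue-side boundary voxel the photon leaves through, binned by elapsed
    time.  Energy bookkeeping is exact: every unit of launched weight ends in
    exactly one of the exited / absorbed / roulette / timeout / cap tallies.
    """
    nx, ny, nz = labels.shape
    n_bins = exit_wt.shape[3]
    eps = 1e-9 * pitch
    ambient = 0

    for i in range(n_photons):
        state = stream_init(seed, i)
        x = src_pos[0]
        y = src_pos[1]
        z = src_pos[2]
        ux = src_dir[0]
        uy = src_dir[1]
        uz = src_dir[2]
        W = 1.0
        t = 0.0
        totals[TOT_LAUNCHED] += 1.0

        ix = int(np.floor((x - origin[0]) / pitch))
        iy = int(np.floor((y - origin[1]) / pitch))
        iz = int(np.floor((z - origin[2]) / pitch))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            totals[TOT_EXITED] += W  # launched outside the grid
            continue
        cur_lab = labels[ix, iy, iz]
        n_int = 0
        carry_s = -1.0  # dimensionless step remainder (carry rule)

        while True:
            if cur_lab == ambient:
                # straight-line traversal: no sampling in vacuum-like ambient
                flag, d, axis, pix, piy, piz, nix, niy, niz = traverse(
                    labels, ix, iy, iz, x, y, z, ux, uy, uz,
                    pitch, origin[0], origin[1], origin[2], 1e300,
                )
                t += d / C_MM_NS  # n = 1 in ambient
                x += ux * d
                y += uy * d
                z += uz * d
                if flag == 2:
                    totals[TOT_EXITED] += W
                    break
                # hit a tissue face: reflect or refract at the entry interface
                row2 = _row_at(labels[nix, niy, niz], x, y, z, nix, niy, niz,
                               label_row, composite_label, sub_row0,
                               ny, nz, refpts, cand_indptr, cand_idx, edges)
                n2 = props[row2, 3]
                if axis == 0:
                    cosi = abs(ux)
                elif axis == 1:
                    cosi = abs(uy)
                else:
                    cosi = abs(uz)
                R = reflectance_coeff(cosi, 1.0, n2, model)
                state, xi = rand_halfopen(state)
                if xi < R:
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                else:
                    eta = 1.0 / n2
                    cost = np.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - cosi * cosi)))
                    ux, uy, uz = _refract_axis(ux, uy, uz, axis, eta, cost)
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                x += ux * eps
                y += uy * eps
                z += uz * eps
                ix = int(np.floor((x - origin[0]) / pitch))
                iy = int(np.floor((y - origin[1]) / pitch))
                iz = int(np.floor((z - origin[2]) / pitch))
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    totals[TOT_EXITED] += W
                    break
                cur_lab = labels[ix, iy, iz]
                if t > max_time:
                    totals[TOT_TIMEOUT] += W
                    break
                n_int += 1
                if n_int > max_interactions:
                    totals[TOT_CAP] += W
                    break
                continue

            # --- inside tissue -------------------------------------------
            row = _row_at(cur_lab, x, y, z, ix, iy, iz, label_row,
                          composite_label, sub_row0, ny, nz,
                          refpts, cand_indptr, cand_idx, edges)
            mua = props[row, 0]
            mus = props[row, 1]
            g = props[row, 2]
            nmed = props[row, 3]
            mut = mua + mus

            if step_rule == STEP_CARRY and carry_s > 0.0:
                s_dimless = carry_s
                carry_s = -1.0
            else:
                state, xi = rand_open(state)
                s_dimless = -np.log(xi)
            # a mu_t = 0 medium never interacts: straight transport
            step = s_dimless / mut if mut > 0.0 else 1e300

            flag, d, axis, pix, piy, piz, nix, niy, niz = traverse(
                labels, ix, iy, iz, x, y, z, ux, uy, uz,
                pitch, origin[0], origin[1], origin[2], step,
            )
            x += ux * d
            y += uy * d
            z += uz * d
            t += d * nmed / C_MM_NS
            consumed_s = d * mut  # dimensionless path in the old medium

            interact = False
            vix, viy, viz = ix, iy, iz
            if flag == 0:
                # interaction inside the current label
                ix, iy, iz = nix, niy, niz
                vix, viy, viz = ix, iy, iz
                interact = True
            elif flag == 2:
                # tissue touched the grid border: treat as an exit
                totals[TOT_EXITED] += W
                bidx = int(t / bin_width)
                if bidx >= n_bins:
                    bidx = n_bins - 1
                exit_w[pix, piy, piz] += W
                exit_sq[pix, piy, piz] += W * W
                exit_wt[pix, piy, piz, bidx] += W
                break
            else:
                # crossed into a different label after distance d
                new_lab = labels[nix, niy, niz]
                row2 = _row_at(new_lab, x, y, z, nix, niy, niz, label_row,
                               composite_label, sub_row0, ny, nz,
                               refpts, cand_indptr, cand_idx, edges)
                n2 = props[row2, 3]
                if axis == 0:
                    cosi = abs(ux)
                elif axis == 1:
                    cosi = abs(uy)
                else:
                    cosi = abs(uz)
                R = reflectance_coeff(cosi, nmed, n2, model)
                state, xi = rand_halfopen(state)
                if xi < R:
                    # specular reflection back into the current medium
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                    ix, iy, iz = pix, piy, piz
                    vix, viy, viz = pix, piy, piz
                else:
                    eta = nmed / n2
                    cost = np.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - cosi * cosi)))
                    ux, uy, uz = _refract_axis(ux, uy, uz, axis, eta, cost)
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    if new_lab == ambient:
                        # transmission out of the tissue: record and terminate
                        totals[TOT_EXITED] += W
                        bidx = int(t / bin_width)
                        if bidx >= n_bins:
                            bidx = n_bins - 1
                        exit_w[pix, piy, piz] += W
                        exit_sq[pix, piy, piz] += W * W
                        exit_wt[pix, piy, piz, bidx] += W
                        break
                    cur_lab = new_lab
                    ix, iy, iz = nix, niy, niz
                    vix, viy, viz = nix, niy, niz
                    row = row2
                    mua = props[row, 0]
                    mus = props[row, 1]
                    g = props[row, 2]
                    mut = mua + mus
                x += ux * eps
                y += uy * eps
                z += uz * eps
                if step_rule == STEP_CARRY:
                    rem = s_dimless - consumed_s
                    carry_s = rem if rem > 0.0 else -1.0
                else:
                    # resample rule: the interface is an interaction site
                    interact = True

            if interact and mut > 0.0:
                # absorb (deposited at the interaction/relocation voxel)
                dW = W * mua / mut
                absorbed[vix, viy, viz] += dW
                totals[TOT_ABSORBED] += dW
                W -= dW
                if W <= 0.0:
                    break  # fully absorbed (pure-absorber degenerate case)
                # scatter
                state, xi1 = rand_halfopen(state)
                state, xi2 = rand_halfopen(state)
                cost = hg_cos(g, xi1)
                phi = 2.0 * np.pi * xi2
                ux, uy, uz = rotate_direction(ux, uy, uz, cost, phi)
                # roulette; the survivor's weight boost is netted against the
                # roulette tally so the run's energy books balance exactly
                if W < cutoff:
                    state, xi = rand_halfopen(state)
                    if xi <= 1.0 / rc:
                        totals[TOT_ROULETTE] -= (rc - 1.0) * W
                        W *= rc
                    else:
                        totals[TOT_ROULETTE] += W
                        break

            if t > max_time:
                totals[TOT_TIMEOUT] += W
                break
            n_int += 1
            if n_int > max_interactions:
                totals[TOT_CAP] += W
                break


@njit(cache=True)
def sample_steps(mu_t, n, seed):
    """Vector of ``n`` free-path steps -ln(xi)/mu_t from the seeded stream."""
    out = np.empty(n)
    state = stream_init(seed, 0)
    for i in range(n):
        state, xi = rand_open(state)
        out[i] = -np.log(xi) / mu_t
    return out


@njit(cache=True)
def sample_hg_cosines(g, n, seed):
    """Vector of ``n`` HG deflection cosines from the seeded photon streams."""
    out = np.empty(n)
    state = stream_init(seed, 0)
    for i in range(n):
        state, xi = rand_halfopen(state)
        out[i] = hg_cos(g, xi)
    return out
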