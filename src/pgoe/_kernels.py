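"""Numba-compiled inner loops of the origin-ensembles engine.

These kernels mirror the pure-python chain logic in :mod:`pgoe.recon`
(one Markov step per event per sweep, Metropolis acceptance
``(c_j + 1) / c_i`` under uniform voxel sensitivity) but run the full
per-step resolution-recovery resampling — two Normal energy draws and
six (doubles) or nine (triples) uniform position draws — in compiled
code.  All randomness comes from numba's global NumPy legacy RNG, seeded
once per kernel call, so runs are reproducible given the seed.
"""

import numpy as np
from numba import njit

MEC2 = 0.511


@njit(cache=True)
def _sigma_e(e, ekind, ea, eb, eeta):
    """Energy sigma in MeV; ekind 0 = ab FWHM model (keV), 1 = eta*sqrt(E)."""
    if ekind == 0:
        fw = ea + eb * np.sqrt(e * 1000.0)
        if fw < 0.0:
            fw = 0.0
        return fw / 2.355 / 1000.0
    return eeta * np.sqrt(e)


@njit(cache=True)
def _positive_normal(mu, sigma):
    if sigma == 0.0:
        return mu
    for _ in range(100):
        v = mu + sigma * np.random.standard_normal()
        if v > 0.0:
            return v
    return mu


@njit(cache=True)
def _event_cone(e, nint, pos, energy, stage,
                depth_err, pitch_u, pitch_v, x_lo, x_hi,
                ekind, ea, eb, eeta, correct_pos, correct_energy,
                work, apex, axis):
    """Build the (optionally resolution-corrected) origin cone of event e.

    ``work`` is a (3, 3) scratch for corrected positions; ``apex`` and
    ``axis`` are length-3 outputs.  Returns (ok, cos_beta).
    """
    ni = nint[e]
    for k in range(ni):
        s = stage[e, k]
        if correct_pos:
            x = pos[e, k, 0] + (np.random.random() - 0.5) * depth_err[s]
            if x < x_lo[s]:
                x = x_lo[s]
            elif x > x_hi[s]:
                x = x_hi[s]
            work[k, 0] = x
            work[k, 1] = pos[e, k, 1] + (np.random.random() - 0.5) * pitch_u[s]
            work[k, 2] = pos[e, k, 2] + (np.random.random() - 0.5) * pitch_v[s]
        else:
            work[k, 0] = pos[e, k, 0]
            work[k, 1] = pos[e, k, 1]
            work[k, 2] = pos[e, k, 2]
    e1 = energy[e, 0]
    e2 = energy[e, 1]
    if correct_energy:
        e1 = _positive_normal(e1, _sigma_e(e1, ekind, ea, eb, eeta))
        e2 = _positive_normal(e2, _sigma_e(e2, ekind, ea, eb, eeta))

    if ni == 2:
        et = e1 + e2  # full absorption assumed for doubles
    else:
        ax = work[1, 0] - work[0, 0]
        ay = work[1, 1] - work[0, 1]
        az = work[1, 2] - work[0, 2]
        bx = work[2, 0] - work[1, 0]
        by = work[2, 1] - work[1, 1]
        bz = work[2, 2] - work[1, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        if na <= 0.0 or nb <= 0.0:
            return False, 0.0
        c = (ax * bx + ay * by + az * bz) / (na * nb)
        if c < -1.0:
            c = -1.0
        if c >= 1.0 - 1e-12:
            return False, 0.0
        et = e1 + e2 / 2.0 + np.sqrt(e2 * e2 / 4.0 + e2 * MEC2 / (1.0 - c))

    rem = et - e1
    if rem <= 0.0 or et <= 0.0:
        return False, 0.0
    cosb = 1.0 - MEC2 * (1.0 / rem - 1.0 / et)
    if cosb < -1.0 or cosb > 1.0:
        return False, 0.0

    dx = work[0, 0] - work[1, 0]
    dy = work[0, 1] - work[1, 1]
    dz = work[0, 2] - work[1, 2]
    nn = np.sqrt(dx * dx + dy * dy + dz * dz)
    if nn <= 0.0:
        return False, 0.0
    apex[0] = work[0, 0]
    apex[1] = work[0, 1]
    apex[2] = work[0, 2]
    axis[0] = dx / nn
    axis[1] = dy / nn
    axis[2] = dz / nn
    return True, cosb


@njit(cache=True)
def _sample_on_cone(apex, axis, cosb, lo, binw, dims,
                    max_trials, area_weighted, g, pt):
    """Random point on the cone surface inside the VOI box.

    With ``area_weighted`` (the default policy) the point is uniform with
    respect to the cone surface-area measure (density ~ t dt dphi):
    azimuths are drawn uniformly, kept by rejection with probability
    proportional to the in-box chord's area weight thi^2 - tlo^2, and the
    distance t along the generatrix follows the area element.  Without it
    the legacy chord measure is used (azimuth uniform over the visible
    arc, t uniform on the chord), which overweights short corner-grazing
    chords.  Returns the flat voxel index or -1 after ``max_trials``
    azimuth draws.
    """
    # area-weight rejection bound: squared apex distance to the farthest corner
    d2max = 0.0
    for c0 in range(2):
        for c1 in range(2):
            for c2 in range(2):
                dx = lo[0] + c0 * binw[0] * dims[0] - apex[0]
                dy = lo[1] + c1 * binw[1] * dims[1] - apex[1]
                dz = lo[2] + c2 * binw[2] * dims[2] - apex[2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > d2max:
                    d2max = d2
    sb2 = 1.0 - cosb * cosb
    sinb = np.sqrt(sb2) if sb2 > 0.0 else 0.0
    # orthonormal basis (u, v) perpendicular to the cone axis
    if abs(axis[0]) < 0.9:
        a0, a1, a2 = 1.0, 0.0, 0.0
    else:
        a0, a1, a2 = 0.0, 1.0, 0.0
    d = a0 * axis[0] + a1 * axis[1] + a2 * axis[2]
    ux = a0 - d * axis[0]
    uy = a1 - d * axis[1]
    uz = a2 - d * axis[2]
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = axis[1] * uz - axis[2] * uy
    vy = axis[2] * ux - axis[0] * uz
    vz = axis[0] * uy - axis[1] * ux

    for _ in range(max_trials):
        phi = 2.0 * np.pi * np.random.random()
        cp = np.cos(phi)
        sp = np.sin(phi)
        g[0] = cosb * axis[0] + sinb * (cp * ux + sp * vx)
        g[1] = cosb * axis[1] + sinb * (cp * uy + sp * vy)
        g[2] = cosb * axis[2] + sinb * (cp * uz + sp * vz)
        tlo = 1e-12
        thi = 1e30
        ok = True
        for k in range(3):
            a = apex[k]
            gk = g[k]
            l = lo[k]
            h = l + binw[k] * dims[k]
            if -1e-14 < gk < 1e-14:
                if a < l or a >= h:
                    ok = False
                    break
            else:
                t1 = (l - a) / gk
                t2 = (h - a) / gk
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tlo:
                    tlo = t1
                if t2 < thi:
                    thi = t2
                if tlo >= thi:
                    ok = False
                    break
        if not ok:
            continue
        if area_weighted:
            w = thi * thi - tlo * tlo
            if np.random.random() * d2max > w:
                continue
            t = np.sqrt(tlo * tlo + np.random.random() * w)
        else:
            t = tlo + np.random.random() * (thi - tlo)
        pt[0] = apex[0] + t * g[0]
        pt[1] = apex[1] + t * g[1]
        pt[2] = apex[2] + t * g[2]
        i0 = int((pt[0] - lo[0]) / binw[0])
        i1 = int((pt[1] - lo[1]) / binw[1])
        i2 = int((pt[2] - lo[2]) / binw[2])
        if pt[0] < lo[0] or pt[1] < lo[1] or pt[2] < lo[2]:
            continue  # floating-point edge graze
        if i0 >= dims[0] or i1 >= dims[1] or i2 >= dims[2]:
            continue
        return (i0 * dims[1] + i1) * dims[2] + i2
    return -1


@njit(cache=True)
def run_sweeps(nint, pos, energy, stage,
               depth_err, pitch_u, pitch_v, x_lo, x_hi,
               ekind, ea, eb, eeta, correct_pos, correct_energy,
               lo, binw, dims,
               origins, vox, counts, accum,
               n_sweeps, burn_in, seed, max_trials, area_weighted, ordered):
    """Run ``n_sweeps`` ordered (or stochastic) origin-ensemble sweeps
    in place; accumulate voxel counts after ``burn_in`` sweeps.

    Returns (per-sweep acceptance rates, number of accumulated sweeps).
    """
    np.random.seed(seed)
    n = nint.shape[0]
    work = np.empty((3, 3))
    apex = np.empty(3)
    axis = np.empty(3)
    g = np.empty(3)
    pt = np.empty(3)
    acc_rate = np.zeros(n_sweeps)
    n_acc = 0
    for s in range(n_sweeps):
        accepted = 0
        attempted = 0
        for step in range(n):
            if ordered:
                e = step
            else:
                e = int(np.random.random() * n)
                if e >= n:
                    e = n - 1
            if vox[e] < 0:
                continue
            attempted += 1
            ok, cosb = _event_cone(
                e, nint, pos, energy, stage,
                depth_err, pitch_u, pitch_v, x_lo, x_hi,
                ekind, ea, eb, eeta, correct_pos, correct_energy,
                work, apex, axis,
            )
            if not ok:
                continue
            j = _sample_on_cone(apex, axis, cosb, lo, binw, dims,
                                max_trials, area_weighted, g, pt)
            if j < 0:
                continue
            i = vox[e]
            ratio = (counts[j] + 1.0) / counts[i]
            if ratio >= 1.0 or np.random.random() < ratio:
                counts[i] -= 1
                counts[j] += 1
                vox[e] = j
                origins[e, 0] = pt[0]
                origins[e, 1] = pt[1]
                origins[e, 2] = pt[2]
                accepted += 1
        if attempted > 0:
            acc_rate[s] = accepted / attempted
        if s >= burn_in:
            for v in range(counts.shape[0]):
                accum[v] += counts[v]
            n_acc += 1
    return acc_rate, n_acc


@njit(cache=True)
def sample_candidates(nint, pos, energy, stage,
                      depth_err, pitch_u, pitch_v, x_lo, x_hi,
                      ekind, ea, eb, eeta, correct_pos, correct_energy,
                      lo, binw, dims,
                      k, n_resample_tries, seed, max_trials, area_weighted):
    """Draw k candidate origin points per event for the pre-calculated
    initialization; invalid candidates are marked with voxel -1."""
    np.random.seed(seed)
    n = nint.shape[0]
    cand_vox = np.full((n, k), -1, dtype=np.int64)
    cand_pos = np.zeros((n, k, 3))
    work = np.empty((3, 3))
    apex = np.empty(3)
    axis = np.empty(3)
    g = np.empty(3)
    pt = np.empty(3)
    for e in range(n):
        for c in range(k):
            for _ in range(n_resample_tries):
                ok, cosb = _event_cone(
                    e, nint, pos, energy, stage,
                    depth_err, pitch_u, pitch_v, x_lo, x_hi,
                    ekind, ea, eb, eeta, correct_pos, correct_energy,
                    work, apex, axis,
                )
                if not ok:
                    continue
                j = _sample_on_cone(apex, axis, cosb, lo, binw, dims,
                                    max_trials, area_weighted, g, pt)
                if j >= 0:
                    cand_vox[e, c] = j
                    cand_pos[e, c, 0] = pt[0]
                    cand_pos[e, c, 1] = pt[1]
                    cand_pos[e, c, 2] = pt[2]
                    break
    return cand_vox, cand_pos
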