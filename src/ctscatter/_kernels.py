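"""Numba-compiled transport kernels shared by the Monte Carlo and quadrature
scatter engines.

Both engines evaluate the same single-scatter estimator: photons start on the
discrete set of channel rays (incident planes distributed uniformly over the
collimated cone's z-extent), attenuate through blocker and phantom wall,
interact once in the fill cylinder with probability density mu*exp(-mu*s),
Compton-scatter with the Klein-Nishina angular law, and deposit their scattered
energy at the detector element their exit ray hits, attenuated along the exit
path.  The Monte Carlo samples this chain; the quadrature kernel integrates it,
using an even-quadratic interpolation of the slowly varying out-of-plane factor
(the detector subtends at most ~5 degrees out of plane, over which the
Klein-Nishina kernel and exit attenuation change by well under 1%).

All lengths are in mm and attenuation coefficients in mm^-1 inside the kernels.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MEC2 = 511.0


@njit(cache=False)
def _interp_mu(e_kev, e0, inv_step, mu_fine):
    """Linear lookup on the fine attenuation grid (clamped at the ends)."""
    x = (e_kev - e0) * inv_step
    if x <= 0.0:
        return mu_fine[0]
    n = mu_fine.shape[0]
    if x >= n - 1:
        return mu_fine[n - 1]
    k = int(x)
    f = x - k
    return mu_fine[k] * (1.0 - f) + mu_fine[k + 1] * f


@njit(cache=False)
def _kn(cos_th, e_kev):
    """Klein-Nishina dsigma/dOmega in r_e^2 units, and the scattered energy."""
    ep = e_kev / (1.0 + (e_kev / MEC2) * (1.0 - cos_th))
    r = ep / e_kev
    kn = 0.5 * r * r * (r + 1.0 / r - (1.0 - cos_th * cos_th))
    return kn, ep


@njit(cache=False)
def quadrature_scatter(
    inc_idx,                # incident channel indices to process
    alpha,                  # channel centre fan angles, rad (n_ch)
    edge_x, edge_y,         # arc coordinates of the n_ch+1 channel edges, mm
    ax, ay,                 # arc coordinates of channel centres, mm
    bfac,                   # incident blocker factor per channel
    e_bins, w_bins,         # spectrum bin centres (keV) and weights
    mu_f, mu_w,             # attenuation of fill/wall at bin energies, mm^-1
    fcs,                    # compton_fraction / sigma_KN per bin
    e0, inv_step,           # fine energy grid origin and 1/step
    mu_f_fine, mu_w_fine,   # fine-grid attenuation for scattered energies
    xc, rf, ro,             # phantom centre x, fill radius, outer radius, mm
    ds,                     # chord step, mm
    z_edges,                # row boundary z at the detector (n_rows+1), mm
    row_sel,                # row indices to resolve (empty => collapse rows)
    phi0,                   # photons per incident ray (tube output scale)
    out,                    # (n_out_rows, n_ch) accumulator
):
    n_ch = alpha.shape[0]
    n_e = e_bins.shape[0]
    zmax = z_edges[z_edges.shape[0] - 1]
    collapse = row_sel.shape[0] == 0
    psi_e = np.empty(n_ch + 1)
    w_ek = np.empty(n_e)
    for ii in range(inc_idx.shape[0]):
        i = inc_idx[ii]
        w0 = phi0 * bfac[i]
        ca = math.cos(alpha[i])
        sa = math.sin(alpha[i])
        dperp = abs(xc * sa)
        if dperp >= rf:
            continue
        lf_chord = 2.0 * math.sqrt(rf * rf - dperp * dperp)
        lo_chord = 2.0 * math.sqrt(ro * ro - dperp * dperp) if ro > rf else lf_chord
        w_front = 0.5 * (lo_chord - lf_chord)
        t_entry = xc * ca - 0.5 * lf_chord
        nk = max(1, int(round(lf_chord / ds)))
        h = lf_chord / nk
        # per-energy incident factors that do not depend on the step
        for e in range(n_e):
            w_ek[e] = w0 * w_bins[e] * fcs[e] * math.exp(-mu_w[e] * w_front)
        for k in range(nk):
            s0 = k * h
            s1 = s0 + h
            sm = s0 + 0.5 * h
            t = t_entry + sm
            px = t * ca
            py = t * sa
            for j in range(n_ch + 1):
                psi_e[j] = math.atan2(edge_y[j] - py, edge_x[j] - px)
            qx = px - xc
            qy = py
            q2 = qx * qx + qy * qy
            for i2 in range(n_ch):
                vx = ax[i2] - px
                vy = ay[i2] - py
                d2 = math.sqrt(vx * vx + vy * vy)
                nx = vx / d2
                ny = vy / d2
                cos_ip = ca * nx + sa * ny
                if cos_ip > 1.0:
                    cos_ip = 1.0
                elif cos_ip < -1.0:
                    cos_ip = -1.0
                bb = qx * nx + qy * ny
                lf = -bb + math.sqrt(bb * bb - (q2 - rf * rf))
                lw = 0.0
                if ro > rf:
                    lw = (-bb + math.sqrt(bb * bb - (q2 - ro * ro))) - lf
                zeta_m = math.atan(zmax / d2)
                cz = math.cos(zeta_m)
                sec = 1.0 / cz
                cos_tilt = cz * cos_ip
                a0 = 0.0
                a2 = 0.0
                for e in range(n_e):
                    dp = math.exp(-mu_f[e] * s0) - math.exp(-mu_f[e] * s1)
                    we = w_ek[e] * dp
                    if we <= 0.0:
                        continue
                    kn0, ep0 = _kn(cos_ip, e_bins[e])
                    x0 = (_interp_mu(ep0, e0, inv_step, mu_f_fine) * lf
                          + _interp_mu(ep0, e0, inv_step, mu_w_fine) * lw)
                    g0 = we * kn0 * ep0 * math.exp(-x0)
                    kn1, ep1 = _kn(cos_tilt, e_bins[e])
                    x1 = (_interp_mu(ep1, e0, inv_step, mu_f_fine) * lf
                          + _interp_mu(ep1, e0, inv_step, mu_w_fine) * lw) * sec
                    g1 = we * kn1 * ep1 * math.exp(-x1)
                    a0 += g0
                    a2 += (g1 - g0) / (zeta_m * zeta_m)
                dpsi = psi_e[i2 + 1] - psi_e[i2]
                if collapse:
                    sz = math.sin(zeta_m)
                    fz = zeta_m * zeta_m * sz + 2.0 * zeta_m * cz - 2.0 * sz
                    out[0, i2] += (a0 * 2.0 * sz + a2 * 2.0 * fz) * dpsi
                else:
                    for jr in range(row_sel.shape[0]):
                        j = row_sel[jr]
                        zl = math.atan(z_edges[j] / d2)
                        zh = math.atan(z_edges[j + 1] / d2)
                        il = (a0 * (math.sin(zh) - math.sin(zl))
                              + a2 * ((zh * zh * math.sin(zh) + 2.0 * zh * math.cos(zh)
                                       - 2.0 * math.sin(zh))
                                      - (zl * zl * math.sin(zl) + 2.0 * zl * math.cos(zl)
                                         - 2.0 * math.sin(zl))))
                        out[jr, i2] += il * dpsi


@njit(cache=False)
def mc_scatter(
    n_photons,
    n_splits,               # exit directions sampled per interaction
    rng_seed,
    counts,                 # photons assigned to each incident channel
    alpha, bfac,
    e_idx,                  # per-photon spectrum bin index
    u_path,                 # per-photon uniform for the interaction depth
    u_plane,                # per-photon uniform for the incident-plane z offset
    z_half_width,           # half z-extent of the illuminated cone at the phantom, mm
    q_grid, ctheta_tab,     # per-energy inverse CDF of cos(theta) under KN
    e_bins, mu_f, mu_w, fc,
    e0, inv_step, mu_f_fine, mu_w_fine,
    xc, rf, ro,
    r_det, pitch_rad, row_pitch_det,
    n_rows,
    phi0,
    sums, sumsq,            # (n_rows, n_ch) accumulators
):
    np.random.seed(rng_seed)
    n_ch = alpha.shape[0]
    half_idx = (n_ch - 1) / 2.0
    n_q = q_grid.shape[0]
    inv_split = 1.0 / n_splits
    for j in range(n_photons):
        i = j % n_ch
        ca = math.cos(alpha[i])
        sa = math.sin(alpha[i])
        dperp = abs(xc * sa)
        if dperp >= rf:
            continue
        lf_chord = 2.0 * math.sqrt(rf * rf - dperp * dperp)
        lo_chord = 2.0 * math.sqrt(ro * ro - dperp * dperp) if ro > rf else lf_chord
        w_front = 0.5 * (lo_chord - lf_chord)
        t_entry = xc * ca - 0.5 * lf_chord
        e = e_idx[j]
        muf = mu_f[e]
        p_int = 1.0 - math.exp(-muf * lf_chord)
        s = -math.log(1.0 - u_path[j] * p_int) / muf
        t = t_entry + s
        px = t * ca
        py = t * sa
        wgt = (phi0 / counts[i]) * bfac[i] * p_int * fc[e] \
            * math.exp(-mu_w[e] * w_front) * inv_split
        zo = (2.0 * u_plane[j] - 1.0) * z_half_width
        qx = px - xc
        qy = py
        q2 = qx * qx + qy * qy
        for _ in range(n_splits):
            # inverse-CDF sample of cos(theta) for this energy bin
            u1 = np.random.random()
            pos = u1 * (n_q - 1)
            k = int(pos)
            if k >= n_q - 1:
                k = n_q - 2
            f = pos - k
            cth = ctheta_tab[e, k] * (1.0 - f) + ctheta_tab[e, k + 1] * f
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            sth = math.sqrt(1.0 - cth * cth)
            ph = 2.0 * math.pi * np.random.random()
            cph = math.cos(ph)
            sph = math.sin(ph)
            # incident frame: u = (ca, sa, 0), v = (-sa, ca, 0), w = z
            ex = cth * ca - sth * cph * sa
            ey = cth * sa + sth * cph * ca
            ez = sth * sph
            cz = math.sqrt(ex * ex + ey * ey)
            if cz < 1e-12:
                continue
            nx = ex / cz
            ny = ey / cz
            b = px * nx + py * ny
            disc = b * b - (px * px + py * py - r_det * r_det)
            tau = -b + math.sqrt(disc)
            hx = px + tau * nx
            hy = py + tau * ny
            u_hit = math.atan2(hy, hx) / pitch_rad + half_idx
            i2 = int(math.floor(u_hit + 0.5))
            if i2 < 0 or i2 >= n_ch:
                continue
            z = zo + tau * (ez / cz)
            row = int(math.floor(z / row_pitch_det + n_rows / 2.0))
            if row < 0 or row >= n_rows:
                continue
            bb = qx * nx + qy * ny
            lf = -bb + math.sqrt(bb * bb - (q2 - rf * rf))
            lw = 0.0
            if ro > rf:
                lw = (-bb + math.sqrt(bb * bb - (q2 - ro * ro))) - lf
            ep = e_bins[e] / (1.0 + (e_bins[e] / MEC2) * (1.0 - cth))
            x = (_interp_mu(ep, e0, inv_step, mu_f_fine) * lf
                 + _interp_mu(ep, e0, inv_step, mu_w_fine) * lw) / cz
            dep = wgt * ep * math.exp(-x)
            sums[row, i2] += dep
            sumsq[row, i2] += dep * dep
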