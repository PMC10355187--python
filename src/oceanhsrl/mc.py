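"""Semianalytic Monte Carlo simulation of multi-FOV oceanic HSRL returns.

Photon packets are traced through the water column: free paths are drawn
from the local scattering coefficient, absorption attenuates the packet
weight continuously along the path, and at every collision an analytic
estimator adds the expected return to each receiver channel --- packet
weight times the probability of scattering straight into the receiver
aperture times the transmission of the return ray.  The range bin of a
contribution is half the total optical path (lidar time-of-flight
convention).

Channel split (ideal iodine filter): a molecular (Brillouin) scattering
shifts the photon frequency off the laser line, and subsequent particulate
scattering is elastic, so a packet belongs to the molecular channels as
soon as its history contains one molecular event --- either the
receiver-directed scattering itself is molecular, or the packet is already
Brillouin-shifted and a particle redirects it into the aperture.  The
combined channel accumulates everything.  Molecular scattering events are
importance-boosted (with exact weight compensation) so that the
Brillouin-shifted upward population, which carries the multiply scattered
wide-FOV return, is well sampled.

The estimator makes every collision of every packet contribute, which is
what keeps the variance low enough to use 10^6-photon budgets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import LidarConfig
from .optics import (
    MolecularPhase,
    fournier_forand_cumulative,
    fournier_forand_phase,
)
from .profiles import IOPProfile
from .signals import SignalSet

__all__ = ["simulate_mc", "add_noise"]

_N_THETA = 2048
_N_U = 4096
_THETA_MIN = 1e-6
_W_MIN = 1e-6  # roulette threshold on packet weight

# receiver-aimed splitting for Brillouin-shifted packets: the outgoing
# direction distribution is partitioned into the cone of half-angle _AIM_TH1
# around the receiver direction (carried by a spawned sub-packet) and its
# complement (carried by the parent)
_AIM_TH1 = 0.3  # receiver cone half-angle, rad
_AIM_T0 = 0.01  # core angle of the in-cone proposal density, rad
_AIM_MARGIN = 0.05  # switch between rejection and proposal sampling, rad
_SPAWN_FLOOR = 3e-5  # skip splitting when w * P_C falls below this
_STACK_CAP = 192


def _ff_tables(xis: np.ndarray):
    """Log-angle pdf/cdf tables and inverse-CDF table, one row per slope."""
    log_th = np.linspace(np.log(_THETA_MIN), np.log(np.pi), _N_THETA)
    theta = np.exp(log_th)
    u = np.linspace(0.0, 1.0, _N_U)
    pdf = np.empty((xis.size, _N_THETA))
    cdf = np.empty((xis.size, _N_THETA))
    ppf = np.empty((xis.size, _N_U))
    for i, xi in enumerate(xis):
        pdf[i] = fournier_forand_phase(xi, theta)
        ci = fournier_forand_cumulative(xi, theta)
        ci[0], ci[-1] = 0.0, 1.0
        cdf[i] = np.maximum.accumulate(ci)
        ppf[i] = np.interp(u, cdf[i], theta)
    return log_th, pdf, cdf, ppf


def _mol_ppf(f: float) -> np.ndarray:
    phase = MolecularPhase(f=f)
    grid = np.linspace(0.0, np.pi, _N_THETA)
    return np.interp(np.linspace(0.0, 1.0, _N_U), phase.cumulative(grid), grid)


# aperture-disk convolution table grids
_N_THR = 512  # receiver-direction angles
_N_THAP = 24  # aperture half-angles


def _cap_tables(xis: np.ndarray):
    """Exact disk integral of the particulate phase over the aperture.

    ``T[x, i_ap, i_r]`` is the integral of the Fournier-Forand phase
    function of slope ``xis[x]`` over a cone of half-angle ``thap[i_ap]``
    centred at angle ``thr[i_r]`` from the phase-function axis.  A point
    evaluation p(theta_r) * dOmega is badly biased (and heavy-tailed) when
    the aperture overlaps the forward peak, so the estimator uses this
    table instead.
    """
    log_ap = np.linspace(np.log(5e-4), np.log(0.06), _N_THAP)
    thap = np.exp(log_ap)
    log_r = np.linspace(np.log(_THETA_MIN), np.log(np.pi), _N_THR)
    thr = np.exp(log_r)
    nodes, weights = np.polynomial.legendre.leggauss(48)
    T = np.empty((xis.size, _N_THAP, _N_THR))
    for xdx, xi in enumerate(xis):
        for i, ap in enumerate(thap):
            lo = np.maximum(thr - ap, 0.0)
            hi = np.minimum(thr + ap, np.pi)
            # region fully inside the disk (when the axis is inside it)
            inner = np.where(thr < ap, np.minimum(ap - thr, np.pi), 0.0)
            t_in = np.where(
                inner > 0, fournier_forand_cumulative(xi, inner), 0.0
            )
            a_lo = np.maximum(lo, inner)
            mid = 0.5 * (hi + a_lo)
            half = 0.5 * (hi - a_lo)
            th_nodes = mid[:, None] + half[:, None] * nodes[None, :]
            th_nodes = np.clip(th_nodes, 1e-9, np.pi)
            p = fournier_forand_phase(xi, th_nodes)
            ct, cr = np.cos(th_nodes), np.cos(thr)[:, None]
            st, sr = np.sin(th_nodes), np.sin(thr)[:, None]
            arg = (np.cos(ap) - ct * cr) / np.maximum(st * sr, 1e-300)
            frac = np.arccos(np.clip(arg, -1.0, 1.0)) / np.pi
            band = 2.0 * np.pi * np.sum(
                weights[None, :] * p * st * frac, axis=1
            ) * half
            T[xdx, i] = t_in + np.maximum(band, 0.0)
    return log_ap, log_r, T


def _cone_mass(phase_fn, thr: np.ndarray, ap: float) -> np.ndarray:
    """Integral of an axisymmetric phase density over an off-axis cone.

    ``thr`` is the angle between the phase axis and the cone axis; ``ap``
    the cone half-angle.  Same construction as :func:`_cap_tables`.
    """
    phase_fn, cum_fn = phase_fn
    nodes, weights = np.polynomial.legendre.leggauss(64)
    lo = np.maximum(thr - ap, 0.0)
    hi = np.minimum(thr + ap, np.pi)
    inner = np.where(thr < ap, np.minimum(ap - thr, np.pi), 0.0)
    t_in = np.where(inner > 0, cum_fn(np.maximum(inner, 1e-12)), 0.0)
    a_lo = np.maximum(lo, inner)
    mid = 0.5 * (hi + a_lo)
    half = 0.5 * (hi - a_lo)
    th_nodes = np.clip(mid[:, None] + half[:, None] * nodes[None, :], 1e-9, np.pi)
    p = phase_fn(th_nodes)
    ct, cr = np.cos(th_nodes), np.cos(thr)[:, None]
    st, sr = np.sin(th_nodes), np.sin(thr)[:, None]
    arg = (np.cos(ap) - ct * cr) / np.maximum(st * sr, 1e-300)
    frac = np.arccos(np.clip(arg, -1.0, 1.0)) / np.pi
    band = 2.0 * np.pi * np.sum(weights[None, :] * p * st * frac, axis=1) * half
    return np.clip(t_in + np.maximum(band, 0.0), 0.0, 1.0)


def _cone_tables(xis: np.ndarray, mol_f: float):
    """Receiver-cone mass tables P_C(theta_or) for splitting."""
    log_r = np.linspace(np.log(_THETA_MIN), np.log(np.pi), _N_THR)
    thr = np.exp(log_r)
    cone_p = np.empty((xis.size, _N_THR))
    for i, xi in enumerate(xis):
        cone_p[i] = _cone_mass(
            (
                lambda t, x=xi: fournier_forand_phase(x, t),
                lambda t, x=xi: fournier_forand_cumulative(x, t),
            ),
            thr,
            _AIM_TH1,
        )
    mphase = MolecularPhase(f=mol_f)
    cone_m = _cone_mass((mphase, mphase.cumulative), thr, _AIM_TH1)
    return log_r, cone_p, cone_m


@njit(cache=True)
def _pdf_at(pdf_row, log_th0, dlog_th, theta):
    """Phase density from the log-angle table."""
    if theta < _THETA_MIN:
        theta = _THETA_MIN
    ti = (np.log(theta) - log_th0) / dlog_th
    ii = int(ti)
    if ii < 0:
        ii = 0
    if ii >= pdf_row.size - 1:
        ii = pdf_row.size - 2
    frac = ti - ii
    return pdf_row[ii] * (1.0 - frac) + pdf_row[ii + 1] * frac


@njit(cache=True)
def _rotate(ux, uy, uz, theta, phi):
    """Rotate a unit vector by polar angle theta, azimuth phi."""
    st = np.sin(theta)
    ct = np.cos(theta)
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        return st * cp, st * sp, ct * (1.0 if uz > 0 else -1.0)
    den = np.sqrt(1.0 - uz * uz)
    nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
    ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
    nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _sample_theta(ppf_row, du, u):
    fi = u / du
    ii = int(fi)
    if ii >= ppf_row.size - 1:
        ii = ppf_row.size - 2
    return ppf_row[ii] + (ppf_row[ii + 1] - ppf_row[ii]) * (fi - ii)


@njit(cache=True, fastmath=True)
def _trace(seed, n_photons, dz, n_bins, a, bp, bm, xi_row, c_edges,
           log_th0, dlog_th, ff_pdf, ff_ppf, mol_ppf, mol_f,
           cap_lap0, cap_dlap, cap_lr0, cap_dlr, cap_ap0, cap_ap1, cap_T,
           cone_p, cone_m,
           height, radius, area, fov_half, max_depth):
    # 16 internal batches give per-bin standard errors that respect the
    # correlation of contributions within one photon family
    mol = np.zeros((16, 3, n_bins))
    comb = np.zeros((16, n_bins))
    np.random.seed(seed)
    mol_norm = 1.0 / (4.0 * np.pi * (1.0 + mol_f / 3.0))
    du = 1.0 / (ff_ppf.shape[1] - 1.0)
    l_kill = 2.0 * max_depth
    z_kill = 1.5 * max_depth
    # in-cone proposal density constants
    gnorm = 0.5 * np.log(1.0 + (_AIM_TH1 / _AIM_T0) ** 2)
    gpow = 1.0 + (_AIM_TH1 / _AIM_T0) ** 2
    # stack of spawned receiver-cone sub-packets
    st = np.empty((_STACK_CAP, 8))

    for ph in range(n_photons):
        batch = ph * 16 // n_photons
        n_stack = 0
        x = 0.0
        y = 0.0
        z = 1e-9
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        length = 0.0
        alive = True
        shifted = False  # True once the packet has Brillouin-scattered
        can_split = True
        ncol = 0
        while True:
            if not alive or ncol > 400:
                # parent finished: continue with a spawned sub-packet
                if n_stack == 0:
                    break
                n_stack -= 1
                x = st[n_stack, 0]
                y = st[n_stack, 1]
                z = st[n_stack, 2]
                ux = st[n_stack, 3]
                uy = st[n_stack, 4]
                uz = st[n_stack, 5]
                w = st[n_stack, 6]
                length = st[n_stack, 7]
                shifted = True
                can_split = False
                alive = True
                ncol = 0
            ncol += 1
            # --- propagate to the next collision ---------------------------
            tau_s = -np.log(1.0 - np.random.random())
            while True:
                j = int(z / dz)
                if j < 0:
                    j = 0
                elif j >= n_bins:
                    j = n_bins - 1
                b_loc = bm + bp[j]
                if uz > 1e-12:
                    s_bound = ((j + 1) * dz - z) / uz
                elif uz < -1e-12:
                    s_bound = (j * dz - z) / uz
                else:
                    s_bound = 1e30
                # photons below the profile see the deepest bin's water
                if j == n_bins - 1 and uz > 1e-12:
                    s_bound = 1e30
                s_need = tau_s / b_loc
                if s_need <= s_bound:
                    x += ux * s_need
                    y += uy * s_need
                    z += uz * s_need
                    length += s_need
                    w *= np.exp(-a[j] * s_need)
                    break
                s = s_bound + 1e-9
                x += ux * s
                y += uy * s
                z += uz * s
                length += s
                w *= np.exp(-a[j] * s)
                tau_s -= b_loc * s
                if z <= 0.0:
                    alive = False  # escaped through the surface
                    break
                if z >= z_kill or length >= l_kill:
                    alive = False
                    break
            if not alive or length >= l_kill or z >= z_kill:
                alive = False
                continue

            # --- analytic estimator: expected return to each channel -------
            j = int(z / dz)
            if j >= n_bins:
                j = n_bins - 1
            b_loc = bm + bp[j]
            rho = np.sqrt(x * x + y * y)
            zh = z + height
            dist = np.sqrt(rho * rho + zh * zh)
            alpha = np.arctan2(rho, zh)
            s_w = dist * z / zh  # in-water part of the return ray
            kbin = int(0.5 * (length + s_w) / dz)
            if kbin < n_bins:
                # vertical two-way-free attenuation integral to depth z
                je = int(z / dz)
                if je >= n_bins:
                    je = n_bins - 1
                tau_v = c_edges[je] + (a[je] + bm + bp[je]) * (z - je * dz)
                trans = np.exp(-tau_v * (s_w / z))
                cos_r = (ux * (-x) + uy * (-y) + uz * (-zh)) / dist
                if cos_r > 1.0:
                    cos_r = 1.0
                elif cos_r < -1.0:
                    cos_r = -1.0
                theta_r = np.arccos(cos_r)
                dom = area / (dist * dist)
                pm = (1.0 + mol_f * cos_r * cos_r) * mol_norm
                # particulate phase integrated exactly over the aperture
                # disk (table): a point evaluation p(theta_r) * dOmega is
                # biased and heavy-tailed when the aperture overlaps the
                # Fournier-Forand forward peak
                row = xi_row[j]
                th_ap = radius / dist
                if th_ap < cap_ap0:
                    th_ap = cap_ap0
                elif th_ap > cap_ap1:
                    th_ap = cap_ap1
                ai = (np.log(th_ap) - cap_lap0) / cap_dlap
                ia = int(ai)
                if ia >= cap_T.shape[1] - 1:
                    ia = cap_T.shape[1] - 2
                fa = ai - ia
                tr = theta_r
                if tr < _THETA_MIN:
                    tr = _THETA_MIN
                ri = (np.log(tr) - cap_lr0) / cap_dlr
                ir = int(ri)
                if ir < 0:
                    ir = 0
                if ir >= cap_T.shape[2] - 1:
                    ir = cap_T.shape[2] - 2
                fr = ri - ir
                pp_int = (
                    cap_T[row, ia, ir] * (1.0 - fa) * (1.0 - fr)
                    + cap_T[row, ia + 1, ir] * fa * (1.0 - fr)
                    + cap_T[row, ia, ir + 1] * (1.0 - fa) * fr
                    + cap_T[row, ia + 1, ir + 1] * fa * fr
                )
                cm = w * (bm / b_loc) * pm * dom * trans
                cp = w * (bp[j] / b_loc) * pp_int * trans
                # already-shifted packets stay in the molecular channels
                # even when a particle makes the final redirection
                c_mol = cm + cp if shifted else cm
                for ch in range(3):
                    if alpha <= fov_half[ch]:
                        mol[batch, ch, kbin] += c_mol
                if alpha <= fov_half[2]:
                    comb[batch, kbin] += cm + cp

            # --- scatter ---------------------------------------------------
            # importance-boosted molecular branch: the rare Brillouin
            # events are sampled with probability q >= b_m/b and the packet
            # weight compensated exactly, so that the shifted upward
            # population is well represented
            u1 = np.random.random()
            u2 = np.random.random()
            p_mol_nat = bm / b_loc
            q = p_mol_nat if shifted else max(p_mol_nat, 0.1)
            is_mol = u1 < q
            row = xi_row[j]
            if is_mol:
                w *= p_mol_nat / q
                theta = _sample_theta(mol_ppf, du, u2)
            else:
                w *= (1.0 - p_mol_nat) / (1.0 - q)
                theta = _sample_theta(ff_ppf[row], du, u2)

            # receiver-cone splitting: a Brillouin-shifted packet that is
            # redirected toward the aperture carries the multiply scattered
            # molecular return, so the outgoing phase function is
            # partitioned into the receiver cone (spawned sub-packet) and
            # its complement (the parent), each with its exact mass
            did_split = False
            if (shifted or is_mol) and can_split and n_stack < _STACK_CAP:
                zh = z + height
                dist = np.sqrt(x * x + y * y + zh * zh)
                rxd = -x / dist
                ryd = -y / dist
                rzd = -zh / dist
                cos_or = ux * rxd + uy * ryd + uz * rzd
                if cos_or > 1.0:
                    cos_or = 1.0
                elif cos_or < -1.0:
                    cos_or = -1.0
                th_or = np.arccos(cos_or)
                if is_mol:
                    p_c = _pdf_at(cone_m, cap_lr0, cap_dlr, th_or)
                else:
                    p_c = _pdf_at(cone_p[row], cap_lr0, cap_dlr, th_or)
                if w * p_c > _SPAWN_FLOOR and p_c < 0.999:
                    w_sub = -1.0
                    sux = 0.0
                    suy = 0.0
                    suz = 1.0
                    if th_or > _AIM_TH1 + _AIM_MARGIN:
                        # phase peak lies outside the cone: bounded proposal
                        uu = np.random.random()
                        tg = _AIM_T0 * np.sqrt(gpow**uu - 1.0)
                        if tg < 1e-9:
                            tg = 1e-9
                        sux, suy, suz = _rotate(
                            rxd, ryd, rzd, tg, 2.0 * np.pi * np.random.random()
                        )
                        cos_act = sux * ux + suy * uy + suz * uz
                        if cos_act > 1.0:
                            cos_act = 1.0
                        elif cos_act < -1.0:
                            cos_act = -1.0
                        if is_mol:
                            p_act = (1.0 + mol_f * cos_act * cos_act) * mol_norm
                        else:
                            p_act = _pdf_at(
                                ff_pdf[row], log_th0, dlog_th, np.arccos(cos_act)
                            )
                        g_den = tg / (
                            (tg * tg + _AIM_T0 * _AIM_T0)
                            * gnorm
                            * 2.0
                            * np.pi
                            * np.sin(tg)
                        )
                        w_sub = w * p_act / g_den
                    else:
                        # peak may lie inside the cone: rejection into it
                        for _try in range(400):
                            if is_mol:
                                tn = _sample_theta(mol_ppf, du, np.random.random())
                            else:
                                tn = _sample_theta(
                                    ff_ppf[row], du, np.random.random()
                                )
                            tux, tuy, tuz = _rotate(
                                ux, uy, uz, tn, 2.0 * np.pi * np.random.random()
                            )
                            ca = tux * rxd + tuy * ryd + tuz * rzd
                            if ca >= np.cos(_AIM_TH1):
                                sux, suy, suz = tux, tuy, tuz
                                w_sub = w * p_c
                                break
                    if w_sub > 0.0:
                        st[n_stack, 0] = x
                        st[n_stack, 1] = y
                        st[n_stack, 2] = z
                        st[n_stack, 3] = sux
                        st[n_stack, 4] = suy
                        st[n_stack, 5] = suz
                        st[n_stack, 6] = w_sub
                        st[n_stack, 7] = length
                        n_stack += 1
                        did_split = True
                        # the parent keeps the complement of the cone
                        w *= 1.0 - p_c
                        accepted = False
                        for _try in range(400):
                            if is_mol:
                                tn = _sample_theta(mol_ppf, du, np.random.random())
                            else:
                                tn = _sample_theta(
                                    ff_ppf[row], du, np.random.random()
                                )
                            tux, tuy, tuz = _rotate(
                                ux, uy, uz, tn, 2.0 * np.pi * np.random.random()
                            )
                            ca = tux * rxd + tuy * ryd + tuz * rzd
                            if ca < np.cos(_AIM_TH1):
                                ux, uy, uz = tux, tuy, tuz
                                accepted = True
                                break
                        if not accepted:
                            alive = False
            if not did_split:
                ux, uy, uz = _rotate(
                    ux, uy, uz, theta, 2.0 * np.pi * np.random.random()
                )
            if is_mol:
                shifted = True

            # --- Russian roulette ------------------------------------------
            if w < _W_MIN:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    alive = False
    return mol, comb


def simulate_mc(
    iop: IOPProfile,
    config: LidarConfig,
    n_photons: int = 1_000_000,
    seed: int = 0,
) -> SignalSet:
    """Simulate triple-FOV molecular + combined signals by semianalytic MC.

    Deterministic for a fixed ``(iop, config, n_photons, seed)``.  Returns
    bin-averaged signals (same units and grid convention as
    :func:`oceanhsrl.qssa.forward_analytic`).
    """
    if n_photons < 10_000:
        raise ValueError("n_photons must be at least 10^4")
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    z = iop.depths
    dz = iop.dz
    n_bins = z.size
    if not np.isclose(z[0], dz / 2.0, rtol=1e-6):
        raise ValueError("profile grid must start at the first bin center dz/2")
    water = iop.water
    b_p = np.ascontiguousarray(iop.b_p)
    a = np.ascontiguousarray(iop.a)
    if np.any(b_p < -1e-12) or np.any(a < 0):
        raise ValueError("non-physical IOP profile")
    b_p = np.maximum(b_p, 0.0)

    xis, xi_row = np.unique(iop.xi, return_inverse=True)
    log_th, ff_pdf, ff_cdf, ff_ppf = _ff_tables(xis)
    cap_lap, cap_lr, cap_T = _cap_tables(xis)
    _, cone_p, cone_m = _cone_tables(xis, config.molecular_f)
    mol_ppf = _mol_ppf(config.molecular_f)
    c = a + water.b_w + b_p
    c_edges = np.concatenate([[0.0], np.cumsum(c * dz)])

    mol, comb = _trace(
        int(seed) & 0x7FFFFFFF,
        int(n_photons),
        dz,
        n_bins,
        a,
        b_p,
        water.b_w,
        xi_row.astype(np.int64),
        c_edges,
        log_th[0],
        log_th[1] - log_th[0],
        ff_pdf,
        ff_ppf,
        mol_ppf,
        config.molecular_f,
        cap_lap[0],
        cap_lap[1] - cap_lap[0],
        cap_lr[0],
        cap_lr[1] - cap_lr[0],
        float(np.exp(cap_lap[0])),
        float(np.exp(cap_lap[-1])),
        cap_T,
        cone_p,
        cone_m,
        config.lidar_height,
        config.receiver_radius,
        config.receiver_area,
        np.asarray(config.fov_half),
        float(z[-1] + dz / 2.0),
    )
    scale = config.system_constant / (n_photons * dz)
    # batch totals -> signal means and standard errors
    mol_tot = mol.sum(axis=0) * scale
    comb_tot = comb.sum(axis=0) * scale
    nb = mol.shape[0]
    mol_se = np.sqrt(nb / (nb - 1) * np.sum(
        (mol * scale - mol_tot[None] / nb) ** 2, axis=0
    ))
    comb_se = np.sqrt(nb / (nb - 1) * np.sum(
        (comb * scale - comb_tot[None] / nb) ** 2, axis=0
    ))
    meta = {
        "model": "mc",
        "seed": int(seed),
        "n_photons": int(n_photons),
        "config_hash": config.hash(),
    }
    if np.any(mol_tot <= 0.0):
        # photon budget too small to cover every bin of every channel
        meta["coverage_warning"] = True
    return SignalSet(z.copy(), mol_tot, comb_tot, meta, mol_se, comb_se)


def add_noise(
    signals: SignalSet,
    scale: float,
    background: float = 0.0,
    seed: int = 0,
) -> SignalSet:
    """Apply Poisson photon-counting noise.

    Counts are drawn as Poisson(scale * signal + background) and converted
    back to signal units with the background subtracted, so the expectation
    equals the input; ``scale`` is the photon count per signal unit.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if background < 0:
        raise ValueError("background must be non-negative")
    rng = np.random.default_rng(seed)
    out = signals.copy()
    out.mol = (rng.poisson(signals.mol * scale + background) - background) / scale
    out.comb_wide = (
        rng.poisson(signals.comb_wide * scale + background) - background
    ) / scale
    out.meta = dict(signals.meta)
    out.meta.update({"noise_scale": scale, "noise_background": background, "noise_seed": seed})
    return out
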