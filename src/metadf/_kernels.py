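"""Numba-compiled numerical kernels.

Everything here operates on plain float64 arrays; the object-level API in
`landscape`, `bias`, `sampler` and `convergence` wraps these kernels.

Unit conventions follow :mod:`metadf.constants` (Å, kJ/mol, ps, u); the
factor ``EC = 100`` converts kJ/mol-derived forces into u·Å/ps²
accelerations.

Two integration kernels are provided:

``run_sampler_kernel``
    General-purpose Langevin/metadynamics run.  The bias is evaluated by
    exact summation over the hill history (with a 6σ cutoff per hill) and
    the full per-step trace is recorded.

``run_convergence_kernel``
    Long-run benchmark variant.  The bias lives on a fine (z, γ) grid that
    is updated incrementally at each deposition and interpolated
    bilinearly; bias-weighted mean-force statistics are accumulated
    in-kernel and snapshotted at user checkpoints, so million-step runs
    need neither a stored trace nor O(n_hills) per-step work.
"""

import numpy as np
from numba import njit

EC = 100.0  # kJ/mol -> u·Å²/ps²
TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# analytic landscape
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _smoothstep_down(z, z_on, z_off):
    """C² switch: 1 below z_on, 0 above z_off, with its derivative."""
    if z <= z_on:
        return 1.0, 0.0
    if z >= z_off:
        return 0.0, 0.0
    t = (z - z_on) / (z_off - z_on)
    s = 1.0 - t * t * t * (10.0 - 15.0 * t + 6.0 * t * t)
    ds = -30.0 * t * t * (1.0 - t) * (1.0 - t) / (z_off - z_on)
    return s, ds


@njit(cache=True)
def landscape_value(z, g, gc, ga, gw, z_on, z_off, c_amp, zc, wc, m_gamma,
                    two_d):
    """Potential U(z, γ) of the analytic adsorption landscape."""
    s, _ = _smoothstep_down(z, z_on, z_off)
    if s == 0.0:
        return 0.0
    gsum = 0.0
    for j in range(gc.shape[0]):
        dz = (z - gc[j]) / gw[j]
        gsum += ga[j] * np.exp(-0.5 * dz * dz)
    u = gsum
    if two_d:
        dzc = (z - zc) / wc
        c = c_amp * np.exp(-0.5 * dzc * dzc)
        u += c * (1.0 - np.cos(m_gamma * g))
    return s * u


@njit(cache=True)
def landscape_grad(z, g, gc, ga, gw, z_on, z_off, c_amp, zc, wc, m_gamma,
                   two_d):
    """(dU/dz, dU/dγ) of the analytic landscape."""
    s, ds = _smoothstep_down(z, z_on, z_off)
    gsum = 0.0
    dgsum = 0.0
    for j in range(gc.shape[0]):
        dz = (z - gc[j]) / gw[j]
        e = ga[j] * np.exp(-0.5 * dz * dz)
        gsum += e
        dgsum += -e * dz / gw[j]
    u = gsum
    du = dgsum
    dug = 0.0
    if two_d:
        dzc = (z - zc) / wc
        c = c_amp * np.exp(-0.5 * dzc * dzc)
        dc = -c * dzc / wc
        ang = 1.0 - np.cos(m_gamma * g)
        u += c * ang
        du += dc * ang
        dug = s * c * m_gamma * np.sin(m_gamma * g)
    return ds * u + s * du, dug


@njit(cache=True)
def landscape_value_grid(zs, gs, gc, ga, gw, z_on, z_off, c_amp, zc, wc,
                         m_gamma, two_d):
    """U evaluated on the outer product of z and γ grids."""
    out = np.empty((zs.shape[0], gs.shape[0]))
    for i in range(zs.shape[0]):
        for k in range(gs.shape[0]):
            out[i, k] = landscape_value(zs[i], gs[k], gc, ga, gw, z_on,
                                        z_off, c_amp, zc, wc, m_gamma, two_d)
    return out


# ---------------------------------------------------------------------------
# hill bias: exact summation (6σ cutoff per hill)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _wrap_angle(dg):
    while dg > np.pi:
        dg -= TWO_PI
    while dg < -np.pi:
        dg += TWO_PI
    return dg


@njit(cache=True)
def bias_value_kernel(z, g, hz, hg, hsz, hsg, hh, n, use_gamma, periodic):
    v = 0.0
    for i in range(n):
        dz = z - hz[i]
        if abs(dz) > 6.0 * hsz[i]:
            continue
        a = dz / hsz[i]
        e = 0.5 * a * a
        if use_gamma:
            dg = g - hg[i]
            if periodic:
                dg = _wrap_angle(dg)
            b = dg / hsg[i]
            e += 0.5 * b * b
        if e < 40.0:
            v += hh[i] * np.exp(-e)
    return v


@njit(cache=True)
def bias_force_kernel(z, g, hz, hg, hsz, hsg, hh, n, use_gamma, periodic):
    """Force components (−dV/dz, −dV/dγ) and the value V."""
    v = 0.0
    fz = 0.0
    fg = 0.0
    for i in range(n):
        dz = z - hz[i]
        if abs(dz) > 6.0 * hsz[i]:
            continue
        a = dz / hsz[i]
        e = 0.5 * a * a
        dg = 0.0
        if use_gamma:
            dg = g - hg[i]
            if periodic:
                dg = _wrap_angle(dg)
            b = dg / hsg[i]
            e += 0.5 * b * b
        if e < 40.0:
            w = hh[i] * np.exp(-e)
            v += w
            fz += w * dz / (hsz[i] * hsz[i])
            if use_gamma:
                fg += w * dg / (hsg[i] * hsg[i])
    return v, fz, fg


# ---------------------------------------------------------------------------
# general sampler kernel (exact bias, full trace)
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_sampler_kernel(n_steps, dt, fric, m_z, m_g, kT,
                       z, g, vz, vg, noise,
                       gc, ga, gw, z_on, z_off, c_amp, zc, wc, m_gamma,
                       two_d,
                       z_wall, k_wall, z_lo, k_lo,
                       deposit_stride, w0, sigma_z, sigma_g, wt_dT,
                       hz, hg, hsz, hsg, hh, ht, n_hills0,
                       record_stride,
                       rec_t, rec_z, rec_g, rec_f, rec_vb, rec_ht):
    """BAOAB Langevin dynamics with on-the-fly hill deposition.

    Returns (n_hills, error_step); error_step is −1 on success.  `noise`
    has shape (nw, n_steps, 2) of standard normals; walkers advance in
    lock-step and share the single hill history.
    """
    nw = z.shape[0]
    n_hills = n_hills0
    use_gamma = two_d  # hills carry a γ dimension only on 2-D landscapes

    c1 = np.exp(-fric * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sz = np.sqrt(kT * EC / m_z)
    sg = np.sqrt(kT * EC / m_g)

    # cached total forces and landscape-only z-force per walker
    fz = np.empty(nw)
    fg = np.empty(nw)
    fphys = np.empty(nw)
    vb = np.empty(nw)
    for w in range(nw):
        duz, dug = landscape_grad(z[w], g[w], gc, ga, gw, z_on, z_off,
                                  c_amp, zc, wc, m_gamma, two_d)
        v, bfz, bfg = bias_force_kernel(z[w], g[w], hz, hg, hsz, hsg, hh,
                                        n_hills, use_gamma, True)
        wf = 0.0
        if z[w] > z_wall:
            wf = -k_wall * (z[w] - z_wall)
        elif z[w] < z_lo:
            wf = k_lo * (z_lo - z[w])
        fphys[w] = -duz
        vb[w] = v
        fz[w] = -duz + bfz + wf
        fg[w] = -dug + bfg

    irec = 0
    for step in range(1, n_steps + 1):
        for w in range(nw):
            # B: half kick
            vz[w] += 0.5 * dt * fz[w] * EC / m_z
            vg[w] += 0.5 * dt * fg[w] * EC / m_g
            # A: half drift
            z[w] += 0.5 * dt * vz[w]
            g[w] += 0.5 * dt * vg[w]
            # O: Ornstein-Uhlenbeck
            vz[w] = c1 * vz[w] + c2 * sz * noise[w, step - 1, 0]
            vg[w] = c1 * vg[w] + c2 * sg * noise[w, step - 1, 1]
            # A: half drift
            z[w] += 0.5 * dt * vz[w]
            g[w] += 0.5 * dt * vg[w]
            if two_d:
                g[w] = _wrap_angle(g[w])

        deposited = False
        if deposit_stride > 0 and step % deposit_stride == 0:
            t_now = step * dt
            for w in range(nw):
                h = w0
                if wt_dT > 0.0:
                    vcur = bias_value_kernel(z[w], g[w], hz, hg, hsz, hsg,
                                             hh, n_hills, use_gamma, True)
                    h = w0 * np.exp(-vcur / (0.0083144621 * wt_dT))
                hz[n_hills] = z[w]
                hg[n_hills] = g[w]
                hsz[n_hills] = sigma_z
                hsg[n_hills] = sigma_g
                hh[n_hills] = h
                ht[n_hills] = t_now
                n_hills += 1
            deposited = True

        for w in range(nw):
            duz, dug = landscape_grad(z[w], g[w], gc, ga, gw, z_on, z_off,
                                      c_amp, zc, wc, m_gamma, two_d)
            v, bfz, bfg = bias_force_kernel(z[w], g[w], hz, hg, hsz, hsg,
                                            hh, n_hills, use_gamma, True)
            wf = 0.0
            if z[w] > z_wall:
                wf = -k_wall * (z[w] - z_wall)
            elif z[w] < z_lo:
                wf = k_lo * (z_lo - z[w])
            fphys[w] = -duz
            vb[w] = v
            fz[w] = -duz + bfz + wf
            fg[w] = -dug + bfg
            if not np.isfinite(fz[w]) or not np.isfinite(fg[w]):
                return n_hills, step
            # B: half kick
            vz[w] += 0.5 * dt * fz[w] * EC / m_z
            vg[w] += 0.5 * dt * fg[w] * EC / m_g
        _ = deposited

        if step % record_stride == 0:
            rec_t[irec] = step * dt
            for w in range(nw):
                rec_z[w, irec] = z[w]
                rec_g[w, irec] = g[w]
                rec_f[w, irec] = fphys[w]
                rec_vb[w, irec] = vb[w]
            rec_ht[irec] = n_hills
            irec += 1

    return n_hills, -1


# ---------------------------------------------------------------------------
# grid-bias benchmark kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _interp2(grid, zg0, dzg, ngz, g, dgg, ngg, zq, gq):
    """Bilinear interpolation; z clamped to the grid, γ periodic."""
    x = (zq - zg0) / dzg
    if x < 0.0:
        x = 0.0
    if x > ngz - 1.001:
        x = ngz - 1.001
    i = int(x)
    tx = x - i
    y = (gq + np.pi) / dgg
    k = int(y) % ngg
    ty = y - int(y)
    k1 = (k + 1) % ngg
    v00 = grid[i, k]
    v01 = grid[i, k1]
    v10 = grid[i + 1, k]
    v11 = grid[i + 1, k1]
    return (v00 * (1 - tx) * (1 - ty) + v10 * tx * (1 - ty)
            + v01 * (1 - tx) * ty + v11 * tx * ty)


@njit(cache=True)
def _deposit_on_grid(Vg, Fzg, Fgg, zg0, dzg, ngz, dgg, ngg,
                     z0, g0, sz, sg, h):
    """Add one Gaussian hill (value and force components) to the grids."""
    ilo = int(np.floor((z0 - 6.0 * sz - zg0) / dzg))
    ihi = int(np.ceil((z0 + 6.0 * sz - zg0) / dzg))
    if ilo < 0:
        ilo = 0
    if ihi > ngz - 1:
        ihi = ngz - 1
    klo = int(np.floor((g0 - 6.0 * sg + np.pi) / dgg))
    khi = int(np.ceil((g0 + 6.0 * sg + np.pi) / dgg))
    if khi - klo >= ngg:
        klo = 0
        khi = ngg - 1
        full = True
    else:
        full = False
    for i in range(ilo, ihi + 1):
        zi = zg0 + i * dzg
        dz = zi - z0
        a = dz / sz
        ez = 0.5 * a * a
        if ez > 40.0:
            continue
        wz = h * np.exp(-ez)
        if full:
            for k in range(ngg):
                gk = -np.pi + k * dgg
                dg = _wrap_angle(gk - g0)
                b = dg / sg
                eg = 0.5 * b * b
                if eg > 40.0:
                    continue
                w = wz * np.exp(-eg)
                Vg[i, k] += w
                Fzg[i, k] += w * dz / (sz * sz)
                Fgg[i, k] += w * dg / (sg * sg)
        else:
            for kk in range(klo, khi + 1):
                k = kk % ngg
                gk = -np.pi + k * dgg
                dg = _wrap_angle(gk - g0)
                b = dg / sg
                eg = 0.5 * b * b
                if eg > 40.0:
                    continue
                w = wz * np.exp(-eg)
                Vg[i, k] += w
                Fzg[i, k] += w * dz / (sz * sz)
                Fgg[i, k] += w * dg / (sg * sg)


@njit(cache=True)
def run_convergence_kernel(n_steps, dt, fric, m_z, m_g, kT,
                           z, g, vz, vg, seed,
                           gc, ga, gw, z_on, z_off, c_amp, zc, wc, m_gamma,
                           z_wall, k_wall, z_lo, k_lo,
                           deposit_stride, w0, sigma_z, sigma_g, wt_dT,
                           zg0, dzg, ngz, ngg,
                           bin_lo, bin_w, n_bins, burn_in,
                           checkpoints,
                           mf_snap, cnt_snap, ess_snap, v_snap):
    """Long 2-D metadynamics run with grid bias and in-kernel statistics.

    At each checkpoint the per-bin bias-weighted mean force (with raw count
    and Kish effective sample size) and the bias grid V(z, γ) are
    snapshotted.  Noise is drawn from numba's global PRNG seeded with
    ``seed``.  Returns (n_hills, error_step).
    """
    np.random.seed(seed)
    nw = z.shape[0]
    dgg = TWO_PI / ngg
    Vg = np.zeros((ngz, ngg))
    Fzg = np.zeros((ngz, ngg))
    Fgg = np.zeros((ngz, ngg))

    # per-bin accumulators (weights carried relative to exp(shift/kT))
    sw = np.zeros(n_bins)
    swf = np.zeros(n_bins)
    sw2 = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    shift = 0.0

    c1 = np.exp(-fric * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sz_th = np.sqrt(kT * EC / m_z)
    sg_th = np.sqrt(kT * EC / m_g)

    fz = np.empty(nw)
    fg = np.empty(nw)
    for w in range(nw):
        duz, dug = landscape_grad(z[w], g[w], gc, ga, gw, z_on, z_off,
                                  c_amp, zc, wc, m_gamma, True)
        wf = 0.0
        if z[w] > z_wall:
            wf = -k_wall * (z[w] - z_wall)
        elif z[w] < z_lo:
            wf = k_lo * (z_lo - z[w])
        fz[w] = -duz + wf
        fg[w] = -dug

    n_hills = 0
    ick = 0
    n_ck = checkpoints.shape[0]
    step = 0
    while ick < n_ck and checkpoints[ick] <= 0:
        # checkpoint at step 0: empty statistics, zero bias
        for b in range(n_bins):
            mf_snap[ick, b] = 0.0
            cnt_snap[ick, b] = 0.0
            ess_snap[ick, b] = 0.0
        ick += 1

    for step in range(1, n_steps + 1):
        for w in range(nw):
            vz[w] += 0.5 * dt * fz[w] * EC / m_z
            vg[w] += 0.5 * dt * fg[w] * EC / m_g
            z[w] += 0.5 * dt * vz[w]
            g[w] += 0.5 * dt * vg[w]
            vz[w] = c1 * vz[w] + c2 * sz_th * np.random.normal()
            vg[w] = c1 * vg[w] + c2 * sg_th * np.random.normal()
            z[w] += 0.5 * dt * vz[w]
            g[w] += 0.5 * dt * vg[w]
            g[w] = _wrap_angle(g[w])

        if deposit_stride > 0 and step % deposit_stride == 0:
            for w in range(nw):
                h = w0
                if wt_dT > 0.0:
                    vcur = _interp2(Vg, zg0, dzg, ngz, 0.0, dgg, ngg,
                                    z[w], g[w])
                    h = w0 * np.exp(-vcur / (0.0083144621 * wt_dT))
                _deposit_on_grid(Vg, Fzg, Fgg, zg0, dzg, ngz, dgg, ngg,
                                 z[w], g[w], sigma_z, sigma_g, h)
                n_hills += 1

        for w in range(nw):
            duz, dug = landscape_grad(z[w], g[w], gc, ga, gw, z_on, z_off,
                                      c_amp, zc, wc, m_gamma, True)
            vb = _interp2(Vg, zg0, dzg, ngz, 0.0, dgg, ngg, z[w], g[w])
            bfz = _interp2(Fzg, zg0, dzg, ngz, 0.0, dgg, ngg, z[w], g[w])
            bfg = _interp2(Fgg, zg0, dzg, ngz, 0.0, dgg, ngg, z[w], g[w])
            wf = 0.0
            if z[w] > z_wall:
                wf = -k_wall * (z[w] - z_wall)
            elif z[w] < z_lo:
                wf = k_lo * (z_lo - z[w])
            fz[w] = -duz + bfz + wf
            fg[w] = -dug + bfg
            if not np.isfinite(fz[w]) or not np.isfinite(fg[w]):
                return n_hills, step
            vz[w] += 0.5 * dt * fz[w] * EC / m_z
            vg[w] += 0.5 * dt * fg[w] * EC / m_g

            if step > burn_in:
                b = int((z[w] - bin_lo) / bin_w)
                if 0 <= b < n_bins:
                    if vb - shift > 120.0:
                        # renormalize so weights stay in range
                        fac = np.exp((shift - (vb - 60.0)) / kT)
                        fac2 = fac * fac
                        for bb in range(n_bins):
                            sw[bb] *= fac
                            swf[bb] *= fac
                            sw2[bb] *= fac2
                        shift = vb - 60.0
                    wgt = np.exp((vb - shift) / kT)
                    sw[b] += wgt
                    swf[b] += wgt * (-duz)
                    sw2[b] += wgt * wgt
                    cnt[b] += 1.0

        while ick < n_ck and step == checkpoints[ick]:
            for b in range(n_bins):
                cnt_snap[ick, b] = cnt[b]
                if sw[b] > 0.0:
                    mf_snap[ick, b] = swf[b] / sw[b]
                    ess_snap[ick, b] = sw[b] * sw[b] / sw2[b]
                else:
                    mf_snap[ick, b] = 0.0
                    ess_snap[ick, b] = 0.0
            for i in range(ngz):
                for k in range(ngg):
                    v_snap[ick, i, k] = Vg[i, k]
            ick += 1

    return n_hills, -1
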